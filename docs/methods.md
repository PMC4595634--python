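# Methods

This note records the models, parameter choices and numerical conventions
behind `exoniche`, and what the synthetic experiments do and do not
establish about real data.

## Ion resolution

Untargeted LC–MS reports spectral features (m/z, retention time, polarity),
several per metabolite: adducts, multimers, in-source fragments and
isotopologues. Resolution proceeds in four steps.

**Grouping.** Single-linkage transitive closure over a pairwise gate: two
features may link only if they share polarity, their retention times differ
by at most `rt_tol` (default 0.3 min), and the Pearson correlation of their
peak-area vectors is at least `corr_min` (default 0.9). Correlation is
computed on raw areas over the samples where at least one of the pair is
detected, requiring at least three such samples; features detected nowhere
become singletons flagged `all_zero`. Raw rather than log areas keep zeros
meaningful (0 = not detected, and log is undefined there). Both thresholds
are explicit configuration knobs, since acceptable values depend on the
chromatography and the sample count.

Two consequences of this design are worth knowing:

* *Which samples to correlate over matters.* Correlation is restricted to
  the comparable media runs (controls + spent media of the utilization
  assay). Cell-extract samples live on a different intensity scale (up to
  ~10⁶ counts against ~10⁴ in media); including them makes any two
  extract-rich metabolites correlate near 1 regardless of their behaviour
  in the media — a leverage artifact, not co-elution. The pipeline
  therefore passes the utilization-assay samples as the correlation subset
  while still quantifying all samples in the abundance table.
* *Identically-behaving co-eluters merge.* Two distinct metabolites that
  co-elute within `rt_tol` **and** are consumed/released by the same
  isolates have genuinely correlated vectors and will merge; conversely,
  ions of a metabolite never detected in the media split off as flagged
  singletons. On the default synthetic design this costs a few percent of
  metabolites (607 groups for 555 planted metabolite-polarity pairs, <5%
  impure groups); the classification-recovery numbers below include these
  losses.

Group retention centre is the midpoint of the member RT range. A
single-linkage chain can in principle span more than twice `rt_tol`; such
groups are flagged `rt_span_exceeded` rather than split, on the view that a
flag for manual inspection is more honest than an arbitrary cut.

**Ion-type assignment.** Every (member, rule) pair of matching polarity
proposes a neutral mass M = (m/z·z − shift)/multiplicity; the candidate
explaining the most members within `mz_tol` (default 0.02 Da, the ±20 mDa
convention of the upstream integration) wins. Ties break to the
higher-priority rule, then to the **strongest** anchor ion, then to lower
m/z: anchoring on the lightest ion would systematically promote in-source
fragments to molecular species, which is chemically backwards. Tied
candidates disagreeing by more than `mz_tol` flag the group
`ambiguous_neutral_mass`. The final mass is the mean of the masses implied
by all explained members. The default rule table is [M+H]⁺, [M+NH₄]⁺,
[M+Na]⁺, [2M+H]⁺, [M−H]⁻, [M+CH₃COO]⁻, [2M−H]⁻ — the usual quantifier ions
plus companions expected under an ammonium-acetate mobile phase — editable
as YAML. Ion masses carry the electron implicitly (proton mass 1.007276
Da); the residual error is orders of magnitude below every tolerance used.

**Characteristic ion.** The member with the highest median area across all
samples among protonated/deprotonated/ammoniated annotations, falling back
to all members; ties break to lower m/z then feature id. Fragments never
quantify a metabolite unless nothing else matched.

**Polarity merge.** Positive and negative groups merge when both carry a
neutral mass agreeing within `mass_tol` (default 5 mDa) and retention times
within `rt_tol`; matching is greedy by ascending mass difference, multiple
partners flag `merge_ambiguous`. Metabolite numbers are assigned in
(rt, m/z) order.

## Formula assignment

Exhaustive CHNOPS enumeration: the C/N/O/P/S grid (bounds C≤40, N≤20, O≤25,
P≤5, S≤5; masses up to 1,200 Da) is enumerated once and cached; hydrogen is
solved per query from the residual mass, so one call is a single vectorised
scan. Candidates within `mass_tol_ppm` (default 5) are filtered by
ring-plus-double-bond equivalents ≥ 0 and by heuristic element-ratio ranges
(H/C ≤ 3.1, N/C ≤ 1.3, O/C ≤ 2.5, P/C ≤ 0.3, S/C ≤ 0.8, carbon required) —
the standard plausibility windows covering the vast majority of known
organic molecules; both filters can be disabled.

Score = |mass error in ppm| + 100 · (relative M+1/M misfit) when an
observed M+1 ratio is available. The predicted M+1 abundance sums the
minor-isotope contributions (¹³C 1.07%/C dominating, plus ¹⁵N, ³³S, ¹⁷O,
²H). The weight 100 makes a 10% isotope misfit cost as much as 10 ppm of
mass error, reflecting that measured isotope ratios are usable to roughly
that precision on a Q-TOF. Accurate mass alone is often not decisive: near
342.116 Da three CHNO compositions lie within 0.04 ppm of each other, and
only the isotope term separates a dihexose from nitrogen-rich alternatives.
The pipeline estimates the observed M+1 ratio from a co-grouped
isotopologue feature (one ¹³C–¹²C shift above the characteristic ion) when
present.

## Utilization classification

*Availability.* A metabolite is available when its characteristic ion
reaches `min_area` (default 5,000 counts) in **at least one individual
control sample**, any medium. The alternative reading — a control-group
mean — is implemented as `abundance_mode="group_mean"`.

*Calls.* Two-sided pooled-variance Student's t between spent (S) and
matched control (C) replicate areas, on raw counts. With α = 0.05:
p < α and mean(S) < mean(C) ⇒ uptake; p < α and mean(S) > mean(C) ⇒
release; otherwise unchanged. When max(C) < `min_area`: mean(S) ≥
`detect_area` (default 1,000 counts) **and** mean(S) > mean(C) ⇒ release
from below detection (flagged), else not_available. The extra direction
condition keeps every release call consistent with its mean-direction
invariant when controls carry low-level background near the gate.
Zero pooled variance is handled explicitly: equal means ⇒ p = 1, unequal ⇒
p = 0 flagged `degenerate_variance` — this is what makes the noise-free
limit exact. No multiple-testing correction by default, matching the
per-metabolite star convention of endpoint footprinting assays; a
Benjamini–Hochberg option exists. Significance tiers \*, \*\*, \*\*\* at
0.05/0.01/0.001.

*Consensus across media.* Informative calls (uptake/release) beat
unchanged; an uptake-vs-release conflict resolves to the smaller p and is
flagged `conflict`; all-not_available stays not_available. Conflicted cells
count toward the niche statistics per a configurable policy (default: as
their resolved call).

## Niche statistics

All fractions use the available-set size as denominator; metabolites
released de novo but never available are tracked separately
(`released_novel`) and excluded from fractions — they were never on offer
for uptake. Reported percentages round half away from zero (70/372 → 19%).
Competition candidates: ≥2 uptake cells, 0 release cells. Cross-feeding
candidates: some isolate releases and a *different* isolate takes up;
disjoint from competition by construction. Pairwise overlap: Jaccard
(default) or Simpson on uptake sets, 0 when the denominator set is empty.

## Wetting time course

Per metabolite, a two-sided Student's t between the first (3 min) and last
(18 h) timepoint replicates, direction + significance → depleted /
accumulated / flat. The 9 h point is carried in the means table and usable
as an alternate endpoint. Water replenished mid-course dilutes the last
timepoint; `dilution_factor` (default 1.0 — no correction) multiplies the
last-timepoint areas to undo a known dilution. Cross-experiment metabolite
mapping is greedy nearest-m/z within (mz_tol, rt_tol, same polarity), and
`unused_but_depleted` returns depleted soil-water metabolites whose mapped
matrix column has zero uptake cells. Media-vs-soil-water comparability is
the fraction of mapped metabolites whose mean areas agree within one order
of magnitude (|log₁₀ ratio| ≤ 1).

## Synthetic experiments

The generator emulates the study design the analysis assumes: 470
metabolites (372 available), 7 isolates, two supplemented media with 3
uninoculated controls and 3 spent replicates per isolate (the producer
strain gets its own control set in the producer-extract medium), a producer
cell-extract / spent-minimal-medium block for release profiling, and a
soil-water time course of 400 metabolites × 3 timepoints × 8 replicates.

Key modelling choices, each made once:

* **Catalog.** Random CHNO formulas (masses 80–900 Da, element ratios
  within the plausibility windows), retention times uniform on 1–14 min,
  redrawn so that no two metabolites within 10 mDa in mass co-elute within
  0.7 min (which would make polarity merging ill-posed by construction).
  Polarity mode positive/negative/both at 45/35/20%.
* **Ion envelope.** 1–5 features per metabolite: primary adduct(s), an M+1
  isotopologue at the formula-implied ratio, and optionally one secondary
  adduct at 5–60% relative abundance.
* **Noise.** Multiplicative log-normal, total replicate CV 0.2 on the
  characteristic ion, split into a per-(metabolite, sample) shared factor
  and a small per-ion residual (CV 0.05). The shared factor is what keeps
  ions of one metabolite correlated across samples (log-scale r ≈ 0.94);
  without it, adducts of an unchanged metabolite would decorrelate and
  grouping would be impossible — a structural fact about
  correlation-based grouping, not a tuning convenience.
* **Abundance guard band.** Available metabolites draw base areas
  log-uniform on 8×10³–10⁶ counts, scarce ones on 10²–8×10². The gap
  around the 5,000-count threshold makes planted availability unambiguous
  under replicate noise, and the scarce tier sits below the de-novo
  release gate so planted truth is self-consistent with the classifier's
  contract. Detection floor 100 counts (values below report as 0).
* **Classes.** Per-isolate used fractions drawn uniform on 0.13–0.35 of
  the available set, with exactly 40% of available metabolites consumed by
  no isolate (the usable pool is covered first, then isolates fill to
  quota; infeasible combinations raise before generation). Uptake
  multipliers uniform 0.02–0.5, release 2–50; de-novo releases of scarce
  metabolites target a clearly detectable 5×10³–10⁵ counts. A planted
  class applies to both supplemented media — one biological phenotype,
  observed twice.
* **Time course.** 65 depleted (end-point multiplier 0.05–0.2, ≥5-fold),
  30 accumulated (2–10×), remainder flat; geometric interpolation at the
  middle timepoint; CV 0.25. Soil-water baselines sit within roughly an
  order of magnitude of the media levels (log₁₀ offset ~ N(0, 0.55)).

**What passing tests show — and don't.** On this design the full pipeline
achieves ~0.94 uptake and ~0.85 release sensitivity at a ~0.06
false-positive rate per call, with null p-values passing a KS uniformity
test, and the noise-free limit recovers planted classes exactly. The
generator does not simulate chromatographic peak shapes, mass error,
retention drift, batch effects, heavy-tailed or correlated-across-metabolite
noise, or missingness beyond a hard detection floor; real-data performance
degrades with each of these. Recovery is scored per (isolate, metabolite,
medium) call — the unit the classifier emits; consensus-level error rates
are necessarily slightly higher because two media give two chances for a
false positive.

## Numerical conventions

Determinism throughout: a single seed drives generation; grouping and all
tie-breaks are order-independent (sorting by polarity/rt/m/z/id, greedy
matches by ascending distance then id); reports carry no timestamps, so
identical seeds give hash-identical output bundles. Degenerate inputs are
handled explicitly rather than propagated as NaN: zero-variance t-tests
(above), all-zero features (flagged singletons), empty formula candidate
lists, zero-denominator overlaps (0), empty release universe (error).

## Known limitations

* Correlation-based grouping cannot separate co-eluting metabolites with
  identical utilization patterns, and treats sub-detection ions as
  singletons; both effects are flagged, not silently resolved.
* The consensus rule and the conflict policy are pragmatic choices; with
  more than two media a voting scheme would be preferable.
* Formula assignment covers CHNOPS only and ranks by a two-term score; it
  does not use MS/MS evidence or adduct-specific isotope envelopes.
* The t-test assumes approximately normal replicate noise; at n = 3 it is
  tolerant of the mild log-normality used here (the KS calibration test
  verifies this under the study conditions), but heavier-tailed real noise
  would inflate error rates.
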