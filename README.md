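# exoniche

Exometabolite niche partitioning from untargeted LC–MS data.

Soil microbial communities can host enormous diversity in what looks like a
single homogeneous habitat. One proposed explanation is *substrate
specialization*: each organism consumes only a small, partially overlapping
subset of the hundreds of metabolites dissolved around it, so the metabolite
pool itself supplies the niches. `exoniche` implements the complete analysis
needed to test this with metabolic footprinting: profile spent culture media
of individual isolates against uninoculated controls, resolve the redundant
ions of untargeted LC–MS into putative metabolites, classify each
isolate × metabolite pair as uptake or release, and turn the resulting call
matrix into niche statistics — per-isolate used fractions, shared-use
distributions, candidate competition and cross-feeding metabolite sets, and
a bipartite isolate–metabolite network. A wetting time-course module follows
soil-water metabolites after a rain pulse, and a synthetic-data generator
produces complete experiments with planted ground truth so every stage is
testable end to end.

Audience: microbial ecologists and metabolomics analysts working with
feature tables (m/z, retention time, polarity × samples) exported from
untargeted LC–MS processing.

## The method

**Ion resolution.** One metabolite yields several ions — adducts such as
[M+H]⁺, [M+NH₄]⁺, [M−H]⁻, dimers [2M+H]⁺, in-source fragments, and the M+1
isotopologue. Features are grouped by single-linkage clustering over a
pairwise gate: same polarity, |Δrt| ≤ 0.3 min, and Pearson correlation of
intensity vectors across comparable samples ≥ 0.9. Within a group, the
neutral mass M maximizing the number of members explained by the adduct
table within ±0.02 Da is chosen; the strongest protonated / deprotonated /
ammoniated member becomes the characteristic (quantifier) ion. Groups of
opposite polarity merge into one metabolite when neutral masses agree within
5 mDa and retention times within 0.3 min. Molecular formulas are assigned by
exhaustive CHNOPS enumeration within a ppm window, scored by mass error and
the fit of the predicted M+1/M isotope ratio.

**Utilization calls.** A metabolite is *available* when its characteristic
ion reaches 5,000 counts in at least one control-medium sample. For each
isolate × metabolite × medium, spent and control peak areas (n ≥ 2, 3 in the
emulated design) are compared with a two-sided pooled-variance Student's
t-test: p < α with depleted mean ⇒ **uptake**; p < α with increased mean ⇒
**release**; a metabolite below the availability gate in controls but
detected in spent medium (≥ 1,000 counts) is **release** from below
detection. Calls from the two medium formulations combine into a consensus
(informative calls beat unchanged; rare uptake/release conflicts resolve to
the smaller p and are flagged).

**Niche statistics.** With U(i) the uptake set of isolate i over the
available metabolites: used fraction |U(i)|/n_available; shared-use
histogram (#isolates consuming each metabolite); *competition candidates* =
metabolites taken up by ≥2 isolates and released by none; *cross-feeding
candidates* = metabolites released by one isolate and taken up by a
different one; pairwise overlap J(i,j) = |U(i)∩U(j)|/|U(i)∪U(j)| (Simpson
variant available); GraphML bipartite network of utilization/release edges.

**Wetting time course.** Soil-water metabolites sampled at 3 min, 9 h and
18 h after wetting (8 independent replicates each) are tested first-vs-last
with the same t-test; depleted metabolites whose matrix column shows no
isolate uptake mark niches held by organisms missing from the panel.

## Worked example

Run the numbered drivers (each is a thin script over the library; all
outputs land under `results/`):

```bash
python analysis/01_simulate.py --seed 1      # synthetic study + truth
python analysis/02_resolve_ions.py           # features -> metabolites
python analysis/03_classify_utilization.py   # uptake/release calls
python analysis/04_niche_metrics.py          # niche statistics + network
python analysis/05_release_profile.py        # extract vs spent minimal medium
python analysis/06_wetting_timecourse.py     # soil-water dynamics
python analysis/07_recovery_evaluation.py    # score against planted truth
```

With seed 1 the drivers print:

```
metabolites: 470 (abundant: 372)
features: 1283  samples: 60

1283 features -> 607 ion groups -> 530 putative metabolites
neutral mass for 530, formula for 521, 77 seen in both polarities

available metabolites: 356; isolates: 7
per-isolate used fraction: 21-32% (unused by all: 30%)
used by every isolate: 2
competition candidates (>=2 uptake, 0 release): 132
cross-feeding candidates (release + uptake by another): 99

metabolites tested: 400  depleted: 69  accumulated: 41
depleted but not taken up by any isolate: 13

uptake sensitivity:  0.941 (1224 planted calls)
release sensitivity: 0.847 (288 planted calls)
false-positive rate on planted-unchanged: 0.058 (3582 null calls)
```

Reading this: the generator planted 470 metabolites emitting 1,283 redundant
ions; ion resolution recovered 530 putative metabolites (a few co-eluting,
identically-behaving metabolites merge, a few sub-detection ions split off),
of which 356 passed the 5,000-count availability filter. Each isolate
consumed only 21–32% of the available pool, two metabolites were consumed by
all seven isolates, and 30% by none — the niche-partitioning signature the
statistics are built to expose. The recovery evaluation shows what the
pipeline would do to real data with this noise structure: ~94% of planted
uptake calls recovered at a 5.8% false-positive rate, with well-calibrated
null p-values.

The same stages are available as a CLI (`exoniche simulate | group |
classify | niche | release | timecourse | run-all`) for file-based use.

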