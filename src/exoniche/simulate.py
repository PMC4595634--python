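"""Synthetic exometabolomic experiments with planted ground truth.

Generates complete inputs for the pipeline — a spectral feature table, a
sample-metadata table, and the planted truth — with the statistical
structure the analysis assumes:

* ~470 metabolites, each emitting 1–5 redundant ion features (adducts,
  dimers, an M+1 isotopologue) whose areas co-vary across samples;
* two supplemented medium formulations with n=3 uninoculated controls and
  n=3 spent replicates per isolate (the producer strain gets its own
  control set in the producer-extract medium, mirroring its longer
  culturing time);
* planted per-isolate uptake (multiplier < 1) and release (multiplier > 1)
  classes, a 5,000-count abundance structure, log-normal replicate noise;
* optional cell-extract and spent-minimal-medium samples for release
  profiling, and an n=8-per-timepoint soil-water wetting time course.

Replicate noise is multiplicative log-normal and is split into a component
shared by all ions of a metabolite in a sample (biological + injection
variation) plus a small per-ion residual; the split keeps ions of one
metabolite correlated across samples (which ion grouping requires) while
the characteristic ion's total CV stays at ``noise_cv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .chem import (
    DEFAULT_ADDUCT_RULES,
    format_formula,
    m1_ratio as formula_m1_ratio,
    monoisotopic_mass,
)
from .formulas import plausible_ratios
from .io import FeatureTable, validate_sample_metadata

C13_SHIFT = 1.0033548378  # 13C - 12C

RULES_BY_NAME = {r.name: r for r in DEFAULT_ADDUCT_RULES}

#: Media that constitute the utilization assay; the minimal medium carries
#: the producer's release-profile experiment and is analyzed separately.
UTILIZATION_MEDIA = ("het_pool", "cyano_extract")
RELEASE_MEDIUM = "minimal"


class InfeasibleConfig(ValueError):
    """Raised when the planted design cannot satisfy its own constraints."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design constants of the emulated experiment."""

    n_metabolites: int = 470
    fraction_abundant: float = 372 / 470
    n_isolates: int = 7
    used_fraction_range: tuple[float, float] = (0.13, 0.35)
    unused_fraction: float = 0.40
    n_media_replicates: int = 3
    n_soilwater_replicates: int = 8
    noise_cv: float = 0.2
    feature_noise_cv: float = 0.05
    detection_floor: float = 100.0
    timepoints_min: tuple[float, ...] = (3.0, 540.0, 1080.0)
    uptake_multiplier_range: tuple[float, float] = (0.02, 0.5)
    release_multiplier_range: tuple[float, float] = (2.0, 50.0)
    release_fraction_range: tuple[float, float] = (0.03, 0.08)
    abundant_base_range: tuple[float, float] = (8e3, 1e6)
    scarce_base_range: tuple[float, float] = (1e2, 8e2)
    min_area: float = 5000.0
    mass_range: tuple[float, float] = (80.0, 900.0)
    rt_range: tuple[float, float] = (1.0, 14.0)
    include_release_profile: bool = True
    # wetting time course
    n_timecourse_metabolites: int = 400
    n_depleted: int = 65
    n_accumulated: int = 30
    timecourse_noise_cv: float = 0.25
    depletion_multiplier_range: tuple[float, float] = (0.05, 0.2)
    accumulation_multiplier_range: tuple[float, float] = (2.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fraction_abundant <= 1):
            raise InfeasibleConfig("fraction_abundant must be in (0, 1]")
        if not (0 <= self.unused_fraction < 1):
            raise InfeasibleConfig("unused_fraction must be in [0, 1)")
        lo, hi = self.used_fraction_range
        if not (0 < lo <= hi <= 1):
            raise InfeasibleConfig("bad used_fraction_range")
        if self.n_media_replicates < 2 or self.n_soilwater_replicates < 2:
            raise InfeasibleConfig("need >=2 replicates")
        if self.n_isolates < 1 or self.n_metabolites < 1:
            raise InfeasibleConfig("need >=1 isolate and metabolite")
        if self.feature_noise_cv >= self.noise_cv and self.noise_cv > 0:
            raise InfeasibleConfig("feature_noise_cv must be below noise_cv")
        n_ab = self.n_abundant
        n_usable = round((1 - self.unused_fraction) * n_ab)
        lo_n, hi_n = round(lo * n_ab), round(hi * n_ab)
        if lo_n > n_usable:
            raise InfeasibleConfig(
                "used-fraction range incompatible with unused target: every isolate "
                f"needs >= {lo_n} usable metabolites but only {n_usable} exist"
            )
        if self.n_isolates * hi_n < n_usable:
            raise InfeasibleConfig(
                "used-fraction range incompatible with unused target: isolates cannot "
                f"cover the {n_usable} usable metabolites"
            )
        if self.n_depleted + self.n_accumulated > self.n_timecourse_metabolites:
            raise InfeasibleConfig("planted trends exceed time-course metabolite count")
        if len(self.timepoints_min) < 2 or list(self.timepoints_min) != sorted(
            set(self.timepoints_min)
        ):
            raise InfeasibleConfig("timepoints must be strictly increasing")

    @property
    def n_abundant(self) -> int:
        return round(self.fraction_abundant * self.n_metabolites)

    @property
    def isolates(self) -> list[str]:
        return [f"iso{i}" for i in range(1, self.n_isolates + 1)]


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic experiment."""

    metabolites: pd.DataFrame  # index met_key: formula, neutral_mass, rt, mode, base_area, abundant, m1_ratio
    adducts: pd.DataFrame  # feature_id, met_key, polarity, ion_type, rel_abundance, mz
    classes: pd.DataFrame  # isolate_id, met_key, class, multiplier (non-unchanged only)
    extract_areas: pd.Series | None = None  # met_key -> mean extract area (0 = absent)
    minimal_release_areas: pd.Series | None = None  # met_key -> spent-minimal area
    timecourse: pd.DataFrame | None = None  # met_key, trend, multiplier, base_sw
    seed: int = 0

    def planted_class(self, isolate_id: str, met_key: str) -> str:
        sel = self.classes[
            (self.classes["isolate_id"] == isolate_id) & (self.classes["met_key"] == met_key)
        ]
        return sel["class"].iloc[0] if len(sel) else "unchanged"

    def consensus_truth(self) -> pd.DataFrame:
        """Ideal consensus calls: the planted class, masked by availability."""
        abundant = set(self.metabolites.index[self.metabolites["abundant"]])
        planted = {
            (iso, met): cls
            for iso, met, cls in zip(
                self.classes["isolate_id"], self.classes["met_key"], self.classes["class"]
            )
        }
        rows = []
        isolates = sorted(self.classes["isolate_id"].unique())
        for iso in isolates:
            for met in self.metabolites.index:
                cls = planted.get((iso, met), "unchanged")
                if met not in abundant and cls != "release":
                    cls = "not_available"
                rows.append(
                    {"isolate_id": iso, "metabolite_id": met, "call": cls, "p_value": 0.0,
                     "flags": ""}
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "metabolites": self.metabolites.to_json(orient="split"),
            "adducts": self.adducts.to_json(orient="split"),
            "classes": self.classes.to_json(orient="split"),
            "extract_areas": None
            if self.extract_areas is None
            else self.extract_areas.to_json(orient="split"),
            "minimal_release_areas": None
            if self.minimal_release_areas is None
            else self.minimal_release_areas.to_json(orient="split"),
            "timecourse": None if self.timecourse is None else self.timecourse.to_json(orient="split"),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        raw = json.loads(text)

        def frame(key):
            return None if raw[key] is None else pd.read_json(StringIO(raw[key]), orient="split")

        def series(key):
            if raw[key] is None:
                return None
            return pd.read_json(StringIO(raw[key]), orient="split", typ="series")

        metabolites = frame("metabolites")
        metabolites.index.name = "met_key"  # orient="split" drops index names
        return cls(
            metabolites=metabolites,
            adducts=frame("adducts"),
            classes=frame("classes"),
            extract_areas=series("extract_areas"),
            minimal_release_areas=series("minimal_release_areas"),
            timecourse=frame("timecourse"),
            seed=raw["seed"],
        )


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _draw_formula(rng: np.random.Generator, mass_range) -> dict[str, int]:
    """Random CHNO composition with plausible H count and mass in range."""
    lo, hi = mass_range
    while True:
        c = int(rng.integers(3, 31))
        n = int(rng.choice([0, 1, 2, 3, 4], p=[0.35, 0.25, 0.2, 0.12, 0.08]))
        o = int(rng.integers(0, 13))
        max_rdbe = min(c, 9)
        r = int(rng.integers(0, max_rdbe + 1))
        h = 2 * c + 2 + n - 2 * r
        if h < 1:
            continue
        counts = {"C": c, "H": h, "N": n, "O": o}
        m = monoisotopic_mass(counts)
        if lo <= m <= hi and plausible_ratios(counts):
            return counts


def _catalog(rng: np.random.Generator, cfg: GeneratorConfig) -> pd.DataFrame:
    """Metabolite catalog: formula, mass, rt, polarity mode, base area."""
    rows = []
    for i in range(cfg.n_metabolites):
        counts = _draw_formula(rng, cfg.mass_range)
        rows.append(
            {
                "formula": format_formula(counts),
                "neutral_mass": monoisotopic_mass(counts),
                "m1_ratio": formula_m1_ratio(counts),
            }
        )
    df = pd.DataFrame(rows, index=[f"M{i + 1:04d}" for i in range(cfg.n_metabolites)])
    df.index.name = "met_key"
    # retention times; re-draw until no same-mass co-elution that could
    # cross-link polarity merging between distinct metabolites
    lo, hi = cfg.rt_range
    rt = rng.uniform(lo, hi, cfg.n_metabolites)
    mass = df["neutral_mass"].to_numpy()
    for _ in range(200):
        clash = False
        order = np.argsort(mass)
        sm, srt = mass[order], rt[order]
        for i in range(len(sm) - 1):
            j = i + 1
            while j < len(sm) and sm[j] - sm[i] < 0.01:
                if abs(srt[j] - srt[i]) < 0.7:
                    rt[order[j]] = rng.uniform(lo, hi)
                    clash = True
                j += 1
        if not clash:
            break
    df["rt"] = rt
    df["mode"] = rng.choice(["positive", "negative", "both"], cfg.n_metabolites, p=[0.45, 0.35, 0.2])

    abundant = np.zeros(cfg.n_metabolites, dtype=bool)
    abundant[rng.choice(cfg.n_metabolites, cfg.n_abundant, replace=False)] = True
    df["abundant"] = abundant
    base = np.where(
        abundant,
        np.exp(rng.uniform(*np.log(cfg.abundant_base_range), cfg.n_metabolites)),
        np.exp(rng.uniform(*np.log(cfg.scarce_base_range), cfg.n_metabolites)),
    )
    df["base_area"] = base
    return df


def _adduct_envelope(rng: np.random.Generator, catalog: pd.DataFrame) -> pd.DataFrame:
    """1–5 ion features per metabolite: primary adduct(s), optional
    secondary adduct, M+1 isotopologue of the positive/primary ion."""
    rows = []
    secondary = {"positive": ["[M+NH4]+", "[M+Na]+", "[2M+H]+"], "negative": ["[M+CH3COO]-", "[2M-H]-"]}
    for met, rec in catalog.iterrows():
        mass = rec["neutral_mass"]
        pols = ["positive", "negative"] if rec["mode"] == "both" else [rec["mode"]]
        k = 0
        for pol in pols:
            primary = RULES_BY_NAME["[M+H]+" if pol == "positive" else "[M-H]-"]
            mz0 = primary.mz_from_neutral(mass)
            rows.append((f"{met}_f{k}", met, pol, primary.name, 1.0, mz0))
            k += 1
            if pol == pols[0]:  # isotopologue rides on the first polarity's primary
                rows.append((f"{met}_f{k}", met, pol, "M+1", rec["m1_ratio"], mz0 + C13_SHIFT))
                k += 1
            if rng.random() < (0.5 if len(pols) == 1 else 0.3):
                rule = RULES_BY_NAME[str(rng.choice(secondary[pol]))]
                rows.append(
                    (
                        f"{met}_f{k}",
                        met,
                        pol,
                        rule.name,
                        float(rng.uniform(0.05, 0.6)),
                        rule.mz_from_neutral(mass),
                    )
                )
                k += 1
    return pd.DataFrame(
        rows, columns=["feature_id", "met_key", "polarity", "ion_type", "rel_abundance", "mz"]
    )


def _plant_classes(rng: np.random.Generator, cfg: GeneratorConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Per-isolate uptake/release sets honoring the design fractions."""
    abundant_ids = list(catalog.index[catalog["abundant"]])
    n_ab = len(abundant_ids)
    n_usable = round((1 - cfg.unused_fraction) * n_ab)
    usable = list(rng.choice(abundant_ids, n_usable, replace=False))
    isolates = cfg.isolates
    lo, hi = cfg.used_fraction_range
    n_up = {iso: int(round(rng.uniform(lo, hi) * n_ab)) for iso in isolates}
    if any(v > n_usable for v in n_up.values()) or sum(n_up.values()) < n_usable:
        raise InfeasibleConfig(
            "drawn per-isolate uptake counts cannot cover the usable pool "
            f"({n_up} vs {n_usable} usable)"
        )
    uptake: dict[str, set] = {iso: set() for iso in isolates}
    # every usable metabolite gets at least one consumer
    for met in rng.permutation(usable):
        open_isos = [i for i in isolates if len(uptake[i]) < n_up[i]]
        pick = str(rng.choice(open_isos))
        uptake[pick].add(met)
    for iso in isolates:
        pool = [m for m in usable if m not in uptake[iso]]
        need = n_up[iso] - len(uptake[iso])
        if need > 0:
            uptake[iso].update(rng.choice(pool, need, replace=False))

    rows = []
    rel_lo, rel_hi = cfg.release_fraction_range
    for iso in isolates:
        for met in sorted(uptake[iso]):
            rows.append(
                {
                    "isolate_id": iso,
                    "met_key": met,
                    "class": "uptake",
                    "multiplier": float(rng.uniform(*cfg.uptake_multiplier_range)),
                }
            )
        n_rel = int(round(rng.uniform(rel_lo, rel_hi) * cfg.n_metabolites))
        candidates = [m for m in catalog.index if m not in uptake[iso]]
        released = rng.choice(candidates, min(n_rel, len(candidates)), replace=False)
        for met in sorted(released):
            if catalog.loc[met, "abundant"]:
                mult = float(rng.uniform(*cfg.release_multiplier_range))
            else:
                # de-novo release of a scarce metabolite: target a clearly
                # detectable spent-medium level
                target = float(np.exp(rng.uniform(np.log(5e3), np.log(1e5))))
                mult = target / float(catalog.loc[met, "base_area"])
            rows.append({"isolate_id": iso, "met_key": met, "class": "release", "multiplier": mult})
    return pd.DataFrame(rows, columns=["isolate_id", "met_key", "class", "multiplier"])


def _sample_plan(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    rep = range(1, cfg.n_media_replicates + 1)
    for r in rep:
        rows.append(("ctl_het_%d" % r, "control", None, "het_pool", "cg_het", None, r))
        rows.append(("ctl_cyano_%d" % r, "control", None, "cyano_extract", "cg_cyano", None, r))
        rows.append(("ctl_cyano_mv_%d" % r, "control", None, "cyano_extract", "cg_cyano_mv", None, r))
    producer = cfg.isolates[0]
    for iso in cfg.isolates:
        for r in rep:
            rows.append((f"sp_{iso}_het_{r}", "spent", iso, "het_pool", "cg_het", None, r))
            cg = "cg_cyano_mv" if iso == producer else "cg_cyano"
            rows.append((f"sp_{iso}_cyano_{r}", "spent", iso, "cyano_extract", cg, None, r))
    if cfg.include_release_profile:
        for r in rep:
            rows.append((f"ctl_min_{r}", "control", None, "minimal", "cg_min", None, r))
            rows.append((f"sp_{producer}_min_{r}", "spent", producer, "minimal", "cg_min", None, r))
            rows.append((f"ext_{producer}_{r}", "cell_extract", producer, None, None, None, r))
    meta = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "role",
            "isolate_id",
            "medium_id",
            "control_group_id",
            "timepoint_min",
            "replicate",
        ],
    )
    return validate_sample_metadata(meta)


def _mean_levels(
    catalog: pd.DataFrame,
    classes: pd.DataFrame,
    meta: pd.DataFrame,
    extract_areas: pd.Series,
    minimal_release: pd.Series,
) -> np.ndarray:
    """Noise-free (metabolite x sample) mean area matrix."""
    mult = pd.DataFrame(1.0, index=catalog.index, columns=sorted(set(meta["isolate_id"].dropna())))
    for r in classes.itertuples(index=False):
        mult.loc[r.met_key, r.isolate_id] = r.multiplier
    mean_level = np.zeros((len(catalog), len(meta.index)))
    base = catalog["base_area"].to_numpy()
    for j, sid in enumerate(meta.index):
        rec = meta.loc[sid]
        if rec["role"] == "control":
            mean_level[:, j] = 0.0 if rec["medium_id"] == RELEASE_MEDIUM else base
        elif rec["role"] == "cell_extract":
            mean_level[:, j] = extract_areas.to_numpy()
        elif rec["medium_id"] == RELEASE_MEDIUM:
            mean_level[:, j] = minimal_release.to_numpy()
        else:  # spent, supplemented
            mean_level[:, j] = base * mult[rec["isolate_id"]].to_numpy()
    return mean_level


def expected_abundance(
    truth: SyntheticTruth, meta: pd.DataFrame, detection_floor: float = 100.0
) -> pd.DataFrame:
    """Noise-free characteristic-ion abundance table implied by the truth.

    Metabolite keys index the rows; useful for testing the classification
    and niche stages in isolation from ion resolution.
    """
    ext = truth.extract_areas if truth.extract_areas is not None else pd.Series(0.0, index=truth.metabolites.index)
    rel = (
        truth.minimal_release_areas
        if truth.minimal_release_areas is not None
        else pd.Series(0.0, index=truth.metabolites.index)
    )
    levels = _mean_levels(truth.metabolites, truth.classes, meta, ext, rel)
    levels[levels < detection_floor] = 0.0
    return pd.DataFrame(levels, index=truth.metabolites.index.copy(), columns=list(meta.index))


def generate_experiment(
    config: GeneratorConfig | None = None,
) -> tuple[FeatureTable, pd.DataFrame, SyntheticTruth]:
    """Generate a complete synthetic culture experiment.

    Returns ``(feature_table, sample_metadata, truth)``; deterministic for
    a fixed ``config.seed``.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    catalog = _catalog(rng, cfg)
    adducts = _adduct_envelope(rng, catalog)
    classes = _plant_classes(rng, cfg, catalog)
    meta = _sample_plan(cfg)
    producer = cfg.isolates[0]

    # planted extract / minimal-medium structure for release profiling
    extract_areas = pd.Series(0.0, index=catalog.index)
    minimal_release = pd.Series(0.0, index=catalog.index)
    if cfg.include_release_profile:
        n_ext = round(0.45 * cfg.n_metabolites)
        ext_ids = rng.choice(catalog.index, n_ext, replace=False)
        extract_areas[ext_ids] = np.exp(rng.uniform(np.log(2e3), np.log(1e6), n_ext))
        # most extract metabolites are released into minimal medium
        released_mask = rng.random(n_ext) < 0.8
        rel_ids = np.asarray(ext_ids)[released_mask]
        minimal_release[rel_ids] = np.exp(rng.uniform(np.log(3e3), np.log(2e5), rel_ids.size))

    # per (metabolite, sample) mean level
    sample_ids = list(meta.index)
    n_met = len(catalog)
    mean_level = _mean_levels(catalog, classes, meta, extract_areas, minimal_release)

    sig_tot, sig_feat = _sigma(cfg.noise_cv), _sigma(cfg.feature_noise_cv)
    sig_shared = float(np.sqrt(max(sig_tot**2 - sig_feat**2, 0.0)))
    shared = np.exp(sig_shared * rng.standard_normal((n_met, len(sample_ids))))
    met_pos = {m: i for i, m in enumerate(catalog.index)}
    rows_met = adducts["met_key"].map(met_pos).to_numpy()
    rel = adducts["rel_abundance"].to_numpy()[:, None]
    feat_noise = np.exp(sig_feat * rng.standard_normal((len(adducts), len(sample_ids))))
    inten = mean_level[rows_met] * shared[rows_met] * rel * feat_noise
    inten[inten < cfg.detection_floor] = 0.0

    features = pd.DataFrame(
        {
            "mz": adducts["mz"].to_numpy(),
            "rt": catalog["rt"].to_numpy()[rows_met],
            "polarity": adducts["polarity"].to_numpy(),
        },
        index=pd.Index(adducts["feature_id"], name="feature_id"),
    )
    table = FeatureTable(features, pd.DataFrame(inten, index=features.index, columns=sample_ids))
    truth = SyntheticTruth(
        metabolites=catalog,
        adducts=adducts,
        classes=classes,
        extract_areas=extract_areas if cfg.include_release_profile else None,
        minimal_release_areas=minimal_release if cfg.include_release_profile else None,
        seed=cfg.seed,
    )
    return table, meta, truth


def generate_timecourse(
    config: GeneratorConfig | None = None,
    truth: SyntheticTruth | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate a soil-water wetting time course with planted trends.

    When ``truth`` from :func:`generate_experiment` is passed, time-course
    metabolites are a subset of that experiment's catalog (so they can be
    cross-referenced against isolate capabilities); otherwise a fresh
    catalog is drawn.  Returns ``(abundance, metadata, truth)`` where
    ``abundance`` is a metabolite x sample table and ``truth`` carries the
    ``timecourse`` frame (trend + end-point multiplier + soil-water base).
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)

    if truth is None:
        catalog = _catalog(rng, cfg)
        truth = SyntheticTruth(
            metabolites=catalog,
            adducts=_adduct_envelope(rng, catalog),
            classes=pd.DataFrame(columns=["isolate_id", "met_key", "class", "multiplier"]),
            seed=cfg.seed,
        )
    catalog = truth.metabolites
    n_tc = min(cfg.n_timecourse_metabolites, len(catalog))
    mets = list(rng.choice(catalog.index, n_tc, replace=False))
    mets.sort()
    scale = n_tc / cfg.n_timecourse_metabolites  # shrink planted counts with the catalog
    n_dep = round(cfg.n_depleted * scale)
    n_acc = round(cfg.n_accumulated * scale)

    # soil-water baseline within ~an order of magnitude of the medium level
    base_sw = catalog.loc[mets, "base_area"].to_numpy() * np.power(
        10.0, rng.normal(0.0, 0.55, n_tc)
    )
    trend = np.array(["flat"] * n_tc, dtype=object)
    planted = rng.choice(n_tc, n_dep + n_acc, replace=False)
    dep, acc = planted[:n_dep], planted[n_dep:]
    trend[dep] = "depleted"
    trend[acc] = "accumulated"
    mult_last = np.ones(n_tc)
    mult_last[dep] = rng.uniform(*cfg.depletion_multiplier_range, n_dep)
    mult_last[acc] = rng.uniform(*cfg.accumulation_multiplier_range, n_acc)

    tps = list(cfg.timepoints_min)
    t0, t_last = tps[0], tps[-1]
    rows_meta = []
    cols = []
    sig = _sigma(cfg.timecourse_noise_cv)
    blocks = []
    for t in tps:
        frac = 0.0 if t_last == t0 else (t - t0) / (t_last - t0)
        level = base_sw * np.power(mult_last, frac)  # geometric interpolation
        noise = np.exp(sig * rng.standard_normal((n_tc, cfg.n_soilwater_replicates)))
        block = level[:, None] * noise
        block[block < cfg.detection_floor] = 0.0
        blocks.append(block)
        for r in range(1, cfg.n_soilwater_replicates + 1):
            sid = f"sw_t{t:g}_{r}"
            cols.append(sid)
            rows_meta.append((sid, "soil_water", None, None, None, float(t), r))
    abundance = pd.DataFrame(
        np.hstack(blocks), index=pd.Index(mets, name="metabolite_id"), columns=cols
    )
    meta = validate_sample_metadata(
        pd.DataFrame(
            rows_meta,
            columns=[
                "sample_id",
                "role",
                "isolate_id",
                "medium_id",
                "control_group_id",
                "timepoint_min",
                "replicate",
            ],
        )
    )
    truth.timecourse = pd.DataFrame(
        {"met_key": mets, "trend": trend, "multiplier": mult_last, "base_sw": base_sw}
    )
    return abundance, meta, truth


def degrade(
    table: FeatureTable,
    missingness: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> FeatureTable:
    """Robustness harness: random dropout + extra multiplicative noise."""
    if not (0 <= missingness < 1):
        raise ValueError("missingness must be in [0, 1)")
    rng = np.random.default_rng(seed)
    x = table.intensities.to_numpy(float).copy()
    if noise_cv > 0:
        x *= np.exp(_sigma(noise_cv) * rng.standard_normal(x.shape))
    if missingness > 0:
        x[rng.random(x.shape) < missingness] = 0.0
    return FeatureTable(table.features.copy(), pd.DataFrame(x, index=table.intensities.index, columns=table.intensities.columns))


def feature_to_met_key(feature_id: str) -> str:
    """Recover the planted metabolite key from a synthetic feature id."""
    return str(feature_id).rsplit("_f", 1)[0]
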