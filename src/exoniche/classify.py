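"""Per-isolate metabolite uptake/release classification.

Metabolic footprinting: for every (isolate, metabolite, medium) the
characteristic-ion peak areas in spent medium are compared against the
matched uninoculated control medium with a two-sided pooled-variance
Student's t-test.  Significant depletion is called *uptake*, significant
increase *release*; metabolites never reaching the abundance threshold in
the controls are *not_available* unless they appear de novo in the spent
medium (release from below detection).  No multiple-testing correction is
applied by default, matching the per-metabolite star convention of the
source assay; a Benjamini–Hochberg option is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CALLS = ("uptake", "release", "unchanged", "not_available")


@dataclass(frozen=True)
class ClassifyParams:
    alpha: float = 0.05
    min_area: float = 5000.0  # abundance ("available") threshold in control
    detect_area: float = 1000.0  # de-novo release detection gate
    abundance_mode: str = "any_sample"  # or "group_mean"
    fdr: bool = False  # Benjamini-Hochberg across metabolites per isolate x medium
    log10_areas: bool = False


@dataclass
class UtilizationCall:
    isolate_id: str
    metabolite_id: object
    medium_id: str
    call: str
    p_value: float
    fold_change: float
    mean_control: float
    mean_spent: float
    significance_tier: str
    flags: set[str] = field(default_factory=set)


def significance_tier(p: float, alpha: float = 0.05) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < alpha:
        return "*"
    return "ns"


def two_sample_t(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test.

    Degenerate samples (zero pooled variance) yield p = 1 when the means
    agree and p = 0 otherwise; see :func:`two_sample_t_flagged` for the
    degeneracy flag.
    """
    t, p, _ = two_sample_t_flagged(a, b)
    return t, p


def two_sample_t_flagged(a, b) -> tuple[float, float, bool]:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >=2 replicates per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, False
        return (np.inf if a.mean() > b.mean() else -np.inf), 0.0, True
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p), False


def _t_matrix(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled t-test: A (m x na) vs B (m x nb).

    Returns (t, p, degenerate); degenerate rows (zero pooled variance) get
    p=1 for equal means, p=0 otherwise.
    """
    na, nb = A.shape[1], B.shape[1]
    ma, mb = A.mean(axis=1), B.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_var = sp2 == 0
    eq = zero_var & (ma == mb)
    ne = zero_var & (ma != mb)
    t = np.where(eq, 0.0, t)
    p = np.where(eq, 1.0, p)
    t = np.where(ne, np.where(ma > mb, np.inf, -np.inf), t)
    p = np.where(ne, 0.0, p)
    return t, p, ne


def filter_abundant(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    min_area: float = 5000.0,
    mode: str = "any_sample",
) -> pd.Index:
    """Metabolites reaching ``min_area`` in the control media ("available").

    ``mode='any_sample'``: the area must reach the threshold in at least one
    individual control sample (the default reading of "in any one of the
    control media"); ``'group_mean'``: in at least one control group's mean.
    """
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    controls = meta.index[meta["role"] == "control"]
    controls = [s for s in controls if s in abundance.columns]
    if not controls:
        raise ValueError("no control samples present — cannot apply abundance filter")
    sub = abundance[controls]
    if mode == "any_sample":
        keep = (sub >= min_area).any(axis=1)
    elif mode == "group_mean":
        cg = meta.loc[controls, "control_group_id"]
        means = sub.T.groupby(cg.to_numpy()).mean().T
        keep = (means >= min_area).any(axis=1)
    else:
        raise ValueError(f"unknown abundance mode {mode!r}")
    return abundance.index[keep]


def _spent_control_samples(meta: pd.DataFrame, isolate_id: str, medium_id: str):
    spent = meta[
        (meta["role"] == "spent")
        & (meta["isolate_id"] == isolate_id)
        & (meta["medium_id"] == medium_id)
    ]
    if spent.empty:
        return None, None
    cgs = spent["control_group_id"].unique()
    if len(cgs) != 1:
        raise ValueError(
            f"isolate {isolate_id!r} in medium {medium_id!r} spans control groups {list(cgs)}"
        )
    ctl = meta[(meta["role"] == "control") & (meta["control_group_id"] == cgs[0])]
    if len(ctl) < 2 or len(spent) < 2:
        raise ValueError(
            f"isolate {isolate_id!r} / medium {medium_id!r}: need >=2 spent and control replicates"
        )
    return list(spent.index), list(ctl.index)


def classify_utilization(
    metabolite_id,
    isolate_id: str,
    medium_id: str,
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    params: ClassifyParams = ClassifyParams(),
) -> UtilizationCall:
    """Classify one (isolate, metabolite, medium) triple."""
    spent_ids, ctl_ids = _spent_control_samples(meta, isolate_id, medium_id)
    if spent_ids is None:
        raise ValueError(f"no spent samples for {isolate_id!r} in {medium_id!r}")
    row = abundance.loc[metabolite_id]
    s = row[spent_ids].to_numpy(float)
    c = row[ctl_ids].to_numpy(float)
    if (s < 0).any() or (c < 0).any():
        raise ValueError("negative peak areas")
    return _classify_arrays(metabolite_id, isolate_id, medium_id, s, c, params)


def _classify_arrays(mid, iso, med, s, c, params: ClassifyParams) -> UtilizationCall:
    flags: set[str] = set()
    if params.log10_areas:
        s_t, c_t = np.log10(s + 1.0), np.log10(c + 1.0)
    else:
        s_t, c_t = s, c
    mean_c, mean_s = float(c.mean()), float(s.mean())
    fold = np.inf if mean_c == 0 else mean_s / mean_c
    if c.max() < params.min_area:
        if mean_s < params.detect_area or mean_s <= mean_c:
            return UtilizationCall(
                iso, mid, med, "not_available", 1.0, fold, mean_c, mean_s, "ns", flags
            )
        t, p, degen = two_sample_t_flagged(s_t, c_t)
        if degen:
            flags.add("degenerate_variance")
        flags.add("release_below_control_detection")
        return UtilizationCall(
            iso, mid, med, "release", p, fold, mean_c, mean_s,
            significance_tier(p, params.alpha), flags,
        )
    t, p, degen = two_sample_t_flagged(s_t, c_t)
    if degen:
        flags.add("degenerate_variance")
    if p < params.alpha and mean_s < mean_c:
        call = "uptake"
    elif p < params.alpha and mean_s > mean_c:
        call = "release"
    else:
        call = "unchanged"
    return UtilizationCall(
        iso, mid, med, call, float(p), fold, mean_c, mean_s,
        significance_tier(p, params.alpha), flags,
    )


def classify_experiment(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    params: ClassifyParams = ClassifyParams(),
    metabolite_ids: pd.Index | None = None,
    media: list[str] | None = None,
) -> pd.DataFrame:
    """Vectorised classification over all (isolate, metabolite, medium).

    Returns a long DataFrame with one row per triple; every isolate is
    classified in every medium where it has spent samples (restricted to
    ``media`` when given).  Metabolites outside the abundance filter still
    get de-novo-release / not_available calls, so novel released compounds
    are retained downstream.
    """
    if metabolite_ids is None:
        metabolite_ids = abundance.index
    spent_meta = meta[meta["role"] == "spent"]
    if media is not None:
        spent_meta = spent_meta[spent_meta["medium_id"].isin(media)]
    if spent_meta.empty:
        raise ValueError("no spent samples in metadata")
    rows = []
    for (iso, med), _ in spent_meta.groupby(["isolate_id", "medium_id"], sort=True):
        spent_ids, ctl_ids = _spent_control_samples(meta, iso, med)
        S = abundance.loc[metabolite_ids, spent_ids].to_numpy(float)
        C = abundance.loc[metabolite_ids, ctl_ids].to_numpy(float)
        if (S < 0).any() or (C < 0).any():
            raise ValueError("negative peak areas")
        if params.log10_areas:
            t, p, degen = _t_matrix(np.log10(S + 1.0), np.log10(C + 1.0))
        else:
            t, p, degen = _t_matrix(S, C)
        mean_s, mean_c = S.mean(axis=1), C.mean(axis=1)
        max_c = C.max(axis=1)
        with np.errstate(divide="ignore"):
            fold = np.where(mean_c == 0, np.inf, mean_s / np.where(mean_c == 0, 1, mean_c))

        not_avail = max_c < params.min_area
        denovo = not_avail & (mean_s >= params.detect_area) & (mean_s > mean_c)
        sig = p < params.alpha
        call = np.full(len(metabolite_ids), "unchanged", dtype=object)
        call[sig & (mean_s < mean_c)] = "uptake"
        call[sig & (mean_s > mean_c)] = "release"
        call[not_avail] = "not_available"
        call[denovo] = "release"
        p_out = np.where(not_avail & ~denovo, 1.0, p)

        if params.fdr:
            from statsmodels.stats.multitest import multipletests

            tested = ~not_avail
            if tested.any():
                rej, q, *_ = multipletests(p[tested], alpha=params.alpha, method="fdr_bh")
                # a call loses significance if BH rejects it
                sub_call = call[tested]
                sub_call[(~rej) & (sub_call != "not_available")] = "unchanged"
                call[tested] = sub_call

        df = pd.DataFrame(
            {
                "isolate_id": iso,
                "metabolite_id": metabolite_ids,
                "medium_id": med,
                "call": call,
                "p_value": p_out,
                "fold_change": fold,
                "mean_control": mean_c,
                "mean_spent": mean_s,
                "tier": [significance_tier(x, params.alpha) for x in p_out],
                "flags": [
                    ";".join(
                        sorted(
                            ({"degenerate_variance"} if d else set())
                            | ({"release_below_control_detection"} if dn else set())
                        )
                    )
                    for d, dn in zip(degen, denovo)
                ],
            }
        )
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    _assert_direction(out)
    return out


def _assert_direction(calls: pd.DataFrame) -> None:
    up = calls[calls["call"] == "uptake"]
    rel = calls[calls["call"] == "release"]
    if not (up["mean_spent"] < up["mean_control"]).all():
        raise AssertionError("uptake call with non-depleted mean")
    if not (rel["mean_spent"] > rel["mean_control"]).all():
        raise AssertionError("release call with non-increased mean")


def combine_across_media(calls: pd.DataFrame) -> pd.DataFrame:
    """Consensus call per (isolate, metabolite) across medium formulations.

    Informative calls (uptake/release) trump unchanged; an uptake/release
    conflict resolves to the smaller p-value and is flagged; all
    not_available stays not_available.
    """
    if calls.empty:
        raise ValueError("no calls to combine")
    rows = []
    for (iso, mid), grp in calls.groupby(["isolate_id", "metabolite_id"], sort=True):
        informative = grp[grp["call"].isin(("uptake", "release"))]
        flags = set()
        if informative.empty:
            if (grp["call"] == "not_available").all():
                call, p = "not_available", 1.0
            else:
                call = "unchanged"
                p = float(grp.loc[grp["call"] == "unchanged", "p_value"].min())
        else:
            kinds = set(informative["call"])
            if len(kinds) == 2:
                flags.add("conflict")
            best = informative.sort_values(["p_value", "medium_id"], kind="mergesort").iloc[0]
            call, p = best["call"], float(best["p_value"])
        rows.append(
            {
                "isolate_id": iso,
                "metabolite_id": mid,
                "call": call,
                "p_value": p,
                "flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)
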