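"""Soil-water exometabolite dynamics after a wetting pulse.

Desiccated biocrust released metabolites are sampled at successive
timepoints after wetting (default 3 min, 9 h, 18 h; independent replicates
per timepoint).  Per metabolite, a two-sided Student's t-test between the
first and last timepoint classifies the trend (depleted / accumulated /
flat).  Depleted metabolites that no isolate in the culture experiments
takes up point to uncultured consumers occupying those niches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import _t_matrix, significance_tier
from .ion_grouping import MetaboliteRecord
from .niche import UtilizationMatrix


@dataclass
class TimecourseResult:
    table: pd.DataFrame  # per metabolite: means per timepoint, trend, p_value
    t_first: float
    t_last: float
    alpha: float
    dilution_factor: float

    @property
    def depleted(self) -> set:
        return set(self.table.index[self.table["trend"] == "depleted"])

    @property
    def accumulated(self) -> set:
        return set(self.table.index[self.table["trend"] == "accumulated"])


def timepoint_trend(
    soil_water: pd.DataFrame,
    meta: pd.DataFrame,
    t_first: float | None = None,
    t_last: float | None = None,
    alpha: float = 0.05,
    dilution_factor: float = 1.0,
) -> TimecourseResult:
    """Per-metabolite first-vs-last timepoint comparison.

    ``soil_water`` is a metabolite x sample abundance table; ``meta`` must
    mark the samples with role ``soil_water`` and a numeric
    ``timepoint_min``.  ``dilution_factor`` multiplies the last-timepoint
    areas to correct for water replenished between samplings (1.0 = no
    correction).
    """
    sw = meta[meta["role"] == "soil_water"]
    if sw.empty:
        raise ValueError("no soil_water samples in metadata")
    tps = sorted(pd.unique(sw["timepoint_min"].astype(float)))
    if len(tps) < 2:
        raise ValueError("need at least two timepoints")
    t_first = tps[0] if t_first is None else float(t_first)
    t_last = tps[-1] if t_last is None else float(t_last)
    for t in (t_first, t_last):
        if t not in tps:
            raise ValueError(f"timepoint {t} min not present (have {tps})")
    if t_first >= t_last:
        raise ValueError("t_first must precede t_last")

    cols = {t: list(sw.index[sw["timepoint_min"].astype(float) == t]) for t in tps}
    for t in (t_first, t_last):
        if len(cols[t]) < 2:
            raise ValueError(f"timepoint {t} min has <2 replicates")
    A = soil_water[cols[t_last]].to_numpy(float) * dilution_factor
    B = soil_water[cols[t_first]].to_numpy(float)
    t_stat, p, degen = _t_matrix(A, B)
    mean_first = B.mean(axis=1)
    mean_last = A.mean(axis=1)

    trend = np.full(len(soil_water), "flat", dtype=object)
    sig = p < alpha
    trend[sig & (mean_last < mean_first)] = "depleted"
    trend[sig & (mean_last > mean_first)] = "accumulated"

    table = pd.DataFrame(index=soil_water.index)
    for t in tps:
        factor = dilution_factor if t == t_last else 1.0
        table[f"mean_t{t:g}"] = soil_water[cols[t]].to_numpy(float).mean(axis=1) * factor
    table["trend"] = trend
    table["p_value"] = p
    table["tier"] = [significance_tier(x, alpha) for x in p]
    table["degenerate"] = degen
    return TimecourseResult(table, t_first, t_last, alpha, dilution_factor)


def match_metabolites(
    a: list[MetaboliteRecord],
    b: list[MetaboliteRecord],
    mz_tol: float = 0.02,
    rt_tol: float = 0.3,
) -> pd.DataFrame:
    """Map metabolites between two experiments by (m/z, rt, polarity).

    Greedy nearest-m/z matching; a record with several partners within
    tolerance takes the nearest and is flagged ambiguous.
    """
    cands = []
    n_cand_a: dict = {}
    for ra in a:
        for rb in b:
            if ra.characteristic_polarity != rb.characteristic_polarity:
                continue
            dmz = abs(ra.characteristic_mz - rb.characteristic_mz)
            if dmz <= mz_tol and abs(ra.rt - rb.rt) <= rt_tol:
                cands.append((dmz, ra.metabolite_id, rb.metabolite_id))
                n_cand_a[ra.metabolite_id] = n_cand_a.get(ra.metabolite_id, 0) + 1
    cands.sort()
    used_a, used_b = set(), set()
    rows = []
    for dmz, ia, ib in cands:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        rows.append(
            {
                "metabolite_id_a": ia,
                "metabolite_id_b": ib,
                "delta_mz": dmz,
                "ambiguous": n_cand_a[ia] > 1,
            }
        )
    return pd.DataFrame(rows, columns=["metabolite_id_a", "metabolite_id_b", "delta_mz", "ambiguous"])


def unused_but_depleted(
    trend: TimecourseResult,
    matrix: UtilizationMatrix,
    mapping: pd.DataFrame,
) -> set:
    """Soil-water-depleted metabolites no isolate takes up.

    ``mapping`` links soil-water metabolite ids (column ``metabolite_id_a``)
    to isolate-experiment metabolite ids (``metabolite_id_b``).  Depleted
    metabolites whose mapped matrix column shows zero uptake cells are
    returned (in soil-water ids); these mark niches held by organisms absent
    from the isolate panel.
    """
    up = matrix.uptake_mask().sum(axis=0)
    link = dict(zip(mapping["metabolite_id_a"], mapping["metabolite_id_b"]))
    out = set()
    for m in trend.depleted:
        partner = link.get(m)
        if partner is not None and partner in up.index and up[partner] == 0:
            out.add(m)
    return out


def media_vs_soilwater_comparability(
    media_controls: pd.DataFrame,
    soil_water_first: pd.DataFrame,
    mapping: pd.DataFrame,
) -> pd.DataFrame:
    """Abundance comparability between supplemented media and fresh soil water.

    For every mapped metabolite: log10 of (mean control-medium area / mean
    soil-water area at the first timepoint).  A metabolite with
    |log10 ratio| <= 1 is within one order of magnitude; the summary
    fraction is in attribute ``attrs['fraction_within_order']``.
    """
    rows = []
    for _, rec in mapping.iterrows():
        a, b = rec["metabolite_id_a"], rec["metabolite_id_b"]
        if b not in media_controls.index or a not in soil_water_first.index:
            continue
        med = float(media_controls.loc[b].mean())
        sw = float(soil_water_first.loc[a].mean())
        if med <= 0 or sw <= 0:
            ratio = np.nan
        else:
            ratio = np.log10(med / sw)
        rows.append({"metabolite_id_soil": a, "metabolite_id_media": b, "log10_ratio": ratio})
    out = pd.DataFrame(rows, columns=["metabolite_id_soil", "metabolite_id_media", "log10_ratio"])
    ok = out["log10_ratio"].abs() <= 1.0
    out.attrs["fraction_within_order"] = float(ok.mean()) if len(out) else float("nan")
    return out
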