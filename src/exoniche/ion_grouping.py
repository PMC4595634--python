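"""Resolve redundant spectral features into putative metabolites.

One metabolite typically yields several ions (adducts, multimers, in-source
fragments, isotopologues) that co-elute and whose peak areas co-vary across
samples.  The pipeline here:

1. :func:`group_coeluting_features` — single-linkage clustering over a
   pairwise gate (same polarity, retention times within ``rt_tol``, Pearson
   correlation of intensity vectors >= ``corr_min``).
2. :func:`assign_ion_types` — per group, find the neutral mass explaining
   the most members through a prioritized adduct-rule table.
3. :func:`select_characteristic_ion` — pick the quantifier ion.
4. :func:`merge_polarities` — join positive- and negative-mode groups of
   the same metabolite into one record.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import AdductRule, DEFAULT_ADDUCT_RULES
from .io import FeatureTable

UNASSIGNED = "unassigned fragment"

#: Minimum number of samples (where at least one of the pair is detected)
#: required to trust a correlation.
MIN_SUPPORT = 3


@dataclass
class IonGroup:
    """A set of co-eluting, intensity-correlated features of one polarity."""

    group_id: int
    feature_ids: list[str]
    polarity: str
    rt_center: float
    annotations: dict[str, str] = field(default_factory=dict)  # feature -> rule name / UNASSIGNED
    neutral_mass: float | None = None
    characteristic_feature_id: str | None = None
    flags: set[str] = field(default_factory=set)


@dataclass
class MetaboliteRecord:
    """One resolved putative metabolite (possibly seen in both polarities)."""

    metabolite_id: int
    characteristic_feature_id: str
    characteristic_mz: float
    characteristic_polarity: str
    rt: float
    neutral_mass: float | None = None
    formula: str | None = None
    identity: str | None = None
    n_member_ions: int = 1
    source_groups: tuple[int, ...] = ()
    flags: set[str] = field(default_factory=set)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _pair_gate(
    xa: np.ndarray, xb: np.ndarray, corr_min: float
) -> bool:
    """Correlation gate on the union support (samples where either is detected)."""
    support = (xa > 0) | (xb > 0)
    if support.sum() < MIN_SUPPORT:
        return False
    a, b = xa[support], xb[support]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return False
    r = float(np.corrcoef(a, b)[0, 1])
    return r >= corr_min


def group_coeluting_features(
    table: FeatureTable,
    rt_tol: float = 0.3,
    corr_min: float = 0.9,
    sample_subset: list[str] | None = None,
) -> list[IonGroup]:
    """Partition features into ion groups by RT proximity and co-variation.

    Single-linkage transitive closure over the pairwise gate: same polarity,
    |ΔRT| <= ``rt_tol`` and Pearson r >= ``corr_min`` computed on samples
    where at least one of the pair is detected (>= 3 such samples required).
    Features detected in no sample become flagged singletons.  Deterministic:
    features are processed in (polarity, rt, mz, feature_id) order and group
    ids follow that order.

    ``sample_subset`` restricts the correlation to comparable runs (e.g. the
    control + spent media of the utilization assay).  Samples on a wholly
    different intensity scale — cell extracts versus media — otherwise act
    as high-leverage points that correlate unrelated co-eluting metabolites.
    """
    if len(table.features) == 0:
        raise ValueError("no features to group")
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    if not (0 < corr_min <= 1):
        raise ValueError("corr_min must be in (0, 1]")

    order = table.features.copy()
    order["_fid"] = order.index.astype(str)
    order = order.sort_values(["polarity", "rt", "mz", "_fid"], kind="mergesort")
    fids = order.index.to_numpy()
    rts = order["rt"].to_numpy(float)
    pols = order["polarity"].to_numpy()
    cols = sample_subset if sample_subset is not None else table.intensities.columns
    X = table.intensities.loc[fids, cols].to_numpy(float)
    n = len(fids)
    detected = (X > 0).any(axis=1)

    uf = _UnionFind(n)
    # sliding RT window within polarity blocks
    for i in range(n):
        if not detected[i]:
            continue
        j = i + 1
        while j < n and pols[j] == pols[i] and rts[j] - rts[i] <= rt_tol:
            if detected[j] and _pair_gate(X[i], X[j], corr_min):
                uf.union(i, j)
            j += 1

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(uf.find(i), []).append(i)

    groups: list[IonGroup] = []
    for gid, root in enumerate(sorted(members), start=1):
        idx = members[root]
        grp_rts = rts[idx]
        g = IonGroup(
            group_id=gid,
            feature_ids=[str(fids[i]) for i in idx],
            polarity=str(pols[idx[0]]),
            rt_center=float((grp_rts.min() + grp_rts.max()) / 2.0),
        )
        if len(idx) == 1 and not detected[idx[0]]:
            g.flags.add("all_zero")
        if grp_rts.max() - grp_rts.min() > 2 * rt_tol:
            g.flags.add("rt_span_exceeded")
        groups.append(g)
    return groups


def assign_ion_types(
    group: IonGroup,
    table: FeatureTable,
    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCT_RULES,
    mz_tol: float = 0.02,
) -> IonGroup:
    """Annotate group members with ion types and derive the neutral mass.

    Every (member, rule) pair of matching polarity proposes a candidate
    neutral mass; the candidate explaining the most members wins (ties go to
    the candidate anchored by the highest-priority rule, then lowest m/z,
    and the group is flagged ``ambiguous_neutral_mass`` when tied candidates
    disagree by more than ``mz_tol``).  The winning mass is refined as the
    mean of the masses implied by all explained members.  Members explained
    by no rule are annotated as unassigned in-source fragments.
    """
    if mz_tol <= 0:
        raise ValueError("mz_tol must be positive")
    pol_rules = [r for r in rules if r.polarity == group.polarity]
    mzs = table.features.loc[group.feature_ids, "mz"]
    med = table.intensities.loc[group.feature_ids].median(axis=1)

    candidates = []  # (rule_priority, anchor_median, anchor_mz, M)
    for prio, rule in enumerate(pol_rules):
        for fid in group.feature_ids:
            m = rule.neutral_from_mz(float(mzs[fid]))
            if m > 0:
                candidates.append((prio, float(med[fid]), float(mzs[fid]), m))
    if not candidates:
        group.annotations = {fid: UNASSIGNED for fid in group.feature_ids}
        group.neutral_mass = None
        return group

    def explained(m: float) -> dict[str, AdductRule]:
        hits: dict[str, AdductRule] = {}
        for fid in group.feature_ids:
            for rule in pol_rules:
                if abs(float(mzs[fid]) - rule.mz_from_neutral(m)) <= mz_tol:
                    hits[fid] = rule
                    break
        return hits

    # best candidate: most members explained; ties to the higher-priority
    # rule, then to the strongest anchor ion (an in-source fragment must not
    # out-anchor the molecular species), then to lower m/z
    scored = []
    for prio, anchor_med, anchor_mz, m in candidates:
        scored.append((-len(explained(m)), prio, -anchor_med, anchor_mz, m))
    scored.sort()
    best_count = scored[0][0]
    best_m = scored[0][4]
    ties = [s for s in scored if s[0] == best_count]
    if any(abs(s[4] - best_m) > mz_tol for s in ties):
        group.flags.add("ambiguous_neutral_mass")

    hits = explained(best_m)
    # refine: average the member-implied masses under their assigned rules
    implied = [rule.neutral_from_mz(float(mzs[fid])) for fid, rule in hits.items()]
    group.neutral_mass = float(np.mean(implied)) if implied else None
    group.annotations = {
        fid: (hits[fid].name if fid in hits else UNASSIGNED) for fid in group.feature_ids
    }
    return group


def select_characteristic_ion(group: IonGroup, table: FeatureTable) -> str:
    """Pick the quantifier ion of a group.

    Highest median peak area across all samples among members annotated with
    a characteristic ion type (protonated / deprotonated / ammoniated);
    falls back to all members when none is annotated.  Ties break to the
    lower m/z, then lexically smaller feature id.
    """
    rules_by_name = {}
    char_names = set()
    for r in DEFAULT_ADDUCT_RULES:
        rules_by_name[r.name] = r
    # characteristic-ness is read off the annotation's rule when known;
    # custom rule sets annotate by name, so honor any name marked in table
    med = table.intensities.loc[group.feature_ids].median(axis=1)
    mzs = table.features.loc[group.feature_ids, "mz"]

    def is_char(fid: str) -> bool:
        name = group.annotations.get(fid)
        if name is None or name == UNASSIGNED:
            return False
        rule = rules_by_name.get(name)
        return bool(rule.characteristic) if rule is not None else _looks_characteristic(name)

    pool = [fid for fid in group.feature_ids if is_char(fid)]
    if not pool:
        pool = list(group.feature_ids)
    pool.sort(key=lambda fid: (-float(med[fid]), float(mzs[fid]), fid))
    group.characteristic_feature_id = pool[0]
    return pool[0]


def _looks_characteristic(name: str) -> bool:
    return name in ("[M+H]+", "[M-H]-", "[M+NH4]+")


C13_SHIFT = 1.0033548378  # 13C - 12C


def estimate_m1_ratio(group: IonGroup, table: FeatureTable, mz_tol: float = 0.02) -> float | None:
    """Observed M+1/M ratio from a co-grouped isotopologue feature.

    Looks for a member one 13C-12C shift above the characteristic ion and
    returns the ratio of median peak areas; ``None`` when no such member
    exists.
    """
    fid = group.characteristic_feature_id
    if fid is None:
        return None
    mz0 = float(table.features.loc[fid, "mz"])
    med = table.intensities.loc[group.feature_ids].median(axis=1)
    best = None
    for other in group.feature_ids:
        if other == fid:
            continue
        if abs(float(table.features.loc[other, "mz"]) - (mz0 + C13_SHIFT)) <= mz_tol:
            if best is None or med[other] > med[best]:
                best = other
    if best is None or med[fid] <= 0:
        return None
    return float(med[best] / med[fid])


def annotate_groups(
    groups: list[IonGroup],
    table: FeatureTable,
    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCT_RULES,
    mz_tol: float = 0.02,
) -> list[IonGroup]:
    """Convenience: ion-type assignment + characteristic-ion selection."""
    for g in groups:
        assign_ion_types(g, table, rules, mz_tol)
        select_characteristic_ion(g, table)
    return groups


def merge_polarities(
    groups: list[IonGroup],
    table: FeatureTable,
    mass_tol: float = 0.005,
    rt_tol: float = 0.3,
) -> list[MetaboliteRecord]:
    """Merge positive and negative detections of one metabolite.

    A positive and a negative group merge when both carry a neutral mass,
    the masses agree within ``mass_tol`` and retention times within
    ``rt_tol``; matching is greedy by ascending |Δmass| for determinism, and
    groups with several possible partners are flagged.  Metabolite numbers
    are assigned sequentially in (rt, m/z) order of the characteristic ion.
    """
    if mass_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    for g in groups:
        if g.characteristic_feature_id is None:
            select_characteristic_ion(g, table)

    pos = [g for g in groups if g.polarity == "positive" and g.neutral_mass is not None]
    neg = [g for g in groups if g.polarity == "negative" and g.neutral_mass is not None]
    pairs = []
    partner_count: dict[int, int] = {}
    for p, q in itertools.product(pos, neg):
        dm = abs(p.neutral_mass - q.neutral_mass)
        if dm <= mass_tol and abs(p.rt_center - q.rt_center) <= rt_tol:
            pairs.append((dm, p.group_id, q.group_id, p, q))
            partner_count[p.group_id] = partner_count.get(p.group_id, 0) + 1
            partner_count[q.group_id] = partner_count.get(q.group_id, 0) + 1
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    used: set[int] = set()
    merged: list[tuple[IonGroup, IonGroup | None]] = []
    for dm, pid, qid, p, q in pairs:
        if pid in used or qid in used:
            continue
        used.add(pid)
        used.add(qid)
        merged.append((p, q))
    for g in groups:
        if g.group_id not in used:
            merged.append((g, None))

    med = table.intensities.median(axis=1)
    records: list[MetaboliteRecord] = []
    for p, q in merged:
        if q is None:
            char_group = p
        else:
            # quantify via the polarity whose characteristic ion is stronger
            char_group = max(
                (p, q), key=lambda g: float(med[g.characteristic_feature_id])
            )
        fid = char_group.characteristic_feature_id
        flags = set(p.flags) | (set(q.flags) if q else set())
        if q is not None and (
            partner_count.get(p.group_id, 0) > 1 or partner_count.get(q.group_id, 0) > 1
        ):
            flags.add("merge_ambiguous")
        if q is None:
            nm = p.neutral_mass
        else:
            nm = float(np.mean([p.neutral_mass, q.neutral_mass]))
        records.append(
            MetaboliteRecord(
                metabolite_id=0,  # assigned below
                characteristic_feature_id=str(fid),
                characteristic_mz=float(table.features.loc[fid, "mz"]),
                characteristic_polarity=char_group.polarity,
                rt=float(char_group.rt_center),
                neutral_mass=nm,
                n_member_ions=len(p.feature_ids) + (len(q.feature_ids) if q else 0),
                source_groups=(p.group_id,) if q is None else (p.group_id, q.group_id),
                flags=flags,
            )
        )
    records.sort(key=lambda r: (r.rt, r.characteristic_mz, r.characteristic_feature_id))
    for i, rec in enumerate(records, start=1):
        rec.metabolite_id = i
    return records


def resolve_metabolites(
    table: FeatureTable,
    rules: tuple[AdductRule, ...] = DEFAULT_ADDUCT_RULES,
    rt_tol: float = 0.3,
    corr_min: float = 0.9,
    mz_tol: float = 0.02,
    mass_tol: float = 0.005,
    sample_subset: list[str] | None = None,
) -> tuple[list[IonGroup], list[MetaboliteRecord]]:
    """Full ion-resolution pipeline: group, annotate, merge polarities."""
    groups = group_coeluting_features(
        table, rt_tol=rt_tol, corr_min=corr_min, sample_subset=sample_subset
    )
    annotate_groups(groups, table, rules, mz_tol)
    records = merge_polarities(groups, table, mass_tol=mass_tol, rt_tol=rt_tol)
    return groups, records


def abundance_table(records: list[MetaboliteRecord], table: FeatureTable) -> pd.DataFrame:
    """Characteristic-ion peak areas: metabolite_id x sample_id."""
    idx = [r.metabolite_id for r in records]
    rows = table.intensities.loc[[r.characteristic_feature_id for r in records]].to_numpy(float)
    return pd.DataFrame(rows, index=pd.Index(idx, name="metabolite_id"), columns=table.sample_ids)


def records_frame(records: list[MetaboliteRecord]) -> pd.DataFrame:
    """Metabolite table for export."""
    return pd.DataFrame(
        {
            "metabolite_id": [r.metabolite_id for r in records],
            "mz": [r.characteristic_mz for r in records],
            "polarity": [r.characteristic_polarity for r in records],
            "rt": [r.rt for r in records],
            "neutral_mass": [r.neutral_mass for r in records],
            "formula": [r.formula for r in records],
            "identity": [r.identity for r in records],
            "n_member_ions": [r.n_member_ions for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    ).set_index("metabolite_id")
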