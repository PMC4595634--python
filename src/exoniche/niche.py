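"""Niche-partitioning statistics over the isolate x metabolite call matrix.

The utilization matrix holds one consensus call per isolate and *available*
(abundance-filtered) metabolite.  From it: per-isolate used fractions, the
shared-use distribution (how many isolates consume each metabolite),
candidate competition metabolites (taken up by >=2 isolates, released by
none), candidate cross-feeding metabolites (released by one isolate and
taken up by another), pairwise niche overlap, and a bipartite
isolate-metabolite network.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

CELL_STATES = ("uptake", "release", "unchanged", "not_available")


@dataclass
class UtilizationMatrix:
    """Isolates x available metabolites consensus calls.

    ``calls``: DataFrame (isolate x metabolite) of call strings;
    ``conflict``: boolean mask of cells whose cross-media calls disagreed;
    ``released_novel``: metabolites released by >=1 isolate but never
    abundant in any control medium (excluded from fractions — they were
    never "available" for uptake).
    """

    calls: pd.DataFrame
    conflict: pd.DataFrame
    released_novel: set = field(default_factory=set)
    conflict_policy: str = "as_resolved"  # or "exclude"

    @property
    def isolates(self) -> list:
        return list(self.calls.index)

    @property
    def metabolites(self) -> list:
        return list(self.calls.columns)

    @property
    def denominator(self) -> int:
        return self.calls.shape[1]

    def uptake_mask(self) -> pd.DataFrame:
        m = self.calls == "uptake"
        if self.conflict_policy == "exclude":
            m &= ~self.conflict
        return m

    def release_mask(self) -> pd.DataFrame:
        m = self.calls == "release"
        if self.conflict_policy == "exclude":
            m &= ~self.conflict
        return m


def build_utilization_matrix(
    consensus: pd.DataFrame,
    abundant_ids,
    isolates,
    conflict_policy: str = "as_resolved",
) -> UtilizationMatrix:
    """Pivot consensus calls into the matrix over the available metabolite set.

    Every (isolate, abundant metabolite) pair must be present exactly once;
    gaps raise with the offending pairs listed.  Release calls on
    non-abundant metabolites populate ``released_novel``.
    """
    isolates = list(isolates)
    abundant_ids = list(abundant_ids)
    if not isolates:
        raise ValueError("empty isolate list")
    wide = consensus.pivot(index="isolate_id", columns="metabolite_id", values="call")
    cflags = (
        consensus.assign(c=consensus["flags"].fillna("").str.contains("conflict"))
        .pivot(index="isolate_id", columns="metabolite_id", values="c")
    )
    missing = [
        (i, m)
        for i in isolates
        for m in abundant_ids
        if i not in wide.index or m not in wide.columns or pd.isna(wide.loc[i, m])
    ]
    if missing:
        raise ValueError(f"missing consensus calls for pairs: {missing[:10]}")
    calls = wide.loc[isolates, abundant_ids]
    conflict = cflags.loc[isolates, abundant_ids].fillna(False).astype(bool)

    novel = set()
    other = consensus[~consensus["metabolite_id"].isin(abundant_ids)]
    novel.update(other.loc[other["call"] == "release", "metabolite_id"].tolist())
    return UtilizationMatrix(calls, conflict, novel, conflict_policy)


def per_isolate_fraction(matrix: UtilizationMatrix) -> dict:
    """Fraction of available metabolites taken up, per isolate."""
    up = matrix.uptake_mask().sum(axis=1)
    return {i: float(up[i]) / matrix.denominator for i in matrix.isolates}


def percent(x: float) -> int:
    """Round-half-away-from-zero integer percent (70/372 -> 19)."""
    return int(math.floor(abs(x) * 100 + 0.5) * (1 if x >= 0 else -1))


def shared_use_distribution(matrix: UtilizationMatrix) -> tuple[dict[int, int], dict[int, int]]:
    """Histogram of metabolites by number of consuming isolates.

    Returns ``(histogram, cumulative)`` where ``cumulative[k]`` counts
    metabolites taken up by at least ``k`` isolates.
    """
    n_iso = len(matrix.isolates)
    counts = matrix.uptake_mask().sum(axis=0)
    hist = {k: int((counts == k).sum()) for k in range(n_iso + 1)}
    cum = {k: int((counts >= k).sum()) for k in range(n_iso + 1)}
    return hist, cum


def competition_candidates(matrix: UtilizationMatrix) -> set:
    """Metabolites taken up by >=2 isolates and released by none."""
    up = matrix.uptake_mask().sum(axis=0)
    rel = matrix.release_mask().sum(axis=0)
    return set(matrix.calls.columns[(up >= 2) & (rel == 0)])


def crossfeeding_candidates(matrix: UtilizationMatrix) -> set:
    """Metabolites taken up by >=1 isolate and released by a different one."""
    up = matrix.uptake_mask()
    rel = matrix.release_mask()
    out = set()
    for m in matrix.calls.columns:
        ups = set(up.index[up[m]])
        rels = set(rel.index[rel[m]])
        # at least one releasing isolate distinct from some up-taking isolate
        if any(r != u for r in rels for u in ups):
            out.add(m)
    return out


def pairwise_overlap(matrix: UtilizationMatrix, method: str = "jaccard") -> pd.DataFrame:
    """Symmetric isolate x isolate overlap of uptake sets."""
    if method not in ("jaccard", "simpson"):
        raise ValueError(f"unknown overlap method {method!r}")
    up = matrix.uptake_mask()
    sets = {i: set(up.columns[up.loc[i]]) for i in matrix.isolates}
    n = len(matrix.isolates)
    out = pd.DataFrame(
        np.zeros((n, n)), index=matrix.isolates, columns=matrix.isolates
    )
    for i in matrix.isolates:
        for j in matrix.isolates:
            a, b = sets[i], sets[j]
            inter = len(a & b)
            if method == "jaccard":
                denom = len(a | b)
            else:
                denom = min(len(a), len(b))
            out.loc[i, j] = inter / denom if denom else 0.0
    return out


def export_bipartite(
    matrix: UtilizationMatrix,
    isolate_attrs: dict | None = None,
    metabolite_attrs: dict | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Bipartite isolate-metabolite network of utilization/release edges."""
    g = nx.Graph()
    for i in matrix.isolates:
        g.add_node(f"isolate::{i}", kind="isolate", **(isolate_attrs or {}).get(i, {}))
    for m in matrix.metabolites:
        g.add_node(f"metabolite::{m}", kind="metabolite", **(metabolite_attrs or {}).get(m, {}))
    rows = []
    up, rel = matrix.uptake_mask(), matrix.release_mask()
    for i in matrix.isolates:
        for m in matrix.metabolites:
            if up.loc[i, m]:
                etype = "utilization"
            elif rel.loc[i, m]:
                etype = "release"
            else:
                continue
            g.add_edge(f"isolate::{i}", f"metabolite::{m}", type=etype)
            rows.append({"isolate_id": i, "metabolite_id": m, "type": etype})
    edges = pd.DataFrame(rows, columns=["isolate_id", "metabolite_id", "type"])
    return g, edges


def niche_summary(matrix: UtilizationMatrix) -> dict:
    """All set-level niche statistics in one JSON-ready dict."""
    hist, cum = shared_use_distribution(matrix)
    fracs = per_isolate_fraction(matrix)
    comp = competition_candidates(matrix)
    cross = crossfeeding_candidates(matrix)
    overlap = pairwise_overlap(matrix, "jaccard")
    return {
        "n_isolates": len(matrix.isolates),
        "denominator": matrix.denominator,
        "per_isolate_used_fraction": {str(k): v for k, v in fracs.items()},
        "per_isolate_used_percent": {str(k): percent(v) for k, v in fracs.items()},
        "shared_use_histogram": {str(k): v for k, v in hist.items()},
        "shared_use_cumulative": {str(k): v for k, v in cum.items()},
        "unused_fraction": hist[0] / matrix.denominator,
        "unused_percent": percent(hist[0] / matrix.denominator),
        "n_used_by_all": hist[len(matrix.isolates)],
        "n_competition_candidates": len(comp),
        "n_crossfeeding_candidates": len(cross),
        "n_released_novel": len(matrix.released_novel),
        "mean_pairwise_jaccard": float(
            overlap.to_numpy()[~np.eye(len(matrix.isolates), dtype=bool)].mean()
        )
        if len(matrix.isolates) > 1
        else 0.0,
    }
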