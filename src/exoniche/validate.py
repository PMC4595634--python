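"""Recovery evaluation of pipeline output against planted synthetic truth.

Synthetic feature ids encode their metabolite of origin, so resolved
records are matched to planted metabolites through their characteristic
ion.  The evaluators here score classification recovery (sensitivity per
planted class, false-positive rate on planted-unchanged) and collect null
p-values for calibration checks; planted metabolites that the ion
resolution failed to carry into a record count as misses, so the scores
reflect the whole pipeline, not just the t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import SyntheticTruth, feature_to_met_key


@dataclass(frozen=True)
class RecoveryScore:
    sensitivity_uptake: float
    sensitivity_release: float
    false_positive_rate: float
    n_uptake_planted: int
    n_release_planted: int
    n_null_calls: int


def record_truth_map(records) -> dict:
    """pipeline metabolite_id -> planted metabolite key."""
    return {r.metabolite_id: feature_to_met_key(r.characteristic_feature_id) for r in records}


def annotate_calls_with_truth(
    calls: pd.DataFrame, records, truth: SyntheticTruth
) -> pd.DataFrame:
    """Attach planted met_key and planted class to a pipeline calls table.

    ``records=None`` means the calls were made on a truth-level abundance
    table whose metabolite ids already are planted keys.
    """
    out = calls.copy()
    if records is None:
        out["met_key"] = out["metabolite_id"]
    else:
        out["met_key"] = out["metabolite_id"].map(record_truth_map(records))
    planted = {
        (iso, met): cls
        for iso, met, cls in zip(
            truth.classes["isolate_id"], truth.classes["met_key"], truth.classes["class"]
        )
    }
    out["planted_class"] = [
        planted.get((iso, met), "unchanged")
        for iso, met in zip(out["isolate_id"], out["met_key"])
    ]
    abundant = set(truth.metabolites.index[truth.metabolites["abundant"]])
    out["planted_abundant"] = out["met_key"].isin(abundant)
    return out


def score_recovery(calls: pd.DataFrame, records, truth: SyntheticTruth) -> RecoveryScore:
    """Per-call classification recovery on planted-abundant metabolites.

    Sensitivity is scored per (isolate, metabolite, medium) call against the
    planted class; planted uptake/release pairs whose metabolite never made
    it into a resolved record are counted as misses.  The false-positive
    rate is the fraction of planted-unchanged, available calls classified
    as uptake or release.
    """
    ann = annotate_calls_with_truth(calls, records, truth)
    ab = ann[ann["planted_abundant"]]
    n_media = max(1, ann.groupby("isolate_id")["medium_id"].nunique().max())

    up = ab[ab["planted_class"] == "uptake"]
    rel = ab[ab["planted_class"] == "release"]
    null = ab[(ab["planted_class"] == "unchanged") & (ab["call"] != "not_available")]

    tp_up = int((up["call"] == "uptake").sum())
    tp_rel = int((rel["call"] == "release").sum())
    fp = int(null["call"].isin(("uptake", "release")).sum())

    # planted pairs with no resolved record at all: misses
    abundant = set(truth.metabolites.index[truth.metabolites["abundant"]])
    matched = set(ab["met_key"])
    missed_up = missed_rel = 0
    for met, cls in zip(truth.classes["met_key"], truth.classes["class"]):
        if met in abundant and met not in matched:
            if cls == "uptake":
                missed_up += n_media
            else:
                missed_rel += n_media
    n_up = len(up) + missed_up
    n_rel = len(rel) + missed_rel
    return RecoveryScore(
        sensitivity_uptake=tp_up / n_up if n_up else float("nan"),
        sensitivity_release=tp_rel / n_rel if n_rel else float("nan"),
        false_positive_rate=fp / len(null) if len(null) else float("nan"),
        n_uptake_planted=n_up,
        n_release_planted=n_rel,
        n_null_calls=int(len(null)),
    )


def null_pvalues(calls: pd.DataFrame, records, truth: SyntheticTruth) -> np.ndarray:
    """t-test p-values of planted-unchanged, available calls."""
    ann = annotate_calls_with_truth(calls, records, truth)
    mask = (
        ann["planted_abundant"]
        & (ann["planted_class"] == "unchanged")
        & (ann["call"] != "not_available")
    )
    return ann.loc[mask, "p_value"].to_numpy(float)


def truth_niche_sets(truth: SyntheticTruth) -> dict:
    """Niche statistics computed directly from the planted classes.

    Independent of the call matrix: uptake/release sets are read straight
    off ``truth.classes`` restricted to planted-abundant metabolites.
    """
    abundant = list(truth.metabolites.index[truth.metabolites["abundant"]])
    ab = set(abundant)
    cls = truth.classes
    isolates = sorted(cls["isolate_id"].unique())
    up_sets = {
        iso: set(cls[(cls["isolate_id"] == iso) & (cls["class"] == "uptake")]["met_key"]) & ab
        for iso in isolates
    }
    rel_sets = {
        iso: set(cls[(cls["isolate_id"] == iso) & (cls["class"] == "release")]["met_key"]) & ab
        for iso in isolates
    }
    n_users = {m: sum(m in up_sets[i] for i in isolates) for m in abundant}
    hist = {}
    for m, k in n_users.items():
        hist[k] = hist.get(k, 0) + 1
    hist = {k: hist.get(k, 0) for k in range(len(isolates) + 1)}
    all_rel = {m for s in rel_sets.values() for m in s}
    competition = {m for m in abundant if n_users[m] >= 2 and m not in all_rel}
    crossfeed = {
        m
        for m in abundant
        if any(m in rel_sets[r] and any(m in up_sets[u] for u in isolates if u != r) for r in isolates)
    }
    return {
        "isolates": isolates,
        "abundant": abundant,
        "uptake_sets": up_sets,
        "release_sets": rel_sets,
        "per_isolate_fraction": {i: len(up_sets[i]) / len(abundant) for i in isolates},
        "shared_use_histogram": hist,
        "unused_fraction": hist[0] / len(abundant),
        "competition": competition,
        "crossfeeding": crossfeed,
    }
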