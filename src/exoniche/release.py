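"""Cell-extract vs spent-medium release profiling.

Compares a producer strain's intracellular metabolite complement (cell
extract) against its spent minimal medium.  Metabolites detected in the
extract and in the (control-subtracted) spent medium were released;
extract-only metabolites argue against bulk cell lysis as the release
route.  The paired rank-abundance table drives mirror plots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("released", "extract_only", "medium_only", "absent")


@dataclass
class ReleaseProfile:
    classes: pd.Series  # metabolite_id -> class
    release_breadth: float  # released / (released + extract_only)
    table: pd.DataFrame  # metabolite_id, mean_extract, mean_spent_adj, class
    detect_area: float


def classify_release(
    extract: pd.DataFrame,
    spent: pd.DataFrame,
    control: pd.DataFrame,
    detect_area: float = 1000.0,
) -> ReleaseProfile:
    """Classify each metabolite by extract/spent detection.

    All three inputs are metabolite x replicate-sample area tables over the
    same metabolite universe.  Spent areas are control-subtracted (mean
    control of the matching uninoculated medium, floored at 0) before the
    detection gate, so supplement background does not read as release.
    """
    if detect_area <= 0:
        raise ValueError("detect_area must be positive")
    if len(extract.index) == 0:
        raise ValueError("empty metabolite universe")
    if not (extract.index.equals(spent.index) and extract.index.equals(control.index)):
        raise ValueError("extract/spent/control tables must share one metabolite universe")

    mean_ext = extract.mean(axis=1)
    mean_spent = (spent.mean(axis=1) - control.mean(axis=1)).clip(lower=0.0)
    in_ext = mean_ext >= detect_area
    in_spent = mean_spent >= detect_area
    cls = pd.Series("absent", index=extract.index, dtype=object)
    cls[in_ext & in_spent] = "released"
    cls[in_ext & ~in_spent] = "extract_only"
    cls[~in_ext & in_spent] = "medium_only"

    n_rel = int((cls == "released").sum())
    n_only = int((cls == "extract_only").sum())
    breadth = n_rel / (n_rel + n_only) if (n_rel + n_only) else float("nan")
    table = pd.DataFrame(
        {
            "mean_extract": mean_ext,
            "mean_spent_adj": mean_spent,
            "class": cls,
        }
    )
    return ReleaseProfile(cls, breadth, table, detect_area)


def rank_abundance_table(profile: ReleaseProfile) -> pd.DataFrame:
    """Mirror-plot table: descending extract abundance, paired spent areas.

    Ties in extract area break to the smaller metabolite id; rank is
    1-based.
    """
    t = profile.table.copy()
    t = t.sort_index(kind="mergesort").sort_values(
        "mean_extract", ascending=False, kind="mergesort"
    )  # stable: equal areas keep ascending metabolite_id order
    t.insert(0, "rank", np.arange(1, len(t) + 1))
    return t
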