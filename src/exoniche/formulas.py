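"""Molecular-formula assignment from accurate neutral mass.

Exhaustive CHNOPS compositional enumeration within a ppm window, scored by
mass error and (when an observed M+1/M ratio is available) by the fit of the
predicted first-isotopologue abundance.  The C/N/O/P/S grid is enumerated
once per bounds and cached; the hydrogen count is solved per query from the
residual mass, so a single call scans the full composition space in one
vectorised pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .chem import ELEMENT_MASS, ISOTOPE_M1_RATIO, format_formula

#: Upper element-count bounds, suitable for metabolites below ~1,200 Da.
DEFAULT_BOUNDS: dict[str, int] = {"C": 40, "H": 80, "N": 20, "O": 25, "P": 5, "S": 5}

#: Element-ratio plausibility ranges (heuristic bounds covering the vast
#: majority of known organic molecules; ratios are relative to carbon).
RATIO_BOUNDS = {"H": (0.0, 3.1), "N": (0.0, 1.3), "O": (0.0, 2.5), "P": (0.0, 0.3), "S": (0.0, 0.8)}


def plausible_ratios(counts) -> bool:
    """Heuristic element-ratio check (requires carbon)."""
    c = counts.get("C", 0)
    if c < 1:
        return False
    for elem, (lo, hi) in RATIO_BOUNDS.items():
        if not (lo <= counts.get(elem, 0) / c <= hi):
            return False
    return True

#: Weight converting relative M+1 misfit into score units commensurate with
#: ppm mass error (a 10% relative isotope misfit weighs like 10 ppm).
DEFAULT_ISOTOPE_WEIGHT = 100.0

MAX_MASS_DA = 1200.0


@dataclass(frozen=True)
class FormulaCandidate:
    element_counts: dict[str, int] = field(hash=False)
    formula: str
    monoisotopic_mass: float
    mass_error_ppm: float
    isotope_fit_error: float  # |predicted - observed| / observed M+1 ratio; 0 if unused
    rdbe: float
    score: float


@lru_cache(maxsize=8)
def _grid(c_max: int, n_max: int, o_max: int, p_max: int, s_max: int):
    """Flattened C,N,O,P,S count grid with per-row mass and M+1 contribution."""
    c, n, o, p, s = np.meshgrid(
        np.arange(c_max + 1),
        np.arange(n_max + 1),
        np.arange(o_max + 1),
        np.arange(p_max + 1),
        np.arange(s_max + 1),
        indexing="ij",
    )
    counts = np.stack([a.ravel() for a in (c, n, o, p, s)], axis=1).astype(np.int32)
    mass = (
        counts[:, 0] * ELEMENT_MASS["C"]
        + counts[:, 1] * ELEMENT_MASS["N"]
        + counts[:, 2] * ELEMENT_MASS["O"]
        + counts[:, 3] * ELEMENT_MASS["P"]
        + counts[:, 4] * ELEMENT_MASS["S"]
    )
    m1 = (
        counts[:, 0] * ISOTOPE_M1_RATIO["C"]
        + counts[:, 1] * ISOTOPE_M1_RATIO["N"]
        + counts[:, 2] * ISOTOPE_M1_RATIO["O"]
        + counts[:, 4] * ISOTOPE_M1_RATIO["S"]
    )
    return counts, mass, m1


def assign_formula(
    neutral_mass: float,
    m1_ratio: float | None = None,
    bounds: dict[str, int] | None = None,
    mass_tol_ppm: float = 5.0,
    rdbe_min: float | None = 0.0,
    element_ratio_filter: bool = True,
    isotope_weight: float = DEFAULT_ISOTOPE_WEIGHT,
    max_candidates: int | None = None,
) -> list[FormulaCandidate]:
    """Rank CHNOPS formulas for a neutral monoisotopic mass.

    Parameters
    ----------
    neutral_mass
        Target neutral monoisotopic mass in Da (must be positive and below
        1,200 Da; heavier targets return an empty list).
    m1_ratio
        Observed M+1/M intensity ratio of the molecular ion, if measured.
        When given, each candidate's predicted ratio (13C/15N/33S/17O/2H
        contributions) enters the score.
    bounds
        Per-element maximum counts; defaults to ``DEFAULT_BOUNDS``.
    rdbe_min
        Minimum ring-plus-double-bond equivalents; ``None`` disables the
        filter.
    element_ratio_filter
        Drop compositions outside heuristic H/C, N/C, O/C, P/C, S/C ranges
        (and carbon-free compositions); on by default.

    Returns
    -------
    Candidates sorted by ascending score (|ppm error| + weighted isotope
    misfit), ties broken by element counts for determinism.  Empty list when
    no composition fits.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral_mass must be positive")
    if neutral_mass > MAX_MASS_DA:
        return []
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)

    counts, grid_mass, grid_m1 = _grid(b["C"], b["N"], b["O"], b["P"], b["S"])
    tol_da = neutral_mass * mass_tol_ppm * 1e-6
    m_h = ELEMENT_MASS["H"]

    residual = neutral_mass - grid_mass
    h = np.rint(residual / m_h).astype(np.int64)
    feasible = (h >= 0) & (h <= b["H"])
    err_da = residual - h * m_h
    feasible &= np.abs(err_da) <= tol_da
    if rdbe_min is not None:
        rdbe_vals = counts[:, 0] + 1 + 0.5 * (counts[:, 1] + counts[:, 3]) - 0.5 * h
        feasible &= rdbe_vals >= rdbe_min
    if element_ratio_filter:
        c = counts[:, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            feasible &= c >= 1
            feasible &= h <= 3.1 * c
            feasible &= counts[:, 1] <= 1.3 * c  # N
            feasible &= counts[:, 2] <= 2.5 * c  # O
            feasible &= counts[:, 3] <= 0.3 * c  # P
            feasible &= counts[:, 4] <= 0.8 * c  # S
    idx = np.nonzero(feasible)[0]
    if idx.size == 0:
        return []

    out: list[FormulaCandidate] = []
    for i in idx:
        c, n, o, p, s = (int(x) for x in counts[i])
        nh = int(h[i])
        ec = {"C": c, "H": nh, "N": n, "O": o, "P": p, "S": s}
        ec = {e: k for e, k in ec.items() if k > 0}
        mass = float(grid_mass[i] + nh * m_h)
        err_ppm = (mass - neutral_mass) / neutral_mass * 1e6
        pred_m1 = float(grid_m1[i] + nh * ISOTOPE_M1_RATIO["H"])
        if m1_ratio is not None and m1_ratio > 0:
            iso_err = abs(pred_m1 - m1_ratio) / m1_ratio
        else:
            iso_err = 0.0
        score = abs(err_ppm) + (isotope_weight * iso_err if m1_ratio else 0.0)
        out.append(
            FormulaCandidate(
                element_counts=ec,
                formula=format_formula(ec),
                monoisotopic_mass=mass,
                mass_error_ppm=err_ppm,
                isotope_fit_error=iso_err,
                rdbe=float(c + 1 + 0.5 * (n + p) - 0.5 * nh),
                score=score,
            )
        )
    out.sort(key=lambda f: (f.score, tuple(f.element_counts.get(e, 0) for e in "CHNOPS")))
    if max_candidates is not None:
        out = out[:max_candidates]
    return out
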