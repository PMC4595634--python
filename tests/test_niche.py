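"""Niche statistics: fractions, shared use, competition, cross-feeding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exoniche.niche import (
    build_utilization_matrix,
    competition_candidates,
    crossfeeding_candidates,
    export_bipartite,
    niche_summary,
    pairwise_overlap,
    per_isolate_fraction,
    percent,
    shared_use_distribution,
)
from exoniche.validate import truth_niche_sets


def matrix_from_cells(cells, abundant=None, extra_consensus=()):
    """cells: {isolate: [call per metabolite]} over metabolites m1..mK."""
    isolates = list(cells)
    n = len(next(iter(cells.values())))
    mets = [f"m{i + 1}" for i in range(n)]
    rows = [
        {"isolate_id": iso, "metabolite_id": m, "call": c, "p_value": 0.01, "flags": ""}
        for iso, calls in cells.items()
        for m, c in zip(mets, calls)
    ]
    rows += list(extra_consensus)
    return build_utilization_matrix(pd.DataFrame(rows), abundant or mets, isolates)


class TestMatrix:
    def test_direct_construction(self):
        m = matrix_from_cells(
            {"A": ["uptake", "uptake", "unchanged"], "B": ["unchanged", "uptake", "release"]}
        )
        assert m.calls.shape == (2, 3) and m.denominator == 3

    def test_released_novel_tracked_separately(self):
        extra = [
            {"isolate_id": "A", "metabolite_id": "novel", "call": "release",
             "p_value": 0.001, "flags": ""},
            {"isolate_id": "B", "metabolite_id": "novel", "call": "not_available",
             "p_value": 1.0, "flags": ""},
        ]
        m = matrix_from_cells(
            {"A": ["uptake"], "B": ["unchanged"]}, abundant=["m1"], extra_consensus=extra
        )
        assert "novel" not in m.calls.columns
        assert m.released_novel == {"novel"}

    def test_empty_isolates_rejected(self):
        with pytest.raises(ValueError):
            build_utilization_matrix(pd.DataFrame(columns=["isolate_id", "metabolite_id", "call", "flags"]), ["m1"], [])

    def test_missing_pair_rejected_with_gap_listed(self):
        rows = pd.DataFrame(
            [{"isolate_id": "A", "metabolite_id": "m1", "call": "uptake", "p_value": 0.01,
              "flags": ""}]
        )
        with pytest.raises(ValueError, match="m2"):
            build_utilization_matrix(rows, ["m1", "m2"], ["A"])


class TestFractions:
    def test_rounding_convention_70_of_372(self):
        """70/372 prints as 19% under round-half-away-from-zero."""
        assert percent(70 / 372) == 19

    def test_fraction_values(self):
        m = matrix_from_cells({"A": ["uptake"] * 3, "B": ["unchanged"] * 3})
        f = per_isolate_fraction(m)
        assert f["A"] == 1.0 and f["B"] == 0.0

    def test_fraction_with_mixed_row(self):
        m = matrix_from_cells({"A": ["uptake", "release", "unchanged", "uptake"]})
        assert per_isolate_fraction(m)["A"] == pytest.approx(0.5)


class TestSharedUse:
    def test_histogram_example(self):
        m = matrix_from_cells(
            {"A": ["unchanged", "uptake", "uptake"], "B": ["unchanged", "uptake", "uptake"]}
        )
        hist, cum = shared_use_distribution(m)
        assert hist == {0: 1, 1: 0, 2: 2}
        assert cum == {0: 3, 1: 2, 2: 2}

    def test_histogram_sums_to_denominator(self, default_result):
        hist, _ = shared_use_distribution(default_result.matrix)
        assert sum(hist.values()) == default_result.matrix.denominator


class TestCandidateSets:
    def test_competition_definition(self):
        m = matrix_from_cells(
            {"A": ["uptake", "uptake"], "B": ["uptake", "uptake"], "C": ["unchanged", "release"]}
        )
        assert competition_candidates(m) == {"m1"}

    def test_crossfeeding_requires_distinct_isolates(self):
        m = matrix_from_cells(
            {"A": ["release", "unchanged"], "B": ["uptake", "uptake"]}
        )
        assert crossfeeding_candidates(m) == {"m1"}
        m2 = matrix_from_cells({"A": ["uptake"], "B": ["unchanged"]})
        assert crossfeeding_candidates(m2) == set()

    def test_sets_disjoint_on_pipeline_output(self, default_result):
        comp = competition_candidates(default_result.matrix)
        cross = crossfeeding_candidates(default_result.matrix)
        assert comp & cross == set()

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 99_999))
    def test_disjoint_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n_iso, n_met = int(rng.integers(1, 6)), int(rng.integers(1, 15))
        calls = rng.choice(
            ["uptake", "release", "unchanged", "not_available"], (n_iso, n_met)
        )
        m = matrix_from_cells({f"i{k}": list(calls[k]) for k in range(n_iso)})
        comp, cross = competition_candidates(m), crossfeeding_candidates(m)
        assert comp & cross == set()
        hist, _ = shared_use_distribution(m)
        assert sum(hist.values()) == n_met


class TestOverlap:
    def test_jaccard_example(self):
        m = matrix_from_cells(
            {
                "A": ["uptake", "uptake", "uptake", "unchanged"],
                "B": ["unchanged", "unchanged", "uptake", "uptake"],
            }
        )
        ov = pairwise_overlap(m, "jaccard")
        assert ov.loc["A", "B"] == pytest.approx(0.25)
        assert ov.loc["A", "A"] == 1.0

    def test_identical_and_disjoint_sets(self):
        m = matrix_from_cells({"A": ["uptake", "unchanged"], "B": ["unchanged", "uptake"]})
        assert pairwise_overlap(m, "jaccard").loc["A", "B"] == 0.0
        m2 = matrix_from_cells({"A": ["uptake"], "B": ["uptake"]})
        assert pairwise_overlap(m2, "jaccard").loc["A", "B"] == 1.0

    def test_simpson_dominates_jaccard(self, default_result):
        j = pairwise_overlap(default_result.matrix, "jaccard").to_numpy()
        s = pairwise_overlap(default_result.matrix, "simpson").to_numpy()
        assert (s >= j - 1e-12).all()
        assert ((0 <= j) & (j <= 1)).all() and ((0 <= s) & (s <= 1)).all()


class TestBipartite:
    def test_edge_types(self):
        m = matrix_from_cells({"A": ["uptake", "unchanged"], "B": ["unchanged", "release"]})
        g, edges = export_bipartite(m)
        assert len(edges) == 2
        assert set(edges["type"]) == {"utilization", "release"}

    def test_no_informative_cells_no_edges(self):
        m = matrix_from_cells({"A": ["not_available", "unchanged"]})
        g, edges = export_bipartite(m)
        assert len(edges) == 0

    def test_edge_count_conservation(self, default_result):
        m = default_result.matrix
        _, edges = export_bipartite(m)
        n_up = int(m.uptake_mask().to_numpy().sum())
        n_rel = int(m.release_mask().to_numpy().sum())
        assert len(edges) == n_up + n_rel


class TestTruthIdentity:
    def test_statistics_from_injected_truth_calls(self, default_experiment):
        """Matrix built from planted calls reproduces truth statistics exactly."""
        _, _, truth = default_experiment
        direct = truth_niche_sets(truth)
        consensus = truth.consensus_truth()
        matrix = build_utilization_matrix(
            consensus, direct["abundant"], direct["isolates"]
        )
        assert per_isolate_fraction(matrix) == direct["per_isolate_fraction"]
        hist, _ = shared_use_distribution(matrix)
        assert hist == direct["shared_use_histogram"]
        assert competition_candidates(matrix) == direct["competition"]
        assert crossfeeding_candidates(matrix) == direct["crossfeeding"]
        summary = niche_summary(matrix)
        assert summary["unused_fraction"] == pytest.approx(direct["unused_fraction"])
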