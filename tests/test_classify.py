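"""Uptake/release classification: t-test, abundance filter, consensus."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exoniche.classify import (
    ClassifyParams,
    classify_experiment,
    classify_utilization,
    combine_across_media,
    filter_abundant,
    significance_tier,
    two_sample_t,
    two_sample_t_flagged,
)
from exoniche.io import validate_sample_metadata
from exoniche.simulate import UTILIZATION_MEDIA, expected_abundance
from exoniche.validate import score_recovery


def closed_form_t(a, b):
    """Textbook pooled-variance two-sample t, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def small_meta(n_rep=3):
    rows = []
    for r in range(1, n_rep + 1):
        rows.append((f"c{r}", "control", None, "m1", "cg1", None, r))
        rows.append((f"s{r}", "spent", "isoA", "m1", "cg1", None, r))
    return validate_sample_metadata(
        pd.DataFrame(
            rows,
            columns=[
                "sample_id", "role", "isolate_id", "medium_id",
                "control_group_id", "timepoint_min", "replicate",
            ],
        )
    )


class TestTwoSampleT:
    def test_identical_samples_p_one(self):
        t, p = two_sample_t((10, 11, 9), (10, 11, 9))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_large_separation_significant(self):
        t, p = two_sample_t((10000, 11000, 9000), (100, 120, 90))
        assert p < 0.001

    def test_symmetry(self):
        t1, p1 = two_sample_t((5, 6), (7, 9))
        t2, p2 = two_sample_t((7, 9), (5, 6))
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_zero_variance(self):
        t, p, degen = two_sample_t_flagged((5, 5, 5), (7, 7, 7))
        assert p == 0.0 and degen
        t, p, degen = two_sample_t_flagged((5, 5), (5, 5))
        assert p == 1.0 and not degen

    def test_matches_closed_form_on_random_samples(self):
        """1e-10 agreement with the textbook formula, 100 random draws."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            a = rng.lognormal(rng.uniform(2, 8), rng.uniform(0.1, 1), int(rng.integers(2, 9)))
            b = rng.lognormal(rng.uniform(2, 8), rng.uniform(0.1, 1), int(rng.integers(2, 9)))
            t_ours, p_ours = two_sample_t(a, b)
            t_ref, p_ref = closed_form_t(a, b)
            assert t_ours == pytest.approx(t_ref, abs=1e-10)
            assert p_ours == pytest.approx(p_ref, abs=1e-10)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            two_sample_t([1.0], [2.0, 3.0])


class TestFilterAbundant:
    def _table(self, control_areas):
        meta = small_meta()
        data = {f"c{i+1}": [a] for i, a in enumerate(control_areas)}
        data.update({f"s{i+1}": [0.0] for i in range(3)})
        return pd.DataFrame(data, index=pd.Index(["m"], name="metabolite_id")), meta

    def test_strict_threshold_boundary(self):
        ab, meta = self._table([4999, 4998, 4500])
        assert list(filter_abundant(ab, meta, 5000)) == []

    def test_any_single_control_sample_suffices(self):
        ab, meta = self._table([0, 0, 6000])
        assert list(filter_abundant(ab, meta, 5000)) == ["m"]

    def test_group_mean_mode_is_stricter(self):
        ab, meta = self._table([0, 0, 6000])
        assert list(filter_abundant(ab, meta, 5000, mode="group_mean")) == []

    def test_no_controls_is_an_error(self):
        ab, meta = self._table([0, 0, 6000])
        spent_only = meta[meta["role"] == "spent"]
        with pytest.raises(ValueError, match="control"):
            filter_abundant(ab, spent_only, 5000)

    def test_planted_abundant_set_recovered_exactly(self, default_experiment):
        """The 5,000-count filter returns exactly the planted 372."""
        _, meta, truth = default_experiment
        ab = expected_abundance(truth, meta)
        # noise-free truth table -> the filter must match the planted flag
        got = set(filter_abundant(ab, meta, 5000))
        planted = set(truth.metabolites.index[truth.metabolites["abundant"]])
        assert got == planted and len(got) == 372


class TestClassifyUtilization:
    def _abundance(self, control, spent):
        idx = pd.Index(["m"], name="metabolite_id")
        data = {f"c{i+1}": [c] for i, c in enumerate(control)}
        data.update({f"s{i+1}": [s] for i, s in enumerate(spent)})
        return pd.DataFrame(data, index=idx)

    def test_strong_depletion_is_uptake(self):
        ab = self._abundance((10000, 11000, 9000), (100, 120, 90))
        call = classify_utilization("m", "isoA", "m1", ab, small_meta())
        assert call.call == "uptake" and call.significance_tier == "***"

    def test_denovo_release_without_control_detection(self):
        ab = self._abundance((0, 0, 0), (8000, 9000, 7000))
        call = classify_utilization("m", "isoA", "m1", ab, small_meta())
        assert call.call == "release"
        assert "release_below_control_detection" in call.flags
        assert call.fold_change == np.inf

    def test_small_shift_is_unchanged(self):
        ab = self._abundance((10000, 11000, 9000), (9500, 10500, 9800))
        call = classify_utilization("m", "isoA", "m1", ab, small_meta())
        assert call.call == "unchanged"

    def test_below_both_gates_not_available(self):
        ab = self._abundance((200, 250, 180), (300, 310, 290))
        call = classify_utilization("m", "isoA", "m1", ab, small_meta())
        assert call.call == "not_available"

    def test_negative_areas_rejected(self):
        ab = self._abundance((100, -5, 100), (1, 2, 3))
        with pytest.raises(ValueError, match="negative"):
            classify_utilization("m", "isoA", "m1", ab, small_meta())

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_direction_invariant_and_alpha_monotonicity(self, seed):
        """Calls never contradict their mean direction; raising alpha never
        turns an uptake/release into unchanged."""
        rng = np.random.default_rng(seed)
        ab = self._abundance(rng.lognormal(9, 0.5, 3), rng.lognormal(9, 0.8, 3))
        meta = small_meta()
        lo = classify_utilization("m", "isoA", "m1", ab, meta, ClassifyParams(alpha=0.01))
        hi = classify_utilization("m", "isoA", "m1", ab, meta, ClassifyParams(alpha=0.10))
        for call in (lo, hi):
            if call.call == "uptake":
                assert call.mean_spent < call.mean_control
            if call.call == "release":
                assert call.mean_spent > call.mean_control
        if lo.call in ("uptake", "release"):
            assert hi.call == lo.call


class TestConsensus:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["isolate_id", "metabolite_id", "medium_id", "call", "p_value",
                     "fold_change", "mean_control", "mean_spent", "tier", "flags"],
        )

    def test_informative_beats_unchanged(self):
        calls = self._calls(
            [("A", "m", "m1", "uptake", 0.001, 0.1, 100, 10, "***", ""),
             ("A", "m", "m2", "unchanged", 0.5, 1.0, 100, 100, "ns", "")]
        )
        out = combine_across_media(calls)
        assert out.loc[0, "call"] == "uptake"

    def test_conflict_resolves_to_smaller_p(self):
        calls = self._calls(
            [("A", "m", "m1", "uptake", 0.01, 0.1, 100, 10, "*", ""),
             ("A", "m", "m2", "release", 0.04, 5.0, 100, 500, "*", "")]
        )
        out = combine_across_media(calls)
        assert out.loc[0, "call"] == "uptake"
        assert "conflict" in out.loc[0, "flags"]

    def test_single_informative_call_wins(self):
        calls = self._calls(
            [("A", "m", "m1", "not_available", 1.0, 1.0, 0, 0, "ns", ""),
             ("A", "m", "m2", "release", 0.002, 9.0, 100, 900, "**", "")]
        )
        assert combine_across_media(calls).loc[0, "call"] == "release"

    def test_all_not_available(self):
        calls = self._calls(
            [("A", "m", "m1", "not_available", 1.0, 1.0, 0, 0, "ns", ""),
             ("A", "m", "m2", "not_available", 1.0, 1.0, 0, 0, "ns", "")]
        )
        assert combine_across_media(calls).loc[0, "call"] == "not_available"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_across_media(self._calls([]))


def test_tiers():
    assert significance_tier(0.0005) == "***"
    assert significance_tier(0.005) == "**"
    assert significance_tier(0.03) == "*"
    assert significance_tier(0.2) == "ns"


def test_noiseless_limit_recovers_planted_classes(small_experiment):
    """CV 0: sensitivity 1.0 and FPR 0 via the degenerate-variance rule."""
    from exoniche.simulate import GeneratorConfig, generate_experiment
    from conftest import SMALL_CONFIG

    cfg = GeneratorConfig(seed=11, noise_cv=0.0, feature_noise_cv=0.0, **SMALL_CONFIG)
    _, meta, truth = generate_experiment(cfg)
    ab = expected_abundance(truth, meta)
    calls = classify_experiment(ab, meta, ClassifyParams(), media=list(UTILIZATION_MEDIA))
    score = score_recovery(calls, None, truth)
    assert score.sensitivity_uptake == 1.0
    assert score.sensitivity_release == 1.0
    assert score.false_positive_rate == 0.0


def test_vectorised_path_agrees_with_scalar(default_experiment, default_result):
    """Spot-check classify_experiment rows against classify_utilization."""
    table, meta, _ = default_experiment
    calls = default_result.calls
    rng = np.random.default_rng(0)
    for i in rng.choice(len(calls), 25, replace=False):
        row = calls.iloc[int(i)]
        single = classify_utilization(
            row["metabolite_id"], row["isolate_id"], row["medium_id"],
            default_result.abundance, meta,
        )
        assert single.call == row["call"]
        assert single.p_value == pytest.approx(row["p_value"], abs=1e-12, nan_ok=True)
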