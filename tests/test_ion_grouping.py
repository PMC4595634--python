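"""Ion grouping: co-elution clustering, ion-type assignment, polarity merge."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from exoniche.chem import DEFAULT_ADDUCT_RULES, PROTON_MASS
from exoniche.io import FeatureTable
from exoniche.ion_grouping import (
    IonGroup,
    abundance_table,
    annotate_groups,
    assign_ion_types,
    estimate_m1_ratio,
    group_coeluting_features,
    merge_polarities,
    select_characteristic_ion,
)
from exoniche.simulate import feature_to_met_key

from conftest import make_feature_table


def brute_force_groups(table, rt_tol=0.3, corr_min=0.9):
    """Oracle: transitive closure of the pairwise gate over all pairs."""
    fids = list(table.features.index)
    X = {f: table.intensities.loc[f].to_numpy(float) for f in fids}
    adj = {f: set() for f in fids}
    for i, a in enumerate(fids):
        for b in fids[i + 1 :]:
            fa, fb = table.features.loc[a], table.features.loc[b]
            if fa["polarity"] != fb["polarity"]:
                continue
            if abs(fa["rt"] - fb["rt"]) > rt_tol:
                continue
            sup = (X[a] > 0) | (X[b] > 0)
            if sup.sum() < 3:
                continue
            xa, xb = X[a][sup], X[b][sup]
            if xa.std() == 0 or xb.std() == 0:
                continue
            if np.corrcoef(xa, xb)[0, 1] >= corr_min:
                adj[a].add(b)
                adj[b].add(a)
    seen, comps = set(), []
    for f in fids:
        if f in seen:
            continue
        stack, comp = [f], set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


class TestGrouping:
    def test_proportional_coeluting_pair_groups(self):
        table = make_feature_table(
            {"a": (100.0, 10.0, "positive"), "b": (200.0, 10.1, "positive")},
            [[1000, 2000, 3000], [100, 200, 300]],
        )
        groups = group_coeluting_features(table, rt_tol=0.3, corr_min=0.9)
        assert len(groups) == 1 and set(groups[0].feature_ids) == {"a", "b"}

    def test_rt_gate_splits(self):
        table = make_feature_table(
            {"a": (100.0, 10.0, "positive"), "b": (200.0, 12.0, "positive")},
            [[1000, 2000, 3000], [100, 200, 300]],
        )
        groups = group_coeluting_features(table, rt_tol=0.3, corr_min=0.9)
        assert len(groups) == 2

    def test_polarity_never_mixes(self):
        table = make_feature_table(
            {"a": (100.0, 10.0, "positive"), "b": (200.0, 10.0, "negative")},
            [[1000, 2000, 3000], [100, 200, 300]],
        )
        assert len(group_coeluting_features(table)) == 2

    def test_all_zero_features_become_flagged_singletons(self):
        table = make_feature_table(
            {"a": (100.0, 10.0, "positive"), "z": (101.0, 10.0, "positive")},
            [[1000, 2000, 3000], [0, 0, 0]],
        )
        groups = group_coeluting_features(table)
        flags = {tuple(g.feature_ids): g.flags for g in groups}
        assert ("z",) in flags and "all_zero" in flags[("z",)]

    def test_planted_adduct_groups_match_bruteforce(self):
        """12 features from 4 planted metabolites, 3 adducts each, CV 5%."""
        rng = np.random.default_rng(0)
        rows, inten = {}, []
        for k in range(4):
            base = 10 ** rng.uniform(3.5, 5)
            rt = 5 + k * 1.0
            sample_profile = np.exp(0.5 * rng.standard_normal(8))
            for a, rel in enumerate([1.0, 0.4, 0.1]):
                rows[f"m{k}_f{a}"] = (100.0 + 30 * k + 20 * a, rt, "positive")
                inten.append(base * rel * sample_profile * np.exp(0.05 * rng.standard_normal(8)))
        table = make_feature_table(rows, inten)
        groups = group_coeluting_features(table)
        got = {frozenset(g.feature_ids) for g in groups}
        planted = {frozenset(f"m{k}_f{a}" for a in range(3)) for k in range(4)}
        assert got == planted == brute_force_groups(table)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_bruteforce_on_random_instances(self, seed):
        """Oracle equivalence on random <=20-feature instances."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 21))
        n_samples = int(rng.integers(3, 9))
        rows, inten = {}, []
        for i in range(n):
            rows[f"f{i:02d}"] = (
                float(rng.uniform(80, 600)),
                float(rng.uniform(0, 3)),
                str(rng.choice(["positive", "negative"])),
            )
            x = rng.lognormal(rng.uniform(3, 10), rng.uniform(0.1, 1.0), n_samples)
            x[rng.random(n_samples) < 0.3] = 0.0
            inten.append(x)
        table = make_feature_table(rows, inten)
        groups = group_coeluting_features(table)
        assert {frozenset(g.feature_ids) for g in groups} == brute_force_groups(table)
        # partition property
        all_members = [f for g in groups for f in g.feature_ids]
        assert sorted(all_members) == sorted(rows)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        rows = {
            f"f{i}": (float(rng.uniform(80, 500)), float(rng.uniform(0, 2)), "positive")
            for i in range(12)
        }
        inten = rng.lognormal(6, 1, (12, 6))
        table = make_feature_table(rows, inten)
        perm = list(rng.permutation(list(rows)))
        shuffled = FeatureTable(table.features.loc[perm], table.intensities.loc[perm])
        g1 = {frozenset(g.feature_ids) for g in group_coeluting_features(table)}
        g2 = {frozenset(g.feature_ids) for g in group_coeluting_features(shuffled)}
        assert g1 == g2


class TestIonTypes:
    def test_proton_and_ammonium_pair(self):
        """m/z 331.1445 + 348.1710 -> one neutral mass ~330.1372."""
        table = make_feature_table(
            {"h": (331.1445, 8.0, "positive"), "nh4": (348.1710, 8.0, "positive")},
            [[5000, 6000, 7000], [1000, 1200, 1400]],
        )
        g = IonGroup(1, ["h", "nh4"], "positive", 8.0)
        assign_ion_types(g, table)
        assert g.annotations["h"] == "[M+H]+"
        assert g.annotations["nh4"] == "[M+NH4]+"
        assert g.neutral_mass == pytest.approx(330.1372, abs=2e-4)

    def test_single_protonated_ion(self):
        """The unknown at m/z 330.1445 (positive) implies M = 329.1372."""
        table = make_feature_table({"x": (330.1445, 5.0, "positive")}, [[100, 200, 300]])
        g = IonGroup(1, ["x"], "positive", 5.0)
        assign_ion_types(g, table)
        assert g.neutral_mass == pytest.approx(330.1445 - PROTON_MASS, abs=1e-9)

    def test_proton_bound_dimer(self):
        """m/z 181.0707 + 361.1341 -> M = 180.0634 via [M+H]+ and [2M+H]+."""
        table = make_feature_table(
            {"h": (181.0707, 3.0, "positive"), "dim": (361.1341, 3.0, "positive")},
            [[9000, 9500, 8800], [500, 520, 480]],
        )
        g = IonGroup(1, ["h", "dim"], "positive", 3.0)
        assign_ion_types(g, table)
        assert g.annotations["dim"] == "[2M+H]+"
        assert g.neutral_mass == pytest.approx(180.0634, abs=2e-4)

    def test_unexplained_member_is_fragment(self):
        table = make_feature_table(
            {"h": (181.0707, 3.0, "positive"), "frag": (110.0500, 3.0, "positive")},
            [[9000, 9500, 8800], [700, 650, 720]],
        )
        g = IonGroup(1, ["h", "frag"], "positive", 3.0)
        assign_ion_types(g, table)
        assert g.annotations["frag"] == "unassigned fragment"
        assert g.neutral_mass == pytest.approx(180.0634, abs=2e-4)

    def test_zero_noise_roundtrip(self):
        """Planted neutral mass is recovered to <1e-9 with exact m/z."""
        M = 247.0936
        rules = DEFAULT_ADDUCT_RULES
        pos = [r for r in rules if r.polarity == "positive"]
        rows = {
            f"a{i}": (rule.mz_from_neutral(M), 4.0, "positive") for i, rule in enumerate(pos)
        }
        table = make_feature_table(rows, [[1000, 1100, 900]] * len(rows))
        g = IonGroup(1, list(rows), "positive", 4.0)
        assign_ion_types(g, table, rules)
        assert g.neutral_mass == pytest.approx(M, abs=1e-9)
        assert all(v != "unassigned fragment" for v in g.annotations.values())


class TestCharacteristicIon:
    def _group(self, table, annotations):
        g = IonGroup(1, list(table.features.index), "positive", 1.0)
        g.annotations = annotations
        return g

    def test_prefers_characteristic_adduct(self):
        table = make_feature_table(
            {"h": (181.07, 1.0, "positive"), "na": (203.05, 1.0, "positive")},
            [[2000, 2000, 2000], [10000, 10000, 10000]],
        )
        g = self._group(table, {"h": "[M+H]+", "na": "[M+Na]+"})
        assert select_characteristic_ion(g, table) == "h"

    def test_falls_back_to_highest_median(self):
        table = make_feature_table(
            {"a": (181.07, 1.0, "positive"), "b": (203.05, 1.0, "positive")},
            [[500, 500, 500], [700, 700, 700]],
        )
        g = self._group(table, {"a": "unassigned fragment", "b": "unassigned fragment"})
        assert select_characteristic_ion(g, table) == "b"

    def test_median_tie_breaks_to_lower_mz(self):
        table = make_feature_table(
            {"hi": (300.2, 1.0, "positive"), "lo": (200.1, 1.0, "positive")},
            [[5000, 5000, 5000], [5000, 5000, 5000]],
        )
        g = self._group(table, {"hi": "[M+H]+", "lo": "[M+H]+"})
        assert select_characteristic_ion(g, table) == "lo"


class TestMergePolarities:
    def _tables_and_groups(self, rt_neg=8.05):
        M = 147.0532
        mz_pos = M + PROTON_MASS
        mz_neg = M - PROTON_MASS
        table = make_feature_table(
            {"p": (mz_pos, 8.0, "positive"), "n": (mz_neg, rt_neg, "negative")},
            [[9000, 9100, 8900], [4000, 4100, 3900]],
        )
        groups = group_coeluting_features(table)
        annotate_groups(groups, table)
        return table, groups

    def test_merges_matching_masses(self):
        table, groups = self._tables_and_groups()
        records = merge_polarities(groups, table, mass_tol=0.005, rt_tol=0.3)
        assert len(records) == 1
        assert records[0].n_member_ions == 2
        assert len(records[0].source_groups) == 2

    def test_rt_gate_blocks_merge(self):
        table, groups = self._tables_and_groups(rt_neg=9.0)
        records = merge_polarities(groups, table, mass_tol=0.005, rt_tol=0.3)
        assert len(records) == 2

    def test_distinct_masses_stay_separate(self):
        rng = np.random.default_rng(5)
        rows, inten = {}, []
        for i in range(6):
            rows[f"f{i}"] = (100.0 + 7 * i, 1.0 + 0.05 * i, "positive" if i % 2 else "negative")
            inten.append(rng.lognormal(8, 0.3, 4))
        table = make_feature_table(rows, inten)
        groups = group_coeluting_features(table, corr_min=0.999)
        annotate_groups(groups, table)
        records = merge_polarities(groups, table)
        assert len(records) == len(groups)

    def test_metabolite_ids_sequential_and_unique(self, default_result):
        ids = [r.metabolite_id for r in default_result.records]
        assert ids == list(range(1, len(ids) + 1))


class TestPipelineLevel:
    def test_partition_of_all_features(self, default_experiment, default_result):
        table, _, _ = default_experiment
        members = [f for g in default_result.groups for f in g.feature_ids]
        assert sorted(members) == sorted(table.features.index)

    def test_groups_mostly_pure(self, default_experiment, default_result):
        """Co-elution collisions exist but stay rare (<8% of groups)."""
        impure = sum(
            1
            for g in default_result.groups
            if len({feature_to_met_key(f) for f in g.feature_ids}) > 1
        )
        assert impure / len(default_result.groups) < 0.08

    def test_abundance_table_is_characteristic_ion_rows(self, default_experiment, default_result):
        table, _, _ = default_experiment
        ab = abundance_table(default_result.records, table)
        rec = default_result.records[0]
        assert np.array_equal(
            ab.loc[rec.metabolite_id].to_numpy(),
            table.intensities.loc[rec.characteristic_feature_id].to_numpy(),
        )

    def test_m1_ratio_estimate_close_to_planted(self, default_experiment, default_result):
        table, _, truth = default_experiment
        group_by_id = {g.group_id: g for g in default_result.groups}
        checked = 0
        for r in default_result.records[:200]:
            est = None
            for gid in r.source_groups:
                est = estimate_m1_ratio(group_by_id[gid], table)
                if est is not None:
                    break
            if est is None:
                continue
            met = feature_to_met_key(r.characteristic_feature_id)
            planted = truth.metabolites.loc[met, "m1_ratio"]
            if abs(est - planted) / planted < 0.25:
                checked += 1
        assert checked >= 20  # plenty of records carry a usable isotopologue
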