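"""FPKM arithmetic, DE thresholds, BH, Venn, clustering and patterns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from folliscan.core import FolliscanError, SampleDesign
from folliscan.expression import (
    ComparisonResult,
    ExpressionTable,
    assign_pattern_group,
    benjamini_hochberg,
    compute_fpkm,
    differential_expression,
    hierarchical_cluster_samples,
    kmeans_patterns,
    run_all_comparisons,
    standardize_profiles,
    venn_stage_specific,
)
from folliscan.simulate import generate_de_benchmark, pattern_stage_means

from _oracles import bh_formula, fpkm_two_loops, venn_powerset

DESIGN = SampleDesign()


def _table(values: np.ndarray, ids=None) -> ExpressionTable:
    ids = ids or [f"f{i}" for i in range(len(values))]
    return ExpressionTable(
        pd.DataFrame(values, index=ids, columns=DESIGN.samples), DESIGN
    )


class TestFpkm:
    def test_definition_arithmetic(self):
        counts = pd.DataFrame(
            {"s1": [100, 9_999_900]}, index=["f1", "filler"]
        )
        fpkm = compute_fpkm(counts, {"f1": 2000, "filler": 1000})
        # 100 / (2 kb * 10 M fragments) = 5.0
        assert fpkm.loc["f1", "s1"] == pytest.approx(5.0)

    def test_zero_count_gives_zero(self):
        counts = pd.DataFrame({"s1": [0, 10]}, index=["a", "b"])
        assert compute_fpkm(counts, {"a": 500, "b": 500}).loc["a", "s1"] == 0.0

    def test_matches_two_loop_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 1000, size=(20, 6)) + 1
        lengths = rng.integers(200, 5000, size=20)
        df = pd.DataFrame(counts, index=[f"f{i}" for i in range(20)],
                          columns=[f"s{j}" for j in range(6)])
        got = compute_fpkm(df, {f"f{i}": lengths[i] for i in range(20)})
        want = fpkm_two_loops(counts.tolist(), lengths.tolist())
        assert np.allclose(got.values, want)

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame({"good": [5], "empty": [0]}, index=["f"])
        with pytest.raises(FolliscanError, match="empty"):
            compute_fpkm(counts, {"f": 1000})


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        assert np.allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.2] * 7), [0.2] * 7)

    def test_out_of_range_rejected(self):
        with pytest.raises(FolliscanError):
            benjamini_hochberg([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_formula_and_permutation_invariance(self, p):
        got = benjamini_hochberg(p)
        assert np.allclose(got, bh_formula(p))
        # invariant to input permutation
        perm = np.random.default_rng(0).permutation(len(p))
        got_perm = benjamini_hochberg([p[i] for i in perm])
        assert np.allclose(np.array(got)[perm], got_perm)
        # monotone non-decreasing on the sorted p scale
        order = np.argsort(p, kind="stable")
        assert (np.diff(np.array(got)[order]) >= -1e-12).all()


class TestDifferentialExpression:
    def test_identical_groups_not_de(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 50, size=(10, 3))
        values = np.hstack([np.tile(base[:, :3], 6)])
        tab = _table(values)
        res = differential_expression(tab, ("E85", "E65"))
        assert np.allclose(res.table.log2fc, 0)
        assert not res.table.de.any()

    def test_flag_is_conjunction_of_printed_thresholds(self):
        rng = np.random.default_rng(1)
        tab = _table(rng.uniform(0, 400, size=(300, 18)))
        res = differential_expression(tab, ("D30", "E65"))
        want = (res.table.padj <= 0.05) & (res.table.log2fc.abs() >= 2)
        assert (res.table.de == want).all()
        de = res.table[res.table.de]
        assert ((de.direction == "up") == (de.log2fc > 0)).all()

    def test_constant_zero_feature_is_null(self):
        values = np.zeros((2, 18))
        values[1] = 10.0
        res = differential_expression(_table(values), ("E85", "E65"))
        assert res.table.loc["f0", "p"] == 1.0
        assert res.table.loc["f0", "log2fc"] == 0.0

    def test_planted_recovery_and_null_control(self):
        """>= 90% of planted 8-fold changes flagged; <= 5% false flags."""
        tab, truth = generate_de_benchmark(seed=1, n_de=200, n_null=200)
        recovered = tested = 0
        false_flags = nulls = 0
        for res in run_all_comparisons(tab):
            col = truth[f"de_{res.label}"]
            de = res.table.de
            direction = res.table.direction
            planted = col[col != "null"]
            for fid, want in planted.items():
                tested += 1
                recovered += bool(de[fid]) and direction[fid] == want
            null_ids = col.index[col == "null"]
            nulls += len(null_ids)
            false_flags += int(de[null_ids].sum())
        assert tested >= 200
        assert recovered / tested >= 0.90
        assert false_flags / nulls <= 0.05

    def test_type_one_control_under_global_null(self):
        """Flagged fraction <= 5% on 200 pure-noise features."""
        tab, _ = generate_de_benchmark(seed=1, n_de=0, n_null=200)
        for res in run_all_comparisons(tab):
            assert res.table.de.mean() <= 0.05


class TestVenn:
    def _fake_results(self, sets):
        labels = [(f"S{i}", "C") for i in range(len(sets))]
        out = []
        for (trt, ctl), s in zip(labels, sets):
            universe = sorted(set().union(*sets) | {"pad"})
            table = pd.DataFrame(
                {
                    "log2fc": 0.0, "p": 1.0, "padj": 1.0,
                    "de": [x in s for x in universe],
                    "direction": "null",
                },
                index=universe,
            )
            out.append(ComparisonResult(comparison=(trt, ctl), table=table))
        return out

    def test_stage_specific_definition(self):
        results = self._fake_results([{"a", "b"}, {"b", "c"}])
        venn = venn_stage_specific(results)
        assert venn.stage_specific["S0-VS-C"] == {"a"}
        assert venn.stage_specific["S1-VS-C"] == {"c"}

    def test_regions_match_power_set_oracle(self):
        rng = np.random.default_rng(3)
        universe = [f"x{i}" for i in range(40)]
        sets = [
            {x for x in universe if rng.random() < 0.3} for _ in range(6)
        ]
        venn = venn_stage_specific(self._fake_results(sets))
        assert venn.regions == venn_powerset(sets)
        assert sum(venn.regions.values()) == venn.union_size


class TestHierarchicalClustering:
    def test_duplicated_samples_merge_first(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0, 50, size=(10, 18))
        values[:, 1] = values[:, 0]  # duplicate E65-2 := E65-1
        tab = _table(values)
        dendro = hierarchical_cluster_samples(tab)
        first = dendro.linkage[0]
        merged = {dendro.labels[int(first[0])], dendro.labels[int(first[1])]}
        assert merged == {"E65-1", "E65-2"} and first[2] == 0.0

    def test_replicates_form_stage_clades_on_synthetic_data(self, bundle):
        lnc = bundle.truth[
            bundle.truth.planted_role.isin(["lncRNA", "known_lncRNA"])
            & (bundle.truth.planted_pattern != "stable")
        ].transcript_id
        tab = ExpressionTable(
            bundle.expression.values.loc[list(lnc)], bundle.design
        )
        dendro = hierarchical_cluster_samples(tab)
        assert all(dendro.stage_clades(bundle.design).values())

    def test_fetal_and_postnatal_super_groups_split_at_root(self, bundle):
        lnc = bundle.truth[
            bundle.truth.planted_role.isin(["lncRNA", "known_lncRNA"])
            & (bundle.truth.planted_pattern != "stable")
        ].transcript_id
        tab = ExpressionTable(
            bundle.expression.values.loc[list(lnc)], bundle.design
        )
        a, b = hierarchical_cluster_samples(tab).root_split()
        early = {f"{s}-{r}" for s in ("E65", "E85", "E105") for r in (1, 2, 3)}
        late = {f"{s}-{r}" for s in ("E135", "D7", "D30") for r in (1, 2, 3)}
        assert {a, b} == {frozenset(early), frozenset(late)}

    def test_requires_two_features(self):
        with pytest.raises(FolliscanError):
            hierarchical_cluster_samples(_table(np.ones((1, 18))))


class TestKmeansPatterns:
    def _archetype_table(self, n_per=25, cv=0.1, seed=1):
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1 + cv**2))
        rows, labels = [], []
        for pattern in ("increasing", "decreasing", "transient", "stable"):
            for i in range(n_per):
                means = pattern_stage_means(pattern, float(rng.uniform(5, 50)), 8.0)
                noise = np.exp(sigma * rng.standard_normal(18) - sigma**2 / 2)
                rows.append(np.repeat(means, 3) * noise)
                labels.append(pattern)
        return _table(np.array(rows)), labels

    def test_recovers_four_planted_archetypes(self):
        from sklearn.metrics import adjusted_rand_score

        tab, labels = self._archetype_table()
        cl = kmeans_patterns(tab, k=4, seed=1)
        assert adjusted_rand_score(labels, cl.assignments.values) >= 0.9

    def test_deterministic_for_fixed_seed(self):
        tab, _ = self._archetype_table()
        a = kmeans_patterns(tab, k=4, seed=3).assignments
        b = kmeans_patterns(tab, k=4, seed=3).assignments
        assert (a == b).all()

    def test_identical_profiles_collapse_to_one_cluster(self):
        values = np.tile(np.linspace(1, 10, 18), (12, 1))
        cl = kmeans_patterns(_table(values), k=3, seed=0)
        assert cl.assignments.nunique() == 1

    def test_fewer_features_than_k_errors(self):
        with pytest.raises(FolliscanError, match="smaller k"):
            kmeans_patterns(_table(np.random.default_rng(0).uniform(1, 9, (4, 18))), k=10)

    def test_standardize_floor_keeps_flat_profiles_near_origin(self):
        profiles = pd.DataFrame(
            [[1.0, 1.0, 1.01, 1.0, 1.0, 1.0], [0.0, 1, 2, 3, 4, 5.0]],
            columns=list(DESIGN.stages),
        )
        z = standardize_profiles(profiles)
        assert np.abs(z.iloc[0]).max() < 0.1
        assert np.abs(z.iloc[1]).max() > 1.0


class TestPatternGroups:
    def test_constant_vector_is_stable(self):
        assert assign_pattern_group([2, 2, 2, 2, 2, 2], tau=0.5) == "stable"

    def test_strictly_increasing_is_increasing(self):
        assert assign_pattern_group([0, 1, 2, 3, 4, 5], tau=0.5) == "increasing"

    def test_strictly_decreasing_is_decreasing(self):
        assert assign_pattern_group([5, 4, 3, 2, 1, 0], tau=0.5) == "decreasing"

    def test_planted_transient_is_fluctuating(self):
        centroid = pattern_stage_means("transient", 10.0, 8.0)
        tau = 0.1 * (centroid.max() - centroid.min())
        assert assign_pattern_group(centroid, tau) == "fluctuating"

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6),
           st.floats(0.01, 5))
    def test_rule_cases_are_exhaustive_and_exclusive(self, centroid, tau):
        d = np.diff(centroid)
        group = assign_pattern_group(centroid, tau)
        if np.all(np.abs(d) <= tau):
            assert group == "stable"
        elif np.all(d >= -tau) and np.any(d > tau):
            assert group == "increasing"
        elif np.all(d <= tau) and np.any(d < -tau):
            assert group == "decreasing"
        else:
            assert group == "fluctuating"
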