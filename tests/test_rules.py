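"""Wang–Mendel induction, rule-feature prefilter, aggregation, defuzzification."""

import json

import numpy as np
import pytest

import fuzzyhisto as fh
from fuzzyhisto.membership import MembershipFunction
from fuzzyhisto.rules import FuzzyRule, RuleBase


def _partitions_1d():
    return [fh.build_partition(np.array([0.0, 2.0]), "x", n_levels=3)]


class TestWangMendel:
    def test_single_sample_single_rule_degree_is_membership_product(self):
        X_fit = np.array([[0.0, 0.0], [2.0, 2.0]])
        parts = fh.build_partitions(X_fit, n_levels=3)
        X = np.array([[0.25, 1.75]])
        base = fh.wang_mendel(X, np.array([1]), parts)
        assert base.n_rules == 1
        rule = base.rules[0]
        # oracle: recompute max memberships per variable directly
        expected = 1.0
        for j, part in enumerate(parts):
            expected *= max(fh.eval_mf(m, X[0, j]) for m in part.mfs)
        assert rule.degree == pytest.approx(expected)
        assert rule.consequent == 1

    def test_identical_samples_deduplicate(self):
        parts = _partitions_1d()
        X = np.array([[0.1], [0.1]])
        base = fh.wang_mendel(X, np.array([0, 0]), parts)
        assert base.n_rules == 1
        assert base.provenance == {"primitive": 2, "deduplicated": 1,
                                   "final": 1}

    def test_conflict_resolved_by_max_degree(self):
        parts = _partitions_1d()
        # both samples map to level 0; degrees 0.9 vs 0.6; labels differ
        X = np.array([[0.1], [0.4]])
        y = np.array([0, 1])
        base = fh.wang_mendel(X, y, parts)
        assert base.n_rules == 1
        # oracle: brute-force the two candidate degrees
        d0 = max(fh.eval_mf(m, 0.1) for m in parts[0].mfs)
        d1 = max(fh.eval_mf(m, 0.4) for m in parts[0].mfs)
        assert d0 > d1
        assert base.rules[0].consequent == 0
        assert base.rules[0].degree == pytest.approx(d0)

    def test_primitive_count_equals_sample_count(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=25, n_features=4, n_informative=2, seed=8))
        parts = fh.build_partitions(tab.matrix, tab.feature_ids)
        base = fh.wang_mendel(tab.matrix, tab.labels, parts)
        assert base.provenance["primitive"] == tab.n_samples
        assert base.provenance["final"] <= base.provenance["deduplicated"]
        assert base.provenance["final"] == base.n_rules

    def test_antecedents_pairwise_distinct(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=40, n_features=3, n_informative=1, seed=3))
        parts = fh.build_partitions(tab.matrix, tab.feature_ids, n_levels=3)
        base = fh.wang_mendel(tab.matrix, tab.labels, parts)
        ants = [r.antecedent for r in base.rules]
        assert len(set(ants)) == len(ants)

    def test_sample_order_invariance(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=30, n_features=3, n_informative=2, seed=12))
        parts = fh.build_partitions(tab.matrix, tab.feature_ids, n_levels=5)
        base_a = fh.wang_mendel(tab.matrix, tab.labels, parts)
        perm = np.random.default_rng(0).permutation(tab.n_samples)
        base_b = fh.wang_mendel(tab.matrix[perm], tab.labels[perm], parts)
        rules_a = {r.antecedent: (r.consequent, round(r.degree, 12))
                   for r in base_a.rules}
        rules_b = {r.antecedent: (r.consequent, round(r.degree, 12))
                   for r in base_b.rules}
        assert rules_a == rules_b

    def test_rule_base_json_roundtrip(self, tmp_path):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=10, n_features=3, n_informative=1, seed=1))
        parts = fh.build_partitions(tab.matrix, tab.feature_ids)
        base = fh.wang_mendel(tab.matrix, tab.labels, parts)
        path = tmp_path / "rules.json"
        base.to_json(path)
        loaded = RuleBase.from_json(path)
        assert loaded.provenance == base.provenance
        assert [(r.antecedent, r.consequent) for r in loaded.rules] == \
               [(r.antecedent, r.consequent) for r in base.rules]
        json.loads(path.read_text())  # valid JSON on disk

    def test_duplicate_antecedents_rejected_in_rulebase(self):
        parts = _partitions_1d()
        with pytest.raises(ValueError, match="duplicate"):
            RuleBase([FuzzyRule((0,), 0, 0.5), FuzzyRule((0,), 1, 0.4)],
                     parts)


class TestPrefilterAndRank:
    def test_high_zero_fraction_column_dropped(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3)) + 5.0
        X[:15, 1] = 0.0  # 30% zeros
        y = (rng.uniform(size=50) > 0.5).astype(int)
        tab = fh.FeatureTable(X, y, ["a", "b", "c"])
        out = fh.prefilter_and_rank(tab, zero_frac_threshold=0.10, top_k=2,
                                    seed=0)
        assert "b" not in out.feature_ids

    def test_label_copy_ranked_first(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 25)
        X = np.column_stack([rng.normal(size=50), y.astype(float) + 0.5,
                             rng.normal(size=50)])
        tab = fh.FeatureTable(X, y, ["n1", "label_copy", "n2"])
        out = fh.prefilter_and_rank(tab, top_k=2, seed=1)
        assert out.feature_ids[0] == "label_copy"

    def test_informative_set_recovered(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=100, n_features=30, n_informative=8,
            class_separation=4.0, seed=6))
        out = fh.prefilter_and_rank(tab, top_k=8, seed=6)
        assert set(out.feature_ids) == set(tab.informative_ids)

    def test_rows_shuffled_but_pairing_kept(self):
        tab = fh.make_feature_table(fh.FixtureSpec(
            n_per_class=20, n_features=5, n_informative=2, seed=2))
        out = fh.prefilter_and_rank(tab, top_k=3, seed=2)
        assert not np.array_equal(out.labels, tab.labels)  # shuffled
        # sample/label pairing preserved: match rows back by value
        col = out.feature_ids[0]
        src = tab.matrix[:, tab.feature_ids.index(col)]
        for v, lab in zip(out.matrix[:, 0], out.labels):
            i = np.argmin(np.abs(src - v))
            assert tab.labels[i] == lab

    def test_no_surviving_columns_rejected(self):
        X = np.zeros((10, 2))
        tab = fh.FeatureTable(X, np.repeat([0, 1], 5), ["a", "b"])
        with pytest.raises(ValueError, match="survive"):
            fh.prefilter_and_rank(tab, zero_frac_threshold=0.5, top_k=1)


class TestInference:
    def test_single_rule_full_activation_is_identity(self):
        grid = np.linspace(0, 1, 101)
        cons = np.clip(1 - np.abs(grid - 0.5) * 4, 0, 1)
        out = fh.aggregate_maxmin([1.0], cons[None, :])
        assert np.allclose(out, cons)

    def test_null_firing_gives_zero_set(self):
        sets = np.ones((3, 11))
        assert np.allclose(fh.aggregate_maxmin([0.0, 0.0, 0.0], sets), 0.0)

    def test_two_rules_match_grid_bruteforce(self):
        grid = np.linspace(0, 1, 101)
        s1 = np.clip(1 - np.abs(grid - 0.3) * 5, 0, 1)
        s2 = np.clip(1 - np.abs(grid - 0.7) * 5, 0, 1)
        acts = [0.8, 0.4]
        out = fh.aggregate_maxmin(acts, np.stack([s1, s2]))
        # brute-force oracle: explicit loops over rules and grid points
        expected = np.array([max(min(acts[0], s1[g]), min(acts[1], s2[g]))
                             for g in range(101)])
        assert np.allclose(out, expected)

    def test_centroid_of_symmetric_triangle(self):
        grid = np.linspace(0, 6, 601)
        mu = np.clip(1 - np.abs(grid - 3.0), 0, 1)
        assert fh.defuzz_centroid(grid, mu) == pytest.approx(3.0, abs=1e-9)

    def test_centroid_of_indicator(self):
        grid = np.linspace(0, 1, 1001)
        assert fh.defuzz_centroid(grid, np.ones_like(grid)) == pytest.approx(
            0.5, abs=1e-9)

    def test_asymmetric_centroid_matches_highres_integration(self):
        grid = np.linspace(0, 4, 401)
        mu = np.clip((grid / 3) ** 2, 0, 1) * (grid <= 3.5)
        got = fh.defuzz_centroid(grid, mu)
        # oracle: midpoint Riemann sums on a 40x finer grid
        fine = np.linspace(0, 4, 16001)
        mu_f = np.interp(fine, grid, mu)
        mid_mu = 0.5 * (mu_f[1:] + mu_f[:-1])
        mid_y = 0.5 * (fine[1:] + fine[:-1])
        dx = np.diff(fine)
        expected = (mid_y * mid_mu * dx).sum() / (mid_mu * dx).sum()
        assert got == pytest.approx(expected, abs=1e-4)

    def test_all_zero_set_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            fh.defuzz_centroid(np.linspace(0, 1, 11), np.zeros(11))
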