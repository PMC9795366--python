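"""Tests for the evaluation protocol, metrics and shift statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from helpers_oracles import aupr_steps, auroc_pairs, ranksum_exact_p

from gsem import (
    AssociationMatrix,
    GsemHyperparams,
    SimilarityGraph,
    aupr,
    auroc,
    group_metrics,
    integration_eval,
    per_entity_auroc,
    rrf,
    rrf_shift_test,
    selfrep_similarity_bins,
    split_associations,
)
from gsem.exceptions import (
    DegenerateInputError,
    UndefinedMetricError,
    ValidationError,
)
from conftest import random_instance


class TestSplitAssociations:
    def test_partitions_positives_exactly(self, rng):
        X = random_instance(rng, 20, 15, density=0.3)
        split = split_associations(X, 0.2, 0.2, seed=5)
        pos = {(int(i), int(j)) for i, j in np.argwhere(X.values == 1)}
        assert split.train_pos | split.val_pos | split.test_pos == pos
        assert not (split.train_pos & split.val_pos)
        assert not (split.train_pos & split.test_pos)
        assert not (split.val_pos & split.test_pos)

    def test_negatives_are_zeros_and_disjoint(self, rng):
        X = random_instance(rng, 20, 15, density=0.3)
        split = split_associations(X, 0.2, 0.2, seed=5)
        for i, j in split.val_neg | split.test_neg:
            assert X.values[i, j] == 0
        assert not (split.val_neg & split.test_neg)
        assert len(split.val_neg) == 2 * len(split.val_pos)
        assert len(split.test_neg) == 2 * len(split.test_pos)

    def test_same_seed_bit_identical(self, rng):
        X = random_instance(rng, 15, 12, density=0.3)
        a = split_associations(X, 0.15, 0.15, seed=9)
        b = split_associations(X, 0.15, 0.15, seed=9)
        assert a == b

    def test_floor_rounding_boundary(self, rng):
        X = random_instance(rng, 10, 8, density=0.4)
        p = X.n_positives
        split = split_associations(X, test_frac=1 / (2 * p), val_frac=0.2, seed=0)
        assert len(split.test_pos) == 0
        assert len(split.val_pos) > 0

    def test_insufficient_zeros_warns(self, caplog):
        x = np.ones((4, 5))
        x[0, 0] = x[1, 1] = 0
        X = AssociationMatrix(tuple("abcd"), tuple("uvwxy"), x)
        with caplog.at_level("WARNING"):
            split = split_associations(X, 0.3, 0.3, seed=1)
        assert len(split.test_neg | split.val_neg) == 2
        assert "zero entries" in caplog.text


class TestRankingMetrics:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_tied_is_chance(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_worked_example(self):
        assert auroc([0.8, 0.6, 0.4], [1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(UndefinedMetricError):
            aupr([0.1, 0.2], [0, 0])

    @settings(deadline=None, max_examples=200)
    @given(data=st.data())
    def test_match_exhaustive_oracles(self, data):
        n = data.draw(st.integers(2, 12))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        # few distinct score values to force plenty of ties
        scores = data.draw(
            st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=n, max_size=n)
        )
        assert auroc(scores, labels) == pytest.approx(auroc_pairs(scores, labels), abs=1e-12)
        assert aupr(scores, labels) == pytest.approx(aupr_steps(scores, labels), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(data=st.data())
    def test_auroc_invariant_under_monotone_transform(self, data):
        n = data.draw(st.integers(3, 10))
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda y: 0 < sum(y) < len(y)
            )
        )
        # integer scores so the strictly monotone map cannot collapse
        # distinct values to the same float
        scores = np.array(
            data.draw(st.lists(st.integers(-8, 8), min_size=n, max_size=n)), dtype=float
        )
        assert auroc(np.exp(scores / 3), labels) == pytest.approx(
            auroc(scores, labels), abs=1e-12
        )


class TestRrf:
    def test_toy_column_counts(self):
        x = np.zeros((3, 3))
        x[:, 0] = 1  # count 3
        x[0, 1] = 1  # count 1
        x[:2, 2] = 1  # count 2
        X = AssociationMatrix(tuple("abc"), tuple("uvw"), x)
        vec = rrf(X)
        assert vec.z == 3
        assert np.allclose(vec.rrf, [1.0, 1 / 3, 2 / 3])

    def test_max_rrf_is_one_and_counts_conserved(self, rng):
        X = random_instance(rng, 12, 9, density=0.4)
        vec = rrf(X)
        assert vec.rrf.max() == 1.0
        assert np.allclose(vec.rrf * vec.z, X.values.sum(axis=0))

    def test_all_zero_matrix_degenerate(self):
        X = AssociationMatrix(("a", "b"), ("u", "v"), np.zeros((2, 2)))
        # construction is fine; RRF is undefined
        with pytest.raises(DegenerateInputError):
            rrf(X)


class TestPerEntityAuroc:
    def test_planted_perfect_drug(self):
        x = np.zeros((2, 24))
        x[0, :4] = 1  # training positives for drug 0
        x[1, :12] = 1
        X = AssociationMatrix(("a", "b"), tuple(f"s{j}" for j in range(24)), x)
        scores = np.zeros((2, 24))
        test_pos = [(0, j) for j in range(4, 14)]  # ten test positives
        for _, j in test_pos:
            scores[0, j] = 1.0
        out = per_entity_auroc(scores, X, test_pos, axis="drug", min_test=10)
        assert out["a"] == 1.0

    def test_below_min_test_omitted(self):
        x = np.zeros((2, 20))
        x[1, :5] = 1
        X = AssociationMatrix(("a", "b"), tuple(f"s{j}" for j in range(20)), x)
        test_pos = [(0, j) for j in range(9)]  # nine < ten
        out = per_entity_auroc(np.zeros((2, 20)), X, test_pos, axis="drug", min_test=10)
        assert "a" not in out

    def test_matches_pairwise_oracle(self, rng):
        X = random_instance(rng, 12, 10, density=0.25)
        zeros = np.argwhere(X.values == 0)
        picked = zeros[rng.choice(len(zeros), size=30, replace=False)]
        test_pos = [(int(i), int(j)) for i, j in picked]
        scores = rng.random((12, 10))
        out = per_entity_auroc(scores, X, test_pos, axis="drug", min_test=2)
        mask = np.zeros_like(X.values, dtype=bool)
        for i, j in test_pos:
            mask[i, j] = True
        for ent, value in out.items():
            i = X.drug_ids.index(ent)
            cand = X.values[i] == 0
            expected = auroc_pairs(scores[i][cand], mask[i][cand].astype(int))
            assert value == pytest.approx(expected, abs=1e-12)


class TestGroupMetrics:
    def test_single_group_equals_global(self):
        vals = {"a": 0.6, "b": 0.8, "c": 0.7}
        out = group_metrics(vals, {e: "g" for e in vals})
        assert out.loc["g", "mean"] == pytest.approx(0.7)
        assert out.loc["g", "n"] == 3

    def test_two_known_groups(self):
        out = group_metrics(
            {"a": 0.6, "b": 0.8, "c": 0.7}, {"a": "g1", "b": "g1", "c": "g2"}
        )
        assert out.loc["g1", "mean"] == pytest.approx(0.7)
        assert out.loc["g2", "mean"] == pytest.approx(0.7)

    def test_unmapped_goes_to_unclassified_and_loop_oracle(self, rng):
        vals = {f"e{i}": float(rng.random()) for i in range(50)}
        grouping = {f"e{i}": f"g{i % 3}" for i in range(40)}
        out = group_metrics(vals, grouping)
        sums: dict[str, list] = {}
        for e, v in vals.items():
            sums.setdefault(grouping.get(e, "unclassified"), []).append(v)
        for g, members in sums.items():
            assert out.loc[g, "mean"] == pytest.approx(np.mean(members))
            assert out.loc[g, "n"] == len(members)


class TestRrfShiftTest:
    def test_identical_distribution_not_significant(self, rng):
        vals = {f"e{i}": float(v) for i, v in enumerate(rng.normal(size=60))}
        groups = {"g1": {f"e{i}" for i in range(30)}, "g2": {f"e{i}" for i in range(30, 60)}}
        res = rrf_shift_test(vals, groups)
        assert all(not r.significant for r in res)

    def test_shifted_group_detected_with_direction(self, rng):
        low = rng.normal(0, 1, 40)
        high = rng.normal(3, 1, 20)
        vals = {f"a{i}": float(v) for i, v in enumerate(low)}
        vals.update({f"b{i}": float(v) for i, v in enumerate(high)})
        groups = {"high": {f"b{i}" for i in range(20)}, "low": {f"a{i}" for i in range(40)}}
        res = {r.group: r for r in rrf_shift_test(vals, groups)}
        assert res["high"].tail == "greater" and res["high"].significant
        assert res["high"].effect_size > 0
        assert res["low"].tail == "less"

    def test_small_group_skipped_with_warning(self, rng, caplog):
        vals = {f"e{i}": float(rng.random()) for i in range(20)}
        groups = {"tiny": {"e0", "e1"}, "rest": {f"e{i}" for i in range(2, 20)}}
        with caplog.at_level("WARNING"):
            res = rrf_shift_test(vals, groups)
        assert "tiny" not in {r.group for r in res}
        assert "skipped" in caplog.text

    def test_pvalues_match_exact_enumeration(self, rng):
        # n=8 per side, continuous values -> exact null distribution
        g = rng.normal(1.0, 1.0, 8)
        rest = rng.normal(0.0, 1.0, 8)
        vals = {f"g{i}": float(v) for i, v in enumerate(g)}
        vals.update({f"r{i}": float(v) for i, v in enumerate(rest)})
        groups = {"g": {f"g{i}" for i in range(8)}, "r": {f"r{i}" for i in range(8)}}
        res = {r.group: r for r in rrf_shift_test(vals, groups)}
        expected = min(
            ranksum_exact_p(g, rest, "greater"), ranksum_exact_p(g, rest, "less")
        )
        assert res["g"].p_raw == pytest.approx(expected, rel=1e-9)

    def test_bh_adjustment_monotone(self, rng):
        vals = {f"e{i}": float(v) for i, v in enumerate(rng.normal(size=80))}
        groups = {
            f"g{k}": {f"e{i}" for i in range(10 * k, 10 * (k + 1))} for k in range(8)
        }
        res = rrf_shift_test(vals, groups)
        ordered = sorted(res, key=lambda r: r.p_raw)
        adj = [r.p_adjusted for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))


def _integration_fixture(rng, n=12, m=10):
    clin = np.zeros((n, m))
    clin[:, : m // 2] = (rng.random((n, m // 2)) < 0.5).astype(float)
    clin[0, 0] = 1  # target needs at least one clinical positive
    post = np.zeros((n, m))
    post[:, m // 2 :] = (rng.random((n, m - m // 2)) < 0.4).astype(float)
    post[0, m - 1] = 1
    post[clin == 1] = 0
    drugs = tuple(f"d{i}" for i in range(n))
    ses = tuple(f"s{j}" for j in range(m))
    chem = rng.uniform(0, 0.5, (n, n))
    chem = (chem + chem.T) / 2
    np.fill_diagonal(chem, 0.0)
    return (
        AssociationMatrix(drugs, ses, clin),
        AssociationMatrix(drugs, ses, post),
        SimilarityGraph(drugs, chem, name="chem"),
    )


class TestIntegrationEval:
    PARAMS = GsemHyperparams(l2=1.0, l1=0.01, tol=1e-2, max_iter=200, seed=0)

    def test_empty_postmarket_makes_strategies_identical(self, rng):
        X_clin, X_post, chem = _integration_fixture(rng)
        s1 = integration_eval(
            "d0", X_clin, X_post, 1, chem, self.PARAMS, self.PARAMS
        )
        # strategy 2 with the *same* postmarket matrix for others but empty
        empty = AssociationMatrix(
            X_post.drug_ids, X_post.side_effect_ids, np.zeros_like(X_post.values)
        )
        empty_plus_target = empty.values.copy()
        empty_plus_target[0] = X_post.values[0]
        masked = AssociationMatrix(
            X_post.drug_ids, X_post.side_effect_ids, empty_plus_target
        )
        s2 = integration_eval("d0", X_clin, masked, 2, chem, self.PARAMS, self.PARAMS)
        assert s1 == pytest.approx(s2)

    def test_leak_threshold_boundaries(self, rng):
        X_clin, X_post, chem = _integration_fixture(rng)
        # threshold above any similarity: nobody removed, runs fine
        val = integration_eval(
            "d0", X_clin, X_post, 1, chem, self.PARAMS, self.PARAMS, leak_threshold=1.01
        )
        assert 0.0 <= val <= 1.0
        # threshold 0 removes everyone
        with pytest.raises(DegenerateInputError):
            integration_eval(
                "d0", X_clin, X_post, 1, chem, self.PARAMS, self.PARAMS, leak_threshold=0.0
            )

    def test_target_without_positives_rejected(self, rng):
        X_clin, X_post, chem = _integration_fixture(rng)
        no_post = AssociationMatrix(
            X_post.drug_ids, X_post.side_effect_ids, np.zeros_like(X_post.values)
        )
        with pytest.raises(ValidationError):
            integration_eval("d0", X_clin, no_post, 1, chem, self.PARAMS, self.PARAMS)


class TestSelfrepSimilarityBins:
    def test_constant_selfrep_fills_first_bin(self, rng):
        m = np.full((5, 5), 0.03)
        np.fill_diagonal(m, 0.0)
        side = rng.random((5, 5))
        side = (side + side.T) / 2
        out = selfrep_similarity_bins(m, side)
        assert out["n"].iloc[0] == 10  # all C(5,2) off-diagonal pairs in bin 1
        assert out["n"].sum() == 10

    def test_constant_side_info_means_equal(self):
        m = np.array(
            [[0, 0.01, 0.07], [0.01, 0, 0.3], [0.07, 0.3, 0]]
        )
        side = np.full((3, 3), 0.4)
        np.fill_diagonal(side, 0.0)
        out = selfrep_similarity_bins(m, side)
        nonempty = out[out["n"] > 0]
        assert np.allclose(nonempty["mean"], 0.4)

    def test_planted_monotone_relation(self, rng):
        k = 30
        base = rng.random((k, k))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 0.0)
        side = base.copy()  # side info equals self-rep similarity -> monotone
        out = selfrep_similarity_bins(base, side, bin_edges=(0, 0.25, 0.5, 0.75, np.inf))
        means = out.loc[out["n"] > 0, "mean"].to_numpy()
        assert (np.diff(means) > 0).all()

    def test_empty_bin_reported_with_zero_count(self):
        m = np.zeros((3, 3))
        out = selfrep_similarity_bins(m, np.zeros((3, 3)))
        assert out["n"].iloc[0] == 3
        assert (out["n"].iloc[1:] == 0).all()
        assert out["mean"].iloc[1:].isna().all()
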