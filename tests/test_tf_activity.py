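"""Regulon construction, permutation GSEA, gating, and TF aggregation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltacomm.expression import FoldChangeTable
from deltacomm.tf_activity import (
    GseaResult,
    TFActivity,
    adjust_pvalues,
    aggregate_tf_scores,
    build_regulon,
    gsea,
    rank_genes,
    tf_activity_score,
)
from tests.test_expression import make_matrix


def fc_table(mapping):
    return FoldChangeTable(cell_type="T", fc=pd.Series(mapping), epsilon=0.01)


class TestBuildRegulon:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(0)
        tf = rng.normal(5, 1, 30)
        counts = np.vstack([
            tf,                      # TF itself
            tf,                      # perfect copy -> retained
            tf[::-1],                # anti-correlated -> excluded
            rng.normal(5, 1, 30),    # independent -> excluded (usually)
        ])
        m = make_matrix(counts, ["T"] * 30, ["disease", "control"] * 15,
                        genes=["TF", "COPY", "ANTI", "RAND"])
        m.adata.uns["normalized"] = True
        return m

    def test_perfect_copy_retained(self, matrix):
        mask = np.ones(30, dtype=bool)
        reg = build_regulon("TF", {"COPY", "ANTI"}, matrix, mask)
        assert "COPY" in reg.targets
        rho, p = reg.stats["COPY"]
        assert rho == pytest.approx(1.0)

    def test_anticorrelated_excluded(self, matrix):
        reg = build_regulon("TF", {"ANTI"}, matrix, np.ones(30, dtype=bool))
        assert reg.targets == set()

    def test_correlated_gene_not_in_prior_excluded(self, matrix):
        reg = build_regulon("TF", {"RAND"}, matrix, np.ones(30, dtype=bool))
        assert "COPY" not in reg.targets

    def test_too_few_cells_errors(self, matrix):
        mask = np.zeros(30, dtype=bool)
        mask[:2] = True
        with pytest.raises(ValueError, match="3 cells"):
            build_regulon("TF", {"COPY"}, matrix, mask)

    def test_absent_tf_gives_empty_regulon_with_warning(self, matrix):
        with pytest.warns(UserWarning, match="absent"):
            reg = build_regulon("NOPE", {"COPY"}, matrix, np.ones(30, dtype=bool))
        assert reg.targets == set()


class TestRankGenes:
    def test_descending_with_symbol_tiebreak(self):
        ranked = rank_genes(fc_table({"A": 1.0, "B": -1.0, "C": 0.0}))
        assert list(ranked.index) == ["A", "C", "B"]
        ranked = rank_genes(fc_table({"B": 0.5, "A": 0.5}))
        assert list(ranked.index) == ["A", "B"]


def brute_force_gsea_p(scores, k, observed_idx, w=1.0):
    """Independent oracle: enumerate all C(n, k) placements, compute the
    running-sum ES by direct accumulation, and apply the same-sign
    permutation p with the +1 floor."""
    n = len(scores)

    def es_of(idx):
        hits = set(idx)
        nr = sum(abs(scores[i]) ** w for i in idx)
        run, best = 0.0, 0.0
        for i in range(n):
            if i in hits:
                run += (abs(scores[i]) ** w) / nr if nr > 0 else 1.0 / k
            else:
                run -= 1.0 / (n - k)
            if abs(run) > abs(best):
                best = run
        return best

    es = es_of(observed_idx)
    null = [es_of(c) for c in itertools.combinations(range(n), k)]
    if es > 0:
        same = [e for e in null if e > 0]
    elif es < 0:
        same = [e for e in null if e < 0]
    else:
        same = []
    if not same:
        return es, 1.0
    p = (1 + sum(abs(e) >= abs(es) for e in same)) / (1 + len(same))
    return es, p


class TestGsea:
    def test_top_block_strongly_enriched(self):
        scores = np.linspace(3, 0.5, 50)
        ranked = pd.Series(scores, index=[f"G{i}" for i in range(50)])
        res = gsea(ranked, {"G0", "G1", "G2"}, n_perm=1000, seed=1)
        assert res.es > 0 and res.nes > 0
        assert res.p < 0.02

    @pytest.mark.parametrize("n,k,seed", [(6, 2, 0), (7, 3, 1), (8, 3, 2), (5, 1, 3)])
    def test_exhaustive_mode_matches_enumeration_oracle(self, n, k, seed):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(0, 1, n))[::-1]
        ranked = pd.Series(scores, index=[f"G{i}" for i in range(n)])
        observed = sorted(rng.choice(n, size=k, replace=False))
        res = gsea(ranked, {f"G{i}" for i in observed}, exhaustive=True)
        es_ref, p_ref = brute_force_gsea_p(list(scores), k, observed)
        assert res.es == es_ref
        assert res.p == p_ref

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(4)
        scores = np.sort(rng.normal(0, 1, 40))[::-1]
        ranked = pd.Series(scores, index=[f"G{i}" for i in range(40)])
        relabeled = pd.Series(scores, index=[f"X{i}" for i in range(40)])
        r1 = gsea(ranked, {"G3", "G7", "G20"}, n_perm=300, seed=9)
        r2 = gsea(relabeled, {"X3", "X7", "X20"}, n_perm=300, seed=9)
        assert (r1.es, r1.nes, r1.p) == (r2.es, r2.nes, r2.p)

    def test_set_members_missing_from_ranking_dropped_with_warning(self):
        ranked = pd.Series([2.0, 1.0, -1.0], index=["A", "B", "C"])
        with pytest.warns(UserWarning, match="dropped"):
            res = gsea(ranked, {"A", "ZZ"}, n_perm=50, seed=0)
        assert res.set_size == 1

    def test_degenerate_sets_rejected(self):
        ranked = pd.Series([2.0, 1.0, -1.0], index=["A", "B", "C"])
        with pytest.raises(ValueError):
            gsea(ranked, {"X", "Y"}, n_perm=10, seed=0)
        with pytest.raises(ValueError):
            gsea(ranked, {"A", "B", "C"}, n_perm=10, seed=0)


class TestAdjustPvalues:
    def test_hand_computed_bh(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(adjust_pvalues([0.01]), [0.01])
        np.testing.assert_allclose(adjust_pvalues([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


def result(nes, p, adj_p=None):
    return GseaResult(tf="T", es=np.sign(nes) * 0.5, nes=nes, p=p,
                      adj_p=adj_p, n_perm=100, seed=0, set_size=5)


class TestGate:
    @pytest.mark.parametrize("nes,p,direction,expected", [
        (2.0, 0.01, "both", 2.0),
        (-1.5, 0.01, "up", 0.0),
        (-1.5, 0.01, "down", 1.5),
        (2.0, 0.20, "both", 0.0),
        (1.2, 0.01, "up", 1.2),
    ])
    def test_directional_gating(self, nes, p, direction, expected):
        act = tf_activity_score(result(nes, p, adj_p=p), direction)
        assert act.score == pytest.approx(expected)

    def test_gate_on_raw_p_switch(self):
        res = result(2.0, 0.01, adj_p=0.5)
        assert tf_activity_score(res, "both", gate_on="adj_p").score == 0.0
        assert tf_activity_score(res, "both", gate_on="p").score == 2.0

    @given(st.floats(-3, 3), st.floats(0.001, 1))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_up_plus_down_equals_both(self, nes, p):
        res = result(nes, p, adj_p=p)
        up = tf_activity_score(res, "up").score
        down = tf_activity_score(res, "down").score
        both = tf_activity_score(res, "both").score
        assert up + down == pytest.approx(both)


class TestAggregate:
    def act(self, score):
        return TFActivity(tf="T", direction="both", score=score, alpha=0.05)

    def test_single_tf_weights_cancel(self):
        assert aggregate_tf_scores([(self.act(1.7), 4)]).tf_k == pytest.approx(1.7)

    def test_equal_distances_arithmetic_mean(self):
        agg = aggregate_tf_scores([(self.act(2.0), 1), (self.act(4.0), 1)])
        assert agg.tf_k == pytest.approx(3.0)

    def test_inverse_distance_weighting(self):
        agg = aggregate_tf_scores([(self.act(3.0), 1), (self.act(0.0), 2)])
        assert agg.tf_k == pytest.approx(2.0, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(0, 5), st.integers(1, 6)), min_size=1, max_size=6))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_bounded_and_order_invariant(self, items):
        scored = [(self.act(s), m) for s, m in items]
        agg = aggregate_tf_scores(scored)
        scores = [s for s, _ in items]
        assert min(scores) - 1e-9 <= agg.tf_k <= max(scores) + 1e-9
        assert aggregate_tf_scores(scored[::-1]).tf_k == pytest.approx(agg.tf_k)
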