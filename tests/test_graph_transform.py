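import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gainet.graph_transform import (
    RegulatoryGraphs,
    TransformConfig,
    TransformError,
    build_graphs,
    combine_delta,
    delta1_gene_sample,
    delta2_gene_sample,
    normalize_interaction_scores,
    transform_matrix,
)
from gainet.io_formats import InteractionTable, OmicsKind, OmicsMatrix, PromoterMap
from gainet.reference import naive_transform
from tests.conftest import random_instance


class TestScoreNormalization:
    def test_minmax_with_floor(self):
        t = InteractionTable(
            pd.DataFrame(
                {"mirna_id": list("abc"), "gene_id": list("xyz"), "raw_score": [-0.2, -0.6, -1.0]}
            )
        )
        out = normalize_interaction_scores(t, is_floor=0.01)
        np.testing.assert_allclose(out.table["is_score"], [0.01, 0.505, 1.0])

    @pytest.mark.parametrize("scores", [[-0.4], [-0.5, -0.5, -0.5]])
    def test_degenerate_tables_map_to_one(self, scores):
        t = InteractionTable(
            pd.DataFrame(
                {
                    "mirna_id": [f"m{i}" for i in range(len(scores))],
                    "gene_id": [f"g{i}" for i in range(len(scores))],
                    "raw_score": scores,
                }
            )
        )
        out = normalize_interaction_scores(t)
        np.testing.assert_allclose(out.table["is_score"], 1.0)

    def test_empty_table_raises(self):
        t = InteractionTable(pd.DataFrame(columns=["mirna_id", "gene_id", "raw_score"]))
        with pytest.raises(TransformError):
            normalize_interaction_scores(t)

    def test_stronger_raw_score_keeps_larger_is(self):
        rng = np.random.default_rng(0)
        raw = -rng.uniform(0.1, 1.5, size=20)
        t = InteractionTable(
            pd.DataFrame(
                {"mirna_id": [f"m{i}" for i in range(20)], "gene_id": ["g"] * 20, "raw_score": raw}
            )
        )
        out = normalize_interaction_scores(t)
        order_raw = np.argsort(np.abs(raw))
        assert np.all(np.diff(out.table["is_score"].to_numpy()[order_raw]) >= 0)


class TestBuildGraphs:
    def _matrices(self):
        s = ["s1", "s2"]
        mrna = OmicsMatrix(["g1", "g2"], s, np.ones((2, 2)), OmicsKind.MRNA_COUNTS)
        mirna = OmicsMatrix(["m1", "m2"], s, np.ones((2, 2)), OmicsKind.MIRNA_COUNTS)
        meth = OmicsMatrix(["c1"], s, np.full((1, 2), 0.5), OmicsKind.METHYLATION_BETA)
        return mrna, mirna, meth

    def test_absent_partner_dropped_and_counted(self):
        mrna, mirna, meth = self._matrices()
        t = normalize_interaction_scores(
            InteractionTable(
                pd.DataFrame(
                    {
                        "mirna_id": ["m1", "m2", "mMISSING"],
                        "gene_id": ["g1", "g1", "g2"],
                        "raw_score": [-0.2, -0.6, -1.0],
                    }
                )
            )
        )
        pm = PromoterMap(
            pd.DataFrame({"cpg_id": ["c1"], "gene_id": ["g2"], "tss_distance_bp": [100]})
        )
        g = build_graphs(t, pm, mrna, mirna, meth)
        assert g.n_mirna_edges == 2 and g.n_mirna_edges_dropped == 1
        assert g.cpg_edges == {"g2": ["c1"]}

    def test_no_usable_edges_raises(self):
        mrna, mirna, meth = self._matrices()
        t = normalize_interaction_scores(
            InteractionTable(
                pd.DataFrame({"mirna_id": ["zz"], "gene_id": ["qq"], "raw_score": [-0.5]})
            )
        )
        pm = PromoterMap(
            pd.DataFrame({"cpg_id": ["nn"], "gene_id": ["qq"], "tss_distance_bp": [0]})
        )
        with pytest.raises(TransformError, match="no usable edges"):
            build_graphs(t, pm, mrna, mirna, meth)


class TestDeltaClosedForms:
    """Spot values verified symbolically before implementation."""

    @pytest.mark.parametrize(
        "exprs, iss, expected",
        [
            ([0], [1.0], 1.0),  # log2(1)=0
            ([1, 1], [1, 1], math.exp(-1.5)),
            ([3], [0.5], 2 * math.exp(-3)),  # log2(4)=2, term = 1/(0.5 e^3)
        ],
    )
    def test_delta1(self, exprs, iss, expected):
        assert delta1_gene_sample(exprs, iss, alpha=1.5, pseudocount=1) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize(
        "betas, expected",
        [
            ([1.0], 1.0),
            ([0.5], math.exp(1.5)),
            ([0.5, 1.0], (math.exp(1.5) + 1) / 2),
        ],
    )
    def test_delta2(self, betas, expected):
        assert delta2_gene_sample(betas, beta_exp=1.5) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "d1, d2, w1, w2, expected",
        [
            (1.0, 1.0, 1, 1, 1.0),
            (0.2, 4.0, 1, 1, 2.1),
            (0.2, 4.0, 3, 1, 1.15),
        ],
    )
    def test_combine(self, d1, d2, w1, w2, expected):
        assert combine_delta(d1, d2, w1, w2) == pytest.approx(expected, abs=1e-9)

    def test_missing_partner_policies(self):
        nan = float("nan")
        assert combine_delta(0.5, nan, policy="fallback") == 0.5
        assert combine_delta(nan, 3.0, policy="fallback") == 3.0
        assert combine_delta(0.5, nan, policy="neutral_one") == 1.0
        assert combine_delta(nan, nan) == 1.0

    def test_single_partner_closed_form_grid(self):
        """delta1 with one partner, pc=1: IS^-1 * (e+1)^(-alpha/ln 2)."""
        for e in np.linspace(0, 50, 10):
            for is_score in np.linspace(0.05, 1.0, 10):
                expect = (1 / is_score) * (e + 1) ** (-1.5 / math.log(2))
                assert delta1_gene_sample([e], [is_score], 1.5, 1) == pytest.approx(
                    expect, rel=1e-12
                )


@given(
    d1=st.floats(0.01, 100),
    d2=st.floats(0.01, 100),
    w1=st.floats(0.01, 10),
    w2=st.floats(0.01, 10),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_combined_factor_lies_between_its_parts(d1, d2, w1, w2):
    out = combine_delta(d1, d2, w1, w2)
    assert min(d1, d2) - 1e-9 <= out <= max(d1, d2) + 1e-9


@given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=8))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_methylation_factor_is_at_least_one(betas):
    # beta <= 1 makes every 1/exp(beta_exp*log2(beta)) term >= 1
    assert delta2_gene_sample(betas, 1.5) >= 1.0 - 1e-12


class TestMonotonicity:
    def test_delta1_decreasing_in_expression_and_is(self):
        grid = np.linspace(0, 100, 10)
        vals = [delta1_gene_sample([e, 5.0], [0.5, 0.8], 1.5, 1) for e in grid]
        assert np.all(np.diff(vals) < 0)
        is_grid = np.linspace(0.05, 1.0, 10)
        vals = [delta1_gene_sample([5.0, 5.0], [s, 0.8], 1.5, 1) for s in is_grid]
        assert np.all(np.diff(vals) < 0)

    def test_delta2_decreasing_in_beta(self):
        grid = np.linspace(0.01, 1.0, 10)
        vals = [delta2_gene_sample([b, 0.7], 1.5) for b in grid]
        assert np.all(np.diff(vals) < 0)


class TestTransformMatrix:
    def test_partnerless_gene_returned_unchanged(self):
        s = ["s1", "s2"]
        mrna = OmicsMatrix(["g1", "g2"], s, np.array([[10.0, 20.0], [5.0, 7.0]]), OmicsKind.MRNA_COUNTS)
        mirna = OmicsMatrix(["m1"], s, np.zeros((1, 2)), OmicsKind.MIRNA_COUNTS)
        meth = OmicsMatrix(["c1"], s, np.ones((1, 2)), OmicsKind.METHYLATION_BETA)
        graphs = RegulatoryGraphs({"g1": [("m1", 1.0)]}, {"g1": ["c1"]})
        res = transform_matrix(mrna, mirna, meth, graphs)
        # g2 has no partners at all -> identity, bit-exact
        assert np.array_equal(res.transformed[1], mrna.values[1])
        assert np.all(res.delta[1] == 1.0)

    def test_neutral_partners_give_identity(self):
        s = ["s1"]
        mrna = OmicsMatrix(["g1"], s, np.array([[42.0]]), OmicsKind.MRNA_COUNTS)
        mirna = OmicsMatrix(["m1"], s, np.array([[0.0]]), OmicsKind.MIRNA_COUNTS)
        meth = OmicsMatrix(["c1"], s, np.array([[1.0]]), OmicsKind.METHYLATION_BETA)
        graphs = RegulatoryGraphs({"g1": [("m1", 1.0)]}, {"g1": ["c1"]})
        res = transform_matrix(mrna, mirna, meth, graphs)
        assert res.delta[0, 0] == 1.0
        assert res.transformed[0, 0] == 42.0

    def test_misaligned_samples_raise(self):
        mrna = OmicsMatrix(["g"], ["s1", "s2"], np.ones((1, 2)), OmicsKind.MRNA_COUNTS)
        mirna = OmicsMatrix(["m"], ["s2", "s1"], np.ones((1, 2)), OmicsKind.MIRNA_COUNTS)
        meth = OmicsMatrix(["c"], ["s1", "s2"], np.full((1, 2), 0.5), OmicsKind.METHYLATION_BETA)
        with pytest.raises(TransformError, match="aligned"):
            transform_matrix(mrna, mirna, meth, RegulatoryGraphs({"g": [("m", 1.0)]}, {}))

    @pytest.mark.parametrize("policy", ["fallback", "neutral_one"])
    def test_agrees_with_naive_oracle_on_random_instances(self, policy):
        rng = np.random.default_rng(42)
        cfg = TransformConfig(missing_partner_policy=policy)
        for _ in range(150):
            mrna, mirna, meth, graphs = random_instance(rng)
            fast = transform_matrix(mrna, mirna, meth, graphs, cfg)
            slow = naive_transform(mrna, mirna, meth, graphs, cfg)
            np.testing.assert_allclose(fast.delta, slow.delta, atol=1e-9, rtol=0)
            np.testing.assert_allclose(fast.transformed, slow.transformed, atol=1e-9, rtol=0)

    def test_sample_permutation_permutes_columns(self):
        rng = np.random.default_rng(11)
        mrna, mirna, meth, graphs = random_instance(rng, max_genes=6, max_samples=5)
        res = transform_matrix(mrna, mirna, meth, graphs)
        perm = rng.permutation(len(mrna.sample_ids))
        ids = [mrna.sample_ids[i] for i in perm]
        res_p = transform_matrix(
            mrna.subset(sample_ids=ids),
            mirna.subset(sample_ids=ids),
            meth.subset(sample_ids=ids),
            graphs,
        )
        np.testing.assert_array_equal(res_p.transformed, res.transformed[:, perm])

    def test_weight_ratio_variants_interpolate(self):
        """delta under w1:w2 lies between delta1-only and delta2-only."""
        rng = np.random.default_rng(13)
        mrna, mirna, meth, graphs = random_instance(rng, max_genes=5, max_samples=3)
        res13 = transform_matrix(mrna, mirna, meth, graphs, TransformConfig(w1=1, w2=3))
        res31 = transform_matrix(mrna, mirna, meth, graphs, TransformConfig(w1=3, w2=1))
        both = ~np.isnan(res13.delta1) & ~np.isnan(res13.delta2)
        lo = np.minimum(res13.delta1[both], res13.delta2[both])
        hi = np.maximum(res13.delta1[both], res13.delta2[both])
        for res in (res13, res31):
            assert np.all(res.delta[both] >= lo - 1e-12)
            assert np.all(res.delta[both] <= hi + 1e-12)

    def test_deterministic_bit_identical(self):
        rng = np.random.default_rng(21)
        mrna, mirna, meth, graphs = random_instance(rng)
        a = transform_matrix(mrna, mirna, meth, graphs)
        b = transform_matrix(mrna, mirna, meth, graphs)
        assert np.array_equal(a.transformed, b.transformed)
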