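"""Shapley attributions, grouped importance, waterfalls, pre-ranked GSEA."""

import numpy as np
import pandas as pd
import pytest

from synscreen.interpretation import (
    AttributionSet,
    PermutationShapley,
    exact_shapley,
    group_attributions,
    preranked_gsea,
    rank_features,
    waterfall_data,
)
from synscreen.omics_features import GeneSetCollection


def _random_mlp(rng, n_in):
    """A small fixed random nonlinear model as a predict function."""
    w1 = rng.normal(size=(n_in, 8))
    b1 = rng.normal(size=8)
    w2 = rng.normal(size=8)

    def predict(X):
        X = np.atleast_2d(X)
        return np.tanh(X @ w1 + b1) @ w2

    return predict


class TestExactShapley:
    def test_linear_model_gives_coef_times_delta(self):
        coef = np.array([2.0, 3.0])
        f = lambda X: np.atleast_2d(X) @ coef
        phi, base = exact_shapley(f, np.array([1.0, 1.0]), np.zeros(2))
        np.testing.assert_allclose(phi, [2.0, 3.0])
        assert base == 0.0

    def test_symmetry_axiom(self):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        phi, _ = exact_shapley(f, np.array([1.0, 1.0]), np.zeros(2))
        assert phi[0] == pytest.approx(phi[1])

    @pytest.mark.parametrize("n_features", [4, 8])
    def test_local_accuracy_on_random_models(self, n_features, rng):
        f = _random_mlp(rng, n_features)
        sample = rng.normal(size=n_features)
        background = rng.normal(size=n_features)
        phi, base = exact_shapley(f, sample, background)
        assert base + phi.sum() == pytest.approx(float(f(sample)[0]), abs=1e-8)
        assert base == pytest.approx(float(f(background)[0]), abs=1e-12)

    def test_feature_cap(self, rng):
        f = lambda X: np.atleast_2d(X).sum(axis=1)
        with pytest.raises(ValueError, match="exceeds"):
            exact_shapley(f, np.zeros(20), np.zeros(20))


class TestPermutationBackend:
    def test_local_accuracy_exact_for_any_budget(self, rng):
        f = _random_mlp(rng, 6)
        samples = rng.normal(size=(3, 6))
        background = rng.normal(size=6)
        attrs = PermutationShapley(n_permutations=2, seed=1).attribute(
            f, samples, background
        )
        preds = f(samples)
        for i in range(3):
            assert attrs.base_value + attrs.values[i].sum() == pytest.approx(
                float(preds[i]), abs=1e-8
            )

    def test_agrees_with_exact_oracle(self, rng):
        """Pearson >= 0.95 against enumeration on tiny dense models."""
        for seed in range(3):
            local = np.random.default_rng(seed)
            f = _random_mlp(local, 8)
            sample = local.normal(size=8)
            background = local.normal(size=8)
            phi_exact, _ = exact_shapley(f, sample, background)
            attrs = PermutationShapley(n_permutations=64, seed=seed).attribute(
                f, sample[None, :], background
            )
            r = np.corrcoef(phi_exact, attrs.values[0])[0, 1]
            assert r >= 0.95

    def test_linear_model_exact_from_one_permutation(self, rng):
        coef = rng.normal(size=5)
        f = lambda X: np.atleast_2d(X) @ coef + 2.0
        sample, background = rng.normal(size=5), rng.normal(size=5)
        attrs = PermutationShapley(n_permutations=1, seed=0).attribute(
            f, sample[None, :], background
        )
        np.testing.assert_allclose(attrs.values[0], coef * (sample - background), atol=1e-10)


class TestGroupedImportance:
    def _attrs(self, values):
        return AttributionSet(
            base_value=0.0,
            values=np.asarray(values),
            feature_labels=["a1", "a2", "e1"],
            group_labels={"a1": "drugA", "a2": "drugA", "e1": "expr"},
        )

    def test_sum_then_mean_abs(self):
        grouped = group_attributions(self._attrs([[2.0, -1.0, 4.0]]))
        assert grouped.per_sample.loc[0, "drugA"] == pytest.approx(1.0)
        assert grouped.mean_abs["drugA"] == pytest.approx(1.0)
        assert grouped.mean_abs["expr"] == pytest.approx(4.0)

    def test_abs_after_sum_order(self):
        grouped = group_attributions(
            self._attrs([[3.0, 0.0, 0.0], [-3.0, 0.0, 0.0]])
        )
        assert grouped.mean_abs["drugA"] == pytest.approx(3.0)

    def test_partition_conservation(self, rng):
        values = rng.normal(size=(5, 3))
        grouped = group_attributions(self._attrs(values))
        np.testing.assert_allclose(
            grouped.per_sample.sum(axis=1).to_numpy(), values.sum(axis=1), atol=1e-12
        )

    def test_unlabeled_feature_rejected(self):
        attrs = AttributionSet(0.0, np.zeros((1, 2)), ["a", "b"], {"a": "expr"})
        with pytest.raises(ValueError, match="without a group"):
            group_attributions(attrs)


class TestRankAndWaterfall:
    ATTRS = AttributionSet(
        base_value=0.0,
        values=np.array([[5.0, -7.0, 1.0]]),
        feature_labels=["f1", "f2", "f3"],
    )

    def test_sample_scope_order(self):
        ranked = rank_features(self.ATTRS, k=3, scope="sample")
        assert [r[0] for r in ranked] == ["f2", "f1", "f3"]

    def test_zero_column_ranked_last(self):
        attrs = AttributionSet(
            0.0, np.array([[0.0, 1.0], [0.0, -2.0]]), ["zero", "live"]
        )
        ranked = rank_features(attrs, k=2)
        assert ranked[-1][0] == "zero"

    def test_global_invariant_to_sample_order(self, rng):
        values = rng.normal(size=(6, 4))
        labels = ["a", "b", "c", "d"]
        r1 = rank_features(AttributionSet(0.0, values, labels), k=4)
        r2 = rank_features(AttributionSet(0.0, values[::-1], labels), k=4)
        assert [x[0] for x in r1] == [x[0] for x in r2]
        np.testing.assert_allclose([x[1] for x in r1], [x[1] for x in r2])

    def test_waterfall_cumulative_path(self):
        attrs = AttributionSet(0.0, np.array([[2.0, 3.0]]), ["a", "b"])
        rows = waterfall_data(attrs, sample=0, k=2)
        assert [(r[0], r[2]) for r in rows] == [("b", 3.0), ("a", 5.0)]

    def test_residual_telescopes_to_prediction(self, rng):
        row = rng.normal(size=9)
        attrs = AttributionSet(1.5, row[None, :], [f"f{j}" for j in range(9)])
        rows = waterfall_data(attrs, sample=0, k=3)
        assert rows[-1][0] == "all other features"
        assert rows[-1][2] == pytest.approx(1.5 + row.sum(), abs=1e-8)


class TestPrerankedGsea:
    GENES = [f"g{i:02d}" for i in range(20)]

    def _ranking(self):
        return pd.Series(np.arange(20, 0, -1, dtype=float), index=self.GENES)

    def test_planted_top_set_unit_es(self):
        sets = GeneSetCollection({"top": frozenset(self.GENES[:3])})
        res = preranked_gsea(self._ranking(), sets, weight_p=0.0, n_perm=50, seed=0)
        assert res.loc["top", "es"] == pytest.approx(1.0)

    def test_reversed_ranking_negates_es(self):
        sets = GeneSetCollection({"s": frozenset(self.GENES[:4])})
        fwd = preranked_gsea(self._ranking(), sets, weight_p=0.0, n_perm=20, seed=0)
        rev = preranked_gsea(-self._ranking(), sets, weight_p=0.0, n_perm=20, seed=0)
        assert rev.loc["s", "es"] == pytest.approx(-fwd.loc["s", "es"])

    def test_degenerate_whole_ranking_set_skipped(self):
        sets = GeneSetCollection(
            {"all": frozenset(self.GENES), "ok": frozenset(self.GENES[:5])}
        )
        with pytest.warns(UserWarning, match="all"):
            res = preranked_gsea(self._ranking(), sets, n_perm=20, seed=0)
        assert list(res.index) == ["ok"]

    def test_es_bounded(self, rng):
        for seed in range(5):
            local = np.random.default_rng(seed)
            ranking = pd.Series(local.normal(size=20), index=self.GENES)
            members = frozenset(local.choice(self.GENES, 6, replace=False))
            res = preranked_gsea(
                ranking, GeneSetCollection({"s": members}), n_perm=20, seed=seed
            )
            assert -1.0 <= res.loc["s", "es"] <= 1.0

    def test_bh_fdr_monotone_in_p(self, rng):
        sets = {
            f"s{i}": frozenset(rng.choice(self.GENES, 5, replace=False)) for i in range(6)
        }
        res = preranked_gsea(
            pd.Series(rng.normal(size=20), index=self.GENES),
            GeneSetCollection(sets),
            n_perm=100,
            seed=0,
        )
        ordered = res.sort_values("p_perm")
        assert (np.diff(ordered["fdr"].to_numpy()) >= -1e-12).all()

    def test_duplicate_genes_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["g", "g"])
        with pytest.raises(ValueError, match="duplicate"):
            preranked_gsea(ranking, GeneSetCollection({"s": frozenset({"g"})}))

    def test_es_matches_independent_reference(self):
        """Cross-check the enrichment statistic against gseapy on a fixed case."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(7)
        ranking = pd.Series(
            np.sort(rng.normal(size=40))[::-1], index=[f"G{i}" for i in range(40)]
        )
        members = [f"G{i}" for i in [0, 3, 5, 11, 22, 37]]
        ours = preranked_gsea(
            ranking,
            GeneSetCollection({"S": frozenset(members)}),
            weight_p=1.0,
            n_perm=50,
            min_size=2,
            seed=0,
        )
        ref = gseapy.prerank(
            rnk=ranking.reset_index(),
            gene_sets={"S": members},
            permutation_num=10,
            min_size=2,
            max_size=500,
            weight=1.0,
            seed=0,
            outdir=None,
            no_plot=True,
        ).res2d
        assert ours.loc["S", "es"] == pytest.approx(float(ref["ES"].iloc[0]), abs=1e-6)
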