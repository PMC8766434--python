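"""Elastic-net IBC classifier, tertile stratification, calling statistics."""

import numpy as np
import pandas as pd
import pytest

import ibcnet as ib
from ibcnet.classifier import _fit_enet


class TestStratifyTertiles:
    def test_one_to_nine_splits_evenly(self):
        labels = ib.stratify_tertiles(pd.Series(range(1, 10)))
        assert labels.value_counts().to_dict() == {"low": 3, "moderate": 3, "high": 3}

    def test_monotone_transform_invariance(self, rng):
        x = pd.Series(rng.normal(size=40))
        a = ib.stratify_tertiles(x)
        b = ib.stratify_tertiles(np.exp(3 * x))
        assert (a == b).all()

    def test_n300_strata_within_one_of_100(self, rng):
        x = pd.Series(rng.normal(size=300))
        sizes = ib.stratify_tertiles(x).value_counts()
        assert (sizes.sub(100).abs() <= 1).all()

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError, match="no strata"):
            ib.stratify_tertiles(pd.Series([2.0] * 10))

    def test_boundary_ties_go_low(self):
        x = pd.Series([1.0, 1.0, 1.0, 5.0, 9.0, 9.0])
        labels = ib.stratify_tertiles(x)
        # values equal to the lower cut belong to the lower stratum
        assert (labels[x == 1.0] == "low").all()


def _separable_compendium(seed=5):
    spec = ib.CompendiumSpec(
        seed=seed, n_genes=120,
        modules=(ib.ModuleSpec(40, 2.0, "IBC", phenotype_shift=3.0),),
        n_cell_lines_ibc=10, n_cell_lines_nibc=22,
        replicates_per_line=3, noise_sd=0.2,
    )
    return ib.generate_cell_line_compendium(spec)


class TestTrainElasticNet:
    def test_separable_data_high_validation_accuracy(self):
        comp = _separable_compendium()
        sig = list(comp.module_truth.index[comp.module_truth == 1])
        model = ib.train_elastic_net(
            comp.values, comp.annotation["phenotype"], sig,
            alpha_grid=(0.0, 0.5, 1.0), lambda_grid=(0.001, 0.01, 0.1),
            repeats=1, seed=0,
        )
        assert model.validation_accuracy >= 0.95

    def test_ridge_column_matches_newton_oracle(self, rng):
        # alpha = 0: coefficients equal the closed-form (Newton-iterated)
        # ridge logistic solution on a 2-gene toy problem
        n, lam = 200, 0.05
        X = rng.normal(size=(n, 2))
        w_true = np.array([1.5, -2.0])
        y = (rng.random(n) < 1 / (1 + np.exp(-(X @ w_true)))).astype(int)
        clf = _fit_enet(X, y, alpha=0.0, lam=lam)

        beta = np.zeros(3)  # intercept + 2 coefficients, independent Newton
        Xd = np.column_stack([np.ones(n), X])
        for _ in range(100):
            eta = Xd @ beta
            p = 1 / (1 + np.exp(-eta))
            W = p * (1 - p)
            pen = n * lam * np.diag([0.0, 1.0, 1.0])
            g = Xd.T @ (y - p) - pen @ beta
            H = Xd.T @ (Xd * W[:, None]) + pen
            step = np.linalg.solve(H, g)
            beta += step
            if np.abs(step).max() < 1e-12:
                break
        np.testing.assert_allclose(clf.coef_.ravel(), beta[1:], atol=1e-4)
        assert clf.intercept_[0] == pytest.approx(beta[0], abs=1e-4)

    def test_duplicated_training_set_gives_identical_fit(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        a = _fit_enet(X, y, alpha=0.5, lam=0.01)
        b = _fit_enet(np.vstack([X, X]), np.concatenate([y, y]), alpha=0.5, lam=0.01)
        np.testing.assert_allclose(a.coef_, b.coef_, atol=1e-4)

    def test_missing_signature_genes_rejected(self, random_expression):
        y = pd.Series(["IBC"] * 6 + ["nIBC"] * 6, index=random_expression.columns)
        with pytest.raises(KeyError, match="missing"):
            ib.train_elastic_net(random_expression, y, ["nope1", "nope2"])

    def test_posterior_invariant_to_gene_affine_transform(self):
        comp = _separable_compendium(seed=8)
        sig = list(comp.module_truth.index[comp.module_truth == 1])
        kw = dict(alpha_grid=(0.5,), lambda_grid=(0.01,), repeats=1, seed=1)
        m1 = ib.train_elastic_net(comp.values, comp.annotation["phenotype"], sig, **kw)
        scaled = comp.values.mul(
            np.linspace(0.5, 2.0, comp.values.shape[0]), axis=0
        ).add(np.arange(comp.values.shape[0]), axis=0)
        m2 = ib.train_elastic_net(scaled, comp.annotation["phenotype"], sig, **kw)
        p1 = m1.posterior(comp.values)
        p2 = m2.posterior(scaled)
        np.testing.assert_allclose(p1, p2, atol=1e-3)


class TestCallModels:
    def _model(self):
        comp = _separable_compendium()
        sig = list(comp.module_truth.index[comp.module_truth == 1])
        model = ib.train_elastic_net(
            comp.values, comp.annotation["phenotype"], sig,
            alpha_grid=(0.5,), lambda_grid=(0.01,), repeats=1, seed=0,
        )
        return comp, model

    def test_median_rule_on_replicates(self):
        comp, model = self._model()
        preds = ib.call_models(model, comp.values, comp.annotation["replicate_group"])
        med = preds.posterior.groupby(
            comp.annotation["replicate_group"], sort=False
        ).median()
        pd.testing.assert_series_equal(preds.median_posterior, med, check_names=False)
        assert set(preds.call.unique()) <= {"IBC", "nIBC"}

    def test_tie_at_half_calls_ibc(self):
        _, model = self._model()
        med = pd.Series([0.5, 0.49])
        call = np.where(med >= 0.5, "IBC", "nIBC")
        assert call[0] == "IBC" and call[1] == "nIBC"

    def test_missing_gene_listed(self):
        comp, model = self._model()
        broken = comp.values.drop(index=model.signature[0])
        with pytest.raises(KeyError, match=model.signature[0]):
            ib.call_models(model, broken, comp.annotation["replicate_group"])


class TestConfusionStats:
    def test_printed_shape_of_study_statistics(self):
        calls = pd.Series(["IBC"] * 10 + ["nIBC"] * 15 + ["IBC"] * 7)
        truth = pd.Series(["IBC"] * 10 + ["nIBC"] * 22)
        stats = ib.confusion_stats(calls, truth)
        assert stats["sensitivity"] == 1.0
        assert stats["specificity"] == pytest.approx(15 / 22)
        assert stats["accuracy"] == pytest.approx(25 / 32)

    def test_perfect_calls(self):
        calls = pd.Series(["IBC", "nIBC", "IBC"])
        stats = ib.confusion_stats(calls, calls.copy())
        assert all(stats[k] == 1.0 for k in
                   ("accuracy", "sensitivity", "specificity", "ppv", "npv"))

    def test_all_positive_calls(self):
        calls = pd.Series(["IBC"] * 6)
        truth = pd.Series(["IBC"] * 3 + ["nIBC"] * 3)
        stats = ib.confusion_stats(calls, truth)
        assert stats["sensitivity"] == 1.0 and stats["specificity"] == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ib.confusion_stats(pd.Series(dtype=object), pd.Series(dtype=object))


class TestMcnemar:
    def test_chi_square_closed_form(self):
        a = pd.Series([True] * 10 + [False] * 2 + [True] * 30)
        b = pd.Series([False] * 10 + [True] * 2 + [True] * 30)
        stat, p, method = ib.mcnemar_test(a, b, exact_below=0)
        assert method == "chi2"
        assert stat == pytest.approx(64 / 12)
        assert p == pytest.approx(0.02092, abs=2e-4)

    def test_balanced_discordance_is_null(self):
        a = pd.Series([True] * 30 + [False] * 30)
        b = pd.Series([False] * 30 + [True] * 30)
        stat, p, _ = ib.mcnemar_test(a, b, exact_below=0)
        assert stat == 0.0 and p == 1.0

    def test_exact_binomial_small_discordance(self):
        a = pd.Series([True] * 3 + [False] * 5)
        b = pd.Series([False] * 3 + [False] * 5)
        stat, p, method = ib.mcnemar_test(a, b)
        assert method == "exact-binomial"
        assert p == pytest.approx(0.25)

    def test_no_discordance(self):
        a = pd.Series([True, False])
        _, p, method = ib.mcnemar_test(a, a.copy())
        assert p == 1.0 and "degenerate" in method


class TestNearestCentroid:
    def _fixture(self, rng, n_genes=30, n_centroids=3):
        genes = [f"g{i}" for i in range(n_genes)]
        cents = pd.DataFrame(rng.normal(size=(n_genes, n_centroids)), index=genes,
                             columns=[f"c{i}" for i in range(n_centroids)])
        return genes, cents

    def test_sample_equal_to_centroid(self, rng):
        genes, cents = self._fixture(rng)
        vals = cents[["c1"]].rename(columns={"c1": "sample"})
        out = ib.classify_nearest_centroid(vals, cents)
        assert out["sample"] == "c1"

    def test_negated_sample_prefers_other_centroid(self, rng):
        genes, cents = self._fixture(rng, n_centroids=2)
        vals = (-cents[["c0"]]).rename(columns={"c0": "sample"})
        out = ib.classify_nearest_centroid(vals, cents)
        assert out["sample"] == "c1"

    def test_matches_brute_force_argmax(self, rng):
        from scipy.stats import spearmanr

        genes, cents = self._fixture(rng)
        vals = pd.DataFrame(rng.normal(size=(30, 8)), index=genes,
                            columns=[f"s{i}" for i in range(8)])
        out = ib.classify_nearest_centroid(vals, cents)
        for s in vals.columns:
            cors = [spearmanr(vals[s], cents[c])[0] for c in cents.columns]
            assert out[s] == cents.columns[int(np.argmax(cors))]

    def test_insufficient_overlap_rejected(self, rng):
        genes, cents = self._fixture(rng)
        vals = pd.DataFrame(rng.normal(size=(3, 2)), index=["x1", "x2", "x3"],
                            columns=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            ib.classify_nearest_centroid(vals, cents)
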