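"""Co-expression network: bicor, soft threshold, TOM, modules, preservation."""

import numpy as np
import pandas as pd
import pytest

import ibcnet as ib
from ibcnet.network import _eigengene, signed_adjacency


def _df(arr):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"g{i}" for i in range(arr.shape[0])],
                        columns=[f"s{i}" for i in range(arr.shape[1])])


class TestBicor:
    def test_affine_relation_gives_unit_correlation(self, rng):
        x = rng.normal(size=20)
        vals = _df(np.vstack([x, 2 * x + 1]))
        c = ib.bicor(vals)
        assert c.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_close_to_pearson_for_bivariate_normal(self, rng):
        cov = [[1, 0.5], [0.5, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=1000).T
        c = ib.bicor(_df(xy))
        pearson = np.corrcoef(xy)[0, 1]
        assert abs(c.iloc[0, 1] - pearson) < 0.05

    def test_more_robust_to_gross_outlier_than_pearson(self):
        wins = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=30)
            y = x + 0.3 * r.normal(size=30)
            xo = x.copy()
            xo[0] = 40.0  # gross outlier
            c = ib.bicor(_df(np.vstack([xo, y])))
            pearson = np.corrcoef(xo, y)[0, 1]
            wins += abs(c.iloc[0, 1]) > abs(pearson)
        assert wins >= 95

    def test_symmetry_and_range(self, random_expression):
        c = ib.bicor(random_expression).to_numpy()
        assert np.abs(c - c.T).max() <= 1e-12
        assert c.min() >= -1.0 and c.max() <= 1.0
        np.testing.assert_allclose(np.diag(c), 1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="4 samples"):
            ib.bicor(_df(np.ones((3, 3))))


class TestSoftThreshold:
    def test_adjacency_monotone_decreasing_in_beta(self, random_expression):
        cor = ib.bicor(random_expression)
        a3 = signed_adjacency(cor, 3)
        a6 = signed_adjacency(cor, 6)
        off = ~np.eye(a3.shape[0], dtype=bool)
        strict = cor.to_numpy()[off] < 1
        assert (a6[off][strict] < a3[off][strict]).all()

    def test_identity_correlation_is_degenerate(self):
        cor = pd.DataFrame(np.eye(30), index=range(30), columns=range(30))
        params = ib.pick_soft_threshold(cor)
        # constant connectivity: no valid fit anywhere, flagged via NaN R^2
        assert params.fit_table["r2"].isna().all()

    def test_planted_modules_reach_scale_free_fit(self, three_module_compendium):
        cor = ib.bicor(three_module_compendium.values)
        params = ib.pick_soft_threshold(cor)
        assert params.fit_table.loc[params.beta, "r2"] >= 0.8


class TestTOM:
    def test_complete_graph_gives_unit_overlap(self):
        A = np.ones((6, 6))
        T, D = ib.tom(A)
        np.testing.assert_allclose(T, 1.0)
        np.testing.assert_allclose(D, 0.0)

    def test_single_edge_hand_computation(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 1.0
        T, _ = ib.tom(A)
        assert T[0, 1] == pytest.approx(1.0)

    def test_zero_adjacency_gives_zero_overlap(self):
        A = np.eye(5)
        T, _ = ib.tom(A)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(T[off], 0.0)

    def test_matches_triple_loop_brute_force(self, rng):
        n = 30
        raw = rng.random((n, n))
        A = (raw + raw.T) / 2
        np.fill_diagonal(A, 1.0)
        T, _ = ib.tom(A)
        k = A.sum(axis=1) - 1.0
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
                expect = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
                assert T[i, j] == pytest.approx(expect, abs=1e-12)

    def test_asymmetric_input_rejected(self, rng):
        A = rng.random((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            ib.tom(A)


class TestDetectModules:
    def test_planted_modules_recovered(self, three_module_compendium):
        from sklearn.metrics import adjusted_rand_score

        comp = three_module_compendium
        _, assign, _ = ib.build_network(comp.values, min_size=100)
        ari = adjusted_rand_score(comp.module_truth, assign.labels)
        assert ari >= 0.9
        assert (assign.sizes >= 100).all()

    def test_same_factor_blocks_end_up_in_one_module(self):
        # two planted blocks driven by the same latent factor, against a
        # noise background, collapse into a single module
        rng = np.random.default_rng(0)
        factor = rng.normal(size=12)
        load = 2 * (0.3 + np.abs(rng.standard_normal(200)))
        signal = np.outer(load, factor)
        noise = rng.normal(0, 1, size=(200, 12))
        background = rng.normal(0, 1, size=(200, 12))
        vals = _df(np.vstack([signal + noise, background]))
        _, assign, _ = ib.build_network(vals, beta=6, min_size=50)
        labels = assign.labels
        block_mods = set(labels.iloc[:200]) - {0}
        assert len(block_mods) == 1
        # the two halves of the planted signal share that module
        m = block_mods.pop()
        assert (labels.iloc[:100] == m).mean() > 0.8
        assert (labels.iloc[100:200] == m).mean() > 0.8

    def test_pure_noise_rarely_yields_many_modules(self):
        bad = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            vals = _df(r.normal(size=(400, 12)))
            _, assign, _ = ib.build_network(vals, beta=6, min_size=100)
            n_mods = len(set(assign.labels) - {0})
            bad += n_mods > 3
        assert bad <= 2

    def test_min_size_larger_than_genes_rejected(self, random_expression):
        _, dissim = ib.tom(signed_adjacency(ib.bicor(random_expression), 6))
        with pytest.raises(ValueError, match="min_size"):
            ib.detect_modules(dissim, random_expression, min_size=1000)


class TestEigengene:
    def test_perfectly_correlated_module_has_unit_gmm(self, rng):
        base = rng.normal(size=10)
        vals = _df(np.vstack([base * s for s in (1.0, 2.0, 0.5, 3.0)]))
        assign = ib.ModuleAssignment(labels=pd.Series([1, 1, 1, 1], index=vals.index))
        gm = ib.module_eigengene(vals, assign)
        np.testing.assert_allclose(gm.gmm["M1"], 1.0, atol=1e-10)

    def test_orientation_convention_survives_global_negation(self, rng):
        vals = _df(rng.normal(size=(20, 10)))
        vals.iloc[:10] += np.outer(np.ones(10), rng.normal(size=10)) * 2
        assign = ib.ModuleAssignment(labels=pd.Series([1] * 10 + [0] * 10, index=vals.index))
        gm1 = ib.module_eigengene(vals, assign)
        neg = vals.copy()
        neg.iloc[:10] *= -1
        gm2 = ib.module_eigengene(neg, assign)
        member_sign_1 = np.sign(gm1.gmm["M1"].iloc[:10].mean())
        member_sign_2 = np.sign(gm2.gmm["M1"].iloc[:10].mean())
        assert member_sign_1 == member_sign_2 == 1.0

    def test_members_have_higher_gmm_than_non_members(self, three_module_compendium):
        comp = three_module_compendium
        _, assign, gm = ib.build_network(comp.values, min_size=100)
        labels = assign.labels
        for col in gm.gmm.columns:
            m = int(col[1:])
            member = gm.gmm.loc[labels == m, col].abs().mean()
            non = gm.gmm.loc[labels != m, col].abs().mean()
            assert member - non >= 0.2

    def test_constant_module_rejected(self):
        vals = _df(np.ones((4, 6)))
        assign = ib.ModuleAssignment(labels=pd.Series([1] * 4, index=vals.index))
        with pytest.raises(ValueError, match="constant"):
            ib.module_eigengene(vals, assign)


class TestPreservation:
    def _paired_data(self, seed):
        spec = ib.CompendiumSpec(
            seed=seed, n_genes=400, modules=(ib.ModuleSpec(120, 2.0, "none"),),
            n_cell_lines_ibc=5, n_cell_lines_nibc=8, replicates_per_line=3,
        )
        comp = ib.generate_cell_line_compendium(spec)
        ann = comp.annotation
        ref = comp.values[ann.index[ann.phenotype == "IBC"]]
        test = comp.values[ann.index[ann.phenotype == "nIBC"]]
        assign = ib.ModuleAssignment(labels=pd.Series(comp.module_truth))
        return assign, ref, test

    def test_planted_module_well_preserved(self):
        assign, ref, test = self._paired_data(0)
        rep = ib.module_preservation(assign, ref, test, beta=12, n_perm=100, seed=0)
        assert rep.table.loc[1, "Zsummary"] >= 10
        assert rep.table.loc[1, "band"] == "good"

    def test_permuted_test_labels_destroy_preservation(self):
        assign, ref, test = self._paired_data(1)
        rng = np.random.default_rng(0)
        test_perm = test.copy()
        test_perm.index = rng.permutation(test.index)
        rep = ib.module_preservation(assign, ref, test_perm, beta=12, n_perm=100, seed=0)
        assert rep.table.loc[1, "Zsummary"] < 2
        assert rep.table.loc[1, "band"] == "poor"

    def test_band_boundaries(self):
        from ibcnet.network import preservation_band

        assert preservation_band(1.9) == "poor"
        assert preservation_band(2.0) == "moderate"
        assert preservation_band(9.9) == "moderate"
        assert preservation_band(10.0) == "good"

    def test_missing_genes_skip_module(self):
        assign, ref, test = self._paired_data(2)
        rep = ib.module_preservation(assign, ref, test.iloc[5:], beta=12,
                                     n_perm=20, seed=0)
        assert rep.skipped == (1,)
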