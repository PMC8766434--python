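"""Preprocessing chain: filtering, batch correction, normalization, collapsing."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ibcnet as ib
from ibcnet.preprocess import DEFAULT_EXPRESSION_THRESHOLD


def _frame(rows, columns=None):
    arr = np.asarray(rows, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"g{i}" for i in range(arr.shape[0])],
        columns=columns or [f"s{i}" for i in range(arr.shape[1])],
    )


class TestFilterExpressed:
    def test_row_below_background_removed(self):
        vals = _frame([[5.0, 5.0, 5.0], [7.0, 7.0, 5.0]])
        out = ib.filter_expressed(vals)
        assert list(out.index) == ["g1"]  # two entries above log2(100) ~ 6.64

    def test_threshold_minus_infinity_is_identity(self):
        vals = _frame([[1.0, 2.0], [3.0, 4.0]])
        out = ib.filter_expressed(vals, threshold=-math.inf)
        pd.testing.assert_frame_equal(out, vals)

    def test_min_samples_exceeding_columns_errors(self):
        with pytest.raises(ValueError, match="min_samples"):
            ib.filter_expressed(_frame([[7.0, 7.0]]), min_samples=3)

    def test_order_preserved(self):
        vals = _frame([[9, 9, 9], [1, 1, 1], [8, 8, 8]])
        out = ib.filter_expressed(vals)
        assert list(out.index) == ["g0", "g2"]


class TestCorrectBatch:
    def test_constant_shift_removed_exactly(self, rng):
        # equal-variance genes: the EB prior mean coincides with every
        # per-gene batch effect, so the adjustment is exact mean-centering
        pattern = rng.normal(0, 1, 6)
        offsets = rng.normal(8, 2, 40)
        base = offsets[:, None] + pattern[None, :]
        vals = _frame(np.concatenate([base, base + 3.0], axis=1))
        batch = pd.Series(["a"] * 6 + ["b"] * 6, index=vals.columns)
        adj = ib.correct_batch(vals, batch)
        diff = adj.iloc[:, :6].mean(axis=1) - adj.iloc[:, 6:].mean(axis=1)
        assert diff.abs().max() <= 1e-6

    def test_single_batch_unchanged(self, random_expression):
        batch = pd.Series(["only"] * 12, index=random_expression.columns)
        out = ib.correct_batch(random_expression, batch)
        pd.testing.assert_frame_equal(out, random_expression)

    def test_planted_covariate_effect_preserved(self, rng):
        base = rng.normal(8, 1, size=(60, 12))
        cov = pd.Series(["x", "y"] * 6)
        base[:, (cov == "y").to_numpy()] += 2.0
        base[:, 6:] += 3.0
        vals = _frame(base)
        cov.index = vals.columns
        batch = pd.Series(["a"] * 6 + ["b"] * 6, index=vals.columns)
        adj = ib.correct_batch(vals, batch, cov)
        eff = adj.loc[:, cov == "y"].mean(axis=1) - adj.loc[:, cov == "x"].mean(axis=1)
        assert eff.mean() == pytest.approx(2.0, abs=0.1)
        assert (eff > 0).all()  # planted effect sign unchanged per gene

    def test_confounded_covariate_raises(self, random_expression):
        batch = pd.Series(["a"] * 6 + ["b"] * 6, index=random_expression.columns)
        cov = pd.Series(["x"] * 6 + ["y"] * 6, index=random_expression.columns)
        with pytest.raises(ValueError, match="confounded"):
            ib.correct_batch(random_expression, batch, cov)

    def test_batch_variance_fraction_below_one_percent(self):
        comp = ib.generate_cell_line_compendium(ib.CompendiumSpec(
            seed=0, n_genes=300, modules=(ib.ModuleSpec(80, 2.0, "IBC"),),
            n_cell_lines_ibc=8, n_cell_lines_nibc=8, n_batches=2, batch_shift_sd=1.0,
        ))
        adj = ib.correct_batch(comp.values, comp.annotation["batch"],
                               comp.annotation[["replicate_group"]])
        b = pd.get_dummies(comp.annotation["batch"]).to_numpy(dtype=float)
        fracs = []
        for g in range(adj.shape[0]):
            y = adj.iloc[g].to_numpy()
            yc = y - y.mean()
            beta, *_ = np.linalg.lstsq(b, yc, rcond=None)
            fracs.append(1 - ((yc - b @ beta) ** 2).sum() / (yc ** 2).sum())
        assert np.mean(fracs) < 0.01


class TestQuantileNormalize:
    def test_two_column_example(self):
        vals = _frame(np.array([[1, 4], [2, 5], [3, 6]]))
        out = ib.quantile_normalize(vals)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.to_numpy(), expected)

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 2.0])
        vals = _frame(np.column_stack([col, col, col]))
        out = ib.quantile_normalize(vals)
        np.testing.assert_allclose(out.to_numpy(), vals.to_numpy())

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_columns_share_sorted_values(self, seed):
        rng = np.random.default_rng(seed)
        vals = _frame(rng.normal(0, 3, size=(15, 4)))
        out = ib.quantile_normalize(vals).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_averaged(self):
        vals = _frame(np.array([[1.0, 5.0], [1.0, 6.0], [2.0, 7.0]]))
        out = ib.quantile_normalize(vals)
        # tied entries share the average of the means at their rank span
        assert out.iloc[0, 0] == out.iloc[1, 0]


class TestCollapseProbes:
    def test_highest_sd_probe_kept(self):
        vals = _frame([[0, 4, 8], [3, 4, 5]])
        pm = pd.Series({"g0": "GENE", "g1": "GENE"})
        out = ib.collapse_probes(vals, pm)
        assert out.shape[0] == 1
        np.testing.assert_allclose(out.iloc[0], [0, 4, 8])

    def test_tie_breaks_to_lexicographically_first(self):
        vals = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["p2", "p1"],
                            columns=["s0", "s1"])
        pm = pd.Series({"p1": "GENE", "p2": "GENE"})
        out = ib.collapse_probes(vals, pm)
        np.testing.assert_allclose(out.loc["GENE"], [1.0, 2.0])
        # the kept row is probe p1 (checked via a marker value)
        vals.loc["p1", "s0"] = 7.0
        out = ib.collapse_probes(vals, pm)
        assert out.loc["GENE", "s0"] == 7.0

    def test_matches_brute_force_argmax(self, rng):
        vals = _frame(rng.normal(size=(10, 6)))
        genes = [f"GENE{i % 5}" for i in range(10)]
        pm = pd.Series(genes, index=vals.index)
        out = ib.collapse_probes(vals, pm)
        for gene in set(genes):
            probes = [p for p, g in pm.items() if g == gene]
            best = max(sorted(probes), key=lambda p: vals.loc[p].std())
            np.testing.assert_allclose(out.loc[gene], vals.loc[best])

    def test_unmapped_probe_listed(self, rng):
        vals = _frame(rng.normal(size=(3, 4)))
        pm = pd.Series({"g0": "A", "g1": "B"})
        with pytest.raises(KeyError, match="g2"):
            ib.collapse_probes(vals, pm)


class TestAverageReplicates:
    def test_group_mean(self):
        vals = _frame(np.array([[0, 2], [2, 4]]))
        groups = pd.Series(["L1", "L1"], index=vals.columns)
        out = ib.average_replicates(vals, groups)
        np.testing.assert_allclose(out["L1"], [1, 3])

    def test_singleton_groups_identity_up_to_names(self, random_expression):
        groups = pd.Series(random_expression.columns, index=random_expression.columns)
        out = ib.average_replicates(random_expression, groups)
        np.testing.assert_allclose(out.to_numpy(), random_expression.to_numpy())

    def test_first_appearance_column_order(self):
        vals = _frame(np.ones((2, 4)))
        groups = pd.Series(["B", "A", "B", "A"], index=vals.columns)
        out = ib.average_replicates(vals, groups)
        assert list(out.columns) == ["B", "A"]

    def test_empty_label_rejected(self):
        vals = _frame(np.ones((2, 2)))
        groups = pd.Series(["A", ""], index=vals.columns)
        with pytest.raises(ValueError, match="empty"):
            ib.average_replicates(vals, groups)


class TestChain:
    def test_collapse_filter_commute_when_filter_keeps_kept_probes(self, rng):
        vals = _frame(rng.normal(12, 1, size=(10, 6)))  # all above threshold
        pm = pd.Series([f"GENE{i % 5}" for i in range(10)], index=vals.index)
        a = ib.collapse_probes(ib.filter_expressed(vals), pm)
        b = ib.filter_expressed(ib.collapse_probes(vals, pm))
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_full_chain_shapes(self, small_compendium):
        out = ib.run_preprocess(small_compendium)
        assert out.shape[1] == 10  # one column per cell line
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        # averaging happens after quantile normalization, so columns need not
        # share sorted values; but the matrix must be finite and gene-indexed
        assert np.isfinite(sorted_cols).all()
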