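"""Normalization, marker typing, TF split, Mann-Whitney DEG stage, BH."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from tfgate.annotation_io import CellMatrix
from tfgate.scrna_stage import (
    DEGConfig,
    classify_cells,
    diff_expr,
    expressed_genes,
    normalize_counts,
    split_by_tf,
    summarize_panel,
)

from oracles import bh_stepup, mannwhitney_permutation_p


def matrix_from_dense(dense, cell_prefix="c", gene_prefix="g", meta=None):
    dense = np.asarray(dense)
    return CellMatrix(
        sp.csr_matrix(dense.astype(np.int64)),
        [f"{cell_prefix}{i}" for i in range(dense.shape[0])],
        [f"{gene_prefix}{j}" for j in range(dense.shape[1])],
        meta,
    )


class TestNormalize:
    def test_cp10k_scaling(self):
        mat = matrix_from_dense([[10, 0, 90]])
        norm = normalize_counts(mat)
        np.testing.assert_allclose(
            norm.cp10k.toarray(), [[1000.0, 0.0, 9000.0]]
        )

    def test_zero_total_cell_excluded_with_warning(self):
        mat = matrix_from_dense([[1, 2], [0, 0]])
        with pytest.warns(UserWarning, match="zero total"):
            norm = normalize_counts(mat)
        assert norm.cell_ids == ("c0",)
        assert norm.excluded_cells == ("c1",)

    def test_row_sums_equal_10k(self, rng):
        dense = rng.integers(0, 20, size=(50, 30))
        dense[dense.sum(axis=1) == 0, 0] = 1
        norm = normalize_counts(matrix_from_dense(dense))
        np.testing.assert_allclose(
            np.asarray(norm.cp10k.sum(axis=1)).ravel(), 10_000.0
        )

    def test_empty_matrix_is_error(self):
        with pytest.raises(ValueError):
            normalize_counts(
                CellMatrix(sp.csr_matrix((0, 3)), [], ["g0", "g1", "g2"])
            )


class TestClassify:
    MARKERS = {"rod": ["g0", "g1"], "bipolar": ["g2", "g3"]}

    def test_pure_marker_expression_forces_label(self):
        mat = matrix_from_dense([[50, 50, 0, 0], [0, 0, 50, 50]])
        labels = classify_cells(normalize_counts(mat), self.MARKERS)
        assert list(labels) == ["rod", "bipolar"]

    def test_tied_scores_are_unassigned(self):
        mat = matrix_from_dense([[10, 10, 10, 10]])
        labels = classify_cells(normalize_counts(mat), self.MARKERS)
        assert list(labels) == ["unassigned"]

    def test_no_marker_genes_at_all_is_error(self):
        mat = matrix_from_dense([[1, 2]])
        with pytest.warns(UserWarning, match="absent"):
            with pytest.raises(ValueError, match="no marker gene"):
                classify_cells(normalize_counts(mat), {"rod": ["absent"]})

    def test_missing_markers_warn_but_present_ones_score(self):
        mat = matrix_from_dense([[50, 0, 0, 0]])
        markers = {"rod": ["g0", "absent"], "bipolar": ["g2"]}
        with pytest.warns(UserWarning, match="absent"):
            labels = classify_cells(normalize_counts(mat), markers)
        assert list(labels) == ["rod"]

    def test_recovers_planted_types_on_synthetic_data(self, bundle):
        norm = normalize_counts(bundle.matrix)
        labels = classify_cells(norm, bundle.truth.marker_map)
        truth = pd.Series(bundle.truth.cell_types).loc[labels.index]
        assert (labels == truth).mean() >= 0.95


class TestSplitByTF:
    CFG = DEGConfig(tf_gene_id="g0")

    def test_threshold_one_partitions_on_any_count(self):
        mat = matrix_from_dense([[0], [1], [3], [0]])
        pos, neg = split_by_tf(mat, ["c0", "c1", "c2", "c3"], self.CFG)
        assert set(pos) == {"c1", "c2"}
        assert set(neg) == {"c0", "c3"}

    def test_no_positive_side_is_named_in_error(self):
        mat = matrix_from_dense([[0], [1], [3], [0]])
        cfg = DEGConfig(tf_gene_id="g0", positive_threshold=4)
        with pytest.raises(ValueError, match="TF-positive"):
            split_by_tf(mat, ["c0", "c1", "c2", "c3"], cfg)

    def test_empty_subset_is_error(self):
        mat = matrix_from_dense([[1]])
        with pytest.raises(ValueError, match="empty"):
            split_by_tf(mat, [], self.CFG)

    def test_partition_property_on_random_inputs(self, rng):
        dense = rng.integers(0, 3, size=(100, 2))
        dense[0, 0] = 1  # guarantee both sides non-empty
        dense[1, 0] = 0
        mat = matrix_from_dense(dense)
        subset = [f"c{i}" for i in range(100)]
        pos, neg = split_by_tf(mat, subset, self.CFG)
        assert set(pos) | set(neg) == set(subset)
        assert not set(pos) & set(neg)


class TestDiffExpr:
    CFG = DEGConfig(tf_gene_id="g0")

    @staticmethod
    def _norm_from_values(a_vals, b_vals):
        """Build a normalized matrix whose CP10K values equal the inputs.

        Two constant companion genes absorb the library so that the gene
        under test carries exactly the requested values after scaling.
        """
        a_vals, b_vals = np.asarray(a_vals, float), np.asarray(b_vals, float)
        values = np.concatenate([a_vals, b_vals])
        dense = np.column_stack([values, 10_000 - values - 1, np.ones_like(values)])
        mat = CellMatrix(
            sp.csr_matrix(dense.astype(np.int64)),
            [f"a{i}" for i in range(len(a_vals))]
            + [f"b{i}" for i in range(len(b_vals))],
            ["gene", "filler", "one"],
        )
        norm = normalize_counts(mat)
        a_ids = [f"a{i}" for i in range(len(a_vals))]
        b_ids = [f"b{i}" for i in range(len(b_vals))]
        return norm, a_ids, b_ids

    def test_identical_constant_groups_are_null(self):
        norm, a, b = self._norm_from_values([5, 5, 5, 5], [5, 5, 5, 5])
        table = diff_expr(norm, a, b, self.CFG)
        assert table.loc["gene", "p_value"] == 1.0
        assert table.loc["gene", "log2_fold_change"] == 0.0

    def test_exact_p_matches_full_permutation_enumeration(self):
        a_vals, b_vals = [1, 2, 3, 4], [5, 6, 7, 8]
        norm, a, b = self._norm_from_values(a_vals, b_vals)
        table = diff_expr(norm, a, b, self.CFG)
        expected = mannwhitney_permutation_p(a_vals, b_vals)
        assert expected == pytest.approx(2 / 70)
        assert table.loc["gene", "p_value"] == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_p_matches_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        a_vals = rng.integers(0, 4, size=6).tolist()
        b_vals = rng.integers(0, 4, size=7).tolist()
        if len(set(a_vals + b_vals)) == 1:
            a_vals[0] += 1
        norm, a, b = self._norm_from_values(a_vals, b_vals)
        table = diff_expr(norm, a, b, self.CFG)
        assert table.loc["gene", "p_value"] == pytest.approx(
            mannwhitney_permutation_p(a_vals, b_vals)
        )

    def test_label_symmetry(self, rng):
        dense = rng.integers(0, 12, size=(30, 20))
        dense[:, 0] += 1  # keep totals positive
        mat = matrix_from_dense(dense)
        norm = normalize_counts(mat)
        a = [f"c{i}" for i in range(15)]
        b = [f"c{i}" for i in range(15, 30)]
        t_ab = diff_expr(norm, a, b, self.CFG)
        t_ba = diff_expr(norm, b, a, self.CFG)
        np.testing.assert_allclose(t_ab["p_value"], t_ba["p_value"], atol=1e-12)
        np.testing.assert_allclose(
            t_ab["log2_fold_change"], -t_ba["log2_fold_change"], atol=1e-12
        )

    def test_overlapping_groups_error(self):
        norm, a, b = self._norm_from_values([1, 2, 3], [4, 5, 6])
        with pytest.raises(ValueError, match="overlap"):
            diff_expr(norm, a, a, self.CFG)

    def test_planted_degs_recovered_with_fdr_control(self, bundle, deg_config):
        """4x planted effects in disease rods: sensitivity >= 0.9, FDR <= 0.1."""
        norm = normalize_counts(bundle.matrix)
        labels = classify_cells(norm, bundle.truth.marker_map)
        meta = bundle.matrix.cell_meta.set_index("cell_id")
        focal = [
            c
            for c in norm.cell_ids
            if meta.loc[c, "group"] == "OIR"
            and meta.loc[c, "timepoint"] == "P14"
            and labels.loc[c] == "rod"
        ]
        pos, neg = split_by_tf(bundle.matrix, focal, deg_config)
        table = diff_expr(norm, pos, neg, deg_config)
        called = set(table.index[table["significant"]])
        planted = set(bundle.truth.planted_degs)
        sensitivity = len(called & planted) / len(planted)
        fdr = len(called - planted) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.1


class TestBH:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200)
    )
    def test_q_values_match_stepup_oracle(self, p):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(np.array(p), method="fdr_bh")[1]
        np.testing.assert_allclose(q, bh_stepup(p), atol=1e-12)

    def test_rejections_are_prefix_of_p_sorted_order(self, rng):
        p = rng.random(300) ** 3
        q = bh_stepup(p)
        order = np.argsort(p, kind="stable")
        rejected = (q <= 0.05)[order]
        first_accept = np.argmax(~rejected) if (~rejected).any() else len(p)
        assert not rejected[first_accept:].any()


class TestExpressedGenes:
    def test_examples_and_oracle(self, rng):
        dense = rng.integers(0, 2, size=(60, 25)) * rng.integers(0, 5, size=(60, 25))
        dense[:, 0] = 1  # everywhere detected
        dense[:, 1] = 0  # never detected
        mat = matrix_from_dense(dense)
        cfg = DEGConfig(tf_gene_id="g0", expressed_min_fraction=0.1)
        subset = [f"c{i}" for i in range(60)]
        result = expressed_genes(mat, subset, cfg)
        assert "g0" in result
        assert "g1" not in result
        frac = (dense > 0).mean(axis=0)
        expected = {f"g{j}" for j in range(25) if frac[j] >= 0.1}
        assert result == expected


class TestSummarizePanel:
    def _setup(self):
        dense = np.array(
            [
                [8, 3],
                [8, 3],
                [64, 3],
                [64, 3],
            ]
        )
        meta = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(4)],
                "group": ["normal", "normal", "OIR", "OIR"],
                "timepoint": ["P14"] * 4,
            }
        )
        mat = matrix_from_dense(dense, meta=meta)
        norm = normalize_counts(mat)
        labels = pd.Series(["rod"] * 4, index=[f"c{i}" for i in range(4)])
        return norm, labels, meta

    def test_two_condition_z_scores_are_pm_one(self):
        norm, labels, meta = self._setup()
        means, z, missing = summarize_panel(norm, labels, ["g0"], meta)
        assert missing == []
        np.testing.assert_allclose(
            z.loc["g0", ["normal_P14", "OIR_P14"]].to_numpy(), [-1.0, 1.0]
        )

    def test_absent_panel_gene_flagged_and_omitted(self):
        norm, labels, meta = self._setup()
        with pytest.warns(UserWarning, match="ghost"):
            means, _, missing = summarize_panel(norm, labels, ["g0", "ghost"], meta)
        assert missing == ["ghost"]
        assert list(means.index) == ["g0"]

    def test_means_equal_brute_force_group_means(self, rng):
        n = 40
        dense = rng.integers(0, 10, size=(n, 6)) + 1
        meta = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "group": rng.choice(["normal", "OIR"], size=n),
                "timepoint": rng.choice(["P14", "P17"], size=n),
            }
        )
        mat = matrix_from_dense(dense, meta=meta)
        norm = normalize_counts(mat)
        labels = pd.Series(
            rng.choice(["rod", "bipolar"], size=n), index=[f"c{i}" for i in range(n)]
        )
        panel = [f"g{j}" for j in range(6)]
        means, _, _ = summarize_panel(norm, labels, panel, meta)
        log_vals = np.log1p(
            dense / dense.sum(axis=1, keepdims=True) * 10_000
        )
        for cond in means.columns:
            group, tp = cond.split("_")
            mask = (
                (meta["group"] == group)
                & (meta["timepoint"] == tp)
                & (labels.to_numpy() == "rod")
            ).to_numpy()
            if not mask.any():
                assert means[cond].isna().all()
                continue
            for j, g in enumerate(panel):
                np.testing.assert_allclose(
                    means.loc[g, cond], log_vals[mask, j].mean(), rtol=1e-9
                )
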