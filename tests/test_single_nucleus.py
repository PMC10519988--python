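import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from notchtrunc.single_nucleus import (
    CountMatrix,
    compare_ratio_groups,
    endothelial_normalize,
    lognormalize,
    marker_table,
    pseudobulk,
    qc_filter,
    remove_doublet_clusters,
    select_coexpressing,
    target_ratio,
)


def tiny_matrix(counts, mito=None, **cell_cols):
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = pd.DataFrame(
        {"mito": mito if mito is not None else [False] * n_genes},
        index=pd.Index([f"G{i}" for i in range(n_genes)], name="gene"),
    )
    defaults = {
        "sample": ["S1"] * n_cells,
        "doublet_score": [0.0] * n_cells,
        "label": ["x"] * n_cells,
    }
    defaults.update(cell_cols)
    cells = pd.DataFrame(defaults, index=pd.Index([f"C{i}" for i in range(n_cells)], name="cell"))
    return CountMatrix(counts, genes, cells)


class TestQcFilter:
    def _matrix_with_detected(self, detected_counts, n_genes=8000):
        cols = []
        for d in detected_counts:
            col = np.zeros(n_genes, dtype=int)
            col[:d] = 1
            cols.append(col)
        return tiny_matrix(np.column_stack(cols))

    def test_gene_count_boundaries(self):
        m = self._matrix_with_detected([999, 1000, 7500, 7501])
        filtered, report = qc_filter(m)
        assert list(filtered.cell_ids) == ["C1", "C2"]
        assert report.removed_low_genes == 1 and report.removed_high_genes == 1

    def test_mito_boundary_removed_at_10pct(self):
        counts = np.zeros((2000, 2), dtype=int)
        counts[:1500, :] = 1  # 1500 detected genes each
        mito = [True] + [False] * 1999
        counts[0, 0] = 150 + 149  # cell 0: mito 299/(1499+299) well above 10%
        m = tiny_matrix(counts, mito=mito)
        frac = m.mito_fraction_per_cell()
        assert frac[0] >= 0.10 > frac[1]
        filtered, report = qc_filter(m)
        assert report.removed_high_mito == 1 and filtered.n_cells == 1

    def test_exactly_10pct_removed(self):
        counts = np.zeros((3000, 1), dtype=int)
        counts[:2000] = 1
        counts[0] = 200  # 200 mito of 200+1999 -> 0.0909... keep? compute exact
        mito = [True] + [False] * 2999
        m = tiny_matrix(counts, mito=mito)
        # construct exact 10%: mito 222, other 1998 -> 222/2220 = 0.1
        counts2 = np.zeros((3000, 1), dtype=int)
        counts2[1:1999] = 1
        counts2[0] = 222
        m2 = tiny_matrix(counts2, mito=mito)
        assert m2.mito_fraction_per_cell()[0] == pytest.approx(0.10)
        _, report = qc_filter(m2)
        assert report.removed_high_mito == 1

    def test_no_mito_genes_warns_and_skips(self):
        m = self._matrix_with_detected([1500, 2000])
        with pytest.warns(UserWarning, match="mito"):
            filtered, report = qc_filter(m)
        assert filtered.n_cells == 2
        assert report.notes

    def test_qc_commutes_with_subsetting(self, counts_matrix):
        full, _ = qc_filter(counts_matrix)
        half_mask = np.arange(counts_matrix.n_cells) % 2 == 0
        sub, _ = qc_filter(counts_matrix.subset_cells(half_mask))
        kept_full = set(full.cell_ids) & set(counts_matrix.cell_ids[half_mask])
        assert kept_full == set(sub.cell_ids)


class TestLognormalize:
    def test_count_one_of_ten_thousand(self):
        counts = np.zeros((2, 1), dtype=int)
        counts[0, 0] = 1
        counts[1, 0] = 9999
        m = tiny_matrix(counts)
        assert lognormalize(m)[0, 0] == pytest.approx(np.log(2.0))

    def test_zero_count_maps_to_zero(self):
        m = tiny_matrix([[0, 1], [5, 5]])
        assert lognormalize(m)[0, 0] == 0.0

    def test_depth_invariance(self):
        a = tiny_matrix([[1, 0], [3, 4]])
        b = tiny_matrix([[2, 0], [6, 8]])
        np.testing.assert_allclose(lognormalize(a), lognormalize(b))

    def test_zero_total_cell_rejected(self):
        m = tiny_matrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="zero-total"):
            lognormalize(m)


class TestDoubletClusters:
    def test_planted_doublet_cluster_removed(self):
        rng = np.random.default_rng(0)
        singlet = rng.poisson(5, size=(50, 80))
        doublet = rng.poisson(5, size=(50, 20))
        counts = np.hstack([singlet, doublet])
        scores = np.concatenate([rng.uniform(0, 0.05, 80), rng.uniform(0.4, 0.8, 20)])
        m = tiny_matrix(counts, doublet_score=scores)
        labels = np.array([0] * 80 + [1] * 20)
        filtered, report = remove_doublet_clusters(m, cluster_labels=labels)
        assert filtered.n_cells == 80
        assert report.removed_doublet_clusters == 20

    def test_all_zero_scores_nothing_removed(self):
        m = tiny_matrix(np.random.default_rng(1).poisson(5, size=(30, 40)))
        filtered, report = remove_doublet_clusters(m, cluster_labels=np.zeros(40, dtype=int))
        assert filtered.n_cells == 40 and report.removed_doublet_clusters == 0

    def test_cluster_mean_exactly_threshold_retained(self):
        counts = np.random.default_rng(2).poisson(5, size=(20, 10))
        m = tiny_matrix(counts, doublet_score=[0.1] * 10)
        filtered, report = remove_doublet_clusters(m, cluster_labels=np.zeros(10, dtype=int))
        assert filtered.n_cells == 10
        m2 = tiny_matrix(counts, doublet_score=[0.100001] * 10)
        filtered2, _ = remove_doublet_clusters(m2, cluster_labels=np.zeros(10, dtype=int))
        assert filtered2.n_cells == 0

    def test_missing_scores_rejected(self):
        m = tiny_matrix(np.ones((5, 4), dtype=int))
        m.cells = m.cells.drop(columns="doublet_score")
        with pytest.raises(ValueError, match="doublet_score"):
            remove_doublet_clusters(m, cluster_labels=np.zeros(4, dtype=int))


class TestSelectCoexpressing:
    def test_gating(self):
        counts = np.array(
            [
                [5, 0, 2],  # REN
                [3, 4, 1],  # NOTCH1
                [2, 6, 0],  # NRARP
                [10, 10, 10],
            ]
        )
        m = tiny_matrix(counts)
        m.genes.index = pd.Index(["REN", "NOTCH1", "NRARP", "OTHER"], name="gene")
        mask = select_coexpressing(m)
        np.testing.assert_array_equal(mask, [True, False, False])

    def test_empty_gene_list_selects_all(self):
        m = tiny_matrix([[1, 2], [3, 4]])
        assert select_coexpressing(m, genes=()).all()

    def test_absent_gene_named(self):
        m = tiny_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="MISSING"):
            select_coexpressing(m, genes=("MISSING",))


class TestMarkerTable:
    def test_planted_marker_found(self):
        rng = np.random.default_rng(3)
        n_a, n_b = 300, 700
        counts = rng.poisson(3, size=(40, n_a + n_b))
        counts[7, :n_a] = rng.poisson(24, size=n_a)  # 8-fold marker in cluster a
        m = tiny_matrix(counts)
        labels = np.array(["a"] * n_a + ["b"] * n_b)
        table = marker_table(m, labels)
        hits = table[(table["cluster"] == "a") & (table["log2fc"] > 0)]
        assert "G7" in set(hits["gene"])

    def test_low_detection_gene_excluded(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, size=(30, 200))
        # gene 3: detected in only ~5% of cluster a, but huge where present
        counts[3] = 0
        idx = rng.choice(100, size=5, replace=False)
        counts[3, idx] = 500
        m = tiny_matrix(counts)
        labels = np.array(["a"] * 100 + ["b"] * 100)
        table = marker_table(m, labels)
        assert "G3" not in set(table.loc[table["cluster"] == "a", "gene"])

    def test_identical_clusters_empty(self):
        counts = np.tile(np.arange(1, 21)[:, None], (1, 40))
        m = tiny_matrix(counts)
        labels = np.array(["a", "b"] * 20)
        assert marker_table(m, labels).empty

    def test_singleton_cluster_skipped(self):
        counts = np.random.default_rng(5).poisson(4, size=(10, 21))
        m = tiny_matrix(counts)
        labels = np.array(["a"] * 20 + ["b"])
        with pytest.warns(UserWarning, match="singleton"):
            marker_table(m, labels)


def ratio_frame(**overrides):
    base = dict(
        cell=[f"C{i}" for i in range(6)],
        target=["HEYL"] * 6,
        ratio=[2.0, 4.0, 6.0, 1.0, 2.0, 3.0],
        sample=["S1"] * 6,
        label=["tumour", "tumour", "tumour", "endothelial", "endothelial", "endothelial"],
    )
    base.update(overrides)
    return pd.DataFrame(base)


class TestTargetRatio:
    def test_equal_values_give_ratio_one(self):
        counts = np.array([[3, 3], [3, 3], [1, 1]])
        m = tiny_matrix(counts)
        m.genes.index = pd.Index(["HEYL", "NRARP", "OTHER"], name="gene")
        out = target_ratio(m, targets=("HEYL",))
        np.testing.assert_allclose(out["ratio"], 1.0)

    def test_zero_denominator_excluded_and_counted(self):
        counts = np.array([[3, 5], [3, 0], [1, 1]])
        m = tiny_matrix(counts)
        m.genes.index = pd.Index(["HEYL", "NRARP", "OTHER"], name="gene")
        out = target_ratio(m, targets=("HEYL",))
        assert len(out) == 1
        assert out.attrs["n_excluded"]["HEYL"] == 1

    def test_absent_denominator_rejected(self):
        m = tiny_matrix([[1, 2], [3, 4]])
        with pytest.raises(ValueError, match="NRARP"):
            target_ratio(m, targets=("G0",), denominator="NRARP")


class TestEndothelialNormalize:
    def test_direct_arithmetic(self):
        df = ratio_frame(ratio=[6.0, 6.0, 6.0, 1.0, 2.0, 3.0])
        out = endothelial_normalize(df)
        assert out.loc[0, "normalized_ratio"] == pytest.approx(3.0)  # endo median 2

    def test_self_normalization_median_one(self):
        df = ratio_frame()
        out = endothelial_normalize(df)
        endo = out[out["label"] == "endothelial"]
        assert endo["normalized_ratio"].median() == pytest.approx(1.0)

    def test_second_application_with_same_reference_divides_again(self):
        from notchtrunc.single_nucleus import endothelial_median_reference

        df = ratio_frame()
        ref = endothelial_median_reference(df)
        once = endothelial_normalize(df, reference=ref)
        twice = endothelial_normalize(
            once.drop(columns="ratio").rename(columns={"normalized_ratio": "ratio"}),
            reference=ref,
        )
        np.testing.assert_allclose(
            twice["normalized_ratio"], once["normalized_ratio"] / ref[("S1", "HEYL")]
        )
        assert not np.allclose(once["normalized_ratio"], twice["normalized_ratio"])

    def test_missing_endothelium_lists_sample(self):
        df = ratio_frame(label=["tumour"] * 6)
        with pytest.raises(ValueError, match="S1"):
            endothelial_normalize(df)


class TestCompareRatioGroups:
    def test_identical_groups_nonsignificant(self, rng):
        vals = rng.uniform(1, 2, size=100)
        df = pd.DataFrame(
            {
                "target": ["HEYL"] * 100,
                "normalized_ratio": vals,
                "label": ["tumour", "mesangial"] * 50,
            }
        )
        out = compare_ratio_groups(df)
        assert (out["padj"] > 0.05).all()

    def test_label_permutation_null_uniform(self, rng):
        vals = rng.normal(10, 2, size=120)
        pvals = []
        for _ in range(200):
            labels = rng.permutation(["tumour"] * 60 + ["mesangial"] * 60)
            df = pd.DataFrame(
                {"target": "HEYL", "normalized_ratio": vals, "label": labels}
            )
            pvals.append(compare_ratio_groups(df)["pvalue"].iloc[0])
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_group_skipped_and_reported(self):
        df = pd.DataFrame(
            {"target": ["HEYL"] * 3, "normalized_ratio": [1.0, 2.0, 3.0], "label": ["tumour"] * 3}
        )
        out = compare_ratio_groups(df)
        assert out.empty and out.attrs["skipped"] == ["HEYL"]


class TestPseudobulk:
    def test_single_cell_groups(self):
        counts = np.array([[1, 2], [3, 4]])
        m = tiny_matrix(counts, label=["a", "b"])
        pb = pseudobulk(m)
        np.testing.assert_array_equal(pb["a"], [1, 3])
        np.testing.assert_array_equal(pb["b"], [2, 4])

    def test_conservation(self, counts_matrix):
        pb = pseudobulk(counts_matrix, group_key="truth")
        np.testing.assert_array_equal(pb.sum(axis=1), counts_matrix.counts.sum(axis=1))

    def test_two_mesangial_samples_two_columns(self):
        counts = np.random.default_rng(0).poisson(4, size=(10, 6))
        m = tiny_matrix(counts, label=["mes1", "mes1", "mes1", "mes2", "mes2", "mes2"])
        assert list(pseudobulk(m).columns) == ["mes1", "mes2"]

    def test_missing_key_rejected(self, counts_matrix):
        with pytest.raises(ValueError, match="nope"):
            pseudobulk(counts_matrix, group_key="nope")
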