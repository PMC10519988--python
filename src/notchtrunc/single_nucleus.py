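"""Single-nucleus QC, normalization, gating and the endothelial-normalized
target/denominator expression-ratio statistic.

The processing order mirrors the intended pipeline: gene-count and
mitochondrial QC, doublet-cluster removal on an over-clustered manifold,
log-normalization to 10,000 counts per cell (natural log), co-expression
gating, per-nucleus target/denominator ratios, per-sample endothelial-median
normalization, and rank-based group comparisons with Benjamini-Hochberg
control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import benjamini_hochberg, bonferroni, rank_sum_test

__all__ = [
    "CountMatrix",
    "QCReport",
    "qc_filter",
    "overcluster",
    "remove_doublet_clusters",
    "lognormalize",
    "select_coexpressing",
    "marker_table",
    "target_ratio",
    "endothelial_median_reference",
    "endothelial_normalize",
    "compare_ratio_groups",
    "pseudobulk",
    "run_ratio_pipeline",
    "DEFAULT_TARGETS",
    "MIN_GENES",
    "MAX_GENES",
    "MAX_MITO_FRACTION",
    "DOUBLET_CLUSTER_MEAN",
]

MIN_GENES = 1000
MAX_GENES = 7500
MAX_MITO_FRACTION = 0.10
DOUBLET_CLUSTER_MEAN = 0.10
DOUBLET_CALL_THRESHOLD = 0.25
TARGET_SCALE = 1e4

DEFAULT_TARGETS = ("HEYL", "HEY1", "HEY2", "HES1", "HES4", "HES5")


@dataclass
class CountMatrix:
    """Genes x cells integer counts with aligned metadata frames.

    ``genes`` is indexed by gene name with at least a boolean ``mito``
    column; ``cells`` is indexed by cell barcode with ``sample``,
    ``doublet_score`` and (optionally) ``label``/``truth`` columns.
    """

    counts: np.ndarray
    genes: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x cells)")
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match metadata "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.genes.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.cells.index

    def detected_genes_per_cell(self) -> np.ndarray:
        return (self.counts > 0).sum(axis=0)

    def total_counts_per_cell(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def mito_fraction_per_cell(self) -> np.ndarray:
        mito = self.genes["mito"].to_numpy(dtype=bool)
        totals = self.total_counts_per_cell().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = self.counts[mito].sum(axis=0) / totals
        return np.where(totals > 0, frac, 0.0)

    def subset_cells(self, mask) -> "CountMatrix":
        mask = np.asarray(mask)
        return CountMatrix(self.counts[:, mask], self.genes, self.cells.iloc[mask].copy())

    def gene_row(self, gene: str) -> np.ndarray:
        if gene not in self.genes.index:
            raise KeyError(f"gene {gene!r} absent from matrix")
        return self.counts[self.genes.index.get_loc(gene)]


@dataclass
class QCReport:
    n_input: int
    n_kept: int
    removed_low_genes: int = 0
    removed_high_genes: int = 0
    removed_high_mito: int = 0
    removed_doublet_clusters: int = 0
    removed_doublet_calls: int = 0
    notes: list = field(default_factory=list)


def qc_filter(
    matrix: CountMatrix,
    min_genes: int = MIN_GENES,
    max_genes: int = MAX_GENES,
    max_mito: float = MAX_MITO_FRACTION,
) -> tuple[CountMatrix, QCReport]:
    """Keep cells with min_genes <= detected genes <= max_genes and a
    mitochondrial fraction strictly below ``max_mito``."""
    detected = matrix.detected_genes_per_cell()
    low = detected < min_genes
    high = detected > max_genes
    notes = []
    if "mito" not in matrix.genes.columns or not matrix.genes["mito"].any():
        warnings.warn("no mitochondrial genes flagged; mito rule skipped")
        notes.append("mito rule skipped: no flagged genes")
        mito_fail = np.zeros(matrix.n_cells, dtype=bool)
    else:
        mito_fail = matrix.mito_fraction_per_cell() >= max_mito
    keep = ~(low | high | mito_fail)
    report = QCReport(
        n_input=matrix.n_cells,
        n_kept=int(keep.sum()),
        removed_low_genes=int(low.sum()),
        removed_high_genes=int(high.sum()),
        removed_high_mito=int(mito_fail.sum()),
        notes=notes,
    )
    return matrix.subset_cells(keep), report


def lognormalize(matrix: CountMatrix, scale: float = TARGET_SCALE) -> np.ndarray:
    """ln(1 + scale * count / cell_total); natural log, per-cell scaling."""
    totals = matrix.total_counts_per_cell().astype(float)
    if (totals == 0).any():
        bad = matrix.cell_ids[totals == 0].tolist()
        raise ValueError(f"zero-total cells present (should be QC-filtered): {bad[:5]}")
    return np.log1p(scale * matrix.counts / totals)


def _variable_gene_mask(norm: np.ndarray, n_top: int) -> np.ndarray:
    var = norm.var(axis=1)
    n_top = min(n_top, norm.shape[0])
    keep = np.argsort(var)[::-1][:n_top]
    mask = np.zeros(norm.shape[0], dtype=bool)
    mask[keep] = True
    return mask


def _regress_out(norm: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    # residual of each gene on the covariate matrix (with intercept)
    X = np.column_stack([np.ones(covariates.shape[0]), covariates])
    beta, *_ = np.linalg.lstsq(X, norm.T, rcond=None)
    return norm - (X @ beta).T


def overcluster(
    matrix: CountMatrix,
    n_variable_genes: int = 2000,
    n_pcs: int = 30,
    k: int | None = None,
    random_state: int = 0,
) -> np.ndarray:
    """Built-in over-clustering: log-normalize, take the most variable
    genes, regress out totals and mito fraction, PCA, k-means with
    k = max(20, cells/50). External labels bypass this entirely."""
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_cells = matrix.n_cells
    if k is None:
        k = max(20, n_cells // 50)
    if k > n_cells:
        warnings.warn(f"k={k} exceeds {n_cells} cells; reducing")
        k = n_cells
    norm = lognormalize(matrix)
    norm = norm[_variable_gene_mask(norm, n_variable_genes)]
    covs = np.column_stack(
        [
            np.log1p(matrix.total_counts_per_cell().astype(float)),
            matrix.mito_fraction_per_cell(),
        ]
    )
    resid = _regress_out(norm, covs)
    n_pcs = min(n_pcs, min(resid.shape) - 1)
    pcs = PCA(n_components=n_pcs, random_state=random_state).fit_transform(resid.T)
    km = KMeans(n_clusters=k, random_state=random_state, n_init=4)
    return km.fit_predict(pcs)


def remove_doublet_clusters(
    matrix: CountMatrix,
    cluster_labels: np.ndarray | None = None,
    mean_score_threshold: float = DOUBLET_CLUSTER_MEAN,
    call_threshold: float = DOUBLET_CALL_THRESHOLD,
    random_state: int = 0,
) -> tuple[CountMatrix, QCReport]:
    """Drop whole clusters whose mean doublet score exceeds the threshold
    (strict >), then drop any remaining individually-called doublets."""
    if "doublet_score" not in matrix.cells.columns:
        raise ValueError("cell metadata lacks 'doublet_score'")
    scores = matrix.cells["doublet_score"].to_numpy(dtype=float)
    if cluster_labels is None:
        cluster_labels = overcluster(matrix, random_state=random_state)
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape[0] != matrix.n_cells:
        raise ValueError("cluster labels do not match cell count")
    drop = np.zeros(matrix.n_cells, dtype=bool)
    for cl in np.unique(cluster_labels):
        members = cluster_labels == cl
        if scores[members].mean() > mean_score_threshold:
            drop |= members
    n_cluster_removed = int(drop.sum())
    calls = (~drop) & (scores > call_threshold)
    n_call_removed = int(calls.sum())
    drop |= calls
    report = QCReport(
        n_input=matrix.n_cells,
        n_kept=int((~drop).sum()),
        removed_doublet_clusters=n_cluster_removed,
        removed_doublet_calls=n_call_removed,
    )
    return matrix.subset_cells(~drop), report


def select_coexpressing(
    matrix: CountMatrix,
    genes=("REN", "NOTCH1", "NRARP"),
    norm: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean cell mask: log-normalized expression > 0 for every gene."""
    if norm is None:
        norm = lognormalize(matrix)
    mask = np.ones(matrix.n_cells, dtype=bool)
    for gene in genes:
        if gene not in matrix.genes.index:
            raise ValueError(f"gene {gene!r} absent from matrix")
        mask &= norm[matrix.genes.index.get_loc(gene)] > 0
    return mask


def marker_table(
    matrix: CountMatrix,
    labels,
    min_pct: float = 0.10,
    min_abs_log2fc: float = 0.2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster marker genes: rank-sum vs all other cells, requiring
    in-cluster detection >= min_pct, |log2FC| >= threshold and a
    Bonferroni-adjusted p <= alpha.

    log2FC is computed on expm1 of mean log-normalized values with a
    pseudocount of 1.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != matrix.n_cells:
        raise ValueError("labels do not match cell count")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least two clusters")
    norm = lognormalize(matrix)
    detected = matrix.counts > 0
    rows = []
    for cl in uniq:
        members = labels == cl
        if members.sum() < 2:
            warnings.warn(f"cluster {cl!r} is a singleton; skipped")
            continue
        inside, outside = norm[:, members], norm[:, ~members]
        pct = detected[:, members].mean(axis=1)
        lfc = np.log2((np.expm1(inside.mean(axis=1)) + 1) / (np.expm1(outside.mean(axis=1)) + 1))
        candidates = np.flatnonzero((pct >= min_pct) & (np.abs(lfc) >= min_abs_log2fc))
        if candidates.size == 0:
            continue
        res = sps.mannwhitneyu(
            inside[candidates], outside[candidates], axis=1, alternative="two-sided"
        )
        padj = bonferroni(res.pvalue) if candidates.size > 1 else np.minimum(res.pvalue, 1.0)
        for gi, p, pa in zip(candidates, res.pvalue, padj):
            if pa <= alpha:
                rows.append(
                    {
                        "cluster": cl,
                        "gene": matrix.gene_names[gi],
                        "pct_in": float(pct[gi]),
                        "log2fc": float(lfc[gi]),
                        "pvalue": float(p),
                        "padj": float(pa),
                    }
                )
    return pd.DataFrame(rows, columns=["cluster", "gene", "pct_in", "log2fc", "pvalue", "padj"])


def target_ratio(
    matrix: CountMatrix,
    targets=DEFAULT_TARGETS,
    denominator: str = "NRARP",
    norm: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-nucleus target/denominator ratios of log-normalized values.

    Only nuclei with both the target and the denominator expressed
    (normalized value > 0) contribute; excluded nuclei are counted in the
    ``n_excluded`` attribute of the returned frame.
    """
    if denominator not in matrix.genes.index:
        raise ValueError(f"denominator gene {denominator!r} absent from matrix")
    if norm is None:
        norm = lognormalize(matrix)
    den = norm[matrix.genes.index.get_loc(denominator)]
    frames = []
    n_excluded = {}
    for tgt in targets:
        if tgt not in matrix.genes.index:
            raise ValueError(f"target gene {tgt!r} absent from matrix")
        num = norm[matrix.genes.index.get_loc(tgt)]
        ok = (num > 0) & (den > 0)
        n_excluded[tgt] = int((~ok).sum())
        frames.append(
            pd.DataFrame(
                {
                    "cell": matrix.cell_ids[ok],
                    "target": tgt,
                    "ratio": num[ok] / den[ok],
                    "sample": matrix.cells["sample"].to_numpy()[ok],
                    "label": matrix.cells["label"].to_numpy()[ok]
                    if "label" in matrix.cells.columns
                    else "",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["cell", "target", "ratio", "sample", "label"]
    )
    out.attrs["n_excluded"] = n_excluded
    return out


def endothelial_median_reference(
    ratios: pd.DataFrame,
    endothelial_label: str = "endothelial",
    label_column: str = "label",
) -> dict:
    """Per-(sample, target) median endothelial ratio."""
    out = {}
    for (sample, tgt), sub in ratios.groupby(["sample", "target"]):
        endo = sub.loc[sub[label_column] == endothelial_label, "ratio"]
        if endo.empty:
            raise ValueError(
                f"no endothelial nuclei with defined {tgt!r} ratio in sample {sample!r}"
            )
        out[(sample, tgt)] = float(endo.median())
    return out


def endothelial_normalize(
    ratios: pd.DataFrame,
    endothelial_label: str = "endothelial",
    label_column: str = "label",
    reference: dict | None = None,
) -> pd.DataFrame:
    """Divide each ratio by the per-sample, per-target endothelial median.

    ``reference`` may supply precomputed medians (as returned by
    :func:`endothelial_median_reference`); by default they are recomputed
    from the input. Note the operation always divides: re-applying it with
    the same fixed reference divides a second time.
    """
    if reference is None:
        reference = endothelial_median_reference(ratios, endothelial_label, label_column)
    out = ratios.copy()
    out["normalized_ratio"] = np.nan
    for (sample, tgt), idx in out.groupby(["sample", "target"]).groups.items():
        if (sample, tgt) not in reference:
            raise ValueError(f"no endothelial reference for {tgt!r} in sample {sample!r}")
        out.loc[idx, "normalized_ratio"] = out.loc[idx, "ratio"] / reference[(sample, tgt)]
    return out


def compare_ratio_groups(
    ratios: pd.DataFrame,
    group_a: str = "tumour",
    group_b: str = "mesangial",
    value_column: str = "normalized_ratio",
    label_column: str = "label",
) -> pd.DataFrame:
    """Per-target two-sided rank-sum of group_a vs group_b, BH-adjusted
    across the target family. Empty comparisons are skipped and reported."""
    rows = []
    skipped = []
    for tgt, sub in ratios.groupby("target"):
        a = sub.loc[sub[label_column] == group_a, value_column].to_numpy()
        b = sub.loc[sub[label_column] == group_b, value_column].to_numpy()
        if a.size == 0 or b.size == 0:
            skipped.append(tgt)
            continue
        res = rank_sum_test(a, b)
        rows.append(
            {
                "target": tgt,
                "n_a": a.size,
                "n_b": b.size,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "statistic": res.statistic,
                "pvalue": res.pvalue,
            }
        )
    out = pd.DataFrame(rows, columns=["target", "n_a", "n_b", "median_a", "median_b", "statistic", "pvalue"])
    out["padj"] = benjamini_hochberg(out["pvalue"].to_numpy()) if len(out) else []
    out.attrs["skipped"] = skipped
    return out


def pseudobulk(matrix: CountMatrix, group_key: str = "label") -> pd.DataFrame:
    """Per-gene sums of raw counts per metadata group."""
    if group_key not in matrix.cells.columns:
        raise ValueError(f"group key {group_key!r} not in cell metadata")
    groups = matrix.cells[group_key].to_numpy()
    cols = {}
    for grp in pd.unique(groups):
        cols[grp] = matrix.counts[:, groups == grp].sum(axis=1)
    return pd.DataFrame(cols, index=matrix.gene_names)


def run_ratio_pipeline(
    matrix: CountMatrix,
    targets=DEFAULT_TARGETS,
    denominator: str = "NRARP",
    tumour_label: str = "tumour",
    reference_label: str = "mesangial",
    endothelial_label: str = "endothelial",
    cluster_labels: np.ndarray | None = None,
    random_state: int = 0,
) -> dict:
    """End-to-end: QC -> doublet-cluster removal -> normalize -> ratios ->
    endothelial normalization -> group tests (plus a REN comparison)."""
    filtered, qc_report = qc_filter(matrix)
    filtered, doublet_report = remove_doublet_clusters(
        filtered, cluster_labels=cluster_labels, random_state=random_state
    )
    norm = lognormalize(filtered)
    ratios = target_ratio(filtered, targets=targets, denominator=denominator, norm=norm)
    normalized = endothelial_normalize(ratios, endothelial_label=endothelial_label)
    tests = compare_ratio_groups(normalized, group_a=tumour_label, group_b=reference_label)

    labels = filtered.cells["label"].to_numpy()
    ren = norm[filtered.genes.index.get_loc("REN")] if "REN" in filtered.genes.index else None
    ren_test = None
    if ren is not None:
        a = ren[labels == tumour_label]
        b = ren[labels == reference_label]
        if a.size and b.size:
            res = rank_sum_test(a, b)
            ren_test = {
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
            }
    # one BH family across every comparison made (targets + REN)
    if ren_test is not None and len(tests):
        family = benjamini_hochberg(np.append(tests["pvalue"].to_numpy(), ren_test["pvalue"]))
        tests["padj"] = family[:-1]
        ren_test["padj"] = float(family[-1])
    elif ren_test is not None:
        ren_test["padj"] = ren_test["pvalue"]
    return {
        "matrix": filtered,
        "qc_report": qc_report,
        "doublet_report": doublet_report,
        "ratios": normalized,
        "tests": tests,
        "ren_test": ren_test,
    }
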