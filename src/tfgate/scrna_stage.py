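"""Single-cell stage: normalization, marker typing, TF split, DEG testing.

Cells are normalized to counts-per-10k with a log1p transform, typed by the
mean normalized expression of per-type marker genes (argmax with a score
margin; ties are unassigned), and the cell type of interest — rod
photoreceptors here — is split into TF-positive and TF-negative groups on
the raw count of the TF gene.  Differential expression between the two
groups uses the two-sided Mann-Whitney U test (tie-corrected normal
approximation; exact enumeration when both groups have <= 8 cells) with
Benjamini-Hochberg FDR control, and log2 fold changes of group means on the
CP10K scale with a pseudocount.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
import yaml
from statsmodels.stats.multitest import multipletests

from .annotation_io import CellMatrix

TARGET_SUM = 10_000.0

#: Maximum per-group size for the exact Mann-Whitney enumeration path.
EXACT_MAX_N = 8


@dataclass(frozen=True)
class DEGConfig:
    """Thresholds of the TF+/TF- differential-expression comparison.

    tf_gene_id
        Gene used to split cells into TF-positive / TF-negative.
    positive_threshold
        Minimal raw count for a cell to be TF-positive (default 1).
    alpha_fdr
        BH false-discovery-rate cutoff (default 0.05).
    min_abs_log2fc
        Minimal |log2 fold change| for a DEG call (default 0.25).
    expressed_min_fraction
        A gene is "expressed" when detected (raw count > 0) in at least this
        fraction of the cells under consideration (default 0.01).
    pseudocount
        Added to group means on the CP10K scale before the log ratio.
    """

    tf_gene_id: str = ""
    alpha_fdr: float = 0.05
    min_abs_log2fc: float = 0.25
    positive_threshold: int = 1
    expressed_min_fraction: float = 0.01
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ValueError("alpha_fdr must be in (0, 1)")
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be non-negative")
        if self.positive_threshold <= 0:
            raise ValueError("positive_threshold must be positive")
        if not 0 < self.expressed_min_fraction <= 1:
            raise ValueError("expressed_min_fraction must be in (0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


@dataclass
class NormalizedMatrix:
    """CP10K-normalized expression aligned with the source raw matrix.

    ``cp10k`` rows sum to 10,000 (pre-log); ``log1p`` is its elementwise
    log(1 + x) used for scoring and rank tests.  Cells with zero total count
    are excluded and listed in ``excluded_cells``.
    """

    cp10k: sp.csr_matrix
    cell_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    excluded_cells: tuple[str, ...] = ()

    @property
    def log1p(self) -> sp.csr_matrix:
        return self.cp10k.log1p()

    def cell_indices(self, cell_ids: Iterable[str]) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.cell_ids)}
        return np.array([lookup[c] for c in cell_ids], dtype=int)


def load_marker_map(source) -> dict[str, list[str]]:
    """Read a cell_type -> marker gene list map from YAML."""
    from .annotation_io import _open_text

    with _open_text(source) as fh:
        raw = yaml.safe_load(fh)
    markers = {str(k): [str(g) for g in v] for k, v in raw.items()}
    for cell_type, genes in markers.items():
        if not genes:
            raise ValueError(f"marker list for {cell_type!r} is empty")
    return markers


def normalize_counts(matrix: CellMatrix) -> NormalizedMatrix:
    """Scale each cell to 10,000 total counts (CP10K).

    Cells with zero total are excluded with a warning — they carry no
    expression information and would divide by zero.
    """
    if matrix.counts.shape[0] == 0 or matrix.counts.shape[1] == 0:
        raise ValueError("cannot normalize an empty matrix")
    totals = np.asarray(matrix.counts.sum(axis=1)).ravel()
    keep = totals > 0
    excluded = tuple(c for c, k in zip(matrix.cell_ids, keep) if not k)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} cell(s) with zero total counts",
            stacklevel=2,
        )
    counts = sp.csr_matrix(matrix.counts[keep], dtype=float)
    scale = TARGET_SUM / totals[keep]
    cp10k = sp.diags(scale) @ counts
    return NormalizedMatrix(
        cp10k=sp.csr_matrix(cp10k),
        cell_ids=tuple(c for c, k in zip(matrix.cell_ids, keep) if k),
        gene_ids=matrix.gene_ids,
        excluded_cells=excluded,
    )


def classify_cells(
    norm: NormalizedMatrix,
    markers: Mapping[str, Sequence[str]],
    min_score_margin: float = 0.25,
) -> pd.Series:
    """Label cells by the highest mean marker score; close calls unassigned.

    The score of a cell for a type is the mean log1p(CP10K) over that type's
    marker genes present in the matrix.  A cell is labeled with the argmax
    type unless the top score beats the runner-up by less than
    ``min_score_margin`` (ties included), in which case it is "unassigned".
    Marker genes absent from the matrix are dropped with a warning; if no
    marker gene is found at all this is an error.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    log_mat = norm.log1p
    scores = {}
    missing: dict[str, list[str]] = {}
    for cell_type, marker_genes in markers.items():
        idx = [gene_pos[g] for g in marker_genes if g in gene_pos]
        absent = [g for g in marker_genes if g not in gene_pos]
        if absent:
            missing[cell_type] = absent
        if idx:
            scores[cell_type] = np.asarray(log_mat[:, idx].mean(axis=1)).ravel()
    if missing:
        warnings.warn(f"marker genes absent from matrix: {missing}", stacklevel=2)
    if not scores:
        raise ValueError("no marker gene of any cell type is present in the matrix")
    score_mat = np.column_stack([scores[t] for t in scores])
    types = list(scores)
    order = np.argsort(score_mat, axis=1)
    top = order[:, -1]
    top_score = score_mat[np.arange(len(top)), top]
    if score_mat.shape[1] > 1:
        runner = score_mat[np.arange(len(top)), order[:, -2]]
    else:
        runner = np.full(len(top), -np.inf)
    labels = np.array([types[i] for i in top], dtype=object)
    labels[top_score - runner < min_score_margin] = "unassigned"
    return pd.Series(labels, index=list(norm.cell_ids), name="cell_type")


def split_by_tf(
    matrix: CellMatrix, cell_subset: Sequence[str], config: DEGConfig
) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Partition a cell subset into TF-positive and TF-negative groups.

    A cell is TF-positive iff its raw count of the TF gene is at least
    ``positive_threshold``.  An empty subset or an empty side is an error —
    the downstream two-group comparison would be meaningless.
    """
    subset = list(cell_subset)
    if not subset:
        raise ValueError("cell subset is empty")
    gi = matrix.gene_index(config.tf_gene_id)
    rows = matrix.cell_indices(subset)
    tf_counts = np.asarray(matrix.counts[rows, gi].todense()).ravel()
    pos_mask = tf_counts >= config.positive_threshold
    positives = tuple(c for c, m in zip(subset, pos_mask) if m)
    negatives = tuple(c for c, m in zip(subset, pos_mask) if not m)
    if not positives:
        raise ValueError(
            f"no TF-positive cells at threshold {config.positive_threshold}"
        )
    if not negatives:
        raise ValueError(
            f"no TF-negative cells at threshold {config.positive_threshold}"
        )
    return positives, negatives


def _exact_mannwhitney(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by full enumeration of group labelings.

    Returns (U of group a, p).  The p-value is the fraction of the
    C(n1+n2, n1) relabelings whose U deviates from the null mean n1*n2/2 at
    least as much as observed; tie-safe because ranks are fixed.
    """
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    base = n1 * (n1 + 1) / 2
    for idx in itertools.combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - base
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return float(u_obs), count / total


def diff_expr(
    norm: NormalizedMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    config: DEGConfig,
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney DEG test of group A vs group B.

    Returns a DataFrame indexed by gene_id with columns log2_fold_change
    (A over B, CP10K means + pseudocount), test_statistic (U of group A),
    p_value, q_value (BH), direction, and significant (q < alpha and
    |log2FC| >= min_abs_log2fc).  Groups must be disjoint with >= 3 cells
    each.  Genes with identical values in all cells get p = 1 by convention.
    """
    a_ids, b_ids = list(group_a), list(group_b)
    overlap = set(a_ids) & set(b_ids)
    if overlap:
        raise ValueError(f"groups overlap on {len(overlap)} cell(s)")
    if len(a_ids) < 3 or len(b_ids) < 3:
        raise ValueError("each group needs at least 3 cells")
    cp10k = norm.cp10k
    rows_a = norm.cell_indices(a_ids)
    rows_b = norm.cell_indices(b_ids)
    dense_a = np.asarray(cp10k[rows_a].todense())
    dense_b = np.asarray(cp10k[rows_b].todense())
    n1, n2 = len(a_ids), len(b_ids)
    n_genes = dense_a.shape[1]

    constant = np.array(
        [
            np.ptp(np.concatenate([dense_a[:, g], dense_b[:, g]])) == 0
            for g in range(n_genes)
        ]
    )
    pvals = np.ones(n_genes)
    stats = np.full(n_genes, n1 * n2 / 2.0)
    varying = ~constant
    if varying.any():
        if n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N:
            for g in np.nonzero(varying)[0]:
                stats[g], pvals[g] = _exact_mannwhitney(dense_a[:, g], dense_b[:, g])
        else:
            res = scipy.stats.mannwhitneyu(
                dense_a[:, varying],
                dense_b[:, varying],
                axis=0,
                alternative="two-sided",
                method="asymptotic",
            )
            stats[varying] = res.statistic
            pvals[varying] = np.clip(np.nan_to_num(res.pvalue, nan=1.0), 0.0, 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    mean_a = dense_a.mean(axis=0)
    mean_b = dense_b.mean(axis=0)
    lfc = np.log2((mean_a + config.pseudocount) / (mean_b + config.pseudocount))
    direction = np.where(lfc > 0, "up", np.where(lfc < 0, "down", "flat"))
    significant = (qvals < config.alpha_fdr) & (np.abs(lfc) >= config.min_abs_log2fc)
    return pd.DataFrame(
        {
            "log2_fold_change": lfc,
            "test_statistic": stats,
            "p_value": pvals,
            "q_value": qvals,
            "direction": direction,
            "significant": significant,
        },
        index=pd.Index(norm.gene_ids, name="gene_id"),
    )


def expressed_genes(
    matrix: CellMatrix, cell_subset: Sequence[str], config: DEGConfig
) -> frozenset[str]:
    """Genes detected (raw count > 0) in >= expressed_min_fraction of cells."""
    subset = list(cell_subset)
    if not subset:
        raise ValueError("cell subset is empty")
    rows = matrix.cell_indices(subset)
    sub = matrix.counts[rows]
    detected = np.asarray((sub > 0).sum(axis=0)).ravel() / len(subset)
    keep = detected >= config.expressed_min_fraction
    return frozenset(g for g, k in zip(matrix.gene_ids, keep) if k)


def summarize_panel(
    norm: NormalizedMatrix,
    labels: pd.Series,
    panel: Sequence[str],
    cell_meta: pd.DataFrame,
    cell_type: str = "rod",
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Mean normalized expression of a gene panel per condition in one type.

    Returns (means, row z-scores, missing genes).  Rows are panel genes
    present in the matrix, columns are condition labels (group_timepoint);
    a condition with no cells of the requested type yields NaN.  Z-scores
    are per-row with population (ddof=0) standard deviation, NaN for
    constant rows.
    """
    gene_pos = {g: i for i, g in enumerate(norm.gene_ids)}
    present = [g for g in panel if g in gene_pos]
    missing = [g for g in panel if g not in gene_pos]
    if missing:
        warnings.warn(f"panel genes absent from matrix: {missing}", stacklevel=2)
    meta = cell_meta.copy()
    if "cell_id" not in meta.columns:
        raise ValueError("cell metadata must carry a cell_id column")
    meta = meta.set_index("cell_id").loc[list(norm.cell_ids)]
    cond_labels = meta["group"].astype(str) + "_" + meta["timepoint"].astype(str)
    in_type = labels.reindex(list(norm.cell_ids)) == cell_type
    log_mat = norm.log1p
    conditions = sorted(cond_labels.unique())
    means = pd.DataFrame(index=present, columns=conditions, dtype=float)
    for cond in conditions:
        mask = (cond_labels == cond).to_numpy() & in_type.to_numpy()
        if not mask.any():
            continue
        rows = np.nonzero(mask)[0]
        for g in present:
            means.loc[g, cond] = float(
                np.asarray(log_mat[rows, gene_pos[g]].todense()).mean()
            )
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=0)
    zscores = means.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return means, zscores, missing
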