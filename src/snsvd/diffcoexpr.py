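"""Differential miRNA-gene co-expression analysis.

Pipeline for matched two-condition expression data (e.g. tumor vs
adjacent normal): after expression filtering, log transform,
differential-expression prefiltering and KNN imputation, condition-wise
Pearson correlation matrices between genes and miRNAs are formed,

    X1[g, m] = corr(gene g, miRNA m | condition 1),
    X2[g, m] = corr(gene g, miRNA m | condition 2),
    X = X1 - X2,

and the sparse network-regularized SVD is run on the differential
matrix X (gene rows carry the network penalty, miRNA columns the
cardinality constraint) to find differentially co-expressed
miRNA-gene modules.  Modules are evaluated by their average adPCC
(mean |X| over the module submatrix) with a permutation test against
size-matched random submatrices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .graph import normalized_laplacian
from .io import ExpressionMatrix, GeneNetwork, ModuleRecord, ModuleSet
from .selection import deflate
from .solver import SolverConfig

logger = logging.getLogger(__name__)


@dataclass
class MatchedExpressionSet:
    """Matched gene (A) and miRNA (B) expression for two conditions.

    A1/B1 share condition-1 samples, A2/B2 share condition-2 samples;
    the gene and miRNA universes are shared across conditions.
    """

    A1: ExpressionMatrix
    A2: ExpressionMatrix
    B1: ExpressionMatrix
    B2: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.A1.sample_ids != self.B1.sample_ids:
            raise ValueError("A1 and B1 must share sample IDs")
        if self.A2.sample_ids != self.B2.sample_ids:
            raise ValueError("A2 and B2 must share sample IDs")
        if self.A1.gene_ids != self.A2.gene_ids:
            raise ValueError("A1 and A2 must share gene IDs")
        if self.B1.gene_ids != self.B2.gene_ids:
            raise ValueError("B1 and B2 must share miRNA IDs")


@dataclass
class DifferentialCorrelation:
    """Condition-wise correlation matrices and their difference X = X1 - X2."""

    X1: np.ndarray
    X2: np.ndarray
    X: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)


@dataclass
class DEFilterResult:
    """Selected features plus the filtered, log-transformed matrices."""

    features: list[str]
    case: ExpressionMatrix
    control: ExpressionMatrix
    p_values: dict


def de_filter(
    case: ExpressionMatrix,
    control: ExpressionMatrix,
    alpha: float = 0.05,
    expressed_fraction: float = 0.70,
    log_transform: bool = True,
) -> DEFilterResult:
    """Expression filter + log2 transform + Wilcoxon rank-sum DE prefilter.

    A feature is dropped when its fraction of zero/missing raw values
    across all samples (both conditions pooled) exceeds
    ``expressed_fraction``; surviving values get ``log2(x + 1)``; a
    feature is selected when its two-sided Wilcoxon rank-sum p-value
    times the number of tested features (Bonferroni) is below
    ``alpha``.
    """
    if case.gene_ids != control.gene_ids:
        raise ValueError("case and control must share feature IDs")
    if case.shape[1] < 3 or control.shape[1] < 3:
        raise ValueError("need at least 3 samples per condition")
    pooled = np.hstack([case.values, control.values])
    absent = np.isnan(pooled) | (pooled == 0)
    keep = absent.mean(axis=1) <= expressed_fraction
    kept_ids = [g for g, k in zip(case.gene_ids, keep) if k]
    if not kept_ids:
        raise ValueError(
            "no feature passes the expression filter; relax expressed_fraction"
        )
    cv = case.values[keep]
    gv = control.values[keep]
    if log_transform:
        cv = np.log2(cv + 1.0)
        gv = np.log2(gv + 1.0)

    n_tests = len(kept_ids)
    p_values = {}
    selected = []
    for row, gene in enumerate(kept_ids):
        a = cv[row][~np.isnan(cv[row])]
        b = gv[row][~np.isnan(gv[row])]
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        p_values[gene] = p
        if p * n_tests < alpha:
            selected.append(gene)
    if not selected:
        raise ValueError(
            f"no differentially expressed feature at Bonferroni alpha={alpha}; "
            "consider relaxing alpha"
        )
    sel_rows = [kept_ids.index(g) for g in selected]
    return DEFilterResult(
        features=selected,
        case=ExpressionMatrix(cv[sel_rows], selected, case.sample_ids),
        control=ExpressionMatrix(gv[sel_rows], selected, control.sample_ids),
        p_values=p_values,
    )


def knn_impute(expr: ExpressionMatrix, k: int = 10) -> ExpressionMatrix:
    """Fill missing entries with the k-nearest-rows mean (scikit-learn).

    Rows are compared by nan-aware Euclidean distance over co-observed
    columns; each missing cell becomes the mean of that column over the
    k nearest rows with the value observed.  A fully missing row is a
    hard error.
    """
    if expr.n_missing == 0:
        return ExpressionMatrix(
            expr.values.copy(), expr.gene_ids, expr.sample_ids
        )
    if np.any(expr.missing_mask.all(axis=1)):
        bad = [
            g for g, row in zip(expr.gene_ids, expr.missing_mask) if row.all()
        ]
        raise ValueError(f"fully missing row(s): {bad[:5]}")
    from sklearn.impute import KNNImputer

    values = expr.values.copy()
    values[expr.missing_mask] = np.nan
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    filled = imputer.fit_transform(values)
    return ExpressionMatrix(filled, expr.gene_ids, expr.sample_ids)


def _row_standardize(values: np.ndarray) -> np.ndarray:
    """Center and scale rows to zero mean / unit variance; flat rows -> 0."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s); their correlations are 0",
            stacklevel=3,
        )
    sd = np.where(sd == 0, 1.0, sd)
    out = (values - mu) / sd
    out[flat] = 0.0
    return out


def differential_matrix(mset: MatchedExpressionSet) -> DifferentialCorrelation:
    """Pearson gene x miRNA correlations per condition and their difference."""
    a1 = _row_standardize(mset.A1.values)
    b1 = _row_standardize(mset.B1.values)
    a2 = _row_standardize(mset.A2.values)
    b2 = _row_standardize(mset.B2.values)
    x1 = np.clip((a1 @ b1.T) / a1.shape[1], -1.0, 1.0)
    x2 = np.clip((a2 @ b2.T) / a2.shape[1], -1.0, 1.0)
    return DifferentialCorrelation(
        X1=x1, X2=x2, X=x1 - x2,
        gene_ids=list(mset.A1.gene_ids), mirna_ids=list(mset.B1.gene_ids),
    )


def find_diff_modules(
    dc: DifferentialCorrelation,
    gene_net: GeneNetwork,
    cfg: SolverConfig | None = None,
    n_modules: int = 10,
    target_nnz_gene: int = 100,
    k_v_mirna: int = 10,
    n_restarts: int = 5,
    seed: int = 0,
) -> ModuleSet:
    """Top differentially co-expressed miRNA-gene modules via deflation.

    Genes play the role of u (network penalty on rows), miRNAs of v
    (cardinality constraint on columns).  Each module's stats carry its
    average adPCC (mean |X| over the module submatrix), induced
    gene-edge count and singular value.
    """
    if gene_net.nodes != list(dc.gene_ids):
        raise ValueError("network nodes must align with the gene rows of X")
    base = cfg or SolverConfig()
    run_cfg = SolverConfig(
        lambda_=base.lambda_, sigma=base.sigma, k_v=k_v_mirna,
        max_outer_iters=base.max_outer_iters, outer_tol=base.outer_tol,
        max_inner_sweeps=base.max_inner_sweeps, inner_tol=base.inner_tol,
        seed=base.seed,
    )
    lap = normalized_laplacian(gene_net) if run_cfg.sigma > 0 else None
    seq = deflate(
        dc.X, lap, run_cfg, n_modules, n_restarts=n_restarts, seed=seed,
        support_target=target_nnz_gene,
    )
    gene_index = np.asarray(dc.gene_ids, dtype=object)
    mirna_index = np.asarray(dc.mirna_ids, dtype=object)
    records = []
    for k, fp in enumerate(seq.factors, start=1):
        gi = np.flatnonzero(fp.u)
        mi = np.flatnonzero(fp.v)
        genes = set(gene_index[gi])
        mirnas = set(mirna_index[mi])
        adpcc = (
            float(np.abs(dc.X[np.ix_(gi, mi)]).mean()) if gi.size and mi.size else 0.0
        )
        records.append(
            ModuleRecord(
                module_index=k,
                genes=genes,
                samples=mirnas,  # the "sample" side of this factorization is the miRNA set
                d=fp.d,
                stats={
                    "adPCC": adpcc,
                    "n_gene_edges": gene_net.induced_edge_count(genes),
                    "d": fp.d,
                },
                gene_weights={g: float(fp.u[i]) for g, i in zip(gene_index[gi], gi)},
                sample_weights={m: float(fp.v[j]) for m, j in zip(mirna_index[mi], mi)},
            )
        )
    return ModuleSet(records)


def adPCC_permutation_test(
    dc: DifferentialCorrelation,
    module: ModuleRecord,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for a module's average adPCC.

    The statistic is the mean of |X| over the module's gene x miRNA
    submatrix; the null resamples same-shape submatrices with uniform
    random gene and miRNA index sets, and
    ``p = (1 + #{null >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    gidx = [dc.gene_ids.index(g) for g in sorted(module.genes)]
    midx = [dc.mirna_ids.index(m) for m in sorted(module.samples)]
    if not gidx or not midx:
        return 1.0
    absx = np.abs(dc.X)
    observed = float(absx[np.ix_(gidx, midx)].mean())
    rng = np.random.default_rng(seed)
    p_genes, p_mirnas = absx.shape
    count = 0
    for _ in range(n_perm):
        rg = rng.choice(p_genes, size=len(gidx), replace=False)
        rm = rng.choice(p_mirnas, size=len(midx), replace=False)
        if absx[np.ix_(rg, rm)].mean() >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def sigma_sweep(
    dc: DifferentialCorrelation,
    gene_net: GeneNetwork,
    sigmas=(0, 1, 10, 20, 40, 60, 80, 90, 100, 150, 200),
    n_modules: int = 10,
    target_nnz_gene: int = 100,
    k_v_mirna: int = 10,
    n_random: int = 20,
    n_restarts: int = 3,
    seed: int = 0,
):
    """Per-sigma module summary: mean induced edge count, fold change of
    that count versus size-matched random gene sets, and mean singular
    value.  Returns a pandas DataFrame (one row per sigma).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for sigma in sigmas:
        mods = find_diff_modules(
            dc, gene_net, SolverConfig(sigma=float(sigma)),
            n_modules=n_modules, target_nnz_gene=target_nnz_gene,
            k_v_mirna=k_v_mirna, n_restarts=n_restarts, seed=seed,
        )
        edge_counts = [m.stats["n_gene_edges"] for m in mods]
        d_values = [m.d for m in mods]
        random_counts = []
        for m in mods:
            for _ in range(n_random):
                pick = rng.choice(gene_net.n_nodes, size=m.n_genes, replace=False)
                random_counts.append(
                    gene_net.induced_edge_count([gene_net.nodes[i] for i in pick])
                )
        rand_avg = float(np.mean(random_counts)) if random_counts else np.nan
        edge_avg = float(np.mean(edge_counts)) if edge_counts else np.nan
        rows.append(
            {
                "sigma": sigma,
                "edge_avg": edge_avg,
                "fold_change": edge_avg / rand_avg if rand_avg else np.nan,
                "d_avg": float(np.mean(d_values)) if d_values else np.nan,
            }
        )
    return pd.DataFrame(rows)
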