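"""Module extraction (absolute z-score filter) and evaluation statistics.

A fitted factor pair (u, v) nominates genes and samples through its
nonzero loadings; the z-score filter then trims weakly loaded members:
for each nonzero loading x_ij of a factor column,

    z_ij = | |x_ij| - mu_j | / sigma_j,

where mu_j and sigma_j are the mean and standard deviation of the
absolute nonzero loadings of that column, and members with z_ij at or
above a threshold are kept.  Modules are scored by

* modularity: mean absolute pairwise Pearson correlation of the
  module's genes across the module's samples (in [0, 1]);
* gene-gene interaction enrichment: -log10 of the right-tailed
  hypergeometric probability of the module's induced edge count, given
  the network's edge density (score > 1.3, i.e. p < 0.05, flags a
  significantly inter-connected module);
* pairwise overlap significance between modules (right-tailed
  hypergeometric on both the gene and the sample overlap).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .io import ExpressionMatrix, GeneNetwork, ModuleRecord

_MIN_P = 1e-300  # floor before taking -log10


@dataclass
class ZScoreFilterConfig:
    threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ValueError("threshold must be nonnegative")


class InteractionEnrichment(NamedTuple):
    p_value: float
    score: float
    n_genes: int
    n_edges: int
    significant: bool


class OverlapSignificance(NamedTuple):
    p_genes: float
    p_samples: float
    significant: bool


def enrichment_score(p_value: float) -> float:
    """Interaction enrichment score s = -log10(p)."""
    return -math.log10(max(p_value, _MIN_P))


def _zscore_select(x: np.ndarray, threshold: float) -> np.ndarray:
    """Indices of entries passing the absolute z-score filter."""
    x = np.asarray(x, dtype=float).ravel()
    nz = np.flatnonzero(x)
    if nz.size < 2:
        if nz.size:
            warnings.warn(
                "fewer than 2 nonzero loadings; keeping members verbatim",
                stacklevel=3,
            )
        return nz
    a = np.abs(x[nz])
    mu = a.mean()
    sd = a.std(ddof=1)
    if sd == 0.0:  # all magnitudes equal: no outliers to trim
        return nz
    z = np.abs(a - mu) / sd
    return nz[z >= threshold]


def extract_module(
    u: np.ndarray,
    v: np.ndarray,
    cfg: ZScoreFilterConfig,
    gene_ids,
    sample_ids,
) -> ModuleRecord:
    """Turn one factor pair into a module via the z-score filter."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    gi = _zscore_select(u, cfg.threshold)
    si = _zscore_select(v, cfg.threshold)
    genes = {gene_ids[i] for i in gi}
    samples = {sample_ids[j] for j in si}
    return ModuleRecord(
        module_index=1,
        genes=genes,
        samples=samples,
        gene_weights={gene_ids[i]: float(u[i]) for i in gi},
        sample_weights={sample_ids[j]: float(v[j]) for j in si},
    )


def _module_submatrix(expr: ExpressionMatrix, module: ModuleRecord) -> np.ndarray:
    gidx = [expr.gene_ids.index(g) for g in sorted(module.genes)]
    sidx = [expr.sample_ids.index(s) for s in sorted(module.samples)]
    return expr.values[np.ix_(gidx, sidx)]


def modularity_score(expr: ExpressionMatrix, module: ModuleRecord) -> float:
    """Mean |Pearson r| over ordered gene pairs across the module's samples."""
    if module.n_genes < 2 or module.n_samples < 2:
        raise ValueError("modularity needs >= 2 genes and >= 2 samples")
    sub = _module_submatrix(expr, module)
    return _mean_abs_correlation(sub)


def _mean_abs_correlation(sub: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.corrcoef(sub)
    if np.isnan(w).any():
        warnings.warn(
            "zero-variance gene(s) in module; their correlations set to 0",
            stacklevel=3,
        )
        w = np.nan_to_num(w, nan=0.0)
    np.fill_diagonal(w, 0.0)
    pk = sub.shape[0]
    return float(np.abs(w).sum() / (pk * (pk - 1)))


def modularity_significance(
    expr: ExpressionMatrix,
    module: ModuleRecord,
    n_random: int = 100,
    seed: int = 0,
) -> float:
    """One-sided Wilcoxon signed-rank p-value against randomized modules.

    Draws ``n_random`` uniform random gene sets of the module's size
    (same samples), scores their modularity, and tests whether the
    module's score exceeds them (signed ranks of the paired
    differences).
    """
    if n_random < 20:
        raise ValueError("n_random must be at least 20")
    score = modularity_score(expr, module)
    rng = np.random.default_rng(seed)
    p = len(expr.gene_ids)
    sidx = [expr.sample_ids.index(s) for s in sorted(module.samples)]
    null = np.empty(n_random)
    for r in range(n_random):
        gidx = rng.choice(p, size=module.n_genes, replace=False)
        null[r] = _mean_abs_correlation(expr.values[np.ix_(gidx, sidx)])
    diffs = score - null
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="greater").pvalue)


def interaction_enrichment(
    net: GeneNetwork, module: ModuleRecord
) -> InteractionEnrichment:
    """Right-tailed hypergeometric test of the module's induced edge count.

    With a network of n genes and m edges and a module inducing m_i
    edges among its n_i member genes, the p-value is
    P(K >= m_i) for K ~ Hypergeometric(N = C(n,2), m, N_i = C(n_i,2)).
    """
    member_genes = [g for g in module.genes if g in set(net.nodes)]
    n_i = len(member_genes)
    if n_i < 2:
        return InteractionEnrichment(1.0, 0.0, n_i, 0, False)
    m_i = net.induced_edge_count(member_genes)
    n = net.n_nodes
    m = net.n_edges
    big_n = n * (n - 1) // 2
    big_n_i = n_i * (n_i - 1) // 2
    p = float(stats.hypergeom.sf(m_i - 1, big_n, m, big_n_i))
    p = min(max(p, _MIN_P), 1.0)
    s = enrichment_score(p)
    return InteractionEnrichment(p, s, n_i, m_i, s > 1.3)


def module_overlap_significance(
    mod_a: ModuleRecord,
    mod_b: ModuleRecord,
    gene_universe_size: int,
    sample_universe_size: int,
    alpha: float = 0.05,
) -> OverlapSignificance:
    """Right-tailed hypergeometric overlap test on gene AND sample sets.

    Two modules are called significantly overlapping when both the
    gene-set and the sample-set overlap p-values fall below ``alpha``.
    """

    def tail(a: set, b: set, universe: int) -> float:
        if not a or not b:
            return 1.0
        k = len(a & b)
        return float(stats.hypergeom.sf(k - 1, universe, len(a), len(b)))

    p_genes = tail(mod_a.genes, mod_b.genes, gene_universe_size)
    p_samples = tail(mod_a.samples, mod_b.samples, sample_universe_size)
    return OverlapSignificance(
        p_genes, p_samples, p_genes < alpha and p_samples < alpha
    )


def pairwise_overlap(
    modules,
    gene_universe_size: int,
    sample_universe_size: int,
    alpha: float = 0.05,
):
    """All unordered module-pair overlap tests (K modules -> K(K-1)/2 rows)."""
    out = []
    mods = list(modules)
    for a in range(len(mods)):
        for b in range(a + 1, len(mods)):
            res = module_overlap_significance(
                mods[a], mods[b], gene_universe_size, sample_universe_size, alpha
            )
            out.append((mods[a].module_index, mods[b].module_index, res))
    return out
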