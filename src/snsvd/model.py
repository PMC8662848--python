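"""Model/Results interface for sparse network-regularized SVD.

Usage::

    model = SNSVD(expr, network=net, sigma=100.0, k_v=50, support_u=200)
    res = model.fit(n_factors=40, n_restarts=5, seed=1)
    print(res.summary())
    modules = res.modules(threshold=1.0)

``SNSVD`` holds the data (a genes x samples matrix and an optional
gene-gene interaction network) and the penalty configuration;
``fit`` runs the deflation loop and returns an :class:`SNSVDResults`
carrying the loading matrices, singular values, per-factor diagnostics
and module extraction/evaluation helpers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import LaplacianPair, normalized_laplacian
from .io import ExpressionMatrix, GeneNetwork, ModuleSet
from .selection import (
    CvResult,
    DEFAULT_SIGMA_GRID,
    FactorSequence,
    cross_validate_sigma,
    deflate,
)
from .solver import SolverConfig


class SNSVD:
    """Sparse network-regularized SVD of a labelled expression matrix.

    Parameters
    ----------
    X : ExpressionMatrix, pandas.DataFrame or array-like
        Genes in rows, samples in columns.
    network : GeneNetwork or iterable of (gene, gene) pairs, optional
        Prior interaction network over the row genes; genes absent from
        it are kept as isolated nodes.
    sigma : float
        Weight of the graph-Laplacian smoothness penalty on u.
    lambda_ : float, optional
        L1 weight on u.  Ignored when ``support_u`` is given.
    support_u : int, optional
        Desired number of nonzero gene loadings; lambda is tuned per
        factor by bisection to hit it.
    k_v : int, optional
        Cardinality bound on the sample loading v (default: no bound).
    """

    def __init__(
        self,
        X,
        network: GeneNetwork | None = None,
        *,
        sigma: float = 0.0,
        lambda_: float = 0.0,
        support_u: int | None = None,
        k_v: int | None = None,
        solver_config: SolverConfig | None = None,
    ) -> None:
        if isinstance(X, ExpressionMatrix):
            self.data = X
        elif hasattr(X, "index") and hasattr(X, "columns"):
            self.data = ExpressionMatrix.from_dataframe(X)
        else:
            Xm = np.asarray(X, dtype=float)
            self.data = ExpressionMatrix(
                Xm,
                [f"g{i + 1}" for i in range(Xm.shape[0])],
                [f"s{j + 1}" for j in range(Xm.shape[1])],
            )
        if self.data.n_missing:
            raise ValueError(
                "expression matrix has missing entries; impute first "
                "(see snsvd.diffcoexpr.knn_impute)"
            )
        if network is not None and not isinstance(network, GeneNetwork):
            network = GeneNetwork.from_edge_ids(self.data.gene_ids, network)
        if network is not None and network.nodes != self.data.gene_ids:
            raise ValueError("network nodes must align with expression rows")
        self.network = network
        self.laplacian: LaplacianPair | None = (
            normalized_laplacian(network) if network is not None else None
        )
        if sigma > 0 and network is None:
            raise ValueError("sigma > 0 requires a network")
        base = solver_config or SolverConfig()
        self.config = SolverConfig(
            lambda_=lambda_, sigma=sigma, k_v=k_v,
            max_outer_iters=base.max_outer_iters, outer_tol=base.outer_tol,
            max_inner_sweeps=base.max_inner_sweeps, inner_tol=base.inner_tol,
            seed=base.seed,
        )
        self.support_u = support_u

    @classmethod
    def from_dataframe(cls, df, edges=None, **kwargs) -> "SNSVD":
        """Build from a pandas DataFrame (genes x samples) and optional edges."""
        return cls(df, network=edges, **kwargs)

    def fit(
        self, n_factors: int = 1, n_restarts: int = 5, seed: int = 0
    ) -> "SNSVDResults":
        seq = deflate(
            self.data, self.laplacian, self.config, n_factors,
            n_restarts=n_restarts, seed=seed, support_target=self.support_u,
        )
        return SNSVDResults(self, seq)

    def select_sigma(
        self,
        sigma_grid=DEFAULT_SIGMA_GRID,
        n_folds: int = 5,
        seed: int = 0,
        lambda_policy=None,
    ) -> CvResult:
        """5-fold entry-holdout cross-validation for the network weight."""
        if lambda_policy is None:
            lambda_policy = (
                ("target", self.support_u)
                if self.support_u is not None
                else ("fixed", self.config.lambda_)
            )
        return cross_validate_sigma(
            self.data, self.laplacian, sigma_grid,
            lambda_policy=lambda_policy, k_v=self.config.k_v,
            n_folds=n_folds, seed=seed, cfg=self.config,
        )


@dataclass
class SNSVDResults:
    """Fitted factors plus module extraction and reporting."""

    model: SNSVD
    sequence: FactorSequence

    @property
    def factors(self):
        return self.sequence.factors

    @property
    def U(self) -> np.ndarray:
        return self.sequence.U

    @property
    def V(self) -> np.ndarray:
        return self.sequence.V

    @property
    def d(self) -> np.ndarray:
        return self.sequence.d

    @property
    def n_factors(self) -> int:
        return len(self.sequence)

    @property
    def residual_norm(self) -> float:
        return self.sequence.residual_norm

    def modules(self, threshold: float = 1.0, evaluate: bool = True) -> ModuleSet:
        """Extract one module per factor via the absolute z-score filter.

        With ``evaluate=True`` each module's stats include its
        modularity (mean |Pearson r| over member genes across member
        samples) and, when a network is attached, the gene-gene
        interaction enrichment score.
        """
        from .modules import (
            ZScoreFilterConfig,
            extract_module,
            interaction_enrichment,
            modularity_score,
        )

        cfg = ZScoreFilterConfig(threshold=threshold)
        records = []
        for k, fp in enumerate(self.factors, start=1):
            rec = extract_module(
                fp.u, fp.v, cfg,
                self.model.data.gene_ids, self.model.data.sample_ids,
            )
            rec.module_index = k
            rec.d = fp.d
            if evaluate:
                if rec.n_genes >= 2 and rec.n_samples >= 2:
                    rec.stats["modularity"] = modularity_score(self.model.data, rec)
                if self.model.network is not None:
                    enr = interaction_enrichment(self.model.network, rec)
                    rec.stats["interaction_p"] = enr.p_value
                    rec.stats["interaction_score"] = enr.score
                    rec.stats["n_edges"] = enr.n_edges
            records.append(rec)
        return ModuleSet(records)

    def summary(self) -> str:
        lines = [
            "Sparse network-regularized SVD",
            "==============================",
            f"data: {self.model.data.shape[0]} genes x "
            f"{self.model.data.shape[1]} samples",
            (
                f"network: {self.model.network.n_edges} edges"
                if self.model.network is not None
                else "network: none"
            ),
            f"sigma={self.model.config.sigma:g}  "
            + (
                f"support_u={self.model.support_u}"
                if self.model.support_u is not None
                else f"lambda={self.model.config.lambda_:g}"
            )
            + f"  k_v={self.model.config.k_v}",
            f"residual Frobenius norm: {self.residual_norm:.4f}",
            "",
            f"{'factor':>6} {'d':>12} {'nnz(u)':>8} {'nnz(v)':>8} "
            f"{'iters':>6} {'converged':>10}",
        ]
        for k, fp in enumerate(self.factors, start=1):
            lines.append(
                f"{k:>6} {fp.d:>12.4f} {fp.nnz_u:>8} {fp.nnz_v:>8} "
                f"{fp.n_iters:>6} {str(fp.converged):>10}"
            )
        return "\n".join(lines)

    def plot_objective(self, ax=None):
        """Objective traces of all factors (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for k, fp in enumerate(self.factors, start=1):
            ax.plot(fp.objective_trace, label=f"factor {k}")
        ax.set_xlabel("outer iteration")
        ax.set_ylabel("F(u, v)")
        ax.legend(fontsize="small")
        return ax
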