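"""Labelled expression matrices, gene networks and module containers.

File formats:

* expression: TSV/CSV, header row = sample IDs, first column = gene IDs;
* network: two-column edge list, or SIF (``nodeA relation nodeB``,
  relation ignored);
* modules: long-format TSV (module_index, member_id, member_type, weight)
  plus a JSON sidecar carrying per-module statistics.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Cell tokens treated as missing on read (imputation is a separate,
#: explicit step; see :func:`snsvd.diffcoexpr.knn_impute`).
MISSING_TOKENS = frozenset({"NA", "NaN", ""})


@dataclass
class ExpressionMatrix:
    """A genes x samples real matrix with row and column identifiers.

    ``values`` has shape ``(len(gene_ids), len(sample_ids))``; entries
    flagged in ``missing_mask`` are placeholders (stored as NaN) awaiting
    imputation.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    missing_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.sample_ids = list(self.sample_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-d matrix")
        p, n = self.values.shape
        if len(self.gene_ids) != p:
            raise ValueError(
                f"{len(self.gene_ids)} gene IDs for {p} rows"
            )
        if len(self.sample_ids) != n:
            raise ValueError(
                f"{len(self.sample_ids)} sample IDs for {n} columns"
            )
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {name} ID: {dup!r}")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
            if self.missing_mask.shape != self.values.shape:
                raise ValueError("missing mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_missing(self) -> int:
        return int(self.missing_mask.sum())

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_dataframe(cls, df) -> "ExpressionMatrix":
        return cls(
            np.asarray(df.values, dtype=float),
            [str(g) for g in df.index],
            [str(s) for s in df.columns],
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_ids.index(g) for g in genes]
        return ExpressionMatrix(
            self.values[idx, :], [self.gene_ids[i] for i in idx], self.sample_ids
        )


@dataclass
class GeneNetwork:
    """Undirected, unweighted graph over an ordered gene universe.

    ``nodes`` is aligned to an :class:`ExpressionMatrix`'s rows; genes
    with no interactions are kept as isolated nodes (degree 0).  Edges
    are stored as index pairs ``(i, j)`` with ``i < j``.
    """

    nodes: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        dup = _first_duplicate(self.nodes)
        if dup is not None:
            raise ValueError(f"duplicate network node: {dup!r}")
        canon = set()
        for i, j in self.edges:
            if i == j:
                continue
            a, b = (i, j) if i < j else (j, i)
            if not (0 <= a < len(self.nodes) and 0 <= b < len(self.nodes)):
                raise ValueError(f"edge ({i},{j}) outside node range")
            canon.add((a, b))
        self.edges = canon

    @classmethod
    def from_edge_ids(
        cls, nodes: Sequence[str], edge_ids: Iterable[tuple[str, str]]
    ) -> "GeneNetwork":
        index = {g: k for k, g in enumerate(nodes)}
        edges = set()
        for a, b in edge_ids:
            if a in index and b in index and a != b:
                i, j = sorted((index[a], index[b]))
                edges.add((i, j))
        return cls(list(nodes), edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self):
        """Symmetric binary adjacency with zero diagonal (CSR)."""
        import scipy.sparse as sp

        p = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((p, p))
        rows, cols = zip(*self.edges)
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        data = np.ones(rows.size)
        a = sp.coo_matrix(
            (np.r_[data, data], (np.r_[rows, cols], np.r_[cols, rows])),
            shape=(p, p),
        )
        return a.tocsr()

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=int)
        for i, j in self.edges:
            d[i] += 1
            d[j] += 1
        return d

    def induced_edge_count(self, genes: Iterable[str]) -> int:
        """Number of network edges with both endpoints in ``genes``."""
        index = {g: k for k, g in enumerate(self.nodes)}
        keep = {index[g] for g in genes if g in index}
        return sum(1 for i, j in self.edges if i in keep and j in keep)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((self.nodes[i], self.nodes[j]) for i, j in self.edges)
        return g


@dataclass
class ModuleRecord:
    """One bicluster: a gene set and a sample set from a factor pair."""

    module_index: int
    genes: set[str]
    samples: set[str]
    d: float = 0.0
    stats: dict = field(default_factory=dict)
    gene_weights: dict = field(default_factory=dict)
    sample_weights: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class ModuleSet:
    modules: list[ModuleRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules)

    def __getitem__(self, k) -> ModuleRecord:
        return self.modules[k]


def _first_duplicate(items: Sequence[str]) -> str | None:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_expression(path, delimiter: str = "\t", transpose: bool = False) -> ExpressionMatrix:
    """Read a delimited expression table (column 1 = gene IDs, header = samples).

    Cells equal to one of :data:`MISSING_TOKENS` become NaN and are
    recorded in the returned matrix's ``missing_mask``.  Duplicate gene
    IDs and ragged rows are hard errors.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = [c.strip() for c in header[1:]]
        n = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, rec in enumerate(reader, start=2):
            if not rec or (len(rec) == 1 and not rec[0].strip()):
                continue
            if len(rec) != n + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(rec)} fields, expected {n + 1}"
                )
            gene = rec[0].strip()
            if gene in set(gene_ids):
                raise ValueError(f"{path}: duplicate gene ID {gene!r}")
            vals = []
            for cell in rec[1:]:
                cell = cell.strip()
                if cell in MISSING_TOKENS:
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(cell))
                    except ValueError:
                        raise ValueError(
                            f"{path}: line {lineno}: cannot parse {cell!r} as a number"
                        ) from None
            gene_ids.append(gene)
            rows.append(vals)
    values = np.asarray(rows, dtype=float).reshape(len(gene_ids), n)
    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    if transpose:
        expr = ExpressionMatrix(expr.values.T, expr.sample_ids, expr.gene_ids)
    logger.info(
        "read expression %s: %d genes x %d samples (%d missing)",
        path, expr.shape[0], expr.shape[1], expr.n_missing,
    )
    return expr


def write_expression(expr: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["gene_id", *expr.sample_ids])
        for g, row in zip(expr.gene_ids, expr.values):
            writer.writerow(
                [g, *(repr(float(x)) if not np.isnan(x) else "NA" for x in row)]
            )


def read_network(path, node_universe: Sequence[str], delimiter: str = "\t") -> GeneNetwork:
    """Read a two-column edge list (or three-column SIF) over a gene universe.

    Edges touching genes outside ``node_universe`` are dropped with a
    warning; self-loops are dropped; duplicate edges collapse.  Genes of
    the universe absent from the file remain isolated nodes.
    """
    path = Path(path)
    index = {g: k for k, g in enumerate(node_universe)}
    if not index:
        raise ValueError("empty node universe")
    edges: set[tuple[int, int]] = set()
    n_dropped = 0
    any_hit = False
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter in line else line.split()
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:  # SIF: nodeA relation nodeB
                a, _, b = parts
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 (edge list) or 3 (SIF) fields"
                )
            a, b = a.strip(), b.strip()
            if a in index or b in index:
                any_hit = True
            if a not in index or b not in index:
                n_dropped += 1
                continue
            if a == b:
                continue
            i, j = sorted((index[a], index[b]))
            edges.add((i, j))
    if not any_hit:
        raise ValueError(
            f"{path}: no edge endpoint intersects the gene universe"
        )
    if n_dropped:
        warnings.warn(
            f"{path}: dropped {n_dropped} edge(s) outside the gene universe",
            stacklevel=2,
        )
    net = GeneNetwork(list(node_universe), edges)
    logger.info(
        "read network %s: %d nodes, %d edges", path, net.n_nodes, net.n_edges
    )
    return net


def write_network(net: GeneNetwork, path, delimiter: str = "\t") -> None:
    with open(path, "w") as fh:
        for i, j in sorted(net.edges):
            fh.write(f"{net.nodes[i]}{delimiter}{net.nodes[j]}\n")


def write_modules(modules: ModuleSet, path) -> None:
    """Write modules as long-format TSV plus a ``<path>.json`` stats sidecar."""
    if len(modules) == 0:
        raise ValueError("refusing to write an empty ModuleSet")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["module_index", "member_id", "member_type", "weight"])
        for mod in modules:
            for g in sorted(mod.genes):
                writer.writerow(
                    [mod.module_index, g, "gene",
                     repr(float(mod.gene_weights.get(g, 0.0)))]
                )
            for s in sorted(mod.samples):
                writer.writerow(
                    [mod.module_index, s, "sample",
                     repr(float(mod.sample_weights.get(s, 0.0)))]
                )
    sidecar = {
        str(mod.module_index): {"d": mod.d, "stats": mod.stats} for mod in modules
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def read_modules(path) -> ModuleSet:
    """Inverse of :func:`write_modules` (lossless round trip)."""
    path = Path(path)
    records: dict[int, ModuleRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader)  # header
        for idx_s, member, mtype, weight in reader:
            idx = int(idx_s)
            rec = records.setdefault(idx, ModuleRecord(idx, set(), set()))
            if mtype == "gene":
                rec.genes.add(member)
                rec.gene_weights[member] = float(weight)
            elif mtype == "sample":
                rec.samples.add(member)
                rec.sample_weights[member] = float(weight)
            else:
                raise ValueError(f"unknown member_type {mtype!r}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
        for key, payload in sidecar.items():
            rec = records.get(int(key))
            if rec is not None:
                rec.d = float(payload.get("d", 0.0))
                rec.stats = dict(payload.get("stats", {}))
    return ModuleSet([records[k] for k in sorted(records)])
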