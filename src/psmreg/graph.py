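"""Peptide affinity graph: similarity matrix W, degrees D, normalized S.

Nodes are peptide-spectrum matches.  Two nodes are joined when their
peptides share at least one protein; the edge weight is the probability
that the two peptides belong to the same protein, estimated from the
protein membership sets.  The normalized operator S = D^(-1/2) W D^(-1/2)
has spectrum inside [-1, 1], which is what makes the regularizer's
linear system well-posed and the diffusion iteration a contraction.

Isolated matches (no protein shared with anyone) would give a zero row
in W and a singular degree matrix; each one receives a private dummy
neighbor attached with a tiny weight (1e-8 by default) instead.  Dummy
nodes live at the end of the index space and are stripped from every
downstream output.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, ContractError
from .io import PSMRecord

#: Default weight of a dummy edge, per the isolated-node construction.
DUMMY_WEIGHT = 1e-8


def _jaccard(u: frozenset, v: frozenset) -> float:
    return len(u & v) / len(u | v)


def _product(u: frozenset, v: frozenset) -> float:
    return len(u & v) / (len(u) * len(v))


def _min(u: frozenset, v: frozenset) -> float:
    return len(u & v) / min(len(u), len(v))


#: Selectable similarity kernels over protein membership sets.
KERNELS: dict[str, Callable[[frozenset, frozenset], float]] = {
    "jaccard": _jaccard,
    "product": _product,
    "min": _min,
}


def pairwise_similarity(u_i: frozenset | set, u_j: frozenset | set, kernel: str = "jaccard") -> float:
    """Similarity of two peptides from their protein membership sets.

    The default Jaccard kernel |U_i ∩ U_j| / |U_i ∪ U_j| is a
    probability in [0, 1]: 1 when the peptides co-occur in exactly the
    same proteins, 0 when they share none.  Symmetric in its arguments.
    """
    if not u_i or not u_j:
        raise ContractError("protein membership sets must be non-empty")
    try:
        fn = KERNELS[kernel]
    except KeyError:
        raise ConfigError(f"unknown similarity kernel {kernel!r}; choose from {sorted(KERNELS)}") from None
    return fn(frozenset(u_i), frozenset(u_j))


@dataclass(frozen=True)
class AffinityGraph:
    """Sparse affinity graph over PSM nodes plus dummy bookkeeping.

    ``W`` is symmetric, nonnegative, zero-diagonal, of shape
    (n_total, n_total); ``D`` is the diagonal matrix of its row sums and
    ``S = D^(-1/2) W D^(-1/2)``.  Indices < ``n_real`` are PSM nodes, the
    rest are dummies; ``dummy_of`` maps each isolated real node to its
    dummy.
    """

    n_real: int
    n_total: int
    W: sp.csr_matrix
    D: sp.csr_matrix
    S: sp.csr_matrix
    dummy_of: dict[int, int]

    @property
    def degrees(self) -> np.ndarray:
        return self.D.diagonal()

    @property
    def n_dummy(self) -> int:
        return self.n_total - self.n_real

    def edges(self, include_dummy: bool = False) -> Iterator[tuple[int, int, float]]:
        """Yield undirected edges (i, j, weight) with i < j."""
        coo = sp.triu(self.W, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            if include_dummy or (i < self.n_real and j < self.n_real):
                yield int(i), int(j), float(w)

    def n_edges(self, include_dummy: bool = False) -> int:
        """Count undirected positive-weight edges among real nodes."""
        return sum(1 for _ in self.edges(include_dummy=include_dummy))


def build_graph(
    records: Sequence[PSMRecord],
    dummy_weight: float = DUMMY_WEIGHT,
    kernel: str = "jaccard",
) -> AffinityGraph:
    """Construct the affinity graph for a list of PSM records.

    One node per record in input order.  Edges are found through an
    inverted protein index, so only pairs sharing a protein are ever
    scored; the kernel then gives the weight.  Two records of the same
    peptide have identical membership sets and get a weight-1 edge
    (duplicate peptides across spectra are legitimate distinct nodes).
    """
    if dummy_weight <= 0:
        raise ConfigError(f"dummy_weight must be positive, got {dummy_weight}")
    n = len(records)
    for rec in records:
        if not rec.proteins:
            raise ContractError(f"psm {rec.psm_id} has an empty protein set")

    by_protein: dict[str, list[int]] = defaultdict(list)
    for i, rec in enumerate(records):
        for acc in rec.proteins:
            by_protein[acc].append(i)

    pairs: set[tuple[int, int]] = set()
    for members in by_protein.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = members[a], members[b]
                pairs.add((i, j) if i < j else (j, i))

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    connected = np.zeros(n, dtype=bool)
    for i, j in pairs:
        w = pairwise_similarity(records[i].proteins, records[j].proteins, kernel=kernel)
        if w > 0:
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
            connected[i] = connected[j] = True

    dummy_of: dict[int, int] = {}
    next_idx = n
    for i in np.flatnonzero(~connected):
        dummy_of[int(i)] = next_idx
        rows += [int(i), next_idx]
        cols += [next_idx, int(i)]
        vals += [dummy_weight, dummy_weight]
        next_idx += 1
    n_total = next_idx

    W = sp.coo_matrix((vals, (rows, cols)), shape=(n_total, n_total)).tocsr()
    D = degree_matrix(W)
    S = normalize(W, D)
    return AffinityGraph(n_real=n, n_total=n_total, W=W, D=D, S=S, dummy_of=dummy_of)


def degree_matrix(W: sp.spmatrix) -> sp.csr_matrix:
    """Diagonal matrix of row sums d_ii = sum_j w_ij."""
    d = np.asarray(W.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ContractError(
            "zero row sum in W; insert dummy nodes before computing degrees"
        )
    return sp.diags(d).tocsr()


def normalize(W: sp.spmatrix, D: sp.spmatrix) -> sp.csr_matrix:
    """Symmetric normalization S = D^(-1/2) W D^(-1/2).

    Preserves W's sparsity pattern; S is symmetric whenever W is.
    """
    d = D.diagonal()
    if np.any(d <= 0):
        raise ContractError("degree matrix must be strictly positive on the diagonal")
    inv_sqrt = sp.diags(1.0 / np.sqrt(d))
    return (inv_sqrt @ W @ inv_sqrt).tocsr()


def write_edge_list(graph: AffinityGraph, path: str | Path, include_dummy: bool = False) -> None:
    """Export edges as a TSV (node_i, node_j, weight) for inspection."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("node_i\tnode_j\tweight\n")
        for i, j, w in graph.edges(include_dummy=include_dummy):
            fh.write(f"{i}\t{j}\t{w:.17g}\n")
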