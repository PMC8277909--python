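"""Lattice, cross-layer and clustered connectivity construction.

All builders are pure functions of (spec, seed): the same seed yields a
bit-identical structure.  Connection fractions are realised by exact
count (edges are removed one by one until the target is met), not by
Bernoulli sampling, so a configured fraction is met to within one edge.
The fully connected 4-neighbour lattice counts as 100% intracortical
connectivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

__all__ = [
    "LatticeSpec",
    "ClusterSpec",
    "ConnectivitySet",
    "build_lattice4",
    "thin_uniform",
    "thin_clustered",
    "random_bipartite",
    "random_cell_mask",
    "build_C_TH",
    "assign_ei",
    "connectivity_fraction",
    "export_coo",
    "import_coo",
]


@dataclass(frozen=True)
class LatticeSpec:
    """Shape of one neural layer (rows x cols cells)."""

    rows: int = 60
    cols: int = 60

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("lattice must be at least 2x2")

    @property
    def n(self) -> int:
        return self.rows * self.cols

    def index(self, i: int, j: int) -> int:
        return i * self.cols + j

    def full_edge_count(self) -> int:
        """Edges of the complete 4-neighbour lattice."""
        return self.rows * (self.cols - 1) + self.cols * (self.rows - 1)


@dataclass(frozen=True)
class ClusterSpec:
    """Rectangular high-connectivity regions inside the cortical sheet.

    ``regions`` are (row0, row1, col0, col1) half-open index blocks.
    Inside each block the 4-neighbour edges are kept at
    ``intra_fraction``; outside, edges are removed so the global fraction
    equals ``overall_fraction``.
    """

    regions: tuple[tuple[int, int, int, int], ...]
    intra_fraction: float = 0.90
    overall_fraction: float = 0.25


@dataclass
class ConnectivitySet:
    """The realised binary structures of one network instance."""

    lattice: LatticeSpec
    x_sparse: sp.csr_matrix          # intra-cortical, symmetric
    m_sparse: sp.csr_matrix          # CX -> RE / CX -> TC (shared draw)
    w_sparse: sp.csr_matrix          # TC -> CX and RE -> CX
    c_th: sp.csr_matrix              # 4-nearest-neighbour cross map
    ei_labels: np.ndarray            # bool, True = excitatory
    w_sparse_th: sp.csr_matrix | None = None   # TH -> CX (reduced model)

    @property
    def excitatory_count(self) -> int:
        return int(self.ei_labels.sum())


# ---------------------------------------------------------------------------

def build_lattice4(spec: LatticeSpec) -> sp.csr_matrix:
    """Undirected 4-neighbour grid adjacency (symmetric, zero diagonal)."""
    r, c = spec.rows, spec.cols
    idx = np.arange(r * c).reshape(r, c)
    rows, cols = [], []
    # horizontal edges
    a = idx[:, :-1].ravel()
    b = idx[:, 1:].ravel()
    rows.extend([a, b])
    cols.extend([b, a])
    # vertical edges
    a = idx[:-1, :].ravel()
    b = idx[1:, :].ravel()
    rows.extend([a, b])
    cols.extend([b, a])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    adj = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(r * c, r * c)
    )
    adj.data[:] = 1.0
    return adj


def _edge_list(adj: sp.spmatrix) -> np.ndarray:
    """Unique undirected edges (i < j) as an (m, 2) array."""
    coo = sp.triu(adj, k=1).tocoo()
    return np.column_stack([coo.row, coo.col])


def _from_edges(edges: np.ndarray, n: int) -> sp.csr_matrix:
    if len(edges) == 0:
        return sp.csr_matrix((n, n))
    i, j = edges[:, 0], edges[:, 1]
    adj = sp.csr_matrix(
        (np.ones(2 * len(edges)),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    adj.data[:] = 1.0
    return adj


def thin_uniform(adj: sp.spmatrix, target_fraction: float,
                 rng: np.random.Generator,
                 reference_edges: int | None = None) -> sp.csr_matrix:
    """Remove edges uniformly at random down to a target fraction.

    The fraction is measured against ``reference_edges`` (default: the
    current edge count, so thinning a full lattice measures against the
    full lattice).  A target at or above the current fraction is a no-op
    with a warning.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    edges = _edge_list(adj)
    ref = reference_edges if reference_edges is not None else len(edges)
    keep = int(round(target_fraction * ref))
    if keep >= len(edges):
        if keep > len(edges):
            import warnings

            warnings.warn("target above current connectivity; no edges added")
        return sp.csr_matrix(adj)
    order = rng.permutation(len(edges))
    return _from_edges(edges[order[:keep]], adj.shape[0])


def thin_clustered(adj: sp.spmatrix, spec: LatticeSpec,
                   cluster: ClusterSpec,
                   rng: np.random.Generator) -> sp.csr_matrix:
    """Keep dense 4-way wiring inside clusters, thin the rest.

    Edges with both endpoints inside a cluster region are kept at
    ``intra_fraction``; the remaining edges are thinned so the global
    fraction (against the full 4-neighbour lattice) equals
    ``overall_fraction``.  Raises if the spec is infeasible.
    """
    edges = _edge_list(adj)
    total_ref = spec.full_edge_count()
    in_cluster = np.zeros(len(edges), dtype=bool)
    inside = np.zeros(spec.n, dtype=bool)
    for (r0, r1, c0, c1) in cluster.regions:
        blk = np.zeros((spec.rows, spec.cols), dtype=bool)
        blk[r0:r1, c0:c1] = True
        inside |= blk.ravel()
    in_cluster = inside[edges[:, 0]] & inside[edges[:, 1]]

    n_in = int(in_cluster.sum())
    keep_in = int(round(cluster.intra_fraction * n_in))
    keep_total = int(round(cluster.overall_fraction * total_ref))
    keep_out = keep_total - keep_in
    n_out = len(edges) - n_in
    if keep_out < 0 or keep_out > n_out:
        raise ValueError(
            f"infeasible cluster spec: overall fraction requires "
            f"{keep_out} edges outside clusters but only 0..{n_out} "
            f"available (intra keeps {keep_in}/{n_in})"
        )
    ein = edges[in_cluster]
    eout = edges[~in_cluster]
    sel_in = ein[rng.permutation(n_in)[:keep_in]]
    sel_out = eout[rng.permutation(n_out)[:keep_out]]
    return _from_edges(np.vstack([sel_in, sel_out]), spec.n)


def random_bipartite(n_pre: int, n_post: int, fraction: float,
                     rng: np.random.Generator) -> sp.csr_matrix:
    """Binary (n_post x n_pre) matrix with an exact count of ones.

    Row i gathers presynaptic cells feeding postsynaptic cell i.  Exactly
    ``round(fraction * n_pre * n_post)`` entries are one, placed
    uniformly without replacement.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    total = n_pre * n_post
    k = int(round(fraction * total))
    if k == 0:
        return sp.csr_matrix((n_post, n_pre))
    flat = rng.choice(total, size=k, replace=False)
    rows, cols = np.divmod(flat, n_pre)
    return sp.csr_matrix((np.ones(k), (rows, cols)), shape=(n_post, n_pre))


def random_cell_mask(n: int, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Binary per-cell gate with exactly round(fraction * n) ones.

    The topographic realisation of an "x% of neurons project" sparsity
    structure: each gated cell projects one-to-one to the co-registered
    cell of the target layer.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    k = int(round(fraction * n))
    mask = np.zeros(n)
    mask[rng.choice(n, size=k, replace=False)] = 1.0
    return mask


def build_C_TH(spec: LatticeSpec) -> sp.csr_matrix:
    """4-nearest-neighbour cross map between two co-registered lattices.

    Row for cell (i, j) has ones at (i+-1, j) and (i, j+-1) of the other
    layer; boundary rows are truncated.  The same map serves RE <-> TC
    coupling and the lateral excitation of the reduced thalamic layer.
    """
    # identical index geometry to the 4-neighbour lattice adjacency
    return build_lattice4(spec)


def assign_ei(n: int, excitatory_fraction: float,
              rng: np.random.Generator) -> np.ndarray:
    """Boolean labels with exactly round(n * fraction) excitatory cells."""
    if not 0 <= excitatory_fraction <= 1:
        raise ValueError("excitatory_fraction must be in [0, 1]")
    k = int(round(n * excitatory_fraction))
    labels = np.zeros(n, dtype=bool)
    labels[rng.choice(n, size=k, replace=False)] = True
    return labels


def connectivity_fraction(adj: sp.spmatrix, reference: int) -> float:
    """Kept/possible connections against a stated reference count."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    nnz = adj.nnz
    if adj.shape[0] == adj.shape[1]:
        # undirected adjacency stores each edge twice
        sym = (abs(adj - adj.T)).nnz == 0
        if sym:
            return nnz / 2 / reference
    return nnz / reference


# ---------------------------------------------------------------------------
# Text export/import (coordinate list + JSON sidecar) for exact replay.
# ---------------------------------------------------------------------------

def export_coo(adj: sp.spmatrix, path, meta: dict | None = None) -> None:
    """Write a binary matrix as 'row col' lines plus a JSON sidecar."""
    path = Path(path)
    coo = sp.coo_matrix(adj)
    with open(path, "w") as f:
        f.write(f"# shape {adj.shape[0]} {adj.shape[1]}\n")
        for i, j in zip(coo.row, coo.col):
            f.write(f"{i} {j}\n")
    side = dict(meta or {})
    side["shape"] = list(adj.shape)
    side["nnz"] = int(adj.nnz)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(side, indent=1)
    )


def import_coo(path) -> sp.csr_matrix:
    """Read a matrix written by :func:`export_coo`."""
    path = Path(path)
    with open(path) as f:
        header = f.readline().split()
        shape = (int(header[2]), int(header[3]))
        ij = np.loadtxt(f, dtype=int, ndmin=2)
    if ij.size == 0:
        return sp.csr_matrix(shape)
    return sp.csr_matrix(
        (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=shape
    )
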