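"""Bipartite adjacency and the symmetric spectrally normalized propagation operator.

Node ordering convention, fixed everywhere in the package: indices
``[0, m)`` are ncRNAs and ``[m, m + n)`` are drugs. The bipartite adjacency

    A = [[0,   R ],
         [R^T, 0 ]]

has no intra-domain edges. Propagation uses the spectral rule on the
self-looped adjacency:

    P = D~^-1/2 (A + I) D~^-1/2,

where D~ is the diagonal degree matrix of A~ = A + I. Self-loops guarantee
every degree is >= 1, so the normalization is defined even for isolated
nodes, and each edge weight accounts for the degrees of both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .data_io import AssociationDataset

#: graphs up to this many nodes also expose a dense view for oracle checks
DENSE_LIMIT = 512


@dataclass
class BipartiteAdjacency:
    """Symmetric (m+n) x (m+n) binary adjacency with zero diagonal blocks."""

    A: sp.csr_matrix
    m: int
    n: int

    @property
    def size(self) -> int:
        return self.m + self.n

    def to_dense(self) -> np.ndarray:
        if self.size > DENSE_LIMIT:
            raise ValueError(f"dense view limited to {DENSE_LIMIT} nodes")
        return self.A.toarray()


@dataclass
class NormalizedAdjacency:
    """The propagation operator P = D~^-1/2 (A + I) D~^-1/2."""

    P: sp.csr_matrix
    degrees: np.ndarray  # degrees of A~ (raw degree + 1), length m+n
    m: int
    n: int

    @property
    def size(self) -> int:
        return self.m + self.n

    def to_dense(self) -> np.ndarray:
        if self.size > DENSE_LIMIT:
            raise ValueError(f"dense view limited to {DENSE_LIMIT} nodes")
        return self.P.toarray()

    def __matmul__(self, other: np.ndarray) -> np.ndarray:
        return self.P @ other


def build_adjacency(ds: AssociationDataset) -> BipartiteAdjacency:
    """Assemble the bipartite adjacency from the dataset's pair set.

    Only the 2 * |pairs| inter-domain entries are nonzero.
    """
    m, n = ds.m, ds.n
    if ds.pairs:
        rows, cols = zip(*sorted(ds.pairs))
        rows = np.asarray(rows)
        cols = np.asarray(cols) + m
    else:
        rows = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
    data = np.ones(2 * len(rows))
    A = sp.coo_matrix(
        (data, (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(m + n, m + n),
    ).tocsr()
    return BipartiteAdjacency(A=A, m=m, n=n)


def normalize(adj: BipartiteAdjacency) -> NormalizedAdjacency:
    """Symmetric spectral normalization of the self-looped adjacency."""
    A_tilde = (adj.A + sp.identity(adj.size, format="csr")).tocsr()
    deg = np.asarray(A_tilde.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(deg)  # deg >= 1 always: self-loops
    D_inv_sqrt = sp.diags(inv_sqrt)
    P = (D_inv_sqrt @ A_tilde @ D_inv_sqrt).tocsr()
    return NormalizedAdjacency(P=P, degrees=deg, m=adj.m, n=adj.n)


def export_mtx(op: BipartiteAdjacency | NormalizedAdjacency, path: str | Path) -> None:
    """Write the operator in MatrixMarket coordinate format for inspection."""
    mat = op.A if isinstance(op, BipartiteAdjacency) else op.P
    sp_path = Path(path)
    sp_path.parent.mkdir(parents=True, exist_ok=True)
    from scipy.io import mmwrite

    mmwrite(str(sp_path), mat.tocoo())
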