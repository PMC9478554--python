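"""VanRaden genomic relationship matrices.

G = W W' / (2 * sum_k p_k (1 - p_k)) with W the column-centered dosage
matrix (dosage - 2p, p the in-sample alternate-allele frequency).  With
in-sample frequencies every column of W sums to zero, so G annihilates the
vector of ones — G is singular by construction and is stabilized with a
small diagonal shift before any REML fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

__all__ = ["GRM", "vanraden_grm", "grm_correlation", "stabilize", "write_grm", "read_grm"]


@dataclass
class GRM:
    matrix: np.ndarray
    individual_ids: np.ndarray
    n_markers_used: int
    denom: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or len(self.individual_ids) != n:
            raise ValueError("GRM shape / id mismatch")
        if self.denom <= 0:
            raise ValueError("GRM denominator must be positive")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"id {exc.args[0]!r} not in GRM") from exc


def vanraden_grm(g: GenotypeMatrix, method: int = 1, on_monomorphic: str = "error") -> GRM:
    """Build a VanRaden genomic relationship matrix from dosages.

    ``method=1`` is the ratio form W W' / (2 Σ p q); ``method=2`` scales each
    marker by its own 2 p q before averaging.  Missing dosages are
    mean-imputed (2p) here — after QC, never before.  Monomorphic markers
    contribute nothing to the denominator; ``on_monomorphic`` chooses between
    raising and silently dropping them.
    """
    if method not in (1, 2):
        raise ValueError("method must be 1 or 2")
    p = g.allele_freq.copy()
    mono = ~(np.nan_to_num(p) * (1 - np.nan_to_num(p)) > 0)
    if mono.all():
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    if mono.any():
        if on_monomorphic == "error":
            raise ValueError(f"{mono.sum()} monomorphic markers; drop them or pass on_monomorphic='drop'")
        g = g.take_markers(np.flatnonzero(~mono))
        p = g.allele_freq
    W = g.dosages - 2.0 * p
    if np.isnan(W).any():
        W = np.where(np.isnan(W), 0.0, W)  # mean imputation: dosage -> 2p
    pq = p * (1.0 - p)
    if method == 1:
        denom = float(2.0 * pq.sum())
        G = (W @ W.T) / denom
    else:
        denom = float(g.n_markers)
        Ws = W / np.sqrt(2.0 * pq)
        G = (Ws @ Ws.T) / denom
    G = 0.5 * (G + G.T)
    return GRM(matrix=G, individual_ids=g.individual_ids, n_markers_used=g.n_markers, denom=denom)


def grm_correlation(a: GRM, b: GRM, include_diagonal: bool = True) -> float:
    """Pearson correlation between two GRMs over the upper triangle.

    The diagonal (self-relationship) is included by default; both matrices
    must cover the same individuals in the same order.
    """
    if a.n != b.n or not np.array_equal(a.individual_ids, b.individual_ids):
        raise ValueError("GRMs cover different individuals")
    iu = np.triu_indices(a.n, k=0 if include_diagonal else 1)
    x, y = a.matrix[iu], b.matrix[iu]
    return float(np.corrcoef(x, y)[0, 1])


def stabilize(a: GRM, epsilon: float = 1e-6) -> GRM:
    """Add ``epsilon`` to the diagonal, shifting every eigenvalue up by it."""
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0:
        return a
    return GRM(
        matrix=a.matrix + epsilon * np.eye(a.n),
        individual_ids=a.individual_ids,
        n_markers_used=a.n_markers_used,
        denom=a.denom,
    )


def write_grm(a: GRM, prefix: str | Path, format: str = "csv") -> None:
    """Persist a GRM: ``csv`` (ids + dense matrix) or GCTA ``grm-bin``."""
    prefix = Path(prefix)
    if format == "csv":
        df = pd.DataFrame(a.matrix, index=a.individual_ids, columns=a.individual_ids)
        df.index.name = "id"
        df.to_csv(prefix.with_suffix(".grm.csv"))
        return
    if format != "grm-bin":
        raise ValueError("format must be 'csv' or 'grm-bin'")
    ids = pd.DataFrame({0: a.individual_ids, 1: a.individual_ids})
    ids.to_csv(prefix.with_suffix(".grm.id"), sep="\t", header=False, index=False)
    il = np.tril_indices(a.n)
    a.matrix[il].astype("<f4").tofile(prefix.with_suffix(".grm.bin"))
    np.full(il[0].size, a.n_markers_used, dtype="<f4").tofile(prefix.with_suffix(".grm.N.bin"))


def read_grm(prefix: str | Path, format: str = "csv") -> GRM:
    prefix = Path(prefix)
    if format == "csv":
        df = pd.read_csv(prefix.with_suffix(".grm.csv"), index_col=0)
        return GRM(
            matrix=df.to_numpy(dtype=float),
            individual_ids=df.index.astype(str).to_numpy(),
            n_markers_used=0 or df.shape[0],
            denom=1.0,
        )
    if format != "grm-bin":
        raise ValueError("format must be 'csv' or 'grm-bin'")
    ids = pd.read_csv(prefix.with_suffix(".grm.id"), sep="\t", header=None)[1].astype(str).to_numpy()
    n = len(ids)
    tri = np.fromfile(prefix.with_suffix(".grm.bin"), dtype="<f4").astype(float)
    il = np.tril_indices(n)
    G = np.zeros((n, n))
    G[il] = tri
    G = G + np.tril(G, -1).T
    nmark = np.fromfile(prefix.with_suffix(".grm.N.bin"), dtype="<f4")
    return GRM(matrix=G, individual_ids=ids, n_markers_used=int(nmark[0]) if nmark.size else n, denom=1.0)
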