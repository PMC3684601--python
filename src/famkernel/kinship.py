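"""Relationship matrices (2x kinship) from pedigrees or genome-wide markers.

The relationship convention (R = 2*Phi, diagonal 1 for non-inbred members)
makes sigma2_g the additive genetic variance in V = sigma2_g R + sigma2_e I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import MISSING_PARENT, PedigreeTable

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric N x N matrix of pairwise additive genetic relationships."""

    values: np.ndarray
    ids: np.ndarray
    source: str = "pedigree"  # {pedigree, genomic, file}
    jitter: float = 0.0  # added to the diagonal by condition_psd

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix dimension does not match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.ids)

    def reorder(self, ids) -> "RelationshipMatrix":
        pos = {s: k for k, s in enumerate(self.ids)}
        try:
            idx = np.array([pos[s] for s in ids])
        except KeyError as e:
            raise ValueError(f"id {e.args[0]!r} not in relationship matrix") from None
        return RelationshipMatrix(self.values[np.ix_(idx, idx)],
                                  np.asarray(list(ids), dtype=object),
                                  self.source, self.jitter)


def pedigree_relationship(ped: PedigreeTable) -> RelationshipMatrix:
    """Expected relationships R = 2*Phi by the standard kinship recursion.

    Founders are unrelated and non-inbred; an individual with exactly one
    known parent is treated as if the unknown parent were a founder (logged).
    Inbreeding implied by the pedigree (e.g. offspring of sib matings)
    propagates through the recursion, so diagonals can exceed 1.
    """
    order = ped.topological_order()
    idx = {s: k for k, s in enumerate(order)}
    parents = ped.parent_map()
    n = len(order)
    phi = np.zeros((n, n))
    n_half = 0
    for s in order:
        i = idx[s]
        f, m = parents[s]
        if (f == MISSING_PARENT) != (m == MISSING_PARENT):
            n_half += 1
        fi = idx.get(f, -1)
        mi = idx.get(m, -1)
        phi_fm = phi[fi, mi] if fi >= 0 and mi >= 0 else 0.0
        phi[i, i] = 0.5 + 0.5 * phi_fm
        row = np.zeros(n)
        if fi >= 0:
            row += 0.5 * phi[fi]
        if mi >= 0:
            row += 0.5 * phi[mi]
        row[i] = phi[i, i]
        phi[i, :] = row
        phi[:, i] = row
    if n_half:
        logger.info("%d individuals with one known parent treated as "
                    "founder-by-unknown-parent", n_half)
    # back to the pedigree's own row order
    perm = np.array([idx[s] for s in ped.ids])
    R = 2.0 * phi[np.ix_(perm, perm)]
    return RelationshipMatrix(R, ped.ids, source="pedigree")


def genomic_relationship(G: np.ndarray, ids, maf_floor: float = 0.01) -> RelationshipMatrix:
    """Marker-based relationship estimate from a genome-wide {0,0.5,1} matrix.

    Allele-frequency-weighted estimator on allele dosage x = 2g:
    R_ij = (1/M) sum_m (x_im - 2p_m)(x_jm - 2p_m) / (2 p_m (1 - p_m)).
    Variants with MAF below ``maf_floor`` are excluded.
    """
    G = np.asarray(G, dtype=float)
    n, m_all = G.shape
    if m_all < 10 * n:
        logger.warning("only %d variants for %d samples; genomic relationships "
                       "are noisy below ~10 variants per sample", m_all, n)
    p = G.mean(axis=0)  # coded-allele frequency (mean of dosage/2)
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_floor
    if not keep.any():
        raise ValueError("all variants filtered by the MAF floor")
    x = 2.0 * G[:, keep]
    pk = p[keep]
    z = (x - 2.0 * pk) / np.sqrt(2.0 * pk * (1.0 - pk))
    R = (z @ z.T) / z.shape[1]
    return RelationshipMatrix(R, np.asarray(list(ids), dtype=object),
                              source="genomic")


def kinship_pcs(R: RelationshipMatrix | np.ndarray, k: int = 10) -> np.ndarray:
    """Leading principal components of the column-centered relationship matrix.

    Returns an N x k matrix of unit-norm eigenvectors for the k largest
    eigenvalues, with a deterministic sign convention (the largest-magnitude
    entry of each component is positive).
    """
    A = R.values if isinstance(R, RelationshipMatrix) else np.asarray(R, float)
    n = A.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than N = {n}")
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    C = H @ A @ H  # double-centered similarity, symmetric
    w, v = np.linalg.eigh(C)
    top = np.argsort(w)[::-1][:k]
    pcs = v[:, top]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs


def condition_psd(R: RelationshipMatrix, eps: float = 1e-8) -> RelationshipMatrix:
    """Add the minimal diagonal jitter making R positive semi-definite.

    If the smallest eigenvalue is negative, ``(|lambda_min| + eps) * I`` is
    added; the jitter magnitude is recorded on the returned matrix.
    """
    lam_min = float(np.linalg.eigvalsh(R.values)[0])
    if lam_min >= 0:
        return R
    jitter = abs(lam_min) + eps
    logger.info("conditioning relationship matrix: lambda_min = %.3e, "
                "jitter = %.3e", lam_min, jitter)
    return RelationshipMatrix(R.values + jitter * np.eye(R.n), R.ids,
                              R.source, jitter=R.jitter + jitter)
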