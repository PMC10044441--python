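"""Genomic relationship matrix construction and single-step H^-1 assembly.

The genomic relationship matrix is built from allele-frequency-centered
dosages, G = ZZ' / (2 * sum_j p_j (1 - p_j)) (VanRaden method 1), then tuned
so its diagonal / off-diagonal means match the pedigree relationships A22 of
the genotyped animals, blended as alpha*G + beta*A22 (defaults 0.90 / 0.10) to
guarantee invertibility, and inserted into the single-step inverse

    H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1]

which replaces A^-1 in the mixed-model equations so genotyped and
non-genotyped animals are evaluated jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

logger = logging.getLogger(__name__)


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


def center_genotypes(m: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Z_ij = dosage_ij - 2 p_j (the allele-frequency adjustment)."""
    m = np.asarray(m, dtype=np.float64)
    return m - 2.0 * np.asarray(p)


def compute_grm(z: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Raw genomic relationship matrix G = ZZ' / (2 sum p(1-p))."""
    p = np.asarray(p, dtype=np.float64)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError(
            "GRM scaling denominator 2*sum(p(1-p)) is zero: all SNPs are "
            "monomorphic (p in {0,1})"
        )
    g = (z @ z.T) / denom
    return 0.5 * (g + g.T)


def tune_grm_to_a22(
    g_raw: np.ndarray, a22: np.ndarray, mode: str = "both"
) -> tuple[np.ndarray, float, float]:
    """Rescale G as a + b*G so its mean diagonal (and, in ``both`` mode, mean
    off-diagonal) matches A22.

    Returns (g_tuned, a, b).  ``mode``: "both" solves the 2x2 system on both
    means, "diag" rescales the diagonal mean only (b = mean ratio, a = 0),
    "none" leaves G untouched.
    """
    if g_raw.shape != a22.shape:
        raise ValueError(f"shape mismatch: G {g_raw.shape} vs A22 {a22.shape}")
    n = g_raw.shape[0]
    if mode == "none":
        return g_raw.copy(), 0.0, 1.0
    md_g = float(np.mean(np.diag(g_raw)))
    md_a = float(np.mean(np.diag(a22)))
    if mode == "diag":
        b = md_a / md_g
        return b * g_raw, 0.0, b
    if mode != "both":
        raise ValueError(f"unknown tuning mode {mode!r}")
    if n == 1:
        a, b = md_a - md_g, 1.0
        return g_raw + a, a, b
    off = ~np.eye(n, dtype=bool)
    mo_g = float(np.mean(g_raw[off]))
    mo_a = float(np.mean(a22[off]))
    denom = md_g - mo_g
    if abs(denom) < 1e-12:
        logger.warning(
            "tuning system singular (G diagonal mean equals off-diagonal "
            "mean); falling back to a diagonal-mean shift"
        )
        a, b = md_a - md_g, 1.0
    else:
        b = (md_a - mo_a) / denom
        a = md_a - b * md_g
    return a + b * g_raw, a, b


def blend_grm(
    g_tuned: np.ndarray, a22: np.ndarray, alpha: float = 0.90, beta: float = 0.10
) -> np.ndarray:
    """Entrywise alpha*G + beta*A22; checks the result is positive definite."""
    if not np.isclose(alpha + beta, 1.0):
        raise ValueError(f"alpha + beta must be 1, got {alpha} + {beta}")
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    g = alpha * g_tuned + beta * a22
    try:
        sla.cholesky(g, lower=True)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"blended G is not positive definite at alpha={alpha}; "
            "increase beta (more pedigree weight) or check the genotypes"
        ) from None
    return g


def invert_pd(matrix: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Inverse via symmetric positive-definite factorization."""
    try:
        factor = sla.cho_factor(matrix, lower=True)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            f"{what} is not positive definite and cannot be inverted; "
            "no automatic ridge is applied"
        ) from None
    inv = sla.cho_solve(factor, np.eye(matrix.shape[0]))
    return 0.5 * (inv + inv.T)


@dataclass
class GrmBundle:
    """All intermediate genomic matrices for one dataset."""

    animal_ids: list[str]
    z_matrix: np.ndarray
    g_raw: np.ndarray
    g_tuned: np.ndarray
    g_blended: np.ndarray
    g_inverse: np.ndarray
    tuning: tuple[float, float]
    blend: tuple[float, float]


def build_grm_bundle(
    imputed: np.ndarray,
    p: np.ndarray,
    a22: np.ndarray,
    animal_ids,
    alpha: float = 0.90,
    beta: float = 0.10,
    tune: str = "both",
) -> GrmBundle:
    """Full chain: center -> GRM -> tune to A22 -> blend -> invert."""
    z = center_genotypes(imputed, p)
    g_raw = compute_grm(z, p)
    g_tuned, a, b = tune_grm_to_a22(g_raw, a22, mode=tune)
    g_blended = blend_grm(g_tuned, a22, alpha=alpha, beta=beta)
    g_inverse = invert_pd(g_blended, "blended G")
    return GrmBundle(
        animal_ids=list(animal_ids),
        z_matrix=z,
        g_raw=g_raw,
        g_tuned=g_tuned,
        g_blended=g_blended,
        g_inverse=g_inverse,
        tuning=(a, b),
        blend=(alpha, beta),
    )


@dataclass
class HInverse:
    """Sparse single-step H^-1 over all pedigree animals.

    Restricted to non-genotyped animals it equals A^-1 exactly; the genotyped
    block additionally carries G^-1 - A22^-1.
    """

    matrix: sp.csr_matrix
    ids: list[str]
    genotyped_index: np.ndarray

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def csr_parts(self):
        m = self.matrix.tocsr()
        return (
            m.indptr.astype(np.int64),
            m.indices.astype(np.int64),
            m.data.astype(np.float64),
        )


def assemble_h_inverse(
    a_inv: sp.spmatrix,
    g_inv: np.ndarray | None,
    a22_inv: np.ndarray | None,
    genotyped_index,
    ids=None,
) -> HInverse:
    """A^-1 plus the dense genomic correction on the genotyped block.

    With no genotyped animals (empty index) H^-1 is just A^-1.
    """
    n = a_inv.shape[0]
    idx = np.asarray(genotyped_index, dtype=np.int64)
    if idx.size and (idx.min() < 0 or idx.max() >= n):
        raise IndexError(f"genotyped index out of range for {n} animals")
    if ids is None:
        ids = [str(i) for i in range(n)]
    if idx.size == 0:
        return HInverse(sp.csr_matrix(a_inv), list(ids), idx)
    corr = np.asarray(g_inv) - np.asarray(a22_inv)
    rows = np.repeat(idx, idx.size)
    cols = np.tile(idx, idx.size)
    correction = sp.coo_matrix((corr.ravel(), (rows, cols)), shape=(n, n))
    h_inv = (sp.csr_matrix(a_inv) + correction.tocsr()).tocsr()
    return HInverse(h_inv, list(ids), idx)


def h_inverse_from_a(a_inv: sp.spmatrix, ids=None) -> HInverse:
    """Pedigree-only evaluation: H^-1 = A^-1 (no genotyped animals)."""
    return assemble_h_inverse(a_inv, None, None, np.array([], dtype=np.int64), ids)
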