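"""Minimal dense EM-REML for small single-trait animal models.

This exists as an independent frequentist cross-check on the Gibbs sampler
(the posterior mean of the additive variance under weak priors should land
near the REML estimate on the same data).  It is deliberately dense and
simple — expectation-maximisation on Henderson's mixed-model equations — and
is only intended for desk-scale balanced designs (a few hundred to ~1,000
records).
"""

from __future__ import annotations

import numpy as np

from .mcmc import MixedModelSystem, dense_mme


def em_reml(
    system: MixedModelSystem,
    vu0: float | None = None,
    ve0: float | None = None,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> tuple[float, float, int]:
    """EM-REML estimates (sigma2_u, sigma2_e, iterations) for a linear trait.

    Updates per round, with C the inverse MME coefficient matrix in lambda
    form (so C * sigma2_e is the sampling covariance of the solutions):

        sigma2_u <- (u' Hinv u + sigma2_e * tr(Hinv C_uu)) / q
        sigma2_e <- (y'y - theta' rhs) / (n - rank(X))
    """
    if system.kind != "linear":
        raise ValueError("EM-REML supports linear traits only")
    if system.nw > 0:
        raise ValueError("EM-REML oracle does not model an uncorrelated group")
    y = system.y
    n = system.n_records
    q = system.n_animals
    vy = float(np.var(y))
    vu = vu0 if vu0 is not None else 0.3 * vy
    ve = ve0 if ve0 is not None else 0.7 * vy
    h_inv = system.h_inv.matrix.toarray()
    rank_x = np.linalg.matrix_rank(system.x_csc.toarray())
    yy = float(y @ y)
    it = 0
    for it in range(1, max_iter + 1):
        c, rhs, slices = dense_mme(system, vu, ve)
        cinv = np.linalg.inv(c)
        theta = cinv @ rhs
        u = theta[slices["animal"]]
        cuu = cinv[slices["animal"], slices["animal"]]
        # tr(Hinv @ Cuu) = elementwise sum for symmetric Hinv
        tr = float(np.sum(h_inv * cuu))
        vu_new = (float(u @ h_inv @ u) + ve * tr) / q
        ve_new = (yy - float(theta @ rhs)) / (n - rank_x)
        if abs(vu_new - vu) < tol * max(vu, 1e-12) and abs(
            ve_new - ve
        ) < tol * max(ve, 1e-12):
            vu, ve = vu_new, ve_new
            break
        vu, ve = vu_new, ve_new
    return vu, ve, it
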