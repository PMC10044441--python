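"""Compiled numerical kernels.

Everything in this file is plain-array code compiled with numba so that pedigree
recursions (O(n^2)) and single-site Gibbs sweeps (tens of thousands of
iterations over thousands of effects) run at native speed.  All random draws
inside the samplers use numba's own global RNG, seeded once per chain, so a
chain is bit-reproducible at a fixed seed.

Array conventions
-----------------
* pedigrees: parallel int64 arrays ``sire``/``dam`` holding the topological
  index of each parent, or -1 for unknown;
* sparse matrices: CSR triplets (indptr, indices, data) storing the full
  symmetric pattern;
* design matrices: CSC triplets (data, row indices, column pointers) plus the
  per-column sums of squares.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# pedigree recursions
# ---------------------------------------------------------------------------


@njit(cache=True)
def meuwissen_luo_inbreeding(sire, dam):
    """Exact inbreeding coefficients by the Meuwissen & Luo style recursion.

    Computes each animal's diagonal of A as sum_j L_ij^2 d_j by walking its
    ancestor closure, where d_j is the within-family (Mendelian sampling)
    variance coefficient.  Parents must precede offspring.
    """
    n = sire.shape[0]
    f = np.zeros(n)
    dvec = np.zeros(n)
    coef = np.zeros(n)
    for i in range(n):
        s = sire[i]
        d = dam[i]
        fs = f[s] if s >= 0 else -1.0
        fd = f[d] if d >= 0 else -1.0
        # unknown parent encoded as F=-1 gives the right d for 0/1/2 known parents
        dvec[i] = 0.5 - 0.25 * (fs + fd)
        if s < 0 or d < 0:
            f[i] = 0.0
            continue
        for j in range(i + 1):
            coef[j] = 0.0
        coef[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            c = coef[j]
            if c == 0.0:
                continue
            aii += c * c * dvec[j]
            sj = sire[j]
            dj = dam[j]
            if sj >= 0:
                coef[sj] += 0.5 * c
            if dj >= 0:
                coef[dj] += 0.5 * c
        f[i] = aii - 1.0
    return f


@njit(cache=True)
def tabular_a(sire, dam):
    """Dense numerator relationship matrix by the tabular method."""
    n = sire.shape[0]
    a = np.zeros((n, n))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        for j in range(i):
            v = 0.0
            if s >= 0:
                v += 0.5 * a[j, s]
            if d >= 0:
                v += 0.5 * a[j, d]
            a[i, j] = v
            a[j, i] = v
        aii = 1.0
        if s >= 0 and d >= 0:
            aii += 0.5 * a[s, d]
        a[i, i] = aii
    return a


# ---------------------------------------------------------------------------
# truncated-normal draw (threshold-model liabilities)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _tnorm_std_lower(a):
    """Draw z ~ N(0,1) conditional on z >= a.

    Plain rejection when the acceptance region carries decent mass, Robert's
    translated-exponential rejection in the tail.
    """
    if a < 0.45:
        while True:
            z = np.random.standard_normal()
            if z >= a:
                return z
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        z = a - np.log(np.random.random()) / lam
        diff = z - lam
        if np.random.random() <= np.exp(-0.5 * diff * diff):
            return z


@njit(cache=True, inline="always")
def _draw_liability(mu, success):
    """Liability draw from N(mu, 1) truncated at 0 by the observed category."""
    if success:
        return mu + _tnorm_std_lower(-mu)
    return mu - _tnorm_std_lower(mu)


# ---------------------------------------------------------------------------
# single-trait Gibbs sampler (linear or threshold)
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_gibbs_single(
    y,
    success,
    is_threshold,
    xdata,
    xrow,
    xptr,
    xss,
    wlev,
    nw,
    aptr,
    arec,
    hptr,
    hidx,
    hval,
    total,
    burnin,
    thin,
    nu_u,
    s_u,
    nu_e,
    s_e,
    nu_w,
    s_w,
    vu0,
    ve0,
    vw0,
    seed,
):
    """Single-site Gibbs sampler for one trait.

    Model: y = X b + W w + Z a + e with a ~ N(0, H sigma2_u),
    w ~ N(0, I sigma2_w) (optional uncorrelated random group) and
    e ~ N(0, I sigma2_e).  For a threshold trait ``y`` is the latent liability
    vector (resampled each sweep from its truncated-normal full conditional)
    and sigma2_e is fixed at 1.

    Returns the retained draws of (sigma2_u, sigma2_w, sigma2_e).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = xss.shape[0]
    q = hptr.shape[0] - 1
    b = np.zeros(p)
    w = np.zeros(max(nw, 1))
    wd = np.zeros(max(nw, 1))
    wsum = np.zeros(max(nw, 1))
    wcnt = np.zeros(max(nw, 1))
    a = np.zeros(q)
    e = y.copy()
    if nw > 0:
        for r in range(n):
            wcnt[wlev[r]] += 1.0
    vu = vu0
    ve = 1.0 if is_threshold else ve0
    vw = vw0
    nkeep = (total - burnin) // thin
    out_vu = np.empty(nkeep)
    out_vw = np.full(nkeep, np.nan)
    out_ve = np.empty(nkeep)
    kept = 0
    for it in range(1, total + 1):
        # --- latent liabilities -------------------------------------------
        if is_threshold:
            for r in range(n):
                mu = y[r] - e[r]
                lnew = _draw_liability(mu, success[r] == 1)
                e[r] += lnew - y[r]
                y[r] = lnew
        # --- fixed effects (flat prior) -----------------------------------
        for j in range(p):
            rhs = xss[j] * b[j]
            for k in range(xptr[j], xptr[j + 1]):
                rhs += xdata[k] * e[xrow[k]]
            mean = rhs / xss[j]
            bnew = mean + np.random.standard_normal() * np.sqrt(ve / xss[j])
            diff = bnew - b[j]
            for k in range(xptr[j], xptr[j + 1]):
                e[xrow[k]] -= xdata[k] * diff
            b[j] = bnew
        # --- uncorrelated random group ------------------------------------
        if nw > 0:
            for l in range(nw):
                wsum[l] = 0.0
            for r in range(n):
                wsum[wlev[r]] += e[r]
            for l in range(nw):
                prec = wcnt[l] / ve + 1.0 / vw
                mean = (wsum[l] + wcnt[l] * w[l]) / ve / prec
                wnew = mean + np.random.standard_normal() / np.sqrt(prec)
                wd[l] = wnew - w[l]
                w[l] = wnew
            for r in range(n):
                e[r] -= wd[wlev[r]]
        # --- animal additive effects --------------------------------------
        inv_vu = 1.0 / vu
        for i in range(q):
            sacc = 0.0
            hii = 0.0
            for k in range(hptr[i], hptr[i + 1]):
                jj = hidx[k]
                if jj == i:
                    hii = hval[k]
                else:
                    sacc += hval[k] * a[jj]
            cnt = aptr[i + 1] - aptr[i]
            rsum = 0.0
            for k in range(aptr[i], aptr[i + 1]):
                rsum += e[arec[k]]
            prec = cnt / ve + hii * inv_vu
            rhs = (rsum + cnt * a[i]) / ve - sacc * inv_vu
            anew = rhs / prec + np.random.standard_normal() / np.sqrt(prec)
            da = anew - a[i]
            a[i] = anew
            for k in range(aptr[i], aptr[i + 1]):
                e[arec[k]] -= da
        # --- variance components ------------------------------------------
        quad = 0.0
        for i in range(q):
            for k in range(hptr[i], hptr[i + 1]):
                quad += a[i] * hval[k] * a[hidx[k]]
        vu = (quad + nu_u * s_u) / np.random.chisquare(q + nu_u)
        if vu < 1e-12:
            vu = 1e-12
        if nw > 0:
            ssw = 0.0
            for l in range(nw):
                ssw += w[l] * w[l]
            vw = (ssw + nu_w * s_w) / np.random.chisquare(nw + nu_w)
            if vw < 1e-12:
                vw = 1e-12
        if is_threshold:
            ve = 1.0
        else:
            sse = 0.0
            for r in range(n):
                sse += e[r] * e[r]
            ve = (sse + nu_e * s_e) / np.random.chisquare(n + nu_e)
            if ve < 1e-12:
                ve = 1e-12
        # --- bookkeeping ---------------------------------------------------
        if it > burnin and (it - burnin) % thin == 0:
            out_vu[kept] = vu
            if nw > 0:
                out_vw[kept] = vw
            out_ve[kept] = ve
            kept += 1
    return out_vu, out_vw, out_ve


# ---------------------------------------------------------------------------
# 2x2 helpers for the bi-trait sampler
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _inv2(a00, a01, a11):
    det = a00 * a11 - a01 * a01
    return a11 / det, -a01 / det, a00 / det


@njit(cache=True)
def _draw_invwishart2(s00, s01, s11, df):
    """Draw a 2x2 matrix from InvWishart(df, S) via the Bartlett decomposition
    of its Wishart-distributed inverse."""
    i00, i01, i11 = _inv2(s00, s01, s11)  # S^-1
    # Cholesky of S^-1
    l00 = np.sqrt(i00)
    l10 = i01 / l00
    l11 = np.sqrt(i11 - l10 * l10)
    # Bartlett factor
    c00 = np.sqrt(np.random.chisquare(df))
    c10 = np.random.standard_normal()
    c11 = np.sqrt(np.random.chisquare(df - 1.0))
    # T = L @ C (lower triangular); W = T T' ~ Wishart(df, S^-1)
    t00 = l00 * c00
    t10 = l10 * c00 + l11 * c10
    t11 = l11 * c11
    w00 = t00 * t00
    w01 = t00 * t10
    w11 = t10 * t10 + t11 * t11
    return _inv2(w00, w01, w11)  # G = W^-1 ~ InvWishart(df, S)


# ---------------------------------------------------------------------------
# bi-trait Gibbs sampler
# ---------------------------------------------------------------------------


@njit(cache=True)
def run_gibbs_bitrait(
    y1,
    success1,
    th1,
    x1data,
    x1row,
    x1ptr,
    x1ss,
    w1lev,
    nw1,
    a1ptr,
    a1rec,
    y2,
    success2,
    th2,
    x2data,
    x2row,
    x2ptr,
    x2ss,
    w2lev,
    nw2,
    a2ptr,
    a2rec,
    hptr,
    hidx,
    hval,
    total,
    burnin,
    thin,
    nu_g,
    sg00,
    sg11,
    nu_e,
    s_e1,
    s_e2,
    nu_w,
    s_w1,
    s_w2,
    g0_00,
    g0_11,
    ve10,
    ve20,
    vw10,
    vw20,
    seed,
):
    """Single-site Gibbs sampler for a two-trait animal model.

    The two traits are separate record sets (possibly on disjoint animals,
    e.g. a male and a female trait) linked through the additive effects
    a_i = (a_i1, a_i2) ~ N(0, H x G_a).  The residual covariance between
    traits is structurally zero because no record carries both traits; each
    linear trait's residual variance is sampled, each threshold trait's is
    fixed at 1.  G_a gets an inverse-Wishart full conditional.

    Returns retained draws of G_a (flattened), per-trait residual variances
    and per-trait uncorrelated-group variances.
    """
    np.random.seed(seed)
    n1 = y1.shape[0]
    n2 = y2.shape[0]
    p1 = x1ss.shape[0]
    p2 = x2ss.shape[0]
    q = hptr.shape[0] - 1
    b1 = np.zeros(p1)
    b2 = np.zeros(p2)
    w1 = np.zeros(max(nw1, 1))
    w2 = np.zeros(max(nw2, 1))
    wd = np.zeros(max(max(nw1, nw2), 1))
    wsum = np.zeros(max(max(nw1, nw2), 1))
    w1cnt = np.zeros(max(nw1, 1))
    w2cnt = np.zeros(max(nw2, 1))
    a = np.zeros((q, 2))
    e1 = y1.copy()
    e2 = y2.copy()
    if nw1 > 0:
        for r in range(n1):
            w1cnt[w1lev[r]] += 1.0
    if nw2 > 0:
        for r in range(n2):
            w2cnt[w2lev[r]] += 1.0
    g00 = g0_00
    g01 = 0.0
    g11 = g0_11
    ve1 = 1.0 if th1 else ve10
    ve2 = 1.0 if th2 else ve20
    vw1 = vw10
    vw2 = vw20
    nkeep = (total - burnin) // thin
    out_g = np.empty((nkeep, 3))
    out_ve = np.empty((nkeep, 2))
    out_vw = np.full((nkeep, 2), np.nan)
    kept = 0
    for it in range(1, total + 1):
        # --- liabilities ---------------------------------------------------
        if th1:
            for r in range(n1):
                mu = y1[r] - e1[r]
                lnew = _draw_liability(mu, success1[r] == 1)
                e1[r] += lnew - y1[r]
                y1[r] = lnew
        if th2:
            for r in range(n2):
                mu = y2[r] - e2[r]
                lnew = _draw_liability(mu, success2[r] == 1)
                e2[r] += lnew - y2[r]
                y2[r] = lnew
        # --- fixed effects -------------------------------------------------
        for j in range(p1):
            rhs = x1ss[j] * b1[j]
            for k in range(x1ptr[j], x1ptr[j + 1]):
                rhs += x1data[k] * e1[x1row[k]]
            bnew = rhs / x1ss[j] + np.random.standard_normal() * np.sqrt(ve1 / x1ss[j])
            diff = bnew - b1[j]
            for k in range(x1ptr[j], x1ptr[j + 1]):
                e1[x1row[k]] -= x1data[k] * diff
            b1[j] = bnew
        for j in range(p2):
            rhs = x2ss[j] * b2[j]
            for k in range(x2ptr[j], x2ptr[j + 1]):
                rhs += x2data[k] * e2[x2row[k]]
            bnew = rhs / x2ss[j] + np.random.standard_normal() * np.sqrt(ve2 / x2ss[j])
            diff = bnew - b2[j]
            for k in range(x2ptr[j], x2ptr[j + 1]):
                e2[x2row[k]] -= x2data[k] * diff
            b2[j] = bnew
        # --- uncorrelated random groups -----------------------------------
        if nw1 > 0:
            for l in range(nw1):
                wsum[l] = 0.0
            for r in range(n1):
                wsum[w1lev[r]] += e1[r]
            for l in range(nw1):
                prec = w1cnt[l] / ve1 + 1.0 / vw1
                mean = (wsum[l] + w1cnt[l] * w1[l]) / ve1 / prec
                wnew = mean + np.random.standard_normal() / np.sqrt(prec)
                wd[l] = wnew - w1[l]
                w1[l] = wnew
            for r in range(n1):
                e1[r] -= wd[w1lev[r]]
        if nw2 > 0:
            for l in range(nw2):
                wsum[l] = 0.0
            for r in range(n2):
                wsum[w2lev[r]] += e2[r]
            for l in range(nw2):
                prec = w2cnt[l] / ve2 + 1.0 / vw2
                mean = (wsum[l] + w2cnt[l] * w2[l]) / ve2 / prec
                wnew = mean + np.random.standard_normal() / np.sqrt(prec)
                wd[l] = wnew - w2[l]
                w2[l] = wnew
            for r in range(n2):
                e2[r] -= wd[w2lev[r]]
        # --- animal effects (2-vectors) -----------------------------------
        gi00, gi01, gi11 = _inv2(g00, g01, g11)
        for i in range(q):
            s0 = 0.0
            s1 = 0.0
            hii = 0.0
            for k in range(hptr[i], hptr[i + 1]):
                jj = hidx[k]
                if jj == i:
                    hii = hval[k]
                else:
                    s0 += hval[k] * a[jj, 0]
                    s1 += hval[k] * a[jj, 1]
            c1 = a1ptr[i + 1] - a1ptr[i]
            c2 = a2ptr[i + 1] - a2ptr[i]
            r1 = 0.0
            for k in range(a1ptr[i], a1ptr[i + 1]):
                r1 += e1[a1rec[k]]
            r2 = 0.0
            for k in range(a2ptr[i], a2ptr[i + 1]):
                r2 += e2[a2rec[k]]
            p00 = c1 / ve1 + hii * gi00
            p01 = hii * gi01
            p11 = c2 / ve2 + hii * gi11
            rhs0 = (r1 + c1 * a[i, 0]) / ve1 - (gi00 * s0 + gi01 * s1)
            rhs1 = (r2 + c2 * a[i, 1]) / ve2 - (gi01 * s0 + gi11 * s1)
            v00, v01, v11 = _inv2(p00, p01, p11)  # conditional covariance
            m0 = v00 * rhs0 + v01 * rhs1
            m1 = v01 * rhs0 + v11 * rhs1
            # Cholesky of the covariance
            l00 = np.sqrt(v00)
            l10 = v01 / l00
            l11 = np.sqrt(v11 - l10 * l10)
            z0 = np.random.standard_normal()
            z1 = np.random.standard_normal()
            a0new = m0 + l00 * z0
            a1new = m1 + l10 * z0 + l11 * z1
            d0 = a0new - a[i, 0]
            d1 = a1new - a[i, 1]
            a[i, 0] = a0new
            a[i, 1] = a1new
            for k in range(a1ptr[i], a1ptr[i + 1]):
                e1[a1rec[k]] -= d0
            for k in range(a2ptr[i], a2ptr[i + 1]):
                e2[a2rec[k]] -= d1
        # --- additive (co)variance matrix ---------------------------------
        q00 = 0.0
        q01 = 0.0
        q11 = 0.0
        for i in range(q):
            for k in range(hptr[i], hptr[i + 1]):
                jj = hidx[k]
                h = hval[k]
                q00 += a[i, 0] * h * a[jj, 0]
                q01 += a[i, 0] * h * a[jj, 1]
                q11 += a[i, 1] * h * a[jj, 1]
        g00, g01, g11 = _draw_invwishart2(
            q00 + nu_g * sg00, q01, q11 + nu_g * sg11, q + nu_g
        )
        # --- residual / group variances -----------------------------------
        if not th1:
            sse = 0.0
            for r in range(n1):
                sse += e1[r] * e1[r]
            ve1 = (sse + nu_e * s_e1) / np.random.chisquare(n1 + nu_e)
        if not th2:
            sse = 0.0
            for r in range(n2):
                sse += e2[r] * e2[r]
            ve2 = (sse + nu_e * s_e2) / np.random.chisquare(n2 + nu_e)
        if nw1 > 0:
            ssw = 0.0
            for l in range(nw1):
                ssw += w1[l] * w1[l]
            vw1 = (ssw + nu_w * s_w1) / np.random.chisquare(nw1 + nu_w)
        if nw2 > 0:
            ssw = 0.0
            for l in range(nw2):
                ssw += w2[l] * w2[l]
            vw2 = (ssw + nu_w * s_w2) / np.random.chisquare(nw2 + nu_w)
        # --- bookkeeping ---------------------------------------------------
        if it > burnin and (it - burnin) % thin == 0:
            out_g[kept, 0] = g00
            out_g[kept, 1] = g01
            out_g[kept, 2] = g11
            out_ve[kept, 0] = ve1
            out_ve[kept, 1] = ve2
            if nw1 > 0:
                out_vw[kept, 0] = vw1
            if nw2 > 0:
                out_vw[kept, 1] = vw2
            kept += 1
    return out_g, out_ve, out_vw
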