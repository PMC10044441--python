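"""Posterior summaries: heritability, genetic correlation, HPD intervals,
Geweke convergence Z-scores, standard errors, and table/heatmap export.

The reporting conventions mirror routine genetic-parameter papers: posterior
mean, a 90%-content highest-posterior-density interval labelled 5%/95%, a
Geweke Z comparing the first 10% against the last 50% of the chain with
spectral-density-at-zero variance estimates, and a standard error defined as
the posterior SD divided by sqrt(number of records) (the field's convention,
statistically unconventional as it mixes Monte Carlo and data scales).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import VarianceDraws

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-draw parameter transforms
# ---------------------------------------------------------------------------


def heritability_draws(
    draws: VarianceDraws, include_uncorrelated: bool = True, trait: int = 0
) -> np.ndarray:
    """Per-draw h2 = sigma2_u / (sigma2_u [+ sigma2_w] + sigma2_e).

    The uncorrelated-group variance counts in the phenotypic variance by
    default (liability scale for threshold traits, where sigma2_e = 1).
    """
    vu = draws.sigma2_u(trait)
    ve = draws.sigma2_e(trait)
    vw = draws.sigma2_w(trait)
    denom = vu + ve
    if include_uncorrelated and not np.isnan(vw).all():
        denom = denom + vw
    return vu / denom


def genetic_correlation_draws(draws: VarianceDraws) -> np.ndarray:
    """Per-draw r_g = sigma_u12 / sqrt(sigma2_u1 * sigma2_u2).

    Draws with a non-positive variance are excluded (logged); the positive-
    definiteness of every stored G_a keeps |r_g| <= 1.
    """
    if draws.n_traits != 2:
        raise ValueError("genetic correlation needs bi-trait draws")
    v1 = draws.additive[:, 0, 0]
    v2 = draws.additive[:, 1, 1]
    c12 = draws.additive[:, 0, 1]
    ok = (v1 > 0) & (v2 > 0)
    if not ok.all():
        logger.warning("excluding %d zero-variance draws from r_g",
                       int((~ok).sum()))
    return c12[ok] / np.sqrt(v1[ok] * v2[ok])


# ---------------------------------------------------------------------------
# interval and convergence diagnostics
# ---------------------------------------------------------------------------


def hpd_interval(samples, content: float = 0.90,
                 method: str = "hpd") -> tuple[float, float]:
    """Credible interval of the given posterior content.

    ``method="hpd"`` returns the shortest window over the sorted samples that
    contains ceil(content * n) of them (leftmost window on ties);
    ``method="equal-tail"`` returns the (1-content)/2 and (1+content)/2
    quantiles.
    """
    if not 0.0 < content < 1.0:
        raise ValueError(f"content must be in (0,1), got {content}")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 samples for an interval")
    if method == "equal-tail":
        lo, hi = np.quantile(x, [(1 - content) / 2, (1 + content) / 2])
        return float(lo), float(hi)
    if method != "hpd":
        raise ValueError(f"unknown interval method {method!r}")
    m = int(math.ceil(content * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the leftmost minimum
    return float(x[i]), float(x[i + m - 1])


def _spectral_variance_at_zero(x: np.ndarray) -> float:
    """Variance of the mean of ``x`` via the Bartlett-windowed estimate of the
    spectral density at frequency zero (Newey-West style lag truncation)."""
    m = x.size
    xc = x - x.mean()
    lag = int(math.floor(4.0 * (m / 100.0) ** (2.0 / 9.0)))
    lag = min(lag, m - 1)
    gamma0 = float(xc @ xc) / m
    s = gamma0
    for k in range(1, lag + 1):
        gk = float(xc[k:] @ xc[:-k]) / m
        s += 2.0 * (1.0 - k / (lag + 1.0)) * gk
    return max(s, 0.0) / m


def _batch_means_variance(x: np.ndarray) -> float:
    m = x.size
    nb = max(2, int(math.sqrt(m)))
    bs = m // nb
    means = x[: nb * bs].reshape(nb, bs).mean(axis=1)
    return float(np.var(means, ddof=1)) / nb


def geweke_z(chain, frac_first: float = 0.1, frac_last: float = 0.5) -> float:
    """Geweke convergence diagnostic.

    Z = (mean of the first ``frac_first`` of the chain minus mean of the last
    ``frac_last``) over the square root of the summed variance estimates of
    those window means.  Spectral-density-at-zero variance estimates are used
    for windows of 50+ draws, a batch-means fallback below that.
    """
    x = np.asarray(chain, dtype=float)
    if x.size < 100:
        raise ValueError("Geweke needs a chain of length >= 100")
    if frac_first + frac_last > 1.0:
        raise ValueError("frac_first + frac_last must be <= 1")
    first = x[: int(frac_first * x.size)]
    last = x[x.size - int(frac_last * x.size):]
    var_est = (
        _spectral_variance_at_zero
        if min(first.size, last.size) >= 50
        else _batch_means_variance
    )
    v1 = var_est(first)
    v2 = var_est(last)
    if v1 + v2 <= 0.0:
        raise ValueError("degenerate chain: zero variance in both windows")
    return float((first.mean() - last.mean()) / math.sqrt(v1 + v2))


def standard_error(draws, n_records: int) -> float:
    """SE = sd(draws) / sqrt(n_records), sample SD with the n-1 denominator."""
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    return float(np.std(np.asarray(draws, dtype=float), ddof=1)
                 / math.sqrt(n_records))


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSummary:
    parameter: str
    mean: float
    hpd_low: float
    hpd_high: float
    geweke_z: float | None
    se: float
    n_draws: int
    n_records: int


def _summarize_chain(name, samples, n_records, content=0.90) -> PosteriorSummary:
    samples = np.asarray(samples, dtype=float)
    lo, hi = hpd_interval(samples, content=content)
    try:
        z = geweke_z(samples)
    except ValueError as exc:
        logger.warning("Geweke unavailable for %s: %s", name, exc)
        z = None
    return PosteriorSummary(
        parameter=name,
        mean=float(samples.mean()),
        hpd_low=lo,
        hpd_high=hi,
        geweke_z=z,
        se=standard_error(samples, n_records),
        n_draws=samples.size,
        n_records=n_records,
    )


def summarize_run(
    draws: VarianceDraws,
    include_uncorrelated: bool = True,
    content: float = 0.90,
) -> pd.DataFrame:
    """One summary row per parameter, pairing each trait's additive variance
    with its heritability (and r_g for bi-trait runs), in the layout of a
    genetic-parameter report table."""
    rows = []
    for t, name in enumerate(draws.trait_names):
        nrec = draws.n_records[t]
        rows.append(_summarize_chain(
            f"sigma2_u[{name}]", draws.sigma2_u(t), nrec, content))
        rows.append(_summarize_chain(
            f"h2[{name}]",
            heritability_draws(draws, include_uncorrelated, trait=t),
            nrec, content))
    if draws.n_traits == 2:
        nrec = sum(draws.n_records)
        rows.append(_summarize_chain(
            "sigma_u12", draws.additive[:, 0, 1], nrec, content))
        rows.append(_summarize_chain(
            "r_g", genetic_correlation_draws(draws), nrec, content))
    df = pd.DataFrame([vars(r) for r in rows])
    return df.rename(columns={"hpd_low": f"hpd_{(1-content)/2:.0%}",
                              "hpd_high": f"hpd_{(1+content)/2:.0%}"})


def correlation_matrix(pairwise: dict[tuple[str, str], float],
                       traits=None) -> pd.DataFrame:
    """Symmetric unit-diagonal matrix from pairwise r_g estimates."""
    if traits is None:
        traits = sorted({t for pair in pairwise for t in pair})
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for (t1, t2), r in pairwise.items():
        mat.loc[t1, t2] = r
        mat.loc[t2, t1] = r
    return mat


def export_correlation_heatmap(matrix: pd.DataFrame, csv_path,
                               png_path=None) -> None:
    """Write the correlation matrix CSV (the tested artifact) and optionally a
    rendered heatmap image."""
    matrix.to_csv(csv_path)
    if png_path is None:
        return
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * len(matrix),) * 2)
    im = ax.imshow(matrix.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix)), matrix.columns, rotation=90)
    ax.set_yticks(range(len(matrix)), matrix.index)
    for i in range(len(matrix)):
        for j in range(len(matrix)):
            ax.text(j, i, f"{matrix.iat[i, j]:.2f}", ha="center", va="center",
                    fontsize=7)
    fig.colorbar(im, ax=ax, label="genetic correlation")
    fig.tight_layout()
    fig.savefig(png_path, dpi=150)
    plt.close(fig)
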