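"""Bayesian animal models via Gibbs sampling.

Fits single- and two-trait mixed models

    y = X b + W w + Z a + e,    a ~ N(0, H (x) G_a)

where X holds the systematic effects (contemporary group and other class
effects, centered covariates such as age and age squared), W an optional
uncorrelated random group (the weaning management group), Z maps records to
animals, and the additive effects are structured by the single-step
relationship matrix through its sparse inverse H^-1.  Binary traits are fitted
on the probit/liability scale: a latent Gaussian liability with residual
variance fixed at 1 and threshold at 0 is resampled from truncated-normal full
conditionals each sweep.

Sampling is single-site Gibbs over all location effects, with variance
components drawn from scaled inverse chi-square (single trait) or
inverse-Wishart (two-trait additive covariance) full conditionals.  Systematic
effects carry flat priors.  Chains are bit-reproducible at a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import _kernels
from .phenotypes import ModelSpec, SUCCESS
from .relmat import HInverse

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chain configuration
# ---------------------------------------------------------------------------


@dataclass
class ChainConfig:
    """MCMC schedule.  The defaults are the full production schedule
    (800,000 iterations, 200,000 burn-in, thinning 100 -> 6,000 retained
    draws); reduced schedules are passed explicitly for desk-scale work."""

    total_iterations: int = 800_000
    burn_in: int = 200_000
    thin: int = 100
    seed: int | None = None

    def __post_init__(self):
        if self.burn_in >= self.total_iterations:
            raise ValueError(
                f"burn_in ({self.burn_in}) must be below total_iterations "
                f"({self.total_iterations})"
            )
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def retained(self) -> int:
        return (self.total_iterations - self.burn_in) // self.thin

    def kernel_seed(self) -> int:
        if self.seed is None:
            raise ValueError("ChainConfig.seed is mandatory for sampling")
        return int(self.seed) % (2**31 - 1)


def chain_bookkeeping(config: ChainConfig) -> tuple[int, np.ndarray]:
    """Retained-draw count and the 1-based iteration indices that are saved:
    burn_in + thin, burn_in + 2*thin, ..."""
    idx = np.arange(1, config.retained + 1) * config.thin + config.burn_in
    return config.retained, idx


# ---------------------------------------------------------------------------
# model system construction
# ---------------------------------------------------------------------------


@dataclass
class MixedModelSystem:
    """One trait's records in sampler-ready array form."""

    trait_name: str
    kind: str  # linear | threshold
    y: np.ndarray  # observations (liability start values for threshold)
    success: np.ndarray  # int8, 1 = success (threshold traits only)
    x_csc: sp.csc_matrix
    column_names: list[str]
    wlev: np.ndarray  # per-record uncorrelated-group level, or empty
    nw: int
    animal: np.ndarray  # per-record pedigree index
    h_inv: HInverse
    n_records: int

    @property
    def n_animals(self) -> int:
        return self.h_inv.n

    def design_arrays(self):
        x = self.x_csc
        xss = np.asarray(x.multiply(x).sum(axis=0)).ravel()
        aptr, arec = _record_lists(self.animal, self.n_animals)
        hptr, hidx, hval = self.h_inv.csr_parts()
        return (
            x.data.astype(np.float64),
            x.indices.astype(np.int64),
            x.indptr.astype(np.int64),
            xss,
            self.wlev.astype(np.int64),
            self.nw,
            aptr,
            arec,
            hptr,
            hidx,
            hval,
        )


def _record_lists(animal: np.ndarray, q: int):
    """CSR-style per-animal record lists (aptr, arec)."""
    order = np.argsort(animal, kind="stable")
    counts = np.bincount(animal, minlength=q)
    aptr = np.zeros(q + 1, dtype=np.int64)
    np.cumsum(counts, out=aptr[1:])
    return aptr, order.astype(np.int64)


def build_system(
    records: pd.DataFrame,
    model: ModelSpec,
    h_inv: HInverse,
) -> MixedModelSystem:
    """Assemble design matrices for one trait.

    ``records`` needs ``animal_id``, ``value``, a ``cg`` column, any covariate
    columns named in the model (centered here; age is centered before
    squaring), a ``cri_class`` column if CRI is modeled and the uncorrelated
    random group column if one is modeled.  Class-effect coding is full rank
    without an intercept: the first factor keeps all its levels, later factors
    drop their first level.
    """
    df = records.reset_index(drop=True)
    n = len(df)
    if n == 0:
        raise ValueError(f"no records for trait {model.trait_name}")
    missing_y = df["value"].isna()
    if missing_y.any():
        logger.info("dropping %d records with missing value", int(missing_y.sum()))
        df = df.loc[~missing_y].reset_index(drop=True)
        n = len(df)

    ped_index = {a: i for i, a in enumerate(h_inv.ids)}
    try:
        animal = np.array([ped_index[str(a)] for a in df["animal_id"]],
                          dtype=np.int64)
    except KeyError as exc:
        raise KeyError(
            f"record animal {exc.args[0]!r} is absent from the pedigree"
        ) from None

    cols = []
    names: list[str] = []
    factor_cols = {"CG": "cg", "CRI": "cri_class"}
    for k, factor in enumerate(model.fixed_class_effects):
        col = factor_cols.get(factor, factor.lower())
        codes, levels = pd.factorize(df[col], sort=True)
        drop_first = k > 0  # first factor spans the intercept
        for li, level in enumerate(levels):
            if drop_first and li == 0:
                continue
            ind = sp.csc_matrix(
                (np.ones(np.sum(codes == li)),
                 (np.flatnonzero(codes == li), np.zeros(np.sum(codes == li)))),
                shape=(n, 1),
            )
            cols.append(ind)
            names.append(f"{factor}={level}")
    for cov, power in model.covariates:
        x = df[cov].to_numpy(dtype=float)
        xc = x - x.mean()
        v = xc**power
        if np.allclose(v, v[0]):
            raise ValueError(
                f"covariate column {cov}^{power} is constant (empty design column)"
            )
        cols.append(sp.csc_matrix(v.reshape(-1, 1)))
        names.append(f"{cov}^{power}")
    x_csc = sp.hstack(cols, format="csc") if cols else sp.csc_matrix((n, 0))

    if model.uncorrelated_random is not None:
        wcodes, wlevels = pd.factorize(df[model.uncorrelated_random], sort=True)
        wlev = wcodes.astype(np.int64)
        nw = len(wlevels)
    else:
        wlev = np.empty(0, dtype=np.int64)
        nw = 0

    if model.kind == "threshold":
        cats = df["value"].to_numpy()
        success = (cats == SUCCESS).astype(np.int8)
        present = np.unique(cats)
        if len(present) < 2:
            raise ValueError(
                f"threshold trait {model.trait_name} has a single observed "
                f"category ({present.tolist()}); nothing to estimate"
            )
        y = np.where(success == 1, 0.5, -0.5).astype(np.float64)
    else:
        y = df["value"].to_numpy(dtype=np.float64)
        success = np.zeros(n, dtype=np.int8)

    return MixedModelSystem(
        trait_name=model.trait_name,
        kind=model.kind,
        y=y,
        success=success,
        x_csc=x_csc,
        column_names=names,
        wlev=wlev,
        nw=nw,
        animal=animal,
        h_inv=h_inv,
        n_records=n,
    )


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


@dataclass
class VariancePriors:
    """Scaled inverse chi-square / inverse-Wishart hyperparameters.

    Defaults are weakly informative: degrees of freedom = dimension + 1 and
    scales derived from the phenotypic variance with a 0.3 additive share (a
    crude ANOVA-style split); the data dominate for any realistic record
    count.  ``flat=True`` switches to the improper flat prior on variances
    (df = -2, scale 0)."""

    nu_u: float | None = None
    s_u: float | None = None
    nu_e: float = 2.0
    s_e: float | None = None
    nu_w: float = 2.0
    s_w: float | None = None
    flat: bool = False

    def resolved_single(self, vy: float):
        if self.flat:
            return (-2.0, 0.0, -2.0, 0.0, -2.0, 0.0)
        nu_u = 2.0 if self.nu_u is None else self.nu_u
        s_u = 0.3 * vy if self.s_u is None else self.s_u
        s_e = 0.7 * vy if self.s_e is None else self.s_e
        s_w = 0.1 * vy if self.s_w is None else self.s_w
        return (nu_u, s_u, self.nu_e, s_e, self.nu_w, s_w)


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class VarianceDraws:
    """Retained variance-component draws.

    ``additive`` has shape (n_draws, t, t); ``residual`` and ``uncorrelated``
    (n_draws, t), the latter NaN for traits without an uncorrelated random
    group.  Threshold traits carry residual variance exactly 1 in every draw.
    """

    trait_names: tuple
    kinds: tuple
    additive: np.ndarray
    residual: np.ndarray
    uncorrelated: np.ndarray
    config: ChainConfig
    n_records: tuple

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    @property
    def n_draws(self) -> int:
        return self.additive.shape[0]

    def sigma2_u(self, trait: int = 0) -> np.ndarray:
        return self.additive[:, trait, trait]

    def sigma2_e(self, trait: int = 0) -> np.ndarray:
        return self.residual[:, trait]

    def sigma2_w(self, trait: int = 0) -> np.ndarray:
        return self.uncorrelated[:, trait]

    def to_frame(self) -> pd.DataFrame:
        data = {}
        for t, name in enumerate(self.trait_names):
            data[f"sigma2_u_{name}"] = self.sigma2_u(t)
            data[f"sigma2_e_{name}"] = self.sigma2_e(t)
            if not np.isnan(self.uncorrelated[:, t]).all():
                data[f"sigma2_w_{name}"] = self.sigma2_w(t)
        if self.n_traits == 2:
            data["sigma_u_12"] = self.additive[:, 0, 1]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit_single(
    system: MixedModelSystem,
    config: ChainConfig,
    priors: VariancePriors | None,
) -> VarianceDraws:
    priors = priors or VariancePriors()
    is_threshold = system.kind == "threshold"
    vy = 1.0 if is_threshold else float(np.var(system.y))
    nu_u, s_u, nu_e, s_e, nu_w, s_w = priors.resolved_single(vy)
    vu0 = max(0.3 * vy, 1e-8)
    ve0 = max(0.7 * vy, 1e-8)
    vw0 = max(0.1 * vy, 1e-8)
    arrays = system.design_arrays()
    logger.info(
        "Gibbs %s trait %s: n=%d, p=%d, q=%d, chain %d/%d/%d",
        system.kind, system.trait_name, system.n_records,
        system.x_csc.shape[1], system.n_animals,
        config.total_iterations, config.burn_in, config.thin,
    )
    out_vu, out_vw, out_ve = _kernels.run_gibbs_single(
        system.y.copy(),
        system.success,
        is_threshold,
        *arrays,
        config.total_iterations,
        config.burn_in,
        config.thin,
        nu_u, s_u, nu_e, s_e, nu_w, s_w,
        vu0, ve0, vw0,
        config.kernel_seed(),
    )
    nk = out_vu.shape[0]
    return VarianceDraws(
        trait_names=(system.trait_name,),
        kinds=(system.kind,),
        additive=out_vu.reshape(nk, 1, 1),
        residual=out_ve.reshape(nk, 1),
        uncorrelated=out_vw.reshape(nk, 1),
        config=config,
        n_records=(system.n_records,),
    )


def gibbs_linear(
    system: MixedModelSystem,
    config: ChainConfig,
    priors: VariancePriors | None = None,
) -> VarianceDraws:
    """Fit a single linear (Gaussian) trait."""
    if system.kind != "linear":
        raise ValueError(f"trait {system.trait_name} is not linear")
    return _fit_single(system, config, priors)


def gibbs_threshold(
    system: MixedModelSystem,
    config: ChainConfig,
    priors: VariancePriors | None = None,
) -> VarianceDraws:
    """Fit a single binary trait on the probit/liability scale (residual
    variance fixed at 1, threshold at 0)."""
    if system.kind != "threshold":
        raise ValueError(f"trait {system.trait_name} is not threshold")
    return _fit_single(system, config, priors)


def gibbs_bitrait(
    system1: MixedModelSystem,
    system2: MixedModelSystem,
    config: ChainConfig,
    priors: VariancePriors | None = None,
) -> VarianceDraws:
    """Fit a two-trait animal model; the traits may be recorded on disjoint
    animal sets (e.g. a male and a female trait) and are then linked only
    through the relationship matrix.

    The 2x2 additive covariance gets an inverse-Wishart full conditional; the
    residual covariance between traits is structurally zero because the two
    record sets are distinct measurement events.
    """
    if system1.h_inv is not system2.h_inv and (
        system1.h_inv.ids != system2.h_inv.ids
    ):
        raise ValueError("both traits must share one relationship matrix")
    priors = priors or VariancePriors()
    th1 = system1.kind == "threshold"
    th2 = system2.kind == "threshold"
    vy1 = 1.0 if th1 else float(np.var(system1.y))
    vy2 = 1.0 if th2 else float(np.var(system2.y))
    if priors.flat:
        nu_g, sg00, sg11 = 0.0, 0.0, 0.0
        nu_e = -2.0
        s_e1 = s_e2 = 0.0
        nu_w = -2.0
        s_w1 = s_w2 = 0.0
    else:
        nu_g = 3.0 if priors.nu_u is None else priors.nu_u
        sg00 = 0.3 * vy1 if priors.s_u is None else priors.s_u
        sg11 = 0.3 * vy2 if priors.s_u is None else priors.s_u
        nu_e = priors.nu_e
        s_e1, s_e2 = 0.7 * vy1, 0.7 * vy2
        nu_w = priors.nu_w
        s_w1, s_w2 = 0.1 * vy1, 0.1 * vy2
    a1 = system1.design_arrays()
    a2 = system2.design_arrays()
    hptr, hidx, hval = a1[8:11]
    logger.info(
        "Gibbs bi-trait %s(%s) x %s(%s): n=(%d, %d), q=%d, chain %d/%d/%d",
        system1.trait_name, system1.kind, system2.trait_name, system2.kind,
        system1.n_records, system2.n_records, system1.n_animals,
        config.total_iterations, config.burn_in, config.thin,
    )
    out_g, out_ve, out_vw = _kernels.run_gibbs_bitrait(
        system1.y.copy(), system1.success, th1,
        *a1[0:4], a1[4], a1[5], a1[6], a1[7],
        system2.y.copy(), system2.success, th2,
        *a2[0:4], a2[4], a2[5], a2[6], a2[7],
        hptr, hidx, hval,
        config.total_iterations, config.burn_in, config.thin,
        nu_g, sg00, sg11,
        nu_e, s_e1, s_e2,
        nu_w, s_w1, s_w2,
        max(0.3 * vy1, 1e-8), max(0.3 * vy2, 1e-8),
        max(0.7 * vy1, 1e-8), max(0.7 * vy2, 1e-8),
        max(0.1 * vy1, 1e-8), max(0.1 * vy2, 1e-8),
        config.kernel_seed(),
    )
    nk = out_g.shape[0]
    additive = np.empty((nk, 2, 2))
    additive[:, 0, 0] = out_g[:, 0]
    additive[:, 0, 1] = additive[:, 1, 0] = out_g[:, 1]
    additive[:, 1, 1] = out_g[:, 2]
    return VarianceDraws(
        trait_names=(system1.trait_name, system2.trait_name),
        kinds=(system1.kind, system2.kind),
        additive=additive,
        residual=out_ve,
        uncorrelated=out_vw,
        config=config,
        n_records=(system1.n_records, system2.n_records),
    )


# ---------------------------------------------------------------------------
# dense mixed-model equations (desk-scale checks and starting values)
# ---------------------------------------------------------------------------


def dense_mme(system: MixedModelSystem, vu: float, ve: float,
              vw: float | None = None):
    """Dense Henderson mixed-model equations for a single-trait system.

    Returns (C, rhs, slices) with effect order [fixed, uncorrelated-group,
    animal].  Intended for small systems (oracle checks, EM-REML); the
    coefficient matrix is formed explicitly.
    """
    n = system.n_records
    q = system.n_animals
    x = system.x_csc.toarray()
    blocks = [x]
    if system.nw > 0:
        w = np.zeros((n, system.nw))
        w[np.arange(n), system.wlev] = 1.0
        blocks.append(w)
    z = np.zeros((n, q))
    z[np.arange(n), system.animal] = 1.0
    blocks.append(z)
    wmat = np.hstack(blocks)
    c = wmat.T @ wmat
    p = x.shape[1]
    lam_u = ve / vu
    h_inv = system.h_inv.matrix.toarray()
    c[-q:, -q:] += lam_u * h_inv
    if system.nw > 0:
        if vw is None:
            raise ValueError("vw required when the system has a random group")
        c[p:p + system.nw, p:p + system.nw] += (ve / vw) * np.eye(system.nw)
    rhs = wmat.T @ system.y
    slices = {
        "fixed": slice(0, p),
        "group": slice(p, p + system.nw),
        "animal": slice(c.shape[0] - q, c.shape[0]),
    }
    return c, rhs, slices
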