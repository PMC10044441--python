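"""Synthetic beef-cattle datasets with known simulation truth.

Emulates the structure of a seedstock recording scheme: a multi-generation
pedigree with large paternal half-sib families, a genotyped subset with
gene-dropped SNPs, multivariate breeding values drawn under the infinitesimal
model (founders N(0, G_a), descendants parent-average plus Mendelian sampling
with the parental-inbreeding correction), and phenotypes with contemporary
group structure, age covariates, an optional weaning-management random group,
and sex-limited recording — continuous traits on males, binary success/failure
traits (coded 1/2) on females so bi-trait runs link only through the pedigree.

Everything is reproducible under a fixed seed and every generated quantity is
traceable to a :class:`SimulationTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .pedigree import Pedigree
from .phenotypes import ModelSpec, SUCCESS, FAILURE, season_from_month


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mating: str = "half-sib-heavy",
    n_offspring: int | None = None,
    dams_per_sire: float = 20.0,
    seed: int = 0,
) -> tuple[Pedigree, pd.DataFrame]:
    """Discrete-generation pedigree.

    ``half-sib-heavy`` uses roughly one sire per ``dams_per_sire`` matings
    (large paternal half-sib families, the typical beef-cattle shape);
    ``random`` lets every male of the previous generation sire.  Returns the
    renumbered pedigree and a per-animal metadata frame (id, sex, generation,
    birth_year, birth_month).

    Raises on an infeasible mating structure (no males or no females to mate).
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if mating not in ("random", "half-sib-heavy"):
        raise ValueError(f"unknown mating scheme {mating!r}")
    rng = np.random.default_rng(seed)
    n_offspring = n_offspring or n_founders
    ids: list[str] = []
    sire_idx: list[int] = []
    dam_idx: list[int] = []
    sexes: list[str] = []
    gens: list[int] = []
    for i in range(n_founders):
        ids.append(f"G0_{i}")
        sire_idx.append(-1)
        dam_idx.append(-1)
        sexes.append("M" if i < n_founders // 2 else "F")
        gens.append(0)
    prev = np.arange(n_founders)
    for g in range(1, n_generations + 1):
        males = prev[np.array([sexes[i] == "M" for i in prev])]
        females = prev[np.array([sexes[i] == "F" for i in prev])]
        if males.size == 0 or females.size == 0:
            raise ValueError(
                f"infeasible mating at generation {g}: "
                f"{males.size} males, {females.size} females"
            )
        if mating == "half-sib-heavy":
            n_sires = max(1, int(round(n_offspring / dams_per_sire)))
            sires = rng.choice(males, size=min(n_sires, males.size),
                               replace=False)
        else:
            sires = males
        start = len(ids)
        new_sex = rng.random(n_offspring) < 0.5
        # guarantee both sexes so later generations stay feasible
        if new_sex.all():
            new_sex[0] = False
        if not new_sex.any():
            new_sex[0] = True
        for k in range(n_offspring):
            ids.append(f"G{g}_{k}")
            sire_idx.append(int(rng.choice(sires)))
            dam_idx.append(int(rng.choice(females)))
            sexes.append("M" if new_sex[k] else "F")
            gens.append(g)
        prev = np.arange(start, len(ids))
    ped = Pedigree(
        ids=ids,
        sire=np.array(sire_idx, dtype=np.int64),
        dam=np.array(dam_idx, dtype=np.int64),
    )
    months = rng.integers(1, 13, size=len(ids))
    meta = pd.DataFrame(
        {
            "animal_id": ids,
            "sex": sexes,
            "generation": gens,
            "birth_year": 2000 + np.array(gens) * 3,
            "birth_month": months,
        }
    )
    return ped, meta


# ---------------------------------------------------------------------------
# genotypes (gene dropping)
# ---------------------------------------------------------------------------


def simulate_genotypes(
    ped: Pedigree,
    n_snps: int,
    founder_maf_range: tuple[float, float] = (0.05, 0.5),
    error_rate: float = 0.0,
    n_chromosomes: int = 29,
    seed: int = 0,
) -> GenotypeMatrix:
    """Gene-drop SNP genotypes down the pedigree.

    Founder alleles are drawn at frequencies uniform in ``founder_maf_range``;
    each descendant inherits one random allele per locus from each known
    parent (alleles for an unknown parent are drawn from the founder
    frequencies).  ``error_rate`` replaces that fraction of calls with a
    random genotype, to exercise downstream QC.
    """
    lo, hi = founder_maf_range
    if not 0.0 < lo <= hi <= 0.5:
        raise ValueError("founder MAF range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    n = ped.n
    p = rng.uniform(lo, hi, size=n_snps)
    hap1 = np.zeros((n, n_snps), dtype=np.int8)
    hap2 = np.zeros((n, n_snps), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0:
            pick = rng.integers(0, 2, size=n_snps, dtype=np.int8)
            hap1[i] = np.where(pick == 0, hap1[s], hap2[s])
        else:
            hap1[i] = rng.random(n_snps) < p
        if d >= 0:
            pick = rng.integers(0, 2, size=n_snps, dtype=np.int8)
            hap2[i] = np.where(pick == 0, hap1[d], hap2[d])
        else:
            hap2[i] = rng.random(n_snps) < p
    vals = (hap1 + hap2).astype(np.int8)
    if error_rate > 0:
        err = rng.random(vals.shape) < error_rate
        vals[err] = rng.integers(0, 3, size=int(err.sum()), dtype=np.int8)
    chrom = (np.arange(n_snps) % n_chromosomes) + 1
    pos = np.arange(n_snps) // n_chromosomes * 1000 + 1000
    snp_map = pd.DataFrame(
        {"snp_id": [f"snp{j}" for j in range(n_snps)],
         "chrom": chrom.astype(str), "pos": pos}
    )
    return GenotypeMatrix(vals, list(ped.ids), snp_map)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------


def simulate_breeding_values(
    ped: Pedigree,
    g_a: np.ndarray | float,
    mode: str = "pedigree",
    genotypes: GenotypeMatrix | None = None,
    seed: int = 0,
) -> np.ndarray:
    """True breeding values (n_animals x n_traits) under the model the
    sampler assumes, a ~ N(0, A (x) G_a).

    Pedigree mode is the exact recursion: founders MVN(0, G_a), descendants
    parent average plus Mendelian sampling with variance factor
    1/2 (1 - (F_s + F_d)/2) (3/4 - F/4 with one parent known, 1 with none).
    Genomic mode sums centered SNP dosages times MVN SNP effects scaled so the
    base-population variance is G_a.
    """
    g_a = np.atleast_2d(np.asarray(g_a, dtype=float))
    t = g_a.shape[0]
    try:
        chol = np.linalg.cholesky(g_a) if np.any(g_a) else np.zeros_like(g_a)
    except np.linalg.LinAlgError:
        raise ValueError("g_a must be positive (semi-)definite") from None
    rng = np.random.default_rng(seed)
    if mode == "genomic":
        if genotypes is None:
            raise ValueError("genomic mode needs gene-dropped genotypes")
        vals = genotypes.values.astype(float)
        p = vals.mean(axis=0) / 2.0
        denom = 2.0 * np.sum(p * (1.0 - p))
        effects = rng.standard_normal((vals.shape[1], t)) @ chol.T
        return (vals - 2.0 * p) @ effects / np.sqrt(denom)
    if mode != "pedigree":
        raise ValueError(f"unknown mode {mode!r}")
    f = ped.inbreeding
    bv = np.zeros((ped.n, t))
    z = rng.standard_normal((ped.n, t))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        if s >= 0 and d >= 0:
            mean = 0.5 * (bv[s] + bv[d])
            msv = 0.5 * (1.0 - 0.5 * (f[s] + f[d]))
        elif s >= 0 or d >= 0:
            pknown = s if s >= 0 else d
            mean = 0.5 * bv[pknown]
            msv = 0.75 - 0.25 * f[pknown]
        else:
            mean = 0.0
            msv = 1.0
        bv[i] = mean + np.sqrt(msv) * (chol @ z[i])
    return bv


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


@dataclass
class TraitDesign:
    """Systematic-effect layout for one simulated trait."""

    n_cg: int = 20
    cg_sd: float = 1.0
    n_farms: int = 2
    beta_age: tuple = (0.02, -2e-4)  # linear, quadratic on centered age (d)
    age_mean: float = 450.0
    age_sd: float = 30.0
    n_gmand: int = 0
    gmand_sd: float = 0.0
    sex: str | None = None  # "M", "F" or None (both sexes recorded)
    with_cri: bool = False
    record_from_generation: int = 1


def simulate_phenotypes(
    ped: Pedigree,
    meta: pd.DataFrame,
    bv: np.ndarray,
    residual_variance: float,
    kind: str = "linear",
    incidence: float | None = None,
    design: TraitDesign | None = None,
    trait_name: str = "trait",
    seed: int = 0,
) -> pd.DataFrame:
    """One record per eligible animal:

        y = CG effect + b1*age_c + b2*age_c^2 + GMAND effect + BV + residual.

    Threshold traits treat y as the latent liability (pass
    ``residual_variance=1``) and cut it at the empirical quantile that yields
    the target ``incidence`` of successes, coding success=2 / failure=1.
    """
    design = design or TraitDesign()
    rng = np.random.default_rng(seed)
    bv = np.asarray(bv, dtype=float).ravel()
    eligible = meta["generation"] >= design.record_from_generation
    if design.sex is not None:
        eligible &= meta["sex"] == design.sex
    sub = meta.loc[eligible].reset_index(drop=True)
    if len(sub) == 0:
        raise ValueError("no eligible animals for this trait design")
    if kind == "threshold":
        if incidence is None or not 0.0 < incidence < 1.0:
            raise ValueError("threshold trait needs incidence in (0,1)")
    m = len(sub)
    cg_ids = rng.integers(0, design.n_cg, size=m)
    cg_eff = rng.normal(0.0, design.cg_sd, size=design.n_cg)
    farms = np.array([f"farm{c % design.n_farms}" for c in range(design.n_cg)])
    mgmt = np.array([f"mg{c // design.n_farms}" for c in range(design.n_cg)])
    age = rng.normal(design.age_mean, design.age_sd, size=m)
    age_c = age - age.mean()
    b1, b2 = design.beta_age
    y = cg_eff[cg_ids] + b1 * age_c + b2 * age_c**2
    if design.n_gmand > 0:
        gmand_ids = rng.integers(0, design.n_gmand, size=m)
        gmand_eff = rng.normal(0.0, design.gmand_sd, size=design.n_gmand)
        y = y + gmand_eff[gmand_ids]
    idx = ped.indices_of(sub["animal_id"])
    y = y + bv[idx] + rng.normal(0.0, np.sqrt(residual_variance), size=m)
    out = pd.DataFrame(
        {
            "animal_id": sub["animal_id"],
            "trait": trait_name,
            # the generating CG is emitted directly (a ready-made ``cg`` key)
            # alongside the descriptive fields a field recording scheme would
            # carry, so both fitting and CG-construction code paths have input
            "cg": [f"cg{c}|{s}" for c, s in zip(cg_ids, sub["sex"])],
            "farm": farms[cg_ids],
            "birth_year": sub["birth_year"],
            "birth_season": [season_from_month(mo) for mo in sub["birth_month"]],
            "sex": sub["sex"],
            "management_group": mgmt[cg_ids],
            "idap": np.round(age, 1),
            "sire_id": [ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else ""
                        for i in idx],
        }
    )
    if design.n_gmand > 0:
        out["gmand"] = [f"gm{g}" for g in gmand_ids]
    if design.with_cri:
        out["cri_days"] = rng.integers(20, 220, size=m)
    if kind == "threshold":
        cut = np.quantile(y, 1.0 - incidence)
        out["value"] = np.where(y > cut, SUCCESS, FAILURE)
        out["liability"] = y
    else:
        out["value"] = y
    return out


# ---------------------------------------------------------------------------
# study-like bundles
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Generating parameters: everything a recovery test needs."""

    trait_names: tuple
    kinds: tuple
    g_a: np.ndarray  # additive (co)variance, t x t
    residual: np.ndarray  # per-trait residual variance (1 for threshold)
    gmand: np.ndarray  # per-trait uncorrelated-group variance (0 if absent)
    incidence: tuple  # per-trait target incidence (None for linear)
    seed: int

    def h2(self, trait: int) -> float:
        vu = self.g_a[trait, trait]
        return vu / (vu + self.gmand[trait] + self.residual[trait])

    def rg(self, t1: int, t2: int) -> float:
        return self.g_a[t1, t2] / np.sqrt(
            self.g_a[t1, t1] * self.g_a[t2, t2]
        )


@dataclass
class StudyDataset:
    """A full synthetic study: pedigree, genotyped subset, phenotypes, truth."""

    pedigree: Pedigree
    meta: pd.DataFrame
    genotypes: GenotypeMatrix  # genotyped subset only
    genotyped_ids: list
    phenotypes: dict  # trait name -> record DataFrame
    models: dict  # trait name -> ModelSpec
    breeding_values: np.ndarray
    truth: SimulationTruth


#: trait menu of the study-like bundle: a high-h2 male biometry trait, a
#: low-h2 male semen-quality trait, and two binary female traits at their
#: published liability heritabilities and incidences
_STUDY_TRAITS = (
    ("SC_like", "linear", 0.75, "M", None),
    ("VOL_like", "linear", 0.05, "M", None),
    ("STAY_like", "threshold", 0.17, "F", 0.28),
    ("PP14_like", "threshold", 0.39, "F", 0.18),
)

_SCALES = {
    "tiny": dict(n_founders=80, n_generations=3, n_offspring=80,
                 n_genotyped=60, n_snps=200, n_cg=6),
    "desk": dict(n_founders=1000, n_generations=4, n_offspring=1000,
                 n_genotyped=1000, n_snps=2000, n_cg=40),
}


def make_study_like_dataset(
    scale: str = "tiny",
    seed: int = 0,
    rg_cross_sex: float = 0.5,
) -> StudyDataset:
    """Build the full synthetic study at ``tiny`` (smoke-test) or ``desk``
    scale (5,000 pedigree animals, 1,000 genotyped, 2,000 SNPs).

    ``rg_cross_sex`` is the generating genetic correlation between the
    high-h2 male trait and the first binary female trait; all other trait
    pairs are generated uncorrelated.
    """
    if scale not in _SCALES:
        raise ValueError(f"scale must be one of {sorted(_SCALES)}")
    cfg = _SCALES[scale]
    names = tuple(t[0] for t in _STUDY_TRAITS)
    kinds = tuple(t[1] for t in _STUDY_TRAITS)
    h2s = tuple(t[2] for t in _STUDY_TRAITS)
    sexes = tuple(t[3] for t in _STUDY_TRAITS)
    incidences = tuple(t[4] for t in _STUDY_TRAITS)
    t = len(names)

    # variance components on a unit-phenotypic scale for linear traits and
    # the unit-residual liability scale for threshold traits
    gmand_share = {0: 0.05}  # the SC-like trait carries a GMAND group
    vu = np.empty(t)
    ve = np.empty(t)
    vw = np.zeros(t)
    for k in range(t):
        if kinds[k] == "linear":
            vw[k] = gmand_share.get(k, 0.0)
            vu[k] = h2s[k]
            ve[k] = 1.0 - vu[k] - vw[k]
        else:
            ve[k] = 1.0
            vu[k] = h2s[k] * (ve[k] + vw[k]) / (1.0 - h2s[k])
    corr = np.eye(t)
    corr[0, 2] = corr[2, 0] = rg_cross_sex
    sd = np.sqrt(vu)
    g_a = corr * np.outer(sd, sd)

    ped, meta = simulate_pedigree(
        cfg["n_founders"], cfg["n_generations"],
        n_offspring=cfg["n_offspring"], seed=seed,
    )
    bv = simulate_breeding_values(ped, g_a, seed=seed + 1)
    last_gen = meta.loc[meta["generation"] == cfg["n_generations"],
                        "animal_id"]
    genotyped_ids = list(last_gen.iloc[: cfg["n_genotyped"]])
    geno_all = simulate_genotypes(ped, cfg["n_snps"], seed=seed + 2)
    keep = np.isin(np.array(geno_all.animal_ids), np.array(genotyped_ids))
    genotypes = geno_all.subset(animal_mask=keep)

    phenotypes = {}
    models = {}
    for k, name in enumerate(names):
        design = TraitDesign(
            n_cg=cfg["n_cg"],
            cg_sd=0.5,
            sex=sexes[k],
            n_gmand=8 if vw[k] > 0 else 0,
            gmand_sd=float(np.sqrt(vw[k])) if vw[k] > 0 else 0.0,
        )
        phenotypes[name] = simulate_phenotypes(
            ped, meta, bv[:, k], residual_variance=float(ve[k]),
            kind=kinds[k], incidence=incidences[k], design=design,
            trait_name=name, seed=seed + 10 + k,
        )
        models[name] = ModelSpec(
            trait_name=name,
            kind=kinds[k],
            fixed_class_effects=("CG",),
            covariates=(("idap", 1), ("idap", 2)) if kinds[k] == "linear"
            else (),
            uncorrelated_random="gmand" if vw[k] > 0 else None,
        )
    truth = SimulationTruth(
        trait_names=names, kinds=kinds, g_a=g_a, residual=ve, gmand=vw,
        incidence=incidences, seed=seed,
    )
    return StudyDataset(
        pedigree=ped, meta=meta, genotypes=genotypes,
        genotyped_ids=genotyped_ids, phenotypes=phenotypes, models=models,
        breeding_values=bv, truth=truth,
    )
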