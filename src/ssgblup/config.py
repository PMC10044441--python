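"""Run configuration and end-to-end pipeline orchestration.

A :class:`RunConfig` captures every knob of an analysis — QC thresholds,
G-matrix blending (alpha/beta), tuning mode, model template, MCMC schedule
and the master seed — with defaults matching the production settings
(alpha 0.90 / beta 0.10; 800,000 iterations, 200,000 burn-in, thinning 100).
Configs round-trip through YAML, and :func:`run_pipeline` executes the stages
simulate -> relationships -> qc/genomics -> prep -> fit -> summarize, writing
per-stage artifacts and a manifest (input hashes, seed, versions, timings)
that suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .genotypes import QcThresholds, apply_qc, allele_frequencies, \
    impute_missing, read_genotypes, write_plink
from .mcmc import ChainConfig, build_system, gibbs_linear, gibbs_threshold
from .pedigree import read_pedigree, build_a_inverse, build_a22, \
    save_matrix_bundle
from .phenotypes import ModelSpec, STUDY_MODELS, build_contemporary_groups, \
    filter_records
from .relmat import build_grm_bundle, assemble_h_inverse, h_inverse_from_a, \
    invert_pd
from .simulate import make_study_like_dataset
from .summaries import summarize_run

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything needed to reproduce one analysis run."""

    seed: int = 1
    outdir: str = "ssgblup_run"
    # inputs; all None -> a synthetic study-like dataset is generated
    pedigree_path: str | None = None
    genotype_path: str | None = None
    phenotype_path: str | None = None
    simulate_scale: str = "tiny"
    trait: str = "SC_like"
    # genomic-matrix construction
    alpha: float = 0.90
    beta: float = 0.10
    tune: str = "both"
    use_genomics: bool = True
    qc: QcThresholds = field(default_factory=QcThresholds)
    # record filters
    sd_limit: float = 3.5
    min_cg_size: int = 5
    min_sires: int = 2
    # sampling
    chain: ChainConfig = field(default_factory=lambda: ChainConfig(seed=1))

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["qc"]["autosomes"] = sorted(d["qc"]["autosomes"],
                                      key=lambda c: (len(c), c))
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        d = yaml.safe_load(text)
        if "qc" in d:
            if "autosomes" in d["qc"]:
                d["qc"]["autosomes"] = frozenset(
                    str(c) for c in d["qc"]["autosomes"]
                )
            d["qc"] = QcThresholds(**d["qc"])
        if "chain" in d:
            d["chain"] = ChainConfig(**d["chain"])
        return cls(**d)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of configuration problems (empty = ok)."""
    issues = []
    if not np.isclose(config.alpha + config.beta, 1.0):
        issues.append(
            f"alpha + beta must equal 1 (got {config.alpha} + {config.beta})"
        )
    if not 0.0 < config.alpha <= 1.0:
        issues.append(f"alpha must be in (0, 1], got {config.alpha}")
    if config.chain.burn_in >= config.chain.total_iterations:
        issues.append("chain burn_in must be below total_iterations")
    if config.chain.thin < 1:
        issues.append("chain thin must be >= 1")
    for name, val in (("snp_call_rate", config.qc.snp_call_rate),
                      ("animal_call_rate", config.qc.animal_call_rate),
                      ("het_deviation", config.qc.het_deviation),
                      ("mendelian_rate", config.qc.mendelian_rate)):
        if not 0.0 <= val <= 1.0:
            issues.append(f"qc.{name} must be in [0,1], got {val}")
    if not 0.0 <= config.qc.maf <= 0.5:
        issues.append(f"qc.maf must be in [0, 0.5], got {config.qc.maf}")
    if config.tune not in ("both", "diag", "none"):
        issues.append(f"tune must be both/diag/none, got {config.tune!r}")
    if config.simulate_scale not in ("tiny", "desk"):
        issues.append(f"simulate_scale must be tiny/desk, got "
                      f"{config.simulate_scale!r}")
    if config.pedigree_path is not None \
            and not Path(config.pedigree_path).exists():
        issues.append(f"pedigree_path does not exist: {config.pedigree_path}")
    return issues


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest (also written to
    ``<outdir>/manifest.json``)."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid configuration: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "config": yaml.safe_load(config.to_yaml()),
        "stages": [],
        "inputs": {},
    }

    def stage(name):
        t0 = time.perf_counter()

        def done(**info):
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3),
                 **info}
            )
            logger.info("stage %s done (%.2fs)", name,
                        time.perf_counter() - t0)

        return done

    # ----- stage 1: obtain data (simulate or load) ------------------------
    done = stage("simulate" if config.pedigree_path is None else "load")
    if config.pedigree_path is None:
        ds = make_study_like_dataset(config.simulate_scale, seed=config.seed)
        ped = ds.pedigree
        ped_path = outdir / "pedigree.csv"
        with open(ped_path, "w") as fh:
            fh.write("animal,sire,dam\n")
            for i, a in enumerate(ped.ids):
                s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else "0"
                d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else "0"
                fh.write(f"{a},{s},{d}\n")
        write_plink(ds.genotypes, outdir / "genotypes")
        records = ds.phenotypes[config.trait]
        records.to_csv(outdir / f"phenotypes_{config.trait}.csv", index=False)
        model = ds.models[config.trait]
        genotypes = ds.genotypes
        truth = {"h2": float(ds.truth.h2(
            ds.truth.trait_names.index(config.trait)))}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
        manifest["inputs"]["pedigree"] = _sha256(ped_path)
        done(n_animals=ped.n, n_records=len(records))
    else:
        import pandas as pd

        ped = read_pedigree(config.pedigree_path)
        manifest["inputs"]["pedigree"] = _sha256(Path(config.pedigree_path))
        genotypes = (read_genotypes(config.genotype_path)
                     if config.genotype_path else None)
        if config.phenotype_path is None:
            raise ValueError("phenotype_path is required with real inputs")
        records = pd.read_csv(config.phenotype_path)
        manifest["inputs"]["phenotypes"] = _sha256(Path(config.phenotype_path))
        model = STUDY_MODELS.get(config.trait) or ModelSpec(
            config.trait, "linear")
        done(n_animals=ped.n, n_records=len(records))

    # ----- stage 2: pedigree relationships --------------------------------
    done = stage("relationships")
    a_inv = build_a_inverse(ped)
    done(nnz=int(a_inv.nnz))

    # ----- stage 3: genomic matrices ---------------------------------------
    done = stage("genomics")
    if genotypes is not None and config.use_genomics:
        clean, qc_report = apply_qc(genotypes, ped, config.qc)
        qc_report.to_json(outdir / "qc_report.json")
        p = allele_frequencies(clean)
        imputed = impute_missing(clean, p)
        a22 = build_a22(ped, clean.animal_ids)
        bundle = build_grm_bundle(
            imputed, p, a22, clean.animal_ids,
            alpha=config.alpha, beta=config.beta, tune=config.tune,
        )
        a22_inv = invert_pd(a22, "A22")
        h_inv = assemble_h_inverse(
            a_inv, bundle.g_inverse, a22_inv,
            ped.indices_of(clean.animal_ids), ids=ped.ids,
        )
        save_matrix_bundle(
            outdir / "relationship_matrices.npz",
            h_inverse=h_inv.matrix, g_blended=bundle.g_blended, a22=a22,
            genotyped_ids=list(clean.animal_ids),
        )
        done(n_genotyped=clean.n_animals, n_snps=clean.n_snps,
             tuning=list(bundle.tuning))
    else:
        h_inv = h_inverse_from_a(a_inv, ids=ped.ids)
        done(n_genotyped=0)

    # ----- stage 4: phenotype prep -----------------------------------------
    done = stage("prep")
    if "cg" not in records.columns:
        records = build_contemporary_groups(records, model)
    records, filter_report = filter_records(
        records, kind=model.kind, sd_limit=config.sd_limit,
        min_cg_size=config.min_cg_size, min_sires=config.min_sires,
    )
    filter_report.to_json(outdir / "filter_report.json")
    done(n_records=len(records))

    # ----- stage 5: fit -----------------------------------------------------
    done = stage("fit")
    chain = ChainConfig(
        total_iterations=config.chain.total_iterations,
        burn_in=config.chain.burn_in,
        thin=config.chain.thin,
        seed=config.seed if config.chain.seed is None else config.chain.seed,
    )
    system = build_system(records, model, h_inv)
    fit = gibbs_threshold if model.kind == "threshold" else gibbs_linear
    draws = fit(system, chain)
    draws.to_frame().to_csv(outdir / f"draws_{config.trait}.csv", index=False)
    done(retained=draws.n_draws)

    # ----- stage 6: summarize ----------------------------------------------
    done = stage("summarize")
    summary = summarize_run(draws)
    summary.to_csv(outdir / f"summary_{config.trait}.csv", index=False)
    done(parameters=len(summary))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
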