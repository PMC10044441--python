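"""SNP genotype input/output and quality control.

Genotypes are stored as alt-allele dosages in {0, 1, 2} with -1 for a missing
call, animals in rows and SNPs in columns, alongside a SNP map (id, chromosome,
base-pair position).  Supported on-disk formats are a plain matrix CSV (header
row of SNP ids, first column of animal ids, companion map CSV) and PLINK
.bed/.bim/.fam triples (2-bit SNP-major encoding).

The default QC thresholds reproduce a standard beef-cattle genotyping panel
cleanup: call rate >= 90% for both SNPs and animals, MAF >= 0.05, observed vs
expected heterozygosity deviation <= 0.15, parent-progeny Mendelian-conflict
rate <= 1%, autosomes only, unique known positions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

MISSING = -1

#: Bos taurus autosomes
DEFAULT_AUTOSOMES = frozenset(str(c) for c in range(1, 30))


@dataclass
class GenotypeMatrix:
    """Animals x SNPs dosage matrix with its SNP map."""

    values: np.ndarray  # int8, codes {0,1,2,-1}
    animal_ids: list[str]
    snp_map: pd.DataFrame  # columns: snp_id, chrom (str), pos (int)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, [0, 1, 2, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {int(self.values[i, j])} at animal "
                f"{self.animal_ids[i]!r}, snp {self.snp_map.iloc[j]['snp_id']!r}"
            )
        if len(self.animal_ids) != self.values.shape[0]:
            raise ValueError("animal_ids length does not match matrix rows")
        if len(self.snp_map) != self.values.shape[1]:
            raise ValueError("snp_map length does not match matrix columns")
        self.snp_map = self.snp_map.reset_index(drop=True)

    @property
    def n_animals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset(self, animal_mask=None, snp_mask=None) -> "GenotypeMatrix":
        vals = self.values
        ids = self.animal_ids
        smap = self.snp_map
        if animal_mask is not None:
            vals = vals[animal_mask]
            ids = [a for a, keep in zip(ids, animal_mask) if keep]
        if snp_mask is not None:
            vals = vals[:, snp_mask]
            smap = smap.loc[np.asarray(snp_mask)]
        return GenotypeMatrix(vals.copy(), list(ids), smap.reset_index(drop=True))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_genotypes(path, format: str = "auto", map_path=None) -> GenotypeMatrix:
    """Read genotypes from ``matrix-csv`` or ``plink-bed``.

    ``auto`` picks by suffix (.bed -> plink).  For matrix CSV, ``map_path``
    defaults to ``<stem>.map.csv`` next to the matrix; if absent, SNPs get
    placeholder positions on chromosome "1".
    """
    path = Path(path)
    if format == "auto":
        format = "plink-bed" if path.suffix == ".bed" else "matrix-csv"
    if format == "plink-bed":
        return read_plink(path.with_suffix(""))
    if format != "matrix-csv":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    vals = np.where(np.isnan(vals), MISSING, vals)
    if not np.isin(vals, [0, 1, 2, MISSING]).all():
        bad = vals[~np.isin(vals, [0, 1, 2, MISSING])][0]
        raise ValueError(f"invalid genotype code {bad!r} in {path}")
    if map_path is None:
        candidate = path.with_suffix("").with_suffix(".map.csv")
        map_path = candidate if candidate.exists() else None
    if map_path is not None:
        smap = pd.read_csv(map_path, dtype={"chrom": str})
    else:
        smap = pd.DataFrame(
            {"snp_id": df.columns, "chrom": "1",
             "pos": np.arange(1, df.shape[1] + 1)}
        )
    smap["chrom"] = smap["chrom"].astype(str)
    return GenotypeMatrix(vals.astype(np.int8), [str(a) for a in df.index], smap)


def write_genotypes_csv(g: GenotypeMatrix, path, map_path=None) -> None:
    path = Path(path)
    df = pd.DataFrame(
        np.where(g.values == MISSING, np.nan, g.values),
        index=g.animal_ids,
        columns=g.snp_map["snp_id"],
    )
    df.to_csv(path)
    if map_path is None:
        map_path = path.with_suffix("").with_suffix(".map.csv")
    g.snp_map.to_csv(map_path, index=False)


# PLINK .bed 2-bit codes (SNP-major): 00=hom A1, 10=het, 11=hom A2, 01=missing.
# Dosages count the A1 allele: 00 -> 2, 10 -> 1, 11 -> 0.
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, MISSING: 1, 1: 2, 0: 3}


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major .bed)."""
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      dtype={0: str})
    animal_ids = [str(a) for a in fam[1]]
    smap = pd.DataFrame({"snp_id": bim[1].astype(str), "chrom": bim[0].astype(str),
                         "pos": bim[3].astype(int)})
    n, m = len(animal_ids), len(smap)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if body.size != bytes_per_snp * m:
        raise ValueError(
            f"{prefix}.bed size mismatch: expected {bytes_per_snp * m} body "
            f"bytes for {n} animals x {m} SNPs, found {body.size}"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    vals = _CODE_TO_DOSAGE[codes].T.copy()  # animals x snps
    return GenotypeMatrix(vals, animal_ids, smap)


def write_plink(g: GenotypeMatrix, prefix) -> None:
    """Write a PLINK .bed/.bim/.fam triple readable by :func:`read_plink`."""
    prefix = Path(prefix)
    n, m = g.n_animals, g.n_snps
    fam = pd.DataFrame(
        {"fid": g.animal_ids, "iid": g.animal_ids, "pat": 0, "mat": 0,
         "sex": 0, "phen": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    bim = pd.DataFrame(
        {"chrom": g.snp_map["chrom"], "snp_id": g.snp_map["snp_id"], "cm": 0,
         "pos": g.snp_map["pos"], "a1": "A", "a2": "B"}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    codes = np.empty((m, n), dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[g.values.T == dosage] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate(
            [codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    packed = (
        codes.reshape(m, -1, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint16).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# per-SNP / per-animal statistics
# ---------------------------------------------------------------------------


def allele_frequencies(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Observed alt-allele frequency per SNP: sum(dosage) / (2 * called)."""
    vals = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g)
    called = vals != MISSING
    n_called = called.sum(axis=0)
    if (n_called == 0).any():
        j = int(np.flatnonzero(n_called == 0)[0])
        raise ValueError(f"SNP column {j} has no non-missing calls")
    return np.where(called, vals, 0).sum(axis=0) / (2.0 * n_called)


def hwe_het_deviation(g: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """|observed het fraction - 2p(1-p)| per SNP, both from the same column."""
    vals = g.values if isinstance(g, GenotypeMatrix) else np.asarray(g)
    p = allele_frequencies(vals)
    called = vals != MISSING
    obs_het = (vals == 1).sum(axis=0) / called.sum(axis=0)
    return np.abs(obs_het - 2.0 * p * (1.0 - p))


def mendelian_conflict_rate(g: GenotypeMatrix, ped: Pedigree) -> np.ndarray:
    """Per-animal opposing-homozygote conflict rate against genotyped parents.

    For each genotyped animal, calls where the animal and a genotyped parent
    are opposing homozygotes (0 vs 2) count as conflicts; the rate pools over
    both parents and divides by the comparable (both non-missing) calls.
    Animals with no genotyped parent get rate 0.
    """
    gen_index = {a: i for i, a in enumerate(g.animal_ids)}
    rates = np.zeros(g.n_animals)
    no_parent = 0
    for a, row in zip(g.animal_ids, g.values):
        pi = ped.index.get(a)
        conflicts = 0
        comparable = 0
        if pi is not None:
            for p in (ped.sire[pi], ped.dam[pi]):
                if p < 0:
                    continue
                gp = gen_index.get(ped.ids[p])
                if gp is None:
                    continue
                prow = g.values[gp]
                both = (row != MISSING) & (prow != MISSING)
                comparable += int(both.sum())
                opposing = both & (
                    ((row == 0) & (prow == 2)) | ((row == 2) & (prow == 0))
                )
                conflicts += int(opposing.sum())
        if comparable:
            rates[gen_index[a]] = conflicts / comparable
        else:
            no_parent += 1
    if no_parent:
        logger.debug("%d genotyped animals had no genotyped parent "
                     "(conflict rate 0)", no_parent)
    return rates


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------


@dataclass
class QcThresholds:
    """Filter thresholds; the defaults are the standard panel-cleanup values."""

    snp_call_rate: float = 0.90
    animal_call_rate: float = 0.90
    maf: float = 0.05
    het_deviation: float = 0.15
    mendelian_rate: float = 0.01
    autosomes: frozenset = DEFAULT_AUTOSOMES


@dataclass
class QcReport:
    """Removal tallies per filter plus the per-item statistics behind them."""

    thresholds: QcThresholds
    animals_in: int
    snps_in: int
    snps_removed: dict = field(default_factory=dict)
    animals_removed: dict = field(default_factory=dict)
    snp_stats: pd.DataFrame | None = None
    animal_stats: pd.DataFrame | None = None

    @property
    def animals_out(self) -> int:
        return self.animals_in - sum(self.animals_removed.values())

    @property
    def snps_out(self) -> int:
        return self.snps_in - sum(self.snps_removed.values())

    def to_dict(self) -> dict:
        th = asdict(self.thresholds)
        th["autosomes"] = sorted(th["autosomes"], key=lambda c: (len(c), c))
        return {
            "thresholds": th,
            "animals_in": self.animals_in,
            "animals_out": self.animals_out,
            "animals_removed": self.animals_removed,
            "snps_in": self.snps_in,
            "snps_out": self.snps_out,
            "snps_removed": self.snps_removed,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def __str__(self) -> str:
        lines = [
            f"QC: {self.animals_in} -> {self.animals_out} animals, "
            f"{self.snps_in} -> {self.snps_out} SNPs",
        ]
        for name, cnt in self.snps_removed.items():
            lines.append(f"  SNPs removed by {name}: {cnt}")
        for name, cnt in self.animals_removed.items():
            lines.append(f"  animals removed by {name}: {cnt}")
        return "\n".join(lines)


#: filter order: map/position filters first, call rates, Mendelian conflicts,
#: then frequency-based filters on the cleaned sample
QC_FILTER_ORDER = (
    "position",
    "snp_call_rate",
    "animal_call_rate",
    "mendelian",
    "maf",
    "het_deviation",
)


def apply_qc(
    g: GenotypeMatrix,
    ped: Pedigree | None = None,
    thresholds: QcThresholds | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply the fixed-order QC filter stack; every removal is attributed to
    its first failing filter.  Missing calls survive QC (imputation is a
    separate, later step)."""
    th = thresholds or QcThresholds()
    report = QcReport(thresholds=th, animals_in=g.n_animals, snps_in=g.n_snps)
    logger.info("QC filter order: %s", ", ".join(QC_FILTER_ORDER))

    # (1) unknown/duplicate position, non-autosome
    smap = g.snp_map
    known = smap["pos"].notna() & (smap["pos"] > 0)
    autosomal = smap["chrom"].astype(str).isin(th.autosomes)
    dup = smap.duplicated(subset=["chrom", "pos"], keep=False)
    keep_snp = (known & autosomal & ~dup).to_numpy()
    report.snps_removed["position"] = int((~keep_snp).sum())
    g = g.subset(snp_mask=keep_snp)

    # (2) SNP call rate
    called = g.values != MISSING
    snp_cr = called.mean(axis=0) if g.n_animals else np.ones(g.n_snps)
    keep_snp = snp_cr >= th.snp_call_rate
    report.snps_removed["snp_call_rate"] = int((~keep_snp).sum())
    g = g.subset(snp_mask=keep_snp)

    # (3) animal call rate
    called = g.values != MISSING
    animal_cr = called.mean(axis=1) if g.n_snps else np.ones(g.n_animals)
    keep_animal = animal_cr >= th.animal_call_rate
    report.animals_removed["animal_call_rate"] = int((~keep_animal).sum())
    report.animal_stats = pd.DataFrame(
        {"animal_id": g.animal_ids, "call_rate": animal_cr}
    )
    g = g.subset(animal_mask=keep_animal)

    # (4) animal Mendelian-conflict rate
    if ped is not None:
        mrate = mendelian_conflict_rate(g, ped)
        keep_animal = mrate <= th.mendelian_rate
        report.animals_removed["mendelian"] = int((~keep_animal).sum())
        g = g.subset(animal_mask=keep_animal)
    else:
        report.animals_removed["mendelian"] = 0

    if g.n_animals == 0 or g.n_snps == 0:
        raise ValueError("QC removed all animals or all SNPs")

    # (5) MAF on the cleaned sample
    p = allele_frequencies(g)
    maf = np.minimum(p, 1.0 - p)
    keep_snp = maf >= th.maf
    report.snps_removed["maf"] = int((~keep_snp).sum())
    g = g.subset(snp_mask=keep_snp)

    # (6) heterozygosity deviation
    dev = hwe_het_deviation(g)
    keep_snp = dev <= th.het_deviation
    report.snps_removed["het_deviation"] = int((~keep_snp).sum())
    g = g.subset(snp_mask=keep_snp)

    if g.n_snps == 0:
        raise ValueError("QC removed all SNPs")

    p = allele_frequencies(g)
    report.snp_stats = pd.DataFrame(
        {
            "snp_id": g.snp_map["snp_id"],
            "freq": p,
            "maf": np.minimum(p, 1 - p),
            "call_rate": (g.values != MISSING).mean(axis=0),
            "het_deviation": hwe_het_deviation(g),
        }
    )
    logger.info("%s", report)
    return g, report


def impute_missing(
    g: GenotypeMatrix, p: np.ndarray | None = None
) -> np.ndarray:
    """Replace missing calls with the mean dosage 2p; returns a float matrix."""
    if p is None:
        p = allele_frequencies(g)
    vals = g.values.astype(np.float64)
    miss = g.values == MISSING
    vals[miss] = np.broadcast_to(2.0 * p, vals.shape)[miss]
    return vals
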