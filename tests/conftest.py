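"""Shared fixtures: small pedigrees, genotype fixtures and a tiny synthetic
study bundle, all generated programmatically."""

import numpy as np
import pandas as pd
import pytest

from ssgblup.pedigree import Pedigree, from_records
from ssgblup.genotypes import GenotypeMatrix


@pytest.fixture
def trio():
    """Sire, dam (unrelated founders) and one offspring."""
    return from_records([("S", "0", "0"), ("D", "0", "0"), ("O", "S", "D")])


@pytest.fixture
def fullsib_mating():
    """Offspring of a full-sib mating: F = 0.25."""
    return from_records(
        [
            ("GS", "0", "0"),
            ("GD", "0", "0"),
            ("S", "GS", "GD"),
            ("D", "GS", "GD"),
            ("X", "S", "D"),
        ]
    )


def random_pedigree(n: int, seed: int, p_known: float = 0.8) -> Pedigree:
    """Random acyclic pedigree: each animal's parents drawn from earlier
    animals with probability ``p_known`` (founders otherwise)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        s = d = "0"
        if i >= 2:
            if rng.random() < p_known:
                s = f"a{rng.integers(0, i)}"
            if rng.random() < p_known:
                d = f"a{rng.integers(0, i)}"
            if s == d:
                d = "0"
        rows.append((f"a{i}", s, d))
    return from_records(rows)


@pytest.fixture
def random_pedigree_factory():
    return random_pedigree


@pytest.fixture
def toy_genotypes():
    """5 animals x 6 SNPs built so that QC (with the SNP call-rate threshold
    at 0.75 — with only 5 animals a single missing cell puts a SNP at 0.8)
    removes exactly one animal (low call rate) and two SNPs (one
    non-autosomal, one monomorphic)."""
    # columns: s0/s2/s5 clean, s1 on chromosome X (position filter),
    # s3 polymorphic, s4 monomorphic -> fails MAF
    values = np.array(
        [
            [0, 1, 2, 1, 0, 1],
            [1, 0, 1, 0, 0, 1],
            [2, 1, 0, 1, 0, 2],
            [1, 2, 1, 2, 0, 0],
            [-1, -1, -1, -1, 0, 1],  # animal a4: call rate 2/6 < 0.9
        ],
        dtype=np.int8,
    )
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"s{j}" for j in range(6)],
            "chrom": ["1", "X", "2", "3", "4", "5"],
            "pos": [100, 200, 300, 400, 500, 600],
        }
    )
    return GenotypeMatrix(values, [f"a{i}" for i in range(5)], snp_map)


@pytest.fixture
def toy_qc_thresholds():
    from ssgblup.genotypes import QcThresholds

    return QcThresholds(snp_call_rate=0.75)
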