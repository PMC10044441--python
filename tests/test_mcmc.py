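"""Gibbs sampler machinery: bookkeeping, system construction, and
sampler-correctness checks (determinism, prior recovery, mixed-model-equation
oracle, degenerate data)."""

import numpy as np
import pandas as pd
import pytest

import ssgblup as s
from ssgblup.mcmc import (
    ChainConfig,
    VariancePriors,
    build_system,
    chain_bookkeeping,
    dense_mme,
)
from ssgblup.pedigree import from_records
from ssgblup.phenotypes import ModelSpec
from ssgblup.relmat import h_inverse_from_a


class TestChainBookkeeping:
    def test_production_schedule_retains_6000(self):
        cfg = ChainConfig(800_000, 200_000, 100, seed=1)
        retained, idx = chain_bookkeeping(cfg)
        assert retained == 6000
        assert idx[0] == 200_100 and idx[-1] == 800_000

    def test_no_burnin_no_thinning(self):
        retained, idx = chain_bookkeeping(ChainConfig(100, 0, 1, seed=1))
        assert retained == 100
        assert idx.tolist() == list(range(1, 101))

    def test_floor_division(self):
        retained, _ = chain_bookkeeping(ChainConfig(1000, 400, 7, seed=1))
        assert retained == 85

    def test_burnin_must_precede_total(self):
        with pytest.raises(ValueError, match="burn_in"):
            ChainConfig(1000, 1000, 10, seed=1)


def small_dataset(seed=0, n_cg=2, n=10):
    rng = np.random.default_rng(seed)
    rows = [("s1", "0", "0"), ("s2", "0", "0")]
    animals = []
    for i in range(n):
        a = f"p{i}"
        rows.append((a, "s1" if i % 2 else "s2", "0"))
        animals.append(a)
    ped = from_records(rows)
    h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
    df = pd.DataFrame(
        {
            "animal_id": animals,
            "value": rng.normal(size=n),
            "cg": [f"c{i % n_cg}" for i in range(n)],
            "age": rng.normal(450, 30, size=n),
            "gmand": [f"g{i % 2}" for i in range(n)],
        }
    )
    return ped, h_inv, df


class TestBuildSystem:
    def test_design_dimensions(self):
        _, h_inv, df = small_dataset()
        model = ModelSpec("t", "linear", ("CG",), (("age", 1), ("age", 2)))
        sys_ = build_system(df, model, h_inv)
        # 2 CG columns (first factor keeps all levels) + age + age^2
        assert sys_.x_csc.shape == (10, 4)
        assert sys_.nw == 0

    def test_gmand_levels(self):
        _, h_inv, df = small_dataset()
        model = ModelSpec("t", "linear", ("CG",), (), "gmand")
        sys_ = build_system(df, model, h_inv)
        assert sys_.nw == 2
        assert sys_.wlev.shape == (10,)

    def test_animal_missing_from_pedigree(self):
        _, h_inv, df = small_dataset()
        df.loc[0, "animal_id"] = "ghost"
        with pytest.raises(KeyError, match="absent from the pedigree"):
            build_system(df, ModelSpec("t", "linear"), h_inv)

    def test_constant_covariate_rejected(self):
        _, h_inv, df = small_dataset()
        df["age"] = 450.0
        model = ModelSpec("t", "linear", ("CG",), (("age", 1),))
        with pytest.raises(ValueError, match="constant"):
            build_system(df, model, h_inv)

    def test_threshold_single_category_rejected(self):
        _, h_inv, df = small_dataset()
        df["value"] = 2
        with pytest.raises(ValueError, match="single observed category"):
            build_system(df, ModelSpec("t", "threshold"), h_inv)

    def test_covariate_centered_before_squaring(self):
        _, h_inv, df = small_dataset()
        model = ModelSpec("t", "linear", ("CG",), (("age", 1), ("age", 2)))
        sys_ = build_system(df, model, h_inv)
        x = sys_.x_csc.toarray()
        centered = df["age"] - df["age"].mean()
        np.testing.assert_allclose(x[:, 2], centered)
        np.testing.assert_allclose(x[:, 3], centered**2)


def linear_fit_dataset(seed, n_off=700, h2=0.4):
    ped, meta = s.simulate_pedigree(400, 3, n_offspring=n_off,
                                    dams_per_sire=15, seed=seed)
    bv = s.simulate_breeding_values(ped, h2, seed=seed + 1)
    recs = s.simulate_phenotypes(
        ped, meta, bv, residual_variance=1 - h2, kind="linear",
        design=s.TraitDesign(n_cg=15, cg_sd=0.4, sex=None),
        trait_name="T", seed=seed + 2,
    )
    h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
    model = ModelSpec("T", "linear", ("CG",), (("idap", 1), ("idap", 2)))
    return build_system(recs, model, h_inv)


class TestGibbsLinear:
    def test_same_seed_identical_draws(self):
        sys_ = linear_fit_dataset(0, n_off=80)
        cfg = ChainConfig(500, 100, 2, seed=42)
        d1 = s.gibbs_linear(sys_, cfg)
        d2 = s.gibbs_linear(sys_, cfg)
        np.testing.assert_array_equal(d1.additive, d2.additive)
        np.testing.assert_array_equal(d1.residual, d2.residual)

    def test_kind_mismatch_rejected(self):
        sys_ = linear_fit_dataset(0, n_off=80)
        with pytest.raises(ValueError, match="not threshold"):
            s.gibbs_threshold(sys_, ChainConfig(200, 50, 1, seed=1))

    def test_zero_variance_data_collapses_additive_variance(self):
        """All observations equal within CG: the additive variance collapses
        to its prior floor (there is no variation left to explain)."""
        _, h_inv, df = small_dataset(n=30, n_cg=2)
        df["value"] = np.where(df["cg"] == "c0", 3.0, 5.0)
        sys_ = build_system(df, ModelSpec("t", "linear", ("CG",)), h_inv)
        d = s.gibbs_linear(sys_, ChainConfig(4000, 1000, 2, seed=3),
                           VariancePriors(flat=True))
        vy = float(np.var(df["value"]))
        assert d.sigma2_u().mean() < 0.05 * vy

    def test_pure_noise_h2_near_zero(self):
        """Half-sib structured records with no genetic signal: posterior h2
        concentrates near zero."""
        rng = np.random.default_rng(4)
        rows = [(f"s{i}", "0", "0") for i in range(100)]
        animals = []
        for i in range(100):
            for j in range(20):
                a = f"p{i}_{j}"
                rows.append((a, f"s{i}", "0"))
                animals.append(a)
        ped = from_records(rows)
        h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
        df = pd.DataFrame({"animal_id": animals,
                           "value": rng.normal(size=len(animals)),
                           "cg": "c"})
        sys_ = build_system(df, ModelSpec("t", "linear", ("CG",)), h_inv)
        d = s.gibbs_linear(sys_, ChainConfig(6000, 2000, 4, seed=5),
                           VariancePriors(flat=True))
        assert s.heritability_draws(d).mean() < 0.05

    def test_prior_only_run_recovers_prior_mean(self):
        """With no informative data the additive-variance draws must
        reproduce the scaled-inverse-chi-square prior (standard sampler
        correctness check)."""
        rows = [(f"f{i}", "0", "0") for i in range(25)]
        ped = from_records(rows)
        h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
        # a single constant pseudo-record keeps the system well-formed while
        # carrying no information about the additive variance of founders
        # other than through its single animal
        df = pd.DataFrame({"animal_id": ["f0"], "value": [0.0],
                           "cg": ["c"]})
        sys_ = build_system(df, ModelSpec("t", "linear", ("CG",)), h_inv)
        nu, scale = 6.0, 0.8
        priors = VariancePriors(nu_u=nu, s_u=scale, s_e=1.0, s_w=1.0)
        d = s.gibbs_linear(sys_, ChainConfig(60_000, 10_000, 10, seed=9),
                           priors)
        vu = d.sigma2_u()
        prior_mean = nu * scale / (nu - 2.0)
        se = vu.std(ddof=1) / np.sqrt(len(vu) / 20)  # crude ESS correction
        assert abs(vu.mean() - prior_mean) < 3 * se

    def test_location_sweeps_converge_to_mme_solution(self):
        """With variances fixed, repeated conditional-mean sweeps are
        Gauss-Seidel on Henderson's equations and must converge to the dense
        MME solution."""
        sys_ = linear_fit_dataset(3, n_off=15)
        vu, ve = 0.4, 0.6
        c, rhs, _ = dense_mme(sys_, vu, ve)
        direct = np.linalg.solve(c, rhs)
        theta = np.zeros(c.shape[0])
        for _ in range(3000):
            for j in range(len(theta)):
                r = rhs[j] - c[j] @ theta + c[j, j] * theta[j]
                theta[j] = r / c[j, j]
        np.testing.assert_allclose(theta, direct, atol=1e-8)


class TestGibbsThreshold:
    def test_null_heritability_concentrates_near_zero(self):
        """Binary data with no genetic signal (incidence 0.5): under flat
        variance priors the liability h2 posterior sits near zero."""
        ped, meta = s.simulate_pedigree(400, 2, n_offspring=1600,
                                        dams_per_sire=10, seed=5)
        bv = s.simulate_breeding_values(ped, 1e-12, seed=6)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=1.0, kind="threshold",
            incidence=0.5, design=s.TraitDesign(n_cg=4, cg_sd=0.2, sex=None),
            trait_name="B", seed=7,
        )
        h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
        sys_ = build_system(recs, ModelSpec("B", "threshold"), h_inv)
        d = s.gibbs_threshold(sys_, ChainConfig(8000, 3000, 5, seed=8),
                              VariancePriors(flat=True))
        assert s.heritability_draws(d).mean() < 0.05

    def test_residual_variance_fixed_at_one(self):
        ped, meta = s.simulate_pedigree(100, 2, n_offspring=150, seed=9)
        bv = s.simulate_breeding_values(ped, 0.3, seed=10)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=1.0, kind="threshold",
            incidence=0.4, design=s.TraitDesign(n_cg=3, cg_sd=0.2, sex=None),
            trait_name="B", seed=11,
        )
        h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
        sys_ = build_system(recs, ModelSpec("B", "threshold"), h_inv)
        d = s.gibbs_threshold(sys_, ChainConfig(400, 100, 2, seed=12))
        np.testing.assert_array_equal(d.residual, 1.0)


class TestGibbsBitrait:
    def test_shared_relationship_matrix_required(self):
        s1 = linear_fit_dataset(0, n_off=60)
        s2 = linear_fit_dataset(1, n_off=80)  # different pedigree
        with pytest.raises(ValueError, match="share one relationship"):
            s.gibbs_bitrait(s1, s2, ChainConfig(200, 50, 1, seed=1))

    def test_stored_ga_symmetric_positive_definite(self):
        ped, meta = s.simulate_pedigree(150, 2, n_offspring=300,
                                        dams_per_sire=10, seed=20)
        ga = np.array([[0.4, 0.5 * 0.4], [0.5 * 0.4, 0.4]])
        bv = s.simulate_breeding_values(ped, ga, seed=21)
        h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
        m = ModelSpec("x", "linear", ("CG",))
        recs = [
            s.simulate_phenotypes(
                ped, meta, bv[:, k], residual_variance=0.6, kind="linear",
                design=s.TraitDesign(n_cg=3, cg_sd=0.3, sex=sx),
                trait_name="x", seed=22 + k,
            )
            for k, sx in enumerate(["M", "F"])
        ]
        d = s.gibbs_bitrait(
            build_system(recs[0], m, h_inv), build_system(recs[1], m, h_inv),
            ChainConfig(1000, 200, 2, seed=23),
        )
        dets = (d.additive[:, 0, 0] * d.additive[:, 1, 1]
                - d.additive[:, 0, 1] ** 2)
        assert (dets > 0).all()
        assert (d.additive[:, 0, 0] > 0).all()
        np.testing.assert_array_equal(d.additive[:, 0, 1],
                                      d.additive[:, 1, 0])
        rg = s.genetic_correlation_draws(d)
        assert (np.abs(rg) <= 1).all()
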