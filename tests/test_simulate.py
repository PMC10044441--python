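"""Synthetic-data generator: reproducibility and statistical fidelity of the
pedigree, gene-dropped genotypes, breeding values and phenotypes."""

import numpy as np
import pytest

import ssgblup as s
from ssgblup.mcmc import ChainConfig, build_system
from ssgblup.pedigree import tabular_a
from ssgblup.phenotypes import ModelSpec
from ssgblup.relmat import h_inverse_from_a


class TestSimulatePedigree:
    def test_founders_only(self):
        ped, meta = s.simulate_pedigree(10, 0, seed=1)
        assert ped.n == 10
        assert (ped.sire == -1).all() and (ped.dam == -1).all()

    def test_deterministic_under_seed(self):
        p1, m1 = s.simulate_pedigree(20, 3, seed=1)
        p2, m2 = s.simulate_pedigree(20, 3, seed=1)
        assert p1.ids == p2.ids
        np.testing.assert_array_equal(p1.sire, p2.sire)
        assert m1.equals(m2)

    def test_half_sib_family_size_tracks_ratio(self):
        ped, meta = s.simulate_pedigree(200, 2, n_offspring=400,
                                        dams_per_sire=20, seed=2)
        last = meta["generation"] == 2
        sires = ped.sire[meta.index[last]]
        sizes = np.bincount(sires[sires >= 0])
        sizes = sizes[sizes > 0]
        assert abs(sizes.mean() - 20) <= 5

    def test_infeasible_mating_raises(self):
        with pytest.raises(ValueError, match="founders"):
            s.simulate_pedigree(1, 1, seed=3)


class TestSimulateGenotypes:
    def test_homozygous_parents_transmit_exactly(self):
        from ssgblup.pedigree import from_records

        ped = from_records([("S", "0", "0"), ("D", "0", "0"),
                            ("O", "S", "D")])
        geno = s.simulate_genotypes(ped, 500,
                                    founder_maf_range=(0.5, 0.5), seed=4)
        vals = geno.values
        both0 = (vals[0] == 0) & (vals[1] == 0)
        both2 = (vals[0] == 2) & (vals[1] == 2)
        assert (vals[2][both0] == 0).all()
        assert (vals[2][both2] == 2).all()

    def test_founder_maf_concentration(self):
        ped, _ = s.simulate_pedigree(200, 0, seed=5)
        geno = s.simulate_genotypes(ped, 10_000,
                                    founder_maf_range=(0.5, 0.5), seed=6)
        freq = geno.values.mean(axis=0) / 2.0
        assert abs(freq.mean() - 0.5) < 0.01

    def test_error_rate_triggers_mendelian_filter(self):
        ped, _ = s.simulate_pedigree(60, 2, n_offspring=60, seed=7)
        clean = s.simulate_genotypes(ped, 400, seed=8)
        noisy = s.simulate_genotypes(ped, 400, error_rate=0.05, seed=8)
        rates_clean = s.mendelian_conflict_rate(clean, ped)
        rates_noisy = s.mendelian_conflict_rate(noisy, ped)
        assert rates_clean.max() == 0.0
        assert (rates_noisy > 0.01).sum() > 10

    def test_gene_dropped_relationships_converge_to_a(self):
        ped, _ = s.simulate_pedigree(30, 3, n_offspring=50, seed=9)
        a = tabular_a(ped)
        devs = {}
        for n_snps in (500, 10_000):
            geno = s.simulate_genotypes(ped, n_snps,
                                        founder_maf_range=(0.3, 0.5), seed=10)
            vals = geno.values.astype(float)
            p = vals[:30].mean(axis=0) / 2.0
            keep = (p > 0.05) & (p < 0.95)
            z = vals[:, keep] - 2 * p[keep]
            g = z @ z.T / (2 * np.sum(p[keep] * (1 - p[keep])))
            devs[n_snps] = np.abs(g - a).mean()
        assert devs[10_000] < devs[500]


class TestSimulateBreedingValues:
    def test_zero_variance_all_zero(self, trio):
        bv = s.simulate_breeding_values(trio, 0.0, seed=11)
        np.testing.assert_array_equal(bv, 0.0)

    def test_founder_variance(self):
        ped, _ = s.simulate_pedigree(2000, 0, seed=12)
        bv = s.simulate_breeding_values(ped, 1.0, seed=13)
        assert bv[:, 0].var() == pytest.approx(1.0, abs=0.07)

    def test_bivariate_founder_correlation(self):
        ped, _ = s.simulate_pedigree(2000, 0, seed=14)
        ga = np.array([[1.0, 0.7], [0.7, 1.0]])
        bv = s.simulate_breeding_values(ped, ga, seed=15)
        assert np.corrcoef(bv.T)[0, 1] == pytest.approx(0.7, abs=0.05)

    def test_descendant_variance_matches_pedigree_expectation(self):
        ped, meta = s.simulate_pedigree(300, 3, n_offspring=1500,
                                        dams_per_sire=5, seed=16)
        bv = s.simulate_breeding_values(ped, 1.0, seed=17)
        last = meta.index[meta["generation"] == 3].to_numpy()
        a = tabular_a(ped)
        expected = np.diag(a)[last].mean()  # 1 + mean F
        assert bv[last, 0].var() == pytest.approx(expected, abs=0.12)

    def test_genomic_mode_variance_scale(self):
        ped, _ = s.simulate_pedigree(500, 0, seed=18)
        geno = s.simulate_genotypes(ped, 2000,
                                    founder_maf_range=(0.2, 0.5), seed=19)
        bv = s.simulate_breeding_values(ped, 1.0, mode="genomic",
                                        genotypes=geno, seed=20)
        assert bv[:, 0].var() == pytest.approx(1.0, abs=0.15)

    def test_non_pd_rejected(self, trio):
        with pytest.raises(ValueError, match="definite"):
            s.simulate_breeding_values(
                trio, np.array([[1.0, 2.0], [2.0, 1.0]]), seed=21
            )


class TestSimulatePhenotypes:
    def test_pure_breeding_value_phenotype(self):
        ped, meta = s.simulate_pedigree(50, 1, seed=22)
        bv = s.simulate_breeding_values(ped, 1.0, seed=23)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=1e-18, kind="linear",
            design=s.TraitDesign(n_cg=1, cg_sd=0.0, beta_age=(0.0, 0.0),
                                 n_gmand=0, sex=None),
            trait_name="T", seed=24,
        )
        idx = ped.indices_of(recs["animal_id"])
        np.testing.assert_allclose(recs["value"], bv[idx, 0], atol=1e-6)

    def test_threshold_incidence_on_target(self):
        ped, meta = s.simulate_pedigree(300, 2, n_offspring=2500, seed=25)
        bv = s.simulate_breeding_values(ped, 0.43, seed=26)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=1.0, kind="threshold",
            incidence=0.30, design=s.TraitDesign(sex=None),
            trait_name="B", seed=27,
        )
        assert (recs["value"] == 2).mean() == pytest.approx(0.30, abs=0.02)
        assert set(recs["value"]) == {1, 2}

    def test_offspring_midparent_regression(self):
        """Classical quantitative-genetics oracle: the offspring-on-midparent
        regression slope estimates h2."""
        h2 = 0.4
        ped, meta = s.simulate_pedigree(600, 2, n_offspring=1600,
                                        dams_per_sire=3, seed=28)
        bv = s.simulate_breeding_values(ped, h2, seed=29)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=1 - h2, kind="linear",
            design=s.TraitDesign(n_cg=1, cg_sd=0.0, beta_age=(0.0, 0.0),
                                 sex=None, record_from_generation=0),
            trait_name="T", seed=30,
        )
        y = recs.set_index("animal_id")["value"]
        mid, off = [], []
        for i in range(ped.n):
            sx, d = ped.sire[i], ped.dam[i]
            if sx >= 0 and d >= 0:
                trio_ids = (ped.ids[i], ped.ids[sx], ped.ids[d])
                if all(t in y.index for t in trio_ids):
                    off.append(y[trio_ids[0]])
                    mid.append((y[trio_ids[1]] + y[trio_ids[2]]) / 2)
        slope = np.polyfit(mid, off, 1)[0]
        assert slope == pytest.approx(h2, abs=0.08)

    def test_sex_limited_assignment(self):
        ped, meta = s.simulate_pedigree(60, 2, seed=31)
        bv = s.simulate_breeding_values(ped, 0.4, seed=32)
        recs = s.simulate_phenotypes(
            ped, meta, bv, residual_variance=0.6,
            design=s.TraitDesign(sex="M"), trait_name="T", seed=33,
        )
        assert (recs["sex"] == "M").all()

    def test_unreachable_incidence_rejected(self):
        ped, meta = s.simulate_pedigree(20, 1, seed=34)
        bv = s.simulate_breeding_values(ped, 0.4, seed=35)
        with pytest.raises(ValueError, match="incidence"):
            s.simulate_phenotypes(
                ped, meta, bv, residual_variance=1.0, kind="threshold",
                incidence=1.5, design=s.TraitDesign(sex=None),
                trait_name="B", seed=36,
            )


class TestStudyBundle:
    def test_tiny_bundle_structure(self):
        ds = s.make_study_like_dataset("tiny", seed=1)
        assert set(ds.phenotypes) == {"SC_like", "VOL_like", "STAY_like",
                                      "PP14_like"}
        assert ds.truth.h2(0) == pytest.approx(0.75)
        assert ds.truth.h2(2) == pytest.approx(0.17)
        assert ds.truth.rg(0, 2) == pytest.approx(0.5)
        assert (ds.phenotypes["SC_like"]["sex"] == "M").all()
        assert (ds.phenotypes["STAY_like"]["sex"] == "F").all()
        assert set(ds.phenotypes["PP14_like"]["value"]) <= {1, 2}
        assert len(ds.genotypes.animal_ids) == 60

    def test_seed_reproducibility(self):
        d1 = s.make_study_like_dataset("tiny", seed=9)
        d2 = s.make_study_like_dataset("tiny", seed=9)
        np.testing.assert_array_equal(d1.genotypes.values,
                                      d2.genotypes.values)
        assert d1.phenotypes["SC_like"].equals(d2.phenotypes["SC_like"])
        np.testing.assert_array_equal(d1.breeding_values, d2.breeding_values)

    def test_tiny_end_to_end_fit(self):
        """Smoke: a tiny bundle fits end-to-end with a short chain."""
        ds = s.make_study_like_dataset("tiny", seed=2)
        h_inv = h_inverse_from_a(s.build_a_inverse(ds.pedigree),
                                 ids=ds.pedigree.ids)
        recs = ds.phenotypes["SC_like"]
        sys_ = build_system(recs, ds.models["SC_like"], h_inv)
        d = s.gibbs_linear(sys_, ChainConfig(1500, 500, 2, seed=3))
        h2 = s.heritability_draws(d)
        assert 0.0 < h2.mean() < 1.0


class TestThresholdPipelineLinearity:
    def test_h2_estimates_track_truth_across_grid(self):
        """Regressing pipeline liability-h2 estimates on the generating h2
        over a grid should give a slope near 1 (threshold model recovers
        the liability scale, not the observed scale)."""
        grid = [0.1, 0.2, 0.3, 0.4]
        reps = 5
        truths, ests = [], []
        base = 0
        for h2 in grid:
            for r in range(reps):
                seed = base + int(h2 * 1000) + r * 17
                ped, meta = s.simulate_pedigree(
                    250, 2, n_offspring=600, dams_per_sire=12, seed=seed)
                vu = h2 / (1 - h2)
                bv = s.simulate_breeding_values(ped, vu, seed=seed + 1)
                recs = s.simulate_phenotypes(
                    ped, meta, bv, residual_variance=1.0, kind="threshold",
                    incidence=0.35,
                    design=s.TraitDesign(n_cg=4, cg_sd=0.3, sex=None),
                    trait_name="B", seed=seed + 2,
                )
                h_inv = h_inverse_from_a(s.build_a_inverse(ped), ids=ped.ids)
                sys_ = build_system(recs, ModelSpec("B", "threshold"), h_inv)
                d = s.gibbs_threshold(
                    sys_, ChainConfig(5000, 1500, 5, seed=seed + 3))
                truths.append(h2)
                ests.append(s.heritability_draws(d).mean())
        slope = np.polyfit(truths, ests, 1)[0]
        assert 0.8 <= slope <= 1.2
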