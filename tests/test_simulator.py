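import numpy as np
import pytest

from fblmm import simulator as S
from fblmm.io import Pedigree, PedigreeRecord
from fblmm.kernels import pedigree_kinship

from conftest import make_genotypes


def fixed_maf(value):
    return lambda p, rng: np.full(p, value)


class TestFounders:
    def test_empirical_maf_concentrates_on_target(self):
        g = S.simulate_founders(10000, 5, fixed_maf(0.5), seed=0)
        assert np.all(np.abs(g.dosages.mean(axis=0) / 2 - 0.5) < 0.01)

    def test_invalid_sampler_domain_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 0.5\]"):
            S.simulate_founders(10, 3, fixed_maf(0.0), seed=0)

    def test_same_seed_identical(self):
        a = S.simulate_founders(50, 20, S.MafSampler(), seed=5)
        b = S.simulate_founders(50, 20, S.MafSampler(), seed=5)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_rare_monomorphic_columns_dropped_not_exported(self):
        g = S.simulate_founders(5, 200, fixed_maf(0.001), seed=1)
        sums = g.dosages.sum(axis=0)
        assert np.all((sums > 0) & (sums < 2 * 5))


class TestPedigreeConstruction:
    @pytest.mark.parametrize(
        "structure,count,individuals",
        [
            ("half-sib-5", 30, 150),
            ("nuclear-2-offspring", 177, 708),
            ("nuclear-4-offspring", 197, 1182),
            ("trio", 10, 30),
        ],
    )
    def test_deterministic_counts(self, structure, count, individuals):
        ped = S.build_pedigrees([(structure, count)])
        assert len(ped.individuals) == individuals

    def test_two_generation_design_totals(self):
        ped = S.build_pedigrees(
            [("half-sib-5", 30), ("nuclear-2-offspring", 177),
             ("nuclear-4-offspring", 197)]
        )
        assert len(ped.individuals) == 2040
        assert len(ped.families) == 404

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="unknown pedigree structure"):
            S.build_pedigrees([("octuplets", 1)])

    def test_half_sib_kinship(self):
        ped = S.build_pedigrees([("half-sib-5", 1)])
        K = pedigree_kinship(ped)
        i = {s: k for k, s in enumerate(ped.individuals)}
        assert K[i["F1_c1"], i["F1_c2"]] == pytest.approx(0.25)

    def test_mz_twin_structure_flags_group(self):
        ped = S.build_pedigrees([("mz-twin", 2)])
        mz = [r for r in ped.records if r.mz_group is not None]
        assert len(mz) == 4
        assert len({r.mz_group for r in mz}) == 2


class TestGeneDrop:
    def test_homozygote_parents_transmit_deterministically(self):
        recs = [
            PedigreeRecord("f", "F1", None, None),
            PedigreeRecord("m", "F1", None, None),
            PedigreeRecord("c", "F1", "f", "m"),
        ]
        ped = Pedigree(records=recs)
        founders = make_genotypes([[0.0, 2.0], [0.0, 2.0]])
        g = S.gene_drop(ped, founders, seed=0)
        child = g.dosages[g.samples.index("c")]
        np.testing.assert_array_equal(child, [0.0, 2.0])

    def test_het_by_het_segregation_law(self):
        # one het x het couple, 10000 variant draws for one child
        recs = [
            PedigreeRecord("f", "F1", None, None),
            PedigreeRecord("m", "F1", None, None),
            PedigreeRecord("c", "F1", "f", "m"),
        ]
        ped = Pedigree(records=recs)
        founders = make_genotypes(np.ones((2, 10000)))
        g = S.gene_drop(ped, founders, seed=2)
        child = g.dosages[g.samples.index("c")]
        freqs = [np.mean(child == d) for d in (0, 1, 2)]
        np.testing.assert_allclose(freqs, [0.25, 0.5, 0.25], atol=0.02)

    def test_mz_twins_receive_identical_genomes(self):
        ped = S.build_pedigrees([("mz-twin", 1)])
        founders = S.simulate_founders(10, 50, S.MafSampler(rare_fraction=0), seed=3)
        g = S.gene_drop(ped, founders, seed=3)
        c1 = g.dosages[g.samples.index("F1_c1")]
        c2 = g.dosages[g.samples.index("F1_c2")]
        np.testing.assert_array_equal(c1, c2)

    def test_allele_frequency_preserved_in_expectation(self):
        founders = S.simulate_founders(200, 30, S.MafSampler(rare_fraction=0), seed=4)
        ped = S.build_pedigrees([("nuclear-4-offspring", 50)])
        g = S.gene_drop(ped, founders, seed=4)
        offspring = [s for s in g.samples if "_c" in s]
        go = g.subset(samples=offspring)
        pool_freq = founders.dosages.mean(axis=0) / 2
        n_off = go.n_samples
        se = np.sqrt(pool_freq * (1 - pool_freq) / (2 * n_off)) * 3 + 0.05
        assert np.all(np.abs(go.dosages.mean(axis=0) / 2 - pool_freq) < se)


class TestEnvOnly:
    def test_no_family_effect_no_family_correlation(self):
        ped = S.build_pedigrees([("nuclear-2-offspring", 500)])
        pheno, comps = S.simulate_env_only(ped, 0.0, 1.0, seed=0)
        y = pheno.phenotype.reshape(500, 4)
        r = np.corrcoef(y[:, 2], y[:, 3])[0, 1]  # sibling pairs
        assert abs(r) < 0.05
        assert np.all(comps["env"] == 0.0)

    def test_intraclass_correlation_half(self):
        ped = S.build_pedigrees([("nuclear-2-offspring", 1000)])
        pheno, _ = S.simulate_env_only(ped, 1.0, 1.0, seed=1)
        y = pheno.phenotype.reshape(1000, 4)
        r = np.corrcoef(y[:, 0], y[:, 1])[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_covariance_matches_block_structure(self):
        ped = S.build_pedigrees([("nuclear-2-offspring", 1)])
        rng = np.random.default_rng(2)
        draws = np.array(
            [S.simulate_env_only(ped, 0.6, 0.4, rng)[0].phenotype
             for _ in range(2000)]
        )
        emp = np.cov(draws.T)
        expected = 0.6 * np.ones((4, 4)) + 0.4 * np.eye(4)
        np.testing.assert_allclose(emp, expected, atol=0.08)


@pytest.fixture(scope="module")
def study():
    return S.run_scenario(
        "fig3A",
        overrides={
            "pedigree_blocks": (("nuclear-2-offspring", 125),),
            "n_variants": 80, "founder_pool": 300,
            "causal_region_sizes": (10, 10, 10),
        },
        seed=6,
    )


class TestGeneticOnly:
    def test_variance_partition_hits_targets(self, study):
        # components are rescaled to the target partition in-sample
        h, uf = study.config.h_total, study.config.unmeasured_fraction
        part = study.variance_partition
        assert part["unmeasured"] == pytest.approx(h * uf, abs=0.05)
        measured = [v for k, v in part.items() if k.startswith("region:")]
        assert sum(measured) == pytest.approx(h * (1 - uf), abs=0.05)
        assert part["residual"] == pytest.approx(1 - h, abs=0.05)

    def test_unmeasured_region_absent_from_export(self, study):
        hidden = set(study.hidden_genotypes.variants.index)
        assert hidden.isdisjoint(study.genotypes.variants.index)
        assert not any(
            v in hidden for vs in study.region_map.regions.values() for v in vs
        )

    def test_components_sum_exactly_to_phenotype(self, study):
        total = np.sum(list(study.components.values()), axis=0)
        np.testing.assert_allclose(total, study.phenotype, atol=1e-12)

    def test_zero_heritability_is_pure_noise(self):
        study = S.run_scenario(
            "fig3A",
            overrides={
                "pedigree_blocks": (("trio", 40),), "n_variants": 60,
                "founder_pool": 100, "causal_region_sizes": (8, 8, 8),
                "h_total": 0.0,
            },
            seed=7,
        )
        for key, comp in study.components.items():
            if key != "residual":
                assert np.all(comp == 0.0)


class TestCombined:
    @pytest.mark.parametrize(
        "model,check",
        [
            # shares of explained variance: env vs (measured, unmeasured) genetic
            ("S1", lambda e, m, u: e == 0.0 and abs(u - m) < 1e-9),
            ("S2", lambda e, m, u: e > m),
            ("S3", lambda e, m, u: u > e + m),
        ],
    )
    def test_disease_model_inequalities(self, model, check):
        study = S.run_scenario(
            model,
            overrides={
                "pedigree_blocks": (("mz-twin", 20), ("twin", 20)),
                "n_variants": 60, "founder_pool": 100,
                "causal_region_sizes": (8, 8, 8),
            },
            seed=8,
        )
        part = study.variance_partition
        env = part.get("env", 0.0)
        measured = sum(v for k, v in part.items() if k.startswith("region:"))
        unmeasured = part["unmeasured"]
        assert check(env, measured, unmeasured)

    def test_equal_contribution_mode(self):
        study = S.run_scenario(
            "fig4",
            overrides={
                "pedigree_blocks": (("nuclear-2-offspring", 125),),
                "n_variants": 80, "founder_pool": 300,
                "causal_region_sizes": (10, 10, 10),
            },
            seed=9,
        )
        part = study.variance_partition
        genetic = part["unmeasured"] + sum(
            v for k, v in part.items() if k.startswith("region:")
        )
        assert part["env"] == pytest.approx(genetic, abs=0.05)


class TestReproducibility:
    def test_full_study_bitwise_reproducible(self):
        ov = {"pedigree_blocks": (("trio", 10),), "n_variants": 30,
              "founder_pool": 40, "causal_region_sizes": (6, 6, 6)}
        a = S.run_scenario("fig2", overrides=ov, seed=11)
        b = S.run_scenario("fig2", overrides=ov, seed=11)
        np.testing.assert_array_equal(a.genotypes.dosages, b.genotypes.dosages)
        np.testing.assert_array_equal(a.phenotype, b.phenotype)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            S.run_scenario("fig99")
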