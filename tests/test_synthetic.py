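import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from segscan.pedigree import compute_kinship, load_pedigree
from segscan.scoring import read_variant_vcf
from segscan.segregation import fit_beta_observed
from segscan.synthetic import (
    SimulationConfig,
    baseline_logodds,
    generate_cohort,
    generate_families,
    generate_pedigree,
    simulate_affections,
    simulate_quant_trait,
)


class TestConfig:
    def test_roundtrips_through_json(self):
        cfg = SimulationConfig(seed=5, beta=2.5, pool_size=100)
        again = SimulationConfig.from_json(cfg.to_json())
        assert again == cfg

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, prevalence=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, generations=0)
        with pytest.raises(ValueError):
            SimulationConfig(seed=1, trait_sigma2=-1.0)


class TestGeneratePedigree:
    def test_single_generation_founders_only(self):
        ped = generate_pedigree(SimulationConfig(seed=1, generations=1))
        assert len(ped.nonfounders) == 0
        assert len(ped) == 2

    def test_fixed_sibship_member_count_closed_form(self):
        # one child per couple, spouse always marries in: each extra
        # generation adds exactly one child + one spouse, except the
        # last which adds only the child
        cfg = SimulationConfig(
            seed=2, generations=3, mean_sibship=1.0, max_sibship=1,
            mate_prob=1.0,
        )
        ped = generate_pedigree(cfg)
        assert len(ped) == 2 + 2 + 1

    def test_many_seeds_all_validate(self):
        sizes = []
        for seed in range(200):
            ped = generate_pedigree(SimulationConfig(seed=seed))
            sizes.append(len(ped))  # construction runs full validation
        assert np.mean(sizes) > 10  # discovery-family scale on average

    def test_deterministic_given_seed(self):
        a = generate_pedigree(SimulationConfig(seed=77))
        b = generate_pedigree(SimulationConfig(seed=77))
        assert a.order == b.order
        assert all(a[i].father_id == b[i].father_id for i in a.order)

    def test_families_are_disjoint_blocks(self):
        ped = generate_families(SimulationConfig(seed=1), n_families=3)
        km = compute_kinship(ped)
        fams = {}
        for iid in ped.order:
            fams.setdefault(iid.split("_")[0], []).append(iid)
        for a in fams["F0"]:
            for b in fams["F1"]:
                assert km.loc(a, b) == 0.0


class TestSimulateAffections:
    def test_null_beta_equalizes_prevalence(self):
        rng = np.random.default_rng(6)
        n = 100_000
        ids = [str(i) for i in range(n)]
        f = dict.fromkeys(ids, logit(0.1))
        g = pd.Series(rng.integers(0, 2, n), index=ids)
        aff = simulate_affections(ids, f, 0.0, g, rng)
        p1 = aff[g == 1].mean()
        p0 = aff[g == 0].mean()
        se = np.sqrt(2 * 0.1 * 0.9 / (n / 2))
        assert abs(p1 - p0) <= 3 * se

    def test_carrier_prevalence_matches_penetrance(self):
        rng = np.random.default_rng(7)
        n = 100_000
        ids = [str(i) for i in range(n)]
        f = dict.fromkeys(ids, logit(0.01))
        g = pd.Series(1, index=ids)
        aff = simulate_affections(ids, f, np.log(100.0), g, rng)
        p = 100.0 / 199.0
        assert abs(aff.mean() - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_bit_identical_on_repeat(self):
        ids = [str(i) for i in range(100)]
        f = dict.fromkeys(ids, -2.0)
        g = pd.Series(0, index=ids)
        a = simulate_affections(ids, f, 1.0, g, 42)
        b = simulate_affections(ids, f, 1.0, g, 42)
        assert a.equals(b)


class TestSimulateQuantTrait:
    def test_founders_only_iid_with_variance_sigma2(self):
        n = 10_000
        phi = 0.5 * np.eye(n)
        y = simulate_quant_trait(phi, 1.0, 0.0, 2.0, np.zeros(n), 8)
        # 2*sigma^2*phi = sigma^2 * I
        assert abs(y.mean() - 1.0) < 3 * np.sqrt(2.0 / n)
        assert abs(y.var(ddof=1) - 2.0) < 0.1

    def test_sib_pair_covariance(self):
        # full sibs: phi_off = 1/4 so cov = 2*sigma^2/4
        reps = 10_000
        phi = np.array([[0.5, 0.25], [0.25, 0.5]])
        rng = np.random.default_rng(9)
        draws = np.array(
            [simulate_quant_trait(phi, 0.0, 0.0, 1.0, np.zeros(2), rng)
             for _ in range(reps)]
        )
        emp = np.cov(draws.T)[0, 1]
        assert abs(emp - 0.5) <= 3 * np.sqrt(2.0 / reps)

    def test_reproducible_and_validates(self):
        phi = 0.5 * np.eye(5)
        a = simulate_quant_trait(phi, 0.0, -1.6, 1.0, np.arange(5) % 2, 3)
        b = simulate_quant_trait(phi, 0.0, -1.6, 1.0, np.arange(5) % 2, 3)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            simulate_quant_trait(phi, 0.0, 0.0, -1.0, np.zeros(5), 3)


class TestGenerateCohort:
    def test_files_roundtrip_through_readers(self, tmp_path):
        cfg = SimulationConfig(seed=11, pool_size=300)
        cohort = generate_cohort(cfg, tmp_path)
        ped = load_pedigree(cohort.files["ped"])
        assert ped.order == cohort.ped.order
        recs = read_variant_vcf(cohort.files["vcf"])
        assert len(recs) == 2
        causal = next(r for r in recs if r.impact == "LoF")
        assert set(causal.carriers) == set(
            cohort.genotypes[cohort.genotypes == 1].index
        )
        pheno = pd.read_csv(cohort.files["phenotypes"], sep="\t", index_col="id")
        assert pheno["affection"].astype(bool).equals(
            cohort.affection.rename_axis("id").rename(None).astype(bool)
        ) or np.array_equal(
            pheno["affection"].to_numpy(), cohort.affection.astype(int).to_numpy()
        )
        cov = pd.read_csv(cohort.files["covariates"], sep="\t", index_col="id")
        assert list(cov.columns) == list(cohort.covariates.columns)

    def test_pool_carrier_count_binomial(self, tmp_path):
        cfg = SimulationConfig(seed=12, pool_size=20_000, pool_carrier_freq=1e-3)
        cohort = generate_cohort(cfg)
        count = int(cohort.genotypes[cohort.pool_ids].sum())
        mean = 20.0
        assert abs(count - mean) <= 3 * np.sqrt(mean)

    def test_strong_effect_yields_positive_llr_across_seeds(self):
        # beta = 3 fixture: the segregation machinery should find
        # nonzero evidence in nearly every realization
        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed, pool_size=0)
            cohort = generate_cohort(cfg)
            ped = cohort.ped
            order = ped.order
            f = cohort.f[order].to_numpy()
            aff = cohort.affection[order].to_numpy()
            carriers = cohort.genotypes[order].to_numpy(dtype=bool)[None, :]
            _, llr = fit_beta_observed(f, carriers, aff)
            if llr[0] > 0:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_ground_truth_emitted(self, tmp_path):
        import json

        cohort = generate_cohort(SimulationConfig(seed=13, pool_size=50), tmp_path)
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["config"]["beta"] == cohort.config.beta
        assert truth["origin_founder"] == cohort.origin_founder
        assert truth["n_pedigree"] == len(cohort.ped)

    def test_baseline_logodds_uses_config_effects(self):
        cfg = SimulationConfig(seed=1, sex_effect=0.0, birth_year_effect=0.0)
        cov = pd.DataFrame(
            {"sex": [0, 1], "birth_year": [1950.0, 1960.0]},
            index=["a", "b"],
        )
        f = baseline_logodds(cfg, cov)
        assert np.allclose(f, logit(cfg.prevalence))
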