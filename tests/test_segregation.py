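import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from segscan.pedigree import Individual, Pedigree, parse_ped
from segscan.segregation import (
    FounderModel,
    MendelianInconsistencyError,
    fit_beta,
    fit_beta_observed,
    llr_observed,
    pedigree_loglik,
)

from conftest import random_pedigree
from oracles import brute_force_loglik, grid_search_beta


def _mixed_six_member_ped():
    """Couple, three children, one grandchild; mixed statuses/carriers."""
    ped = parse_ped(
        [
            "F pa 0 0 1 2",
            "F ma 0 0 2 1",
            "F c1 pa ma 1 2",
            "F c2 pa ma 2 1",
            "F sp 0 0 1 1",
            "F g1 sp c2 2 2",
        ]
    )
    ped.set_genotypes({"pa": 1, "c1": 1, "c2": 0})
    return ped


class TestPedigreeLoglik:
    def test_single_founder_carrier_affected(self):
        ped = Pedigree([Individual(id="solo", affection=True, genotype=1)])
        fm = FounderModel(carrier_prior=0.2, mode="iid-founders")
        # P = prior * penetrance(f=0, beta=0) = 0.2 * 0.5
        assert pedigree_loglik(ped, {"solo": 0.0}, 0.0, fm) == pytest.approx(
            np.log(0.2 * 0.5)
        )

    def test_beta_zero_factorizes(self, rng):
        from scipy.special import log_expit

        ped = random_pedigree(rng, n=9, p_genotyped=0.5)
        f = {i: float(rng.normal(-1, 1)) for i in ped.order}
        fm = FounderModel(carrier_prior=0.05, mode="iid-founders")
        ll = pedigree_loglik(ped, f, 0.0, fm)
        # genotype-only part: same pedigree with affections hidden
        bare = Pedigree(
            [
                Individual(
                    id=i,
                    father_id=ped[i].father_id,
                    mother_id=ped[i].mother_id,
                    sex=ped[i].sex,
                    genotype=ped[i].genotype,
                )
                for i in ped.order
            ]
        )
        ll_geno = pedigree_loglik(bare, f, 0.0, fm)
        ll_aff = sum(
            float(log_expit(f[i]) if ped[i].affection else log_expit(-f[i]))
            for i in ped.order
            if ped[i].affection is not None
        )
        assert ll == pytest.approx(ll_geno + ll_aff, abs=1e-10)

    @pytest.mark.parametrize("mode", ["iid-founders", "single-introduction"])
    def test_peeling_equals_enumeration_on_random_pedigrees(self, mode):
        rng = np.random.default_rng(4321)
        checked = 0
        for _ in range(60):
            ped = random_pedigree(rng, n=int(rng.integers(4, 11)), p_genotyped=0.4)
            f = {i: float(rng.normal(-1, 1)) for i in ped.order}
            beta = float(rng.normal(0, 2))
            fm = FounderModel(carrier_prior=0.1, mode=mode)
            expected = brute_force_loglik(ped, f, beta, fm)
            if np.isneginf(expected):
                with pytest.raises(MendelianInconsistencyError):
                    pedigree_loglik(ped, f, beta, fm)
                continue
            assert pedigree_loglik(ped, f, beta, fm) == pytest.approx(
                expected, abs=1e-10
            )
            checked += 1
        assert checked >= 30

    def test_mendelian_inconsistency_raises(self):
        ped = parse_ped(
            ["F pa 0 0 1 0", "F ma 0 0 2 0", "F kid pa ma 1 0"]
        )
        ped.set_genotypes({"pa": 0, "ma": 0, "kid": 1})
        with pytest.raises(MendelianInconsistencyError):
            pedigree_loglik(
                ped, dict.fromkeys(ped.order, 0.0), 1.0,
                FounderModel(0.1, "iid-founders"),
            )

    def test_relabeling_invariance(self, rng):
        ped = _mixed_six_member_ped()
        f = {i: -0.5 for i in ped.order}
        rename = {i: f"z{k}" for k, i in enumerate(ped.order)}
        ped2 = Pedigree(
            [
                Individual(
                    id=rename[i],
                    father_id=rename.get(ped[i].father_id),
                    mother_id=rename.get(ped[i].mother_id),
                    sex=ped[i].sex,
                    affection=ped[i].affection,
                    genotype=ped[i].genotype,
                )
                for i in ped.order
            ]
        )
        f2 = {rename[i]: f[i] for i in f}
        for beta in (-1.0, 0.0, 2.0):
            assert pedigree_loglik(ped, f, beta) == pytest.approx(
                pedigree_loglik(ped2, f2, beta), abs=1e-12
            )


class TestFitBeta:
    def test_all_observed_noncarriers_gives_zero_llr(self):
        ped = parse_ped(
            ["F pa 0 0 1 2", "F ma 0 0 2 1", "F c pa ma 1 2"]
        )
        ped.set_genotypes({"pa": 0, "ma": 0, "c": 0})
        fm = FounderModel(carrier_prior=1e-4, mode="iid-founders")
        res = fit_beta(ped, dict.fromkeys(ped.order, -1.0), fm)
        assert res.beta_hat == 0.0
        assert res.llr == 0.0
        assert res.degenerate
        # under single-introduction conditioning the same observation is
        # impossible (the introduced variant must be carried by someone)
        with pytest.raises(MendelianInconsistencyError):
            fit_beta(ped, dict.fromkeys(ped.order, -1.0), FounderModel())

    def test_perfect_cosegregation_hits_upper_bound(self):
        ped = parse_ped(
            [
                "F pa 0 0 1 2",
                "F ma 0 0 2 1",
                "F c1 pa ma 1 2",
                "F c2 pa ma 2 1",
            ]
        )
        ped.set_genotypes({"pa": 1, "ma": 0, "c1": 1, "c2": 0})
        res = fit_beta(ped, dict.fromkeys(ped.order, -1.0), bounds=(-10, 10))
        assert res.beta_hat == pytest.approx(10.0, abs=1e-4)
        assert res.at_bound
        assert res.llr > 0

    def test_matches_dense_grid_search(self):
        ped = _mixed_six_member_ped()
        f = {i: -0.8 for i in ped.order}
        fm = FounderModel()
        res = fit_beta(ped, f, fm)
        b_grid, _ = grid_search_beta(
            lambda b: pedigree_loglik(ped, f, b, fm), step=1e-3
        )
        assert abs(res.beta_hat - b_grid) <= 2e-3
        assert res.llr >= 0

    def test_joint_fit_pools_evidence_across_pedigrees(self):
        peds, f = [], {}
        for k in range(3):
            p = parse_ped(
                [
                    f"F pa{k} 0 0 1 2",
                    f"F ma{k} 0 0 2 1",
                    f"F c{k} pa{k} ma{k} 1 2",
                ]
            )
            p.set_genotypes({f"pa{k}": 1, f"ma{k}": 0, f"c{k}": 1})
            peds.append(p)
            f.update(dict.fromkeys(p.order, -1.0))
        joint = fit_beta(peds, f)
        single = fit_beta(peds[0], f)
        assert joint.llr > single.llr

    def test_outside_carriers_shift_the_fit(self):
        ped = _mixed_six_member_ped()
        f = {i: -0.8 for i in ped.order}
        base = fit_beta(ped, f)
        # five affected carriers outside the pedigree strengthen the signal
        extra = (np.full(5, -0.8), np.ones(5), np.ones(5, dtype=bool))
        boosted = fit_beta(ped, f, extra_observed=extra)
        assert boosted.llr > base.llr


class TestLLRObserved:
    def test_zero_beta_gives_zero(self, rng):
        f = rng.normal(size=8)
        g = rng.integers(0, 2, 8)
        a = rng.integers(0, 2, 8).astype(bool)
        assert llr_observed(f, g, a, 0.0) == 0.0

    def test_affected_carrier_positive_term(self):
        # sigma(ln 3) = 0.75 against sigma(0) = 0.5
        val = llr_observed([0.0], [1], [True], np.log(3.0))
        assert val == pytest.approx(np.log(1.5), abs=1e-12)

    def test_unaffected_carrier_negative_term(self):
        val = llr_observed([0.0], [1], [False], np.log(3.0))
        assert val == pytest.approx(-np.log(2.0), abs=1e-12)

    def test_noncarriers_and_unknowns_contribute_nothing(self):
        val = llr_observed(
            [0.3, -1.2, 0.7], [0, 0, 1], [True, False, None], 2.0
        )
        assert val == 0.0

    def test_sign_structure_for_positive_beta(self, rng):
        f = rng.normal(size=20)
        for fi in f:
            assert llr_observed([fi], [1], [True], 1.5) >= 0
            assert llr_observed([fi], [1], [False], 1.5) <= 0

    def test_matches_peeling_when_fully_observed(self):
        ped = parse_ped(
            ["F pa 0 0 1 2", "F ma 0 0 2 1", "F c pa ma 1 2"]
        )
        ped.set_genotypes({"pa": 1, "ma": 0, "c": 1})
        f = {"pa": -0.3, "ma": -0.3, "c": -0.3}
        beta = 1.7
        fm = FounderModel()
        diff = pedigree_loglik(ped, f, beta, fm) - pedigree_loglik(ped, f, 0.0, fm)
        obs = llr_observed(
            [f[i] for i in ped.order],
            [ped[i].genotype for i in ped.order],
            [ped[i].affection for i in ped.order],
            beta,
        )
        assert diff == pytest.approx(obs, abs=1e-10)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            llr_observed([0.0], [1], [True], np.inf)


class TestFitBetaObserved:
    def test_matches_scalar_optimizer(self, rng):
        n = 12
        f = rng.normal(-1, 1, n)
        aff = rng.random(n) < 0.4
        carriers = rng.random((30, n)) < 0.3
        beta_hat, llr = fit_beta_observed(f, carriers, aff)
        for m in rng.choice(30, size=5, replace=False):
            res = minimize_scalar(
                lambda b: -llr_observed(f, carriers[m].astype(int), aff, b),
                bounds=(-10, 10),
                method="bounded",
                options={"xatol": 1e-10},
            )
            assert llr[m] == pytest.approx(
                max(-res.fun, 0.0), abs=1e-6
            )
            if 1e-6 < llr[m]:
                assert beta_hat[m] == pytest.approx(res.x, abs=1e-4)

    def test_uninformative_markers_are_zero(self):
        f = np.array([-1.0, 0.5])
        aff = np.array([True, False])
        beta, llr = fit_beta_observed(f, np.zeros((3, 2), dtype=bool), aff)
        assert np.all(beta == 0) and np.all(llr == 0)
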