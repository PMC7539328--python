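"""Relationship matrix, animal-model variance components and r_g."""

import numpy as np
import pandas as pd
import pytest

import driftgarden as dg
from driftgarden.quantgen import (
    VarianceComponents, build_A, cv_a, fit_animal_model, genetic_correlation,
    heritability, heritability_samples,
)


class TestBuildA:
    def test_mother_and_two_offspring(self, tiny_pedigree):
        a = build_A(tiny_pedigree)
        assert a.loc("o1", "o2") == 0.25
        assert a.loc("m1", "o1") == 0.5
        assert a.loc("m1", "m1") == 1.0
        assert a.loc("f2", "o1") == 0.0

    def test_founders_only_identity(self):
        ped = dg.Pedigree(pd.DataFrame([
            {"individual_id": f"f{i}", "mother_id": None,
             "population": "A", "generation": "founder"} for i in range(4)]))
        assert np.allclose(build_A(ped).A, np.eye(4))

    def test_rho_sib_option_rescales_sibs(self, tiny_pedigree):
        a = build_A(tiny_pedigree, rho_sib=0.5)
        assert a.loc("o1", "o2") == 0.5
        assert a.loc("m1", "o1") == 0.5

    def test_matches_tabular_recursion_on_simulated_pedigree(self):
        truth = dg.star_scenario(2, 0.1)
        ped = dg.simulate_pedigree(truth, 3, 4)
        a = build_A(ped)
        # independent recursion: a(o, x) = 0.5 * a(mother(o), x), diag 1
        t = ped.table
        mothers = dict(zip(t.individual_id, t.mother_id))
        ids = list(t.individual_id)
        expected = {}
        for i in ids:
            for j in ids:
                if i == j:
                    expected[(i, j)] = 1.0
                else:
                    mi, mj = mothers[i], mothers[j]
                    if mi is None and mj is None:
                        expected[(i, j)] = 0.0
                    elif mi is not None and mj is None:
                        expected[(i, j)] = 0.5 if mi == j else 0.0
                    elif mi is None and mj is not None:
                        expected[(i, j)] = 0.5 if mj == i else 0.0
                    else:
                        expected[(i, j)] = 0.25 if mi == mj else 0.0
        for (i, j), v in expected.items():
            assert a.loc(i, j) == v, (i, j)

    def test_psd(self):
        truth = dg.star_scenario(1, 0.1)
        ped = dg.simulate_pedigree(truth, 4, 5)
        for rho in (0.25, 0.5, 0.95):
            eig = np.linalg.eigvalsh(build_A(ped, rho_sib=rho).A)
            assert eig.min() > -1e-10


def _vc(V_A=0.0, V_pop=0.0, V_M=0.0, V_E=1.0, mean=10.0):
    return VarianceComponents(V_A=V_A, V_pop=V_pop, V_M=V_M, V_E=V_E,
                              trait_mean=mean)


class TestDerivedQuantities:
    def test_heritability_closed_forms(self):
        assert heritability(_vc(V_A=1.0, V_E=0.5)) == pytest.approx(1 / 1.5)
        assert heritability(_vc(V_A=0.0, V_E=1.0)) == 0.0

    def test_heritability_fraction_fixture(self):
        # a trait with V_A = 0.69 * V_T reports h2 = 0.69
        assert heritability(_vc(V_A=0.69, V_E=0.31)) == pytest.approx(0.69)

    def test_cv_a(self):
        assert cv_a(_vc(V_A=4.0, mean=10.0)) == pytest.approx(0.2)
        assert cv_a(_vc(V_A=0.0, mean=10.0)) == 0.0
        with pytest.raises(ValueError):
            cv_a(_vc(V_A=1.0, mean=0.0))


class TestAnimalModel:
    def test_h2_recovery_at_study_scale(self):
        truth = dg.star_scenario(16, 0.05, seed=201, sigma2_A=0.4, sigma2_E=0.6)
        ped = dg.simulate_pedigree(truth, 30, 17)
        ph = dg.simulate_phenotypes(truth, ped)
        vc = fit_animal_model(ph, ped, chains=2, burn_in=600, iters=1200,
                              thin=3, seed=201)
        h2 = heritability(vc)
        assert h2 == pytest.approx(0.4, abs=0.1)
        assert max(vc.psrf.values()) < 1.2

    def test_null_heritability_recovery(self):
        truth = dg.star_scenario(8, 0.02, seed=202, sigma2_A=0.0, sigma2_E=1.0)
        ped = dg.simulate_pedigree(truth, 15, 10)
        ph = dg.simulate_phenotypes(truth, ped)
        vc = fit_animal_model(ph, ped, chains=2, burn_in=600, iters=1200,
                              thin=3, seed=202)
        h2s = heritability_samples(vc)
        assert np.quantile(h2s, 0.05) < 0.05

    def test_permuted_families_destroy_additive_signal(self, small_truth):
        ped = dg.simulate_pedigree(small_truth, 15, 10)
        ph = dg.simulate_phenotypes(small_truth, ped)
        vc = fit_animal_model(ph, ped, chains=2, burn_in=500, iters=1000,
                              thin=2, seed=203)
        rng = np.random.default_rng(203)
        shuffled = ped.table.copy()
        off = shuffled["generation"] == "offspring"
        shuffled.loc[off, "mother_id"] = rng.permutation(
            shuffled.loc[off, "mother_id"].to_numpy())
        # keep populations consistent with the new mother
        founders = shuffled[~off].set_index("individual_id")["population"]
        shuffled.loc[off, "population"] = founders.reindex(
            shuffled.loc[off, "mother_id"]).to_numpy()
        ped_perm = dg.Pedigree(shuffled)
        vc_perm = fit_animal_model(ph, ped_perm, chains=2, burn_in=500,
                                   iters=1000, thin=2, seed=203)
        assert vc_perm.V_A < 0.5 * vc.V_A

    def test_maternal_configuration_runs(self, small_truth):
        ped = dg.simulate_pedigree(small_truth, 10, 8)
        ph = dg.simulate_phenotypes(small_truth, ped)
        vc = fit_animal_model(ph, ped, chains=2, burn_in=200, iters=400,
                              thin=2, seed=204, seed_weight="maternal")
        assert vc.V_M >= 0.0
        assert "V_M" in vc.samples


def _bivariate_data(rg_true, seed, n_fams=120, k=8, va=0.4, ve=0.6):
    """Direct bivariate half-sib simulation used as r_g recovery oracle."""
    rng = np.random.default_rng(seed)
    g_cov = np.array([[va, rg_true * va], [rg_true * va, va]])
    lu = np.linalg.cholesky(0.25 * g_cov + 1e-12 * np.eye(2))
    ld = np.linalg.cholesky(0.75 * g_cov + 1e-12 * np.eye(2))
    rows, ped_rows = [], []
    for f in range(n_fams):
        mid = f"M{f:03d}"
        ped_rows.append({"individual_id": mid, "mother_id": None,
                         "population": "A", "generation": "founder"})
        u = lu @ rng.normal(size=2)
        for o in range(k):
            oid = f"{mid}_O{o}"
            ped_rows.append({"individual_id": oid, "mother_id": mid,
                             "population": "A", "generation": "offspring"})
            a = u + ld @ rng.normal(size=2)
            e = rng.normal(scale=np.sqrt(ve), size=2)
            for t, name in enumerate(("t1", "t2")):
                rows.append({"individual_id": oid, "trait": name,
                             "value": 10.0 + a[t] + e[t], "block": "B1"})
    return (dg.PhenotypeTable(pd.DataFrame(rows)),
            dg.Pedigree(pd.DataFrame(ped_rows)))


class TestGeneticCorrelation:
    def test_recovers_planted_correlation(self):
        pheno, ped = _bivariate_data(0.8, seed=301)
        res = genetic_correlation(pheno, ped, chains=2, burn_in=500,
                                  iters=1000, thin=2, seed=301)
        assert res.mean == pytest.approx(0.8, abs=0.15)

    def test_independent_traits_interval_covers_zero(self):
        pheno, ped = _bivariate_data(0.0, seed=302)
        res = genetic_correlation(pheno, ped, chains=2, burn_in=500,
                                  iters=1000, thin=2, seed=302)
        lo, hi = res.interval(0.95)
        assert lo < 0 < hi

    def test_duplicated_trait_self_correlation(self):
        pheno, ped = _bivariate_data(1.0 - 1e-9, seed=303)
        res = genetic_correlation(pheno, ped, chains=2, burn_in=500,
                                  iters=1000, thin=2, seed=303)
        assert res.mean > 0.8

    def test_all_draws_in_unit_interval_and_G_psd(self):
        pheno, ped = _bivariate_data(0.5, seed=304, n_fams=40, k=5)
        res = genetic_correlation(pheno, ped, chains=2, burn_in=200,
                                  iters=400, thin=2, seed=304)
        assert (np.abs(res.samples) <= 1.0).all()
        assert (np.linalg.eigvalsh(res.G_samples) > 0).all()


class TestRobustnessInvariants:
    def test_family_ranking_stable_across_greenhouses(self, small_truth):
        """Full-data and per-greenhouse fits rank families consistently."""
        from scipy import stats as st
        ped = dg.simulate_pedigree(small_truth, 15, 12)
        ph = dg.simulate_phenotypes(small_truth, ped, n_blocks=4)
        vc_full = fit_animal_model(ph, ped, chains=2, burn_in=500, iters=1000,
                                   thin=2, seed=501)
        gh1 = dg.PhenotypeTable(ph.table[ph.table["greenhouse"] == 1].copy())
        vc_gh1 = fit_animal_model(gh1, ped, chains=2, burn_in=500, iters=1000,
                                  thin=2, seed=501)
        shared = vc_gh1.family_effects.index
        rho = st.spearmanr(vc_full.family_effects.reindex(shared),
                           vc_gh1.family_effects).statistic
        assert rho > 0.8

    def test_h2_interval_coverage_across_replicates(self):
        """90% credible intervals for h2 cover the truth in >= 7/10 replicates."""
        hits = 0
        for rep in range(10):
            truth = dg.star_scenario(16, 0.05, seed=700 + rep,
                                     sigma2_A=0.4, sigma2_E=0.6)
            ped = dg.simulate_pedigree(truth, 30, 17)
            ph = dg.simulate_phenotypes(truth, ped)
            vc = fit_animal_model(ph, ped, chains=2, burn_in=500, iters=1000,
                                  thin=2, seed=700 + rep)
            h2s = heritability_samples(vc)
            # truth on the configured decomposition includes the drift component
            h2_true = 0.4 / (0.4 + 0.6 + 2 * 0.4 * 0.05)
            lo, hi = np.quantile(h2s, 0.05), np.quantile(h2s, 0.95)
            if lo <= h2_true <= hi:
                hits += 1
        assert hits >= 7, f"coverage {hits}/10"
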