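import numpy as np
import pandas as pd
import pytest

import ftirblup as fb
from ftirblup.mixed_models import (
    ConvergenceError,
    ModelSpec,
    TraitModel,
    VarianceComponents,
    reml_loglik,
)

from conftest import dense_blup_oracle


def trio_pheno(values=(3.0, 5.0, 6.5)):
    return pd.DataFrame({"cow_id": [1, 2, 3], "cohort": "LAB", "value": list(values)})


def mean_only_spec(name="y"):
    return ModelSpec(traits=[TraitModel(name, "LAB")])


def unit_components(name="y", sigma_a2=1.0, sigma_e2=1.0):
    return VarianceComponents(
        trait_names=[name], sigma_a=[[sigma_a2]], sigma_e=[sigma_e2], sigma_pe=[0.0]
    )


class TestHeritabilityFormulas:
    @pytest.mark.parametrize(
        "sigma_a2,sigma_e2,sigma_pe2,expected",
        [
            # printed variance components for rennet coagulation time
            (7.155, 14.967, 0.0, 0.323),
            (5.911, 8.901, 2.091, 0.350),
            (0.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_h2_from_components(self, sigma_a2, sigma_e2, sigma_pe2, expected):
        h2 = fb.heritability_from_components(sigma_a2, sigma_e2, sigma_pe2)
        assert round(h2, 3) == pytest.approx(expected, abs=5e-4)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValueError):
            fb.heritability_from_components(0.0, 0.0, 0.0)

    @pytest.mark.parametrize(
        "va1,va2,cov,expected",
        [(4.0, 9.0, 6.0, 1.0), (4.0, 9.0, 0.0, 0.0), (4.0, 9.0, 3.0, 0.5)],
    )
    def test_genetic_correlation_closed_forms(self, va1, va2, cov, expected):
        vc = VarianceComponents(
            trait_names=["a", "b"],
            sigma_a=[[va1, cov], [cov, va2]],
            sigma_e=[1.0, 1.0],
            sigma_pe=[0.0, 0.0],
        )
        assert fb.genetic_correlation(vc) == pytest.approx(expected)

    def test_zero_additive_variance_rejected(self):
        vc = VarianceComponents(
            trait_names=["a", "b"],
            sigma_a=[[0.0, 0.0], [0.0, 1.0]],
            sigma_e=[1.0, 1.0],
            sigma_pe=[0.0, 0.0],
        )
        with pytest.raises(ValueError):
            fb.genetic_correlation(vc)


class TestMMEAssembly:
    def test_textbook_trio_coefficient_matrix(self, trio_pedigree):
        """Mean + 3 animals with sigma_a2 = sigma_e2 = 1: the MME is the
        4x4 system [X'X X'Z; Z'X Z'Z + A^-1] (hand assembly)."""
        ainv = fb.build_A_inverse(trio_pedigree)
        sys_ = fb.build_mme(trio_pheno(), mean_only_spec(), unit_components(), ainv)
        C = sys_.C.toarray()
        Ai = ainv.values.toarray()
        expected = np.zeros((4, 4))
        expected[0, 0] = 3
        expected[0, 1:] = 1
        expected[1:, 0] = 1
        expected[1:, 1:] = np.eye(3) + Ai
        np.testing.assert_allclose(C, expected, atol=1e-12)

    def test_bivariate_decouples_without_covariance(self, small_dataset):
        """sigma_a12 = 0 and disjoint record sets: bivariate solutions equal
        the stacked univariate solutions."""
        cfg = small_dataset.config
        ainv = fb.build_A_inverse(small_dataset.pedigree)
        lab = TraitModel("LAB", "LAB", fixed=("htd",))
        fld = TraitModel("FIELD", "FIELD", fixed=("hys",), permanent_env=True)
        vc2 = VarianceComponents(
            trait_names=["LAB", "FIELD"],
            sigma_a=[[cfg.true_sigma_a2_lab, 0.0], [0.0, cfg.true_sigma_a2_field]],
            sigma_e=[cfg.true_sigma_e2_lab, cfg.true_sigma_e2_field],
            sigma_pe=[0.0, cfg.true_sigma_pe2_field],
        )
        sol2 = fb.solve_mme(
            fb.build_mme(small_dataset.phenotypes, ModelSpec(traits=[lab, fld]), vc2, ainv)
        )
        for tm, va, pe, se in [
            (lab, cfg.true_sigma_a2_lab, 0.0, cfg.true_sigma_e2_lab),
            (fld, cfg.true_sigma_a2_field, cfg.true_sigma_pe2_field, cfg.true_sigma_e2_field),
        ]:
            vc1 = VarianceComponents(
                trait_names=[tm.name], sigma_a=[[va]], sigma_e=[se], sigma_pe=[pe]
            )
            sol1 = fb.solve_mme(
                fb.build_mme(small_dataset.phenotypes, ModelSpec(traits=[tm]), vc1, ainv)
            )
            np.testing.assert_allclose(
                sol2.ebv_for(tm.name, small_dataset.pedigree.animal),
                sol1.ebv_for(tm.name, small_dataset.pedigree.animal),
                atol=1e-8,
            )

    def test_zero_pe_variance_drops_term(self, small_dataset):
        cfg = small_dataset.config
        ainv = fb.build_A_inverse(small_dataset.pedigree)
        fld = TraitModel("FIELD", "FIELD", fixed=("hys",), permanent_env=True)
        fld_nope = TraitModel("FIELD", "FIELD", fixed=("hys",), permanent_env=False)
        vc_zero = VarianceComponents(
            trait_names=["FIELD"], sigma_a=[[cfg.true_sigma_a2_field]],
            sigma_e=[cfg.true_sigma_e2_field], sigma_pe=[0.0],
        )
        sys_pe0 = fb.build_mme(
            small_dataset.phenotypes, ModelSpec(traits=[fld]), vc_zero, ainv
        )
        sys_none = fb.build_mme(
            small_dataset.phenotypes, ModelSpec(traits=[fld_nope]), vc_zero, ainv
        )
        assert sys_pe0.n_equations == sys_none.n_equations
        np.testing.assert_allclose(
            fb.solve_mme(sys_pe0).x, fb.solve_mme(sys_none).x, atol=1e-10
        )

    def test_unknown_animal_rejected(self, trio_pedigree):
        ainv = fb.build_A_inverse(trio_pedigree)
        pheno = trio_pheno().assign(cow_id=[1, 2, 99])
        with pytest.raises(ValueError, match="no relationship row"):
            fb.build_mme(pheno, mean_only_spec(), unit_components(), ainv)


class TestSolve:
    def test_trio_matches_dense_gls_oracle(self, trio_pedigree):
        ainv = fb.build_A_inverse(trio_pedigree)
        sol = fb.solve_mme(
            fb.build_mme(trio_pheno(), mean_only_spec(), unit_components(), ainv)
        )
        A = fb.build_A(trio_pedigree).values
        b, u = dense_blup_oracle(
            np.array([3, 5, 6.5]), np.ones((3, 1)), np.eye(3), A, 1.0, 1.0
        )
        np.testing.assert_allclose(sol.ebv_for("y", [1, 2, 3]), u, atol=1e-8)
        intercept = sol.fixed.loc[sol.fixed.factor == "(intercept)", "estimate"].iloc[0]
        assert intercept == pytest.approx(b[0], abs=1e-8)

    def test_constant_records_give_zero_ebv(self, trio_pedigree):
        ainv = fb.build_A_inverse(trio_pedigree)
        sol = fb.solve_mme(
            fb.build_mme(trio_pheno((4, 4, 4)), mean_only_spec(), unit_components(), ainv)
        )
        np.testing.assert_allclose(sol.ebv["ebv"], 0.0, atol=1e-10)

    def test_blup_matches_oracle_on_structured_data(self, small_dataset):
        """Sparse MME solutions equal dense GLS/BLUP on the LAB cohort."""
        cfg = small_dataset.config
        ped = small_dataset.pedigree
        ainv = fb.build_A_inverse(ped)
        pheno = small_dataset.phenotypes
        lab = pheno[pheno.cohort == "LAB"].reset_index(drop=True)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB")])
        vc = unit_components("LAB", cfg.true_sigma_a2_lab, cfg.true_sigma_e2_lab)
        sol = fb.solve_mme(fb.build_mme(pheno, spec, vc, ainv))

        A = fb.build_A(ped).values
        pos = {a: i for i, a in enumerate(ped.animal)}
        Z = np.zeros((len(lab), ped.n))
        for r, a in enumerate(lab["cow_id"]):
            Z[r, pos[a]] = 1.0
        b, u = dense_blup_oracle(
            lab["value"].to_numpy(), np.ones((len(lab), 1)), Z, A,
            cfg.true_sigma_a2_lab, cfg.true_sigma_e2_lab,
        )
        np.testing.assert_allclose(sol.ebv_for("LAB", ped.animal), u, atol=1e-8)

    def test_pcg_agrees_with_direct(self, small_dataset):
        cfg = small_dataset.config
        ainv = fb.build_A_inverse(small_dataset.pedigree)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB", fixed=("htd",))])
        vc = unit_components("LAB", cfg.true_sigma_a2_lab, cfg.true_sigma_e2_lab)
        sys_ = fb.build_mme(small_dataset.phenotypes, spec, vc, ainv)
        x_direct = fb.solve_mme(sys_, method="direct").x
        x_pcg = fb.solve_mme(sys_, method="pcg", tol=1e-12).x
        np.testing.assert_allclose(x_direct, x_pcg, atol=1e-6)

    def test_solutions_reproducible(self, small_dataset):
        cfg = small_dataset.config
        ainv = fb.build_A_inverse(small_dataset.pedigree)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB")])
        vc = unit_components("LAB", cfg.true_sigma_a2_lab, cfg.true_sigma_e2_lab)
        s1 = fb.solve_mme(fb.build_mme(small_dataset.phenotypes, spec, vc, ainv))
        s2 = fb.solve_mme(fb.build_mme(small_dataset.phenotypes, spec, vc, ainv))
        assert np.array_equal(s1.x, s2.x)


def reml_fixture(seed=5, n_herds=5):
    cfg = fb.SimConfig(
        n_founders=60, n_generations=2, n_sires_per_gen=12,
        daughters_per_sire_lab=10, daughters_per_sire_field=10,
        n_markers=5, n_wavelengths=5, n_records_per_field_cow=3,
        n_herds=n_herds, true_r_a=0.9, seed=seed,
    )
    ped = fb.simulate_pedigree(cfg)
    tv = fb.simulate_breeding_values(ped, cfg)
    _, pheno = fb.simulate_spectra_and_phenotypes(ped, tv, cfg)
    return cfg, ped, pheno


class TestREML:
    def test_em_loglik_monotone(self):
        """EM-REML iterations never decrease the REML log-likelihood."""
        from ftirblup.mixed_models import _build_design

        cfg, ped, pheno = reml_fixture()
        ainv = fb.build_A_inverse(ped)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB", fixed=("htd",))])
        design = _build_design(pheno, spec, ainv)
        logls = [reml_loglik(design, unit_components("LAB", 2.0, 20.0))]
        # run EM one round at a time via max_rounds and chained starts
        current = unit_components("LAB", 2.0, 20.0)
        for _ in range(8):
            try:
                current = fb.estimate_varcomp_reml(
                    pheno, spec, ainv, method="em", conv=1e-300, max_rounds=1,
                    start=current, dense_cutoff=10**6,
                )
            except ConvergenceError as exc:
                current = exc.components
            logls.append(reml_loglik(design, current))
        assert all(b >= a - 1e-8 for a, b in zip(logls, logls[1:]))

    def test_dense_and_sparse_traces_agree(self):
        """Selected-inverse (Takahashi) REML equals dense-inverse REML."""
        cfg, ped, pheno = reml_fixture()
        ainv = fb.build_A_inverse(ped)
        spec = ModelSpec(
            traits=[
                TraitModel("LAB", "LAB", fixed=("htd",)),
                TraitModel("FIELD", "FIELD", fixed=("hys",), permanent_env=True),
            ]
        )
        vc_d = fb.estimate_varcomp_reml(pheno, spec, ainv, conv=1e-10, dense_cutoff=10**6)
        vc_s = fb.estimate_varcomp_reml(pheno, spec, ainv, conv=1e-10, dense_cutoff=1)
        np.testing.assert_allclose(vc_d.sigma_a, vc_s.sigma_a, atol=1e-6)
        np.testing.assert_allclose(vc_d.sigma_e, vc_s.sigma_e, atol=1e-6)
        np.testing.assert_allclose(vc_d.sigma_pe, vc_s.sigma_pe, atol=1e-6)

    def test_univariate_recovery(self):
        """REML recovers the generating h2 on one mid-sized replicate."""
        cfg = fb.SimConfig(
            n_founders=300, n_generations=2, n_sires_per_gen=100,
            daughters_per_sire_lab=20, daughters_per_sire_field=1,
            n_markers=5, n_wavelengths=5, seed=11,
        )
        ped = fb.simulate_pedigree(cfg)
        tv = fb.simulate_breeding_values(ped, cfg)
        _, pheno = fb.simulate_spectra_and_phenotypes(ped, tv, cfg)
        ainv = fb.build_A_inverse(ped)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB", fixed=("htd", "dim_class"))])
        vc = fb.estimate_varcomp_reml(pheno, spec, ainv, conv=1e-10)
        assert vc.converged
        assert fb.heritability(vc, 0) == pytest.approx(0.323, abs=0.12)

    def test_null_additive_variance_hits_boundary(self):
        cfg = fb.SimConfig(
            n_founders=100, n_generations=1, n_sires_per_gen=20,
            daughters_per_sire_lab=20, daughters_per_sire_field=1,
            true_sigma_a2_lab=1e-6, true_sigma_e2_lab=22.0,
            sigma2_htd=0.0, sigma2_dim=0.0,
            n_markers=5, n_wavelengths=5, seed=13,
        )
        ped = fb.simulate_pedigree(cfg)
        tv = fb.simulate_breeding_values(ped, cfg)
        _, pheno = fb.simulate_spectra_and_phenotypes(ped, tv, cfg)
        ainv = fb.build_A_inverse(ped)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB")])
        try:
            vc = fb.estimate_varcomp_reml(pheno, spec, ainv, conv=1e-8, max_rounds=80)
        except ConvergenceError as exc:
            vc = exc.components
        assert fb.heritability(vc, 0) < 0.05

    def test_matches_lme4_on_random_intercept_model(self, tmp_path):
        """With unrelated animals and repeated records the animal model is a
        random-intercept model; REML estimates must match lme4 (independent
        oracle) to numerical precision."""
        import subprocess

        rng = np.random.default_rng(42)
        n_anim, n_rec = 60, 4
        a = rng.normal(0, np.sqrt(3.0), n_anim)
        rows = [
            dict(cow_id=i + 1, cohort="LAB",
                 value=10 + a[i] + rng.normal(0, np.sqrt(5.0)))
            for i in range(n_anim)
            for _ in range(n_rec)
        ]
        df = pd.DataFrame(rows)
        ped = fb.Pedigree(
            animal=np.arange(1, n_anim + 1), sire=np.zeros(n_anim, int),
            dam=np.zeros(n_anim, int), generation=np.zeros(n_anim, int),
        )
        vc = fb.estimate_varcomp_reml(
            df, ModelSpec(traits=[TraitModel("LAB", "LAB")]),
            fb.build_A_inverse(ped), conv=1e-12, dense_cutoff=10**6,
        )
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "s.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{csv}")\n'
            "m <- lmer(value ~ 1 + (1|cow_id), data=d, REML=TRUE)\n"
            "vc <- as.data.frame(VarCorr(m))\n"
            'cat(vc$vcov[1], vc$vcov[2], "\\n")\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True
        )
        if out.returncode != 0:
            pytest.skip("Rscript/lme4 unavailable")
        va_r, ve_r = map(float, out.stdout.split())
        assert vc.sigma_a2(0) == pytest.approx(va_r, rel=1e-4)
        assert vc.sigma_e[0] == pytest.approx(ve_r, rel=1e-4)

    def test_convergence_error_carries_estimates(self):
        cfg, ped, pheno = reml_fixture()
        ainv = fb.build_A_inverse(ped)
        spec = ModelSpec(traits=[TraitModel("LAB", "LAB", fixed=("htd",))])
        with pytest.raises(ConvergenceError) as exc:
            fb.estimate_varcomp_reml(pheno, spec, ainv, conv=1e-300, max_rounds=2)
        assert exc.value.components is not None
        assert exc.value.components.sigma_a2(0) > 0
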