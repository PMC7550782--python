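import numpy as np
import pandas as pd
import pytest

import ftirblup as fb
from ftirblup.crossval import SCENARIOS, ScenarioSpec, _training_table
from ftirblup.mixed_models import TraitModel, VarianceComponents


class TestFoldAssignment:
    def test_equal_counts_spread_one_per_fold(self):
        out = fb.assign_sire_folds({1: 5, 2: 5, 3: 5, 4: 5}, seed=0)
        assert sorted(out["fold"]) == [1, 2, 3, 4]

    def test_greedy_hand_trace(self):
        """Counts (8,1,1,1,1,1,1,1,1): the big sire fills one fold, the
        eight singletons spread over the other three (greedy rule)."""
        counts = {10: 8, 11: 1, 12: 1, 13: 1, 14: 1, 15: 1, 16: 1, 17: 1, 18: 1}
        out = fb.assign_sire_folds(counts, seed=1)
        loads = out.groupby("fold")["n_lab_daughters"].sum().sort_values()
        assert loads.max() == 8
        assert sorted(loads) == [2, 3, 3, 8]
        big_fold = out.loc[out.sire_id == 10, "fold"].iloc[0]
        assert not (out.loc[out.sire_id != 10, "fold"] == big_fold).any()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        counts = {i: int(c) for i, c in enumerate(rng.integers(1, 7, size=30))}
        a = fb.assign_sire_folds(counts, seed=9)
        b = fb.assign_sire_folds(counts, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_balance_on_random_small_counts(self):
        """With many small family sizes the greedy loads are near-even."""
        rng = np.random.default_rng(3)
        for rep in range(1000):
            n = int(rng.integers(40, 200))
            counts = dict(enumerate(rng.integers(1, 7, size=n)))
            out = fb.assign_sire_folds(counts, seed=rep)
            loads = out.groupby("fold")["n_lab_daughters"].sum()
            bound = max(2, 0.05 * loads.mean())
            assert loads.max() - loads.min() <= bound

    def test_too_few_sires_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fb.assign_sire_folds({1: 2, 2: 3}, n_folds=4)


class TestGridCovariances:
    def test_default_grid(self):
        pairs = fb.grid_covariances(4.0, 9.0)
        assert len(pairs) == 10
        rs = [r for r, _ in pairs]
        np.testing.assert_allclose(rs, np.arange(0.1, 1.01, 0.1), atol=1e-9)
        for r, g0 in pairs:
            assert np.linalg.eigvalsh(g0).min() > 0  # PD even at r = 1

    def test_half_correlation_covariance(self):
        pairs = dict(fb.grid_covariances(4.0, 9.0, grid=[0.5]))
        assert pairs[0.5][0, 1] == pytest.approx(3.0)

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError):
            fb.grid_covariances(0.0, 1.0)


@pytest.fixture(scope="module")
def cv_bundle():
    cfg = fb.SimConfig(
        n_founders=120, n_generations=2, n_sires_per_gen=16,
        daughters_per_sire_lab=6, daughters_per_sire_field=12,
        n_markers=400, n_wavelengths=10, n_records_per_field_cow=2,
        true_r_a=0.9, seed=3, male_founder_fraction=0.1,
    )
    data = fb.simulate_dataset(cfg)
    ped = data.pedigree
    g, _ = fb.qc_markers(data.genotypes)
    G = fb.build_G(g)
    a22 = fb.build_A22(ped, G.ids)
    ainv = fb.build_A_inverse(ped)
    hinv = fb.build_H_inverse(ainv, G, a22)
    bundle = fb.CVData(
        pheno=data.phenotypes,
        rel_inv=hinv,
        sire_of=dict(zip(ped.animal.tolist(), ped.sire.tolist())),
        lab_trait=TraitModel("LAB", "LAB", fixed=("htd", "dim_class")),
        field_trait=TraitModel(
            "FIELD", "FIELD", fixed=("hys", "stage_parity"), permanent_env=True
        ),
    )
    vc_lab = VarianceComponents(
        trait_names=["LAB"], sigma_a=[[cfg.true_sigma_a2_lab]],
        sigma_e=[cfg.true_sigma_e2_lab], sigma_pe=[0.0],
    )
    vc_fld = VarianceComponents(
        trait_names=["FIELD"], sigma_a=[[cfg.true_sigma_a2_field]],
        sigma_e=[cfg.true_sigma_e2_field], sigma_pe=[cfg.true_sigma_pe2_field],
    )
    return bundle, vc_lab, vc_fld


class TestScenarios:
    def test_validation_lab_records_never_in_training(self, cv_bundle):
        bundle, *_ = cv_bundle
        folds = fb.assign_sire_folds(bundle.lab_daughter_counts(), seed=0)
        for name, scen in SCENARIOS.items():
            for fold in (1, 2, 3, 4):
                val_sires = set(folds.loc[folds.fold == fold, "sire_id"])
                train, val = _training_table(bundle, scen, val_sires)
                lab_train = train[train.cohort == "LAB"]
                assert not set(lab_train.sample_id) & set(val.sample_id)
                # every validation daughter's LAB record is masked
                val_cows = {
                    c for c, s in bundle.sire_of.items() if s in val_sires
                }
                assert not set(lab_train.cow_id) & val_cows

    def test_forbidden_unmasking_detected(self, cv_bundle):
        bundle, vc_lab, vc_fld = cv_bundle
        folds = fb.assign_sire_folds(bundle.lab_daughter_counts(), seed=0)
        bad = ScenarioSpec("LAB.t+LAB.v", lab_t=True, lab_v=True)
        with pytest.raises(fb.LeakageError):
            fb.run_scenario(bundle, bad, folds, 1, None, vc_lab, vc_fld)

    def test_field_v_unmasks_validation_daughters(self, cv_bundle):
        bundle, *_ = cv_bundle
        folds = fb.assign_sire_folds(bundle.lab_daughter_counts(), seed=0)
        val_sires = set(folds.loc[folds.fold == 1, "sire_id"])
        t_only, _ = _training_table(bundle, SCENARIOS["FIELD.t"], val_sires)
        t_all, _ = _training_table(bundle, SCENARIOS["FIELD.t+FIELD.v"], val_sires)
        assert len(t_all) == len(bundle.field_records())
        assert len(t_only) < len(t_all)

    def test_scenario_row_fields(self, cv_bundle):
        bundle, vc_lab, vc_fld = cv_bundle
        folds = fb.assign_sire_folds(bundle.lab_daughter_counts(), seed=0)
        g0 = fb.grid_covariances(vc_lab.sigma_a2(0), vc_fld.sigma_a2(0), grid=[0.9])[0][1]
        row = fb.run_scenario(
            bundle, SCENARIOS["LAB.t+FIELD.t"], folds, 1, g0, vc_lab, vc_fld, r_a=0.9
        )
        assert row["defined"]
        assert -1 <= row["accuracy"] <= 1
        assert row["n_val"] >= 3


class TestRunCV:
    def test_factorial_row_count_and_determinism(self, cv_bundle):
        bundle, vc_lab, vc_fld = cv_bundle
        grid = [0.3, 0.9]
        t1, s1 = fb.run_cv(bundle, vc_lab, vc_fld, grid=grid, seed=5)
        # LAB.t once per fold; 4 grid scenarios x 2 grid values x 4 folds
        assert len(t1) == 4 + 4 * len(grid) * 4
        t2, s2 = fb.run_cv(bundle, vc_lab, vc_fld, grid=grid, seed=5)
        pd.testing.assert_frame_equal(t1, t2)
        # best grid value attains the row maximum
        for _, row in s1.iterrows():
            if row.scenario == "LAB.t":
                continue
            sub = t1[t1.scenario == row.scenario].groupby("r_a")["accuracy"].mean()
            assert row.accuracy == pytest.approx(sub.max())
            assert row.best_r_a == pytest.approx(sub.idxmax())

    def test_noise_free_limit_accuracy_near_one(self):
        """With a noise-free LAB trait, r_a = 1 and all FIELD relatives
        phenotyped, predicting masked LAB records approaches perfection."""
        cfg = fb.SimConfig(
            n_founders=80, n_generations=2, n_sires_per_gen=12,
            daughters_per_sire_lab=6, daughters_per_sire_field=12,
            n_markers=5, n_wavelengths=5, n_records_per_field_cow=4,
            true_r_a=1.0, true_sigma_a2_lab=7.155, true_sigma_a2_field=7.155,
            true_sigma_e2_lab=1e-4, true_sigma_e2_field=1e-4,
            true_sigma_pe2_field=1e-4, sigma2_htd=0.0, sigma2_dim=0.0,
            sigma2_hys=0.0, sigma2_stage=0.0, seed=11,
        )
        data = fb.simulate_dataset(cfg)
        ped = data.pedigree
        ainv = fb.build_A_inverse(ped)
        # noise-free limit: give the LAB cows their own (noise-free) FIELD
        # test-day records, so masked LAB values are recoverable exactly
        pos = {a: i for i, a in enumerate(data.truth.animal_id)}
        extra = []
        sid = int(data.phenotypes["sample_id"].max())
        for a in ped.cohort_ids("LAB"):
            sid += 1
            extra.append(
                dict(sample_id=sid, cow_id=int(a), cohort="FIELD", herd="H000",
                     htd="", parity=1, dim_class="", stage="S00", hys="HYS0000",
                     stage_parity="S00xP1", calving_date="2014-03-01",
                     value=cfg.mean_field + data.truth.tbv_field[pos[a]])
            )
        pheno = pd.concat(
            [data.phenotypes, pd.DataFrame(extra)], ignore_index=True
        )
        bundle = fb.CVData(
            pheno=pheno,
            rel_inv=ainv,
            sire_of=dict(zip(ped.animal.tolist(), ped.sire.tolist())),
            lab_trait=TraitModel("LAB", "LAB"),
            field_trait=TraitModel("FIELD", "FIELD", permanent_env=True),
        )
        vc_lab = VarianceComponents(
            trait_names=["LAB"], sigma_a=[[7.155]], sigma_e=[1e-4], sigma_pe=[0.0]
        )
        vc_fld = VarianceComponents(
            trait_names=["FIELD"], sigma_a=[[7.155]], sigma_e=[1e-4], sigma_pe=[1e-4]
        )
        table, summary = fb.run_cv(
            bundle, vc_lab, vc_fld,
            scenarios=["FIELD.t+FIELD.v"], grid=[1.0], seed=1,
        )
        assert summary["accuracy"].iloc[0] > 0.97

    def test_null_heritability_gives_null_accuracy(self):
        """sigma_a2 -> 0: EBVs carry no signal, accuracy is about zero."""
        cfg = fb.SimConfig(
            n_founders=80, n_generations=2, n_sires_per_gen=12,
            daughters_per_sire_lab=8, daughters_per_sire_field=10,
            n_markers=5, n_wavelengths=5, n_records_per_field_cow=2,
            true_sigma_a2_lab=1e-4, true_sigma_a2_field=1e-4,
            true_r_a=0.9, seed=21,
        )
        data = fb.simulate_dataset(cfg)
        ped = data.pedigree
        ainv = fb.build_A_inverse(ped)
        bundle = fb.CVData(
            pheno=data.phenotypes,
            rel_inv=ainv,
            sire_of=dict(zip(ped.animal.tolist(), ped.sire.tolist())),
            lab_trait=TraitModel("LAB", "LAB", fixed=("htd",)),
            field_trait=TraitModel("FIELD", "FIELD", fixed=("hys",), permanent_env=True),
        )
        vc_lab = VarianceComponents(
            trait_names=["LAB"], sigma_a=[[1e-4]],
            sigma_e=[cfg.true_sigma_e2_lab], sigma_pe=[0.0],
        )
        vc_fld = VarianceComponents(
            trait_names=["FIELD"], sigma_a=[[1e-4]],
            sigma_e=[cfg.true_sigma_e2_field], sigma_pe=[cfg.true_sigma_pe2_field],
        )
        table, summary = fb.run_cv(
            bundle, vc_lab, vc_fld, scenarios=["LAB.t"], grid=[0.9], seed=2
        )
        acc = summary["accuracy"].iloc[0]
        assert np.isnan(acc) or abs(acc) < 0.25
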