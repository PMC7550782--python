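"""Fourfold sire cross-validation over phenotyping scenarios.

Emulates progeny-test evaluation: sires with daughters in both cohorts are
split into four groups balanced on their number of LAB daughters; in each
fold the LAB records of the validation sires' daughters are masked and
predicted by single-step (or pedigree) BLUP under five phenotyping
scenarios, sweeping the assumed LAB-FIELD genetic correlation over a grid.
Predictive ability is the Pearson correlation between the masked LAB
records and the LAB-trait (G)EBVs of the validation daughters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixed_models import (
    ModelSpec,
    TraitModel,
    VarianceComponents,
    build_mme,
    solve_mme,
)
from .relmat import RelationshipMatrix


class LeakageError(RuntimeError):
    """A validation cow's masked LAB record would enter a training system."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Which phenotype sets are unmasked for training.

    ``lab_t``/``field_t``: records of training-sires' daughters;
    ``field_v``: FIELD records of validation-sires' daughters.  LAB records
    of validation daughters are never unmasked (``lab_v`` exists only so the
    forbidden configuration is detectable).
    """

    name: str
    lab_t: bool = False
    field_t: bool = False
    field_v: bool = False
    lab_v: bool = False

    @property
    def single_trait(self) -> bool:
        return self.lab_t and not (self.field_t or self.field_v)


SCENARIOS = {
    s.name: s
    for s in (
        ScenarioSpec("LAB.t", lab_t=True),
        ScenarioSpec("FIELD.t", field_t=True),
        ScenarioSpec("LAB.t+FIELD.t", lab_t=True, field_t=True),
        ScenarioSpec("FIELD.t+FIELD.v", field_t=True, field_v=True),
        ScenarioSpec("LAB.t+FIELD.t+FIELD.v", lab_t=True, field_t=True, field_v=True),
    )
}


def assign_sire_folds(counts, n_folds: int = 4, seed: int = 0) -> pd.DataFrame:
    """Greedy balanced partition of sires into folds by LAB-daughter count.

    Sires are shuffled (seeded), stably sorted by descending daughter
    count, and each is assigned to the currently lightest fold.  Returns a
    table (sire_id, n_lab_daughters, fold) with folds numbered 1..n_folds.
    """
    if isinstance(counts, dict):
        counts = pd.DataFrame(
            {"sire_id": list(counts), "n_lab_daughters": list(counts.values())}
        )
    counts = counts[["sire_id", "n_lab_daughters"]].copy()
    if len(counts) < n_folds:
        raise ValueError(f"need at least {n_folds} sires, got {len(counts)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(counts))
    counts = counts.iloc[perm]
    counts = counts.sort_values("n_lab_daughters", ascending=False, kind="stable")
    loads = np.zeros(n_folds)
    folds = []
    for c in counts["n_lab_daughters"]:
        f = int(np.argmin(loads))
        folds.append(f + 1)
        loads[f] += c
    out = counts.assign(fold=folds).reset_index(drop=True)
    return out


def grid_covariances(
    sigma_a2_lab: float, sigma_a2_field: float, grid=None
) -> list[tuple[float, np.ndarray]]:
    """Bivariate additive covariance matrices over a genetic-correlation grid.

    Defaults to r = 0.1 .. 1.0 in 0.1 steps; r = 1 is nudged to 1 - 1e-6 so
    every matrix stays positive definite.  Returns [(r, G0), ...] with the
    nominal grid value as the key.
    """
    if sigma_a2_lab <= 0 or sigma_a2_field <= 0:
        raise ValueError("additive variances must be positive")
    if grid is None:
        grid = np.round(np.arange(0.1, 1.0001, 0.1), 10)
    out = []
    for r in np.asarray(grid, dtype=float):
        r_eff = np.sign(r) * (1.0 - 1e-6) if abs(r) >= 1.0 else r
        cov = r_eff * np.sqrt(sigma_a2_lab * sigma_a2_field)
        out.append(
            (float(r), np.array([[sigma_a2_lab, cov], [cov, sigma_a2_field]]))
        )
    return out


@dataclass
class CVData:
    """Everything one cross-validation needs: records, kinship, model terms."""

    pheno: pd.DataFrame  # LAB + FIELD records (cohort column)
    rel_inv: RelationshipMatrix  # H^-1 (or A^-1) over all pedigree animals
    sire_of: dict  # cow_id -> sire_id
    lab_trait: TraitModel
    field_trait: TraitModel

    def lab_records(self) -> pd.DataFrame:
        return self.pheno[self.pheno["cohort"] == self.lab_trait.cohort]

    def field_records(self) -> pd.DataFrame:
        return self.pheno[self.pheno["cohort"] == self.field_trait.cohort]

    def lab_daughter_counts(self) -> pd.DataFrame:
        lab = self.lab_records()
        sires = lab["cow_id"].map(self.sire_of)
        tab = sires.value_counts()
        return pd.DataFrame(
            {"sire_id": tab.index.to_numpy(), "n_lab_daughters": tab.to_numpy()}
        )


def _training_table(
    data: CVData, scenario: ScenarioSpec, val_sires: set
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(training records, masked validation LAB records) for one fold."""
    if scenario.lab_v:
        raise LeakageError(
            "scenario would unmask validation cows' own LAB records; "
            "this configuration is forbidden"
        )
    lab = data.lab_records()
    fld = data.field_records()
    lab_sire = lab["cow_id"].map(data.sire_of)
    fld_sire = fld["cow_id"].map(data.sire_of)
    val_lab = lab[lab_sire.isin(val_sires)]

    parts = []
    if scenario.lab_t:
        parts.append(lab[~lab_sire.isin(val_sires)])
    if scenario.field_t and scenario.field_v:
        parts.append(fld)
    elif scenario.field_t:
        parts.append(fld[~fld_sire.isin(val_sires)])
    elif scenario.field_v:
        parts.append(fld[fld_sire.isin(val_sires)])
    train = (
        pd.concat(parts, ignore_index=True)
        if parts
        else data.pheno.iloc[0:0].copy()
    )

    # structural leakage guard: masked LAB records never enter training
    leaked = set(train.loc[train["cohort"] == data.lab_trait.cohort, "sample_id"]) & set(
        val_lab["sample_id"]
    )
    if leaked:
        raise LeakageError(
            f"{len(leaked)} masked validation LAB records present in training data"
        )
    return train, val_lab


def run_scenario(
    data: CVData,
    scenario: ScenarioSpec,
    fold_assignment: pd.DataFrame,
    fold: int,
    g0: np.ndarray,
    vc_lab: VarianceComponents,
    vc_field: VarianceComponents,
    r_a: float = np.nan,
) -> dict:
    """Solve one (scenario, fold, G0) evaluation and score its accuracy.

    Variance components are fixed inputs (single-trait estimates); only the
    additive covariance varies with the grid.  Accuracy is the Pearson
    correlation between raw masked LAB records of validation daughters and
    their LAB-trait (G)EBVs; undefined (NaN) with fewer than 3 validation
    records.
    """
    val_sires = set(
        fold_assignment.loc[fold_assignment["fold"] == fold, "sire_id"]
    )
    train, val_lab = _training_table(data, scenario, val_sires)

    lab_name = data.lab_trait.name
    if scenario.single_trait:
        spec = ModelSpec(traits=[data.lab_trait])
        vc = VarianceComponents(
            trait_names=[lab_name],
            sigma_a=np.array([[vc_lab.sigma_a2(0)]]),
            sigma_e=np.array([vc_lab.sigma_e[0]]),
            sigma_pe=np.array([0.0]),
        )
    else:
        spec = ModelSpec(traits=[data.lab_trait, data.field_trait])
        vc = VarianceComponents(
            trait_names=[lab_name, data.field_trait.name],
            sigma_a=np.asarray(g0, dtype=float),
            sigma_e=np.array([vc_lab.sigma_e[0], vc_field.sigma_e[0]]),
            sigma_pe=np.array([0.0, float(vc_field.sigma_pe[0])]),
        )
    sol = solve_mme(build_mme(train, spec, vc, data.rel_inv))

    y_val = val_lab["value"].to_numpy(dtype=float)
    row = {
        "trait": lab_name,
        "scenario": scenario.name,
        "fold": fold,
        "r_a": r_a,
        "n_val": int(len(val_lab)),
        "n_train": int(len(train)),
    }
    if len(val_lab) < 3:
        row["accuracy"] = np.nan
        row["defined"] = False
        return row
    gebv = sol.ebv_for(lab_name, val_lab["cow_id"].to_numpy())
    if np.std(gebv) == 0 or np.std(y_val) == 0:
        row["accuracy"] = np.nan
        row["defined"] = False
        return row
    row["accuracy"] = float(np.corrcoef(y_val, gebv)[0, 1])
    row["defined"] = True
    return row


def run_cv(
    data: CVData,
    vc_lab: VarianceComponents,
    vc_field: VarianceComponents,
    scenarios=None,
    grid=None,
    n_folds: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full factorial scenario x fold x grid cross-validation.

    The fold assignment is fixed across scenarios and grid values.  The
    single-trait LAB.t scenario bypasses the grid.  Returns (long table,
    summary) where the summary holds, per scenario, the fold-mean accuracy
    at its best-performing grid value.
    """
    if scenarios is None:
        scenarios = list(SCENARIOS.values())
    scenarios = [SCENARIOS[s] if isinstance(s, str) else s for s in scenarios]
    folds_tab = assign_sire_folds(data.lab_daughter_counts(), n_folds=n_folds, seed=seed)
    pairs = grid_covariances(
        vc_lab.sigma_a2(0), vc_field.sigma_a2(0), grid=grid
    )

    rows = []
    for scen in scenarios:
        for fold in range(1, n_folds + 1):
            if scen.single_trait:
                rows.append(
                    run_scenario(
                        data, scen, folds_tab, fold, None, vc_lab, vc_field
                    )
                )
            else:
                for r, g0 in pairs:
                    rows.append(
                        run_scenario(
                            data, scen, folds_tab, fold, g0, vc_lab, vc_field, r_a=r
                        )
                    )
    table = pd.DataFrame(rows)

    summaries = []
    for scen in scenarios:
        sub = table[table["scenario"] == scen.name]
        if scen.single_trait:
            summaries.append(
                {
                    "trait": data.lab_trait.name,
                    "scenario": scen.name,
                    "best_r_a": np.nan,
                    "accuracy": float(sub["accuracy"].mean()),
                }
            )
        else:
            by_r = sub.groupby("r_a")["accuracy"].mean()
            best = by_r.idxmax()
            summaries.append(
                {
                    "trait": data.lab_trait.name,
                    "scenario": scen.name,
                    "best_r_a": float(best),
                    "accuracy": float(by_r.loc[best]),
                }
            )
    return table, pd.DataFrame(summaries)
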