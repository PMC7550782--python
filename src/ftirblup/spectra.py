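"""Spectral and phenotype editing.

Within-group standardization of FTIR absorbance spectra, Mahalanobis
outlier detection on principal-component scores, removal of FIELD records
for cows already in the LAB cohort (so the two cohorts connect only
through the pedigree), and 3-SD phenotype screens (raw values for the
single-record LAB cohort, mixed-model residuals for the repeated-record
FIELD cohort).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .simulate import SpectraMatrix


def standardize_spectra(spectra: SpectraMatrix) -> SpectraMatrix:
    """Center and scale every wavelength within each year-period group.

    After the transform each wavelength column has zero mean and unit
    sample variance (ddof=1) inside every group.  A constant column within
    a group is an error (it cannot be scaled).
    """
    X = np.array(spectra.absorbance, dtype=float, copy=True)
    groups = np.asarray(spectra.year_period)
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) < 2:
            raise ValueError(f"year period {g!r} has fewer than 2 samples")
        block = X[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                f"constant absorbance at wavelength index {int(zero[0])} "
                f"within year period {g!r}"
            )
        X[idx] = (block - mu) / sd
    return replace(spectra, absorbance=X)


def detect_spectral_outliers(
    spectra: SpectraMatrix, n_pcs: int = 5, alpha: float = 0.01
) -> pd.DataFrame:
    """Mahalanobis screen on the first principal-component scores.

    PCA is computed on the (already standardized) spectra; each sample's
    squared Mahalanobis distance of its first ``n_pcs`` scores from the
    score centroid is referred to the upper tail of a chi-square with
    ``n_pcs`` degrees of freedom.  Samples with p < alpha are flagged.
    """
    X = np.asarray(spectra.absorbance, dtype=float)
    n = X.shape[0]
    if n <= n_pcs:
        raise ValueError(f"need more than n_pcs={n_pcs} samples, got {n}")
    Xc = X - X.mean(axis=0)
    # scores = U S from the thin SVD; their covariance is diagonal
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    scores -= scores.mean(axis=0)
    var = (s[:n_pcs] ** 2) / (n - 1)
    if np.any(var <= 0):
        raise ValueError("degenerate principal components: zero score variance")
    d2 = np.sum(scores**2 / var, axis=1)
    p = chi2.sf(d2, df=n_pcs)
    return pd.DataFrame(
        {
            "sample_id": spectra.sample_id,
            "mahalanobis_d2": d2,
            "p_value": p,
            "flagged": p < alpha,
        }
    )


def drop_flagged_samples(spectra: SpectraMatrix, report: pd.DataFrame) -> SpectraMatrix:
    """Remove the samples flagged by ``detect_spectral_outliers``."""
    keep_ids = set(report.loc[~report["flagged"], "sample_id"])
    mask = np.array([sid in keep_ids for sid in spectra.sample_id])
    return SpectraMatrix(
        sample_id=np.asarray(spectra.sample_id)[mask],
        cow_id=np.asarray(spectra.cow_id)[mask],
        year_period=np.asarray(spectra.year_period)[mask],
        absorbance=np.asarray(spectra.absorbance)[mask],
    )


def filter_field_records(
    field: pd.DataFrame,
    lab: pd.DataFrame,
    pedigree_ids=None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Record-level FIELD filters.

    Removes (i) FIELD records of any cow that also has a LAB record, so the
    cohorts connect only through the additive genetic effect; (ii) records
    with missing parity, calving date or animal id; (iii) records whose cow
    is absent from the pedigree (if ``pedigree_ids`` is given).  Returns
    the filtered table and per-rule removal counts.
    """
    out = field.copy()
    counts: dict[str, int] = {}

    lab_cows = set(lab["cow_id"].dropna()) if len(lab) else set()
    overlap = out["cow_id"].isin(lab_cows)
    counts["lab_overlap"] = int(overlap.sum())
    out = out[~overlap]

    def missing(col: str) -> pd.Series:
        if col not in out.columns:
            return pd.Series(False, index=out.index)
        s = out[col]
        return s.isna() | (s.astype(str).str.strip() == "")

    miss_parity = missing("parity")
    counts["missing_parity"] = int(miss_parity.sum())
    out = out[~miss_parity]

    miss_date = missing("calving_date")
    counts["missing_calving_date"] = int(miss_date.sum())
    out = out[~miss_date]

    miss_id = out["cow_id"].isna()
    counts["missing_id"] = int(miss_id.sum())
    out = out[~miss_id]

    if pedigree_ids is not None:
        known = set(np.asarray(pedigree_ids).tolist())
        no_ped = ~out["cow_id"].isin(known)
        counts["missing_pedigree"] = int(no_ped.sum())
        out = out[~no_ped]
    else:
        counts["missing_pedigree"] = 0

    counts["kept"] = int(len(out))
    return out.reset_index(drop=True), counts


def detect_phenotype_outliers(
    pheno: pd.DataFrame,
    cohort: str,
    k_sd: float = 3.0,
    value_col: str = "value",
    model_spec=None,
    vc=None,
    rel_inv=None,
) -> tuple[pd.DataFrame, int]:
    """3-SD phenotype screen; returns (filtered table, n removed).

    LAB records are screened on the raw trait deviation from its mean;
    FIELD records on residuals of the repeatability animal model (fitted
    via :mod:`ftirblup.mixed_models` with the supplied model spec, variance
    components and relationship inverse).  ``k_sd=inf`` is a no-op.
    """
    sub = pheno[pheno["cohort"] == cohort] if "cohort" in pheno.columns else pheno
    rest = pheno.drop(index=sub.index)
    if len(sub) == 0 or not np.isfinite(k_sd):
        return pheno.copy(), 0

    if cohort == "LAB" or model_spec is None:
        y = sub[value_col].to_numpy(dtype=float)
        dev = y - y.mean()
        sd = dev.std(ddof=1) if len(dev) > 1 else 0.0
        flag = np.abs(dev) > k_sd * sd if sd > 0 else np.zeros(len(dev), bool)
    else:
        from .mixed_models import build_mme, solve_mme

        sys_ = build_mme(sub, model_spec, vc, rel_inv)
        sol = solve_mme(sys_)
        resid = sol.residuals[sys_.spec.traits[0].name]
        sd = resid.std(ddof=1)
        flag = np.abs(resid - resid.mean()) > k_sd * sd if sd > 0 else np.zeros(len(resid), bool)

    kept = pd.concat([rest, sub.iloc[~flag]]).sort_index().reset_index(drop=True)
    return kept, int(flag.sum())
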