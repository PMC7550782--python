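"""Plain-text readers/writers for the package's tables and models."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .calibration import CalibrationModel
from .relmat import GenotypeMatrix, RelationshipMatrix
from .simulate import Pedigree, SimConfig, SimData, SpectraMatrix, TrueValues


def load_sim_config(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return SimConfig(**raw)


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_frame().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path)
    kw = {}
    for opt in ("sex", "cohort", "genotyped"):
        if opt in df.columns:
            kw[opt] = df[opt].fillna("").to_numpy()
    if "genotyped" in kw:
        kw["genotyped"] = df["genotyped"].astype(bool).to_numpy()
    return Pedigree(
        animal=df["animal"].to_numpy(np.int64),
        sire=df["sire"].to_numpy(np.int64),
        dam=df["dam"].to_numpy(np.int64),
        generation=df["generation"].to_numpy(np.int64),
        **kw,
    )


def write_genotypes(g: GenotypeMatrix, path, info_path=None) -> None:
    df = pd.DataFrame(g.dosage, columns=g.marker_ids)
    df.insert(0, "animal_id", g.animal_ids)
    df.to_csv(path, index=False)
    if info_path is not None:
        g.marker_info.assign(marker_id=g.marker_ids).to_csv(info_path, index=False)


def read_genotypes(path, info_path=None) -> GenotypeMatrix:
    df = pd.read_csv(path)
    marker_ids = np.array([c for c in df.columns if c != "animal_id"])
    info = pd.read_csv(info_path) if info_path else pd.DataFrame()
    return GenotypeMatrix(
        animal_ids=df["animal_id"].to_numpy(),
        marker_ids=marker_ids,
        dosage=df[marker_ids].to_numpy(np.int8),
        marker_info=info,
    )


def write_spectra(s: SpectraMatrix, path) -> None:
    s.to_frame().to_csv(path, index=False)


def read_spectra(path) -> SpectraMatrix:
    df = pd.read_csv(path)
    wcols = [c for c in df.columns if c.startswith("w") and c[1:].isdigit()]
    return SpectraMatrix(
        sample_id=df["sample_id"].to_numpy(),
        cow_id=df["cow_id"].to_numpy(),
        year_period=df["year_period"].to_numpy(object),
        absorbance=df[wcols].to_numpy(float),
    )


def write_truth(tv: TrueValues, path) -> None:
    tv.to_frame().to_csv(path, index=False)


def write_dataset(data: SimData, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_pedigree(data.pedigree, out / "pedigree.csv")
    write_genotypes(data.genotypes, out / "genotypes.csv", out / "markers.csv")
    write_spectra(data.spectra, out / "spectra.csv")
    data.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    write_truth(data.truth, out / "truth.csv")


def save_calibration_model(model: CalibrationModel, path) -> None:
    """Persist a calibration equation as a portable JSON archive."""
    payload = {
        "trait_id": model.trait_id,
        "intercept": model.intercept,
        "effects": model.effects.tolist(),
        "inclusion_prob": model.inclusion_prob.tolist(),
        "posterior_mean_sigma_e2": model.posterior_mean_sigma_e2,
        "posterior_mean_pi": model.posterior_mean_pi,
        "mcmc_meta": model.mcmc_meta,
        "n_wavelengths": model.n_wavelengths,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_calibration_model(path) -> CalibrationModel:
    with open(path) as fh:
        payload = json.load(fh)
    return CalibrationModel(
        trait_id=payload["trait_id"],
        intercept=payload["intercept"],
        effects=np.asarray(payload["effects"]),
        inclusion_prob=np.asarray(payload["inclusion_prob"]),
        posterior_mean_sigma_e2=payload["posterior_mean_sigma_e2"],
        posterior_mean_pi=payload["posterior_mean_pi"],
        mcmc_meta=payload["mcmc_meta"],
    )


def write_relmat_triplets(rm: RelationshipMatrix, path) -> None:
    """Plain-text (i, j, value) export (upper triangle, 1-based positions)."""
    v = rm.values
    if sp.issparse(v):
        coo = sp.triu(v).tocoo()
        df = pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data})
    else:
        iu = np.triu_indices(v.shape[0])
        df = pd.DataFrame({"i": iu[0] + 1, "j": iu[1] + 1, "value": np.asarray(v)[iu]})
    df.to_csv(path, index=False)
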