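"""Synthetic milk-recording data with a sire-daughter two-cohort design.

Generates a multi-generation pedigree in which a pool of sires has
daughters in both a small, single-record "LAB" cohort (gold-standard
wet-lab phenotypes such as rennet coagulation time) and a larger,
repeated-record "FIELD" cohort (routine test-day milk samples).  SNP
genotypes come from Mendelian gene dropping, true breeding values for the
two traits from a bivariate infinitesimal model with configurable additive
correlation, and each milk sample carries an FTIR-like absorbance spectrum
whose wavelengths encode the sample's trait value at a configurable
signal-to-noise level.

Everything downstream of the simulator (spectral editing, calibration,
variance-component estimation, single-step cross-validation) is exercised
against these data, so the generator is first-class, tested code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .relmat import GenotypeMatrix, inbreeding_coefficients

N_WAVELENGTHS = 1060  # MilkoScan FT6000 grid: 5,010 to 925 cm^-1


@dataclass
class SimConfig:
    """Study-design and genetic-architecture knobs for the simulator.

    Default variances are the rennet-coagulation-time scale: LAB additive
    7.155 and residual 14.967 (min^2), FIELD additive 5.911, permanent
    environment 2.091 and residual 8.901.  The default additive correlation
    between the LAB trait and its spectral FIELD counterpart is 0.9, and
    the default spectral signal strength corresponds to a calibration
    correlation of about 0.86 (r^2 = 0.736).
    """

    n_founders: int = 120
    n_generations: int = 2
    n_sires_per_gen: int = 25
    daughters_per_sire_lab: int = 4
    daughters_per_sire_field: int = 12
    n_markers: int = 1000
    n_wavelengths: int = N_WAVELENGTHS
    true_sigma_a2_lab: float = 7.155
    true_sigma_a2_field: float = 5.911
    true_r_a: float = 0.9
    true_sigma_pe2_field: float = 2.091
    true_sigma_e2_lab: float = 14.967
    true_sigma_e2_field: float = 8.901
    n_herds: int = 20
    n_records_per_field_cow: int = 6
    calibration_signal_r2: float = 0.736
    seed: int = 20100929

    # fixed-effect dispersion (non-genetic structure; see docs/methods.md)
    mean_lab: float = 19.8
    mean_field: float = 20.0
    sigma2_htd: float = 2.0
    sigma2_dim: float = 1.0
    sigma2_hys: float = 2.0
    sigma2_stage: float = 1.0
    n_year_periods: int = 4
    n_active_wavelengths: int = 20
    # genotyping design: all sires and all LAB cows are genotyped, plus this
    # fraction of FIELD cows (default mirrors the ~1:1.45 LAB:FIELD ratio of
    # genotyped cows at the default cohort sizes)
    field_genotyped_fraction: float = 0.48
    genotype_missing_rate: float = 0.0
    male_founder_fraction: float = 0.25
    # routine milk recording covers cows of every generation, so
    # intermediate-generation females carry FIELD records too (the real
    # FIELD tier spans many generations and supplies the dams of later cows)
    field_cows_in_earlier_generations: bool = True

    def __post_init__(self) -> None:
        for name in ("true_sigma_a2_lab", "true_sigma_a2_field"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        # residual / permanent-environment variances may be zero (noise-free
        # limits are useful for exactness tests) but never negative
        for name in ("true_sigma_pe2_field", "true_sigma_e2_lab", "true_sigma_e2_field"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.true_r_a) > 1:
            raise ValueError("|true_r_a| must be <= 1")
        if not 0 <= self.calibration_signal_r2 < 1:
            raise ValueError("calibration_signal_r2 must be in [0, 1)")
        for name in (
            "n_founders",
            "n_sires_per_gen",
            "daughters_per_sire_lab",
            "daughters_per_sire_field",
            "n_markers",
            "n_wavelengths",
            "n_herds",
            "n_records_per_field_cow",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")

    def g0(self) -> np.ndarray:
        """True additive covariance matrix (LAB, FIELD)."""
        sa1 = np.sqrt(self.true_sigma_a2_lab)
        sa2 = np.sqrt(self.true_sigma_a2_field)
        cov = self.true_r_a * sa1 * sa2
        return np.array(
            [[self.true_sigma_a2_lab, cov], [cov, self.true_sigma_a2_field]]
        )


@dataclass
class Pedigree:
    """Ordered animal/sire/dam triples; 0 marks an unknown parent.

    Animals are numbered 1..n with parents preceding offspring.  ``sex``
    ('M'/'F'), ``cohort`` ('LAB'/'FIELD'/'' for unphenotyped) and the
    ``genotyped`` flag carry the study design.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    generation: np.ndarray
    sex: np.ndarray = None
    cohort: np.ndarray = None
    genotyped: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.animal)
        if self.sex is None:
            self.sex = np.full(n, "F")
        if self.cohort is None:
            self.cohort = np.full(n, "", dtype=object)
        if self.genotyped is None:
            self.genotyped = np.zeros(n, dtype=bool)
        if np.any(np.asarray(self.animal) <= 0):
            raise ValueError("animal ids must be positive")
        seen = set()
        for a, s, d in zip(self.animal, self.sire, self.dam):
            for p in (s, d):
                if p != 0 and p not in seen:
                    raise ValueError(
                        f"parent {p} of animal {a} missing or not preceding it"
                    )
            seen.add(a)

    @property
    def n(self) -> int:
        return len(self.animal)

    def ids_where(self, mask: np.ndarray) -> np.ndarray:
        return np.asarray(self.animal)[mask]

    def cohort_ids(self, cohort: str) -> np.ndarray:
        return self.ids_where(np.asarray(self.cohort) == cohort)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "sire": self.sire,
                "dam": self.dam,
                "generation": self.generation,
                "sex": self.sex,
                "cohort": self.cohort,
                "genotyped": self.genotyped,
            }
        )


@dataclass
class TrueValues:
    """True breeding values and permanent-environment effects per animal."""

    animal_id: np.ndarray
    tbv_lab: np.ndarray
    tbv_field: np.ndarray
    pe_field: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "tbv_lab": self.tbv_lab,
                "tbv_field": self.tbv_field,
                "pe_field": self.pe_field,
            }
        )


@dataclass
class SpectraMatrix:
    """Milk-sample FTIR spectra: samples x wavelengths absorbance values."""

    sample_id: np.ndarray
    cow_id: np.ndarray
    year_period: np.ndarray
    absorbance: np.ndarray  # (n_samples, n_wavelengths)

    def __post_init__(self) -> None:
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be 2-D (samples x wavelengths)")
        if not np.isfinite(self.absorbance).all():
            raise ValueError("missing/non-finite absorbance values")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"w{j + 1:04d}" for j in range(self.n_wavelengths)]
        df = pd.DataFrame(self.absorbance, columns=cols)
        df.insert(0, "year_period", self.year_period)
        df.insert(0, "cow_id", self.cow_id)
        df.insert(0, "sample_id", self.sample_id)
        return df


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Founders plus generations of sire-family offspring.

    Intermediate generations keep the population at roughly founder size;
    the final generation expands into the phenotyped LAB and FIELD daughter
    cohorts, with every sire of that generation contributing daughters to
    both cohorts (the connection that identifies the LAB-FIELD genetic
    correlation).
    """
    rng = np.random.default_rng(config.seed)
    animal, sire, dam, gen, sex = [], [], [], [], []
    # a small male founder pool clusters later sires into half-sib families,
    # the hallmark of dairy bull pedigrees; generations with fewer available
    # males than n_sires_per_gen simply use every male
    n_male = max(int(round(config.n_founders * config.male_founder_fraction)), 1)
    if config.n_generations > 0 and n_male >= config.n_founders:
        n_male = config.n_founders - 1
    for i in range(config.n_founders):
        animal.append(i + 1)
        sire.append(0)
        dam.append(0)
        gen.append(0)
        sex.append("M" if i < n_male else "F")
    cohort = [""] * config.n_founders
    next_id = config.n_founders + 1

    def pick_sires(g: int) -> np.ndarray:
        males = [a for a, gg, sx in zip(animal, gen, sex) if sx == "M" and gg < g]
        males = np.asarray(males)
        k = min(config.n_sires_per_gen, len(males))
        if k == 0:
            raise ValueError("no male candidates available for sires")
        return rng.choice(males, size=k, replace=False)

    for g in range(1, config.n_generations + 1):
        sires_g = pick_sires(g)
        females = np.asarray(
            [a for a, gg, sx in zip(animal, gen, sex) if sx == "F" and gg < g]
        )
        if len(females) == 0:
            raise ValueError("no female candidates available for dams")
        final = g == config.n_generations
        for s in sires_g:
            if final:
                plan = [("LAB", "F")] * config.daughters_per_sire_lab + [
                    ("FIELD", "F")
                ] * config.daughters_per_sire_field
            else:
                # intermediate-generation females are routine-recorded FIELD
                # cows (the FIELD tier spans generations); many later serve
                # as dams, so validation daughters have recorded dams
                brood = max(2, int(np.ceil(config.n_founders / len(sires_g))))
                coh = "FIELD" if config.field_cows_in_earlier_generations else ""
                plan = [
                    ("" if k < max(1, brood // 4) else coh,
                     "M" if k < max(1, brood // 4) else "F")
                    for k in range(brood)
                ]
            dams_s = rng.choice(females, size=len(plan), replace=True)
            for (coh, sx), d in zip(plan, dams_s):
                animal.append(next_id)
                sire.append(int(s))
                dam.append(int(d))
                gen.append(g)
                sex.append(sx)
                cohort.append(coh)
                next_id += 1

    ped = Pedigree(
        animal=np.asarray(animal, dtype=np.int64),
        sire=np.asarray(sire, dtype=np.int64),
        dam=np.asarray(dam, dtype=np.int64),
        generation=np.asarray(gen, dtype=np.int64),
        sex=np.asarray(sex, dtype=object),
        cohort=np.asarray(cohort, dtype=object),
    )
    # genotyping design: all final-generation sires, all LAB cows, and a
    # seeded fraction of FIELD cows
    genotyped = np.zeros(ped.n, dtype=bool)
    is_parent_sire = np.isin(ped.animal, np.unique(ped.sire[ped.sire > 0]))
    genotyped |= is_parent_sire
    genotyped |= np.asarray(ped.cohort) == "LAB"
    field_mask = np.asarray(ped.cohort) == "FIELD"
    field_idx = np.flatnonzero(field_mask)
    k = int(round(config.field_genotyped_fraction * len(field_idx)))
    if k > 0:
        genotyped[rng.choice(field_idx, size=min(k, len(field_idx)), replace=False)] = True
    ped.genotyped = genotyped
    return ped


# ---------------------------------------------------------------------------
# genotypes (gene dropping)
# ---------------------------------------------------------------------------


def simulate_genotypes(ped: Pedigree, config: SimConfig) -> GenotypeMatrix:
    """Mendelian gene dropping over the pedigree, unlinked biallelic markers.

    Founder allele frequencies are drawn Uniform(0.05, 0.5) per marker;
    each offspring inherits one random allele per parent per marker.  Only
    the animals flagged ``genotyped`` appear in the returned matrix.
    """
    if ped.n == 0:
        raise ValueError("empty pedigree")
    rng = np.random.default_rng(config.seed + 1)
    m = config.n_markers
    freq = rng.uniform(0.05, 0.5, size=m)

    pos = {a: i for i, a in enumerate(ped.animal)}
    haps = np.zeros((ped.n, 2, m), dtype=np.int8)
    cols = np.arange(m)
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        for k, p in enumerate((s, d)):
            if p == 0:
                haps[i, k] = rng.random(m) < freq
            else:
                pick = rng.integers(0, 2, size=m)
                haps[i, k] = haps[pos[p], pick, cols]

    gidx = np.flatnonzero(ped.genotyped)
    dosage = haps[gidx].sum(axis=1).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random(dosage.shape) < config.genotype_missing_rate
        dosage[miss] = -1

    chrom = (np.arange(m) % 29 + 1).astype(str)
    info = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(m) // 29 + 1) * 50_000,
            "founder_freq": freq,
        }
    )
    return GenotypeMatrix(
        animal_ids=ped.animal[gidx],
        marker_ids=np.array([f"snp{j + 1:05d}" for j in range(m)]),
        dosage=dosage,
        marker_info=info,
    )


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------


def simulate_breeding_values(ped: Pedigree, config: SimConfig) -> TrueValues:
    """Bivariate infinitesimal model over the pedigree.

    Founders draw (tbv_lab, tbv_field) from N(0, G0); descendants follow
    tbv = (tbv_sire + tbv_dam)/2 + m, with the Mendelian term m drawn from
    N(0, 0.5 * (1 - (F_s + F_d)/2) * G0) using parental inbreeding F.
    """
    g0 = config.g0()
    try:
        L = np.linalg.cholesky(g0 if abs(config.true_r_a) < 1 else g0 + 1e-12 * np.eye(2))
    except np.linalg.LinAlgError as exc:
        raise ValueError("additive covariance matrix G0 is not positive definite") from exc
    rng = np.random.default_rng(config.seed + 2)
    F = inbreeding_coefficients(ped)
    pos = {a: i for i, a in enumerate(ped.animal)}
    tbv = np.zeros((ped.n, 2))
    for i in range(ped.n):
        s, d = ped.sire[i], ped.dam[i]
        z = L @ rng.standard_normal(2)
        if s == 0 and d == 0:
            tbv[i] = z
        else:
            fs = F[pos[s]] if s else 0.0
            fd = F[pos[d]] if d else 0.0
            pa = np.zeros(2)
            nk = 0
            for p in (s, d):
                if p:
                    pa += tbv[pos[p]]
                    nk += 1
            scale = np.sqrt(0.5 * (1.0 - 0.5 * (fs + fd)))
            tbv[i] = pa / 2.0 + scale * z
    pe = rng.normal(0.0, np.sqrt(config.true_sigma_pe2_field), size=ped.n)
    return TrueValues(
        animal_id=ped.animal.copy(),
        tbv_lab=tbv[:, 0],
        tbv_field=tbv[:, 1],
        pe_field=pe,
    )


# ---------------------------------------------------------------------------
# spectra and phenotypes
# ---------------------------------------------------------------------------


def simulate_spectra_and_phenotypes(
    ped: Pedigree, tv: TrueValues, config: SimConfig
) -> tuple[SpectraMatrix, pd.DataFrame]:
    """Milk records for both cohorts plus one spectrum per milk sample.

    LAB cows get one record y = mean + herd-test-day + DIM-class + tbv + e;
    FIELD cows get repeated test-day records y = mean + herd-year-season +
    stage + tbv + pe + e.  Each sample's spectrum places the standardized
    record value on ``n_active_wavelengths`` wavelengths with total loading
    norm chosen so the best linear spectral predictor of the record has
    R^2 = ``calibration_signal_r2``; all other variation is independent
    unit-variance wavelength noise.
    """
    if config.calibration_signal_r2 >= 1:
        raise ValueError("calibration_signal_r2 must be < 1")
    rng = np.random.default_rng(config.seed + 3)
    pos = {a: i for i, a in enumerate(ped.animal)}

    lab_ids = ped.cohort_ids("LAB")
    field_ids = ped.cohort_ids("FIELD")
    missing = [a for a in np.concatenate([lab_ids, field_ids]) if a not in set(tv.animal_id)]
    if missing:
        raise ValueError("TrueValues must cover all phenotyped animals")

    htd_eff = rng.normal(0, np.sqrt(config.sigma2_htd), size=config.n_herds)
    dim_eff = rng.normal(0, np.sqrt(config.sigma2_dim), size=60)
    n_hys = config.n_herds * 4  # herd x year-season combinations
    hys_eff = rng.normal(0, np.sqrt(config.sigma2_hys), size=n_hys)
    stage_eff = rng.normal(0, np.sqrt(config.sigma2_stage), size=12)

    rows = []
    sample_id = 0
    for a in lab_ids:
        i = pos[a]
        herd = int(rng.integers(config.n_herds))
        dim_class = int(rng.integers(60))
        parity = int(rng.integers(1, 6))
        y = (
            config.mean_lab
            + htd_eff[herd]
            + dim_eff[dim_class]
            + tv.tbv_lab[i]
            + rng.normal(0, np.sqrt(config.true_sigma_e2_lab))
        )
        sample_id += 1
        rows.append(
            dict(
                sample_id=sample_id,
                cow_id=int(a),
                cohort="LAB",
                herd=f"H{herd:03d}",
                htd=f"HTD{herd:03d}",
                parity=parity,
                dim_class=f"D{dim_class:02d}",
                stage="",
                hys="",
                stage_parity="",
                calving_date="2014-03-01",
                value=y,
            )
        )
    for a in field_ids:
        i = pos[a]
        herd = int(rng.integers(config.n_herds))
        parity = int(rng.integers(1, 6))
        pe = tv.pe_field[i]
        for _ in range(config.n_records_per_field_cow):
            stage = int(rng.integers(12))
            ys = int(rng.integers(4))
            hys = herd * 4 + ys
            y = (
                config.mean_field
                + hys_eff[hys]
                + stage_eff[stage]
                + tv.tbv_field[i]
                + pe
                + rng.normal(0, np.sqrt(config.true_sigma_e2_field))
            )
            sample_id += 1
            rows.append(
                dict(
                    sample_id=sample_id,
                    cow_id=int(a),
                    cohort="FIELD",
                    herd=f"H{herd:03d}",
                    htd="",
                    parity=parity,
                    dim_class="",
                    stage=f"S{stage:02d}",
                    hys=f"HYS{hys:04d}",
                    stage_parity=f"S{stage:02d}xP{parity}",
                    calving_date="2014-03-01",
                    value=y,
                )
            )
    pheno = pd.DataFrame(rows)

    # spectra: standardized record value drives a sparse loading vector
    y_all = pheno["value"].to_numpy()
    sd = y_all.std()
    latent = (y_all - y_all.mean()) / (sd if sd > 0 else 1.0)
    r2 = config.calibration_signal_r2
    nw, na = config.n_wavelengths, min(config.n_active_wavelengths, config.n_wavelengths)
    active = rng.choice(nw, size=na, replace=False)
    b = rng.standard_normal(na)
    if r2 > 0:
        b *= np.sqrt(r2 / (1.0 - r2)) / np.linalg.norm(b)
    else:
        b[:] = 0.0
    X = rng.standard_normal((len(pheno), nw))
    X[:, active] += np.outer(latent, b)

    spectra = SpectraMatrix(
        sample_id=pheno["sample_id"].to_numpy(),
        cow_id=pheno["cow_id"].to_numpy(),
        year_period=np.array(
            [f"YP{i % config.n_year_periods}" for i in range(len(pheno))], dtype=object
        ),
        absorbance=X,
    )
    return spectra, pheno


@dataclass
class SimData:
    """Bundle of one simulated study: pedigree, genotypes, truth, records."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    truth: TrueValues
    spectra: SpectraMatrix
    phenotypes: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimData:
    """Run the whole generator under one configuration."""
    ped = simulate_pedigree(config)
    geno = simulate_genotypes(ped, config)
    tv = simulate_breeding_values(ped, config)
    spectra, pheno = simulate_spectra_and_phenotypes(ped, tv, config)
    return SimData(
        config=config,
        pedigree=ped,
        genotypes=geno,
        truth=tv,
        spectra=spectra,
        phenotypes=pheno,
    )
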