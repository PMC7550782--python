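"""Pedigree, genomic and combined relationship matrices.

Builds the numerator relationship matrix A (tabular method, with
inbreeding), its sparse inverse (Henderson's rules with Meuwissen-Luo
inbreeding coefficients), the VanRaden genomic relationship matrix G from
SNP dosages, and the single-step H-inverse that augments A-inverse with a
genotyped-block correction.  Marker quality control (call rate, MAF,
Hardy-Weinberg, chromosome filters) lives here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from numba import njit
from scipy.stats import chi2


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix together with its animal index.

    ``values`` is a dense ndarray or a scipy sparse matrix; ``kind`` is one
    of ``{"A", "A_inverse", "A22", "G", "H_inverse"}``.
    """

    ids: np.ndarray
    values: object
    kind: str

    def to_dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    @property
    def n(self) -> int:
        return len(self.ids)

    def position_of(self, ids) -> np.ndarray:
        """Positions of ``ids`` within this matrix's index."""
        lookup = {a: i for i, a in enumerate(self.ids)}
        try:
            return np.array([lookup[a] for a in np.atleast_1d(ids)], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"animal {exc.args[0]} not in relationship index") from None


@dataclass
class GenotypeMatrix:
    """Animals x markers allele dosages with per-marker metadata.

    Dosages are 0/1/2 counts of the reference allele; ``-1`` marks a
    missing call.  ``marker_info`` carries one row per marker with at least
    ``chrom`` (string label, autosomes "1".."29", "X"/"Y" for sex
    chromosomes, "0" unknown) and ``pos`` (bp, 0 = unknown).
    """

    animal_ids: np.ndarray
    marker_ids: np.ndarray
    dosage: np.ndarray  # (n_animals, n_markers), int8, -1 missing
    marker_info: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        bad = ~np.isin(self.dosage, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 for missing")
        if self.dosage.shape != (len(self.animal_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match id vectors")

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)


# ---------------------------------------------------------------------------
# pedigree utilities
# ---------------------------------------------------------------------------


def _parent_arrays(ped) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """0-based (animal order) sire/dam position arrays, -1 for unknown.

    Requires the pedigree to be sorted parents-first (every parent appears
    earlier than its offspring), which is validated here.
    """
    animal = np.asarray(ped.animal, dtype=np.int64)
    sire = np.asarray(ped.sire, dtype=np.int64)
    dam = np.asarray(ped.dam, dtype=np.int64)
    pos = {a: i for i, a in enumerate(animal)}
    if len(pos) != len(animal):
        raise ValueError("duplicate animal ids in pedigree")

    def locate(parents: np.ndarray) -> np.ndarray:
        out = np.full(len(animal), -1, dtype=np.int64)
        for i, p in enumerate(parents):
            if p == 0:
                continue
            j = pos.get(p)
            if j is None:
                raise ValueError(f"parent {p} of animal {animal[i]} not in pedigree")
            if j >= i:
                raise ValueError(
                    f"pedigree not sorted parents-first: parent {p} does not "
                    f"precede animal {animal[i]}"
                )
            out[i] = j
        return out

    return animal, locate(sire), locate(dam)


@njit(cache=True)
def _inbreeding_ml(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Meuwissen & Luo inbreeding coefficients for a parents-first pedigree."""
    n = sire.size
    F = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        # accumulate generalized Cholesky row for animal i
        L[: i + 1] = 0.0
        L[i] = 1.0
        fi = -1.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            sj, dj = sire[j], dam[j]
            fs = F[sj] if sj >= 0 else -1.0
            fd = F[dj] if dj >= 0 else -1.0
            dvar = 0.5 - 0.25 * (fs + fd)
            if sj >= 0:
                L[sj] += 0.5 * lj
            if dj >= 0:
                L[dj] += 0.5 * lj
            fi += lj * lj * dvar
        F[i] = fi
    return F


def inbreeding_coefficients(ped) -> np.ndarray:
    """Inbreeding coefficient F per animal, pedigree order."""
    _, sire, dam = _parent_arrays(ped)
    if sire.size == 0:
        return np.zeros(0)
    return _inbreeding_ml(sire, dam)


def build_A(ped) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Dense output; intended for pedigrees up to a few thousand animals
    (memory grows as n^2).
    """
    animal, sire, dam = _parent_arrays(ped)
    n = len(animal)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            if i > 0:
                row = 0.5 * (A[s, :i] + A[d, :i])
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            if i > 0:
                row = 0.5 * A[p, :i]
                A[i, :i] = row
                A[:i, i] = row
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
    return RelationshipMatrix(ids=animal, values=A, kind="A")


def build_A_inverse(ped) -> RelationshipMatrix:
    """Sparse inverse of A by Henderson's rules with inbreeding.

    Mendelian sampling variances use Meuwissen-Luo inbreeding coefficients,
    so the result is the exact inverse of the tabular A.
    """
    animal, sire, dam = _parent_arrays(ped)
    n = len(animal)
    F = _inbreeding_ml(sire, dam) if n else np.zeros(0)
    rows, cols, vals = [], [], []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            m = 1.0 / (0.5 - 0.25 * (F[s] + F[d]))
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            m = 1.0 / (0.75 - 0.25 * F[p])
        else:
            m = 1.0
        add(i, i, m)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * m)
                add(p, i, -0.5 * m)
                add(p, p, 0.25 * m)
        if s >= 0 and d >= 0:
            add(s, d, 0.25 * m)
            add(d, s, 0.25 * m)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipMatrix(ids=animal, values=ainv, kind="A_inverse")


def build_A22(ped, genotyped_ids) -> RelationshipMatrix:
    """Pedigree relationships among the genotyped animals (subset of A)."""
    A = build_A(ped)
    idx = A.position_of(genotyped_ids)
    sub = A.values[np.ix_(idx, idx)].copy()
    return RelationshipMatrix(ids=np.asarray(genotyped_ids), values=sub, kind="A22")


# ---------------------------------------------------------------------------
# marker QC and genomic relationships
# ---------------------------------------------------------------------------

_SEX_CHROMS = {"X", "Y", "x", "y", "30", "31"}


def hwe_chi2(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, float]:
    """One-degree-of-freedom Hardy-Weinberg chi-square test.

    Genotype counts are (0, 1, 2) dosage counts.  Returns (statistic,
    p-value); a monomorphic marker gives statistic 0.
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 0.0, 1.0
    p = (2 * n_bb + n_ab) / (2 * n)
    q = 1.0 - p
    if p <= 0.0 or q <= 0.0:
        return 0.0, 1.0
    exp = np.array([q * q, 2 * p * q, p * p]) * n
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    stat = float(np.sum((obs - exp) ** 2 / exp))
    return stat, float(chi2.sf(stat, df=1))


def qc_markers(
    g: GenotypeMatrix,
    min_call_rate: float = 0.95,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Marker editing: call rate, MAF, HWE and chromosome/position filters.

    Removal counts are reported per rule (a marker failing several rules is
    counted under each).  Returns the filtered matrix and the counts.
    """
    d = g.dosage
    n_anim, n_mark = d.shape
    observed = d >= 0
    call_rate = observed.mean(axis=0) if n_anim else np.zeros(n_mark)

    with np.errstate(invalid="ignore"):
        p = np.where(
            observed.sum(axis=0) > 0,
            np.where(d < 0, 0, d).sum(axis=0) / np.maximum(2 * observed.sum(axis=0), 1),
            0.0,
        )
    maf = np.minimum(p, 1.0 - p)

    hwe_p = np.ones(n_mark)
    for j in range(n_mark):
        col = d[observed[:, j], j]
        hwe_p[j] = hwe_chi2(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )[1]

    info = g.marker_info
    if {"chrom", "pos"}.issubset(info.columns):
        chrom = info["chrom"].astype(str).to_numpy()
        pos = pd.to_numeric(info["pos"], errors="coerce").fillna(0).to_numpy()
        bad_map = np.isin(chrom, list(_SEX_CHROMS)) | (chrom == "0") | (pos <= 0)
    else:
        bad_map = np.zeros(n_mark, dtype=bool)

    fail_call = call_rate < min_call_rate
    fail_maf = maf < min_maf
    fail_hwe = hwe_p < hwe_alpha
    keep = ~(fail_call | fail_maf | fail_hwe | bad_map)

    counts = {
        "call_rate": int(fail_call.sum()),
        "maf": int(fail_maf.sum()),
        "hwe": int(fail_hwe.sum()),
        "map": int(bad_map.sum()),
        "removed": int((~keep).sum()),
        "kept": int(keep.sum()),
    }
    info_kept = info.iloc[keep].reset_index(drop=True) if len(info) == n_mark else info
    if len(info_kept) == counts["kept"]:
        info_kept = info_kept.assign(
            call_rate=call_rate[keep], maf=maf[keep], hwe_p=hwe_p[keep]
        )
    out = GenotypeMatrix(
        animal_ids=g.animal_ids,
        marker_ids=np.asarray(g.marker_ids)[keep],
        dosage=d[:, keep],
        marker_info=info_kept,
    )
    return out, counts


def impute_mean(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by their marker mean (float output)."""
    d = dosage.astype(float)
    miss = dosage < 0
    if miss.any():
        obs = np.where(miss, np.nan, d)
        col_mean = np.nanmean(obs, axis=0)
        col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
        d = np.where(miss, col_mean[None, :], d)
    return d


def build_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """VanRaden (method 1) genomic relationship matrix.

    G = ZZ' / (2 * sum_j p_j (1 - p_j)) with Z the dosage matrix centered
    by twice the observed allele frequencies; missing dosages are
    mean-imputed first.
    """
    d = impute_mean(g.dosage)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: genomic relationship undefined")
    Z = d - 2.0 * p[None, :]
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(ids=np.asarray(g.animal_ids), values=G, kind="G")


# ---------------------------------------------------------------------------
# single-step H-inverse
# ---------------------------------------------------------------------------


def blend_and_tune_G(
    G: np.ndarray, A22: np.ndarray, blend_alpha: float = 0.95, tune: bool = True
) -> np.ndarray:
    """Blend G with A22 and rescale so its mean diagonal/off-diagonal match A22.

    Blending guarantees invertibility; tuning (a two-coefficient linear
    adjustment) puts G on the same base as the pedigree relationships.
    """
    Gs = blend_alpha * G + (1.0 - blend_alpha) * A22
    if tune:
        md_g, m_g = float(np.mean(np.diag(Gs))), float(np.mean(Gs))
        md_a, m_a = float(np.mean(np.diag(A22))), float(np.mean(A22))
        if abs(md_g - m_g) > 1e-12:
            b = (md_a - m_a) / (md_g - m_g)
            a = m_a - b * m_g
            Gs = a + b * Gs
    return Gs


def build_H_inverse(
    a_inv: RelationshipMatrix,
    g: RelationshipMatrix,
    a22: RelationshipMatrix,
    blend_alpha: float = 0.95,
    tune: bool = True,
) -> RelationshipMatrix:
    """H-inverse for single-step evaluation.

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1] on the genotyped block, where
    G* is the blended (and optionally tuned) genomic matrix.  With no
    genotyped animals this is exactly A^-1.
    """
    ainv = a_inv.values.tocsr() if sp.issparse(a_inv.values) else sp.csr_matrix(a_inv.values)
    if g is None or g.n == 0:
        return RelationshipMatrix(ids=a_inv.ids.copy(), values=ainv.copy(), kind="H_inverse")
    if not np.array_equal(np.asarray(g.ids), np.asarray(a22.ids)):
        raise ValueError("G and A22 must share the same animal index")
    idx = a_inv.position_of(g.ids)

    Gs = blend_and_tune_G(g.to_dense(), a22.to_dense(), blend_alpha, tune)
    try:
        gs_inv = np.linalg.inv(Gs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "blended genomic matrix is singular; use a smaller blend_alpha "
            "(stronger blending toward A22)"
        ) from exc
    corr = gs_inv - np.linalg.inv(a22.to_dense())

    n = a_inv.n
    block = sp.coo_matrix(
        (
            corr.ravel(),
            (np.repeat(idx, len(idx)), np.tile(idx, len(idx))),
        ),
        shape=(n, n),
    ).tocsr()
    hinv = (ainv + block).tocsr()
    return RelationshipMatrix(ids=a_inv.ids.copy(), values=hinv, kind="H_inverse")
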