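"""Henderson's mixed-model equations, BLUP solutions and REML.

Implements the animal models used throughout the package:

    (1)  y = Xb + Z_a a + e                       (single-record LAB traits)
    (2)  y = Xb + Z_a a + Z_pe pe + e             (repeated-record FIELD traits)

univariate or bivariate, with the additive effects a distributed
N(0, G0 (x) K) for a relationship matrix K given through its sparse
inverse (pedigree A^-1 or single-step H^-1), independent permanent
environment for repeated records, and residuals uncorrelated across traits
(each trait has its own residual variance; traits may be recorded on
disjoint sets of animals).

Variance components are estimated by EM-REML (unconditionally convergent
reference algorithm) with average-information (AI) acceleration and
automatic EM fallback whenever an AI step leaves the parameter space or
would decrease the REML log-likelihood.  Traces of the inverse coefficient
matrix are exact in both regimes: dense inversion for small systems, and a
sparse LDL' factorization with the Takahashi selected inverse for large
ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit
from scipy.linalg import cho_factor, cho_solve

from .relmat import RelationshipMatrix

VAR_FLOOR_REL = 1e-8  # variance floor, relative to the trait's data variance
COR_BOUND = 0.999  # additive-correlation bound inside REML (|r_a| <= bound)


def _factorize(C: sp.csc_matrix):
    """Sparse LU of the (symmetric positive definite) coefficient matrix.

    Minimum-degree ordering on C + C' keeps fill-in small for MME-like
    patterns; SuperLU's default column ordering is catastrophically worse
    here because of the dense intercept row.
    """
    return spla.splu(
        C, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True}
    )


# ---------------------------------------------------------------------------
# sparse LDL' factorization with Takahashi selected inverse
#
# REML needs traces like tr(A^-1 C^{aa}) and tr(W C^-1 W'), i.e. entries of
# the inverse coefficient matrix on the sparsity pattern of C itself.  The
# Takahashi equations deliver exactly those entries from a sparse Cholesky
# factor at roughly the cost of the factorization - the classical approach
# of sparse REML software.  The LDL' routines below follow the compact
# up-looking formulation (etree + row-pattern walks).
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ldl_symbolic(n, Ap, Ai):
    """Elimination tree and column counts for the upper-triangular CSC A."""
    parent = np.full(n, -1, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            while i < k and flag[i] != k:
                if parent[i] == -1:
                    parent[i] = k
                lnz[i] += 1
                flag[i] = k
                i = parent[i]
    Lp = np.zeros(n + 1, dtype=np.int64)
    for k in range(n):
        Lp[k + 1] = Lp[k] + lnz[k]
    return parent, Lp


@njit(cache=True)
def _ldl_numeric(n, Ap, Ai, Ax, parent, Lp):
    """Numeric LDL': returns (Li, Lx, D); raises on a non-positive pivot."""
    Li = np.zeros(Lp[n], dtype=np.int64)
    Lx = np.zeros(Lp[n])
    D = np.zeros(n)
    Y = np.zeros(n)
    pattern = np.zeros(n, dtype=np.int64)
    flag = np.full(n, -1, dtype=np.int64)
    lnz = np.zeros(n, dtype=np.int64)
    for k in range(n):
        Y[k] = 0.0
        top = n
        flag[k] = k
        for p in range(Ap[k], Ap[k + 1]):
            i = Ai[p]
            if i > k:
                continue
            Y[i] += Ax[p]
            length = 0
            while flag[i] != k:
                pattern[length] = i
                length += 1
                flag[i] = k
                i = parent[i]
            while length > 0:
                length -= 1
                top -= 1
                pattern[top] = pattern[length]
        D[k] = Y[k]
        Y[k] = 0.0
        for s in range(top, n):
            i = pattern[s]
            yi = Y[i]
            Y[i] = 0.0
            p2 = Lp[i] + lnz[i]
            for p in range(Lp[i], p2):
                Y[Li[p]] -= Lx[p] * yi
            l_ki = yi / D[i]
            D[k] -= l_ki * yi
            Li[p2] = k
            Lx[p2] = l_ki
            lnz[i] += 1
        if D[k] <= 0.0:
            raise ValueError("matrix is not positive definite")
    return Li, Lx, D


@njit(cache=True)
def _ldl_solve(Lp, Li, Lx, D, perm, b):
    """Solve C x = b (columns of b) given LDL' of the permuted matrix."""
    n = D.size
    nrhs = b.shape[1]
    out = np.zeros_like(b)
    x = np.zeros(n)
    for r in range(nrhs):
        for i in range(n):
            x[i] = b[perm[i], r]
        for j in range(n):
            xj = x[j]
            if xj != 0.0:
                for p in range(Lp[j], Lp[j + 1]):
                    x[Li[p]] -= Lx[p] * xj
        for j in range(n):
            x[j] /= D[j]
        for j in range(n - 1, -1, -1):
            s = x[j]
            for p in range(Lp[j], Lp[j + 1]):
                s -= Lx[p] * x[Li[p]]
            x[j] = s
        for i in range(n):
            out[perm[i], r] = x[i]
    return out


@njit(cache=True)
def _z_entry(Lp, Li, Zx, Zd, a, b):
    """Selected-inverse entry Z[a, b] (permuted indices); 0 if off-pattern."""
    if a == b:
        return Zd[a]
    if a < b:
        a, b = b, a
    lo, hi = Lp[b], Lp[b + 1]
    while lo < hi:
        mid = (lo + hi) // 2
        if Li[mid] < a:
            lo = mid + 1
        else:
            hi = mid
    if lo < Lp[b + 1] and Li[lo] == a:
        return Zx[lo]
    return 0.0


@njit(cache=True)
def _takahashi(Lp, Li, Lx, D):
    """Entries of C^-1 on the Cholesky pattern (Takahashi equations)."""
    n = D.size
    Zx = np.zeros_like(Lx)
    Zd = np.zeros(n)
    for j in range(n - 1, -1, -1):
        start, end = Lp[j], Lp[j + 1]
        for idx in range(end - 1, start - 1, -1):
            i = Li[idx]
            s = 0.0
            for kdx in range(start, end):
                k = Li[kdx]
                s += Lx[kdx] * _z_entry(Lp, Li, Zx, Zd, i, k)
            Zx[idx] = -s
        s = 0.0
        for kdx in range(start, end):
            s += Lx[kdx] * Zx[kdx]
        Zd[j] = 1.0 / D[j] - s
    return Zx, Zd


@njit(cache=True)
def _z_weighted_sum(Lp, Li, Zx, Zd, rows, cols, vals):
    """sum_k vals[k] * Cinv[rows[k], cols[k]] over pattern entries."""
    s = 0.0
    for k in range(rows.size):
        s += vals[k] * _z_entry(Lp, Li, Zx, Zd, rows[k], cols[k])
    return s


class _SelectedInverseFactor:
    """LDL' of the MME coefficient matrix with selected-inverse traces.

    The fill-reducing (symmetric minimum-degree) permutation and the
    symbolic factorization are computed once per pattern; each REML round
    refactorizes numerically and reruns the Takahashi recursion.
    """

    def __init__(self, C: sp.csc_matrix):
        n = C.shape[0]
        self.n = n
        lu = _factorize(C)
        # the symmetric fill-reducing order is the inverse of SuperLU's
        # column permutation (scipy's perm_c maps factor order -> original)
        pc = np.asarray(lu.perm_c, dtype=np.int64)
        self.perm = np.empty(n, dtype=np.int64)
        self.perm[pc] = np.arange(n)
        self.pinv = pc.copy()
        self._pattern_ready = False

    def refactor(self, C: sp.csc_matrix) -> None:
        Cp = C[self.perm][:, self.perm]
        upper = sp.triu(Cp, format="csc").sorted_indices()
        if not self._pattern_ready:
            self._Ap_ref = upper.indptr.astype(np.int64)
            self._Ai_ref = upper.indices.astype(np.int64)
            self.parent, self.Lp = _ldl_symbolic(self.n, self._Ap_ref, self._Ai_ref)
            self._pattern_ready = True
        Ap = upper.indptr.astype(np.int64)
        Ai = upper.indices.astype(np.int64)
        if len(Ai) != len(self._Ai_ref) or not np.array_equal(Ai, self._Ai_ref):
            # pattern changed (e.g. a covariance crossed zero): redo symbolic
            self._Ap_ref, self._Ai_ref = Ap, Ai
            self.parent, self.Lp = _ldl_symbolic(self.n, Ap, Ai)
        self.Li, self.Lx, self.D = _ldl_numeric(
            self.n, Ap, Ai, upper.data, self.parent, self.Lp
        )
        self._Z = None

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self.D)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        b2 = b[:, None] if b.ndim == 1 else b
        out = _ldl_solve(self.Lp, self.Li, self.Lx, self.D, self.perm, np.asarray(b2, float))
        return out[:, 0] if b.ndim == 1 else out

    def selected_inverse(self) -> tuple[np.ndarray, np.ndarray]:
        if self._Z is None:
            self._Z = _takahashi(self.Lp, self.Li, self.Lx, self.D)
        return self._Z

    def trace_product(self, rows: np.ndarray, cols: np.ndarray, vals: np.ndarray) -> float:
        """tr-like sum of Cinv entries (original indices) weighted by vals."""
        Zx, Zd = self.selected_inverse()
        return float(
            _z_weighted_sum(
                self.Lp, self.Li, Zx, Zd, self.pinv[rows], self.pinv[cols], vals
            )
        )


class ConvergenceError(RuntimeError):
    """REML or iterative solver failed to converge; carries last estimates."""

    def __init__(self, message: str, components: "VarianceComponents | None" = None):
        super().__init__(message)
        self.components = components


@dataclass
class TraitModel:
    """One trait's model: cohort selector, fixed factors, random terms."""

    name: str
    cohort: str
    fixed: tuple = ()
    permanent_env: bool = False
    value_col: str = "value"


@dataclass
class ModelSpec:
    traits: list

    def __post_init__(self) -> None:
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("ModelSpec supports 1 or 2 traits")

    @property
    def names(self) -> list:
        return [t.name for t in self.traits]


@dataclass
class VarianceComponents:
    """Additive (co)variances, permanent-environment and residual variances."""

    trait_names: list
    sigma_a: np.ndarray  # t x t additive covariance matrix
    sigma_e: np.ndarray  # residual variance per trait
    sigma_pe: np.ndarray  # pe variance per trait (0 = term absent)
    se: dict = None
    n_rounds: int = 0
    converged: bool = True
    loglik: float = None

    def __post_init__(self) -> None:
        self.sigma_a = np.atleast_2d(np.asarray(self.sigma_a, dtype=float))
        self.sigma_e = np.atleast_1d(np.asarray(self.sigma_e, dtype=float))
        self.sigma_pe = np.atleast_1d(np.asarray(self.sigma_pe, dtype=float))

    def index(self, trait) -> int:
        return self.trait_names.index(trait) if isinstance(trait, str) else int(trait)

    def sigma_a2(self, trait) -> float:
        i = self.index(trait)
        return float(self.sigma_a[i, i])

    def sigma_p2(self, trait) -> float:
        i = self.index(trait)
        return float(self.sigma_a[i, i] + self.sigma_pe[i] + self.sigma_e[i])


def heritability(vc: VarianceComponents, trait) -> float:
    """h2 = sigma_a2 / (sigma_a2 + [sigma_pe2] + sigma_e2).

    The permanent-environment variance enters only where the trait has one
    (repeated-record FIELD traits); for single-record LAB traits sigma_pe2
    is structurally zero and the formula reduces to sigma_a2/(sigma_a2+sigma_e2).
    """
    i = vc.index(trait)
    total = vc.sigma_p2(trait)
    if total <= 0:
        raise ValueError("zero total phenotypic variance")
    return float(vc.sigma_a[i, i] / total)


def heritability_from_components(
    sigma_a2: float, sigma_e2: float, sigma_pe2: float = 0.0
) -> float:
    """Heritability directly from printed variance components."""
    total = sigma_a2 + sigma_pe2 + sigma_e2
    if total <= 0:
        raise ValueError("zero total phenotypic variance")
    return sigma_a2 / total


def genetic_correlation(vc: VarianceComponents) -> float:
    """r_a = sigma_a12 / (sigma_a1 * sigma_a2), clamped only at the boundary."""
    if vc.sigma_a.shape != (2, 2):
        raise ValueError("genetic correlation requires a bivariate model")
    va1, va2 = vc.sigma_a[0, 0], vc.sigma_a[1, 1]
    if va1 <= 0 or va2 <= 0:
        raise ValueError("additive variances must be positive")
    r = float(vc.sigma_a[0, 1] / np.sqrt(va1 * va2))
    if abs(r) > 1.0:
        if abs(r) - 1.0 < 1e-8:
            r = float(np.sign(r))
        # otherwise return as-is; the caller sees the violated bound
    return r


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    """Model frame: per-trait design matrices in a shared column layout."""

    spec: ModelSpec
    rel_inv: RelationshipMatrix
    n_cols: int
    q: int
    W: list  # per trait: csr (n_records x n_cols)
    y: list  # per trait: ndarray
    WtW: list  # per trait: csc
    Wty: list  # per trait: ndarray
    n_records: list
    rec_animal: list  # per trait: animal positions per record
    blocks: dict  # ('fixed', i) / ('a', i) / ('pe', i) -> slice
    fixed_info: list  # per trait: list of (factor, levels) incl. intercept
    fixed_keep: list  # per trait: kept (non-aliased) fixed-column indices
    pe_ids: list  # per trait: animal ids of pe levels (or None)


def _build_design(pheno: pd.DataFrame, spec: ModelSpec, rel_inv: RelationshipMatrix) -> _Design:
    q = rel_inv.n
    pos = {a: i for i, a in enumerate(rel_inv.ids)}
    t = len(spec.traits)

    subs, fixed_cols, fixed_info, rec_animal, pe_levels = [], [], [], [], []
    fixed_keep = []
    for tm in spec.traits:
        sub = pheno[pheno["cohort"] == tm.cohort] if "cohort" in pheno.columns else pheno
        sub = sub.reset_index(drop=True)
        if sub[tm.value_col].isna().any():
            raise ValueError(f"missing {tm.value_col} values for trait {tm.name}")
        subs.append(sub)
        try:
            rec_animal.append(
                np.array([pos[a] for a in sub["cow_id"]], dtype=np.int64)
                if len(sub)
                else np.zeros(0, dtype=np.int64)
            )
        except KeyError as exc:
            raise ValueError(
                f"animal {exc.args[0]} has phenotypes but no relationship row"
            ) from None
        info = []
        cols = []
        if len(sub):
            info.append(("(intercept)", ["(intercept)"]))
            cols.append(np.ones((len(sub), 1)))
            for f in tm.fixed:
                levels = sorted(sub[f].astype(str).unique())
                if len(levels) < 2:
                    continue
                codes = pd.Categorical(sub[f].astype(str), categories=levels).codes
                D = np.zeros((len(sub), len(levels) - 1))
                for j in range(1, len(levels)):
                    D[codes == j, j - 1] = 1.0
                info.append((f, levels))
                cols.append(D)
        fixed_info.append(info)
        Xf = np.hstack(cols) if cols else np.zeros((len(sub), 0))
        # drop aliased columns (rank-revealing QR) so the MME stays full
        # rank; dropped levels are absorbed into the reference/intercept,
        # the generalized-inverse convention for confounded fixed effects
        keep = np.arange(Xf.shape[1])
        if Xf.shape[1] > 1:
            from scipy.linalg import qr

            _, R, piv = qr(Xf, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            tol = max(Xf.shape) * np.finfo(float).eps * (diag[0] if diag.size else 1.0)
            rank = int(np.sum(diag > tol))
            keep = np.sort(piv[:rank])
        fixed_keep.append(keep)
        fixed_cols.append(Xf[:, keep])
        if spec.traits[len(subs) - 1].permanent_env and len(sub):
            ids = pd.unique(sub["cow_id"])
            pe_levels.append(np.asarray(ids))
        else:
            pe_levels.append(None)

    # global column layout: fixed blocks, additive blocks (trait-major), pe
    blocks = {}
    off = 0
    for i in range(t):
        nf = fixed_cols[i].shape[1]
        blocks[("fixed", i)] = slice(off, off + nf)
        off += nf
    for i in range(t):
        blocks[("a", i)] = slice(off, off + q)
        off += q
    for i in range(t):
        if pe_levels[i] is not None:
            npe = len(pe_levels[i])
            blocks[("pe", i)] = slice(off, off + npe)
            off += npe
    n_cols = off

    W, yv, WtW, Wty, n_records = [], [], [], [], []
    for i, tm in enumerate(spec.traits):
        sub = subs[i]
        n = len(sub)
        n_records.append(n)
        yv.append(sub[tm.value_col].to_numpy(dtype=float))
        rows, cols_, vals = [], [], []
        Xf = fixed_cols[i]
        fsl = blocks[("fixed", i)]
        r_idx, c_idx = np.nonzero(Xf)
        rows.extend(r_idx.tolist())
        cols_.extend((c_idx + fsl.start).tolist())
        vals.extend(Xf[r_idx, c_idx].tolist())
        asl = blocks[("a", i)]
        rows.extend(range(n))
        cols_.extend((rec_animal[i] + asl.start).tolist())
        vals.extend([1.0] * n)
        if pe_levels[i] is not None:
            pe_pos = {a: j for j, a in enumerate(pe_levels[i])}
            psl = blocks[("pe", i)]
            rows.extend(range(n))
            cols_.extend([psl.start + pe_pos[a] for a in sub["cow_id"]])
            vals.extend([1.0] * n)
        Wi = sp.coo_matrix((vals, (rows, cols_)), shape=(n, n_cols)).tocsr()
        W.append(Wi)
        WtW.append((Wi.T @ Wi).tocsc())
        Wty.append(Wi.T @ yv[i])

    return _Design(
        spec=spec,
        rel_inv=rel_inv,
        n_cols=n_cols,
        q=q,
        W=W,
        y=yv,
        WtW=WtW,
        Wty=Wty,
        n_records=n_records,
        rec_animal=rec_animal,
        blocks=blocks,
        fixed_info=fixed_info,
        fixed_keep=fixed_keep,
        pe_ids=pe_levels,
    )


def _coefficient_matrix(design: _Design, vc: VarianceComponents) -> tuple[sp.csc_matrix, np.ndarray]:
    t = len(design.spec.traits)
    if np.any(vc.sigma_e[:t] <= 0):
        raise ValueError("residual variances must be positive to assemble the MME")
    G0 = vc.sigma_a[:t, :t]
    try:
        G0_inv = np.linalg.inv(G0)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular additive covariance matrix G0") from exc
    if t > 1 and np.linalg.eigvalsh(G0).min() <= 0:
        raise ValueError("additive covariance matrix G0 is not positive definite")

    C = sp.csc_matrix((design.n_cols, design.n_cols))
    rhs = np.zeros(design.n_cols)
    for i in range(t):
        if design.n_records[i]:
            C = C + design.WtW[i] / vc.sigma_e[i]
            rhs += design.Wty[i] / vc.sigma_e[i]

    Kinv = design.rel_inv.values
    if not sp.issparse(Kinv):
        Kinv = sp.csr_matrix(Kinv)
    a0 = design.blocks[("a", 0)].start
    # keep the full t x t block pattern even when G0_inv has exact zeros, so
    # the assembled pattern (and its Cholesky) is stable across REML rounds
    tt = G0_inv.shape[0]
    g0_struct = sp.coo_matrix(
        (
            G0_inv.ravel(),
            (np.repeat(np.arange(tt), tt), np.tile(np.arange(tt), tt)),
        ),
        shape=(tt, tt),
    )
    add = sp.kron(g0_struct, Kinv, format="coo")
    add = sp.coo_matrix(
        (add.data, (add.row + a0, add.col + a0)), shape=(design.n_cols, design.n_cols)
    )
    C = (C + add.tocsc()).tocsc()

    for i in range(t):
        if design.pe_ids[i] is not None:
            if vc.sigma_pe[i] <= 0:
                raise ValueError(
                    "permanent-environment variance must be positive; drop the "
                    "pe term instead of forcing it to zero"
                )
            psl = design.blocks[("pe", i)]
            npe = psl.stop - psl.start
            pe_block = sp.coo_matrix(
                (
                    np.full(npe, 1.0 / vc.sigma_pe[i]),
                    (np.arange(psl.start, psl.stop), np.arange(psl.start, psl.stop)),
                ),
                shape=(design.n_cols, design.n_cols),
            )
            C = (C + pe_block.tocsc()).tocsc()
    return C, rhs


@dataclass
class MMESystem:
    """Assembled mixed-model equations plus the design they came from."""

    C: sp.csc_matrix
    rhs: np.ndarray
    design: _Design
    vc: VarianceComponents

    @property
    def spec(self) -> ModelSpec:
        return self.design.spec

    @property
    def n_equations(self) -> int:
        return self.design.n_cols


def build_mme(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    vc: VarianceComponents,
    rel_inv: RelationshipMatrix,
) -> MMESystem:
    """Assemble Henderson's MME for the given records, model and components.

    The pe term is included for a trait only when the model requests it and
    its variance is positive (a zero pe variance means the term is absent).
    """
    spec_eff = ModelSpec(
        traits=[
            TraitModel(
                name=tm.name,
                cohort=tm.cohort,
                fixed=tm.fixed,
                permanent_env=bool(tm.permanent_env and vc.sigma_pe[i] > 0),
                value_col=tm.value_col,
            )
            for i, tm in enumerate(spec.traits)
        ]
    )
    design = _build_design(pheno, spec_eff, rel_inv)
    C, rhs = _coefficient_matrix(design, vc)
    return MMESystem(C=C, rhs=rhs, design=design, vc=vc)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------


@dataclass
class Solutions:
    """Fixed-effect estimates, EBVs and pe solutions from one MME solve."""

    x: np.ndarray
    fixed: pd.DataFrame
    ebv: pd.DataFrame
    pe: pd.DataFrame
    residuals: dict
    relative_residual: float
    method: str

    def ebv_for(self, trait: str, animal_ids) -> np.ndarray:
        sub = self.ebv[self.ebv["trait"] == trait].set_index("animal_id")["ebv"]
        return sub.loc[np.asarray(animal_ids)].to_numpy()


def solve_mme(
    sys: MMESystem,
    method: str = "direct",
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> Solutions:
    """Solve the MME directly (sparse LU) or by diagonal-preconditioned CG."""
    C, rhs = sys.C, sys.rhs
    if method == "direct":
        x = _factorize(C).solve(rhs)
    elif method == "pcg":
        d = C.diagonal()
        M = spla.LinearOperator(C.shape, matvec=lambda v: v / d)
        x, info = spla.cg(C, rhs, rtol=tol, atol=0.0, maxiter=max_iter, M=M)
        if info != 0:
            res = float(np.linalg.norm(C @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
            raise ConvergenceError(
                f"PCG did not converge in {max_iter} iterations (relative residual {res:.3e})"
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    rel = float(np.linalg.norm(C @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))

    design = sys.design
    fixed_rows = []
    for i, tm in enumerate(design.spec.traits):
        fsl = design.blocks[("fixed", i)]
        n_full = sum(
            1 if f == "(intercept)" else len(lv) - 1
            for f, lv in design.fixed_info[i]
        )
        coefs = np.zeros(n_full)
        coefs[design.fixed_keep[i]] = x[fsl]
        off = 0
        raw = {}
        for factor, levels in design.fixed_info[i]:
            if factor == "(intercept)":
                raw[factor] = {"(intercept)": coefs[off]}
                off += 1
            else:
                eff = np.concatenate([[0.0], coefs[off : off + len(levels) - 1]])
                raw[factor] = dict(zip(levels, eff))
                off += len(levels) - 1
        # report within-factor sum-to-zero effects; the intercept absorbs means
        intercept_shift = 0.0
        for factor, eff in raw.items():
            if factor == "(intercept)":
                continue
            m = float(np.mean(list(eff.values())))
            intercept_shift += m
            for lvl, v in eff.items():
                fixed_rows.append(
                    {"trait": tm.name, "factor": factor, "level": lvl, "estimate": v - m}
                )
        if "(intercept)" in raw:
            fixed_rows.append(
                {
                    "trait": tm.name,
                    "factor": "(intercept)",
                    "level": "(intercept)",
                    "estimate": raw["(intercept)"]["(intercept)"] + intercept_shift,
                }
            )
    ebv_rows = []
    for i, tm in enumerate(design.spec.traits):
        asl = design.blocks[("a", i)]
        ebv_rows.append(
            pd.DataFrame(
                {
                    "animal_id": design.rel_inv.ids,
                    "trait": tm.name,
                    "ebv": x[asl],
                }
            )
        )
    pe_rows = []
    for i, tm in enumerate(design.spec.traits):
        if design.pe_ids[i] is not None:
            psl = design.blocks[("pe", i)]
            pe_rows.append(
                pd.DataFrame(
                    {"animal_id": design.pe_ids[i], "trait": tm.name, "pe": x[psl]}
                )
            )
    residuals = {
        tm.name: design.y[i] - design.W[i] @ x for i, tm in enumerate(design.spec.traits)
    }
    return Solutions(
        x=x,
        fixed=pd.DataFrame(fixed_rows),
        ebv=pd.concat(ebv_rows, ignore_index=True),
        pe=pd.concat(pe_rows, ignore_index=True) if pe_rows else pd.DataFrame(),
        residuals=residuals,
        relative_residual=rel,
        method=method,
    )


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def _sym_e(t: int, k: int, l: int) -> np.ndarray:
    E = np.zeros((t, t))
    E[k, l] += 1.0
    E[l, k] += 1.0
    if k == l:
        E[k, l] = 1.0
    return E


@dataclass
class _Traces:
    T: np.ndarray  # t x t block traces tr(K^-1 C^{a_k a_l})
    pe: np.ndarray  # per trait tr(C^{pe pe}) (0 where absent)
    W: np.ndarray  # per trait tr(W_t C^-1 W_t')


def _compute_traces_dense(design: _Design, Cinv: np.ndarray, Kinv) -> _Traces:
    t = len(design.spec.traits)
    T = np.zeros((t, t))
    for k in range(t):
        for l in range(t):
            sk, sl = design.blocks[("a", k)], design.blocks[("a", l)]
            T[k, l] = float(Kinv.multiply(Cinv[sk, sl]).sum())
    T = 0.5 * (T + T.T)
    pe = np.zeros(t)
    trW = np.zeros(t)
    for i in range(t):
        if design.pe_ids[i] is not None:
            psl = design.blocks[("pe", i)]
            pe[i] = float(np.trace(Cinv[psl, psl]))
        if design.n_records[i]:
            trW[i] = float(np.sum(design.WtW[i].multiply(Cinv)))
    return _Traces(T=T, pe=pe, W=trW)


def _trace_coordinates(design: _Design, Kinv) -> dict:
    """Global (row, col, value) lists whose Cinv-weighted sums are the traces.

    tr(K^-1 C^{a_k a_l}) sums K^-1_{ij} * Cinv[a_k+j, a_l+i]; the pe trace is
    the diagonal of the pe block; tr(W_t C^-1 W_t') sums (W_t'W_t)_{ij} *
    Cinv[j, i].  All positions lie inside the coefficient-matrix pattern, so
    the Takahashi selected inverse covers them exactly.
    """
    t = len(design.spec.traits)
    coords = {}
    Kcoo = Kinv.tocoo()
    for k in range(t):
        for l in range(t):
            rk = design.blocks[("a", k)].start + Kcoo.col.astype(np.int64)
            cl = design.blocks[("a", l)].start + Kcoo.row.astype(np.int64)
            coords[("a", k, l)] = (rk, cl, Kcoo.data.astype(float))
    for i in range(t):
        if design.pe_ids[i] is not None:
            psl = design.blocks[("pe", i)]
            d = np.arange(psl.start, psl.stop, dtype=np.int64)
            coords[("pe", i)] = (d, d, np.ones(len(d)))
        if design.n_records[i]:
            Wcoo = design.WtW[i].tocoo()
            coords[("w", i)] = (
                Wcoo.col.astype(np.int64),
                Wcoo.row.astype(np.int64),
                Wcoo.data.astype(float),
            )
    return coords


def _compute_traces_selected(
    design: _Design, factor: "_SelectedInverseFactor", coords: dict
) -> _Traces:
    t = len(design.spec.traits)
    T = np.zeros((t, t))
    for k in range(t):
        for l in range(t):
            T[k, l] = factor.trace_product(*coords[("a", k, l)])
    T = 0.5 * (T + T.T)
    pe = np.zeros(t)
    trW = np.zeros(t)
    for i in range(t):
        if ("pe", i) in coords:
            pe[i] = factor.trace_product(*coords[("pe", i)])
        if ("w", i) in coords:
            trW[i] = factor.trace_product(*coords[("w", i)])
    return _Traces(T=T, pe=pe, W=trW)


def reml_loglik(design_or_sys, vc: VarianceComponents) -> float:
    """REML log-likelihood (up to a constant); dense computation, small systems."""
    design = design_or_sys.design if isinstance(design_or_sys, MMESystem) else design_or_sys
    t = len(design.spec.traits)
    C, rhs = _coefficient_matrix(design, vc)
    Cd = C.toarray()
    x = np.linalg.solve(Cd, rhs)
    sign, logdet_c = np.linalg.slogdet(Cd)
    if sign <= 0:
        raise ValueError("coefficient matrix not positive definite")
    Kinv = design.rel_inv.values
    Kd = Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv)
    sign_k, logdet_kinv = np.linalg.slogdet(Kd)
    G0 = vc.sigma_a[:t, :t]
    log_g = design.q * float(np.linalg.slogdet(G0)[1]) - t * logdet_kinv
    log_r = 0.0
    ypy = 0.0
    for i in range(t):
        n = design.n_records[i]
        log_r += n * np.log(vc.sigma_e[i])
        ypy += float(design.y[i] @ design.y[i]) / vc.sigma_e[i]
        if design.pe_ids[i] is not None:
            log_g += len(design.pe_ids[i]) * np.log(vc.sigma_pe[i])
    ypy -= float(rhs @ x)
    return -0.5 * (log_g + log_r + logdet_c + ypy)


def _default_start(design: _Design, spec: ModelSpec) -> VarianceComponents:
    t = len(spec.traits)
    vy = np.array(
        [np.var(design.y[i]) if design.n_records[i] > 1 else 1.0 for i in range(t)]
    )
    vy = np.maximum(vy, 1e-12)
    sa = np.diag(0.3 * vy)
    if t == 2:
        sa[0, 1] = sa[1, 0] = 0.5 * np.sqrt(sa[0, 0] * sa[1, 1])
    pe = np.array(
        [0.1 * vy[i] if spec.traits[i].permanent_env else 0.0 for i in range(t)]
    )
    se = vy - np.diag(sa) - pe
    return VarianceComponents(
        trait_names=spec.names, sigma_a=sa, sigma_e=se, sigma_pe=pe
    )


def estimate_varcomp_reml(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    rel_inv: RelationshipMatrix,
    method: str = "ai",
    conv: float = 1e-10,
    max_rounds: int = 300,
    start: VarianceComponents = None,
    dense_cutoff: int = 900,
    verbose: bool = False,
) -> VarianceComponents:
    """EM/AI-REML variance components for models (1) and (2).

    ``method="em"`` runs pure EM-REML; ``method="ai"`` runs two EM warm-up
    rounds then damped average-information steps, each accepted only if it
    does not decrease the REML log-likelihood, with EM fallback otherwise.
    Traces of the inverse coefficient matrix are exact: dense inversion for
    systems up to ``dense_cutoff`` equations, sparse-Cholesky selected
    inverse (Takahashi) beyond.  Convergence is declared when the summed
    squared relative change of all parameters drops below ``conv``.
    Raises :class:`ConvergenceError` (carrying the last estimates) if
    ``max_rounds`` is exhausted.
    """
    if method not in ("em", "ai"):
        raise ValueError("method must be 'em' or 'ai'")
    design = _build_design(pheno, spec, rel_inv)
    t = len(spec.traits)
    vc = start or _default_start(design, spec)
    vc = VarianceComponents(
        trait_names=spec.names,
        sigma_a=vc.sigma_a.copy(),
        sigma_e=vc.sigma_e.copy(),
        sigma_pe=vc.sigma_pe.copy(),
    )
    has_pe = np.array([design.pe_ids[i] is not None for i in range(t)])
    floors = np.array(
        [
            VAR_FLOOR_REL * (np.var(design.y[i]) if design.n_records[i] > 1 else 1.0)
            for i in range(t)
        ]
    )
    Kinv = design.rel_inv.values
    if not sp.issparse(Kinv):
        Kinv = sp.csr_matrix(Kinv)
    q = design.q
    use_dense = design.n_cols <= dense_cutoff
    factor_obj = None
    trace_coords = None
    if not use_dense:
        trace_coords = _trace_coordinates(design, Kinv)

    def params(v: VarianceComponents) -> np.ndarray:
        out = [v.sigma_a[k, l] for k in range(t) for l in range(k, t)]
        out += [v.sigma_pe[i] for i in range(t) if has_pe[i]]
        out += list(v.sigma_e[:t])
        return np.array(out)

    def unpack(vec: np.ndarray) -> VarianceComponents:
        sa = np.zeros((t, t))
        m = 0
        for k in range(t):
            for l in range(k, t):
                sa[k, l] = sa[l, k] = vec[m]
                m += 1
        pe = np.zeros(t)
        for i in range(t):
            if has_pe[i]:
                pe[i] = vec[m]
                m += 1
        se = np.array(vec[m : m + t])
        return VarianceComponents(
            trait_names=spec.names, sigma_a=sa, sigma_e=se, sigma_pe=pe
        )

    def repair(v: VarianceComponents) -> tuple[VarianceComponents, bool]:
        """Project a proposal back into the parameter space.

        Variances are floored, and the additive covariance is clamped so
        |r_a| <= COR_BOUND (at the +-1 boundary G0 is singular and EM
        creeps forever; bounded-correlation estimates are the standard
        resolution in REML software).  Returns (repaired, cov_was_bounded).
        """
        sa = v.sigma_a.copy()
        for i in range(t):
            sa[i, i] = max(sa[i, i], floors[i])
        bounded = False
        if t == 2:
            denom = np.sqrt(sa[0, 0] * sa[1, 1])
            if abs(sa[0, 1]) > COR_BOUND * denom:
                sa[0, 1] = sa[1, 0] = np.sign(sa[0, 1]) * COR_BOUND * denom
                bounded = True
        se = np.maximum(v.sigma_e[:t], floors)
        pe = v.sigma_pe.copy()
        for i in range(t):
            if has_pe[i]:
                pe[i] = max(pe[i], floors[i])
        return (
            VarianceComponents(
                trait_names=spec.names, sigma_a=sa, sigma_e=se, sigma_pe=pe
            ),
            bounded,
        )

    yty = [float(design.y[i] @ design.y[i]) for i in range(t)]

    def fit_state(v: VarianceComponents) -> dict:
        """Factorize the MME at v; return solver, solutions and REML logL.

        The log-likelihood drops the constant log|K| term (it never changes
        across rounds), so it is comparable only within one estimation run.
        """
        nonlocal factor_obj
        C, rhs = _coefficient_matrix(design, v)
        if use_dense:
            factor = cho_factor(C.toarray(), lower=True)
            solve = lambda b: cho_solve(factor, b)
            logdet_c = 2.0 * float(np.sum(np.log(np.diag(factor[0]))))
        else:
            if factor_obj is None:
                factor_obj = _SelectedInverseFactor(C)
            factor_obj.refactor(C)
            solve = factor_obj.solve
            logdet_c = factor_obj.logdet
        x = solve(rhs)
        log_g = design.q * float(np.linalg.slogdet(v.sigma_a[:t, :t])[1])
        log_r = 0.0
        ypy = -float(rhs @ x)
        for i in range(t):
            log_r += design.n_records[i] * np.log(v.sigma_e[i])
            ypy += yty[i] / v.sigma_e[i]
            if design.pe_ids[i] is not None:
                log_g += len(design.pe_ids[i]) * np.log(v.sigma_pe[i])
        return {
            "solve": solve,
            "x": x,
            "logl": -0.5 * (log_g + log_r + logdet_c + ypy),
        }

    state = fit_state(vc)
    last_ai = None
    n_rounds = 0
    prev_cov_bounded = False
    for rnd in range(1, max_rounds + 1):
        n_rounds = rnd
        G0 = vc.sigma_a[:t, :t]
        G0_inv = np.linalg.inv(G0)
        x = state["x"]
        solve = state["solve"]
        if use_dense:
            Cinv = solve(np.eye(design.n_cols))
            traces = _compute_traces_dense(design, Cinv, Kinv)
        else:
            # selected inverse of the accepted factorization (exact traces)
            traces = _compute_traces_selected(design, factor_obj, trace_coords)

        U = np.column_stack([x[design.blocks[("a", i)]] for i in range(t)])
        ehat = [design.y[i] - design.W[i] @ x for i in range(t)]

        # EM updates
        G0_em = (U.T @ (Kinv @ U) + traces.T) / q
        pe_em = np.zeros(t)
        for i in range(t):
            if has_pe[i]:
                psl = design.blocks[("pe", i)]
                phat = x[psl]
                pe_em[i] = (phat @ phat + traces.pe[i]) / (psl.stop - psl.start)
        se_em = np.array(
            [
                (ehat[i] @ ehat[i] + traces.W[i]) / design.n_records[i]
                if design.n_records[i]
                else vc.sigma_e[i]
                for i in range(t)
            ]
        )
        vc_em = VarianceComponents(
            trait_names=spec.names, sigma_a=G0_em, sigma_e=se_em, sigma_pe=pe_em
        )

        vc_new = None
        new_state = None
        cov_bounded = False
        used = "EM"
        if method == "ai" and rnd > 2:
            step, ai_mat, grad_vec = _ai_direction(
                design, vc, x, ehat, traces, G0_inv, solve, has_pe, q, t
            )
            # the bound stays active while the likelihood still pushes the
            # covariance outward; otherwise the constraint is released
            bound_active = (
                t == 2
                and prev_cov_bounded
                and grad_vec is not None
                and float(np.sign(vc.sigma_a[0, 1]) * grad_vec[1]) > 0
            )
            if step is not None:
                theta = params(vc)
                if bound_active and ai_mat is not None:
                    # correlation pinned at the bound: the covariance is an
                    # implicit function of the variances, cov = b*sqrt(v1*v2),
                    # so Newton must act in the reduced space through the
                    # chain-rule Jacobian (ignoring it flips step directions)
                    n_par = len(theta)
                    free_idx = [i for i in range(n_par) if i != 1]
                    J = np.zeros((n_par, n_par - 1))
                    for col, i in enumerate(free_idx):
                        J[i, col] = 1.0
                    b_sign = np.sign(vc.sigma_a[0, 1]) or 1.0
                    v1, v2 = vc.sigma_a[0, 0], vc.sigma_a[1, 1]
                    J[1, free_idx.index(0)] = 0.5 * b_sign * COR_BOUND * np.sqrt(v2 / v1)
                    J[1, free_idx.index(2)] = 0.5 * b_sign * COR_BOUND * np.sqrt(v1 / v2)
                    try:
                        step_free = np.linalg.solve(J.T @ ai_mat @ J, J.T @ grad_vec)
                        step = J @ step_free
                    except np.linalg.LinAlgError:
                        step = None
                if step is not None:
                    # Newton steps along near-flat likelihood ridges can be
                    # huge; start from a damping that caps the largest
                    # relative change at 2x, then shrink until the REML logL
                    # does not decrease.
                    max_rel = float(
                        np.max(np.abs(step) / np.maximum(np.abs(theta), floors.max()))
                    )
                    damp0 = min(1.0, 2.0 / max_rel) if max_rel > 0 else 1.0
                    for shrink in (1.0, 0.5, 0.25, 0.1, 0.03, 0.01):
                        damp = damp0 * shrink
                        prop = unpack(theta + damp * step)
                        if bound_active:
                            sa = prop.sigma_a.copy()
                            sign = np.sign(sa[0, 1]) if sa[0, 1] else 1.0
                            sa[0, 1] = sa[1, 0] = (
                                sign * COR_BOUND * np.sqrt(max(sa[0, 0], floors[0]) * max(sa[1, 1], floors[1]))
                            )
                            prop.sigma_a = sa
                        cand, bounded = repair(prop)
                        bounded = bounded or bound_active
                        try:
                            cand_state = fit_state(cand)
                        except (np.linalg.LinAlgError, ValueError):
                            continue  # numerically non-PD system: reject
                        if cand_state["logl"] >= state["logl"] - 1e-10:
                            vc_new, new_state = cand, cand_state
                            cov_bounded = bounded
                            last_ai = ai_mat
                            used = f"AI({damp:.2g})"
                            break
        if vc_new is None:
            vc_new, cov_bounded = repair(vc_em)
            new_state = fit_state(vc_new)

        old, new = params(vc), params(vc_new)
        if verbose:
            print(
                f"round {rnd:3d} [{used}] logL={new_state['logl']:.6f} "
                f"params={np.round(new, 5)}"
            )
        pinned = np.abs(old) <= np.repeat(floors.max(), len(old)) * 2
        if t == 2 and cov_bounded and prev_cov_bounded:
            pinned[1] = True  # covariance held at the correlation bound
        prev_cov_bounded = cov_bounded
        denom = np.maximum(np.abs(old), floors.max())
        delta = float(np.sum(((new - old) / denom)[~pinned] ** 2)) if (~pinned).any() else 0.0
        vc = vc_new
        state = new_state
        if delta < conv:
            vc.converged = True
            vc.n_rounds = rnd
            vc.loglik = float(state["logl"])
            if last_ai is not None:
                try:
                    cov = np.linalg.inv(last_ai)
                    labels = _param_labels(spec, has_pe, t)
                    vc.se = dict(zip(labels, np.sqrt(np.maximum(np.diag(cov), 0.0))))
                except np.linalg.LinAlgError:
                    vc.se = None
            return vc
    vc.converged = False
    vc.n_rounds = n_rounds
    raise ConvergenceError(
        f"REML did not reach {conv:g} in {max_rounds} rounds", components=vc
    )


def _param_labels(spec: ModelSpec, has_pe: np.ndarray, t: int) -> list:
    labels = []
    for k in range(t):
        for l in range(k, t):
            labels.append(
                f"sigma_a({spec.names[k]},{spec.names[l]})" if k != l else f"sigma_a2({spec.names[k]})"
            )
    for i in range(t):
        if has_pe[i]:
            labels.append(f"sigma_pe2({spec.names[i]})")
    labels += [f"sigma_e2({spec.names[i]})" for i in range(t)]
    return labels


def _ai_direction(design, vc, x, ehat, traces, G0_inv, solve, has_pe, q, t):
    """Average-information Newton direction; returns (step, AI, gradient)."""
    # Py per trait (record space), and the stacked first derivatives
    Py = [ehat[i] / vc.sigma_e[i] for i in range(t)]
    U = np.column_stack([x[design.blocks[("a", i)]] for i in range(t)])  # q x t

    param_list = [("a", (k, l)) for k in range(t) for l in range(k, t)]
    param_list += [("pe", i) for i in range(t) if has_pe[i]]
    param_list += [("e", i) for i in range(t)]
    n_par = len(param_list)

    # f_i = dV/dtheta_i @ Py, assembled per trait in record space
    fvecs = []
    for kind, idx in param_list:
        f = [np.zeros(design.n_records[i]) for i in range(t)]
        if kind == "a":
            k, l = idx
            M = _sym_e(t, k, l) @ G0_inv  # t x t
            V = U @ M.T  # q x t : (M u)_trait per animal
            for i in range(t):
                if design.n_records[i]:
                    f[i] = V[design.rec_animal[i], i]
        elif kind == "pe":
            i = idx
            psl = design.blocks[("pe", i)]
            phat = x[psl] / vc.sigma_pe[i]
            pe_pos = {a: j for j, a in enumerate(design.pe_ids[i])}
            rec_pe = np.array(
                [pe_pos[a] for a in design.rel_inv.ids[design.rec_animal[i]]]
            )
            f[i] = phat[rec_pe]
        else:
            i = idx
            f[i] = ehat[i] / vc.sigma_e[i]
        fvecs.append(f)

    # P f_i via one MME solve per parameter
    Pf = []
    for f in fvecs:
        rhs_f = np.zeros(design.n_cols)
        for i in range(t):
            if design.n_records[i]:
                rhs_f += design.W[i].T @ (f[i] / vc.sigma_e[i])
        xf = solve(rhs_f)
        Pf.append(
            [
                (f[i] - design.W[i] @ xf) / vc.sigma_e[i] if design.n_records[i] else f[i]
                for i in range(t)
            ]
        )

    AI = np.zeros((n_par, n_par))
    for a_ in range(n_par):
        for b_ in range(a_, n_par):
            v = sum(float(fvecs[a_][i] @ Pf[b_][i]) for i in range(t))
            AI[a_, b_] = AI[b_, a_] = 0.5 * v

    # gradients
    grad = np.zeros(n_par)
    for m, (kind, idx) in enumerate(param_list):
        ydot = sum(float(fvecs[m][i] @ Py[i]) for i in range(t))
        if kind == "a":
            k, l = idx
            E = _sym_e(t, k, l)
            B = G0_inv @ E @ G0_inv
            tr_p = q * float(np.trace(G0_inv @ E)) - float(np.sum(B * traces.T))
        elif kind == "pe":
            i = idx
            npe = len(design.pe_ids[i])
            tr_p = npe / vc.sigma_pe[i] - traces.pe[i] / vc.sigma_pe[i] ** 2
        else:
            i = idx
            tr_p = (
                design.n_records[i] / vc.sigma_e[i]
                - traces.W[i] / vc.sigma_e[i] ** 2
            )
        grad[m] = -0.5 * (tr_p - ydot)

    try:
        step = np.linalg.solve(AI, grad)
    except np.linalg.LinAlgError:
        return None, None, grad
    if not np.all(np.isfinite(step)):
        return None, None, grad
    return step, AI, grad
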