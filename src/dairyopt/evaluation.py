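"""Breeding-value estimation: pedigree BLUP and single-step GBLUP.

The model is a repeatability animal model with the overall year mean as the
only fixed effect and additive-genetic, permanent-environment and herd-year
random effects.  Herd and herd-test-day are deliberately not fitted (the
data structure of a small population does not support them): the herd
variance folds into herd-year and the herd-test-day variance into the
residual, so with the simulation's true components the solver uses
sigma2_hy = 2/3 and sigma2_e = 4/3 in additive-variance units.

Repeated records of a cow within a herd-year are exchangeable under this
model, so they are collapsed to their cell mean with weight n before the
equations are built; the solutions are algebraically identical to the
record-level system.

Henderson's mixed-model equations are solved by preconditioned conjugate
gradients (diagonal preconditioner, relative residual 1e-8).  The additive
covariance structure is A^-1 (Meuwissen & Luo inbreeding, Henderson rules)
or, with genotyped animals, the single-step H^-1 built from a VanRaden
genomic relationship matrix that is tuned to A22 (matching mean diagonal
and off-diagonal) and blended 0.95 G + 0.05 A22.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "PedigreeError",
    "ConvergenceError",
    "ModelSpec",
    "EvaluationResult",
    "TrainingPopulation",
    "inbreeding",
    "build_A_inverse",
    "pedigree_A22",
    "pedigree_A22_flow",
    "build_G",
    "tune_and_blend_G",
    "build_H_inverse",
    "solve_mme",
]


class PedigreeError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Variance components of the evaluation model (additive-variance units).

    Defaults are the simulation's true components with herd folded into
    herd-year and herd-test-day into the residual.  Components are treated
    as known, not re-estimated.
    """

    sigma2_a: float = 1.0
    sigma2_pe: float = 1.0
    sigma2_hy: float = 2.0 / 3.0
    sigma2_e: float = 4.0 / 3.0

    def __post_init__(self) -> None:
        if min(self.sigma2_a, self.sigma2_pe, self.sigma2_hy, self.sigma2_e) <= 0:
            raise ValueError("variance components must be positive")


@dataclass
class EvaluationResult:
    ebv: np.ndarray  # one EBV per pedigree animal
    pe: np.ndarray
    hy: np.ndarray
    fixed: np.ndarray
    model: str  # "pedigree" | "single-step"
    year: int | None = None
    n_iterations: int = 0


# ---------------------------------------------------------------------------
# pedigree machinery


def _validate_pedigree(sire: np.ndarray, dam: np.ndarray, sex: np.ndarray | None) -> None:
    n = len(sire)
    if len(dam) != n:
        raise PedigreeError("sire and dam arrays differ in length")
    ids = np.arange(n)
    if np.any(sire >= ids) or np.any(dam >= ids):
        raise PedigreeError("parents must precede offspring (cycle or bad ordering)")
    if sex is not None:
        s_ok = sire[sire >= 0]
        d_ok = dam[dam >= 0]
        if np.any(sex[s_ok] != 1):
            raise PedigreeError("a recorded sire is not male")
        if np.any(sex[d_ok] != 0):
            raise PedigreeError("a recorded dam is not female")


@njit(cache=True)
def _inbreeding_ml(sire, dam, F, start):  # pragma: no cover - exercised via wrapper
    """Meuwissen & Luo (1992): F[i] for i in [start, n), given F[:start]."""
    n = sire.shape[0]
    L = np.zeros(n)
    heap = np.empty(n, dtype=np.int64)
    for i in range(start, n):
        s, d = sire[i], dam[i]
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        # A_ii = sum_j L_ij^2 * d_j over ancestors j (including i)
        hs = 0
        heap[hs] = i
        hs += 1
        L[i] = 1.0
        aii = 0.0
        while hs > 0:
            # pop max
            j = heap[0]
            hs -= 1
            heap[0] = heap[hs]
            k = 0
            while True:
                c1, c2 = 2 * k + 1, 2 * k + 2
                big = k
                if c1 < hs and heap[c1] > heap[big]:
                    big = c1
                if c2 < hs and heap[c2] > heap[big]:
                    big = c2
                if big == k:
                    break
                heap[k], heap[big] = heap[big], heap[k]
                k = big
            lj = L[j]
            L[j] = 0.0
            sj, dj = sire[j], dam[j]
            if sj >= 0 and dj >= 0:
                dcoef = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0 or dj >= 0:
                p = sj if sj >= 0 else dj
                dcoef = 0.75 - 0.25 * F[p]
            else:
                dcoef = 1.0
            aii += lj * lj * dcoef
            for p in (sj, dj):
                if p >= 0:
                    if L[p] == 0.0:
                        # push
                        heap[hs] = p
                        hs += 1
                        k = hs - 1
                        while k > 0:
                            par = (k - 1) // 2
                            if heap[par] < heap[k]:
                                heap[par], heap[k] = heap[k], heap[par]
                                k = par
                            else:
                                break
                    L[p] += 0.5 * lj
        F[i] = aii - 1.0
    return F


def inbreeding(sire, dam, known_f: np.ndarray | None = None) -> np.ndarray:
    """Inbreeding coefficients for a chronologically ordered pedigree.

    ``known_f`` may carry already-computed coefficients for a prefix of the
    pedigree (they never change when animals are appended).
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam, None)
    F = np.zeros(len(sire))
    start = 0
    if known_f is not None:
        start = len(known_f)
        F[:start] = known_f
    return _inbreeding_ml(sire, dam, F, start)


def _mendelian_variances(sire, dam, F) -> np.ndarray:
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    d = np.ones(len(sire))
    fs = np.where(sire >= 0, F[np.maximum(sire, 0)], 0.0)
    fd = np.where(dam >= 0, F[np.maximum(dam, 0)], 0.0)
    d[both] = 0.5 - 0.25 * (fs[both] + fd[both])
    d[one] = 0.75 - 0.25 * (fs[one] + fd[one])
    return d


def build_A_inverse(
    sire, dam, sex: np.ndarray | None = None, known_f: np.ndarray | None = None
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Sparse inverse of the numerator relationship matrix, with inbreeding.

    Henderson's rules with Mendelian-sampling variances from the computed
    inbreeding coefficients.  Pedigree must be ordered parents-first; a
    violation (which includes any cycle) raises, as does a sire recorded as
    female when ``sex`` (0=female, 1=male) is given.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    _validate_pedigree(sire, dam, sex)
    n = len(sire)
    F = inbreeding(sire, dam, known_f)
    alpha = 1.0 / _mendelian_variances(sire, dam, F)
    ids = np.arange(n)

    rows, cols, vals = [ids], [ids], [alpha]

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for par in (sire, dam):
        m = par >= 0
        add(ids[m], par[m], -0.5 * alpha[m])
        add(par[m], ids[m], -0.5 * alpha[m])
        add(par[m], par[m], 0.25 * alpha[m])
    m2 = (sire >= 0) & (dam >= 0)
    add(sire[m2], dam[m2], 0.25 * alpha[m2])
    add(dam[m2], sire[m2], 0.25 * alpha[m2])

    A_inv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    return A_inv, F


def pedigree_A22(A_inv: sp.spmatrix, idx: np.ndarray) -> np.ndarray:
    """Dense pedigree relationships among ``idx`` via sparse factorization.

    Columns of A are obtained by solving A^-1 x = e_i, so no dense n x n
    matrix is ever formed.
    """
    idx = np.asarray(idx, dtype=np.int64)
    lu = spla.splu(A_inv.tocsc())
    rhs = np.zeros((A_inv.shape[0], len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)
    a22 = cols[idx, :]
    return 0.5 * (a22 + a22.T)  # symmetrize roundoff


@njit(cache=True)
def _a_matvec_flow(sire, dam, d, v):  # pragma: no cover - exercised via wrapper
    """w = A v via Colleau's pedigree-flow decomposition A = T D T'."""
    n = sire.shape[0]
    u = v.copy()
    for i in range(n - 1, -1, -1):  # u = T' v
        ui = u[i]
        if ui != 0.0:
            if sire[i] >= 0:
                u[sire[i]] += 0.5 * ui
            if dam[i] >= 0:
                u[dam[i]] += 0.5 * ui
    w = np.zeros(n)
    for i in range(n):  # w = T (D u)
        wi = d[i] * u[i]
        if sire[i] >= 0:
            wi += 0.5 * w[sire[i]]
        if dam[i] >= 0:
            wi += 0.5 * w[dam[i]]
        w[i] = wi
    return w


def pedigree_A22_flow(sire, dam, F, idx: np.ndarray) -> np.ndarray:
    """A22 by Colleau's indirect method: one A-matvec per genotyped animal.

    O(n) per column, so much faster than sparse factorization for large
    pedigrees; agrees with :func:`pedigree_A22` to machine precision.
    """
    sire = np.asarray(sire, dtype=np.int64)
    dam = np.asarray(dam, dtype=np.int64)
    idx = np.asarray(idx, dtype=np.int64)
    d = _mendelian_variances(sire, dam, np.asarray(F))
    n = len(sire)
    a22 = np.empty((len(idx), len(idx)))
    for k, j in enumerate(idx):
        v = np.zeros(n)
        v[j] = 1.0
        a22[k] = _a_matvec_flow(sire, dam, d, v)[idx]
    return 0.5 * (a22 + a22.T)


# ---------------------------------------------------------------------------
# genomic machinery


def build_G(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Dosages (n_g x m, coded 0/1/2) are centred at twice the founder allele
    frequency and cross-products scaled by 2 * sum p(1-p).
    """
    dosages = np.asarray(dosages, dtype=np.float64)
    if dosages.ndim != 2 or dosages.shape[0] < 2:
        raise ValueError("need a (n_g x m) dosage matrix with n_g >= 2")
    freqs = np.asarray(freqs, dtype=np.float64)
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    if denom == 0:
        raise ValueError("all markers monomorphic: genomic relationships undefined")
    z = dosages - 2.0 * freqs
    return (z @ z.T) / denom


def tune_and_blend_G(G: np.ndarray, A22: np.ndarray, blend: float = 0.05) -> np.ndarray:
    """Rescale G to A22's mean diagonal/off-diagonal, then blend with A22.

    The two-parameter tuning (b*G + a) makes G compatible with the pedigree
    base; the 0.95/0.05 blend guarantees invertibility.  Both match common
    single-step software defaults.
    """
    n = G.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genotyped animals")
    off = ~np.eye(n, dtype=bool)
    gd, go = G.diagonal().mean(), G[off].mean()
    ad, ao = A22.diagonal().mean(), A22[off].mean()
    if abs(gd - go) < 1e-12:
        b, a = 1.0, ad - gd
    else:
        b = (ad - ao) / (gd - go)
        a = ad - b * gd
    G_t = a + b * G
    out = (1.0 - blend) * G_t + blend * A22
    # The rank-one tuning shift can leave a marginally indefinite matrix when
    # G is near-singular (few markers relative to genotyped animals); add the
    # smallest diagonal jitter that restores a Cholesky factorization.
    jitter = 1e-8 * np.mean(out.diagonal())
    for _ in range(12):
        try:
            np.linalg.cholesky(out)
            return out
        except np.linalg.LinAlgError:
            out = out + jitter * np.eye(n)
            jitter *= 10.0
    raise np.linalg.LinAlgError("blended G could not be made positive definite")


def build_H_inverse(
    A_inv: sp.spmatrix,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    A22: np.ndarray | None = None,
) -> sp.csr_matrix:
    """Single-step H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] on the genotyped block.

    ``G`` should already be tuned/blended.  With an empty genotyped set this
    returns A^-1 unchanged (single-step reduces to pedigree BLUP).
    """
    genotyped_idx = np.asarray(genotyped_idx, dtype=np.int64)
    if genotyped_idx.size == 0:
        return A_inv.tocsr()
    if A22 is None:
        A22 = pedigree_A22(A_inv, genotyped_idx)
    try:
        G_inv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "G is singular — tune/blend it with A22 (tune_and_blend_G) before "
            "building H^-1, or remove duplicate genotypes"
        ) from err
    delta = G_inv - np.linalg.inv(A22)
    ng = len(genotyped_idx)
    block = sp.coo_matrix(
        (delta.ravel(), (np.repeat(genotyped_idx, ng), np.tile(genotyped_idx, ng))),
        shape=A_inv.shape,
    )
    return (A_inv + block).tocsr()


# ---------------------------------------------------------------------------
# mixed-model equations


def _pcg(C, b, x0, tol, max_iter):
    """Jacobi-preconditioned conjugate gradients on the (SPD) MME."""
    diag = C.diagonal()
    if np.any(diag <= 0):
        raise ValueError("non-positive diagonal in the mixed-model equations")
    minv = 1.0 / diag
    x = np.zeros_like(b) if x0 is None else x0.copy()
    r = b - C @ x
    z = minv * r
    p = z.copy()
    rz = r @ z
    bnorm = np.linalg.norm(b)
    if bnorm == 0:
        return np.zeros_like(b), 0
    for it in range(1, max_iter + 1):
        q = C @ p
        alpha = rz / (p @ q)
        x += alpha * p
        r -= alpha * q
        if np.linalg.norm(r) <= tol * bnorm:
            return x, it
        z = minv * r
        rz_new = r @ z
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise ConvergenceError(
        f"PCG did not reach relative residual {tol} in {max_iter} iterations "
        f"(final {np.linalg.norm(r) / bnorm:.2e})"
    )


def collapse_records(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeated records per (animal, herd, year) to weighted means.

    Exact for this model: within a cell all records share every fitted
    effect, so the cell mean with weight n carries the full information.
    """
    g = records.groupby(["animal", "herd", "year"], sort=False)
    out = g.agg(y=("y", "mean"), weight=("y", "size")).reset_index()
    return out


def solve_mme(
    records: pd.DataFrame,
    n_animals: int,
    k_inv: sp.spmatrix,
    spec: ModelSpec = ModelSpec(),
    *,
    model: str = "pedigree",
    year: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    x0: np.ndarray | None = None,
) -> EvaluationResult:
    """Solve the repeatability-model MME and return EBVs for every animal.

    ``records`` needs columns ``animal`` (0-based pedigree index), ``herd``,
    ``year``, ``y`` and optionally ``weight`` (number of raw records a row
    represents; default 1).  ``k_inv`` is A^-1 or H^-1 over the n_animals
    pedigree.  With no records at all, every solution is the prior mean 0.
    """
    if k_inv.shape != (n_animals, n_animals):
        raise ValueError("k_inv shape does not match n_animals")
    if len(records) == 0:
        z = np.zeros(n_animals)
        return EvaluationResult(ebv=z, pe=np.zeros(0), hy=np.zeros(0),
                                fixed=np.zeros(0), model=model, year=year)

    w = records["weight"].to_numpy(float) if "weight" in records else np.ones(len(records))
    y = records["y"].to_numpy(float)
    an = records["animal"].to_numpy(np.int64)
    if an.min() < 0 or an.max() >= n_animals:
        raise ValueError("record refers to an animal outside the pedigree")

    year_codes, _ = pd.factorize(records["year"], sort=True)
    hy_codes, _ = pd.factorize(
        records["herd"].astype(np.int64) * 1_000_003 + records["year"].astype(np.int64),
        sort=True,
    )
    pe_ids = np.unique(an)
    pe_codes = np.searchsorted(pe_ids, an)

    n_year, n_pe, n_hy = year_codes.max() + 1, len(pe_ids), hy_codes.max() + 1
    nrec = len(records)
    o_year, o_a, o_pe, o_hy = (
        0,
        n_year,
        n_year + n_animals,
        n_year + n_animals + n_pe,
    )
    n_eq = n_year + n_animals + n_pe + n_hy

    rows = np.arange(nrec)
    W = sp.coo_matrix(
        (
            np.ones(4 * nrec),
            (
                np.tile(rows, 4),
                np.concatenate(
                    [o_year + year_codes, o_a + an, o_pe + pe_codes, o_hy + hy_codes]
                ),
            ),
        ),
        shape=(nrec, n_eq),
    ).tocsr()

    lam_a = spec.sigma2_e / spec.sigma2_a
    lam_pe = spec.sigma2_e / spec.sigma2_pe
    lam_hy = spec.sigma2_e / spec.sigma2_hy

    C = (W.T @ sp.diags(w) @ W).tocsr()
    reg = sp.block_diag(
        [
            sp.csr_matrix((n_year, n_year)),
            k_inv * lam_a,
            sp.identity(n_pe) * lam_pe,
            sp.identity(n_hy) * lam_hy,
        ],
        format="csr",
    )
    C = C + reg
    rhs = W.T @ (w * y)

    sol, n_iter = _pcg(C, rhs, x0, tol, max_iter)
    return EvaluationResult(
        ebv=sol[o_a:o_pe],
        pe=sol[o_pe:o_hy],
        hy=sol[o_hy:],
        fixed=sol[:n_year],
        model=model,
        year=year,
        n_iterations=n_iter,
    )


# ---------------------------------------------------------------------------
# training-population management


@dataclass
class TrainingPopulation:
    """Genotyped-animal set with a hard cap (software genotype limit).

    When the cap is exceeded, genotypes of the oldest-genotyped animals are
    dropped first (ties by ascending id); phenotypes are never touched.
    """

    cap: int
    ids: list[int]
    geno_years: list[int]

    @classmethod
    def empty(cls, cap: int) -> "TrainingPopulation":
        return cls(cap=cap, ids=[], geno_years=[])

    @property
    def size(self) -> int:
        return len(self.ids)

    def update(self, new_ids, year: int) -> list[int]:
        """Add newly genotyped animals; return ids whose genotypes were dropped."""
        for i in new_ids:
            self.ids.append(int(i))
            self.geno_years.append(int(year))
        dropped: list[int] = []
        if len(self.ids) > self.cap:
            order = sorted(range(len(self.ids)), key=lambda k: (self.geno_years[k], self.ids[k]))
            n_drop = len(self.ids) - self.cap
            drop_set = set(order[:n_drop])
            dropped = [self.ids[k] for k in sorted(drop_set)]
            self.ids = [v for k, v in enumerate(self.ids) if k not in drop_set]
            self.geno_years = [v for k, v in enumerate(self.geno_years) if k not in drop_set]
        return dropped
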