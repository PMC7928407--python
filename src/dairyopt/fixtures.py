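"""Deterministic toy datasets with independently computed expected answers.

Everything here is synthetic and tiny (milliseconds to build), so every
numerical module can be tested without running the full simulator.  The
oracle solutions are computed by a *dense* algebra path — tabular
relationship recursion and direct matrix inversion — deliberately separate
from the sparse/PCG production code it validates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ToyDataset", "tabular_A", "make_toy_pedigree", "make_toy_mixed_model",
           "dense_mme_solution"]


@dataclass
class ToyDataset:
    """Small pedigree/records bundle plus dense-oracle expected values."""

    pedigree: pd.DataFrame  # id, sire, dam, sex (-1 = unknown parent)
    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    A: np.ndarray | None = None  # dense numerator relationship (oracle)
    oracle_ebv: np.ndarray | None = None
    sigma2: dict | None = None

    @property
    def sire(self) -> np.ndarray:
        return self.pedigree["sire"].to_numpy(np.int64)

    @property
    def dam(self) -> np.ndarray:
        return self.pedigree["dam"].to_numpy(np.int64)


def tabular_A(sire, dam) -> np.ndarray:
    """Numerator relationship matrix by the tabular recursion (dense oracle).

    a_ij = 0.5 (a_{j,s(i)} + a_{j,d(i)}) for j < i;
    a_ii = 1 + 0.5 a_{s(i),d(i)}.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            val = 0.0
            if s >= 0:
                val += 0.5 * A[j, s]
            if d >= 0:
                val += 0.5 * A[j, d]
            A[i, j] = A[j, i] = val
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A


def make_toy_pedigree(depth: int = 3, seed: int = 0) -> ToyDataset:
    """Small pedigree (<= 20 animals) containing one inbred full-sib loop.

    Founders first, then ``depth`` layers of offspring; the last layer mates
    two full sibs so at least one animal is inbred.
    """
    if depth > 5:
        raise ValueError("depth must be <= 5 for a toy pedigree")
    rng = np.random.default_rng(seed)
    sire, dam, sex = [-1, -1, -1, -1], [-1, -1, -1, -1], [1, 1, 0, 0]
    males, females = [0, 1], [2, 3]
    for _ in range(max(0, depth - 1)):
        for _ in range(2):
            s = int(rng.choice(males))
            d = int(rng.choice(females))
            sx = int(rng.integers(0, 2))
            sire.append(s)
            dam.append(d)
            sex.append(sx)
            (males if sx == 1 else females).append(len(sire) - 1)
    # full sibs, then their inbred offspring
    s0, d0 = males[0], females[0]
    for sx in (1, 0):
        sire.append(s0)
        dam.append(d0)
        sex.append(sx)
    sire.append(len(sire) - 2)
    dam.append(len(dam) - 1)
    sex.append(1)
    ped = pd.DataFrame({"id": np.arange(len(sire)), "sire": sire, "dam": dam, "sex": sex})
    return ToyDataset(pedigree=ped, A=tabular_A(sire, dam))


def dense_mme_solution(
    records: pd.DataFrame,
    A: np.ndarray,
    sigma2_a: float = 1.0,
    sigma2_pe: float = 1.0,
    sigma2_hy: float = 2.0 / 3.0,
    sigma2_e: float = 4.0 / 3.0,
) -> np.ndarray:
    """EBVs by direct dense inversion of the mixed-model equations (oracle).

    Same model definition as the production solver (year mean fixed; animal,
    permanent-environment, herd-year random) but assembled with dense design
    matrices and solved with numpy's direct solver.
    """
    n_animals = A.shape[0]
    if len(records) == 0:
        return np.zeros(n_animals)
    w = records["weight"].to_numpy(float) if "weight" in records else np.ones(len(records))
    y = records["y"].to_numpy(float)
    an = records["animal"].to_numpy(np.int64)
    years = pd.factorize(records["year"], sort=True)[0]
    hys = pd.factorize(records["herd"].astype(str) + "_" + records["year"].astype(str),
                       sort=True)[0]
    pe_ids = np.unique(an)
    pes = np.searchsorted(pe_ids, an)
    nrec = len(records)

    def design(codes, ncol):
        Z = np.zeros((nrec, ncol))
        Z[np.arange(nrec), codes] = 1.0
        return Z

    X = design(years, years.max() + 1)
    Za = design(an, n_animals)
    Zp = design(pes, len(pe_ids))
    Zh = design(hys, hys.max() + 1)
    W = np.hstack([X, Za, Zp, Zh])
    C = W.T @ np.diag(w) @ W
    o = X.shape[1]
    C[o: o + n_animals, o: o + n_animals] += np.linalg.inv(A) * (sigma2_e / sigma2_a)
    o2 = o + n_animals
    C[o2: o2 + len(pe_ids), o2: o2 + len(pe_ids)] += np.eye(len(pe_ids)) * (
        sigma2_e / sigma2_pe
    )
    o3 = o2 + len(pe_ids)
    C[o3:, o3:] += np.eye(hys.max() + 1) * (sigma2_e / sigma2_hy)
    sol = np.linalg.solve(C, W.T @ (w * y))
    return sol[o: o + n_animals]


def make_toy_mixed_model(n_animals: int = 10, n_records: int = 20, seed: int = 0) -> ToyDataset:
    """Pedigree + repeated records with the dense-oracle EBV vector attached."""
    if n_animals > 20:
        raise ValueError("toy datasets are capped at 20 animals")
    rng = np.random.default_rng(seed)
    n_founders = max(2, n_animals // 3)
    sire = np.full(n_animals, -1, dtype=np.int64)
    dam = np.full(n_animals, -1, dtype=np.int64)
    sex = np.array([1, 0] * (n_animals // 2 + 1))[:n_animals]
    for i in range(n_founders, n_animals):
        males = np.flatnonzero(sex[:i] == 1)
        females = np.flatnonzero(sex[:i] == 0)
        if len(males) and len(females):
            sire[i] = rng.choice(males)
            dam[i] = rng.choice(females)
    A = tabular_A(sire, dam)

    sig = dict(sigma2_a=1.0, sigma2_pe=1.0, sigma2_hy=2.0 / 3.0, sigma2_e=4.0 / 3.0)
    a = np.linalg.cholesky(A + 1e-10 * np.eye(n_animals)) @ rng.standard_normal(n_animals)
    pe = rng.normal(0, 1, n_animals)
    rows = []
    for r in range(n_records):
        i = int(rng.integers(0, n_animals))
        herd = int(rng.integers(0, 2))
        year = int(rng.integers(0, 2))
        hy_eff = np.sin(herd * 3 + year)  # fixed realized values, any will do
        e = rng.normal(0, np.sqrt(sig["sigma2_e"]))
        rows.append({"animal": i, "herd": herd, "year": year,
                     "y": a[i] + pe[i] + hy_eff + e, "weight": 1.0})
    records = pd.DataFrame(rows)
    ped = pd.DataFrame({"id": np.arange(n_animals), "sire": sire, "dam": dam, "sex": sex})
    oracle = dense_mme_solution(records, A, **sig)
    return ToyDataset(pedigree=ped, records=records, A=A, oracle_ebv=oracle, sigma2=sig)
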