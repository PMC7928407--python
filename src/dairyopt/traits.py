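"""Repeated test-day phenotypes for a dairy trait.

The phenotype model is

    y_ijkl = a_i + p_i + h_j + hy_jk + htd_jkl + e_ijkl

with additive genetic (a), permanent environment (p), herd (h), herd-year
(hy), herd-test-day (htd) and residual (e) effects.  In additive-variance
units the components are 1, 1, 1/3, 1/3, 1/3 and 1, which gives a trait with
heritability 0.25 and repeatability 0.50 (animal-level record correlation).
Each cow keeps one herd for life; herd effects are constant, herd-year
effects are redrawn per year and herd-test-day effects per recording day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceComponents",
    "TestDayRecord",
    "HerdStructure",
    "assign_herds",
    "record_lactation",
    "realized_ratios",
]

MAX_RECORDS_PER_LACTATION = 11


@dataclass(frozen=True)
class VarianceComponents:
    """Phenotype variance components in units of the additive variance."""

    sigma2_a: float = 1.0
    sigma2_p: float = 1.0
    sigma2_h: float = 1.0 / 3.0
    sigma2_hy: float = 1.0 / 3.0
    sigma2_htd: float = 1.0 / 3.0
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_p", "sigma2_h", "sigma2_hy", "sigma2_htd", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> float:
        return (self.sigma2_a + self.sigma2_p + self.sigma2_h
                + self.sigma2_hy + self.sigma2_htd + self.sigma2_e)

    @property
    def heritability(self) -> float:
        return self.sigma2_a / self.total

    @property
    def repeatability(self) -> float:
        """Correlation of two records sharing only animal-level effects (a, p)."""
        return (self.sigma2_a + self.sigma2_p) / self.total

    # The evaluation model does not fit herd or herd-test-day: herd folds into
    # herd-year and herd-test-day into the residual.
    @property
    def model_herd_year(self) -> float:
        return self.sigma2_h + self.sigma2_hy

    @property
    def model_residual(self) -> float:
        return self.sigma2_htd + self.sigma2_e


@dataclass(frozen=True)
class TestDayRecord:
    animal_id: int
    herd: int
    year: int
    test_day: int
    lactation: int
    y: float

    def __post_init__(self) -> None:
        if self.lactation < 1:
            raise ValueError("lactation number must be >= 1")
        if not 1 <= self.test_day <= MAX_RECORDS_PER_LACTATION:
            raise ValueError("test-day index out of range")


@dataclass
class HerdStructure:
    """Lifetime herd assignment plus the herd-level random effects.

    Herd-year and herd-test-day effects are drawn lazily per year from a
    dedicated child generator so that the draw for a given (herd, year) is
    independent of call order.
    """

    n_herds: int
    herd_of: dict[int, int]  # animal id -> herd
    herd_effects: np.ndarray  # (n_herds,)
    vc: VarianceComponents
    _year_seed: int = 0

    def year_effects(self, year: int, n_test_days: int) -> tuple[np.ndarray, np.ndarray]:
        """(hy[herd], htd[herd, test_day]) for one year."""
        # domain tag keeps this stream disjoint from the herd-effect draws
        rng = np.random.default_rng(
            np.random.SeedSequence((self._year_seed, 0x9E37, year + 1))
        )
        hy = rng.normal(0.0, np.sqrt(self.vc.sigma2_hy), size=self.n_herds)
        htd = rng.normal(0.0, np.sqrt(self.vc.sigma2_htd), size=(self.n_herds, n_test_days))
        return hy, htd

    def assign(self, animal_ids, rng: np.random.Generator) -> None:
        """Assign new cows to uniformly random herds (kept for life)."""
        herds = rng.integers(0, self.n_herds, size=len(animal_ids))
        for a, h in zip(animal_ids, herds):
            self.herd_of[int(a)] = int(h)


def assign_herds(cow_ids, n_herds: int, vc: VarianceComponents, seed: int) -> HerdStructure:
    if n_herds < 1:
        raise ValueError("n_herds must be >= 1")
    rng = np.random.default_rng(seed)
    hs = HerdStructure(
        n_herds=n_herds,
        herd_of={},
        herd_effects=rng.normal(0.0, np.sqrt(vc.sigma2_h), size=n_herds),
        vc=vc,
        _year_seed=seed,
    )
    hs.assign(cow_ids, rng)
    return hs


def record_lactation(
    animal_id: int,
    tbv: float,
    pe: float,
    herd: int,
    year: int,
    lactation: int,
    n_records: int,
    vc: VarianceComponents,
    hy_j: float,
    htd_j: np.ndarray,
    rng: np.random.Generator,
    herd_effect: float = 0.0,
) -> list[TestDayRecord]:
    """One lactation of repeated test-day records for one cow.

    a, p, h and hy are shared across the lactation's records; htd (passed per
    test day, shared by herd mates) and the residual are fresh per record.
    """
    if not 1 <= n_records <= MAX_RECORDS_PER_LACTATION:
        raise ValueError(f"n_records must be in [1, {MAX_RECORDS_PER_LACTATION}]")
    if len(htd_j) < n_records:
        raise ValueError("need one herd-test-day effect per record")
    e = rng.normal(0.0, np.sqrt(vc.sigma2_e), size=n_records)
    base = tbv + pe + herd_effect + hy_j
    return [
        TestDayRecord(animal_id=animal_id, herd=herd, year=year, test_day=l + 1,
                      lactation=lactation, y=float(base + htd_j[l] + e[l]))
        for l in range(n_records)
    ]


def records_to_frame(records: list[TestDayRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def realized_ratios(records: pd.DataFrame, animals: pd.DataFrame) -> tuple[float, float]:
    """Empirical heritability and repeatability realized in simulated records.

    ``animals`` carries the simulation's animal-level truth (columns
    ``animal_id``, ``tbv``, ``pe``).  Heritability is var(a)/var(y) and
    repeatability var(a + p)/var(y) — the correlation of records sharing
    only animal-level effects.  The within-herd-year record correlation is
    higher (records also share h and hy) and is not what these ratios
    measure.
    """
    counts = records.groupby("animal_id").size()
    if (counts >= 2).sum() < 100:
        raise ValueError("need >= 2 records for >= 100 animals")
    merged = records.merge(animals[["animal_id", "tbv", "pe"]], on="animal_id")
    var_y = merged["y"].var(ddof=1)
    per_animal = merged.drop_duplicates("animal_id")
    h2 = per_animal["tbv"].var(ddof=1) / var_y
    rep = (per_animal["tbv"] + per_animal["pe"]).var(ddof=1) / var_y
    return float(h2), float(rep)
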