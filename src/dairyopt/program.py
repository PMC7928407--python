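"""Year-by-year stochastic simulation of a small dairy breeding program.

The program mimics a closed population of roughly 22,500 animals with
~10,850 active cows.  Each year: calves are born from the matings planned
the year before, cows age through at most four parities (with culling tuned
once so the active-cow census stays at target), active cows produce repeated
test-day records, designated animals are genotyped, breeding values are
estimated (pedigree BLUP, or single-step GBLUP once genotypes exist), and
the next round of selections and matings is made.

Selection structure (conventional path): 3,849 of 4,320 newborn females are
kept as replacements; 139 bull dams are picked from cows in parities 2-4;
elite matings of bull dams with proven sires produce 45 male calves, of
which the top 8 by parent average enter progeny testing and 4 are eventually
selected as proven sires.  Genomic scenarios instead genotype a budgeted
number of male calves (always including all elite calves) and select the 5
highest genomic breeding values as sires immediately, which collapses the
sire generation interval.

All quotas scale multiplicatively (with small floors) through
``ProgramConfig.scaled`` so that the same program can be run desk-scale.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .allocation import (
    CostModel,
    GenotypingBudget,
    TrainingPopPolicy,
    apply_tp_policy,
    genotyping_counts,
    annual_savings,
)
from .evaluation import (
    ModelSpec,
    TrainingPopulation,
    build_A_inverse,
    build_G,
    build_H_inverse,
    inbreeding,
    pedigree_A22_flow,
    solve_mme,
    tune_and_blend_G,
)
from .genome import (
    FounderPopulation,
    GenomeSpec,
    QtlEffects,
    meiosis,
    sample_qtl_effects,
    simulate_founders,
    true_breeding_value,
)
from .traits import HerdStructure, VarianceComponents, assign_herds

__all__ = [
    "ProgramConfig",
    "ScenarioSpec",
    "BreedingProgram",
    "initialize_program",
    "select_females",
    "select_bull_dams",
    "elite_matings",
    "choose_male_candidates",
    "select_sires",
]

FEMALE, MALE = 0, 1

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProgramConfig:
    """Census and quota structure of the breeding program."""

    newborn_females_per_year: int = 4320
    newborn_males_per_year: int = 4320  # mirror of female births (sex ratio 1/2)
    selected_females: int = 3849
    bull_dams: int = 139
    elite_male_calves: int = 45
    progeny_test_males: int = 8
    proven_sires_conventional: int = 4
    proven_sires_genomic: int = 5
    active_cows_target: int = 10852
    max_parities: int = 4
    bull_dam_parities: tuple[int, ...] = (2, 3, 4)
    test_share: float = 0.20  # fraction of commercial matings to test sires
    progeny_test_age: int = 5  # sire age at proven selection (daughters recorded)
    burnin_years: int = 20
    eval_years: int = 20
    n_herds: int = 100
    elite_sire_memory: int = 80  # recent proven sires in the initial TP
    genotype_cap: int = 25000
    tp_threshold: int = 2000

    def __post_init__(self) -> None:
        if self.selected_females > self.newborn_females_per_year:
            raise ValueError("cannot select more females than are born")
        if self.progeny_test_males > self.elite_male_calves:
            raise ValueError("cannot progeny-test more males than elite calves")

    def scaled(self, factor: float) -> "ProgramConfig":
        """Shrink all census numbers by ``factor`` with structural floors."""
        if not 0 < factor <= 1:
            raise ValueError("scale factor must be in (0, 1]")
        if factor == 1.0:
            return self

        def s(x: int, floor: int = 1) -> int:
            return max(floor, round(x * factor))

        # Male-path quotas keep their structural values: scaling the number
        # of proven sires below ~4 would turn the sire path into pure drift
        # and destroy the two-stage selection structure the study compares.
        test_males = self.progeny_test_males
        elite = max(s(self.elite_male_calves), 2 * test_males)
        nf = s(self.newborn_females_per_year, 8)
        return replace(
            self,
            newborn_females_per_year=nf,
            newborn_males_per_year=max(s(self.newborn_males_per_year, 8), elite),
            selected_females=min(s(self.selected_females, 6), nf),
            bull_dams=max(s(self.bull_dams), elite),
            elite_male_calves=elite,
            progeny_test_males=test_males,
            active_cows_target=s(self.active_cows_target, 20),
            n_herds=s(self.n_herds),
            elite_sire_memory=s(self.elite_sire_memory),
            genotype_cap=s(self.genotype_cap),
            tp_threshold=s(self.tp_threshold),
        )

    def parity_cohort_sizes(self) -> list[int]:
        """Per-parity cow cohort targets summing ~ to the active-cow census.

        A single per-parity survival rate s is solved once from
        selected * (1 + s + ... + s^(P-1)) = target.
        """
        ratio = self.active_cows_target / self.selected_females
        P = self.max_parities
        if ratio <= 1:
            s_rate = 0.0
        elif ratio >= P:
            s_rate = 1.0
        else:
            s_rate = brentq(
                lambda s: sum(s**p for p in range(P)) - ratio, 1e-9, 1.0
            )
        return [max(1, round(self.selected_females * s_rate**p)) for p in range(P)]


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study grid.

    ``cost`` is None for the conventional scenario (no genotyping); genomic
    scenarios derive their yearly genotyping budget from the cost model and
    run under the given training-population policy.
    """

    name: str
    n_records: int
    cost: CostModel | None = None
    tp_policy: TrainingPopPolicy | None = None
    budget: GenotypingBudget | None = None  # overrides the cost-model derivation

    @property
    def is_genomic(self) -> bool:
        return self.cost is not None or self.budget is not None


# ---------------------------------------------------------------------------
# selection operations (pure functions over arrays)


def _top_k(ids: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Top k by score, ties broken by ascending id (reproducibility)."""
    order = np.lexsort((ids, -np.asarray(scores, float)))
    return np.asarray(ids)[order[:k]]


def select_females(cohort_ids, ebvs, quota: int) -> np.ndarray:
    """Keep the top ``quota`` newborn females by (pedigree) EBV."""
    cohort_ids = np.asarray(cohort_ids)
    if len(cohort_ids) < quota:
        raise ValueError(f"cohort of {len(cohort_ids)} smaller than quota {quota}")
    return _top_k(cohort_ids, ebvs, quota)


def select_bull_dams(cow_ids, parities, ebvs, quota: int,
                     eligible_parities=(2, 3, 4)) -> np.ndarray:
    """Top ``quota`` cows by EBV among parities 2-4."""
    cow_ids = np.asarray(cow_ids)
    mask = np.isin(np.asarray(parities), eligible_parities)
    if mask.sum() < quota:
        raise ValueError(f"only {mask.sum()} eligible cows for {quota} bull dams")
    return _top_k(cow_ids[mask], np.asarray(ebvs, float)[mask], quota)


def elite_matings(bull_dam_ids, proven_sire_ids, n_calves: int,
                  rng: np.random.Generator) -> list[tuple[int, int]]:
    """(sire, dam) pairs for the elite male calves; sires allocated evenly."""
    sires = np.asarray(proven_sire_ids)
    dams = np.asarray(bull_dam_ids)
    if sires.size == 0:
        raise ValueError("need at least one proven sire")
    chosen = rng.choice(dams, size=n_calves, replace=n_calves > dams.size)
    return [(int(sires[i % sires.size]), int(chosen[i])) for i in range(n_calves)]


def choose_male_candidates(
    elite_ids, general_ids, parent_avg: dict[int, float], budget: int
) -> np.ndarray:
    """Male calves to genotype: all elite calves plus top parent-average
    calves from the general pool, up to ``budget``.

    A budget below the elite-calf count (never on the study grid) truncates
    the elite set itself by parent average.
    """
    if budget < 0:
        raise ValueError("budget must be non-negative")
    elite_ids = np.asarray(elite_ids)
    general_ids = np.asarray(general_ids)
    if budget <= len(elite_ids):
        return _top_k(elite_ids, [parent_avg[int(i)] for i in elite_ids], budget)
    extra = min(budget - len(elite_ids), len(general_ids))
    top_general = _top_k(general_ids, [parent_avg[int(i)] for i in general_ids], extra)
    return np.concatenate([np.sort(elite_ids), top_general])


def select_sires(candidate_ids, ebvs, quota: int) -> np.ndarray:
    """Top ``quota`` candidates by (genomic) EBV become proven sires."""
    candidate_ids = np.asarray(candidate_ids)
    if len(candidate_ids) < quota:
        raise ValueError(f"only {len(candidate_ids)} candidates for {quota} sire slots")
    return _top_k(candidate_ids, ebvs, quota)


# ---------------------------------------------------------------------------
# population state


class Population:
    """Columnar animal table plus haplotype store (grown geometrically)."""

    def __init__(self, n_loci: int, capacity: int = 1024):
        self.n = 0
        self.n_loci = n_loci
        self._cap = capacity
        self.sire = np.full(capacity, -1, dtype=np.int64)
        self.dam = np.full(capacity, -1, dtype=np.int64)
        self.sex = np.zeros(capacity, dtype=np.int8)
        self.birth_year = np.zeros(capacity, dtype=np.int32)
        self.tbv = np.zeros(capacity)
        self.pe = np.zeros(capacity)
        self.parity = np.zeros(capacity, dtype=np.int16)
        self.herd = np.full(capacity, -1, dtype=np.int32)
        self.ebv = np.zeros(capacity)
        self.alive = np.zeros(capacity, dtype=bool)
        self.genotyped = np.zeros(capacity, dtype=bool)
        self.is_cow = np.zeros(capacity, dtype=bool)
        self.selected = np.zeros(capacity, dtype=bool)  # female replacements
        self.phenotyped = np.zeros(capacity, dtype=bool)
        self.haplo = np.zeros((capacity, 2, n_loci), dtype=np.uint8)

    def _grow(self, need: int) -> None:
        if self.n + need <= self._cap:
            return
        new_cap = max(self._cap * 2, self.n + need)
        for name in ("sire", "dam", "sex", "birth_year", "tbv", "pe", "parity",
                     "herd", "ebv", "alive", "genotyped", "is_cow", "selected",
                     "phenotyped"):
            old = getattr(self, name)
            fresh = np.zeros(new_cap, dtype=old.dtype)
            if name in ("sire", "dam", "herd"):
                fresh[:] = -1
            fresh[: self.n] = old[: self.n]
            setattr(self, name, fresh)
        h = np.zeros((new_cap, 2, self.n_loci), dtype=np.uint8)
        h[: self.n] = self.haplo[: self.n]
        self.haplo = h
        self._cap = new_cap

    def add(self, n_new: int, **cols) -> np.ndarray:
        self._grow(n_new)
        idx = np.arange(self.n, self.n + n_new)
        self.n += n_new
        for name, val in cols.items():
            getattr(self, name)[idx] = val
        return idx


# ---------------------------------------------------------------------------
# the program


class BreedingProgram:
    """Stateful simulator; see module docstring for the yearly cycle."""

    def __init__(
        self,
        founders: FounderPopulation,
        qtl: QtlEffects,
        config: ProgramConfig,
        vc: VarianceComponents = VarianceComponents(),
        seed: int = 0,
    ):
        self.config = config
        self.vc = vc
        self.spec = founders.genome_map.spec
        self.gmap = founders.genome_map
        self.qtl = qtl
        self.marker_idx = self.gmap.marker_idx
        self.marker_freqs = founders.allele_frequencies()[self.marker_idx]
        self.rng = np.random.default_rng(seed)
        self.year = 0
        self.model_spec = ModelSpec(
            sigma2_a=vc.sigma2_a, sigma2_pe=vc.sigma2_p,
            sigma2_hy=vc.model_herd_year, sigma2_e=vc.model_residual,
        )

        cohort_sizes = config.parity_cohort_sizes()
        n_cows = sum(cohort_sizes)
        n_heifers = 2 * config.selected_females
        n_test = config.progeny_test_males * config.progeny_test_age
        n_males = n_test + config.proven_sires_conventional
        n_founders_needed = n_cows + n_heifers + n_males
        if founders.n_founders < n_founders_needed:
            raise ValueError(
                f"need {n_founders_needed} founders, got {founders.n_founders}"
            )

        self.pop = Population(n_loci=founders.haplotypes.shape[2],
                              capacity=2 * n_founders_needed)
        self.F = np.zeros(0)  # full-pedigree inbreeding, extended lazily
        self.records: list[tuple[np.ndarray, ...]] = []  # collapsed record blocks
        self.tp = TrainingPopulation.empty(cap=config.genotype_cap)
        self.marker_store: dict[int, np.ndarray] = {}
        self.elite_sire_history: list[int] = []
        self.elite_flag: dict[int, bool] = {}
        self.yearly: list[dict] = []
        self._last_solution = None
        self._census_raise = 0.10

        self._init_founders(founders, cohort_sizes)
        self.herds = assign_herds(
            self.pop_ids(self.pop.is_cow), config.n_herds, vc,
            seed=int(self.rng.integers(2**31 - 1)),
        )
        self._plan_matings(genomic=False)

    # -- helpers ----------------------------------------------------------

    def pop_ids(self, mask: np.ndarray) -> np.ndarray:
        return np.flatnonzero(mask[: self.pop.n])

    def _init_founders(self, founders: FounderPopulation, cohort_sizes: list[int]) -> None:
        cfg = self.config
        perm = self.rng.permutation(founders.n_founders)
        cursor = 0

        def take(k):
            nonlocal cursor
            rows = perm[cursor: cursor + k]
            cursor += k
            return rows

        tbv_all = true_breeding_value(founders.haplotypes, self.qtl)
        pe_sd = np.sqrt(self.vc.sigma2_p)

        def add(rows, sex, parity, birth_year, **extra):
            idx = self.pop.add(
                len(rows), sex=sex, parity=parity, birth_year=birth_year,
                tbv=tbv_all[rows], pe=self.rng.normal(0, pe_sd, len(rows)),
                alive=True, **extra,
            )
            self.pop.haplo[idx] = founders.haplotypes[rows]
            return idx

        # cows in parities 1..P (parity p cohort born year -(p+1))
        for p, size in enumerate(cohort_sizes, start=1):
            add(take(size), FEMALE, p, -(p + 1), is_cow=True, selected=True)
        # replacement heifers born years -1 and 0
        for by in (-1, 0):
            add(take(cfg.selected_females), FEMALE, 0, by, selected=True)
        # progeny-test male cohorts born years -(age-1) .. 0
        self.test_cohorts: dict[int, np.ndarray] = {}
        for by in range(-(cfg.progeny_test_age - 1), 1):
            idx = add(take(cfg.progeny_test_males), MALE, 0, by)
            self.test_cohorts[by] = idx
        # founder proven sires
        self.proven_sires = add(
            take(cfg.proven_sires_conventional), MALE, 0, -(cfg.progeny_test_age + 1)
        )
        self.elite_sire_history.extend(int(i) for i in self.proven_sires)

    # -- yearly cycle ------------------------------------------------------

    def _plan_matings(self, genomic: bool) -> None:
        """Decide next year's calves: (sire, dam, sex, elite) per calf."""
        cfg = self.config
        cows = self.pop_ids(self.pop.is_cow)
        dams_pool = cows
        bd = getattr(self, "bull_dam_ids", None)
        if bd is None or len(bd) == 0:
            bd = select_bull_dams(
                cows, self.pop.parity[cows], self.pop.ebv[cows], cfg.bull_dams,
                cfg.bull_dam_parities,
            )
        pairs = elite_matings(bd, self.proven_sires, cfg.elite_male_calves, self.rng)

        n_general_m = cfg.newborn_males_per_year - cfg.elite_male_calves
        n_general = cfg.newborn_females_per_year + n_general_m
        pool = np.setdiff1d(dams_pool, np.asarray([d for _, d in pairs]))
        if len(pool) >= n_general:
            gen_dams = self.rng.choice(pool, size=n_general, replace=False)
        else:
            gen_dams = self.rng.choice(pool, size=n_general, replace=True)

        test_cohort = self.test_cohorts.get(self.year, np.array([], dtype=np.int64))
        n_test_mat = (
            0 if genomic or len(test_cohort) == 0
            else round(cfg.test_share * n_general)
        )
        gen_sires = np.empty(n_general, dtype=np.int64)
        if n_test_mat:
            gen_sires[:n_test_mat] = test_cohort[np.arange(n_test_mat) % len(test_cohort)]
        n_prov = n_general - n_test_mat
        gen_sires[n_test_mat:] = np.asarray(self.proven_sires)[
            np.arange(n_prov) % len(self.proven_sires)
        ]
        order = self.rng.permutation(n_general)
        gen_sires, gen_dams = gen_sires[order], gen_dams[order]

        sexes = np.concatenate([
            np.full(cfg.elite_male_calves, MALE, dtype=np.int8),
            np.full(cfg.newborn_females_per_year, FEMALE, dtype=np.int8),
            np.full(n_general_m, MALE, dtype=np.int8),
        ])
        sires = np.concatenate([[s for s, _ in pairs], gen_sires])
        dams = np.concatenate([[d for _, d in pairs], gen_dams])
        elite = np.zeros(len(sires), dtype=bool)
        elite[: cfg.elite_male_calves] = True
        self._planned = (sires.astype(np.int64), dams.astype(np.int64), sexes, elite)

    def _births(self) -> np.ndarray:
        sires, dams, sexes, elite = self._planned
        n = len(sires)
        haplo = np.empty((n, 2, self.pop.n_loci), dtype=np.uint8)
        for i in range(n):
            haplo[i, 0] = meiosis(self.pop.haplo[sires[i]], self.gmap, self.rng)
            haplo[i, 1] = meiosis(self.pop.haplo[dams[i]], self.gmap, self.rng)
        tbv = true_breeding_value(haplo, self.qtl)
        idx = self.pop.add(
            n, sire=sires, dam=dams, sex=sexes, birth_year=self.year,
            tbv=tbv, pe=self.rng.normal(0, np.sqrt(self.vc.sigma2_p), n),
            alive=True,
        )
        self.pop.haplo[idx] = haplo
        for i, e in zip(idx, elite):
            if e:
                self.elite_flag[int(i)] = True
        return idx

    def _age_and_cull(self) -> None:
        cfg = self.config
        p = self.pop
        cows = self.pop_ids(p.is_cow)
        p.parity[cows] += 1
        # promote replacement heifers born year-2
        heifers = self.pop_ids(
            p.selected & (p.sex == FEMALE) & (p.birth_year == self.year - 2)
            & ~p.is_cow & p.alive
        )
        p.is_cow[heifers] = True
        p.parity[heifers] = 1
        self.herds.assign(heifers, self.rng)
        # cull beyond max parity, then trim each cohort to target (lowest EBV out)
        targets = cfg.parity_cohort_sizes()
        for par in range(1, cfg.max_parities + 2):
            cohort = self.pop_ids(p.is_cow & (p.parity == par) & p.alive)
            target = targets[par - 1] if par <= cfg.max_parities else 0
            if len(cohort) > target:
                order = np.lexsort((cohort, p.ebv[cohort]))
                out = cohort[order[: len(cohort) - target]]
                p.alive[out] = False
                p.is_cow[out] = False
        active = self.pop_ids(p.is_cow & p.alive)
        drift = abs(len(active) - cfg.active_cows_target) / cfg.active_cows_target
        if drift > self._census_raise:
            raise RuntimeError(
                f"active-cow census {len(active)} drifted beyond "
                f"{self._census_raise:.0%} of target {cfg.active_cows_target}"
            )

    def _phenotype(self, n_records: int) -> None:
        p = self.pop
        cows = self.pop_ids(p.is_cow & p.alive)
        herds = np.array([self.herds.herd_of[int(c)] for c in cows])
        hy, htd = self.herds.year_effects(self.year, n_records)
        htd_mean = htd[:, :n_records].mean(axis=1)
        e_mean = self.rng.normal(0, np.sqrt(self.vc.sigma2_e / n_records), len(cows))
        y = (p.tbv[cows] + p.pe[cows] + self.herds.herd_effects[herds]
             + hy[herds] + htd_mean[herds] + e_mean)
        p.phenotyped[cows] = True
        self.records.append((
            cows.copy(), herds.astype(np.int64),
            np.full(len(cows), self.year, dtype=np.int64),
            y, np.full(len(cows), float(n_records)),
        ))

    def _record_frame(self, keep: np.ndarray | None = None) -> pd.DataFrame:
        blocks = self.records
        an = np.concatenate([b[0] for b in blocks])
        df = pd.DataFrame({
            "animal": an,
            "herd": np.concatenate([b[1] for b in blocks]),
            "year": np.concatenate([b[2] for b in blocks]),
            "y": np.concatenate([b[3] for b in blocks]),
            "weight": np.concatenate([b[4] for b in blocks]),
        })
        if keep is not None:
            df = df[np.isin(df["animal"], keep)]
        return df

    def _evaluate(self) -> None:
        """Yearly evaluation; writes EBVs back to the population table."""
        p = self.pop
        self.F = inbreeding(p.sire[: p.n], p.dam[: p.n], known_f=self.F)
        core = self.pop_ids(p.alive | p.phenotyped)
        tp_ids = np.asarray(self.tp.ids, dtype=np.int64)
        core = np.union1d(core, tp_ids)
        incl = core
        for _ in range(3):  # three ancestral generations
            parents = np.concatenate([p.sire[incl], p.dam[incl]])
            incl = np.union1d(incl, parents[parents >= 0])
        incl = np.sort(incl)
        local = np.full(p.n, -1, dtype=np.int64)
        local[incl] = np.arange(len(incl))
        sub_sire = np.where(p.sire[incl] >= 0, local[p.sire[incl]], -1)
        sub_dam = np.where(p.dam[incl] >= 0, local[p.dam[incl]], -1)

        a_inv, _ = build_A_inverse(sub_sire, sub_dam, known_f=self.F[incl])
        model = "pedigree"
        k_inv = a_inv
        if self.tp.size >= 2:
            g_local = local[tp_ids]
            dos = np.stack([self.marker_store[int(i)] for i in tp_ids]).astype(np.float64)
            a22 = pedigree_A22_flow(sub_sire, sub_dam, self.F[incl], g_local)
            g = tune_and_blend_G(build_G(dos, self.marker_freqs), a22)
            k_inv = build_H_inverse(a_inv, g, g_local, a22)
            model = "single-step"

        recs = self._record_frame(keep=incl)
        recs["animal"] = local[recs["animal"].to_numpy()]
        res = solve_mme(recs, len(incl), k_inv, self.model_spec,
                        model=model, year=self.year)
        p.ebv[incl] = res.ebv
        self._last_solution = res
        self._model_used = model

    def _genotype_animals(self, ids: np.ndarray) -> None:
        p = self.pop
        fresh = np.asarray([i for i in ids if not p.genotyped[i]], dtype=np.int64)
        if fresh.size == 0:
            return
        p.genotyped[fresh] = True
        for i in fresh:
            self.marker_store[int(i)] = (
                self.pop.haplo[i, :, self.marker_idx].sum(axis=1).astype(np.uint8)
            )
        self.tp.update(fresh, self.year)

    def parent_average(self, ids: np.ndarray) -> np.ndarray:
        p = self.pop
        pa = np.zeros(len(ids))
        for k, i in enumerate(ids):
            vals = []
            if p.sire[i] >= 0:
                vals.append(p.ebv[p.sire[i]])
            if p.dam[i] >= 0:
                vals.append(p.ebv[p.dam[i]])
            pa[k] = np.mean(vals) if vals else 0.0
        return pa

    def tp_cow_count(self) -> int:
        p = self.pop
        return int(sum(p.sex[i] == FEMALE for i in self.tp.ids))

    # -- one year ---------------------------------------------------------

    def step_year(self, scenario: ScenarioSpec | None = None) -> None:
        """Advance the program by one year under the given scenario policy.

        ``scenario=None`` (or a non-genomic scenario) runs the conventional
        progeny-testing program with the scenario's record count.
        """
        cfg = self.config
        p = self.pop
        self.year += 1
        born = self._births()
        self._age_and_cull()

        n_records = scenario.n_records if scenario else 11
        self._phenotype(n_records)

        genomic_selection = False
        directive = None
        if scenario is not None and scenario.is_genomic:
            budget = self._scenario_budget(scenario)
            directive = apply_tp_policy(
                scenario.tp_policy, self.year - cfg.burnin_years,
                self.tp_cow_count(), budget,
            )
            if directive.genotype_initial:
                cows = self.pop_ids(p.is_cow & p.alive)
                sires = np.asarray(self.elite_sire_history[-cfg.elite_sire_memory:],
                                   dtype=np.int64)
                self._genotype_animals(np.union1d(cows, sires))
            if directive.genotype_females > 0:
                first_parity = self.pop_ids(
                    p.is_cow & p.alive & (p.parity == 1) & ~p.genotyped
                )
                k = min(directive.genotype_females, len(first_parity))
                if k:
                    chosen = self.rng.choice(first_parity, size=k, replace=False)
                    self._genotype_animals(chosen)
            genomic_selection = directive.genomic_male_selection

        # male candidates of this year's calf crop
        calves_m = born[p.sex[born] == MALE]
        elite_m = np.asarray([i for i in calves_m if self.elite_flag.get(int(i))],
                             dtype=np.int64)
        general_m = np.setdiff1d(calves_m, elite_m)
        pa = {int(i): v for i, v in zip(calves_m, self.parent_average(calves_m))}
        candidates = None
        if genomic_selection:
            candidates = choose_male_candidates(
                elite_m, general_m, pa, directive.genotype_males
            )
            self._genotype_animals(candidates)

        self._evaluate()

        # selections
        calves_f = born[p.sex[born] == FEMALE]
        keep = select_females(calves_f, p.ebv[calves_f], cfg.selected_females)
        p.selected[keep] = True

        cows = self.pop_ids(p.is_cow & p.alive)
        self.bull_dam_ids = select_bull_dams(
            cows, p.parity[cows], p.ebv[cows], cfg.bull_dams, cfg.bull_dam_parities
        )

        if genomic_selection:
            # a tiny male budget can leave fewer candidates than sire slots
            quota = min(cfg.proven_sires_genomic, len(candidates))
            new_proven = select_sires(candidates, p.ebv[candidates], quota)
        else:
            self.test_cohorts[self.year] = select_sires(
                elite_m, [pa[int(i)] for i in elite_m], cfg.progeny_test_males
            )
            eligible = self.test_cohorts.get(self.year - cfg.progeny_test_age)
            if eligible is None or len(eligible) == 0:
                new_proven = self.proven_sires  # bootstrap gap: keep current team
            else:
                new_proven = select_sires(
                    eligible, p.ebv[eligible], cfg.proven_sires_conventional
                )
        self.proven_sires = np.asarray(new_proven, dtype=np.int64)
        for s in self.proven_sires:
            if int(s) not in self.elite_sire_history:
                self.elite_sire_history.append(int(s))

        self._record_metrics(born, calves_f, elite_m, candidates, scenario)
        row = self.yearly[-1]
        logger.info(
            "year %d [%s] cows=%d tp=%d mean_tbv_newborn=%.3f model=%s",
            self.year, row["scenario"], row["n_cows"], row["tp_size"],
            row["mean_tbv_newborn"], row["model"],
        )
        self._plan_matings(genomic=genomic_selection)

    def _scenario_budget(self, scenario: ScenarioSpec) -> GenotypingBudget:
        if scenario.budget is not None:
            return scenario.budget
        cfg = self.config
        savings = annual_savings(
            scenario.n_records, cfg.active_cows_target, scenario.cost
        )
        return genotyping_counts(
            savings, scenario.cost, first_parity_cap=cfg.selected_females
        )

    def _record_metrics(self, born, calves_f, elite_m, candidates, scenario) -> None:
        p = self.pop

        def acc(ids):
            ids = np.asarray(ids)
            if len(ids) < 3:
                return np.nan
            e, t = p.ebv[ids], p.tbv[ids]
            if e.std() == 0 or t.std() == 0:
                return np.nan
            return float(np.corrcoef(e, t)[0, 1])

        cand_m = candidates if candidates is not None else elite_m
        pa_vals = self.parent_average(np.asarray(cand_m))
        tb = p.tbv[np.asarray(cand_m)]
        acc_pa = (float(np.corrcoef(pa_vals, tb)[0, 1])
                  if len(cand_m) >= 3 and np.std(pa_vals) > 0 and tb.std() > 0 else np.nan)
        cows = self.pop_ids(p.is_cow & p.alive)
        sire_of_born = p.sire[born]
        self.yearly.append({
            "year": self.year,
            "scenario": scenario.name if scenario else "burnin",
            "model": getattr(self, "_model_used", "pedigree"),
            "n_cows": int(len(cows)),
            "tp_size": self.tp.size,
            "tp_cows": self.tp_cow_count(),
            "mean_tbv_newborn": float(p.tbv[born].mean()),
            "sd_tbv_newborn": float(p.tbv[born].std(ddof=1)),
            "acc_candidate_males": acc(cand_m),
            "acc_pa_candidate_males": acc_pa,
            "acc_proven_males": acc(self.proven_sires),
            "acc_candidate_females": acc(calves_f),
            "acc_proven_females": acc(cows),
            "mean_sire_age_newborn": float(
                (self.year - p.birth_year[sire_of_born]).mean()
            ),
            "n_candidate_males": int(len(cand_m)),
        })

    # -- orchestration -----------------------------------------------------

    def run_burnin(self) -> None:
        """Twenty (configurable) years of conventional progeny-test selection."""
        for _ in range(self.config.burnin_years):
            self.step_year(None)

    def run_scenario(self, scenario: ScenarioSpec) -> pd.DataFrame:
        """Run the evaluation phase; returns the per-year metrics frame."""
        for _ in range(self.config.eval_years):
            self.step_year(scenario)
        df = pd.DataFrame(self.yearly)
        return df[df["scenario"] == scenario.name].reset_index(drop=True)

    def pedigree_frame(self) -> pd.DataFrame:
        """Pedigree table (id, sire, dam, sex, birth_year, status); -1 = unknown."""
        p = self.pop
        status = np.where(
            p.alive[: p.n],
            np.where(p.is_cow[: p.n], "cow",
                     np.where(p.sex[: p.n] == MALE, "male", "female")),
            "culled",
        )
        return pd.DataFrame({
            "id": np.arange(p.n),
            "sire": p.sire[: p.n],
            "dam": p.dam[: p.n],
            "sex": np.where(p.sex[: p.n] == MALE, "M", "F"),
            "birth_year": p.birth_year[: p.n],
            "status": status,
        })

    def phenotype_frame(self) -> pd.DataFrame:
        """Collapsed phenotype records (animal, herd, year, y, weight)."""
        return self._record_frame()

    def newborn_history(self) -> pd.DataFrame:
        """Birth-year cohort table (for genetic-gain standardization)."""
        p = self.pop
        return pd.DataFrame({
            "birth_year": p.birth_year[: p.n],
            "tbv": p.tbv[: p.n],
            "sex": p.sex[: p.n],
        })

    def snapshot(self) -> "BreedingProgram":
        """Deep copy of the full state (shared burn-in for paired scenarios)."""
        return copy.deepcopy(self)

    def state_hash(self) -> str:
        h = hashlib.sha256()
        p = self.pop
        for arr in (p.sire[: p.n], p.dam[: p.n], p.tbv[: p.n], p.ebv[: p.n],
                    p.parity[: p.n], p.alive[: p.n]):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(str(self.rng.bit_generator.state).encode())
        return h.hexdigest()


def initialize_program(
    genome_spec: GenomeSpec,
    config: ProgramConfig,
    vc: VarianceComponents = VarianceComponents(),
    seed: int = 0,
) -> BreedingProgram:
    """Simulate founders, sample QTL effects and set up the initial herd."""
    ss = np.random.SeedSequence(seed)
    s_founder, s_qtl, s_prog = (int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3))
    cohort = config.parity_cohort_sizes()
    n_founders = (
        sum(cohort) + 2 * config.selected_females
        + config.progeny_test_males * config.progeny_test_age
        + config.proven_sires_conventional
    )
    founders = simulate_founders(genome_spec, n_founders, s_founder)
    qtl = sample_qtl_effects(genome_spec, founders, s_qtl)
    return BreedingProgram(founders, qtl, config, vc, seed=s_prog)
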