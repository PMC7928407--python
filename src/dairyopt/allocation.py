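"""Phenotyping-to-genotyping resource reallocation.

Reducing the number of milk records per lactation (from the conventional 11)
frees part of the recording budget; this module converts that saving into an
annual genotyping budget under a phenotyping:genotyping price ratio ($P:$G),
a 7:1 female:male split, a cap at the number of first-parity cows, and an
initial-training-population policy.

The canonical price input is the cost of a full 11-record lactation
(P_total, default EUR 19.55); the per-record price is a derived display
value.  A 6% multiplicative quantity discount applies per additional record:
c(n) = (P_total / 11) * 0.94^(n - 11).  Per-lactation savings are rounded to
cents before multiplying by the cow count — the order that reproduces the
published worked example (EUR 0.64/lactation, EUR 6,945/year for 10,852
cows, 710 genotypes at $P:$G = 2:1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostModel",
    "GenotypingBudget",
    "TrainingPopPolicy",
    "YearDirective",
    "cost_per_record",
    "lactation_cost",
    "annual_savings",
    "genotyping_counts",
    "apply_tp_policy",
]

FULL_RECORDS = 11
FEMALE_SHARE = 7.0 / 8.0  # females:males genotyped 7:1

_RATIOS = {"2:1": 0.5, "1:1": 1.0, "1:2": 2.0}


def _round_cents(x: float) -> float:
    """Round half-up to whole cents."""
    return math.floor(x * 100.0 + 0.5) / 100.0


def _round_ten(x: float) -> int:
    """Round half-up to the nearest 10."""
    return int(math.floor(x / 10.0 + 0.5)) * 10


@dataclass(frozen=True)
class CostModel:
    """$P:$G economy: lactation price, quantity discount and price ratio."""

    p_total: float = 19.55
    discount: float = 0.06
    ratio: str = "1:1"

    def __post_init__(self) -> None:
        if self.p_total <= 0:
            raise ValueError("p_total must be positive")
        if not 0 <= self.discount < 1:
            raise ValueError("discount must be in [0, 1)")
        if self.ratio not in _RATIOS:
            raise ValueError(f"ratio must be one of {sorted(_RATIOS)}")

    @property
    def g_price(self) -> float:
        """Cost of genotyping one animal: P_total scaled by the $P:$G ratio."""
        return self.p_total * _RATIOS[self.ratio]


@dataclass(frozen=True)
class GenotypingBudget:
    females_per_year: int
    males_per_year: int
    leftover: float  # unspent female funds when the first-parity cap binds

    def __post_init__(self) -> None:
        if self.females_per_year < 0 or self.males_per_year < 0 or self.leftover < -1e-9:
            raise ValueError("budget components must be non-negative")

    @property
    def total(self) -> int:
        return self.females_per_year + self.males_per_year


def cost_per_record(n: int, model: CostModel) -> float:
    """Price of one milk record when collecting n per lactation (full precision)."""
    if not 1 <= n <= FULL_RECORDS:
        raise ValueError(f"n must be in [1, {FULL_RECORDS}]")
    return (model.p_total / FULL_RECORDS) * (1.0 - model.discount) ** (n - FULL_RECORDS)


def lactation_cost(n: int, model: CostModel) -> float:
    return n * cost_per_record(n, model)


def annual_savings(n: int, n_cows: int, model: CostModel) -> float:
    """Yearly saving from recording n instead of 11 records per lactation.

    The per-lactation saving is rounded to cents first, then multiplied by
    the cow count.
    """
    if n_cows <= 0:
        raise ValueError("n_cows must be positive")
    per_lactation = _round_cents(model.p_total - lactation_cost(n, model))
    return per_lactation * n_cows


def genotyping_counts(
    savings: float, model: CostModel, first_parity_cap: int = 3850
) -> GenotypingBudget:
    """Split an annual saving into female/male genotyping counts.

    floor(savings / $G) animals in total; the female share (7/8, rounded to
    the nearest 10) is capped at the number of first-parity cows, and funds
    stranded by the cap become leftover — they are never shifted to males.
    """
    if savings < 0:
        raise ValueError("savings must be non-negative")
    total = int(savings // model.g_price)
    female_share = min(_round_ten(total * FEMALE_SHARE), total)
    males = total - female_share
    females = min(female_share, first_parity_cap)
    leftover = (female_share - females) * model.g_price
    return GenotypingBudget(females_per_year=females, males_per_year=males, leftover=leftover)


@dataclass(frozen=True)
class TrainingPopPolicy:
    """How the training population is started.

    initial_TP genotypes every active cow plus the recent elite sires once,
    before the first genomic male selection; build_TP genotypes females only
    until the training population holds ``threshold_cows`` cows, at which
    point male genotyping and genomic sire selection begin.
    """

    mode: str = "initial_TP"  # or "build_TP"
    initial_cows: int = 10852
    initial_sires: int = 80
    threshold_cows: int = 2000

    def __post_init__(self) -> None:
        if self.mode not in ("initial_TP", "build_TP"):
            raise ValueError("mode must be 'initial_TP' or 'build_TP'")


@dataclass(frozen=True)
class YearDirective:
    genotype_initial: bool  # one-off genotyping of all cows + elite sires
    genotype_females: int
    genotype_males: int
    genomic_male_selection: bool


def apply_tp_policy(
    policy: TrainingPopPolicy,
    year: int,
    tp_cows: int,
    budget: GenotypingBudget,
) -> YearDirective:
    """Per-year genotyping directive.

    ``year`` counts from 1 within the genomic-selection phase; ``tp_cows``
    is the number of cows in the training population before this year's
    genotyping.  In build_TP mode the whole yearly budget buys first-parity
    cow genotypes until the threshold is in reach (counting this year's
    cows), after which the standard female/male split and genomic male
    selection apply; a budget of >= threshold cows/year therefore starts
    genomic selection in year 1.
    """
    if policy.mode == "initial_TP":
        return YearDirective(
            genotype_initial=(year == 1),
            genotype_females=budget.females_per_year,
            genotype_males=budget.males_per_year,
            genomic_male_selection=True,
        )
    reached = tp_cows + budget.total >= policy.threshold_cows
    return YearDirective(
        genotype_initial=False,
        genotype_females=budget.females_per_year if reached else budget.total,
        genotype_males=budget.males_per_year if reached else 0,
        genomic_male_selection=reached,
    )
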