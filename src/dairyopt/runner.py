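"""Scenario-grid orchestration: burn-in sharing, seeding, result layout.

The study grid crosses 6 genomic scenarios (records per lactation n in
{10, 9, 8, 5, 2, 1}) with 3 price ratios ($P:$G in {2:1, 1:1, 1:2}) and 2
training-population policies, all compared against the conventional C11
scenario.  Within a replicate every scenario restarts from the identical
burn-in snapshot (paired design); replicate seeds derive deterministically
from the master seed.

A scale factor < 1 shrinks every census number proportionally for
desk-scale runs; genotyping budgets are computed at full scale from the
cost model (reproducing the published per-scenario counts) and then scaled,
so the 7:1 female:male split survives scaling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .allocation import (
    CostModel,
    GenotypingBudget,
    TrainingPopPolicy,
    annual_savings,
    genotyping_counts,
)
from .genome import GenomeSpec
from .metrics import TwoStageSelectionSpec, genetic_gain, two_stage_intensity
from .program import BreedingProgram, ProgramConfig, ScenarioSpec, initialize_program
from .traits import VarianceComponents

__all__ = [
    "GridCell",
    "default_grid",
    "scaled_budget",
    "make_scenario",
    "run_grid",
    "report",
    "save_results",
    "load_results",
]

GENOMIC_RECORDS = (10, 9, 8, 5, 2, 1)
RATIOS = ("2:1", "1:1", "1:2")
TP_MODES = ("initial_TP", "build_TP")


@dataclass(frozen=True)
class GridCell:
    """One scenario cell: C11 has ratio/tp_mode None."""

    scenario: str  # "C11", "G10", ... "G1"
    ratio: str | None = None
    tp_mode: str | None = None

    @property
    def n_records(self) -> int:
        return 11 if self.scenario == "C11" else int(self.scenario[1:])

    @property
    def label(self) -> str:
        if self.scenario == "C11":
            return "C11"
        return f"{self.scenario}_{self.ratio}_{self.tp_mode}"


def default_grid() -> list[GridCell]:
    cells = [GridCell("C11")]
    for n in GENOMIC_RECORDS:
        for ratio in RATIOS:
            for mode in TP_MODES:
                cells.append(GridCell(f"G{n}", ratio, mode))
    return cells


def scaled_budget(
    n_records: int,
    ratio: str,
    scale: float = 1.0,
    base_config: ProgramConfig = ProgramConfig(),
) -> GenotypingBudget:
    """Per-year genotyping counts: full-scale cost arithmetic, then scaled."""
    cost = CostModel(ratio=ratio)
    savings = annual_savings(n_records, base_config.active_cows_target, cost)
    full = genotyping_counts(savings, cost, first_parity_cap=3850)
    if scale == 1.0:
        return full
    return GenotypingBudget(
        females_per_year=max(1, round(full.females_per_year * scale)),
        males_per_year=max(1, round(full.males_per_year * scale)),
        leftover=full.leftover * scale,
    )


def make_scenario(
    cell: GridCell, scale: float = 1.0,
    base_config: ProgramConfig = ProgramConfig(),
    scaled_config: ProgramConfig | None = None,
) -> ScenarioSpec:
    if cell.scenario == "C11":
        return ScenarioSpec(name="C11", n_records=11)
    cfg = scaled_config or base_config.scaled(scale)
    policy = TrainingPopPolicy(
        mode=cell.tp_mode,
        initial_cows=cfg.active_cows_target,
        initial_sires=cfg.elite_sire_memory,
        threshold_cows=cfg.tp_threshold,
    )
    return ScenarioSpec(
        name=cell.label,
        n_records=cell.n_records,
        cost=CostModel(ratio=cell.ratio),
        tp_policy=policy,
        budget=scaled_budget(cell.n_records, cell.ratio, scale, base_config),
    )


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_replicate(
    cells: list[GridCell],
    seed: int,
    scale: float = 1.0,
    genome_spec: GenomeSpec = GenomeSpec(),
    base_config: ProgramConfig = ProgramConfig(),
    vc: VarianceComponents = VarianceComponents(),
    replicate: int = 0,
) -> pd.DataFrame:
    """All cells of one replicate from a single shared burn-in state."""
    cfg = base_config.scaled(scale)
    prog = initialize_program(genome_spec, cfg, vc, seed=seed)
    prog.run_burnin()
    anchor = cfg.burnin_years + 1

    frames = []
    for cell in cells:
        spec = make_scenario(cell, scale, base_config, scaled_config=cfg)
        p = prog.snapshot()
        df = p.run_scenario(spec)
        cohorts = p.newborn_history()
        gain = genetic_gain(cohorts, anchor_year=anchor)
        df = df.assign(
            gain=df["year"].map(gain),
            scenario=cell.scenario,
            ratio=cell.ratio,
            tp_policy=cell.tp_mode,
            cell=cell.label,
            replicate=replicate,
            scale=scale,
        )
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def run_grid(
    cells: list[GridCell] | None = None,
    replicates: int = 10,
    master_seed: int = 1,
    scale: float = 1.0,
    genome_spec: GenomeSpec = GenomeSpec(),
    base_config: ProgramConfig = ProgramConfig(),
    vc: VarianceComponents = VarianceComponents(),
    on_error: str = "raise",
) -> pd.DataFrame:
    """Run the scenario grid; returns one tidy frame of per-year metrics.

    ``on_error='log'`` records a failed cell (column ``failed``) instead of
    aborting the grid; failures are never silently dropped.
    """
    cells = cells if cells is not None else default_grid()
    seeds = _replicate_seeds(master_seed, replicates)
    frames = []
    for r, seed in enumerate(seeds):
        try:
            frames.append(
                run_replicate(cells, seed, scale, genome_spec, base_config, vc, replicate=r)
            )
        except Exception:
            if on_error == "raise":
                raise
            frames.append(pd.DataFrame([{"replicate": r, "failed": True}]))
    out = pd.concat(frames, ignore_index=True)
    if "failed" not in out.columns:
        out["failed"] = False
    return out


def tidy(results: pd.DataFrame) -> pd.DataFrame:
    """Long format: scenario, ratio, tp_policy, replicate, year, metric, value."""
    id_cols = ["cell", "scenario", "ratio", "tp_policy", "replicate", "year"]
    value_cols = [c for c in results.columns
                  if c not in id_cols + ["scale", "model", "failed"]]
    return results.melt(id_vars=id_cols, value_vars=value_cols,
                        var_name="metric", value_name="value")


def report(results: pd.DataFrame, base_config: ProgramConfig = ProgramConfig()) -> dict[str, pd.DataFrame]:
    """Summary tables: final-year gain, relative gain vs C11, accuracies, intensity."""
    res = results[results["scenario"] != "burnin"].copy()
    final_year = res["year"].max()
    fin = res[res["year"] == final_year]
    gain = (fin.groupby("cell")["gain"].agg(["mean", "std"])
            .rename(columns={"mean": "final_gain", "std": "sd"}).reset_index())
    c11 = gain.loc[gain["cell"] == "C11", "final_gain"]
    if len(c11):
        gain["relative_pct"] = 100.0 * gain["final_gain"] / float(c11.iloc[0])

    acc_cols = [c for c in res.columns if c.startswith("acc_")]
    acc = res.groupby("cell")[acc_cols].mean().reset_index()

    # two-stage male selection intensity from the scenario's own accuracies
    rows = []
    newborn_m = None
    for cell, sub in res.groupby("cell"):
        # second-stage criterion: genomic EBV for G cells, progeny-test EBV for C11
        acc_g = (sub["acc_proven_males"].mean() if cell == "C11"
                 else sub["acc_candidate_males"].mean())
        acc_pa = sub["acc_pa_candidate_males"].mean()
        n_cand = sub["n_candidate_males"].mean()
        nm = base_config.newborn_males_per_year
        scale = sub["scale"].iloc[0] if "scale" in sub else 1.0
        nm = max(1, round(nm * scale))
        quota = (base_config.proven_sires_conventional if cell == "C11"
                 else base_config.proven_sires_genomic)
        quota = max(1, round(quota * scale))
        p1 = min(1.0, n_cand / nm)
        p2 = min(p1, quota / nm)
        rho = np.clip(acc_pa / acc_g, -1.0, 1.0) if acc_g and not np.isnan(acc_g) else np.nan
        try:
            i_val = two_stage_intensity(TwoStageSelectionSpec(p1=p1, p2=p2, rho=float(rho)))
        except (ValueError, FloatingPointError):
            i_val = np.nan
        rows.append({"cell": cell, "p1": p1, "p2": p2, "rho": rho, "intensity": i_val})
    intensity = pd.DataFrame(rows)
    return {"gain": gain, "accuracy": acc, "intensity": intensity}


def save_results(results: pd.DataFrame, out_dir: str | Path, config: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "metrics.csv", index=False)
    manifest = {
        "config": config or {},
        "hash": hashlib.sha256(
            results.to_csv(index=False).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def load_results(out_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "metrics.csv")
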