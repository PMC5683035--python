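"""Factorial prediction-accuracy experiment over TPS x MD x population x trait.

For every cell of the grid (population, trait-environment, training
population size TPS, marker density MD) a fixed number of training lines is
drawn at random (default 100 independent draws), RR-BLUP is fitted on the
training lines' BLUP phenotypes using a random MD-marker subset, GEBVs are
computed for the complement, and the Pearson correlation between GEBV and
BLUP phenotype in the prediction set is recorded. The prediction accuracy
r_MG of a cell is the mean of the defined replicate correlations; r_MG / h
relates it to phenotypic-selection accuracy h = sqrt(h2).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng
from .gs import DegenerateFitError, accuracy, fit_rrblup, predict_gebv
from .simulate import TRAIT_ENVS, BiparentalPopulation

__all__ = [
    "Scenario",
    "ScenarioGrid",
    "TrainTestSplit",
    "AccuracyResult",
    "ALL_MARKERS",
    "build_grid",
    "draw_split",
    "run_scenario",
    "summarize",
    "summarize_subgroups",
]

#: Sentinel marker-density level meaning "all polymorphic SNPs of the population".
ALL_MARKERS = "all"

DEFAULT_TPS_LEVELS = (30, 50, 70, 90)
DEFAULT_MD_LEVELS = (50, 100, ALL_MARKERS)
DEFAULT_N_REPLICATES = 100


@dataclass(frozen=True)
class Scenario:
    population_id: str
    trait_env: str
    tps: int
    md: int | str
    feasible: bool = True


@dataclass(frozen=True)
class ScenarioGrid:
    scenarios: tuple[Scenario, ...]
    tps_levels: tuple[int, ...]
    md_levels: tuple[int | str, ...]
    n_replicates: int
    master_seed: int

    @property
    def n_scenarios(self) -> int:
        return len(self.scenarios)


def build_grid(
    population_sizes: dict[str, int],
    trait_envs: tuple[str, ...] = TRAIT_ENVS,
    tps_levels: tuple[int, ...] = DEFAULT_TPS_LEVELS,
    md_levels: tuple[int | str, ...] = DEFAULT_MD_LEVELS,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
    marker_counts: dict[str, int] | None = None,
) -> ScenarioGrid:
    """Enumerate the full Cartesian grid deterministically (sorted keys).

    A cell whose TPS reaches the population size, or whose numeric MD
    exceeds the population's polymorphic marker count, is kept but flagged
    infeasible rather than silently dropped.
    """
    scenarios = []
    for pop_id in sorted(population_sizes):
        n_fam = population_sizes[pop_id]
        n_mark = None if marker_counts is None else marker_counts.get(pop_id)
        for te, tps, md in itertools.product(trait_envs, tps_levels, md_levels):
            feasible = tps < n_fam
            if n_mark is not None and md != ALL_MARKERS and md > n_mark:
                feasible = False
            scenarios.append(Scenario(pop_id, te, tps, md, feasible))
    return ScenarioGrid(
        scenarios=tuple(scenarios),
        tps_levels=tuple(tps_levels),
        md_levels=tuple(md_levels),
        n_replicates=n_replicates,
        master_seed=master_seed,
    )


@dataclass(frozen=True)
class TrainTestSplit:
    training_ids: tuple[str, ...]
    prediction_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    replicate: int


def draw_split(
    pop: BiparentalPopulation,
    tps: int,
    md: int | str,
    replicate: int,
    rng: np.random.Generator,
) -> TrainTestSplit:
    """Simple random training sample of size ``tps``; complement predicts.

    The marker subset of size ``md`` is redrawn from the population's
    polymorphic SNPs each replicate; ``md="all"`` uses the full panel.
    """
    if tps >= pop.n_families:
        raise ValueError("TPS must be smaller than the population size")
    fams = np.array(pop.family_ids, dtype=object)
    train_idx = rng.choice(pop.n_families, size=tps, replace=False)
    mask = np.zeros(pop.n_families, dtype=bool)
    mask[train_idx] = True
    if md == ALL_MARKERS:
        markers = pop.polymorphic_marker_ids
    else:
        if md > pop.n_markers:
            raise ValueError("marker density exceeds the polymorphic SNP count")
        cols = np.sort(rng.choice(pop.n_markers, size=int(md), replace=False))
        markers = tuple(pop.polymorphic_marker_ids[j] for j in cols)
    return TrainTestSplit(
        training_ids=tuple(fams[mask]),
        prediction_ids=tuple(fams[~mask]),
        marker_ids=markers,
        replicate=replicate,
    )


@dataclass
class AccuracyResult:
    population_id: str
    trait_env: str
    tps: int
    md: int | str
    replicate_correlations: np.ndarray
    h: float
    n_failed_replicates: int = 0

    @property
    def r_mg(self) -> float:
        vals = self.replicate_correlations
        return float(np.mean(vals)) if vals.size else float("nan")

    @property
    def sd(self) -> float:
        vals = self.replicate_correlations
        return float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")

    @property
    def r_mg_over_h(self) -> float:
        return self.r_mg / self.h if self.h > 0 else float("nan")


def run_scenario(
    pop: BiparentalPopulation,
    blups: pd.Series,
    trait_env: str,
    tps: int,
    md: int | str,
    h: float,
    n_replicates: int = DEFAULT_N_REPLICATES,
    master_seed: int = 0,
) -> AccuracyResult:
    """Replicated random-sampling evaluation of one grid cell.

    Each replicate draws its own training set and marker subset from a
    stream keyed by (population, trait-env, TPS, MD, replicate), so any
    execution order reproduces the same result. Replicates whose
    correlation is undefined (degenerate fit or zero-variance prediction
    set) are counted as failed and excluded from the mean.
    """
    y_all = blups.loc[list(pop.family_ids)]
    fam_pos = {f: i for i, f in enumerate(pop.family_ids)}
    corrs = []
    failed = 0
    for rep in range(1, n_replicates + 1):
        rng = child_rng(master_seed, pop.population_id, trait_env, tps, md, rep)
        split = draw_split(pop, tps, md, rep, rng)
        sub = pop.marker_columns(split.marker_ids).astype(float)
        tr = [fam_pos[f] for f in split.training_ids]
        pr = [fam_pos[f] for f in split.prediction_ids]
        try:
            model = fit_rrblup(y_all.iloc[tr].to_numpy(), sub[tr])
        except DegenerateFitError:
            failed += 1
            continue
        gebv = predict_gebv(model, sub[pr])
        r = accuracy(y_all.iloc[pr].to_numpy(), gebv)
        if math.isnan(r):
            failed += 1
        else:
            corrs.append(r)
    return AccuracyResult(
        population_id=pop.population_id,
        trait_env=trait_env,
        tps=tps,
        md=md,
        replicate_correlations=np.array(corrs),
        h=h,
        n_failed_replicates=failed,
    )


def results_frame(results: list[AccuracyResult]) -> pd.DataFrame:
    """Tidy per-cell table: one row per (population, trait_env, tps, md)."""
    rows = [
        {
            "population_id": res.population_id,
            "trait_env": res.trait_env,
            "tps": res.tps,
            "md": res.md,
            "r_mg": res.r_mg,
            "sd": res.sd,
            "r_mg_over_h": res.r_mg_over_h,
            "n_failed": res.n_failed_replicates,
        }
        for res in results
    ]
    return pd.DataFrame(rows).sort_values(
        ["trait_env", "population_id", "tps", "md"], key=_sort_key
    ).reset_index(drop=True)


def _sort_key(col: pd.Series) -> pd.Series:
    if col.name == "md":
        return col.map(lambda v: float("inf") if v == ALL_MARKERS else float(v))
    return col


def summarize(results: list[AccuracyResult]) -> pd.DataFrame:
    """Mean and SD of r_MG and r_MG/h per trait-env x TPS x MD across populations."""
    if not results:
        raise ValueError("no results to summarize")
    df = results_frame(results)
    out = (
        df.groupby(["trait_env", "tps", "md"], sort=False)
        .agg(
            r_mg_mean=("r_mg", "mean"),
            r_mg_sd=("r_mg", lambda v: v.std(ddof=1) if len(v) > 1 else 0.0),
            r_mg_over_h_mean=("r_mg_over_h", "mean"),
            n_populations=("population_id", "size"),
        )
        .reset_index()
    )
    return out.sort_values(["trait_env", "tps", "md"], key=_sort_key).reset_index(drop=True)


def summarize_subgroups(
    results: list[AccuracyResult],
    h2_by_population: pd.Series,
    subgroup: pd.Series,
    tps: int = 90,
    md: int | str = ALL_MARKERS,
) -> pd.DataFrame:
    """Mean r_MG per heritability subgroup at one reference (TPS, MD) cell."""
    df = results_frame(results)
    df = df[(df["tps"] == tps) & (df["md"] == md)].copy()
    df["subgroup"] = df["population_id"].map(subgroup)
    df["h2"] = df["population_id"].map(h2_by_population)
    return (
        df.groupby("subgroup")
        .agg(r_mg_mean=("r_mg", "mean"), h2_mean=("h2", "mean"), n=("population_id", "size"))
        .reset_index()
    )
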