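"""End-to-end synthetic study assembly: populations, trials, BLUPs, grids.

This module wires the simulator, the trial analysis and the prediction
engine into the study designs the package evaluates:

* ``simulate_trait`` — one population x trait-env: calibrated architecture,
  balanced trials, variance components, heritability and family BLUPs;
* ``trend_study`` — a panel of populations with heritability targets
  spanning a range, run over the full TPS x MD grid, for studying how
  accuracy responds to heritability, training size and marker density;
* ``halfsib_null_study`` — half-sib pairs whose trait architecture lives
  entirely outside the shared-marker set, the no-transferable-signal null.

Default heritability targets per regime follow typical testcross values for
tropical maize: grain yield ~0.38 (WW) / 0.27 (WS), anthesis date
~0.55 / 0.47, plant height ~0.59 / 0.37.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_rng
from . import pheno
from .experiment import (
    ALL_MARKERS,
    DEFAULT_MD_LEVELS,
    DEFAULT_TPS_LEVELS,
    AccuracyResult,
    run_scenario,
)
from .halfsib import HalfsibPair, predict_across
from .simulate import (
    BiparentalPopulation,
    TraitArchitecture,
    default_map,
    random_trait_architecture,
    simulate_halfsib_set,
    simulate_population,
    simulate_trials,
    FounderPair,
)

__all__ = [
    "REGIME_H2_MEANS",
    "TraitAnalysis",
    "simulate_trait",
    "trend_study",
    "halfsib_null_study",
]

#: Default broad-sense heritability targets per trait-environment regime.
REGIME_H2_MEANS = {
    "GY_WW": 0.38,
    "GY_WS": 0.27,
    "AD_WW": 0.55,
    "AD_WS": 0.47,
    "PH_WW": 0.59,
    "PH_WS": 0.37,
}


@dataclass
class TraitAnalysis:
    """Everything the downstream experiment needs for one population x trait-env."""

    population: BiparentalPopulation
    architecture: TraitArchitecture
    trials: pd.DataFrame
    components: pheno.VarianceComponents
    heritability: pheno.HeritabilityResult
    blups: pd.Series


def simulate_trait(
    pop: BiparentalPopulation,
    trait_env: str,
    target_h2: float,
    master_seed: int,
    n_qtl: int = 40,
    e: int = 4,
    r: int = 2,
    exclude_markers: tuple[str, ...] = (),
) -> TraitAnalysis:
    """Simulate balanced trials at a target h2 and run the phenotype analysis."""
    rng_arch = child_rng(master_seed, pop.population_id, trait_env, "arch")
    arch = random_trait_architecture(
        pop, trait_env, target_h2, rng_arch, n_qtl=n_qtl, e=e, r=r,
        exclude_markers=exclude_markers,
    )
    rng_trial = child_rng(master_seed, pop.population_id, trait_env, "trials")
    trials = simulate_trials(pop, arch, rng_trial)
    vc = pheno.estimate_components(trials)
    h2 = pheno.heritability(vc, trait_env=trait_env)
    blups = pheno.genotype_blups(trials, vc)
    return TraitAnalysis(pop, arch, trials, vc, h2, blups)


def trend_study(
    n_populations: int = 20,
    n_families: int = 180,
    markers_per_chromosome: int = 20,
    h2_targets: np.ndarray | None = None,
    trait_env: str = "GY_WW",
    tps_levels: tuple[int, ...] = DEFAULT_TPS_LEVELS,
    md_levels: tuple[int | str, ...] = DEFAULT_MD_LEVELS,
    n_replicates: int = 100,
    e: int = 4,
    r: int = 2,
    master_seed: int = 0,
) -> tuple[list[AccuracyResult], pd.Series, pd.Series]:
    """Panel of simulated populations run over the full TPS x MD grid.

    Heritability targets default to an even spread over [0.25, 0.60] across
    populations. Returns the per-cell accuracy results, the estimated h2
    per population, and the target h2 per population.
    """
    if h2_targets is None:
        h2_targets = np.linspace(0.25, 0.60, n_populations)
    gmap = default_map(markers_per_chromosome=markers_per_chromosome)
    results: list[AccuracyResult] = []
    h2_est, h2_tgt = {}, {}
    for i in range(n_populations):
        pid = f"Sim{i + 1}"
        rng = child_rng(master_seed, "trend", pid)
        hap_a = np.zeros(gmap.n_markers, dtype=np.int8)
        hap_b = np.ones(gmap.n_markers, dtype=np.int8)
        ped = FounderPair(f"{pid}_A", f"{pid}_B", hap_a, hap_b)
        pop = simulate_population(ped, "F2", n_families, gmap, rng, population_id=pid)
        ta = simulate_trait(
            pop, trait_env, float(h2_targets[i]), master_seed, e=e, r=r
        )
        h2_est[pid] = ta.heritability.h2
        h2_tgt[pid] = float(h2_targets[i])
        for tps in tps_levels:
            for md in md_levels:
                results.append(
                    run_scenario(
                        pop, ta.blups, trait_env, tps, md,
                        h=ta.heritability.h, n_replicates=n_replicates,
                        master_seed=master_seed,
                    )
                )
    return results, pd.Series(h2_est), pd.Series(h2_tgt)


def halfsib_null_study(
    n_pairs: int = 10,
    n_families: int = 150,
    trait_env: str = "GY_WW",
    target_h2: float = 0.4,
    panel_size: int = 180,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Half-sib predictions when no trait signal crosses the common markers.

    Each pair shares one parent and ~44-100 common panel markers; the trait
    architecture of each population is drawn exclusively from markers
    OUTSIDE the common set, so transferred marker effects carry no causal
    signal and the across-population accuracy should be centred on zero.
    Returns one row per ordered (train, predict) direction.
    """
    gmap = default_map(markers_per_chromosome=45)  # denser genome: per-pop panels
    rows = []
    for k in range(n_pairs):
        rng = child_rng(master_seed, "halfsib", k)
        pop1, pop2, common = simulate_halfsib_set(
            f"S{k}", (f"A{k}", f"B{k}"), (n_families, n_families), gmap, rng,
            panel_size=panel_size,
            population_ids=(f"HS{k}a", f"HS{k}b"),
        )
        analyses = {
            p.population_id: simulate_trait(
                p, trait_env, target_h2, master_seed, exclude_markers=common
            )
            for p in (pop1, pop2)
        }
        pops = {p.population_id: p for p in (pop1, pop2)}
        blups = {pid: a.blups for pid, a in analyses.items()}
        for train, predict in ((pop1, pop2), (pop2, pop1)):
            pair = HalfsibPair(
                train_population_id=train.population_id,
                predict_population_id=predict.population_id,
                shared_parent_id=f"S{k}",
                platform_group="sim",
            )
            r_mg, n_common = predict_across(pair, pops, blups, common)
            rows.append(
                {
                    "train": train.population_id,
                    "predict": predict.population_id,
                    "trait_env": trait_env,
                    "n_common_markers": n_common,
                    "r_mg": r_mg,
                }
            )
    return pd.DataFrame(rows)
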