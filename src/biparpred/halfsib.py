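"""Across-population genomic prediction between half-sib crosses.

Two bi-parental populations are half-sibs when they share exactly one
parent. Prediction trains RR-BLUP on the whole training population and
predicts every family of the other population, using only markers present
on both populations' panels. Because each cross codes genotypes relative
to its own parent A, marker codes are first re-oriented so that ``+1``
means "homozygous for the shared parent's allele" in both populations;
without that common reference the sign of every transferred marker effect
would be arbitrary. Pairs are only formed within a genotyping-platform
group (different assay platforms share too few markers to compare).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gs import accuracy, fit_rrblup, predict_gebv
from .simulate import BiparentalPopulation

__all__ = ["HalfsibPair", "enumerate_halfsib_pairs", "predict_across"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HalfsibPair:
    train_population_id: str
    predict_population_id: str
    shared_parent_id: str
    platform_group: str


def enumerate_halfsib_pairs(
    pedigrees: dict[str, tuple[str, str]],
    platform_groups: dict[str, str],
) -> list[HalfsibPair]:
    """All ordered (train, predict) pairs sharing exactly one parent.

    Pairs sharing both parents (full-sibs) are excluded, as are pairs whose
    populations were genotyped on different platforms. The order of the
    returned list is deterministic in the iteration order of ``pedigrees``.
    """
    pairs = []
    pop_ids = list(pedigrees)
    for a in pop_ids:
        for b in pop_ids:
            if a == b:
                continue
            if platform_groups[a] != platform_groups[b]:
                continue
            shared = set(pedigrees[a]) & set(pedigrees[b])
            if len(shared) != 1:
                continue
            pairs.append(
                HalfsibPair(
                    train_population_id=a,
                    predict_population_id=b,
                    shared_parent_id=shared.pop(),
                    platform_group=platform_groups[a],
                )
            )
    return pairs


def _oriented_common_genotypes(
    pop: BiparentalPopulation, shared_parent_id: str, marker_ids: tuple[str, ...]
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Genotype columns re-coded so +1 = homozygous shared-parent allele.

    Within a cross ``+1`` codes parent A's allele; at markers where the
    shared parent contributed the parent-B allele the sign is flipped. A
    marker where the shared parent's haplotype cannot be resolved against
    either founder haplotype is dropped with a log entry.
    """
    ped = pop.pedigree
    if shared_parent_id not in (ped.parent_a_id, ped.parent_b_id):
        raise ValueError(
            f"{shared_parent_id!r} is not a parent of {pop.population_id}"
        )
    if pop.founder_allele_a is None or pop.founder_allele_b is None:
        raise ValueError(
            f"population {pop.population_id} lacks founder allele phase"
        )
    own = {m: i for i, m in enumerate(pop.polymorphic_marker_ids)}
    z = pop.marker_columns(marker_ids).astype(float)
    keep, signs = [], []
    for j, m in enumerate(marker_ids):
        i = own[m]
        a, b = pop.founder_allele_a[i], pop.founder_allele_b[i]
        if a == b:
            logger.warning(
                "marker %s orientation unresolved in %s; dropped", m, pop.population_id
            )
            continue
        # +1 currently codes the parent-A allele; flip where the shared
        # parent contributed the parent-B allele
        signs.append(1.0 if shared_parent_id == ped.parent_a_id else -1.0)
        keep.append(j)
    return z[:, keep] * np.array(signs), tuple(marker_ids[j] for j in keep)


def predict_across(
    pair: HalfsibPair,
    populations: dict[str, BiparentalPopulation],
    blups: dict[str, pd.Series],
    common_marker_ids: tuple[str, ...] | None = None,
) -> tuple[float, int]:
    """Train on one half-sib population, predict the other; single correlation.

    Returns ``(r_mg, n_common_markers)``. The entire training population is
    used (no resampling); the correlation is between the prediction
    population's BLUP phenotypes and their GEBVs on the common, re-oriented
    markers.
    """
    train = populations[pair.train_population_id]
    pred = populations[pair.predict_population_id]
    if common_marker_ids is None:
        common_marker_ids = tuple(
            m for m in train.polymorphic_marker_ids
            if m in set(pred.polymorphic_marker_ids)
        )
    if not common_marker_ids:
        raise ValueError("half-sib pair shares no polymorphic markers")

    z_train, ids_train = _oriented_common_genotypes(
        train, pair.shared_parent_id, common_marker_ids
    )
    z_pred, ids_pred = _oriented_common_genotypes(
        pred, pair.shared_parent_id, common_marker_ids
    )
    usable = tuple(m for m in ids_train if m in set(ids_pred))
    if usable != ids_train:
        z_train = z_train[:, [ids_train.index(m) for m in usable]]
    if usable != ids_pred:
        z_pred = z_pred[:, [ids_pred.index(m) for m in usable]]

    y_train = blups[pair.train_population_id].loc[list(train.family_ids)].to_numpy()
    y_pred = blups[pair.predict_population_id].loc[list(pred.family_ids)].to_numpy()
    model = fit_rrblup(y_train, z_train, marker_ids=usable)
    gebv = predict_gebv(model, z_pred, marker_ids=usable)
    return accuracy(y_pred, gebv), len(usable)
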