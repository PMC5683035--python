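"""Synthetic bi-parental maize populations and multi-environment testcross trials.

The generator emulates the data structure of low-density-SNP bi-parental
breeding populations: two fully inbred founders are crossed, the F1 is
selfed (or backcrossed) and each family is represented by the genotype of
its founding F2 (or BC1) plant, coded ``+1`` (homozygous for the parent-A
allele), ``0`` (heterozygous) and ``-1`` (homozygous parent-B).  Meiosis
follows the Haldane map function (no crossover interference): the
recombination fraction between adjacent markers ``d`` centiMorgans apart is
``(1 - exp(-2 d / 100)) / 2``, with independent assortment across
chromosomes.

Phenotypes are simulated for a balanced multi-environment trial: for family
``i``, environment ``j`` and replicate ``k``,

    y_ijk = mu + g_i + (ge)_ij + eps_ijk,

where ``g_i`` is an additive genetic value built from QTL effects on coded
marker genotypes and rescaled so its sample variance equals ``sigma_g2``
exactly, ``(ge)_ij ~ N(0, sigma_ge2)`` and ``eps_ijk ~ N(0, sigma_e2)``.
Variance components can be calibrated analytically to hit any target
broad-sense heritability on an entry-mean basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "GeneticMap",
    "FounderPair",
    "BiparentalPopulation",
    "TraitArchitecture",
    "TRAIT_ENVS",
    "default_map",
    "simulate_gamete",
    "simulate_population",
    "segregation_filter",
    "calibrate_variances",
    "simulate_trials",
    "simulate_halfsib_set",
    "random_trait_architecture",
]

#: The six trait-environment regimes: grain yield (GY), anthesis date (AD)
#: and plant height (PH) under well-watered (WW) and water-stressed (WS)
#: management.
TRAIT_ENVS = ("GY_WW", "GY_WS", "AD_WW", "AD_WS", "PH_WW", "PH_WS")


class SimulationError(ValueError):
    """Structurally invalid simulation input (monomorphic cross, bad map...)."""


@dataclass(frozen=True)
class GeneticMap:
    """Marker positions in centiMorgans on numbered chromosomes."""

    chromosome: np.ndarray  # int, one entry per marker
    marker_id: tuple[str, ...]
    position_cm: np.ndarray  # float cM, non-decreasing within chromosome

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=int)
        pos = np.asarray(self.position_cm, dtype=float)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cm", pos)
        if len(self.marker_id) != chrom.size or pos.size != chrom.size:
            raise SimulationError("map fields have inconsistent lengths")
        if len(set(self.marker_id)) != len(self.marker_id):
            raise SimulationError("marker ids must be unique genome-wide")
        if np.any(pos < 0):
            raise SimulationError("map positions must be non-negative")
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise SimulationError(f"positions not sorted on chromosome {c}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def subset(self, marker_ids) -> "GeneticMap":
        idx = {m: i for i, m in enumerate(self.marker_id)}
        keep = sorted((idx[m] for m in marker_ids))
        return GeneticMap(
            self.chromosome[keep],
            tuple(self.marker_id[i] for i in keep),
            self.position_cm[keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": list(self.marker_id),
                "chromosome": self.chromosome,
                "position_cm": self.position_cm,
            }
        )


def default_map(
    n_chromosomes: int = 10,
    chromosome_length_cm: float = 170.0,
    markers_per_chromosome: int = 20,
) -> GeneticMap:
    """Evenly spaced default genome: 10 chromosomes x 170 cM, ~200 markers.

    Mirrors a maize-like genome with low-density coverage; around 150-200
    evenly spaced markers is the density regime the package targets.
    """
    chroms, ids, pos = [], [], []
    for c in range(1, n_chromosomes + 1):
        p = np.linspace(0.0, chromosome_length_cm, markers_per_chromosome)
        chroms.extend([c] * markers_per_chromosome)
        ids.extend(f"chr{c}_m{i + 1}" for i in range(markers_per_chromosome))
        pos.extend(p)
    return GeneticMap(np.array(chroms), tuple(ids), np.array(pos))


@dataclass(frozen=True)
class FounderPair:
    """Two fully homozygous inbred founders, one haplotype (0/1 alleles) each."""

    parent_a_id: str
    parent_b_id: str
    haplotype_a: np.ndarray  # 0/1 per marker
    haplotype_b: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.haplotype_a, dtype=np.int8)
        b = np.asarray(self.haplotype_b, dtype=np.int8)
        object.__setattr__(self, "haplotype_a", a)
        object.__setattr__(self, "haplotype_b", b)
        if a.shape != b.shape:
            raise SimulationError("founder haplotypes differ in length")
        if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
            raise SimulationError("founder alleles must be coded 0/1")

    @property
    def polymorphic_mask(self) -> np.ndarray:
        """Markers segregating in the cross (founder alleles differ)."""
        return self.haplotype_a != self.haplotype_b


@dataclass
class BiparentalPopulation:
    """Coded genotypes of one segregating cross, restricted to its polymorphic markers."""

    population_id: str
    pedigree: FounderPair
    generation: str  # "F2" or "BC1"
    genotypes: np.ndarray  # n_families x n_polymorphic, values in {-1, 0, +1}
    polymorphic_marker_ids: tuple[str, ...]
    genetic_map: GeneticMap  # subset covering polymorphic_marker_ids
    family_ids: tuple[str, ...] = field(default=())
    #: founder alleles aligned with polymorphic_marker_ids (for re-orienting
    #: marker codes against a shared parent in across-population prediction)
    founder_allele_a: np.ndarray | None = None
    founder_allele_b: np.ndarray | None = None

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        self.genotypes = g
        if not self.family_ids:
            self.family_ids = tuple(
                f"{self.population_id}_F{i + 1}" for i in range(g.shape[0])
            )
        if g.shape != (len(self.family_ids), len(self.polymorphic_marker_ids)):
            raise SimulationError("genotype matrix shape mismatch")
        if not np.isin(g, (-1, 0, 1)).all():
            raise SimulationError("coded genotypes must lie in {-1, 0, +1}")
        if g.shape[0] < 2:
            raise SimulationError("a population needs at least 2 families")

    @property
    def n_families(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def marker_columns(self, marker_ids) -> np.ndarray:
        idx = {m: i for i, m in enumerate(self.polymorphic_marker_ids)}
        try:
            cols = [idx[m] for m in marker_ids]
        except KeyError as err:
            raise SimulationError(f"marker {err.args[0]!r} absent from population") from err
        return self.genotypes[:, cols]

    def subset_markers(self, marker_ids) -> "BiparentalPopulation":
        keep = tuple(marker_ids)
        idx = {m: i for i, m in enumerate(self.polymorphic_marker_ids)}
        cols = [idx[m] for m in keep]
        return BiparentalPopulation(
            population_id=self.population_id,
            pedigree=self.pedigree,
            generation=self.generation,
            genotypes=self.marker_columns(keep),
            polymorphic_marker_ids=keep,
            genetic_map=self.genetic_map.subset(keep),
            family_ids=self.family_ids,
            founder_allele_a=None if self.founder_allele_a is None else self.founder_allele_a[cols],
            founder_allele_b=None if self.founder_allele_b is None else self.founder_allele_b[cols],
        )


def _haldane_recomb_fraction(d_cm: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_gamete(
    haplotypes: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from a phased diploid under the Haldane model.

    ``haplotypes`` is a (2, n_markers) array of 0/1 alleles aligned with
    ``gmap``. Chromosomes assort independently; within a chromosome a
    crossover occurs between adjacent markers with the Haldane probability
    for their map distance.
    """
    hap = np.asarray(haplotypes)
    if hap.shape != (2, gmap.n_markers):
        raise SimulationError(
            f"expected phased haplotypes of shape (2, {gmap.n_markers}), got {hap.shape}"
        )
    gamete = np.empty(gmap.n_markers, dtype=np.int8)
    chrom = gmap.chromosome
    for c in np.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        d = np.diff(gmap.position_cm[sel])
        r = _haldane_recomb_fraction(d)
        cross = rng.random(r.size) < r
        start = rng.integers(0, 2)
        # cumulative crossovers toggle which parental strand is copied
        strand = (start + np.concatenate(([0], np.cumsum(cross)))) % 2
        gamete[sel] = hap[strand, sel]
    return gamete


def simulate_population(
    pedigree: FounderPair,
    generation: str,
    n_families: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    population_id: str = "pop",
) -> BiparentalPopulation:
    """Simulate a segregating cross; one coded genotype per family.

    Each family is founded by a single F2 plant (two gametes of the F1) or,
    for ``generation="BC1"``, a single backcross plant (one F1 gamete plus
    the recurrent parent-A haplotype). The family is coded from that
    founding plant, which is what gives F2-derived families the 1:2:1
    (+1:0:-1) expectation exploited by the segregation filter.
    """
    if n_families < 2:
        raise SimulationError("n_families must be >= 2")
    if generation not in ("F2", "BC1"):
        raise SimulationError(f"unknown generation {generation!r}")
    if pedigree.haplotype_a.size != gmap.n_markers:
        raise SimulationError("founder haplotypes do not match the map")
    poly = pedigree.polymorphic_mask
    if not poly.any():
        raise SimulationError("cross is monomorphic at every marker")

    f1 = np.vstack([pedigree.haplotype_a, pedigree.haplotype_b])
    plants = np.empty((n_families, 2, gmap.n_markers), dtype=np.int8)
    for i in range(n_families):
        if generation == "F2":
            plants[i, 0] = simulate_gamete(f1, gmap, rng)
            plants[i, 1] = simulate_gamete(f1, gmap, rng)
        else:  # BC1 to parent A (recurrent parent)
            plants[i, 0] = simulate_gamete(f1, gmap, rng)
            plants[i, 1] = pedigree.haplotype_a
    # code relative to parent A: number of parent-A alleles minus 1
    match_a = (plants == pedigree.haplotype_a[None, None, :]).sum(axis=1)
    coded = (match_a - 1).astype(np.int8)

    keep = np.flatnonzero(poly)
    marker_ids = tuple(gmap.marker_id[i] for i in keep)
    return BiparentalPopulation(
        population_id=population_id,
        pedigree=pedigree,
        generation=generation,
        genotypes=coded[:, keep],
        polymorphic_marker_ids=marker_ids,
        genetic_map=gmap.subset(marker_ids),
        founder_allele_a=pedigree.haplotype_a[keep].copy(),
        founder_allele_b=pedigree.haplotype_b[keep].copy(),
    )


_EXPECTED_RATIOS = {"F2": {1: 0.25, 0: 0.5, -1: 0.25}, "BC1": {1: 0.5, 0: 0.5}}


def segregation_filter(
    pop: BiparentalPopulation,
    expected_ratio: dict[int, float] | None = None,
    alpha: float = 0.05,
) -> BiparentalPopulation:
    """Drop markers showing segregation distortion (chi-square goodness of fit).

    Observed genotype-class counts at each marker are tested against the
    Mendelian expectation for the population's generation (1:2:1 for
    F2-derived, 1:1 for BC1-derived by default); markers with p < ``alpha``
    are removed. No multiplicity correction is applied.
    """
    from scipy import stats

    if expected_ratio is None:
        expected_ratio = _EXPECTED_RATIOS[pop.generation]
    classes = sorted(expected_ratio)
    probs = np.array([expected_ratio[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    n = pop.n_families

    keep = []
    for j, marker in enumerate(pop.polymorphic_marker_ids):
        col = pop.genotypes[:, j]
        observed = np.array([(col == c).sum() for c in classes], dtype=float)
        if observed.sum() != n:  # genotype class outside the expectation
            continue
        _, p = stats.chisquare(observed, f_exp=probs * n)
        if p >= alpha:
            keep.append(marker)
    if not keep:
        raise SimulationError("no markers survive the segregation filter")
    return pop.subset_markers(keep)


def calibrate_variances(
    target_h2: float,
    e: int,
    r: int,
    sigma_g2: float = 1.0,
    ge_to_e_ratio: float = 0.5,
) -> tuple[float, float]:
    """Solve for (sigma_ge2, sigma_e2) hitting a target entry-mean heritability.

    Inverts h2 = sg2 / (sg2 + sge2/e + se2/(e r)) with the constraint
    sge2 = ge_to_e_ratio * se2, keeping ``sigma_g2`` fixed.
    """
    if not (0.0 < target_h2 <= 1.0):
        raise ValueError("target_h2 must lie in (0, 1]")
    if sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive")
    if target_h2 == 1.0:
        return 0.0, 0.0
    rho = float(ge_to_e_ratio)
    denom = rho / e + 1.0 / (e * r)
    sigma_e2 = sigma_g2 * (1.0 - target_h2) / target_h2 / denom
    return rho * sigma_e2, sigma_e2


@dataclass
class TraitArchitecture:
    """QTL effects plus trial dimensions and noise variances for one trait-env."""

    trait_env: str
    qtl_marker_ids: tuple[str, ...]
    additive_effects: np.ndarray
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    n_environments: int = 4
    n_replicates: int = 2
    mu: float = 0.0

    def __post_init__(self):
        self.additive_effects = np.asarray(self.additive_effects, dtype=float)
        if self.additive_effects.size != len(self.qtl_marker_ids):
            raise SimulationError("one additive effect per QTL required")
        for name in ("sigma_g2", "sigma_ge2", "sigma_e2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SimulationError(f"{name} must be finite and >= 0")
        if self.n_environments < 1 or self.n_replicates < 1:
            raise SimulationError("need at least one environment and replicate")

    @property
    def h2(self) -> float:
        """Realized entry-mean heritability implied by the variance targets."""
        e, r = self.n_environments, self.n_replicates
        denom = self.sigma_g2 + self.sigma_ge2 / e + self.sigma_e2 / (e * r)
        return self.sigma_g2 / denom


def random_trait_architecture(
    pop: BiparentalPopulation,
    trait_env: str,
    target_h2: float,
    rng: np.random.Generator,
    n_qtl: int = 40,
    e: int = 4,
    r: int = 2,
    sigma_g2: float = 1.0,
    ge_to_e_ratio: float = 0.5,
    mu: float = 0.0,
    exclude_markers: tuple[str, ...] = (),
) -> TraitArchitecture:
    """Polygenic architecture: ``n_qtl`` markers drawn at random with N(0,1) effects."""
    candidates = [m for m in pop.polymorphic_marker_ids if m not in set(exclude_markers)]
    n_qtl = min(n_qtl, len(candidates))
    qtl = tuple(rng.choice(candidates, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    sge2, se2 = calibrate_variances(target_h2, e, r, sigma_g2, ge_to_e_ratio)
    return TraitArchitecture(
        trait_env=trait_env,
        qtl_marker_ids=qtl,
        additive_effects=effects,
        sigma_g2=sigma_g2,
        sigma_ge2=sge2,
        sigma_e2=se2,
        n_environments=e,
        n_replicates=r,
        mu=mu,
    )


def genetic_values(pop: BiparentalPopulation, arch: TraitArchitecture) -> np.ndarray:
    """True genetic values, rescaled so their sample variance equals sigma_g2."""
    z = pop.marker_columns(arch.qtl_marker_ids).astype(float)
    g = z @ arch.additive_effects
    g = g - g.mean()
    if arch.sigma_g2 == 0:
        return np.zeros_like(g)
    sd = g.std(ddof=1)
    if sd == 0:
        raise SimulationError("QTL genotypes carry no variation; cannot scale to sigma_g2")
    return g / sd * np.sqrt(arch.sigma_g2)


def simulate_trials(
    pop: BiparentalPopulation, arch: TraitArchitecture, rng: np.random.Generator
) -> pd.DataFrame:
    """Balanced multi-environment trial records for one population and trait-env.

    Returns a long-format frame with columns (population_id, family_id,
    environment_id, replicate_id, trait_env, value), every family x
    environment x replicate cell present exactly once.
    """
    g = genetic_values(pop, arch)
    e, r = arch.n_environments, arch.n_replicates
    n = pop.n_families
    ge = rng.normal(0.0, np.sqrt(arch.sigma_ge2), size=(n, e)) if arch.sigma_ge2 > 0 else np.zeros((n, e))
    eps = rng.normal(0.0, np.sqrt(arch.sigma_e2), size=(n, e, r)) if arch.sigma_e2 > 0 else np.zeros((n, e, r))
    values = arch.mu + g[:, None, None] + ge[:, :, None] + eps

    fam = np.repeat(np.array(pop.family_ids, dtype=object), e * r)
    env = np.tile(np.repeat([f"E{j + 1}" for j in range(e)], r), n)
    rep = np.tile([k + 1 for k in range(r)], n * e)
    return pd.DataFrame(
        {
            "population_id": pop.population_id,
            "family_id": fam,
            "environment_id": env,
            "replicate_id": rep,
            "trait_env": arch.trait_env,
            "value": values.reshape(-1),
        }
    )


def simulate_halfsib_set(
    shared_parent_id: str,
    other_parent_ids: tuple[str, str],
    n_families_each: tuple[int, int],
    gmap: GeneticMap,
    rng: np.random.Generator,
    panel_size: int = 180,
    population_ids: tuple[str, str] = ("HS1", "HS2"),
) -> tuple[BiparentalPopulation, BiparentalPopulation, tuple[str, ...]]:
    """Two crosses sharing one parent, each genotyped on its own marker panel.

    The shared parent's haplotype and the two non-shared haplotypes are drawn
    independently (Bernoulli 1/2 per marker), so roughly half the genome
    segregates in each cross and a quarter in both. Each population's panel
    is a random ``panel_size`` subset of its own polymorphic markers,
    emulating per-population assay panels; the returned common-marker set is
    the intersection of the two panels. The shared parent is parent A of
    both crosses, so ``+1`` codes the shared allele in both.
    """
    if other_parent_ids[0] == other_parent_ids[1]:
        raise SimulationError("full-sib configuration: both non-shared parents identical")
    if shared_parent_id in other_parent_ids:
        raise SimulationError("shared parent duplicated among the non-shared parents")
    m = gmap.n_markers
    hap_shared = rng.integers(0, 2, size=m).astype(np.int8)
    pops = []
    for pid, other, nfam in zip(population_ids, other_parent_ids, n_families_each):
        hap_other = rng.integers(0, 2, size=m).astype(np.int8)
        ped = FounderPair(shared_parent_id, other, hap_shared, hap_other)
        pop = simulate_population(ped, "F2", nfam, gmap, rng, population_id=pid)
        avail = list(pop.polymorphic_marker_ids)
        if len(avail) > panel_size:
            panel = sorted(rng.choice(avail, size=panel_size, replace=False),
                           key=avail.index)
            pop = pop.subset_markers(panel)
        pops.append(pop)
    common = tuple(
        m_ for m_ in pops[0].polymorphic_marker_ids
        if m_ in set(pops[1].polymorphic_marker_ids)
    )
    if not common:
        raise SimulationError("half-sib pair shares no polymorphic markers")
    return pops[0], pops[1], common


def simulate_study_population(
    pop_no: int,
    n_families: int,
    n_snps: int,
    master_seed: int,
    gmap: GeneticMap | None = None,
) -> BiparentalPopulation:
    """One population sized like a study entry: exact family and SNP counts.

    Founders differ at every map position, so the polymorphic count equals
    the panel size by construction; the panel is a random subset of the
    genome map of size ``n_snps``.
    """
    if gmap is None:
        gmap = default_map(markers_per_chromosome=30)  # 300 sites >= largest panel
    if n_snps > gmap.n_markers:
        raise SimulationError("panel larger than the genome map")
    rng = child_rng(master_seed, "population", pop_no)
    hap_a = np.zeros(gmap.n_markers, dtype=np.int8)
    hap_b = np.ones(gmap.n_markers, dtype=np.int8)
    ped = FounderPair(f"PA{pop_no}", f"PB{pop_no}", hap_a, hap_b)
    pop = simulate_population(ped, "F2", n_families, gmap, rng, population_id=f"Pop{pop_no}")
    panel = sorted(
        rng.choice(len(pop.polymorphic_marker_ids), size=n_snps, replace=False)
    )
    return pop.subset_markers(tuple(pop.polymorphic_marker_ids[i] for i in panel))
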