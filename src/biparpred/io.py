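"""File formats, the bundled population-metadata table, and study aggregates.

Formats (all plain CSV; lines starting with ``#`` are provenance comments
carrying the master seed and a config hash, skipped on read):

* genotypes: first column ``family_id``, one column per marker id, coded
  values in {-1, 0, 1};
* genetic map: columns (marker_id, chromosome, position_cm);
* phenotypes: long format (population_id, family_id, environment_id,
  replicate_id, trait_env, value).

The bundled ``population_metadata.csv`` describes a reference panel of 22
bi-parental tropical maize testcross populations (pedigree code, tester,
family count, polymorphic SNP count, and mean/SD for the six
trait-environment combinations); it sizes the synthetic study and anchors
the half-sib pedigree graph.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import TRAIT_ENVS, BiparentalPopulation, GeneticMap

__all__ = [
    "PopulationMetadata",
    "read_metadata",
    "summarize_metadata",
    "platform_group_for_tester",
    "round_half_up",
    "write_genotypes",
    "read_genotypes",
    "write_map",
    "read_map",
    "write_phenotypes",
    "read_phenotypes",
]

#: Testers T1/T2 belong to one genotyping-platform group (TaqMan-like),
#: T3..T6 to the other (KASP-like).
_TESTER_PLATFORM = {"T1": "taqman", "T2": "taqman"}


def platform_group_for_tester(tester: str) -> str:
    return _TESTER_PLATFORM.get(tester, "kasp")


@dataclass(frozen=True)
class PopulationMetadata:
    pop_no: int
    parent_a: str
    parent_b: str
    tester: str
    n_families: int
    n_snps: int
    trait_means: dict[str, float]
    trait_sds: dict[str, float]

    @property
    def population_id(self) -> str:
        return f"Pop{self.pop_no}"

    @property
    def platform_group(self) -> str:
        return platform_group_for_tester(self.tester)


def _bundled_metadata_path() -> Path:
    return Path(resources.files("biparpred").joinpath("data/population_metadata.csv"))


def read_metadata(path: str | Path | None = None) -> list[PopulationMetadata]:
    """Parse the population metadata table (bundled panel by default)."""
    path = _bundled_metadata_path() if path is None else Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as err:
        raise ValueError(f"metadata file {path} is empty") from err
    required = {"pop_no", "pedigree", "tester", "n_families", "n_snps"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata file missing columns {required - set(df.columns)}")
    out = []
    for _, row in df.iterrows():
        parents = [p.strip() for p in str(row["pedigree"]).split("x")]
        if len(parents) != 2 or not all(parents):
            raise ValueError(f"malformed pedigree {row['pedigree']!r}")
        means = {te: float(row[f"{te.lower()}_mean"]) for te in TRAIT_ENVS}
        sds = {te: float(row[f"{te.lower()}_sd"]) for te in TRAIT_ENVS}
        out.append(
            PopulationMetadata(
                pop_no=int(row["pop_no"]),
                parent_a=parents[0],
                parent_b=parents[1],
                tester=str(row["tester"]),
                n_families=int(row["n_families"]),
                n_snps=int(row["n_snps"]),
                trait_means=means,
                trait_sds=sds,
            )
        )
    return out


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding, matching how summary tables are printed."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_metadata(meta: list[PopulationMetadata]) -> dict[str, float]:
    """Panel-level aggregates: totals, SNP mean, per-trait mean of means."""
    if not meta:
        raise ValueError("no metadata rows")
    agg: dict[str, float] = {
        "n_populations": len(meta),
        "total_families": int(sum(m.n_families for m in meta)),
        "mean_polymorphic_snps": round_half_up(
            float(np.mean([m.n_snps for m in meta]))
        ),
        "min_polymorphic_snps": min(m.n_snps for m in meta),
        "max_polymorphic_snps": max(m.n_snps for m in meta),
        "min_families": min(m.n_families for m in meta),
        "max_families": max(m.n_families for m in meta),
    }
    for te in TRAIT_ENVS:
        # exact decimal mean: the printed table carries fixed 2-dp values,
        # and half-up ties (e.g. x.xx5) must not be lost to binary floats
        total = sum(Decimal(repr(m.trait_means[te])) for m in meta)
        mean = total / len(meta)
        agg[f"{te.lower()}_mean"] = float(
            mean.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
        )
    return agg


# ---------------------------------------------------------------------------
# file writers / readers


def _provenance_lines(seed: int | None, config: dict | None) -> str:
    lines = []
    if seed is not None:
        lines.append(f"# master_seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config_hash: {digest}")
    return "".join(line + "\n" for line in lines)


def write_genotypes(
    pop: BiparentalPopulation,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> None:
    df = pd.DataFrame(
        pop.genotypes, columns=list(pop.polymorphic_marker_ids),
        index=pd.Index(pop.family_ids, name="family_id"),
    )
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config))
        df.to_csv(fh)


def read_genotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", index_col="family_id")
    bad = ~df.isin((-1, 0, 1)).all()
    if bad.any():
        raise ValueError(f"non-coded genotype values in columns {list(df.columns[bad])[:5]}")
    return df


def write_map(gmap: GeneticMap, path: str | Path, seed: int | None = None,
              config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config))
        gmap.to_frame().to_csv(fh, index=False)


def read_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, comment="#")
    return GeneticMap(
        chromosome=df["chromosome"].to_numpy(),
        marker_id=tuple(df["marker_id"]),
        position_cm=df["position_cm"].to_numpy(),
    )


PHENO_COLUMNS = (
    "population_id", "family_id", "environment_id", "replicate_id", "trait_env", "value",
)


def write_phenotypes(trials: pd.DataFrame, path: str | Path, seed: int | None = None,
                     config: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_lines(seed, config))
        trials[list(PHENO_COLUMNS)].to_csv(fh, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"phenotype file missing columns {missing}")
    return df
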