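"""What drives prediction accuracy: correlation and variance decomposition.

For one trait-environment regime the dataset has one row per
(population, TPS, MD) cell with the cell's r_MG as response and three
quantitative predictors: the population's heritability h2, the training
population size, and the realized marker count (the "all SNPs" level enters
as the population-specific polymorphic count). Two analyses are offered:

* Pearson correlation of r_MG with each predictor (two-sided t test), and
* a sequential (type-I) ANOVA of the linear model r_MG ~ h2 + TPS + MD in
  a fixed, configurable order, reporting each factor's percentage of the
  total sum of squares plus the residual percentage; the shares sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FactorDecomposition",
    "build_factor_dataset",
    "correlate_factors",
    "variance_decompose",
]

PREDICTORS = ("h2", "tps", "md")


@dataclass(frozen=True)
class FactorDecomposition:
    trait_env: str
    order: tuple[str, ...]
    variance_explained: dict[str, float]  # percent of total SS per factor
    p_values: dict[str, float]
    residual_percent: float

    def as_row(self) -> dict:
        row = {"trait_env": self.trait_env}
        for f in self.order:
            row[f"{f}_pct"] = self.variance_explained[f]
            row[f"{f}_p"] = self.p_values[f]
        row["residual_pct"] = self.residual_percent
        return row


def build_factor_dataset(
    results_frame: pd.DataFrame,
    h2_by_population: pd.Series,
    trait_env: str,
    marker_counts: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Rows (r_mg, h2, tps, md) for one trait-env, MD as realized marker count."""
    df = results_frame[results_frame["trait_env"] == trait_env].copy()
    if df.empty:
        raise ValueError(f"no results for trait-env {trait_env!r}")
    df["h2"] = df["population_id"].map(h2_by_population)

    def md_numeric(row):
        if isinstance(row["md"], str):
            if marker_counts is None:
                raise ValueError("marker_counts needed to encode the 'all SNPs' level")
            return float(marker_counts[row["population_id"]])
        return float(row["md"])

    df["md"] = df.apply(md_numeric, axis=1)
    df["tps"] = df["tps"].astype(float)
    return df[["population_id", "r_mg", "h2", "tps", "md"]].reset_index(drop=True)


def correlate_factors(ds: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p of r_MG against each predictor."""
    if len(ds) < 3:
        raise ValueError("need at least 3 rows")
    rows = []
    for f in PREDICTORS:
        x = ds[f].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"factor": f, "r": float("nan"), "p": float("nan"),
                         "defined": False})
            continue
        res = stats.pearsonr(x, ds["r_mg"].to_numpy(dtype=float))
        rows.append({"factor": f, "r": float(res.statistic),
                     "p": float(res.pvalue), "defined": True})
    return pd.DataFrame(rows)


def variance_decompose(
    ds: pd.DataFrame,
    order: tuple[str, ...] = PREDICTORS,
    trait_env: str = "",
) -> FactorDecomposition:
    """Sequential (type-I) sums of squares of r_MG ~ predictors in ``order``.

    Percentages are SS_factor / SS_total * 100 around the response mean;
    p-values are the type-I F tests against the full-model residual.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    y = ds["r_mg"].to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(ds))] + [ds[f].to_numpy(dtype=float) for f in order])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # identify which added column(s) fail to increase the rank
        bad = []
        r = 1
        for j, f in enumerate(order, start=1):
            rj = np.linalg.matrix_rank(x[:, : j + 1])
            if rj == r:
                bad.append(f)
            r = rj
        raise ValueError(f"design is rank deficient; collinear predictors: {bad}")

    model = ols("r_mg ~ " + " + ".join(order), data=ds).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    ss_total = float(((y - y.mean()) ** 2).sum())
    shares = {f: float(anova.loc[f, "sum_sq"]) / ss_total * 100.0 for f in order}
    pvals = {f: float(anova.loc[f, "PR(>F)"]) for f in order}
    residual = float(anova.loc["Residual", "sum_sq"]) / ss_total * 100.0
    return FactorDecomposition(
        trait_env=trait_env,
        order=tuple(order),
        variance_explained=shares,
        p_values=pvals,
        residual_percent=residual,
    )
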