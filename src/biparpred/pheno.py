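"""Multi-environment trial analysis: variance components, heritability, BLUPs.

The model is the all-random two-way classification used for combined trial
analysis within a management regime,

    y_ijk = mu + E_j + g_i + (ge)_ij + eps_ijk,

with genotypes, environments, genotype-by-environment interaction and
residual all random. On a balanced design the variance components have the
classical expected-mean-squares (ANOVA) solutions

    sigma_e2  = MSE
    sigma_ge2 = (MS_GE - MSE) / r
    sigma_g2  = (MS_G - MS_GE) / (e r)

(negative estimates truncated at zero), and the entry-mean broad-sense
heritability is

    h2 = sigma_g2 / (sigma_g2 + sigma_ge2 / e + sigma_e2 / (e r)).

For unbalanced data a REML fit over the same model is used; on balanced
data it coincides with the ANOVA estimators whenever those are interior
(non-negative), which the tests verify. Genotype BLUPs on balanced data are
shrunken centred family means, BLUP_i = h2 * (ybar_i - ybar), identical to
the mixed-model-equation solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "VarianceComponents",
    "HeritabilityResult",
    "estimate_components",
    "heritability",
    "genotype_blups",
    "sort_and_subgroup",
]


@dataclass(frozen=True)
class VarianceComponents:
    sigma_g2: float
    sigma_ge2: float
    sigma_e2: float
    e: int  # environments in the analysis
    r: int  # replicates per environment

    def __post_init__(self):
        if min(self.sigma_g2, self.sigma_ge2, self.sigma_e2) < 0:
            raise ValueError("variance components must be non-negative")
        if self.e < 1 or self.r < 1:
            raise ValueError("e and r must be >= 1")


@dataclass(frozen=True)
class HeritabilityResult:
    trait_env: str
    h2: float

    @property
    def h(self) -> float:
        return float(np.sqrt(self.h2))


def _layout(trials: pd.DataFrame):
    fams = trials["family_id"].unique()
    envs = trials["environment_id"].unique()
    counts = trials.groupby(["family_id", "environment_id"], sort=False).size()
    balanced = (
        len(counts) == len(fams) * len(envs) and counts.nunique() == 1
    )
    r = int(counts.iloc[0]) if balanced else int(round(counts.mean()))
    return fams, envs, r, balanced


def estimate_components(trials: pd.DataFrame) -> VarianceComponents:
    """Estimate (sigma_g2, sigma_ge2, sigma_e2) from long-format trial records.

    Balanced data take the closed-form ANOVA path; unbalanced data fall back
    to REML on the all-random model. Requires >= 2 families, >= 2
    environments and >= 2 replicates per cell (with one replicate the
    residual variance is not identifiable from the interaction).
    """
    fams, envs, r, balanced = _layout(trials)
    g, e = len(fams), len(envs)
    if g < 2:
        raise ValueError("need at least two families")
    if e < 2:
        raise ValueError("sigma_ge2 is unidentifiable with fewer than two environments")
    if balanced and r < 2:
        raise ValueError("need replicate measurements to separate residual variance")

    if balanced:
        sg2, sge2, se2 = _anova_components(trials, fams, envs, r)
    else:
        sg2, sge2, se2 = _reml_components(trials)
    return VarianceComponents(sg2, sge2, se2, e=e, r=r)


def _anova_components(trials, fams, envs, r):
    g, e = len(fams), len(envs)
    cell = trials.pivot_table(
        index="family_id", columns="environment_id", values="value",
        aggfunc="mean", sort=False,
    ).loc[fams, envs].to_numpy()
    grand = trials["value"].mean()
    fam_means = cell.mean(axis=1)
    env_means = cell.mean(axis=0)

    ss_g = e * r * np.sum((fam_means - grand) ** 2)
    ss_ge = r * np.sum((cell - fam_means[:, None] - env_means[None, :] + grand) ** 2)
    # within-cell (replicate) sum of squares
    ss_within = (
        trials.groupby(["family_id", "environment_id"], sort=False)["value"]
        .apply(lambda v: ((v - v.mean()) ** 2).sum())
        .sum()
    )
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    mse = ss_within / (g * e * (r - 1))

    se2 = mse
    sge2 = max((ms_ge - mse) / r, 0.0)
    sg2 = max((ms_g - ms_ge) / (e * r), 0.0)
    return sg2, sge2, se2


def _design(trials: pd.DataFrame):
    y = trials["value"].to_numpy(dtype=float)
    fam = pd.Categorical(trials["family_id"])
    env = pd.Categorical(trials["environment_id"])
    cell = pd.Categorical(
        trials["family_id"].astype(str) + ":" + trials["environment_id"].astype(str)
    )
    def indicator(codes, k):
        z = np.zeros((len(codes), k))
        z[np.arange(len(codes)), codes] = 1.0
        return z
    z_g = indicator(fam.codes, len(fam.categories))
    z_env = indicator(env.codes, len(env.categories))
    z_ge = indicator(cell.codes, len(cell.categories))
    return y, z_g, z_env, z_ge, list(fam.categories)


def _reml_components(trials, tol=1e-10, max_iter=4000):
    """REML by direct optimization of the profiled restricted likelihood.

    Variance ratios gamma = sigma^2 / sigma_e2 for (genotype, environment,
    GxE) are optimized on the log scale; the residual variance is profiled
    out analytically. Intended for the modest table sizes of trial data.
    """
    y, z_g, z_env, z_ge, _ = _design(trials)
    n = y.size
    x = np.ones((n, 1))
    p = 1
    zs = [z_g, z_env, z_ge]

    def neg_restricted_ll(log_gamma):
        gam = np.exp(np.clip(log_gamma, -30, 30))
        h = np.eye(n)
        for gk, zk in zip(gam, zs):
            h += gk * (zk @ zk.T)
        sign, logdet_h = np.linalg.slogdet(h)
        hinv = np.linalg.inv(h)
        xt_hinv_x = x.T @ hinv @ x
        beta = np.linalg.solve(xt_hinv_x, x.T @ hinv @ y)
        resid = y - x @ beta
        quad = resid @ hinv @ resid
        _, logdet_x = np.linalg.slogdet(xt_hinv_x)
        return logdet_h + logdet_x + (n - p) * np.log(quad)

    best = None
    for start in ([0.0, 0.0, 0.0], [1.0, 0.0, -1.0], [-2.0, -2.0, -2.0]):
        res = optimize.minimize(
            neg_restricted_ll, np.array(start), method="Nelder-Mead",
            options={"xatol": tol, "fatol": tol, "maxiter": max_iter},
        )
        if best is None or res.fun < best.fun:
            best = res
    # quasi-Newton polish: Nelder-Mead alone can stall short of the optimum
    polish = optimize.minimize(neg_restricted_ll, best.x, method="BFGS",
                               options={"gtol": 1e-12})
    if polish.fun <= best.fun:
        best = polish
    gam = np.exp(best.x)
    h = np.eye(n)
    for gk, zk in zip(gam, zs):
        h += gk * (zk @ zk.T)
    hinv = np.linalg.inv(h)
    beta = np.linalg.solve(x.T @ hinv @ x, x.T @ hinv @ y)
    resid = y - x.flatten() * beta[0]
    se2 = float(resid @ hinv @ resid) / (n - p)
    sg2, _senv2, sge2 = (float(g * se2) for g in gam)
    return max(sg2, 0.0), max(sge2, 0.0), max(se2, 0.0)


def heritability(vc: VarianceComponents, trait_env: str = "") -> HeritabilityResult:
    """Entry-mean broad-sense heritability from variance components."""
    denom = vc.sigma_g2 + vc.sigma_ge2 / vc.e + vc.sigma_e2 / (vc.e * vc.r)
    if denom == 0:
        raise ValueError("all variance components are zero; h2 undefined")
    return HeritabilityResult(trait_env=trait_env, h2=vc.sigma_g2 / denom)


def genotype_blups(trials: pd.DataFrame, vc: VarianceComponents) -> pd.Series:
    """BLUPs of family genetic effects (deviations from the grand mean).

    On balanced data these are the shrunken centred family means with
    shrinkage factor equal to the entry-mean heritability; on unbalanced
    data the mixed-model equations of the all-random model are solved. The
    returned Series is indexed by family_id and carries
    ``attrs['basis'] = 'deviation'``.
    """
    fams, envs, r, balanced = _layout(trials)
    if balanced:
        fam_means = (
            trials.groupby("family_id", sort=False)["value"].mean().loc[fams]
        )
        shrink = heritability(vc).h2
        blups = shrink * (fam_means - trials["value"].mean())
    else:
        blups = _mme_blups(trials, vc)
    blups.attrs["basis"] = "deviation"
    return blups


def _mme_blups(trials: pd.DataFrame, vc: VarianceComponents) -> pd.Series:
    y, z_g, z_env, z_ge, fam_levels = _design(trials)
    n = y.size
    x = np.ones((n, 1))
    se2 = vc.sigma_e2 if vc.sigma_e2 > 0 else 1e-12
    blocks = []
    lam = []
    for z, s2 in ((z_g, vc.sigma_g2), (z_env, se2 * 1e6), (z_ge, vc.sigma_ge2)):
        if s2 <= 0:  # component absent: effect pinned at zero via huge ridge
            lam.append(1e12)
        else:
            lam.append(se2 / s2)
        blocks.append(z)
    z = np.hstack(blocks)
    q = z.shape[1]
    ridge = np.concatenate([
        np.full(b.shape[1], l) for b, l in zip(blocks, lam)
    ])
    lhs = np.block([
        [x.T @ x, x.T @ z],
        [z.T @ x, z.T @ z + np.diag(ridge)],
    ])
    rhs = np.concatenate([x.T @ y, z.T @ y])
    sol = np.linalg.solve(lhs, rhs)
    u_g = sol[1 : 1 + z_g.shape[1]]
    return pd.Series(u_g, index=fam_levels)


def sort_and_subgroup(
    h2_by_population: pd.Series, sizes: tuple[int, ...] = (6, 5, 5, 6)
) -> pd.Series:
    """Assign populations to heritability subgroups (ascending h2).

    Populations are sorted by h2 ascending (stable: ties keep input order)
    and cut into consecutive groups of the given sizes; subgroup 1 is the
    lowest-heritability group. The default sizes partition a 22-population
    panel as {1-6}, {7-11}, {12-16}, {17-22}: six populations in the lowest
    subgroup, five in each middle subgroup, with the remainder (six) in the
    top subgroup so that every population is assigned.
    """
    h2 = pd.Series(h2_by_population)
    if len(h2) != sum(sizes):
        raise ValueError(
            f"{len(h2)} populations cannot be split into groups of sizes {sizes}"
        )
    order = np.argsort(h2.to_numpy(), kind="stable")
    labels = np.empty(len(h2), dtype=int)
    start = 0
    for gi, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = gi
        start += size
    return pd.Series(labels, index=h2.index, name="subgroup")
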