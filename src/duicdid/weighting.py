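"""Post-stratification weighting to population margins and design-corrected
contingency tests.

Weights are computed independently within each (country, wave) group and
renormalised to mean 1 there, so weighted totals equal the unweighted sample
sizes. Two modes are provided: exact cell weighting on the joint
age x gender x education x region grid, and raking (iterative proportional
fitting) on the four marginal distributions. Chi-square tests on weighted
counts use a first-order Rao-Scott correction via the Kish design effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import GeneratorConfig
from .errors import (ConfigurationError, DegenerateCellError,
                     DegenerateTableError, RakingConvergenceError)

#: Post-stratification dimensions, in raking order.
PS_DIMS = ("age_group", "gender", "education", "region")


@dataclass
class PopulationMargins:
    """Per-country target distribution over the post-stratification cells.

    ``tables[country]`` is a DataFrame with the four cell columns plus a
    ``proportion`` column summing to 1.
    """
    tables: dict

    def __post_init__(self) -> None:
        for country, tab in self.tables.items():
            missing = [c for c in (*PS_DIMS, "proportion")
                       if c not in tab.columns]
            if missing:
                raise ConfigurationError(
                    f"margins[{country}] missing columns {missing}")
            props = tab["proportion"].to_numpy(dtype=float)
            if (props < 0).any():
                raise ConfigurationError(
                    f"margins[{country}] has negative proportions")
            if abs(props.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"margins[{country}] proportions sum to {props.sum()!r}, "
                    "expected 1")

    def marginal(self, country: str, dim: str) -> pd.Series:
        """One-dimensional target margin, summed from the joint table."""
        tab = self.tables[country]
        return tab.groupby(dim)["proportion"].sum()

    @classmethod
    def from_csv(cls, path) -> "PopulationMargins":
        df = pd.read_csv(path)
        return cls({c: g.drop(columns="country").reset_index(drop=True)
                    for c, g in df.groupby("country")})

    def to_csv(self, path) -> None:
        frames = []
        for country, tab in self.tables.items():
            t = tab.copy()
            t.insert(0, "country", country)
            frames.append(t)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def margins_from_config(cfg: GeneratorConfig) -> PopulationMargins:
    """Product-of-marginals joint margins implied by the generator config
    (covariates are drawn independently, so the product is the true joint).
    Nonbinary mass is split evenly between male and female, mirroring the
    gender recode applied before weighting.
    """
    p_nb = cfg.gender_dist.get("nonbinary", 0.0)
    gender = {"male": cfg.gender_dist["male"] + p_nb / 2,
              "female": cfg.gender_dist["female"] + p_nb / 2}
    dims = {"age_group": cfg.age_dist, "gender": gender,
            "education": cfg.education_dist, "region": cfg.region_dist}
    idx = pd.MultiIndex.from_product(
        [list(d.keys()) for d in dims.values()], names=list(dims.keys()))
    tab = idx.to_frame(index=False)
    prop = np.ones(len(tab))
    for dim, dist in dims.items():
        prop *= tab[dim].map(dist).to_numpy(dtype=float)
    tab["proportion"] = prop / prop.sum()
    return PopulationMargins({c: tab.copy() for c in cfg.n_cells})


@dataclass
class WeightedDesign:
    """Sample rows plus per-respondent weights and weight diagnostics."""
    rows: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)

    @property
    def weights(self) -> np.ndarray:
        return self.rows["weight"].to_numpy(dtype=float)


def weight_diagnostics(weights: np.ndarray) -> dict:
    """Min/max weight, Kish effective sample size and design effect."""
    w = np.asarray(weights, dtype=float)
    sw, sw2 = w.sum(), (w ** 2).sum()
    n = len(w)
    return {"n": n, "min_weight": float(w.min()), "max_weight": float(w.max()),
            "mean_weight": float(w.mean()),
            "kish_ess": float(sw ** 2 / sw2),
            "design_effect": float(n * sw2 / sw ** 2)}


def _cell_weights(group: pd.DataFrame, margin: pd.DataFrame) -> np.ndarray:
    key = list(PS_DIMS)
    target = margin.set_index(key)["proportion"]
    share = group.groupby(key, observed=True).size() / len(group)
    cells = pd.MultiIndex.from_frame(group[key])
    unknown = ~cells.isin(target.index)
    if unknown.any():
        raise DegenerateCellError(
            f"{int(unknown.sum())} sample rows map to no margin cell, e.g. "
            f"{tuple(cells[unknown][0])}")
    empty = target.index[(target > 0)
                         & ~target.index.isin(share.index)]
    if len(empty):
        raise DegenerateCellError(
            f"margin cell {tuple(empty[0])} has positive target share but no "
            "sample rows; consider mode='raking'")
    ratio = (target / share).reindex(cells).to_numpy(dtype=float)
    return ratio


def _rake_weights(group: pd.DataFrame, margins: PopulationMargins,
                  country: str, tol: float, max_iter: int) -> np.ndarray:
    w = np.ones(len(group))
    targets = {dim: margins.marginal(country, dim) for dim in PS_DIMS}
    codes = {dim: group[dim].to_numpy(dtype=object) for dim in PS_DIMS}
    resid = np.inf
    for _ in range(max_iter):
        for dim in PS_DIMS:
            shares = pd.Series(w).groupby(codes[dim]).sum() / w.sum()
            factor = (targets[dim] / shares).reindex(shares.index)
            if factor.isna().any() or np.isinf(factor.to_numpy()).any():
                raise DegenerateCellError(
                    f"empty level in dimension {dim!r} with positive target")
            w = w * pd.Series(codes[dim]).map(factor).to_numpy(dtype=float)
        resid = max(
            float((pd.Series(w).groupby(codes[d]).sum() / w.sum()
                   - targets[d]).abs().max())
            for d in PS_DIMS)
        if resid < tol:
            return w
    raise RakingConvergenceError(
        f"raking did not reach tolerance {tol} in {max_iter} iterations "
        f"(last residual {resid:.3e})")


def poststratify(sample: pd.DataFrame, margins: PopulationMargins,
                 mode: str = "cell", tol: float = 1e-8,
                 max_iter: int = 100) -> WeightedDesign:
    """Post-stratification weights per (country, wave), mean 1 per group."""
    if mode not in ("cell", "raking"):
        raise ConfigurationError(f"mode must be 'cell' or 'raking', got {mode!r}")
    rows = sample.reset_index(drop=True).copy()
    weights = np.ones(len(rows))
    per_group = {}
    for (country, wave), group in rows.groupby(["country", "wave"]):
        margin = margins.tables[country]
        if mode == "cell":
            w = _cell_weights(group, margin)
        else:
            w = _rake_weights(group, margins, country, tol, max_iter)
        w = w / w.mean()
        weights[group.index.to_numpy()] = w
        per_group[(country, wave)] = weight_diagnostics(w)
    rows["weight"] = weights
    diag = weight_diagnostics(weights)
    diag["per_group"] = per_group
    return WeightedDesign(rows=rows, diagnostics=diag)


def weighted_crosstab(df: pd.DataFrame, row: str, col: str,
                      weights: np.ndarray | None = None) -> pd.DataFrame:
    w = np.ones(len(df)) if weights is None else np.asarray(weights, float)
    return pd.crosstab(df[row], df[col], values=w, aggfunc="sum").fillna(0.0)


def rao_scott_chisq(table: pd.DataFrame | np.ndarray,
                    weights: np.ndarray) -> tuple[float, int, float]:
    """First-order Rao-Scott corrected chi-square on weighted counts.

    The weighted table is rescaled to the actual sample size, the Pearson
    statistic computed, then deflated by the Kish design effect of the
    weights; the p-value uses (r-1)(c-1) degrees of freedom.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise DegenerateTableError("need a table with >= 2 rows and columns")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has a zero marginal")
    w = np.asarray(weights, dtype=float)
    n = len(w)
    t = t * (n / t.sum())
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    pearson = float(((t - expected) ** 2 / expected).sum())
    deff = weight_diagnostics(w)["design_effect"]
    adj = pearson / deff
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return adj, df, float(stats.chi2.sf(adj, df))
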