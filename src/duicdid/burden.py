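"""DUIC(-)/DUIC(+) episode allocation and the burden decomposition by
cannabis-use frequency.

Categorical 30-day episode counts are converted to numbers by interval
midpoints (once -> 1, 2-3 -> 2.5, 4-9 -> 6.5, 10-15 -> 12.5, exact entry
above 15). Each respondent's episodes are then split between cannabis-only
driving (DUIC(-)) and driving after combining cannabis with alcohol or
other drugs (DUIC(+)) according to the verbal co-use category: the primary
scheme assigns 100/75/25/0 percent of episodes to DUIC(-) for
cannabis-only/occasionally/mostly/always. Fractional episodes are kept
(allocation is proportional, not per-episode). Shares are reported on the
0-100 scale; population shares use all past-year non-medical users as the
denominator, not only DUIC reporters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import COUSE_LEVELS, USE_FREQ_LEVELS
from .errors import (ConfigurationError, IncompleteRecordError,
                     UndefinedShareError)
from .rand import stage_rng

_MIDPOINTS = {"once": 1.0, "2-3": 2.5, "4-9": 6.5, "10-15": 12.5}


@dataclass(frozen=True)
class AllocationScheme:
    """Fraction of a respondent's episodes classified DUIC(-) per co-use
    category."""
    cannabis_only: float = 1.00
    occasionally: float = 0.75
    mostly: float = 0.25
    always: float = 0.00

    def __post_init__(self) -> None:
        for name in ("cannabis_only", "occasionally", "mostly", "always"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"scheme fraction {name} must lie in [0, 1], got {v!r}")

    def fraction(self, category: str) -> float:
        if category not in COUSE_LEVELS:
            raise ConfigurationError(f"unknown co-use category {category!r}")
        return float(getattr(self, category))


PRIMARY_SCHEME = AllocationScheme(1.00, 0.75, 0.25, 0.00)


def code_count_category(category: str, exact_count: float | None = None
                        ) -> float:
    """Numeric 30-day episode count from the categorical response."""
    if category in _MIDPOINTS:
        return _MIDPOINTS[category]
    if category == "more":
        if exact_count is None or not np.isfinite(exact_count):
            raise IncompleteRecordError(
                "category 'more' requires the exact entered count")
        if exact_count <= 15:
            raise IncompleteRecordError(
                f"exact count for 'more' must exceed 15, got {exact_count!r}")
        return float(exact_count)
    raise ConfigurationError(f"unknown episode category {category!r}")


def allocate_episodes(count: float, couse_category: str,
                      scheme: AllocationScheme = PRIMARY_SCHEME
                      ) -> tuple[float, float]:
    """Split a respondent's episode count into (DUIC(-), DUIC(+))."""
    if count < 0:
        raise ValueError("episode count must be nonnegative")
    minus = count * scheme.fraction(couse_category)
    return minus, count - minus


def episode_allocations(sample3: pd.DataFrame,
                        scheme: AllocationScheme = PRIMARY_SCHEME
                        ) -> pd.DataFrame:
    """Per-respondent episode totals and DUIC(-)/(+) split."""
    counts = np.array([
        code_count_category(c, e) for c, e in
        zip(sample3["duic_count_category"], sample3["duic_count_exact"])])
    frac = sample3["couse_category"].map(
        {lev: scheme.fraction(lev) for lev in COUSE_LEVELS})
    if frac.isna().any():
        raise ConfigurationError("missing or unknown co-use category")
    minus = counts * frac.to_numpy(dtype=float)
    return pd.DataFrame({
        "id": sample3["id"].to_numpy(),
        "freq_group": sample3["cannabis_freq"].to_numpy(),
        "total": counts, "duic_minus": minus, "duic_plus": counts - minus,
    })


@dataclass
class BurdenTable:
    """Per-frequency-group shares (percent) of users and of DUIC(-)/(+)
    episodes, plus overall totals."""
    table: pd.DataFrame
    totals: dict
    scheme: AllocationScheme = PRIMARY_SCHEME


def _group_sums(alloc: pd.DataFrame) -> pd.DataFrame:
    g = alloc.groupby("freq_group")[["total", "duic_minus", "duic_plus"]] \
        .sum().reindex(USE_FREQ_LEVELS).fillna(0.0)
    return g


def _user_shares(users: pd.DataFrame) -> pd.Series:
    counts = users["cannabis_freq"].value_counts() \
        .reindex(USE_FREQ_LEVELS).fillna(0.0)
    return 100.0 * counts / counts.sum()


def burden_decomposition(sample3: pd.DataFrame,
                         scheme: AllocationScheme = PRIMARY_SCHEME,
                         users: pd.DataFrame | None = None) -> BurdenTable:
    """Point-estimate burden decomposition.

    ``users`` is the past-year non-medical user table providing the
    population-share denominator; when omitted, shares are computed over the
    DUIC reporters themselves.
    """
    alloc = episode_allocations(sample3, scheme)
    sums = _group_sums(alloc)
    total = float(alloc["total"].sum())
    if total <= 0:
        raise UndefinedShareError("total episode count is zero")
    minus_tot = float(alloc["duic_minus"].sum())
    plus_tot = float(alloc["duic_plus"].sum())
    tab = pd.DataFrame(index=pd.Index(USE_FREQ_LEVELS, name="freq_group"))
    tab["pop_share_pct"] = _user_shares(users if users is not None
                                        else sample3)
    tab["minus_share_pct"] = (100.0 * sums["duic_minus"] / minus_tot
                              if minus_tot > 0 else np.nan)
    tab["plus_share_pct"] = (100.0 * sums["duic_plus"] / plus_tot
                             if plus_tot > 0 else np.nan)
    totals = {
        "n_respondents": int(len(sample3)),
        "n_users": int(len(users)) if users is not None else int(len(sample3)),
        "total_episodes": total, "duic_minus_episodes": minus_tot,
        "duic_plus_episodes": plus_tot,
        "duic_plus_pct": 100.0 * plus_tot / total,
        "duic_minus_pct": 100.0 * minus_tot / total,
    }
    return BurdenTable(table=tab, totals=totals, scheme=scheme)


def bootstrap_burden(sample3: pd.DataFrame,
                     scheme: AllocationScheme = PRIMARY_SCHEME,
                     B: int = 2000, seed: int = 0,
                     users: pd.DataFrame | None = None,
                     rng: np.random.Generator | None = None,
                     stratify: str | None = None) -> BurdenTable:
    """Burden decomposition with percentile 95% bootstrap CIs.

    Respondents are resampled with replacement (pooled across countries by
    default; pass ``stratify='country'`` to resample within country); the
    user table is resampled independently for the population-share CIs.
    Resamples with an undefined share (zero episode denominator) are skipped
    and counted; a warning is raised if more than 1% are skipped.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = stage_rng(seed, "burden")
    point = burden_decomposition(sample3, scheme, users=users)
    alloc = episode_allocations(sample3.reset_index(drop=True), scheme)
    codes = alloc["freq_group"].map(
        {f: i for i, f in enumerate(USE_FREQ_LEVELS)}).to_numpy()
    minus = alloc["duic_minus"].to_numpy()
    plus = alloc["duic_plus"].to_numpy()
    n = len(alloc)

    if stratify is not None:
        strata = sample3.reset_index(drop=True).groupby(stratify).indices
        idx = np.empty((B, n), dtype=np.int64)
        col = 0
        for _, members in sorted(strata.items()):
            m = len(members)
            idx[:, col:col + m] = np.asarray(members)[
                rng.integers(0, m, size=(B, m))]
            col += m
    else:
        idx = rng.integers(0, n, size=(B, n))
    k = len(USE_FREQ_LEVELS)
    minus_g = np.empty((B, k))
    plus_g = np.empty((B, k))
    c = codes[idx]
    for g in range(k):
        mask = c == g
        minus_g[:, g] = np.where(mask, minus[idx], 0.0).sum(axis=1)
        plus_g[:, g] = np.where(mask, plus[idx], 0.0).sum(axis=1)
    minus_tot = minus_g.sum(axis=1)
    plus_tot = plus_g.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        minus_share = np.where(minus_tot[:, None] > 0,
                               100.0 * minus_g / minus_tot[:, None], np.nan)
        plus_share = np.where(plus_tot[:, None] > 0,
                              100.0 * plus_g / plus_tot[:, None], np.nan)
        plus_pct = np.where(minus_tot + plus_tot > 0,
                            100.0 * plus_tot / (minus_tot + plus_tot), np.nan)
    n_skipped = int(np.isnan(minus_share).any(axis=1).sum()
                    + np.isnan(plus_share).any(axis=1).sum())
    if n_skipped > 0.01 * 2 * B:
        warnings.warn(f"{n_skipped} bootstrap resamples had undefined "
                      "shares and were skipped")

    pop_users = users if users is not None else sample3
    ucodes = pop_users["cannabis_freq"].map(
        {f: i for i, f in enumerate(USE_FREQ_LEVELS)}).to_numpy()
    nu = len(ucodes)
    uidx = rng.integers(0, nu, size=(B, nu))
    pop_share = np.stack(
        [100.0 * (ucodes[uidx] == g).mean(axis=1) for g in
         range(k)], axis=1)

    tab = point.table.copy()
    for name, arr in (("pop_share_pct", pop_share),
                      ("minus_share_pct", minus_share),
                      ("plus_share_pct", plus_share)):
        lo, hi = np.nanpercentile(arr, [2.5, 97.5], axis=0)
        tab[f"{name}_low"] = lo
        tab[f"{name}_high"] = hi
    totals = dict(point.totals)
    lo, hi = np.nanpercentile(plus_pct, [2.5, 97.5])
    totals["duic_plus_pct_ci"] = (float(lo), float(hi))
    totals["bootstrap_B"] = B
    totals["bootstrap_skipped"] = n_skipped
    return BurdenTable(table=tab, totals=totals, scheme=scheme)


def sensitivity_schemes(sample3: pd.DataFrame, schemes,
                        users: pd.DataFrame | None = None) -> list:
    """One decomposition per scheme, with the group rank order by DUIC(+)
    share for qualitative-stability checks."""
    schemes = list(schemes)
    if not schemes:
        raise ConfigurationError("need at least one allocation scheme")
    out = []
    for scheme in schemes:
        bt = burden_decomposition(sample3, scheme, users=users)
        ranks = bt.table["plus_share_pct"].sort_values(ascending=False)
        out.append({"scheme": scheme, "table": bt,
                    "plus_rank_order": list(ranks.index)})
    return out
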