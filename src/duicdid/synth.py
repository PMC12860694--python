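"""Synthetic survey microdata with the statistical structure the
difference-in-differences analysis assumes.

The generator draws, per design cell (country x wave), quota covariates from
their margins, past-year cannabis use with a configurable injected DiD odds
ratio on the intervention country at wave t1, use frequency, the DUIC module
(only for users above the per-wave routing threshold), co-use and episode
counts (t1 only), and response-quality metadata. Planted quality artifacts
(speeders, straightliners, control-check failures, cross-wave duplicates)
are recorded in a truth ledger so the preprocessing filters can be verified
row for row.

Covariates shift individual outcome odds, but the intercept of every design
cell is recalibrated so the cell's mean outcome probability equals its
target exactly; the marginal (saturated-model) interaction therefore equals
the injected log odds ratio despite the noncollapsibility of the odds ratio.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import (COUNTRIES, COUSE_LEVELS, EPISODE_CATEGORIES,
                     GeneratorConfig, USE_FREQ_LEVELS, WAVES)
from .errors import ConfigurationError
from .rand import stage_rng

#: Column order of the respondent table; also the CSV header contract.
RESPONDENT_COLUMNS = [
    "id", "country", "wave", "age_group", "gender_raw", "education",
    "region", "urbanisation", "driver_licence", "cannabis_12m",
    "cannabis_freq", "medical_only_rx", "duic_12m", "duic_30d",
    "duic_count_category", "duic_count_exact", "couse_category", "nq_minus",
    "alcohol_freq", "gambling_freq", "activity_freq", "response_seconds",
    "variability_index", "control_check_pass",
]


def _draw_categorical(rng: np.random.Generator, dist: dict, n: int) -> np.ndarray:
    levels = np.array(list(dist.keys()), dtype=object)
    probs = np.fromiter(dist.values(), dtype=float)
    return rng.choice(levels, size=n, p=probs / probs.sum())


def calibrated_bernoulli(rng: np.random.Generator, target: float,
                         offsets: np.ndarray) -> np.ndarray:
    """Bernoulli draws with heterogeneous log-odds offsets whose intercept is
    solved so the realized mean success probability equals ``target``.
    """
    n = len(offsets)
    if n == 0:
        return np.zeros(0, dtype=bool)
    if target <= 0.0:
        return np.zeros(n, dtype=bool)
    if target >= 1.0:
        return np.ones(n, dtype=bool)
    off = np.asarray(offsets, dtype=float)
    base = float(logit(target))
    lo, hi = base - off.max(), base - off.min()
    if hi - lo < 1e-12:
        a = base - off.mean()
    else:
        a = brentq(lambda x: expit(x + off).mean() - target, lo, hi,
                   xtol=1e-12)
    p = expit(a + off)
    return rng.random(n) < p


def _covariate_offsets(frame: pd.DataFrame, logor_map: dict) -> np.ndarray:
    off = np.zeros(len(frame))
    for col, levels in logor_map.items():
        if col == "driver_licence":
            vals = np.where(frame[col].to_numpy(dtype=bool),
                            levels.get("yes", 0.0), levels.get("no", 0.0))
            off += vals
        else:
            off += frame[col].map(levels).fillna(0.0).to_numpy(dtype=float)
    return off


def _generate_cell(cfg: GeneratorConfig, country: str, wave: str,
                   rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_cells[country][wave]
    d = pd.DataFrame({
        "country": country,
        "wave": wave,
        "age_group": _draw_categorical(rng, cfg.age_dist, n),
        "gender_raw": _draw_categorical(rng, cfg.gender_dist, n),
        "education": _draw_categorical(rng, cfg.education_dist, n),
        "region": _draw_categorical(rng, cfg.region_dist, n),
        "urbanisation": _draw_categorical(rng, cfg.urbanisation_dist, n),
        "driver_licence": rng.random(n) < cfg.driver_licence_prob,
        "alcohol_freq": _draw_categorical(rng, cfg.alcohol_dist, n),
        "gambling_freq": _draw_categorical(rng, cfg.gambling_dist, n),
        "activity_freq": _draw_categorical(rng, cfg.activity_dist, n),
        "nq_minus": rng.normal(cfg.nq_mean, cfg.nq_sd, size=n),
    }, index=pd.RangeIndex(n))

    # past-year use with per-cell calibrated intercept
    use_off = _covariate_offsets(d, cfg.use_covariate_logor)
    use = calibrated_bernoulli(rng, cfg.cell_prevalence(country, wave), use_off)
    d["cannabis_12m"] = use

    freq = np.full(n, "never", dtype=object)
    n_use = int(use.sum())
    if n_use:
        freq[use] = _draw_categorical(rng, cfg.freq_given_use, n_use)
    d["cannabis_freq"] = freq

    med = np.zeros(n, dtype=bool)
    med[use] = rng.random(n_use) < cfg.medical_only_rx_prob
    d["medical_only_rx"] = med

    # DUIC module: only users above the per-wave routing threshold are asked
    duic12 = np.full(n, np.nan)
    duic30 = np.full(n, np.nan)
    policy_log = (math.log(cfg.duic_country_or) * (country == "intervention")
                  + math.log(cfg.duic_time_or) * (wave == "t1")
                  + math.log(cfg.duic_did_or)
                  * (country == "intervention" and wave == "t1"))
    nq_std = (d["nq_minus"].to_numpy() - cfg.nq_mean) / cfg.nq_sd
    duic_off = _covariate_offsets(d, cfg.duic_covariate_logor) \
        + cfg.duic_nq_logor * nq_std
    for f in USE_FREQ_LEVELS:
        if not cfg.duic_asked(wave, f):
            continue
        mask = use & (freq == f)
        m = int(mask.sum())
        if m == 0:
            continue
        target = expit(float(logit(cfg.duic12_by_freq[f])) + policy_log)
        duic12[mask] = calibrated_bernoulli(rng, target, duic_off[mask])
    asked12 = duic12 == 1.0
    duic30[~np.isnan(duic12)] = 0.0
    duic30[asked12] = (rng.random(int(asked12.sum()))
                       < cfg.duic30_given_12).astype(float)
    d["duic_12m"] = duic12
    d["duic_30d"] = duic30

    # co-use and 30-day episode counts: t1 only
    couse = np.full(n, None, dtype=object)
    cat = np.full(n, None, dtype=object)
    exact = np.full(n, np.nan)
    if wave == "t1":
        rep = asked12
        m = int(rep.sum())
        if m:
            couse[rep] = _draw_categorical(rng, cfg.couse_dist, m)
        rep30 = duic30 == 1.0
        m30 = int(rep30.sum())
        if m30:
            cat[rep30] = _draw_categorical(rng, cfg.episode_cat_dist, m30)
            more = rep30 & (cat == "more")
            k = int(more.sum())
            if k:
                p_tail = 1.0 / (cfg.episode_tail_mean - 15.0)
                exact[more] = 15 + rng.geometric(min(p_tail, 1.0), size=k)
    d["couse_category"] = couse
    d["duic_count_category"] = cat
    d["duic_count_exact"] = exact

    # response-quality metadata; unflagged records stay above the cutoffs so
    # exclusions later match the planted truth exactly
    secs = rng.lognormal(math.log(cfg.response_median_seconds),
                         cfg.response_sigma, size=n)
    d["response_seconds"] = np.maximum(secs,
                                       cfg.speeder_threshold_seconds * 1.05)
    d["variability_index"] = rng.uniform(0.1, 1.0, size=n)
    d["control_check_pass"] = True
    return d


def generate_survey(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate the respondent table: a pure function of (config, seed)."""
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "generate")
    cells = [_generate_cell(config, c, w, rng)
             for c in COUNTRIES for w in WAVES]
    table = pd.concat(cells, ignore_index=True)
    table.insert(0, "id", [f"r{i:07d}" for i in range(len(table))])
    return table[RESPONDENT_COLUMNS]


def inject_artifacts(table: pd.DataFrame, config: GeneratorConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plant response-quality failures into a clean table.

    Returns the modified table and a truth ledger with one row per planted
    record: its positional row index, respondent id and artifact kind
    (``speeder``, ``straightliner``, ``control_fail``, ``duplicate``).
    Duplicate planting copies a t0 id onto a t1 row; both rows enter the
    ledger since the downstream filter drops duplicated ids from both waves.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "artifacts")
    out = table.reset_index(drop=True).copy()
    n = len(out)
    k_speed = math.floor(config.speeder_rate * n)
    k_straight = math.floor(config.straightliner_rate * n)
    k_ctrl = math.floor(config.control_fail_rate * n)
    k_dup = math.floor(config.duplicate_rate * n)
    if k_speed + k_straight + k_ctrl + 2 * k_dup > n:
        raise ConfigurationError(
            "quality-artifact rates imply more planted rows than the table has")

    perm = rng.permutation(n)
    pos = 0
    rows_speed = perm[pos:pos + k_speed]; pos += k_speed
    rows_straight = perm[pos:pos + k_straight]; pos += k_straight
    rows_ctrl = perm[pos:pos + k_ctrl]; pos += k_ctrl
    remaining = perm[pos:]
    wave = out["wave"].to_numpy()
    t0_pool = remaining[wave[remaining] == "t0"][:k_dup]
    t1_pool = remaining[wave[remaining] == "t1"][:k_dup]
    k_dup_eff = min(len(t0_pool), len(t1_pool))
    t0_pool, t1_pool = t0_pool[:k_dup_eff], t1_pool[:k_dup_eff]

    out.loc[rows_speed, "response_seconds"] = rng.uniform(
        10.0, config.speeder_threshold_seconds * 0.9, size=k_speed)
    out.loc[rows_straight, "variability_index"] = 0.0
    out.loc[rows_ctrl, "control_check_pass"] = False
    out.loc[t1_pool, "id"] = out.loc[t0_pool, "id"].to_numpy()

    entries = (
        [(int(r), "speeder") for r in rows_speed]
        + [(int(r), "straightliner") for r in rows_straight]
        + [(int(r), "control_fail") for r in rows_ctrl]
        + [(int(r), "duplicate") for r in np.concatenate([t0_pool, t1_pool])]
    )
    ledger = pd.DataFrame(entries, columns=["row", "artifact"])
    ledger["id"] = out.loc[ledger["row"], "id"].to_numpy() if len(ledger) \
        else pd.Series(dtype=object)
    return out, ledger.sort_values("row").reset_index(drop=True)


def write_survey(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_survey(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"id": str})
    for col in ("driver_licence", "cannabis_12m", "medical_only_rx",
                "control_check_pass"):
        table[col] = table[col].astype(bool)
    return table[RESPONDENT_COLUMNS]
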