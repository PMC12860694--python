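"""Exclusion filters and analytic-sample derivation.

Quality exclusions run in a fixed order -- cross-wave duplicate, speeder,
straightliner, control-check failure -- and each removed row is attributed
to the first rule it violates, so per-filter counts are invariant to row
order. Three analytic samples are then derived:

* Sample 1: all respondents (population prevalence of past-year use),
* Sample 2: at-least-monthly users without a medical-only prescription
  (12-month DUIC),
* Sample 3: past-year non-medical users at t1 reporting DUIC in the past
  30 days with complete episode-count and co-use items (episode burden).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (AGE_GROUPS, EDUCATION_LEVELS, FREQ_LEVELS,
                     GENDER_RAW_LEVELS)
from .errors import RecodeError, UndefinedRateError
from .rand import stage_rng

FILTER_ORDER = ("duplicate", "speeder", "straightliner", "control_check")


@dataclass
class QualityThresholds:
    """Exclusion cutoffs. The study's exact appendix values are not public;
    these defaults are assumptions aligned with the generator's planted
    artifacts (flagged records fall below them, clean records above)."""
    speeder_seconds: float = 180.0
    variability_min: float = 0.05
    exclude_control_fail: bool = True


@dataclass
class AnalyticSample:
    """A filtered respondent subset with its derivation audit trail."""
    sample_id: int
    rows: pd.DataFrame
    derivation_log: list = field(default_factory=list)

    def log_step(self, name: str, before: int, removed: int) -> None:
        self.derivation_log.append(
            {"filter": name, "rows_before": before, "removed": removed})

    def check(self) -> None:
        """Assert the log reconciles step by step down to len(rows)."""
        n = None
        for step in self.derivation_log:
            if n is not None and step["rows_before"] != n:
                raise AssertionError("derivation log does not reconcile")
            n = step["rows_before"] - step["removed"]
        if n is not None and n != len(self.rows):
            raise AssertionError("derivation log does not reconcile")

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.derivation_log)


def apply_quality_filters(table: pd.DataFrame,
                          thresholds: QualityThresholds | None = None
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop low-quality records; return (clean table, exclusion log).

    Duplicated ids (present in both waves) are removed from both waves.
    The log has one row per filter in fixed order with the row count before
    that filter and the count it removed.
    """
    thresholds = thresholds or QualityThresholds()
    df = table.reset_index(drop=True)
    if df.empty:
        log = pd.DataFrame({"filter": FILTER_ORDER,
                            "rows_before": 0, "removed": 0})
        return df.copy(), log

    wave_sets = df.groupby("id")["wave"].nunique()
    dup_ids = set(wave_sets.index[wave_sets > 1])
    masks = {
        "duplicate": df["id"].isin(dup_ids).to_numpy(),
        "speeder": (df["response_seconds"]
                    < thresholds.speeder_seconds).to_numpy(),
        "straightliner": (df["variability_index"]
                          < thresholds.variability_min).to_numpy(),
        "control_check": (~df["control_check_pass"].to_numpy(dtype=bool)
                          if thresholds.exclude_control_fail
                          else np.zeros(len(df), dtype=bool)),
    }

    taken = np.zeros(len(df), dtype=bool)
    records = []
    for name in FILTER_ORDER:
        hit = masks[name] & ~taken
        records.append({"filter": name,
                        "rows_before": int((~taken).sum()),
                        "removed": int(hit.sum())})
        taken |= hit
    clean = df.loc[~taken].reset_index(drop=True)
    return clean, pd.DataFrame(records)


def response_metrics(invited: int, accessed: int, completed: int) -> dict:
    """Access and completion rates as percentages rounded to one decimal."""
    if not invited >= accessed >= completed >= 0:
        raise ValueError("require invited >= accessed >= completed >= 0")
    if invited == 0 or accessed == 0:
        raise UndefinedRateError("zero denominator in response metrics")
    return {
        "access_rate_pct": round(100.0 * accessed / invited, 1),
        "completion_rate_pct": round(100.0 * completed / accessed, 1),
    }


def recode_covariates(table: pd.DataFrame, seed: int = 0,
                      p_male: float = 0.5,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Derive analysis covariates; deterministic given the seed.

    Nonbinary respondents are reassigned to male/female by a seeded coin
    (the analysis models gender as binary to avoid empty cells); the raw
    response is retained in ``gender_raw``.
    """
    if rng is None:
        rng = stage_rng(seed, "recode")
    checks = {"gender_raw": GENDER_RAW_LEVELS, "age_group": AGE_GROUPS,
              "education": EDUCATION_LEVELS, "cannabis_freq": FREQ_LEVELS}
    for col, levels in checks.items():
        bad = ~table[col].isin(levels)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RecodeError(
                f"unknown level {table[col].iloc[row]!r} in field {col!r} "
                f"at row {row}")
    out = table.copy()
    gender = out["gender_raw"].to_numpy(dtype=object).copy()
    nb = gender == "nonbinary"
    k = int(nb.sum())
    if k:
        gender[nb] = np.where(rng.random(k) < p_male, "male", "female")
    out["gender"] = gender
    return out


def _past_year_nonmedical(df: pd.DataFrame) -> pd.DataFrame:
    return df.loc[df["cannabis_12m"] & ~df["medical_only_rx"]]


def past_year_users(clean: pd.DataFrame, wave: str | None = "t1"
                    ) -> pd.DataFrame:
    """Past-year users excluding medical-only-with-prescription; the
    population-share denominator of the burden decomposition."""
    users = _past_year_nonmedical(clean)
    if wave is not None:
        users = users.loc[users["wave"] == wave]
    return users.reset_index(drop=True)


def derive_samples(clean: pd.DataFrame
                   ) -> tuple[AnalyticSample, AnalyticSample, AnalyticSample]:
    """Derive Samples 1-3 from a quality-filtered table."""
    s1 = AnalyticSample(1, clean.reset_index(drop=True))
    s1.log_step("all_respondents", len(clean), 0)

    n0 = len(clean)
    monthly_plus = clean.loc[
        clean["cannabis_freq"].isin(["monthly", "weekly", "daily"])]
    n1 = len(monthly_plus)
    s2_rows = monthly_plus.loc[~monthly_plus["medical_only_rx"]]
    s2 = AnalyticSample(2, s2_rows.reset_index(drop=True))
    s2.log_step("at_least_monthly_use", n0, n0 - n1)
    s2.log_step("medical_only_rx", n1, n1 - len(s2_rows))

    t1 = clean.loc[clean["wave"] == "t1"]
    users = _past_year_nonmedical(t1)
    duic30 = users.loc[users["duic_30d"] == 1.0]
    complete = duic30.loc[
        duic30["duic_count_category"].notna()
        & duic30["couse_category"].notna()
        & ((duic30["duic_count_category"] != "more")
           | duic30["duic_count_exact"].notna())]
    s3 = AnalyticSample(3, complete.reset_index(drop=True))
    s3.log_step("wave_t1", len(clean), len(clean) - len(t1))
    s3.log_step("past_year_nonmedical_use", len(t1), len(t1) - len(users))
    s3.log_step("duic_past_30d", len(users), len(users) - len(duic30))
    s3.log_step("complete_episode_items", len(duic30),
                len(duic30) - len(complete))
    for s in (s1, s2, s3):
        s.check()
    return s1, s2, s3
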