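"""Generator configuration: the design quantities of the two-country,
two-wave repeated cross-sectional survey.

The defaults encode the study conditions the pipeline emulates: Germany-style
intervention cells of n = 6670 (t0) and 9692 (t1), Austria-style control
cells of 2132 and 2102, past-year cannabis-use prevalences of 12.1%/9.4%/9.6%
with an injected difference-in-differences odds ratio of 1.194 on the
intervention country at wave t1 (the value implied by an observed 14.4%
post-legalisation prevalence), and a DUIC process whose country/time/DiD
odds multipliers reproduce prevalences of roughly 28.5/26.8% (intervention)
and 12.8/16.3% (control) among at-least-monthly users.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .errors import ConfigurationError

COUNTRIES = ("intervention", "control")
WAVES = ("t0", "t1")

#: Use-frequency levels among past-year users, ordered by intensity.
USE_FREQ_LEVELS = ("less_than_monthly", "monthly", "weekly", "daily")
FREQ_LEVELS = ("never",) + USE_FREQ_LEVELS

COUSE_LEVELS = ("cannabis_only", "occasionally", "mostly", "always")
EPISODE_CATEGORIES = ("once", "2-3", "4-9", "10-15", "more")

AGE_GROUPS = ("18-24", "25-34", "35-44", "45-64")
GENDER_RAW_LEVELS = ("male", "female", "nonbinary")
EDUCATION_LEVELS = ("low", "medium", "high")
URBANISATION_LEVELS = ("city", "town_suburb", "rural")
#: 5-level ordinal used for the behavioural covariates.
BEHAVIOUR_LEVELS = ("never", "less_than_monthly", "monthly", "weekly", "daily")

_SIMPLEX_TOL = 1e-9


def expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def intervention_t1_prevalence(p_treat_t0: float, p_ctrl_t0: float,
                               p_ctrl_t1: float, did_or: float) -> float:
    """Intervention wave-1 prevalence on the logit scale.

    logit(p) = logit(p_treat_t0) + [logit(p_ctrl_t1) - logit(p_ctrl_t0)]
               + log(did_or), so the saturated-model time-by-country
    interaction equals exactly the injected odds ratio. Degenerate anchors
    propagate: zero baseline or zero control-trend odds give 0, and a
    saturated bound gives 1.
    """
    if p_treat_t0 <= 0.0 or p_ctrl_t1 <= 0.0:
        return 0.0
    if p_treat_t0 >= 1.0 or p_ctrl_t0 >= 1.0:
        return 1.0
    if p_ctrl_t0 <= 0.0 or p_ctrl_t1 >= 1.0:
        return 1.0
    return expit(logit(p_treat_t0) + logit(p_ctrl_t1) - logit(p_ctrl_t0)
                 + math.log(did_or))


def did_or_from_prevalences(p_treat_t0: float, p_treat_t1: float,
                            p_ctrl_t0: float, p_ctrl_t1: float) -> float:
    """Ratio of odds ratios implied by four observed cell prevalences."""
    def odds(p: float) -> float:
        return p / (1.0 - p)
    return (odds(p_treat_t1) / odds(p_treat_t0)) / (odds(p_ctrl_t1) / odds(p_ctrl_t0))


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ConfigurationError(f"{name} must lie in [0, 1], got {p!r}")


def _check_simplex(name: str, dist: Mapping[str, float], levels: tuple) -> None:
    if set(dist) != set(levels):
        raise ConfigurationError(
            f"{name} must have exactly the levels {levels}, got {tuple(dist)}")
    for lev, p in dist.items():
        _check_prob(f"{name}[{lev}]", p)
    total = sum(dist.values())
    if abs(total - 1.0) > _SIMPLEX_TOL:
        raise ConfigurationError(f"{name} must sum to 1 (got {total!r})")


@dataclass
class GeneratorConfig:
    """All design quantities of the synthetic survey, with study-condition
    defaults. Every probability is on [0, 1]; every distribution is a simplex.
    """

    # -- design cells ------------------------------------------------------
    n_cells: dict = field(default_factory=lambda: {
        "intervention": {"t0": 6670, "t1": 9692},
        "control": {"t0": 2132, "t1": 2102},
    })

    # -- past-year cannabis use -------------------------------------------
    prev_treat_t0: float = 0.121
    prev_ctrl_t0: float = 0.094
    prev_ctrl_t1: float = 0.096
    #: Injected DiD odds ratio on the intervention country at t1.
    did_or: float = 1.194

    #: Use frequency among past-year users.
    freq_given_use: dict = field(default_factory=lambda: {
        "less_than_monthly": 0.413, "monthly": 0.203,
        "weekly": 0.184, "daily": 0.200,
    })

    #: Past-year users whose use is exclusively medical with a prescription.
    medical_only_rx_prob: float = 0.20

    # -- DUIC process ------------------------------------------------------
    #: Baseline (control country, t0) 12-month DUIC probability by frequency.
    duic12_by_freq: dict = field(default_factory=lambda: {
        "less_than_monthly": 0.04, "monthly": 0.09,
        "weekly": 0.13, "daily": 0.17,
    })
    #: Odds multipliers moving the per-person DUIC odds by design cell.
    duic_country_or: float = 2.72
    duic_time_or: float = 1.33
    duic_did_or: float = 0.69
    #: P(DUIC in past 30 days | DUIC in past 12 months).
    duic30_given_12: float = 0.45

    couse_dist: dict = field(default_factory=lambda: {
        "cannabis_only": 0.55, "occasionally": 0.27,
        "mostly": 0.12, "always": 0.06,
    })
    episode_cat_dist: dict = field(default_factory=lambda: {
        "once": 0.30, "2-3": 0.32, "4-9": 0.23, "10-15": 0.08, "more": 0.07,
    })
    #: Mean of the truncated-geometric law for exact counts above 15.
    episode_tail_mean: float = 25.0

    #: Which users are routed to the DUIC module, per wave. At t0 only
    #: at-least-monthly users were asked; at t1 all past-year users.
    duic_ask_threshold: dict = field(default_factory=lambda: {
        "t0": "monthly", "t1": "less_than_monthly",
    })

    # -- covariate margins -------------------------------------------------
    age_dist: dict = field(default_factory=lambda: {
        "18-24": 0.11, "25-34": 0.22, "35-44": 0.22, "45-64": 0.45,
    })
    gender_dist: dict = field(default_factory=lambda: {
        "male": 0.470, "female": 0.526, "nonbinary": 0.004,
    })
    education_dist: dict = field(default_factory=lambda: {
        "low": 0.05, "medium": 0.60, "high": 0.35,
    })
    region_dist: dict = field(default_factory=lambda: {
        "R1": 0.20, "R2": 0.18, "R3": 0.15, "R4": 0.13,
        "R5": 0.12, "R6": 0.10, "R7": 0.07, "R8": 0.05,
    })
    urbanisation_dist: dict = field(default_factory=lambda: {
        "city": 0.42, "town_suburb": 0.38, "rural": 0.20,
    })
    driver_licence_prob: float = 0.78

    alcohol_dist: dict = field(default_factory=lambda: {
        "never": 0.15, "less_than_monthly": 0.20, "monthly": 0.15,
        "weekly": 0.35, "daily": 0.15,
    })
    gambling_dist: dict = field(default_factory=lambda: {
        "never": 0.60, "less_than_monthly": 0.20, "monthly": 0.10,
        "weekly": 0.08, "daily": 0.02,
    })
    activity_dist: dict = field(default_factory=lambda: {
        "never": 0.05, "less_than_monthly": 0.10, "monthly": 0.15,
        "weekly": 0.45, "daily": 0.25,
    })

    #: Additive log-odds effects of covariates on past-year use. Intercepts
    #: are recalibrated per design cell so the marginal cell prevalence still
    #: hits its target exactly in expectation (see docs/methods.md).
    use_covariate_logor: dict = field(default_factory=lambda: {
        "age_group": {"18-24": 0.6, "25-34": 0.4, "35-44": 0.0, "45-64": -0.6},
        "gender_raw": {"male": 0.3, "female": 0.0, "nonbinary": 0.3},
    })
    #: Same mechanism for 12-month DUIC among users asked the module.
    duic_covariate_logor: dict = field(default_factory=lambda: {
        "gender_raw": {"male": 0.0, "female": -0.39, "nonbinary": 0.0},
        "driver_licence": {"yes": 0.74, "no": 0.0},
        "age_group": {"18-24": 0.0, "25-34": 0.13, "35-44": -0.27, "45-64": -0.80},
        "education": {"low": 0.0, "medium": 0.74, "high": 1.16},
    })

    # -- social desirability ----------------------------------------------
    nq_mean: float = 0.0
    nq_sd: float = 1.0
    #: Log-odds effect of a one-SD higher NQ- score on reporting DUIC.
    duic_nq_logor: float = -0.5

    # -- response-quality artifacts ---------------------------------------
    speeder_rate: float = 0.02
    straightliner_rate: float = 0.01
    control_fail_rate: float = 0.01
    duplicate_rate: float = 0.005
    #: Below this many seconds a record counts as an unrealistically fast
    #: completion (the study's exact appendix threshold is not public; this
    #: is a configurable assumption).
    speeder_threshold_seconds: float = 180.0
    response_median_seconds: float = 600.0
    response_sigma: float = 0.4

    seed: int = 0

    # ----------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for country in COUNTRIES:
            if country not in self.n_cells:
                raise ConfigurationError(f"n_cells missing country {country!r}")
            for wave in WAVES:
                n = self.n_cells[country].get(wave)
                if not isinstance(n, (int,)) or n <= 0:
                    raise ConfigurationError(
                        f"n_cells[{country}][{wave}] must be a positive "
                        f"integer, got {n!r}")
        for name in ("prev_treat_t0", "prev_ctrl_t0", "prev_ctrl_t1",
                     "medical_only_rx_prob", "duic30_given_12",
                     "driver_licence_prob", "speeder_rate",
                     "straightliner_rate", "control_fail_rate",
                     "duplicate_rate"):
            _check_prob(name, getattr(self, name))
        for name in ("did_or", "duic_country_or", "duic_time_or",
                     "duic_did_or"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        _check_simplex("freq_given_use", self.freq_given_use, USE_FREQ_LEVELS)
        for lev, p in self.duic12_by_freq.items():
            _check_prob(f"duic12_by_freq[{lev}]", p)
        _check_simplex("couse_dist", self.couse_dist, COUSE_LEVELS)
        _check_simplex("episode_cat_dist", self.episode_cat_dist,
                       EPISODE_CATEGORIES)
        if self.episode_tail_mean <= 15.0:
            raise ConfigurationError("episode_tail_mean must exceed 15")
        _check_simplex("age_dist", self.age_dist, AGE_GROUPS)
        _check_simplex("gender_dist", self.gender_dist, GENDER_RAW_LEVELS)
        _check_simplex("education_dist", self.education_dist, EDUCATION_LEVELS)
        _check_simplex("region_dist", self.region_dist,
                       tuple(self.region_dist))
        _check_simplex("urbanisation_dist", self.urbanisation_dist,
                       URBANISATION_LEVELS)
        for name in ("alcohol_dist", "gambling_dist", "activity_dist"):
            _check_simplex(name, getattr(self, name), BEHAVIOUR_LEVELS)
        for wave, thr in self.duic_ask_threshold.items():
            if thr not in USE_FREQ_LEVELS:
                raise ConfigurationError(
                    f"duic_ask_threshold[{wave}] must be one of "
                    f"{USE_FREQ_LEVELS}, got {thr!r}")
        if self.nq_sd <= 0:
            raise ConfigurationError("nq_sd must be > 0")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a nonnegative integer")

    # ----------------------------------------------------------------------
    @property
    def prev_treat_t1(self) -> float:
        """Intervention t1 prevalence implied by the anchors and did_or."""
        return intervention_t1_prevalence(
            self.prev_treat_t0, self.prev_ctrl_t0, self.prev_ctrl_t1,
            self.did_or)

    def cell_prevalence(self, country: str, wave: str) -> float:
        """Target past-year use prevalence for one design cell."""
        return {
            ("intervention", "t0"): self.prev_treat_t0,
            ("intervention", "t1"): self.prev_treat_t1,
            ("control", "t0"): self.prev_ctrl_t0,
            ("control", "t1"): self.prev_ctrl_t1,
        }[(country, wave)]

    def duic_asked(self, wave: str, freq: str) -> bool:
        """Whether a user of the given frequency is routed to the DUIC items."""
        if freq not in USE_FREQ_LEVELS:
            return False
        threshold = self.duic_ask_threshold[wave]
        return USE_FREQ_LEVELS.index(freq) >= USE_FREQ_LEVELS.index(threshold)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "GeneratorConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown generator config keys: {sorted(unknown)}")
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
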