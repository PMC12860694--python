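"""Monte-Carlo power and minimum detectable effect (MDE) for the
two-country x two-wave binary DiD design.

Outcomes are drawn per arm as binomials; the injected effect sits entirely
on the intervention wave-1 arm on the logit scale, so the saturated-model
time-by-country interaction equals the injected log odds ratio. For the
saturated model the Wald test has a closed form in the 2x2x2 counts
(log ratio of odds ratios over the square root of the summed reciprocal
cell counts), identical to the IRLS fit; simulation therefore scales to
thousands of replicates per bisection step. Datasets with an empty cell
cannot be fitted and are counted conservatively as non-rejections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import intervention_t1_prevalence
from .errors import BracketError, ConfigurationError
from .rand import stage_rng

#: Arm order everywhere in this module.
ARMS = ("treat_t0", "treat_t1", "ctrl_t0", "ctrl_t1")


@dataclass
class PowerDesign:
    """Arm sizes, anchor prevalences and simulation settings."""
    n_treat_t0: int
    n_treat_t1: int
    n_ctrl_t0: int
    n_ctrl_t1: int
    p_treat_t0: float
    p_ctrl_t0: float
    p_ctrl_t1: float
    alpha: float = 0.05
    target_power: float = 0.80
    nsim: int = 2000
    seed: int = 0
    or_bracket: tuple | None = None

    def __post_init__(self) -> None:
        for name in ("n_treat_t0", "n_treat_t1", "n_ctrl_t0", "n_ctrl_t1"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("p_treat_t0", "p_ctrl_t0", "p_ctrl_t1"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not self.alpha < self.target_power < 1.0:
            raise ConfigurationError("target_power must lie in (alpha, 1)")
        if self.nsim < 100:
            raise ConfigurationError("nsim must be >= 100")

    @property
    def ns(self) -> np.ndarray:
        return np.array([self.n_treat_t0, self.n_treat_t1,
                         self.n_ctrl_t0, self.n_ctrl_t1])

    def arm_probs(self, or_did: float) -> np.ndarray:
        """Success probabilities per arm for a given DiD odds ratio."""
        if or_did <= 0:
            raise ConfigurationError("or_did must be > 0")
        p11 = intervention_t1_prevalence(
            self.p_treat_t0, self.p_ctrl_t0, self.p_ctrl_t1, or_did)
        if not 0.0 < p11 < 1.0:
            raise ConfigurationError(
                f"implied intervention t1 prevalence {p11!r} outside (0, 1)")
        return np.array([self.p_treat_t0, p11,
                         self.p_ctrl_t0, self.p_ctrl_t1])


def sample1_power_design(**kw) -> PowerDesign:
    """Population cannabis-use design: printed arm sizes and prevalences."""
    kw.setdefault("nsim", 2000)
    return PowerDesign(n_treat_t0=6670, n_treat_t1=9692,
                       n_ctrl_t0=2132, n_ctrl_t1=2102,
                       p_treat_t0=0.121, p_ctrl_t0=0.094, p_ctrl_t1=0.096,
                       **kw)


def sample2_power_design(**kw) -> PowerDesign:
    """At-least-monthly-user DUIC design: printed sizes and prevalences."""
    kw.setdefault("nsim", 2000)
    return PowerDesign(n_treat_t0=393, n_treat_t1=589,
                       n_ctrl_t0=86, n_ctrl_t1=92,
                       p_treat_t0=0.285, p_ctrl_t0=0.128, p_ctrl_t1=0.163,
                       **kw)


def simulate_arm_counts(design: PowerDesign, or_did: float,
                        rng: np.random.Generator | None = None,
                        nsim: int = 1) -> np.ndarray:
    """Binomial success counts, shape (nsim, 4) in :data:`ARMS` order."""
    if rng is None:
        rng = stage_rng(design.seed, "power")
    probs = design.arm_probs(or_did)
    return rng.binomial(design.ns, probs, size=(nsim, 4))


def wald_interaction_stats(successes: np.ndarray, ns: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form saturated-model interaction z statistic per dataset.

    Returns (log_or, se, valid); datasets with an empty success or failure
    cell are flagged invalid.
    """
    s = np.atleast_2d(np.asarray(successes, dtype=float))
    f = np.asarray(ns, dtype=float) - s
    valid = (s > 0).all(axis=1) & (f > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lo = np.log(s) - np.log(f)
        log_or = (lo[:, 1] - lo[:, 0]) - (lo[:, 3] - lo[:, 2])
        se = np.sqrt((1.0 / s + 1.0 / f).sum(axis=1))
    return log_or, se, valid


@dataclass
class PowerEstimate:
    power: float
    mc_se: float
    n_invalid: int


def estimate_power(design: PowerDesign, or_did: float,
                   rng: np.random.Generator | None = None) -> PowerEstimate:
    """Fraction of simulated datasets whose two-sided Wald test of the
    interaction rejects at alpha; unfittable datasets count as
    non-rejections."""
    if rng is None:
        rng = stage_rng(design.seed, "power")
    s = simulate_arm_counts(design, or_did, rng=rng, nsim=design.nsim)
    log_or, se, valid = wald_interaction_stats(s, design.ns)
    zcrit = stats.norm.ppf(1.0 - design.alpha / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(valid, log_or / np.where(se > 0, se, np.inf), 0.0)
    reject = valid & (np.abs(z) > zcrit)
    p_hat = float(reject.mean())
    return PowerEstimate(
        power=p_hat,
        mc_se=float(math.sqrt(p_hat * (1.0 - p_hat) / design.nsim)),
        n_invalid=int((~valid).sum()))


def analytic_mde(design: PowerDesign) -> float:
    """Wald approximation to the MDE: exp((z_{1-a/2} + z_power) * SE) with
    SE^2 = sum over arms of 1/(n p (1-p)) at the null-anchored prevalences."""
    probs = design.arm_probs(1.0)
    var = float((1.0 / (design.ns * probs * (1.0 - probs))).sum())
    z = stats.norm.ppf(1.0 - design.alpha / 2.0) \
        + stats.norm.ppf(design.target_power)
    return float(math.exp(z * math.sqrt(var)))


@dataclass
class MDEResult:
    """Simulated MDE with its analytic cross-check and power curve."""
    mde_or: float
    analytic_or: float
    bracket: tuple
    curve: pd.DataFrame = field(repr=False)
    seed: int = 0


def minimum_detectable_effect(design: PowerDesign,
                              rng: np.random.Generator | None = None,
                              tol_log: float = 0.01) -> MDEResult:
    """Bisection on the log odds ratio for the smallest effect detected with
    the target power; each step re-estimates power with ``design.nsim``
    simulated datasets."""
    if rng is None:
        rng = stage_rng(design.seed, "power")
    analytic = analytic_mde(design)
    if design.or_bracket is not None:
        lo_or, hi_or = design.or_bracket
    else:
        lo_or, hi_or = max(1.0001, analytic / 1.8), analytic * 1.8
    records = []

    def power_at(or_did: float) -> PowerEstimate:
        est = estimate_power(design, or_did, rng=rng)
        records.append({"or": or_did, "power": est.power,
                        "mc_se": est.mc_se, "n_invalid": est.n_invalid})
        return est

    p_lo = power_at(lo_or)
    p_hi = power_at(hi_or)
    target = design.target_power
    if not (p_lo.power < target < p_hi.power):
        raise BracketError(
            f"power at bracket ({lo_or:.3f}, {hi_or:.3f}) = "
            f"({p_lo.power:.3f}, {p_hi.power:.3f}) does not straddle "
            f"{target}; widen or_bracket")
    lo, hi = math.log(lo_or), math.log(hi_or)
    while hi - lo > tol_log:
        mid = 0.5 * (lo + hi)
        est = power_at(math.exp(mid))
        if est.power < target:
            lo = mid
        else:
            hi = mid
    mde = math.exp(0.5 * (lo + hi))
    return MDEResult(mde_or=float(mde), analytic_or=analytic,
                     bracket=(float(lo_or), float(hi_or)),
                     curve=pd.DataFrame(records), seed=design.seed)
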