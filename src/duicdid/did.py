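"""Weighted logistic regression by IRLS and the difference-in-differences
interaction estimate, with screening, diagnostics, imputation, and bootstrap
prevalence intervals.

The DiD model is ``outcome ~ time + country + time:country [+ covariates]``
with treatment (dummy) coding; the time-by-country coefficient is the DiD
log odds ratio. Post-stratification weights enter the Bernoulli likelihood
as frequency-style case weights, so the reported Wald intervals are
model-based. Fits are deterministic; convergence is declared when the
largest coefficient update falls below tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

from .errors import AliasingError, SeparationError
from .rand import stage_rng

#: Reference levels exactly as the regression tables print them.
REFERENCE_LEVELS = {
    "wave": "t0", "country": "control", "gender": "male",
    "driver_licence": "no", "age_group": "18-24", "education": "low",
    "urbanisation": "city", "alcohol_freq": "never",
    "gambling_freq": "never", "activity_freq": "never",
    "cannabis_freq": "never",
}

TIME_TERM = "time[t1]"
COUNTRY_TERM = "country[intervention]"
DID_TERM = "time[t1]:country[intervention]"


@dataclass
class ModelSpec:
    """A DiD model specification: outcome, optional covariates, weighting."""
    outcome: str
    covariates: tuple = ()
    weighted: bool = False
    interaction: bool = True
    reference: dict = field(default_factory=lambda: dict(REFERENCE_LEVELS))


def build_design(df: pd.DataFrame, spec: ModelSpec
                 ) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Design matrix with treatment coding; returns (X, y, term->columns)."""
    y = df[spec.outcome].to_numpy(dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {spec.outcome!r} must be binary 0/1 "
                         "without missing values")
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    terms: dict[str, list[str]] = {}
    X[TIME_TERM] = (df["wave"] == "t1").astype(float)
    terms["time"] = [TIME_TERM]
    X[COUNTRY_TERM] = (df["country"] == "intervention").astype(float)
    terms["country"] = [COUNTRY_TERM]
    if spec.interaction:
        X[DID_TERM] = X[TIME_TERM] * X[COUNTRY_TERM]
        terms["time:country"] = [DID_TERM]
    for cov in spec.covariates:
        if ":" in cov:  # product term, e.g. nq_minus:time
            left, right = cov.split(":", 1)
            if right != "time":
                raise ValueError(f"unsupported product term {cov!r}")
            col = f"{left}:{TIME_TERM}"
            X[col] = df[left].to_numpy(dtype=float) * X[TIME_TERM]
            terms[cov] = [col]
            continue
        series = df[cov]
        if series.dtype == bool:
            series = series.map({True: "yes", False: "no"})
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            ref = spec.reference.get(cov)
            levels = list(pd.unique(series.dropna()))
            if ref is None or ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} for {cov!r} not found in data")
            cols = []
            for lev in [l for l in levels if l != ref]:
                col = f"{cov}[{lev}]"
                X[col] = (series == lev).astype(float)
                cols.append(col)
            terms[cov] = cols
        else:
            X[cov] = series.to_numpy(dtype=float)
            terms[cov] = [cov]
    return X, y, terms


class LogisticIRLS(BaseEstimator):
    """Binary logistic regression fitted by iteratively reweighted least
    squares (Newton-Raphson on the weighted Bernoulli log-likelihood).

    sklearn-style estimator: ``fit(X, y, sample_weight)`` sets ``coef_``
    (including the first column's intercept if present in X), ``cov_``
    (inverse observed information), ``loglik_``, ``null_loglik_``,
    ``converged_``, ``n_iter_`` and ``n_``. Raises
    :class:`~duicdid.errors.SeparationError` when coefficients diverge and
    :class:`~duicdid.errors.AliasingError` on rank-deficient designs.
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 50,
                 separation_bound: float = 15.0):
        self.tol = tol
        self.max_iter = max_iter
        self.separation_bound = separation_bound

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        w = np.ones(n) if sample_weight is None \
            else np.asarray(sample_weight, dtype=float)
        if (w <= 0).any():
            raise ValueError("sample_weight must be positive")
        # aliasing check via pivoted QR
        _, r, piv = linalg.qr(X * np.sqrt(w)[:, None], mode="economic",
                              pivoting=True)
        diag = np.abs(np.diag(r))
        rank = int((diag > diag[0] * 1e-10).sum()) if diag[0] > 0 else 0
        if rank < p:
            self._aliased_ = list(piv[rank:])
            raise AliasingError(
                f"design is rank deficient; aliased column indices "
                f"{sorted(self._aliased_)}")

        def loglik(b):
            m = expit(X @ b)
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = w * (y * np.log(m) + (1 - y) * np.log1p(-m))
            return float(np.where(np.isfinite(ll), ll, -1e30).sum())

        beta = np.zeros(p)
        ll_old = loglik(beta)
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = X @ beta
            mu = expit(eta)
            wls = w * mu * (1.0 - mu)
            info = X.T @ (X * wls[:, None])
            score = X.T @ (w * (y - mu))
            try:
                step = linalg.solve(info, score, assume_a="pos")
            except linalg.LinAlgError:
                raise SeparationError(
                    "information matrix singular during IRLS (separation?)")
            # step-halving keeps the likelihood monotone, so a transient
            # Newton overshoot is not mistaken for separation
            lam = 1.0
            for _ in range(30):
                cand = beta + lam * step
                ll_new = loglik(cand)
                if ll_new >= ll_old - 1e-12:
                    break
                lam *= 0.5
            beta = cand
            if np.abs(beta).max() > self.separation_bound:
                raise SeparationError(
                    "coefficients diverged beyond "
                    f"{self.separation_bound}; data are (quasi-)separated")
            if np.abs(lam * step).max() < self.tol:
                converged = True
                break
            ll_old = ll_new
        eta = X @ beta
        mu = expit(eta)
        info = X.T @ (X * (w * mu * (1 - mu))[:, None])
        self.coef_ = beta
        self.cov_ = linalg.inv(info)
        self.n_iter_ = it
        self.converged_ = converged
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = w * (y * np.log(mu) + (1 - y) * np.log1p(-mu))
        self.loglik_ = float(np.where(np.isfinite(ll), ll, 0.0).sum())
        pbar = float((w * y).sum() / w.sum())
        if 0.0 < pbar < 1.0:
            self.null_loglik_ = float(
                w.sum() * (pbar * np.log(pbar) + (1 - pbar) * np.log(1 - pbar)))
        else:
            self.null_loglik_ = 0.0
        self.n_ = float(w.sum())
        return self

    def predict_proba(self, X):
        p1 = expit(np.asarray(X, dtype=float) @ self.coef_)
        return np.column_stack([1.0 - p1, p1])


@dataclass
class FitResult:
    """A fitted logistic model with named coefficients."""
    params: pd.Series
    cov: pd.DataFrame
    loglik: float
    null_loglik: float
    n: float
    converged: bool
    n_iter: int
    terms: dict = field(default_factory=dict)
    #: correlation matrix of the non-intercept design columns (for GVIF)
    design_corr: pd.DataFrame | None = None

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())),
                         index=self.params.index)


def fit_logistic_irls(X: pd.DataFrame, y: np.ndarray,
                      weights: np.ndarray | None = None,
                      tol: float = 1e-10, max_iter: int = 50,
                      terms: dict | None = None) -> FitResult:
    """Fit a named design matrix; thin wrapper over :class:`LogisticIRLS`."""
    est = LogisticIRLS(tol=tol, max_iter=max_iter)
    try:
        est.fit(X.to_numpy(dtype=float), y, sample_weight=weights)
    except AliasingError:
        cols = [X.columns[i] for i in getattr(est, "_aliased_", [])]
        raise AliasingError(f"design is rank deficient; aliased columns {cols}")
    pred_cols = [c for c in X.columns if c != "Intercept"]
    corr = None
    if len(pred_cols) >= 2:
        corr = pd.DataFrame(
            np.corrcoef(X[pred_cols].to_numpy(dtype=float), rowvar=False),
            index=pred_cols, columns=pred_cols)
    return FitResult(
        params=pd.Series(est.coef_, index=X.columns),
        cov=pd.DataFrame(est.cov_, index=X.columns, columns=X.columns),
        loglik=est.loglik_, null_loglik=est.null_loglik_, n=est.n_,
        converged=est.converged_, n_iter=est.n_iter_, terms=terms or {},
        design_corr=corr)


def nagelkerke_r2(fit: FitResult) -> float:
    """Cox-Snell pseudo-R2 rescaled by its maximum attainable value."""
    n = fit.n
    cox_snell = 1.0 - np.exp((2.0 / n) * (fit.null_loglik - fit.loglik))
    max_cs = 1.0 - np.exp((2.0 / n) * fit.null_loglik)
    if max_cs <= 0.0:
        return 0.0
    return float(min(cox_snell / max_cs, 1.0))


def gvif(fit: FitResult) -> pd.DataFrame:
    """Generalised variance inflation factors (determinant ratio on the
    predictor correlation matrix), grouped by model term."""
    if len(fit.terms) < 2:
        raise ValueError("GVIF requires at least two model terms")
    if fit.design_corr is None:
        raise ValueError("fit carries no design correlation matrix")
    cols = list(fit.design_corr.columns)
    corr = fit.design_corr.to_numpy(dtype=float)
    if not np.isfinite(corr).all():
        raise AliasingError("degenerate (constant) predictor in GVIF")
    det_all = linalg.det(corr)
    if abs(det_all) < 1e-300:
        raise AliasingError("singular predictor correlation matrix")
    records = []
    for term, tcols in fit.terms.items():
        sel = np.array([cols.index(c) for c in tcols])
        rest = np.array([i for i in range(len(cols)) if i not in sel])
        det_sel = linalg.det(corr[np.ix_(sel, sel)])
        det_rest = linalg.det(corr[np.ix_(rest, rest)]) if len(rest) else 1.0
        g = det_sel * det_rest / det_all
        df = len(sel)
        records.append({"term": term, "gvif": float(g), "df": df,
                        "gvif_adj": float(g ** (1.0 / (2.0 * df)))})
    return pd.DataFrame(records).set_index("term")


@dataclass
class DiDResult:
    """The DiD interaction odds ratio with its full model context."""
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    or_table: pd.DataFrame
    nagelkerke: float
    model_chisq: float
    model_df: int
    gvif_table: pd.DataFrame | None
    fit: FitResult


def did_effect(df: pd.DataFrame, spec: ModelSpec,
               weights: np.ndarray | None = None,
               alpha: float = 0.05) -> DiDResult:
    """Estimate the time-by-country DiD odds ratio with Wald CI and p."""
    if not spec.interaction:
        raise ValueError("DiD spec must include the time:country interaction")
    data = df.reset_index(drop=True)
    X, y, terms = build_design(data, spec)
    w = None
    if spec.weighted:
        if weights is None:
            if "weight" not in data.columns:
                raise ValueError("weighted spec requires weights")
            w = data["weight"].to_numpy(dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
    fit = fit_logistic_irls(X, y, weights=w, terms=terms)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    beta, se = fit.params, fit.bse
    table = pd.DataFrame({
        "coef": beta, "se": se, "odds_ratio": np.exp(beta),
        "ci_low": np.exp(beta - z * se), "ci_high": np.exp(beta + z * se),
        "p_value": 2.0 * stats.norm.sf(np.abs(beta / se)),
    })
    b, s = float(beta[DID_TERM]), float(se[DID_TERM])
    gtab = None
    if len(terms) >= 2:
        try:
            gtab = gvif(fit)
        except AliasingError:
            gtab = None
    return DiDResult(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - z * s)), ci_high=float(np.exp(b + z * s)),
        p_value=float(2.0 * stats.norm.sf(abs(b / s))),
        or_table=table, nagelkerke=nagelkerke_r2(fit),
        model_chisq=float(2.0 * (fit.loglik - fit.null_loglik)),
        model_df=int(len(fit.params) - 1), gvif_table=gtab, fit=fit)


def screen_covariates(df: pd.DataFrame, outcome: str, candidates,
                      alpha: float = 0.10, wave: str = "t0"
                      ) -> tuple[list, pd.DataFrame]:
    """Chi-square screening of candidate covariates against the outcome in
    the pooled baseline wave; candidates with p < alpha are retained."""
    base = df.loc[df["wave"] == wave] if wave is not None else df
    records = []
    selected = []
    for cand in candidates:
        sub = base[[outcome, cand]].dropna()
        if sub[cand].nunique() < 2 or sub[outcome].nunique() < 2:
            warnings.warn(f"covariate {cand!r} has a single level; skipped")
            records.append({"covariate": cand, "chisq": np.nan,
                            "df": 0, "p_value": np.nan, "selected": False})
            continue
        table = pd.crosstab(sub[outcome], sub[cand])
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        keep = bool(p < alpha)
        records.append({"covariate": cand, "chisq": float(chi2),
                        "df": int(dof), "p_value": float(p),
                        "selected": keep})
        if keep:
            selected.append(cand)
    return selected, pd.DataFrame(records)


def impute_subgroup(df: pd.DataFrame, t1_rate: float,
                    mode: str = "deterministic", seed: int = 0,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Impute 12-month DUIC for less-than-monthly users at t0 (who were not
    routed to the DUIC module) from the corresponding t1 rate.

    Deterministic mode assigns the expected number of cases by
    largest-remainder rounding; stochastic mode draws Bernoulli(rate).
    """
    if not 0.0 <= t1_rate <= 1.0:
        raise ValueError("t1_rate must lie in [0, 1]")
    out = df.reset_index(drop=True).copy()
    mask = ((out["wave"] == "t0")
            & (out["cannabis_freq"] == "less_than_monthly")
            & out["duic_12m"].isna())
    m = int(mask.sum())
    if m == 0:
        warnings.warn("imputation subgroup is empty; no-op")
        out.attrs["imputation_mode"] = mode
        return out
    if mode == "deterministic":
        k = int(np.floor(m * t1_rate + 0.5))
        order = out.loc[mask].sort_values("id").index.to_numpy()
        values = pd.Series(0.0, index=out.index[mask])
        values.loc[order[:k]] = 1.0
        out.loc[mask, "duic_12m"] = values
    elif mode == "stochastic":
        if rng is None:
            rng = stage_rng(seed, "impute")
        out.loc[mask, "duic_12m"] = (rng.random(m) < t1_rate).astype(float)
    else:
        raise ValueError("mode must be 'deterministic' or 'stochastic'")
    out.attrs["imputation_mode"] = mode
    return out


def bootstrap_prevalence(df: pd.DataFrame, outcome: str,
                         weights: np.ndarray | None = None, B: int = 2000,
                         seed: int = 0,
                         strata: tuple = ("country", "wave"),
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Percentile bootstrap 95% CI for the (weighted) prevalence, resampling
    respondents with replacement within each stratum."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if df.empty:
        raise ValueError("empty sample")
    if rng is None:
        rng = stage_rng(seed, "bootstrap")
    data = df.reset_index(drop=True)
    w_all = np.ones(len(data)) if weights is None \
        else np.asarray(weights, dtype=float)
    records = []
    for key, group in data.groupby(list(strata)):
        y = group[outcome].to_numpy(dtype=float)
        w = w_all[group.index.to_numpy()]
        n = len(y)
        if n == 0:
            raise ValueError(f"empty stratum {key!r}")
        point = float((w * y).sum() / w.sum())
        est = np.empty(B)
        chunk = max(1, min(B, 20_000_000 // max(n, 1)))
        done = 0
        while done < B:
            b = min(chunk, B - done)
            idx = rng.integers(0, n, size=(b, n))
            wy = (w * y)[idx].sum(axis=1)
            ws = w[idx].sum(axis=1)
            est[done:done + b] = wy / ws
            done += b
        lo, hi = np.percentile(est, [2.5, 97.5])
        rec = dict(zip(strata, key if isinstance(key, tuple) else (key,)))
        rec.update({"n": n, "prevalence": point,
                    "ci_low": float(lo), "ci_high": float(hi)})
        records.append(rec)
    return pd.DataFrame(records)
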