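import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from duicdid import GeneratorConfig, apply_quality_filters, derive_samples
from duicdid import generate_survey, inject_artifacts, recode_covariates

settings.register_profile(
    "suite", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


SMALL_CELLS = {"intervention": {"t0": 900, "t1": 1300},
               "control": {"t0": 450, "t1": 450}}


@pytest.fixture(scope="session")
def small_cfg() -> GeneratorConfig:
    return GeneratorConfig(n_cells=SMALL_CELLS, seed=11)


@pytest.fixture(scope="session")
def small_table(small_cfg):
    return generate_survey(small_cfg)


@pytest.fixture(scope="session")
def planted(small_cfg, small_table):
    return inject_artifacts(small_table, small_cfg)


@pytest.fixture(scope="session")
def clean_samples(planted):
    table, _ = planted
    clean, _ = apply_quality_filters(table)
    clean = recode_covariates(clean, seed=11)
    return (clean,) + derive_samples(clean)


def did_frame_from_counts(successes, ns) -> tuple[pd.DataFrame, np.ndarray]:
    """Aggregated 2x2x2 dataset: 8 rows (cell x outcome) with case weights.

    Arm order (treat_t0, treat_t1, ctrl_t0, ctrl_t1); all success and
    failure cells must be positive.
    """
    arms = [("intervention", "t0"), ("intervention", "t1"),
            ("control", "t0"), ("control", "t1")]
    rows, weights = [], []
    for (country, wave), s, n in zip(arms, successes, ns):
        rows.append({"country": country, "wave": wave, "y": 1.0})
        weights.append(float(s))
        rows.append({"country": country, "wave": wave, "y": 0.0})
        weights.append(float(n - s))
    return pd.DataFrame(rows), np.array(weights)


def saturated_oracle(successes, ns) -> dict:
    """Closed-form coefficients of the saturated time-by-country logistic
    model, straight from the 2x2x2 counts."""
    s = np.asarray(successes, dtype=float)
    f = np.asarray(ns, dtype=float) - s
    lo = np.log(s) - np.log(f)  # per-arm empirical logits
    return {
        "Intercept": lo[2],
        "time[t1]": lo[3] - lo[2],
        "country[intervention]": lo[0] - lo[2],
        "time[t1]:country[intervention]": (lo[1] - lo[0]) - (lo[3] - lo[2]),
        "se_interaction": float(np.sqrt((1.0 / s + 1.0 / f).sum())),
    }


def make_sample3(freqs, categories, exacts, couses) -> pd.DataFrame:
    """Hand-built Sample-3-like table for burden tests."""
    n = len(freqs)
    return pd.DataFrame({
        "id": [f"x{i}" for i in range(n)],
        "country": "intervention", "wave": "t1",
        "cannabis_freq": freqs,
        "duic_count_category": categories,
        "duic_count_exact": [e if e is not None else np.nan for e in exacts],
        "couse_category": couses,
    })
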