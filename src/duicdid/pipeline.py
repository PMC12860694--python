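"""End-to-end orchestration: generate -> preprocess -> weight -> DiD ->
power -> burden, from a single config with one global seed.

Each stage draws from its own Philox substream keyed by a stable stage name,
so disabling a stage never perturbs the randomness of another. All outputs
carry the config hash and seed; two runs with identical (config, seed)
produce byte-identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import burden as burden_mod
from . import did as did_mod
from . import power as power_mod
from . import preprocess as pre
from . import synth, weighting
from .config import GeneratorConfig
from .errors import ConfigurationError
from .rand import stage_rng

log = logging.getLogger("duicdid")

STAGE_ORDER = ("generate", "preprocess", "weight", "did", "power", "burden")

#: Candidate covariates screened for each hypothesis, per design.
H1_SOCIO = ("gender", "age_group", "education", "urbanisation")
H1_BEHAV = ("alcohol_freq", "gambling_freq", "activity_freq")
H2_SOCIO = ("gender", "age_group", "education", "driver_licence",
            "urbanisation")
H2_BEHAV = ("alcohol_freq", "gambling_freq")


@dataclass
class RunConfig:
    """Run configuration; everything optional except the seed."""
    seed: int = 0
    outdir: str = "out"
    stages: tuple = STAGE_ORDER
    generator: dict = field(default_factory=dict)
    microdata_csv: str | None = None
    margins_csv: str | None = None
    weight_mode: str = "raking"
    power_nsim: int = 1000
    bootstrap_B: int = 500
    schemes: tuple = ((1.00, 0.75, 0.25, 0.00),)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGE_ORDER]
        if bad:
            raise ConfigurationError(f"unknown stages {bad}; valid: "
                                     f"{STAGE_ORDER}")
        if self.microdata_csv is None and "generate" not in self.stages \
                and self.stages:
            raise ConfigurationError(
                "config key 'microdata_csv' is required when the "
                "'generate' stage is disabled")
        if not self.schemes:
            raise ConfigurationError("config key 'schemes' must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "schemes" in data:
            data["schemes"] = tuple(tuple(s) for s in data["schemes"])
        return cls(**data)

    def resolved_generator(self) -> GeneratorConfig:
        g = dict(self.generator)
        g.setdefault("seed", self.seed)
        return GeneratorConfig.from_dict(g)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _did_summary(res: did_mod.DiDResult) -> dict:
    return {
        "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
        "ci_high": res.ci_high, "p_value": res.p_value,
        "nagelkerke_r2": res.nagelkerke, "model_chisq": res.model_chisq,
        "model_df": res.model_df,
        "converged": res.fit.converged, "n": res.fit.n,
    }


def run_pipeline(config: "RunConfig | str | Path") -> dict:
    """Execute the enabled stages in fixed order; returns the summary dict
    (also written to ``<outdir>/summary.json``)."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gcfg = config.resolved_generator()
    stages = [s for s in STAGE_ORDER if s in config.stages]
    summary: dict = {"seed": config.seed,
                     "config_hash": config.config_hash(),
                     "stages": stages}

    table = None
    if "generate" in stages:
        log.info("generating survey microdata")
        table = synth.generate_survey(gcfg)
        table, ledger = synth.inject_artifacts(table, gcfg)
        synth.write_survey(table, outdir / "survey.csv")
        ledger.to_csv(outdir / "truth_ledger.csv", index=False)
        summary["generate"] = {"n_rows": len(table),
                               "n_planted": len(ledger)}
    elif config.microdata_csv:
        table = synth.read_survey(config.microdata_csv)

    clean = s1 = s2 = s3 = None
    if "preprocess" in stages:
        if table is None:
            raise ConfigurationError(
                "preprocess requires generated or loaded microdata "
                "(config key 'microdata_csv')")
        log.info("applying quality filters and deriving samples")
        clean, exc_log = pre.apply_quality_filters(table)
        clean = pre.recode_covariates(clean, seed=config.seed)
        s1, s2, s3 = pre.derive_samples(clean)
        clean.to_csv(outdir / "clean.csv", index=False)
        exc_log.to_csv(outdir / "exclusion_log.csv", index=False)
        for s in (s1, s2, s3):
            s.log_frame().to_csv(
                outdir / f"sample{s.sample_id}_derivation.csv", index=False)
        summary["preprocess"] = {
            "n_clean": len(clean),
            "exclusions": exc_log.set_index("filter")["removed"].to_dict(),
            "sample_sizes": {f"sample{s.sample_id}": len(s.rows)
                             for s in (s1, s2, s3)},
        }

    design = None
    if "weight" in stages:
        if clean is None:
            raise ConfigurationError("weight stage requires preprocess")
        if config.margins_csv:
            margins = weighting.PopulationMargins.from_csv(config.margins_csv)
        elif config.microdata_csv and not config.generator:
            raise ConfigurationError(
                "config key 'margins_csv' is required when weighting "
                "external microdata")
        else:
            margins = weighting.margins_from_config(gcfg)
        log.info("post-stratifying (%s mode)", config.weight_mode)
        design = weighting.poststratify(clean, margins,
                                        mode=config.weight_mode)
        design.rows.to_csv(outdir / "weighted.csv", index=False)
        diag = {k: v for k, v in design.diagnostics.items()
                if k != "per_group"}
        diag["per_group"] = {f"{c}:{w}": d for (c, w), d
                             in design.diagnostics["per_group"].items()}
        summary["weight"] = diag

    if "did" in stages:
        if s1 is None:
            raise ConfigurationError("did stage requires preprocess")
        log.info("fitting DiD models")
        rows1 = design.rows if design is not None else s1.rows
        h1_selected, h1_screen = did_mod.screen_covariates(
            rows1, "cannabis_12m", list(H1_SOCIO) + list(H1_BEHAV))
        h1_screen.to_csv(outdir / "h1_screening.csv", index=False)
        def _try_did(rows, spec):
            try:
                return did_mod.did_effect(rows, spec)
            except (did_mod.SeparationError, did_mod.AliasingError) as err:
                log.warning("model failed: %s", err)
                return err

        did_out = {}
        spec_w = did_mod.ModelSpec("cannabis_12m",
                                   weighted=design is not None)
        did_out["h1_weighted" if design is not None else "h1_unweighted"] = \
            _try_did(rows1, spec_w)
        if design is not None:
            did_out["h1_unweighted"] = _try_did(
                rows1, did_mod.ModelSpec("cannabis_12m"))
        socio_sel = tuple(c for c in H1_SOCIO if c in h1_selected)
        did_out["h1_adjusted"] = _try_did(
            rows1, did_mod.ModelSpec("cannabis_12m", covariates=socio_sel))

        s2_rows = s2.rows.loc[s2.rows["duic_12m"].notna()]
        h2_selected, h2_screen = did_mod.screen_covariates(
            s2_rows, "duic_12m", list(H2_SOCIO) + list(H2_BEHAV))
        h2_screen.to_csv(outdir / "h2_screening.csv", index=False)
        did_out["h2_unadjusted"] = _try_did(
            s2_rows, did_mod.ModelSpec("duic_12m"))
        h2_cov = tuple(c for c in H2_SOCIO if c in h2_selected)
        did_out["h2_adjusted"] = _try_did(
            s2_rows, did_mod.ModelSpec("duic_12m", covariates=h2_cov))

        summary["did"] = {}
        for name, res in did_out.items():
            if isinstance(res, Exception):
                summary["did"][name] = {"error": str(res)}
                continue
            res.or_table.to_csv(outdir / f"{name}_coefficients.csv")
            if res.gvif_table is not None:
                res.gvif_table.to_csv(outdir / f"{name}_gvif.csv")
            summary["did"][name] = _did_summary(res)
        summary["did"]["h1_screening"] = h1_selected
        summary["did"]["h2_screening"] = h2_selected

        w1 = design.weights[rows1.index.to_numpy()] \
            if design is not None else None
        prev1 = did_mod.bootstrap_prevalence(
            rows1, "cannabis_12m", weights=w1, B=config.bootstrap_B,
            seed=config.seed)
        prev2 = did_mod.bootstrap_prevalence(
            s2_rows, "duic_12m", B=config.bootstrap_B, seed=config.seed)
        prev1.to_csv(outdir / "prevalence_sample1.csv", index=False)
        prev2.to_csv(outdir / "prevalence_sample2.csv", index=False)
        summary["prevalence"] = {
            "sample1": prev1.to_dict("records"),
            "sample2": prev2.to_dict("records"),
        }

    if "power" in stages:
        if s1 is None:
            raise ConfigurationError("power stage requires preprocess")
        log.info("estimating minimum detectable effects")
        summary["power"] = {}
        for name, sample, outcome in (("sample1", s1.rows, "cannabis_12m"),
                                      ("sample2", s2.rows, "duic_12m")):
            rows = sample.loc[sample[outcome].notna()]
            cells = {}
            for (c, w), g in rows.groupby(["country", "wave"]):
                cells[(c, w)] = (len(g),
                                 float(g[outcome].astype(float).mean()))
            try:
                pdes = power_mod.PowerDesign(
                    n_treat_t0=cells[("intervention", "t0")][0],
                    n_treat_t1=cells[("intervention", "t1")][0],
                    n_ctrl_t0=cells[("control", "t0")][0],
                    n_ctrl_t1=cells[("control", "t1")][0],
                    p_treat_t0=cells[("intervention", "t0")][1],
                    p_ctrl_t0=cells[("control", "t0")][1],
                    p_ctrl_t1=cells[("control", "t1")][1],
                    nsim=config.power_nsim, seed=config.seed)
                mde = power_mod.minimum_detectable_effect(pdes)
            except (ConfigurationError, KeyError,
                    power_mod.BracketError) as err:
                summary["power"][name] = {"error": str(err)}
                continue
            mde.curve.to_csv(outdir / f"power_curve_{name}.csv", index=False)
            summary["power"][name] = {
                "mde_or": mde.mde_or, "analytic_or": mde.analytic_or,
                "bracket": list(mde.bracket), "nsim": config.power_nsim,
            }

    if "burden" in stages:
        if s3 is None:
            raise ConfigurationError("burden stage requires preprocess")
        log.info("decomposing DUIC episode burden")
        users = pre.past_year_users(clean, wave="t1")
        schemes = [burden_mod.AllocationScheme(*s) for s in config.schemes]
        bt = burden_mod.bootstrap_burden(
            s3.rows, schemes[0], B=config.bootstrap_B, seed=config.seed,
            users=users)
        bt.table.to_csv(outdir / "burden.csv")
        summary["burden"] = {
            "totals": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in bt.totals.items()},
            "table": bt.table.round(6).reset_index().to_dict("records"),
        }
        if len(schemes) > 1:
            sens = burden_mod.sensitivity_schemes(s3.rows, schemes,
                                                  users=users)
            summary["burden"]["sensitivity_rank_orders"] = [
                {"scheme": list(dataclasses.astuple(e["scheme"])),
                 "plus_rank_order": e["plus_rank_order"]} for e in sens]

    summary = _round_floats(summary)
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


# ---------------------------------------------------------------------------
FIXTURE_PROFILES = ("null-effect", "paper-scale", "burden-demo")


def make_fixture(profile: str, seed: int = 0, outdir=None
                 ) -> tuple[pd.DataFrame, pd.DataFrame, GeneratorConfig]:
    """Small seeded datasets with truth ledgers for tests and demos."""
    if profile == "null-effect":
        cfg = GeneratorConfig(
            n_cells={"intervention": {"t0": 600, "t1": 600},
                     "control": {"t0": 300, "t1": 300}},
            did_or=1.0, seed=seed)
    elif profile == "paper-scale":
        cfg = GeneratorConfig(
            speeder_rate=0.0, straightliner_rate=0.0,
            control_fail_rate=0.0, duplicate_rate=0.0, seed=seed)
    elif profile == "burden-demo":
        cfg = GeneratorConfig(
            n_cells={"intervention": {"t0": 300, "t1": 3000},
                     "control": {"t0": 150, "t1": 800}},
            duic12_by_freq={"less_than_monthly": 0.15, "monthly": 0.30,
                            "weekly": 0.40, "daily": 0.50},
            duic30_given_12=0.7, medical_only_rx_prob=0.1,
            speeder_rate=0.0, straightliner_rate=0.0,
            control_fail_rate=0.0, duplicate_rate=0.0, seed=seed)
    else:
        raise ConfigurationError(
            f"unknown profile {profile!r}; choose from {FIXTURE_PROFILES}")
    rng = stage_rng(seed, "fixture")
    table = synth.generate_survey(cfg, rng=rng)
    table, ledger = synth.inject_artifacts(table, cfg, rng=rng)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        synth.write_survey(table, outdir / f"{profile}.csv")
        ledger.to_csv(outdir / f"{profile}_truth.csv", index=False)
        cfg.to_yaml(outdir / f"{profile}_config.yaml")
    return table, ledger, cfg
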