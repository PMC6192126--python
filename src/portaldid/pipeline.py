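"""End-to-end pipeline: simulate -> prepare -> match -> fit -> omega -> render.

``analyze_cohort`` is the library entry point used by the analysis scripts,
the sensitivity scenarios and the CLI; ``run_pipeline`` adds structured
configuration, CSV artifacts and a run manifest with file digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigError, SimulationConfig
from .matching import balance_table, estimate_propensity, match_nearest
from .omega import fit_paired_outcome_models, omega_test
from .panel import build_panel, design_matrix, fit_overdispersed_poisson, lag_effect_table
from .prep import (
    DEMOGRAPHIC_COLUMNS,
    STATUS_USER,
    apply_inclusion_criteria,
    baseline_table,
    validate_observations,
)
from .report import plot_rr_trajectories, render_effect_report
from .simulate import generate_cohort, write_cohort

log = logging.getLogger(__name__)

REQUIRED_CONFIG_FIELDS = ("seed", "n_patients")


def analyze_cohort(
    patients: pd.DataFrame,
    quarters: pd.DataFrame,
    stratify_by_new_visit: bool = True,
    caliper: float | None = None,
    n_boot: int = 500,
    omega_method: str = "bootstrap",
    omega_seed: int = 0,
    n_quarters: int = 12,
    keep_window_start_users: bool = False,
    events: tuple[str, ...] = ("no_show", "cancelled"),
) -> dict:
    """Run prepare -> match -> DID fit -> omega tests; return the result bundle.

    The bundle maps stage names to their tables/fits: ``included``,
    ``exclusions``, ``baseline``, ``matched``, ``balance``, ``panel``,
    ``fit_arrived``, ``table_arrived``, and per-event omega tables
    (``omega_no_show``, ``omega_cancelled``).
    """
    included, exclusions = apply_inclusion_criteria(
        patients, allow_window_start_adoption=keep_window_start_users
    )
    baseline = baseline_table(included, quarters)

    covs = (
        included.set_index("patient_id")[list(DEMOGRAPHIC_COLUMNS)]
        .join(baseline.set_index("patient_id")[["apn_cat", "arrived_cat", "noshow_cat", "cancel_cat"]])
    )
    user_flag = included.set_index("patient_id")["status"].eq(STATUS_USER)
    propensity = estimate_propensity(covs, user_flag)

    ids = included["patient_id"].to_numpy()
    users = ids[user_flag.loc[ids].to_numpy()]
    nonusers = ids[~user_flag.loc[ids].to_numpy()]
    strata = (
        included.set_index("patient_id")["new_index"] if stratify_by_new_visit else None
    )
    matched = match_nearest(propensity.scores, users, nonusers, strata=strata, caliper=caliper)
    matched.propensity = propensity
    balance = balance_table(covs, user_flag, matched)

    analysis_ids = matched.matched_ids
    cohort = included[included["patient_id"].isin(analysis_ids)]
    panel = build_panel(cohort, quarters, n_quarters=n_quarters)
    X = design_matrix(panel, n_quarters=n_quarters)

    fit_arrived = fit_overdispersed_poisson(panel, "arrived", n_quarters, X=X)
    table_arrived = lag_effect_table(fit_arrived, "treatment")

    bundle = {
        "included": included,
        "exclusions": exclusions,
        "baseline": baseline,
        "matched": matched,
        "balance": balance,
        "panel": panel,
        "fit_arrived": fit_arrived,
        "table_arrived": table_arrived,
    }
    for i, event in enumerate(events):
        fit_y, fit_z = fit_paired_outcome_models(panel, event, n_quarters, X=X)
        bundle[f"omega_{event}"] = omega_test(
            fit_y,
            fit_z,
            panel,
            pairs=matched.pairs,
            n_boot=n_boot,
            seed=omega_seed + i,
            method=omega_method,
            n_quarters=n_quarters,
        )
        bundle[f"fit_{event}"] = fit_y
    return bundle


def load_config(config: str | Path | dict) -> dict:
    """Load and validate the structured pipeline configuration."""
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("configuration must be a mapping")
    for name in REQUIRED_CONFIG_FIELDS:
        if name not in config:
            raise ConfigError(f"configuration missing required field {name!r}")
    return config


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _fit_to_dict(fit) -> dict:
    return {
        "params": fit.params.to_dict(),
        "cov": fit.cov.to_dict(),
        "dispersion": fit.scale,
        "n_obs": fit.n_obs,
        "df_resid": fit.df_resid,
        "converged": fit.converged,
        "dropped": fit.dropped,
    }


def run_pipeline(
    config: str | Path | dict, outdir: str | Path | None = None, seed: int | None = None
) -> dict:
    """Execute the full pipeline from a config file; write artifacts + manifest."""
    cfg = load_config(config)
    if seed is not None:
        cfg = {**cfg, "seed": seed}
    outdir = Path(outdir or cfg.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)

    gen_overrides = dict(cfg.get("generator", {}))
    sim_config = SimulationConfig(
        n_patients=int(cfg["n_patients"]), seed=int(cfg["seed"]), **gen_overrides
    )
    log.info("simulate: n=%d seed=%d", sim_config.n_patients, sim_config.seed)
    patients, quarters = generate_cohort(sim_config)
    validate_observations(quarters)
    write_cohort(patients, quarters, outdir)

    m_cfg = cfg.get("matching", {})
    o_cfg = cfg.get("omega", {})
    bundle = analyze_cohort(
        patients,
        quarters,
        stratify_by_new_visit=bool(m_cfg.get("stratify_by_new_visit", True)),
        caliper=m_cfg.get("caliper"),
        n_boot=int(o_cfg.get("n_boot", 500)),
        omega_method=o_cfg.get("method", "bootstrap"),
        omega_seed=int(cfg["seed"]),
        n_quarters=sim_config.n_quarters,
    )

    files: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False, float_format="%.10g")
        files[name] = path

    emit("baseline.csv", bundle["baseline"])
    emit("exclusions.csv", bundle["exclusions"])
    emit("pairs.csv", bundle["matched"].pairs)
    emit("balance.csv", bundle["balance"])
    emit("panel.csv", bundle["panel"])
    arrived = bundle["table_arrived"].rename(columns={"lag": "quarter_post_adoption"})
    emit("table2.csv", arrived)
    emit(
        "noshow_omega.csv",
        bundle["omega_no_show"].rename(columns={"lag": "quarter_post_adoption"}),
    )
    emit(
        "cancel_omega.csv",
        bundle["omega_cancelled"].rename(columns={"lag": "quarter_post_adoption"}),
    )
    files["patients.csv"] = outdir / "patients.csv"
    files["quarters.csv"] = outdir / "quarters.csv"

    (outdir / "fit_arrived.json").write_text(
        json.dumps(_fit_to_dict(bundle["fit_arrived"]), indent=1, sort_keys=True)
    )
    files["fit_arrived.json"] = outdir / "fit_arrived.json"

    report = render_effect_report(
        bundle["table_arrived"], bundle["omega_no_show"], bundle["omega_cancelled"]
    )
    (outdir / "report.txt").write_text(report + "\n")
    files["report.txt"] = outdir / "report.txt"
    try:
        plot_rr_trajectories(
            {
                "arrived": bundle["table_arrived"],
                "no-show": bundle["omega_no_show"],
                "cancellation": bundle["omega_cancelled"],
            },
            outdir / "trajectory.png",
        )
    except Exception:  # plotting must never sink a run
        log.exception("trajectory plot failed")

    manifest = {
        "package_version": __version__,
        "seed": int(cfg["seed"]),
        "config": {k: v for k, v in cfg.items() if k != "outdir"},
        "generator_config": {
            k: v for k, v in asdict(sim_config).items()
            if isinstance(v, (int, float, bool, str))
        },
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "digests": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    bundle["manifest"] = manifest
    bundle["outdir"] = outdir
    bundle["report"] = report
    return bundle
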