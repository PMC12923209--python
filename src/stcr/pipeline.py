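"""End-to-end pipeline: simulate → calibrate → prescribe → validate.

``run_pipeline`` ties the three experimental phases and the analysis
stages into one reproducible run driven by a single config (see
:func:`stcr.data_model.default_config`): it simulates (or ingests) the
gradient and main experiments, calibrates the basic parameters, derives
the six prescription equations, emits a ready reckoner, builds the
validation-trial dose plan, simulates (or ingests) the validation trial
and computes the validation metrics. Every output table is written with a
header comment citing its producing stage and parameters, and a run
manifest records the config snapshot, seeds and file digests so identical
configs reproduce identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .data_model import (
    NUTRIENTS, PriceBook, TargetSpec, default_config, read_plot_table,
    records_to_frame, write_table,
)
from .synthetic import (
    TruthParameters, default_strip_specs, main_experiment_design,
    simulate_gradient_strips, simulate_main_experiment, simulate_validation_trial,
)
from .calibration import (
    calibrate_basic_parameters, correlate_yield_uptake, fit_yield_regression,
    summarize_by_strip,
)
from .prescription import DEFAULT_GRIDS, build_reckoner, derive_equation_set, recommend
from .metrics import validation_report

logger = logging.getLogger("stcr")

__all__ = ["RunManifest", "run_pipeline", "build_validation_doses"]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict[str, Any]
    seed: int
    version: str
    digests: dict[str, str] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def comparable(self) -> dict[str, Any]:
        """Manifest content minus the wall-clock timestamp."""
        data = dataclasses.asdict(self)
        data.pop("timestamp")
        return data


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_validation_doses(equations, config: Mapping[str, Any]) -> pd.DataFrame:
    """The 7-treatment validation dose plan.

    Four STCR treatments (two targets × with/without FYM) get doses from
    the prescription equations at the validation field's soil tests; the
    blanket (GRD) and soil-fertility-rating (SFR) doses come verbatim from
    the config; the absolute control receives nothing.
    """
    vconf = config["validation"]
    stv = vconf["stv"]
    grd = vconf["grd_doses"]
    fraction = config["maintenance_fraction"]
    rows = []
    for entry in vconf["targets"]:
        spec = TargetSpec(target_t=entry["target_t"], stv_n=stv["n"],
                          stv_p=stv["p"], stv_k=stv["k"],
                          om=entry.get("fym", 0.0))
        doses = recommend(equations, spec,
                          reference_doses={x: grd[x] for x in NUTRIENTS},
                          fraction=fraction)
        rows.append({"treatment_id": entry["id"],
                     **{f"fert_{x}": doses[x].final_dose for x in NUTRIENTS},
                     "fym": entry.get("fym", 0.0),
                     "target_t": entry["target_t"]})
    for tid, dose_set in (("T5", grd), ("T6", vconf["sfr_doses"])):
        rows.append({"treatment_id": tid,
                     **{f"fert_{x}": float(dose_set[x]) for x in NUTRIENTS},
                     "fym": float(dose_set.get("fym", 0.0)),
                     "target_t": float("nan")})
    rows.append({"treatment_id": "T7",
                 **{f"fert_{x}": 0.0 for x in NUTRIENTS},
                 "fym": 0.0, "target_t": float("nan")})
    frame = pd.DataFrame(rows)
    for x in NUTRIENTS:
        frame[f"stv_{x}"] = float(stv[x])
    return frame


def run_pipeline(config: Mapping[str, Any] | None = None,
                 out_dir: str | Path = "stcr_run") -> RunManifest:
    """Execute the full workflow; write all tables and a manifest.

    ``config['input_plots']`` / ``config['input_validation_plots']`` switch
    a stage from simulation to ingesting a user table (consumed unchanged).
    """
    config = dict(config) if config is not None else default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    truth = TruthParameters.from_config(config)

    def stage(name: str):
        logger.info("stage: %s", name)

    # --- phase I + II: main-experiment data -------------------------------
    stage("main experiment")
    if config.get("input_plots"):
        records = read_plot_table(config["input_plots"])
        main_frame = records_to_frame(records)
        main_header = f"stage: ingest, source: {config['input_plots']}"
    else:
        strips = simulate_gradient_strips(default_strip_specs(config), seed=seed)
        records = simulate_main_experiment(
            truth, strips, main_experiment_design(tuple(config["fym_levels"])),
            seed=seed, yield_model=config["yield_model"])
        main_frame = records_to_frame(records)
        main_header = (f"stage: simulate_main_experiment, seed: {seed}, "
                       f"yield_model: {config['yield_model']}")
    write_table(main_frame, out / "main_experiment.csv", header_comment=main_header)

    # --- calibration ------------------------------------------------------
    stage("calibration")
    params = calibrate_basic_parameters(
        main_frame, cf_integrated_convention=config["cf_integrated_convention"])
    for x in NUTRIENTS:
        logger.info("  %s: NR %.3f/%.3f CS %.3f CF %.3f/%.3f COM %.4f", x,
                    params.nr(x, "alone"), params.nr(x, "integrated"),
                    params.cs_pct(x), params.cf_pct(x, "alone"),
                    params.cf_pct(x, "integrated"), params.com_pct(x))
    write_table(params, out / "basic_parameters.csv",
                header_comment=f"stage: calibrate_basic_parameters, "
                               f"cf_integrated_convention: {config['cf_integrated_convention']}")
    write_table(summarize_by_strip(main_frame), out / "descriptives.csv",
                header_comment="stage: summarize_by_strip")
    corr = pd.DataFrame(
        [{"nutrient": x, **dict(zip(("r", "r2"), correlate_yield_uptake(main_frame, x)))}
         for x in NUTRIENTS])
    write_table(corr, out / "yield_uptake_correlations.csv",
                header_comment="stage: correlate_yield_uptake")
    write_table(fit_yield_regression(main_frame).to_frame(), out / "yield_regression.csv",
                header_comment="stage: fit_yield_regression (yield kg/ha on stv_n, stv_p, stv_k)")

    # --- prescription -----------------------------------------------------
    stage("prescription")
    equations = derive_equation_set(params, om_convention=config["om_term_convention"])
    eq_frame = pd.DataFrame(
        [{"nutrient": x, "regime": regime, "a_t": eq.a_t, "b_soil": eq.b_soil,
          "c_om": eq.c_om} for (x, regime), eq in equations.items()])
    write_table(eq_frame, out / "prescription_equations.csv",
                header_comment=f"stage: derive_equation_set, "
                               f"om_term_convention: {config['om_term_convention']}")
    rconf = config["reckoner"]
    grids = rconf["grids"] if isinstance(rconf.get("grids"), Mapping) else DEFAULT_GRIDS
    reckoner = build_reckoner(equations, grids, target_t=rconf["target_t"],
                              om=rconf["om"])
    write_table(reckoner.display_frame(), out / "ready_reckoner.csv",
                header_comment=f"stage: build_reckoner, target_t: {rconf['target_t']}, "
                               f"om: {rconf['om']}")

    # --- phase III: validation -------------------------------------------
    stage("validation")
    doses = build_validation_doses(equations, config)
    write_table(doses, out / "validation_doses.csv",
                header_comment="stage: build_validation_doses")
    if config.get("input_validation_plots"):
        vrecords = read_plot_table(config["input_validation_plots"])
    else:
        vrecords = simulate_validation_trial(
            truth, doses, seed=seed,
            replicates=int(config["validation"].get("replicates", 3)))
    vframe = records_to_frame(vrecords)
    write_table(vframe, out / "validation_plots.csv",
                header_comment=f"stage: simulate_validation_trial, seed: {seed}")

    targets = {entry["id"]: float(entry["target_t"])
               for entry in config["validation"]["targets"]}
    prices = PriceBook.from_mapping(config["prices"]) if config.get("prices") else None
    report = validation_report(vframe, targets, prices=prices, baseline_id="T5")
    for name, table in report.items():
        write_table(table.reset_index(), out / f"validation_{name}.csv",
                    header_comment=f"stage: validation_report/{name}, baseline: T5")
    logger.info("  percent deviation: %s",
                report["economics"]["percent_deviation"].round(2).to_dict())

    # --- manifest ---------------------------------------------------------
    manifest = RunManifest(
        config=json.loads(json.dumps(config, default=str)),
        seed=seed, version=__version__,
        digests={p.name: _digest(p) for p in sorted(out.glob("*.csv"))},
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
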