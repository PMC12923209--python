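"""Synthetic three-phase fertility-trial generator.

Emulates the statistical structure of a soil-test crop response (STCR)
study so every downstream stage (calibration → prescription → validation
metrics) is testable without field data:

* Phase I — a fertility-gradient experiment: three strips (LFS/MFS/HFS)
  whose per-plot soil-test N/P₂O₅/K₂O values are drawn from truncated
  normals with strip-specific means.
* Phase II — the main test-crop experiment: 24 NPK×FYM treatments laid on
  each strip (72 plots), generating nutrient uptakes additively from soil,
  fertilizer and farmyard-manure contributions, and green-foliage yield
  from the nutrient supplies.
* Phase III — a 7-treatment × 3-replicate validation trial.

Generative model
----------------
For plot *i* and nutrient X with soil test STV, mineral dose F (kg ha⁻¹)
and FYM dose OM (t ha⁻¹), the uptake supply is

    S_X = (CS_X/100)·STV_X + (CF_{X,R}/100)·F_X            if F_X > 0
    S_X = (CS_X/100)·STV_X + (COM_X/100)·(1000·OM)          if F_X = 0

with R = "integrated" when OM > 0 else "alone". The FYM credit appears
only for nutrients receiving no mineral fertilizer: where fertilizer is
applied, the manure effect is expressed as the larger integrated fertilizer
contribution (CF integrated > CF alone), mirroring how the calibrated
parameters attribute the synergy. Yield starts from the plain average of
the nutrient-implied yields, Y = mean_X(S_X/NR_{X,R}), and receives the
smallest relative per-plot adjustment that makes each regime's mean
uptake:yield ratios equal the specified NR exactly — so the whole
calibration chain is exactly invertible at zero noise. The pre-sowing
soil tests of the main experiment are re-centred (P and K only, nitrogen
anchored) to the crop's stoichiometry; see :func:`_balance_presowing`.
An alternative "liebig" yield model uses min_X S_X/NR_X instead. Noise is
multiplicative Gaussian (truncated at zero) on each uptake and on yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("stcr")

from .data_model import NUTRIENTS, PlotRecord, ValidationError, default_config

__all__ = [
    "NutrientTruth", "TruthParameters", "StripSpec",
    "default_truth", "default_strip_specs", "main_experiment_design",
    "simulate_gradient_strips", "simulate_main_experiment",
    "simulate_validation_trial",
]

#: the 24-treatment main-experiment design: (N, P2O5, K2O) doses in kg ha-1
MAIN_DESIGN_DOSES: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0),
    (0.0, 0.0, 0.0),
    (0.0, 35.0, 35.0),
    (17.5, 17.5, 17.5),
    (17.5, 17.5, 35.0),
    (17.5, 35.0, 17.5),
    (17.5, 35.0, 35.0),
    (35.0, 0.0, 35.0),
    (35.0, 17.5, 17.5),
    (35.0, 17.5, 35.0),
    (35.0, 35.0, 0.0),
    (35.0, 35.0, 17.5),
    (35.0, 35.0, 52.5),
    (35.0, 35.0, 35.0),
    (35.0, 52.5, 35.0),
    (35.0, 52.5, 52.5),
    (52.5, 17.5, 17.5),
    (52.5, 35.0, 35.0),
    (52.5, 35.0, 17.5),
    (52.5, 35.0, 52.5),
    (52.5, 52.5, 17.5),
    (52.5, 52.5, 35.0),
    (52.5, 52.5, 52.5),
)

FYM_LEVELS = (0.0, 7.5, 15.0)

_YIELD_FLOOR = 0.05  # t ha-1


@dataclass
class NutrientTruth:
    """True contribution parameters for one nutrient.

    ``nr_*`` is the nutrient requirement in kg of uptake per tonne of
    yield; ``cs_pct`` the % of the soil-test value recovered by the crop;
    ``cf_*_pct`` the % of an applied fertilizer dose recovered (may exceed
    100 for potassium, where applied K primes uptake of native reserves);
    ``com_pct`` the % of applied FYM mass recovered as uptake.
    """

    nr_alone: float
    nr_integrated: float
    cs_pct: float
    cf_alone_pct: float
    cf_integrated_pct: float
    com_pct: float

    def __post_init__(self) -> None:
        if self.nr_alone <= 0 or self.nr_integrated <= 0:
            raise ValidationError("nutrient requirement must be > 0")
        if self.cf_alone_pct <= 0 or self.cf_integrated_pct <= 0:
            raise ValidationError("fertilizer contribution must be > 0")
        if self.cs_pct < 0 or self.com_pct < 0:
            raise ValidationError("cs_pct and com_pct must be >= 0")

    def nr(self, regime: str) -> float:
        return self.nr_integrated if regime == "integrated" else self.nr_alone

    def cf_pct(self, regime: str) -> float:
        return self.cf_integrated_pct if regime == "integrated" else self.cf_alone_pct


@dataclass
class TruthParameters:
    """Full generative truth: per-nutrient parameters plus noise scales."""

    n: NutrientTruth
    p: NutrientTruth
    k: NutrientTruth
    sigma_uptake_rel: float = 0.05
    sigma_yield_rel: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma_uptake_rel < 0 or self.sigma_yield_rel < 0:
            raise ValidationError("noise sigmas must be >= 0")

    def nutrient(self, name: str) -> NutrientTruth:
        return getattr(self, name)

    def with_noise(self, sigma_uptake_rel: float, sigma_yield_rel: float) -> "TruthParameters":
        return replace(self, sigma_uptake_rel=sigma_uptake_rel,
                       sigma_yield_rel=sigma_yield_rel)

    @classmethod
    def from_config(cls, config: Mapping | None = None) -> "TruthParameters":
        config = config or default_config()
        truth = config["truth"]
        noise = config.get("noise", {})
        return cls(
            n=NutrientTruth(**truth["n"]),
            p=NutrientTruth(**truth["p"]),
            k=NutrientTruth(**truth["k"]),
            sigma_uptake_rel=noise.get("sigma_uptake_rel", 0.05),
            sigma_yield_rel=noise.get("sigma_yield_rel", 0.05),
        )


def default_truth(sigma_uptake_rel: float = 0.05,
                  sigma_yield_rel: float = 0.05) -> TruthParameters:
    """The calibrated basic-parameter set of the source study as truth."""
    truth = TruthParameters.from_config()
    return truth.with_noise(sigma_uptake_rel, sigma_yield_rel)


@dataclass
class StripSpec:
    """Soil-test distribution of one fertility strip."""

    name: str
    mean: dict[str, float]          # kg ha-1 per nutrient
    sd: dict[str, float]            # kg ha-1 per nutrient
    plots_per_strip: int = 24

    def __post_init__(self) -> None:
        for x in NUTRIENTS:
            if self.mean[x] <= 0:
                raise ValidationError(f"strip {self.name}: mean {x} must be > 0")
            if self.sd[x] < 0:
                raise ValidationError(f"strip {self.name}: SD {x} must be >= 0")


def default_strip_specs(config: Mapping | None = None) -> list[StripSpec]:
    config = config or default_config()
    specs = []
    for entry in config["strips"]:
        mean = {x: float(entry["mean"][x]) for x in NUTRIENTS}
        if "sd" in entry:
            sd = {x: float(entry["sd"][x]) for x in NUTRIENTS}
        else:
            cv = float(entry.get("cv", 0.05))
            sd = {x: cv * mean[x] for x in NUTRIENTS}
        specs.append(StripSpec(name=entry["name"], mean=mean, sd=sd,
                               plots_per_strip=int(entry.get("plots", 24))))
    return specs


def main_experiment_design(fym_levels: Sequence[float] = FYM_LEVELS) -> pd.DataFrame:
    """The 24-treatment dose table (kg ha⁻¹), without strip assignment."""
    frame = pd.DataFrame(MAIN_DESIGN_DOSES, columns=["fert_n", "fert_p", "fert_k"])
    frame.insert(0, "treatment_id", [f"M{i + 1:02d}" for i in range(len(frame))])
    frame.attrs["fym_levels"] = tuple(fym_levels)
    return frame


# ---------------------------------------------------------------------------
# phase I — fertility gradient
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      size: int) -> np.ndarray:
    """Normal(mean, sd) truncated at zero (degenerate when sd == 0)."""
    if sd == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                               random_state=rng)


def simulate_gradient_strips(specs: Sequence[StripSpec] | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Draw per-plot soil-test values for each fertility strip.

    Returns a table with columns ``strip, stv_n, stv_p, stv_k`` and
    ``plots_per_strip`` rows per spec, drawn from zero-truncated normals.
    """
    specs = list(specs) if specs is not None else default_strip_specs()
    if not specs:
        raise ValidationError("at least one strip spec is required")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rows = []
    for spec in specs:
        draws = {f"stv_{x}": _truncated_normal(rng, spec.mean[x], spec.sd[x],
                                               spec.plots_per_strip)
                 for x in NUTRIENTS}
        strip = pd.DataFrame(draws)
        strip.insert(0, "strip", spec.name)
        rows.append(strip)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# phase II — main experiment
# ---------------------------------------------------------------------------

def _supply(truth: TruthParameters, nutrient: str, stv: float, fert: float,
            fym: float) -> float:
    """Noise-free uptake supply (kg ha⁻¹) for one plot and nutrient."""
    t = truth.nutrient(nutrient)
    regime = "integrated" if fym > 0 else "alone"
    supply = t.cs_pct / 100.0 * stv
    if fert > 0:
        supply += t.cf_pct(regime) / 100.0 * fert
    elif fym > 0:
        supply += t.com_pct / 100.0 * (1000.0 * fym)
    return supply


def _balance_presowing(strips: pd.DataFrame, truth: TruthParameters,
                       design: pd.DataFrame) -> pd.DataFrame:
    """Re-centre pre-sowing P and K soil tests to the crop's stoichiometry.

    The gradient table describes phase I's *post-harvest* soil tests; the
    main experiment is re-sampled pre-sowing, and a calibratable trial
    needs soil supplies commensurate with the crop's nutrient-requirement
    ratios (a soil whose P supply alone would feed twice the yield its N
    supply can is not informative about NR_P). Keeping nitrogen as the
    anchor, the P and K columns are rescaled multiplicatively — strip
    gradient and relative spread preserved — so that the mean nutrient
    supply of a fertilized plot sits on the NR ray:

        centre_X = (NR_X·Ȳ − (CF_X/100)·F̄_X) · 100/CS_X

    with Ȳ the mean nitrogen-implied yield and F̄_X the design's mean
    fertilized dose.
    """
    out = strips.copy()
    nr = np.array([truth.nutrient(x).nr_alone for x in NUTRIENTS])
    cs = np.array([truth.nutrient(x).cs_pct for x in NUTRIENTS])
    cf = np.array([truth.nutrient(x).cf_alone_pct for x in NUTRIENTS])
    fert = design[["fert_n", "fert_p", "fert_k"]].to_numpy(dtype=float)
    fertilized = (fert > 0).any(axis=1)
    fbar = fert[fertilized].mean(axis=0) if fertilized.any() else np.zeros(3)
    ybar = (cs[0] / 100.0 * out["stv_n"].mean() + cf[0] / 100.0 * fbar[0]) / nr[0]
    centers = (nr * ybar - cf / 100.0 * fbar) * 100.0 / cs
    for i, x in enumerate(NUTRIENTS):
        if x == "n":
            continue
        if centers[i] <= 0:  # degenerate truth: fall back to soil-only balance
            centers[i] = nr[i] * ybar * 100.0 / cs[i]
        out[f"stv_{x}"] = out[f"stv_{x}"] / out[f"stv_{x}"].mean() * centers[i]
    return out


def _moment_matched_yields(supplies: np.ndarray, nr: np.ndarray) -> np.ndarray:
    """Yields whose mean supply:yield ratios equal NR exactly.

    Starts from the plain average of nutrient-implied yields
    y₀ = mean_X(S_X/NR_X) and applies the smallest relative adjustment (a
    weighted projection of z = 1/y onto the affine set mean_i(S_Xi·z_i) =
    NR_X) that makes the finite-sample moments exact. The adjustments play
    the role of plot-level yield efficiency heterogeneity.
    """
    n = len(supplies)
    y0 = (supplies / nr).mean(axis=1)
    z0 = 1.0 / y0
    A = supplies.T / n                       # rows: mean(S_X · z)
    w = z0 ** 2                              # relative-change metric
    gram = (A * w) @ A.T
    correction = w * (A.T @ np.linalg.lstsq(gram, nr - A @ z0, rcond=None)[0])
    z = z0 + correction
    if (z <= 0).any():
        # supply composition too far from the NR ratios (small or skewed
        # designs): keep the plain average; moments are then approximate
        logger.warning("moment matching infeasible for this design; "
                       "yields fall back to the plain implied-yield average")
        return y0
    return 1.0 / z


def _assign_yields(frame: pd.DataFrame, truth: TruthParameters,
                   yield_model: str) -> np.ndarray:
    """Noise-free plot yields (t ha⁻¹) from the supply columns of ``frame``."""
    supplies = frame[["supply_n", "supply_p", "supply_k"]].to_numpy()
    integrated = frame["fym"].to_numpy() > 0
    fertilized = (frame[["fert_n", "fert_p", "fert_k"]].to_numpy() > 0).any(axis=1)
    yields = np.empty(len(frame))
    for regime, mask in (("alone", ~integrated), ("integrated", integrated)):
        if not mask.any():
            continue
        nr = np.array([truth.nutrient(x).nr(regime) for x in NUTRIENTS])
        if yield_model == "liebig":
            yields[mask] = (supplies[mask] / nr).min(axis=1)
            continue
        yields[mask] = (supplies[mask] / nr).mean(axis=1)
        solve_on = mask & fertilized
        # with >=3 fertilized plots the regime's uptake:yield moments are
        # matched exactly to NR, making calibration exactly invertible
        if solve_on.sum() >= 3:
            yields[solve_on] = _moment_matched_yields(supplies[solve_on], nr)
    return yields


def _apply_noise(rng: np.random.Generator, values: np.ndarray,
                 sigma_rel: float) -> np.ndarray:
    if sigma_rel == 0:
        return values
    factors = _truncated_normal(rng, 1.0, sigma_rel, values.size)
    return values * factors


def simulate_main_experiment(truth: TruthParameters | None = None,
                             strips: pd.DataFrame | None = None,
                             design: pd.DataFrame | None = None,
                             seed: int = 0,
                             fym_levels: Sequence[float] = FYM_LEVELS,
                             yield_model: str = "balanced",
                             presowing: str = "balanced") -> list[PlotRecord]:
    """Generate the 24-treatment × 3-strip main test-crop experiment.

    ``strips`` is a gradient table from :func:`simulate_gradient_strips`
    (one row per plot); ``design`` a dose table with columns
    ``treatment_id, fert_n, fert_p, fert_k`` and optionally ``fym``. When
    ``fym`` is absent the three FYM levels are rotated systematically over
    treatments and strips so every strip carries all three manure regimes
    and every treatment meets every FYM level across the gradient.
    ``presowing="balanced"`` (default) re-centres the P and K soil tests to
    the crop's stoichiometry before sowing (see :func:`_balance_presowing`);
    ``"as_given"`` uses the gradient table verbatim.
    """
    truth = truth or default_truth()
    if strips is None:
        strips = simulate_gradient_strips(seed=seed)
    design = design if design is not None else main_experiment_design(fym_levels)
    if presowing == "balanced":
        strips = _balance_presowing(strips, truth, design)
    elif presowing != "as_given":
        raise ValueError(f"unknown presowing mode {presowing!r}")
    doses = design[["fert_n", "fert_p", "fert_k"]].to_numpy(dtype=float)
    if not (doses == 0).all(axis=1).any():
        raise ValidationError(
            "design must include control plots (zero NPK); calibration of the "
            "soil contribution would otherwise be impossible")

    strip_names = list(dict.fromkeys(strips["strip"]))
    rows = []
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    for s_idx, strip_name in enumerate(strip_names):
        strip_rows = strips[strips["strip"] == strip_name].reset_index(drop=True)
        if len(strip_rows) < len(design):
            raise ValidationError(
                f"strip {strip_name!r} has {len(strip_rows)} plots for "
                f"{len(design)} treatments")
        for t_idx, drow in design.iterrows():
            if "fym" in design.columns:
                fym = float(drow["fym"])
            else:
                fym = float(fym_levels[(t_idx + s_idx) % len(fym_levels)])
            srow = strip_rows.iloc[t_idx]
            rec = {
                "plot_id": f"{strip_name}-{drow['treatment_id']}",
                "strip": strip_name,
                "treatment_id": str(drow["treatment_id"]),
                "fert_n": float(drow["fert_n"]),
                "fert_p": float(drow["fert_p"]),
                "fert_k": float(drow["fert_k"]),
                "fym": fym,
                "stv_n": float(srow["stv_n"]),
                "stv_p": float(srow["stv_p"]),
                "stv_k": float(srow["stv_k"]),
            }
            for x in NUTRIENTS:
                rec[f"supply_{x}"] = _supply(truth, x, rec[f"stv_{x}"],
                                             rec[f"fert_{x}"], fym)
            rows.append(rec)
    frame = pd.DataFrame(rows)
    yields = _assign_yields(frame, truth, yield_model)

    records = []
    for i, row in frame.iterrows():
        uptakes = {x: float(_apply_noise(rng, np.array([row[f"supply_{x}"]]),
                                         truth.sigma_uptake_rel)[0])
                   for x in NUTRIENTS}
        y = float(_apply_noise(rng, np.array([yields[i]]),
                               truth.sigma_yield_rel)[0])
        records.append(PlotRecord(
            plot_id=row["plot_id"], strip=row["strip"],
            treatment_id=row["treatment_id"],
            fert_n=row["fert_n"], fert_p=row["fert_p"], fert_k=row["fert_k"],
            fym=row["fym"], stv_n=row["stv_n"], stv_p=row["stv_p"],
            stv_k=row["stv_k"], yield_t=max(y, _YIELD_FLOOR),
            uptake_n=uptakes["n"], uptake_p=uptakes["p"], uptake_k=uptakes["k"],
        ).validate())
    return records


# ---------------------------------------------------------------------------
# phase III — validation trial
# ---------------------------------------------------------------------------

def simulate_validation_trial(truth: TruthParameters | None = None,
                              doses: pd.DataFrame | None = None,
                              seed: int = 0,
                              replicates: int = 3) -> list[PlotRecord]:
    """Generate the randomized-block validation trial (7 × 3 by default).

    ``doses`` needs one row per treatment with columns ``treatment_id,
    fert_n, fert_p, fert_k, fym, stv_n, stv_p, stv_k``. An absolute-control
    row (all doses and FYM zero) must be present. Yield uses the plain
    average of nutrient-implied yields, so a dose set chosen to make each
    nutrient supply equal NR·T achieves the target exactly at zero noise.
    """
    truth = truth or default_truth()
    if doses is None:
        raise ValidationError("a per-treatment dose table is required")
    dose_cols = doses[["fert_n", "fert_p", "fert_k", "fym"]].to_numpy(dtype=float)
    if not (dose_cols == 0).all(axis=1).any():
        raise ValidationError("validation design must include an absolute control")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    records = []
    for _, row in doses.iterrows():
        fym = float(row["fym"])
        regime = "integrated" if fym > 0 else "alone"
        nr = np.array([truth.nutrient(x).nr(regime) for x in NUTRIENTS])
        supplies = np.array([
            _supply(truth, x, float(row[f"stv_{x}"]), float(row[f"fert_{x}"]), fym)
            for x in NUTRIENTS])
        y0 = float(np.mean(supplies / nr))
        for rep in range(1, replicates + 1):
            uptakes = _apply_noise(rng, supplies, truth.sigma_uptake_rel)
            y = float(_apply_noise(rng, np.array([y0]), truth.sigma_yield_rel)[0])
            records.append(PlotRecord(
                plot_id=f"{row['treatment_id']}-R{rep}",
                strip="VALIDATION", treatment_id=str(row["treatment_id"]),
                fert_n=float(row["fert_n"]), fert_p=float(row["fert_p"]),
                fert_k=float(row["fert_k"]), fym=fym,
                stv_n=float(row["stv_n"]), stv_p=float(row["stv_p"]),
                stv_k=float(row["stv_k"]), yield_t=max(y, _YIELD_FLOOR),
                uptake_n=float(uptakes[0]), uptake_p=float(uptakes[1]),
                uptake_k=float(uptakes[2]), replicate=rep,
            ).validate())
    return records
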