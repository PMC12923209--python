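"""Validation-trial metrics: target deviation, economics and efficiency.

Given the validation trial's treatment means, this module computes

* percent deviation — signed relative difference of achieved vs targeted
  yield, the primary test of a prescription equation's validity
  (±10% is the conventional acceptance band);
* response yardstick (RYS) — yield response over the unfertilized control
  per kg of total nutrient applied;
* value:cost ratio (VCR) — value of the yield gain per unit cost of the
  fertilizer + FYM inputs;
* the four nutrient-use-efficiency indices, per nutrient:
  partial factor productivity PFP = Y/F, agronomic efficiency
  AE = (Y−Y₀)/F, partial nutrient balance PNB = U/F and internal
  utilization efficiency IUE = Y/U (yields and uptakes in kg ha⁻¹).

Indices are computed on treatment means (replicates averaged first, then
the ratio), which matches how validation trials are conventionally
reported; a per-replicate mode supports uncertainty work. Undefined
ratios (zero denominators, e.g. PFP of an unfertilized control) are
returned as NaN markers rather than errors, so the rest of a report can
still be assembled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import NUTRIENTS, PriceBook, ValidationError, as_frame

__all__ = [
    "EconomicMetrics", "EfficiencyIndices",
    "percent_deviation", "response_yardstick", "value_cost_ratio",
    "efficiency_indices", "compare_treatments",
    "treatment_means", "validation_report",
]


@dataclass
class EconomicMetrics:
    """Percent deviation, response yardstick and value:cost ratio."""

    percent_deviation: float
    rys: float
    vcr: float


@dataclass
class EfficiencyIndices:
    """PFP / AE / PNB / IUE (kg kg⁻¹), one value per nutrient."""

    pfp: dict[str, float]
    ae: dict[str, float]
    pnb: dict[str, float]
    iue: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"nutrient": list(NUTRIENTS),
             "pfp": [self.pfp[x] for x in NUTRIENTS],
             "ae": [self.ae[x] for x in NUTRIENTS],
             "pnb": [self.pnb[x] for x in NUTRIENTS],
             "iue": [self.iue[x] for x in NUTRIENTS]})


def percent_deviation(actual_yield_t: float, target_t: float) -> float:
    """Signed % deviation of achieved yield from the target (same units)."""
    if target_t <= 0:
        raise ValidationError("yield target must be > 0")
    return 100.0 * (actual_yield_t - target_t) / target_t


def response_yardstick(treated_yield_kg: float, control_yield_kg: float,
                       total_nutrient_kg: float) -> float:
    """Yield response (kg ha⁻¹) per kg of total nutrient applied."""
    if total_nutrient_kg <= 0:
        return math.nan
    return (treated_yield_kg - control_yield_kg) / total_nutrient_kg


def value_cost_ratio(treated_yield_kg: float, control_yield_kg: float,
                     doses: Mapping[str, float], fym_t: float,
                     prices: PriceBook) -> float:
    """Value of the yield gain over control per unit input cost."""
    cost = prices.input_cost(doses.get("n", 0.0), doses.get("p", 0.0),
                             doses.get("k", 0.0), fym_t)
    if cost <= 0:
        return math.nan
    gain = (treated_yield_kg - control_yield_kg) * prices.price_per_kg_leaf
    return gain / cost


def efficiency_indices(yield_t: float, uptakes_kg: Mapping[str, float],
                       control_yield_t: float,
                       doses_kg: Mapping[str, float]) -> EfficiencyIndices:
    """The four indices for one treatment (mean yields in t ha⁻¹).

    Yields enter the ratios in kg ha⁻¹ (t ha⁻¹ × 1000), the only
    convention matching the indices' conventional magnitudes (IUE of a
    leafy crop ≈ 150–200). PFP/AE/PNB are NaN where the dose is zero and
    IUE is NaN where uptake is zero; the remaining indices are still
    computed.
    """
    y_kg = yield_t * 1000.0
    y0_kg = control_yield_t * 1000.0
    pfp, ae, pnb, iue = {}, {}, {}, {}
    for x in NUTRIENTS:
        dose = doses_kg.get(x, 0.0)
        uptake = uptakes_kg[x]
        if dose > 0:
            pfp[x] = y_kg / dose
            ae[x] = (y_kg - y0_kg) / dose
            pnb[x] = uptake / dose
        else:
            pfp[x] = ae[x] = pnb[x] = math.nan
        iue[x] = y_kg / uptake if uptake > 0 else math.nan
    return EfficiencyIndices(pfp=pfp, ae=ae, pnb=pnb, iue=iue)


def compare_treatments(metric_table: pd.DataFrame, baseline_id: str) -> pd.DataFrame:
    """Relative difference (%) of every numeric metric vs a baseline row.

    ``metric_table`` must be indexed by treatment id. Metrics whose
    baseline value is zero (or missing) come back as NaN.
    """
    if baseline_id not in metric_table.index:
        raise ValidationError(f"baseline treatment {baseline_id!r} not in table")
    numeric = metric_table.select_dtypes(include=[np.number])
    base = numeric.loc[baseline_id]
    out = 100.0 * (numeric - base) / base
    for col in out.columns:
        if base[col] == 0 or pd.isna(base[col]):
            out[col] = np.nan
    return out


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def treatment_means(plots) -> pd.DataFrame:
    """Mean yield, uptakes and quality traits per treatment (over replicates)."""
    frame = as_frame(plots)
    value_cols = [c for c in frame.columns
                  if c in ("yield_t", "uptake_n", "uptake_p", "uptake_k",
                           "fert_n", "fert_p", "fert_k", "fym")
                  or c.startswith("quality_")]
    return frame.groupby("treatment_id", sort=False)[value_cols].mean()


def validation_report(plots, targets: Mapping[str, float],
                      prices: PriceBook | None = None,
                      control_id: str | None = None,
                      baseline_id: str | None = None) -> dict[str, pd.DataFrame]:
    """Assemble the full validation-metric report from plot records.

    ``targets`` maps treatment id → targeted yield (t ha⁻¹) for the
    treatments that carry one. The control is auto-detected as the
    treatment with zero doses and FYM unless given. Returns a dict of
    tables: treatment ``means``, ``economics`` (percent deviation, RYS and
    — when prices are supplied — VCR) and ``efficiency`` (the four indices
    per nutrient), plus ``relative_to_baseline`` when a baseline id is
    given.
    """
    means = treatment_means(plots)
    if control_id is None:
        zero = means[[f"fert_{x}" for x in NUTRIENTS] + ["fym"]].sum(axis=1) == 0
        if not zero.any():
            raise ValidationError("no absolute-control treatment found")
        control_id = zero.idxmax()
    y0_t = float(means.loc[control_id, "yield_t"])

    econ_rows, eff_rows = [], []
    for tid, row in means.iterrows():
        doses = {x: float(row[f"fert_{x}"]) for x in NUTRIENTS}
        total_nutrient = sum(doses.values())
        y_t = float(row["yield_t"])
        deviation = (percent_deviation(y_t, targets[tid])
                     if tid in targets else math.nan)
        rys = response_yardstick(y_t * 1000.0, y0_t * 1000.0, total_nutrient)
        vcr = (value_cost_ratio(y_t * 1000.0, y0_t * 1000.0, doses,
                                float(row["fym"]), prices)
               if prices is not None else math.nan)
        econ_rows.append({"treatment_id": tid, "yield_t": y_t,
                          "target_t": targets.get(tid, math.nan),
                          "percent_deviation": deviation, "rys": rys, "vcr": vcr})
        indices = efficiency_indices(
            y_t, {x: float(row[f"uptake_{x}"]) for x in NUTRIENTS}, y0_t, doses)
        eff_row: dict[str, float | str] = {"treatment_id": tid}
        for name in ("pfp", "ae", "pnb", "iue"):
            for x in NUTRIENTS:
                eff_row[f"{name}_{x}"] = getattr(indices, name)[x]
        eff_rows.append(eff_row)

    report = {
        "means": means,
        "economics": pd.DataFrame(econ_rows).set_index("treatment_id"),
        "efficiency": pd.DataFrame(eff_rows).set_index("treatment_id"),
    }
    if baseline_id is not None:
        report["relative_to_baseline"] = compare_treatments(means, baseline_id)
    return report
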