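"""Fertilizer prescription equations, dose policy and ready reckoners.

A calibrated basic-parameter set turns into one linear dose rule per
nutrient and regime:

    F_X = (100·NR/CF)·T − (CS/CF)·STV_X − c_OM·OM

with T the yield target (t ha⁻¹), STV_X the soil-test value (kg ha⁻¹) and
OM the farmyard manure (t ha⁻¹; integrated regime only). Coefficients are
kept unrounded internally; rounding happens only at display time.

The OM term has two conventions. The symbolic statement of the method
writes (COM/CF)·OM, but the published dose tables (and the printed
−0.08/−0.09/−0.07 OM coefficients) are only reproduced by c_OM = COM%
applied to OM in t ha⁻¹ — so that reckoner-consistent convention is the
default and the symbolic variant stays available behind a flag.

A raw dose may be negative at high soil tests: fertilizer is not needed
for the target, but a maintenance fraction (default 25%, from the
methodology's "25–30 percent" guidance) of a reference dose is recommended
to preserve soil fertility. Negative raw values are reported alongside the
policy outcome, never silently clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import NUTRIENTS, TargetSpec, ValidationError
from .calibration import BasicParameters

__all__ = [
    "PrescriptionEquation", "Recommendation", "ReckonerTable",
    "derive_equation", "derive_equation_set", "prescribe_dose",
    "apply_maintenance_rule", "recommend", "build_reckoner",
    "DEFAULT_GRIDS",
]

#: soil-test grids of the published ready reckoner (kg ha⁻¹)
DEFAULT_GRIDS: dict[str, tuple[float, ...]] = {
    "n": (250, 260, 280, 290, 300, 320, 340, 400, 440, 480, 520, 560, 600),
    "p": (15, 17, 19, 21, 23, 25, 30, 32, 35, 38, 41, 44, 46, 47, 50, 52, 54, 58),
    "k": (110, 120, 125, 130, 140, 150, 160, 170, 180, 200, 220, 240, 260,
          280, 300, 320, 340, 440),
}

#: display rounding of reckoner dose columns (decimals), mirroring the
#: published table: nitrogen to 1 decimal, P₂O₅ and K₂O to 2
DISPLAY_DECIMALS = {"n": 1, "p": 2, "k": 2}


class DerivationError(ValueError):
    """An equation cannot be derived from the given parameters."""


@dataclass
class PrescriptionEquation:
    """The linear dose rule for one nutrient and regime.

    ``a_t`` multiplies the yield target (kg ha⁻¹ of fertilizer per t ha⁻¹
    of target), ``b_soil`` the soil-test value (dimensionless), ``c_om``
    the FYM quantity in t ha⁻¹ (zero in the alone regime).
    """

    nutrient: str
    regime: str
    a_t: float
    b_soil: float
    c_om: float = 0.0
    provenance: BasicParameters | None = None

    def __post_init__(self) -> None:
        if self.a_t <= 0:
            raise DerivationError("target coefficient a_t must be > 0")
        if self.b_soil < 0 or self.c_om < 0:
            raise DerivationError("b_soil and c_om must be >= 0")

    def __str__(self) -> str:
        text = f"F{self.nutrient.upper()} = {self.a_t:.2f} T - {self.b_soil:.2f} S{self.nutrient.upper()}"
        if self.regime == "integrated":
            text += f" - {self.c_om:.2f} OM"
        return text


def derive_equation(params: BasicParameters, nutrient: str, regime: str,
                    om_convention: str = "reckoner") -> PrescriptionEquation:
    """Turn basic parameters into the dose rule for one nutrient/regime.

    ``om_convention`` is ``"reckoner"`` (c_OM = COM%, the convention that
    reproduces the published dose tables) or ``"symbolic"`` (c_OM =
    COM%/CF%, the method's symbolic statement).
    """
    cf = params.cf_pct(nutrient, regime)
    if cf == 0:
        raise DerivationError(f"cf_pct is zero for {nutrient} ({regime})")
    nr = params.nr(nutrient, regime)
    cs = params.cs_pct(nutrient)
    if regime == "integrated":
        com = params.com_pct(nutrient)
        c_om = com if om_convention == "reckoner" else com / cf
    else:
        c_om = 0.0
    return PrescriptionEquation(nutrient=nutrient, regime=regime,
                                a_t=100.0 * nr / cf, b_soil=cs / cf,
                                c_om=c_om, provenance=params)


def derive_equation_set(params: BasicParameters, om_convention: str = "reckoner"
                        ) -> dict[tuple[str, str], PrescriptionEquation]:
    """All six equations, keyed by (nutrient, regime)."""
    return {(x, regime): derive_equation(params, x, regime, om_convention)
            for regime in ("alone", "integrated") for x in NUTRIENTS}


def prescribe_dose(eq: PrescriptionEquation, spec: TargetSpec) -> float:
    """Raw dose (kg ha⁻¹, may be negative) for a field/target spec."""
    if eq.regime == "alone" and spec.om != 0:
        raise ValidationError("alone-regime equation evaluated with om != 0")
    if eq.regime == "integrated" and spec.om is None:
        raise ValidationError("integrated equation requires an om value")
    return eq.a_t * spec.target_t - eq.b_soil * spec.stv(eq.nutrient) \
        - eq.c_om * spec.om


@dataclass
class Recommendation:
    """Final dose for one nutrient after the negative-dose policy."""

    nutrient: str
    raw_dose: float
    final_dose: float
    policy_applied: str            # "none" | "maintenance"
    maintenance_reference: float | None = None

    def __post_init__(self) -> None:
        if self.final_dose < 0:
            raise ValidationError("final dose must be >= 0")


def apply_maintenance_rule(raw_dose: float, reference_dose: float,
                           fraction: float = 0.25,
                           nutrient: str = "") -> Recommendation:
    """Replace a non-positive raw dose by fraction × reference dose.

    A raw dose ≤ 0 (boundary included) means the soil already supplies the
    target; the maintenance policy recommends a fraction of a reference
    dose (typically the blanket recommendation) to sustain fertility.
    Positive raw doses pass through unchanged.
    """
    if not 0 <= fraction <= 1:
        raise ValidationError("maintenance fraction must be in [0,1]")
    if reference_dose < 0:
        raise ValidationError("reference dose must be >= 0")
    if raw_dose > 0:
        return Recommendation(nutrient, raw_dose, raw_dose, "none")
    return Recommendation(nutrient, raw_dose, fraction * reference_dose,
                          "maintenance", reference_dose)


def recommend(equations: Mapping[tuple[str, str], PrescriptionEquation],
              spec: TargetSpec,
              reference_doses: Mapping[str, float] | None = None,
              fraction: float = 0.25) -> dict[str, Recommendation]:
    """Doses for all three nutrients of one regime, with policy applied.

    The regime is chosen from ``spec.om`` (integrated iff om > 0). When no
    reference doses are given, negative raw doses resolve to a zero
    maintenance dose (reference 0) — still flagged as maintenance.
    """
    regime = "integrated" if spec.om > 0 else "alone"
    out = {}
    for x in NUTRIENTS:
        raw = prescribe_dose(equations[(x, regime)], spec)
        reference = (reference_doses or {}).get(x, 0.0)
        out[x] = apply_maintenance_rule(raw, reference, fraction, nutrient=x)
    return out


@dataclass
class ReckonerTable:
    """A ready-reckoner: doses over soil-test grids for a fixed target.

    Columns follow the published layout: the three soil-test grids, then
    the NPK-alone dose columns, then the +FYM dose columns. Grids may have
    different lengths; shorter columns are padded with NaN. Doses are
    stored unrounded; :meth:`display_frame` applies the published rounding
    (N to 1 decimal, P and K to 2).
    """

    target_t: float
    om: float
    frame: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.frame

    def display_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        for x in NUTRIENTS:
            out[f"fert_{x}_alone"] = out[f"fert_{x}_alone"].round(DISPLAY_DECIMALS[x])
            out[f"fert_{x}_fym"] = out[f"fert_{x}_fym"].round(DISPLAY_DECIMALS[x])
        return out

    def column(self, nutrient: str, regime: str) -> pd.Series:
        suffix = "fym" if regime == "integrated" else "alone"
        return self.frame[f"fert_{nutrient}_{suffix}"].dropna()


def build_reckoner(equations: Mapping[tuple[str, str], PrescriptionEquation],
                   grids: Mapping[str, Sequence[float]] | None = None,
                   target_t: float = 8.0, om: float = 7.5) -> ReckonerTable:
    """Evaluate all six equations over per-nutrient soil-test grids.

    Each dose column depends only on its own nutrient's soil-test grid
    (columns are fully independent, as in the published table). Grids must
    be sorted ascending and nonempty.
    """
    grids = {x: list(v) for x, v in (grids or DEFAULT_GRIDS).items()}
    for x in NUTRIENTS:
        grid = grids.get(x, [])
        if not grid:
            raise ValidationError(f"empty soil-test grid for {x}")
        if list(grid) != sorted(grid):
            raise ValidationError(f"soil-test grid for {x} must be sorted ascending")
    length = max(len(g) for g in grids.values())
    data: dict[str, list[float]] = {}
    for x in NUTRIENTS:
        pad = [np.nan] * (length - len(grids[x]))
        data[f"stv_{x}"] = list(grids[x]) + pad
    for regime, suffix in (("alone", "alone"), ("integrated", "fym")):
        use_om = om if regime == "integrated" else 0.0
        for x in NUTRIENTS:
            eq = equations[(x, regime)]
            doses = [eq.a_t * target_t - eq.b_soil * stv - eq.c_om * use_om
                     if not np.isnan(stv) else np.nan
                     for stv in data[f"stv_{x}"]]
            data[f"fert_{x}_{suffix}"] = doses
    columns = ([f"stv_{x}" for x in NUTRIENTS]
               + [f"fert_{x}_alone" for x in NUTRIENTS]
               + [f"fert_{x}_fym" for x in NUTRIENTS])
    return ReckonerTable(target_t=target_t, om=om,
                         frame=pd.DataFrame(data, columns=columns))
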