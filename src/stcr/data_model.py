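"""Shared record types and delimited-table / config I/O.

Every stage of the targeted-yield workflow exchanges data through the types
defined here: plot-level trial records, the field/target specification a
prescription is computed for, and the price book used by trial economics.

Units are part of the column contract and are never converted silently:
yields are t ha⁻¹, nutrient doses and uptakes kg ha⁻¹, farmyard manure
(FYM) t ha⁻¹, soil-test values kg ha⁻¹.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("stcr")

NUTRIENTS = ("n", "p", "k")

#: mandatory columns of a plot table, in canonical order
PLOT_COLUMNS = (
    "plot_id",
    "strip",
    "treatment_id",
    "fert_n",
    "fert_p",
    "fert_k",
    "fym",
    "stv_n",
    "stv_p",
    "stv_k",
    "yield_t",
    "uptake_n",
    "uptake_p",
    "uptake_k",
)

#: optional columns; quality traits ride along as ``quality_<trait>`` columns
OPTIONAL_COLUMNS = ("replicate",)

NONNEGATIVE_FIELDS = (
    "fert_n", "fert_p", "fert_k", "fym",
    "stv_n", "stv_p", "stv_k",
    "yield_t", "uptake_n", "uptake_p", "uptake_k",
)

STRIP_NAMES = ("LFS", "MFS", "HFS", "VALIDATION")


class SchemaError(ValueError):
    """A table does not follow the documented column contract."""


class ValidationError(ValueError):
    """A record violates a stated invariant (e.g. a negative dose)."""


class EstimationError(ValueError):
    """A parameter estimate is requested from data that cannot support it."""


class ConfigError(ValueError):
    """A configuration value is invalid."""


@dataclass
class PlotRecord:
    """One experimental plot: design factors, soil tests, yield, uptakes."""

    plot_id: str
    strip: str
    treatment_id: str
    fert_n: float
    fert_p: float
    fert_k: float
    fym: float
    stv_n: float
    stv_p: float
    stv_k: float
    yield_t: float
    uptake_n: float
    uptake_p: float
    uptake_k: float
    replicate: int | None = None
    quality: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "PlotRecord":
        for name in NONNEGATIVE_FIELDS:
            value = getattr(self, name)
            if value is not None and not pd.isna(value) and value < 0:
                raise ValidationError(
                    f"plot {self.plot_id!r}: field {name!r} must be >= 0, got {value}"
                )
        return self


@dataclass
class TargetSpec:
    """A yield target T with the field's soil tests and FYM plan.

    ``target_t`` is the targeted yield in t ha⁻¹; ``stv_n/p/k`` are the
    pre-sowing soil-test values (SN, SP, SK) in kg ha⁻¹; ``om`` is the
    farmyard-manure quantity (OM) in t ha⁻¹.
    """

    target_t: float
    stv_n: float
    stv_p: float
    stv_k: float
    om: float = 0.0

    def __post_init__(self) -> None:
        if self.target_t <= 0:
            raise ValidationError(f"target_t must be > 0, got {self.target_t}")
        for name in ("stv_n", "stv_p", "stv_k", "om"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def stv(self, nutrient: str) -> float:
        return getattr(self, f"stv_{nutrient}")


@dataclass
class PriceBook:
    """Unit prices for produce and inputs (any consistent currency).

    The trial economics (value:cost ratio) need prices for the leaf produce
    (per kg), each fertilizer nutrient (per kg) and FYM (per t). The source
    study publishes none, so values are always user-supplied.
    """

    price_per_kg_leaf: float
    cost_per_kg_n: float
    cost_per_kg_p: float
    cost_per_kg_k: float
    cost_per_t_fym: float = 0.0

    def __post_init__(self) -> None:
        for name in ("price_per_kg_leaf", "cost_per_kg_n", "cost_per_kg_p",
                     "cost_per_kg_k", "cost_per_t_fym"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    @classmethod
    def from_mapping(cls, data: Mapping[str, float]) -> "PriceBook":
        return cls(**{k: float(v) for k, v in data.items()})

    def input_cost(self, fert_n: float, fert_p: float, fert_k: float,
                   fym: float = 0.0) -> float:
        """Total cost of a dose set (kg ha⁻¹) plus FYM (t ha⁻¹)."""
        return (fert_n * self.cost_per_kg_n + fert_p * self.cost_per_kg_p
                + fert_k * self.cost_per_kg_k + fym * self.cost_per_t_fym)


# ---------------------------------------------------------------------------
# plot tables
# ---------------------------------------------------------------------------

_DELIMITERS = {"comma": ",", "tab": "\t", ",": ",", "\t": "\t", "csv": ",", "tsv": "\t"}


def _delimiter(dialect: str) -> str:
    try:
        return _DELIMITERS[dialect]
    except KeyError:
        raise ConfigError(f"unknown dialect {dialect!r}; use 'comma' or 'tab'") from None


def read_plot_table(path: str | Path, dialect: str = "comma") -> list[PlotRecord]:
    """Read a delimited plot table into validated :class:`PlotRecord` s.

    Header names are matched case-insensitively against the documented
    contract; ``#`` lines are treated as comments. Raises
    :class:`SchemaError` when a mandatory column is missing and
    :class:`ValidationError` when a nonnegative field is negative.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_delimiter(dialect), comment="#")
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = [c for c in PLOT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    return frame_to_records(frame)


def frame_to_records(frame: pd.DataFrame) -> list[PlotRecord]:
    """Convert a conforming DataFrame to validated records (row order kept)."""
    quality_cols = [c for c in frame.columns if c.startswith("quality_")]
    records: list[PlotRecord] = []
    for _, row in frame.iterrows():
        rep = row.get("replicate")
        quality = {c[len("quality_"):]: float(row[c])
                   for c in quality_cols if not pd.isna(row[c])}
        rec = PlotRecord(
            plot_id=str(row["plot_id"]),
            strip=str(row["strip"]),
            treatment_id=str(row["treatment_id"]),
            **{c: float(row[c]) for c in PLOT_COLUMNS[3:]},
            replicate=None if rep is None or pd.isna(rep) else int(rep),
            quality=quality,
        )
        records.append(rec.validate())
    return records


def records_to_frame(records: Iterable[PlotRecord]) -> pd.DataFrame:
    """Tabulate records in the canonical column order."""
    records = list(records)
    quality_traits: list[str] = []
    for rec in records:
        for trait in rec.quality:
            if trait not in quality_traits:
                quality_traits.append(trait)
    rows = []
    for rec in records:
        row: dict[str, Any] = {c: getattr(rec, c) for c in PLOT_COLUMNS}
        row["replicate"] = rec.replicate
        for trait in quality_traits:
            row[f"quality_{trait}"] = rec.quality.get(trait)
        rows.append(row)
    columns = list(PLOT_COLUMNS) + ["replicate"] + [f"quality_{t}" for t in quality_traits]
    frame = pd.DataFrame(rows, columns=columns)
    if frame["replicate"].isna().all():
        frame = frame.drop(columns=["replicate"])
    return frame


def as_frame(plots: pd.DataFrame | Iterable[PlotRecord]) -> pd.DataFrame:
    """Accept either representation of a plot table; return a DataFrame."""
    if isinstance(plots, pd.DataFrame):
        return plots
    return records_to_frame(plots)


def write_table(records: Any, path: str | Path, dialect: str = "comma",
                allow_empty: bool = False, header_comment: str | None = None) -> None:
    """Write any tabular result as a delimited text file.

    Accepts a DataFrame, a sequence of :class:`PlotRecord`, or any object
    with a ``to_frame()`` method (e.g. a reckoner or parameter set, whose
    frames carry their documented column order). Numeric values are written
    at full precision so a read-back round-trips exactly.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    elif hasattr(records, "to_frame"):
        frame = records.to_frame()
    else:
        frame = records_to_frame(records)
    if frame.empty and not allow_empty:
        raise ValidationError(
            "refusing to write an empty table; pass allow_empty=True if intended")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep=_delimiter(dialect), index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_config() -> dict[str, Any]:
    """The full default configuration of the pipeline.

    Truth parameters default to the calibrated basic-parameter set of the
    source field study (nutrient requirement in kg t⁻¹; soil, fertilizer
    and FYM contribution percentages), strip means to its post-harvest
    gradient soil tests, and the treatment design to its 24-row main trial.
    Prices are illustrative placeholders — the study publishes none.
    """
    return {
        "seed": 42,
        "noise": {"sigma_uptake_rel": 0.05, "sigma_yield_rel": 0.05},
        "truth": {
            "n": {"nr_alone": 6.10, "nr_integrated": 6.55, "cs_pct": 10.67,
                  "cf_alone_pct": 33.32, "cf_integrated_pct": 44.68, "com_pct": 0.075},
            "p": {"nr_alone": 2.23, "nr_integrated": 2.54, "cs_pct": 11.66,
                  "cf_alone_pct": 26.90, "cf_integrated_pct": 36.14, "com_pct": 0.095},
            "k": {"nr_alone": 7.91, "nr_integrated": 8.90, "cs_pct": 10.40,
                  "cf_alone_pct": 91.45, "cf_integrated_pct": 130.35, "com_pct": 0.072},
        },
        "strips": [
            {"name": "LFS", "mean": {"n": 245.56, "p": 149.51, "k": 230.54},
             "cv": 0.05, "plots": 24},
            {"name": "MFS", "mean": {"n": 272.64, "p": 165.44, "k": 251.24},
             "cv": 0.05, "plots": 24},
            {"name": "HFS", "mean": {"n": 299.71, "p": 181.37, "k": 271.93},
             "cv": 0.05, "plots": 24},
        ],
        "fym_levels": [0.0, 7.5, 15.0],
        "yield_model": "balanced",              # or "liebig"
        "cf_integrated_convention": "lumped",   # or "strict_ledger"
        "om_term_convention": "reckoner",       # or "symbolic"
        "maintenance_fraction": 0.25,
        "reckoner": {"target_t": 8.0, "om": 7.5, "grids": "builtin"},
        "validation": {
            "stv": {"n": 280.0, "p": 23.0, "k": 140.0},
            "targets": [
                {"id": "T1", "target_t": 10.0, "regime": "alone", "fym": 0.0},
                {"id": "T2", "target_t": 10.0, "regime": "integrated", "fym": 7.5},
                {"id": "T3", "target_t": 8.0, "regime": "alone", "fym": 0.0},
                {"id": "T4", "target_t": 8.0, "regime": "integrated", "fym": 7.5},
            ],
            # blanket/general recommended dose and soil-fertility-rating dose;
            # site-specific inputs the user should review, stated explicitly
            "grd_doses": {"n": 35.0, "p": 35.0, "k": 35.0, "fym": 0.0},
            "sfr_doses": {"n": 35.0, "p": 26.25, "k": 35.0, "fym": 0.0},
            "replicates": 3,
        },
        # illustrative prices (currency units per kg / per t); no defaults
        # are derivable from the source study
        "prices": {"price_per_kg_leaf": 8.0, "cost_per_kg_n": 18.0,
                   "cost_per_kg_p": 50.0, "cost_per_kg_k": 20.0,
                   "cost_per_t_fym": 1500.0},
    }


_FRACTION_KEYS = ("maintenance_fraction",)


def _merge(base: dict, extra: Mapping) -> dict:
    for key, value in extra.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            _merge(base[key], value)
        else:
            base[key] = copy.deepcopy(value)
    return base


def _hoist_nested_seed(config: dict) -> None:
    """A ``seed`` key at any nesting overrides the top-level one (last wins)."""
    def walk(node: Any) -> None:
        if isinstance(node, dict):
            for key, value in node.items():
                if key == "seed" and node is not config:
                    logger.warning("nested 'seed' found; last occurrence wins")
                    config["seed"] = value
                else:
                    walk(value)
        elif isinstance(node, list):
            for item in node:
                walk(item)
    walk(config)


def validate_config(config: dict[str, Any]) -> dict[str, Any]:
    if not isinstance(config["seed"], int):
        raise ConfigError("invalid value for 'seed': must be an integer")
    for key in _FRACTION_KEYS:
        value = config[key]
        if not (0 <= value <= 1):
            raise ConfigError(f"invalid value for {key!r}: must be in [0,1]")
    for key, value in config["noise"].items():
        if value < 0:
            raise ConfigError(f"invalid value for noise.{key}: must be >= 0")
    grids = config["reckoner"].get("grids")
    if isinstance(grids, Mapping):
        for nutrient, grid in grids.items():
            if list(grid) != sorted(grid):
                raise ConfigError(
                    f"invalid value for reckoner.grids.{nutrient}: must be sorted ascending")
    return config


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load a YAML config, fill defaults, and validate.

    Unknown top-level keys are logged as warnings and kept; invalid values
    raise :class:`ConfigError` naming the key. An empty (or absent) file
    yields the full default configuration.
    """
    config = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"{path}: config root must be a mapping")
        for key in user:
            if key not in config:
                logger.warning("unknown config key %r (kept as-is)", key)
        _merge(config, user)
    if overrides:
        _merge(config, overrides)
    _hoist_nested_seed(config)
    return validate_config(config)
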