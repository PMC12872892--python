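"""CSV/YAML readers and writers for the pipeline's external interfaces.

All files are UTF-8, comma-separated, ISO-8601 dates, decimal point.
Readers validate schemas eagerly and report the offending file, column and
(where applicable) line so failures surface before any computation.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .elements import KNOWN_ELEMENTS, ORGANS
from .errors import SchemaError
from .gravimetric import MassSeries

_SOLUTION_COLUMNS = (
    "date",
    "plant_id",
    "cultivar",
    "element",
    "concentration_mg_per_L",
    "sample_type",
)
_TISSUE_COLUMNS = (
    "plant_id",
    "cultivar",
    "organ",
    "element",
    "concentration_mg_per_g",
    "organ_dry_mass_g",
)
_MASS_COLUMNS = ("timestamp", "container_id", "mass_g")

#: pandas' default float formatting is the shortest round-trip repr:
#: lossless on re-read and deterministic across reruns.
FLOAT_FORMAT = None


def _check_columns(df: pd.DataFrame, required: tuple[str, ...], path) -> None:
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")


def _check_values(df: pd.DataFrame, column: str, allowed, path) -> None:
    bad = df.loc[~df[column].isin(allowed)]
    if len(bad):
        line = int(bad.index[0]) + 2  # header + 1-based
        raise SchemaError(
            f"{path}, line {line}, column {column!r}: "
            f"unexpected value {bad[column].iloc[0]!r}"
        )


def _check_numeric(df: pd.DataFrame, column: str, path, minimum=None) -> pd.DataFrame:
    values = pd.to_numeric(df[column], errors="coerce")
    bad = df.loc[values.isna()]
    if len(bad):
        line = int(bad.index[0]) + 2
        raise SchemaError(
            f"{path}, line {line}, column {column!r}: "
            f"non-numeric value {bad[column].iloc[0]!r}"
        )
    if minimum is not None:
        low = df.loc[values < minimum]
        if len(low):
            line = int(low.index[0]) + 2
            raise SchemaError(
                f"{path}, line {line}, column {column!r}: value below {minimum}"
            )
    df = df.copy()
    df[column] = values
    return df


def read_solution_samples(path) -> pd.DataFrame:
    """Supply/leachate element concentrations per sampling event."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _SOLUTION_COLUMNS, path)
    _check_values(df, "sample_type", {"supply", "leachate"}, path)
    _check_values(df, "element", set(KNOWN_ELEMENTS), path)
    df = _check_numeric(df, "concentration_mg_per_L", path, minimum=0.0)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_tissue(path) -> pd.DataFrame:
    """Harvest organ dry biomass and tissue element concentrations."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _TISSUE_COLUMNS, path)
    _check_values(df, "organ", set(ORGANS), path)
    _check_values(df, "element", set(KNOWN_ELEMENTS), path)
    df = _check_numeric(df, "concentration_mg_per_g", path, minimum=0.0)
    df = _check_numeric(df, "organ_dry_mass_g", path, minimum=0.0)
    return df


def read_mass_log(path) -> dict[str, MassSeries]:
    """Gravimetric balance log -> one MassSeries per container."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, _MASS_COLUMNS, path)
    df = _check_numeric(df, "mass_g", path, minimum=0.0)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return {
        cid: MassSeries.from_dataframe(df, cid)
        for cid in df["container_id"].unique()
    }


def read_recipe(path) -> dict[str, float]:
    """Fertigation recipe: YAML mapping or two-column CSV (element, mg/L)."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise SchemaError(f"{path}: recipe YAML must be a mapping")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        _check_columns(df, ("element", "concentration_mg_per_L"), path)
        raw = dict(zip(df["element"], df["concentration_mg_per_L"]))
    out = {}
    for el, v in raw.items():
        if el not in KNOWN_ELEMENTS:
            raise SchemaError(f"{path}: unknown element {el!r} in recipe")
        out[str(el)] = float(v)
    return out


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one pipeline run; round-trips losslessly via YAML."""

    solution_csv: str = ""
    tissue_csv: str = ""
    mass_log_csv: str = ""
    output_dir: str = "fertimass_out"
    recipe: str | None = None  # optional override of per-event supply rows
    capacity_volume_L: float = 4.0
    event_threshold_g: float = 50.0
    smooth_window: int = 3
    day_window_start: str = "07:00"
    day_window_end: str = "19:00"
    deviation_ndigits: int = 1
    contrast_family: str = "group_within_time"
    report_gg_epsilon: bool = True
    seed: int = 0
    _extra: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_extra")
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def content_hash(self) -> str:
        """Stable hash of the canonical serialized config (provenance)."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
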