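"""Shared data model and file formats for olfactometric proficiency tests.

The canonical in-memory container for measurement data is a tidy
:class:`pandas.DataFrame` with one row per olfactometric determination,
keyed by (test, participant, component, replicate) and carrying the dosed
mass concentration [µg/m³] and the measured odor concentration [ou_E/m³].
All concentrations refer to olfactometric normal conditions
(p = 1013.25 mbar, T = 293.15 K); no temperature/pressure conversion is
ever performed.  Statistics downstream are computed in log10 space; linear
values are derived on output only.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
from pydantic import BaseModel, Field, model_validator

#: Fixed CSV schema for measurement tables (UTF-8, '.' decimal separator).
MEASUREMENT_COLUMNS = (
    "test_id",
    "participant_id",
    "component",
    "replicate",
    "dosed_mass_conc_ug_m3",
    "measured_odor_conc_oue_m3",
)

#: Columns forming the unique key of a measurement row.
KEY_COLUMNS = ("test_id", "participant_id", "component", "replicate")


class SchemaError(ValueError):
    """The file does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A row violates a data-model invariant (non-positive value, duplicate key...)."""


class ComponentConfig(BaseModel):
    """Per-odorant scoring configuration.

    Parameters
    ----------
    component
        Odorant label (e.g. ``"NBU"`` for n-butanol, ``"AAC"`` amyl acetate,
        ``"ETX"`` aromatic-solvent mixture, ``"PIG"`` pig odor mixture,
        ``"RLI"`` (R)-(+)-limonene, ``"THT"`` tetrahydrothiophene).
    fixed_threshold
        Conventionally fixed odor threshold in µg/m³, if one exists.  For
        n-butanol EN 13725 defines c0 = 123 µg/m³; other odorants have no
        fixed value and use the consensus estimate instead.
    base_sigma
        Base proficiency-assessment criterion σ_k in log10 units (default
        0.10), applied unless the assigned-value uncertainty forces an
        adaptation.
    u_ck
        Relative standard uncertainty of the dosed mass concentration
        (dimensionless fraction; 0.0101 for the dosing rig used here).
    """

    component: str
    fixed_threshold: float | None = None
    base_sigma: float = 0.10
    u_ck: float = 0.0101

    @model_validator(mode="after")
    def _check(self) -> "ComponentConfig":
        if self.fixed_threshold is not None and not self.fixed_threshold > 0:
            raise ValueError("fixed_threshold must be > 0 when present")
        if not self.base_sigma > 0:
            raise ValueError("base_sigma must be > 0")
        if not (0 <= self.u_ck < 1):
            raise ValueError("u_ck must lie in [0, 1)")
        return self


@dataclasses.dataclass(frozen=True)
class OdorLevel:
    """A concentration ratio on the logarithmic 'odor level' scale.

    ``value_db`` is exactly ``10 * value_log10`` (decibel convention for
    odor levels).
    """

    value_log10: float

    @property
    def value_db(self) -> float:
        return 10.0 * self.value_log10

    @classmethod
    def from_db(cls, db: float) -> "OdorLevel":
        return cls(db / 10.0)


def _validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df.loc[:, list(MEASUREMENT_COLUMNS)].copy()
    df["test_id"] = df["test_id"].astype(str)
    df["participant_id"] = df["participant_id"].astype(str)
    df["component"] = df["component"].astype(str)
    try:
        df["replicate"] = df["replicate"].astype(int)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"replicate must be an integer: {exc}") from exc
    for col in ("dosed_mass_conc_ug_m3", "measured_odor_conc_oue_m3"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values <= 0)
        if bad.any():
            idx = int(df.index[bad][0])
            raise ValidationError(
                f"column {col!r} must be a positive number (log10 must be "
                f"defined); offending row index {idx}"
            )
        df[col] = values.astype(float)
    dup = df.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        key = tuple(df.loc[df.index[dup][0], list(KEY_COLUMNS)])
        raise ValidationError(f"duplicate measurement key {key}")
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement table from CSV.

    Returns a DataFrame with the columns of :data:`MEASUREMENT_COLUMNS`,
    row order preserved.  Raises :class:`SchemaError` for a malformed
    header and :class:`ValidationError` for rows violating invariants
    (non-positive concentrations, duplicate keys).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    return _validate_measurements(df)


def write_measurements(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table as CSV; round-trips losslessly at 15 s.f."""
    df = _validate_measurements(df)
    # pandas' default float formatting is the shortest round-trip repr,
    # so write/read is bit-exact
    df.to_csv(path, index=False)


def validate_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory measurement table (same checks as the reader)."""
    return _validate_measurements(df)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, BaseModel):
        return obj.model_dump()
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if hasattr(obj, "item") and not isinstance(obj, (str, bytes)):
        try:
            return obj.item()  # numpy scalars
        except Exception:
            pass
    return obj


def _format_section(name: str, content: Any) -> str:
    lines = [name, "-" * len(name)]
    if isinstance(content, Mapping):
        rows = [(str(k), v) for k, v in content.items()]
        width = max((len(k) for k, _ in rows), default=0)
        for k, v in rows:
            if isinstance(v, float):
                lines.append(f"{k:<{width}}  {v:.6g}")
            else:
                lines.append(f"{k:<{width}}  {v}")
    elif isinstance(content, list):
        for item in content:
            lines.append(f"- {item}")
    else:
        lines.append(str(content))
    return "\n".join(lines)


def format_report(results: Mapping[str, Any]) -> str:
    """Render a result bundle as a human-readable text table."""
    sections = [
        _format_section(name, _to_jsonable(content))
        for name, content in results.items()
    ]
    return "\n\n".join(sections) + "\n" if sections else "(empty report)\n"


def write_report(results: Mapping[str, Any], path: str | Path) -> None:
    """Write a result bundle as machine-readable JSON plus a text rendering.

    Numbers are serialized at full precision; display rounding is the text
    renderer's concern only.  The text twin is written next to ``path``
    with a ``.txt`` suffix.
    """
    path = Path(path)
    payload = _to_jsonable(dict(results))
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, allow_nan=False)
        fh.write("\n")
    path.with_suffix(".txt").write_text(format_report(results), encoding="utf-8")


def read_report(path: str | Path) -> dict[str, Any]:
    """Read back a JSON result bundle written by :func:`write_report`."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def measurements_from_records(records: Iterable[Mapping[str, Any]]) -> pd.DataFrame:
    """Build a validated measurement table from an iterable of row mappings."""
    return _validate_measurements(pd.DataFrame.from_records(list(records)))
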