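"""CSV / YAML readers and writers plus the JSON report.

Object tables are CSV with header
``id,x_cm,y_cm,visible_width_cm,visible_depth_cm[,placed_at_min,placement_rank]``
(UTF-8, '.' decimal separator); geometry configs are flat YAML with the
court-frame fields, lengths in cm and angles in degrees.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .geometry import CourtGeometry, CourtObject, GeometryError

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_objects",
    "write_objects",
    "write_placements",
    "objects_to_dataframe",
    "objects_from_dataframe",
    "read_geometry",
    "write_geometry",
    "write_report",
    "file_digest",
]

REQUIRED_COLUMNS = ("id", "x_cm", "y_cm", "visible_width_cm", "visible_depth_cm")
OPTIONAL_COLUMNS = ("placed_at_min", "placement_rank")


class SchemaError(ValueError):
    """Input file violates the declared schema (names the row and column)."""


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Analysis-wide configuration knobs with their defaults."""

    geometry_path: str | None = None
    angle_convention: str = "exact"
    sd_convention: str = "sample"
    n_permutations: int = 20_000
    seed: int = 0
    alpha: float = 0.05
    fov_handling: str = "exclude_and_log"

    def __post_init__(self) -> None:
        if self.angle_convention not in ("exact", "small_angle"):
            raise ValueError("angle_convention must be 'exact' or 'small_angle'")
        if self.sd_convention not in ("sample", "population"):
            raise ValueError("sd_convention must be 'sample' or 'population'")
        if self.fov_handling not in ("exclude_and_log", "error"):
            raise ValueError("fov_handling must be 'exclude_and_log' or 'error'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


def objects_from_dataframe(df: pd.DataFrame, *, source: str = "<dataframe>") -> list[CourtObject]:
    """Validate a table row by row and build CourtObject records."""
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing columns {missing}")
    ids = df["id"].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        has_rank = "placement_rank" in df.columns and df["placement_rank"].notna().any()
        if not has_rank:
            row = int(dup.index[0]) + 2  # header is line 1
            raise SchemaError(
                f"{source}: duplicate id {dup.iloc[0]!r} at row {row} (column 'id')"
            )
    objs: list[CourtObject] = []
    for pos, (_, rec) in enumerate(df.iterrows()):
        row = pos + 2
        vals: dict[str, float] = {}
        for col in REQUIRED_COLUMNS[1:]:
            try:
                vals[col] = float(rec[col])
            except (TypeError, ValueError):
                raise SchemaError(
                    f"{source}: non-numeric value {rec[col]!r} at row {row}, "
                    f"column {col!r}"
                ) from None
            if not np.isfinite(vals[col]):
                raise SchemaError(
                    f"{source}: non-finite value at row {row}, column {col!r}"
                )
        for col in ("visible_width_cm", "visible_depth_cm"):
            if vals[col] <= 0:
                raise SchemaError(
                    f"{source}: non-positive extent at row {row}, column {col!r}"
                )
        placed_at = None
        rank = None
        if "placed_at_min" in df.columns and pd.notna(rec["placed_at_min"]):
            placed_at = float(rec["placed_at_min"])
        if "placement_rank" in df.columns and pd.notna(rec["placement_rank"]):
            rank = int(rec["placement_rank"])
        try:
            objs.append(
                CourtObject(
                    id=str(rec["id"]),
                    x=vals["x_cm"],
                    y=vals["y_cm"],
                    visible_width=vals["visible_width_cm"],
                    visible_depth=vals["visible_depth_cm"],
                    placed_at=placed_at,
                    placement_rank=rank,
                )
            )
        except GeometryError as exc:
            raise SchemaError(f"{source}: row {row}: {exc}") from None
    return objs


def read_objects(path: str | Path) -> list[CourtObject]:
    """Read and validate an object-table CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"{path}: unreadable CSV ({exc})") from None
    return objects_from_dataframe(df, source=str(path))


def objects_to_dataframe(objects: Sequence[CourtObject]) -> pd.DataFrame:
    rows: list[dict[str, Any]] = []
    any_time = any(o.placed_at is not None or o.placement_rank is not None
                   for o in objects)
    for o in objects:
        row: dict[str, Any] = {
            "id": o.id,
            "x_cm": o.x,
            "y_cm": o.y,
            "visible_width_cm": o.visible_width,
            "visible_depth_cm": o.visible_depth,
        }
        if any_time:
            row["placed_at_min"] = o.placed_at
            row["placement_rank"] = o.placement_rank
        rows.append(row)
    return pd.DataFrame(rows)


def write_objects(objects: Sequence[CourtObject], path: str | Path) -> None:
    """Write an object table (full float precision, round-trip safe)."""
    objects_to_dataframe(objects).to_csv(path, index=False, float_format="%.17g")


def write_placements(placements: Sequence[CourtObject], path: str | Path) -> None:
    """Write a placement-event table (always includes the timing columns)."""
    df = objects_to_dataframe(placements)
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    df.to_csv(path, index=False, float_format="%.17g")


_GEOM_FIELDS = (
    "viewer_xy", "entrance_xy", "court_length", "court_width",
    "fov_half_angle", "eye_height",
)


def read_geometry(path: str | Path) -> CourtGeometry:
    """Read a court-geometry YAML config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: invalid YAML ({exc})") from None
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: geometry config must be a mapping")
    unknown = set(raw) - set(_GEOM_FIELDS)
    if unknown:
        raise SchemaError(f"{path}: unknown geometry keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, val in raw.items():
        if key in ("viewer_xy", "entrance_xy"):
            if not (isinstance(val, (list, tuple)) and len(val) == 2):
                raise SchemaError(f"{path}: {key} must be a 2-element list")
            kwargs[key] = (float(val[0]), float(val[1]))
        else:
            kwargs[key] = float(val)
    try:
        return CourtGeometry(**kwargs)
    except GeometryError as exc:
        raise SchemaError(f"{path}: {exc}") from None


def write_geometry(geom: CourtGeometry, path: str | Path) -> None:
    data = {
        "viewer_xy": list(geom.viewer_xy),
        "entrance_xy": list(geom.entrance_xy),
        "court_length": geom.court_length,
        "court_width": geom.court_width,
        "fov_half_angle": geom.fov_half_angle,
        "eye_height": geom.eye_height,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(results: Any, path: str | Path, *, config: RunConfig | None = None) -> dict:
    """Serialise an analysis result (dataclasses, arrays) to a JSON report.

    The report embeds the configuration echo and the package version so any
    run can be reproduced from the report alone.
    """
    from . import __version__

    payload = {
        "software": {"package": "bowercourt", "version": __version__},
        "config": _jsonable(config) if config is not None else None,
        "results": _jsonable(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
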