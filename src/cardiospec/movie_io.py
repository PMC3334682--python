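"""Readers and writers for every on-disk artifact.

Formats
-------
* movies: multi-page grayscale TIFF (written as 16-bit unsigned, intensities
  clipped to [0, 65535]) or a directory of lexicographically ordered
  single-frame images.
* ROI sets: JSON, schema documented in :func:`write_rois`.
* trace tables: tab-delimited ``.dat`` or comma-delimited ``.csv``, header row
  ``time_s`` followed by one ROI id per intensity column.
* reports / ground truth: JSON with sorted keys (byte-deterministic).

The frame rate is never stored in TIFF tags; it travels as an explicit
argument or sidecar field, so every reader that needs it takes ``fs_hz``.

Pixel coordinates are 0-based ``(row, col)`` with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, RoiValidationError

__all__ = [
    "MovieStack",
    "IntensityTrace",
    "RoiSpec",
    "TraceTable",
    "read_movie",
    "write_movie",
    "read_rois",
    "write_rois",
    "read_trace_table",
    "write_trace_table",
    "write_json_report",
]

_IMAGE_EXTENSIONS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}


@dataclass
class MovieStack:
    """Ordered grayscale frames plus the acquisition frame rate.

    ``frames`` has shape ``(n_frames, rows, cols)``; intensities are in
    arbitrary units (float while synthetic, integer after disk round-trip).
    """

    frames: np.ndarray
    fs_hz: float
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise FormatError(
                f"a movie needs >= 2 frames of equal shape, got array of shape {self.frames.shape}"
            )
        if not self.fs_hz > 0:
            raise FormatError(f"fs_hz must be positive, got {self.fs_hz}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return int(self.frames.shape[1]), int(self.frames.shape[2])

    @property
    def times(self) -> np.ndarray:
        """Frame timestamps, first frame at t = 0."""
        return np.arange(self.n_frames) / self.fs_hz


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame mean intensity of one ROI (or any scalar time series)."""

    values: np.ndarray
    fs_hz: float
    roi_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise FormatError("an intensity trace must be one-dimensional")
        if not self.fs_hz > 0:
            raise FormatError(f"fs_hz must be positive, got {self.fs_hz}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs_hz

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs_hz


@dataclass(frozen=True)
class RoiSpec:
    """A spatial region: circle (center + radius) or polygon (vertex list).

    Coordinates are 0-based ``(row, col)`` pixel positions; they may be
    fractional.
    """

    id: str
    kind: str
    center: tuple[float, float] | None = None
    radius: float | None = None
    vertices: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.id, str) or not self.id:
            raise RoiValidationError("field 'id': must be a non-empty string")
        if self.kind == "circle":
            if self.center is None or len(self.center) != 2:
                raise RoiValidationError(
                    f"roi {self.id!r}, field 'center': circle needs a (row, col) pair"
                )
            if self.radius is None or not self.radius > 0:
                raise RoiValidationError(
                    f"roi {self.id!r}, field 'radius': must be > 0, got {self.radius}"
                )
            object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))
            object.__setattr__(self, "radius", float(self.radius))
        elif self.kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise RoiValidationError(
                    f"roi {self.id!r}, field 'vertices': polygon needs >= 3 vertices"
                )
            verts = tuple((float(r), float(c)) for r, c in self.vertices)
            arr = np.asarray(verts)
            # collinearity: all cross products of successive edge vectors vanish
            e = np.diff(arr, axis=0)
            crosses = e[:-1, 0] * e[1:, 1] - e[:-1, 1] * e[1:, 0]
            closing = arr[0] - arr[-1]
            crosses = np.append(crosses, e[-1, 0] * closing[1] - e[-1, 1] * closing[0])
            scale = float(np.abs(arr).max()) + 1.0
            if np.all(np.abs(crosses) <= 1e-12 * scale * scale):
                raise RoiValidationError(
                    f"roi {self.id!r}, field 'vertices': vertices are collinear"
                )
            object.__setattr__(self, "vertices", verts)
        else:
            raise RoiValidationError(
                f"roi {self.id!r}, field 'kind': unknown shape kind {self.kind!r}"
            )

    def to_dict(self) -> dict:
        if self.kind == "circle":
            return {
                "id": self.id,
                "kind": "circle",
                "center": list(self.center),
                "radius": self.radius,
            }
        return {
            "id": self.id,
            "kind": "polygon",
            "vertices": [list(v) for v in self.vertices],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RoiSpec":
        if not isinstance(d, Mapping):
            raise RoiValidationError("each ROI must be a JSON object")
        kind = d.get("kind")
        if kind == "circle":
            return cls(
                id=d.get("id", ""),
                kind="circle",
                center=tuple(d["center"]) if "center" in d else None,
                radius=d.get("radius"),
            )
        if kind == "polygon":
            verts = d.get("vertices")
            return cls(
                id=d.get("id", ""),
                kind="polygon",
                vertices=tuple(tuple(v) for v in verts) if verts is not None else None,
            )
        raise RoiValidationError(
            f"roi {d.get('id', '?')!r}, field 'kind': unknown shape kind {kind!r}"
        )


class TraceTable:
    """Time column (seconds) plus one mean-intensity column per ROI.

    The time base must be uniform; ``fs_hz`` is 1 / (mean time step) and is
    validated against the column to a relative tolerance of 1e-6.
    """

    def __init__(self, data: pd.DataFrame, fs_hz: float | None = None):
        if "time_s" not in data.columns or list(data.columns)[0] != "time_s":
            raise FormatError("first column must be 'time_s'")
        if len(data) < 2:
            raise FormatError("a trace table needs >= 2 rows")
        t = data["time_s"].to_numpy(dtype=float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("time_s must be strictly increasing")
        mean_dt = float(dt.mean())
        if float(np.abs(dt - mean_dt).max()) > 1e-6 * mean_dt:
            raise FormatError(
                "time_s step is not uniform (relative deviation > 1e-6)"
            )
        inferred = 1.0 / mean_dt
        if fs_hz is not None and not math.isclose(fs_hz, inferred, rel_tol=1e-6):
            raise FormatError(
                f"fs_hz {fs_hz} inconsistent with time column (inferred {inferred})"
            )
        self.data = data.reset_index(drop=True)
        self.fs_hz = float(fs_hz if fs_hz is not None else inferred)

    @classmethod
    def from_traces(
        cls, time_s: np.ndarray, traces: Mapping[str, np.ndarray], fs_hz: float | None = None
    ) -> "TraceTable":
        df = pd.DataFrame({"time_s": np.asarray(time_s, dtype=float)})
        for roi_id, vals in traces.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != df["time_s"].shape:
                raise FormatError(f"column {roi_id!r} length differs from time column")
            df[roi_id] = vals
        return cls(df, fs_hz=fs_hz)

    @property
    def roi_ids(self) -> list[str]:
        return [c for c in self.data.columns if c != "time_s"]

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def times(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(dtype=float)

    def trace(self, roi_id: str) -> IntensityTrace:
        if roi_id not in self.data.columns:
            raise KeyError(f"no ROI column {roi_id!r}")
        return IntensityTrace(
            self.data[roi_id].to_numpy(dtype=float), self.fs_hz, roi_id=roi_id
        )

    def slice_time(self, start_s: float, end_s: float) -> "TraceTable":
        """Rows with start_s <= time_s < end_s, time re-zeroed to the slice."""
        t = self.times
        sel = (t >= start_s - 1e-9) & (t < end_s - 1e-9)
        sub = self.data.loc[sel].copy()
        sub["time_s"] = sub["time_s"] - float(sub["time_s"].iloc[0])
        return TraceTable(sub, fs_hz=self.fs_hz)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TraceTable)
            and math.isclose(self.fs_hz, other.fs_hz, rel_tol=1e-9)
            and self.data.equals(other.data)
        )


# ---------------------------------------------------------------------------
# movies


def read_movie(path: str | Path, fs_hz: float) -> MovieStack:
    """Load a multi-page TIFF or a directory of single-frame images.

    Directory frames are taken in lexicographic filename order.  Intensities
    of integer inputs are preserved losslessly.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTENSIONS
        )
        if len(files) < 2:
            raise FormatError(f"directory {path} holds fewer than 2 image files")
        frames = []
        for p in files:
            try:
                arr = iio.imread(p)
            except Exception as exc:  # pragma: no cover - backend specific
                raise OSError(f"cannot read frame {p}: {exc}") from exc
            if arr.ndim != 2:
                raise FormatError(f"frame {p.name} is not grayscale (shape {arr.shape})")
            frames.append(arr)
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
        return MovieStack(np.stack(frames), fs_hz, source=str(path))
    try:
        with tifffile.TiffFile(path) as tf:
            frames = [page.asarray() for page in tf.pages]
    except (FileNotFoundError, PermissionError):
        raise
    except Exception as exc:
        raise OSError(f"cannot read movie {path}: {exc}") from exc
    if len(frames) < 2:
        raise FormatError(f"{path} holds fewer than 2 frames")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame shapes in {path}: {sorted(shapes)}")
    for f in frames:
        if f.ndim != 2:
            raise FormatError(f"{path} frames are not grayscale (shape {f.shape})")
    return MovieStack(np.stack(frames), fs_hz, source=str(path))


def write_movie(stack: MovieStack, path: str | Path) -> None:
    """Write as 16-bit unsigned multi-page TIFF, clipping to [0, 65535]."""
    arr = np.clip(np.rint(np.asarray(stack.frames, dtype=float)), 0, 65535).astype(
        np.uint16
    )
    tifffile.imwrite(Path(path), arr, photometric="minisblack")


# ---------------------------------------------------------------------------
# ROIs

ROI_SCHEMA_VERSION = 1


def write_rois(rois: Sequence[RoiSpec], path: str | Path) -> None:
    """Write an ROI set as JSON.

    Schema::

        {"version": 1,
         "rois": [{"id": str, "kind": "circle",
                   "center": [row, col], "radius": float}
                  | {"id": str, "kind": "polygon",
                     "vertices": [[row, col], ...]}]}
    """
    ids = [r.id for r in rois]
    if len(set(ids)) != len(ids):
        raise RoiValidationError("field 'id': duplicate ROI ids in set")
    doc = {"version": ROI_SCHEMA_VERSION, "rois": [r.to_dict() for r in rois]}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_rois(path: str | Path) -> list[RoiSpec]:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(doc, Mapping) or "rois" not in doc:
        raise RoiValidationError("field 'rois': missing top-level ROI list")
    rois = [RoiSpec.from_dict(d) for d in doc["rois"]]
    ids = [r.id for r in rois]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise RoiValidationError(f"field 'id': duplicate ROI ids {dup}")
    return rois


# ---------------------------------------------------------------------------
# trace tables

_DIALECT_SEP = {"dat": "\t", "csv": ","}


def _dialect_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in _DIALECT_SEP:
            raise FormatError(f"unknown dialect {dialect!r}; use 'dat' or 'csv'")
        return dialect
    return "csv" if path.suffix.lower() == ".csv" else "dat"


def write_trace_table(table: TraceTable, path: str | Path, dialect: str | None = None) -> None:
    """Write tab-delimited ``.dat`` or RFC-4180 ``.csv``.

    Floats are printed with %.17g so numeric round-trips are exact.
    """
    path = Path(path)
    sep = _DIALECT_SEP[_dialect_for(path, dialect)]
    table.data.to_csv(path, sep=sep, index=False, float_format="%.17g", lineterminator="\n")


def read_trace_table(path: str | Path, dialect: str | None = None) -> TraceTable:
    path = Path(path)
    sep = _DIALECT_SEP[_dialect_for(path, dialect)]
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return TraceTable(df)


def write_json_report(obj, path: str | Path) -> None:
    """Deterministic JSON writer used for reports and ground-truth sidecars."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
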