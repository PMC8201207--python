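"""Reading and writing radiometric temperature matrices.

A capture pairs a calibrated temperature grid (default 240 x 320, degrees
Celsius) with a visible-light photograph taken by the same bifocal camera.
Temperature grids travel as plain-text numeric tables: permissive on read
(whitespace or comma delimiters, optional ``#`` metadata header), canonical
on write (tab-delimited, shortest round-tripping float representation).

Coordinates are row-major and 0-based with the origin at the top-left
corner; ``(row, col)`` is used everywhere in this package.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import FormatError, ParameterError, ParseError, ValidationError

#: Radiometric range of the supported microbolometer array, in Celsius.
SENSOR_MIN_C = -20.0
SENSOR_MAX_C = 600.0

#: Default infrared grid shape (rows, cols).
IR_SHAPE = (240, 320)
#: Default visible-light shape (rows, cols).
VISIBLE_SHAPE = (480, 640)

#: Defaults used when capture metadata is absent: room temperature of the
#: controlled acquisition environment and the emissivity of human skin.
DEFAULT_ROOM_TEMP_C = 20.0
DEFAULT_EMISSIVITY = 0.98


@dataclass(frozen=True)
class TemperatureFrame:
    """A calibrated H x W grid of temperatures plus capture metadata.

    Parameters
    ----------
    values
        2-D float array of temperatures in degrees Celsius.
    frame_id
        Free-form identifier of the capture.
    angle_deg
        Acquisition angle in degrees relative to the normal (frontal)
        viewpoint, in ``[0, 360)``.
    room_temp_c
        Ambient temperature ``Ta`` during acquisition.
    emissivity
        Surface emissivity assumed by the camera, in ``(0, 1]``.
    calibration_offset_c
        Scalar calibration correction already applied to ``values``.
    """

    values: np.ndarray
    frame_id: str = ""
    angle_deg: float = 0.0
    room_temp_c: float = DEFAULT_ROOM_TEMP_C
    emissivity: float = DEFAULT_EMISSIVITY
    calibration_offset_c: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError(
                f"temperature grid must be at least 2x2, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError("temperature grid contains non-finite values")
        if arr.min() < SENSOR_MIN_C or arr.max() > SENSOR_MAX_C:
            raise ValidationError(
                f"temperatures outside sensor range [{SENSOR_MIN_C}, {SENSOR_MAX_C}] C: "
                f"grid spans [{arr.min():.2f}, {arr.max():.2f}]"
            )
        if not 0.0 <= float(self.angle_deg) < 360.0:
            raise ValidationError(f"angle_deg must lie in [0, 360), got {self.angle_deg}")
        if not 0.0 < float(self.emissivity) <= 1.0:
            raise ValidationError(f"emissivity must lie in (0, 1], got {self.emissivity}")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, **meta) -> "TemperatureFrame":
        """Return a copy with replaced grid (and optionally metadata)."""
        kwargs = dataclasses.asdict(self)
        kwargs["values"] = values
        kwargs.update(meta)
        return TemperatureFrame(**kwargs)


@dataclass
class CaptureSet:
    """An ordered angular sweep of IR frames with paired visible photographs.

    The acquisition protocol rotates the camera around the subject in fixed
    angular steps (default 12 degrees, 15 captures); frames must be supplied
    in sweep order with strictly monotone angles.
    """

    frames: list[TemperatureFrame]
    visibles: list[np.ndarray] = field(default_factory=list)
    angular_step_deg: float = 12.0

    def __post_init__(self) -> None:
        if self.visibles and len(self.visibles) != len(self.frames):
            raise ValidationError(
                f"{len(self.frames)} frames but {len(self.visibles)} visible images"
            )
        angles = [f.angle_deg for f in self.frames]
        if any(b <= a for a, b in zip(angles, angles[1:])):
            raise ValidationError(f"sweep angles must be strictly monotone, got {angles}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def angles_deg(self) -> list[float]:
        return [f.angle_deg for f in self.frames]


def _parse_header(line: str) -> dict:
    """Parse a ``# key=value key=value`` metadata header line."""
    meta: dict = {}
    for token in line.lstrip("#").split():
        if "=" not in token:
            continue
        key, _, raw = token.partition("=")
        try:
            meta[key] = float(raw)
        except ValueError:
            meta[key] = raw
    return meta


_META_FIELDS = ("frame_id", "angle_deg", "room_temp_c", "emissivity", "calibration_offset_c")


def read_temperature_matrix(path, metadata: Mapping | None = None) -> TemperatureFrame:
    """Read a plain-text temperature grid into a :class:`TemperatureFrame`.

    Accepts whitespace- or comma-delimited numeric rows of constant length,
    optionally preceded by one ``#`` header line carrying ``key=value``
    metadata.  Explicit ``metadata`` entries override the header.

    Raises
    ------
    FormatError
        If rows have differing lengths or the file holds no data.
    ParseError
        If a token is not numeric; the message names the (row, col) cell.
    ValidationError
        If a value lies outside the sensor range.
    """
    header_meta: dict = {}
    rows: list[list[float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                if not rows:
                    header_meta.update(_parse_header(stripped))
                continue
            tokens = stripped.replace(",", " ").split()
            row = []
            for col, tok in enumerate(tokens):
                try:
                    row.append(float(tok))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric token {tok!r} at row {len(rows)}, col {col}"
                    ) from None
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no numeric data found")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged grid, row {i} has {len(row)} columns, expected {width}"
            )
    meta = {k: v for k, v in header_meta.items() if k in _META_FIELDS}
    if metadata:
        meta.update({k: v for k, v in metadata.items() if k in _META_FIELDS})
    if "frame_id" in meta:
        meta["frame_id"] = str(meta["frame_id"])
    return TemperatureFrame(values=np.array(rows, dtype=float), **meta)


def write_temperature_matrix(frame: TemperatureFrame, path, include_metadata: bool = False) -> None:
    """Write a frame as a tab-delimited text grid.

    Each value is written with :func:`repr`-style shortest representation so
    that a read of the written file reproduces the grid bit-exactly.
    """
    lines = []
    if include_metadata:
        lines.append(
            "# "
            + " ".join(
                f"{k}={getattr(frame, k)}" for k in _META_FIELDS if getattr(frame, k) != ""
            )
        )
    for row in frame.values:
        lines.append("\t".join(repr(float(v)) for v in row))
    tmp = os.fspath(path)
    with open(tmp, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def apply_calibration_offset(frame: TemperatureFrame, delta_c: float) -> TemperatureFrame:
    """Shift every cell by the scalar calibration correction ``delta_c``.

    The offset is accumulated in ``calibration_offset_c``; the input frame is
    left untouched.  Successive offsets compose additively, so applying
    ``+d`` then ``-d`` restores the original grid exactly.
    """
    if not np.isfinite(delta_c):
        raise ParameterError(f"calibration offset must be finite, got {delta_c}")
    return frame.with_values(
        frame.values + float(delta_c),
        calibration_offset_c=frame.calibration_offset_c + float(delta_c),
    )


def as_uint8_rgb(image: np.ndarray | Sequence) -> np.ndarray:
    """Validate/coerce an array to H x W x 3 uint8 RGB."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValidationError(f"expected H x W x 3 RGB image, got shape {arr.shape}")
    return arr.astype(np.uint8, copy=False)
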