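"""Reading, writing and validating tabular gaze recordings.

Screen-mounted ("remote") eye trackers export one row per sample: a
timestamp, a gaze point on the screen, and a device validity flag. This
module normalises such delimited-text exports into :class:`GazeRecording`,
the container the rest of the pipeline operates on, and writes them back
losslessly.

Conventions
-----------
* Coordinate origin at the top-left of the screen, x rightward, y downward,
  in pixels (or in [0, 1] x [0, 1] when the geometry is flagged normalised).
* Screen bounds are inclusive: a gaze point exactly on the edge counts as
  on-screen.
* A sample is *invalid* if the device flagged it so **or** its coordinates
  are missing/non-finite; the two are not distinguished downstream.
* Timestamps are taken as ground truth and must be strictly increasing; no
  resampling happens on read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "GazeSample",
    "GazeRecording",
    "GazeTableFormatError",
    "GazeValidationError",
    "read_gaze_table",
    "write_gaze_table",
    "on_screen",
    "DEFAULT_DIALECT",
]


class GazeTableFormatError(ValueError):
    """A gaze table file does not have the expected columns/shape."""


class GazeValidationError(ValueError):
    """A gaze table parsed but violates a recording invariant."""


#: Default column mapping for delimited gaze exports. ``delimiter`` of
#: ``None`` means "infer from extension" (.csv -> comma, else tab).
DEFAULT_DIALECT: Mapping[str, str | None] = {
    "time": "time_ms",
    "x": "gaze_x",
    "y": "gaze_y",
    "validity": "validity",
    "delimiter": None,
}

_TRUTHY = {"valid", "1", "true", "yes", "1.0"}
_FALSY = {"invalid", "0", "false", "no", "", "nan", "0.0"}


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical screen extent gaze coordinates are measured against.

    Parameters
    ----------
    width, height
        Screen extent in pixels, or 1.0 each when ``normalized``.
    normalized
        True when coordinates are already scaled to [0, 1] x [0, 1].
    """

    width: float
    height: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"screen dimensions must be positive, got {self.width}x{self.height}"
            )


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample: time in ms from recording start plus gaze point."""

    t: float
    x: float
    y: float
    valid: bool

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"sample time must be >= 0, got {self.t}")
        if self.valid and not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("a valid sample must have finite coordinates")


class GazeRecording:
    """Ordered gaze samples for one participant x one test variant.

    Samples are stored as numpy arrays (``t`` in ms, ``x``, ``y``, boolean
    ``valid``) so that long 60 Hz recordings stay cheap to score; the
    :attr:`samples` iterator exposes them as :class:`GazeSample` objects for
    convenience.

    Parameters
    ----------
    participant_id
        Opaque participant label.
    variant
        Test variant label, normally ``"standard"`` or ``"cartoon"``.
    t, x, y, valid
        Per-sample arrays. ``t`` must be strictly increasing.
    screen
        Geometry the coordinates refer to.
    rate
        Nominal device sampling rate in Hz (default 60).
    interruption_t
        Optional time in ms after which the test was interrupted and no
        data exists. When set, no sample may lie at or past it.
    """

    def __init__(
        self,
        participant_id: str,
        variant: str,
        t: Sequence[float],
        x: Sequence[float],
        y: Sequence[float],
        valid: Sequence[bool],
        screen: ScreenGeometry,
        rate: float = 60.0,
        interruption_t: float | None = None,
    ) -> None:
        if rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {rate}")
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        valid = np.asarray(valid, dtype=bool)
        if not (t.shape == x.shape == y.shape == valid.shape):
            raise ValueError("sample arrays must share one length")
        if t.size and np.any(t < 0):
            raise GazeValidationError("timestamps must be non-negative")
        if t.size > 1:
            bad = np.nonzero(np.diff(t) <= 0)[0]
            if bad.size:
                i = int(bad[0]) + 1
                raise GazeValidationError(
                    f"timestamps must be strictly increasing; row {i} "
                    f"(t={t[i]!r}) does not follow t={t[i - 1]!r}"
                )
        # missing/non-finite coordinates are treated as invalid samples
        valid = valid & np.isfinite(x) & np.isfinite(y)
        if interruption_t is not None and t.size and t[-1] >= interruption_t:
            raise GazeValidationError(
                f"sample at t={t[-1]} lies past interruption_t={interruption_t}"
            )
        self.participant_id = participant_id
        self.variant = variant
        self.t = t
        self.x = x
        self.y = y
        self.valid = valid
        self.screen = screen
        self.rate = float(rate)
        self.interruption_t = interruption_t
        self._on_screen: np.ndarray | None = None

    @classmethod
    def from_samples(
        cls,
        participant_id: str,
        variant: str,
        samples: Sequence[GazeSample],
        screen: ScreenGeometry,
        rate: float = 60.0,
        interruption_t: float | None = None,
    ) -> "GazeRecording":
        return cls(
            participant_id,
            variant,
            [s.t for s in samples],
            [s.x for s in samples],
            [s.y for s in samples],
            [s.valid for s in samples],
            screen,
            rate=rate,
            interruption_t=interruption_t,
        )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def n_samples(self) -> int:
        return len(self)

    @property
    def samples(self) -> Iterator[GazeSample]:
        for i in range(len(self)):
            yield self.sample(i)

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            float(self.t[i]), float(self.x[i]), float(self.y[i]), bool(self.valid[i])
        )

    def on_screen_mask(self) -> np.ndarray:
        """Boolean mask: sample is valid and inside the (inclusive) bounds."""
        if self._on_screen is None:
            self._on_screen = _on_screen_mask(self.x, self.y, self.valid, self.screen)
        return self._on_screen

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"GazeRecording({self.participant_id!r}, {self.variant!r}, "
            f"n={len(self)}, rate={self.rate} Hz)"
        )


def _on_screen_mask(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray, screen: ScreenGeometry
) -> np.ndarray:
    w = 1.0 if screen.normalized else screen.width
    h = 1.0 if screen.normalized else screen.height
    with np.errstate(invalid="ignore"):
        inside = (x >= 0) & (x <= w) & (y >= 0) & (y <= h)
    return valid & np.nan_to_num(inside, nan=False)


def on_screen(sample: GazeSample, screen: ScreenGeometry) -> bool:
    """True iff the sample is valid and its gaze point lies inside the screen.

    Bounds are inclusive: (0, 0) and (width, height) are on-screen. Invalid
    samples are never on-screen regardless of coordinates.
    """
    if not sample.valid:
        return False
    w = 1.0 if screen.normalized else screen.width
    h = 1.0 if screen.normalized else screen.height
    return bool(0 <= sample.x <= w and 0 <= sample.y <= h)


def _resolve_delimiter(path: str, dialect: Mapping[str, str | None]) -> str:
    delim = dialect.get("delimiter")
    if delim:
        return str(delim)
    return "," if str(path).lower().endswith(".csv") else "\t"


def _parse_floats(col: pd.Series) -> np.ndarray:
    """Exact (correctly rounded) float parsing; unparsable cells become NaN.

    Python's ``float`` is used per cell because pandas' fast converter is
    not correctly rounded, which would break bit-for-bit round-trips.
    """
    out = np.empty(len(col), dtype=float)
    for i, v in enumerate(col):
        s = str(v).strip()
        try:
            out[i] = float(s) if s else np.nan
        except ValueError:
            out[i] = np.nan
    return out


def _parse_validity(col: pd.Series, path: str) -> np.ndarray:
    vals = col.astype(str).str.strip().str.lower()
    out = np.empty(len(vals), dtype=bool)
    for i, v in enumerate(vals):
        if v in _TRUTHY:
            out[i] = True
        elif v in _FALSY:
            out[i] = False
        else:
            raise GazeTableFormatError(
                f"{path}: unrecognised validity value {v!r} in row {i}"
            )
    return out


def read_gaze_table(
    path: str,
    screen: ScreenGeometry,
    dialect: Mapping[str, str | None] | None = None,
    participant_id: str = "unknown",
    variant: str = "unknown",
    rate: float = 60.0,
    interruption_t: float | None = None,
) -> GazeRecording:
    """Read a delimited gaze table into a :class:`GazeRecording`.

    Rows with unparsable coordinates become invalid samples rather than
    being dropped, so the sample grid the device delivered is preserved.

    Raises
    ------
    GazeTableFormatError
        If a required column is missing or a validity value is unparsable.
    GazeValidationError
        If timestamps are not strictly increasing (the first offending row
        is named).
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = _resolve_delimiter(path, d)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [k for k in ("time", "x", "y", "validity") if d[k] not in df.columns]
    if missing:
        names = ", ".join(str(d[k]) for k in missing)
        raise GazeTableFormatError(
            f"{path}: missing required column(s) {names}; found {list(df.columns)}"
        )
    t = _parse_floats(df[d["time"]])
    if np.any(~np.isfinite(t)):
        i = int(np.nonzero(~np.isfinite(t))[0][0])
        raise GazeValidationError(f"{path}: unparsable timestamp in row {i}")
    x = _parse_floats(df[d["x"]])
    y = _parse_floats(df[d["y"]])
    valid = _parse_validity(df[d["validity"]], path)
    return GazeRecording(
        participant_id,
        variant,
        t,
        x,
        y,
        valid,
        screen,
        rate=rate,
        interruption_t=interruption_t,
    )


def write_gaze_table(
    rec: GazeRecording,
    path: str,
    dialect: Mapping[str, str | None] | None = None,
) -> None:
    """Write a recording as a delimited gaze table.

    Values are printed with Python's shortest round-trip float repr, so
    reading the file back reproduces timestamps and coordinates exactly.
    Coordinates are written as-is (off-screen values are not clipped);
    invalid samples get empty coordinate cells.
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    sep = _resolve_delimiter(path, d)

    def fmt(v: float) -> str:
        return "" if not math.isfinite(v) else repr(float(v))

    df = pd.DataFrame(
        {
            d["time"]: [repr(float(v)) for v in rec.t],
            d["x"]: [fmt(v) for v in rec.x],
            d["y"]: [fmt(v) for v in rec.y],
            d["validity"]: np.where(rec.valid, "valid", "invalid"),
        }
    )
    df.to_csv(path, sep=sep, index=False)
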