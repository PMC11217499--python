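"""Localization-table data model and I/O.

A localization table is the universal input of SMLM cluster analysis: one
row per detected single-molecule event with the camera frame it appeared
in, its fitted 2D position, and optionally the fitted localization
uncertainty and a colour-channel label.

Coordinate convention: continuous coordinates with the origin at the image
top-left; pixel (row i, col j) covers the half-open square
[j*p, (j+1)*p) x [i*p, (i+1)*p) where p is the pixel size.  All interval
membership in this package (extents, ROIs, pixel bins) is half-open,
``min <= v < max``, which removes boundary double-counting.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ParseError",
    "Dialect",
    "DIALECTS",
    "LocalizationTable",
    "Snapshot",
    "read_localizations",
    "write_localizations",
    "split_snapshots",
    "crop_roi",
]


class FormatError(ValueError):
    """The file's column layout does not match the requested dialect."""


class ParseError(ValueError):
    """A data line could not be parsed; the message names the line."""


@dataclass(frozen=True)
class Dialect:
    """Header-name mapping for a localization CSV flavour.

    ``columns`` maps canonical field names (frame, x, y, uncertainty,
    channel) to the header names used in the file; fields absent from the
    mapping are treated as optional and absent.
    """

    name: str
    unit: str
    columns: Mapping[str, str]

    @property
    def mandatory(self) -> tuple[str, ...]:
        return ("frame", "x", "y")


#: Registry of known CSV dialects.  The default ("nm") mirrors common
#: localization-software exports; "pixel" is used by the simulators.
DIALECTS: dict[str, Dialect] = {
    "nm": Dialect(
        "nm",
        "nm",
        {
            "frame": "frame",
            "x": "x_nm",
            "y": "y_nm",
            "uncertainty": "uncertainty_nm",
            "channel": "channel",
        },
    ),
    "pixel": Dialect(
        "pixel",
        "pixel",
        {
            "frame": "frame",
            "x": "x_px",
            "y": "y_px",
            "uncertainty": "uncertainty_px",
            "channel": "channel",
        },
    ),
}

_CANONICAL = ("frame", "x", "y", "uncertainty", "channel")


@dataclass
class LocalizationTable:
    """Per-molecule 2D positions with frame/channel/uncertainty metadata.

    Parameters
    ----------
    data
        DataFrame with columns ``frame`` (positive int), ``x``, ``y``
        (float, in ``unit``), optionally ``uncertainty`` (positive float)
        and ``channel`` (str).  Extra columns are carried along untouched.
    unit
        "nm" for cell-style data, "pixel" for simulated data.
    extent
        ``(x_min, x_max, y_min, y_max)``; every record satisfies
        ``x_min <= x < x_max`` and likewise for y.
    """

    data: pd.DataFrame
    unit: str
    extent: tuple[float, float, float, float]
    source: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def x(self) -> np.ndarray:
        return self.data["x"].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.data["y"].to_numpy(float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates."""
        return np.column_stack([self.x, self.y])

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(int)

    @property
    def area(self) -> float:
        x0, x1, y0, y1 = self.extent
        return (x1 - x0) * (y1 - y0)

    def validate(self) -> None:
        for col in ("frame", "x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"table lacks mandatory column {col!r}")
        if self.unit not in ("nm", "pixel"):
            raise ValueError(f"unknown unit {self.unit!r}")
        x0, x1, y0, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate extent {self.extent}")
        if len(self.data):
            if (self.data["frame"] <= 0).any():
                raise ValueError("frames must be strictly positive")
            x, y = self.x, self.y
            if not (
                (x >= x0).all() and (x < x1).all() and (y >= y0).all() and (y < y1).all()
            ):
                raise ValueError("coordinates outside the table extent")
            if "uncertainty" in self.data.columns:
                u = self.data["uncertainty"].to_numpy(float)
                if (u[~np.isnan(u)] <= 0).any():
                    raise ValueError("uncertainties must be positive")

    def with_data(self, data: pd.DataFrame, **meta) -> "LocalizationTable":
        kw = dict(unit=self.unit, extent=self.extent, source=self.source, seed=self.seed)
        kw.update(meta)
        return LocalizationTable(data.reset_index(drop=True), **kw)


@dataclass
class Snapshot:
    """A localization table restricted to a contiguous frame window.

    A "snapshot" is a slice of the acquisition (e.g. 1000 frames) short
    enough that repeated blinking of one fluorophore is rare; each is
    analysed as an independent time point.
    """

    table: LocalizationTable
    first: int
    last: int
    partial: bool = False

    def __post_init__(self) -> None:
        if len(self.table):
            f = self.table.frames
            if f.min() < self.first or f.max() > self.last:
                raise ValueError("snapshot contains frames outside its window")

    @property
    def span(self) -> int:
        return self.last - self.first + 1


def _infer_extent(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    # Half-open upper bound: nudge past the observed maximum.
    if len(x) == 0:
        return (0.0, 1.0, 0.0, 1.0)
    return (
        float(x.min()),
        float(np.nextafter(x.max(), math.inf)),
        float(y.min()),
        float(np.nextafter(y.max(), math.inf)),
    )


def read_localizations(
    path: str | Path | io.IOBase,
    dialect: str | Dialect = "nm",
    extent: tuple[float, float, float, float] | None = None,
) -> LocalizationTable:
    """Read a localization CSV under the named dialect.

    Mandatory columns (frame, x, y) must be present under the dialect's
    header names; unknown extra columns are preserved verbatim.  Malformed
    numeric entries raise :class:`ParseError` naming the offending line
    (1-based, counting the header as line 1).
    """
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    rename = {v: k for k, v in dialect.columns.items() if v in raw.columns}
    for canon in dialect.mandatory:
        header = dialect.columns[canon]
        if header not in raw.columns:
            raise FormatError(
                f"missing mandatory column {header!r} (dialect {dialect.name!r})"
            )
    df = raw.rename(columns=rename)
    for col in ("frame", "x", "y", "uncertainty"):
        if col not in df.columns:
            continue
        values = df[col].to_numpy()
        try:
            # numpy's parser is correctly rounded, so written values
            # round-trip bit-identically (pandas' to_numeric is not).
            num = np.asarray(values, dtype=float)
        except (ValueError, TypeError):
            for i, v in enumerate(values):
                try:
                    if not (v is None or (isinstance(v, float) and math.isnan(v))):
                        float(v)
                except (ValueError, TypeError):
                    raise ParseError(
                        f"non-numeric value {v!r} in column {col!r} at line "
                        f"{i + 2}"  # +1 header, +1 one-based
                    ) from None
            raise  # pragma: no cover - unlocatable parse failure
        df[col] = num
    if len(df) and df["frame"].isna().any():
        line = int(df["frame"].isna().idxmax()) + 2
        raise ParseError(f"missing frame value at line {line}")
    if len(df):
        df["frame"] = df["frame"].astype(int)
    else:
        df = df.astype({c: float for c in ("x", "y") if c in df.columns})
        df["frame"] = df.get("frame", pd.Series(dtype=int)).astype(int)
    if extent is None:
        extent = _infer_extent(
            df["x"].to_numpy(float) if len(df) else np.empty(0),
            df["y"].to_numpy(float) if len(df) else np.empty(0),
        )
    src = getattr(path, "name", str(path))
    return LocalizationTable(df.reset_index(drop=True), dialect.unit, extent, source=src)


def write_localizations(
    table: LocalizationTable,
    path: str | Path | io.IOBase,
    dialect: str | Dialect | None = None,
) -> None:
    """Write a table as CSV at full float precision (round-trip exact).

    The dialect defaults to the one matching the table's unit.  Extra
    columns (e.g. a snapshot index, generator pool labels) are appended
    after the canonical ones.
    """
    if dialect is None:
        dialect = table.unit
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    out = table.data.copy()
    cols = [c for c in _CANONICAL if c in out.columns]
    cols += [c for c in out.columns if c not in _CANONICAL]
    out = out[cols]
    out = out.rename(columns={k: v for k, v in dialect.columns.items()})
    # pandas' default float formatting is repr(), the shortest string that
    # round-trips bit-identically.
    out.to_csv(path, index=False)


def split_snapshots(table: LocalizationTable, window: int) -> list[Snapshot]:
    """Split a table into consecutive frame windows of ``window`` frames.

    Windows cover frames 1..max(frame); the union of the snapshots'
    records equals the input records.  A final partial window is kept and
    flagged ``partial``.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if len(table) == 0:
        return []
    fmax = int(table.frames.max())
    n_windows = math.ceil(fmax / window)
    snaps: list[Snapshot] = []
    frames = table.data["frame"]
    for k in range(n_windows):
        first, last = k * window + 1, (k + 1) * window
        sub = table.data[(frames >= first) & (frames <= last)]
        partial = last > fmax
        snaps.append(Snapshot(table.with_data(sub), first, last, partial=partial))
    return snaps


def crop_roi(
    table: LocalizationTable, roi: tuple[float, float, float, float]
) -> LocalizationTable:
    """Restrict a table to a rectangular ROI ``(x0, x1, y0, y1)``.

    Membership is half-open (``x0 <= x < x1``); the output extent becomes
    the ROI.  The ROI must lie within the table extent.
    """
    x0, x1, y0, y1 = roi
    ex0, ex1, ey0, ey1 = table.extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate roi {roi}")
    if x0 < ex0 or x1 > ex1 or y0 < ey0 or y1 > ey1:
        raise ValueError(f"roi {roi} outside table extent {table.extent}")
    x, y = table.x, table.y
    keep = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    return table.with_data(table.data[keep], extent=(x0, x1, y0, y1))
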