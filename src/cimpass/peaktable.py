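"""Peak-list tables from cyclic ion-mobility acquisitions.

A multipass cIM-MS experiment is a *series* of acquisitions: the same sample
is measured repeatedly while the separation time (how long ions circulate in
the cyclic device before ejection) is stepped up. Vendor post-processing
exports one peak list per acquisition — a table of (m/z, drift bin or arrival
time, intensity) rows. This module reads those tables, converts drift bins to
milliseconds, and groups the tables into a :class:`SeparationSeries` keyed by
separation time, which is the input to the multipass extraction step.

Peak lists are plain CSV/TSV; column names vary between exports, so the
reader takes a :class:`PeaklistDialect` mapping the required columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

#: Acquisition/ejection window of the cyclic device, ms.
DEFAULT_ACQUISITION_WINDOW_MS = 26.4
#: Number of drift bins spanning the acquisition window.
DEFAULT_N_BINS = 200
#: Default drift-bin width in ms (window / bin count).
DEFAULT_BIN_WIDTH_MS = DEFAULT_ACQUISITION_WINDOW_MS / DEFAULT_N_BINS

_POLARITIES = ("positive", "negative")


def bins_to_ms(drift_bin, bin_width: float = DEFAULT_BIN_WIDTH_MS, offset: float = 0.0):
    """Convert drift-bin indices to arrival times in milliseconds.

    ``arrival_time = offset + drift_bin * bin_width``. The offset covers the
    case where exported bins are relative to the start of the acquisition
    window rather than to ion injection.

    Parameters
    ----------
    drift_bin : int or array-like of int
        Bin index (>= 0).
    bin_width : float
        Width of one bin in ms (> 0). Default is 26.4 ms / 200 bins.
    offset : float
        Additive offset in ms applied to every converted value.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    bins = np.asarray(drift_bin)
    if np.any(bins < 0):
        raise ValueError("drift_bin must be non-negative")
    out = offset + bins * float(bin_width)
    return float(out) if np.isscalar(drift_bin) else out


@dataclass(frozen=True)
class Peak:
    """A detected ion: m/z, arrival time (or raw drift bin) and intensity."""

    mz: float
    intensity: float
    arrival_time: float | None = None
    drift_bin: int | None = None

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"mz must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"intensity must be non-negative, got {self.intensity}")
        if self.arrival_time is None and self.drift_bin is None:
            raise ValueError("a peak needs an arrival_time or a drift_bin")
        if self.drift_bin is not None and self.drift_bin < 0:
            raise ValueError(f"drift_bin must be non-negative, got {self.drift_bin}")


@dataclass
class PeakTable:
    """One acquisition's peaks at a known separation time."""

    separation_time: float
    peaks: list[Peak] = field(default_factory=list)
    polarity: str = "positive"
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.separation_time < 0:
            raise ValueError("separation_time must be non-negative")
        if self.polarity not in _POLARITIES:
            raise ValueError(f"polarity must be one of {_POLARITIES}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def top_n(self, n: int) -> "PeakTable":
        """Keep the ``n`` most intense peaks (original order preserved)."""
        if n >= len(self.peaks):
            return self
        order = np.argsort([-p.intensity for p in self.peaks], kind="stable")[:n]
        keep = sorted(order)
        return replace(self, peaks=[self.peaks[i] for i in keep])

    def with_arrival_times(
        self, bin_width: float = DEFAULT_BIN_WIDTH_MS, offset: float = 0.0
    ) -> "PeakTable":
        """Fill arrival times from drift bins where missing."""
        peaks = [
            p
            if p.arrival_time is not None
            else replace(p, arrival_time=bins_to_ms(p.drift_bin, bin_width, offset))
            for p in self.peaks
        ]
        return replace(self, peaks=peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": [p.mz for p in self.peaks],
                "arrival_time": [p.arrival_time for p in self.peaks],
                "drift_bin": [p.drift_bin for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
            }
        )


@dataclass(frozen=True)
class PeaklistDialect:
    """Column mapping for tabular peak-list exports.

    ``drift_unit`` says whether the drift column holds bin indices (``"bin"``)
    or arrival times already in milliseconds (``"ms"``).
    """

    mz: str = "mz"
    drift: str = "drift"
    intensity: str = "intensity"
    drift_unit: str = "bin"
    sep: str = ","

    def __post_init__(self) -> None:
        if self.drift_unit not in ("bin", "ms"):
            raise ValueError("drift_unit must be 'bin' or 'ms'")


def read_peaklist(
    path,
    dialect: PeaklistDialect | None = None,
    *,
    separation_time: float = 0.0,
    polarity: str = "positive",
    source_id: str | None = None,
) -> PeakTable:
    """Read one peak-list table.

    Rows that fail numeric parsing are reported through a warning (with their
    positions) and excluded; a file with zero parsable rows is an error.
    """
    dialect = dialect or PeaklistDialect()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        raw = pd.read_csv(path, sep=dialect.sep, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"zero parsable rows in {path}") from None
    missing = [c for c in (dialect.mz, dialect.drift, dialect.intensity) if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    cols = raw[[dialect.mz, dialect.drift, dialect.intensity]].apply(
        pd.to_numeric, errors="coerce"
    )
    bad = cols.isna().any(axis=1) | ~(cols[dialect.mz] > 0) | (cols[dialect.intensity] < 0)
    if dialect.drift_unit == "bin":
        bad |= cols[dialect.drift] < 0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} malformed row(s) skipped in {path.name} "
            f"(rows {list(cols.index[bad])})",
            stacklevel=2,
        )
    cols = cols[~bad]
    if cols.empty:
        raise ValueError(f"zero parsable rows in {path}")
    peaks = []
    for mz, drift, inten in cols.itertuples(index=False):
        if dialect.drift_unit == "bin":
            peaks.append(Peak(mz=mz, intensity=inten, drift_bin=int(drift)))
        else:
            peaks.append(Peak(mz=mz, intensity=inten, arrival_time=float(drift)))
    return PeakTable(
        separation_time=separation_time,
        peaks=peaks,
        polarity=polarity,
        source_id=source_id if source_id is not None else str(path),
    )


class SeparationSeries:
    """Peak tables of one multipass experiment, keyed by separation time."""

    def __init__(self, tables: Iterable[PeakTable] = ()) -> None:
        self._tables: dict[float, PeakTable] = {}
        for t in tables:
            self.add(t)

    def add(self, table: PeakTable) -> None:
        key = float(table.separation_time)
        if key in self._tables:
            raise ValueError(f"duplicate separation time {key}")
        self._tables[key] = table

    @property
    def schedule(self) -> list[float]:
        """Separation times, strictly increasing."""
        return sorted(self._tables)

    def __len__(self) -> int:
        return len(self._tables)

    def __iter__(self) -> Iterator[PeakTable]:
        return (self._tables[t] for t in self.schedule)

    def __getitem__(self, separation_time: float) -> PeakTable:
        return self._tables[float(separation_time)]

    def __contains__(self, separation_time: float) -> bool:
        return float(separation_time) in self._tables

    def zero_pass_table(self, zero_pass_time: float = 0.01) -> PeakTable:
        """The table acquired at the zero-pass separation time."""
        key = float(zero_pass_time)
        if key not in self._tables:
            raise ValueError(
                f"no table at the zero-pass separation time {zero_pass_time} ms"
            )
        return self._tables[key]

    @classmethod
    def from_manifest(cls, path) -> "SeparationSeries":
        """Load a series from a YAML manifest mapping files to separation times.

        Manifest keys: ``polarity``, ``dialect`` (column mapping), ``bin_width``,
        ``offset`` and ``tables`` (list of ``{path, separation_time}``). Relative
        table paths resolve against the manifest's directory.
        """
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        spec = yaml.safe_load(path.read_text())
        if not spec or "tables" not in spec or not spec["tables"]:
            raise ValueError(f"manifest {path} lists no tables")
        dialect = PeaklistDialect(**spec.get("dialect", {}))
        polarity = spec.get("polarity", "positive")
        bin_width = float(spec.get("bin_width", DEFAULT_BIN_WIDTH_MS))
        offset = float(spec.get("offset", 0.0))
        series = cls()
        for entry in spec["tables"]:
            table_path = Path(entry["path"])
            if not table_path.is_absolute():
                table_path = path.parent / table_path
            table = read_peaklist(
                table_path,
                dialect,
                separation_time=float(entry["separation_time"]),
                polarity=polarity,
            )
            if dialect.drift_unit == "bin":
                table = table.with_arrival_times(bin_width, offset)
            series.add(table)
        return series


def write_series_dir(series: SeparationSeries, out_dir, *, manifest_name: str = "manifest.yaml") -> Path:
    """Write a series as per-acquisition CSVs plus a YAML manifest.

    Arrival times are written in milliseconds, so the round trip through
    :meth:`SeparationSeries.from_manifest` is unit-faithful.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    polarity = "positive"
    for i, table in enumerate(series):
        if table.peaks and any(p.arrival_time is None for p in table.peaks):
            table = table.with_arrival_times()
        name = f"peaks_{i:03d}.csv"
        frame = table.to_frame()[["mz", "arrival_time", "intensity"]]
        frame.columns = ["mz", "drift", "intensity"]
        frame.to_csv(out_dir / name, index=False)
        entries.append({"path": name, "separation_time": table.separation_time})
        polarity = table.polarity
    manifest = {
        "polarity": polarity,
        "dialect": {"mz": "mz", "drift": "drift", "intensity": "intensity", "drift_unit": "ms"},
        "tables": entries,
    }
    manifest_path = out_dir / manifest_name
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


_SERIES_TABLE_COLUMNS = ["name", "adduct", "mz", "separation_time", "arrival_time", "intensity"]


def write_series_table(frame: pd.DataFrame, path) -> None:
    """Write the per-compound arrival-time table (one row per compound x separation time)."""
    if frame is None or len(frame) == 0:
        raise ValueError("series table is empty")
    missing = [c for c in _SERIES_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"series table missing column(s) {missing}")
    frame[_SERIES_TABLE_COLUMNS].to_csv(path, index=False)


def read_series_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SERIES_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"series table missing column(s) {missing}")
    return frame
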