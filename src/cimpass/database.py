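"""Multipass arrival-time database and joint m/z + arrival-time annotation.

The database stores, per species/adduct, the corrected zero-pass time ``t0``,
periodic drift time ``tp`` and the reconstructed multipass arrival times
``t_n = t0 + n * tp`` for passes 1..N (default N=10). A feature measured once
(e.g. in an imaging experiment) is annotated by filtering entries on m/z
(default 20 ppm) and, for each surviving entry, finding the pass whose
reconstructed arrival time is closest to the measured, corrected arrival
time; candidates are ranked by that relative arrival-time error in percent.
This turns the corrected arrival time into a second separation dimension and
determines the pass number as a by-product.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .extraction import MobilityFit, reconstruct_tn
from .matching import ppm_error

_SCHEMA = 1
_TN_TOL = 1e-9


@dataclass
class DatabaseEntry:
    """A species/adduct with its reconstructed multipass arrival times."""

    species: str
    adduct: str
    mz: float
    t0: float
    tp: float
    tn_by_pass: dict[int, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError("mz must be positive")
        if not self.tp > 0:
            raise ValueError("tp must be positive")
        if not self.tn_by_pass:
            raise ValueError("tn_by_pass is empty")
        for n, tn in self.tn_by_pass.items():
            expected = self.t0 + n * self.tp
            if abs(tn - expected) > _TN_TOL:
                raise ValueError(
                    f"inconsistent entry {self.species} {self.adduct}: "
                    f"t{n}={tn} but t0 + {n}*tp = {expected}"
                )

    @property
    def n_max(self) -> int:
        return max(self.tn_by_pass)

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.adduct)


@dataclass
class AnnotationCandidate:
    """One ranked database hit for a measured (m/z, arrival time) feature."""

    entry: DatabaseEntry
    pass_n: int
    ppm_error: float
    tn_error_pct: float
    rank: int = 0


def build_entry(
    fit: MobilityFit,
    corrected: bool = False,
    n_max: int = 10,
    *,
    session_id: str = "",
    line_id: str = "",
) -> DatabaseEntry:
    """Build a database entry from a mobility fit via arrival-time reconstruction.

    ``provenance`` records the source session and whether (and through which
    line) the stored values were corrected.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    tn = {n: reconstruct_tn(fit, n) for n in range(1, n_max + 1)}
    prov = f"session={session_id};corrected={str(bool(corrected)).lower()}"
    if line_id:
        prov += f";line={line_id}"
    return DatabaseEntry(
        species=fit.name,
        adduct=fit.adduct,
        mz=fit.mz,
        t0=fit.t0,
        tp=fit.tp,
        tn_by_pass=tn,
        provenance=prov,
    )


def estimate_pass_number(measured_tn: float, entry: DatabaseEntry) -> int:
    """Pass whose reconstructed arrival time is nearest to the measured one.

    Ties (a measurement exactly midway between consecutive passes) break to
    the lower pass number.
    """
    best_n, best_d = None, np.inf
    for n in sorted(entry.tn_by_pass):
        d = abs(measured_tn - entry.tn_by_pass[n])
        if d < best_d:
            best_n, best_d = n, d
    return best_n


def annotate(
    mz: float,
    tn: float,
    entries: Sequence[DatabaseEntry],
    mz_tol_ppm: float = 20.0,
    max_pass: int | None = None,
    extrapolate: bool = False,
) -> list[AnnotationCandidate]:
    """Rank database entries against a measured (m/z, corrected arrival time).

    Entries within ``mz_tol_ppm`` of the measured m/z are kept; for each, the
    best pass ``n <= max_pass`` minimises ``|tn - t_n|`` and the candidate is
    scored by ``100 * |tn - t_n| / t_n``. Candidates are returned ascending in
    that error, rank starting at 1. An empty database yields an empty list.
    Requests beyond an entry's reconstructed range are refused unless
    ``extrapolate`` is set, in which case ``t0 + n * tp`` extends the table.
    """
    if not mz_tol_ppm > 0:
        raise ValueError("mz_tol_ppm must be positive")
    candidates: list[AnnotationCandidate] = []
    for entry in entries:
        err_ppm = ppm_error(mz, entry.mz)
        if abs(err_ppm) > mz_tol_ppm:
            continue
        limit = entry.n_max if max_pass is None else max_pass
        if limit > entry.n_max and not extrapolate:
            raise ValueError(
                f"max_pass={limit} exceeds the database range (N={entry.n_max}); "
                "pass extrapolate=True to extend via t0 + n*tp"
            )
        best_n, best_d = None, np.inf
        for n in range(1, limit + 1):
            t_ref = entry.tn_by_pass.get(n)
            if t_ref is None:
                t_ref = entry.t0 + n * entry.tp
            d = abs(tn - t_ref)
            if d < best_d:
                best_n, best_d = n, d
        t_best = entry.tn_by_pass.get(best_n, entry.t0 + best_n * entry.tp)
        candidates.append(
            AnnotationCandidate(
                entry=entry,
                pass_n=best_n,
                ppm_error=float(err_ppm),
                tn_error_pct=float(100.0 * best_d / t_best),
            )
        )
    candidates.sort(key=lambda c: (c.tn_error_pct, abs(c.ppm_error)))
    for rank, cand in enumerate(candidates, start=1):
        cand.rank = rank
    return candidates


class MultipassAnnotator(BaseEstimator):
    """Database annotator with a scikit-learn estimator surface.

    ``fit`` ingests the database entries; ``annotate`` ranks candidates for a
    single feature and ``predict`` returns the top candidate label
    (``"species adduct @ pass n"``, or ``""`` when nothing matches) for each
    row of an ``(m/z, arrival_time)`` array.
    """

    def __init__(
        self,
        mz_tol_ppm: float = 20.0,
        max_pass: int | None = None,
        extrapolate: bool = False,
    ):
        self.mz_tol_ppm = mz_tol_ppm
        self.max_pass = max_pass
        self.extrapolate = extrapolate

    def fit(self, X, y=None):
        entries = list(X)
        for e in entries:
            if not isinstance(e, DatabaseEntry):
                raise TypeError("MultipassAnnotator.fit expects DatabaseEntry items")
        self.entries_ = entries
        return self

    def annotate(self, mz: float, tn: float) -> list[AnnotationCandidate]:
        self._check_fitted()
        return annotate(
            mz,
            tn,
            self.entries_,
            mz_tol_ppm=self.mz_tol_ppm,
            max_pass=self.max_pass,
            extrapolate=self.extrapolate,
        )

    def predict(self, X):
        self._check_fitted()
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("X must be an (n_features, 2) array of (mz, arrival_time)")
        labels = []
        for mz, tn in arr:
            cands = self.annotate(mz, tn)
            if cands:
                top = cands[0]
                labels.append(f"{top.entry.species} {top.entry.adduct} @ pass {top.pass_n}")
            else:
                labels.append("")
        return np.asarray(labels, dtype=object)

    def _check_fitted(self) -> None:
        if not hasattr(self, "entries_"):
            raise ValueError("MultipassAnnotator is not fitted")


def write_database(
    entries: Sequence[DatabaseEntry],
    path,
    *,
    polarity: str = "positive",
) -> None:
    """Write the database as CSV with a structured comment header."""
    if not entries:
        raise ValueError("no entries to write")
    n_max = max(e.n_max for e in entries)
    rows = []
    for e in entries:
        row = {
            "species": e.species,
            "adduct": e.adduct,
            "mz": e.mz,
            "t0": e.t0,
            "tp": e.tp,
            "provenance": e.provenance,
        }
        for n in range(1, n_max + 1):
            row[f"t{n}"] = e.tn_by_pass.get(n, e.t0 + n * e.tp)
        rows.append(row)
    frame = pd.DataFrame(rows)
    buf = io.StringIO()
    buf.write("# cimpass multipass arrival-time database\n")
    buf.write(f"# schema={_SCHEMA}\n")
    buf.write(f"# polarity={polarity}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_database(path) -> tuple[list[DatabaseEntry], dict]:
    """Read a database CSV; the ``t_n = t0 + n*tp`` invariant is revalidated.

    Returns the entries and the parsed header metadata.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    for line in path.read_text().splitlines():
        if not line.startswith("#"):
            break
        m = re.match(r"#\s*(\w+)=(.*)", line)
        if m:
            meta[m.group(1)] = m.group(2).strip()
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    pass_cols = sorted(
        (int(c[1:]) for c in frame.columns if re.fullmatch(r"t\d+", c) and c != "t0"),
    )
    if not pass_cols:
        raise ValueError(f"database {path} has no reconstructed pass columns")
    entries = []
    for row in frame.itertuples(index=False):
        entries.append(
            DatabaseEntry(
                species=str(row.species),
                adduct=str(row.adduct),
                mz=float(row.mz),
                t0=float(row.t0),
                tp=float(row.tp),
                tn_by_pass={n: float(getattr(row, f"t{n}")) for n in pass_cols},
                provenance=str(getattr(row, "provenance", "")),
            )
        )
    return entries, meta
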