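"""Workflow glue: series extraction, session correction and annotation runs.

These functions (and the :class:`MobilityExtractor` estimator) connect the
building blocks into the three standard workflows: extract (t0, tp) for every
reference compound from a separation-time series; align a measured fit table
to a reference table with calibrant lines and screen residuals; and annotate
single-measurement features against a multipass database, optionally after a
calibrant-based arrival-time correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .correction import (
    CorrectionLine,
    LinearDriftCorrector,
    fit_correction_line,
    mean_relative_error,
    screen_by_residual,
    warn_on_cross_class,
)
from .database import DatabaseEntry, annotate, build_entry, estimate_pass_number
from .extraction import (
    MobilityFit,
    PassAssignmentError,
    assign_pass_numbers,
    fit_mobility,
    measure_t0,
)
from .matching import CompoundRef, match_mz
from .peaktable import SeparationSeries

log = logging.getLogger("cimpass")


class MobilityExtractor(BaseEstimator):
    """Extract per-compound (t0, tp) from a separation-time series.

    scikit-learn style: ``fit(series, refs)`` matches every reference
    compound across the series, assigns pass numbers and fits the
    arrival-time line; results land in ``fits_`` (list of
    :class:`MobilityFit`) and ``failures_`` (compound -> reason).

    Parameters
    ----------
    tol_ppm : float
        m/z matching window for targeted peak lookup.
    zero_pass_time : float
        Separation time (ms) of the zero-pass acquisition.
    top_n : int
        Keep only the N most intense peaks per acquisition before matching.
    min_passes : int
        Distinct passes required for a fully trusted slope.
    """

    def __init__(
        self,
        tol_ppm: float = 10.0,
        zero_pass_time: float = 0.01,
        top_n: int = 500,
        min_passes: int = 5,
        max_iter: int = 50,
        residual_k: float = 3.0,
    ):
        self.tol_ppm = tol_ppm
        self.zero_pass_time = zero_pass_time
        self.top_n = top_n
        self.min_passes = min_passes
        self.max_iter = max_iter
        self.residual_k = residual_k

    def fit(self, X: SeparationSeries, y: Sequence[CompoundRef]):
        series, refs = X, list(y)
        zero_table = series.zero_pass_table(self.zero_pass_time).top_n(self.top_n)
        fits: list[MobilityFit] = []
        failures: dict[tuple[str, str], str] = {}
        for ref in refs:
            try:
                t0 = measure_t0(zero_table, ref, self.tol_ppm, self.zero_pass_time)
                arrivals = []
                for T in series.schedule:
                    peak = match_mz(series[T].top_n(self.top_n), ref, self.tol_ppm)
                    if peak is not None and peak.arrival_time is not None:
                        arrivals.append((T, peak.arrival_time, peak.intensity))
                result = assign_pass_numbers(
                    arrivals,
                    t0,
                    name=ref.name,
                    adduct=ref.adduct,
                    max_iter=self.max_iter,
                    residual_k=self.residual_k,
                )
                fit = fit_mobility(
                    result.observations,
                    t0_measured=t0,
                    min_passes=self.min_passes,
                    mz=ref.ref_mz,
                    class_tag=ref.class_tag,
                )
                fits.append(fit)
            except (ValueError, PassAssignmentError) as exc:
                failures[ref.key] = str(exc)
                log.warning("extraction failed for %s %s: %s", ref.name, ref.adduct, exc)
        self.fits_ = fits
        self.failures_ = failures
        return self

    def to_frame(self) -> pd.DataFrame:
        if not hasattr(self, "fits_"):
            raise ValueError("MobilityExtractor is not fitted")
        return fits_to_frame(self.fits_)


def extract_series(
    series: SeparationSeries,
    refs: Sequence[CompoundRef],
    **params,
) -> tuple[list[MobilityFit], dict]:
    """Functional wrapper over :class:`MobilityExtractor`."""
    extractor = MobilityExtractor(**params).fit(series, refs)
    return extractor.fits_, extractor.failures_


def collect_series_table(
    series: SeparationSeries,
    refs: Sequence[CompoundRef],
    tol_ppm: float = 10.0,
    top_n: int = 500,
) -> pd.DataFrame:
    """Matched arrival times per compound across the whole schedule.

    One row per compound x separation time; unmatched cells are NaN so the
    table shape reflects the schedule, not detectability.
    """
    rows = []
    for ref in refs:
        for T in series.schedule:
            peak = match_mz(series[T].top_n(top_n), ref, tol_ppm)
            rows.append(
                {
                    "name": ref.name,
                    "adduct": ref.adduct,
                    "mz": peak.mz if peak else ref.ref_mz,
                    "separation_time": T,
                    "arrival_time": peak.arrival_time if peak else np.nan,
                    "intensity": peak.intensity if peak else np.nan,
                }
            )
    return pd.DataFrame(rows)


_FIT_COLUMNS = ["name", "adduct", "mz", "class_tag", "t0", "tp", "t0_fitted", "r2", "n_passes", "flag"]


def fits_to_frame(fits: Sequence[MobilityFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "name": f.name,
                "adduct": f.adduct,
                "mz": f.mz,
                "class_tag": f.class_tag,
                "t0": f.t0,
                "tp": f.tp,
                "t0_fitted": f.t0_fitted,
                "r2": f.r2,
                "n_passes": f.n_passes_used,
                "flag": f.quality_flag,
            }
            for f in fits
        ],
        columns=_FIT_COLUMNS,
    )


def frame_to_fits(frame: pd.DataFrame) -> list[MobilityFit]:
    """Rehydrate fits from a fit table (residuals are not persisted)."""
    fits = []
    for row in frame.itertuples(index=False):
        fits.append(
            MobilityFit(
                name=str(row.name),
                adduct=str(row.adduct),
                t0=float(row.t0),
                tp=float(row.tp),
                t0_fitted=float(getattr(row, "t0_fitted", row.t0)),
                r2=float(getattr(row, "r2", np.nan)),
                n_passes_used=int(getattr(row, "n_passes", 0)),
                quality_flag=str(getattr(row, "flag", "ok")),
                mz=float(getattr(row, "mz", np.nan)),
                class_tag=str(getattr(row, "class_tag", "lipid")),
            )
        )
    return fits


@dataclass
class CorrectionOutcome:
    """Per-quantity lines plus the per-compound correction report."""

    lines: dict[str, CorrectionLine]
    report: pd.DataFrame
    corrected: pd.DataFrame
    pre_mre_pct: dict[str, float]
    post_mre_pct: dict[str, float]


def correct_fit_tables(
    measured: pd.DataFrame,
    reference: pd.DataFrame,
    calibrants: Sequence[str],
    *,
    quantities: Sequence[str] = ("tp", "t0"),
    residual_threshold_pct: float = 0.7,
) -> CorrectionOutcome:
    """Align a measured fit table to a reference table via calibrant lines.

    ``calibrants`` names the compounds whose (measured, reference) pairs fit
    the per-quantity lines; the lines are then applied to every shared
    compound. The report carries pre/post residuals in percent and a
    residual-based class flag computed on the first quantity (tp by default).
    """
    merged = measured.merge(
        reference, on=["name", "adduct"], suffixes=("_meas", "_ref"), how="inner"
    )
    if merged.empty:
        raise ValueError("measured and reference tables share no compounds")
    cal_mask = merged["name"].isin(set(calibrants)).to_numpy()
    if cal_mask.sum() < 2:
        raise ValueError(
            f"need at least 2 shared calibrants, found {int(cal_mask.sum())}"
        )
    class_col = "class_tag_meas" if "class_tag_meas" in merged else (
        "class_tag" if "class_tag" in merged else None
    )
    if class_col:
        warn_on_cross_class(merged.loc[cal_mask, class_col], merged.loc[~cal_mask, class_col])

    corrected = measured.copy()
    report_parts = []
    lines: dict[str, CorrectionLine] = {}
    pre_mre: dict[str, float] = {}
    post_mre: dict[str, float] = {}
    for q in quantities:
        meas = merged[f"{q}_meas"].to_numpy(dtype=float)
        ref = merged[f"{q}_ref"].to_numpy(dtype=float)
        cal_ids = merged.loc[cal_mask, ["name", "adduct"]].agg(" ".join, axis=1).tolist()
        line = fit_correction_line(
            zip(meas[cal_mask], ref[cal_mask]), quantity=q, calibrant_ids=cal_ids
        )
        lines[q] = line
        corr = line(meas)
        pre = 100.0 * np.abs(meas - ref) / ref
        post = 100.0 * np.abs(corr - ref) / ref
        ana = ~cal_mask
        pre_mre[q] = float(pre[ana].mean()) if ana.any() else float(pre.mean())
        post_mre[q] = float(post[ana].mean()) if ana.any() else float(post.mean())
        log.info(
            "correction line %s: slope=%.6f intercept=%.6f R2=%.6f calibrants=%s",
            q, line.slope, line.intercept, line.r2, line.calibrant_ids,
        )
        report_parts.append(
            pd.DataFrame(
                {
                    "name": merged["name"],
                    "adduct": merged["adduct"],
                    "quantity": q,
                    "is_calibrant": cal_mask,
                    "measured": meas,
                    "reference": ref,
                    "corrected": corr,
                    "pre_residual_pct": pre,
                    "post_residual_pct": post,
                }
            )
        )
        key_cols = corrected.set_index(["name", "adduct"]).index
        corr_by_key = dict(zip(zip(merged["name"], merged["adduct"]), corr))
        corrected[q] = [
            corr_by_key.get(k, v) for k, v in zip(key_cols, corrected[q])
        ]
    report = pd.concat(report_parts, ignore_index=True)

    flag_q = quantities[0]
    flag_rows = report[report["quantity"] == flag_q]
    screening = screen_by_residual(
        flag_rows["post_residual_pct"].to_numpy(),
        threshold=residual_threshold_pct,
        feature_ids=flag_rows["name"].tolist(),
    )
    flags = {s.feature_id: s.class_flag for s in screening}
    report["class_flag"] = report["name"].map(flags)
    return CorrectionOutcome(
        lines=lines,
        report=report,
        corrected=corrected,
        pre_mre_pct=pre_mre,
        post_mre_pct=post_mre,
    )


def build_database_entries(
    fits: Sequence[MobilityFit],
    n_max: int = 10,
    *,
    corrected: bool = False,
    session_id: str = "",
    line_id: str = "",
) -> list[DatabaseEntry]:
    return [
        build_entry(f, corrected=corrected, n_max=n_max, session_id=session_id, line_id=line_id)
        for f in fits
    ]


@dataclass
class AnnotationRun:
    """Annotation report plus the arrival-time correction line, if one was fitted."""

    report: pd.DataFrame
    tn_line: CorrectionLine | None


def annotate_table(
    queries: pd.DataFrame,
    entries: Sequence[DatabaseEntry],
    *,
    mz_tol_ppm: float = 20.0,
    calibrant_species: Sequence[str] | None = None,
    max_pass: int | None = None,
    max_rank: int | None = None,
) -> AnnotationRun:
    """Annotate measured (m/z, arrival time) features against the database.

    ``queries`` needs columns ``mz`` and ``tn`` (optional ``query_id``). When
    ``calibrant_species`` is given, the single-measurement correction workflow
    runs first: each calibrant's measured arrival time is located among the
    queries by m/z, its pass number is estimated from the database, and the
    (measured, database) pairs fit an arrival-time line that is applied to all
    queries before the search.
    """
    if not entries:
        raise ValueError("database is empty")
    q = queries.copy()
    if "query_id" not in q.columns:
        q["query_id"] = [f"q{i}" for i in range(len(q))]

    tn_line = None
    tn_values = q["tn"].to_numpy(dtype=float)
    if calibrant_species:
        pairs, cal_ids = [], []
        for entry in entries:
            if entry.species not in set(calibrant_species):
                continue
            ppm = np.abs((q["mz"].to_numpy(dtype=float) - entry.mz) / entry.mz * 1e6)
            if ppm.min() > mz_tol_ppm:
                continue
            idx = int(np.argmin(ppm))
            measured = float(q["tn"].iloc[idx])
            n_est = estimate_pass_number(measured, entry)
            pairs.append((measured, entry.tn_by_pass[n_est]))
            cal_ids.append(f"{entry.species} {entry.adduct} @ pass {n_est}")
        if len(pairs) < 2:
            raise ValueError(
                f"need at least 2 calibrants matched among the queries, found {len(pairs)}"
            )
        tn_line = fit_correction_line(pairs, quantity="tn", calibrant_ids=cal_ids)
        log.info(
            "tn correction line: slope=%.6f intercept=%.6f R2=%.6f calibrants=%s",
            tn_line.slope, tn_line.intercept, tn_line.r2, cal_ids,
        )
        tn_values = tn_line(tn_values)

    rows = []
    for (row, tn_corr) in zip(q.itertuples(index=False), tn_values):
        candidates = annotate(
            float(row.mz), float(tn_corr), entries, mz_tol_ppm=mz_tol_ppm, max_pass=max_pass
        )
        if max_rank is not None:
            candidates = candidates[:max_rank]
        for cand in candidates:
            rows.append(
                {
                    "query_id": row.query_id,
                    "mz": row.mz,
                    "tn_measured": row.tn,
                    "tn_corrected": tn_corr,
                    "species": cand.entry.species,
                    "adduct": cand.entry.adduct,
                    "pass_n": cand.pass_n,
                    "ppm_error": cand.ppm_error,
                    "tn_error_pct": cand.tn_error_pct,
                    "rank": cand.rank,
                }
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "query_id", "mz", "tn_measured", "tn_corrected", "species",
            "adduct", "pass_n", "ppm_error", "tn_error_pct", "rank",
        ],
    )
    return AnnotationRun(report=report, tn_line=tn_line)
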