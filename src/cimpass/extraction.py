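"""Multipass arrival-time extraction: pass assignment and (t0, tp) fitting.

The arrival time of an ion that completes ``n`` cycles of the cyclic mobility
device is linear in the pass number::

    t_n = t0 + n * tp

where ``t0`` is the zero-pass arrival time (measured directly at a minimal
separation time, by default 0.01 ms) and ``tp`` is the periodic drift time
(one cycle of the device). A separation-time series yields one matched
arrival time per acquisition; because the acquisition window is finite and
faster ions overtake slower ones across cycles (wrap-around), the pass number
behind each observation is not recorded by the instrument and has to be
inferred. This module assigns pass numbers by iteratively refitting the line
above, then estimates ``tp`` as the slope of arrival time versus pass number,
using per-pass mean arrival times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .matching import CompoundRef, match_mz
from .peaktable import PeakTable

QUALITY_FLAGS = ("ok", "low_pass_count", "poor_fit")


class PassAssignmentError(RuntimeError):
    """Raised when iterative pass assignment fails to reach a fixed point."""


@dataclass(frozen=True)
class PassObservation:
    """One (compound, pass number, arrival time) assignment from the series."""

    name: str
    adduct: str
    n: int
    t_n: float
    separation_time: float
    intensity: float = np.nan

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("pass number must be non-negative")
        if not self.t_n > 0:
            raise ValueError("arrival time must be positive")

    @property
    def compound(self) -> tuple[str, str]:
        return (self.name, self.adduct)


@dataclass
class MobilityFit:
    """Per-compound (t0, tp) with fit diagnostics.

    ``t0`` is the canonical zero-pass arrival time stored downstream: the
    directly measured value when available (it has far lower variance than the
    extrapolated intercept), otherwise the fitted intercept. The intercept is
    always reported separately as ``t0_fitted``.
    """

    name: str
    adduct: str
    t0: float
    tp: float
    t0_fitted: float
    r2: float
    n_passes_used: int
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    quality_flag: str = "ok"
    mz: float = np.nan
    class_tag: str = "lipid"

    def __post_init__(self) -> None:
        if not self.tp > 0:
            raise ValueError("tp must be positive")
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if self.quality_flag not in QUALITY_FLAGS:
            raise ValueError(f"quality_flag must be one of {QUALITY_FLAGS}")

    @property
    def compound(self) -> tuple[str, str]:
        return (self.name, self.adduct)


@dataclass
class AssignmentResult:
    """Outcome of iterative pass assignment."""

    observations: list[PassObservation]
    unassigned: list[int]
    tp_estimate: float
    t0_estimate: float
    n_iter: int


@dataclass(frozen=True)
class ThreePointResult:
    """Pass number and periodic drift time from a three-measurement scheme."""

    n: int
    tp: float
    n_raw: float

    @property
    def consistency(self) -> float:
        """|n_raw - n|; large values signal an inconsistent triple."""
        return abs(self.n_raw - self.n)


def _round_ties_down(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, exact halves toward the lower integer."""
    return np.ceil(np.asarray(x) - 0.5).astype(int)


def measure_t0(
    table: PeakTable,
    ref: CompoundRef,
    tol_ppm: float = 10.0,
    zero_pass_time: float = 0.01,
) -> float:
    """Read the zero-pass arrival time from the minimal-separation-time table."""
    if not np.isclose(table.separation_time, zero_pass_time):
        raise ValueError(
            f"table is at separation time {table.separation_time} ms, "
            f"expected the zero-pass setting {zero_pass_time} ms"
        )
    peak = match_mz(table, ref, tol_ppm)
    if peak is None or peak.arrival_time is None:
        raise ValueError(f"t0 unavailable: no peak within {tol_ppm} ppm of {ref.key}")
    return float(peak.arrival_time)


def assign_pass_numbers(
    arrivals: Sequence,
    t0: float,
    tp_seed: float | None = None,
    *,
    name: str = "",
    adduct: str = "",
    max_iter: int = 50,
    residual_k: float = 3.0,
    min_pass_gap: float = 0.5,
) -> AssignmentResult:
    """Assign an integer pass number to each observed arrival time.

    ``arrivals`` is a sequence of ``(separation_time, t)`` or
    ``(separation_time, t, intensity)`` rows for one compound. Starting from a
    periodic-drift-time estimate (``tp_seed``, or the lowest-separation-time
    observation that sits at least ``min_pass_gap`` ms above ``t0``, assumed
    to be pass 1), each observation gets ``n = round((t - t0) / tp_est)`` and
    the line ``t = t0 + n * tp`` is refit until assignments are stable.
    Rounding ties break toward the lower pass. Observations whose residual to
    the refit line exceeds ``residual_k`` times a robust residual scale are
    flagged unassigned rather than forced onto the line.
    """
    rows = [tuple(map(float, row)) for row in arrivals]
    if len(rows) < 2:
        raise ValueError("cannot assign: need at least 2 observations")
    T = np.array([r[0] for r in rows])
    t = np.array([r[1] for r in rows])
    inten = np.array([r[2] if len(r) > 2 else np.nan for r in rows])

    if tp_seed is not None:
        if not tp_seed > 0:
            raise ValueError("tp_seed must be positive")
        tp_est = float(tp_seed)
    else:
        above = np.flatnonzero(t - t0 > min_pass_gap)
        if above.size == 0:
            raise ValueError(
                "cannot assign: no observation above t0; provide tp_seed"
            )
        first = above[np.argmin(T[above])]
        tp_est = float(t[first] - t0)  # lowest-separation-time excursion ~ pass 1

    slope, intercept = tp_est, float(t0)
    n = _round_ties_down(np.maximum((t - intercept) / slope, 0.0))
    mask = np.ones(len(t), dtype=bool)
    converged = False
    seen: set[tuple] = set()
    for it in range(1, max_iter + 1):
        if np.unique(n[mask]).size >= 2:
            slope, intercept = np.polyfit(n[mask], t[mask], 1)
            if slope <= 0:
                raise PassAssignmentError("refit produced a non-positive drift time")
        n_new = np.maximum(_round_ties_down((t - intercept) / slope), 0)
        resid = t - (intercept + slope * n_new)
        # centre on the median so a contaminated OLS fit cannot drag every
        # residual past the cutoff at once
        med = np.median(resid[mask])
        scale = 1.4826 * np.median(np.abs(resid[mask] - med))
        floor = max(1e-9, 1e-6 * slope)
        mask_new = np.abs(resid - med) <= residual_k * max(scale, floor)
        if not mask_new.any():
            raise ValueError("all observations unassignable")
        state = (tuple(n_new), tuple(mask_new))
        if np.array_equal(n_new, n) and np.array_equal(mask_new, mask) or state in seen:
            # a revisited state means the fit cycles between equivalent inlier
            # sets; the assignments themselves are stable, so accept
            converged = True
            n, mask = n_new, mask_new
            break
        seen.add(state)
        n, mask = n_new, mask_new
    if not converged:
        raise PassAssignmentError(f"pass assignment did not converge in {max_iter} iterations")
    if np.unique(n[mask]).size < 2:
        raise ValueError("cannot assign: observations span fewer than 2 distinct passes")

    observations = [
        PassObservation(
            name=name,
            adduct=adduct,
            n=int(n[i]),
            t_n=float(t[i]),
            separation_time=float(T[i]),
            intensity=float(inten[i]),
        )
        for i in np.flatnonzero(mask)
    ]
    return AssignmentResult(
        observations=observations,
        unassigned=list(np.flatnonzero(~mask)),
        tp_estimate=float(slope),
        t0_estimate=float(intercept),
        n_iter=it,
    )


def fit_mobility(
    observations: Sequence[PassObservation],
    *,
    t0_measured: float | None = None,
    min_passes: int = 5,
    mz: float = np.nan,
    class_tag: str = "lipid",
    poor_fit_r2: float = 0.99,
    dispersion_cv: float = 0.01,
) -> MobilityFit:
    """Least-squares line of arrival time versus pass number.

    When a pass is observed at several separation times, the per-pass mean
    arrival time enters the fit, so every pass carries equal weight. ``tp`` is
    the slope; the intercept is reported as the fitted t0 but the measured
    zero-pass time, when given, is the canonical ``t0``. Fits spanning fewer
    than ``min_passes`` distinct passes are flagged ``low_pass_count``; fits
    with poor linearity or large within-pass dispersion (a symptom of bimodal
    or asymmetric arrival distributions) are flagged ``poor_fit``.
    """
    obs = list(observations)
    if not obs:
        raise ValueError("no observations")
    ns = np.array([o.n for o in obs])
    ts = np.array([o.t_n for o in obs])
    unique_n = np.unique(ns)
    if unique_n.size < 2:
        raise ValueError("need at least 2 distinct pass numbers")
    t_mean = np.array([ts[ns == k].mean() for k in unique_n])
    res = stats.linregress(unique_n.astype(float), t_mean)
    slope, intercept = float(res.slope), float(res.intercept)
    r2 = float(res.rvalue**2)
    if not np.isfinite(r2):  # degenerate: all means identical
        r2 = 0.0

    flag = "ok"
    if unique_n.size < min_passes:
        flag = "low_pass_count"
    within_cv = 0.0
    for k in unique_n:
        grp = ts[ns == k]
        if grp.size >= 2 and grp.mean() > 0:
            within_cv = max(within_cv, grp.std(ddof=1) / grp.mean())
    if r2 < poor_fit_r2 or within_cv > dispersion_cv:
        flag = "poor_fit"

    name, adduct = obs[0].name, obs[0].adduct
    return MobilityFit(
        name=name,
        adduct=adduct,
        t0=float(t0_measured) if t0_measured is not None else intercept,
        tp=slope,
        t0_fitted=intercept,
        r2=r2,
        n_passes_used=int(unique_n.size),
        residuals=ts - (intercept + slope * ns),
        quality_flag=flag,
        mz=mz,
        class_tag=class_tag,
    )


def reconstruct_tn(fit, n: int) -> float:
    """Multipass arrival time at pass ``n``: ``t0 + n * tp``.

    ``fit`` is a :class:`MobilityFit` or a ``(t0, tp)`` pair.
    """
    if n < 0:
        raise ValueError("pass number must be non-negative")
    if isinstance(fit, MobilityFit):
        t0, tp = fit.t0, fit.tp
    else:
        t0, tp = fit
    return float(t0) + int(n) * float(tp)


def three_point_tp(t0: float, t1: float, tn: float) -> ThreePointResult:
    """Pass number and periodic drift time from three measurements.

    Given the zero-pass time ``t0``, the single-pass time ``t1`` and a
    multipass time ``tn`` at some longer separation time, the pass count is
    ``n = (tn - t0) / (t1 - t0)`` rounded to the nearest integer and the
    periodic drift time is ``tp = (tn - t0) / n``. ``|n_raw - n|`` is kept as
    a consistency diagnostic.
    """
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    if tn < t1:
        raise ValueError("tn must be at least t1")
    n_raw = (tn - t0) / (t1 - t0)
    n = int(_round_ties_down(np.array([n_raw]))[0])
    if n == 0:
        raise ValueError("pass number rounds to 0; tn is not a multipass time")
    return ThreePointResult(n=n, tp=(tn - t0) / n, n_raw=float(n_raw))
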