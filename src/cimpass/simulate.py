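"""Synthetic cyclic ion-mobility multipass experiments.

This simulator is the ground-truth oracle for the rest of the package. Each
compound is defined by a true zero-pass time ``t0`` and periodic drift time
``tp``; at a separation time ``T`` the instrument ejects and records, within
an acquisition window of length ``window`` (default 26.4 ms), every pass
``n`` whose arrival time ``t_n = t0 + n*tp`` satisfies ``0 <= t_n - T <=
window``. Because compounds differ in ``tp``, long separation times mix pass
numbers across compounds (wrap-around). Session-to-session drift is modelled
as affine maps acting on ``t0`` and ``tp`` (each quantity follows its own
linear correction line), optionally class-specific so that lipids and
nonlipids drift along different lines. Measurement noise is multiplicative
on arrival times — variation in the real instrument is CV-like — and
intensity decays geometrically with pass number so that a detection floor
reproduces the loss of weak compounds at high passes.

The window model (which passes are observable at a given separation time) is
a stated simplification: the real ejection geometry is more intricate, but
the linear arrival-time structure, wrap-around and drift it generates are the
features the extraction and correction methods rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .peaktable import DEFAULT_ACQUISITION_WINDOW_MS, Peak, PeakTable, SeparationSeries

#: Plausible single-pass drift-time range (ms) for compounds in this regime.
DEFAULT_TP_RANGE = (10.0, 14.0)
DEFAULT_T0_RANGE = (5.0, 8.0)


@dataclass(frozen=True)
class AffineMap:
    """``x -> slope * x + intercept``."""

    slope: float = 1.0
    intercept: float = 0.0

    def __call__(self, x):
        return self.slope * x + self.intercept

    def inverse(self, y):
        return (y - self.intercept) / self.slope


@dataclass(frozen=True)
class SimCompound:
    """Ground-truth compound: true (t0, tp), m/z and base intensity."""

    name: str
    mz: float
    true_t0: float
    true_tp: float
    base_intensity: float = 1e5
    class_tag: str = "lipid"
    adduct: str = "[M+H]+"

    def __post_init__(self) -> None:
        if not self.true_tp > 0:
            raise ValueError("true_tp must be positive")
        if not self.true_t0 >= 0:
            raise ValueError("true_t0 must be non-negative")
        if not self.mz > 0:
            raise ValueError("mz must be positive")


@dataclass(frozen=True)
class SessionDrift:
    """Affine session drift on (tp, t0) plus multiplicative arrival-time noise.

    ``class_maps`` optionally overrides the maps for specific class tags so a
    second molecular class can drift along its own line (the ground truth for
    residual-based class screening).
    """

    tp_map: AffineMap = AffineMap()
    t0_map: AffineMap = AffineMap()
    noise_cv: float = 0.0
    class_maps: Mapping[str, tuple[AffineMap, AffineMap]] | None = None

    def __post_init__(self) -> None:
        if self.tp_map.slope <= 0 or self.t0_map.slope <= 0:
            raise ValueError("drift slopes must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.class_maps:
            for tp_map, t0_map in self.class_maps.values():
                if tp_map.slope <= 0 or t0_map.slope <= 0:
                    raise ValueError("drift slopes must be positive")

    @classmethod
    def identity(cls, noise_cv: float = 0.0) -> "SessionDrift":
        return cls(noise_cv=noise_cv)

    def maps_for(self, class_tag: str) -> tuple[AffineMap, AffineMap]:
        if self.class_maps and class_tag in self.class_maps:
            return self.class_maps[class_tag]
        return (self.tp_map, self.t0_map)

    @property
    def is_stochastic(self) -> bool:
        return self.noise_cv > 0


def default_schedule() -> np.ndarray:
    """The separation-time ladder, in ms.

    0.01 (zero-pass), then 1..20 by 1, 22..40 by 2, 45..100 by 5 and 110..150
    by 10 — 48 values in total, strictly increasing, shared boundary points
    included once.
    """
    steps = np.concatenate(
        [
            [0.01],
            np.arange(1, 21, 1),
            np.arange(22, 41, 2),
            np.arange(45, 101, 5),
            np.arange(110, 151, 10),
        ]
    )
    return steps.astype(float)


def sample_compounds(
    n: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    tp_range: tuple[float, float] = DEFAULT_TP_RANGE,
    t0_range: tuple[float, float] = DEFAULT_T0_RANGE,
    mz_start: float = 400.0,
    mz_step: float = 25.0,
    base_intensity: float = 1e5,
    class_tag: str = "lipid",
    prefix: str = "CPD",
) -> list[SimCompound]:
    """Draw ``n`` compounds with uniform (tp, t0) and well-separated m/z.

    m/z values are spaced ``mz_step`` apart so matching windows never overlap
    between compounds.
    """
    if rng is None:
        if seed is None:
            raise ValueError("seed (or rng) is required: compound sampling is stochastic")
        rng = np.random.default_rng(seed)
    tps = rng.uniform(*tp_range, size=n)
    t0s = rng.uniform(*t0_range, size=n)
    return [
        SimCompound(
            name=f"{prefix}{i:02d}",
            mz=mz_start + i * mz_step,
            true_t0=float(t0s[i]),
            true_tp=float(tps[i]),
            base_intensity=base_intensity,
            class_tag=class_tag,
        )
        for i in range(n)
    ]


def simulate_series(
    compounds: Sequence[SimCompound],
    schedule: Sequence[float] | None = None,
    drift: SessionDrift | None = None,
    *,
    window: float = DEFAULT_ACQUISITION_WINDOW_MS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    intensity_decay: float = 0.7,
    intensity_floor: float = 10.0,
    mz_noise_ppm: float = 0.0,
    polarity: str = "positive",
) -> tuple[SeparationSeries, pd.DataFrame]:
    """Simulate one acquisition series and return it with its ground truth.

    For every compound and separation time ``T``, a peak is emitted for each
    pass ``n`` with ``0 <= (t0' + n*tp') - T <= window`` (primes are the
    drift-transformed values), with arrival time ``(t0' + n*tp') * (1 + eps)``
    where ``eps ~ N(0, noise_cv)``, and intensity ``base * decay^n`` (peaks
    below ``intensity_floor`` are not detected). The ground-truth table holds
    one row per emitted peak: compound, separation time, true pass number,
    noiseless and observed arrival times, intensity.

    A seed (or generator) is mandatory whenever the simulation is stochastic.
    """
    if not window > 0:
        raise ValueError("window must be positive")
    schedule = default_schedule() if schedule is None else np.asarray(schedule, dtype=float)
    if schedule.size == 0:
        raise ValueError("schedule is empty")
    if np.any(np.diff(schedule) <= 0):
        raise ValueError("schedule must be strictly increasing")
    drift = SessionDrift.identity() if drift is None else drift
    stochastic = drift.is_stochastic or mz_noise_ppm > 0
    if rng is None:
        if stochastic and seed is None:
            raise ValueError("seed is required for a stochastic simulation")
        rng = np.random.default_rng(seed)

    series = SeparationSeries()
    truth_rows = []
    for T in schedule:
        peaks = []
        for c in compounds:
            tp_map, t0_map = drift.maps_for(c.class_tag)
            t0d, tpd = float(t0_map(c.true_t0)), float(tp_map(c.true_tp))
            n_lo = max(0, int(np.ceil((T - t0d) / tpd - 1e-12)))
            n_hi = int(np.floor((T + window - t0d) / tpd + 1e-12))
            for n in range(n_lo, n_hi + 1):
                t_true = t0d + n * tpd
                if t_true < T - 1e-12:
                    continue
                inten = c.base_intensity * intensity_decay**n
                if inten < intensity_floor:
                    continue
                t_obs = t_true
                if drift.noise_cv > 0:
                    t_obs = t_true * (1.0 + rng.normal(0.0, drift.noise_cv))
                mz = c.mz
                if mz_noise_ppm > 0:
                    mz = c.mz * (1.0 + rng.normal(0.0, mz_noise_ppm * 1e-6))
                peaks.append(Peak(mz=mz, arrival_time=t_obs, intensity=inten))
                truth_rows.append(
                    {
                        "name": c.name,
                        "adduct": c.adduct,
                        "class_tag": c.class_tag,
                        "separation_time": float(T),
                        "n": n,
                        "t_true": t_true,
                        "t_observed": t_obs,
                        "intensity": inten,
                    }
                )
        series.add(
            PeakTable(
                separation_time=float(T),
                peaks=peaks,
                polarity=polarity,
                source_id=f"sim@{T}",
            )
        )
    return series, pd.DataFrame(truth_rows)


@dataclass
class TwoSessionSim:
    """Paired simulated sessions with the true inter-session maps."""

    series_a: SeparationSeries
    series_b: SeparationSeries
    truth_a: pd.DataFrame
    truth_b: pd.DataFrame
    drift: SessionDrift


def simulate_two_sessions(
    compounds: Sequence[SimCompound],
    drift_a_to_b: SessionDrift,
    seed: int | None = None,
    *,
    schedule: Sequence[float] | None = None,
    window: float = DEFAULT_ACQUISITION_WINDOW_MS,
    **kwargs,
) -> TwoSessionSim:
    """Simulate a reference session A (identity drift) and a drifted session B.

    Both sessions share ``drift_a_to_b.noise_cv``; B additionally applies the
    given affine maps. The true maps travel with the result so correction
    recovery can be checked against them.
    """
    stochastic = drift_a_to_b.is_stochastic or kwargs.get("mz_noise_ppm", 0) > 0
    if stochastic and seed is None:
        raise ValueError("seed is required for a stochastic simulation")
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    series_a, truth_a = simulate_series(
        compounds,
        schedule,
        SessionDrift.identity(noise_cv=drift_a_to_b.noise_cv),
        window=window,
        rng=np.random.default_rng(ss_a),
        **kwargs,
    )
    series_b, truth_b = simulate_series(
        compounds,
        schedule,
        drift_a_to_b,
        window=window,
        rng=np.random.default_rng(ss_b),
        **kwargs,
    )
    return TwoSessionSim(series_a, series_b, truth_a, truth_b, drift_a_to_b)


def session_values(
    compounds: Sequence[SimCompound],
    drift: SessionDrift,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-compound measured (t0, tp) for one session, without the full series.

    Applies the session's affine maps and multiplicative noise directly to the
    true values — the value-level counterpart of running the whole extraction
    pipeline on a simulated series.
    """
    rows = []
    for c in compounds:
        tp_map, t0_map = drift.maps_for(c.class_tag)
        tp = float(tp_map(c.true_tp))
        t0 = float(t0_map(c.true_t0))
        if drift.noise_cv > 0:
            tp *= 1.0 + rng.normal(0.0, drift.noise_cv)
            t0 *= 1.0 + rng.normal(0.0, drift.noise_cv)
        rows.append(
            {
                "name": c.name,
                "adduct": c.adduct,
                "class_tag": c.class_tag,
                "mz": c.mz,
                "true_t0": c.true_t0,
                "true_tp": c.true_tp,
                "t0": t0,
                "tp": tp,
            }
        )
    return pd.DataFrame(rows)
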