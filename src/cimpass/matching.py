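"""m/z matching of detected peaks against reference compounds.

Two kinds of mass matching occur in the workflow: targeted matching of each
reference compound (lipid standard adduct) to at most one peak per acquisition
within a ppm window, and untargeted screening of a feature list against a
reference m/z catalogue (e.g. positive-ion masses from a lipid structure
database) within an absolute Da window.

Conventions: ppm errors are computed relative to the *reference* m/z (the
database-search convention); the ppm window is inclusive ("within"), while the
Da catalogue screen is strict (``< tol_da``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .peaktable import Peak, PeakTable

_CLASS_TAGS = ("lipid", "nonlipid")
_ROLES = ("calibrant", "analyte")


@dataclass(frozen=True)
class CompoundRef:
    """A reference compound adduct with its theoretical m/z.

    ``role`` marks compounds used to fit inter-session correction lines
    (calibrants) versus compounds being measured (analytes); ``class_tag``
    distinguishes lipids from nonlipids, which follow slightly different
    correction lines under the traveling wave.
    """

    name: str
    adduct: str
    ref_mz: float
    class_tag: str = "lipid"
    role: str = "analyte"

    def __post_init__(self) -> None:
        if not self.ref_mz > 0:
            raise ValueError(f"ref_mz must be positive, got {self.ref_mz}")
        if self.class_tag not in _CLASS_TAGS:
            raise ValueError(f"class_tag must be one of {_CLASS_TAGS}")
        if self.role not in _ROLES:
            raise ValueError(f"role must be one of {_ROLES}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.name, self.adduct)


def ppm_error(mz: float, ref_mz: float) -> float:
    """Signed mass error in parts per million, relative to the reference m/z."""
    return (mz - ref_mz) / ref_mz * 1e6


def match_mz(table: PeakTable, ref: CompoundRef, tol_ppm: float = 10.0) -> Peak | None:
    """Find the peak matching ``ref`` within ``tol_ppm``; most intense wins.

    Returns ``None`` when no peak falls inside the window (absence is a valid
    result). Ties on intensity break to the smaller |ppm error|, then to the
    lower m/z, so the result does not depend on peak ordering.
    """
    if not tol_ppm > 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    best: Peak | None = None
    best_key: tuple[float, float, float] | None = None
    for peak in table:
        err = abs(ppm_error(peak.mz, ref.ref_mz))
        if err <= tol_ppm:
            key = (-peak.intensity, err, peak.mz)
            if best_key is None or key < best_key:
                best, best_key = peak, key
    return best


def screen_mz_catalogue(features, catalogue: Sequence[float], tol_da: float = 0.005):
    """Retain features whose m/z lies within ``tol_da`` (strict) of any catalogue mass.

    ``features`` may be a DataFrame with an ``mz`` column (a filtered copy is
    returned) or a 1-D sequence of m/z values (a retained array is returned).
    The catalogue stands in for an external structure-database mass list and
    must be non-empty.
    """
    if not tol_da > 0:
        raise ValueError(f"tol_da must be positive, got {tol_da}")
    cat = np.asarray(catalogue, dtype=float).ravel()
    if cat.size == 0:
        raise ValueError("catalogue is empty")
    if isinstance(features, pd.DataFrame):
        mzs = features["mz"].to_numpy(dtype=float)
    else:
        mzs = np.asarray(features, dtype=float).ravel()
    dmin = np.abs(mzs[:, None] - cat[None, :]).min(axis=1)
    mask = dmin < tol_da
    if isinstance(features, pd.DataFrame):
        return features.loc[mask]
    return mzs[mask]


def read_reference_list(path) -> list[CompoundRef]:
    """Read a reference compound list (CSV: name, adduct, ref_mz, class_tag, role)."""
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"name", "adduct", "ref_mz"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"reference list missing column(s) {sorted(missing)}")
    refs = []
    seen = set()
    for row in frame.itertuples(index=False):
        ref = CompoundRef(
            name=str(row.name),
            adduct=str(row.adduct),
            ref_mz=float(row.ref_mz),
            class_tag=str(getattr(row, "class_tag", "lipid")),
            role=str(getattr(row, "role", "analyte")),
        )
        if ref.key in seen:
            raise ValueError(f"duplicate reference compound {ref.key}")
        seen.add(ref.key)
        refs.append(ref)
    if not refs:
        raise ValueError(f"reference list {path} is empty")
    return refs


def write_reference_list(refs: Iterable[CompoundRef], path) -> None:
    pd.DataFrame(
        [
            {
                "name": r.name,
                "adduct": r.adduct,
                "ref_mz": r.ref_mz,
                "class_tag": r.class_tag,
                "role": r.role,
            }
            for r in refs
        ]
    ).to_csv(path, index=False)


def read_catalogue(path) -> np.ndarray:
    """Read a one-column m/z catalogue (plain text or CSV, header optional)."""
    values = []
    for line in Path(path).read_text().splitlines():
        token = line.strip().split(",")[0].strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            continue  # header or comment line
    if not values:
        raise ValueError(f"catalogue {path} contains no m/z values")
    return np.asarray(values, dtype=float)
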