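"""Core record types shared across the pipeline.

All concentrations are mass-based (mg C/L for carbon, mg N/L for nitrogen
species), absorbance is decadal (base-10, as read off a spectrophotometer),
and cuvette path lengths are in metres.  Missing numeric values are
represented as ``None`` on records and as NaN inside tables; they are never
silently replaced by zero.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Closed vocabulary of hydrologic settings; anything else is flagged "other".
HYDRO_SETTINGS = frozenset(
    {"groundwater", "pond", "creek", "river", "lake", "seep", "other"}
)

#: Rounding tolerance (percentage points) allowed on the sum of LC-OCD fractions.
LCOCD_SUM_TOLERANCE = 2.0


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SampleMeta:
    """Sampling metadata: geographic site code and hydrologic setting."""

    sample_id: str
    site: str
    hydro_setting: str
    date: Optional[_dt.date] = None

    def __post_init__(self):
        if self.hydro_setting not in HYDRO_SETTINGS:
            raise ValueError(
                f"sample {self.sample_id!r}: hydro_setting {self.hydro_setting!r} "
                f"not in {sorted(HYDRO_SETTINGS)}; use 'other'"
            )


@dataclass(frozen=True)
class Spectrum:
    """One sample's decadal absorbance spectrum.

    Parameters
    ----------
    wavelengths : array, nm, strictly increasing
    absorbance : array, decadal absorbance A (unitless), same length
    path_length : cuvette path length L in metres (1 cm cuvette -> 0.01)
    """

    sample_id: str
    wavelengths: np.ndarray
    absorbance: np.ndarray
    path_length: float

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "absorbance", ab)
        if wl.ndim != 1 or ab.shape != wl.shape:
            raise ValueError(
                f"sample {self.sample_id!r}: wavelengths and absorbance must be "
                "1-D arrays of equal length"
            )
        if wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError(
                f"sample {self.sample_id!r}: wavelengths must be strictly increasing"
            )
        if not np.all(np.isfinite(ab)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite absorbance value")
        if not (self.path_length > 0):
            raise ValueError(
                f"sample {self.sample_id!r}: path_length must be > 0 m, "
                f"got {self.path_length}"
            )

    def covers(self, lo: float, hi: float) -> bool:
        """Whether the wavelength grid spans [lo, hi] nm."""
        return self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi


@dataclass(frozen=True)
class ChemRecord:
    """DOC and dissolved nitrogen species for one sample (mg/L)."""

    sample_id: str
    doc: float
    tdn: Optional[float] = None
    no3: Optional[float] = None
    no2: Optional[float] = None
    nh4: Optional[float] = None

    def __post_init__(self):
        if _is_missing(self.doc):
            raise ValueError(f"sample {self.sample_id!r}: doc is required")
        if self.doc < 0:
            raise ValueError(f"sample {self.sample_id!r}: doc must be >= 0")
        for name in ("tdn", "no3", "no2", "nh4"):
            v = getattr(self, name)
            if not _is_missing(v) and v < 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name} must be >= 0, got {v}"
                )


@dataclass(frozen=True)
class LCOCDRecord:
    """Size-exclusion (LC-OCD) fractions as % of DOM plus nominal HS MW."""

    sample_id: str
    bp: float
    hsf: float
    bb: float
    lmwn: float
    lmwa: float
    hs_mw: Optional[float] = None

    def __post_init__(self):
        total = 0.0
        for name in ("bp", "hsf", "bb", "lmwn", "lmwa"):
            v = getattr(self, name)
            if _is_missing(v):
                continue
            if not (0.0 <= v <= 100.0):
                raise ValueError(
                    f"sample {self.sample_id!r}: fraction {name}={v} outside [0, 100]"
                )
            total += v
        if total > 100.0 + LCOCD_SUM_TOLERANCE:
            raise ValueError(
                f"sample {self.sample_id!r}: LC-OCD fractions sum to {total:.2f}% "
                f"(> 100 + {LCOCD_SUM_TOLERANCE} tolerance)"
            )


@dataclass
class SampleSet:
    """Joined per-sample collection; any block may be missing for a sample."""

    meta: dict[str, SampleMeta] = field(default_factory=dict)
    spectra: dict[str, Spectrum] = field(default_factory=dict)
    chem: dict[str, ChemRecord] = field(default_factory=dict)
    lcocd: dict[str, LCOCDRecord] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        """Sorted union of ids across all blocks (deterministic join order)."""
        ids = set(self.meta) | set(self.spectra) | set(self.chem) | set(self.lcocd)
        return sorted(ids)

    def missing_blocks(self, sample_id: str) -> list[str]:
        out = []
        for name in ("meta", "spectra", "chem", "lcocd"):
            if sample_id not in getattr(self, name):
                out.append(name)
        return out
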