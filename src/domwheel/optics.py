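"""Absorbance-derived DOM composition measures.

All indices are computed from a decadal absorbance spectrum.  The Naperian
absorption coefficient is

    a(lambda) = ln(10) * A(lambda) / L        [m^-1]

with A the decadal absorbance and L the cuvette path length in metres.

Note on SUVA: here SUVA is the specific absorption coefficient at **255 nm**
computed as ``ln(10) * A_255 / (L * DOC)`` in L mg^-1 m^-1, i.e. it carries
the ln(10) factor.  The widespread SUVA254 convention uses decadal absorbance
at 254 nm without ln(10); values from the two conventions differ by a factor
of ~2.303 and must not be mixed.  SAC350 and SAC420 are the same quantity at
350 and 420 nm.

Spectral slopes are fitted with nonlinear least squares on the Naperian
coefficients,

    a(lambda) = a_ref * exp(-S * (lambda - lambda_ref)),

with S > 0 for a normally decaying CDOM spectrum; an ordinary least-squares
fit of ln(a) vs lambda is available as a cross-check (``method="log_linear"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import Spectrum

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: Default fit windows (nm) for the two spectral slopes.
WINDOW_275_295 = (275.0, 295.0)
WINDOW_350_400 = (350.0, 400.0)


def naperian(absorbance, path_length: float):
    """Naperian absorption coefficient a = ln(10) * A / L, in m^-1.

    Vectorized over ``absorbance``.  Negative absorbance yields negative a
    (flagged downstream, not rejected here).
    """
    if not (path_length > 0):
        raise ValueError(f"path_length must be > 0 m, got {path_length}")
    return LN10 * np.asarray(absorbance, dtype=float) / path_length


def absorbance_at(spectrum: Spectrum, lam: float) -> float:
    """Decadal absorbance at ``lam`` nm; linear interpolation off-grid."""
    wl = spectrum.wavelengths
    if lam < wl[0] or lam > wl[-1]:
        raise ValueError(
            f"wavelength {lam} nm outside spectrum coverage "
            f"[{wl[0]:g}, {wl[-1]:g}] nm for sample {spectrum.sample_id!r}"
        )
    return float(np.interp(lam, wl, spectrum.absorbance))


def _ratio(spectrum: Spectrum, lam_num: float, lam_den: float, name: str) -> float:
    a_num = absorbance_at(spectrum, lam_num)
    a_den = absorbance_at(spectrum, lam_den)
    if a_den <= 0:
        logger.warning(
            "%s: A_%g = %g <= 0 for sample %r; %s set to missing",
            name, lam_den, a_den, spectrum.sample_id, name,
        )
        return float("nan")
    return a_num / a_den


def e2_e3(spectrum: Spectrum) -> float:
    """E2:E3 = A255 / A365 (inversely related to molecular size).

    The ratio is identical whether decadal or Naperian values are used.
    """
    return _ratio(spectrum, 255.0, 365.0, "E2:E3")


def e4_e6(spectrum: Spectrum) -> float:
    """E4:E6 = A465 / A665 (humic molecular weight and size proxy)."""
    return _ratio(spectrum, 465.0, 665.0, "E4:E6")


def specific_absorbance(spectrum: Spectrum, doc: float, lam: float) -> float:
    """DOC-specific Naperian absorption coefficient at ``lam``, L mg^-1 m^-1.

    ``ln(10) * A_lam / (L * doc)``; SUVA is lam=255, SAC350 lam=350,
    SAC420 lam=420.
    """
    if doc is None or not np.isfinite(doc) or doc <= 0:
        logger.warning(
            "specific absorbance at %g nm: DOC=%r invalid for sample %r; missing",
            lam, doc, spectrum.sample_id,
        )
        return float("nan")
    a = naperian(absorbance_at(spectrum, lam), spectrum.path_length)
    return float(a) / doc


def suva(spectrum: Spectrum, doc: float) -> float:
    """Specific UV absorbance at 255 nm (aromaticity proxy), L mg^-1 m^-1."""
    return specific_absorbance(spectrum, doc, 255.0)


def sac350(spectrum: Spectrum, doc: float) -> float:
    return specific_absorbance(spectrum, doc, 350.0)


def sac420(spectrum: Spectrum, doc: float) -> float:
    return specific_absorbance(spectrum, doc, 420.0)


@dataclass(frozen=True)
class SlopeFit:
    """Result of an exponential fit to the absorption spectrum.

    ``s`` is the spectral slope in nm^-1 (positive for a decaying spectrum),
    ``a_ref`` the fitted Naperian amplitude (m^-1) at ``lam_ref``.
    """

    s: float
    a_ref: float
    lam_ref: float
    window: tuple[float, float]
    rss: float
    n_points: int
    method: str

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("SlopeFit requires n_points >= 3")
        if self.method not in ("nonlinear", "log_linear"):
            raise ValueError(f"unknown slope fit method {self.method!r}")


def _log_linear_fit(lam: np.ndarray, a: np.ndarray, lam_ref: float):
    slope, intercept = np.polyfit(lam - lam_ref, np.log(a), 1)
    return -slope, math.exp(intercept)


def spectral_slope(
    spectrum: Spectrum,
    window: tuple[float, float] = WINDOW_275_295,
    lam_ref: float | None = None,
    method: str = "nonlinear",
) -> SlopeFit | None:
    """Fit a(lambda) = a_ref * exp(-S (lambda - lambda_ref)) over a window.

    Window endpoints are inclusive; points with a <= 0 (log undefined,
    instrument noise floor) are excluded.  Returns ``None`` with a warning if
    fewer than 3 usable points remain.  On non-convergence of the nonlinear
    fit, falls back to the log-linear estimate with a warning.
    """
    if method not in ("nonlinear", "log_linear"):
        raise ValueError(f"unknown slope fit method {method!r}")
    lo, hi = window
    if lam_ref is None:
        lam_ref = lo
    wl = spectrum.wavelengths
    mask = (wl >= lo) & (wl <= hi)
    lam = wl[mask]
    a = naperian(spectrum.absorbance[mask], spectrum.path_length)
    pos = a > 0
    lam, a = lam[pos], a[pos]
    if lam.size < 3:
        logger.warning(
            "spectral slope %s: only %d usable points (a > 0) in window for "
            "sample %r; slope set to missing",
            window, lam.size, spectrum.sample_id,
        )
        return None

    s0, a0 = _log_linear_fit(lam, a, lam_ref)
    if method == "log_linear":
        s_hat, a_hat = s0, a0
        used = "log_linear"
    else:
        def model(x, a_ref, s):
            return a_ref * np.exp(-s * (x - lam_ref))

        try:
            (a_hat, s_hat), _ = curve_fit(
                model, lam, a, p0=(a0, s0), maxfev=10000
            )
            used = "nonlinear"
        except RuntimeError:
            logger.warning(
                "nonlinear slope fit did not converge for sample %r window %s; "
                "falling back to log-linear",
                spectrum.sample_id, window,
            )
            s_hat, a_hat = s0, a0
            used = "log_linear"

    resid = a - a_hat * np.exp(-s_hat * (lam - lam_ref))
    return SlopeFit(
        s=float(s_hat),
        a_ref=float(a_hat),
        lam_ref=float(lam_ref),
        window=(float(lo), float(hi)),
        rss=float(np.dot(resid, resid)),
        n_points=int(lam.size),
        method=used,
    )


def slope_ratio(fit_275_295: SlopeFit | None, fit_350_400: SlopeFit | None) -> float:
    """Slope ratio S_R = S(275-295) / S(350-400)."""
    if fit_275_295 is None or fit_350_400 is None:
        return float("nan")
    if fit_350_400.s == 0:
        logger.warning("slope ratio: S(350-400) is 0; S_R set to missing")
        return float("nan")
    return fit_275_295.s / fit_350_400.s
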