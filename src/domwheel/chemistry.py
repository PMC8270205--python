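"""DON by difference and the molar DOC:DON ratio.

DON = TDN - (NO3-N + NO2-N + NH4-N), all in mg N/L.  A negative difference
(inorganic species over-subtracting TDN within analytical error) is returned
as missing, not clipped to zero, so downstream ratios are never fabricated
from near-zero denominators.

DOC:DON is molar: (DOC / M_C) / (DON / M_N) with M_C = 12.011 g/mol and
M_N = 14.007 g/mol.
"""

from __future__ import annotations

import logging
import math

logger = logging.getLogger(__name__)

ATOMIC_MASS_C = 12.011  # g/mol
ATOMIC_MASS_N = 14.007  # g/mol

_NAN = float("nan")


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def don(tdn, no3, no2, nh4) -> float:
    """Dissolved organic nitrogen by difference, mg N/L.

    Returns NaN if any input is missing, or if the difference is negative
    (with a warning about over-subtraction).
    """
    if any(_missing(v) for v in (tdn, no3, no2, nh4)):
        return _NAN
    result = tdn - (no3 + no2 + nh4)
    if result < 0:
        logger.warning(
            "DON negative (TDN=%g < inorganic N sum %g); set to missing",
            tdn, no3 + no2 + nh4,
        )
        return _NAN
    return float(result)


def doc_don_ratio(doc, don_value) -> float:
    """Molar DOC:DON ratio, (doc/12.011) / (don/14.007); unitless."""
    if _missing(doc) or _missing(don_value):
        return _NAN
    if don_value <= 0:
        logger.warning("DOC:DON: DON=%g <= 0; ratio set to missing", don_value)
        return _NAN
    if doc <= 0:
        logger.warning("DOC:DON: DOC=%g <= 0; ratio set to missing", doc)
        return _NAN
    return (doc / ATOMIC_MASS_C) / (don_value / ATOMIC_MASS_N)
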