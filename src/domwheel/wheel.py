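"""Composition Wheels: normalization, polygon geometry, and classification.

A Composition Wheel places k concentration-independent composition measures
(default k = 4: SUVA, S275-295, HSF, DOC:DON) on radial axes.  Each sample's
value is min-max normalized against the reference dataset,

    v_i = (x_i - min_i) / (max_i - min_i),  clipped to [0, 1],

and the normalized values are joined into a polygon whose shape encodes DOM
character independently of concentration.  With four orthogonal axes the
polygon area reduces to (1/2) * sum_i v_i * v_{i+1}.

End-member templates express characteristic compositions (organic-rich
groundwater DOM; photolyzed surface-water DOM; and conventions for three
further qualitative source/degradation shapes) on the same normalized axes;
samples are classified by nearest template in normalized space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical axis order and default on-screen orientation: SUVA up-left,
#: S275-295 up-right, HSF down-right, DOC:DON down-left (clockwise), so the
#: photolyzed end member elongates toward the top-right corner.
DEFAULT_AXIS_METRICS = ("suva", "s275_295", "hsf", "doc_don")

#: Numeric anchors for qualitative template levels.
LEVEL_ANCHORS = {"low": 0.15, "mid": 0.5, "high": 0.85}

#: Nearest-template distance beyond which a sample is "intermediate".
DEFAULT_CLASSIFY_CUTOFF = 0.6

TEMPLATE_NAMES = (
    "groundwater",
    "photolyzed",
    "microbially_degraded",
    "terrestrial_leachate",
    "aquatic_production",
)

#: Qualitative levels per template on the canonical axes.  The groundwater
#: end member uses high DOC:DON (observed dataset extreme); a variant with
#: low DOC:DON is available via ``default_templates``.
_TEMPLATE_LEVELS = {
    "groundwater": {"suva": "high", "s275_295": "low", "hsf": "high", "doc_don": "high"},
    "photolyzed": {"suva": "low", "s275_295": "high", "hsf": "low", "doc_don": "low"},
    "microbially_degraded": {"suva": "high", "s275_295": "mid", "hsf": "mid", "doc_don": "low"},
    "terrestrial_leachate": {"suva": "mid", "s275_295": "low", "hsf": "high", "doc_don": "high"},
    "aquatic_production": {"suva": "low", "s275_295": "mid", "hsf": "low", "doc_don": "low"},
}

#: Expected direction of change of each axis under a degradation process:
#: photolysis raises S275-295 and lowers the other three; microbial
#: degradation raises SUVA, lowers DOC:DON, and leaves S275-295 and HSF
#: unchanged.
DEGRADATION_SHIFTS = {
    "photolysis": {"suva": -1, "s275_295": +1, "hsf": -1, "doc_don": -1},
    "microbial": {"suva": +1, "s275_295": 0, "hsf": 0, "doc_don": -1},
}


def default_angles(k: int) -> tuple[float, ...]:
    """Evenly spaced axis angles (degrees), clockwise from 135 deg (up-left)."""
    if k < 3:
        raise ValueError("a wheel needs at least 3 axes")
    return tuple(135.0 - 360.0 * i / k for i in range(k))


@dataclass(frozen=True)
class AxisSpec:
    """One wheel axis: metric name, normalization bounds, screen angle."""

    metric: str
    vmin: float
    vmax: float
    angle_deg: float
    direction_label: str = ""

    def __post_init__(self):
        if not (self.vmax > self.vmin):
            raise ValueError(
                f"axis {self.metric!r}: max ({self.vmax}) must exceed min "
                f"({self.vmin})"
            )


@dataclass(frozen=True)
class Wheel:
    """An ordered tuple of normalized axis values in [0, 1] for one sample."""

    key: str
    values: tuple[float, ...]
    axes: tuple[AxisSpec, ...]

    def __post_init__(self):
        if len(self.values) != len(self.axes):
            raise ValueError("values and axes length mismatch")
        if any(not (0.0 <= v <= 1.0) for v in self.values):
            raise ValueError(f"wheel {self.key!r}: values must lie in [0, 1]")

    @property
    def metrics(self) -> tuple[str, ...]:
        return tuple(ax.metric for ax in self.axes)


def fit_axes(
    metric_table: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_AXIS_METRICS,
    angles: tuple[float, ...] | None = None,
) -> tuple[AxisSpec, ...]:
    """Determine per-metric min/max bounds over the reference dataset."""
    if angles is None:
        angles = default_angles(len(metrics))
    if len(angles) != len(metrics):
        raise ValueError("angles and metrics length mismatch")
    axes = []
    for metric, angle in zip(metrics, angles):
        if metric not in metric_table.columns:
            raise ValueError(f"metric {metric!r} not in metric table")
        col = metric_table[metric].dropna()
        if col.nunique() < 2:
            raise ValueError(
                f"metric {metric!r}: needs >= 2 distinct finite values to set "
                "normalization bounds (constant or empty column)"
            )
        axes.append(
            AxisSpec(metric=metric, vmin=float(col.min()), vmax=float(col.max()),
                     angle_deg=float(angle))
        )
    return tuple(axes)


def axes_from_bounds(
    bounds: pd.DataFrame, angles: tuple[float, ...] | None = None
) -> tuple[AxisSpec, ...]:
    """Build axes from an explicit ``metric,min,max`` bounds table."""
    metrics = list(bounds["metric"])
    if angles is None:
        angles = default_angles(len(metrics))
    return tuple(
        AxisSpec(metric=m, vmin=float(lo), vmax=float(hi), angle_deg=float(a))
        for m, lo, hi, a in zip(metrics, bounds["min"], bounds["max"], angles)
    )


def normalize(sample_metrics, axes: tuple[AxisSpec, ...], key: str = "") -> Wheel | None:
    """Min-max normalize one sample onto the wheel axes.

    ``sample_metrics`` is a mapping (or Series) of metric name -> value.
    Returns ``None`` (reported) if any axis metric is missing; values beyond
    the reference bounds are clipped to [0, 1] with a logged warning.
    """
    values = []
    for ax in axes:
        x = sample_metrics.get(ax.metric) if hasattr(sample_metrics, "get") else None
        if x is None or (isinstance(x, float) and math.isnan(x)):
            logger.warning(
                "sample %r: metric %r missing; no wheel constructed", key, ax.metric
            )
            return None
        v = (float(x) - ax.vmin) / (ax.vmax - ax.vmin)
        if v < 0.0 or v > 1.0:
            logger.warning(
                "sample %r: %s = %g outside reference bounds [%g, %g]; clipped",
                key, ax.metric, x, ax.vmin, ax.vmax,
            )
            v = min(max(v, 0.0), 1.0)
        values.append(v)
    return Wheel(key=key, values=tuple(values), axes=tuple(axes))


def wheels_from_table(
    metric_table: pd.DataFrame, axes: tuple[AxisSpec, ...]
) -> dict[str, Wheel]:
    """Normalize every table row that has all axis metrics present."""
    out: dict[str, Wheel] = {}
    for key, row in metric_table.iterrows():
        k = key if isinstance(key, str) else "/".join(map(str, np.atleast_1d(key)))
        w = normalize(row, axes, key=k)
        if w is not None:
            out[k] = w
    return out


def polygon(wheel: Wheel, radius: float = 1.0) -> np.ndarray:
    """Planar vertex coordinates: vertex i at (r v_i cos t_i, r v_i sin t_i)."""
    theta = np.deg2rad([ax.angle_deg for ax in wheel.axes])
    v = np.asarray(wheel.values)
    return radius * np.column_stack([v * np.cos(theta), v * np.sin(theta)])


def area(wheel: Wheel) -> float:
    """Shoelace area of the wheel polygon at unit radius.

    For four orthogonal axes this equals (1/2) * sum_i v_i v_{i+1}.
    """
    pts = polygon(wheel, radius=1.0)
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def distance(wheel_a: Wheel, wheel_b: Wheel) -> float:
    """Euclidean distance between two wheels in normalized axis space."""
    if wheel_a.metrics != wheel_b.metrics or any(
        abs(a.angle_deg - b.angle_deg) > 1e-9
        for a, b in zip(wheel_a.axes, wheel_b.axes)
    ):
        raise ValueError(
            f"wheels have mismatched axes: {wheel_a.metrics} vs {wheel_b.metrics}"
        )
    return float(
        np.linalg.norm(np.asarray(wheel_a.values) - np.asarray(wheel_b.values))
    )


def template_wheel(
    name: str,
    axes: tuple[AxisSpec, ...],
    levels: dict[str, str] | None = None,
) -> Wheel:
    """Build a template wheel from qualitative low/mid/high levels."""
    if levels is None:
        levels = _TEMPLATE_LEVELS[name]
    values = tuple(LEVEL_ANCHORS[levels[ax.metric]] for ax in axes)
    return Wheel(key=name, values=values, axes=tuple(axes))


def default_templates(
    axes: tuple[AxisSpec, ...],
    names: tuple[str, ...] = ("groundwater", "photolyzed"),
    groundwater_caption_variant: bool = False,
) -> dict[str, Wheel]:
    """End-member template wheels on the given axes.

    ``groundwater_caption_variant=True`` switches the groundwater template's
    DOC:DON level from high to low.
    """
    out = {}
    for name in names:
        levels = dict(_TEMPLATE_LEVELS[name])
        if name == "groundwater" and groundwater_caption_variant:
            levels["doc_don"] = "low"
        out[name] = template_wheel(name, axes, levels)
    return out


def classify(
    wheel: Wheel,
    templates: dict[str, Wheel],
    cutoff: float = DEFAULT_CLASSIFY_CUTOFF,
) -> tuple[str, float]:
    """Nearest end-member template; "intermediate" beyond the cutoff.

    Ties are broken by template insertion order and logged.
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    dists = {name: distance(wheel, t) for name, t in templates.items()}
    best = min(dists, key=lambda n: dists[n])
    tied = [n for n, d in dists.items() if d == dists[best] and n != best]
    if tied:
        logger.info(
            "wheel %r equidistant from %s; tie broken by template order -> %r",
            wheel.key, [best, *tied], best,
        )
    if dists[best] > cutoff:
        return "intermediate", dists[best]
    return best, dists[best]


def degradation_shift(wheel: Wheel, process: str) -> dict[str, int]:
    """Expected direction of each wheel axis under a degradation process.

    Returns a metric -> sign (-1, 0, +1) annotation; never applied to the
    data.  ``process`` is "photolysis" or "microbial".
    """
    if process not in DEGRADATION_SHIFTS:
        raise ValueError(
            f"unknown process {process!r}; expected one of "
            f"{sorted(DEGRADATION_SHIFTS)}"
        )
    shifts = DEGRADATION_SHIFTS[process]
    unknown = [m for m in wheel.metrics if m not in shifts]
    if unknown:
        raise ValueError(
            f"no documented {process} response for axis metric(s) {unknown}"
        )
    return {m: shifts[m] for m in wheel.metrics}
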