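"""Deterministic figure output: single wheels, overlays, faceted grids.

SVG is the canonical format: files are assembled from plain element strings
with fixed numeric formatting, no timestamps and no generated ids, so
identical inputs give byte-identical output (diffable in tests).  PNG is a
convenience rasterization through matplotlib.

Layout mirrors the survey-figure convention: colour encodes geographic
site, panel encodes hydrologic setting, end-member samples get a heavier
highlight stroke.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .datatypes import SampleMeta
from .wheel import Wheel, polygon

logger = logging.getLogger(__name__)

_FMT = "{:.3f}"

#: Default site colour cycle (stable assignment by sorted site name).
_PALETTE = (
    "#1b9e77", "#d95f02", "#7570b3", "#e7298a",
    "#66a61e", "#e6ab02", "#a6761d", "#666666",
)


@dataclass(frozen=True)
class RenderSpec:
    """Figure options; ``fmt`` must be "svg" or "png"."""

    facet_keys: tuple[str, ...] = ("site", "hydro_setting")
    colors: dict = field(default_factory=dict)
    radius_px: float = 80.0
    show_axis_labels: bool = True
    overlay_templates: bool = False
    fmt: str = "svg"
    highlight_ids: frozenset = frozenset()

    def __post_init__(self):
        if self.fmt not in ("svg", "png"):
            raise ValueError(f"output format must be 'svg' or 'png', got {self.fmt!r}")


def _f(x: float) -> str:
    return _FMT.format(x)


def _points_attr(wheel: Wheel, radius: float, cx: float, cy: float) -> str:
    pts = polygon(wheel, radius=radius)
    # SVG y grows downward
    return " ".join(f"{_f(cx + x)},{_f(cy - y)}" for x, y in pts)


def _axis_glyphs(axes, radius: float, cx: float, cy: float, labels: bool) -> list[str]:
    import math

    out = []
    for ax in axes:
        t = math.radians(ax.angle_deg)
        x, y = radius * math.cos(t), radius * math.sin(t)
        out.append(
            f'<line class="axis" x1="{_f(cx)}" y1="{_f(cy)}" '
            f'x2="{_f(cx + x)}" y2="{_f(cy - y)}" stroke="#bbbbbb" '
            'stroke-width="1"/>'
        )
        if labels:
            lx, ly = 1.22 * x, 1.22 * y
            out.append(
                f'<text class="axis-label" x="{_f(cx + lx)}" y="{_f(cy - ly)}" '
                'font-size="10" text-anchor="middle" '
                f'dominant-baseline="middle">{ax.metric}</text>'
            )
    return out


def _wheel_polygon(wheel: Wheel, radius, cx, cy, color, highlight=False,
                   dashed=False) -> str:
    stroke_width = "2.5" if highlight else "1.2"
    dash = ' stroke-dasharray="4 3"' if dashed else ""
    return (
        f'<polygon class="wheel" data-key="{wheel.key}" '
        f'points="{_points_attr(wheel, radius, cx, cy)}" '
        f'fill="{color}" fill-opacity="0.15" stroke="{color}" '
        f'stroke-width="{stroke_width}"{dash}/>'
    )


def _panel(wheels, axes, spec, cx, cy, colors, templates=None, title="") -> list[str]:
    r = spec.radius_px
    parts = _axis_glyphs(axes, r, cx, cy, spec.show_axis_labels)
    if title:
        parts.append(
            f'<text class="panel-title" x="{_f(cx)}" y="{_f(cy - 1.45 * r)}" '
            f'font-size="11" text-anchor="middle">{title}</text>'
        )
    if templates:
        for name, tw in templates.items():
            parts.append(
                _wheel_polygon(tw, r, cx, cy, color="#999999", dashed=True)
            )
    for w in wheels:
        color = colors.get(w.key, "#1b9e77")
        parts.append(
            _wheel_polygon(w, r, cx, cy, color, highlight=w.key in spec.highlight_ids)
        )
    return parts


def _write_svg(parts: list[str], width: float, height: float, path) -> None:
    body = "\n".join(parts)
    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" '
        f'height="{_f(height)}" viewBox="0 0 {_f(width)} {_f(height)}">\n'
        f"{body}\n</svg>\n"
    )
    Path(path).write_text(svg, encoding="utf-8")


def _rasterize_svg_polygons(wheels_and_panels, width, height, path):
    # minimal matplotlib rasterization of the same geometry
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Polygon as MplPolygon

    fig, ax = plt.subplots(figsize=(width / 96, height / 96), dpi=96)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)
    ax.axis("off")
    for verts, color, lw in wheels_and_panels:
        ax.add_patch(MplPolygon(verts, closed=True, fill=True, alpha=0.2,
                                facecolor=color, edgecolor=color, lw=lw))
    fig.savefig(path, dpi=96)
    plt.close(fig)


def site_colors(sites) -> dict[str, str]:
    """Stable colour per site (sorted assignment from a fixed palette)."""
    return {s: _PALETTE[i % len(_PALETTE)] for i, s in enumerate(sorted(set(sites)))}


def render_wheel(
    wheels: list[Wheel],
    spec: RenderSpec,
    path,
    templates: dict[str, Wheel] | None = None,
    colors: dict[str, str] | None = None,
) -> Path:
    """Render one panel containing the given wheels (optionally overlaid
    end-member templates); returns the written path."""
    if not wheels:
        raise ValueError("render_wheel needs at least one wheel")
    axes = wheels[0].axes
    for w in wheels[1:]:
        if w.metrics != wheels[0].metrics:
            raise ValueError("all wheels in one panel must share an AxisSpec set")
    r = spec.radius_px
    size = 3.2 * r
    cx = cy = size / 2
    colors = colors or {}
    tpl = templates if (templates and spec.overlay_templates) else None
    parts = _panel(wheels, axes, spec, cx, cy, colors, templates=tpl)
    path = Path(path)
    if spec.fmt == "svg":
        _write_svg(parts, size, size, path)
    else:
        geo = []
        for w in wheels:
            pts = polygon(w, radius=r)
            verts = [(cx + x, cy - y) for x, y in pts]
            geo.append((verts, colors.get(w.key, "#1b9e77"),
                        2.5 if w.key in spec.highlight_ids else 1.2))
        _rasterize_svg_polygons(geo, size, size, path)
    logger.info("wrote %s (%d wheels)", path, len(wheels))
    return path


def render_facets(
    wheels: dict[str, Wheel],
    meta: dict[str, SampleMeta],
    spec: RenderSpec,
    path,
    templates: dict[str, Wheel] | None = None,
) -> Path:
    """Small-multiple grid, one panel per non-empty (site, setting) pair.

    Wheel keys are matched to metadata by sample id; wheels without metadata
    are skipped with a warning.  Panels are laid out row-major in sorted
    facet order; empty combinations are omitted.
    """
    groups: dict[tuple[str, str], list[Wheel]] = {}
    for key, w in wheels.items():
        m = meta.get(key)
        if m is None:
            logger.warning("wheel %r has no metadata; skipped from facets", key)
            continue
        groups.setdefault((m.site, m.hydro_setting), []).append(w)
    if not groups:
        raise ValueError("no wheels joinable to metadata")

    colors = spec.colors or site_colors(m.site for m in meta.values())
    facet_keys = sorted(groups)
    ncol = min(4, len(facet_keys))
    nrow = -(-len(facet_keys) // ncol)
    r = spec.radius_px
    cell = 3.2 * r
    parts = []
    for idx, fk in enumerate(facet_keys):
        row, col = divmod(idx, ncol)
        cx = col * cell + cell / 2
        cy = row * cell + cell / 2
        panel_wheels = sorted(groups[fk], key=lambda w: w.key)
        wheel_colors = {w.key: colors.get(meta[w.key].site, "#1b9e77")
                        for w in panel_wheels}
        parts.extend(
            _panel(
                panel_wheels, panel_wheels[0].axes, spec, cx, cy, wheel_colors,
                templates=templates if spec.overlay_templates else None,
                title=f"{fk[0]} / {fk[1]}",
            )
        )
    width, height = ncol * cell, nrow * cell
    path = Path(path)
    if spec.fmt == "svg":
        _write_svg(parts, width, height, path)
    else:
        geo = []
        for idx, fk in enumerate(facet_keys):
            row, col = divmod(idx, ncol)
            cx = col * cell + cell / 2
            cy = row * cell + cell / 2
            for w in sorted(groups[fk], key=lambda w: w.key):
                pts = polygon(w, radius=r)
                verts = [(cx + x, cy - y) for x, y in pts]
                geo.append((verts, colors.get(meta[w.key].site, "#1b9e77"),
                            2.5 if w.key in spec.highlight_ids else 1.2))
        _rasterize_svg_polygons(geo, width, height, path)
    logger.info("wrote %s (%d panels)", path, len(facet_keys))
    return path
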