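"""Gaze visualization at three abstraction levels.

* ``render_heatmap`` — high abstraction: fixation-count attention map
  (per-pixel accumulation of fixation samples, Gaussian smoothed, mapped
  through a colormap; zero-count pixels stay transparent).
* ``render_scanpath`` — low abstraction: fixation centroids as dots joined
  by straight links in time order, optionally over the raw points.
* ``render_abstract_movement`` — mid abstraction: one heatmap layer per
  stare segment coloured by time order, consecutive layers joined by a
  tapered movement link whose colour stretches from the source layer's
  colour to the destination layer's colour.  Anchors are pulled slightly
  outside the layer's density core so overlapping paths stay separable;
  taper runs thick (source) to thin (destination) to encode direction.

All renderers are deterministic and return RGBA uint8 arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib
import numpy as np
from PIL import Image, ImageDraw
from scipy.ndimage import gaussian_filter

from .core import EventSegment, GazeRecording

__all__ = [
    "Canvas",
    "MovementLink",
    "fixation_count_map",
    "render_heatmap",
    "render_scanpath",
    "render_movement_link",
    "render_abstract_movement",
    "save_png",
]


@dataclass
class Canvas:
    """Raster target and degree->pixel mapping.

    ``extent`` is (xmin, xmax, ymin, ymax) in degrees; None derives it from
    the data with a margin.  ``background`` is an RGBA tuple or an image
    path/array scaled to the canvas.
    """

    width_px: int = 800
    height_px: int = 600
    extent: tuple[float, float, float, float] | None = None
    background: tuple[int, int, int, int] | str | np.ndarray | None = None
    colormap: str = "viridis"

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("canvas size must be positive")
        if matplotlib.colormaps[self.colormap].N < 2:
            raise ValueError("colormap needs at least 2 stops")

    def resolve_extent(self, xs: np.ndarray, ys: np.ndarray, margin: float = 2.0):
        if self.extent is not None:
            return self.extent
        if len(xs) == 0:
            return (-1.0, 1.0, -1.0, 1.0)
        return (
            float(xs.min() - margin),
            float(xs.max() + margin),
            float(ys.min() - margin),
            float(ys.max() + margin),
        )

    def to_px(self, x, y, extent):
        xmin, xmax, ymin, ymax = extent
        px = (np.asarray(x, dtype=float) - xmin) / (xmax - xmin) * self.width_px
        py = (np.asarray(y, dtype=float) - ymin) / (ymax - ymin) * self.height_px
        return px, py

    def px_per_deg(self, extent) -> float:
        xmin, xmax, ymin, ymax = extent
        return min(self.width_px / (xmax - xmin), self.height_px / (ymax - ymin))

    def blank(self) -> np.ndarray:
        img = np.zeros((self.height_px, self.width_px, 4), dtype=np.uint8)
        bg = self.background
        if bg is None:
            return img
        if isinstance(bg, tuple):
            img[:, :] = np.asarray(bg, dtype=np.uint8)
            return img
        if isinstance(bg, (str, Path)):
            pil = Image.open(bg).convert("RGBA").resize((self.width_px, self.height_px))
            return np.asarray(pil, dtype=np.uint8).copy()
        arr = np.asarray(bg, dtype=np.uint8)
        pil = Image.fromarray(arr).convert("RGBA").resize((self.width_px, self.height_px))
        return np.asarray(pil, dtype=np.uint8).copy()


@dataclass
class MovementLink:
    """Tapered, colour-graded link between two consecutive stare layers.

    Width decreases strictly from source to destination; the colour profile
    interpolates from the source layer colour to the destination colour.
    """

    source_layer: int
    dest_layer: int
    source_anchor: tuple[float, float]  # canvas px
    dest_anchor: tuple[float, float]
    width_profile: tuple[float, float] = (6.0, 2.0)  # px at source, destination
    color_profile: tuple[tuple, tuple] = ((255, 0, 0, 255), (0, 0, 255, 255))

    def __post_init__(self) -> None:
        if not self.width_profile[1] < self.width_profile[0]:
            raise ValueError("link width at destination must be < width at source")


def _alpha_composite(base: np.ndarray, over: np.ndarray) -> np.ndarray:
    """Standard 'over' compositing of uint8 RGBA arrays."""
    b = base.astype(np.float64) / 255.0
    o = over.astype(np.float64) / 255.0
    oa = o[..., 3:4]
    ba = b[..., 3:4]
    out_a = oa + ba * (1 - oa)
    with np.errstate(invalid="ignore", divide="ignore"):
        out_rgb = (o[..., :3] * oa + b[..., :3] * ba * (1 - oa)) / np.where(
            out_a > 0, out_a, 1.0
        )
    out = np.concatenate([out_rgb, out_a], axis=-1)
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Heatmap
# ---------------------------------------------------------------------------


def fixation_count_map(
    fixations: Sequence[EventSegment],
    rec: GazeRecording,
    canvas: Canvas,
    extent=None,
) -> np.ndarray:
    """Per-pixel accumulation of fixation-sample counts (pre-smoothing).

    The array total equals the number of fixation samples that fall on the
    canvas; saccade samples contribute nothing.
    """
    extent = extent or canvas.resolve_extent(rec.x, rec.y)
    accum = np.zeros((canvas.height_px, canvas.width_px), dtype=float)
    for seg in fixations:
        if seg.label not in ("fixation", "stare", "smooth_pursuit"):
            continue
        xs = rec.x[seg.start_index : seg.end_index + 1]
        ys = rec.y[seg.start_index : seg.end_index + 1]
        px, py = canvas.to_px(xs, ys, extent)
        ix = np.floor(px).astype(int)
        iy = np.floor(py).astype(int)
        ok = (ix >= 0) & (ix < canvas.width_px) & (iy >= 0) & (iy < canvas.height_px)
        np.add.at(accum, (iy[ok], ix[ok]), 1.0)
    return accum


def render_heatmap(
    fixations: Sequence[EventSegment],
    rec: GazeRecording,
    canvas: Canvas,
    sigma_deg: float = 1.0,
) -> np.ndarray:
    """Gaussian-smoothed fixation-count heatmap as RGBA (transparent at 0)."""
    if not any(
        seg.label in ("fixation", "stare", "smooth_pursuit") for seg in fixations
    ):
        warnings.warn("no fixation segments; returning a blank heatmap")
        return canvas.blank()
    extent = canvas.resolve_extent(rec.x, rec.y)
    accum = fixation_count_map(fixations, rec, canvas, extent)
    sigma_px = sigma_deg * canvas.px_per_deg(extent)
    smooth = gaussian_filter(accum, sigma=sigma_px)
    peak = smooth.max()
    norm = smooth / peak if peak > 0 else smooth
    cmap = matplotlib.colormaps[canvas.colormap]
    rgba = (cmap(norm) * 255).astype(np.uint8)
    rgba[..., 3] = (np.clip(norm, 0, 1) * 255).astype(np.uint8)
    rgba[norm <= 0, 3] = 0
    return _alpha_composite(canvas.blank(), rgba)


# ---------------------------------------------------------------------------
# Scanpath
# ---------------------------------------------------------------------------


def render_scanpath(
    segments: Sequence[EventSegment],
    canvas: Canvas,
    rec: GazeRecording | None = None,
    show_raw: bool = False,
    dot_color=(220, 30, 30, 255),
    link_color=(220, 30, 30, 255),
    base_radius: float = 5.0,
    radius_by_duration: bool = True,
) -> np.ndarray:
    """Fixation/stare centroids as dots joined by straight links in time order.

    When ``show_raw`` the raw gaze points are underlaid as small black dots.
    """
    fix = [s for s in segments if s.label in ("fixation", "stare", "smooth_pursuit")]
    xs = np.array([s.centroid[0] for s in fix])
    ys = np.array([s.centroid[1] for s in fix])
    if rec is not None:
        extent = canvas.resolve_extent(rec.x, rec.y)
    else:
        extent = canvas.resolve_extent(xs, ys)
    img = Image.fromarray(canvas.blank(), mode="RGBA")
    draw = ImageDraw.Draw(img)
    if show_raw and rec is not None:
        rx, ry = canvas.to_px(rec.x, rec.y, extent)
        for x, y in zip(rx, ry):
            draw.ellipse([x - 1, y - 1, x + 1, y + 1], fill=(0, 0, 0, 255))
    if len(fix):
        px, py = canvas.to_px(xs, ys, extent)
        for k in range(len(fix) - 1):
            draw.line(
                [float(px[k]), float(py[k]), float(px[k + 1]), float(py[k + 1])],
                fill=tuple(link_color),
                width=2,
            )
        durations = np.array([s.duration for s in fix])
        dmax = durations.max() if durations.max() > 0 else 1.0
        for k in range(len(fix)):
            r = base_radius
            if radius_by_duration:
                r = base_radius * (0.5 + durations[k] / dmax)
            draw.ellipse(
                [px[k] - r, py[k] - r, px[k] + r, py[k] + r], fill=tuple(dot_color)
            )
    return np.asarray(img, dtype=np.uint8).copy()


# ---------------------------------------------------------------------------
# Abstract gaze-movement visualization
# ---------------------------------------------------------------------------


def render_movement_link(link: MovementLink, canvas: Canvas) -> np.ndarray:
    """Rasterize one tapered link on a transparent canvas.

    The centreline is straight; width and colour interpolate linearly from
    the source to the destination end, drawn as a fan of quads.
    """
    img = Image.new("RGBA", (canvas.width_px, canvas.height_px), (0, 0, 0, 0))
    draw = ImageDraw.Draw(img)
    p0 = np.asarray(link.source_anchor, dtype=float)
    p1 = np.asarray(link.dest_anchor, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length == 0:
        return np.asarray(img, dtype=np.uint8).copy()
    normal = np.array([-d[1], d[0]]) / length
    steps = 32
    c0 = np.asarray(link.color_profile[0], dtype=float)
    c1 = np.asarray(link.color_profile[1], dtype=float)
    w0, w1 = link.width_profile
    for s in range(steps):
        u0 = s / steps
        u1 = (s + 1) / steps
        a0 = p0 + d * u0
        a1 = p0 + d * u1
        hw0 = (w0 + (w1 - w0) * u0) / 2.0
        hw1 = (w0 + (w1 - w0) * u1) / 2.0
        color = tuple(np.round(c0 + (c1 - c0) * (u0 + u1) / 2).astype(int))
        quad = [
            tuple(a0 + normal * hw0),
            tuple(a0 - normal * hw0),
            tuple(a1 - normal * hw1),
            tuple(a1 + normal * hw1),
        ]
        draw.polygon([(float(x), float(y)) for x, y in quad], fill=color)
    return np.asarray(img, dtype=np.uint8).copy()


def movement_links(
    stare_segments: Sequence[EventSegment],
    canvas: Canvas,
    extent,
    sigma_deg: float = 1.0,
    width_profile: tuple[float, float] = (6.0, 2.0),
) -> list[MovementLink]:
    """Build the k-1 links joining k chronological stare layers.

    Anchors are pulled one smoothing bandwidth out of each layer's density
    core along the inter-centroid direction.
    """
    cmap = matplotlib.colormaps[canvas.colormap]
    k = len(stare_segments)
    colors = [
        tuple((np.asarray(cmap(i / max(k - 1, 1))) * 255).round().astype(int))
        for i in range(k)
    ]
    pull_px = sigma_deg * canvas.px_per_deg(extent)
    links = []
    for i in range(k - 1):
        a = np.asarray(
            canvas.to_px(*stare_segments[i].centroid, extent), dtype=float
        )
        b = np.asarray(
            canvas.to_px(*stare_segments[i + 1].centroid, extent), dtype=float
        )
        d = b - a
        norm = float(np.hypot(*d))
        u = d / norm if norm > 0 else np.zeros(2)
        links.append(
            MovementLink(
                source_layer=i,
                dest_layer=i + 1,
                source_anchor=tuple(a + u * pull_px),
                dest_anchor=tuple(b - u * pull_px) if norm > 2 * pull_px else tuple(b),
                width_profile=width_profile,
                color_profile=(colors[i], colors[i + 1]),
            )
        )
    return links


def render_abstract_movement(
    stare_segments: Sequence[EventSegment],
    rec: GazeRecording,
    canvas: Canvas,
    sigma_deg: float = 1.0,
    width_profile: tuple[float, float] = (6.0, 2.0),
    legacy_constant_width: bool = False,
) -> np.ndarray:
    """Time-layered heatmaps joined by tapered, colour-graded links.

    Layers composite oldest-first; each layer is coloured by its time order
    on the canvas colormap.  ``legacy_constant_width`` draws constant-width
    links (the older style) for comparison figures.
    """
    if len(stare_segments) < 1:
        return canvas.blank()
    extent = canvas.resolve_extent(rec.x, rec.y)
    cmap = matplotlib.colormaps[canvas.colormap]
    k = len(stare_segments)
    out = canvas.blank()
    # links go under the layers so anchors visually attach
    wp = width_profile if not legacy_constant_width else (width_profile[0], width_profile[0] - 1e-6)
    for link in movement_links(stare_segments, canvas, extent, sigma_deg, wp):
        out = _alpha_composite(out, render_movement_link(link, canvas))
    sigma_px = sigma_deg * canvas.px_per_deg(extent)
    for i, seg in enumerate(stare_segments):
        accum = fixation_count_map([seg], rec, canvas, extent)
        smooth = gaussian_filter(accum, sigma=sigma_px)
        peak = smooth.max()
        if peak <= 0:
            continue
        norm = smooth / peak
        color = np.asarray(cmap(i / max(k - 1, 1)))
        layer = np.zeros((canvas.height_px, canvas.width_px, 4))
        layer[..., :3] = color[:3]
        layer[..., 3] = np.clip(norm, 0, 1) * 0.85
        out = _alpha_composite(out, (layer * 255).astype(np.uint8))
    return out


def save_png(rgba: np.ndarray, path: str | Path) -> None:
    Image.fromarray(rgba, mode="RGBA").save(path)
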