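"""Deterministic synthetic images and colour tables with known ground truth.

These generators stand in for scanned fruit/tuber cross-sections: coloured
foreground objects on a black background, with controlled patch frequencies
(exact UC ground truth), colour gradients (near-neighbour colour chains
that exercise the non-transitivity of region growing), and families of
jittered colour profiles (replicate images of the same subject) for
cluster-recovery tests.  The module also carries literal, unoptimised
oracle transcriptions of the region-growing and weighted-distance
procedures, used only for cross-checking the production paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .color_core import (
    ColorConversionConfig,
    DEFAULT_CONFIG,
    delta_e2000,
    hex_to_rgb,
    lab_to_srgb,
    rgb_to_hex,
    srgb_to_lab,
)
from .region_growing import PUCTable, UCTable

__all__ = [
    "PatchSpec",
    "GradientSpec",
    "make_patch_image",
    "make_gradient_image",
    "make_profile_family",
    "oracle_region_grow",
    "oracle_directed_distance",
]


@dataclass
class PatchSpec:
    """Foreground patches with exact per-colour pixel counts on a black field."""

    patches: list[tuple[tuple[int, int, int], int]]
    width: int = 64
    background: tuple[int, int, int] = (0, 0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for _, c in self.patches):
            raise ValueError("patch pixel counts must be >= 1")


@dataclass
class GradientSpec:
    """Banded colour gradient; interpolation linear in CIELAB (default) or RGB."""

    start: tuple[int, int, int]
    end: tuple[int, int, int]
    steps: int = 16
    pixels_per_step: int = 8
    band_height: int = 8
    interpolation: str = "lab"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.steps > 1 and self.start == self.end:
            raise ValueError("degenerate gradient: start == end with steps > 1")
        if self.interpolation not in ("lab", "rgb"):
            raise ValueError(f"unknown interpolation {self.interpolation!r}")


def make_patch_image(spec: PatchSpec) -> tuple[np.ndarray, np.ndarray, UCTable]:
    """Raster + ground-truth mask + ground-truth UC table from a patch spec.

    Foreground pixels are laid out row-major; the mask is construction
    ground truth (independent of pixel colour), trailing positions are
    background.
    """
    total = sum(c for _, c in spec.patches)
    height = -(-total // spec.width)
    raster = np.zeros((height, spec.width, 3), dtype=np.uint8)
    raster[...] = spec.background
    mask = np.zeros((height, spec.width), dtype=bool)
    flat = raster.reshape(-1, 3)
    flat_mask = mask.reshape(-1)
    pos = 0
    entries: dict[str, int] = {}
    for rgb, count in spec.patches:
        flat[pos : pos + count] = rgb
        flat_mask[pos : pos + count] = True
        h = rgb_to_hex(rgb)
        entries[h] = entries.get(h, 0) + count
        pos += count
    uc = UCTable(entries=entries, total_pixels=total, source_id=f"patch-{spec.seed}")
    return raster, mask, uc


def make_gradient_image(
    spec: GradientSpec, cfg: ColorConversionConfig = DEFAULT_CONFIG
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]], list[float]]:
    """Banded gradient raster with its mask, band colours and consecutive dE2000.

    Bands are vertical strips of one colour each.  Linear interpolation in
    Lab gives near-uniform consecutive CIEDE2000 gaps, so tests can build
    colour chains that straddle a given threshold.  Adjacent interpolated
    colours may quantise to the same 8-bit RGB; the returned band-colour
    list is per band (possibly with repeats).
    """
    if spec.steps == 1:
        colors = [spec.start]
    elif spec.interpolation == "rgb":
        t = np.linspace(0.0, 1.0, spec.steps)[:, None]
        arr = np.asarray(spec.start) * (1 - t) + np.asarray(spec.end) * t
        colors = [tuple(int(v) for v in row) for row in np.round(arr).astype(int)]
    else:
        lab0 = srgb_to_lab(np.array(spec.start, dtype=np.uint8), cfg)
        lab1 = srgb_to_lab(np.array(spec.end, dtype=np.uint8), cfg)
        t = np.linspace(0.0, 1.0, spec.steps)[:, None]
        labs = lab0 * (1 - t) + lab1 * t
        colors = [tuple(int(v) for v in lab_to_srgb(lab, cfg)) for lab in labs]
    raster = np.zeros((spec.band_height, spec.steps * spec.pixels_per_step, 3), dtype=np.uint8)
    for i, rgb in enumerate(colors):
        raster[:, i * spec.pixels_per_step : (i + 1) * spec.pixels_per_step] = rgb
    mask = np.ones(raster.shape[:2], dtype=bool)
    gaps = []
    for c0, c1 in zip(colors[:-1], colors[1:]):
        gaps.append(
            delta_e2000(srgb_to_lab(np.array(c0, dtype=np.uint8), cfg), srgb_to_lab(np.array(c1, dtype=np.uint8), cfg), cfg)
        )
    return raster, mask, colors, gaps


def _jitter_to_gamut(lab: np.ndarray, cfg: ColorConversionConfig) -> tuple[str, np.ndarray]:
    """Project a jittered Lab point to the nearest representable sRGB colour."""
    rgb = lab_to_srgb(lab, cfg)
    return rgb_to_hex(tuple(int(v) for v in rgb)), srgb_to_lab(rgb, cfg)


def make_profile_family(
    base_color: tuple[int, int, int],
    n_images: int,
    jitter: float,
    seed: int = 0,
    n_palette: int = 6,
    threshold: float = 2.0,
    cfg: ColorConversionConfig = DEFAULT_CONFIG,
    family_id: str = "family",
) -> list[PUCTable]:
    """Synthetic replicate colour profiles around one base colour.

    Each profile's palette is the base colour's Lab coordinate plus fixed
    offsets (lightness/chroma spread within the family), perturbed by
    N(0, jitter) in Lab and projected back into the sRGB gamut.  Abundances
    follow a decreasing series summing to 100, themselves perturbed
    multiplicatively with the same jitter scale (replicate images of one
    subject never share exact colour frequencies).  ``jitter = 0`` gives
    identical profiles.  Deterministic under ``seed``.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    base_lab = srgb_to_lab(np.array(base_color, dtype=np.uint8), cfg)
    offsets = np.array(
        [[0.0, 0.0, 0.0], [6.0, 2.0, -2.0], [-6.0, -2.0, 2.0], [3.0, -4.0, 0.0], [-3.0, 4.0, 0.0], [9.0, 0.0, 3.0]]
    )[:n_palette]
    raw = np.arange(n_palette, 0, -1.0) ** 1.5
    profiles = []
    for i in range(n_images):
        weights = raw.copy()
        if jitter > 0:
            weights = weights * np.exp(rng.normal(0.0, 0.05 * jitter, n_palette))
        pcts = 100.0 * weights / weights.sum()
        entries = {}
        for off, pct in zip(offsets, pcts):
            lab = base_lab + off + (rng.normal(0.0, jitter, 3) if jitter > 0 else 0.0)
            h, _ = _jitter_to_gamut(lab, cfg)
            entries[h] = entries.get(h, 0.0) + float(pct)  # gamut projection may collide
        ordered = sorted(entries.items(), key=lambda hp: (-hp[1], hp[0]))
        profiles.append(
            PUCTable(
                entries=ordered,
                threshold=threshold,
                assignment={h: h for h, _ in ordered},
                source_id=f"{family_id}-r{i + 1}",
            )
        )
    return profiles


def oracle_region_grow(
    uc: UCTable, threshold: float, cfg: ColorConversionConfig = DEFAULT_CONFIG
) -> PUCTable:
    """Literal, unoptimised region growing; test oracle only (<= 2000 colours).

    Pool of (hex, count) sorted by count desc / hex asc.  While the pool is
    non-empty: pop the head as seed, test it pairwise against every other
    pool member with scalar CIEDE2000, reassign the frequency of every
    query at or below the threshold to the seed and remove it from the
    pool.  No transitive chaining.
    """
    if len(uc.entries) > 2000:
        raise ValueError("oracle guard: table too large")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not uc.entries:
        raise ValueError("empty UC table")
    pool = sorted(uc.entries.items(), key=lambda kv: (-kv[1], kv[0]))
    labs = {h: srgb_to_lab(np.array(hex_to_rgb(h), dtype=np.uint8), cfg) for h, _ in pool}
    seeds: list[tuple[str, int]] = []
    assignment: dict[str, str] = {}
    while pool:
        seed_hex, seed_count = pool.pop(0)
        assignment[seed_hex] = seed_hex
        remaining = []
        acc = seed_count
        for q_hex, q_count in pool:
            if delta_e2000(labs[seed_hex], labs[q_hex], cfg) <= threshold:
                acc += q_count
                assignment[q_hex] = seed_hex
            else:
                remaining.append((q_hex, q_count))
        pool = remaining
        seeds.append((seed_hex, acc))
    entries = sorted(
        ((h, 100.0 * c / uc.total_pixels) for h, c in seeds), key=lambda hp: (-hp[1], hp[0])
    )
    return PUCTable(entries=entries, threshold=threshold, assignment=assignment, source_id=uc.source_id)


def oracle_directed_distance(
    a: PUCTable, b: PUCTable, cfg: ColorConversionConfig = DEFAULT_CONFIG
) -> float:
    """Exhaustive double-loop weighted-distance oracle; test use only."""
    labs_a = [srgb_to_lab(np.array(hex_to_rgb(h), dtype=np.uint8), cfg) for h in a.colors]
    labs_b = [srgb_to_lab(np.array(hex_to_rgb(h), dtype=np.uint8), cfg) for h in b.colors]
    total = 0.0
    for i, (ha, pa) in enumerate(a.entries):
        row_min = None
        for j, (hb, pb) in enumerate(b.entries):
            w = delta_e2000(labs_a[i], labs_b[j], cfg) * abs(pa - pb)
            if row_min is None or w < row_min:
                row_min = w
        total += row_min
    return total
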