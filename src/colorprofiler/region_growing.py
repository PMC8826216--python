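"""Unique-colour frequency tables and perceptual colour quantisation.

The central idea: an image's exact colour content is an ordered frequency
table of unique 24-bit colours (UC table).  Region growing condenses it in
a data-driven way — repeatedly take the most frequent unassigned colour as
a seed and absorb every remaining colour within a CIEDE2000 threshold of
that seed; absorbed colours leave the pool, so absorption is strictly
pairwise to the seed and never chains transitively.  The result is a table
of perceptually unique colours (PUC) with percentage abundances, where each
representative is a colour that genuinely occurs in the image (no synthetic
averages).  A count-weighted k-means in CIELAB is provided as the baseline
this approach is compared against, together with recolouring (validation by
rasterising the quantised palette back into the image) and compression /
complexity metrics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .color_core import (
    ColorConversionConfig,
    DEFAULT_CONFIG,
    delta_e2000_batch,
    delta_e2000_matrix,
    hex_to_rgb,
    lab_to_srgb,
    rgb_to_hex,
    srgb_to_lab,
)

__all__ = [
    "UCTable",
    "PUCTable",
    "CentroidTable",
    "ComplexityReport",
    "build_uc_table",
    "ordered_frequency_distribution",
    "region_grow",
    "filter_puc",
    "top_n",
    "recolor_image",
    "kmeans_colors",
    "recolor_by_centroids",
    "complexity_report",
    "regression_fit",
    "write_uc_table",
    "read_uc_table",
    "write_puc_table",
    "read_puc_table",
]


@dataclass
class UCTable:
    """Exact frequency table of every unique foreground colour."""

    entries: dict[str, int]
    total_pixels: int
    source_id: str = ""

    def __post_init__(self) -> None:
        if sum(self.entries.values()) != self.total_pixels:
            raise ValueError("UC counts do not sum to total_pixels")
        if any(c < 1 for c in self.entries.values()):
            raise ValueError("UC counts must be >= 1")


@dataclass
class PUCTable:
    """Perceptually unique colours with percentage abundances.

    ``entries`` is ordered by non-increasing percentage (ties broken by
    ascending hex code); ``assignment`` maps every input colour to the seed
    that absorbed it (seeds map to themselves).
    """

    entries: list[tuple[str, float]]
    threshold: float
    assignment: dict[str, str]
    source_id: str = ""

    @property
    def colors(self) -> list[str]:
        return [h for h, _ in self.entries]

    @property
    def percentages(self) -> np.ndarray:
        return np.array([p for _, p in self.entries])


@dataclass
class CentroidTable:
    """K-means palette: Lab centroids, nearest in-gamut RGB, member percentages."""

    centroids: list[tuple[np.ndarray, tuple[int, int, int], float]]
    K: int
    seed: int
    converged: bool = True

    @property
    def labs(self) -> np.ndarray:
        return np.array([c[0] for c in self.centroids])


@dataclass(frozen=True)
class ComplexityReport:
    uc_count: int
    foreground_pixels: int
    normalized_complexity: float
    puc_count: int
    reduction_pct: float


def _pack(rgb: np.ndarray) -> np.ndarray:
    rgb = rgb.astype(np.uint32)
    return (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]


def _unpack_hex(code: int) -> str:
    return f"#{code:06X}"


def build_uc_table(raster: np.ndarray, mask: np.ndarray, source_id: str = "") -> UCTable:
    """Exact unique-colour counts over the foreground of a raster."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(raster).shape[:2]:
        raise ValueError("mask dimensions do not match the raster")
    if not mask.any():
        raise ValueError("no foreground: the mask is empty")
    fg = np.asarray(raster)[mask]
    codes, counts = np.unique(_pack(fg), return_counts=True)
    entries = {_unpack_hex(int(c)): int(n) for c, n in zip(codes, counts)}
    return UCTable(entries=entries, total_pixels=int(mask.sum()), source_id=source_id)


def ordered_frequency_distribution(uc: UCTable) -> list[tuple[str, int]]:
    """Entries sorted by count descending; ties broken by ascending hex code."""
    return sorted(uc.entries.items(), key=lambda kv: (-kv[1], kv[0]))


def _labs_for(hexes: list[str], cfg: ColorConversionConfig) -> np.ndarray:
    rgb = np.array([hex_to_rgb(h) for h in hexes], dtype=np.uint8)
    return srgb_to_lab(rgb, cfg)


def region_grow(uc: UCTable, threshold: float, cfg: ColorConversionConfig = DEFAULT_CONFIG) -> PUCTable:
    """Condense a UC table into perceptually unique colours.

    Iteratively: take the most frequent unassigned colour as seed (count
    ties broken by ascending hex code), absorb every unassigned colour with
    CIEDE2000(seed, colour) <= threshold into it, remove all of them from
    the pool, and repeat until the pool is empty.  Output percentages are
    accumulated counts over the foreground total.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not uc.entries:
        raise ValueError("empty UC table")
    ordered = ordered_frequency_distribution(uc)
    hexes = [h for h, _ in ordered]
    counts = np.array([c for _, c in ordered], dtype=np.int64)
    labs = _labs_for(hexes, cfg)

    n = len(hexes)
    unassigned = np.ones(n, dtype=bool)
    assignment: dict[str, str] = {}
    seeds: list[tuple[str, int]] = []
    for i in range(n):
        if not unassigned[i]:
            continue
        pool = np.flatnonzero(unassigned)
        de = delta_e2000_batch(labs[i], labs[pool], cfg)
        absorbed = pool[de <= threshold]
        unassigned[absorbed] = False
        unassigned[i] = False
        seed_hex = hexes[i]
        total = int(counts[i])
        assignment[seed_hex] = seed_hex
        for j in absorbed:
            if j == i:
                continue
            assignment[hexes[j]] = seed_hex
            total += int(counts[j])
        seeds.append((seed_hex, total))

    entries = sorted(
        ((h, 100.0 * c / uc.total_pixels) for h, c in seeds),
        key=lambda hp: (-hp[1], hp[0]),
    )
    return PUCTable(entries=entries, threshold=threshold, assignment=assignment, source_id=uc.source_id)


def filter_puc(puc: PUCTable, min_pct: float = 0.1) -> PUCTable:
    """Drop entries whose percentage is not strictly above ``min_pct``.

    Percentages are deliberately NOT renormalised, so cumulative-percentage
    tracks stay interpretable; the assignment is restricted to retained seeds.
    """
    kept = [(h, p) for h, p in puc.entries if p > min_pct]
    if not kept:
        import warnings

        warnings.warn("abundance filter removed every colour; returning an empty profile")
    seeds = {h for h, _ in kept}
    assignment = {q: s for q, s in puc.assignment.items() if s in seeds}
    return PUCTable(entries=kept, threshold=puc.threshold, assignment=assignment, source_id=puc.source_id)


def top_n(puc: PUCTable, n: int = 20) -> tuple[PUCTable, float]:
    """First ``n`` entries of the ordered table and their cumulative percentage."""
    if n < 1:
        raise ValueError("n must be >= 1")
    kept = puc.entries[:n]
    seeds = {h for h, _ in kept}
    assignment = {q: s for q, s in puc.assignment.items() if s in seeds}
    sub = PUCTable(entries=kept, threshold=puc.threshold, assignment=assignment, source_id=puc.source_id)
    return sub, float(sum(p for _, p in kept))


def recolor_image(raster: np.ndarray, mask: np.ndarray, puc: PUCTable) -> np.ndarray:
    """Replace each foreground pixel by its assigned perceptually unique colour."""
    mask = np.asarray(mask, dtype=bool)
    raster = np.asarray(raster)
    out = np.array(raster, dtype=np.uint8)
    fg = raster[mask]
    codes = _pack(fg)
    uniq = np.unique(codes)
    lut = {}
    for code in uniq.tolist():
        h = _unpack_hex(code)
        if h not in puc.assignment:
            raise ValueError(f"colour {h} has no seed assignment in the PUC table")
        lut[code] = hex_to_rgb(puc.assignment[h])
    mapped = np.array([lut[c] for c in codes.tolist()], dtype=np.uint8)
    out[mask] = mapped
    return out


def _weighted_sse(labs: np.ndarray, w: np.ndarray, assign: np.ndarray, cents: np.ndarray) -> float:
    d = labs - cents[assign]
    return float(np.sum(w * np.einsum("ij,ij->i", d, d)))


def kmeans_colors(
    uc: UCTable,
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    cfg: ColorConversionConfig = DEFAULT_CONFIG,
    variant: str = "hartigan-wong",
) -> CentroidTable:
    """Count-weighted k-means over the UC colours in CIELAB.

    Initial centroids are drawn count-weighted without replacement under
    ``seed``.  ``variant`` selects the update rule: ``"hartigan-wong"``
    (single-point transfer criterion) or ``"lloyd"``.  Deterministic given
    the seed; non-convergence within ``max_iter`` is flagged, not an error.
    """
    ordered = ordered_frequency_distribution(uc)
    hexes = [h for h, _ in ordered]
    n = len(hexes)
    if not (1 <= K <= n):
        raise ValueError(f"K={K} outside [1, {n}]")
    if variant not in ("hartigan-wong", "lloyd"):
        raise ValueError(f"unknown k-means variant {variant!r}")
    w = np.array([c for _, c in ordered], dtype=np.float64)
    labs = _labs_for(hexes, cfg)

    rng = np.random.default_rng(seed)
    init = rng.choice(n, size=K, replace=False, p=w / w.sum())
    cents = labs[init].copy()

    def nearest(pts: np.ndarray) -> np.ndarray:
        d2 = ((pts[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)

    assign = nearest(labs)
    converged = False
    if variant == "lloyd" or K == 1 or K == n:
        for _ in range(max_iter):
            for k in range(K):
                sel = assign == k
                if sel.any():
                    cents[k] = np.average(labs[sel], axis=0, weights=w[sel])
                else:
                    # re-seed an empty cluster from the farthest point
                    d = ((labs - cents[assign]) ** 2).sum(axis=1)
                    cents[k] = labs[d.argmax()]
            new = nearest(labs)
            if np.array_equal(new, assign):
                converged = True
                break
            assign = new
    else:
        # Hartigan–Wong: greedy single-point transfers on the weighted
        # within-cluster sum of squares, with the n/(n±1) size correction.
        cluster_w = np.array([w[assign == k].sum() for k in range(K)])
        sums = np.array([(labs[assign == k] * w[assign == k, None]).sum(axis=0) for k in range(K)])
        for _ in range(max_iter):
            moved = False
            for i in range(n):
                src = assign[i]
                Wi = cluster_w[src]
                if Wi <= w[i]:  # sole member of its cluster
                    continue
                ci = sums[src] / Wi
                cost_out = Wi * w[i] / (Wi - w[i]) * float(((labs[i] - ci) ** 2).sum())
                best_gain, best_k = 0.0, -1
                for k in range(K):
                    if k == src:
                        continue
                    Wk = cluster_w[k]
                    ck = sums[k] / Wk
                    cost_in = Wk * w[i] / (Wk + w[i]) * float(((labs[i] - ck) ** 2).sum())
                    gain = cost_out - cost_in
                    if gain > best_gain + 1e-12:
                        best_gain, best_k = gain, k
                if best_k >= 0:
                    cluster_w[src] -= w[i]
                    sums[src] -= w[i] * labs[i]
                    cluster_w[best_k] += w[i]
                    sums[best_k] += w[i] * labs[i]
                    assign[i] = best_k
                    moved = True
            if not moved:
                converged = True
                break
        cents = sums / cluster_w[:, None]

    # final centroids = weighted means of the final assignment
    centroids = []
    total_w = w.sum()
    for k in range(K):
        sel = assign == k
        if not sel.any():
            continue
        lab_c = np.average(labs[sel], axis=0, weights=w[sel])
        rgb_c = tuple(int(v) for v in lab_to_srgb(lab_c, cfg))
        centroids.append((lab_c, rgb_c, 100.0 * w[sel].sum() / total_w))
    return CentroidTable(centroids=centroids, K=K, seed=seed, converged=converged)


def recolor_by_centroids(
    raster: np.ndarray,
    mask: np.ndarray,
    centroids: CentroidTable,
    cfg: ColorConversionConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Replace each foreground pixel by its CIEDE2000-nearest centroid colour."""
    if not centroids.centroids:
        raise ValueError("empty centroid table")
    mask = np.asarray(mask, dtype=bool)
    raster = np.asarray(raster)
    out = np.array(raster, dtype=np.uint8)
    fg = raster[mask]
    codes = np.unique(_pack(fg))
    rgb_u = np.stack([(codes >> 16) & 255, (codes >> 8) & 255, codes & 255], axis=-1).astype(np.uint8)
    labs_u = srgb_to_lab(rgb_u, cfg)
    de = delta_e2000_matrix(labs_u, centroids.labs, cfg)
    best = de.argmin(axis=1)  # ties resolve to the lowest centroid index
    palette = np.array([c[1] for c in centroids.centroids], dtype=np.uint8)
    lut = {int(c): palette[b] for c, b in zip(codes, best)}
    mapped = np.array([lut[int(c)] for c in _pack(fg)], dtype=np.uint8)
    out[mask] = mapped
    return out


def complexity_report(uc: UCTable, puc: PUCTable) -> ComplexityReport:
    """Compression and colour-complexity summary for one image."""
    uc_count = len(uc.entries)
    puc_count = len(puc.entries)
    return ComplexityReport(
        uc_count=uc_count,
        foreground_pixels=uc.total_pixels,
        normalized_complexity=uc_count / uc.total_pixels,
        puc_count=puc_count,
        reduction_pct=(1.0 - puc_count / uc_count) * 100.0,
    )


def regression_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.all(x == x[0]):
        raise ValueError("degenerate fit: x is constant")
    if np.all(y == y[0]):
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


# ---------------------------------------------------------------------------
# persistence: delimited text with a '# key: value' metadata header
# ---------------------------------------------------------------------------

def _config_hash(cfg: ColorConversionConfig) -> str:
    return hashlib.md5(repr(cfg).encode()).hexdigest()[:12]


def write_uc_table(uc: UCTable, path) -> None:
    with open(path, "w") as f:
        f.write(f"# source_id: {uc.source_id}\n")
        f.write(f"# total_pixels: {uc.total_pixels}\n")
        f.write("hex\tcount\n")
        for h, c in ordered_frequency_distribution(uc):
            f.write(f"{h}\t{c}\n")


def read_uc_table(path) -> UCTable:
    meta, rows = _read_table(path)
    entries = {h: int(c) for h, c in rows}
    return UCTable(entries=entries, total_pixels=int(meta["total_pixels"]), source_id=meta.get("source_id", ""))


def write_puc_table(puc: PUCTable, path, cfg: ColorConversionConfig = DEFAULT_CONFIG) -> None:
    with open(path, "w") as f:
        f.write(f"# source_id: {puc.source_id}\n")
        f.write(f"# threshold: {puc.threshold!r}\n")
        f.write(f"# config_hash: {_config_hash(cfg)}\n")
        f.write("hex\tpercentage\tseed\n")
        seed_rows = {h: (h, p) for h, p in puc.entries}
        for h, p in puc.entries:
            f.write(f"{h}\t{float(p)!r}\t{h}\n")
        for q, s in sorted(puc.assignment.items()):
            if q not in seed_rows:
                f.write(f"{q}\t\t{s}\n")


def read_puc_table(path) -> PUCTable:
    meta, rows = _read_table(path)
    entries: list[tuple[str, float]] = []
    assignment: dict[str, str] = {}
    for row in rows:
        h, p, s = row
        assignment[h] = s
        if p != "":
            entries.append((h, float(p)))
    entries.sort(key=lambda hp: (-hp[1], hp[0]))
    return PUCTable(
        entries=entries,
        threshold=float(meta["threshold"]),
        assignment=assignment,
        source_id=meta.get("source_id", ""),
    )


def _read_table(path) -> tuple[dict[str, str], list[list[str]]]:
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header_seen = False
    with open(path) as f:
        for line in f:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("# "):  # metadata; data rows start with '#RRGGBB\t'
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif not header_seen:
                header_seen = True
            else:
                rows.append(line.split("\t"))
    return meta, rows
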