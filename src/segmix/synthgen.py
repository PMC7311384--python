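"""Seeded generators of synthetic microscopy and tabular study data.

Four generators, each paired with a machine-readable ground-truth manifest:

* :func:`generate_aggregate_field` — two-channel (red/green) fields of
  multi-cluster cell aggregates, emulating 1:1 co-cultures of fluorescently
  labeled dissociated blastoderm cells imaged ~16 h after dissociation.
  Each cell is an isotropic Gaussian blob; clusters can be fully intermixed,
  bisected ("sorted") or concentric ("engulfed"), with a continuous mixing
  parameter ``m`` interpolating toward full intermixing.
* :func:`generate_tessellation` — an EVL-like epithelial mosaic: a
  Lloyd-relaxed Voronoi tessellation rendered with bright cell boundaries
  (phalloidin-like) plus a nuclear channel marking a chosen fraction of
  cells as mitotic (pHH3-like). Rosettes (junctions of >= 5 cells) are
  injected by placing a ring of cocircular seeds so the target arity is
  exact and every wedge angle is ``2*pi/arity``.
* :func:`generate_epiboly_table` — per-stage epiboly times for wild-type and
  mutant embryos across repeats, with an optional genotype delay at all
  post-dome stages.
* :func:`generate_qpcr_table` — CT triplicates under perfect amplification
  efficiency (one cycle per two-fold expression change).

All generators are deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import Voronoi, cKDTree
from skimage import draw as skdraw
from skimage import morphology, segmentation

from .aggseg import AggregateROI
from .image import MultiChannelImage

__all__ = [
    "AggregateFieldConfig",
    "AggregateGroundTruth",
    "ClusterTruth",
    "CellTruth",
    "TessellationConfig",
    "TessellationGroundTruth",
    "GeometryError",
    "generate_aggregate_field",
    "rois_from_ground_truth",
    "generate_tessellation",
    "generate_epiboly_table",
    "generate_qpcr_table",
    "STAGE_ORDER",
    "STAGE_REFERENCE_H",
    "round_half_up",
]


class GeometryError(ValueError):
    """Raised when a cluster layout cannot fit in the requested image."""


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties going up (documented convention)."""
    return int(np.floor(x + 0.5))


# ===========================================================================
# aggregate fields
# ===========================================================================

@dataclass
class AggregateFieldConfig:
    """Layout and rendering parameters for one synthetic aggregate field.

    Defaults describe the emulated study conditions: a 10x field holding a
    handful of well-separated aggregates of a few dozen cells each, two
    labels plated 1:1 (``red_fraction=0.5``), gentle read noise (SNR > 5)
    on a 16-bit range. ``mixing_m`` interpolates the sorted/engulfed layout
    toward full intermixing (1 = fully mixed).
    """

    image_height_px: int = 600
    image_width_px: int = 600
    n_clusters: int = 5
    cluster_radius_px: tuple[float, float] = (30.0, 45.0)
    cells_per_cluster: int = 120
    cell_sigma_px: float = 6.0
    mode: str = "mixed"  # mixed | sorted | engulfed
    mixing_m: float = 1.0
    red_fraction: float = 0.5
    core_radius_fraction: float = 0.5
    cell_amplitude: float = 150.0
    background_level: float = 8.0
    gaussian_noise_sd: float = 3.0
    poisson_noise: bool = False
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("mixed", "sorted", "engulfed"):
            raise ValueError("mode must be mixed, sorted or engulfed")
        if not 0.0 <= self.mixing_m <= 1.0:
            raise ValueError("mixing_m must lie in [0, 1]")
        if not 0.0 < self.red_fraction < 1.0:
            raise ValueError("red_fraction must lie in (0, 1)")
        if not 0.0 < self.core_radius_fraction < 1.0:
            raise ValueError("core_radius_fraction must lie in (0, 1)")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.cluster_radius_px[0] > self.cluster_radius_px[1]:
            raise ValueError("cluster_radius_px must be (min, max)")
        if self.background_level < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("background and noise must be >= 0")


@dataclass
class CellTruth:
    channel: str
    center: tuple[float, float]  # (row, col)
    amplitude: float


@dataclass
class ClusterTruth:
    id: int
    center: tuple[float, float]
    radius_px: float
    mode: str
    mixing_m: float
    cells: list[CellTruth]

    def centroid_separation(self) -> float:
        """Distance between red and green cell-position centroids."""
        red = np.array([c.center for c in self.cells if c.channel == "red"])
        green = np.array([c.center for c in self.cells if c.channel == "green"])
        return float(np.linalg.norm(red.mean(axis=0) - green.mean(axis=0)))


@dataclass
class AggregateGroundTruth:
    clusters: list[ClusterTruth]
    seed: int
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AggregateGroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        clusters = [
            ClusterTruth(
                id=c["id"],
                center=tuple(c["center"]),
                radius_px=c["radius_px"],
                mode=c["mode"],
                mixing_m=c["mixing_m"],
                cells=[
                    CellTruth(x["channel"], tuple(x["center"]), x["amplitude"])
                    for x in c["cells"]
                ],
            )
            for c in raw["clusters"]
        ]
        return cls(clusters=clusters, seed=raw["seed"], config=raw["config"])


def _uniform_disk(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.sin(th), r * np.cos(th)])  # (row, col) offsets


def _annulus(rng: np.random.Generator, n: int, r_in: float, r_out: float) -> np.ndarray:
    u = rng.random(n)
    r = np.sqrt(r_in**2 + u * (r_out**2 - r_in**2))
    th = rng.random(n) * 2.0 * np.pi
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


def _place_centers(cfg: AggregateFieldConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping cluster centers inside the border."""
    pad = 3.0 * cfg.cell_sigma_px + 2.0
    radii = rng.uniform(*cfg.cluster_radius_px, size=cfg.n_clusters)
    margin = radii + pad
    if np.any(2 * margin >= min(cfg.image_height_px, cfg.image_width_px)):
        raise GeometryError("geometry infeasible: cluster radius exceeds image")
    centers = np.empty((cfg.n_clusters, 2))
    gap = 4.0 * cfg.cell_sigma_px
    for i, m in enumerate(margin):
        for _ in range(5000):
            c = np.array(
                [
                    rng.uniform(m, cfg.image_height_px - m),
                    rng.uniform(m, cfg.image_width_px - m),
                ]
            )
            if i == 0:
                centers[0] = c
                break
            d = np.hypot(*(centers[:i] - c).T)
            if np.all(d > radii[i] + radii[:i] + gap):
                centers[i] = c
                break
        else:
            raise GeometryError(
                f"geometry infeasible: could not place cluster {i} of {cfg.n_clusters}"
            )
    return centers, radii


def _sample_cluster_cells(
    cfg: AggregateFieldConfig, rng: np.random.Generator, radius: float
) -> tuple[np.ndarray, np.ndarray]:
    """Cell offsets (row, col) and channel assignment for one cluster.

    The sorted mode bisects the cluster along the column axis (red on the
    low-column side); the engulfed mode puts red inside the core. In both,
    every cell is independently relocated to a uniform position over the
    whole disk with probability ``mixing_m``.
    """
    n = cfg.cells_per_cluster
    n_red = round_half_up(cfg.red_fraction * n)
    n_red = min(max(n_red, 1), n - 1)
    n_green = n - n_red
    channels = np.array(["red"] * n_red + ["green"] * n_green)

    if cfg.mode == "mixed":
        pos = _uniform_disk(rng, n, radius)
    elif cfg.mode == "sorted":
        red = _uniform_disk(rng, n_red, radius)
        red[:, 1] = -np.abs(red[:, 1])
        green = _uniform_disk(rng, n_green, radius)
        green[:, 1] = np.abs(green[:, 1])
        pos = np.vstack([red, green])
    else:  # engulfed
        core = cfg.core_radius_fraction * radius
        red = _uniform_disk(rng, n_red, core)
        green = _annulus(rng, n_green, core, radius)
        pos = np.vstack([red, green])

    if cfg.mode != "mixed" and cfg.mixing_m > 0:
        relocate = rng.random(n) < cfg.mixing_m
        pos[relocate] = _uniform_disk(rng, int(relocate.sum()), radius)
    return pos, channels


def _render_blobs(
    canvas: np.ndarray, cells: Sequence[CellTruth], channel_index: Mapping[str, int], sigma: float
) -> None:
    """Accumulate Gaussian blobs onto a (C, H, W) float canvas, in place."""
    _, H, W = canvas.shape
    half = int(np.ceil(4.0 * sigma))
    for cell in cells:
        r, c = cell.center
        r0, r1 = max(0, int(np.floor(r)) - half), min(H, int(np.floor(r)) + half + 1)
        c0, c1 = max(0, int(np.floor(c)) - half), min(W, int(np.floor(c)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows = np.arange(r0, r1, dtype=float)[:, None]
        cols = np.arange(c0, c1, dtype=float)[None, :]
        blob = cell.amplitude * np.exp(
            -((rows - r) ** 2 + (cols - c) ** 2) / (2.0 * sigma**2)
        )
        canvas[channel_index[cell.channel], r0:r1, c0:c1] += blob


def generate_aggregate_field(
    config: AggregateFieldConfig,
) -> tuple[MultiChannelImage, AggregateGroundTruth]:
    """Render one two-channel aggregate field plus its ground truth.

    The image is the sum of per-cell Gaussian blobs, a constant background,
    additive Gaussian read noise and (optionally) Poisson resampling,
    clipped and quantized to the configured bit depth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    centers, radii = _place_centers(cfg, rng)

    clusters: list[ClusterTruth] = []
    for i, (center, radius) in enumerate(zip(centers, radii)):
        offsets, channels = _sample_cluster_cells(cfg, rng, radius)
        amplitudes = cfg.cell_amplitude * rng.uniform(0.8, 1.2, size=len(offsets))
        cells = [
            CellTruth(ch, (float(center[0] + dr), float(center[1] + dc)), float(a))
            for (dr, dc), ch, a in zip(offsets, channels, amplitudes)
        ]
        clusters.append(
            ClusterTruth(
                id=i,
                center=(float(center[0]), float(center[1])),
                radius_px=float(radius),
                mode=cfg.mode,
                mixing_m=cfg.mixing_m,
                cells=cells,
            )
        )

    canvas = np.zeros((2, cfg.image_height_px, cfg.image_width_px), dtype=np.float32)
    idx = {"red": 0, "green": 1}
    for cluster in clusters:
        _render_blobs(canvas, cluster.cells, idx, cfg.cell_sigma_px)
    canvas += np.float32(cfg.background_level)
    if cfg.gaussian_noise_sd > 0:
        noise = rng.standard_normal(canvas.shape, dtype=np.float32)
        noise *= np.float32(cfg.gaussian_noise_sd)
        canvas += noise
    if cfg.poisson_noise:
        canvas = rng.poisson(np.clip(canvas, 0.0, None)).astype(np.float32)
    top = 2**cfg.bit_depth - 1
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    np.clip(canvas, 0, top, out=canvas)
    np.rint(canvas, out=canvas)
    data = canvas.astype(dtype)

    image = MultiChannelImage(data=data, channel_names=["red", "green"])
    truth = AggregateGroundTruth(clusters=clusters, seed=cfg.seed, config=asdict(cfg))
    return image, truth


def rois_from_ground_truth(
    image: MultiChannelImage, truth: AggregateGroundTruth
) -> list[AggregateROI]:
    """Build one disk-mask ROI per ground-truth cluster (bypasses detection).

    Useful for benchmarking the segregation statistics independently of the
    segmentation chain: the mask is the manifest disk of each cluster.
    """
    H, W = image.shape_2d
    rois = []
    for cluster in truth.clusters:
        cr, cc = cluster.center
        rad = cluster.radius_px + 2.0 * truth.config.get("cell_sigma_px", 0.0)
        r0, r1 = max(0, int(cr - rad)), min(H, int(cr + rad) + 1)
        c0, c1 = max(0, int(cc - rad)), min(W, int(cc + rad) + 1)
        rows = np.arange(r0, r1, dtype=float)[:, None]
        cols = np.arange(c0, c1, dtype=float)[None, :]
        mask = (rows - cr) ** 2 + (cols - cc) ** 2 <= rad**2
        intensities = {
            name: np.where(mask, image.channel(name)[r0:r1, c0:c1].astype(float), 0.0)
            for name in image.channel_names
        }
        rois.append(
            AggregateROI(
                id=cluster.id,
                mask=mask,
                bbox=(r0, c0, r1, c1),
                area_px=int(mask.sum()),
                intensities=intensities,
            )
        )
    return rois


# ===========================================================================
# EVL tessellations
# ===========================================================================

@dataclass
class TessellationConfig:
    """Parameters of the synthetic epithelial mosaic.

    Defaults draw ~100 cells on a 512 px field with 2 px bright boundaries —
    cells of a couple of thousand pixels, matching confocal EVL mosaics at
    20-40x. ``rosette_injections`` lists target junction arities (each 5-8)
    to create by edge collapse; ``mitotic_fraction`` of cells receive a
    bright nuclear blob in the second channel.
    """

    n_cells: int = 100
    domain: str = "rectangle"  # rectangle | disk
    domain_size_px: int = 512
    lloyd_iterations: int = 3
    boundary_width_px: float = 2.0
    boundary_intensity: float = 200.0
    interior_intensity: float = 40.0
    noise_sd: float = 3.0
    rosette_injections: list[int] = field(default_factory=list)
    mitotic_fraction: float = 0.0
    junction_merge_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise ValueError("n_cells must be >= 4")
        if self.domain not in ("rectangle", "disk"):
            raise ValueError("domain must be rectangle or disk")
        if self.lloyd_iterations < 0:
            raise ValueError("lloyd_iterations must be >= 0")
        if self.boundary_width_px <= 0:
            raise ValueError("boundary_width_px must be > 0")
        if self.interior_intensity >= self.boundary_intensity:
            raise ValueError("interior_intensity must be < boundary_intensity")
        if not 0.0 <= self.mitotic_fraction <= 1.0:
            raise ValueError("mitotic_fraction must lie in [0, 1]")
        for k in self.rosette_injections:
            if not 5 <= k <= 8:
                raise ValueError("rosette arities must lie in [5, 8]")


@dataclass
class JunctionTruth:
    position: tuple[float, float]
    arity: int
    incident_labels: list[int]


@dataclass
class CellGT:
    label: int
    area_px: int
    centroid: tuple[float, float]
    is_mitotic: bool


@dataclass
class TessellationGroundTruth:
    label_map: np.ndarray  # 0 = boundary/background, 1..n = cells
    cells: list[CellGT]
    junctions: list[JunctionTruth]
    seed: int

    def manifest_dict(self) -> dict:
        """JSON-serializable manifest (label map written separately)."""
        return {
            "seed": self.seed,
            "cells": [asdict(c) for c in self.cells],
            "junctions": [asdict(j) for j in self.junctions],
        }


def _lloyd(seeds: np.ndarray, size: int, iterations: int) -> np.ndarray:
    """Pixel-based Lloyd relaxation on the square domain."""
    if iterations == 0:
        return seeds
    rr, cc = np.mgrid[0:size, 0:size]
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float) + 0.5
    for _ in range(iterations):
        _, lab = cKDTree(seeds).query(pix)
        sums = np.zeros_like(seeds)
        counts = np.bincount(lab, minlength=len(seeds)).astype(float)
        for d in range(2):
            sums[:, d] = np.bincount(lab, weights=pix[:, d], minlength=len(seeds))
        nonzero = counts > 0
        seeds = seeds.copy()
        seeds[nonzero] = sums[nonzero] / counts[nonzero, None]
    return seeds


def _mirrored_voronoi(seeds: np.ndarray, size: int) -> Voronoi:
    """Voronoi of the seeds plus reflections across the four domain edges.

    Reflection makes every original region finite and clipped exactly at the
    domain border.
    """
    refl = [seeds]
    for axis, bound in ((0, 0.0), (0, float(size)), (1, 0.0), (1, float(size))):
        m = seeds.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        refl.append(m)
    return Voronoi(np.vstack(refl))


def _vertex_incidence(vor: Voronoi, n_real: int):
    """Map vertex id -> set of incident real seeds / any-mirror flag / adjacency."""
    incident: dict[int, set[int]] = {}
    touches_mirror: dict[int, bool] = {}
    adjacency: dict[int, set[int]] = {}
    for (p, q), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if -1 in verts:
            continue
        for v in verts:
            inc = incident.setdefault(v, set())
            flag = touches_mirror.get(v, False)
            for pt in (p, q):
                if pt < n_real:
                    inc.add(int(pt))
                else:
                    flag = True
            touches_mirror[v] = flag
        v1, v2 = verts
        adjacency.setdefault(v1, set()).add(v2)
        adjacency.setdefault(v2, set()).add(v1)
    return incident, touches_mirror, adjacency


def _separate_vertices(
    seeds: np.ndarray,
    size: int,
    rng: np.random.Generator,
    min_sep: float = 7.0,
    exclude_centers: Sequence[np.ndarray] = (),
    exclude_radius: float = 30.0,
    frozen: set[int] | None = None,
    max_iter: int = 120,
) -> np.ndarray:
    """Remove near-degenerate Voronoi vertex pairs by nudging seeds.

    Generic tessellations have no coincident vertices, but random seeds
    occasionally produce edges shorter than the pixel resolution, which
    read as spurious junctions of arity > 3. Seeds not shared by both end
    vertices of a short edge are pushed radially off the edge midpoint
    (with a small random jitter if the push cycles) until every interior
    edge is at least ``min_sep`` px, leaving ``exclude_centers``
    (intentional rosettes) untouched.
    """
    seeds = seeds.copy()
    for it in range(max_iter):
        vor = _mirrored_voronoi(seeds, size)
        incident, touches_mirror, adjacency = _vertex_incidence(vor, len(seeds))
        bad: list[tuple[np.ndarray, set[int]]] = []
        for v1, nbrs in adjacency.items():
            if touches_mirror.get(v1, True):
                continue
            for v2 in nbrs:
                if v2 <= v1 or touches_mirror.get(v2, True):
                    continue
                if np.linalg.norm(vor.vertices[v1] - vor.vertices[v2]) >= min_sep:
                    continue
                mid = (vor.vertices[v1] + vor.vertices[v2]) / 2.0
                if any(
                    np.linalg.norm(mid - c) < exclude_radius for c in exclude_centers
                ):
                    continue
                shared = incident[v1] & incident[v2]
                bad.append((mid, (incident[v1] | incident[v2]) - shared))
        if not bad:
            break
        for mid, movers in bad:
            for s in movers:
                if frozen and s in frozen:
                    continue
                v = seeds[s] - mid
                norm = np.linalg.norm(v)
                if norm > 1e-6:
                    seeds[s] = seeds[s] + 2.5 * v / norm
                if it % 8 == 7:
                    # escape cycling configurations with growing jitter
                    seeds[s] = seeds[s] + rng.normal(0.0, 1.0 + it / 16.0, 2)
        np.clip(seeds, 2.0, size - 2.0, out=seeds)
    return seeds


def _inject_rosettes(
    seeds: np.ndarray,
    targets: Sequence[int],
    size: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[tuple[np.ndarray, set[int]]]]:
    """Rearrange seeds so each target arity appears as one exact junction.

    For a target arity ``k`` the ``k`` seeds nearest a chosen interior
    location are placed equally spaced on a circle around it; the circle
    center is then equidistant from exactly those ``k`` seeds (and farther
    from every other), i.e. a degenerate Voronoi vertex where ``k`` cells
    meet with equal wedge angles ``2*pi/k`` — a rosette that survives
    rasterization at any arity up to 8. Returns the adjusted seeds and, per
    injection, the rosette position with its incident seed ids. Raises,
    naming the injection index, if no admissible location exists.
    """
    seeds = seeds.copy()
    injected: list[tuple[np.ndarray, set[int], float]] = []
    centers: list[np.ndarray] = []
    margin = 0.15 * size
    for idx, k in enumerate(targets):
        if k >= len(seeds) - 2:
            raise ValueError(
                f"rosette injection {idx} (arity {k}) infeasible: too few cells"
            )
        done = False
        for i in rng.permutation(len(seeds)):
            c = seeds[i].copy()
            if not (margin < c[0] < size - margin and margin < c[1] < size - margin):
                continue
            if any(np.linalg.norm(c - u) < 0.3 * size for u in centers):
                continue
            dist = np.linalg.norm(seeds - c, axis=1)
            order = np.argsort(dist)
            ring_ids, rest = order[:k], order[k:]
            radius = 0.55 * float(np.median(dist[order[1:k]]))
            if radius < 10.0 or dist[rest].min() < 1.7 * radius:
                continue
            phase = rng.uniform(0.0, 2.0 * np.pi)
            angles = phase + 2.0 * np.pi * np.arange(k) / k
            seeds[ring_ids] = c + radius * np.column_stack(
                [np.sin(angles), np.cos(angles)]
            )
            injected.append((c.copy(), set(int(j) for j in ring_ids), radius))
            centers.append(c.copy())
            done = True
            break
        if not done:
            raise ValueError(
                f"rosette injection {idx} (arity {k}) infeasible: "
                "no admissible location in the tessellation"
            )
    return seeds, injected


def generate_tessellation(
    config: TessellationConfig,
) -> tuple[MultiChannelImage, TessellationGroundTruth]:
    """Render an EVL-like mosaic with boundary and nuclear channels.

    Channel 0 ("boundary") is ``interior_intensity`` inside cells and
    ``boundary_intensity`` on cell borders of nominal width
    ``boundary_width_px``; channel 1 ("phh3") holds one bright nuclear blob
    per mitotic cell. The ground truth records the label map (0 = boundary),
    per-cell areas/centroids/mitotic flags and every junction (position,
    arity, incident labels).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    size = cfg.domain_size_px
    n = cfg.n_cells

    if cfg.domain == "disk":
        seeds = _uniform_disk(rng, n, 0.44 * size) + size / 2.0
    else:
        pad = 0.02 * size
        seeds = np.column_stack(
            [rng.uniform(pad, size - pad, n), rng.uniform(pad, size - pad, n)]
        )
    seeds = _lloyd(seeds, size, cfg.lloyd_iterations)
    seeds = _separate_vertices(seeds, size, rng)
    seeds, injected = _inject_rosettes(seeds, cfg.rosette_injections, size, rng)
    if injected:
        # freeze every seed near an injection site so later nudges cannot
        # push a cell into a rosette and break its empty-circle property
        frozen = set().union(*(ids for _, ids, _ in injected))
        for c, _, radius in injected:
            near = np.nonzero(np.linalg.norm(seeds - c, axis=1) < 2.5 * radius)[0]
            frozen |= set(int(i) for i in near)
        seeds = _separate_vertices(
            seeds,
            size,
            rng,
            exclude_centers=[c for c, _, _ in injected],
            frozen=frozen,
        )

    vor = _mirrored_voronoi(seeds, size)

    # rasterize region polygons
    label_full = np.zeros((size, size), dtype=np.int32)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        coords = []
        for v in region:
            p = vor.vertices[v]
            if not coords or np.linalg.norm(p - coords[-1]) > 1e-9:
                coords.append(np.asarray(p, dtype=float))
        poly = np.array(coords)
        rr, cc = skdraw.polygon(poly[:, 0] - 0.5, poly[:, 1] - 0.5, shape=(size, size))
        label_full[rr, cc] = i + 1
    if np.any(label_full == 0):  # fill rasterization seams with nearest label
        _, (ir, ic) = ndi.distance_transform_edt(label_full == 0, return_indices=True)
        label_full = label_full[ir, ic]

    # boundary mask of the requested nominal width
    bd = segmentation.find_boundaries(label_full, mode="thick")
    extra = int(round(cfg.boundary_width_px)) - 2
    if extra > 0:
        bd = morphology.binary_dilation(bd, morphology.disk((extra + 1) // 2))

    domain_mask = np.ones((size, size), dtype=bool)
    if cfg.domain == "disk":
        rr, cc = np.mgrid[0:size, 0:size]
        domain_mask = (rr - size / 2.0) ** 2 + (cc - size / 2.0) ** 2 <= (0.5 * size) ** 2

    label_map = label_full.copy()
    label_map[bd] = 0
    label_map[~domain_mask] = 0

    # ground-truth cells
    areas = np.bincount(label_map.ravel(), minlength=n + 1)
    centroids = ndi.center_of_mass(label_map > 0, label_map, index=np.arange(1, n + 1))
    n_mitotic = round_half_up(cfg.mitotic_fraction * n)
    mitotic_labels = set(rng.choice(np.arange(1, n + 1), size=n_mitotic, replace=False).tolist())
    cells = [
        CellGT(
            label=i,
            area_px=int(areas[i]),
            centroid=(float(centroids[i - 1][0]), float(centroids[i - 1][1])),
            is_mitotic=i in mitotic_labels,
        )
        for i in range(1, n + 1)
    ]

    # ground-truth junctions: interior Voronoi vertices plus the injected
    # rosette centers, with a pixel-scale merge of near-coincident vertices
    # (the split vertices a degenerate rosette produces collapse into it)
    incident, touches_mirror, _ = _vertex_incidence(vor, n)
    raw: list[tuple[np.ndarray, set[int]]] = [(c, ids) for c, ids, _ in injected]
    for v, inc in incident.items():
        if touches_mirror[v] or len(inc) < 3:
            continue
        pos = vor.vertices[v]
        if not (0 <= pos[0] < size and 0 <= pos[1] < size):
            continue
        if cfg.domain == "disk":
            if (pos[0] - size / 2) ** 2 + (pos[1] - size / 2) ** 2 > (0.45 * size) ** 2:
                continue
        raw.append((pos, set(inc)))
    # vertices closer than the pixel-scale resolution of junction detection
    # are indistinguishable and merge into one ground-truth junction
    junctions = _merge_close_junctions(raw, tol=cfg.junction_merge_px)

    # render
    canvas = np.zeros((2, size, size), dtype=float)
    canvas[0][domain_mask] = cfg.interior_intensity
    canvas[0][bd & domain_mask] = cfg.boundary_intensity
    for i in sorted(mitotic_labels):
        nucleus = CellTruth("phh3", cells[i - 1].centroid, cfg.boundary_intensity)
        r_eq = np.sqrt(max(areas[i], 1) / np.pi)
        _render_blobs(canvas, [nucleus], {"phh3": 1}, max(2.0, 0.3 * r_eq))
    if cfg.noise_sd > 0:
        canvas += rng.normal(0.0, cfg.noise_sd, size=canvas.shape)
    data = np.clip(np.round(canvas), 0, 255).astype(np.uint8)

    image = MultiChannelImage(data=data, channel_names=["boundary", "phh3"])
    truth = TessellationGroundTruth(
        label_map=label_map, cells=cells, junctions=junctions, seed=cfg.seed
    )
    return image, truth


def _merge_close_junctions(
    raw: Sequence[tuple[np.ndarray, set[int]]], tol: float
) -> list[JunctionTruth]:
    """Union-find merge of vertices closer than ``tol`` px.

    Near-coincident Voronoi vertices are indistinguishable at pixel
    resolution; their incident label sets union into one junction.
    """
    n = len(raw)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pts = np.array([p for p, _ in raw]) if raw else np.empty((0, 2))
    if n:
        tree = cKDTree(pts)
        for i, j in tree.query_pairs(tol):
            parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        pos = pts[members].mean(axis=0)
        labels: set[int] = set()
        for i in members:
            labels |= raw[i][1]
        out.append(
            JunctionTruth(
                position=(float(pos[0]), float(pos[1])),
                arity=len(labels),
                incident_labels=sorted(x + 1 for x in labels),  # 1-based labels
            )
        )
    return out


# ===========================================================================
# tabular generators
# ===========================================================================

STAGE_ORDER = ["dome", "30%", "50%", "germ_ring", "shield", "75%", "90%", "100%"]

#: Standard-staging reference times (h post fertilization) for each stage.
STAGE_REFERENCE_H = {
    "dome": 4.33,
    "30%": 4.67,
    "50%": 5.25,
    "germ_ring": 5.67,
    "shield": 6.0,
    "75%": 8.0,
    "90%": 9.0,
    "100%": 10.0,
}


def generate_epiboly_table(
    n_repeats: int = 3,
    stage_offsets_h: Mapping[str, float] | None = None,
    genotype_delay_h: float = 0.0,
    noise_sd_h: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-stage epiboly times for wt and mutant embryos across repeats.

    Each repeat carries a technical clock shift (SD ``noise_sd_h``) shared
    by all its records; the wild-type dome record IS the event that sets
    that clock, so it carries the shift and nothing else, while every other
    record adds independent staging jitter (SD ``noise_sd_h``) on top.
    Mutants are additionally delayed by ``genotype_delay_h`` at every
    post-dome stage. Within each (genotype, repeat) times are made
    non-decreasing in stage order by a running maximum, preserving the
    staging invariant under jitter. Columns:
    ``stage, genotype, repeat, time_h``.
    """
    offsets = dict(STAGE_REFERENCE_H if stage_offsets_h is None else stage_offsets_h)
    stages = [s for s in STAGE_ORDER if s in offsets]
    if stages[0] != "dome":
        raise ValueError("stage list must start at dome")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_repeats):
        repeat_shift = rng.normal(0.0, noise_sd_h) if noise_sd_h > 0 else 0.0
        for genotype in ("wt", "mut"):
            times = []
            for k, stage in enumerate(stages):
                t = offsets[stage] + repeat_shift
                if genotype == "mut" and k > 0:
                    t += genotype_delay_h
                is_clock_anchor = genotype == "wt" and k == 0
                if noise_sd_h > 0 and not is_clock_anchor:
                    t += rng.normal(0.0, noise_sd_h)
                times.append(t)
            times = np.maximum.accumulate(times)
            for stage, t in zip(stages, times):
                rows.append(
                    {"stage": stage, "genotype": genotype, "repeat": rep, "time_h": float(t)}
                )
    return pd.DataFrame(rows)


def generate_qpcr_table(
    genes: Sequence[str],
    true_log2_fold: Mapping[str, float],
    ct_sd: float = 0.0,
    n_samples: int = 4,
    seed: int = 0,
    housekeeping_gene: str = "actb1",
    baseline_ct: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """CT triplicates for wt/mut samples under perfect efficiency.

    A true log2 fold of ``+f`` for a gene lowers the mutant CT by ``f``
    cycles (one cycle per doubling). Per-sample RNA-loading offsets (SD
    ``ct_sd``) shift all genes of a sample together and cancel in the
    housekeeping normalization. Columns:
    ``sample, genotype, gene, ct1, ct2, ct3``.
    """
    if housekeeping_gene not in genes:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} missing from genes")
    if true_log2_fold.get(housekeeping_gene, 0.0) != 0.0:
        raise ValueError("housekeeping gene must have true fold 0")
    rng = np.random.default_rng(seed)
    base = dict(baseline_ct or {})
    rows = []
    for genotype in ("wt", "mut"):
        for s in range(1, n_samples + 1):
            sample = f"{genotype}_{s}"
            loading = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
            for gene in genes:
                ct = base.get(gene, 20.0 if gene == housekeeping_gene else 26.0) + loading
                if genotype == "mut":
                    ct -= float(true_log2_fold.get(gene, 0.0))
                trip = ct + (rng.normal(0.0, ct_sd, 3) if ct_sd > 0 else np.zeros(3))
                rows.append(
                    {
                        "sample": sample,
                        "genotype": genotype,
                        "gene": gene,
                        "ct1": float(trip[0]),
                        "ct2": float(trip[1]),
                        "ct3": float(trip[2]),
                    }
                )
    return pd.DataFrame(rows)
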