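"""Per-cluster segregation statistics S and P and group comparisons.

For each two-channel aggregate the red and green intensity distributions are
treated as probability masses over pixel positions. With per-channel
normalized weights :math:`w_c(r,x)`, the statistics are

* intensity centroids :math:`\\mu_c` and their equal-weight average
  :math:`\\mu` (the combined centroid),
* gyration radii :math:`g_c = \\sqrt{\\sum w_c \\, \\lVert x - \\mu\\rVert^2}`,
* scattering ``S``: either the raw ratio :math:`g_{red}/g_{green}` or the
  bounded symmetric form :math:`2 g_{red}/(g_{red}+g_{green}) \\in [0,2]`;
  ``S ~ 1`` for intermixed populations, deviating toward 0 or 2 under
  asymmetric segregation (e.g. engulfment),
* dipole moment ``P``: the centroid separation normalized by
  :math:`8 R_{eq} / 3\\pi` — the separation of two half-disks of the
  cluster's equivalent-circle radius — so an ideally bisected uniform disk
  scores ``P = 1`` while mixing or concentric engulfment score ``P ~ 0``.

Clusters with ``S`` inside an open window (default ``(0.9, 1.1)``) are
classified as intermixed; groups are compared by an unpaired t-test on
per-repeat intermixed fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .aggseg import AggregateROI

__all__ = [
    "ChannelMoments",
    "SegregationResult",
    "PopulationSummary",
    "GroupComparison",
    "channel_moments",
    "dipole_moment",
    "scattering",
    "compute_segregation",
    "classify_intermixed",
    "summarize_population",
    "compare_groups",
    "HALF_DISK_SEPARATION",
]

#: Centroid separation of two half-disks of unit radius: 8/(3*pi).
HALF_DISK_SEPARATION = 8.0 / (3.0 * np.pi)

RED, GREEN = "red", "green"


class ChannelMoments(NamedTuple):
    centroid_red: tuple[float, float]
    centroid_green: tuple[float, float]
    combined_centroid: tuple[float, float]
    g_red: float
    g_green: float


@dataclass
class SegregationResult:
    """All segregation statistics for one cluster (both S conventions)."""

    roi_id: int
    centroid_red: tuple[float, float]
    centroid_green: tuple[float, float]
    combined_centroid: tuple[float, float]
    g_red: float
    g_green: float
    S_ratio: float
    S_bounded: float
    P: float
    area_px: int
    R_eq: float


@dataclass
class PopulationSummary:
    group_label: str
    n_clusters: int
    intermixed_fraction: float
    intermixed_window: tuple[float, float]
    S_histogram: tuple[np.ndarray, np.ndarray]
    P_histogram: tuple[np.ndarray, np.ndarray]
    per_repeat_fractions: list[float] = field(default_factory=list)


@dataclass
class GroupComparison:
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------

def _normalized_weights(roi: AggregateROI, channel: str) -> np.ndarray:
    grid = roi.intensities[channel]
    total = grid.sum()
    if total <= 0:
        raise ValueError(f"channel {channel!r} has zero total intensity in ROI {roi.id}")
    return grid / total


def channel_moments(roi: AggregateROI) -> ChannelMoments:
    """Intensity centroids and gyration radii about the combined centroid.

    Each channel is normalized to unit mass first, so the moments are
    invariant to overall labeling brightness; the combined centroid weights
    the two normalized channels equally (the midpoint of the two centroids).
    """
    w_red = _normalized_weights(roi, RED)
    w_green = _normalized_weights(roi, GREEN)
    r0, c0 = roi.bbox[0], roi.bbox[1]
    rows = r0 + np.arange(roi.mask.shape[0], dtype=float)[:, None]
    cols = c0 + np.arange(roi.mask.shape[1], dtype=float)[None, :]

    def centroid(w: np.ndarray) -> tuple[float, float]:
        return float((w * rows).sum()), float((w * cols).sum())

    cr = centroid(w_red)
    cg = centroid(w_green)
    cc = ((cr[0] + cg[0]) / 2.0, (cr[1] + cg[1]) / 2.0)
    d2 = (rows - cc[0]) ** 2 + (cols - cc[1]) ** 2
    g_red = float(np.sqrt((w_red * d2).sum()))
    g_green = float(np.sqrt((w_green * d2).sum()))
    return ChannelMoments(cr, cg, cc, g_red, g_green)


def dipole_moment(roi: AggregateROI, moments: ChannelMoments | None = None) -> float:
    """Normalized centroid separation P (bisected-disk calibration)."""
    m = moments or channel_moments(roi)
    sep = float(np.hypot(m.centroid_red[0] - m.centroid_green[0],
                         m.centroid_red[1] - m.centroid_green[1]))
    r_eq = np.sqrt(roi.area_px / np.pi)
    return sep / (HALF_DISK_SEPARATION * r_eq)


def scattering(
    roi: AggregateROI,
    convention: str = "bounded",
    moments: ChannelMoments | None = None,
) -> float:
    """Scattering S under the requested convention.

    ``ratio`` is the raw :math:`g_{red}/g_{green}` with range ``[0, inf)``;
    ``bounded`` (default) is the symmetric :math:`2 g_{red}/(g_{red}+g_{green})`
    with range ``[0, 2]``. Identical channels give 1 under both.
    """
    if convention not in ("ratio", "bounded"):
        raise ValueError("convention must be 'ratio' or 'bounded'")
    m = moments or channel_moments(roi)
    if convention == "ratio":
        if m.g_green == 0:
            raise ZeroDivisionError("g_green is zero; S_ratio undefined")
        return m.g_red / m.g_green
    denom = m.g_red + m.g_green
    if denom == 0:
        raise ZeroDivisionError("both gyration radii are zero")
    return 2.0 * m.g_red / denom


def compute_segregation(roi: AggregateROI) -> SegregationResult:
    """Compute centroids, gyration radii, both S conventions and P."""
    m = channel_moments(roi)
    return SegregationResult(
        roi_id=roi.id,
        centroid_red=m.centroid_red,
        centroid_green=m.centroid_green,
        combined_centroid=m.combined_centroid,
        g_red=m.g_red,
        g_green=m.g_green,
        S_ratio=scattering(roi, "ratio", m),
        S_bounded=scattering(roi, "bounded", m),
        P=dipole_moment(roi, m),
        area_px=roi.area_px,
        R_eq=float(np.sqrt(roi.area_px / np.pi)),
    )


# ---------------------------------------------------------------------------
# population level
# ---------------------------------------------------------------------------

def classify_intermixed(S: float, window: tuple[float, float] = (0.9, 1.1)) -> bool:
    """True iff ``lo < S < hi`` (open interval; boundary values excluded)."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    return lo < S < hi


def _clipped_histogram(values: np.ndarray, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # out-of-range values are clipped into the terminal bins so that counts
    # always sum to the number of clusters
    eps = (edges[-1] - edges[0]) * 1e-12
    clipped = np.clip(values, edges[0], edges[-1] - eps)
    counts, _ = np.histogram(clipped, bins=edges)
    return edges, counts


def summarize_population(
    results: Sequence[SegregationResult],
    repeat_ids: Sequence | None = None,
    window: tuple[float, float] = (0.9, 1.1),
    convention: str = "bounded",
    group_label: str = "",
    s_bin_width: float = 0.1,
    p_bin_width: float = 0.05,
) -> PopulationSummary:
    """Intermixed fraction (overall and per repeat) plus S and P histograms.

    S bins cover [0, 2], P bins cover [0, 1.5] by default; values outside
    land in the terminal bins.
    """
    if len(results) == 0:
        raise ValueError("summarize_population needs at least one cluster")
    S = np.array([r.S_bounded if convention == "bounded" else r.S_ratio for r in results])
    P = np.array([r.P for r in results])
    intermixed = np.array([classify_intermixed(s, window) for s in S])
    per_repeat: list[float] = []
    if repeat_ids is not None:
        if len(repeat_ids) != len(results):
            raise ValueError("repeat_ids length differs from results")
        rep = np.asarray(repeat_ids)
        per_repeat = [float(intermixed[rep == r].mean()) for r in np.unique(rep)]
    s_edges = np.arange(0.0, 2.0 + s_bin_width / 2, s_bin_width)
    p_edges = np.arange(0.0, 1.5 + p_bin_width / 2, p_bin_width)
    return PopulationSummary(
        group_label=group_label,
        n_clusters=len(results),
        intermixed_fraction=float(intermixed.mean()),
        intermixed_window=window,
        S_histogram=_clipped_histogram(S, s_edges),
        P_histogram=_clipped_histogram(P, p_edges),
        per_repeat_fractions=per_repeat,
    )


def compare_groups(
    a: PopulationSummary | Iterable[float],
    b: PopulationSummary | Iterable[float],
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-sided t-test on per-repeat intermixed fractions.

    Accepts either summaries (their ``per_repeat_fractions``) or bare
    sequences of per-repeat fractions. With zero variance in both groups and
    equal means the comparison is degenerate and reported as t=0, p=1.
    """
    xa = np.asarray(a.per_repeat_fractions if isinstance(a, PopulationSummary) else list(a), float)
    xb = np.asarray(b.per_repeat_fractions if isinstance(b, PopulationSummary) else list(b), float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("compare_groups needs >= 2 repeats per group")
    if xa.var(ddof=1) == 0 and xb.var(ddof=1) == 0:
        if xa.mean() == xb.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if xa.mean() > xb.mean() else -np.inf
            p = 0.0
    else:
        t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
    return GroupComparison(
        mean_a=float(xa.mean()),
        mean_b=float(xb.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_a=int(xa.size),
        n_b=int(xb.size),
    )
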