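"""Reproducible synthetic benchmarks of the full analysis chain.

Each function sets up a ground-truthed synthetic experiment, runs the
package's own operations on it, and returns the measured quantities. They
double as the package's validation suite: the calibration cases have known
analytic answers, the recovery cases have generator manifests to compare
against. All randomness flows from an explicit seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import aggseg, evlmorph, segstats, studystats, synthgen
from .aggseg import AggregateROI, SegmentationParams
from .image import MultiChannelImage

__all__ = [
    "disk_roi",
    "sp_calibration",
    "li_threshold_agreement",
    "size_filter_boundary",
    "mixing_response",
    "group_difference",
    "evl_recovery",
    "mitotic_recovery",
    "epiboly_power",
    "epiboly_null_pvalues",
    "ddct_examples",
    "GROUP_BENCH",
]


# ---------------------------------------------------------------------------
# S/P calibration geometry
# ---------------------------------------------------------------------------

def disk_roi(radius: float = 100.0, layout: str = "bisected") -> AggregateROI:
    """Rasterized uniform disk split into red/green per ``layout``.

    Layouts: ``bisected`` (red half-plane vs green), ``engulfed`` (red core
    of radius R/2, green annulus), ``identical`` (both channels uniform over
    the whole disk). Pixel centers sit at half-integer offsets from the disk
    center so the two halves are exactly symmetric.
    """
    n = int(2 * radius + 4)
    coords = np.arange(n, dtype=float) - (n - 1) / 2.0
    rows, cols = coords[:, None], coords[None, :]
    r2 = rows**2 + cols**2
    disk = r2 <= radius**2
    if layout == "bisected":
        red = disk & (cols < 0)
        green = disk & (cols > 0)
    elif layout == "engulfed":
        core = r2 <= (radius / 2.0) ** 2
        red = disk & core
        green = disk & ~core
    elif layout == "identical":
        red = disk
        green = disk
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return AggregateROI(
        id=0,
        mask=disk,
        bbox=(0, 0, n, n),
        area_px=int(disk.sum()),
        intensities={
            "red": red.astype(float),
            "green": green.astype(float),
        },
    )


def sp_calibration(radius: float = 100.0) -> dict[str, float]:
    """S and P for the three analytic disk layouts.

    Continuum values: bisected -> S = 1, P = 1; engulfed -> P = 0,
    S_ratio = 1/sqrt(5) ~ 0.447, S_bounded ~ 0.618; identical -> S = 1,
    P = 0 exactly.
    """
    out: dict[str, float] = {}
    for layout in ("bisected", "engulfed", "identical"):
        res = segstats.compute_segregation(disk_roi(radius, layout))
        out[f"{layout}_P"] = res.P
        out[f"{layout}_S_bounded"] = res.S_bounded
        out[f"{layout}_S_ratio"] = res.S_ratio
    return out


# ---------------------------------------------------------------------------
# Li threshold: iterative fixed point vs exhaustive minimization
# ---------------------------------------------------------------------------

def _cross_entropy_argmin(img: np.ndarray) -> float:
    """Exhaustive scan of the Li cross-entropy criterion over all splits.

    Independent of the fixed-point implementation: evaluates
    ``-(S_lo * ln(m_lo) + S_hi * ln(m_hi))`` at every midpoint between
    consecutive distinct values (after the same shift-to-zero convention)
    and returns the minimizing threshold.
    """
    x = np.sort(np.asarray(img, dtype=float).ravel())
    shift = x[0]
    x = x - shift
    vals = np.unique(x)
    csum = np.cumsum(x)
    best_t, best_ce = None, np.inf
    for t in (vals[:-1] + vals[1:]) / 2.0:
        k = int(np.searchsorted(x, t, side="right"))
        s_lo, s_hi = csum[k - 1], csum[-1] - csum[k - 1]
        if s_lo <= 0 or s_hi <= 0:
            continue
        m_lo, m_hi = s_lo / k, s_hi / (x.size - k)
        ce = -(s_lo * np.log(m_lo) + s_hi * np.log(m_hi))
        if ce < best_ce:
            best_ce, best_t = ce, t
    return float(best_t + shift)


def li_threshold_agreement(n_images: int = 50, seed: int = 0) -> float:
    """Max deviation (gray levels) between fixed point and exhaustive scan.

    Images are random two-component 64x64 fields (dim background, bright
    foreground of random size). Both thresholds are mapped to the effective
    partition boundary — the largest pixel value at or below them — since
    any threshold inside the same empty histogram gap yields the identical
    binarization.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_images):
        n_fg = int(rng.integers(200, 2000))
        img = np.concatenate(
            [
                rng.normal(40.0, 12.0, 64 * 64 - n_fg),
                rng.normal(160.0, 30.0, n_fg),
            ]
        )
        img = np.clip(np.round(img), 1, 255).reshape(64, 64)
        t_iter = aggseg.effective_threshold(img, aggseg.li_threshold(img))
        t_scan = aggseg.effective_threshold(img, _cross_entropy_argmin(img))
        worst = max(worst, abs(t_iter - t_scan))
    return worst


# ---------------------------------------------------------------------------
# size-filter boundary
# ---------------------------------------------------------------------------

def size_filter_boundary(min_area: int = 1000) -> int:
    """ROI count on a field with components of exactly 999/1000/1001 px.

    Rectangles of those areas are placed on a noisy background and pushed
    through the full chain with negligible smoothing so component areas are
    preserved; "smaller than ``min_area``" removes only the 999 px object.
    """
    rng = np.random.default_rng(7)
    H = W = 420
    base = rng.normal(20.0, 1.0, (H, W))
    img = np.zeros((2, H, W))
    img[0] = base
    img[1] = base
    for (r0, c0, h, w) in ((40, 40, 27, 37), (40, 200, 25, 40), (200, 40, 13, 77)):
        assert h * w in (999, 1000, 1001)
        img[0, r0 : r0 + h, c0 : c0 + w] = 220.0
        img[1, r0 : r0 + h, c0 : c0 + w] = 220.0
    image = MultiChannelImage(
        np.clip(img, 0, 255), ["red", "green"], dtype_range=(0.0, 255.0)
    )
    params = SegmentationParams(
        blur_sigma_px=0.01, min_object_area_px=min_area, contrast_block_radius_px=200
    )
    return len(aggseg.segment_aggregates(image, params))


# ---------------------------------------------------------------------------
# mixing response (sorted mode)
# ---------------------------------------------------------------------------

def mixing_response(
    seed: int = 0,
    levels: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_clusters: int = 30,
) -> dict:
    """Segment sorted-mode fields across mixing levels and trace S and P.

    One field of ``n_clusters`` aggregates per level runs through the full
    detection chain; segmented ROIs are matched to manifest clusters by
    center containment. Returns per-level mean P and intermixed fraction
    plus their Spearman rank correlations against the mixing level.
    """
    mean_P: list[float] = []
    frac_intermixed: list[float] = []
    for i, m in enumerate(levels):
        cfg = synthgen.AggregateFieldConfig(
            image_height_px=1500,
            image_width_px=1500,
            n_clusters=n_clusters,
            mode="sorted",
            mixing_m=m,
            seed=seed + i,
        )
        image, truth = synthgen.generate_aggregate_field(cfg)
        rois = aggseg.segment_aggregates(image)
        results = [segstats.compute_segregation(r) for r in rois]
        mean_P.append(float(np.mean([r.P for r in results])))
        frac_intermixed.append(
            float(np.mean([segstats.classify_intermixed(r.S_bounded) for r in results]))
        )
    def _spearman(y: list[float]) -> float:
        if len(set(y)) < 2:
            return 0.0  # constant response: no trend
        return float(stats.spearmanr(levels, y).statistic)

    rho_P = _spearman(mean_P)
    rho_frac = _spearman(frac_intermixed)
    return {
        "levels": list(levels),
        "mean_P": mean_P,
        "intermixed_fraction": frac_intermixed,
        "spearman_P": rho_P,
        "spearman_intermixed": rho_frac,
    }


# ---------------------------------------------------------------------------
# group-difference detection
# ---------------------------------------------------------------------------

#: Study-scale group benchmark: cluster geometry shared by both groups; the
#: engulfed-mode mixing levels are calibrated so group A sits near an
#: intermixed fraction of 0.56 and group B near 0.43, the scale of contrast
#: the statistics are meant to resolve.
GROUP_BENCH = {
    "mixing_a": 0.495,
    "mixing_b": 0.41,
    "cells_per_cluster": 20,
    "cell_sigma_px": 4.0,
    "cluster_radius_px": (25.0, 35.0),
    "n_clusters_per_repeat": 300,
    "n_repeats": 3,
}


def _repeat_fractions(mixing: float, seeds: list[int]) -> list[float]:
    fracs = []
    for s in seeds:
        cfg = synthgen.AggregateFieldConfig(
            image_height_px=2500,
            image_width_px=2500,
            n_clusters=GROUP_BENCH["n_clusters_per_repeat"],
            cluster_radius_px=GROUP_BENCH["cluster_radius_px"],
            cells_per_cluster=GROUP_BENCH["cells_per_cluster"],
            cell_sigma_px=GROUP_BENCH["cell_sigma_px"],
            mode="engulfed",
            mixing_m=mixing,
            seed=s,
        )
        image, truth = synthgen.generate_aggregate_field(cfg)
        rois = synthgen.rois_from_ground_truth(image, truth)
        S = [segstats.compute_segregation(r).S_bounded for r in rois]
        fracs.append(float(np.mean([segstats.classify_intermixed(s_) for s_ in S])))
    return fracs


def group_difference(seed: int = 0, n_replicates: int = 50) -> dict:
    """Power of the per-repeat group comparison at study scale.

    Each replicate builds two groups (3 repeats x 300 clusters) from
    manifest-mask ROIs — the segregation statistics and the group test are
    what is under the microscope here, detection having its own benchmarks —
    and counts how often the comparison finds the second group's intermixed
    fraction significantly lower (t > 0, p < 0.05).
    """
    ss = np.random.SeedSequence(seed)
    child = ss.generate_state(2 * GROUP_BENCH["n_repeats"] * n_replicates, np.uint32)
    detected = 0
    fractions_a: list[float] = []
    fractions_b: list[float] = []
    k = 0
    for _ in range(n_replicates):
        nr = GROUP_BENCH["n_repeats"]
        seeds_a = [int(child[k + i]) for i in range(nr)]
        seeds_b = [int(child[k + nr + i]) for i in range(nr)]
        k += 2 * nr
        fa = _repeat_fractions(GROUP_BENCH["mixing_a"], seeds_a)
        fb = _repeat_fractions(GROUP_BENCH["mixing_b"], seeds_b)
        fractions_a.extend(fa)
        fractions_b.extend(fb)
        cmp = segstats.compare_groups(fa, fb)
        if cmp.p_value < 0.05 and cmp.t_statistic > 0:
            detected += 1
    return {
        "detect_rate": detected / n_replicates,
        "mean_fraction_a": float(np.mean(fractions_a)),
        "mean_fraction_b": float(np.mean(fractions_b)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# EVL morphometry recovery
# ---------------------------------------------------------------------------

def evl_recovery(seed: int = 0, rosettes: tuple[int, ...] = (5, 6, 7)) -> dict:
    """Watershed + junction recovery against the tessellation ground truth.

    Runs the image chain (Li binarize, despeckle, watershed) on a 100-cell
    mosaic, correlates recovered per-cell areas with the manifest, and
    checks the injected rosettes (exact arity within 3 px of the manifest
    position) plus false rosettes on an uninjected control.
    """
    cfg = synthgen.TessellationConfig(seed=seed, rosette_injections=list(rosettes))
    image, truth = synthgen.generate_tessellation(cfg)
    mask = evlmorph.despeckle(evlmorph.binarize_boundaries(image.data[0], method="li"))
    labels = evlmorph.watershed_cells(mask, seed_min_distance=15)
    n_rec = int(labels.max())

    rec_areas, true_areas = [], []
    for cell in truth.cells:
        overlap = labels[truth.label_map == cell.label]
        vals, counts = np.unique(overlap[overlap > 0], return_counts=True)
        if vals.size:
            best = vals[np.argmax(counts)]
            rec_areas.append(float((labels == best).sum()))
            true_areas.append(float(cell.area_px))
    area_r = float(stats.pearsonr(rec_areas, true_areas).statistic)

    detected = evlmorph.detect_junctions(truth.label_map, radius_px=3)
    gt_rosettes = [j for j in truth.junctions if j.arity >= 5]
    exact = 0
    for gj in gt_rosettes:
        for dj in detected:
            d = np.hypot(
                dj.position[0] - gj.position[0], dj.position[1] - gj.position[1]
            )
            if d <= 3.0 and dj.arity == gj.arity:
                exact += 1
                break

    cfg0 = synthgen.TessellationConfig(seed=seed)
    _, truth0 = synthgen.generate_tessellation(cfg0)
    det0 = [
        j
        for j in evlmorph.detect_junctions(truth0.label_map, radius_px=3)
        if j.arity >= 5
    ]
    gt0 = [j for j in truth0.junctions if j.arity >= 5]
    false_rosettes = 0
    for dj in det0:
        matched = any(
            np.hypot(dj.position[0] - gj.position[0], dj.position[1] - gj.position[1])
            <= 3.0
            and dj.arity == gj.arity
            for gj in gt0
        )
        if not matched:
            false_rosettes += 1

    return {
        "n_cells_true": cfg.n_cells,
        "n_cells_recovered": n_rec,
        "area_pearson_r": area_r,
        "n_rosettes_injected": len(gt_rosettes),
        "n_rosettes_exact": exact,
        "false_rosettes_control": false_rosettes,
    }


def mitotic_recovery(seed: int = 0, fraction: float = 0.1, n_cells: int = 100) -> dict:
    """Recover the flagged mitotic percentage from the rendered channels."""
    cfg = synthgen.TessellationConfig(
        seed=seed, n_cells=n_cells, mitotic_fraction=fraction
    )
    image, truth = synthgen.generate_tessellation(cfg)
    measured = evlmorph.mitotic_fraction(truth.label_map, image.data[1])
    flagged = 100.0 * sum(c.is_mitotic for c in truth.cells) / len(truth.cells)
    return {"measured_percent": measured, "flagged_percent": flagged}


# ---------------------------------------------------------------------------
# epiboly statistics
# ---------------------------------------------------------------------------

def epiboly_power(
    seed: int = 0,
    n_sims: int = 200,
    delay_h: float = 25.0 / 60.0,
    noise_sd_h: float = 5.0 / 60.0,
) -> dict:
    """Detection rate of an injected genotype delay across simulations.

    Each simulation draws a 3-repeat staged experiment with the given delay
    and jitter, normalizes to the dome reference and runs the two-way ANOVA;
    a success requires a significant genotype effect and every post-dome
    Bonferroni comparison below 0.05.
    """
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(n_sims, np.uint32)
    hits = 0
    for s in seeds:
        table = synthgen.generate_epiboly_table(
            n_repeats=3, genotype_delay_h=delay_h, noise_sd_h=noise_sd_h, seed=int(s)
        )
        res = studystats.epiboly_anova(studystats.normalize_epiboly(table))
        ok = res["genotype_p"] < 0.05 and all(
            p < 0.05 for p in res["per_stage"].values()
        )
        hits += ok
    return {"power": hits / n_sims, "n_sims": n_sims}


def epiboly_null_pvalues(seed: int = 0, n_sims: int = 500) -> dict:
    """Genotype p-value distribution under the null (no delay).

    Returns the Kolmogorov-Smirnov p-value against Uniform(0, 1).
    """
    ss = np.random.SeedSequence(seed + 1)
    seeds = ss.generate_state(n_sims, np.uint32)
    pvals = []
    for s in seeds:
        table = synthgen.generate_epiboly_table(
            n_repeats=3, genotype_delay_h=0.0, noise_sd_h=5.0 / 60.0, seed=int(s)
        )
        res = studystats.epiboly_anova(studystats.normalize_epiboly(table))
        pvals.append(res["genotype_p"])
    ks = stats.kstest(pvals, "uniform")
    return {"ks_p": float(ks.pvalue), "n_sims": n_sims}


# ---------------------------------------------------------------------------
# ddct
# ---------------------------------------------------------------------------

def ddct_examples(seed: int = 0) -> dict:
    """Worked ΔΔCT cases: textbook deltas and a generator round trip."""
    import pandas as pd

    # hand-built: sample ΔCT 5 vs calibrator ΔCT 7 -> RQ = 2^2 = 4
    rows = []
    for sample, genotype, tgt_ct in (("wt_1", "wt", 27.0), ("mut_1", "mut", 25.0)):
        rows.append(
            {"sample": sample, "genotype": genotype, "gene": "actb1",
             "ct1": 20.0, "ct2": 20.0, "ct3": 20.0}
        )
        rows.append(
            {"sample": sample, "genotype": genotype, "gene": "appb",
             "ct1": tgt_ct, "ct2": tgt_ct, "ct3": tgt_ct}
        )
    per = studystats.ddct_per_sample(
        pd.DataFrame(rows), housekeeping_gene="actb1", calibrator_sample="wt_1"
    )
    worked_rq = float(per.loc[per["sample"] == "mut_1", "rq"].iloc[0])
    calibrator_rq = float(per.loc[per["sample"] == "wt_1", "rq"].iloc[0])

    # generator round trip: true log2 fold +1, no noise -> mutant RQ 2 exactly
    table = synthgen.generate_qpcr_table(
        genes=["actb1", "appb"], true_log2_fold={"appb": 1.0}, ct_sd=0.0,
        n_samples=4, seed=seed,
    )
    summary = studystats.ddct(table, "actb1", "wt_1")
    roundtrip = next(r.rq for r in summary if r.gene == "appb" and r.group == "mut")
    return {
        "worked_rq": worked_rq,
        "calibrator_rq": calibrator_rq,
        "roundtrip_rq": float(roundtrip),
    }
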