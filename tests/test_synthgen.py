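"""Generators: determinism, manifest consistency, mode geometry, tables."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from segmix import synthgen
from segmix.synthgen import (
    AggregateFieldConfig,
    GeometryError,
    TessellationConfig,
    generate_aggregate_field,
    generate_epiboly_table,
    generate_qpcr_table,
    generate_tessellation,
    round_half_up,
)


@settings(derandomize=True, max_examples=80)
@given(st.floats(0.0, 1e6))
def test_round_half_up_matches_decimal_oracle(x):
    """Ties-up rounding agrees with the decimal definition."""
    from decimal import ROUND_HALF_UP, Decimal

    expect = int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    assert round_half_up(x) == expect


class TestAggregateFields:
    def test_determinism_bitwise(self):
        cfg = AggregateFieldConfig(seed=9, n_clusters=2, image_height_px=300, image_width_px=300)
        img1, gt1 = generate_aggregate_field(cfg)
        img2, gt2 = generate_aggregate_field(cfg)
        np.testing.assert_array_equal(img1.data, img2.data)
        assert dataclasses.asdict(gt1) == dataclasses.asdict(gt2)

    def test_sorted_m0_red_left_of_green(self):
        cfg = AggregateFieldConfig(
            seed=4, n_clusters=1, mode="sorted", mixing_m=0.0,
            image_height_px=300, image_width_px=300,
        )
        _, gt = generate_aggregate_field(cfg)
        cl = gt.clusters[0]
        red_c = np.mean([c.center[1] for c in cl.cells if c.channel == "red"])
        green_c = np.mean([c.center[1] for c in cl.cells if c.channel == "green"])
        assert red_c < green_c

    def test_mixed_mode_channels_same_law(self):
        """With many cells, red and green radial distributions coincide."""
        cfg = AggregateFieldConfig(
            seed=1, n_clusters=1, cells_per_cluster=4000, mode="mixed",
            cluster_radius_px=(60.0, 60.0), image_height_px=300, image_width_px=300,
        )
        _, gt = generate_aggregate_field(cfg)
        cl = gt.clusters[0]
        center = np.array(cl.center)
        rad = {"red": [], "green": []}
        for c in cl.cells:
            rad[c.channel].append(np.linalg.norm(np.array(c.center) - center))
        # same law: mean radius of a uniform disk is 2R/3 for both channels
        for ch in ("red", "green"):
            assert np.mean(rad[ch]) == pytest.approx(2 * 60 / 3, rel=0.05)

    def test_engulfed_m0_core_annulus(self):
        cfg = AggregateFieldConfig(
            seed=2, n_clusters=1, mode="engulfed", mixing_m=0.0,
            cluster_radius_px=(40.0, 40.0), image_height_px=300, image_width_px=300,
        )
        _, gt = generate_aggregate_field(cfg)
        cl = gt.clusters[0]
        center = np.array(cl.center)
        for c in cl.cells:
            r = np.linalg.norm(np.array(c.center) - center)
            if c.channel == "red":
                assert r <= 20.0 + 1e-9
            else:
                assert 20.0 - 1e-9 <= r <= 40.0 + 1e-9

    def test_channel_counts_follow_red_fraction(self):
        cfg = AggregateFieldConfig(seed=3, n_clusters=2, red_fraction=0.25,
                                   image_height_px=400, image_width_px=400)
        _, gt = generate_aggregate_field(cfg)
        for cl in gt.clusters:
            n_red = sum(c.channel == "red" for c in cl.cells)
            assert n_red == round_half_up(0.25 * cfg.cells_per_cluster)

    def test_manifest_intensity_consistency(self):
        """Noise-free, zero-background field: rendered channel mass equals
        the sum of per-cell blob integrals (2*pi*sigma^2*A) within 1%."""
        cfg = AggregateFieldConfig(
            seed=5, n_clusters=2, background_level=0.0, gaussian_noise_sd=0.0,
            image_height_px=400, image_width_px=400,
        )
        img, gt = generate_aggregate_field(cfg)
        for ci, ch in enumerate(("red", "green")):
            expected = sum(
                c.amplitude * 2 * np.pi * cfg.cell_sigma_px**2
                for cl in gt.clusters
                for c in cl.cells
                if c.channel == ch
            )
            assert img.data[ci].sum() == pytest.approx(expected, rel=0.01)

    def test_mixing_monotonicity_on_manifests(self):
        """Mean manifest centroid separation is non-increasing in m."""
        seps = []
        for m in (0.0, 0.25, 0.5, 0.75, 1.0):
            cfg = AggregateFieldConfig(
                seed=77, n_clusters=12, mode="sorted", mixing_m=m,
                image_height_px=900, image_width_px=900,
            )
            _, gt = generate_aggregate_field(cfg)
            seps.append(np.mean([cl.centroid_separation() for cl in gt.clusters]))
        assert all(a > b for a, b in zip(seps, seps[1:]))

    def test_infeasible_geometry_raises(self):
        cfg = AggregateFieldConfig(
            seed=0, n_clusters=1, cluster_radius_px=(200.0, 200.0),
            image_height_px=300, image_width_px=300,
        )
        with pytest.raises(GeometryError, match="geometry infeasible"):
            generate_aggregate_field(cfg)

    def test_manifest_json_roundtrip(self, tmp_path):
        cfg = AggregateFieldConfig(seed=6, n_clusters=2, image_height_px=300,
                                   image_width_px=300)
        _, gt = generate_aggregate_field(cfg)
        path = tmp_path / "manifest.json"
        gt.to_json(path)
        back = synthgen.AggregateGroundTruth.from_json(path)
        import json

        canon = lambda g: json.dumps(dataclasses.asdict(g), sort_keys=True, default=list)
        assert canon(back) == canon(gt)


class TestTessellation:
    def test_label_map_covers_n_cells(self, tessellation):
        _, gt = tessellation
        labels = np.unique(gt.label_map)
        assert labels.max() == 100
        assert set(labels) == set(range(0, 101))

    def test_area_conservation(self, tessellation):
        _, gt = tessellation
        total = sum(c.area_px for c in gt.cells)
        boundary = int((gt.label_map == 0).sum())
        assert total + boundary == gt.label_map.size

    def test_injected_arities_exact(self, tessellation):
        _, gt = tessellation
        injected = sorted(j.arity for j in gt.junctions if j.arity >= 5)
        assert injected == [5, 6, 7]

    def test_junction_arity_equals_incident_labels(self, tessellation):
        _, gt = tessellation
        for j in gt.junctions:
            assert j.arity == len(j.incident_labels) >= 3

    def test_generic_junctions_are_threeway(self):
        cfg = TessellationConfig(seed=8)
        _, gt = generate_tessellation(cfg)
        arities = {j.arity for j in gt.junctions}
        assert 3 in arities and max(arities) <= 4  # no spurious rosettes

    @pytest.mark.parametrize(
        "fraction,n,expected", [(0.05, 40, 2), (0.125, 20, 3), (0.1, 100, 10)]
    )
    def test_mitotic_rounding_half_up(self, fraction, n, expected):
        cfg = TessellationConfig(seed=3, n_cells=n, mitotic_fraction=fraction)
        _, gt = generate_tessellation(cfg)
        assert sum(c.is_mitotic for c in gt.cells) == expected

    def test_determinism(self):
        cfg = TessellationConfig(seed=12, n_cells=30, domain_size_px=256)
        img1, gt1 = generate_tessellation(cfg)
        img2, gt2 = generate_tessellation(cfg)
        np.testing.assert_array_equal(img1.data, img2.data)
        np.testing.assert_array_equal(gt1.label_map, gt2.label_map)

    def test_disk_domain_masks_outside(self):
        cfg = TessellationConfig(seed=2, n_cells=40, domain="disk", domain_size_px=256)
        img, gt = generate_tessellation(cfg)
        rr, cc = np.mgrid[0:256, 0:256]
        outside = (rr - 128.0) ** 2 + (cc - 128.0) ** 2 > 128.0**2
        assert (gt.label_map[outside] == 0).all()
        assert gt.label_map.max() == 40


class TestEpibolyTable:
    def test_zero_delay_zero_noise_identical(self):
        t = generate_epiboly_table(genotype_delay_h=0.0, noise_sd_h=0.0, seed=1)
        wt = t[t.genotype == "wt"].set_index(["stage", "repeat"])["time_h"]
        mut = t[t.genotype == "mut"].set_index(["stage", "repeat"])["time_h"]
        assert (wt == mut).all()

    def test_delay_applies_post_dome_only(self):
        delay = 25.0 / 60.0
        t = generate_epiboly_table(genotype_delay_h=delay, noise_sd_h=0.0, seed=1)
        piv = t.pivot_table(index="stage", columns="genotype", values="time_h")
        diff = piv["mut"] - piv["wt"]
        assert diff["dome"] == pytest.approx(0.0)
        for stage in diff.index.drop("dome"):
            assert diff[stage] == pytest.approx(delay)

    def test_times_non_decreasing_in_stage_order(self):
        t = generate_epiboly_table(noise_sd_h=0.3, seed=5)
        order = {s: i for i, s in enumerate(synthgen.STAGE_ORDER)}
        for (_, _), sub in t.groupby(["genotype", "repeat"]):
            sub = sub.sort_values("stage", key=lambda s: s.map(order))
            assert (np.diff(sub["time_h"]) >= 0).all()

    def test_seeded_reproducibility(self):
        a = generate_epiboly_table(noise_sd_h=0.1, seed=3)
        b = generate_epiboly_table(noise_sd_h=0.1, seed=3)
        assert a.equals(b)


class TestQpcrTable:
    def test_fold_two_cycles_below_wt(self):
        t = generate_qpcr_table(
            genes=["actb1", "appb"], true_log2_fold={"appb": 2.0},
            ct_sd=0.0, n_samples=2, seed=1,
        )
        piv = t[t.gene == "appb"].groupby("genotype")["ct1"].mean()
        assert piv["mut"] == pytest.approx(piv["wt"] - 2.0)

    def test_housekeeping_must_have_zero_fold(self):
        with pytest.raises(ValueError):
            generate_qpcr_table(
                genes=["actb1", "appb"], true_log2_fold={"actb1": 1.0}, seed=0
            )

    def test_seeded_reproducibility(self):
        kw = dict(
            genes=["actb1", "appa"], true_log2_fold={"appa": -1.0},
            ct_sd=0.3, n_samples=3, seed=8,
        )
        assert generate_qpcr_table(**kw).equals(generate_qpcr_table(**kw))
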