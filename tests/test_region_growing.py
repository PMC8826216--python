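"""Unique-colour tables, region growing, recolouring, k-means and metrics."""

import numpy as np
import pytest

from colorprofiler import (
    UCTable,
    build_uc_table,
    complexity_report,
    delta_e2000,
    filter_puc,
    hex_to_rgb,
    kmeans_colors,
    ordered_frequency_distribution,
    read_puc_table,
    read_uc_table,
    recolor_by_centroids,
    recolor_image,
    region_grow,
    regression_fit,
    rgb_to_hex,
    srgb_to_lab,
    top_n,
    write_puc_table,
    write_uc_table,
)
from colorprofiler.synthetic_fixtures import PatchSpec, make_patch_image

from conftest import random_uc_table


def lab_of(hex_code):
    return srgb_to_lab(np.array(hex_to_rgb(hex_code), dtype=np.uint8))


class TestUCTable:
    def test_uniform_image(self):
        raster = np.zeros((10, 10, 3), dtype=np.uint8)
        raster[...] = (255, 0, 0)
        uc = build_uc_table(raster, np.ones((10, 10), dtype=bool))
        assert uc.entries == {"#FF0000": 100} and uc.total_pixels == 100

    def test_half_and_half(self):
        raster = np.zeros((10, 10, 3), dtype=np.uint8)
        raster[:5] = (255, 0, 0)
        raster[5:] = (0, 0, 255)
        uc = build_uc_table(raster, np.ones((10, 10), dtype=bool))
        assert uc.entries == {"#FF0000": 50, "#0000FF": 50}

    def test_patch_fixture_ground_truth(self, patch_fixture):
        raster, mask, truth = patch_fixture
        uc = build_uc_table(raster, mask)
        assert uc.entries == truth.entries
        assert uc.total_pixels == truth.total_pixels

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            build_uc_table(np.zeros((4, 4, 3), dtype=np.uint8), np.zeros((4, 4), dtype=bool))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            UCTable({"#FF0000": 5}, total_pixels=7)


class TestOrderedFrequency:
    def test_sorting_and_tie_break(self):
        uc = UCTable({"#0000FF": 5, "#FF0000": 9, "#00FF00": 5}, 19)
        assert ordered_frequency_distribution(uc) == [("#FF0000", 9), ("#0000FF", 5), ("#00FF00", 5)]

    def test_matches_independent_sort(self, rng):
        uc = random_uc_table(rng, 1000)
        got = ordered_frequency_distribution(uc)
        expected = sorted(sorted(uc.entries.items()), key=lambda kv: -kv[1])  # stable two-pass sort
        assert got == expected


class TestRegionGrow:
    def test_mutually_close_colours_collapse_to_most_frequent(self):
        uc = UCTable({"#B43C3C": 50, "#B53C3C": 30, "#B43D3C": 20}, 100)
        puc = region_grow(uc, 2.0)
        assert puc.entries == [("#B43C3C", 100.0)]
        assert set(puc.assignment.values()) == {"#B43C3C"}

    def test_distant_colours_stay_separate(self):
        uc = UCTable({"#FF0000": 60, "#0000FF": 40}, 100)
        puc = region_grow(uc, 2.0)
        assert puc.entries == [("#FF0000", 60.0), ("#0000FF", 40.0)]

    def test_no_transitive_chaining(self):
        # dE(A,B) <= 2 < dE(A,C) and dE(B,C) <= 2: C must NOT merge via B,
        # because B leaves the pool when A absorbs it.
        A, B, C = "#B43C3C", "#B63C3C", "#BE3C3C"
        assert delta_e2000(lab_of(A), lab_of(B)) <= 2.0
        assert delta_e2000(lab_of(B), lab_of(C)) <= 2.0
        assert delta_e2000(lab_of(A), lab_of(C)) > 2.0
        uc = UCTable({A: 50, B: 30, C: 20}, 100)
        puc = region_grow(uc, 2.0)
        assert puc.entries == [(A, 80.0), (C, 20.0)]
        assert puc.assignment == {A: A, B: A, C: C}

    def test_threshold_is_inclusive(self):
        # two greys whose dE2000 equals the threshold exactly must merge
        a, b = "#505050", "#515151"
        t = delta_e2000(lab_of(a), lab_of(b))
        uc = UCTable({a: 2, b: 1}, 3)
        assert len(region_grow(uc, t).entries) == 1

    def test_percentages_sum_to_100_and_counts_conserved(self, rng):
        uc = random_uc_table(rng, 200)
        puc = region_grow(uc, 2.0)
        assert sum(p for _, p in puc.entries) == pytest.approx(100.0, abs=1e-9)
        groups = {}
        for q, s in puc.assignment.items():
            groups[s] = groups.get(s, 0) + uc.entries[q]
        assert sum(groups.values()) == uc.total_pixels

    def test_seeds_are_real_input_colours(self, rng):
        uc = random_uc_table(rng, 150)
        puc = region_grow(uc, 3.0)
        for h, _ in puc.entries:
            assert h in uc.entries

    def test_assigned_colours_within_threshold_of_seed(self, rng):
        uc = random_uc_table(rng, 150)
        puc = region_grow(uc, 2.5)
        for q, s in puc.assignment.items():
            assert delta_e2000(lab_of(q), lab_of(s)) <= 2.5

    def test_deterministic_across_runs(self, rng):
        uc = random_uc_table(rng, 120)
        a = region_grow(uc, 2.0)
        b = region_grow(uc, 2.0)
        assert a.entries == b.entries and a.assignment == b.assignment

    def test_empty_and_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            region_grow(UCTable({"#FF0000": 1}, 1), 0.0)
        with pytest.raises(ValueError):
            region_grow(UCTable({}, 0), 2.0)


class TestFilterAndTopN:
    def test_all_above_filter_unchanged(self):
        uc = UCTable({"#FF0000": 60, "#0000FF": 40}, 100)
        puc = region_grow(uc, 2.0)
        assert filter_puc(puc, 0.1).entries == puc.entries

    def test_strict_filter_drops_trace_colours(self):
        from colorprofiler import PUCTable

        puc = PUCTable(
            entries=[("#FF0000", 99.95), ("#0000FF", 0.05)],
            threshold=2.0,
            assignment={"#FF0000": "#FF0000", "#0000FF": "#0000FF"},
        )
        kept = filter_puc(puc, 0.1)
        assert kept.entries == [("#FF0000", 99.95)]  # not renormalised
        assert "#0000FF" not in kept.assignment

    def test_filter_matches_one_line_oracle(self, rng):
        uc = random_uc_table(rng, 300)
        puc = region_grow(uc, 1.5)
        kept = filter_puc(puc, 0.1)
        assert kept.entries == [(h, p) for h, p in puc.entries if p > 0.1]

    def test_top_n_slice_and_cumulative(self, rng):
        uc = random_uc_table(rng, 300)
        puc = region_grow(uc, 1.0)
        sub, cum = top_n(puc, 20)
        assert sub.entries == puc.entries[:20]
        assert cum == pytest.approx(sum(p for _, p in puc.entries[:20]))

    def test_top_n_larger_than_table(self):
        uc = UCTable({"#FF0000": 1, "#0000FF": 1, "#00FF00": 1}, 3)
        puc = region_grow(uc, 2.0)
        sub, cum = top_n(puc, 20)
        assert len(sub.entries) == len(puc.entries)
        assert cum == pytest.approx(100.0)


class TestRecolor:
    def test_uniform_image_unchanged(self):
        raster = np.full((6, 6, 3), (200, 40, 40), dtype=np.uint8)
        mask = np.ones((6, 6), dtype=bool)
        uc = build_uc_table(raster, mask)
        out = recolor_image(raster, mask, region_grow(uc, 2.0))
        assert np.array_equal(out, raster)

    def test_merged_pair_becomes_uniform_seed(self):
        raster = np.zeros((2, 2, 3), dtype=np.uint8)
        raster[:, 0] = hex_to_rgb("#B43C3C")
        raster[:, 1] = hex_to_rgb("#B53C3C")
        mask = np.ones((2, 2), dtype=bool)
        puc = region_grow(build_uc_table(raster, mask), 2.0)
        out = recolor_image(raster, mask, puc)
        assert (out.reshape(-1, 3) == hex_to_rgb("#B43C3C")).all()

    @pytest.mark.parametrize("threshold", [2.0, 3.0])
    def test_recolour_bound_on_gradient(self, gradient_fixture, threshold):
        raster, mask, _, _ = gradient_fixture
        uc = build_uc_table(raster, mask)
        puc = region_grow(uc, threshold)
        out = recolor_image(raster, mask, puc)
        orig_lab = srgb_to_lab(raster[mask])
        new_lab = srgb_to_lab(out[mask])
        from colorprofiler.color_core import _ciede2000_core

        de = _ciede2000_core(orig_lab, new_lab, 1, 1, 1)
        assert de.max() <= threshold + 1e-9
        out_colors = {rgb_to_hex(tuple(px)) for px in out[mask].reshape(-1, 3)}
        assert out_colors <= set(uc.entries)  # every output colour existed in the input
        assert len(out_colors) <= len(puc.entries)

    def test_background_untouched(self):
        raster = np.zeros((4, 4, 3), dtype=np.uint8)
        raster[1, 1] = (200, 0, 0)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = True
        out = recolor_image(raster, mask, region_grow(build_uc_table(raster, mask), 2.0))
        assert (out[~mask] == 0).all()

    def test_unknown_colour_raises_naming_it(self):
        raster = np.full((2, 2, 3), (9, 9, 9), dtype=np.uint8)
        mask = np.ones((2, 2), dtype=bool)
        puc = region_grow(UCTable({"#FF0000": 4}, 4), 2.0)
        with pytest.raises(ValueError, match="#090909"):
            recolor_image(raster, mask, puc)


class TestKMeans:
    @pytest.mark.parametrize("variant", ["hartigan-wong", "lloyd"])
    def test_k1_is_weighted_mean(self, rng, variant):
        uc = random_uc_table(rng, 40)
        ct = kmeans_colors(uc, K=1, seed=3, variant=variant)
        ordered = ordered_frequency_distribution(uc)
        labs = srgb_to_lab(np.array([hex_to_rgb(h) for h, _ in ordered], dtype=np.uint8))
        w = np.array([c for _, c in ordered], dtype=float)
        expected = np.average(labs, axis=0, weights=w)
        assert np.allclose(ct.centroids[0][0], expected, atol=1e-9)
        assert ct.centroids[0][2] == pytest.approx(100.0)

    @pytest.mark.parametrize("variant", ["hartigan-wong", "lloyd"])
    def test_two_separated_clouds(self, rng, variant):
        entries = {}
        for _ in range(15):  # tight red cloud and tight blue cloud
            r = tuple(int(v) for v in rng.integers(0, 6, 3) + (200, 20, 20))
            b = tuple(int(v) for v in rng.integers(0, 6, 3) + (20, 20, 200))
            entries[rgb_to_hex(r)] = entries.get(rgb_to_hex(r), 0) + int(rng.integers(1, 50))
            entries[rgb_to_hex(b)] = entries.get(rgb_to_hex(b), 0) + int(rng.integers(1, 50))
        uc = UCTable(entries, sum(entries.values()))
        ct = kmeans_colors(uc, K=2, seed=7, variant=variant)
        assert len(ct.centroids) == 2
        labs = {h: lab_of(h) for h in entries}
        red = [h for h in entries if hex_to_rgb(h)[0] > 100]
        blue = [h for h in entries if hex_to_rgb(h)[2] > 100]
        for cloud in (red, blue):
            w = np.array([entries[h] for h in cloud], dtype=float)
            mean = np.average(np.array([labs[h] for h in cloud]), axis=0, weights=w)
            best = min(delta_e2000(mean, c[0]) for c in ct.centroids)
            assert best < 1.0

    def test_k_equal_to_uc_count(self, rng):
        uc = random_uc_table(rng, 12)
        ct = kmeans_colors(uc, K=12, seed=0)
        assert len(ct.centroids) == 12
        seen = {rgb_to_hex(c[1]) for c in ct.centroids}
        assert seen == set(uc.entries)  # zero within-cluster variance

    def test_member_percentages_sum_to_100(self, rng):
        uc = random_uc_table(rng, 60)
        ct = kmeans_colors(uc, K=5, seed=1)
        assert sum(c[2] for c in ct.centroids) == pytest.approx(100.0, abs=1e-9)

    def test_deterministic_given_seed(self, rng):
        uc = random_uc_table(rng, 50)
        a = kmeans_colors(uc, K=4, seed=11)
        b = kmeans_colors(uc, K=4, seed=11)
        assert np.array_equal(a.labs, b.labs)

    def test_k_out_of_range(self, rng):
        uc = random_uc_table(rng, 5)
        with pytest.raises(ValueError):
            kmeans_colors(uc, K=0)
        with pytest.raises(ValueError):
            kmeans_colors(uc, K=6)


class TestRecolorByCentroids:
    def test_single_centroid_uniform_foreground(self, patch_fixture):
        raster, mask, uc = patch_fixture
        ct = kmeans_colors(uc, K=1, seed=0)
        out = recolor_by_centroids(raster, mask, ct)
        fg = out[mask].reshape(-1, 3)
        assert (fg == fg[0]).all()

    def test_pixels_equal_to_centroids_unchanged(self):
        raster = np.zeros((2, 2, 3), dtype=np.uint8)
        raster[0] = (255, 0, 0)
        raster[1] = (0, 0, 255)
        mask = np.ones((2, 2), dtype=bool)
        uc = build_uc_table(raster, mask)
        ct = kmeans_colors(uc, K=2, seed=0)
        out = recolor_by_centroids(raster, mask, ct)
        assert np.array_equal(out, raster)

    def test_assignment_matches_exhaustive_oracle(self, gradient_fixture):
        raster, mask, _, _ = gradient_fixture
        uc = build_uc_table(raster, mask)
        ct = kmeans_colors(uc, K=min(20, len(uc.entries)), seed=5)
        out = recolor_by_centroids(raster, mask, ct)
        idx = np.argwhere(mask)[::17]
        for i, j in idx:
            orig_lab = srgb_to_lab(raster[i, j])
            dists = [delta_e2000(orig_lab, c[0]) for c in ct.centroids]
            assert tuple(out[i, j]) == ct.centroids[int(np.argmin(dists))][1]


class TestMetrics:
    def test_reduction_zero_when_no_compression(self):
        uc = UCTable({"#FF0000": 60, "#0000FF": 40}, 100)
        puc = region_grow(uc, 2.0)
        rep = complexity_report(uc, puc)
        assert rep.reduction_pct == 0.0 and rep.uc_count == rep.puc_count == 2

    def test_reduction_arithmetic(self):
        from colorprofiler import PUCTable

        uc_entries = {f"#{i:06X}": 1 for i in range(100)}
        uc = UCTable(uc_entries, 100)
        puc = PUCTable(entries=[("#000000", 99.0), ("#000063", 1.0)], threshold=2.0, assignment={})
        rep = complexity_report(uc, puc)
        assert rep.reduction_pct == pytest.approx(98.0)
        assert rep.normalized_complexity == pytest.approx(1.0)

    def test_regression_collinear_and_constant(self):
        slope, intercept, r2 = regression_fit([1, 2, 3, 4], [3, 5, 7, 9])
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))
        slope, _, r2 = regression_fit([1, 2, 3], [5, 5, 5])
        assert slope == 0.0 and r2 == 0.0

    def test_regression_matches_closed_form(self, rng):
        x = rng.normal(size=50)
        y = 2.5 * x + rng.normal(size=50)
        slope, intercept, r2 = regression_fit(x, y)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert slope == pytest.approx(sxy / sxx)
        assert intercept == pytest.approx(y.mean() - slope * x.mean())
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            regression_fit([1, 1, 1], [1, 2, 3])


class TestPersistence:
    def test_uc_round_trip(self, tmp_path, rng):
        uc = random_uc_table(rng, 100)
        path = tmp_path / "table.uc.tsv"
        write_uc_table(uc, path)
        back = read_uc_table(path)
        assert back.entries == uc.entries and back.total_pixels == uc.total_pixels

    def test_puc_round_trip_is_lossless(self, tmp_path, rng):
        uc = random_uc_table(rng, 150)
        puc = region_grow(uc, 2.0)
        path = tmp_path / "table.puc.tsv"
        write_puc_table(puc, path)
        back = read_puc_table(path)
        assert back.entries == puc.entries
        assert back.assignment == puc.assignment
        assert back.threshold == puc.threshold
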