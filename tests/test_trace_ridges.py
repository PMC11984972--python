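import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import thin

from traceridges import (
    GrayImage,
    InputError,
    TraceRidgesConfig,
    break_minor_ridges,
    canny_edges,
    fuse,
    recover_missed_ridges,
    remove_dark_segments,
    remove_small_segments,
    repair_double_ridges,
    trace_ridges,
    watershed_ridge_lines,
)
from traceridges.synthetic import SyntheticSpec, generate_fibre_image
from traceridges.trace_ridges import _component_axes

from conftest import gray

E8 = np.ones((3, 3), dtype=int)


def n_components(mask):
    return ndi.label(mask, structure=E8)[1]


class TestWatershedRidgeLines:
    def test_constant_image_has_no_ridges(self):
        assert not watershed_ridge_lines(gray(np.full((20, 20), 0.3))).any()

    def test_parallel_gaussian_ridges_traced_along_crests(self):
        rows = np.arange(40)[:, None].astype(float)
        img = np.exp(-((rows - 10) ** 2) / 8) + np.exp(-((rows - 30) ** 2) / 8)
        img = np.repeat(img, 60, axis=1)
        mask = watershed_ridge_lines(gray(img).normalised())
        crest_rows = np.argwhere(mask)[:, 0]
        assert mask.any()
        # every divide pixel within 1 px of one of the two crest rows
        assert np.all((np.abs(crest_rows - 10) <= 1) | (np.abs(crest_rows - 30) <= 1))
        # both crests present
        assert (np.abs(crest_rows - 10) <= 1).any()
        assert (np.abs(crest_rows - 30) <= 1).any()

    def test_ridge_with_single_surrounding_basin_is_missed(self):
        # an interior ridge whose two flanks drain into one background
        # basin (unique minimum): no divide line appears on the crest
        rows = np.arange(40)[:, None].astype(float)
        cols = np.arange(40)[None, :].astype(float)
        crest = np.exp(-((rows - 20) ** 2) / 6) * np.exp(
            -((cols - 20) ** 4) / 1e4
        )
        ramp = 1e-3 * (rows + cols)  # single global background minimum
        mask = watershed_ridge_lines(gray(crest + ramp).normalised())
        assert not mask[18:23, 10:30].any()


class TestCannyEdges:
    def test_vertical_step_gives_single_edge_line(self):
        img = np.zeros((20, 20))
        img[:, 10:] = 1.0
        edges = canny_edges(gray(img), sigma=1.0)
        cols = np.argwhere(edges)[:, 1]
        assert edges.any()
        assert cols.min() >= 8 and cols.max() <= 11
        assert n_components(edges) == 1

    def test_wide_ridge_flanked_by_two_edges(self):
        img = np.zeros((30, 30))
        img[13:18, :] = 1.0  # 5-px-wide horizontal band, border to border
        edges = canny_edges(gray(img), sigma=1.0)
        rows = np.argwhere(edges)[:, 0]
        assert n_components(edges) == 2
        assert (rows < 15).any() and (rows > 15).any()

    def test_constant_image_yields_no_edges(self):
        assert not canny_edges(gray(np.full((20, 20), 0.6))).any()

    def test_invalid_hysteresis_order_rejected(self):
        with pytest.raises(InputError):
            canny_edges(gray(np.zeros((10, 10))), low=0.8, high=0.2)


class TestBreakMinorRidges:
    def test_disjoint_masks_leave_ridges_unchanged(self):
        ridges = np.zeros((10, 10), dtype=bool)
        ridges[2, :] = True
        edges = np.zeros_like(ridges)
        edges[7, :] = True
        assert np.array_equal(break_minor_ridges(ridges, edges), ridges)

    def test_total_overlap_empties_ridges(self):
        ridges = np.zeros((10, 10), dtype=bool)
        ridges[3, 2:8] = True
        assert not break_minor_ridges(ridges, ridges.copy()).any()

    def test_minor_branch_detached_at_edge_crossing(self):
        # main ridge along row 3; minor branch descends at col 7 and is
        # crossed by an edge at row 8
        ridges = np.zeros((15, 15), dtype=bool)
        ridges[3, :] = True
        ridges[4:13, 7] = True
        edges = np.zeros_like(ridges)
        edges[8, 5:10] = True
        before = n_components(ridges)
        broken = break_minor_ridges(ridges, edges)
        assert n_components(broken) == before + 1

    def test_diagonal_crossing_without_shared_pixel_is_cut(self):
        ridges = np.zeros((6, 6), dtype=bool)
        for i in range(5):
            ridges[i, i] = True
        edges = np.zeros_like(ridges)
        edges[3, 2] = edges[2, 3] = True  # threads between (2,2) and (3,3)
        broken = break_minor_ridges(ridges, edges)
        assert n_components(broken) == 2

    def test_output_is_subset_of_input(self, rng):
        ridges = rng.uniform(size=(20, 20)) < 0.3
        edges = rng.uniform(size=(20, 20)) < 0.3
        broken = break_minor_ridges(ridges, edges)
        assert not (broken & ~ridges).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InputError):
            break_minor_ridges(np.zeros((5, 5), bool), np.zeros((6, 6), bool))


class TestRemoveSmallSegments:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        assert not remove_small_segments(mask, 5.0).any()

    def test_long_segment_retained(self):
        mask = np.zeros((5, 30), dtype=bool)
        mask[2, 5:25] = True  # 1x20: moment-based major axis ~ 23 px
        assert remove_small_segments(mask, 5.0).sum() == 20

    def test_short_segment_removed(self):
        mask = np.zeros((5, 10), dtype=bool)
        mask[2, 3:6] = True  # 1x3: moment-based major axis ~ 3.5 px
        assert not remove_small_segments(mask, 5.0).any()

    def test_zero_threshold_is_identity(self, rng):
        mask = rng.uniform(size=(15, 15)) < 0.2
        assert np.array_equal(remove_small_segments(mask, 0.0), mask)

    def test_component_count_nonincreasing_in_threshold(self, rng):
        mask = rng.uniform(size=(30, 30)) < 0.15
        counts = [
            n_components(remove_small_segments(mask, t)) for t in (0, 2, 5, 10)
        ]
        assert counts == sorted(counts, reverse=True)


class TestRemoveDarkSegments:
    cfg_fixed = TraceRidgesConfig(dark_threshold_mode="fixed",
                                  dark_threshold_value=0.5)

    def test_bright_segment_retained_dark_removed(self):
        img = np.full((10, 20), 0.05)
        img[2, 2:12] = 0.8
        img[7, 2:12] = 0.2
        mask = np.zeros_like(img, dtype=bool)
        mask[2, 2:12] = True
        mask[7, 2:12] = True
        out = remove_dark_segments(mask, gray(img), self.cfg_fixed)
        assert out[2, 2:12].all() and not out[7].any()

    def test_segment_on_zero_background_removed(self):
        img = np.zeros((10, 10))
        img[0, 0] = 1.0  # give Otsu two classes
        mask = np.zeros_like(img, dtype=bool)
        mask[5, 2:8] = True
        cfg = TraceRidgesConfig()
        assert not remove_dark_segments(mask, gray(img), cfg).any()

    def test_fixed_threshold_mean_comparison(self):
        img = np.full((8, 20), 0.0)
        img[2, :10] = 0.2
        img[5, :10] = 0.8
        mask = np.zeros_like(img, dtype=bool)
        mask[2, :10] = True
        mask[5, :10] = True
        out = remove_dark_segments(mask, gray(img), self.cfg_fixed)
        assert out[5, :10].all() and not out[2].any()


class TestRepairDoubleRidges:
    cfg = TraceRidgesConfig()

    @staticmethod
    def euler(mask):
        holes = ndi.binary_fill_holes(mask) & ~mask
        n_holes = ndi.label(holes, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
        return ndi.label(mask, structure=E8)[1] - n_holes

    def test_small_hole_filled_and_thinned_to_open_curve(self):
        mask = np.zeros((9, 10), dtype=bool)
        mask[3:6, 3:7] = True
        mask[4, 4:6] = False  # 3x4 ring with a 1x2 hole
        assert self.euler(mask) == 0
        out = repair_double_ridges(mask, self.cfg)
        assert self.euler(out) == 1
        assert np.array_equal(thin(out), out)

    def test_simply_connected_component_untouched(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[4, 1:9] = True
        assert np.array_equal(repair_double_ridges(mask, self.cfg), mask)

    def test_large_hole_left_alone(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        mask[3:11, 3:11] = False  # ring with a 64-px^2 hole
        assert np.array_equal(repair_double_ridges(mask, self.cfg), mask)

    def test_pixels_outside_holey_components_untouched(self, rng):
        mask = np.zeros((20, 20), dtype=bool)
        mask[2:5, 2:6] = True
        mask[3, 3:5] = False  # holey component
        mask[15, 2:18] = True  # separate clean line
        out = repair_double_ridges(mask, self.cfg)
        assert np.array_equal(out[10:], mask[10:])


class TestRecoverMissedRidges:
    cfg = TraceRidgesConfig()

    def test_parallel_edge_pair_closed_to_centre_line(self):
        edges = np.zeros((20, 40), dtype=bool)
        edges[5, 0:31] = True
        edges[9, 0:31] = True
        main = np.zeros_like(edges)
        img = gray(np.full(edges.shape, 0.5))
        out = recover_missed_ridges(edges, main, img, self.cfg)
        assert out.any()
        rows, cols = np.argwhere(out).T
        assert np.all(np.abs(rows - 7) <= 1)
        # thinning shrinks a band's free ends by a few pixels
        assert cols.min() <= 4 and cols.max() >= 26

    def test_single_edge_discarded(self):
        edges = np.zeros((20, 40), dtype=bool)
        edges[5, 0:31] = True
        main = np.zeros_like(edges)
        img = gray(np.full(edges.shape, 0.5))
        assert not recover_missed_ridges(edges, main, img, self.cfg).any()

    def test_edges_of_already_traced_ridge_not_recovered(self):
        edges = np.zeros((20, 40), dtype=bool)
        edges[5, 0:31] = True
        edges[9, 0:31] = True
        main = np.zeros_like(edges)
        main[7, 0:31] = True  # the watershed already found this ridge
        img = gray(np.full(edges.shape, 0.5))
        assert not recover_missed_ridges(edges, main, img, self.cfg).any()

    @staticmethod
    def _edge_pair_grid(n_rows, n_cols, seg_len=19, gap=4, spacing=40):
        h, w = n_rows * spacing + 20, n_cols * spacing + 20
        edges = np.zeros((h, w), dtype=bool)
        for i in range(n_rows):
            for j in range(n_cols):
                r, c = 10 + i * spacing, 10 + j * spacing
                edges[r, c:c + seg_len] = True
                edges[r + gap, c:c + seg_len] = True
        return edges

    def test_candidate_count_switches_axis_rule(self):
        # each candidate centre line has major axis ~ 22 px: accepted by
        # the relaxed rule (> 15) but rejected by the strict one (>= 25)
        few = self._edge_pair_grid(7, 7)  # 49 candidates < 100
        img = gray(np.full(few.shape, 0.5))
        out_few = recover_missed_ridges(few, np.zeros_like(few), img, self.cfg)
        assert n_components(out_few) == 49

        many = self._edge_pair_grid(12, 12)  # 144 candidates >= 100
        img = gray(np.full(many.shape, 0.5))
        out_many = recover_missed_ridges(
            many, np.zeros_like(many), img, self.cfg
        )
        assert not out_many.any()


class TestFuse:
    def test_empty_recovered_reproduces_main_components(self):
        main = np.zeros((15, 15), dtype=bool)
        main[3, 1:12] = True
        main[10, 2:9] = True
        img = gray(np.full(main.shape, 0.7))
        ts = fuse(main, np.zeros_like(main), img)
        assert len(ts) == 2
        assert all(t.source_tag == "main_ridge" for t in ts.traces)

    def test_disjoint_masks_add_trace_counts(self):
        main = np.zeros((15, 15), dtype=bool)
        main[3, 1:12] = True
        rec = np.zeros_like(main)
        rec[10, 2:9] = True
        img = gray(np.full(main.shape, 0.7))
        ts = fuse(main, rec, img)
        assert len(ts) == 2
        tags = sorted(t.source_tag for t in ts.traces)
        assert tags == ["main_ridge", "recovered_edge"]

    def test_bright_long_trace_wins_crossing(self):
        img = np.zeros((20, 20))
        img[10, :] = 1.0
        img[5:16, 10] = np.maximum(img[5:16, 10], 0.3)
        main = np.zeros((20, 20), dtype=bool)
        main[10, :] = True
        rec = np.zeros_like(main)
        rec[5:16, 10] = True
        ts = fuse(main, rec, gray(img))
        # dim vertical trace split at the crossing; bright one contiguous
        assert len(ts) == 3
        bright = [t for t in ts.traces if t.source_tag == "main_ridge"]
        assert len(bright) == 1 and len(bright[0]) == 20

    def test_all_traces_pairwise_disjoint_and_thin(self, rng):
        main = rng.uniform(size=(25, 25)) < 0.15
        rec = rng.uniform(size=(25, 25)) < 0.1
        img = gray(rng.uniform(size=(25, 25)))
        ts = fuse(main, rec, img)
        seen = np.zeros((25, 25), dtype=int)
        for t in ts.traces:
            for r, c in t.pixel_coords:
                seen[r, c] += 1
            sub = np.zeros((25, 25), dtype=bool)
            rows, cols = zip(*t.pixel_coords)
            sub[list(rows), list(cols)] = True
            assert n_components(sub) == 1
            assert np.array_equal(thin(sub), sub)
        assert seen.max() <= 1


class TestTraceRidgesPipeline:
    def test_constant_image_yields_no_traces(self):
        ts = trace_ridges(gray(np.full((32, 32), 0.4)))
        assert len(ts) == 0

    def test_well_separated_fibres_each_traced_accurately(self):
        spec = SyntheticSpec(n_fibres=5, noise_sigma=0.02, seed=3)
        img, gt = generate_fibre_image(spec)
        ts = trace_ridges(img)
        assert abs(len(ts) - 5) <= 1
        from traceridges import distance_map

        d = distance_map(gt).values
        assert d[ts.mask()].mean() <= 2.0

    def test_deterministic_across_repeated_runs(self):
        spec = SyntheticSpec(n_fibres=3, seed=11)
        img, _ = generate_fibre_image(spec)
        a = trace_ridges(img)
        b = trace_ridges(img)
        assert len(a) == len(b)
        assert all(
            x.pixel_coords == y.pixel_coords for x, y in zip(a.traces, b.traces)
        )

    def test_tiny_image_rejected(self):
        with pytest.raises(InputError):
            trace_ridges(gray(np.zeros((4, 4))))

    @pytest.mark.parametrize("width_sigma", [0.85, 1.7, 2.5, 3.4])
    def test_noiseless_single_fibre_traced_within_1_5_px(self, width_sigma):
        spec = SyntheticSpec(
            n_fibres=1, noise_sigma=0.0, profile_sigma=width_sigma, seed=21
        )
        img, gt = generate_fibre_image(spec)
        ts = trace_ridges(img)
        assert len(ts) >= 1
        from traceridges import distance_map

        d = distance_map(gt).values
        assert d[ts.mask()].mean() <= 1.5

    def test_geometric_equivariance_under_rot90_and_flip(self):
        spec = SyntheticSpec(n_fibres=3, noise_sigma=0.01, seed=5)
        img, _ = generate_fibre_image(spec)
        base = trace_ridges(img).mask()
        rot = trace_ridges(GrayImage(np.rot90(img.pixels).copy())).mask()
        flip = trace_ridges(GrayImage(np.fliplr(img.pixels).copy())).mask()
        for other, mapped in (
            (rot, np.rot90(base).copy()),
            (flip, np.fliplr(base).copy()),
        ):
            d1 = ndi.distance_transform_edt(~mapped)[other]
            d2 = ndi.distance_transform_edt(~other)[mapped]
            assert d1.mean() <= 0.5 and d2.mean() <= 0.5


class TestComponentAxes:
    def test_1xN_line_axes_match_moment_formula(self):
        coords = np.array([(0, c) for c in range(20)])
        major, minor = _component_axes(coords)
        assert major == pytest.approx(4 * np.sqrt(20**2 / 12.0))
        assert minor == pytest.approx(4 * np.sqrt(1 / 12.0))
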