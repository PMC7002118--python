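"""Peak extraction, offset refinement, grouping, suppression."""

import numpy as np
import pytest

from gfscell.decoding import (
    Detection,
    GroupingConfig,
    Peak,
    apply_offset,
    center_grouping,
    extract_peaks,
    suppress,
)
from gfscell.errors import ConfigurationError, InvalidInputError
from gfscell.keypoints import ExtremeSet
from helpers import brute_force_grouping, brute_force_peaks


def peak(x, y, resp, kind=""):
    return Peak(x=float(x), y=float(y), response=float(resp), kind=kind,
                cell=(int(round(y)), int(round(x))))


class TestExtractPeaks:
    def test_flat_map_has_no_peaks(self):
        assert extract_peaks(np.zeros((8, 8)), 0.1) == []

    def test_single_maximum(self):
        hm = np.zeros((5, 5))
        hm[2, 2] = 0.9
        peaks = extract_peaks(hm, 0.1)
        assert len(peaks) == 1
        assert (peaks[0].x, peaks[0].y, peaks[0].response) == (2.0, 2.0, 0.9)

    def test_plateau_ties_qualify_and_truncate_in_scan_order(self):
        hm = np.zeros((5, 5))
        hm[2, 2] = hm[2, 3] = 0.8
        peaks = extract_peaks(hm, 0.1)
        assert {(p.y, p.x) for p in peaks} == {(2.0, 2.0), (2.0, 3.0)}
        top = extract_peaks(hm, 0.1, max_peaks=1)
        assert (top[0].y, top[0].x) == (2.0, 2.0)  # row-major first

    def test_edge_cells_use_truncated_window(self):
        hm = np.zeros((4, 4))
        hm[0, 0] = 0.5
        peaks = extract_peaks(hm, 0.1)
        assert (peaks[0].y, peaks[0].x) == (0.0, 0.0)

    def test_empty_or_bad_input_rejected(self):
        with pytest.raises(InvalidInputError):
            extract_peaks(np.zeros((0, 4)), 0.1)
        with pytest.raises(InvalidInputError):
            extract_peaks(np.zeros((4, 4)), 0.1, window=4)

    def test_matches_brute_force_scan_on_random_maps(self):
        """Exact set equality with the full-scan oracle on 200 random
        64x64 maps with mixed smooth and spiky structure."""
        rng = np.random.default_rng(17)
        for i in range(200):
            hm = rng.random((64, 64))
            if i % 2:  # smooth maps produce sparser peak sets
                from scipy.ndimage import gaussian_filter

                hm = gaussian_filter(hm, 2.0)
            tau = float(rng.uniform(0.05, 0.8))
            got = {(p.cell) for p in extract_peaks(hm, tau)}
            assert got == brute_force_peaks(hm, tau)

    def test_sorted_by_response_descending(self):
        rng = np.random.default_rng(1)
        hm = rng.random((32, 32))
        resp = [p.response for p in extract_peaks(hm, 0.0)]
        assert resp == sorted(resp, reverse=True)


class TestApplyOffset:
    def test_refines_with_stored_offset(self):
        p = Peak(x=3.0, y=3.0, response=0.9, kind="top", cell=(3, 3))
        off = np.zeros((2, 8, 8))
        off[0, 3, 3], off[1, 3, 3] = 0.25, 0.75
        refined = apply_offset(p, off, 4)
        assert (refined.x, refined.y) == (13.0, 15.0)

    def test_zero_offset_at_unit_scale_is_identity(self):
        p = Peak(x=5.0, y=2.0, response=0.5, kind="left", cell=(2, 5))
        refined = apply_offset(p, np.zeros((2, 8, 8)), 1)
        assert (refined.x, refined.y) == (5.0, 2.0)

    def test_missing_map_falls_back_to_cell_center(self, caplog):
        p = Peak(x=3.0, y=3.0, response=0.9, kind="top", cell=(3, 3))
        refined = apply_offset(p, None, 4)
        assert (refined.x, refined.y) == (14.0, 14.0)

    def test_roundtrip_with_renderer(self):
        """A keypoint at x = 13 rendered at s = 4 decodes back to exactly 13."""
        from gfscell.synthetic import RenderConfig, render_heatmaps
        from gfscell.synthetic.scenes import Scene, SceneInstance
        from gfscell.synthetic.shapes import ShapeSpec, extreme_points, make_shape

        spec = ShapeSpec("ellipse", center=(13.0, 15.0), params={"a": 5.0, "b": 5.0})
        poly = make_shape(spec, 64)
        scene = Scene(32, 32, (SceneInstance(spec, poly, extreme_points(poly), "e"),))
        bundle = render_heatmaps(scene, RenderConfig(sigma=1.2, s=4, seed=0))
        peaks = extract_peaks(bundle.heatmaps["e"]["center"], 0.5)
        refined = apply_offset(peaks[0], bundle.offsets["center"], 4)
        assert refined.x == pytest.approx(13.0, abs=1e-9)
        assert refined.y == pytest.approx(15.0, abs=1e-9)


class TestCenterGrouping:
    def diamond_peaks(self):
        return (
            [peak(4, 0, 0.9, "top")],
            [peak(0, 4, 0.8, "left")],
            [peak(4, 8, 0.7, "bottom")],
            [peak(8, 4, 0.6, "right")],
        )

    def test_empty_peak_list_gives_no_candidates(self):
        t, l, b, r = self.diamond_peaks()
        cm = np.full((9, 9), 0.9)
        assert center_grouping([], l, b, r, cm, 0.1) == []

    def test_diamond_candidate_score(self):
        t, l, b, r = self.diamond_peaks()
        cm = np.zeros((9, 9))
        cm[4, 4] = 0.9
        cands = center_grouping(t, l, b, r, cm, 0.1)
        assert len(cands) == 1
        assert cands[0].extremes.score == pytest.approx((0.9 + 0.8 + 0.7 + 0.6 + 0.9) / 5)

    def test_low_center_response_blocks(self):
        t, l, b, r = self.diamond_peaks()
        cm = np.zeros((9, 9))
        cm[4, 4] = 0.05
        assert center_grouping(t, l, b, r, cm, 0.1) == []

    def test_geometrically_invalid_combination_blocked(self):
        t = [peak(4, 8, 0.9, "top")]     # below the bottom peak
        b = [peak(4, 0, 0.9, "bottom")]
        l = [peak(0, 4, 0.9, "left")]
        r = [peak(8, 4, 0.9, "right")]
        cm = np.full((9, 9), 0.9)
        assert center_grouping(t, l, b, r, cm, 0.1) == []

    def test_matches_exhaustive_oracle(self):
        """Same candidate set as exhaustive enumeration for random inputs
        with up to 6 peaks per type."""
        rng = np.random.default_rng(23)
        for _ in range(40):
            cm = rng.random((24, 24)) * (rng.random((24, 24)) < 0.3)
            lists = []
            for kind in ("top", "left", "bottom", "right"):
                k = int(rng.integers(0, 7))
                lists.append(
                    [peak(rng.uniform(0, 23), rng.uniform(0, 23), rng.uniform(0.1, 1), kind)
                     for _ in range(k)]
                )
            tau_c = float(rng.uniform(0.05, 0.5))
            got = center_grouping(*lists, cm, tau_c)
            raw = [[(p.x, p.y, p.response) for p in lst] for lst in lists]
            expect = brute_force_grouping(*raw, cm, tau_c)
            got_keys = set()
            for c in got:
                it = next(i for i, p in enumerate(lists[0]) if p is c.peaks[0])
                il = next(i for i, p in enumerate(lists[1]) if p is c.peaks[1])
                ib = next(i for i, p in enumerate(lists[2]) if p is c.peaks[2])
                ir = next(i for i, p in enumerate(lists[3]) if p is c.peaks[3])
                got_keys.add((it, il, ib, ir))
            assert got_keys == expect

    def test_candidates_ordered_compact_first(self):
        t = [peak(4, 0, 0.9), peak(14, 0, 0.9)]
        l = [peak(0, 4, 0.9), peak(10, 4, 0.9)]
        b = [peak(4, 8, 0.9), peak(14, 8, 0.9)]
        r = [peak(8, 4, 0.9), peak(18, 4, 0.9)]
        cm = np.full((20, 20), 0.9)
        cands = center_grouping(t, l, b, r, cm, 0.1)
        compact = [c.compactness for c in cands]
        assert compact == sorted(compact)

    def test_scores_are_mean_of_five_responses(self):
        rng = np.random.default_rng(9)
        cm = rng.random((16, 16))
        t = [peak(rng.uniform(2, 13), rng.uniform(0, 5), rng.random()) for _ in range(3)]
        l = [peak(rng.uniform(0, 5), rng.uniform(2, 13), rng.random()) for _ in range(3)]
        b = [peak(rng.uniform(2, 13), rng.uniform(10, 15), rng.random()) for _ in range(3)]
        r = [peak(rng.uniform(10, 15), rng.uniform(2, 13), rng.random()) for _ in range(3)]
        for c in center_grouping(t, l, b, r, cm, 0.0):
            assert c.extremes.score == pytest.approx(np.mean(c.extremes.responses), abs=1e-12)


def det(box, score, label="c"):
    es = ExtremeSet(
        top=((box[0] + box[2]) / 2, box[1]),
        left=(box[0], (box[1] + box[3]) / 2),
        bottom=((box[0] + box[2]) / 2, box[3]),
        right=(box[2], (box[1] + box[3]) / 2),
        responses=(score,) * 5,
    )
    return Detection(label=label, box=tuple(box), score=score, extremes=es)


class TestSuppress:
    def test_duplicate_boxes_keep_highest_score(self):
        a, b = det([0, 0, 10, 10], 0.9), det([0, 0, 10, 10], 0.8)
        assert suppress([a, b], 0.5) == [a]

    def test_disjoint_boxes_both_kept(self):
        a, b = det([0, 0, 10, 10], 0.9), det([20, 20, 30, 30], 0.8)
        assert suppress([a, b], 0.5) == [a, b]

    def test_chain_keeps_first_and_third(self):
        """A overlaps B, B overlaps C, A and C disjoint: greedy keeps A and C
        (B is removed by A, so it cannot remove C)."""
        a = det([0, 0, 10, 10], 0.9)
        b = det([4, 0, 14, 10], 0.8)   # IoU with a: 60/140 = 0.43
        c = det([8, 0, 18, 10], 0.7)   # IoU with b: 0.43; with a: 20/180 = 0.11
        assert suppress([a, b, c], 0.3) == [a, c]

    def test_different_classes_do_not_suppress(self):
        a, b = det([0, 0, 10, 10], 0.9, "x"), det([0, 0, 10, 10], 0.8, "y")
        assert suppress([a, b], 0.5) == [a, b]


def test_verification_without_reference_is_a_configuration_error():
    from gfscell.decoding import detect

    maps = {"c": {k: np.zeros((8, 8)) for k in ("top", "left", "bottom", "right", "center")}}
    with pytest.raises(ConfigurationError):
        detect(maps, None, None, GroupingConfig(verify_spectrum=True), s=1)


def test_empty_heatmaps_give_empty_detections():
    from gfscell.decoding import detect

    maps = {"c": {k: np.zeros((8, 8)) for k in ("top", "left", "bottom", "right", "center")}}
    assert detect(maps, None, None, GroupingConfig(), s=1) == []
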