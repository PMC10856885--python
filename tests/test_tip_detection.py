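import numpy as np
import pytest
from scipy.sparse import lil_matrix
from scipy.sparse.csgraph import dijkstra

from circumtrack import synthetic as syn
from circumtrack.exceptions import EpipoleCoincidence
from circumtrack.camera import project
from circumtrack.segmentation import Contour, find_contours
from circumtrack.tip_detection import (
    BaseAnchor,
    epipolar_line,
    extract_candidates_side,
    extract_candidates_top,
    geodesic_tip,
    min_path_tip,
    point_line_distance,
    select_fragments_near_line,
)


def contour_from_mask(mask, cid=1):
    coords = np.column_stack(np.nonzero(mask))
    return Contour(id=cid, area=float(len(coords)), coords=coords)


def dijkstra_oracle(mask, src_rc):
    """Brute-force shortest paths on the 8-connected pixel graph."""
    h, w = mask.shape
    idx = {rc: i for i, rc in enumerate(zip(*np.nonzero(mask)))}
    g = lil_matrix((len(idx), len(idx)))
    for (r, c), i in idx.items():
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = idx.get((r + dr, c + dc))
                if j is not None:
                    g[i, j] = np.hypot(dr, dc)
    dist = dijkstra(g.tocsr(), indices=idx[tuple(src_rc)])
    out = np.full(mask.shape, np.inf)
    for rc, i in idx.items():
        out[rc] = dist[i]
    return out


class TestMinPath:
    def test_single_pixel_fragment(self):
        mask = np.zeros((10, 10), bool)
        mask[5, 5] = True
        cand = min_path_tip(contour_from_mask(mask),
                            BaseAnchor("top", (5, 5)))
        assert (cand.u, cand.v) == (5.0, 5.0)
        assert cand.geodesic_score == 0.0

    def test_straight_bar_endpoint(self):
        mask = np.zeros((220, 220), bool)
        mask[100:201, 99:102] = True  # vertical bar from (100,*) to (200,*)
        cs = extract_candidates_top([contour_from_mask(mask)],
                                    BaseAnchor("top", (100, 100)))
        assert len(cs.candidates) == 1
        c = cs.candidates[0]
        assert abs(c.u - 100) <= 2 and abs(c.v - 200) <= 2
        L = 100
        assert L - 2 <= c.geodesic_score <= L * np.sqrt(2)

    def test_hook_geodesic_beats_euclidean(self):
        """On a hook, the geodesic endpoint differs from the pixel at
        maximal Euclidean distance from the source."""
        mask = np.zeros((60, 64), bool)
        mask[50, 5:56] = True    # long base stroke ->
        mask[20:51, 55] = True   # up
        mask[20, 35:56] = True   # back left
        mask[20:35, 35] = True   # hook down
        base = BaseAnchor("side", (5, 50))
        contour = contour_from_mask(mask)
        (u, v), score = geodesic_tip(contour, base)
        # oracle: full Dijkstra from the source pixel
        oracle = dijkstra_oracle(mask, (50, 5))
        best = np.max(oracle[np.isfinite(oracle)])
        assert np.isclose(score, best, atol=1e-9)
        assert np.isclose(oracle[int(v), int(u)], best, atol=1e-9)
        # hook end (34, 35) is the geodesic endpoint ...
        assert (int(v), int(u)) == (34, 35)
        # ... but NOT the Euclidean argmax from the source
        rr, cc = np.nonzero(mask)
        eu = np.hypot(rr - 50, cc - 5)
        r_eu, c_eu = rr[np.argmax(eu)], cc[np.argmax(eu)]
        assert (r_eu, c_eu) != (34, 35)

    def test_matches_dijkstra_oracle_on_random_masks(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = np.zeros((40, 40), bool)
            # random connected blob built by a random walk
            r, c = 20, 20
            for _ in range(300):
                mask[r, c] = True
                r = int(np.clip(r + rng.integers(-1, 2), 1, 38))
                c = int(np.clip(c + rng.integers(-1, 2), 1, 38))
            contour = contour_from_mask(mask)
            base = BaseAnchor("top", (2, 2))
            (u, v), score = geodesic_tip(contour, base)
            coords = contour.coords
            d_base = np.hypot(coords[:, 1] - 2, coords[:, 0] - 2)
            src = tuple(coords[np.argmin(d_base)])
            oracle = dijkstra_oracle(mask, src)
            assert np.isclose(score, np.max(oracle[np.isfinite(oracle)]),
                              atol=1e-9)


class TestTopCandidates:
    def test_empty_mask_gives_empty_set(self):
        cs = extract_candidates_top([], BaseAnchor("top", (0, 0)))
        assert cs.candidates == []

    def test_two_blobs_give_two_candidates(self):
        mask_a = np.zeros((50, 50), bool)
        mask_a[5:15, 5:15] = True
        mask_b = np.zeros((50, 50), bool)
        mask_b[35:45, 35:46] = True
        cs = extract_candidates_top(
            [contour_from_mask(mask_a, 1), contour_from_mask(mask_b, 2)],
            BaseAnchor("top", (25, 25)))
        assert len(cs.candidates) == 2
        # ranked by area: blob b (110 px) first
        assert cs.candidates[0].contour_id == 2

    def test_candidates_are_foreground_pixels(self):
        rng = np.random.default_rng(1)
        mask = np.zeros((60, 60), bool)
        mask[10:50, 28:32] = True
        mask[40:55, 40:50] = True
        contours = find_contours(mask, min_area=10)
        cs = extract_candidates_top(contours, BaseAnchor("top", (30, 58)))
        for c in cs.candidates:
            assert mask[int(c.v), int(c.u)]

    def test_max_candidates_cap(self):
        blobs = []
        for i in range(8):
            m = np.zeros((100, 100), bool)
            m[i * 12:i * 12 + 5, 0:5 + i] = True
            blobs.append(contour_from_mask(m, i + 1))
        cs = extract_candidates_top(blobs, BaseAnchor("top", (0, 0)),
                                    max_candidates=3)
        assert len(cs.candidates) == 3


class TestEpipolarLine:
    def test_line_contains_true_projection(self, zero_dist_rig):
        rig = zero_dist_rig
        pw = np.array([8.0, -4.0, 55.0])
        p_top = project(rig.top, pw)
        p_side = project(rig.side, pw)
        line = epipolar_line(rig.F, p_top)
        assert abs(np.hypot(line[0], line[1]) - 1) < 1e-12
        assert point_line_distance(line, p_side) < 1e-6

    def test_degenerate_zero_line_rejected(self):
        with pytest.raises(EpipoleCoincidence):
            epipolar_line(np.zeros((3, 3)), (10, 10))

    def test_lines_of_collinear_points_meet_at_the_epipole(self,
                                                           zero_dist_rig):
        """Moving a point along its own top-view epipolar line rotates the
        side-view line about the side epipole (pencil of lines)."""
        rig = zero_dist_rig
        # epipole in the side view: projection of the top camera centre
        e = project(rig.side, rig.top.pose.center)
        pw = np.array([5.0, 3.0, 50.0])
        # 3 world points on the same ray from the top camera centre
        c = rig.top.pose.center
        lines = [epipolar_line(rig.F, project(rig.top, c + s * (pw - c)))
                 for s in (0.8, 1.0, 1.3)]
        for line in lines:
            assert point_line_distance(line, e) < 1e-6


class TestFragmentSelection:
    line = (0.0, 1.0, -30.0)  # horizontal line v = 30

    def make(self, r0, c0, cid):
        m = np.zeros((80, 80), bool)
        m[r0:r0 + 5, c0:c0 + 5] = True
        return contour_from_mask(m, cid)

    def test_crossing_contour_kept(self):
        kept = select_fragments_near_line([self.make(28, 10, 1)], self.line,
                                          20)
        assert [c.id for c in kept] == [1]

    def test_distance_threshold_filters(self):
        near = self.make(35, 10, 1)   # 3 px below the line (rows 35..39)
        far = self.make(70, 10, 2)    # 38 px below
        kept = select_fragments_near_line([near, far], self.line, 20)
        assert [c.id for c in kept] == [1]

    def test_fallback_keeps_single_closest(self):
        a = self.make(60, 10, 1)   # 28 px
        b = self.make(70, 10, 2)   # 38 px
        kept = select_fragments_near_line([a, b], self.line, 5)
        assert [c.id for c in kept] == [1]

    def test_empty_input(self):
        assert select_fragments_near_line([], self.line, 20) == []


class TestSideCandidates:
    def test_no_line_uses_all_fragments(self):
        masks = []
        for i, r in enumerate((10, 40)):
            m = np.zeros((80, 80), bool)
            m[r:r + 6, 10:16] = True
            masks.append(contour_from_mask(m, i + 1))
        cs = extract_candidates_side(masks, BaseAnchor("side", (40, 79)),
                                     line=None)
        assert len(cs.candidates) == 2

    def test_line_filters_to_tip_fragment(self):
        tip_frag = np.zeros((80, 80), bool)
        tip_frag[18:24, 30:36] = True
        stem_frag = np.zeros((80, 80), bool)
        stem_frag[60:70, 30:34] = True
        cs = extract_candidates_side(
            [contour_from_mask(tip_frag, 1), contour_from_mask(stem_frag, 2)],
            BaseAnchor("side", (32, 79)), line=(0.0, 1.0, -20.0),
            dist_threshold=10)
        assert [c.contour_id for c in cs.candidates] == [1]

    def test_rendered_frame_candidate_near_true_tip(self, scene_cfg,
                                                    zero_dist_rig):
        """Candidate from a clean rendered frame pair lies within 3 px of
        the true side-view tip projection."""
        cfg = syn.SceneConfig(seed=21, intensity_noise=0.0)
        tip = np.array([10.0, 6.0, 50.0])
        rng = np.random.default_rng(21)
        cam_t, cam_s = syn.true_cameras(cfg)
        img = syn.render_view(cfg, cam_s, tip, 1.0, "side", rng)
        # plant is dark on the bright wall; threshold the rendered frame
        bg = syn.render_view(cfg, cam_s, tip, 1.0, "side", rng,
                             draw_stem=False)
        mask = img < 45
        mask[int(cfg.image_height * 0.6):, :] = False  # dark band region
        contours = find_contours(mask, min_area=10)
        assert contours
        base = BaseAnchor("side", tuple(project(cam_s, np.zeros(3))))
        p_top = project(cam_t, tip)
        line = epipolar_line(zero_dist_rig.F, p_top)
        cs = extract_candidates_side(contours, base, line=line)
        best = cs.candidates[0]
        true_px = project(cam_s, tip)
        assert np.hypot(best.u - true_px[0], best.v - true_px[1]) < 3.0

    def test_stem_overlap_candidate_stays_on_contour(self):
        """With the tip folded back over the stem (hook pose), the chosen
        candidate may be the elevated stem point, but it is always a pixel
        of the segmented contour."""
        mask = np.zeros((100, 60), bool)
        mask[30:90, 28:31] = True   # stem
        mask[30:40, 28:45] = True   # hook folding right at the top
        contour = contour_from_mask(mask)
        cs = extract_candidates_side([contour], BaseAnchor("side", (29, 95)),
                                     line=None)
        c = cs.candidates[0]
        assert mask[int(c.v), int(c.u)]
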