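"""Grouping/segmentation model: tracing, linking, flood fill, trial logic."""

import numpy as np
import pytest

from crowdbench.grouping import (GroupingParams, SelectionSignal,
                                 estimate_success_prob, extract_edges,
                                 flood_fill, grouping_score, link_contours,
                                 prepare_stimulus, segment_trial,
                                 tune_seed_center)

PARAMS = GroupingParams()


def _bar_image(h=64, w=64, col=32, top=20, length=20):
    img = np.zeros((h, w))
    img[top:top + length, col] = 1.0
    return img


class TestExtractEdges:
    def test_vertical_bar_two_segments(self):
        els = extract_edges(_bar_image(), segment_length=10)
        assert len(els) == 2
        for el in els:
            assert el.orientation == pytest.approx(0.0)

    def test_blank_image_empty(self):
        assert extract_edges(np.zeros((16, 16))) == []

    def test_square_outline_equal_h_v_counts(self):
        img = np.zeros((64, 64))
        img[10, 10:51] = 1.0
        img[50, 10:51] = 1.0
        img[10:51, 10] = 1.0
        img[10:51, 50] = 1.0
        els = extract_edges(img, segment_length=10)
        horiz = sum(1 for e in els
                    if abs(e.orientation - np.pi / 2) < 0.1 and e.length > 2)
        vert = sum(1 for e in els if e.orientation < 0.1 and e.length > 2)
        assert horiz == vert

    def test_covers_every_stroke_pixel(self):
        img = _bar_image()
        img[5, 5:25] = 1.0
        els = extract_edges(img)
        covered = set()
        for el in els:
            covered.update(map(tuple, el.pixels.tolist()))
        assert covered == set(map(tuple, np.argwhere(img > 0).tolist()))


class TestLinkContours:
    def test_seven_squares_one_component(self, db):
        left, _ = db.condition("squares/7")
        from crowdbench.stimgen import StimulusImage
        flankers = StimulusImage(pixels=left.flanker_pixels)
        els = extract_edges(flankers, PARAMS.segment_length)
        graph = link_contours(els, PARAMS.gap_max, PARAMS.angle_tol,
                              PARAMS.lateral_tol)
        assert len(graph.components) == 1

    def test_large_gap_no_link(self):
        img = np.zeros((32, 96))
        img[10, 5:25] = 1.0
        img[10, 60:80] = 1.0  # collinear but 35 px away
        els = extract_edges(img)
        graph = link_contours(els, gap_max=12.0)
        assert len(graph.components) == 2

    def test_lateral_offset_blocks_link(self):
        # parallel, vertically close, but laterally offset beyond tolerance
        img = np.zeros((64, 32))
        img[10:25, 10] = 1.0
        img[30:45, 18] = 1.0   # gap 5 px along y, offset 8 px along x
        els = extract_edges(img, segment_length=20)
        graph = link_contours(els, gap_max=12.0, lateral_tol=3.0)
        comps = graph.components
        assert len(comps) == 2

    def test_collinear_small_gap_links(self):
        img = np.zeros((64, 32))
        img[10:25, 10] = 1.0
        img[30:45, 10] = 1.0   # collinear, 5 px gap
        els = extract_edges(img, segment_length=20)
        graph = link_contours(els, gap_max=12.0)
        assert len(graph.components) == 1
        kinds = {d["type"] for _, _, d in graph.graph.edges(data=True)}
        assert "illusory" in kinds


class TestFloodFill:
    def test_matches_reachability_oracle(self, db):
        left, _ = db.condition("squares/1")
        gs = prepare_stimulus(left, PARAMS)
        g = gs.graph.graph
        for start in list(g.nodes)[::7]:
            # oracle: breadth-first reachability
            seen, frontier = {start}, [start]
            while frontier:
                nxt = []
                for n in frontier:
                    for m in g.neighbors(n):
                        if m not in seen:
                            seen.add(m)
                            nxt.append(m)
                frontier = nxt
            assert flood_fill(gs.graph, start) == seen

    def test_flanker_fill_never_reaches_unlinked_vernier(self, db):
        """With no illusory vernier-flanker links, segmentation seeded on the
        square can never remove the vernier."""
        left, _ = db.condition("squares/1")
        gs = prepare_stimulus(left, PARAMS)
        flanker_el = next(i for i in gs.graph.graph.nodes
                          if i not in gs.graph.vernier_ids)
        assert not (flood_fill(gs.graph, flanker_el) & gs.graph.vernier_ids)


class TestSelectionAndTrials:
    def test_vernier_alone_center_degenerate(self, db):
        gs = prepare_stimulus(db.condition("squares/0")[0], PARAMS)
        h, w = gs.image.pixels.shape
        assert tune_seed_center(gs, PARAMS) == (w / 2.0, h / 2.0)

    def test_tuned_center_off_vernier_for_seven_squares(self, db):
        gs = prepare_stimulus(db.condition("squares/7")[0], PARAMS)
        cx, cy = tune_seed_center(gs, PARAMS)
        p = estimate_success_prob(gs, (cx, cy), PARAMS, n=400)
        assert p > 0.5
        # center lies over the flanker row, well away from the vernier
        assert abs(cx - gs.image.pixels.shape[1] / 2) > PARAMS.footprint_radius

    def test_tuning_deterministic(self, db):
        gs = prepare_stimulus(db.condition("squares/7")[0], PARAMS)
        assert tune_seed_center(gs, PARAMS) == tune_seed_center(gs, PARAMS)

    def test_seed_on_flanker_group_gives_pure_trial(self, db):
        gs = prepare_stimulus(db.condition("squares/7")[0], PARAMS)
        # deterministic-ish: tiny scatter around a far flanker position
        signal = SelectionSignal(center=(460.0, 80.0), sigma=1e-6)
        outcome = segment_trial(gs, signal, np.random.default_rng(0), PARAMS)
        assert outcome.vernier_group_pure

    def test_seed_on_vernier_gives_impure_trial(self, db):
        gs = prepare_stimulus(db.condition("squares/1")[0], PARAMS)
        signal = SelectionSignal(center=(280.0, 80.0), sigma=1e-6)
        outcome = segment_trial(gs, signal, np.random.default_rng(0), PARAMS)
        assert not outcome.vernier_group_pure

    def test_linked_flanker_always_impure(self, db):
        """irregular1 chimneys link flankers to the vernier: segmentation
        always spreads to the vernier, so no trial is pure."""
        gs = prepare_stimulus(db.condition("irregular1/1")[0], PARAMS)
        assert any(i not in gs.graph.vernier_ids
                   for comp in [gs.components[ci] for ci in gs.vernier_comp]
                   for i in comp)
        for seed in range(5):
            signal = SelectionSignal(center=(400.0, 80.0), sigma=PARAMS.sigma)
            outcome = segment_trial(gs, signal,
                                    np.random.default_rng(seed), PARAMS)
            assert not outcome.vernier_group_pure


class TestScores:
    def test_vernier_alone_maximal(self, db):
        score = grouping_score(db.condition("squares/0"), PARAMS, seed=5)
        assert score.value >= 0.95

    def test_single_square_crowds(self, db):
        alone = grouping_score(db.condition("squares/0"), PARAMS, seed=5).value
        one = grouping_score(db.condition("squares/1"), PARAMS, seed=5).value
        assert one < alone - 0.1

    def test_seven_squares_uncrowd(self, db):
        one = grouping_score(db.condition("squares/1"), PARAMS, seed=5).value
        many = grouping_score(db.condition("squares/7"), PARAMS, seed=5).value
        assert many > one + 0.1

    def test_deterministic_given_seed(self, db):
        a = grouping_score(db.condition("squares/1"), PARAMS, seed=9).value
        b = grouping_score(db.condition("squares/1"), PARAMS, seed=9).value
        assert a == b

    def test_monotone_segmentability_in_group_extent(self, db):
        """The probability of hitting the flanker group without the vernier
        is non-decreasing in the spatial extent of the group (Monte Carlo,
        >= 200 samples per condition)."""
        probs = []
        for cond in ("squares/1", "squares/3", "squares/5", "squares/7"):
            gs = prepare_stimulus(db.condition(cond)[0], PARAMS)
            center = tune_seed_center(gs, PARAMS)
            probs.append(estimate_success_prob(gs, center, PARAMS, n=300,
                                               rng=np.random.default_rng(7)))
        assert all(b >= a - 0.05 for a, b in zip(probs, probs[1:])), probs

    def test_uniform_seed_distribution_preserves_ordering(self, db):
        """Even with uniform (untuned) seed locations, wide flanker groups
        are segmented more easily than a single nearby flanker."""
        from crowdbench.grouping import _segmentation_success
        rng = np.random.default_rng(11)
        probs = {}
        for cond in ("squares/1", "squares/7"):
            gs = prepare_stimulus(db.condition(cond)[0], PARAMS)
            h, w = gs.image.pixels.shape
            pts = np.column_stack([rng.uniform(0, w, 400),
                                   rng.uniform(0, h, 400)])
            probs[cond] = float(np.mean(
                _segmentation_success(gs, pts, PARAMS.footprint_radius)))
        assert probs["squares/7"] > probs["squares/1"]
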