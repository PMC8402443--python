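"""The six optimizer criteria: exact identities, oracles, discrimination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormtrack.costs import (CONFIGS, ModelConfig, cost_color,
                             cost_completeness, cost_length, cost_noise,
                             cost_overlap, cost_smoothness, turning_angles)
from wormtrack.evaluation import iou
from wormtrack.segmentation import segment_roi, segment_tracks
from wormtrack.skeleton import SkeletonPath, classical_skeleton
from wormtrack.worm_model import WormModel, build_model, reconstruct_body


def hpath(r, c0, n):
    return SkeletonPath(np.stack([np.full(n, r), np.arange(c0, c0 + n)],
                                 axis=1))


def rect(shape, r0, r1, c0, c1):
    m = np.zeros(shape, bool)
    m[r0:r1, c0:c1] = True
    return m


class TestConfigs:
    def test_table_names_parse(self):
        assert CONFIGS["OCpCl"].enabled == frozenset({"O", "Cp", "Cl"})
        assert CONFIGS["O"].enabled == frozenset({"O"})
        assert CONFIGS["OS"].enabled == frozenset({"O", "S"})
        assert ModelConfig.parse("OLCpNSCl").enabled == \
               frozenset({"O", "L", "Cp", "N", "S", "Cl"})

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig.parse("OX")


class TestCostLength:
    def test_exact_length_zero(self):
        m = WormModel(np.full(30, 2.0), np.full(30, 20.0), 30.0, 0)
        assert cost_length({0: m}, {0: hpath(5, 0, 30)}) == 0.0

    def test_arithmetic_oracle(self):
        """Model L=30, candidate 25, widths all 2 -> 5 * 4 = 20."""
        m = WormModel(np.full(30, 2.0), np.full(30, 20.0), 30.0, 0)
        assert cost_length({0: m}, {0: hpath(5, 0, 25)}) == pytest.approx(20.0)

    def test_additive_over_worms(self):
        m0 = WormModel(np.full(30, 2.0), np.full(30, 20.0), 30.0, 0)
        m1 = WormModel(np.full(28, 1.5), np.full(28, 20.0), 28.0, 1)
        paths = {0: hpath(5, 0, 30), 1: hpath(15, 0, 21)}
        only1 = cost_length({1: m1}, {1: paths[1]})
        assert cost_length({0: m0, 1: m1}, paths) == pytest.approx(only1)
        assert only1 == pytest.approx(7 * np.mean(np.full(28, 1.5) ** 2))


class TestCostOverlap:
    def test_identical_bodies_zero(self):
        a = rect((20, 20), 5, 10, 5, 15)
        assert cost_overlap({0: a}, {0: a.copy()}) == 0

    def test_disjoint_bodies_sum_of_areas(self):
        a = rect((20, 20), 2, 5, 2, 8)
        b = rect((20, 20), 10, 14, 10, 16)
        assert cost_overlap({0: a}, {0: b}) == a.sum() + b.sum()

    def test_swap_costs_more_on_crossing_fixture(self, crossing):
        """Keeping identities beats swapping them, frame over frame."""
        seq, truth = crossing
        roi = segment_roi(seq)
        masks = segment_tracks(seq.frames[0], roi)[0]
        masks.sort(key=lambda m: tuple(np.argwhere(m).mean(axis=0)))
        models = {i: build_model(seq.frames[0], m, i)
                  for i, m in enumerate(masks)}
        shape = seq.shape
        worse = total = 0
        for f in range(1, 6):
            prev = {i: reconstruct_body(truth[f - 1][i], models[i], shape).mask
                    for i in (0, 1)}
            curr = {i: reconstruct_body(truth[f][i], models[i], shape).mask
                    for i in (0, 1)}
            swapped = {0: curr[1], 1: curr[0]}
            total += 1
            worse += cost_overlap(prev, swapped) > cost_overlap(prev, curr)
        assert worse == total


class TestCostCompleteness:
    def test_exact_cover_zero(self):
        a = rect((20, 20), 5, 10, 5, 15)
        assert cost_completeness(a, {0: a.copy()}) == 0

    def test_uncovered_end_counts(self):
        """AS extends k pixels beyond the reconstruction."""
        as_mask = rect((20, 40), 8, 11, 5, 30)
        body = rect((20, 40), 8, 11, 5, 24)
        k = as_mask.sum() - body.sum()
        assert cost_completeness(as_mask, {0: body}) == k

    def test_identity_swap_ties(self):
        """Swapping worm identities leaves the union unchanged."""
        as_mask = rect((20, 40), 5, 8, 2, 38) | rect((20, 40), 12, 15, 2, 38)
        b0 = rect((20, 40), 5, 8, 2, 38)
        b1 = rect((20, 40), 12, 15, 2, 38)
        assert cost_completeness(as_mask, {0: b0, 1: b1}) == \
               cost_completeness(as_mask, {0: b1, 1: b0})

    def test_abandoning_a_worm_costs(self):
        """Both worms piled on one body leave the other uncovered."""
        as_mask = rect((20, 40), 5, 8, 2, 38) | rect((20, 40), 12, 15, 2, 38)
        b0 = rect((20, 40), 5, 8, 2, 38)
        b1 = rect((20, 40), 12, 15, 2, 38)
        good = cost_completeness(as_mask, {0: b0, 1: b1})
        collapsed = cost_completeness(as_mask, {0: b0, 1: b0.copy()})
        assert collapsed > good


class TestCostSmoothness:
    def test_straight_path_zero(self):
        assert cost_smoothness({0: hpath(5, 0, 30)}) == 0.0

    def test_right_angle_oracle(self):
        """Hand-computed windowed turning angles for one 90-degree bend."""
        pixels = [(5, c) for c in range(6)] + [(r, 5) for r in range(6, 11)]
        path = SkeletonPath(np.array(pixels))
        n = len(pixels)
        # independent oracle: turning angle is 90 deg at the corner pixel,
        # 0 elsewhere; windowed average with nA=1 then |.| and mean
        theta = np.zeros(n)
        theta[5] = 90.0
        defined = np.zeros(n, bool)
        defined[1:n - 1] = True
        acc = 0.0
        for x in range(n):
            window = [theta[a] for a in (x - 1, x + 1)
                      if 0 <= a < n and defined[a]]
            # the center pixel's own angle is excluded by construction
            if window:
                acc += abs(sum(window) / len(window))
        expected = acc / n
        assert cost_smoothness({0: path}, n_window=1) == \
               pytest.approx(expected)

    @given(st.integers(0, 3))
    @settings(max_examples=4, deadline=None)
    def test_rotation_invariance(self, quarter_turns):
        """Turning angles are intrinsic: rotating the path changes nothing."""
        t = np.linspace(0, np.pi, 40)
        pts = np.stack([30 + 12 * np.sin(t), 30 + 12 * np.cos(t)], axis=1)
        from wormtrack.skeleton import path_from_points

        base = path_from_points(pts)
        rot = base.pixels.copy()
        for _ in range(quarter_turns):
            rot = np.stack([rot[:, 1], -rot[:, 0]], axis=1)
        rot = rot - rot.min(axis=0)
        assert cost_smoothness({0: SkeletonPath(rot)}) == \
               pytest.approx(cost_smoothness({0: base}), abs=1e-9)

    def test_turning_angles_signed_range(self):
        path = hpath(5, 0, 10)
        assert (turning_angles(path.pixels) == 0).all()


class TestCostNoise:
    def test_no_noise_zero(self):
        body = rect((20, 20), 5, 10, 5, 15)
        assert cost_noise(np.zeros((20, 20), bool), {0: body}) == 0

    def test_body_inside_noise_counts_area(self):
        body = rect((20, 20), 5, 10, 5, 15)
        assert cost_noise(np.ones((20, 20), bool), {0: body}) == body.sum()

    def test_noise_following_candidate_penalized(self):
        """A candidate lying on a noise streak scores higher CN."""
        noise = rect((30, 40), 14, 19, 5, 35)
        m = WormModel(np.full(20, 2.0), np.full(20, 20.0), 20.0, 0)
        on_worm = reconstruct_body(hpath(5, 8, 20), m, (30, 40)).mask
        on_noise = reconstruct_body(hpath(16, 8, 20), m, (30, 40)).mask
        assert cost_noise(noise, {0: on_noise}) > cost_noise(noise,
                                                             {0: on_worm})


class TestCostColor:
    def test_self_rendered_zero(self):
        m = WormModel(np.full(20, 2.0), np.linspace(14, 30, 20), 20.0, 0)
        path = hpath(10, 5, 20)
        body = reconstruct_body(path, m, (20, 40))
        frame = np.full((20, 40), 120.0)
        frame[body.mask] = body.colored[body.mask]
        assert cost_color({0: m}, {0: path}, frame) == 0

    def test_uniform_shift_counts_every_pixel(self):
        m = WormModel(np.full(20, 2.0), np.full(20, 20.0), 20.0, 0)
        path = hpath(10, 5, 20)
        body = reconstruct_body(path, m, (20, 40))
        frame = np.full((20, 40), 120.0)
        frame[body.mask] = 22.0  # +2 gray: above U = 1 everywhere
        assert cost_color({0: m}, {0: path}, frame) == body.mask.sum()

    def test_shift_below_threshold_free(self):
        m = WormModel(np.full(20, 2.0), np.full(20, 20.0), 20.0, 0)
        path = hpath(10, 5, 20)
        body = reconstruct_body(path, m, (20, 40))
        frame = np.full((20, 40), 120.0)
        frame[body.mask] = 21.0  # exactly U: not counted
        assert cost_color({0: m}, {0: path}, frame) == 0

    def test_flipped_candidate_on_ramp_worm(self):
        """Head/tail flip on a ramp-colored worm raises the color cost."""
        m = WormModel(np.full(24, 2.0), np.linspace(14, 30, 24), 24.0, 0)
        path = hpath(10, 5, 24)
        body = reconstruct_body(path, m, (20, 40))
        frame = np.full((20, 40), 120.0)
        frame[body.mask] = body.colored[body.mask]
        flipped = SkeletonPath(path.pixels[::-1].copy())
        assert cost_color({0: m}, {0: flipped}, frame) > \
               cost_color({0: m}, {0: path}, frame)


class TestGroundTruthFavoritism:
    def test_truth_beats_swap_under_ocpcl(self, crossing):
        """Across contact frames, the true assignment's OCpCl total is
        below the identity-swapped assignment's."""
        seq, truth = crossing
        roi = segment_roi(seq)
        masks = segment_tracks(seq.frames[0], roi)[0]
        masks.sort(key=lambda m: tuple(np.argwhere(m).mean(axis=0)))
        models = {i: build_model(seq.frames[0], m, i)
                  for i, m in enumerate(masks)}
        # map model ids onto truth ids at frame 0
        id_of = {}
        for i in (0, 1):
            body = reconstruct_body(truth[0][i], models[i], seq.shape).mask
            id_of[i] = i if iou(body, masks[i]) > 0 else 1 - i
        shape = seq.shape
        wins = total = 0
        for f in range(8, 22):
            prev = {i: reconstruct_body(truth[f - 1][i], models[id_of[i]],
                                        shape).mask for i in (0, 1)}
            frame = seq.frames[f].astype(float)
            as_mask = (frame < 35) & roi.mask
            def cost(assign):
                paths = {i: truth[f][assign[i]] for i in (0, 1)}
                bodies = {i: reconstruct_body(paths[i], models[id_of[i]],
                                              shape).mask for i in (0, 1)}
                return (cost_overlap(prev, bodies)
                        + cost_completeness(as_mask, bodies)
                        + cost_color({i: models[id_of[i]] for i in (0, 1)},
                                     paths, frame))
            total += 1
            wins += cost({0: 0, 1: 1}) < cost({0: 1, 1: 0})
        assert wins / total >= 0.95
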