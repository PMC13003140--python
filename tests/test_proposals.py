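import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from segnew import (
    MaskProposalSet,
    PromptSet,
    available_backends,
    propose_masks,
    region_grow_backend,
    register_backend,
    select_mask,
    si_overlap_score,
)


def prompt_set(positives, negative=None, shape=(8, 8), threshold=0.65):
    labels = np.zeros(shape, dtype=int)
    for i, (r, c) in enumerate(positives, start=1):
        labels[r, c] = i
    return PromptSet(
        positives=list(positives),
        negative=negative,
        threshold=threshold,
        component_labels=labels,
    )


def oracle_iou(a, b):
    inter = int(np.logical_and(a, b).sum())
    union = int(np.logical_or(a, b).sum())
    return inter / union if union else None


class TestProposalSetContract:
    def test_exactly_three_masks_enforced(self):
        ps = prompt_set([(0, 0)])
        m = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="three"):
            MaskProposalSet(masks=[m, m.copy()], confidences=(0.5, 0.5), prompts=ps)

    def test_mismatched_shapes_rejected(self):
        ps = prompt_set([(0, 0)])
        with pytest.raises(ValueError, match="shape"):
            MaskProposalSet(
                masks=[np.zeros((4, 4), bool), np.zeros((4, 4), bool), np.zeros((5, 4), bool)],
                confidences=(1, 1, 1),
                prompts=ps,
            )

    def test_confidences_outside_unit_interval_rejected(self):
        ps = prompt_set([(0, 0)])
        m = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match="confidences"):
            MaskProposalSet(masks=[m, m.copy(), m.copy()], confidences=(0.5, 1.5, 0.5), prompts=ps)


class TestRegionGrowBackend:
    def test_two_level_image_hand_case(self):
        # bright 3x3 plate on dark background: tight tolerance captures exactly it
        img = np.zeros((8, 8))
        img[2:5, 2:5] = 1.0
        out = region_grow_backend(img, prompt_set([(3, 3)]), tolerances=(0.1, 0.2, 0.4))
        expected = img > 0.5
        for m in out.masks:
            np.testing.assert_array_equal(m, expected)

    def test_masks_are_nested_in_tolerance(self, rng):
        img = rng.random((24, 24))
        out = region_grow_backend(img, prompt_set([(12, 12)], shape=(24, 24)))
        m1, m2, m3 = out.masks
        assert np.all(m1 <= m2) and np.all(m2 <= m3)

    def test_nested_even_with_negative_prompt(self, rng):
        img = rng.random((24, 24))
        ps = prompt_set([(4, 4), (20, 20)], negative=(12, 12), shape=(24, 24))
        out = region_grow_backend(img, ps)
        m1, m2, m3 = out.masks
        assert np.all(m1 <= m2) and np.all(m2 <= m3)

    def test_positive_prompts_always_inside_every_mask(self, rng):
        img = rng.random((16, 16))
        ps = prompt_set([(3, 3), (10, 12)], negative=(3, 4), shape=(16, 16))
        out = region_grow_backend(img, ps)
        for m in out.masks:
            for r, c in ps.positives:
                assert m[r, c]

    def test_negative_region_is_subtracted(self):
        # three plateaus at 0, 0.5, 1.0
        img = np.zeros((6, 6))
        img[:, 2:4] = 0.5
        img[:, 4:] = 1.0
        ps = prompt_set([(0, 0)], negative=(0, 5), shape=(6, 6))
        out = region_grow_backend(img, ps, tolerances=(0.1, 0.2, 0.55))
        # at tol 0.55 the positive region reaches the middle plateau, but the
        # negative region (grown from the bright plateau) claims it back
        assert out.masks[2][:, :2].all()
        assert not out.masks[2][:, 2:].any()

    def test_confidences_decrease_with_tolerance(self, rng):
        out = region_grow_backend(rng.random((8, 8)), prompt_set([(2, 2)]))
        c = out.confidences
        assert c[0] == 1.0 and c[2] == 0.0 and c[0] > c[1] > c[2]

    def test_nonincreasing_tolerances_rejected(self, rng):
        with pytest.raises(ValueError, match="increasing"):
            region_grow_backend(rng.random((8, 8)), prompt_set([(2, 2)]), tolerances=(0.2, 0.1, 0.4))

    def test_rgb_image_uses_euclidean_channel_distance(self):
        img = np.zeros((4, 4, 3))
        img[:, 2:] = (0.3, 0.4, 0.0)  # distance 0.5 from black
        out = region_grow_backend(img, prompt_set([(0, 0)], shape=(4, 4)), tolerances=(0.49, 0.51, 1.0))
        assert not out.masks[0][:, 2:].any()
        assert out.masks[1].all()


class TestProposeMasks:
    def test_empty_prompts_short_circuit(self, rng):
        ps = prompt_set([], shape=(8, 8))
        ps.no_instrument = True
        out = propose_masks(rng.random((8, 8)), ps)
        assert out.no_instrument
        assert all(not m.any() for m in out.masks)
        assert out.confidences == (0.0, 0.0, 0.0)

    def test_unknown_backend_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown backend"):
            propose_masks(rng.random((8, 8)), prompt_set([(1, 1)]), backend="no-such")

    def test_custom_backend_registration(self, rng):
        def fake_backend(image, prompts, **params):
            m = np.zeros(image.shape[:2], bool)
            m[0, 0] = True
            return MaskProposalSet(masks=[m, m.copy(), m.copy()], confidences=(1, 1, 1), prompts=prompts)

        register_backend("fake-for-test", fake_backend)
        assert "fake-for-test" in available_backends()
        out = propose_masks(rng.random((4, 4)), prompt_set([(1, 1)], shape=(4, 4)), backend="fake-for-test")
        assert out.masks[0][0, 0]


class TestOverlapScoreAndSelection:
    def test_score_matches_iou_oracle(self, rng):
        a = rng.random((12, 12)) > 0.5
        b = rng.random((12, 12)) > 0.5
        assert si_overlap_score(a, b) == pytest.approx(oracle_iou(a, b))

    def test_both_empty_scores_zero(self):
        z = np.zeros((4, 4), bool)
        assert si_overlap_score(z, z) == 0.0

    def test_identical_nonempty_scores_one(self, rng):
        m = rng.random((6, 6)) > 0.3
        m[0, 0] = True
        assert si_overlap_score(m, m) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            si_overlap_score(np.zeros((2, 2), bool), np.zeros((3, 2), bool))

    def make_proposals(self, masks, confidences=(1.0, 0.5, 0.0)):
        ps = prompt_set([(0, 0)], shape=masks[0].shape)
        return MaskProposalSet(masks=list(masks), confidences=confidences, prompts=ps)

    def test_exact_match_selected_with_score_one(self, rng):
        si_bin = rng.random((8, 8)) > 0.5
        si_bin[0, 0] = True
        other = rng.random((8, 8)) > 0.5
        props = self.make_proposals([other, si_bin.copy(), np.zeros((8, 8), bool)])
        res = select_mask(props, si_bin)
        assert res.selected_index == 2
        assert res.scores[1] == 1.0
        np.testing.assert_array_equal(res.mask, si_bin)

    def test_selection_invariant_under_permutation(self, rng):
        si_bin = rng.random((10, 10)) > 0.6
        masks = [rng.random((10, 10)) > t for t in (0.3, 0.5, 0.7)]
        base = select_mask(self.make_proposals(masks, (0.2, 0.2, 0.2)), si_bin)
        for perm in itertools.permutations(range(3)):
            props = self.make_proposals([masks[i] for i in perm], (0.2, 0.2, 0.2))
            res = select_mask(props, si_bin)
            np.testing.assert_array_equal(res.mask, base.mask)

    def test_tie_breaks_by_confidence_then_index(self):
        m = np.zeros((4, 4), bool)
        m[1, 1] = True
        props = self.make_proposals([m, m.copy(), m.copy()], confidences=(0.2, 0.9, 0.9))
        assert select_mask(props, m).selected_index == 2
        props = self.make_proposals([m, m.copy(), m.copy()], confidences=(0.5, 0.5, 0.5))
        assert select_mask(props, m).selected_index == 1

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_selected_score_is_maximal(self, seed):
        r = np.random.default_rng(seed)
        si_bin = r.random((8, 8)) > 0.5
        masks = [r.random((8, 8)) > 0.5 for _ in range(3)]
        res = select_mask(self.make_proposals(masks, (0.1, 0.2, 0.3)), si_bin)
        assert res.scores[res.selected_index - 1] == max(res.scores)
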