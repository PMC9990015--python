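"""TTA entropy and MC-dropout variance estimators."""

import numpy as np
import pytest

from pulmotex.models import ClassifierContract
from pulmotex.patching import Patch, PatchSet
from pulmotex.phantom import sample_labeled_patches
from pulmotex.preprocess import AugmentSpec, tta_augment_spec
from pulmotex.uncertainty import (
    aleatoric_entropy,
    epistemic_variance,
    label_entropy,
    uncertainty_for_patchset,
)


class VoteStub(ClassifierContract):
    """Returns a fixed label sequence row by row (argmax votes)."""

    input_size = (8, 8, 3)

    def __init__(self, votes):
        self.votes = list(votes)
        self.cursor = 0

    def predict_proba(self, batch, stochastic=False, rng=None):
        p = np.full((len(batch), 6), 0.01)
        for i in range(len(batch)):
            p[i, self.votes[self.cursor % len(self.votes)]] = 0.95
            self.cursor += 1
        return p / p.sum(axis=1, keepdims=True)

    def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
        raise NotImplementedError


class SequenceStub(ClassifierContract):
    """Returns a fixed sequence of probability vectors on stochastic passes."""

    input_size = (8, 8, 3)

    def __init__(self, probs):
        self.probs = [np.asarray(p, dtype=float) for p in probs]
        self.cursor = 0

    def predict_proba(self, batch, stochastic=False, rng=None):
        out = np.stack(
            [self.probs[(self.cursor + i) % len(self.probs)] for i in range(len(batch))]
        )
        self.cursor += len(batch)
        return out

    def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
        raise NotImplementedError


PATCH = np.zeros((8, 8, 3))


def brute_force_entropy(counts, n):
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * np.log(p)
    return h


class TestAleatoric:
    def test_unanimous_prediction_zero_entropy(self):
        res = aleatoric_entropy(VoteStub([4] * 21), PATCH, n=21, seed=0)
        assert res.H == 0.0
        assert res.p_m[4] == 1.0

    def test_two_thirds_one_third_closed_form(self):
        votes = [0] * 14 + [1] * 7
        res = aleatoric_entropy(VoteStub(votes), PATCH, n=21, seed=0)
        expected = -(2 / 3 * np.log(2 / 3) + 1 / 3 * np.log(1 / 3))
        assert res.H == pytest.approx(expected, abs=1e-12)
        assert res.H == pytest.approx(0.6365, abs=5e-5)

    def test_uniform_votes_maximum_entropy(self):
        votes = sum([[c] * 2 for c in range(6)], [])  # 12 draws, 2 per class
        res = aleatoric_entropy(VoteStub(votes), PATCH, n=12, seed=0)
        assert res.H == pytest.approx(np.log(6), abs=1e-12)

    def test_arbitrary_compositions_match_brute_force(self, rng):
        for _ in range(50):
            counts = rng.multinomial(21, np.ones(6) / 6)
            votes = sum([[c] * int(k) for c, k in enumerate(counts)], [])
            res = aleatoric_entropy(VoteStub(votes), PATCH, n=21, seed=0)
            assert res.H == pytest.approx(brute_force_entropy(counts, 21), abs=1e-12)

    def test_modal_mass_transfer_never_decreases_entropy(self):
        """Moving a draw from the modal class elsewhere is entropy-increasing."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.multinomial(21, np.ones(6) / 6)
            m = int(np.argmax(counts))
            for other in range(6):
                if other == m or counts[m] - 1 < counts[other] + 1:
                    continue
                moved = counts.copy()
                moved[m] -= 1
                moved[other] += 1
                assert brute_force_entropy(moved, 21) >= brute_force_entropy(
                    counts, 21
                ) - 1e-12

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            aleatoric_entropy(VoteStub([0]), PATCH, n=1)

    def test_entropy_grows_with_tta_noise(self, quick_classifier, quick_phantom):
        """A boundary patch's label flips more under stronger perturbation."""
        ps = sample_labeled_patches(
            quick_phantom, (32, 32, 3), 8, seed=4, min_purity=0.0,
            min_mask_fraction=0.3,
        )
        hs = []
        for noise in (0.0, 0.15):
            spec = AugmentSpec(rotation_range=15, shift_max=0, scale_range=0.1,
                               noise_sd=noise)
            h = np.mean([
                aleatoric_entropy(quick_classifier, p.data, augment_spec=spec,
                                  n=21, seed=9).H
                for p in ps
            ])
            hs.append(h)
        assert hs[1] >= hs[0]


class TestEpistemic:
    def test_dropout_disabled_zero_variance(self, rng):
        from pulmotex.models import build_denres_mini

        clf = build_denres_mini((8, 8, 3), dropout_p=0.0, seed=0)
        res = epistemic_variance(clf, rng.random((8, 8, 3)), T=5, seed=1)
        assert (res.Var_y == 0.0).all()
        assert res.epistemic_scalar == 0.0

    def test_two_pass_toy_hand_computed(self):
        probs = [
            [0.8, 0.04, 0.04, 0.04, 0.04, 0.04],
            [0.6, 0.08, 0.08, 0.08, 0.08, 0.08],
        ]
        res = epistemic_variance(SequenceStub(probs), PATCH, T=2, seed=0)
        assert res.E_y[0] == pytest.approx(0.7, abs=1e-12)
        # (1/2)(0.8^2 + 0.6^2) - 0.7^2 = 0.01
        assert res.Var_y[0] == pytest.approx(0.01, abs=1e-12)
        assert res.epistemic_scalar == pytest.approx(0.01, abs=1e-12)

    def test_streaming_equals_stored_brute_force(self, quick_classifier, rng):
        patch = rng.random((32, 32, 3))
        T, seed = 15, 3
        res = epistemic_variance(quick_classifier, patch, T=T, seed=seed)
        rng2 = np.random.default_rng(seed)
        stored = np.stack([
            quick_classifier.predict_proba(patch[None], stochastic=True, rng=rng2)[0]
            for _ in range(T)
        ])
        np.testing.assert_allclose(res.E_y, stored.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(res.Var_y, stored.var(axis=0), atol=1e-10)

    def test_variance_shrinks_with_dropout_rate(self, quick_classifier, rng):
        patch = rng.random((32, 32, 3))
        means = []
        original = quick_classifier.net.dropout_p
        try:
            for p in (0.3, 0.1, 0.0):
                quick_classifier.net.dropout_p = p
                res = epistemic_variance(quick_classifier, patch, T=21, seed=5)
                means.append(res.Var_y.sum())
        finally:
            quick_classifier.net.dropout_p = original
        assert means[0] >= means[1] >= means[2] == 0.0

    def test_too_few_passes_rejected(self, quick_classifier):
        with pytest.raises(ValueError, match="at least 2"):
            epistemic_variance(quick_classifier, np.zeros((32, 32, 3)), T=1)

    def test_classifier_without_stochastic_mode_rejected(self):
        class NoDropout(ClassifierContract):
            input_size = (8, 8, 3)

            def predict_proba(self, batch, stochastic=False, rng=None):
                return np.full((len(batch), 6), 1 / 6)

            def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
                raise NotImplementedError

            @property
            def has_stochastic_mode(self):
                return False

        with pytest.raises(ValueError, match="stochastic"):
            epistemic_variance(NoDropout(), PATCH, T=5)


class TestPatchsetUncertainty:
    def test_empty_patchset(self, quick_classifier):
        out = uncertainty_for_patchset(
            quick_classifier, PatchSet(patches=[], source_shape=(1, 1, 1))
        )
        assert out == []

    def test_independent_of_partitioning(self, quick_classifier, quick_phantom):
        ps = sample_labeled_patches(quick_phantom, (32, 32, 3), 2, seed=7)
        full = uncertainty_for_patchset(quick_classifier, ps, n=5, T=5, seed=11)
        # same patches split into two sets, seeds derived from global position
        def subset(idx0, idx1):
            return PatchSet(patches=ps.patches[idx0:idx1],
                            source_shape=ps.source_shape)

        first = uncertainty_for_patchset(quick_classifier, subset(0, 6), n=5, T=5,
                                         seed=11)
        for (a1, e1), (a2, e2) in zip(full[:6], first):
            assert a1.H == a2.H
            np.testing.assert_array_equal(e1.Var_y, e2.Var_y)

    def test_bounds(self, quick_classifier, quick_phantom):
        ps = sample_labeled_patches(quick_phantom, (32, 32, 3), 2, seed=8)
        out = uncertainty_for_patchset(quick_classifier, ps, n=5, T=5, seed=0)
        for a, e in out:
            assert 0.0 <= a.H <= np.log(6) + 1e-12
            assert (e.Var_y >= 0).all()

    def test_repeatable_for_same_seed(self, quick_classifier, quick_phantom):
        ps = sample_labeled_patches(quick_phantom, (32, 32, 3), 1, seed=9)
        a = uncertainty_for_patchset(quick_classifier, ps, n=5, T=5, seed=13)
        b = uncertainty_for_patchset(quick_classifier, ps, n=5, T=5, seed=13)
        for (x1, y1), (x2, y2) in zip(a, b):
            assert x1.H == x2.H
            np.testing.assert_array_equal(y1.E_y, y2.E_y)


def test_label_entropy_zero_iff_degenerate():
    assert label_entropy([0, 0, 1, 0, 0, 0]) == 0.0
    assert label_entropy(np.ones(6) / 6) == pytest.approx(np.log(6), abs=1e-12)
    assert label_entropy([0.5, 0.5, 0, 0, 0, 0]) > 0
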