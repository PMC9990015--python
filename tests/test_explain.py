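"""Grad-CAM, PCA components, correlation ratios and learning-pattern verdicts."""

import numpy as np
import pytest

from pulmotex.explain import (
    ComponentCorrelation,
    component_verdict,
    correlation_ratio,
    generalized_explain,
    gradcam,
    guided_gradcam,
    learning_pattern_verdict,
    pca_fit,
)
from pulmotex.models import ClassifierContract
from pulmotex.nn import relu_backward, relu_forward
from pulmotex.patching import Patch, PatchSet
from pulmotex.phantom import sample_labeled_patches


class MapStub(ClassifierContract):
    """Returns fixed activation/gradient pairs (full patch resolution)."""

    input_size = (8, 8, 3)

    def __init__(self, A, dA):
        self.A, self.dA = A, dA

    def predict_proba(self, batch, stochastic=False, rng=None):
        return np.full((len(batch), 6), 1 / 6)

    def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
        return self.A, self.dA

    def input_gradient(self, patch, target_class, guided=True):
        return np.zeros_like(patch)


class TestGradCam:
    def test_zero_gradient_zero_map(self, rng):
        A = rng.random((8, 8, 4))
        stub = MapStub(A, np.zeros_like(A))
        out = gradcam(stub, np.zeros((8, 8, 3)), 0)
        assert (out.values == 0).all()

    def test_hand_computed_weighted_sum_oracle(self, rng):
        """Map equals ReLU(sum_k alpha_k A_k) computed by hand."""
        A = rng.standard_normal((8, 8, 3))
        dA = rng.standard_normal((8, 8, 3))
        stub = MapStub(A, dA)
        out = gradcam(stub, np.zeros((8, 8, 3)), 2)
        alpha = dA.mean(axis=(0, 1))  # spatial mean per channel, by hand
        expected = np.maximum((A * alpha).sum(axis=2), 0.0)
        if expected.max() > 0:
            expected = expected / expected.max()
        np.testing.assert_allclose(out.values, expected, atol=1e-6)

    def test_single_channel_hand_weights(self):
        A = np.zeros((8, 8, 1))
        A[2, 3, 0] = 2.0
        A[5, 5, 0] = 1.0
        dA = np.full((8, 8, 1), 0.5)
        out = gradcam(MapStub(A, dA), np.zeros((8, 8, 3)), 0)
        expected = np.maximum(0.5 * A[:, :, 0], 0.0)
        expected /= expected.max()
        np.testing.assert_allclose(out.values, expected, atol=1e-6)

    def test_contract_range_and_shape(self, quick_classifier, rng):
        out = gradcam(quick_classifier, rng.random((32, 32, 3)), 3)
        assert out.values.shape == (32, 32)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0


class TestGuided:
    def test_guided_relu_rule_zeroes_negative_gradients(self, rng):
        x = rng.standard_normal((4, 5))
        _, mask = relu_forward(x)
        dout = rng.standard_normal((4, 5))
        g = relu_backward(dout, mask, guided=True)
        assert ((g > 0) == ((dout > 0) & (x > 0) & (dout * mask > 0))).all()
        assert (g >= 0).all() | (dout <= 0).any()  # negatives never pass

    def test_linear_single_rectifier_toy_model(self, rng):
        """Guided gradient of w . relu(x) is w masked to positive w and x."""
        w = rng.standard_normal((6, 6))
        x = rng.standard_normal((6, 6))
        _, mask = relu_forward(x)
        guided = relu_backward(np.broadcast_to(w, x.shape).copy(), mask, guided=True)
        expected = w * (x > 0) * (w > 0)  # analytic positive-weights pattern
        np.testing.assert_allclose(guided, expected, atol=1e-12)

    def test_zero_cam_zero_guided_map(self, rng):
        A = rng.random((8, 8, 2))
        stub = MapStub(A, np.zeros_like(A))
        out = guided_gradcam(stub, rng.random((8, 8, 3)), 1)
        assert (out.values == 0).all()

    def test_guided_map_contract(self, quick_classifier, rng):
        out = guided_gradcam(quick_classifier, rng.random((32, 32, 3)), 0)
        assert out.values.shape == (32, 32)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0


class TestPCA:
    def test_rank_one_direction_recovered(self, rng):
        direction = rng.standard_normal((6, 6))
        direction /= np.linalg.norm(direction)
        images = np.stack([a * direction for a in rng.uniform(-2, 2, 30)])
        images += rng.normal(0, 1e-8, images.shape)
        cs = pca_fit(images, k=2)
        cos = np.abs((cs.components[0] * direction).sum())
        assert cos >= 0.999

    def test_components_match_svd_oracle(self, rng):
        images = rng.standard_normal((25, 5, 4))
        k = 3
        cs = pca_fit(images, k)
        X = images.reshape(25, -1)
        Xc = X - X.mean(axis=0)
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)  # independent oracle
        for i in range(k):
            v = Vt[i].reshape(5, 4)
            got = cs.components[i]
            sign = np.sign((v * got).sum())
            np.testing.assert_allclose(got, sign * v, atol=1e-8)

    def test_orthonormal_and_variance_sorted(self, rng):
        cs = pca_fit(rng.standard_normal((30, 6, 6)), k=5)
        flat = cs.components.reshape(5, -1)
        np.testing.assert_allclose(flat @ flat.T, np.eye(5), atol=1e-8)
        assert (np.diff(cs.explained_variance) <= 1e-12).all()

    def test_sign_convention_deterministic(self, rng):
        images = rng.standard_normal((20, 4, 4))
        a = pca_fit(images, 3)
        b = pca_fit(images, 3)
        np.testing.assert_array_equal(a.components, b.components)
        for comp in a.components:
            j = np.abs(comp).argmax()
            assert comp.ravel()[j] > 0

    def test_depth3_patches_reduced_by_channel_mean(self, rng):
        images4d = rng.standard_normal((20, 4, 4, 3))
        a = pca_fit(images4d, 2)
        b = pca_fit(images4d.mean(axis=3), 2)
        np.testing.assert_allclose(a.components, b.components, atol=1e-12)

    def test_too_few_images_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            pca_fit(rng.standard_normal((4, 3, 3)), k=4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pca_fit(np.ones((10, 3, 3)), k=2)


class TestCorrelationRatio:
    def test_identity_pair(self, rng):
        img = rng.standard_normal((8, 8))
        corr, pos, neg, zero = correlation_ratio(img, img)
        assert corr == pytest.approx(1.0, abs=1e-12)
        assert neg == 0.0
        assert pos + neg + zero == pytest.approx(1.0, abs=1e-12)

    def test_negation_pair(self, rng):
        img = rng.standard_normal((8, 8))
        corr, pos, neg, zero = correlation_ratio(img, -img)
        assert corr == pytest.approx(-1.0, abs=1e-12)
        assert pos == 0.0

    def test_pixel_loop_oracle_exact(self, rng):
        for _ in range(10):
            s = rng.standard_normal((6, 7))
            g = rng.standard_normal((6, 7))
            corr, pos, neg, zero = correlation_ratio(s, g)
            # explicit per-pixel loop
            ms, mg = s.mean(), g.mean()
            np_, nn, nz = 0, 0, 0
            for i in range(6):
                for j in range(7):
                    c = (s[i, j] - ms) * (g[i, j] - mg)
                    if c > 1e-12:
                        np_ += 1
                    elif c < -1e-12:
                        nn += 1
                    else:
                        nz += 1
            assert pos == np_ / 42 and neg == nn / 42 and zero == nz / 42
            oracle_corr = np.corrcoef(s.ravel(), g.ravel())[0, 1]
            assert corr == pytest.approx(oracle_corr, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        s, g = rng.standard_normal((5, 5)), rng.standard_normal((5, 5))
        assert correlation_ratio(s, g)[0] == pytest.approx(
            correlation_ratio(g, s)[0], abs=1e-14
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            correlation_ratio(np.zeros((4, 4)), np.zeros((5, 5)))


class TestVerdicts:
    @pytest.mark.parametrize(
        "pos,neg,orientation,expected",
        [
            (0.6, 0.3, "standard", "correct"),
            (0.6, 0.3, "inverted", "wrong"),
            (0.3, 0.6, "standard", "wrong"),
            (0.3, 0.6, "inverted", "correct"),
            (0.4, 0.4, "standard", "indeterminate"),
        ],
    )
    def test_component_rule(self, pos, neg, orientation, expected):
        assert component_verdict(pos, neg, orientation) == expected

    def test_orientation_flip_antisymmetry(self, rng):
        for _ in range(50):
            pos, neg = rng.random(2)
            std = component_verdict(pos, neg, "standard")
            inv = component_verdict(pos, neg, "inverted")
            if std == "indeterminate":
                assert inv == "indeterminate"
            else:
                assert {std, inv} == {"correct", "wrong"}

    def test_majority_aggregation_and_tie(self):
        def comp(v):
            return ComponentCorrelation(0.0, 0.5, 0.3, 0.2, v)

        assert learning_pattern_verdict(
            [comp("correct"), comp("correct"), comp("wrong")]) == "correct"
        assert learning_pattern_verdict(
            [comp("correct"), comp("wrong")]) == "indeterminate"
        assert learning_pattern_verdict(
            [comp("indeterminate")] * 3) == "indeterminate"
        assert learning_pattern_verdict(
            [comp("correct"), comp("wrong")], aggregation="all") == "wrong"
        assert learning_pattern_verdict(
            [comp("correct"), comp("wrong")], aggregation="any") == "correct"


# ---------------------------------------------------------------------------
# spurious-feature fixture: a classifier attending only an image corner


def corner_fixture(seed=0, n=40):
    """Patches with four bright in-lung blobs plus corner marker patterns.

    Class-defining variation lives in the blobs; independent low-amplitude
    markers vary in a bottom corner strip.  A classifier attending only the
    strip must be flagged as having learned the wrong pattern.
    """
    rng = np.random.default_rng(seed)
    h = w = 32
    rr, cc = np.mgrid[:h, :w]
    cores = [
        (((rr - r0) ** 2 + (cc - c0) ** 2) <= 9).astype(float)
        for r0, c0 in [(10, 10), (10, 22), (22, 10), (22, 22)]
    ]
    marker_patterns = []
    for c0 in (0, 8, 16, 24):
        p = np.zeros((h, w))
        p[28:32, c0:c0 + 4] = -0.3
        p[30, c0 + 2] = 1.0
        marker_patterns.append(p)
    base = np.zeros((h, w))
    for c0 in (0, 8, 16, 24):
        base[28:32, c0:c0 + 4] = 0.5
    base[28:32, 28:32] = 1.0  # constant anchor block
    scales = (1.0, 0.9, 0.8, 0.7)
    patches = []
    for _ in range(n):
        img = base.copy()
        for j in range(4):
            img += rng.uniform(0.2, 1.0) * scales[j] * cores[j]
            img += rng.uniform(0.1, 0.3) * scales[j] * marker_patterns[j]
        img += rng.normal(0, 1e-3, (h, w))
        patches.append(
            Patch(data=np.repeat(img[:, :, None], 3, axis=2),
                  grid_index=(-1, -1, -1), voxel_origin=(0, 0, 0))
        )
    return PatchSet(patches=patches, source_shape=(h, w, 3),
                    mask_fraction=np.ones(n), labels=np.full(n, 2))


class CornerAttendingStub(ClassifierContract):
    """Hand-built classifier whose saliency lives only in the corner strip."""

    input_size = (32, 32, 3)

    def predict_proba(self, batch, stochastic=False, rng=None):
        return np.full((len(batch), 6), 1 / 6)

    def activation_and_gradient(self, patch, target_class, layer_tag="post_concat"):
        A = patch.mean(axis=2).copy()
        A[:28, :] = 0.0
        return A[:, :, None], np.ones((32, 32, 1))


class TestGeneralized:
    def test_spurious_corner_classifier_flagged_wrong(self):
        report = generalized_explain(
            CornerAttendingStub(), corner_fixture(seed=1), k_list=(4,),
            orientation="standard",
        )
        assert report.reports[(2, 4)].verdict == "wrong"

    def test_coverage_all_classes_at_k8(self, quick_classifier, quick_phantom):
        ps = sample_labeled_patches(quick_phantom, (32, 32, 3), 12, seed=31)
        report = generalized_explain(quick_classifier, ps, k_list=(8,))
        for c in range(6):
            assert (c, 8) in report.reports
            assert report.reports[(c, 8)].verdict in (
                "correct", "wrong", "indeterminate"
            )

    def test_undersized_class_rejected(self, quick_classifier, quick_phantom):
        ps = sample_labeled_patches(quick_phantom, (32, 32, 3), 6, seed=32)
        with pytest.raises(ValueError, match="need more than 8"):
            generalized_explain(quick_classifier, ps, k_list=(8,))

    def test_stability_summary_consistent_across_k(self, study_classifier,
                                                   study_phantom):
        """The cross-k stability flags recompute from the per-k verdicts.

        On stationary phantom textures the pixel ratios sit near 0.5/0.5, so
        per-class verdicts are weakly determined; the summary must still
        reflect exactly which classes agree across component counts.
        """
        clf, _ = study_classifier
        ps = sample_labeled_patches(study_phantom, (32, 32, 3), 20, seed=33)
        report = generalized_explain(clf, ps, k_list=(8, 16))
        assert set(report.stability) == set(range(6))
        for c in range(6):
            expected = (
                report.reports[(c, 8)].verdict == report.reports[(c, 16)].verdict
            )
            assert report.stability[c] == expected
            for k in (8, 16):
                r = report.reports[(c, k)]
                assert len(r.per_component) == k
                for comp in r.per_component:
                    assert comp.pos_ratio + comp.neg_ratio + comp.zero_ratio == (
                        pytest.approx(1.0, abs=1e-9)
                    )
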