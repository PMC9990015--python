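"""Transparency toolkit: Grad-CAM and its PCA-based generalization.

Grad-CAM explains one prediction: channel activations at the tagged
convolutional layer (after the two branches are concatenated) are weighted
by the spatial mean of the class-score gradient and passed through a ReLU.
Because single saliency maps are anecdotal, the generalized analysis runs
PCA over *all* patches of a class (PCA-Shape) and over *all* their Grad-CAM
maps (PCA-GradCam), pairs the component images, and summarizes each pair by
the Pearson correlation coefficient together with the fraction of pixels
contributing positively / negatively to it.  Whether "positive beats
negative" certifies a correct learning pattern depends on whether high
PCA-Shape intensity marks the structures of interest or their complement;
that orientation is an analyst input (``standard`` / ``inverted``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize
from sklearn.decomposition import PCA

from .models import ClassifierContract
from .patching import CLASS_NAMES, N_CLASSES, PatchSet

DEFAULT_COMPONENTS = (4, 8, 16)
DEADBAND = 1e-12


@dataclass
class SaliencyMap:
    """Non-negative (h, w) saliency, max-normalized to [0, 1]."""

    values: np.ndarray
    target_class: int
    layer_tag: str


@dataclass
class PCAComponentSet:
    """Top-k orthonormal component images of one class and one source."""

    components: np.ndarray          # (k, h, w)
    explained_variance: np.ndarray  # (k,), non-increasing
    mean_image: np.ndarray          # (h, w)
    k: int
    source: str                     # "shape" | "gradcam"
    class_id: int


@dataclass
class ComponentCorrelation:
    corrcoef: float
    pos_ratio: float
    neg_ratio: float
    zero_ratio: float
    verdict: str  # "correct" | "wrong" | "indeterminate"


@dataclass
class CorrelationRatioReport:
    class_id: int
    k: int
    orientation: str
    per_component: list[ComponentCorrelation]
    verdict: str = "indeterminate"

    def as_dict(self) -> dict:
        return {
            "class": CLASS_NAMES[self.class_id],
            "k": self.k,
            "orientation": self.orientation,
            "verdict": self.verdict,
            "components": [
                {
                    "corrcoef": c.corrcoef,
                    "pos_ratio": c.pos_ratio,
                    "neg_ratio": c.neg_ratio,
                    "zero_ratio": c.zero_ratio,
                    "verdict": c.verdict,
                }
                for c in self.per_component
            ],
        }


def _normalize_map(values: np.ndarray) -> np.ndarray:
    m = values.max()
    return values / m if m > 0 else values


def gradcam(
    classifier: ClassifierContract,
    patch: np.ndarray,
    target_class: int,
    layer_tag: str = "post_concat",
) -> SaliencyMap:
    """Gradient-weighted class activation map for one patch.

    α_k is the spatial mean of ∂score/∂A_k; the map ReLU(Σ α_k A_k) is
    bilinearly upsampled to the patch's in-plane extent and max-normalized.
    """
    A, dA = classifier.activation_and_gradient(patch, target_class, layer_tag)
    alpha = dA.mean(axis=(0, 1))
    cam = np.maximum((A * alpha).sum(axis=-1), 0.0)
    h, w = patch.shape[0], patch.shape[1]
    cam = resize(cam, (h, w), order=1, mode="edge", anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    return SaliencyMap(values=_normalize_map(cam), target_class=target_class,
                       layer_tag=layer_tag)


def guided_backprop(
    classifier: ClassifierContract, patch: np.ndarray, target_class: int
) -> np.ndarray:
    """Guided-backpropagation gradient of the class score, (h, w, d)."""
    return classifier.input_gradient(patch, target_class, guided=True)


def guided_gradcam(
    classifier: ClassifierContract,
    patch: np.ndarray,
    target_class: int,
    layer_tag: str = "post_concat",
) -> SaliencyMap:
    """Elementwise product of guided backprop with the Grad-CAM map."""
    cam = gradcam(classifier, patch, target_class, layer_tag)
    gb = guided_backprop(classifier, patch, target_class).mean(axis=2)
    product = np.maximum(gb * cam.values, 0.0)
    return SaliencyMap(values=_normalize_map(product), target_class=target_class,
                       layer_tag=layer_tag)


def _flatten_images(images: np.ndarray) -> np.ndarray:
    images = np.asarray(images, dtype=float)
    if images.ndim == 4:  # depth-3 patches: reduce to 2D by channel mean
        images = images.mean(axis=3)
    if images.ndim != 3:
        raise ValueError(f"expected (n, h, w) or (n, h, w, d), got {images.shape}")
    return images


def pca_fit(images: np.ndarray, k: int, source: str = "shape",
            class_id: int = -1) -> PCAComponentSet:
    """Top-k principal component images of one class/source collection.

    Components carry a deterministic sign convention: the pixel of largest
    magnitude is made positive.  Requires at least ``k + 1`` images with
    non-zero variance.
    """
    images = _flatten_images(images)
    n, h, w = images.shape
    if n < k + 1:
        raise ValueError(f"PCA with k={k} needs at least {k + 1} images, got {n}")
    X = images.reshape(n, -1)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("zero-variance image set; PCA undefined")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(k):
        j = np.abs(comps[i]).argmax()
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PCAComponentSet(
        components=comps.reshape(k, h, w),
        explained_variance=pca.explained_variance_.copy(),
        mean_image=X.mean(axis=0).reshape(h, w),
        k=k,
        source=source,
        class_id=class_id,
    )


def correlation_ratio(
    shape_comp: np.ndarray, gradcam_comp: np.ndarray, deadband: float = DEADBAND
) -> tuple[float, float, float, float]:
    """Pearson correlation of two component images plus its pixel budget.

    Each pixel contributes ``c(x) = (s(x) - mean_s)(g(x) - mean_g)`` to the
    correlation numerator; ``pos_ratio``/``neg_ratio`` are the fractions of
    pixels with ``c`` above/below a ±deadband around zero, ``zero_ratio``
    the remainder.  The three always sum to 1.
    """
    s = np.asarray(shape_comp, dtype=float)
    g = np.asarray(gradcam_comp, dtype=float)
    if s.shape != g.shape:
        raise ValueError(f"shape mismatch: {s.shape} vs {g.shape}")
    sc = s - s.mean()
    gc = g - g.mean()
    denom = np.sqrt((sc**2).sum() * (gc**2).sum())
    corr = float((sc * gc).sum() / denom) if denom > 0 else 0.0
    c = sc * gc
    n = c.size
    n_pos = int((c > deadband).sum())
    n_neg = int((c < -deadband).sum())
    return corr, n_pos / n, n_neg / n, (n - n_pos - n_neg) / n


def component_verdict(pos: float, neg: float, orientation: str) -> str:
    """Did the network attend to the right structures, per one component?

    Under ``standard`` orientation (high PCA-Shape intensity marks the
    structures of interest) a correct pattern shows more positively than
    negatively contributing pixels; under ``inverted`` orientation (high
    intensity marks the complement) the rule flips.  An exact tie is
    indeterminate.
    """
    if orientation not in ("standard", "inverted"):
        raise ValueError(f"orientation must be standard|inverted, got {orientation!r}")
    if pos == neg:
        return "indeterminate"
    better = pos > neg
    if orientation == "inverted":
        better = not better
    return "correct" if better else "wrong"


def learning_pattern_verdict(
    per_component: list[ComponentCorrelation], aggregation: str = "majority"
) -> str:
    """Aggregate component verdicts into one class verdict."""
    votes = [c.verdict for c in per_component if c.verdict != "indeterminate"]
    if not votes:
        return "indeterminate"
    n_correct = votes.count("correct")
    n_wrong = votes.count("wrong")
    if aggregation == "majority":
        if n_correct == n_wrong:
            return "indeterminate"
        return "correct" if n_correct > n_wrong else "wrong"
    if aggregation == "all":
        return "correct" if n_wrong == 0 else "wrong"
    if aggregation == "any":
        return "correct" if n_correct > 0 else "wrong"
    raise ValueError(f"unknown aggregation {aggregation!r}")


@dataclass
class ExplainReport:
    """Per-class, per-k correlation reports plus the component galleries."""

    reports: dict[tuple[int, int], CorrelationRatioReport]
    shape_components: dict[tuple[int, int], PCAComponentSet]
    gradcam_components: dict[tuple[int, int], PCAComponentSet]
    k_list: tuple[int, ...]
    orientation: str
    stability: dict[int, bool] = field(default_factory=dict)

    def verdict(self, class_id: int, k: int) -> str:
        return self.reports[(class_id, k)].verdict

    def as_dict(self) -> dict:
        return {
            "orientation": self.orientation,
            "k_list": list(self.k_list),
            "reports": [r.as_dict() for r in self.reports.values()],
            "stability": {
                CLASS_NAMES[c]: bool(v) for c, v in self.stability.items()
            },
        }


def generalized_explain(
    classifier: ClassifierContract,
    patchset: PatchSet,
    k_list: tuple[int, ...] = DEFAULT_COMPONENTS,
    orientation: str = "standard",
    aggregation: str = "majority",
    layer_tag: str = "post_concat",
) -> ExplainReport:
    """PCA-Shape vs PCA-GradCam analysis of a labelled patch sample.

    For every class: Grad-CAM of each patch at its own label, PCA of the
    patch images and of the Grad-CAM maps for each requested k, componentwise
    correlation ratios and verdicts, plus a stability flag recording whether
    the class verdict agrees across all k (the rationale for studying several
    component counts).
    """
    if patchset.labels is None:
        raise ValueError("generalized explanation requires a labelled PatchSet")
    labels = np.asarray(patchset.labels)
    k_max = max(k_list)
    classes = sorted(set(labels.tolist()))
    for c in classes:
        if (labels == c).sum() <= k_max:
            raise ValueError(
                f"class {c} ({CLASS_NAMES[c]}) has only {(labels == c).sum()} "
                f"patches; need more than {k_max}"
            )
    reports: dict[tuple[int, int], CorrelationRatioReport] = {}
    shape_sets: dict[tuple[int, int], PCAComponentSet] = {}
    cam_sets: dict[tuple[int, int], PCAComponentSet] = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        shapes = np.stack([patchset.patches[i].data for i in idx])
        cams = np.stack(
            [gradcam(classifier, patchset.patches[i].data, c, layer_tag).values
             for i in idx]
        )
        for k in k_list:
            sset = pca_fit(shapes, k, source="shape", class_id=c)
            gset = pca_fit(cams, k, source="gradcam", class_id=c)
            comps = []
            for i in range(k):
                corr, pos, neg, zero = correlation_ratio(
                    sset.components[i], gset.components[i]
                )
                comps.append(
                    ComponentCorrelation(
                        corrcoef=corr, pos_ratio=pos, neg_ratio=neg,
                        zero_ratio=zero,
                        verdict=component_verdict(pos, neg, orientation),
                    )
                )
            report = CorrelationRatioReport(
                class_id=c, k=k, orientation=orientation, per_component=comps
            )
            report.verdict = learning_pattern_verdict(comps, aggregation)
            reports[(c, k)] = report
            shape_sets[(c, k)] = sset
            cam_sets[(c, k)] = gset
    stability = {
        c: len({reports[(c, k)].verdict for k in k_list}) == 1 for c in classes
    }
    return ExplainReport(
        reports=reports,
        shape_components=shape_sets,
        gradcam_components=cam_sets,
        k_list=tuple(k_list),
        orientation=orientation,
        stability=stability,
    )
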