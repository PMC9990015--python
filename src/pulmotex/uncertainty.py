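"""Aleatoric and epistemic uncertainty of per-patch predictions.

Aleatoric (data) uncertainty: run the deterministic classifier on ``n``
test-time-augmented copies of a patch (rotation, shrink/scale, noise), count
how often each class wins the argmax, and take the Shannon entropy of those
label frequencies,

    H(Y|X) = -sum_m p_m ln p_m   (nats),

which is 0 for unanimous predictions and ln 6 when the six classes are
equally frequent.

Epistemic (model) uncertainty: fix the input and run ``T`` stochastic
forward passes with the Monte-Carlo dropout layers active; report the mean
softmax vector E(y) = (1/T) sum_t y_t and the per-class predictive variance
Var(y) = (1/T) sum_t y_t^2 - E(y)^2.  The scalar summary is the variance at
the predicted (argmax-mean) class.  Both estimators default to 21 draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ClassifierContract
from .patching import N_CLASSES, PatchSet
from .preprocess import AugmentSpec, augment, tta_augment_spec

DEFAULT_DRAWS = 21


@dataclass
class AleatoricResult:
    """Entropy of argmax-label frequencies under test-time augmentation."""

    H: float
    p_m: np.ndarray
    n: int


@dataclass
class EpistemicResult:
    """Mean and per-class variance of softmax outputs under MC dropout."""

    E_y: np.ndarray
    Var_y: np.ndarray
    epistemic_scalar: float
    T: int


def label_entropy(p_m: np.ndarray) -> float:
    """-sum p ln p with 0 ln 0 = 0."""
    p = np.asarray(p_m, dtype=float)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def aleatoric_entropy(
    classifier: ClassifierContract,
    patch: np.ndarray,
    augment_spec: AugmentSpec | None = None,
    n: int = DEFAULT_DRAWS,
    seed: int = 0,
    soft: bool = False,
) -> AleatoricResult:
    """Test-time-augmentation entropy of one patch's predicted label.

    The classifier runs in deterministic mode so only the input perturbation
    varies.  With ``soft=True`` the entropy is taken over the mean softmax
    vector instead of the argmax-vote frequencies.
    """
    if n < 2:
        raise ValueError(f"need at least 2 augmentation draws, got {n}")
    spec = augment_spec if augment_spec is not None else tta_augment_spec(seed)
    rng = np.random.default_rng(seed)
    batch = np.stack([augment(patch, spec, rng) for _ in range(n)])
    probs = classifier.predict_proba(batch, stochastic=False)
    if soft:
        p_m = probs.mean(axis=0)
    else:
        votes = probs.argmax(axis=1)
        p_m = np.bincount(votes, minlength=N_CLASSES) / n
    return AleatoricResult(H=label_entropy(p_m), p_m=p_m, n=n)


def epistemic_variance(
    classifier: ClassifierContract,
    patch: np.ndarray,
    T: int = DEFAULT_DRAWS,
    seed: int = 0,
) -> EpistemicResult:
    """Monte-Carlo dropout predictive mean and variance for one patch.

    The input is fixed; stochasticity comes from the dropout layers alone.
    Variance is accumulated in streaming form (sum and sum of squares).
    """
    if T < 2:
        raise ValueError(f"need at least 2 dropout passes, got {T}")
    if not classifier.has_stochastic_mode:
        raise ValueError("classifier does not support stochastic (dropout) mode")
    rng = np.random.default_rng(seed)
    x = np.asarray(patch, dtype=float)[None]
    # streaming mean/variance anchored at the first draw: exact zero when
    # every pass returns the same vector (dropout effectively disabled)
    y0 = classifier.predict_proba(x, stochastic=True, rng=rng)[0]
    s = np.zeros(N_CLASSES)
    s2 = np.zeros(N_CLASSES)
    for _ in range(T - 1):
        d = classifier.predict_proba(x, stochastic=True, rng=rng)[0] - y0
        s += d
        s2 += d * d
    E_y = y0 + s / T
    Var_y = np.maximum(s2 / T - (s / T) ** 2, 0.0)
    pred = int(E_y.argmax())
    return EpistemicResult(E_y=E_y, Var_y=Var_y,
                           epistemic_scalar=float(Var_y[pred]), T=T)


def uncertainty_for_patchset(
    classifier: ClassifierContract,
    patchset: PatchSet,
    n: int = DEFAULT_DRAWS,
    T: int = DEFAULT_DRAWS,
    seed: int = 0,
    augment_spec: AugmentSpec | None = None,
) -> list[tuple[AleatoricResult, EpistemicResult]]:
    """Both estimators for every patch, with per-patch derived seeds.

    Each patch gets its own seed derived from ``seed`` and its position, so
    results do not depend on how the set is batched or partitioned.
    """
    results = []
    for i, patch in enumerate(patchset):
        ps = (seed + 1000003 * i) % (2**31)
        results.append(
            (
                aleatoric_entropy(classifier, patch.data, augment_spec=augment_spec,
                                  n=n, seed=ps),
                epistemic_variance(classifier, patch.data, T=T, seed=ps),
            )
        )
    return results
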