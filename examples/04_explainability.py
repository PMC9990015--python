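"""Grad-CAM saliency and its PCA-based generalization.

A single Grad-CAM map explains one patch; to judge whether the network
learned a class's pattern *in general*, PCA components of all patch images
(PCA-Shape) are paired with PCA components of all their Grad-CAM maps
(PCA-GradCam).  Each pair is summarized by a Pearson correlation and the
fractions of pixels contributing positively/negatively to it; a majority
vote over components yields a per-class verdict under the analyst-declared
orientation (here "standard": bright shape structure = region of interest).
"""

from pulmotex import (
    CLASS_NAMES,
    TrainSpec,
    build_denres_mini,
    default_phantom_spec,
    generalized_explain,
    generate_phantom,
    gradcam,
    sample_labeled_patches,
    train,
)
from pulmotex.phantom import preprocess_phantom

phantom = preprocess_phantom(generate_phantom(default_phantom_spec(seed=0)))
patches = sample_labeled_patches(phantom, (32, 32, 3), 100, seed=1)
classifier = build_denres_mini((32, 32, 3), seed=2)
classifier, _ = train(classifier, patches, TrainSpec(epochs=5, seed=3))

patch = patches.patches[0]
cam = gradcam(classifier, patch.data, int(patches.labels[0]))
print(f"Grad-CAM for one {CLASS_NAMES[patches.labels[0]]} patch: "
      f"{cam.values.shape} map, peak saliency at "
      f"{tuple(int(i) for i in divmod(cam.values.argmax(), 32))}")

sample = sample_labeled_patches(phantom, (32, 32, 3), 20, seed=4)
report = generalized_explain(classifier, sample, k_list=(4, 8),
                             orientation="standard")
print(f"\n{'class':<28s} {'k=4':>14s} {'k=8':>14s} {'stable':>7s}")
for c in range(6):
    print(f"{CLASS_NAMES[c]:<28s} {report.verdict(c, 4):>14s} "
          f"{report.verdict(c, 8):>14s} {str(report.stability[c]):>7s}")
print("\n'correct' = more pixels support than oppose the shape/saliency "
      "correlation; 'stable' = the verdict agrees across component counts.")
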