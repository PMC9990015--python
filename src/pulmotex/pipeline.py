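"""End-to-end orchestration: volume → patches → labels → patient profile.

``run_pipeline`` executes preprocess → extract → classify → rebuild →
disease profile → uncertainty → explainability and writes every artifact
(NIfTI maps, JSON reports) with provenance (config hash, model hash).  It is
deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .evaluate import auc_roc_per_class  # noqa: F401  (re-exported for CLI use)
from .explain import DEFAULT_COMPONENTS, generalized_explain
from .models import DenResMiniClassifier, classify_patchset
from .patching import (
    CLASS_NAMES,
    DiseaseProfile,
    PatchSet,
    Volume,
    disease_profile,
    extract_patches,
    rebuild_label_map,
    rebuild_uncertainty_map,
)
from .preprocess import diffusion_filter, normalize
from .uncertainty import uncertainty_for_patchset

logger = logging.getLogger("pulmotex")


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run."""

    volume_path: str
    mask_path: str | None
    model_path: str
    out_dir: str
    patch_size: int = 32
    min_mask_fraction: float = 0.05
    diffusion_iterations: int = 5
    diffusion_conductance: float = 1.0
    diffusion_time_step: float = 0.125
    normalize_volume: bool = True
    n_tta: int = 21
    t_dropout: int = 21
    pca_components: tuple[int, ...] = DEFAULT_COMPONENTS
    orientation: str = "standard"
    run_uncertainty: bool = True
    run_explain: bool = False
    explain_patches_per_class: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.patch_size not in (8, 16, 32, 64):
            raise ValueError(f"patch_size must be one of 8/16/32/64, got {self.patch_size}")
        if not 0.0 <= self.min_mask_fraction <= 1.0:
            raise ValueError("min_mask_fraction must be in [0, 1]")
        if not 0 < self.diffusion_time_step <= 0.25:
            raise ValueError("diffusion_time_step must be in (0, 0.25]")
        if self.n_tta < 2 or self.t_dropout < 2:
            raise ValueError("n_tta and t_dropout must be >= 2")
        if self.orientation not in ("standard", "inverted"):
            raise ValueError("orientation must be standard|inverted")
        for p in (self.volume_path, self.model_path):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if self.mask_path is not None and not Path(self.mask_path).exists():
            raise FileNotFoundError(f"mask not found: {self.mask_path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "pca_components" in raw:
            raw["pca_components"] = tuple(raw["pca_components"])
        return cls(**raw)

    def hash(self) -> str:
        """Hash of the computation-defining fields (output location excluded)."""
        fields = asdict(self)
        fields.pop("out_dir")
        payload = json.dumps(fields, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PatientProfile:
    """The framework's output for one patient/volume."""

    ratios: dict[str, float]
    labelmap_path: str
    aleatoric_path: str | None
    epistemic_path: str | None
    explain_path: str | None
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return asdict(self)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PatientProfile:
    """Execute the full framework on one volume; see module docstring."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        t0 = time.time()
        stage = "load"
        volume = pio.read_volume(config.volume_path)
        if config.mask_path is not None:
            mask = pio.read_mask(config.mask_path)
        else:
            mask = pio.otsu_lung_mask(volume)
        if mask.shape != volume.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {volume.shape}"
            )
        classifier = DenResMiniClassifier.load(config.model_path)
        logger.info("loaded volume %s, %d lung voxels", volume.shape, int(mask.sum()))

        stage = "preprocess"
        if config.diffusion_iterations > 0:
            volume = diffusion_filter(
                volume,
                iterations=config.diffusion_iterations,
                conductance=config.diffusion_conductance,
                time_step=config.diffusion_time_step,
            )
        if config.normalize_volume:
            volume = normalize(volume)

        stage = "extract"
        size = (config.patch_size, config.patch_size, 3)
        patchset = extract_patches(volume, mask, size, config.min_mask_fraction)
        logger.info("extracted %d patches of size %s", len(patchset), size)

        stage = "classify"
        labels, probs = classify_patchset(classifier, patchset)

        stage = "rebuild"
        labelmap = rebuild_label_map(patchset, labels, mask,
                                     spacing=volume.spacing, affine=volume.affine)
        labelmap_path = out_dir / "labelmap.nii.gz"
        pio.write_labelmap(labelmap, labelmap_path)
        written.append(labelmap_path)

        stage = "profile"
        profile = disease_profile(labelmap, mask)

        aleatoric_path = epistemic_path = None
        if config.run_uncertainty:
            stage = "uncertainty"
            results = uncertainty_for_patchset(
                classifier, patchset, n=config.n_tta, T=config.t_dropout,
                seed=config.seed,
            )
            H = np.array([a.H for a, _ in results])
            V = np.array([e.epistemic_scalar for _, e in results])
            amap = rebuild_uncertainty_map(patchset, H, mask, spacing=volume.spacing)
            emap = rebuild_uncertainty_map(patchset, V, mask, spacing=volume.spacing)
            aleatoric_path = out_dir / "aleatoric.nii.gz"
            epistemic_path = out_dir / "epistemic.nii.gz"
            pio.write_scalar_map(amap, volume.affine, volume.spacing, aleatoric_path)
            pio.write_scalar_map(emap, volume.affine, volume.spacing, epistemic_path)
            written += [aleatoric_path, epistemic_path]
            _write_uncertainty_csv(out_dir / "uncertainty.csv", patchset, H, V)
            written.append(out_dir / "uncertainty.csv")

        explain_path = None
        if config.run_explain:
            stage = "explain"
            explain_set = _explain_sample(
                patchset, labels, config.explain_patches_per_class,
                max(config.pca_components), config.seed,
            )
            report = generalized_explain(
                classifier, explain_set, k_list=config.pca_components,
                orientation=config.orientation,
            )
            explain_path = out_dir / "explain_report.json"
            explain_path.write_text(json.dumps(report.as_dict(), indent=2))
            written.append(explain_path)

        stage = "finalize"
        provenance = {
            "config_hash": config.hash(),
            "model_hash": _file_hash(config.model_path),
            "seed": config.seed,
            "patch_size": config.patch_size,
            "n_patches": len(patchset),
            "runtime_s": round(time.time() - t0, 3),
        }
        result = PatientProfile(
            ratios=profile.ratios,
            labelmap_path=str(labelmap_path),
            aleatoric_path=str(aleatoric_path) if aleatoric_path else None,
            epistemic_path=str(epistemic_path) if epistemic_path else None,
            explain_path=str(explain_path) if explain_path else None,
            provenance=provenance,
        )
        payload = result.as_dict()
        payload["runtime_s"] = payload["provenance"].pop("runtime_s")
        (out_dir / "profile.json").write_text(json.dumps(payload, indent=2))
        return result
    except Exception as err:
        for path in written:
            if path.exists():
                path.unlink()
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err


def _write_uncertainty_csv(path: Path, patchset: PatchSet, H, V) -> None:
    lines = ["grid_i,grid_j,grid_k,aleatoric_entropy,epistemic_variance"]
    for patch, h, v in zip(patchset.patches, H, V):
        i, j, k = patch.grid_index
        lines.append(f"{i},{j},{k},{h:.8f},{v:.10f}")
    path.write_text("\n".join(lines) + "\n")


def _explain_sample(
    patchset: PatchSet, labels: np.ndarray, per_class: int, k_max: int, seed: int
) -> PatchSet:
    """Balanced subsample of classified patches for the PCA analysis."""
    rng = np.random.default_rng(seed)
    keep_idx: list[int] = []
    keep_labels: list[int] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if len(idx) <= k_max:
            continue  # too few patches for a k_max-component PCA
        chosen = idx if len(idx) <= per_class else rng.choice(idx, per_class, False)
        keep_idx += chosen.tolist()
        keep_labels += [int(c)] * len(chosen)
    return PatchSet(
        patches=[patchset.patches[i] for i in keep_idx],
        source_shape=patchset.source_shape,
        mask_fraction=patchset.mask_fraction[keep_idx]
        if len(patchset.mask_fraction) else patchset.mask_fraction,
        labels=np.asarray(keep_labels),
    )
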