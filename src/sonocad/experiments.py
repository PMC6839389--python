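"""Reproducible study-condition experiments on synthetic phantoms.

These drive the two headline pipelines at the scanner geometry
(1024 x 384, 32-px blocks):

* segmentation recovery — single rectangular hypoechoic lesions whose
  edges align with the analysis block grid (so the >= 50%-pixel block
  ground truth is exact), spanning 6–20 blocks, placed randomly in the
  dermis; recovery is scored as block-level intersection-over-union;
* end-to-end classification — balanced benign/malignant phantom sets,
  whole-image spectral features, the SCG-trained [10, 10] network, and
  stratified 5-fold cross-validated held-out accuracy/AUC.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np

from .classifier import TrainingConfig, crossval_evaluate
from .segmentation import SUSPICIOUS, segment
from .synth import Lesion, PhantomSpec, generate_dataset, generate_phantom

__all__ = [
    "lesion_phantom_spec",
    "segmentation_recovery",
    "null_phantom_suspicion",
    "classification_experiment",
]

_GRID_ROWS, _GRID_COLS = 32, 12  # 1024x384 at 32-px blocks
_BLOCK = 32


def lesion_phantom_spec(rng: np.random.Generator) -> PhantomSpec:
    """One rectangular block-aligned lesion spanning 6-20 blocks."""
    nb_r = int(rng.integers(2, 6))   # 2-5 block rows
    nb_c = int(rng.integers(3, 5))   # 3-4 block cols -> 6-20 blocks
    r0 = int(rng.integers(3, _GRID_ROWS - nb_r - 2)) * _BLOCK  # inside dermis
    c0 = int(rng.integers(0, _GRID_COLS - nb_c + 1)) * _BLOCK
    lesion = Lesion(
        position=(r0, c0),
        size=(nb_r * _BLOCK, nb_c * _BLOCK),
        drop=0.3,
        heterogeneity=0.3,
    )
    return PhantomSpec(lesions=(lesion,), label="malignant",
                       seed=int(rng.integers(0, 2**31 - 1)))


def segmentation_recovery(n_phantoms: int = 20, seed: int = 0,
                          block_size: int = _BLOCK) -> dict:
    """Block-level IoU of segment() against ground truth on seeded phantoms."""
    rng = np.random.default_rng(seed)
    ious = []
    for _ in range(n_phantoms):
        sample = generate_phantom(lesion_phantom_spec(rng))
        m = segment(sample.bmode, block_size=block_size)
        gt = sample.block_mask(block_size)
        pred = m.labels == SUSPICIOUS
        union = (gt | pred).sum()
        ious.append(float((gt & pred).sum() / union) if union else 1.0)
    ious = np.asarray(ious)
    return {
        "iou": ious,
        "mean_iou": float(ious.mean()),
        "n_pass_0p8": int((ious >= 0.8).sum()),
        "n": n_phantoms,
    }


def null_phantom_suspicion(n_phantoms: int = 5, seed: int = 0,
                           block_size: int = _BLOCK) -> dict:
    """Suspicious-block fraction on lesion-free phantoms (should be ~0)."""
    rng = np.random.default_rng(seed)
    fracs = []
    for _ in range(n_phantoms):
        spec = PhantomSpec(seed=int(rng.integers(0, 2**31 - 1)))
        m = segment(generate_phantom(spec).bmode, block_size=block_size)
        fracs.append(m.suspicious_fraction)
    return {"fractions": np.asarray(fracs),
            "max_fraction": float(max(fracs)), "n": n_phantoms}


def classification_experiment(n_per_class: int = 100, seed: int = 0,
                              n_folds: int = 5) -> dict:
    """Cross-validated held-out accuracy/AUC of the full pipeline."""
    _, dataset = generate_dataset(n_per_class, seed=seed)
    res = crossval_evaluate(dataset, TrainingConfig(), seed=seed,
                            n_folds=n_folds)
    return {"accuracy": res["accuracy"], "auc": res["auc"],
            "n": 2 * n_per_class}
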