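"""Synthetic 50 MHz skin-sonogram phantoms with ground-truth masks.

Real high-frequency skin sonograms show bright, near-homogeneous
speckled layers (epidermis, dermis, hypodermis) while malignant
lesions are hypoechoic — dark, internally heterogeneous regions with
little high-frequency echo texture.  The generator reproduces exactly
the statistical structure the analysis pipeline exploits, nothing
more:

* healthy tissue: per-layer mean echogenicity times multiplicative
  unit-mean gamma speckle (signal-dependent variance, as in coherent
  imaging);
* lesions: the local layer mean scaled by an echogenicity drop factor
  in (0, 1), plus low-spatial-frequency heterogeneity obtained by
  Gaussian-smoothing noise with a kernel at least half a block wide,
  so the lesion's DCT energy concentrates at low frequencies relative
  to the surrounding speckle.

No acoustic physics (wave propagation, attenuation, point-spread) is
simulated; passing tests on these phantoms validates the
implementation of the frequency-domain method, not the clinical claim.

RF samples are synthesised as randomly-signed half-amplitudes so that
the standard rectification ``2*|rf| - offset`` (offset 0) reproduces
the constructed B-mode image bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .classifier import LabeledDataset
from .features import extract_features
from .rf_io import BModeImage, RFImage, RFMetadata, rf_to_bmode

__all__ = [
    "Lesion",
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "generate_dataset",
    "benign_template",
    "malignant_template",
    "PhantomSpecError",
]

# default scanner geometry: 1024 depth samples x 384 lateral positions
DEFAULT_HEIGHT = 1024
DEFAULT_WIDTH = 384
MIN_LESION_PX = 4


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Lesion:
    """A hypoechoic inclusion.

    position/size are (row, col) pixel offsets/extents of the bounding
    box; ``drop`` in (0, 1) scales the local echogenicity down;
    ``heterogeneity`` sets the relative amplitude of the smoothed
    intra-lesion texture; ``smooth_sigma`` its correlation length in
    pixels (>= half the default 32-px analysis block).
    """

    position: tuple[int, int]
    size: tuple[int, int]
    drop: float = 0.3
    heterogeneity: float = 0.2
    shape: Literal["rectangle", "ellipse"] = "rectangle"
    smooth_sigma: float = 16.0

    def mask(self, height: int, width: int) -> np.ndarray:
        r0, c0 = self.position
        dr, dc = self.size
        m = np.zeros((height, width), dtype=bool)
        if self.shape == "rectangle":
            m[r0 : r0 + dr, c0 : c0 + dc] = True
        else:
            rr, cc = np.ogrid[:height, :width]
            # pixel-centre ellipse inscribed in the bounding box
            cy, cx = r0 + (dr - 1) / 2.0, c0 + (dc - 1) / 2.0
            m = ((rr - cy) / (dr / 2.0)) ** 2 + ((cc - cx) / (dc / 2.0)) ** 2 <= 1.0
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Generation recipe for one phantom.

    ``layer_boundaries`` are depth fractions at which the epidermis /
    dermis and dermis / hypodermis transitions sit;
    ``layer_echogenicity`` gives the mean intensity of each of the
    three layers (mild contrast: healthy skin looks approximately
    alike and monotonous).  ``speckle_shape`` is the gamma shape of
    the unit-mean multiplicative speckle (sd = 1/sqrt(shape)).
    """

    height: int = DEFAULT_HEIGHT
    width: int = DEFAULT_WIDTH
    layer_boundaries: tuple[float, float] = (0.06, 0.55)
    layer_echogenicity: tuple[float, float, float] = (200.0, 180.0, 160.0)
    speckle_shape: float = 16.0
    lesions: tuple[Lesion, ...] = ()
    label: str = "healthy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise PhantomSpecError("height and width must be >= 1")
        if not 0 < self.layer_boundaries[0] < self.layer_boundaries[1] < 1:
            raise PhantomSpecError("layer boundaries must satisfy 0 < b0 < b1 < 1")
        if self.speckle_shape <= 0:
            raise PhantomSpecError("speckle_shape must be positive")
        for les in self.lesions:
            r0, c0 = les.position
            dr, dc = les.size
            if dr < MIN_LESION_PX or dc < MIN_LESION_PX:
                raise PhantomSpecError(
                    f"lesion smaller than {MIN_LESION_PX} px in a dimension: {les.size}"
                )
            if not (0 < les.drop < 1):
                raise PhantomSpecError(f"lesion drop must be in (0,1), got {les.drop}")
            if r0 < 0 or c0 < 0 or r0 + dr > self.height or c0 + dc > self.width:
                raise PhantomSpecError(
                    f"lesion at {les.position} size {les.size} exceeds "
                    f"{self.height}x{self.width} image"
                )
        # overlapping lesions are a specification error
        if len(self.lesions) > 1:
            acc = np.zeros((self.height, self.width), dtype=int)
            for les in self.lesions:
                acc += les.mask(self.height, self.width)
            if acc.max() > 1:
                raise PhantomSpecError("lesions overlap")


@dataclass(frozen=True)
class PhantomSample:
    """Generated phantom: RF, B-mode, pixel mask and class tag."""

    rf: RFImage
    bmode: BModeImage
    mask: np.ndarray
    label: str
    spec: PhantomSpec

    def block_mask(self, block_size: int) -> np.ndarray:
        """Block-level ground truth: lesion iff >= 50% lesion pixels."""
        h = self.mask.shape[0] // block_size * block_size
        w = self.mask.shape[1] // block_size * block_size
        m = self.mask[:h, :w].astype(float)
        frac = m.reshape(
            h // block_size, block_size, w // block_size, block_size
        ).mean(axis=(1, 3))
        return frac >= 0.5


def _layer_field(spec: PhantomSpec) -> np.ndarray:
    depth = np.arange(spec.height)
    b0 = int(spec.layer_boundaries[0] * spec.height)
    b1 = int(spec.layer_boundaries[1] * spec.height)
    e = np.empty(spec.height)
    e[:b0] = spec.layer_echogenicity[0]
    e[b0:b1] = spec.layer_echogenicity[1]
    e[b1:] = spec.layer_echogenicity[2]
    return np.repeat(e[:, None], spec.width, axis=1)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Deterministic (seeded) phantom generation.

    Healthy tissue is layer echogenicity times unit-mean gamma
    speckle; each lesion replaces the local texture with
    ``layer * drop * (1 + heterogeneity * smoothed noise)``, clipped
    at zero, whose spectrum is low-frequency by construction.
    """
    rng = np.random.default_rng(spec.seed)
    layers = _layer_field(spec)
    speckle = rng.gamma(shape=spec.speckle_shape, scale=1.0 / spec.speckle_shape,
                        size=layers.shape)
    bpix = layers * speckle
    mask = np.zeros(layers.shape, dtype=bool)
    for les in spec.lesions:
        m = les.mask(spec.height, spec.width)
        noise = rng.standard_normal(layers.shape)
        smooth = gaussian_filter(noise, sigma=les.smooth_sigma, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth = smooth / sd
        texture = layers * les.drop * (1.0 + les.heterogeneity * smooth)
        bpix = np.where(m, np.maximum(texture, 0.0), bpix)
        mask |= m

    signs = np.where(rng.random(layers.shape) < 0.5, -1.0, 1.0)
    rf_samples = signs * bpix / 2.0  # 2*|rf| - 0 reproduces bpix exactly
    meta = RFMetadata(
        height=spec.height, width=spec.width, sample_type="float64",
        offset=0, transducer_freq=50.0,
    )
    rf = RFImage(samples=rf_samples, meta=meta)
    bmode = rf_to_bmode(rf)
    return PhantomSample(rf=rf, bmode=bmode, mask=mask, label=spec.label, spec=spec)


# ----------------------------------------------------------- class templates

def benign_template(height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH) -> PhantomSpec:
    """Benign lesions: smaller, milder echo drop, nearly homogeneous.

    Lesion extent scales with the image so custom geometries stay valid.
    """
    size = (max(MIN_LESION_PX, round(96 * height / DEFAULT_HEIGHT)),
            max(MIN_LESION_PX, round(96 * width / DEFAULT_WIDTH)))
    return PhantomSpec(
        height=height, width=width,
        lesions=(Lesion(position=(0, 0), size=size, drop=0.55,
                        heterogeneity=0.1),),
        label="benign",
    )


def malignant_template(height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH) -> PhantomSpec:
    """Malignant lesions: larger, strongly hypoechoic, heterogeneous."""
    size = (max(MIN_LESION_PX, round(224 * height / DEFAULT_HEIGHT)),
            max(MIN_LESION_PX, round(160 * width / DEFAULT_WIDTH)))
    return PhantomSpec(
        height=height, width=width,
        lesions=(Lesion(position=(0, 0), size=size, drop=0.3,
                        heterogeneity=0.35),),
        label="malignant",
    )


def _randomize_lesion(template: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Jitter lesion size (+-25%) and place it uniformly in the dermis."""
    les = template.lesions[0]
    dr = int(les.size[0] * rng.uniform(0.75, 1.25))
    dc = int(les.size[1] * rng.uniform(0.75, 1.25))
    dc = min(dc, template.width - 2)
    b0 = int(template.layer_boundaries[0] * template.height)
    b1 = int(template.layer_boundaries[1] * template.height)
    r_max = max(b0 + 1, min(b1, template.height - dr))
    r0 = int(rng.integers(b0, r_max)) if r_max > b0 else b0
    c0 = int(rng.integers(0, max(1, template.width - dc)))
    new = replace(les, position=(r0, c0), size=(dr, dc))
    return replace(template, lesions=(new,))


def generate_dataset(
    n_per_class: int,
    class_specs: Sequence[PhantomSpec] | None = None,
    seed: int = 0,
    eps: float = 1e-12,
) -> tuple[list[PhantomSample], LabeledDataset]:
    """Balanced phantom set plus extracted whole-image features.

    ``class_specs`` defaults to (benign_template(), malignant_template()).
    Lesion geometry is jittered per sample; per-sample seeds derive
    reproducibly from the master seed.  Returns the samples and a
    :class:`LabeledDataset` of spectral feature vectors.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if class_specs is None:
        class_specs = (benign_template(), malignant_template())
    master = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    feats = []
    labels = []
    for ci, template in enumerate(class_specs):
        for _ in range(n_per_class):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            spec = _randomize_lesion(template, rng) if template.lesions else template
            spec = replace(spec, seed=int(rng.integers(0, 2**31 - 1)))
            sample = generate_phantom(spec)
            samples.append(sample)
            feats.append(extract_features(sample.bmode, eps=eps).values)
            labels.append(ci)
    dataset = LabeledDataset.from_labels(
        np.vstack(feats), labels, [s.label for s in class_specs]
    )
    return samples, dataset
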