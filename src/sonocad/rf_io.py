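"""RF and B-mode image I/O and the RF-to-B-mode conversion.

High-frequency (here: 50 MHz) skin scanners record raw radio-frequency
echo samples as a signed matrix, rows running along depth and columns
along the lateral travel of the transducer.  The display ("brightness
mode") image is obtained by full-wave rectification with a device
offset::

    imgB = 2 * |imgRF| - offset

The scanner's proprietary binary container is not portable, so raw RF
data is exchanged here as a flat binary file next to a JSON sidecar
declaring shape, dtype, endianness and acquisition metadata (see
:class:`RFMetadata`).  B-mode images travel as ordinary grayscale
PNG/TIFF rasters.

Negative B-mode values (possible whenever ``offset > 0``) are kept:
the conversion is exact algebra feeding the spectral analysis, and
clipping happens only at render time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

__all__ = [
    "RFMetadata",
    "RFImage",
    "BModeImage",
    "read_rf",
    "write_rf",
    "rf_to_bmode",
    "load_bmode",
    "save_bmode",
    "render_colormap",
    "FormatError",
    "MetadataError",
]

#: dtype codes accepted in sidecar metadata -> numpy dtype characters
_SAMPLE_TYPES = {
    "int16": "i2",
    "int32": "i4",
    "float32": "f4",
    "float64": "f8",
}
_ENDIAN = {"little": "<", "big": ">"}


class FormatError(ValueError):
    """Raw-binary payload inconsistent with the declared shape/dtype."""


class MetadataError(ValueError):
    """Sidecar metadata missing or invalid required fields."""


@dataclass(frozen=True)
class RFMetadata:
    """Sidecar record describing a raw RF binary.

    Parameters
    ----------
    height, width : int
        Matrix shape; rows are depth samples, columns lateral positions.
    sample_type : str
        One of ``int16 | int32 | float32 | float64``.
    byte_order : str
        ``little`` or ``big``.
    offset : int
        Device rectification offset used in the B-mode conversion.
        Unknown for most devices; defaults to 0.
    transducer_freq : float or None
        Transducer centre frequency in MHz (50 for the skin scanner
        this package targets); optional.
    pixel_spacing_cm : float or None
        Physical edge length of one pixel in cm, if known; used only
        for lesion-area reporting.
    """

    height: int
    width: int
    sample_type: str = "int16"
    byte_order: str = "little"
    offset: int = 0
    transducer_freq: float | None = None
    pixel_spacing_cm: float | None = None

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise MetadataError(
                f"height and width must be >= 1, got {self.height}x{self.width}"
            )
        if self.sample_type not in _SAMPLE_TYPES:
            raise MetadataError(
                f"unsupported sample_type {self.sample_type!r}; "
                f"expected one of {sorted(_SAMPLE_TYPES)}"
            )
        if self.byte_order not in _ENDIAN:
            raise MetadataError(
                f"byte_order must be 'little' or 'big', got {self.byte_order!r}"
            )
        if self.transducer_freq is not None and self.transducer_freq <= 0:
            raise MetadataError("transducer_freq must be positive (MHz)")

    @property
    def dtype(self) -> np.dtype:
        return np.dtype(_ENDIAN[self.byte_order] + _SAMPLE_TYPES[self.sample_type])

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if v is not None}
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RFMetadata":
        try:
            d = json.loads(text)
        except json.JSONDecodeError as exc:
            raise MetadataError(f"sidecar is not valid JSON: {exc}") from exc
        for key in ("height", "width"):
            if key not in d:
                raise MetadataError(f"sidecar missing required field {key!r}")
        known = {
            "height", "width", "sample_type", "byte_order",
            "offset", "transducer_freq", "pixel_spacing_cm",
        }
        return cls(**{k: v for k, v in d.items() if k in known})


@dataclass(frozen=True)
class RFImage:
    """Raw RF scan: signed samples plus acquisition metadata."""

    samples: np.ndarray
    meta: RFMetadata

    def __post_init__(self) -> None:
        s = np.asarray(self.samples)
        if s.ndim != 2:
            raise ValueError(f"samples must be 2D, got ndim={s.ndim}")
        if s.shape != (self.meta.height, self.meta.width):
            raise ValueError(
                f"samples shape {s.shape} does not match metadata "
                f"({self.meta.height}, {self.meta.width})"
            )
        object.__setattr__(self, "samples", s)

    @property
    def height(self) -> int:
        return self.meta.height

    @property
    def width(self) -> int:
        return self.meta.width

    @property
    def offset(self) -> int:
        return self.meta.offset


@dataclass(frozen=True)
class BModeImage:
    """Rectified intensity image; may hold negative values when offset > 0."""

    pixels: np.ndarray
    source_meta: RFMetadata | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={p.ndim}")
        object.__setattr__(self, "pixels", p)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_rf(path: Union[str, Path], meta: Union[RFMetadata, str, Path, None] = None) -> RFImage:
    """Read a flat raw RF binary plus its sidecar metadata.

    ``meta`` may be an :class:`RFMetadata`, a path to a sidecar JSON, or
    None, in which case ``<path>.json`` is read.

    Raises
    ------
    FormatError
        If the payload byte count disagrees with the declared
        height x width x itemsize.
    MetadataError
        If the sidecar is missing or invalid.
    """
    path = Path(path)
    if meta is None:
        meta = path.with_suffix(path.suffix + ".json")
    if isinstance(meta, (str, Path)):
        sidecar = Path(meta)
        if not sidecar.exists():
            raise MetadataError(f"sidecar metadata file not found: {sidecar}")
        meta = RFMetadata.from_json(sidecar.read_text())

    raw = path.read_bytes()
    expected = meta.height * meta.width * meta.dtype.itemsize
    if len(raw) != expected:
        raise FormatError(
            f"{path}: expected {expected} bytes "
            f"({meta.height}x{meta.width} {meta.sample_type}), got {len(raw)}"
        )
    samples = np.frombuffer(raw, dtype=meta.dtype).reshape(meta.height, meta.width)
    return RFImage(samples=samples.astype(samples.dtype.newbyteorder("=")), meta=meta)


def write_rf(rf: RFImage, path: Union[str, Path], sidecar: Union[str, Path, None] = None) -> None:
    """Write the flat binary and its JSON sidecar (default ``<path>.json``)."""
    path = Path(path)
    if sidecar is None:
        sidecar = path.with_suffix(path.suffix + ".json")
    path.write_bytes(np.ascontiguousarray(rf.samples, dtype=rf.meta.dtype).tobytes())
    Path(sidecar).write_text(rf.meta.to_json())


def rf_to_bmode(rf: RFImage) -> BModeImage:
    """Full-wave rectification: every pixel is ``2*|sample| - offset``.

    Shape is preserved and negative outputs (offset > 0) are not clipped.
    """
    pixels = 2.0 * np.abs(rf.samples.astype(np.float64)) - float(rf.offset)
    return BModeImage(pixels=pixels, source_meta=rf.meta)


def load_bmode(path: Union[str, Path]) -> BModeImage:
    """Load a grayscale raster (PNG/TIFF); RGB inputs collapse to luminance."""
    try:
        img = Image.open(path)
        img.load()
    except (OSError, Image.DecompressionBombError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    arr = np.asarray(img)
    if arr.ndim == 3:
        # ITU-R 601 luma, same weighting PIL uses for mode "L"
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    return BModeImage(pixels=np.asarray(arr, dtype=np.float64))


def save_bmode(b: BModeImage, path: Union[str, Path], bit_depth: int = 8) -> None:
    """Save as 8- or 16-bit grayscale; values are clipped to the bit range."""
    if bit_depth == 8:
        arr = np.clip(b.pixels, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path)
    elif bit_depth == 16:
        arr = np.clip(b.pixels, 0, 65535).round().astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(path)
    else:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")


def render_colormap(b: BModeImage, scheme: str = "inferno") -> np.ndarray:
    """Min-max normalise and map through a matplotlib colormap.

    Returns an ``(H, W, 3)`` uint8 RGB array.  A constant image maps to
    the colormap midpoint.  Unknown scheme names raise ``KeyError``.
    """
    import matplotlib

    try:
        cmap = matplotlib.colormaps[scheme]
    except KeyError:
        raise KeyError(f"unknown colormap scheme {scheme!r}") from None
    p = b.pixels
    lo, hi = float(p.min()), float(p.max())
    if hi > lo:
        norm = (p - lo) / (hi - lo)
    else:
        norm = np.full_like(p, 0.5)
    rgba = cmap(norm)
    return (rgba[..., :3] * 255).round().astype(np.uint8)
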