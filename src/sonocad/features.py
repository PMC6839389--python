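"""Whole-image spectral features: singular values of the log-|DCT|.

An M x N B-mode sonogram is mapped to

    S = svd(log(max(|dct2(img)|, eps)))

where svd denotes the economy-size singular values, a descending
nonnegative vector of length min(M, N).  For the 1024 x 384 scanner
geometry this is a 384-vector.  All values are kept (no truncation):
the leading values capture the shared coarse spectral envelope while
the tail carries the discriminative detail.

The eps floor (default 1e-12) bounds log at about -27.6 for the exact
zero coefficients produced by flat image regions, without touching
informative coefficients.  The log is natural.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np

from .rf_io import BModeImage
from .spectral import dct2

__all__ = ["FeatureVector", "FeatureStats", "extract_features", "normalize_features", "denormalize_features"]

DEFAULT_EPS = 1e-12


@dataclass(frozen=True)
class FeatureVector:
    """Descending nonnegative singular values of the log-abs spectrum."""

    values: np.ndarray
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("feature values must be 1D")
        if np.any(v < 0):
            raise ValueError("singular values must be nonnegative")
        if np.any(np.diff(v) > 0):
            raise ValueError("singular values must be non-increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FeatureStats:
    """Per-index location/scale for feature normalisation.

    Estimated from a training set and persisted with the model so the
    identical affine map is applied at prediction time.
    """

    location: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=np.float64)
        sc = np.asarray(self.scale, dtype=np.float64)
        if loc.shape != sc.shape or loc.ndim != 1:
            raise ValueError("location and scale must be 1D and equal length")
        if np.any(sc <= 0):
            raise ValueError("scale entries must be positive")
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", sc)

    @classmethod
    def from_matrix(cls, features: np.ndarray) -> "FeatureStats":
        """Mean/std per column; zero-variance columns get scale 1."""
        f = np.asarray(features, dtype=np.float64)
        loc = f.mean(axis=0)
        sc = f.std(axis=0, ddof=0)
        sc = np.where(sc > 0, sc, 1.0)
        return cls(location=loc, scale=sc)

    @classmethod
    def identity(cls, n: int) -> "FeatureStats":
        return cls(location=np.zeros(n), scale=np.ones(n))


def extract_features(
    b: Union[BModeImage, np.ndarray], eps: float = DEFAULT_EPS
) -> FeatureVector:
    """Economy singular values of ``log(max(|dct2(b)|, eps))``.

    Returns min(M, N) values in descending order; single-row or
    single-column images yield a length-1 vector.  Non-finite pixels
    raise ``ValueError`` (from the transform).
    """
    if eps <= 0:
        raise ValueError(f"eps must be positive, got {eps}")
    spectrum = dct2(b)
    g = np.log(np.maximum(np.abs(spectrum.coeffs), eps))
    s = np.linalg.svd(g, compute_uv=False)
    s = np.sort(s)[::-1]  # LAPACK returns descending already; enforce
    return FeatureVector(values=s, source_shape=g.shape)


def _values(f: Union[FeatureVector, np.ndarray]) -> np.ndarray:
    return f.values if isinstance(f, FeatureVector) else np.asarray(f, dtype=np.float64)


def normalize_features(
    f: Union[FeatureVector, np.ndarray], stats: FeatureStats
) -> np.ndarray:
    """Affine map ``(value - location) / scale`` per index.

    Returns a plain array (normalised values are signed and unordered,
    so no longer a valid :class:`FeatureVector`).
    """
    v = _values(f)
    if v.shape[-1] != stats.location.size:
        raise ValueError(
            f"feature length {v.shape[-1]} != stats length {stats.location.size}"
        )
    return (v - stats.location) / stats.scale


def denormalize_features(v: np.ndarray, stats: FeatureStats) -> np.ndarray:
    """Exact algebraic inverse of :func:`normalize_features`."""
    v = np.asarray(v, dtype=np.float64)
    if v.shape[-1] != stats.location.size:
        raise ValueError(
            f"feature length {v.shape[-1]} != stats length {stats.location.size}"
        )
    return v * stats.scale + stats.location


def features_to_csv(rows: Iterable[Sequence[float]], path) -> None:
    """Write one image per row with an index header (external tooling)."""
    rows = [np.asarray(r, dtype=np.float64) for r in rows]
    if not rows:
        raise ValueError("no feature rows to write")
    n = rows[0].size
    header = ",".join(f"s{i}" for i in range(n))
    np.savetxt(path, np.vstack(rows), delimiter=",", header=header, comments="")
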