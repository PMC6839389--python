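"""Block-wise semantic segmentation of sonograms.

The image is tiled into square blocks (default 32 x 32); each block is
summarised by its mean absolute DCT coefficient excluding DC (a
spatial-frequency activity scalar).  Healthy speckled tissue carries
broadband high-frequency energy, whereas hypoechoic, internally smooth
lesions concentrate their spectrum at low frequencies, so lesion
blocks score low.  Because echo intensity is a relative property that
differs between patients and devices, the decision threshold is
derived per image with Otsu's method applied to the distribution of
per-block scalars: the threshold maximising the between-class variance
w0*w1*(mu0 - mu1)^2 over a 256-bin equal-width histogram.  Blocks with
a statistic above the threshold are healthy, the rest suspicious.

Otsu always returns *some* split, even on a lesion-free image whose
block statistics form a single mode.  segment() therefore accepts the
split only if the suspicious class is markedly darker in mean
frequency than the healthy class (mean ratio below ``min_contrast``,
default 0.6); otherwise the whole image is declared healthy and the
result flagged degenerate.  See docs/methods.md for the rationale.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .rf_io import BModeImage
from .spectral import DEFAULT_BLOCK_SIZE, block_statistics, partition_blocks

__all__ = [
    "BlockMap",
    "otsu_threshold",
    "segment",
    "render_blockmap",
    "blockmap_report",
    "DegenerateHistogramError",
]

HEALTHY, SUSPICIOUS = 0, 1
DEFAULT_N_BINS = 256
DEFAULT_MIN_CONTRAST = 0.6


class DegenerateHistogramError(ValueError):
    """All values identical: no threshold separates two classes."""


@dataclass(frozen=True)
class BlockMap:
    """Per-block labels with the statistics and threshold behind them.

    ``labels[i, j] == HEALTHY`` iff ``block_stats[i, j] > threshold``
    (higher mean frequency means healthy tissue).  ``degenerate`` is
    set when no credible two-class split existed and every block was
    labelled healthy.
    """

    labels: np.ndarray
    block_stats: np.ndarray
    threshold: float
    block_size: int
    crop_origin: tuple[int, int] = (0, 0)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.labels.shape != self.block_stats.shape:
            raise ValueError("labels and block_stats shapes differ")
        if not self.degenerate:
            expect = np.where(self.block_stats > self.threshold, HEALTHY, SUSPICIOUS)
            if not np.array_equal(self.labels, expect):
                raise ValueError("labels inconsistent with stats/threshold")

    @property
    def grid_rows(self) -> int:
        return self.labels.shape[0]

    @property
    def grid_cols(self) -> int:
        return self.labels.shape[1]

    @property
    def n_blocks(self) -> int:
        return self.labels.size

    @property
    def suspicious_fraction(self) -> float:
        return float((self.labels == SUSPICIOUS).mean())


def otsu_threshold(values, n_bins: int = DEFAULT_N_BINS) -> float:
    """Otsu's threshold for a set of continuous scalars.

    A histogram with ``n_bins`` equal-width bins over [min, max] is
    built; every interior bin edge is a candidate threshold, and the
    edge maximising the between-class variance

        w0(t) * w1(t) * (mu0(t) - mu1(t))**2

    is returned (ties broken by the lowest edge).  Class membership and
    class means are computed on the binned representation (bin
    centres), as in the classical grey-level formulation.

    Raises :class:`DegenerateHistogramError` when all values coincide.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("values contain non-finite entries")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        raise DegenerateHistogramError("all values identical")

    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    # cumulative class-0 weight and mean for thresholds at edges[1..n-1]
    cw0 = np.cumsum(w)[:-1]
    cm = np.cumsum(w * centers)
    mu_total = cm[-1]
    cm0 = cm[:-1]
    w0, w1 = cw0, 1.0 - cw0
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.zeros(n_bins - 1)
    mu0 = np.where(valid, cm0 / np.where(w0 > 0, w0, 1.0), 0.0)
    mu1 = np.where(valid, (mu_total - cm0) / np.where(w1 > 0, w1, 1.0), 0.0)
    sigma_b[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    # ties (incl. floating-point near-ties) break toward the lowest edge
    top = sigma_b.max()
    best = int(np.flatnonzero(sigma_b >= top * (1.0 - 1e-10))[0])
    return float(edges[best + 1])


def segment(
    b: Union[BModeImage, np.ndarray],
    block_size: int = DEFAULT_BLOCK_SIZE,
    n_bins: int = DEFAULT_N_BINS,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
) -> BlockMap:
    """Segment a sonogram into healthy vs. suspicious blocks.

    Pipeline: tile the image, compute the per-block mean-frequency
    statistic, derive one Otsu threshold per image from the block-stat
    distribution, and label blocks above the threshold healthy.

    ``min_contrast`` guards against lesion-free images: the Otsu split
    is kept only when (mean suspicious stat) < min_contrast * (mean
    healthy stat); otherwise all blocks are healthy and the map is
    flagged degenerate.  Set ``min_contrast=1.0`` to always accept the
    raw Otsu split.
    """
    grid = partition_blocks(b, block_size)
    stats = block_statistics(grid)
    try:
        t = otsu_threshold(stats.ravel(), n_bins=n_bins)
    except DegenerateHistogramError:
        return BlockMap(
            labels=np.full(stats.shape, HEALTHY, dtype=int),
            block_stats=stats,
            threshold=float(stats.min()) - 1.0,
            block_size=block_size,
            crop_origin=grid.crop_origin,
            degenerate=True,
        )
    labels = np.where(stats > t, HEALTHY, SUSPICIOUS)
    susp = stats[labels == SUSPICIOUS]
    healthy = stats[labels == HEALTHY]
    credible = (
        susp.size > 0
        and healthy.size > 0
        and susp.mean() < min_contrast * healthy.mean()
    )
    if not credible:
        return BlockMap(
            labels=np.full(stats.shape, HEALTHY, dtype=int),
            block_stats=stats,
            threshold=t,
            block_size=block_size,
            crop_origin=grid.crop_origin,
            degenerate=True,
        )
    return BlockMap(
        labels=labels,
        block_stats=stats,
        threshold=t,
        block_size=block_size,
        crop_origin=grid.crop_origin,
    )


def render_blockmap(
    m: BlockMap,
    b: Union[BModeImage, np.ndarray],
    draw_grid: bool = False,
) -> np.ndarray:
    """Overlay the block labels on the (cropped) sonogram as RGB uint8.

    Suspicious blocks are darkened, healthy blocks brightened, per the
    display convention that lesions appear dark and healthy tissue
    bright.  Output shape is the cropped image extent.
    """
    pixels = b.pixels if isinstance(b, BModeImage) else np.asarray(b, dtype=np.float64)
    h = m.grid_rows * m.block_size
    w = m.grid_cols * m.block_size
    if pixels.shape[0] < h or pixels.shape[1] < w:
        raise ValueError(
            f"image {pixels.shape} smaller than block map extent ({h}, {w})"
        )
    img = pixels[:h, :w]
    lo, hi = img.min(), img.max()
    base = (img - lo) / (hi - lo) if hi > lo else np.full_like(img, 0.5)
    gain = np.where(
        np.kron(m.labels, np.ones((m.block_size, m.block_size))) == SUSPICIOUS,
        0.25,
        1.0,
    )
    gray = np.clip(0.25 + 0.75 * base, 0, 1) * gain
    rgb = np.repeat((gray * 255).round().astype(np.uint8)[..., None], 3, axis=2)
    if draw_grid:
        rgb[:: m.block_size, :, :] = 255
        rgb[:, :: m.block_size, :] = 255
    return rgb


def blockmap_report(
    m: BlockMap, pixel_spacing_cm: float | None = None
) -> dict:
    """Structured per-block report.

    Rows carry grid position, the pixel bounding box in the original
    frame, the block statistic and the label.  Lesion area is reported
    in pixels, and in cm^2 when pixel spacing is supplied.
    """
    rows = []
    r0, c0 = m.crop_origin
    s = m.block_size
    for i in range(m.grid_rows):
        for j in range(m.grid_cols):
            rows.append(
                {
                    "grid_row": i,
                    "grid_col": j,
                    "row_start": r0 + i * s,
                    "row_stop": r0 + (i + 1) * s,
                    "col_start": c0 + j * s,
                    "col_stop": c0 + (j + 1) * s,
                    "statistic": float(m.block_stats[i, j]),
                    "label": "suspicious" if m.labels[i, j] == SUSPICIOUS else "healthy",
                }
            )
    n_susp = int((m.labels == SUSPICIOUS).sum())
    area_px = n_susp * s * s
    report = {
        "block_size": s,
        "grid_rows": m.grid_rows,
        "grid_cols": m.grid_cols,
        "threshold": m.threshold,
        "degenerate": m.degenerate,
        "suspicious_blocks": n_susp,
        "suspicious_fraction": m.suspicious_fraction,
        "lesion_area_px": area_px,
        "blocks": rows,
    }
    if pixel_spacing_cm is not None:
        report["lesion_area_cm2"] = area_px * pixel_spacing_cm**2
    return report


def write_report(report: dict, json_path: Union[str, Path], csv_path: Union[str, Path, None] = None) -> None:
    """Persist a block report as JSON, optionally with a CSV block table."""
    Path(json_path).write_text(json.dumps(report, indent=2))
    if csv_path is not None:
        rows = report["blocks"]
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
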