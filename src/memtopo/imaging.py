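"""Image pipeline: render localizations, smooth, normalize, subtract.

The correction for membrane-topography artefacts is image-based: the
protein and membrane-marker localization tables are converted to count
images, Gaussian-smoothed, normalized to a common intensity mean and
subtracted.  Topography-instigated "clusters" (where the protein excess
merely tracks the local amount of membrane) cancel in the difference
image, genuine clusters survive as positively skewed intensity excess.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .locdata import LocalizationTable

__all__ = [
    "PixelImage",
    "DifferenceImage",
    "render_histogram",
    "gaussian_smooth",
    "normalize_common_mean",
    "subtract",
    "background_correct",
    "intensity_values",
    "read_image",
    "write_image",
    "write_mask",
]


@dataclass
class PixelImage:
    """2D float intensity grid with a pixel size (table unit per pixel).

    ``provenance`` accumulates the processing history (source table,
    smoothing sigma, normalization constant) so downstream steps can
    assert their preconditions.
    """

    pixels: np.ndarray
    pixel_size: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixel grid must be 2D with dimensions >= 1")
        if not np.isfinite(self.pixels).all():
            raise ValueError("pixel values must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def mean(self) -> float:
        return float(self.pixels.mean())

    def copy_with(self, pixels: np.ndarray, **prov) -> "PixelImage":
        p = dict(self.provenance)
        p.update(prov)
        return PixelImage(pixels, self.pixel_size, p)


@dataclass
class DifferenceImage:
    """Signed difference of two common-mean-normalized images.

    When both parents were normalized to the same mean and no mask was
    applied, the full-grid mean is zero to floating tolerance.
    """

    image: PixelImage
    parents: tuple[dict, dict]

    @property
    def pixels(self) -> np.ndarray:
        return self.image.pixels

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    def mean(self) -> float:
        return self.image.mean()


def render_histogram(
    table: LocalizationTable,
    pixel_size: float,
    extent: tuple[float, float, float, float] | None = None,
) -> PixelImage:
    """Bin localizations into a per-pixel count image.

    Each in-extent localization adds exactly one count to its containing
    pixel under the half-open convention (a point at ``x = k * p`` lands
    in pixel k); the grid sum equals the number of in-extent
    localizations.  A partial last row/column is padded to a whole pixel.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if extent is None:
        extent = table.extent
    x0, x1, y0, y1 = extent
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"empty extent {extent}")
    ncols = math.ceil((x1 - x0) / pixel_size - 1e-9)
    nrows = math.ceil((y1 - y0) / pixel_size - 1e-9)
    grid = np.zeros((nrows, ncols))
    x, y = table.x, table.y
    inside = (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
    cols = np.floor((x[inside] - x0) / pixel_size).astype(int)
    rows = np.floor((y[inside] - y0) / pixel_size).astype(int)
    np.clip(cols, 0, ncols - 1, out=cols)
    np.clip(rows, 0, nrows - 1, out=rows)
    np.add.at(grid, (rows, cols), 1.0)
    return PixelImage(
        grid,
        pixel_size,
        {"source": table.source, "unit": table.unit, "extent": tuple(extent)},
    )


def gaussian_smooth(img: PixelImage, sigma: float) -> PixelImage:
    """Gaussian-filter an image, guarding the border with a 1-px frame.

    A one-pixel-wide zero frame is appended before filtering (reflective
    boundary outside it) and removed afterwards; published statistics
    additionally use guard areas, so the exact frame handling has
    negligible effect.  ``sigma`` is in pixels; sigma 0 is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return img.copy_with(img.pixels.copy(), sigma=0.0)
    framed = np.pad(img.pixels, 1, mode="constant")
    smooth = ndimage.gaussian_filter(framed, sigma, mode="reflect")
    return img.copy_with(smooth[1:-1, 1:-1], sigma=float(sigma))


def normalize_common_mean(a: PixelImage, b: PixelImage) -> tuple[PixelImage, PixelImage]:
    """Scale each image by the reciprocal of its mean (common mean = 1).

    Factors out differences in the number of protein and marker
    localizations so that the subtraction compares relative densities.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    out = []
    for img in (a, b):
        m = img.mean()
        if m <= 0:
            raise ValueError("cannot normalize an image with non-positive mean")
        out.append(img.copy_with(img.pixels / m, normalized_mean=1.0, scale=1.0 / m))
    return out[0], out[1]


def subtract(protein: PixelImage, membrane: PixelImage) -> DifferenceImage:
    """Pixelwise protein - membrane difference image.

    Both images should have been normalized to a common mean (checked via
    provenance; a warning is issued otherwise), in which case the
    difference has zero full-grid mean.
    """
    if protein.shape != membrane.shape:
        raise ValueError(f"shape mismatch {protein.shape} vs {membrane.shape}")
    for img, name in ((protein, "protein"), (membrane, "membrane")):
        if img.provenance.get("normalized_mean") is None:
            warnings.warn(
                f"{name} image was not normalized to a common mean; "
                "the difference image will not be zero-mean",
                stacklevel=2,
            )
    diff = protein.copy_with(protein.pixels - membrane.pixels)
    return DifferenceImage(diff, (dict(protein.provenance), dict(membrane.provenance)))


def background_correct(
    membrane: PixelImage,
    protein_table: LocalizationTable,
    pixel_size: float | None = None,
    closing_radius: float | None = None,
) -> tuple[PixelImage, np.ndarray]:
    """Subtract the off-cell membrane-probe background.

    Background is defined as the area without protein localizations: the
    protein occupancy image is morphologically closed (structuring disk
    radius = the smoothing sigma by default) to fill intra-cell gaps, and
    its complement is the background.  The mean membrane intensity over
    the background is subtracted from the whole membrane image; the few
    foreground pixels that become negative are excluded from the returned
    foreground mask.
    """
    from skimage.morphology import closing, disk

    if pixel_size is None:
        pixel_size = membrane.pixel_size
    occupancy = render_histogram(
        protein_table, pixel_size, membrane.provenance.get("extent")
    )
    if occupancy.shape != membrane.shape:
        raise ValueError(
            f"protein occupancy grid {occupancy.shape} does not match the "
            f"membrane image {membrane.shape}"
        )
    occupied = occupancy.pixels > 0
    if not occupied.any():
        warnings.warn("no protein localizations: empty foreground, no subtraction")
        return membrane.copy_with(membrane.pixels.copy()), occupied
    radius = closing_radius
    if radius is None:
        radius = membrane.provenance.get("sigma", 1.0)
    foreground = closing(occupied, disk(max(1, int(round(radius)))))
    background = ~foreground
    if not background.any():
        warnings.warn("protein occupies the whole image: no background to subtract")
        return membrane.copy_with(membrane.pixels.copy()), foreground
    offset = float(membrane.pixels[background].mean())
    corrected = membrane.pixels - offset
    mask = foreground & (corrected >= 0)
    return membrane.copy_with(corrected, background_offset=offset), mask


def intensity_values(
    img: DifferenceImage | PixelImage, guard: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Pixel values strictly inside a guard frame, optionally masked.

    The guard strip (width ``guard`` pixels on every side) removes edge
    effects of the smoothing; unmasked, the result has
    (rows - 2 g) * (cols - 2 g) values.
    """
    pixels = img.pixels
    if guard < 0:
        raise ValueError("guard must be >= 0")
    if 2 * guard >= min(pixels.shape):
        raise ValueError(f"guard {guard} too large for image {pixels.shape}")
    inner = pixels[guard : pixels.shape[0] - guard, guard : pixels.shape[1] - guard]
    if mask is None:
        return inner.ravel().copy()
    if mask.shape != pixels.shape:
        raise ValueError("mask shape must match the image")
    inner_mask = mask[guard : pixels.shape[0] - guard, guard : pixels.shape[1] - guard]
    return inner[inner_mask].copy()


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------


def write_image(img: PixelImage | DifferenceImage, path: str | Path) -> None:
    """Write as 32-bit float TIFF."""
    import tifffile

    pixels = img.pixels if isinstance(img, DifferenceImage) else img.pixels
    tifffile.imwrite(path, pixels.astype(np.float32))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit TIFF (255 = foreground)."""
    import tifffile

    tifffile.imwrite(path, (mask.astype(np.uint8) * 255))


def read_image(path: str | Path, pixel_size: float = 1.0) -> PixelImage:
    import tifffile

    return PixelImage(tifffile.imread(path).astype(float), pixel_size, {"source": str(path)})
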