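"""Seeded generators for synthetic SMLM localization datasets.

Three simulation families:

* **Partition-ratio datasets** — a fixed number of localizations split
  between randomly placed, non-touching designated cluster disks and the
  remaining area, at a chosen in/out density ratio R.  Because additions
  are sequentially numbered per pool, datasets at different ratios built
  from one seed are *nested*: the lower-ratio dataset's in-cluster points
  are a prefix of the higher-ratio dataset's.
* **Topography-weighted membranes** — a per-pixel "amount of membrane"
  map M = L*S (stacked layer count L times the surface slope factor
  S = sqrt(1 + |grad h|^2)), from which randomly-distributed membrane
  molecules are sampled with probability proportional to M.  This is how
  folds and ruffles make a random molecule look clustered.
* **Dimer fields** — paired molecules on a pixel grid with partial
  detection, for nearest-neighbour analysis of detection-fraction
  artefacts.

All generators are deterministic given (parameters, seed); the seed is
recorded in the output table metadata.  Coordinates are in pixel units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .locdata import LocalizationTable

__all__ = [
    "InfeasibleLayoutError",
    "ClusterLayout",
    "PartitionSpec",
    "Fold",
    "Bump",
    "Enrichment",
    "MembraneMap",
    "DimerField",
    "generate_cluster_layout",
    "partition_counts",
    "sample_partitioned",
    "build_membrane_map",
    "sample_topography",
    "simulate_dimers",
    "thin_detections",
]

# Fixed chunk size for all rejection sampling.  Accepted draws are taken
# in stream order, so the first n accepted points do not depend on how
# many are ultimately requested -- this is what makes nested-ratio
# datasets share their localizations.
_CHUNK = 8192


class InfeasibleLayoutError(RuntimeError):
    """Rejection sampling could not place the requested disks."""


# ---------------------------------------------------------------------------
# Cluster layouts and partition-ratio datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterLayout:
    """Designated cluster disks: equal-radius, non-touching, fully inside.

    ``centers`` is an (n, 2) array of (x, y) disk centers.  Disks must
    neither overlap nor touch (pairwise center distance strictly > 2r)
    and must not extend across the image edge.
    """

    width: float
    height: float
    radius: float
    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, float).reshape(-1, 2)
        object.__setattr__(self, "centers", c)
        r, w, h = self.radius, self.width, self.height
        if len(c):
            if (c[:, 0] < r).any() or (c[:, 0] > w - r).any():
                raise ValueError("disk extends across the x image edge")
            if (c[:, 1] < r).any() or (c[:, 1] > h - r).any():
                raise ValueError("disk extends across the y image edge")
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if (d <= 2 * r).any():
                raise ValueError("disks overlap or touch")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    @property
    def area_fraction(self) -> float:
        """f = n * pi * r^2 / (W * H); analytic, disks never overlap."""
        return self.n_clusters * math.pi * self.radius**2 / (self.width * self.height)

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask: point inside (or on the rim of) any disk."""
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if self.n_clusters == 0:
            return np.zeros(x.shape, bool)
        dx = x[:, None] - self.centers[None, :, 0]
        dy = y[:, None] - self.centers[None, :, 1]
        return ((dx * dx + dy * dy) <= self.radius**2).any(axis=1)


def generate_cluster_layout(
    n_clusters: int,
    radius: float,
    width: float,
    height: float,
    seed: int,
    max_attempts: int = 10**6,
) -> ClusterLayout:
    """Place ``n_clusters`` equal disks at random, non-touching, inside.

    Sequential rejection sampling: candidate centers are drawn uniformly
    over the admissible rectangle and rejected if within 2r of an
    accepted center.  Raises :class:`InfeasibleLayoutError` after
    ``max_attempts`` total draws.
    """
    if n_clusters < 0:
        raise ValueError("n_clusters must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n_clusters and (2 * radius > width or 2 * radius > height):
        raise InfeasibleLayoutError(
            f"disk of radius {radius} cannot fit in {width} x {height}"
        )
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_clusters:
        if attempts >= max_attempts:
            raise InfeasibleLayoutError(
                f"could not place {n_clusters} disks of radius {radius} in a "
                f"{width} x {height} image after {max_attempts} attempts"
            )
        cx = rng.uniform(radius, width - radius)
        cy = rng.uniform(radius, height - radius)
        attempts += 1
        ok = all((cx - px) ** 2 + (cy - py) ** 2 > (2 * radius) ** 2 for px, py in centers)
        if ok:
            centers.append((cx, cy))
    return ClusterLayout(width, height, radius, np.array(centers).reshape(-1, 2))


def partition_counts(n_total: int, area_fraction: float, ratio: float) -> tuple[int, int]:
    """Split ``n_total`` localizations at in/out density ratio ``ratio``.

    The ratio is the average density over the whole designated-cluster
    area relative to the average density outside it, with the total count
    held constant:

        n_in = round(N * R * f / (R * f + 1 - f)),  n_out = N - n_in.
    """
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    if not 0 < area_fraction < 1:
        raise ValueError("area_fraction must be in (0, 1)")
    if ratio < 1:
        raise ValueError("ratios below 1 are not modelled")
    n_in = int(round(n_total * ratio * area_fraction / (ratio * area_fraction + 1 - area_fraction)))
    return n_in, n_total - n_in


@dataclass(frozen=True)
class PartitionSpec:
    """Total count, partition ratio R >= 1, and the cluster layout."""

    n_total: int
    ratio: float
    layout: ClusterLayout

    def __post_init__(self) -> None:
        partition_counts(self.n_total, self.layout.area_fraction, self.ratio)

    @property
    def counts(self) -> tuple[int, int]:
        return partition_counts(self.n_total, self.layout.area_fraction, self.ratio)


def _sample_in_disks(layout: ClusterLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """First n accepted in-disk points of the rng's rejection stream."""
    r = layout.radius
    out, got = [], 0
    while got < n:
        idx = rng.integers(0, layout.n_clusters, _CHUNK)
        u = rng.uniform(-r, r, _CHUNK)
        v = rng.uniform(-r, r, _CHUNK)
        ok = u * u + v * v <= r * r
        pts = layout.centers[idx[ok]] + np.column_stack([u[ok], v[ok]])
        out.append(pts)
        got += int(ok.sum())
    return np.concatenate(out)[:n] if out else np.empty((0, 2))


def _sample_outside(layout: ClusterLayout, n: int, rng: np.random.Generator) -> np.ndarray:
    """First n accepted complement points of the rng's rejection stream."""
    out, got = [], 0
    while got < n:
        x = rng.uniform(0, layout.width, _CHUNK)
        y = rng.uniform(0, layout.height, _CHUNK)
        ok = ~layout.contains(x, y)
        out.append(np.column_stack([x[ok], y[ok]]))
        got += int(ok.sum())
    return np.concatenate(out)[:n] if out else np.empty((0, 2))


def sample_partitioned(spec: PartitionSpec, seed: int) -> LocalizationTable:
    """Sample a partition-ratio dataset; nested across ratios per seed.

    n_in points are uniform over the union of the cluster disks and
    n_out uniform over the complement.  Each record carries its pool
    ("in"/"out") and a 1-based sequence index within the pool; for the
    same seed and layout, the dataset at a lower ratio is the prefix
    subset of the dataset at a higher ratio within each pool.
    """
    n_in, n_out = spec.counts
    ss = np.random.SeedSequence(seed).spawn(2)
    pts_in = _sample_in_disks(spec.layout, n_in, np.random.default_rng(ss[0])) if n_in else np.empty((0, 2))
    pts_out = _sample_outside(spec.layout, n_out, np.random.default_rng(ss[1])) if n_out else np.empty((0, 2))
    df = pd.DataFrame(
        {
            "frame": np.concatenate(
                [np.arange(1, n_in + 1), np.arange(1, n_out + 1)]
            ).astype(int),
            "x": np.concatenate([pts_in[:, 0], pts_out[:, 0]]),
            "y": np.concatenate([pts_in[:, 1], pts_out[:, 1]]),
            "channel": "sim",
            "pool": ["in"] * n_in + ["out"] * n_out,
            "pool_seq": np.concatenate(
                [np.arange(1, n_in + 1), np.arange(1, n_out + 1)]
            ).astype(int),
        }
    )
    extent = (0.0, float(spec.layout.width), 0.0, float(spec.layout.height))
    return LocalizationTable(
        df, "pixel", extent, source=f"sample_partitioned(R={spec.ratio})", seed=seed
    )


# ---------------------------------------------------------------------------
# Membrane topography maps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Fold:
    """A folded-membrane feature: extra stacked sheets over a rectangle.

    Models ruffles / collapsed filopodia where the imaging volume of a
    pixel contains ``extra_layers`` additional membrane sheets.  The
    rectangle is given in pixel indices, half-open: columns [x0, x1),
    rows [y0, y1).
    """

    x0: int
    x1: int
    y0: int
    y1: int
    extra_layers: int = 2
    name: str = "fold"


@dataclass(frozen=True)
class Bump:
    """A smooth height-field feature raising the local surface slope.

    Gaussian height bump h(r) = a * exp(-r^2 / (2 w^2)) centred at
    (cx, cy), parametrised by its maximum slope; the amplitude is
    a = max_slope * w * sqrt(e) so that max |grad h| = max_slope.
    """

    cx: float
    cy: float
    width: float
    max_slope: float
    name: str = "bump"

    @property
    def amplitude(self) -> float:
        return self.max_slope * self.width * math.sqrt(math.e)


@dataclass(frozen=True)
class Enrichment:
    """A genuine-cluster patch: protein density multiplied by ``factor``
    over a disk, independent of the membrane amount."""

    cx: float
    cy: float
    radius: float
    factor: float
    name: str = "enrichment"


@dataclass
class MembraneMap:
    """Per-pixel relative membrane amount M = L * S.

    L is the integer membrane layer count (>= 1), S >= 1 the slope factor
    sqrt(1 + |grad h|^2) of the membrane height field h.  ``enrichment``
    (E >= 1, optional) multiplies the *protein* sampling weight only;
    a randomly distributed membrane marker samples with weight M while a
    genuinely clustered protein samples with weight M * E.
    ``footprints`` maps feature names to boolean ground-truth masks.
    """

    layers: np.ndarray
    slope: np.ndarray
    enrichment: np.ndarray | None = None
    footprints: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.layers.shape != self.slope.shape:
            raise ValueError("layer and slope grids must have the same shape")
        if (self.layers < 1).any():
            raise ValueError("layer count must be >= 1 everywhere")
        if (self.slope < 1).any():
            raise ValueError("slope factor must be >= 1 everywhere")
        if self.enrichment is not None and (self.enrichment < 1).any():
            raise ValueError("enrichment must be >= 1 everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape

    @property
    def area_factor(self) -> np.ndarray:
        """M = L * S, the relative amount of membrane per pixel."""
        return self.layers * self.slope

    def weights(self, enrichment_on: bool) -> np.ndarray:
        w = self.area_factor
        if enrichment_on and self.enrichment is not None:
            w = w * self.enrichment
        return w


def build_membrane_map(
    width: int,
    height: int,
    features: Sequence[Fold | Bump | Enrichment] = (),
    seed: int | None = None,
) -> MembraneMap:
    """Construct a membrane map from feature primitives.

    With no features the membrane is flat and single-layered (M == 1).
    ``seed`` is accepted for interface uniformity with the samplers and
    recorded nowhere; the construction is deterministic.
    """
    layers = np.ones((height, width), int)
    enrich = np.ones((height, width), float)
    gx = np.zeros((height, width), float)
    gy = np.zeros((height, width), float)
    footprints: dict[str, np.ndarray] = {}
    # pixel centers
    xc = np.arange(width) + 0.5
    yc = np.arange(height) + 0.5
    X, Y = np.meshgrid(xc, yc)
    any_enrichment = False
    for k, feat in enumerate(features):
        key = f"{feat.name}_{k}"
        if isinstance(feat, Fold):
            if not (0 <= feat.x0 < feat.x1 <= width and 0 <= feat.y0 < feat.y1 <= height):
                raise ValueError(f"fold {feat} outside the {width} x {height} image")
            if feat.extra_layers < 0:
                raise ValueError("extra_layers must be >= 0")
            mask = np.zeros((height, width), bool)
            mask[feat.y0 : feat.y1, feat.x0 : feat.x1] = True
            layers[mask] += feat.extra_layers
            footprints[key] = mask
        elif isinstance(feat, Bump):
            if not (0 <= feat.cx <= width and 0 <= feat.cy <= height):
                raise ValueError(f"bump centre {feat.cx, feat.cy} outside the image")
            dx, dy = X - feat.cx, Y - feat.cy
            r2 = dx * dx + dy * dy
            g = -feat.amplitude / feat.width**2 * np.exp(-r2 / (2 * feat.width**2))
            gx += g * dx
            gy += g * dy
            footprints[key] = r2 <= (3 * feat.width) ** 2
        elif isinstance(feat, Enrichment):
            if not (0 <= feat.cx <= width and 0 <= feat.cy <= height):
                raise ValueError(f"enrichment centre outside the image")
            if feat.factor < 1:
                raise ValueError("enrichment factor must be >= 1")
            dx, dy = X - feat.cx, Y - feat.cy
            mask = dx * dx + dy * dy <= feat.radius**2
            enrich[mask] *= feat.factor
            footprints[key] = mask
            any_enrichment = True
        else:
            raise TypeError(f"unknown feature type {type(feat).__name__}")
    slope = np.sqrt(1.0 + gx * gx + gy * gy)
    return MembraneMap(
        layers, slope, enrich if any_enrichment else None, footprints
    )


def sample_topography(
    mmap: MembraneMap, n: int, enrichment_on: bool, seed: int
) -> LocalizationTable:
    """Draw localizations with per-pixel probability proportional to the
    membrane amount M (marker mode) or M * E (protein mode), uniform
    within the pixel."""
    if n < 0:
        raise ValueError("n must be >= 0")
    h, w = mmap.shape
    weights = mmap.weights(enrichment_on).astype(float).ravel()
    total = weights.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("sampling weights must be finite with positive sum")
    rng = np.random.default_rng(seed)
    flat = rng.choice(weights.size, size=n, p=weights / total)
    rows, cols = np.divmod(flat, w)
    x = cols + rng.uniform(0, 1, n)
    y = rows + rng.uniform(0, 1, n)
    df = pd.DataFrame(
        {
            "frame": np.arange(1, n + 1),
            "x": x,
            "y": y,
            "channel": "protein" if enrichment_on else "marker",
        }
    )
    return LocalizationTable(
        df, "pixel", (0.0, float(w), 0.0, float(h)),
        source=f"sample_topography(enrichment={enrichment_on})", seed=seed,
    )


# ---------------------------------------------------------------------------
# Dimer / detection-fraction simulation
# ---------------------------------------------------------------------------

_OFFSETS = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)


@dataclass
class DimerField:
    """Paired molecules on a pixel grid, with partial detection.

    ``black`` and ``red`` are (n, 2) integer (row, col) pixel positions;
    ``partner[i]`` is the index into ``red`` of black molecule i's dimer
    partner, or -1 if the partner went undetected.
    """

    width: int
    height: int
    black: np.ndarray
    red: np.ndarray
    partner: np.ndarray
    detection_fraction: float = 1.0

    @property
    def black_xy(self) -> np.ndarray:
        """(n, 2) pixel-center (x, y) coordinates of the black molecules."""
        return np.column_stack([self.black[:, 1] + 0.5, self.black[:, 0] + 0.5])

    @property
    def red_xy(self) -> np.ndarray:
        return np.column_stack([self.red[:, 1] + 0.5, self.red[:, 0] + 0.5])

    def black_in_central(self, size: int) -> np.ndarray:
        """Mask of black molecules inside the centred ``size x size`` window."""
        r0 = (self.height - size) // 2
        c0 = (self.width - size) // 2
        r, c = self.black[:, 0], self.black[:, 1]
        return (r >= r0) & (r < r0 + size) & (c >= c0) & (c < c0 + size)


def simulate_dimers(n_pairs: int, width: int, height: int, seed: int) -> DimerField:
    """Place ``n_pairs`` dimers: black molecules at distinct random pixels,
    each red partner uniformly in one of the (in-bounds) 8 adjacent pixels.

    Red molecules of different pairs may coincide with each other or with
    black pixels; only the black molecules are constrained to distinct
    pixels.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if n_pairs > width * height:
        raise ValueError("cannot place that many distinct black molecules")
    rng = np.random.default_rng(seed)
    flat = rng.choice(width * height, size=n_pairs, replace=False)
    black = np.column_stack(np.divmod(flat, width))  # (row, col)
    choice = rng.integers(0, 8, n_pairs)
    red = black + _OFFSETS[choice]
    # Edge blacks: redraw uniformly among their in-bounds neighbours.
    bad = np.flatnonzero(
        (red[:, 0] < 0) | (red[:, 0] >= height) | (red[:, 1] < 0) | (red[:, 1] >= width)
    )
    for i in bad:
        cand = black[i] + _OFFSETS
        ok = (
            (cand[:, 0] >= 0)
            & (cand[:, 0] < height)
            & (cand[:, 1] >= 0)
            & (cand[:, 1] < width)
        )
        red[i] = cand[ok][rng.integers(0, ok.sum())]
    return DimerField(width, height, black, red, np.arange(n_pairs), 1.0)


def thin_detections(field: DimerField, fraction: float, seed: int) -> DimerField:
    """Retain a uniform random subset of round(d * |red|) red molecules.

    Black molecules are untouched; the pairing map is reindexed, with
    blacks whose partner was dropped mapped to -1.
    """
    if not 0 < fraction <= 1:
        raise ValueError("detection fraction must be in (0, 1]")
    m = len(field.red)
    keep_n = int(round(fraction * m))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(m, size=keep_n, replace=False))
    newindex = np.full(m, -1)
    newindex[keep] = np.arange(keep_n)
    partner = np.where(field.partner >= 0, newindex[field.partner], -1)
    return DimerField(
        field.width,
        field.height,
        field.black.copy(),
        field.red[keep],
        partner,
        fraction * field.detection_fraction,
    )
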