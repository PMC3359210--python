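"""Synthetic microscopy fixtures with known ground truth.

Two generators mirror the two imaging settings the pipeline targets:

* :func:`make_fluor_field` — fluorescent live-cell fields: a flat gray
  background (empty regions render gray under a digital fluorescence
  microscope) carrying non-overlapping elliptical cells whose blue stain
  is composed with the blue-stain OD vector via the Lambert-Beer forward
  model, so the deconvolution step is genuinely exercised.  Per-cell
  stain magnitudes are drawn around a group-level mean; group means are
  the dial that emulates low / medium / high replication-level cohorts.

* :func:`make_ihc_composite` — IHC-like tissue composites: nuclei with
  Haematoxylin (and optional DAB) concentrations plus a diffuse Eosin
  counterstain background, composed per pixel as
  ``I = I0 * exp(-sum_s c_s v_s)`` with the built-in H/E/D vectors and
  quantised to 8 bits.

Both return the exact ground-truth mask and are bit-reproducible from
their spec (all randomness flows through ``numpy.random.default_rng(seed)``).
Image sizes default to 256 x 256 — far smaller than real captures, but
the pipeline is resolution-agnostic and per-pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import stains
from .quantify import quant_score

__all__ = [
    "FluorFieldSpec",
    "IHCCompositeSpec",
    "FluorField",
    "IHCComposite",
    "PackingError",
    "make_fluor_field",
    "make_ihc_composite",
]

FULL = 255  # generators are 8-bit


class PackingError(ValueError):
    """Raised when the requested cells cannot be placed without overlap."""


@dataclass(frozen=True)
class FluorFieldSpec:
    """Parameters of one synthetic fluorescent live-cell field."""

    image_size: tuple[int, int] = (256, 256)
    n_cells: int = 25
    cell_radius_range: tuple[float, float] = (8.0, 16.0)
    stain_mean: float = 60.0  # per-cell blue stain magnitude, intensity units
    stain_sd: float = 8.0
    background_gray: float = 180.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 1 or w < 1 or self.n_cells < 0:
            raise ValueError("invalid field geometry")
        if not 0 < self.background_gray < FULL:
            raise ValueError("background_gray must lie strictly inside (0, 255)")
        if min(self.cell_radius_range) <= 0 or self.stain_mean <= 0:
            raise ValueError("radii and stain level must be positive")
        if self.stain_sd < 0 or self.noise_sd < 0:
            raise ValueError("spreads must be non-negative")


@dataclass(frozen=True)
class IHCCompositeSpec:
    """Parameters of one synthetic IHC tissue composite."""

    image_size: tuple[int, int] = (256, 256)
    n_nuclei: int = 40
    nucleus_radius_range: tuple[float, float] = (6.0, 12.0)
    haematoxylin_conc_range: tuple[float, float] = (0.7, 1.2)
    dab_conc_range: tuple[float, float] = (0.0, 0.3)
    counterstain_background_conc: float = 0.15
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 1 or w < 1 or self.n_nuclei < 0:
            raise ValueError("invalid composite geometry")
        for lo, hi in (self.haematoxylin_conc_range, self.dab_conc_range):
            if lo < 0 or hi < lo:
                raise ValueError("concentration ranges must be non-negative and ordered")
        if self.counterstain_background_conc < 0 or self.noise_sd < 0:
            raise ValueError("background concentration and noise must be non-negative")


@dataclass(frozen=True)
class FluorField:
    """A rendered fluorescence field with its ground truth."""

    image: np.ndarray = field(repr=False)  # (H, W, 3) uint8, noisy, quantised
    mask: np.ndarray = field(repr=False)  # (H, W) uint8, foreground cells = 0
    true_score: float  # exact pixel-mean score of the noiseless blue channel
    noiseless_channel: np.ndarray = field(repr=False)  # (H, W) float blue intensity
    cell_magnitudes: tuple[float, ...]
    spec: FluorFieldSpec


@dataclass(frozen=True)
class IHCComposite:
    """A rendered IHC composite with its ground-truth nuclear mask."""

    image: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)
    concentrations: np.ndarray = field(repr=False)  # (H, W, 3) H/E/D maps
    spec: IHCCompositeSpec


def _place_ellipses(
    rng: np.random.Generator,
    shape: tuple[int, int],
    n: int,
    radius_range: tuple[float, float],
    max_tries_per_cell: int = 400,
) -> list[tuple[float, float, float, float]]:
    """Rejection-sample non-overlapping axis-aligned ellipses.

    Returns (cy, cx, ry, rx) tuples; overlap is excluded conservatively
    on bounding circles with a 2-px margin.
    """
    h, w = shape
    lo, hi = radius_range
    placed: list[tuple[float, float, float, float]] = []
    for _ in range(n):
        for attempt in range(max_tries_per_cell):
            r = rng.uniform(lo, hi)
            ry = r * (1.0 + rng.uniform(-0.2, 0.2))  # mild eccentricity jitter
            rx = r * (1.0 + rng.uniform(-0.2, 0.2))
            rmax = max(ry, rx)
            if 2 * rmax + 2 >= min(h, w):
                raise PackingError("cell radius too large for the field")
            cy = rng.uniform(rmax + 1, h - rmax - 1)
            cx = rng.uniform(rmax + 1, w - rmax - 1)
            ok = all(
                np.hypot(cy - py, cx - px) > rmax + max(pry, prx) + 2.0
                for py, px, pry, prx in placed
            )
            if ok:
                placed.append((cy, cx, ry, rx))
                break
        else:
            raise PackingError(
                f"could not place cell {len(placed) + 1}/{n} without overlap"
            )
    return placed


def _ellipse_pixels(shape, cy, cx, ry, rx) -> tuple[np.ndarray, np.ndarray]:
    h, w = shape
    y0, y1 = max(0, int(cy - ry) - 1), min(h, int(cy + ry) + 2)
    x0, x1 = max(0, int(cx - rx) - 1), min(w, int(cx + rx) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return yy[inside], xx[inside]


def _quantise(img: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, FULL).astype(np.uint8)


def make_fluor_field(spec: FluorFieldSpec) -> FluorField:
    """Render one fluorescent live-cell field from its spec.

    Cell pixels attenuate the gray background along the blue-stain OD
    vector: a per-cell magnitude ``m`` (intensity units) maps to the
    concentration ``a = -ln(1 - m/255)``, so the blue stain channel of a
    cell drops by a factor ``1 - m/255``.  The returned ``true_score``
    is the exact pixel-mean score of the noiseless, unquantised blue
    channel over the ground-truth mask (``nan`` for an empty field).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    system = stains.get_stain_system("fluor-blue")
    blue_vec = system.od_vectors[0]

    cells = _place_ellipses(rng, (h, w), spec.n_cells, spec.cell_radius_range)
    conc = np.zeros((h, w))
    mask = np.full((h, w), FULL, dtype=np.uint8)
    mags: list[float] = []
    for cy, cx, ry, rx in cells:
        m = float(np.clip(rng.normal(spec.stain_mean, spec.stain_sd), 1.0, 250.0))
        mags.append(m)
        ys, xs = _ellipse_pixels((h, w), cy, cx, ry, rx)
        conc[ys, xs] = -np.log1p(-m / FULL)
        mask[ys, xs] = 0

    rgb = spec.background_gray * np.exp(-conc[..., None] * blue_vec[None, None, :])
    image = _quantise(rgb, rng, spec.noise_sd)

    # exact blue channel of the noiseless composition
    blue_conc = stains.deconvolve(rgb, system, output="concentration")["blue"]
    noiseless = FULL * np.exp(-blue_conc)
    result = quant_score(noiseless, mask)
    return FluorField(
        image=image,
        mask=mask,
        true_score=result.score,
        noiseless_channel=noiseless,
        cell_magnitudes=tuple(mags),
        spec=spec,
    )


def make_ihc_composite(spec: IHCCompositeSpec) -> IHCComposite:
    """Render one IHC-like composite from its spec.

    Per pixel, the RGB triple is ``255 * exp(-C M)`` where ``C`` holds
    the Haematoxylin / Eosin / DAB concentrations and ``M`` the
    normalised stain matrix; nuclei carry Haematoxylin (plus optional
    DAB) on top of a uniform Eosin counterstain background.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    system = stains.get_stain_system("ihc-hed")

    conc = np.zeros((h, w, 3))
    conc[..., 1] = spec.counterstain_background_conc
    mask = np.full((h, w), FULL, dtype=np.uint8)
    nuclei = _place_ellipses(rng, (h, w), spec.n_nuclei, spec.nucleus_radius_range)
    for cy, cx, ry, rx in nuclei:
        ch = rng.uniform(*spec.haematoxylin_conc_range)
        cd = rng.uniform(*spec.dab_conc_range)
        ys, xs = _ellipse_pixels((h, w), cy, cx, ry, rx)
        conc[ys, xs, 0] = ch
        conc[ys, xs, 2] = cd
        mask[ys, xs] = 0

    rgb = FULL * np.exp(-(conc @ system.matrix))
    image = _quantise(rgb, rng, spec.noise_sd)
    return IHCComposite(image=image, mask=mask, concentrations=conc, spec=spec)
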