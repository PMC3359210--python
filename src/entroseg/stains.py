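"""Optical-density conversion and colour deconvolution.

Under the Lambert-Beer law the light transmitted through a stained
specimen falls off exponentially with the amount of stain, so the optical
density ``OD = ln(I0 / I1)`` of each RGB channel is *linear* in stain
amount.  Each stain is characterised by a unit 3-vector of per-channel
optical densities; stacking the vectors of the stains present gives a
matrix ``A`` whose inverse ``K`` unmixes a pixel's OD triple into
per-stain concentrations (``C = K D``, Ruifrok-Johnston colour
deconvolution).

Two stain systems are built in:

``fluor-blue``
    a two-stain system separating the blue stain of fluorescent
    live-cell images from the grayish background colour; the first row
    yields the blue-stain channel used for cell segmentation.
``ihc-hed``
    the three-stain Haematoxylin / Eosin / DAB system for
    immunohistochemistry tissue images.

Two-stain systems are completed to a full 3x3 basis with the normalised
cross product of their rows before inversion; the synthetic third
channel is discarded on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "StainSystem",
    "StainSeparationError",
    "rgb_to_od",
    "build_stain_system",
    "deconvolve",
    "get_stain_system",
    "load_stain_system",
    "BUILTIN_STAIN_SYSTEMS",
]

_VALID_BIT_DEPTHS = (8, 16)


class StainSeparationError(ValueError):
    """Raised when a set of stain vectors cannot be inverted."""


def max_intensity(bit_depth: int) -> int:
    """Full-scale intensity ``2**c - 1`` for a ``c``-bit channel."""
    if bit_depth not in _VALID_BIT_DEPTHS:
        raise ValueError(f"bit_depth must be one of {_VALID_BIT_DEPTHS}, got {bit_depth}")
    return (1 << bit_depth) - 1


def rgb_to_od(
    image: np.ndarray,
    i0: float | Sequence[float] | None = None,
    bit_depth: int = 8,
) -> np.ndarray:
    """Convert an RGB image to per-channel optical density.

    ``od = ln(i0 / max(I, 1))`` for integer images: zero intensities are
    clamped to 1 (the smallest representable nonzero level) so the OD
    stays finite.  Float images keep their sub-1 values and are only
    floored at a tiny epsilon.  Pixels at (or above) the incident
    intensity map to OD 0.  ``i0`` defaults to full scale per channel.

    Parameters
    ----------
    image : (H, W, 3) array
        Channel intensities in ``[0, 2**bit_depth - 1]``.
    i0 : scalar or length-3 sequence, optional
        Incident (background) intensity per channel.
    bit_depth : int
        Bits per channel; 8 or 16.

    Returns
    -------
    (H, W, 3) float array of non-negative optical densities.
    """
    full = max_intensity(bit_depth)
    floor = 1.0 if np.issubdtype(np.asarray(image).dtype, np.integer) else 1e-12
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    if arr.min() < 0 or arr.max() > full:
        raise ValueError(f"pixel values must lie in [0, {full}]")
    i0_arr = np.full(3, float(full)) if i0 is None else np.broadcast_to(
        np.asarray(i0, dtype=float), (3,)
    )
    if np.any(i0_arr <= 0):
        raise ValueError("incident intensity i0 must be positive")
    od = np.log(i0_arr / np.maximum(arr, floor))
    return np.maximum(od, 0.0)


@dataclass(frozen=True)
class StainSystem:
    """A set of stain OD vectors and its deconvolution inverse.

    Attributes
    ----------
    names : tuple of str
        Stain labels, one per physical stain (2 or 3).
    od_vectors : (n_stains, 3) array
        Unit-normalised OD vector of each stain.
    matrix : (3, 3) array
        The normalised stain matrix ``A``; for a 2-stain system the third
        row is the normalised cross product of the first two.
    deconv : (3, 3) array
        ``K = A^{-1}``, the colour-deconvolution matrix.
    """

    names: tuple[str, ...]
    od_vectors: np.ndarray = field(repr=False)
    matrix: np.ndarray = field(repr=False)
    deconv: np.ndarray = field(repr=False)

    @property
    def n_stains(self) -> int:
        return len(self.names)

    def channel_index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown stain {name!r}; system has {self.names}") from None


def build_stain_system(
    od_vectors: Sequence[Sequence[float]],
    names: Sequence[str],
) -> StainSystem:
    """Normalise stain OD vectors and invert them into a deconvolution matrix.

    Accepts 2 or 3 linearly independent nonzero 3-vectors.  Rows are
    scaled to unit Euclidean length; a 2-row system is completed with the
    unit cross product of its rows.  Raises
    :class:`StainSeparationError` for collinear / singular systems.
    """
    vecs = np.asarray(od_vectors, dtype=float)
    if vecs.ndim != 2 or vecs.shape[1] != 3 or vecs.shape[0] not in (2, 3):
        raise ValueError(f"expected 2 or 3 OD 3-vectors, got shape {vecs.shape}")
    if len(names) != vecs.shape[0]:
        raise ValueError("one name per stain vector is required")
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms < 1e-12):
        raise StainSeparationError("zero-length stain vector")
    unit = vecs / norms[:, None]
    if unit.shape[0] == 2:
        third = np.cross(unit[0], unit[1])
        tnorm = np.linalg.norm(third)
        if tnorm < 1e-8:
            raise StainSeparationError("collinear stain vectors cannot be separated")
        full = np.vstack([unit, third / tnorm])
    else:
        full = unit
    if abs(np.linalg.det(full)) < 1e-8:
        raise StainSeparationError("stain vectors are linearly dependent")
    deconv = np.linalg.inv(full)
    return StainSystem(
        names=tuple(names), od_vectors=unit, matrix=full, deconv=deconv
    )


#: rows: blue stain, background colour (fluorescent live-cell system)
FLUOR_BLUE_VECTORS = (
    (0.6443, 0.7167, 0.2669),
    (0.1754, 0.9723, 0.1546),
)

#: rows: Haematoxylin, Eosin, DAB (IHC system)
IHC_HED_VECTORS = (
    (0.65, 0.704, 0.286),
    (0.072, 0.99, 0.105),
    (0.268, 0.57, 0.776),
)

BUILTIN_STAIN_SYSTEMS: Mapping[str, StainSystem] = {
    "fluor-blue": build_stain_system(FLUOR_BLUE_VECTORS, ("blue", "background")),
    "ihc-hed": build_stain_system(IHC_HED_VECTORS, ("haematoxylin", "eosin", "dab")),
}


def get_stain_system(name_or_system: str | StainSystem) -> StainSystem:
    """Resolve a built-in system name (or pass a system through)."""
    if isinstance(name_or_system, StainSystem):
        return name_or_system
    try:
        return BUILTIN_STAIN_SYSTEMS[name_or_system]
    except KeyError:
        known = ", ".join(BUILTIN_STAIN_SYSTEMS)
        raise KeyError(f"unknown stain system {name_or_system!r}; built-ins: {known}") from None


def load_stain_system(path: str | Path) -> StainSystem:
    """Read a stain system from a plain-text config.

    Each non-comment line: ``<stain name> <od_r> <od_g> <od_b>``.
    """
    names: list[str] = []
    rows: list[list[float]] = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"malformed stain line: {raw!r}")
        names.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return build_stain_system(rows, names)


def deconvolve(
    image: np.ndarray,
    system: str | StainSystem,
    i0: float | Sequence[float] | None = None,
    bit_depth: int = 8,
    output: str = "intensity",
) -> dict[str, np.ndarray]:
    """Separate an RGB image into per-stain channels.

    Per pixel, ``C = K D`` where ``D`` is the OD triple.  With
    ``output="intensity"`` (default) each concentration is re-expressed
    on the original intensity scale as
    ``round((2**c - 1) * exp(-C))`` clipped to range, so that full scale
    means "no stain" and stained pixels are *dark* — the polarity the
    entropy segmentation expects.  ``output="concentration"`` returns the
    raw (possibly negative) concentration floats instead.

    Returns a dict mapping stain name to an (H, W) array; the synthetic
    completion channel of a 2-stain system is discarded.
    """
    if output not in ("intensity", "concentration"):
        raise ValueError("output must be 'intensity' or 'concentration'")
    sys_ = get_stain_system(system)
    od = rgb_to_od(image, i0=i0, bit_depth=bit_depth)
    # per pixel the OD row vector is D = C A, hence C = D K with K = A^{-1}
    conc = od @ sys_.deconv
    full = max_intensity(bit_depth)
    out: dict[str, np.ndarray] = {}
    for idx, name in enumerate(sys_.names):
        ci = conc[..., idx]
        if output == "concentration":
            out[name] = ci
        else:
            vals = np.rint(full * np.exp(-ci))
            dtype = np.uint8 if bit_depth == 8 else np.uint16
            out[name] = np.clip(vals, 0, full).astype(dtype)
    return out
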