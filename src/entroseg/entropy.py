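"""Maximum-entropy histogram thresholding and segmentation.

The single-stage segmenter treats foreground and background as two
information sources and picks the intensity cut-off ``j*`` that
maximises a Kapur-style entropy criterion over the image histogram.
With distributions ``A = {p_0..p_j}`` and ``B = {p_{j+1}..p_{L-1}}``
renormalised within each class, the default criterion is the classical
Kapur sum of class entropies

    H_j = H(A/P(A)) + H(B/P(B))
        = ln P(A) + H_A/P(A) + ln P(B) + H_B/P(B)

with ``H_A = -sum_{i<=j} p_i ln p_i`` (raw, unnormalised sums).  Splits
that leave a class empty score ``-inf`` and are never selected; exact
ties go to the smallest ``j``.  A ``printed`` variant,
``H_j = -ln P(A) - ln P(B) - H_A P(A) - H_B P(B)``, is kept for
comparison (see docs/methods.md for why it is not the default).

Thresholded masks use the convention foreground = 0, background =
``2**c - 1``: stained regions are dark in a deconvolved stain channel.

For IHC nuclei a multistage variant first splits the 8-bit range into
four equal-width quarters, finds a maximum-entropy cut inside each
occupied quarter, stratifies the image into (up to) eight layers by the
seven ordered boundaries, and finally applies the same entropy cut to
the 8-bin layer histogram; layers at or below the cut are nuclei.  A
radius-3 mode (majority) filter cleans the resulting mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .stains import max_intensity

__all__ = [
    "IntensityHistogram",
    "ThresholdResult",
    "MultistageResult",
    "histogram",
    "entropy_criterion",
    "criterion_curve",
    "max_entropy_threshold",
    "binarize",
    "multistage_segment",
    "mode_filter",
]

CRITERION_VARIANTS = ("kapur", "printed")


@dataclass(frozen=True)
class IntensityHistogram:
    """Histogram of a single-channel image over the full intensity range."""

    counts: np.ndarray = field(repr=False)

    @property
    def probabilities(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty histogram has no probability distribution")
        return self.counts / total

    @property
    def n_bins(self) -> int:
        return self.counts.size


def histogram(channel: np.ndarray, bit_depth: int = 8) -> IntensityHistogram:
    """Full-range intensity histogram (length ``2**bit_depth``) of a channel."""
    full = max_intensity(bit_depth)
    arr = np.asarray(channel)
    if arr.size == 0:
        raise ValueError("cannot histogram an empty image")
    flat = arr.ravel()
    if not np.issubdtype(flat.dtype, np.integer):
        rounded = np.rint(flat)
        if not np.allclose(flat, rounded):
            raise ValueError("channel values must be integral")
        flat = rounded.astype(np.int64)
    if flat.min() < 0 or flat.max() > full:
        raise ValueError(f"channel values must lie in [0, {full}]")
    counts = np.bincount(flat.astype(np.int64), minlength=full + 1)
    return IntensityHistogram(counts=counts)


def _as_probabilities(hist) -> np.ndarray:
    if isinstance(hist, IntensityHistogram):
        return hist.probabilities
    arr = np.asarray(hist, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("expected a 1-D histogram with at least 2 bins")
    if np.any(arr < 0):
        raise ValueError("histogram entries must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("histogram has zero total mass")
    return arr / total


def criterion_curve(hist, variant: str = "kapur") -> np.ndarray:
    """Entropy criterion ``H_j`` for every candidate cut-off ``j``.

    ``hist`` may be an :class:`IntensityHistogram` or a raw count /
    probability vector.  Cut-offs with an empty class are ``-inf``.
    """
    if variant not in CRITERION_VARIANTS:
        raise ValueError(f"variant must be one of {CRITERION_VARIANTS}")
    p = _as_probabilities(hist)
    n = p.size
    occupied = p > 0
    plogp = np.zeros(n)
    plogp[occupied] = -p[occupied] * np.log(p[occupied])
    pa = np.cumsum(p)
    # right-tail mass computed by reverse cumsum for accuracy
    pb = np.concatenate([np.cumsum(p[::-1])[::-1][1:], [0.0]])
    ha = np.cumsum(plogp)
    hb = ha[-1] - ha
    occ_a = np.cumsum(occupied)
    occ_b = occ_a[-1] - occ_a
    valid = (occ_a > 0) & (occ_b > 0)
    curve = np.full(n, -np.inf)
    a, b = pa[valid], pb[valid]
    if variant == "kapur":
        curve[valid] = (
            np.log(a) + ha[valid] / a + np.log(b) + hb[valid] / b
        )
    else:  # printed
        curve[valid] = (
            -np.log(a) - np.log(b) - ha[valid] * a - hb[valid] * b
        )
    return curve


def entropy_criterion(hist, j: int, variant: str = "kapur") -> float:
    """Criterion value of the single cut-off ``j`` (``-inf`` if a class is empty)."""
    p = _as_probabilities(hist)
    if not 0 <= j < p.size:
        raise ValueError(f"cut-off {j} outside [0, {p.size - 1}]")
    return float(criterion_curve(p, variant)[j])


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a maximum-entropy threshold search on ``[lo, hi]``.

    ``criterion[i]`` is the criterion value at cut-off ``lo + i``.
    ``degenerate`` marks searches where all mass sat in a single bin
    (the cut-off is then that bin).
    """

    cutoff: int
    criterion: np.ndarray = field(repr=False)
    max_entropy: float
    lo: int
    hi: int
    degenerate: bool = False


def max_entropy_threshold(
    hist,
    lo: int = 0,
    hi: int | None = None,
    variant: str = "kapur",
) -> ThresholdResult:
    """Maximum-entropy cut-off of a histogram restricted to ``[lo, hi]``.

    The sub-histogram is renormalised before the criterion is evaluated.
    Ties take the smallest ``j``.
    """
    counts = (
        hist.counts if isinstance(hist, IntensityHistogram) else np.asarray(hist, dtype=float)
    )
    if counts.ndim != 1:
        raise ValueError("histogram must be 1-D")
    if hi is None:
        hi = counts.size - 1
    if not (0 <= lo <= hi < counts.size):
        raise ValueError(f"invalid range [{lo}, {hi}] for {counts.size} bins")
    sub = np.asarray(counts[lo : hi + 1], dtype=float)
    total = sub.sum()
    if total <= 0:
        raise ValueError(f"no histogram mass in [{lo}, {hi}]")
    occupied = np.nonzero(sub > 0)[0]
    if occupied.size == 1:
        curve = np.full(sub.size, -np.inf)
        return ThresholdResult(
            cutoff=lo + int(occupied[0]),
            criterion=curve,
            max_entropy=float("-inf"),
            lo=lo,
            hi=hi,
            degenerate=True,
        )
    curve = criterion_curve(sub / total, variant)
    rel = int(np.argmax(curve))  # argmax returns the first (smallest) maximiser
    return ThresholdResult(
        cutoff=lo + rel,
        criterion=curve,
        max_entropy=float(curve[rel]),
        lo=lo,
        hi=hi,
        degenerate=False,
    )


def binarize(channel: np.ndarray, cutoff: int, bit_depth: int = 8) -> np.ndarray:
    """Binary mask: values ``<= cutoff`` become foreground 0, others ``2**c - 1``."""
    full = max_intensity(bit_depth)
    if not 0 <= cutoff <= full:
        raise ValueError(f"cutoff {cutoff} outside [0, {full}]")
    arr = np.asarray(channel)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.where(arr <= cutoff, 0, full).astype(dtype)


@dataclass(frozen=True)
class MultistageResult:
    """Outcome of the multistage (8-layer) entropy segmentation.

    Attributes
    ----------
    mask : (H, W) uint8
        Final binary mask, foreground (nuclei) = 0.
    layers : (H, W) int array
        Per-pixel layer index (0 = darkest).
    boundaries : tuple of int
        Ordered intensity boundaries separating the layers.
    stage_cutoffs : tuple of int
        The per-quarter maximum-entropy points actually found.
    layer_counts : ndarray
        Histogram of layer labels (the second-stage input).
    layer_cutoff : int
        Layer index at/below which pixels are foreground (-1 if none).
    degenerate : bool
        True when fewer than two layers were occupied; mask is empty.
    """

    mask: np.ndarray = field(repr=False)
    layers: np.ndarray = field(repr=False)
    boundaries: tuple[int, ...]
    stage_cutoffs: tuple[int, ...]
    layer_counts: np.ndarray = field(repr=False)
    layer_cutoff: int
    degenerate: bool


def multistage_segment(
    channel: np.ndarray,
    variant: str = "kapur",
    foreground: str = "dark",
) -> MultistageResult:
    """Eight-layer, two-pass maximum-entropy segmentation of an 8-bit channel.

    Stages: (1) the intensity range is split into four equal-width
    quarters with fixed boundaries 63 / 127 / 191; (2) a maximum-entropy
    point is found inside each occupied quarter (empty quarters collapse);
    (3) the ordered boundaries stratify the image into layers; (4) the
    layer-label histogram is itself entropy-thresholded; (5) layers at or
    below the cut form the foreground (``foreground="dark"``; pass
    ``"bright"`` to invert the polarity).

    Constant or single-layer images return a flagged, empty-foreground
    result rather than raising, so batch runs survive blank fields.
    """
    if foreground not in ("dark", "bright"):
        raise ValueError("foreground must be 'dark' or 'bright'")
    full = max_intensity(8)
    hist = histogram(channel, bit_depth=8)
    counts = hist.counts
    quarters = ((0, 63), (64, 127), (128, 191), (192, 255))
    fixed = (63, 127, 191)
    stage_cutoffs: list[int] = []
    for lo, hi in quarters:
        if counts[lo : hi + 1].sum() > 0:
            stage_cutoffs.append(max_entropy_threshold(hist, lo, hi, variant).cutoff)
    boundaries = tuple(sorted(set(stage_cutoffs) | set(fixed)))
    arr = np.asarray(channel)
    layers = np.searchsorted(boundaries, arr, side="left").astype(np.int64)
    n_layers = len(boundaries) + 1
    layer_counts = np.bincount(layers.ravel(), minlength=n_layers)
    if np.count_nonzero(layer_counts) < 2:
        empty = np.full(arr.shape, full, dtype=np.uint8)
        return MultistageResult(
            mask=empty,
            layers=layers,
            boundaries=boundaries,
            stage_cutoffs=tuple(stage_cutoffs),
            layer_counts=layer_counts,
            layer_cutoff=-1,
            degenerate=True,
        )
    res = max_entropy_threshold(layer_counts, 0, n_layers - 1, variant)
    if foreground == "dark":
        fg = layers <= res.cutoff
    else:
        fg = layers > res.cutoff
    mask = np.where(fg, 0, full).astype(np.uint8)
    return MultistageResult(
        mask=mask,
        layers=layers,
        boundaries=boundaries,
        stage_cutoffs=tuple(stage_cutoffs),
        layer_counts=layer_counts,
        layer_cutoff=res.cutoff,
        degenerate=res.degenerate,
    )


def mode_filter(
    mask: np.ndarray,
    radius: int = 3,
    bit_depth: int = 8,
    tie: str = "foreground",
) -> np.ndarray:
    """Majority vote over a ``(2r+1) x (2r+1)`` window on a binary mask.

    Each pixel is replaced by the more frequent of the two mask values in
    its neighbourhood; windows are clipped at image borders (pixels
    outside the image cast no vote).  Exact ties go to the foreground
    value 0 by default (``tie="background"`` flips that), which favours
    recovering weak, low-contrast foreground pixels.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if tie not in ("foreground", "background"):
        raise ValueError("tie must be 'foreground' or 'background'")
    full = max_intensity(bit_depth)
    arr = np.asarray(mask)
    values = np.unique(arr)
    if not np.all(np.isin(values, (0, full))):
        raise ValueError(f"mask must be binary with values in {{0, {full}}}")
    fg = (arr == 0).astype(np.int64)
    kernel = np.ones((2 * radius + 1, 2 * radius + 1), dtype=np.int64)
    fg_votes = ndimage.correlate(fg, kernel, mode="constant", cval=0)
    window = ndimage.correlate(np.ones_like(fg), kernel, mode="constant", cval=0)
    if tie == "foreground":
        keep_fg = 2 * fg_votes >= window
    else:
        keep_fg = 2 * fg_votes > window
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.where(keep_fg, 0, full).astype(dtype)
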