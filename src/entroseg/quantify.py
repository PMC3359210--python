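"""Cell-based stain quantification scores.

The pixel-mean score ``s`` is the mean stain magnitude over all
segmented foreground pixels.  Because it is an average rather than a
sum, it is invariant to how many cells the microscope happened to
capture in the field of view — the property that makes it usable as a
replication-level readout across sampling locations.

Deconvolved stain channels are intensity-like (full scale = no stain,
dark = heavily stained), so the stain *magnitude* of a pixel defaults to
``2**c - 1 - value``; higher staining then yields a higher score.  Pass
``measure="raw"`` to average the channel values themselves.

A per-cell variant averages the within-cell mean magnitudes over
8-connected foreground components, weighting every cell equally
regardless of its area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .stains import max_intensity

__all__ = ["QuantResult", "quant_score", "cell_mean_score"]

_MEASURES = ("magnitude", "raw")


@dataclass(frozen=True)
class QuantResult:
    """A quantification score together with its provenance.

    ``score`` is ``nan`` (and ``empty`` is True) when the mask contains
    no foreground — a blank field is flagged, never scored as 0, which
    would silently mimic "no stain".
    """

    score: float
    foreground_pixels: int
    n_cells: int
    mode: str  # "pixel-mean" | "cell-mean"
    empty: bool = False


def _foreground(channel: np.ndarray, mask: np.ndarray, bit_depth: int) -> np.ndarray:
    full = max_intensity(bit_depth)
    ch = np.asarray(channel)
    mk = np.asarray(mask)
    if ch.shape != mk.shape:
        raise ValueError(f"channel shape {ch.shape} != mask shape {mk.shape}")
    values = np.unique(mk)
    if not np.all(np.isin(values, (0, full))):
        raise ValueError(f"mask must be binary with values in {{0, {full}}}")
    return mk == 0


def _magnitudes(channel: np.ndarray, measure: str, bit_depth: int) -> np.ndarray:
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {_MEASURES}")
    vals = np.asarray(channel, dtype=float)
    if measure == "magnitude":
        return max_intensity(bit_depth) - vals
    return vals


def quant_score(
    channel: np.ndarray,
    mask: np.ndarray,
    bit_depth: int = 8,
    measure: str = "magnitude",
) -> QuantResult:
    """Pixel-mean quantification score over the segmented foreground.

    ``s = sum of stain magnitude over foreground / number of foreground
    pixels``; the foreground is the set of mask pixels equal to 0.
    """
    fg = _foreground(channel, mask, bit_depth)
    n_fg = int(fg.sum())
    if n_fg == 0:
        return QuantResult(float("nan"), 0, 0, "pixel-mean", empty=True)
    mags = _magnitudes(channel, measure, bit_depth)
    return QuantResult(float(mags[fg].mean()), n_fg, 0, "pixel-mean")


def cell_mean_score(
    channel: np.ndarray,
    mask: np.ndarray,
    bit_depth: int = 8,
    measure: str = "magnitude",
) -> QuantResult:
    """Mean over cells of the per-cell mean stain magnitude.

    Cells are 8-connected foreground components; each contributes its
    own mean with equal weight, so the score differs from the pixel mean
    whenever cell sizes and stain levels covary.
    """
    fg = _foreground(channel, mask, bit_depth)
    n_fg = int(fg.sum())
    if n_fg == 0:
        return QuantResult(float("nan"), 0, 0, "cell-mean", empty=True)
    labels, n_cells = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    mags = _magnitudes(channel, measure, bit_depth)
    cell_means = ndimage.mean(mags, labels=labels, index=np.arange(1, n_cells + 1))
    return QuantResult(float(np.mean(cell_means)), n_fg, int(n_cells), "cell-mean")
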