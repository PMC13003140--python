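"""Point-prompt generation from the instrument score map.

The SI map is min–max normalized per image, binarized with a size-derived
threshold (0.65 when instruments cover roughly 35% of the image, 0.85 for
roughly 15%), split into connected components, and each component contributes
one positive prompt at its SI argmax.  An optional negative prompt marks the
lowest-SI pixel of the image center, useful for modalities whose frames carry
a dark information border.  Coordinates are (row, col), 0-based, origin at the
top-left; ties resolve in row-major order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from skimage import measure

from .anomaly import ScoreMap

Coord = Tuple[int, int]


@dataclass
class PromptSet:
    """Positive (and optional negative) pixel prompts for a segmenter."""

    positives: List[Coord]
    negative: Optional[Coord]
    threshold: float
    component_labels: np.ndarray  # int raster, 0 = background
    no_instrument: bool = False

    @property
    def si_support(self) -> np.ndarray:
        """Binary support of the thresholded SI map (used for mask selection)."""
        return self.component_labels > 0


def binarize_si(si: ScoreMap, threshold: float) -> np.ndarray:
    """Pixels with SI >= threshold; the SI map must be normalized."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if not si.normalized:
        raise ValueError("SI map must be normalized to [0, 1]")
    return si.values >= threshold


def connected_components(binary: np.ndarray, connectivity: int = 8):
    """Label a binary mask; returns (labels, count).  Default 8-connectivity."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels = measure.label(
        np.asarray(binary, dtype=bool), connectivity=1 if connectivity == 4 else 2
    )
    return labels, int(labels.max())


def _flat_argmax(values: np.ndarray, flat_indices: np.ndarray) -> Coord:
    best = flat_indices[int(np.argmax(values.ravel()[flat_indices]))]
    r, c = np.unravel_index(int(best), values.shape)
    return int(r), int(c)


def select_prompts(si: ScoreMap, threshold: float, multi: bool = True) -> PromptSet:
    """Derive point prompts from the SI map.

    The map is min–max rescaled per image before thresholding so that every
    frame with any SI contrast can yield a prompt.  ``multi=False`` returns a
    single prompt at the global argmax; ``multi=True`` returns one prompt per
    connected component at that component's argmax.  If no pixel clears the
    threshold the single global argmax is used as a fallback; an all-zero SI
    map yields an empty prompt set flagged ``no_instrument``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if not si.normalized:
        raise ValueError("SI map must be normalized to [0, 1]")
    v = si.values
    if v.max() <= 0:
        return PromptSet(
            positives=[],
            negative=None,
            threshold=threshold,
            component_labels=np.zeros(v.shape, dtype=int),
            no_instrument=True,
        )
    vmin, vmax = float(v.min()), float(v.max())
    vn = (v - vmin) / (vmax - vmin) if vmax > vmin else np.ones_like(v)
    labels, n = connected_components(vn >= threshold, connectivity=8)

    if multi and n > 0:
        positives = []
        for comp in range(1, n + 1):
            flat = np.flatnonzero(labels.ravel() == comp)
            positives.append(_flat_argmax(v, flat))
    else:
        # single-prompt mode, or fallback when binarization is empty
        flat = np.arange(v.size)
        positives = [_flat_argmax(v, flat)]
    return PromptSet(
        positives=positives,
        negative=None,
        threshold=threshold,
        component_labels=labels,
    )


def select_negative_prompt(si: ScoreMap, central_fraction: float = 0.5) -> Coord:
    """Argmin of SI restricted to the centered window (row-major tie-break).

    ``central_fraction`` is the window side length as a fraction of each image
    dimension; the default 0.5 restricts to the central half in each axis.
    """
    if not 0 < central_fraction <= 1:
        raise ValueError("central_fraction must lie in (0, 1]")
    H, W = si.shape
    h = max(1, int(round(H * central_fraction)))
    w = max(1, int(round(W * central_fraction)))
    r0, c0 = (H - h) // 2, (W - w) // 2
    sub = si.values[r0 : r0 + h, c0 : c0 + w]
    i = int(np.argmin(sub))
    r, c = np.unravel_index(i, sub.shape)
    return int(r0 + r), int(c0 + c)
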