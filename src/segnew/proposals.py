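"""Promptable-segmenter contract, reference backend, and mask selection.

A backend takes an image plus a prompt set and returns exactly three candidate
binary masks with backend confidences (the contract of promptable foundation
segmenters).  The shipped reference backend is a deterministic seeded
region grower at three nested tolerances; an external promptable segmenter can
be registered under its own name.  The final mask is the proposal with the
highest overlap score against the binarized SI support, which replaces the
backend's own confidence ranking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure

from .prompting import PromptSet

BackendFn = Callable[..., "MaskProposalSet"]
_BACKENDS: Dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def available_backends() -> List[str]:
    return sorted(_BACKENDS)


@dataclass
class MaskProposalSet:
    """Exactly three candidate masks with backend confidences."""

    masks: List[np.ndarray]  # three bool rasters
    confidences: Tuple[float, float, float]
    prompts: PromptSet
    no_instrument: bool = False

    def __post_init__(self) -> None:
        if len(self.masks) != 3:
            raise ValueError("a proposal set holds exactly three masks")
        self.masks = [np.asarray(m, dtype=bool) for m in self.masks]
        shapes = {m.shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError("proposal masks must share one shape")
        conf = tuple(float(c) for c in self.confidences)
        if any(not 0 <= c <= 1 for c in conf):
            raise ValueError("confidences must lie in [0, 1]")
        self.confidences = conf  # type: ignore[assignment]


@dataclass
class SegmentationResult:
    """Selected mask plus the three per-proposal selection scores."""

    mask: np.ndarray
    selected_index: int  # 1-based, in {1, 2, 3}
    scores: Tuple[float, float, float]
    prompts: PromptSet


def _channel_distance(image: np.ndarray, seed: Tuple[int, int]) -> np.ndarray:
    """Per-pixel distance to the seed's value (Euclidean over channels)."""
    if image.ndim == 2:
        return np.abs(image - image[seed])
    diff = image - image[seed[0], seed[1], :]
    return np.sqrt((diff * diff).sum(axis=-1))


def _grown_region(image: np.ndarray, seed: Tuple[int, int], tol: float) -> np.ndarray:
    """Connected region around the seed whose values lie within ``tol`` of it.

    Membership is a global threshold on the distance to the seed value, so
    regions are monotone (nested) in the tolerance.
    """
    within = _channel_distance(image, seed) <= tol
    labels = measure.label(within, connectivity=2)
    return labels == labels[seed]


def region_grow_backend(
    image: np.ndarray,
    prompts: PromptSet,
    tolerances: Optional[Sequence[float]] = None,
    base_tolerance_frac: float = 0.08,
) -> MaskProposalSet:
    """Deterministic reference backend: seeded region growing, 3 tolerances.

    Mask i is the union over positive prompts of the connected region whose
    values differ from the seed value by at most tolerance i, minus the region
    grown from the negative prompt (computed at the largest tolerance so the
    three masks stay nested), with positive prompt pixels always re-included.
    Default tolerances are {1, 2, 4} x 0.08 of the image's value range.
    Confidences are 1/(1 + tolerance) rescaled to [0, 1] (tighter masks get
    higher backend confidence).
    """
    img = np.asarray(image, dtype=np.float64)
    if tolerances is None:
        vrange = float(img.max() - img.min()) if img.size else 0.0
        t = base_tolerance_frac * vrange if vrange > 0 else 1e-6
        tolerances = (t, 2 * t, 4 * t)
    tols = [float(t) for t in tolerances]
    if len(tols) != 3 or not (tols[0] < tols[1] < tols[2]):
        raise ValueError("tolerances must be three strictly increasing values")

    shape = img.shape[:2]
    if not prompts.positives:
        empty = np.zeros(shape, dtype=bool)
        return MaskProposalSet(
            masks=[empty.copy() for _ in range(3)],
            confidences=(0.0, 0.0, 0.0),
            prompts=prompts,
            no_instrument=True,
        )

    neg = (
        _grown_region(img, prompts.negative, tols[-1])
        if prompts.negative is not None
        else np.zeros(shape, dtype=bool)
    )
    masks = []
    for tol in tols:
        m = np.zeros(shape, dtype=bool)
        for seed in prompts.positives:
            m |= _grown_region(img, seed, tol)
        m &= ~neg
        for seed in prompts.positives:  # positive prompts are always inside
            m[seed] = True
        masks.append(m)

    raw = 1.0 / (1.0 + np.asarray(tols))
    conf = (raw - raw.min()) / (raw.max() - raw.min())
    return MaskProposalSet(masks=masks, confidences=tuple(conf), prompts=prompts)


register_backend("region-grow", region_grow_backend)


def propose_masks(
    image: np.ndarray, prompts: PromptSet, backend: str = "region-grow", **params
) -> MaskProposalSet:
    """Query a registered backend; empty prompt sets short-circuit to three
    empty masks (the no-instrument path)."""
    if not prompts.positives:
        shape = np.asarray(image).shape[:2]
        empty = np.zeros(shape, dtype=bool)
        return MaskProposalSet(
            masks=[empty.copy() for _ in range(3)],
            confidences=(0.0, 0.0, 0.0),
            prompts=prompts,
            no_instrument=True,
        )
    fn = _BACKENDS.get(backend)
    if fn is None:
        raise ValueError(f"unknown backend: {backend!r}")
    return fn(image, prompts, **params)


def si_overlap_score(mask: np.ndarray, si_bin: np.ndarray) -> float:
    """IoU between a candidate mask and the binarized SI support.

    This is the selection score that replaces the backend's own confidence.
    Both-empty pairs score 0 by convention: an empty proposal never wins.
    """
    a = np.asarray(mask, dtype=bool)
    b = np.asarray(si_bin, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def select_mask(proposals: MaskProposalSet, si_bin: np.ndarray) -> SegmentationResult:
    """Pick the proposal with the highest SI-overlap score.

    Ties break first by higher backend confidence, then by lower index.
    """
    scores = tuple(si_overlap_score(m, si_bin) for m in proposals.masks)
    best = max(scores)
    candidates = [i for i, s in enumerate(scores) if s == best]
    if len(candidates) > 1:
        top_conf = max(proposals.confidences[i] for i in candidates)
        candidates = [i for i in candidates if proposals.confidences[i] == top_conf]
    idx = candidates[0]
    return SegmentationResult(
        mask=proposals.masks[idx],
        selected_index=idx + 1,
        scores=scores,
        prompts=proposals.prompts,
    )
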