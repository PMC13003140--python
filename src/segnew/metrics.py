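"""Evaluation metrics: IoU, DICE, normalized surface distance, prompt accuracy.

Overlap metrics alone are misleading for small structures such as instrument
cross-sections, so the boundary-based normalized surface distance (NSD) with a
pixel tolerance tau complements them.  Conventions: for *evaluation*, a pair
of empty masks counts as perfect agreement (1.0) — agreement on absence —
which deliberately differs from the mask-selection convention where an empty
pair scores 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import ndimage

from .prompting import PromptSet
from .proposals import SegmentationResult


def _pair(a, b):
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union; both empty -> 1.0 (agreement on absence)."""
    a, b = _pair(a, b)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """DICE coefficient; both empty -> 1.0."""
    a, b = _pair(a, b)
    total = a.sum() + b.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / total)


_CROSS = ndimage.generate_binary_structure(2, 1)  # 4-connectivity


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Mask pixels with at least one 4-neighbor outside the mask.

    The image border counts as outside, so a mask touching the border has a
    boundary there.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    eroded = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~eroded


def nsd(a: np.ndarray, b: np.ndarray, tau: float) -> float:
    """Normalized surface distance at pixel tolerance tau.

    (|S_A within tau of S_B| + |S_B within tau of S_A|) / (|S_A| + |S_B|),
    with exact Euclidean distances between pixel centers.  Both boundaries
    empty -> 1.0.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    a, b = _pair(a, b)
    sa = boundary_pixels(a)
    sb = boundary_pixels(b)
    na, nb = int(sa.sum()), int(sb.sum())
    if na + nb == 0:
        return 1.0

    def border_region(s: np.ndarray) -> np.ndarray:
        if not s.any():
            return np.zeros_like(s)
        return ndimage.distance_transform_edt(~s) <= tau

    num = int((sa & border_region(sb)).sum()) + int((sb & border_region(sa)).sum())
    return float(num / (na + nb))


def prompt_accuracy(
    prompt_sets: Sequence[PromptSet], reference_masks: Sequence[np.ndarray]
) -> float:
    """Fraction of frames whose prompt lands inside the reference mask.

    A frame is a hit when at least one positive prompt pixel lies inside the
    reference mask.  A frame with an empty reference mask is a hit exactly
    when no positive prompt was emitted (correct absence call).
    """
    if len(prompt_sets) != len(reference_masks):
        raise ValueError("prompt_sets and reference_masks must have equal length")
    if len(prompt_sets) == 0:
        raise ValueError("no frames to evaluate")
    hits = 0
    for ps, ref in zip(prompt_sets, reference_masks):
        ref = np.asarray(ref, dtype=bool)
        if ref.any():
            hits += any(ref[r, c] for r, c in ps.positives)
        else:
            hits += not ps.positives
    return hits / len(prompt_sets)


@dataclass
class EvalReport:
    """Per-frame metrics plus dataset-level means and population SDs."""

    per_frame: List[Dict[str, float]]
    miou: float
    mdice: float
    mnsd: float
    pacc: float
    sd: Dict[str, float]
    tau: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_frame": self.per_frame,
                "miou": self.miou,
                "mdice": self.mdice,
                "mnsd": self.mnsd,
                "pacc": self.pacc,
                "sd": self.sd,
                "tau": self.tau,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, s: str) -> "EvalReport":
        d = json.loads(s)
        return cls(
            per_frame=d["per_frame"],
            miou=d["miou"],
            mdice=d["mdice"],
            mnsd=d["mnsd"],
            pacc=d["pacc"],
            sd=d["sd"],
            tau=d["tau"],
        )


def evaluate(
    predictions: Sequence[SegmentationResult],
    references: Sequence[np.ndarray],
    tau: float,
) -> EvalReport:
    """Frame-wise IoU/DICE/NSD/prompt hit plus arithmetic means and SDs."""
    if len(predictions) != len(references):
        raise ValueError("predictions and references must have equal length")
    if len(predictions) == 0:
        raise ValueError("no frames to evaluate")
    per_frame = []
    for pred, ref in zip(predictions, references):
        ref = np.asarray(ref, dtype=bool)
        if ref.any():
            hit = any(ref[r, c] for r, c in pred.prompts.positives)
        else:
            hit = not pred.prompts.positives
        per_frame.append(
            {
                "iou": iou(pred.mask, ref),
                "dice": dice(pred.mask, ref),
                "nsd": nsd(pred.mask, ref, tau),
                "prompt_hit": bool(hit),
            }
        )
    ious = np.array([f["iou"] for f in per_frame])
    dices = np.array([f["dice"] for f in per_frame])
    nsds = np.array([f["nsd"] for f in per_frame])
    hits = np.array([f["prompt_hit"] for f in per_frame], dtype=float)
    return EvalReport(
        per_frame=per_frame,
        miou=float(ious.mean()),
        mdice=float(dices.mean()),
        mnsd=float(nsds.mean()),
        pacc=float(hits.mean()),
        sd={
            "iou": float(ious.std()),
            "dice": float(dices.std()),
            "nsd": float(nsds.std()),
        },
        tau=float(tau),
    )
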