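"""Memory-bank anomaly localization.

A memory bank of nominal (instrument-free) patch features is built once, and
query patches are scored by their Euclidean distance to the nearest bank
vector — anything unlike normal anatomy scores high.  The bank is subsampled
with greedy k-center (farthest-point) coreset selection, and raw anomaly maps
are brought to a common [0, 1] scale by min–max calibration on a small set of
example images so that fixed binarization thresholds are meaningful.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import cdist

from .features import (
    FeatureExtractorSpec,
    PatchFeatureGrid,
    aggregate_neighborhood,
    extract_features,
)

SCORE_KINDS = ("anomaly", "filter", "si")


@dataclass
class ScoreMap:
    """Per-pixel non-negative score raster (anomaly map, filter, or SI map)."""

    values: np.ndarray
    kind: str
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("score map must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("score map must be finite")
        if np.any(v < 0):
            raise ValueError("score map must be non-negative")
        if self.kind not in SCORE_KINDS:
            raise ValueError(f"unknown score-map kind: {self.kind!r}")
        if self.normalized and np.any(v > 1.0):
            raise ValueError("normalized score map must lie in [0, 1]")
        self.values = v

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass
class MemoryBank:
    """Nominal patch features plus the extractor spec and calibration state."""

    vectors: np.ndarray  # (N, D)
    extractor: FeatureExtractorSpec
    coreset_ratio: float
    seed: int
    norm_lo: Optional[float] = None
    norm_hi: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1:
            raise ValueError("bank needs at least one feature vector")
        if self.norm_lo is not None and self.norm_hi is not None:
            if not self.norm_hi > self.norm_lo:
                raise ValueError("norm_hi must exceed norm_lo")
        self.vectors = v

    @property
    def n_features(self) -> int:
        return int(self.vectors.shape[1])

    @property
    def calibrated(self) -> bool:
        return self.norm_lo is not None and self.norm_hi is not None


def coreset_select(
    features: np.ndarray,
    ratio: float,
    seed: int = 0,
    start_index: Optional[int] = None,
) -> List[int]:
    """Greedy k-center (farthest-point) subset of row vectors.

    Selects ``max(1, round(ratio * M))`` distinct indices.  Each step adds the
    point with the largest Euclidean distance to the current selection; the
    start point is a seeded uniform draw unless ``start_index`` is given.
    Ties in the farthest-point argmax resolve to the lowest index.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("features must be a non-empty M x D matrix")
    if not 0 < ratio <= 1:
        raise ValueError("ratio must be in (0, 1]")
    M = X.shape[0]
    n = max(1, int(round(ratio * M)))
    if n >= M:
        return list(range(M))
    if start_index is None:
        rng = np.random.default_rng(seed)
        start_index = int(rng.integers(M))
    selected = [int(start_index)]
    mindist = np.linalg.norm(X - X[start_index], axis=1)
    for _ in range(n - 1):
        nxt = int(np.argmax(mindist))
        selected.append(nxt)
        mindist = np.minimum(mindist, np.linalg.norm(X - X[nxt], axis=1))
    return selected


def _pooled_features(
    images: Sequence[np.ndarray], spec: FeatureExtractorSpec
) -> np.ndarray:
    rows = []
    for img in images:
        grid = aggregate_neighborhood(extract_features(img, spec), spec.window)
        rows.append(grid.features.reshape(-1, grid.n_features))
    return np.vstack(rows)


def build_memory_bank(
    nominal_images: Sequence[np.ndarray],
    spec: FeatureExtractorSpec,
    ratio: float = 0.1,
    seed: int = 0,
) -> MemoryBank:
    """Pool aggregated patch features over nominal images and coreset them."""
    if len(nominal_images) == 0:
        raise ValueError("no nominal data")
    pooled = _pooled_features(nominal_images, spec)
    idx = coreset_select(pooled, ratio, seed=seed)
    return MemoryBank(
        vectors=pooled[idx], extractor=spec, coreset_ratio=float(ratio), seed=int(seed)
    )


def score_patches(bank: MemoryBank, grid: PatchFeatureGrid, k: int = 1) -> np.ndarray:
    """Per-cell anomaly score against the bank.

    ``k=1`` (default): distance to the single nearest bank vector.  ``k > 1``:
    mean distance to the k nearest vectors (optional mode; k is clipped to the
    bank size).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if grid.n_features != bank.n_features:
        raise ValueError(
            f"feature dimension mismatch: grid D={grid.n_features}, "
            f"bank D={bank.n_features}"
        )
    hp, wp, D = grid.features.shape
    Q = grid.features.reshape(-1, D)
    scores = np.empty(Q.shape[0], dtype=np.float64)
    k = min(k, bank.vectors.shape[0])
    chunk = max(1, int(4e6 // max(1, bank.vectors.shape[0])))
    for i in range(0, Q.shape[0], chunk):
        d = cdist(Q[i : i + chunk], bank.vectors)
        if k == 1:
            scores[i : i + chunk] = d.min(axis=1)
        else:
            scores[i : i + chunk] = np.partition(d, k - 1, axis=1)[:, :k].mean(axis=1)
    return scores.reshape(hp, wp)


def anomaly_map(
    score_grid: np.ndarray,
    source_shape: Tuple[int, int],
    smoothing_sigma: float = 4.0,
    pad_mode: str = "nearest",
) -> ScoreMap:
    """Upsample a cell-score grid to pixel resolution and smooth it.

    Bilinear upsampling to ``source_shape`` followed by a Gaussian blur of
    ``smoothing_sigma`` pixels (0 disables).  ``pad_mode`` is passed to the
    Gaussian filter; ``"wrap"`` preserves total mass exactly.
    """
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")
    g = np.asarray(score_grid, dtype=np.float64)
    if g.shape == tuple(source_shape):
        up = g
    else:
        from skimage.transform import resize

        up = resize(
            g, source_shape, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    if smoothing_sigma > 0:
        up = gaussian_filter(up, smoothing_sigma, mode=pad_mode)
    return ScoreMap(values=np.clip(up, 0.0, None), kind="anomaly")


def raw_anomaly_map(
    bank: MemoryBank,
    image: np.ndarray,
    smoothing_sigma: float = 4.0,
    k: int = 1,
) -> ScoreMap:
    """Convenience: extract, aggregate, score and upsample in one call."""
    grid = aggregate_neighborhood(
        extract_features(image, bank.extractor), bank.extractor.window
    )
    sg = score_patches(bank, grid, k=k)
    return anomaly_map(sg, image.shape[:2], smoothing_sigma=smoothing_sigma)


def calibrate_normalization(
    bank: MemoryBank,
    calibration_images: Sequence[np.ndarray],
    smoothing_sigma: float = 4.0,
    k: int = 1,
) -> MemoryBank:
    """Fit min–max score-normalization bounds on calibration images.

    The calibration set should contain a few images *with* instruments so
    the upper bound reflects genuine anomalies.  Returns a new bank; the
    upper bound is epsilon-widened if the observed range is degenerate.
    """
    if len(calibration_images) == 0:
        raise ValueError("need at least one calibration image")
    lo = math.inf
    hi = -math.inf
    for img in calibration_images:
        amap = raw_anomaly_map(bank, img, smoothing_sigma=smoothing_sigma, k=k)
        lo = min(lo, float(amap.values.min()))
        hi = max(hi, float(amap.values.max()))
    if hi <= lo:
        hi = lo + 1e-8
    return dataclasses.replace(bank, norm_lo=lo, norm_hi=hi)


def normalize_map(smap: ScoreMap, bank: MemoryBank) -> ScoreMap:
    """Affine rescale by the bank's calibration bounds, clipped to [0, 1]."""
    if not bank.calibrated:
        raise ValueError("bank is not calibrated: run calibrate_normalization first")
    v = (smap.values - bank.norm_lo) / (bank.norm_hi - bank.norm_lo)
    return ScoreMap(values=np.clip(v, 0.0, 1.0), kind=smap.kind, normalized=True)


# ---------------------------------------------------------------------------
# persistence


def save_bank(bank: MemoryBank, path) -> None:
    meta = {
        "extractor": bank.extractor.model_dump(),
        "coreset_ratio": bank.coreset_ratio,
        "seed": bank.seed,
        "norm_lo": bank.norm_lo,
        "norm_hi": bank.norm_hi,
    }
    np.savez(path, vectors=bank.vectors, meta=np.asarray(json.dumps(meta, sort_keys=True)))


def load_bank(path) -> MemoryBank:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        return MemoryBank(
            vectors=z["vectors"],
            extractor=FeatureExtractorSpec(**meta["extractor"]),
            coreset_ratio=meta["coreset_ratio"],
            seed=meta["seed"],
            norm_lo=meta["norm_lo"],
            norm_hi=meta["norm_hi"],
        )


def bank_hash(bank: MemoryBank) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(bank.vectors).tobytes())
    h.update(
        json.dumps(
            {
                "extractor": bank.extractor.model_dump(),
                "coreset_ratio": bank.coreset_ratio,
                "seed": bank.seed,
                "norm_lo": bank.norm_lo,
                "norm_hi": bank.norm_hi,
            },
            sort_keys=True,
        ).encode()
    )
    return h.hexdigest()
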