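"""Patch-level feature extraction.

Turns an image into a spatial grid of locally aggregated feature vectors, the
input representation for memory-bank anomaly scoring.  The default extractor
("multiscale-stats") needs no pretrained weights: per grid cell and per channel
it computes the mean, the standard deviation, and a gradient-orientation
histogram, at every requested downsampling scale, and concatenates everything.
A deep backbone can be plugged in through :func:`register_extractor` as long as
it honours the same grid contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Dict, Tuple

import numpy as np
from pydantic import BaseModel, Field, field_validator


class FeatureExtractorSpec(BaseModel):
    """Configuration of a patch-feature extractor.

    Parameters
    ----------
    name:
        Registered extractor name (default ``"multiscale-stats"``).
    scales:
        Integer downsampling factors, each >= 1.  The default ``(1, 2)``
        mirrors a coarse two-level feature hierarchy.
    window:
        Odd neighborhood size (in grid cells) used by
        :func:`aggregate_neighborhood`.
    params:
        Free-form extractor parameters.  The default extractor reads
        ``stride`` (pixels per grid cell, default 4) and ``grad_bins``
        (orientation-histogram bins, default 8; 0 disables the histogram).
    """

    name: str = "multiscale-stats"
    scales: Tuple[int, ...] = (1, 2)
    window: int = 3
    params: Dict[str, Any] = Field(default_factory=dict)

    @field_validator("scales")
    @classmethod
    def _scales_valid(cls, v: Tuple[int, ...]) -> Tuple[int, ...]:
        if len(v) == 0:
            raise ValueError("scales must be non-empty")
        if any(int(s) < 1 for s in v):
            raise ValueError("every scale must be >= 1")
        return tuple(int(s) for s in v)

    @field_validator("window")
    @classmethod
    def _window_valid(cls, v: int) -> int:
        if v < 1 or v % 2 == 0:
            raise ValueError("window must be odd and >= 1")
        return v

    @property
    def stride(self) -> int:
        return int(self.params.get("stride", 4))

    @property
    def grad_bins(self) -> int:
        return int(self.params.get("grad_bins", 8))


@dataclass
class PatchFeatureGrid:
    """H' x W' grid of D-dimensional patch-feature vectors.

    ``H' = ceil(H / stride)`` and ``W' = ceil(W / stride)`` where ``(H, W)``
    is ``source_shape`` in pixels.
    """

    features: np.ndarray  # (H', W', D) float64
    stride: int
    source_shape: Tuple[int, int]

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64)
        if f.ndim != 3:
            raise ValueError("features must be a 3-D (H', W', D) array")
        if not np.all(np.isfinite(f)):
            raise ValueError("features must be finite")
        H, W = self.source_shape
        hp, wp = math.ceil(H / self.stride), math.ceil(W / self.stride)
        if f.shape[:2] != (hp, wp):
            raise ValueError(
                f"grid shape {f.shape[:2]} inconsistent with "
                f"source_shape {self.source_shape} and stride {self.stride}"
            )
        self.features = f

    @property
    def n_features(self) -> int:
        return int(self.features.shape[2])

    def save(self, path) -> None:
        np.savez(
            path,
            features=self.features,
            stride=np.asarray(self.stride),
            source_shape=np.asarray(self.source_shape),
        )

    @classmethod
    def load(cls, path) -> "PatchFeatureGrid":
        with np.load(path) as z:
            return cls(
                features=z["features"],
                stride=int(z["stride"]),
                source_shape=tuple(int(x) for x in z["source_shape"]),
            )


ExtractorFn = Callable[[np.ndarray, FeatureExtractorSpec], PatchFeatureGrid]
_EXTRACTORS: Dict[str, ExtractorFn] = {}


def register_extractor(name: str, fn: ExtractorFn) -> None:
    """Register a contract-compatible extractor (image, spec) -> grid."""
    _EXTRACTORS[name] = fn


def _as_float_channels(image: np.ndarray) -> list[np.ndarray]:
    if image.ndim == 2:
        chans = [image]
    elif image.ndim == 3 and image.shape[2] == 3:
        chans = [image[..., i] for i in range(3)]
    else:
        raise ValueError("image must be single-channel (H, W) or 3-channel (H, W, 3)")
    out = []
    for c in chans:
        if np.issubdtype(c.dtype, np.integer):
            out.append(c.astype(np.float64) / np.iinfo(c.dtype).max)
        else:
            out.append(c.astype(np.float64))
    return out


def _block_mean(a: np.ndarray, s: int) -> np.ndarray:
    """Downsample by factor ``s`` with truncated block means at the edges."""
    if s == 1:
        return a.astype(np.float64)
    h, w = a.shape
    ri = np.arange(0, h, s)
    ci = np.arange(0, w, s)
    sums = np.add.reduceat(np.add.reduceat(a.astype(np.float64), ri, axis=0), ci, axis=1)
    rcount = np.minimum(ri + s, h) - ri
    ccount = np.minimum(ci + s, w) - ci
    return sums / (rcount[:, None] * ccount[None, :])


def _cell_bounds(extent: int, stride: int, scale: int, n_cells: int):
    """Start/end indices (in scale-downsampled coordinates) for each grid cell."""
    es = math.ceil(extent / scale)
    idx = np.arange(n_cells)
    starts = np.minimum((idx * stride) // scale, es - 1)
    ends = np.minimum(-(-((idx + 1) * stride) // scale), es)
    ends = np.maximum(ends, starts + 1)
    return starts, ends


def _integral(a: np.ndarray) -> np.ndarray:
    h, w = a.shape
    out = np.zeros((h + 1, w + 1), dtype=np.float64)
    out[1:, 1:] = a.cumsum(axis=0).cumsum(axis=1)
    return out


def _box_sums(integral, r0, r1, c0, c1) -> np.ndarray:
    return (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    )


def _multiscale_stats(image: np.ndarray, spec: FeatureExtractorSpec) -> PatchFeatureGrid:
    channels = _as_float_channels(image)
    H, W = image.shape[:2]
    stride = spec.stride
    if stride < 1:
        raise ValueError("stride must be >= 1")
    hp, wp = math.ceil(H / stride), math.ceil(W / stride)
    bins = spec.grad_bins

    planes: list[np.ndarray] = []
    for s in spec.scales:
        r0, r1 = _cell_bounds(H, stride, s, hp)
        c0, c1 = _cell_bounds(W, stride, s, wp)
        counts = (r1 - r0)[:, None] * (c1 - c0)[None, :]
        for ch in channels:
            chs = _block_mean(ch, s)
            sums = _box_sums(_integral(chs), r0, r1, c0, c1)
            sq = _box_sums(_integral(chs * chs), r0, r1, c0, c1)
            mean = sums / counts
            msq = sq / counts
            var = msq - mean * mean
            # E[x^2] - E[x]^2 cancels catastrophically for near-constant
            # blocks; the integral-image cumsums accumulate rounding error
            # of order (pixels summed) * eps * E[x^2], so anything below
            # that is numerical noise, not variance
            tol = chs.size * 8 * np.finfo(np.float64).eps * msq
            var = np.where(var <= tol, 0.0, var)
            planes.append(mean)
            planes.append(np.sqrt(var))
            if bins > 0:
                if min(chs.shape) >= 2:
                    gy, gx = np.gradient(chs)
                else:  # degenerate 1-pixel extent: no gradient defined
                    gy = np.zeros_like(chs)
                    gx = np.zeros_like(chs)
                mag = np.hypot(gx, gy)
                theta = np.arctan2(gy, gx)  # [-pi, pi]
                b = np.clip(
                    np.floor((theta + np.pi) / (2 * np.pi) * bins).astype(int),
                    0,
                    bins - 1,
                )
                for k in range(bins):
                    wmap = np.where(b == k, mag, 0.0)
                    planes.append(_box_sums(_integral(wmap), r0, r1, c0, c1) / counts)

    features = np.stack(planes, axis=-1)
    return PatchFeatureGrid(features=features, stride=stride, source_shape=(H, W))


register_extractor("multiscale-stats", _multiscale_stats)


def extract_features(image: np.ndarray, spec: FeatureExtractorSpec) -> PatchFeatureGrid:
    """Extract a patch-feature grid from a single- or 3-channel image.

    Raises
    ------
    ValueError
        ``"degenerate input"`` for an empty image, ``"unknown extractor"``
        for an unregistered extractor name.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("degenerate input: empty image")
    if not np.all(np.isfinite(img.astype(np.float64, copy=False))):
        raise ValueError("image must contain only finite values")
    fn = _EXTRACTORS.get(spec.name)
    if fn is None:
        raise ValueError(f"unknown extractor: {spec.name!r}")
    return fn(img, spec)


def aggregate_neighborhood(
    grid: PatchFeatureGrid, window: int, mode: str = "truncate"
) -> PatchFeatureGrid:
    """Average each cell's feature vector over a window x window neighborhood.

    ``mode="truncate"`` (default) averages over the valid sub-window at the
    grid edges; ``mode="wrap"`` uses cyclic padding, which preserves the
    per-feature global mean exactly.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if mode not in ("truncate", "wrap"):
        raise ValueError(f"unknown padding mode: {mode!r}")
    if window == 1:
        return PatchFeatureGrid(
            features=grid.features.copy(),
            stride=grid.stride,
            source_shape=grid.source_shape,
        )
    from scipy.ndimage import uniform_filter

    f = grid.features
    if mode == "wrap":
        out = uniform_filter(f, size=(window, window, 1), mode="wrap")
    else:
        area = float(window * window)
        sums = uniform_filter(f, size=(window, window, 1), mode="constant", cval=0.0) * area
        ones = np.ones(f.shape[:2], dtype=np.float64)
        counts = uniform_filter(ones, size=window, mode="constant", cval=0.0) * area
        out = sums / counts[..., None]
    return PatchFeatureGrid(features=out, stride=grid.stride, source_shape=grid.source_shape)
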