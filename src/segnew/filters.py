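"""Domain filters and the instrument score map.

The anomaly map flags *anything* unseen; the domain filter F(I) downweights
pixels unlikely to belong to an instrument.  For true-color scenes, where
instruments are (dark) gray and tissue is reddish, F combines the CIELAB a*
(red–green) channel with HSV value and saturation.  For intensity modalities
(OCT, ultrasound), where the highly reflective instrument casts a near-black
shadow column that is itself anomalous, F is the normalized signal intensity,
so shadow pixels are suppressed.  The instrument score map is the pixel-wise
product SI(I) = A(I) * F(I).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color

from .anomaly import ScoreMap


@dataclass
class ColorChannels:
    """CIELAB a* plus HSV value and saturation, all at pixel resolution."""

    astar: np.ndarray  # red-green opponent channel, may be negative
    value: np.ndarray  # in [0, 1]
    saturation: np.ndarray  # in [0, 1]

    def __post_init__(self) -> None:
        for name in ("astar", "value", "saturation"):
            a = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, a)
        if np.any(self.value < 0) or np.any(self.value > 1):
            raise ValueError("value channel must lie in [0, 1]")
        if np.any(self.saturation < 0) or np.any(self.saturation > 1):
            raise ValueError("saturation channel must lie in [0, 1]")


def _as_unit_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected a 3-channel (H, W, 3) image")
    if np.issubdtype(img.dtype, np.integer):
        return img.astype(np.float64) / np.iinfo(img.dtype).max
    out = img.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("image must be finite")
    return np.clip(out, 0.0, 1.0)


def _as_intensity(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim == 3 and img.shape[2] == 1:
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError("expected a single-channel (H, W) image")
    out = img.astype(np.float64)
    if not np.all(np.isfinite(out)):
        raise ValueError("image must be finite")
    mn = out.min() if out.size else 0.0
    if mn < 0:  # offset removal for signed acquisitions
        out = out - mn
    return out


def rgb_to_channels(image: np.ndarray) -> ColorChannels:
    """Standard sRGB (D65) conversions to CIELAB a* and HSV S/V.

    8-bit (or other integer) input is autodetected by dtype and scaled to
    [0, 1]; float input is assumed to already be unit range.
    """
    rgb = _as_unit_rgb(image)
    lab = color.rgb2lab(rgb)
    hsv = color.rgb2hsv(rgb)
    return ColorChannels(astar=lab[..., 1], value=hsv[..., 2], saturation=hsv[..., 1])


def filter_rgb(image: np.ndarray) -> ScoreMap:
    """True-color instrument filter.

    F = 1 - (a*/max(a*) + V/max(V) + S/max(S)) / 3 per pixel, favouring dark,
    achromatic, non-red pixels.  Each ratio is normalized by its per-image
    maximum and clipped to [0, 1]; the a* term uses the maximum over pixels
    with a* > 0 and contributes 0 when the image has no reddish content, as
    does any channel whose maximum is 0.
    """
    ch = rgb_to_channels(image)
    pos = ch.astar[ch.astar > 0]
    if pos.size:
        ra = np.clip(ch.astar / pos.max(), 0.0, 1.0)
    else:
        ra = np.zeros_like(ch.astar)
    vmax = ch.value.max()
    rv = ch.value / vmax if vmax > 0 else np.zeros_like(ch.value)
    smax = ch.saturation.max()
    rs = ch.saturation / smax if smax > 0 else np.zeros_like(ch.saturation)
    F = np.clip(1.0 - (ra + rv + rs) / 3.0, 0.0, 1.0)
    return ScoreMap(values=F, kind="filter", normalized=True)


def filter_intensity(image: np.ndarray) -> ScoreMap:
    """Intensity filter: F = I / max(I); an all-zero image maps to all-zero F.

    Shadow-suppression guarantee: F (and hence the SI map) is exactly 0
    wherever the signal is 0.
    """
    I = _as_intensity(image)
    mx = I.max() if I.size else 0.0
    F = I / mx if mx > 0 else np.zeros_like(I)
    return ScoreMap(values=F, kind="filter", normalized=True)


def si_map(anomaly: ScoreMap, filt: ScoreMap) -> ScoreMap:
    """Instrument score map: pixel-wise product of anomaly map and filter."""
    if not anomaly.normalized:
        raise ValueError("anomaly map must be normalized before filtering")
    if anomaly.shape != filt.shape:
        raise ValueError(
            f"shape mismatch: anomaly {anomaly.shape} vs filter {filt.shape}"
        )
    return ScoreMap(values=anomaly.values * filt.values, kind="si", normalized=True)
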