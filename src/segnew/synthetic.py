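"""Seeded synthetic surgical scenes with ground-truth masks.

Two domains are emulated so the whole pipeline can be exercised without any
external data:

* ``rgb`` — endoscopy/microscopy-like scenes: a low-frequency reddish tissue
  texture with optional white specular highlights, and gray, low-saturation,
  capsule-shaped (elongated, round-capped) instruments.
* ``intensity`` — OCT-B-scan-like scenes: a dark speckled background, one to
  three bright curved tissue bands, a short bright instrument arc above the
  bands, and a near-black shadow column beneath the instrument (the instrument
  is highly reflective, so almost no signal reaches deeper tissue).  The truth
  mask covers the instrument only, never its shadow — the shadow is an imaging
  artifact, and suppressing prompts on it is exactly what the intensity filter
  is for.

Every output is a pure function of (spec, seed).  Instrument pixels receive a
quarter of the tissue speckle amplitude: metallic specular reflectors return a
much cleaner signal than diffusely scattering tissue.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import numpy as np
from PIL import Image
from pydantic import BaseModel, Field, field_validator, model_validator
from skimage import color as skcolor
from skimage.transform import resize

MANIFEST_VERSION = 1
_SHADOW_ATTENUATION = 0.02  # shadow transmission relative to unshadowed signal


class NoiseSpec(BaseModel):
    texture_scale: int = 16  # pixels per background texture cell (rgb)
    speckle_sigma: float = 0.15  # multiplicative speckle amplitude (intensity)
    highlight_count: int = 2  # specular highlight disks (rgb)

    @field_validator("texture_scale")
    @classmethod
    def _ts(cls, v):
        if v < 1:
            raise ValueError("texture_scale must be >= 1")
        return v

    @field_validator("speckle_sigma")
    @classmethod
    def _ss(cls, v):
        if v < 0:
            raise ValueError("speckle_sigma must be >= 0")
        return v


class SceneSpec(BaseModel):
    """Parameters of one synthetic scene.

    Default shapes are the pipeline working resolutions (128x128 color,
    92x256 intensity); instrument size fractions are relative to
    sqrt(H*W), so the expected truth-mask area per instrument is roughly
    width_frac * length_frac * H * W.
    """

    domain: Literal["rgb", "intensity"]
    shape: Optional[Tuple[int, int]] = None
    n_instruments: int = 1
    instrument_width_frac: Optional[float] = None
    instrument_length_frac: Optional[float] = None
    noise: NoiseSpec = Field(default_factory=NoiseSpec)
    seed: int = 0

    @field_validator("n_instruments")
    @classmethod
    def _ni(cls, v):
        if not 0 <= v <= 3:
            raise ValueError("n_instruments must be in 0..3")
        return v

    @model_validator(mode="after")
    def _fill_defaults(self):
        if self.shape is None:
            self.shape = (128, 128) if self.domain == "rgb" else (92, 256)
        if self.shape[0] < 8 or self.shape[1] < 8:
            raise ValueError("shape must be at least 8x8")
        if self.instrument_width_frac is None:
            self.instrument_width_frac = 0.08 if self.domain == "rgb" else 0.05
        if self.instrument_length_frac is None:
            self.instrument_length_frac = 0.6 if self.domain == "rgb" else 0.3
        for f in (self.instrument_width_frac, self.instrument_length_frac):
            if not 0 < f < 1:
                raise ValueError("instrument size fractions must lie in (0, 1)")
        return self


@dataclass
class ScenePair:
    """Rendered scene with its ground truth and generator-internal maps."""

    image: np.ndarray  # uint8, (H, W) or (H, W, 3)
    truth_mask: np.ndarray  # bool
    spec: SceneSpec
    instrument_masks: List[np.ndarray]  # one bool mask per instrument
    shadow_mask: Optional[np.ndarray] = None  # intensity domain only
    band_mask: Optional[np.ndarray] = None  # intensity domain only
    contrast: float = 0.0  # instrument/background contrast-to-noise statistic


def _smooth_field(rng: np.random.Generator, shape, cell: int) -> np.ndarray:
    """Low-frequency random field in [0, 1] (bicubic-upsampled coarse noise)."""
    h = max(2, math.ceil(shape[0] / cell) + 1)
    w = max(2, math.ceil(shape[1] / cell) + 1)
    coarse = rng.random((h, w))
    f = resize(coarse, shape, order=3, mode="edge", anti_aliasing=False)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _capsule_mask(shape, center, angle, length, width) -> np.ndarray:
    """Pixels within width/2 of the segment of given length through center."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    dr, dc = math.sin(angle), math.cos(angle)
    half = max(0.0, length / 2.0 - width / 2.0)  # cap-to-cap extent = length
    pr, pc = rr - center[0], cc - center[1]
    t = np.clip(pr * dr + pc * dc, -half, half)
    dist = np.hypot(pr - t * dr, pc - t * dc)
    return dist <= width / 2.0


def generate_rgb_scene(spec: SceneSpec, seed: Optional[int] = None) -> ScenePair:
    """Reddish textured tissue + specular highlights + gray capsule instruments."""
    if spec.domain != "rgb":
        raise ValueError("spec.domain must be 'rgb'")
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    H, W = spec.shape
    ts = spec.noise.texture_scale
    t1 = _smooth_field(rng, (H, W), ts)
    t2 = _smooth_field(rng, (H, W), ts)
    t3 = _smooth_field(rng, (H, W), ts)

    hue = (0.98 + 0.04 * t1) % 1.0  # near red
    sat = 0.4 + 0.5 * t2
    val = 0.3 + 0.5 * t3

    for _ in range(spec.noise.highlight_count):
        cr = rng.uniform(0.1 * H, 0.9 * H)
        cc_ = rng.uniform(0.1 * W, 0.9 * W)
        rad = rng.uniform(0.02, 0.05) * math.sqrt(H * W)
        rr, cc = np.mgrid[0:H, 0:W]
        disk = (rr - cr) ** 2 + (cc - cc_) ** 2 <= rad**2
        sat[disk] *= 0.08
        val[disk] = 0.95

    s = math.sqrt(H * W)
    length = spec.instrument_length_frac * s
    width = spec.instrument_width_frac * s
    instrument_masks: List[np.ndarray] = []
    union = np.zeros((H, W), dtype=bool)
    for _ in range(spec.n_instruments):
        mask = None
        for _attempt in range(60):
            angle = rng.uniform(0.0, math.pi)
            dr = abs(math.sin(angle)) * length / 2 + width / 2 + 2
            dc = abs(math.cos(angle)) * length / 2 + width / 2 + 2
            if 2 * dr >= H or 2 * dc >= W:
                continue
            center = (rng.uniform(dr, H - dr), rng.uniform(dc, W - dc))
            cand = _capsule_mask((H, W), center, angle, length, width)
            if not (cand & union).any() or _attempt >= 40:
                mask = cand
                break
        if mask is None:  # image too small for margins: center it axis-aligned
            mask = _capsule_mask((H, W), (H / 2, W / 2), 0.0, min(length, W - 4), width)
        base_val = rng.uniform(0.25, 0.55)
        base_sat = rng.uniform(0.02, 0.12)
        sat[mask] = base_sat
        val[mask] = base_val + 0.04 * (t3[mask] - 0.5)
        instrument_masks.append(mask)
        union |= mask

    rgb = skcolor.hsv2rgb(np.stack([hue, sat, val], axis=-1))
    img = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)

    gray = skcolor.rgb2gray(rgb)
    contrast = _contrast(gray, union, ~union)
    return ScenePair(
        image=img,
        truth_mask=union,
        spec=spec,
        instrument_masks=instrument_masks,
        contrast=contrast,
    )


def _contrast(signal: np.ndarray, instr: np.ndarray, background: np.ndarray) -> float:
    if not instr.any() or not background.any():
        return 0.0
    mu_i = float(signal[instr].mean())
    mu_b = float(signal[background].mean())
    sd_b = float(signal[background].std())
    return (mu_i - mu_b) / (sd_b + 1e-9)


def generate_intensity_scene(spec: SceneSpec, seed: Optional[int] = None) -> ScenePair:
    """Speckled B-scan: bright tissue bands, bright instrument arc, shadow column."""
    if spec.domain != "intensity":
        raise ValueError("spec.domain must be 'intensity'")
    seed = spec.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    H, W = spec.shape
    cols = np.arange(W, dtype=np.float64)
    rows = np.arange(H, dtype=np.float64)[:, None]

    band_mask = np.zeros((H, W), dtype=bool)
    band_ceiling = 0.82  # saturating blend keeps crossings below this level
    transmittance = np.ones((H, W), dtype=np.float64)
    n_bands = int(rng.integers(1, 4))
    for _ in range(n_bands):
        r0 = rng.uniform(0.52 * H, 0.85 * H)
        amp = rng.uniform(1.0, 0.06 * H)
        freq = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * math.pi)
        thick = rng.uniform(0.05 * H, 0.1 * H)
        inten = rng.uniform(0.55, 0.8)
        rc = r0 + amp * np.sin(2 * math.pi * freq * cols / W + phase)
        sigma = thick / 2.0
        profile = inten * np.exp(-((rows - rc[None, :]) ** 2) / (2 * sigma**2))
        # overlapping layers blend sub-additively, as physical backscatter
        # does, instead of summing past the instrument's brightness
        transmittance *= 1.0 - profile / band_ceiling
        band_mask |= np.abs(rows - rc[None, :]) <= sigma
    img = 0.06 + band_ceiling * (1.0 - transmittance)

    s = math.sqrt(H * W)
    length = spec.instrument_length_frac * s
    thick = spec.instrument_width_frac * s
    instrument_masks: List[np.ndarray] = []
    truth = np.zeros((H, W), dtype=bool)
    n = spec.n_instruments
    for i in range(n):
        # disjoint column slots keep multiple instruments separated
        slot_lo = i * W / n + 2
        slot_hi = (i + 1) * W / n - 2
        span = min(length, slot_hi - slot_lo - 2)
        c_lo = rng.uniform(slot_lo, max(slot_lo + 1e-6, slot_hi - span))
        c_hi = c_lo + span
        rc0 = rng.uniform(0.12 * H, 0.24 * H)
        depth = rng.uniform(-4.0, 4.0)  # arc curvature
        cc_mid = (c_lo + c_hi) / 2
        half_span = max(1.0, span / 2)
        centerline = rc0 + depth * ((cols - cc_mid) / half_span) ** 2
        in_span = (cols >= c_lo) & (cols <= c_hi)
        mask = (np.abs(rows - centerline[None, :]) <= thick / 2.0) & in_span[None, :]
        level = rng.uniform(0.9, 0.98)
        img[mask] = level
        instrument_masks.append(mask)
        truth |= mask

    # multiplicative speckle; instruments are specular -> 1/4 the amplitude
    g = rng.standard_normal((H, W))
    sig = spec.noise.speckle_sigma
    mult = np.where(truth, 1.0 + (sig / 4.0) * g, 1.0 + sig * g)
    img = np.clip(img * np.clip(mult, 0.0, None), 0.0, 1.0)

    # shadow: everything strictly below the instrument is attenuated
    shadow = np.zeros((H, W), dtype=bool)
    if truth.any():
        any_instr = truth.any(axis=0)
        bottom = np.where(any_instr, H - 1 - np.argmax(truth[::-1, :], axis=0), H)
        shadow = (rows > bottom[None, :]) & any_instr[None, :]
        img[shadow] *= _SHADOW_ATTENUATION

    background = ~truth & ~shadow
    contrast = _contrast(img, truth, background)
    img_u8 = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    return ScenePair(
        image=img_u8,
        truth_mask=truth,
        spec=spec,
        instrument_masks=instrument_masks,
        shadow_mask=shadow,
        band_mask=band_mask,
        contrast=contrast,
    )


def generate_scene(spec: SceneSpec, seed: Optional[int] = None) -> ScenePair:
    if spec.domain == "rgb":
        return generate_rgb_scene(spec, seed)
    return generate_intensity_scene(spec, seed)


def derive_seed(dataset_seed: int, index: int) -> int:
    """Stable per-image seed; appending images never reshuffles earlier ones."""
    return (int(dataset_seed) * 1_000_003 + int(index) * 7_919 + 17) % (2**31 - 1)


def _save_png(arr: np.ndarray, path: Path) -> None:
    Image.fromarray(arr).save(path)


def generate_dataset(
    spec: SceneSpec, n_nominal: int, n_anomalous: int, seed: int, out_dir
) -> dict:
    """Write nominal/, anomalous/ and masks/ PNGs plus a JSON manifest.

    Nominal images use the spec with ``n_instruments = 0``; anomalous images
    use the spec as given (forced to at least one instrument).  Per-image
    seeds derive from (seed, global index), so regeneration from the manifest
    is byte-identical.
    """
    out = Path(out_dir)
    (out / "nominal").mkdir(parents=True, exist_ok=True)
    (out / "anomalous").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    nominal_spec = spec.model_copy(update={"n_instruments": 0})
    anomalous_spec = (
        spec if spec.n_instruments > 0 else spec.model_copy(update={"n_instruments": 1})
    )

    entries = []
    for i in range(n_nominal):
        s = derive_seed(seed, i)
        pair = generate_scene(nominal_spec, s)
        rel = f"nominal/nominal_{i:04d}.png"
        _save_png(pair.image, out / rel)
        entries.append({"file": rel, "kind": "nominal", "seed": s, "mask": None})
    for j in range(n_anomalous):
        i = n_nominal + j
        s = derive_seed(seed, i)
        pair = generate_scene(anomalous_spec, s)
        rel = f"anomalous/scene_{j:04d}.png"
        mrel = f"masks/scene_{j:04d}.png"
        _save_png(pair.image, out / rel)
        _save_png((pair.truth_mask.astype(np.uint8)) * 255, out / mrel)
        entries.append(
            {
                "file": rel,
                "kind": "anomalous",
                "seed": s,
                "mask": mrel,
                "contrast": pair.contrast,
            }
        )

    manifest = {
        "version": MANIFEST_VERSION,
        "seed": int(seed),
        "nominal_spec": json.loads(nominal_spec.model_dump_json()),
        "anomalous_spec": json.loads(anomalous_spec.model_dump_json()),
        "entries": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def regenerate_dataset(manifest_path, out_dir) -> None:
    """Re-render every image of a dataset from its manifest, byte-identically."""
    manifest = json.loads(Path(manifest_path).read_text())
    out = Path(out_dir)
    nominal_spec = SceneSpec(**manifest["nominal_spec"])
    anomalous_spec = SceneSpec(**manifest["anomalous_spec"])
    for sub in ("nominal", "anomalous", "masks"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    for e in manifest["entries"]:
        spec = nominal_spec if e["kind"] == "nominal" else anomalous_spec
        pair = generate_scene(spec, e["seed"])
        _save_png(pair.image, out / e["file"])
        if e.get("mask"):
            _save_png((pair.truth_mask.astype(np.uint8)) * 255, out / e["mask"])
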