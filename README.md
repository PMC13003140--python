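# segnew

Annotation-free surgical instrument segmentation: **segment anything new**.

Surgical scenes have a convenient asymmetry: tissue looks like tissue the
whole procedure long, while instruments are the only content that is *new*
relative to instrument-free footage. `segnew` exploits this to segment
instruments without a single annotated mask:

1. **Localize anything new.** Patch features from instrument-free ("nominal")
   frames fill a memory bank (greedy k-center coreset, ratio 0.1). At
   inference, each patch's anomaly score is its distance to the nearest bank
   vector; scores are upsampled, smoothed, and min–max calibrated so that 1
   means "as anomalous as an instrument".
2. **Keep only the instrument-like.** A domain filter suppresses anomalous
   but non-instrument pixels. Color scenes: instruments are dark, gray and
   non-red, so `F = 1 − (a*/max a* + V/max V + S/max S)/3`. Intensity scenes
   (OCT/ultrasound): the instrument's shadow is just as anomalous as the
   instrument, so `F = I/max I` zeroes it out exactly. The instrument score
   map is the product `SI = A · F`.
3. **Prompt, propose, select.** The SI map is binarized (0.65 or 0.85,
   depending on expected instrument size) and each connected component
   contributes one point prompt at its maximum. A promptable-segmenter
   backend returns exactly three candidate masks; the winner is the one with
   the highest IoU against the binarized SI support — the score map, not the
   backend's confidence, gets the final word.

Everything runs from scratch: no pretrained weights, no external data. A
seeded synthetic generator emulates both domains (reddish endoscopy-like
color scenes with gray capsule instruments; speckled B-scans with bright
tissue bands, an instrument arc and its shadow) and provides ground truth for
evaluation. See [docs/methods.md](docs/methods.md) for the full model,
parameter rationale, and limitations — in particular, the hand-crafted
patch descriptor is deliberately weights-free and much weaker than deep
features, so scores are not comparable to published results.

## Worked example

```python
from segnew import (
    PipelineConfig, SceneSpec, build_memory_bank, calibrate_normalization,
    derive_seed, dice, generate_scene, iou, nsd, run_pipeline,
)

config = PipelineConfig(filter="rgb", threshold=0.65)

# a memory bank from instrument-free scenes (no annotations anywhere)
nominal_spec = SceneSpec(domain="rgb", n_instruments=0)
nominal = [generate_scene(nominal_spec, derive_seed(7, i)).image for i in range(8)]
bank = build_memory_bank(nominal, config.features, ratio=config.coreset_ratio)

# calibration only needs frames *known to contain* an instrument, not masks
instr_spec = SceneSpec(domain="rgb", n_instruments=1)
calib = [generate_scene(instr_spec, derive_seed(8, i)).image for i in range(4)]
bank = calibrate_normalization(bank, calib)

pair = generate_scene(instr_spec, derive_seed(9, 0))
out = run_pipeline(pair.image, bank, config)
print(out.prompts.positives, out.result.selected_index)
print(iou(out.mask, pair.truth_mask), dice(out.mask, pair.truth_mask))
```

Running [examples/rgb_end_to_end.py](examples/rgb_end_to_end.py) (same flow,
seed 7) prints:

```
prompts at [(32, 46), (81, 87)]
selected proposal 1 with scores 0.808, 0.808, 0.808
IoU  vs truth: 0.878
DICE vs truth: 0.935
NSD  vs truth (tau=10): 0.909
```

[examples/intensity_shadow_filter.py](examples/intensity_shadow_filter.py)
shows the shadow-suppression mechanism: on a B-scan scene the mean anomaly
score inside the shadow is 0.529, the filtered SI mean is 0.002, and the
prompt that lands in the shadow without the filter disappears with it.

## Command line

```sh
segnew simulate --domain intensity --n-nominal 50 --n-anomalous 20 --seed 0 --out ds/
segnew build-bank --nominal ds/nominal --calib ds/anomalous --out bank.npz
segnew run --image ds/anomalous/scene_0000.png --bank bank.npz --domain paso --out-dir out/
segnew evaluate --pred out/ --ref ds/masks --tau 10 --out report.json
```

Exit codes: 0 success, 2 bad input, 3 bank/config incompatibility. Domain
presets: `endovis` (rgb, threshold 0.65), `cadis` (rgb, 0.85), `paso`
(intensity, 0.85).

## Reproduction

Everything is seeded; identical seeds give bit-identical outputs (banks,
maps, masks, PNG/TIFF bytes).

```sh
python -m pytest -q tests/            # unit, property and acceptance tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script builds, per domain, a memory bank from 50 nominal
scenes, calibrates on 15 instrument scenes, and evaluates 200 held-out
instrument scenes with the default configuration. It reports prompt
accuracy, mean IoU/DICE/NSD (τ = 10 px) on the percent scale, and — for the
intensity domain — the fraction of scenes with a prompt inside the shadow,
with and without the intensity filter. The acceptance test suite
(`tests/test_acceptance.py`) pins the same study at seed 0 with explicit
bars (prompt accuracy ≥ 0.95 rgb / ≥ 0.90 intensity, mean IoU ≥ 0.70) plus
exact oracle-equivalence, equation-fidelity, metric-identity, selection,
shadow-suppression and determinism checks.

## Layout

- `src/segnew/` — library: `features`, `anomaly`, `filters`, `prompting`,
  `proposals`, `metrics`, `synthetic`, `pipeline`, `cli`
- `tests/` — oracle-based unit tests, hypothesis property tests, acceptance suite
- `scripts/acceptance.py` — headline numbers as JSON
- `examples/` — short narrative scripts
- `docs/methods.md` — methods note
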