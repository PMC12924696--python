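# fpvs

Frequency-tagging EEG (fast periodic visual stimulation, FPVS) simulation
and analysis in Python: from raw multichannel recordings through spectral
quantification — noise-corrected amplitudes, spectral Z-scores, harmonic
selection and summation, ROI and epoch-screening rules — to group
statistics, with a synthetic FPVS-EEG generator providing known ground
truth.

The paradigm: stimuli stream at a fast base rate (6 Hz) with a category
embedded periodically as every 6th stimulus (1 Hz oddball). Category-
selective activity then appears at exactly 1 Hz and harmonics in the EEG
amplitude spectrum, while the general visual response sits at 6 Hz and
harmonics. Responses are quantified per frequency bin against the local
noise floor (neighboring bins with adjacent and extreme values excluded)
and summed over significant harmonics.

## Layout

| module            | role |
|-------------------|------|
| `fpvs.synth`      | stimulation schedules, steady-state components, 1/f noise, blink/spike artifacts, cohort simulation, phase-scrambling image control |
| `fpvs.preprocess` | Butterworth bandpass, polyphase resampling, sequence cropping, ICA blink removal (adult), amplitude artifact blocking (infant), channel interpolation, symmetric-average re-referencing |
| `fpvs.spectral`   | exact-cycle epochs, condition averaging, FFT amplitude spectra, adult/infant noise recipes, baseline correction, Z-scores, harmonic selection/summation |
| `fpvs.quantify`   | infant epoch screening, ROI presets and data-driven ROI ranking, significance summaries |
| `fpvs.stats`      | balanced RM/mixed ANOVA (Greenhouse–Geisser, partial η²), BH-FDR, paired post-hocs, default-prior Bayes factors, split-half reliability, dependent-correlation comparison, effect-size/power conversion |
| `fpvs.io`         | 16-bit EDF write/read, BrainVision read, event TSVs, manifests |
| `fpvs.pipeline` / `fpvs.cli` | orchestration, YAML configs, two shipped presets (`adult_exp1`, `infant_exp2`) |

## CLI

```bash
# simulate two adult participants to EDF + event TSVs + manifests
fpvs simulate --population adult --seed 1 --out scratch/sim \
     --n-participants 2 --n-sequences 8

# run the full analysis (preprocess -> spectra -> ROIs -> stats)
fpvs analyze --population adult --in scratch/sim --out scratch/results

# or everything at once on a synthetic cohort
fpvs run-all --population infant --seed 1 --out scratch/demo

# RM-ANOVA on any tidy CSV
fpvs stats --roi-table roi.csv --within set --between age --out scratch/st
```

`--config my.yaml` replaces `--population` for custom parameterizations;
presets freeze every adult/infant parameter (0.1–100 Hz 4th-order filter,
200 Hz resampling, 36-s segments, 34-s epochs from +0.833 s, 20-/30-bin
noise recipes, Z > 1.64 harmonic selection, Z > 2.32 epoch screening over
POz/O1/Oz/O2 at 6 and 12 Hz, ±500 μV artifact blocking, ROI channel
lists).

## Library usage

```python
import numpy as np
from fpvs import synth, preprocess, spectral
from fpvs.montage import make_montage
from fpvs.spectral import ADULT_RECIPE

montage = make_montage("adult")
schedule = synth.build_sequence_schedule(6, 6, 0.833, 34, 0.833)
comps = [synth.oddball_component(1.0, montage),
         synth.base_component(2.0, montage)]
rec, truth = synth.simulate_recording(
    schedule, comps, synth.NoiseModel(noise_scale=2.0), montage,
    rate_hz=1000.0, seed=0)

rec = preprocess.bandpass_filter(rec)
rec = preprocess.resample(rec, 200.0)
seg = preprocess.crop_segments(rec, 36.0)[0]
seg = preprocess.rereference_symmetric_average(seg, montage)

epoch = spectral.epoch_exact_cycles(seg)           # 34 s, 6800 samples
spec = spectral.amplitude_spectrum(epoch)          # bins every 1/34 Hz
harmonics = spectral.harmonic_range(1.0, 15.0, overlap_fundamental_hz=6.0)
summed = spectral.sum_harmonic_chunks(spec, harmonics, ADULT_RECIPE)
print(summed.amplitude_uv.max(), summed.z.max())
```
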