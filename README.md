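# ocuclean

Detection and mitigation of ocular artifacts in multichannel EEG epochs.

Eye blinks and eye movements leak electro-oculographic (EOG) potentials into
scalp EEG at 10–100× the amplitude of cortical activity, overlapping it in
both time and frequency. For brain–computer interfaces and clinical review
this contamination must be found and removed without discarding the
underlying brain signal. `ocuclean` implements a two-phase scheme on epoched
recordings (channels × time × epochs) and a semi-simulation module that makes
every stage quantitatively testable against a known clean target.

**Detection.** Each EEG channel of each epoch is decomposed by a five-level
four-band filter cascade (per level, two low/high wavelet splits give the
LFLF/LFHF/HFLF/HFHF subbands; the cascade recurses on LFLF), and each subband
is summarized by its Pisarenko pseudospectrum
`P(f) = 1 / |e(f)ᴴ v_min|²`, where `v_min` is the eigenvector of the smallest
eigenvalue of the order-M autocorrelation matrix. Subband statistics are
averaged over channels, reduced by PCA (covariance eigenproblem, 83
components by default) and ICA (FastICA, log-cosh contrast, 83 components),
concatenated, and classified per epoch by a one-dimensional **deformable
convolutional network**: convolutions whose integer sampling grid is shifted
by learned fractional offsets, read through the triangular kernel
`GS(v, it) = max(0, 1 − |v − it|)`.

**Mitigation.** Flagged epochs are decomposed channel-wise by **empirical
mean curve decomposition** (EMCD): cubic B-spline envelopes through the
maxima and minima are averaged into a mean curve, whose iterated extraction
splits the signal into oscillatory modes plus a leftover trend (summation is
the exact inverse). The slow ocular deflection concentrates in the leftover,
which passes through a deformable-network denoiser; the retrieved signal is
the untouched modes plus the denoised trend.

**Hyperparameter search.** The network's epoch count (10–20) and learning
rate (0.1–0.9) are tuned by the **distance-sorted electric fish optimizer**
(DS-EFO): a population metaheuristic where each candidate's frequency is its
relative fitness, its amplitude an exponential moving average of frequency,
and moves are either an active neighbor-relative probe or a passive step
toward an amplitude-weighted reference; DS-EFO assigns the mode by comparing
each candidate's distance to the best against the population mean distance.
Detection minimizes `fr1 = 1/(accuracy + precision)`; mitigation minimizes
the MAE against the clean target.

## Worked example

```python
import numpy as np
from ocuclean import PipelineConfig, make_fixture
from ocuclean.pipeline import run_full

cfg = PipelineConfig(seed=7)
cfg.data.n_channels = 8; cfg.data.n_eog = 1      # 7 EEG + 1 EOG channels
cfg.data.n_epochs = 60; cfg.data.duration = 2.0  # 60 epochs of 2 s at 250 Hz
cfg.features.n_components = 20                   # scaled-down feature count

data = make_fixture(cfg)                         # semi-simulated, snr = 1
res = run_full(data, cfg)

rep, mit = res.detection.report, res.mitigation
print(f"held-out detection accuracy: {rep.accuracy:.3f}")
print(f"mean MAE  retrieved vs clean: "
      f"{np.mean([s.mae for s in mit.epoch_scores]):.3f} uV "
      f"(contaminated: {np.mean([s.mae for s in mit.baseline_scores]):.3f} uV)")
print(f"mean corr retrieved vs clean: "
      f"{np.mean([s.corr for s in mit.epoch_scores]):.3f} "
      f"(contaminated: {np.mean([s.corr for s in mit.baseline_scores]):.3f})")
```

prints

```
held-out detection accuracy: 1.000
mean MAE  retrieved vs clean: 1.625 uV (contaminated: 3.172 uV)
mean corr retrieved vs clean: 0.919 (contaminated: 0.732)
```

Half of the 60 epochs carry additive blink trains whose power equals the
clean EEG power (snr = 1). The detector labels the held-out epochs
perfectly, and mitigation halves the mean absolute error against the clean
target while raising the mean correlation from 0.73 to 0.92. The default
configuration instead reproduces the full study geometry — 25 channels
(22 EEG + 3 EOG), 288 epochs of 1500 samples at 250 Hz.

The same steps are available from a shell:

```bash
ocuclean simulate --seed 7 --out run/
ocuclean run --seed 7 --input run/semisim.h5 --out run/
ocuclean report run/mitigation_report.txt
```

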