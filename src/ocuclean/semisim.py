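"""Semi-simulated EEG: synthetic clean signals plus blink-like EOG contaminants.

Quantitative evaluation of artifact removal needs a ground truth that real
recordings cannot provide: once an eye blink leaks into a scalp channel the
uncontaminated signal is gone.  The standard workaround is *semi-simulation* —
take artifact-free EEG (here generated synthetically), add a known ocular
waveform at a controlled power ratio, and keep the clean signal as the target.

The default geometry mirrors a common motor-imagery recording block:
25 channels (22 EEG + 3 EOG reference channels), 288 epochs of 6 s sampled at
250 Hz, i.e. a ``25 x 1500 x 288`` tensor.  Ocular artifacts are 10-100x
stronger than cortical EEG; the EOG reference channels carry the raw blink
waveform at that amplitude while the EEG channels receive a leak scaled to a
configurable clean-power / artifact-power ratio (``snr``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EpochTensor",
    "ContaminationSpec",
    "generate_clean_eeg",
    "generate_eog_waveform",
    "contaminate",
]

#: canonical per-channel-role tags
EEG, EOG = "EEG", "EOG"

# band-limited rhythms mixed into every synthetic channel, Hz
_BANDS = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
# relative RMS weight of each rhythm (alpha dominant, as in eyes-closed rest)
_BAND_WEIGHTS = {"theta": 0.8, "alpha": 1.0, "beta": 0.5}
_OSC_PER_BAND = 3
_EEG_RMS_UV = 10.0  # target RMS amplitude of clean EEG, microvolts


@dataclass
class EpochTensor:
    """Multichannel epoched signal block.

    ``data`` has shape ``(n_channels, n_timepoints, n_epochs)`` in microvolts.
    ``labels`` flags artifact-contaminated epochs (1 = contaminated).  After
    :func:`contaminate`, ``clean`` holds the retained target tensor and
    ``artifact`` the additive component, so ``data == clean + artifact``
    elementwise.
    """

    data: np.ndarray
    fs: float
    labels: np.ndarray
    channel_roles: list[str]
    clean: np.ndarray | None = None
    artifact: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_timepoints, n_epochs)")
        if self.labels.shape != (self.data.shape[2],):
            raise ValueError("labels length must equal n_epochs")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("channel_roles length must equal n_channels")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[2]

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == EEG])

    @property
    def eog_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.channel_roles) if r == EOG])


@dataclass
class ContaminationSpec:
    """Parameters of the additive ocular contamination.

    ``snr`` is the per-epoch ratio of mean-square clean EEG to mean-square
    added artifact on the EEG channels (the sweep variable; lower = heavier
    contamination).  ``amplitude_ratio`` sets the EOG reference-channel
    amplitude relative to the clean-EEG RMS, physiologically 10-100.
    """

    snr: float = 1.0
    amplitude_ratio: float = 50.0
    artifact_fraction: float = 0.5
    blink_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if not 10.0 <= self.amplitude_ratio <= 100.0:
            raise ValueError("amplitude_ratio must lie in [10, 100]")
        if not 0.0 < self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in (0, 1]")


def _check_counts(**counts: int) -> None:
    for name, value in counts.items():
        if int(value) != value or value < 1:
            raise ValueError(f"{name} must be a positive integer, got {value!r}")


def _n_samples(fs: float, duration: float) -> int:
    n = fs * duration
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"fs * duration must be integral, got {n}")
    return int(round(n))


def generate_clean_eeg(
    n_channels: int = 25,
    n_epochs: int = 288,
    fs: float = 250.0,
    duration: float = 6.0,
    seed: int = 0,
    n_eog: int = 3,
) -> EpochTensor:
    """Generate an artifact-free synthetic EEG tensor.

    Every channel/epoch is a seeded mixture of band-limited oscillations
    (theta 4-8 Hz, alpha 8-13 Hz, beta 13-30 Hz) with random frequencies and
    phases, plus 1/f background noise, forced to zero mean.  The last
    ``n_eog`` channels are tagged as EOG reference channels (their clean
    content is generated identically; they only differ in what
    :func:`contaminate` adds to them).
    """
    _check_counts(n_channels=n_channels, n_epochs=n_epochs)
    if n_eog >= n_channels:
        n_eog = 0
    n_t = _n_samples(fs, duration)
    osc_seq, noise_seq = np.random.SeedSequence(seed).spawn(2)
    osc_rng = np.random.default_rng(osc_seq)
    noise_rng = np.random.default_rng(noise_seq)

    t = np.arange(n_t) / fs
    data = np.zeros((n_channels, n_t, n_epochs))
    for name, (lo, hi) in _BANDS.items():
        w = _BAND_WEIGHTS[name]
        freqs = osc_rng.uniform(lo, hi, size=(n_channels, n_epochs, _OSC_PER_BAND))
        phases = osc_rng.uniform(0, 2 * np.pi, size=freqs.shape)
        amps = w * osc_rng.uniform(0.5, 1.5, size=freqs.shape)
        # (ch, ep, osc, t) summed over oscillators
        arg = 2 * np.pi * freqs[..., None] * t + phases[..., None]
        data += np.einsum("ceo,ceot->cte", amps, np.sin(arg))

    data += _pink_noise(noise_rng, (n_channels, n_t, n_epochs), fs)
    data -= data.mean(axis=1, keepdims=True)
    # scale to a realistic microvolt RMS
    rms = np.sqrt(np.mean(data**2, axis=1, keepdims=True))
    data *= _EEG_RMS_UV / rms

    roles = [EEG] * (n_channels - n_eog) + [EOG] * n_eog
    labels = np.zeros(n_epochs, dtype=np.int8)
    return EpochTensor(data=data, fs=fs, labels=labels, channel_roles=roles)


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int, int], fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise along the time axis (axis 1)."""
    n_ch, n_t, n_ep = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_t, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    spec *= scale[None, :, None]
    pink = np.fft.irfft(spec, n=n_t, axis=1)
    return pink / pink.std(axis=1, keepdims=True)


def generate_eog_waveform(
    fs: float,
    duration: float,
    blink_rate: float = 0.5,
    seed: int = 0,
    min_pulses: int = 0,
) -> np.ndarray:
    """Blink train: squared-half-sine pulses at Poisson-random onsets.

    Pulse widths are drawn uniformly in 200-400 ms, the physiological blink
    duration.  The waveform is nonnegative and, when at least one pulse is
    present, normalized to unit peak before any scaling by the caller.
    ``min_pulses`` lets a caller force a nonempty train (used for epochs that
    must actually be contaminated).
    """
    if blink_rate < 0:
        raise ValueError("blink_rate must be nonnegative")
    n_t = _n_samples(fs, duration)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_pulses = rng.poisson(blink_rate * duration)
    n_pulses = max(n_pulses, min_pulses)
    wave = np.zeros(n_t)
    if n_pulses == 0:
        return wave
    onsets = rng.uniform(0, duration, size=n_pulses)
    widths = rng.uniform(0.2, 0.4, size=n_pulses)
    t = np.arange(n_t) / fs
    for onset, width in zip(onsets, widths):
        u = (t - onset) / width
        mask = (u >= 0) & (u <= 1)
        wave[mask] += np.sin(np.pi * u[mask]) ** 2
    peak = np.abs(wave).max()
    if peak > 0:
        wave /= peak
    return wave


def contaminate(clean: EpochTensor, spec: ContaminationSpec) -> EpochTensor:
    """Add scaled blink artifacts to a seeded subset of epochs.

    On each contaminated epoch the EEG channels receive the blink waveform
    scaled so that the epoch's clean-power / artifact-power ratio equals
    ``spec.snr`` exactly; the EOG channels receive the waveform at
    ``spec.amplitude_ratio`` times the clean-EEG RMS.  The clean tensor is
    retained as the target and the additive component stored, so the model is
    strictly additive: ``data - artifact == clean``.
    """
    if np.any(clean.labels != 0):
        raise ValueError("input tensor must be artifact-free (labels all 0)")
    n_ep = clean.n_epochs
    n_contam = int(round(spec.artifact_fraction * n_ep))
    root = np.random.SeedSequence(spec.seed)
    pick_rng = np.random.default_rng(root.spawn(1)[0])
    contam_idx = np.sort(pick_rng.choice(n_ep, size=n_contam, replace=False))

    eeg_idx = clean.eeg_indices
    eog_idx = clean.eog_indices
    duration = clean.n_timepoints / clean.fs
    wave_seeds = root.spawn(n_contam + 1)[1:]

    artifact = np.zeros_like(clean.data)
    labels = np.zeros(n_ep, dtype=np.int8)
    for k, ep in enumerate(contam_idx):
        wave = _epoch_wave(clean.fs, duration, spec.blink_rate, wave_seeds[k])
        clean_power = np.mean(clean.data[eeg_idx, :, ep] ** 2)
        wave_power = np.mean(wave**2)
        leak = np.sqrt(clean_power / (spec.snr * wave_power))
        artifact[eeg_idx, :, ep] = leak * wave
        if eog_idx.size:
            eeg_rms = np.sqrt(clean_power)
            artifact[eog_idx, :, ep] = spec.amplitude_ratio * eeg_rms * wave
        labels[ep] = 1

    return EpochTensor(
        data=clean.data + artifact,
        fs=clean.fs,
        labels=labels,
        channel_roles=list(clean.channel_roles),
        clean=clean.data.copy(),
        artifact=artifact,
    )


def _epoch_wave(
    fs: float, duration: float, blink_rate: float, seq: np.random.SeedSequence
) -> np.ndarray:
    """Blink waveform driven directly by a spawned SeedSequence."""
    rng = np.random.default_rng(seq)
    n_t = _n_samples(fs, duration)
    n_pulses = max(rng.poisson(blink_rate * duration), 1)
    wave = np.zeros(n_t)
    onsets = rng.uniform(0, duration, size=n_pulses)
    widths = rng.uniform(0.2, 0.4, size=n_pulses)
    t = np.arange(n_t) / fs
    for onset, width in zip(onsets, widths):
        u = (t - onset) / width
        mask = (u >= 0) & (u <= 1)
        wave[mask] += np.sin(np.pi * u[mask]) ** 2
    wave /= np.abs(wave).max()
    return wave
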