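"""End-to-end orchestration of the detection and mitigation phases.

Detection path: every EEG channel of every epoch is decomposed (wavelet
subbands + Pisarenko spectra), flattened to per-subband statistics and
averaged over channels, producing one observation row per epoch.  PCA and
ICA features are fitted on the training split, concatenated and fed to the
deformable-network detector, which labels each epoch contaminated or clean.
Epochs are split 60/10/30 into train/validation/test by a seeded
permutation; reported detection metrics are computed on the held-out test
split.

Mitigation path: each flagged epoch is decomposed channel-wise by EMCD into
oscillatory modes and a leftover trend.  One of the two parts (default: the
leftover, where slow ocular deflections accumulate) passes through the
deformable-network denoiser trained to reproduce the clean signal minus the
untouched part; the retrieved signal is the untouched part plus the denoised
output (the inverse-EMCD summation).  Epochs flagged clean are never
modified.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import dcn, decomp, dsefo, emcd, features, metrics
from .config import PipelineConfig
from .semisim import ContaminationSpec, EpochTensor, contaminate, generate_clean_eeg

__all__ = [
    "RunResult",
    "make_fixture",
    "epoch_feature_matrix",
    "run_detection",
    "run_mitigation",
    "run_full",
]


@dataclass
class DetectionOutput:
    predictions: np.ndarray  # per-epoch 0/1
    report: metrics.DetectionReport | None
    test_indices: np.ndarray
    feature_matrix: features.FeatureMatrix | None = None


@dataclass
class MitigationOutput:
    retrieved: np.ndarray  # full tensor, unflagged epochs untouched
    epoch_scores: list[metrics.SignalPairScores]
    baseline_scores: list[metrics.SignalPairScores]
    flagged: np.ndarray  # epoch indices that passed through mitigation


@dataclass
class RunResult:
    detection: DetectionOutput | None = None
    mitigation: MitigationOutput | None = None
    provenance: dict = field(default_factory=dict)


def make_fixture(config: PipelineConfig) -> EpochTensor:
    """Semi-simulated dataset under the configured study conditions."""
    d = config.data
    clean = generate_clean_eeg(
        n_channels=d.n_channels,
        n_epochs=d.n_epochs,
        fs=d.fs,
        duration=d.duration,
        seed=config.seed,
        n_eog=d.n_eog,
    )
    spec = ContaminationSpec(
        snr=d.snr,
        amplitude_ratio=d.amplitude_ratio,
        artifact_fraction=d.artifact_fraction,
        blink_rate=d.blink_rate,
        seed=config.seed + 1,
    )
    return contaminate(clean, spec)


def epoch_feature_matrix(data: EpochTensor, config: PipelineConfig) -> np.ndarray:
    """Per-epoch observation rows: subband statistics averaged over EEG channels."""
    eeg = data.eeg_indices
    per_epoch = []
    for ep in range(data.n_epochs):
        per_channel = [
            decomp.decompose_epoch(
                data.data[ch, :, ep],
                wavelet_name=config.decomp.wavelet,
                model_order=config.decomp.pisarenko_order,
                grid_size=config.decomp.pisarenko_grid,
            )
            for ch in eeg
        ]
        stats = features.flatten_decomposed(per_channel)
        per_epoch.append(stats.mean(axis=0))
    return np.asarray(per_epoch)


def _split_indices(
    n: int, config: PipelineConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = int(round(config.split.train * n))
    n_val = int(round(config.split.val * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _standardize(train_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train_rows.mean(axis=0)
    sd = train_rows.std(axis=0)
    sd[sd == 0] = 1.0
    return mu, sd


def run_detection(
    data: EpochTensor,
    config: PipelineConfig | None = None,
    observations: np.ndarray | None = None,
) -> RunResult:
    """Decompose, extract features, train the detector, label every epoch.

    When the tensor carries ground-truth labels a :class:`DetectionReport`
    is computed on the held-out test split; otherwise only predictions are
    emitted.  ``observations`` short-circuits the (costly) decomposition
    when the caller has already computed the per-epoch observation matrix.
    """
    config = config or PipelineConfig()
    t_start = time.time()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed + 101))
    X = observations if observations is not None else epoch_feature_matrix(data, config)
    n = X.shape[0]
    train_idx, val_idx, test_idx = _split_indices(n, config, rng)

    mu, sd = _standardize(X[train_idx])
    Xz = (X - mu) / sd

    n_comp = min(
        config.features.n_components, min(len(train_idx) - 1, Xz.shape[1])
    )
    pca_model, _ = features.pca_fit_transform(Xz[train_idx], n_comp)
    pca_all = features.pca_transform(pca_model, Xz)
    ica_model, _ = features.ica_fit_transform(
        Xz[train_idx], n_comp, seed=config.seed
    )
    ica_all = features.ica_transform(ica_model, Xz)
    fmat = features.concat_features(pca_all, ica_all)

    # scale features globally (not per column): per-column z-scoring would
    # inflate the low-variance tail components to the scale of the leading
    # discriminative ones and the network would fit noise; the sqrt(n)
    # factor keeps the observation vector norm (hence the logit scale)
    # independent of the feature count, so the whole learning-rate search
    # box remains usable
    fscale = (fmat.values[train_idx].std() or 1.0) * np.sqrt(fmat.values.shape[1])
    F = (fmat.values / fscale)[:, None, :]  # (epochs, 1, n_features)

    # labels < 0 mark unknown ground truth (e.g. raw EDF recordings); without
    # labels the detector cannot be trained -> predictions from the seeded
    # initialization are still emitted but the report is omitted
    labels = data.labels.astype(float)
    have_labels = not np.any(labels < 0)

    net_cfg = dcn.NetworkConfig(
        epochs=config.detector.epochs,
        learning_rate=config.detector.learning_rate,
        batch_size=config.detector.batch_size,
        seed=config.seed,
    )
    if config.detector.tune and have_labels:
        efo_params = dsefo.EFOParams(
            bounds=np.array([dcn.EPOCH_RANGE, dcn.LR_RANGE], dtype=float),
            pop_size=config.dsefo.pop,
            iterations=config.dsefo.iters,
            beta=config.dsefo.beta,
            reinit_prob=config.dsefo.reinit_prob,
            seed=config.seed,
        )
        net_cfg = dcn.tune_hyperparams(
            dcn.DETECTOR_SPEC,
            "detector",
            F[train_idx],
            labels[train_idx],
            F[val_idx],
            labels[val_idx],
            dsefo_params=efo_params,
            batch_size=config.detector.batch_size,
            net_seed=config.seed,
            variant=config.dsefo.variant,
        )

    model = dcn.build_model(
        dcn.DETECTOR_SPEC, 1, F.shape[2], "detector", seed=config.seed
    )
    if have_labels:
        dcn.train(model, F[train_idx], labels[train_idx], net_cfg)
    predictions = model.predict(F)

    report = None
    if have_labels:
        report = metrics.detection_report(
            metrics.confusion(data.labels[test_idx], predictions[test_idx])
        )
    detection = DetectionOutput(
        predictions=predictions,
        report=report,
        test_indices=test_idx,
        feature_matrix=fmat,
    )
    return RunResult(
        detection=detection,
        provenance=_provenance(config, t_start),
    )


def _emcd_parts(
    signal: np.ndarray, component: str, max_levels: int
) -> tuple[np.ndarray, np.ndarray]:
    """(part handed to the denoiser, untouched part) of one channel-epoch."""
    result = emcd.emcd_decompose(signal, max_levels=max_levels)
    mode_sum = (
        np.sum(result.modes, axis=0) if result.modes else np.zeros_like(signal)
    )
    if component == "leftover":
        return result.leftover, mode_sum
    return mode_sum, result.leftover


def run_mitigation(
    data: EpochTensor,
    config: PipelineConfig | None = None,
    clean_target: np.ndarray | None = None,
    flagged: np.ndarray | None = None,
) -> RunResult:
    """Denoise flagged epochs through EMCD + network + inverse EMCD.

    ``flagged`` defaults to the tensor's ground-truth labels.  Training
    pairs require a clean target (``clean_target`` or ``data.clean``); with
    ``denoiser.passthrough`` the network is skipped and the retrieved signal
    is exactly the EMCD reconstruction, i.e. the contaminated input.
    """
    config = config or PipelineConfig()
    t_start = time.time()
    dn = config.denoiser
    if clean_target is None:
        clean_target = data.clean
    if flagged is None:
        flagged = np.flatnonzero(data.labels == 1)
    else:
        flagged = np.asarray(flagged, dtype=int)
    eeg = data.eeg_indices
    n_t = data.n_timepoints

    # channel-wise EMCD of every flagged epoch
    pairs = []  # (epoch, channel, to_denoise, untouched)
    for ep in flagged:
        for ch in eeg:
            part, untouched = _emcd_parts(
                data.data[ch, :, ep], dn.component, dn.max_levels
            )
            pairs.append((ep, ch, part, untouched))

    retrieved = data.data.copy()
    scores: list[metrics.SignalPairScores] = []
    baseline: list[metrics.SignalPairScores] = []

    if dn.passthrough or not pairs:
        for ep, ch, part, untouched in pairs:
            retrieved[ch, :, ep] = part + untouched
    else:
        # the part sent to the denoiser is a band-limited trend: decimate it
        # so the network's receptive field spans a whole blink, then
        # interpolate the denoised output back to the full rate
        dec = max(1, dn.decimation)
        t_full = np.arange(n_t)
        t_dec = t_full[::dec]
        X = np.array([p[2][::dec] for p in pairs])[:, None, :]  # (N, 1, T/dec)
        scale = X.std() or 1.0

        model = dcn.build_model(
            dcn.DENOISER_SPEC, 1, X.shape[2], "denoiser", seed=config.seed
        )
        if clean_target is not None:
            targets = np.array(
                [(clean_target[ch, :, ep] - unt)[::dec] for ep, ch, _, unt in pairs]
            )[:, None, :]
            rng = np.random.default_rng(np.random.SeedSequence(config.seed + 202))
            n_train = min(dn.max_train_signals, len(pairs))
            sel = rng.choice(len(pairs), size=n_train, replace=False)
            net_cfg = dcn.NetworkConfig(
                epochs=dn.epochs,
                learning_rate=dn.learning_rate,
                batch_size=dn.batch_size,
                seed=config.seed,
            )
            if dn.tune:
                n_val = max(1, n_train // 5)
                efo_params = dsefo.EFOParams(
                    bounds=np.array([dcn.EPOCH_RANGE, dcn.LR_RANGE], dtype=float),
                    pop_size=config.dsefo.pop,
                    iterations=config.dsefo.iters,
                    beta=config.dsefo.beta,
                    reinit_prob=config.dsefo.reinit_prob,
                    seed=config.seed,
                )
                net_cfg = dcn.tune_hyperparams(
                    dcn.DENOISER_SPEC,
                    "denoiser",
                    X[sel[n_val:]] / scale,
                    targets[sel[n_val:]] / scale,
                    X[sel[:n_val]] / scale,
                    targets[sel[:n_val]] / scale,
                    dsefo_params=efo_params,
                    batch_size=dn.batch_size,
                    net_seed=config.seed,
                    variant=config.dsefo.variant,
                )
            # annealed SGD: the MAE loss has constant-magnitude gradients, so
            # its error floor scales with the learning rate; three stages at
            # lr, lr/3 and lr/10 push the floor down at fixed epoch budget
            for stage, lr_factor in enumerate((1.0, 1.0 / 3.0, 0.1)):
                stage_cfg = dcn.NetworkConfig(
                    epochs=net_cfg.epochs,
                    learning_rate=net_cfg.learning_rate * lr_factor,
                    batch_size=net_cfg.batch_size,
                    seed=net_cfg.seed + stage,
                )
                dcn.train(model, X[sel] / scale, targets[sel] / scale, stage_cfg)

        denoised = np.vstack(
            [
                model.forward(X[i : i + 256] / scale)[:, 0, :] * scale
                for i in range(0, len(pairs), 256)
            ]
        )
        for (ep, ch, _, untouched), den in zip(pairs, denoised):
            den_full = np.interp(t_full, t_dec, den) if dec > 1 else den
            retrieved[ch, :, ep] = untouched + den_full

    if clean_target is not None:
        for ep in flagged:
            ret = retrieved[eeg, :, ep].ravel()
            cln = clean_target[eeg, :, ep].ravel()
            con = data.data[eeg, :, ep].ravel()
            scores.append(metrics.signal_scores(ret, cln))
            baseline.append(metrics.signal_scores(con, cln))

    mitigation = MitigationOutput(
        retrieved=retrieved,
        epoch_scores=scores,
        baseline_scores=baseline,
        flagged=flagged,
    )
    return RunResult(mitigation=mitigation, provenance=_provenance(config, t_start))


def run_full(data: EpochTensor, config: PipelineConfig | None = None) -> RunResult:
    """Detection followed by mitigation of the epochs predicted artifactual.

    Epochs predicted clean are left untouched bit-for-bit.
    """
    config = config or PipelineConfig()
    t_start = time.time()
    det = run_detection(data, config)
    flagged = np.flatnonzero(det.detection.predictions == 1)
    if flagged.size:
        mit = run_mitigation(data, config, flagged=flagged)
        mitigation = mit.mitigation
    else:
        mitigation = MitigationOutput(
            retrieved=data.data.copy(),
            epoch_scores=[],
            baseline_scores=[],
            flagged=flagged,
        )
    return RunResult(
        detection=det.detection,
        mitigation=mitigation,
        provenance=_provenance(config, t_start),
    )


def _provenance(config: PipelineConfig, t_start: float) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "started": t_start,
        "finished": time.time(),
    }
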