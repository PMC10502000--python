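"""End-to-end phantom studies: the package's standard self-experiments.

These are the desk-scale counterparts of the clinical study design: generate
phantoms with exact truth, simulate the annotation process, reconstruct, and
quantify agreement.  They are used by the test suite and by
``scripts/acceptance.py``; problem sizes are chosen to run in minutes on one
CPU (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agreement import dice
from .model import predict  # noqa: F401  (re-exported surface for demos)
from .nn import UNetConfig, build_unet, train
from .nn.train import stack_samples
from .phantom import GazeNoiseModel, generate_phantom, simulate_gaze_recording
from .preprocessing import TrainingSample, make_training_sample
from .reconstruction import VolumeGrid, reconstruct

__all__ = [
    "noiseless_roundtrip",
    "repeatability_curve",
    "phantom_training_slices",
    "overfit_capacity",
    "DESK_TRAIN_KWARGS",
]

#: Training settings for the tiny CPU preset.  With only a few samples there
#: are few optimizer steps per epoch, so the desk recipe uses a larger Adam
#: step and single-sample batches, and balances the diameter term on data.
DESK_TRAIN_KWARGS = dict(lr=0.01, batch_size=1, lam="auto", val_fraction=0.0)


def noiseless_roundtrip(seed: int = 0, side: int = 128) -> dict[str, float]:
    """Annotate a default phantom with a noise-free recording and reconstruct.

    Returns the foreground Dice against the exact truth and the mean absolute
    diameter error (mm; 1 mm voxels, so also voxels) over in-tube voxels that
    the reconstruction covers — uncovered voxels are a segmentation error
    already measured by the Dice term.
    """
    grid = VolumeGrid((side, side, side), (1.0, 1.0, 1.0))
    phantom = generate_phantom(grid=grid, seed=seed)
    recording = simulate_gaze_recording(
        phantom, GazeNoiseModel(jitter_sd=0.0, diameter_error_sd=0.0), seed=seed
    )
    labels, diam = reconstruct(recording, phantom.grid)
    truth_fg = phantom.truth_labels.values > 0
    score = dice(labels.values > 0, truth_fg)
    covered = truth_fg & (diam.values > 0)
    mae = float(
        np.abs(diam.values[covered] - phantom.truth_diameters.values[covered]).mean()
    )
    return {"dice": float(score), "diam_mae_mm": mae, "n_voxels": int(grid.n_voxels)}


def repeatability_curve(
    jitters=(0.0, 1.0, 2.0, 4.0),
    n_seeds: int = 10,
    base_seed: int = 0,
    side: int = 80,
) -> dict[float, float]:
    """Mean Dice between two independent noisy annotation repetitions per jitter.

    Phantoms and the underlying gaze randomness are shared across jitter
    levels (common random numbers), so the curve isolates the effect of the
    jitter magnitude.  Returns {jitter_sd: mean foreground Dice}.
    """
    grid = VolumeGrid((side, side, side), (1.0, 1.0, 1.0))
    scores: dict[float, list[float]] = {j: [] for j in jitters}
    for i in range(n_seeds):
        seed = base_seed + 101 * i
        phantom = generate_phantom(
            n_tubes=2, grid=grid, seed=seed, diameter_range=(10.0, 30.0)
        )
        for j in jitters:
            noise = GazeNoiseModel(jitter_sd=float(j), diameter_error_sd=1.0)
            masks = []
            for rep in (1, 2):
                ann = simulate_gaze_recording(
                    phantom, noise, repetition=rep, seed=seed + rep
                )
                labels, _ = reconstruct(ann, grid)
                masks.append(labels.values > 0)
            scores[j].append(dice(*masks))
    return {j: float(np.mean(v)) for j, v in scores.items()}


def phantom_training_slices(seed: int, n_slices: int = 8) -> list[TrainingSample]:
    """Model-ready 64x64 slices (the ones richest in bowel) from a small phantom."""
    grid = VolumeGrid((64, 64, 16), (1.0, 1.0, 3.0))
    phantom = generate_phantom(
        n_tubes=2, grid=grid, seed=seed, diameter_range=(10.0, 22.0)
    )
    volume = make_training_sample(
        phantom.ct, phantom.truth_labels, phantom.truth_diameters
    )
    fg_per_slice = (volume.labels3 > 0).sum(axis=(0, 1))
    keep = sorted(np.argsort(fg_per_slice)[::-1][:n_slices])
    return [
        TrainingSample(
            volume.image[:, :, k], volume.labels3[:, :, k],
            volume.diam_vox[:, :, k], volume.weights[:, :, k],
        )
        for k in keep
    ]


def overfit_capacity(seed: int, epochs: int = 200) -> dict[str, float]:
    """Capacity check: can the tiny preset memorize 8 phantom slices?

    Trains the desk U-net on the slices themselves (no hold-out — the point
    is memorization) and reports the training foreground Dice and the mean
    absolute diameter error in voxels over in-tube voxels.
    """
    samples = phantom_training_slices(seed)
    net = build_unet(UNetConfig.desk(2), seed=seed)
    net, history = train(net, samples, epochs=epochs, seed=seed, **DESK_TRAIN_KWARGS)
    x, t, d, w = stack_samples(samples)
    probs, diam = net.predict_proba(x)
    predicted = probs.argmax(axis=1)
    truth = np.stack([s.labels3 for s in samples])
    score = dice(predicted > 0, truth > 0)
    in_tube = truth > 0
    mae = float(np.abs(diam[:, 0][in_tube] - d[in_tube]).mean())
    return {"dice": float(score), "diam_mae_vox": mae, "epochs": epochs,
            "lam": history.lam}
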