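"""Neural regressors for voxel-wise parameter estimation from MESE signals.

Two fully connected models are trained purely on synthetic EPG signals:

* **Fat-Net** — input: the unit-norm MESE signal of a subcutaneous-fat voxel
  (FF fixed at 0.9 during simulation); outputs: T2f, T2w, B1.
* **Muscle-Net** — input: the unit-norm MESE signal concatenated with the
  calibrated T2f (scaled to [0, 1] over its training range); outputs: FF,
  T2w, B1.

Both use a bottleneck stack of ReLU hidden layers with a linear 3-wide
output (six weighted layers with the default widths), mean-absolute-error
loss on range-scaled targets, and the Adam optimizer.  Training signals are
drawn uniformly over the physiological parameter ranges; at every gradient
step the noiseless signals are freshly corrupted with complex Gaussian noise
(magnitude taken afterwards, i.e. Rician, matching acquired magnitude data)
and renormalized, which is what makes the regressors robust to measurement
noise.  Predictions are exactly invariant to positive rescaling of the
input signal because of the unit-norm normalization.

A trained model is tied to one sequence configuration (TE, ETL, pulse
profiles); a new training is required whenever these change, which is why
the bundle records the sequence fingerprint and refuses mismatched inputs
downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._mlp import AdamMLP
from .epg_core import (
    T1_FAT_MS,
    T1_WATER_MS,
    SequenceConfig,
    mese_single_component_batch,
)

__all__ = [
    "NoiseSpec",
    "RegressorBundle",
    "TRAINING_RANGES",
    "DEFAULT_HIDDEN",
    "DEFAULT_MUSCLE_NOISE",
    "DEFAULT_FAT_NOISE",
    "sample_training_params",
    "simulate_training_signals",
    "augment_and_normalize",
    "build_model",
    "train",
    "predict_fat",
    "predict_muscle",
    "save_bundle",
    "load_bundle",
]

#: Uniform sampling ranges of the training parameter spaces.
TRAINING_RANGES = {
    "fat": {"t2f": (50.0, 250.0), "t2w": (10.0, 110.0), "b1": (0.4, 1.2)},
    "muscle": {
        "t2f": (50.0, 250.0),
        "t2w": (10.0, 80.0),
        "ff": (0.0, 1.0),
        "b1": (0.4, 1.2),
    },
}

#: Output parameter names per model kind.
OUTPUTS = {"fat": ("t2f", "t2w", "b1"), "muscle": ("ff", "t2w", "b1")}

DEFAULT_HIDDEN = (256, 128, 64, 32, 16)

#: Muscle training noise: per-channel variance uniform in [1e-7, 5e-5].
DEFAULT_MUSCLE_NOISE = None  # set below after NoiseSpec definition
#: Fat training noise: first-echo SNR uniform in [1e3, 1e4].
DEFAULT_FAT_NOISE = None


@dataclass(frozen=True)
class NoiseSpec:
    """Training noise distribution.

    ``variance_range``: per-channel Gaussian variance drawn uniformly from
    [lo, hi] (signals are O(1) unit-norm scale).  ``snr_range``: SNR drawn
    uniformly from [lo, hi]; the per-channel sigma is the first-echo
    amplitude divided by the SNR.
    """

    mode: str
    lo: float
    hi: float

    def __post_init__(self):
        if self.mode not in ("variance_range", "snr_range"):
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if not (0 < self.lo <= self.hi):
            raise ValueError("need 0 < lo <= hi")

    def sigma(self, first_echo: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Per-signal noise sigma.  Both modes are anchored to the first-echo
        amplitude (the natural reference of magnitude MESE data), so the
        noise level is independent of the arbitrary simulation amplitude
        convention: variance mode uses sigma = sqrt(var) * first_echo, SNR
        mode sigma = first_echo / SNR."""
        n = first_echo.size
        if self.mode == "variance_range":
            return np.sqrt(rng.uniform(self.lo, self.hi, n)) * first_echo
        return first_echo / rng.uniform(self.lo, self.hi, n)


DEFAULT_MUSCLE_NOISE = NoiseSpec("variance_range", 1e-7, 5e-5)
DEFAULT_FAT_NOISE = NoiseSpec("snr_range", 1e3, 1e4)


@dataclass
class RegressorBundle:
    """A (possibly trained) regressor plus everything needed to apply it."""

    kind: str
    layer_sizes: tuple
    net: AdamMLP
    seq_hash: str = ""
    training_meta: dict = field(default_factory=dict)
    loss_history: list = field(default_factory=list)
    # fixed affine input standardization (set at training time)
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None

    @property
    def output_names(self) -> tuple:
        return OUTPUTS[self.kind]

    @property
    def output_ranges(self) -> list:
        return [TRAINING_RANGES[self.kind][nm] for nm in self.output_names]


def sample_training_params(kind: str, n: int, seed: int) -> pd.DataFrame:
    """Uniformly sample the training parameter space; reproducible under seed."""
    if kind not in TRAINING_RANGES:
        raise ValueError(f"unknown kind {kind!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for nm, (lo, hi) in TRAINING_RANGES[kind].items():
        cols[nm] = rng.uniform(lo, hi, n)
    if kind == "fat":
        cols["ff"] = np.full(n, 0.9)
    return pd.DataFrame(cols)


def simulate_training_signals(params: pd.DataFrame, seq: SequenceConfig) -> np.ndarray:
    """Noiseless two-pool echo trains, one row per parameter row."""
    t2f = params["t2f"].to_numpy()
    t2w = params["t2w"].to_numpy()
    ff = params["ff"].to_numpy()
    b1 = params["b1"].to_numpy()
    s_fat = mese_single_component_batch(t2f, b1, T1_FAT_MS, seq)
    s_wat = mese_single_component_batch(t2w, b1, T1_WATER_MS, seq)
    return ff[:, None] * s_fat + (1.0 - ff)[:, None] * s_wat


def augment_and_normalize(
    signals: np.ndarray, noise: NoiseSpec | None, rng: np.random.Generator
) -> np.ndarray:
    """Corrupt with two-channel Gaussian noise, take magnitude, unit-normalize.

    The noiseless signal sits on the real channel; independent Gaussian noise
    of a per-signal level drawn from ``noise`` is added to both quadrature
    channels, the magnitude is taken (Rician statistics, as in acquired
    magnitude images), and each row is scaled to unit Euclidean norm.
    ``noise=None`` skips corruption (pure normalization).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    n = signals.shape[0]
    if noise is None:
        out = signals.copy()
    else:
        sigma = noise.sigma(signals[:, 0], rng)
        re = signals + sigma[:, None] * rng.standard_normal(signals.shape)
        im = sigma[:, None] * rng.standard_normal(signals.shape)
        out = np.hypot(re, im)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return out / norms


def build_model(
    kind: str,
    layer_sizes=DEFAULT_HIDDEN,
    etl: int = 17,
    seed: int = 0,
) -> RegressorBundle:
    """Untrained regressor: ``etl`` (+1 for muscle) inputs, 3 linear outputs.

    Hidden widths must be non-increasing after the first (bottleneck).
    """
    if kind not in OUTPUTS:
        raise ValueError(f"unknown kind {kind!r}")
    layer_sizes = tuple(int(s) for s in layer_sizes)
    if any(s <= 0 for s in layer_sizes) or not layer_sizes:
        raise ValueError("hidden layer sizes must be positive")
    if any(b > a for a, b in zip(layer_sizes[:-1], layer_sizes[1:])):
        raise ValueError("hidden widths must be non-increasing after the first")
    in_dim = etl + (1 if kind == "muscle" else 0)
    net = AdamMLP([in_dim, *layer_sizes, 3], seed=seed)
    return RegressorBundle(kind=kind, layer_sizes=layer_sizes, net=net)


def _scale_targets(params: pd.DataFrame, kind: str) -> np.ndarray:
    cols = []
    for nm, (lo, hi) in zip(OUTPUTS[kind], (TRAINING_RANGES[kind][n] for n in OUTPUTS[kind])):
        cols.append((params[nm].to_numpy() - lo) / (hi - lo))
    return np.stack(cols, axis=1)


def _scale_t2f(t2f_ms) -> np.ndarray:
    lo, hi = TRAINING_RANGES["muscle"]["t2f"]
    return (np.asarray(t2f_ms, dtype=float) - lo) / (hi - lo)


def train(
    bundle: RegressorBundle,
    seq: SequenceConfig,
    noise: NoiseSpec | None = None,
    n_train: int = 100_000,
    epochs: int = 500,
    steps_per_epoch: int = 1000,
    batch: int = 500,
    seed: int = 0,
    lr: float = 3e-3,
    lr_final: float = 3e-5,
) -> RegressorBundle:
    """Train a regressor on freshly-noised synthetic signals.

    The training pool of ``n_train`` noiseless signals is simulated once; at
    every gradient step a batch is drawn with replacement and corrupted with
    fresh noise.  Inputs are standardized by a fixed affine map (per-feature
    mean/std of the noiseless normalized pool, stored in the bundle).  The
    learning rate decays exponentially from ``lr`` to ``lr_final`` over the
    epochs.  Per-epoch mean losses are recorded in ``bundle.loss_history``;
    a non-finite loss aborts with diagnostics.
    """
    if min(n_train, epochs, steps_per_epoch, batch) < 1:
        raise ValueError("all training counts must be >= 1")
    if noise is None:
        noise = DEFAULT_MUSCLE_NOISE if bundle.kind == "muscle" else DEFAULT_FAT_NOISE
    rng = np.random.default_rng(seed)
    params = sample_training_params(bundle.kind, n_train, seed=int(rng.integers(2**31)))
    signals = simulate_training_signals(params, seq)
    targets = _scale_targets(params, bundle.kind)
    extra = _scale_t2f(params["t2f"].to_numpy()) if bundle.kind == "muscle" else None

    clean = augment_and_normalize(signals, None, rng)
    mu, sd = clean.mean(axis=0), clean.std(axis=0)
    if extra is not None:
        # the scaled-T2f column is U[0,1]: mean 1/2, std 1/sqrt(12)
        mu = np.concatenate([mu, [0.5]])
        sd = np.concatenate([sd, [1.0 / np.sqrt(12.0)]])
    sd[sd == 0] = 1.0
    bundle.input_mean, bundle.input_std = mu, sd

    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr_e = lr * (lr_final / lr) ** frac
        losses = np.empty(steps_per_epoch)
        for step in range(steps_per_epoch):
            idx = rng.integers(0, n_train, batch)
            x = augment_and_normalize(signals[idx], noise, rng)
            if extra is not None:
                x = np.concatenate([x, extra[idx, None]], axis=1)
            x = (x - mu) / sd
            losses[step] = bundle.net.train_step(x, targets[idx], lr=lr_e)
        mean_loss = float(np.mean(losses))
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged at epoch {epoch}: loss={mean_loss} "
                f"(lr={lr_e:g}, batch={batch})"
            )
        bundle.loss_history.append(mean_loss)
    bundle.seq_hash = seq.seq_hash
    bundle.training_meta = {
        "seed": seed,
        "n_train": n_train,
        "epochs": epochs,
        "steps_per_epoch": steps_per_epoch,
        "batch": batch,
        "noise": {"mode": noise.mode, "lo": noise.lo, "hi": noise.hi},
        "lr": lr,
        "lr_final": lr_final,
    }
    return bundle


def _unscale(pred: np.ndarray, kind: str) -> dict:
    out = {}
    clipped = np.zeros(pred.shape[0], dtype=bool)
    for i, nm in enumerate(OUTPUTS[kind]):
        lo, hi = TRAINING_RANGES[kind][nm]
        phys = lo + pred[:, i] * (hi - lo)
        clipped |= (phys < lo) | (phys > hi)
        out[nm] = np.clip(phys, lo, hi)
    out["clipped"] = clipped
    return out


def _check_signals(bundle, signals, seq_hash=None):
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    expect = bundle.net.layer_sizes[0] - (1 if bundle.kind == "muscle" else 0)
    if signals.shape[1] != expect:
        raise ValueError(f"expected signal length {expect}, got {signals.shape[1]}")
    if not np.all(np.isfinite(signals)):
        raise ValueError("signals must be finite")
    return signals


def _standardize(bundle, x):
    if bundle.input_mean is not None:
        return (x - bundle.input_mean) / bundle.input_std
    return x


def predict_fat(bundle: RegressorBundle, signals) -> dict:
    """Apply Fat-Net: per-voxel (t2f, t2w, b1), clipped to training ranges."""
    if bundle.kind != "fat":
        raise ValueError("bundle is not a fat model")
    signals = _check_signals(bundle, signals)
    rng = np.random.default_rng(0)  # unused (no noise), required by signature
    x = augment_and_normalize(signals, None, rng)
    return _unscale(bundle.net.forward(_standardize(bundle, x)), "fat")


def predict_muscle(bundle: RegressorBundle, signals, t2f_ms: float) -> dict:
    """Apply Muscle-Net given the calibrated T2f: per-voxel (ff, t2w, b1)."""
    if bundle.kind != "muscle":
        raise ValueError("bundle is not a muscle model")
    lo, hi = TRAINING_RANGES["muscle"]["t2f"]
    if not (lo <= t2f_ms <= hi):
        raise ValueError(f"t2f_ms must lie within the training range [{lo}, {hi}]")
    signals = _check_signals(bundle, signals)
    rng = np.random.default_rng(0)
    x = augment_and_normalize(signals, None, rng)
    t2f_col = np.full((x.shape[0], 1), _scale_t2f(t2f_ms))
    x = np.concatenate([x, t2f_col], axis=1)
    return _unscale(bundle.net.forward(_standardize(bundle, x)), "muscle")


# ---------------------------------------------------------------------------
# Persistence: directory with weights blob + JSON metadata
# ---------------------------------------------------------------------------


def save_bundle(bundle: RegressorBundle, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    state = bundle.net.state_dict()
    if bundle.input_mean is not None:
        state["input_mean"] = bundle.input_mean
        state["input_std"] = bundle.input_std
    np.savez(path / "weights.npz", **state)
    meta = {
        "kind": bundle.kind,
        "layer_sizes": list(bundle.layer_sizes),
        "seq_hash": bundle.seq_hash,
        "training_meta": bundle.training_meta,
        "loss_history": bundle.loss_history,
        "output_names": list(bundle.output_names),
        "output_ranges": [list(r) for r in bundle.output_ranges],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))


def load_bundle(path) -> RegressorBundle:
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    with np.load(path / "weights.npz") as st:
        state = dict(st)
    mean = state.pop("input_mean", None)
    std = state.pop("input_std", None)
    net = AdamMLP.from_state_dict(state)
    return RegressorBundle(
        kind=meta["kind"],
        layer_sizes=tuple(meta["layer_sizes"]),
        net=net,
        seq_hash=meta["seq_hash"],
        training_meta=meta["training_meta"],
        loss_history=meta["loss_history"],
        input_mean=mean,
        input_std=std,
    )
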