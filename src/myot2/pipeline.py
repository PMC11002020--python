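"""Subject-level workflow: subcutaneous fat segmentation, subject-specific
fat-T2 calibration, voxel-wise muscle mapping, Dixon reference FF, ROI stats.

The processing chain per subject is:

1. segment subcutaneous fat on the first MESE echo (k-means on intensities,
   keeping the bright border-adjacent ring);
2. calibrate the subject's fat T2 (T2f) in that region with any of the
   three estimators (Fat-Net / dictionary / NLSQ), aggregating per-voxel
   estimates to a scalar (median by default);
3. estimate voxel-wise (FF, T2w, B1) in the muscle with the calibrated T2f,
   again with any estimator;
4. compute reference Dixon fat fraction and per-ROI statistics.

Geometry is never resampled silently: masks must share the MESE grid, and
model/dictionary resources must carry the fingerprint of the sequence they
were built for, otherwise the pipeline refuses to run.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.vq import kmeans2

from . import dictionary_fit, nlsq_fit, nn_fit
from .epg_core import SequenceConfig
from .rf_pulses import preset_profiles

__all__ = [
    "SubjectMaps",
    "segment_subcutaneous_fat",
    "calibrate_t2f",
    "map_subject",
    "dixon_ff",
    "roi_stats",
    "t2f_sensitivity",
    "sequence_from_yaml",
]

_METHODS = ("nn", "dict", "nlsq")


@dataclass
class SubjectMaps:
    """Co-registered voxel maps with provenance."""

    t2w_map: np.ndarray
    ff_map: np.ndarray
    b1_map: np.ndarray
    quality_mask: np.ndarray  # True where the estimate is usable
    t2f_calibrated_ms: float
    provenance: dict = field(default_factory=dict)

    def to_json_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance | {"t2f_calibrated_ms": self.t2f_calibrated_ms}, fh, indent=2)


# ---------------------------------------------------------------------------
# Subcutaneous fat segmentation
# ---------------------------------------------------------------------------


def segment_subcutaneous_fat(first_echo_image, k_clusters: int = 3, seed: int = 0) -> np.ndarray:
    """Bright subcutaneous ring by Lloyd k-means on first-echo intensities.

    Voxels are clustered by intensity; the highest-mean cluster is the fat
    candidate.  Of its connected components, only those adjacent to the
    border-connected background (the darkest cluster touching the image
    border) are kept — this selects the subcutaneous ring and rejects
    interior bright structures such as bone marrow.  Deterministic under
    ``seed``.
    """
    img = np.asarray(first_echo_image, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D image")
    if k_clusters < 2:
        raise ValueError("k_clusters must be >= 2")
    flat = img.ravel()
    if np.unique(flat).size < k_clusters:
        raise ValueError("image has fewer distinct intensities than clusters")
    centroids, labels = kmeans2(flat, k_clusters, minit="++", seed=seed, iter=50)
    order = np.argsort(centroids)
    bright = labels.reshape(img.shape) == order[-1]
    dark = labels.reshape(img.shape) == order[0]
    if not np.any(bright):
        raise ValueError("no fat cluster found; supply a manual mask")

    # background: dark-cluster component(s) touching the image border
    dark_lab, nlab = ndimage.label(dark)
    border_ids = set()
    for axis in range(img.ndim):
        sl_lo = [slice(None)] * img.ndim
        sl_lo[axis] = 0
        sl_hi = [slice(None)] * img.ndim
        sl_hi[axis] = -1
        border_ids |= set(np.unique(dark_lab[tuple(sl_lo)])) | set(np.unique(dark_lab[tuple(sl_hi)]))
    border_ids.discard(0)
    background = np.isin(dark_lab, sorted(border_ids))
    bg_halo = ndimage.binary_dilation(background, iterations=2)

    lab, nlab = ndimage.label(bright)
    keep = np.zeros_like(bright)
    for i in range(1, nlab + 1):
        comp = lab == i
        if np.any(comp & bg_halo):
            keep |= comp
    if not np.any(keep):
        raise ValueError("fat cluster is not adjacent to the background; supply a manual mask")
    return keep


# ---------------------------------------------------------------------------
# Calibration and mapping
# ---------------------------------------------------------------------------


def _masked_signals(mese_stack, mask):
    stack = np.asarray(mese_stack, dtype=float)
    if stack.ndim == 3:
        stack = stack[:, :, None, :]
    if stack.ndim != 4:
        raise ValueError("MESE stack must be (x, y, slice, echo)")
    if mask.shape != stack.shape[:3] and mask.shape != stack.shape[:2]:
        raise ValueError("mask geometry does not match the MESE grid")
    if mask.ndim == 2:
        mask = mask[:, :, None] & np.ones(stack.shape[:3], dtype=bool)
    idx = np.where(mask)
    return stack, idx, stack[idx]


def _check_resources(method, seq, model=None, dictionary=None):
    if method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if method == "nn":
        if model is None:
            raise ValueError("method 'nn' requires a trained model bundle")
        if model.seq_hash and model.seq_hash != seq.seq_hash:
            raise ValueError(
                "model was trained for a different sequence configuration "
                f"(hash {model.seq_hash} != {seq.seq_hash}); retrain it"
            )
    if method == "dict":
        if dictionary is None:
            raise ValueError("method 'dict' requires a prebuilt dictionary")
        if dictionary.seq_hash != seq.seq_hash:
            raise ValueError(
                "dictionary was built for a different sequence configuration "
                f"(hash {dictionary.seq_hash} != {seq.seq_hash}); rebuild it"
            )


def calibrate_t2f(
    mese_stack,
    fat_mask,
    seq: SequenceConfig,
    method: str = "dict",
    model=None,
    dictionary=None,
    aggregator: str = "median",
    min_voxels: int = 50,
) -> tuple[float, np.ndarray, bool]:
    """Subject-specific fat T2 from the subcutaneous region.

    Per-voxel T2f estimates from the chosen estimator (fat mode, FF fixed at
    0.9) are aggregated to a scalar (median by default — robust against mask
    impurities).  Poor fits are excluded: dictionary matches with score
    below 0.98, NLSQ fits with relative residual above 10%, and invalid
    voxels.  Returns ``(t2f_ms, per_voxel_estimates, low_count_warning)``.
    """
    if not np.any(fat_mask):
        raise ValueError("empty subcutaneous mask")
    _check_resources(method, seq, model, dictionary)
    _, _, signals = _masked_signals(mese_stack, np.asarray(fat_mask, dtype=bool))
    if method == "nn":
        out = nn_fit.predict_fat(model, signals)
        t2f = out["t2f"]
        good = np.isfinite(t2f)
    elif method == "dict":
        res = dictionary_fit.match(signals, dictionary)
        t2f = res["t2f"]
        good = np.isfinite(t2f) & (res["score"] >= 0.98)
    else:
        res = nlsq_fit.fit_fat_voxels(signals, seq)
        t2f = res["t2f"]
        norm2 = np.sum(signals**2, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = np.sqrt(res["residual"] / np.where(norm2 > 0, norm2, 1.0))
        good = res["valid"] & (rel <= 0.1)
    vals = t2f[good]
    if vals.size == 0:
        raise ValueError("no valid subcutaneous voxels for calibration")
    agg = {"median": np.median, "mean": np.mean}[aggregator]
    return float(agg(vals)), vals, bool(vals.size < min_voxels)


def map_subject(
    mese_stack,
    t2f_ms: float,
    seq: SequenceConfig,
    method: str = "dict",
    muscle_mask=None,
    model=None,
    dictionary=None,
    seed: int = 0,
) -> SubjectMaps:
    """Voxel-wise (FF, T2w, B1) maps of the muscle with the calibrated T2f.

    Estimation is restricted to ``muscle_mask`` (whole volume if ``None``).
    Out-of-range estimates are clipped and flagged, not discarded; voxels
    with FF > 0.95 are flagged unreliable (the water pool is then too weak
    to carry T2w information).
    """
    if not (50.0 <= t2f_ms <= 250.0):
        raise ValueError("t2f_ms must lie in [50, 250] ms")
    _check_resources(method, seq, model, dictionary)
    stack = np.asarray(mese_stack, dtype=float)
    if stack.ndim == 3:
        stack = stack[:, :, None, :]
    if stack.shape[-1] != seq.etl:
        raise ValueError("stack echo count does not match the sequence ETL")
    if muscle_mask is None:
        muscle_mask = np.ones(stack.shape[:3], dtype=bool)
    stack, idx, signals = _masked_signals(stack, np.asarray(muscle_mask, dtype=bool))

    if method == "nn":
        out = nn_fit.predict_muscle(model, signals, t2f_ms)
        ff, t2w, b1 = out["ff"], out["t2w"], out["b1"]
        usable = np.isfinite(t2w) & ~out["clipped"]
    elif method == "dict":
        res = dictionary_fit.match(signals, dictionary)
        ff, t2w, b1 = res["ff"], res["t2w"], res["b1"]
        usable = np.isfinite(t2w)
    else:
        res = nlsq_fit.fit_muscle_voxels(signals, t2f_ms, seq)
        ff, t2w, b1 = res["ff"], res["t2w"], res["b1"]
        usable = res["valid"]

    shape = stack.shape[:3]
    t2w_map = np.full(shape, np.nan)
    ff_map = np.full(shape, np.nan)
    b1_map = np.full(shape, np.nan)
    quality = np.zeros(shape, dtype=bool)
    t2w_map[idx] = np.clip(t2w, 10.0, 110.0)
    ff_map[idx] = np.clip(ff, 0.0, 1.0)
    b1_map[idx] = np.clip(b1, 0.4, 1.2)
    quality[idx] = usable & ~(np.nan_to_num(ff, nan=1.0) > nlsq_fit.HIGH_FF_FLAG_THRESHOLD)
    return SubjectMaps(
        t2w_map=t2w_map,
        ff_map=ff_map,
        b1_map=b1_map,
        quality_mask=quality,
        t2f_calibrated_ms=float(t2f_ms),
        provenance={
            "method": method,
            "seq_hash": seq.seq_hash,
            "seed": seed,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "n_voxels": int(signals.shape[0]),
        },
    )


# ---------------------------------------------------------------------------
# Dixon reference and ROI statistics
# ---------------------------------------------------------------------------


def dixon_ff(water_img, fat_img) -> np.ndarray:
    """Reference fat-fraction map in percent: If / (Iw + If) * 100.

    Exact voxel-wise arithmetic, invariant under common intensity scaling;
    voxels with zero total intensity are NaN (flagged invalid).
    """
    w = np.asarray(water_img, dtype=float)
    f = np.asarray(fat_img, dtype=float)
    if w.shape != f.shape:
        raise ValueError("water and fat images must have the same shape")
    if np.any(w < 0) or np.any(f < 0):
        raise ValueError("intensities must be nonnegative")
    total = w + f
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, f / np.where(total > 0, total, 1.0) * 100.0, np.nan)
    return out


def roi_stats(value_map, roi_masks: dict, quality_mask=None) -> pd.DataFrame:
    """Per-ROI mean/sd/voxel-count over unflagged, finite voxels."""
    vm = np.asarray(value_map, dtype=float)
    rows = []
    for name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != vm.shape:
            raise ValueError(f"ROI {name!r} does not match the map shape")
        sel = mask & np.isfinite(vm)
        if quality_mask is not None:
            sel &= np.asarray(quality_mask, dtype=bool)
        vals = vm[sel]
        rows.append(
            {
                "roi": name,
                "mean": float(np.mean(vals)) if vals.size else np.nan,
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else (0.0 if vals.size else np.nan),
                "n_voxels": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def t2f_sensitivity(
    mese_stack,
    t2f_values,
    seq: SequenceConfig,
    method: str = "dict",
    muscle_mask=None,
    model=None,
    dictionary_builder=None,
    **kwargs,
) -> pd.DataFrame:
    """Mean muscle T2w as a function of the assumed calibrated T2f.

    Quantifies how calibration errors propagate into T2w.  For the
    dictionary method a fresh dictionary must be built per T2f, so a
    ``dictionary_builder(t2f_ms)`` callable is required.
    """
    rows = []
    for t2f in t2f_values:
        dic = dictionary_builder(t2f) if (method == "dict" and dictionary_builder) else None
        maps = map_subject(
            mese_stack, t2f, seq, method=method, muscle_mask=muscle_mask,
            model=model, dictionary=dic, **kwargs,
        )
        sel = maps.quality_mask & np.isfinite(maps.t2w_map)
        rows.append({"t2f_ms": float(t2f), "mean_t2w_ms": float(np.mean(maps.t2w_map[sel]))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sequence configuration file
# ---------------------------------------------------------------------------


def sequence_from_yaml(path) -> SequenceConfig:
    """Build a SequenceConfig from a YAML file.

    Keys: ``te_ms``, ``etl``, ``tr_ms`` and a ``profiles`` section — either
    ``{preset: <name>, n_bins: 64}`` or explicit SLR/waveform sources
    (``ex_file``/``ref_file`` with durations, flips and time-bandwidths).
    """
    import yaml

    from .rf_pulses import load_waveform, sequence_profiles

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    prof = cfg.get("profiles", {"preset": "ideal"})
    if "preset" in prof:
        exp, refp = preset_profiles(prof["preset"], prof.get("n_bins", 64))
    else:
        ex = load_waveform(
            prof["ex_file"], prof.get("ex_duration_ms", 2.56), 90.0, "excitation",
            prof.get("ex_tbw"),
        )
        ref = load_waveform(
            prof["ref_file"], prof.get("ref_duration_ms", 2.56), 180.0, "refocusing",
            prof.get("ref_tbw"),
        )
        exp, refp, _ = sequence_profiles(ex, ref, prof.get("n_bins", 64))
    return SequenceConfig(
        te_ms=float(cfg["te_ms"]),
        etl=int(cfg["etl"]),
        tr_ms=float(cfg.get("tr_ms", 5000.0)),
        ex_profile=exp,
        ref_profile=refp,
    )
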