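"""Digital thigh phantom: synthetic multi-echo spin-echo subjects with known
ground truth.

The phantom stands in for in vivo data so the full pipeline — subcutaneous
segmentation, fat-T2 calibration, voxel-wise mapping, ROI statistics — can
be exercised end to end with exact truth maps.  The default layout mimics a
single mid-thigh slice: a bright subcutaneous fat ring (FF = 0.9) around ten
elliptical muscle compartments with graded fat infiltration, on a smooth
left-right B1+ gradient such as a surface-coil transmit field produces.

Noise is Rician (magnitude of a complex Gaussian), the statistics of
acquired magnitude MR images; the noise level is set so every voxel's
first-echo SNR equals the requested value.  The truth T2w values are
assigned to compartments in an order exactly uncorrelated with their fat
fractions, so that an estimator free of fat bias shows a zero regression
slope of estimated T2w on true FF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .epg_core import (
    T1_FAT_MS,
    T1_WATER_MS,
    SequenceConfig,
    mese_single_component_batch,
)

__all__ = ["Compartment", "PhantomSpec", "PhantomData", "make_phantom", "default_thigh_phantom"]


@dataclass(frozen=True)
class Compartment:
    """Elliptical tissue region with homogeneous true parameters."""

    label: str
    center: tuple  # (row, col)
    semi_axes: tuple  # (a_row, a_col) in voxels
    t2w_ms: float
    ff: float


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + tissue truth + acquisition noise of a synthetic subject."""

    shape: tuple = (160, 160)
    compartments: tuple = ()
    ring_center: tuple = (80.0, 80.0)
    ring_radii: tuple = (60.0, 70.0)  # (inner, outer)
    ring_ff: float = 0.9
    ring_t2w_ms: float = 35.0
    t2f_ms: float = 150.0
    b1_range: tuple = (0.8, 1.1)
    snr: float = 100.0  # first-echo SNR; np.inf disables noise
    seed: int = 0

    def __post_init__(self):
        if not (50.0 <= self.t2f_ms <= 250.0):
            raise ValueError("shared t2f must lie in [50, 250] ms")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        masks = [_ellipse_mask(self.shape, c) for c in self.compartments]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                if np.any(masks[i] & masks[j]):
                    raise ValueError(
                        f"compartments {self.compartments[i].label!r} and "
                        f"{self.compartments[j].label!r} overlap"
                    )


def _ellipse_mask(shape, comp: Compartment) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - comp.center[0]) / comp.semi_axes[0]) ** 2 + (
        (cc - comp.center[1]) / comp.semi_axes[1]
    ) ** 2 <= 1.0


@dataclass
class PhantomData:
    """Simulated stack plus ground truth and masks."""

    stack: np.ndarray  # (ny, nx, 1, etl)
    t2w_map: np.ndarray
    ff_map: np.ndarray
    b1_map: np.ndarray
    fat_mask: np.ndarray  # subcutaneous ring
    muscle_masks: dict  # label -> bool mask
    water_img: np.ndarray  # synthetic Dixon-like water-only image
    fat_img: np.ndarray  # synthetic Dixon-like fat-only image
    spec: PhantomSpec
    seq: SequenceConfig

    @property
    def muscle_mask(self) -> np.ndarray:
        out = np.zeros(self.stack.shape[:2], dtype=bool)
        for m in self.muscle_masks.values():
            out |= m
        return out

    def write_nifti(self, outdir) -> None:
        """Write stack, truth maps, masks and the spec JSON to a directory."""
        import nibabel as nib
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aff = np.diag([3.0, 3.0, 6.0, 1.0])  # voxel size like a thigh protocol

        def save(name, arr):
            nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), aff), outdir / name)

        save("mese.nii.gz", self.stack)
        save("truth_t2w.nii.gz", self.t2w_map[..., None])
        save("truth_ff.nii.gz", self.ff_map[..., None])
        save("truth_b1.nii.gz", self.b1_map[..., None])
        save("fat_mask.nii.gz", self.fat_mask.astype(np.float32)[..., None])
        save("water.nii.gz", self.water_img[..., None])
        save("fat.nii.gz", self.fat_img[..., None])
        labels = np.zeros(self.stack.shape[:2], dtype=np.float32)
        for i, (lbl, m) in enumerate(self.muscle_masks.items(), start=1):
            labels[m] = i
        save("muscle_labels.nii.gz", labels[..., None])
        meta = {
            "labels": {str(i): lbl for i, lbl in enumerate(self.muscle_masks, start=1)},
            "t2f_ms": self.spec.t2f_ms,
            "snr": None if np.isinf(self.spec.snr) else self.spec.snr,
            "seed": self.spec.seed,
            "seq": {"te_ms": self.seq.te_ms, "etl": self.seq.etl},
        }
        (outdir / "phantom.json").write_text(json.dumps(meta, indent=2))


def make_phantom(spec: PhantomSpec, seq: SequenceConfig) -> PhantomData:
    """Simulate the phantom: noiseless EPG signals per voxel, then Rician noise.

    Each in-tissue voxel gets the two-pool signal for its local (T2w, FF,
    B1); noise adds independent Gaussians of sigma = S1/snr to both
    quadrature channels of every tissue voxel (and sigma based on the mean
    tissue S1 for background voxels), then takes the magnitude.  Everything
    is reproducible from the seed.
    """
    ny, nx = spec.shape
    t2w_map = np.zeros((ny, nx))
    ff_map = np.zeros((ny, nx))
    tissue = np.zeros((ny, nx), dtype=bool)

    rr, cc = np.mgrid[0:ny, 0:nx]
    rad = np.hypot(rr - spec.ring_center[0], cc - spec.ring_center[1])
    fat_mask = (rad >= spec.ring_radii[0]) & (rad <= spec.ring_radii[1])
    t2w_map[fat_mask] = spec.ring_t2w_ms
    ff_map[fat_mask] = spec.ring_ff
    tissue |= fat_mask

    muscle_masks = {}
    for comp in spec.compartments:
        m = _ellipse_mask(spec.shape, comp)
        if np.any(m & tissue):
            raise ValueError(f"compartment {comp.label!r} overlaps other tissue")
        muscle_masks[comp.label] = m
        t2w_map[m] = comp.t2w_ms
        ff_map[m] = comp.ff
        tissue |= m

    b1_lo, b1_hi = spec.b1_range
    b1_map = b1_lo + (b1_hi - b1_lo) * (cc / max(nx - 1, 1))

    # voxel-wise signals (two pools share the local B1)
    idx = np.where(tissue)
    t2w_v = t2w_map[idx]
    ff_v = ff_map[idx]
    b1_v = b1_map[idx]
    s_wat = mese_single_component_batch(t2w_v, b1_v, T1_WATER_MS, seq)
    s_fat = mese_single_component_batch(
        np.full(t2w_v.size, spec.t2f_ms), b1_v, T1_FAT_MS, seq
    )
    sig = ff_v[:, None] * s_fat + (1.0 - ff_v)[:, None] * s_wat

    stack = np.zeros((ny, nx, 1, seq.etl))
    stack[idx[0], idx[1], 0, :] = sig

    rng = np.random.default_rng(spec.seed)
    if np.isfinite(spec.snr):
        sigma_map = np.zeros((ny, nx))
        sigma_map[idx] = sig[:, 0] / spec.snr
        sigma_map[~tissue] = np.mean(sig[:, 0]) / spec.snr
        noise_re = rng.standard_normal(stack.shape) * sigma_map[:, :, None, None]
        noise_im = rng.standard_normal(stack.shape) * sigma_map[:, :, None, None]
        stack = np.hypot(stack + noise_re, noise_im)

    scale = 1000.0  # arbitrary scanner-like intensity scale
    water_img = scale * (1.0 - ff_map) * tissue
    fat_img = scale * ff_map * tissue

    return PhantomData(
        stack=stack,
        t2w_map=t2w_map,
        ff_map=ff_map,
        b1_map=b1_map,
        fat_mask=fat_mask,
        muscle_masks=muscle_masks,
        water_img=water_img,
        fat_img=fat_img,
        spec=spec,
        seq=seq,
    )


#: Fat fractions of the ten default muscle compartments.
_DEFAULT_FF = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
#: True T2w values (ms), ordered so that corr(T2w, FF) over compartments is 0.
_DEFAULT_T2W = (29.0, 31.0, 33.0, 37.0, 39.0, 43.0, 41.0, 45.0, 25.0, 27.0)


def default_thigh_phantom(seed: int = 0, snr: float = 100.0) -> PhantomSpec:
    """Single-slice 160x160 thigh-like layout.

    Ten elliptical muscle compartments (FF from 0 to 0.8, T2w in [25, 45] ms,
    assigned so truth T2w is uncorrelated with FF) inside a subcutaneous fat
    ring (FF 0.9, shared T2f 150 ms), with a smooth B1+ gradient from 0.8 to
    1.1 across the image.  Different seeds change only the noise, never the
    geometry.
    """
    comps = []
    for k in range(10):
        ang = 2.0 * np.pi * k / 10.0
        comps.append(
            Compartment(
                label=f"muscle_{k:02d}",
                center=(80.0 + 38.0 * np.sin(ang), 80.0 + 38.0 * np.cos(ang)),
                semi_axes=(7.0, 5.0),
                t2w_ms=_DEFAULT_T2W[k],
                ff=_DEFAULT_FF[k],
            )
        )
    return PhantomSpec(
        shape=(160, 160),
        compartments=tuple(comps),
        ring_center=(80.0, 80.0),
        ring_radii=(60.0, 70.0),
        ring_ff=0.9,
        t2f_ms=150.0,
        b1_range=(0.8, 1.1),
        snr=snr,
        seed=seed,
    )
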