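"""EPG signal dictionaries: construction, dot-product matching, SVD compression.

A dictionary is built on a rectangular parameter grid; each atom is a
unit-norm simulated MESE echo train.  A measured voxel is matched by
normalizing it and taking the atom with the maximal dot product (ties broken
by the lowest atom index).  Optionally the dictionary is compressed by
projecting atoms and signals onto the top-k right singular vectors of the
atom matrix, which preserves dot products up to the discarded variance.

The default grids follow the established practice for fat calibration and
muscle mapping:

* fat:    T2f in [50, 250] ms step 0.25, T2w in [10, 110] ms step 0.5,
          B1 in [0.4, 1.2] step 0.025, FF fixed at 0.9;
* muscle: FF in [0, 1] step 0.015, T2w in [10, 80] ms step 0.2,
          B1 in [0.4, 1.2] step 0.025, T2f fixed at the calibrated value.

The B1 step is dimensionless (B1 is a flip-angle efficiency ratio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epg_core import (
    T1_FAT_MS,
    T1_WATER_MS,
    SequenceConfig,
    mese_single_component_batch,
)

__all__ = [
    "ParamGrid",
    "SignalDictionary",
    "CompressedDictionary",
    "build_grid",
    "build_dictionary",
    "match",
    "compress_svd",
    "match_compressed",
    "save_dictionary",
    "load_dictionary",
    "DEFAULT_ATOM_LIMIT",
]

#: Refuse to build larger dictionaries unless explicitly overridden.
DEFAULT_ATOM_LIMIT = 20_000_000


def _axis_points(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class ParamGrid:
    """Ordered rectangular grid: ``axes`` is a list of (name, lo, hi, step)."""

    axes: tuple
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        for name, lo, hi, step in self.axes:
            if step <= 0:
                raise ValueError(f"axis {name}: step must be > 0")
            if hi < lo:
                raise ValueError(f"axis {name}: max must be >= min")

    def axis_values(self, name: str) -> np.ndarray:
        for nm, lo, hi, step in self.axes:
            if nm == name:
                return _axis_points(lo, hi, step)
        raise KeyError(name)

    @property
    def axis_names(self) -> list:
        return [a[0] for a in self.axes]

    @property
    def shape(self) -> tuple:
        return tuple(self.axis_values(a[0]).size for a in self.axes)

    @property
    def n_points(self) -> int:
        return int(np.prod(self.shape))

    def points(self) -> np.ndarray:
        """All grid points, lexicographic over the axes as listed; (n, ndim)."""
        values = [self.axis_values(nm) for nm in self.axis_names]
        mesh = np.meshgrid(*values, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)


def build_grid(kind: str, **overrides) -> ParamGrid:
    """Default fat or muscle parameter grid, with optional axis overrides.

    Overrides are given as ``name=(lo, hi, step)``; the muscle grid requires
    a calibrated ``t2f`` (ms) fixed value, the fat grid fixes ``ff=0.9``.
    """
    if kind == "fat":
        axes = {
            "t2f": (50.0, 250.0, 0.25),
            "t2w": (10.0, 110.0, 0.5),
            "b1": (0.4, 1.2, 0.025),
        }
        fixed = {"ff": 0.9}
    elif kind == "muscle":
        t2f = float(overrides.pop("t2f", 151.0))
        if not (50.0 <= t2f <= 250.0):
            raise ValueError("calibrated t2f must lie in [50, 250] ms")
        axes = {
            "ff": (0.0, 1.0, 0.015),
            "t2w": (10.0, 80.0, 0.2),
            "b1": (0.4, 1.2, 0.025),
        }
        fixed = {"t2f": t2f}
    else:
        raise ValueError(f"unknown grid kind {kind!r}")
    for name, spec in overrides.items():
        if name not in axes:
            raise KeyError(f"unknown axis {name!r} for kind {kind!r}")
        lo, hi, step = map(float, spec)
        if step <= 0 or hi < lo:
            raise ValueError(f"invalid override for axis {name}: {spec}")
        axes[name] = (lo, hi, step)
    return ParamGrid(
        axes=tuple((nm, *axes[nm]) for nm in axes),
        fixed=fixed,
    )


@dataclass(frozen=True)
class SignalDictionary:
    """Unit-norm simulated echo trains plus the grid that generated them."""

    atoms: np.ndarray  # (n_atoms, etl)
    grid: ParamGrid
    seq_hash: str

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def etl(self) -> int:
        return self.atoms.shape[1]


def build_dictionary(
    grid: ParamGrid,
    seq: SequenceConfig,
    atom_limit: int = DEFAULT_ATOM_LIMIT,
    force: bool = False,
) -> SignalDictionary:
    """Simulate one atom per grid point and normalize each to unit norm.

    Two-component simulations are factorized: unique single-pool echo trains
    are computed once per distinct (T2, B1) pair, then mixed linearly over
    the fat-fraction axis, which makes the large default grids tractable.
    Atom ordering is lexicographic over the axes as listed in the grid.
    """
    if grid.n_points > atom_limit and not force:
        raise MemoryError(
            f"grid has {grid.n_points} atoms > limit {atom_limit}; pass force=True"
        )
    names = grid.axis_names
    params = {nm: grid.axis_values(nm) for nm in names}
    fixed = dict(grid.fixed)

    def axis_or_fixed(nm):
        if nm in params:
            return params[nm]
        return np.array([fixed[nm]])

    t2f = axis_or_fixed("t2f")
    t2w = axis_or_fixed("t2w")
    ff = axis_or_fixed("ff")
    b1 = axis_or_fixed("b1")

    # unique (t2, b1) pairs per pool
    tf, bf = np.meshgrid(t2f, b1, indexing="ij")
    s_fat = mese_single_component_batch(tf.ravel(), bf.ravel(), T1_FAT_MS, seq).reshape(
        t2f.size, b1.size, seq.etl
    )
    tw, bw = np.meshgrid(t2w, b1, indexing="ij")
    s_wat = mese_single_component_batch(tw.ravel(), bw.ravel(), T1_WATER_MS, seq).reshape(
        t2w.size, b1.size, seq.etl
    )

    # assemble in lexicographic order of the grid axes
    shape = grid.shape
    atoms = np.empty((grid.n_points, seq.etl))
    pts_idx = np.indices(shape).reshape(len(shape), -1)
    idx = {nm: pts_idx[i] for i, nm in enumerate(names)}
    zero = np.zeros(grid.n_points, dtype=int)
    i_t2f = idx.get("t2f", zero)
    i_t2w = idx.get("t2w", zero)
    i_b1 = idx.get("b1", zero)
    ffv = ff[idx["ff"]] if "ff" in idx else np.full(grid.n_points, fixed["ff"])
    atoms = (
        ffv[:, None] * s_fat[i_t2f, i_b1, :]
        + (1.0 - ffv)[:, None] * s_wat[i_t2w, i_b1, :]
    )
    norms = np.linalg.norm(atoms, axis=1)
    norms[norms == 0] = 1.0
    atoms /= norms[:, None]
    return SignalDictionary(atoms=atoms, grid=grid, seq_hash=seq.seq_hash)


def _normalize_signals(signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    norms = np.linalg.norm(signals, axis=1)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    return signals / safe[:, None], valid


def _result_table(dictionary, best, scores, valid):
    pts = dictionary.grid.points()
    out = {}
    for i, nm in enumerate(dictionary.grid.axis_names):
        col = pts[best, i].astype(float)
        col[~valid] = np.nan
        out[nm] = col
    scores = scores.astype(float)
    scores[~valid] = np.nan
    out["score"] = scores
    return out


def match(signals: np.ndarray, dictionary: SignalDictionary, chunk: int | None = None) -> dict:
    """Match each signal to its best dictionary atom by normalized dot product.

    Returns a dict of per-voxel parameter arrays (one key per grid axis)
    plus ``score``.  All-zero signals are flagged invalid (NaN outputs).
    Ties are broken by the lowest atom index.
    """
    sig, valid = _normalize_signals(signals)
    if sig.shape[1] != dictionary.etl:
        raise ValueError("signal length does not match dictionary echo count")
    n = sig.shape[0]
    if chunk is None:
        # keep the score block around ~2e7 elements (~160 MB)
        chunk = max(1, int(2e7 / max(dictionary.n_atoms, 1)))
    best = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    for i0 in range(0, n, chunk):
        dots = sig[i0 : i0 + chunk] @ dictionary.atoms.T
        best[i0 : i0 + chunk] = np.argmax(dots, axis=1)
        scores[i0 : i0 + chunk] = np.max(dots, axis=1)
    return _result_table(dictionary, best, scores, valid)


@dataclass(frozen=True)
class CompressedDictionary:
    """Rank-k SVD compression of a dictionary."""

    basis: np.ndarray  # (k, etl) top right singular vectors
    projected_atoms: np.ndarray  # (n_atoms, k)
    explained_variance_ratio: np.ndarray  # per component, uncentered atoms
    explained_variance_ratio_centered: np.ndarray  # diagnostic: mean-removed
    grid: ParamGrid
    seq_hash: str
    etl: int

    @property
    def k(self) -> int:
        return self.basis.shape[0]


def compress_svd(dictionary: SignalDictionary, k: int) -> CompressedDictionary:
    """Project the atom matrix onto its top-k right singular vectors.

    The explained-variance ratios are computed from the squared singular
    values of the *raw* (uncentered) atom matrix, consistent with matching
    on raw dot products.
    """
    if not (1 <= k <= dictionary.etl):
        raise ValueError(f"k must be in [1, {dictionary.etl}]")
    _, s, vt = np.linalg.svd(dictionary.atoms, full_matrices=False)
    evr = (s**2) / np.sum(s**2)
    sc = np.linalg.svd(
        dictionary.atoms - dictionary.atoms.mean(axis=0), compute_uv=False
    )
    evr_centered = (sc**2) / np.sum(sc**2)
    basis = vt[:k]
    return CompressedDictionary(
        basis=basis,
        projected_atoms=dictionary.atoms @ basis.T,
        explained_variance_ratio=evr,
        explained_variance_ratio_centered=evr_centered,
        grid=dictionary.grid,
        seq_hash=dictionary.seq_hash,
        etl=dictionary.etl,
    )


def match_compressed(
    signals: np.ndarray, cdict: CompressedDictionary, chunk: int | None = None
) -> dict:
    """As :func:`match`, using k-dimensional projections of signals and atoms."""
    sig, valid = _normalize_signals(signals)
    if sig.shape[1] != cdict.etl:
        raise ValueError("signal length does not match dictionary echo count")
    proj = sig @ cdict.basis.T
    n = proj.shape[0]
    if chunk is None:
        chunk = max(1, int(2e7 / max(cdict.projected_atoms.shape[0], 1)))
    best = np.zeros(n, dtype=int)
    scores = np.zeros(n)
    for i0 in range(0, n, chunk):
        dots = proj[i0 : i0 + chunk] @ cdict.projected_atoms.T
        best[i0 : i0 + chunk] = np.argmax(dots, axis=1)
        scores[i0 : i0 + chunk] = np.max(dots, axis=1)
    return _result_table(cdict, best, scores, valid)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_dictionary(dictionary: SignalDictionary, path) -> None:
    """Persist as HDF5: /atoms, /axes/<name>, /fixed, seq_hash attribute."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("atoms", data=dictionary.atoms)
        ax = f.create_group("axes")
        for name, lo, hi, step in dictionary.grid.axes:
            d = ax.create_dataset(name, data=np.array([lo, hi, step]))
            d.attrs["spec"] = "lo hi step"
        fx = f.create_group("fixed")
        for k, v in dictionary.grid.fixed.items():
            fx.attrs[k] = v
        f.attrs["seq_hash"] = dictionary.seq_hash
        f.attrs["axis_order"] = ",".join(dictionary.grid.axis_names)


def load_dictionary(path) -> SignalDictionary:
    import h5py

    with h5py.File(path, "r") as f:
        atoms = f["atoms"][...]
        order = f.attrs["axis_order"].split(",")
        axes = tuple((nm, *map(float, f["axes"][nm][...])) for nm in order)
        fixed = {k: float(v) for k, v in f["fixed"].attrs.items()}
        seq_hash = f.attrs["seq_hash"]
    return SignalDictionary(atoms=atoms, grid=ParamGrid(axes=axes, fixed=fixed), seq_hash=seq_hash)
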