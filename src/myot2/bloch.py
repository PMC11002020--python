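"""Time-domain isochromat (Bloch) simulation of MESE echo trains.

This is an independent cross-check for the EPG recursion: instead of
configuration states it propagates classical magnetization vectors for a set
of isochromats that accumulate crusher-gradient phase, then averages their
transverse magnetization at the echo times.  With the dephasing angles on a
uniform grid of ``n_dephase`` points, the isochromat average is exact for all
coherence orders below ``n_dephase``, so the two simulations should agree to
numerical precision — any systematic difference indicates a bug in one of
them.
"""

from __future__ import annotations

import numpy as np

from .epg_core import SequenceConfig

__all__ = ["rotation_about_transverse_axis", "mese_bloch"]


def rotation_about_transverse_axis(flip_rad: float, phase_rad: float) -> np.ndarray:
    """3x3 rotation by ``flip`` about the in-plane axis (cos p, sin p, 0)."""
    c, s = np.cos(flip_rad), np.sin(flip_rad)
    cp, sp = np.cos(phase_rad), np.sin(phase_rad)
    # Rodrigues formula for unit axis u = (cp, sp, 0)
    return np.array(
        [
            [c + cp * cp * (1 - c), cp * sp * (1 - c), sp * s],
            [cp * sp * (1 - c), c + sp * sp * (1 - c), -cp * s],
            [-sp * s, cp * s, c],
        ]
    )


def mese_bloch(
    t1_ms: float,
    t2_ms: float,
    b1: float,
    seq: SequenceConfig,
    n_dephase: int = 128,
    scale_excitation: bool = False,
) -> np.ndarray:
    """MESE echo magnitudes by brute-force isochromat simulation.

    For every sub-slice bin of the sequence profiles, ``n_dephase``
    isochromats (uniform crusher phase grid) are propagated through
    excitation, the CPMG refocusing train, relaxation, and per-half-TE
    dephasing.  Echoes are the magnitude of the complex transverse average
    over all isochromats and bins — directly comparable to
    :func:`myot2.epg_core.mese_single_component`.

    ``n_dephase`` must exceed the largest coherence order (2 * etl + 1) for
    the average to be alias-free; the default 128 is exact for etl <= 63.
    """
    if n_dephase <= 2 * seq.etl + 1:
        raise ValueError("n_dephase must exceed 2*etl + 1 to avoid coherence aliasing")
    nbins = seq.n_bins
    e1 = np.exp(-0.5 * seq.te_ms / t1_ms)
    e2 = np.exp(-0.5 * seq.te_ms / t2_ms)
    theta = 2.0 * np.pi * np.arange(n_dephase) / n_dephase
    ct, st = np.cos(theta), np.sin(theta)

    echoes = np.zeros(seq.etl, dtype=complex)
    for j in range(nbins):
        m = np.zeros((n_dephase, 3))
        m[:, 2] = 1.0
        ex = np.deg2rad(seq.ex_profile[j]) * (b1 if scale_excitation else 1.0)
        m = m @ rotation_about_transverse_axis(ex, 0.0).T
        r_ref = rotation_about_transverse_axis(np.deg2rad(seq.ref_profile[j]) * b1, np.pi / 2)
        for e in range(seq.etl):
            for _half in range(2):
                # relaxation then crusher dephasing (z-rotation per isochromat)
                m[:, 0] *= e2
                m[:, 1] *= e2
                m[:, 2] = m[:, 2] * e1 + (1.0 - e1)
                mx = m[:, 0] * ct - m[:, 1] * st
                my = m[:, 0] * st + m[:, 1] * ct
                m[:, 0], m[:, 1] = mx, my
                if _half == 0:
                    m = m @ r_ref.T
            echoes[e] += np.mean(m[:, 0] + 1j * m[:, 1])
    return np.abs(echoes) / nbins
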