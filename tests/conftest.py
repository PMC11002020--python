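"""Shared fixtures.

Expensive resources (slice-profile sequence, scaled-down trained regressors,
the noisy phantom) are session-scoped so the recovery tests and the
end-to-end tests reuse them instead of rebuilding.
"""

import numpy as np
import pytest

from myot2.epg_core import SequenceConfig
from myot2.nn_fit import build_model, train
from myot2.phantom import default_thigh_phantom, make_phantom
from myot2.rf_pulses import preset_profiles

#: Scaled-down training recipe used throughout the suite.
TRAIN_KW = dict(n_train=20_000, epochs=30, steps_per_epoch=200, batch=256)


@pytest.fixture(scope="session")
def seq_ideal():
    """Single-bin perfect 90/180 pulses: the CPMG analytic limit."""
    return SequenceConfig(te_ms=7.5, etl=17)


@pytest.fixture(scope="session")
def seq_profile():
    """Realistic SLR slice profiles (generic Siemens-like preset, 64 bins)."""
    ex, ref = preset_profiles("generic-siemens-like", 64)
    return SequenceConfig(te_ms=7.5, etl=17, tr_ms=5633.0, ex_profile=ex, ref_profile=ref)


@pytest.fixture(scope="session")
def muscle_bundle(seq_profile):
    """Muscle-Net after the scaled-down training run."""
    bundle = build_model("muscle", etl=seq_profile.etl, seed=0)
    return train(bundle, seq_profile, seed=1, **TRAIN_KW)


@pytest.fixture(scope="session")
def fat_bundle(seq_profile):
    """Fat-Net after the scaled-down training run."""
    bundle = build_model("fat", etl=seq_profile.etl, seed=0)
    return train(bundle, seq_profile, seed=2, **TRAIN_KW)


@pytest.fixture(scope="session")
def thigh_phantom(seq_profile):
    """Default thigh phantom at first-echo SNR 100."""
    return make_phantom(default_thigh_phantom(seed=7, snr=100.0), seq_profile)


@pytest.fixture(scope="session")
def thigh_phantom_noiseless(seq_profile):
    return make_phantom(default_thigh_phantom(seed=7, snr=np.inf), seq_profile)


@pytest.fixture(scope="session")
def calib_dict(seq_profile):
    """Fat-calibration dictionary at 1 ms T2f resolution."""
    from myot2.dictionary_fit import build_dictionary, build_grid

    grid = build_grid("fat", t2f=(50.0, 250.0, 1.0), t2w=(10.0, 110.0, 2.0))
    return build_dictionary(grid, seq_profile)


@pytest.fixture(scope="session")
def muscle_dict(seq_profile):
    """Muscle dictionary on the default (uncoarsened) grid, T2f 150 ms."""
    from myot2.dictionary_fit import build_dictionary, build_grid

    return build_dictionary(build_grid("muscle", t2f=150.0), seq_profile)
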