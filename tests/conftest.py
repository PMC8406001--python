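"""Shared fixtures: canonical parameter sets and synthetic inputs."""

import numpy as np
import pytest

from ttrstab import StabilityModelParams, params_from_midpoints

#: protomer concentration used throughout: 1.5 uM tetramer = 6 uM protomer
PROTOMER_CONC = 6.0e-6


@pytest.fixture
def wt_params() -> StabilityModelParams:
    """Wild-type-like single-population truth: Cm1 = 3.2 M at 1.5 uM tetramer.

    The monomer-unfolding midpoint sits far above the sampled window and the
    intermediate/unfolded baselines coincide, so the curve is a clean single
    dissociation transition.
    """
    return params_from_midpoints(
        PROTOMER_CONC, cm1=3.2, m_diss=2.0, cm_unf=15.0, m_unf=2.0,
        s_T0=1.0, s_M0=2.0, s_U0=2.0,
    )


@pytest.fixture
def twopop_params() -> StabilityModelParams:
    """Two-population truth: 40% stabilized tetramers, transitions at 2.0/6.5 M."""
    return params_from_midpoints(
        PROTOMER_CONC, cm1=2.0, m_diss=2.0, cm_unf=15.0, m_unf=2.0,
        alpha_stab=0.4, cm2=6.5, m2_app=4.0,
        s_T0=1.0, s_M0=2.0, s_U0=2.0,
    )


@pytest.fixture
def urea_grid() -> np.ndarray:
    return np.linspace(0.0, 9.0, 30)
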