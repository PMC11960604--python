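import numpy as np
import pytest

from synpet.frames import TimeActivityCurve, default_schedule
from synpet.kinetics import ReferenceBasis
from synpet.simulate import CohortConfig, InputFunctionParams, simulate_cohort, \
    simulate_tissue_tac

REF_K1 = 0.3
REF_K2 = 0.055


@pytest.fixture(scope="session")
def schedule():
    """The 35-frame / 90-min acquisition schedule."""
    return default_schedule()


@pytest.fixture(scope="session")
def plasma():
    return InputFunctionParams(scale=0.072)


@pytest.fixture(scope="session")
def ref_tac(schedule, plasma):
    """Noiseless 1TC reference-tissue curve (K1'=0.3, k2'=0.055 /min)."""
    tac = simulate_tissue_tac(REF_K1, REF_K2, plasma, schedule)
    tac.name = "reference"
    return tac


@pytest.fixture(scope="session")
def ref_basis(ref_tac):
    return ReferenceBasis(ref_tac)


def srtm_forward(ref_basis, r1, k2p, bp_nd):
    """Noiseless SRTM-consistent target curve from its generative
    parameters — the forward-model oracle for the fitters."""
    k2 = r1 * k2p
    k2a = k2 / (bp_nd + 1.0)
    phi = k2 - r1 * k2a
    values = r1 * ref_basis.cr_frames + phi * ref_basis.basis(k2a)
    return TimeActivityCurve.from_schedule(ref_basis.reference.schedule, values)


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-subject cohort at default noise, for the cheaper end-to-end
    checks."""
    return simulate_cohort(CohortConfig(seed=7, n_young=3, n_old=4, n_patient=3))


@pytest.fixture(scope="session")
def cohort28():
    """The default-size 28-subject cohort at default noise."""
    return simulate_cohort(CohortConfig(seed=11))
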