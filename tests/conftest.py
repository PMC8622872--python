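import numpy as np
import pytest

from bcellfate import presets
from bcellfate.models import ModelConfig, KineticParams
from bcellfate.simulate import CohortDesign, NoiseModel


class ConstantSource:
    """Source with constant size / chimerism / Ki67 (analytic test bed)."""

    def __init__(self, size=1e7, chi=1.0, kappa=0.8, chi_stable=None, t_min=0.0):
        self._size = size
        self._chi = chi
        self._kappa = kappa
        self.chi_stable = chi if chi_stable is None else chi_stable
        self.t_min = t_min
        self.t_max = 1e9

    def size(self, t):
        return np.full_like(np.asarray(t, float), self._size)

    def chimerism(self, t, t_bmt):
        return np.full_like(np.asarray(t, float), self._chi)

    def ki67(self, t):
        return np.full_like(np.asarray(t, float), self._kappa)


@pytest.fixture(scope="session")
def const_source():
    return ConstantSource


@pytest.fixture(scope="session")
def fm_ref():
    return presets.fm_reference()


@pytest.fixture(scope="session")
def gc_spleen_ref():
    return presets.gc_spleen_reference()


@pytest.fixture(scope="session")
def gc_ln_ref():
    return presets.gc_ln_reference()


@pytest.fixture(scope="session")
def default_noise():
    return presets.DEFAULT_NOISE


def compact_design(n_per_group=5, seed=0, noise=presets.DEFAULT_NOISE):
    """Small cohort with one transplant date per group (fast likelihoods)."""
    return CohortDesign(
        groups=((42.0, 42.0, n_per_group), (70.0, 70.0, n_per_group), (98.0, 98.0, n_per_group)),
        sampling_ages=np.arange(77.0, 601.0, 7.0),
        noise=noise,
        seed=seed,
    )


@pytest.fixture(scope="session")
def fm_small_cohort(fm_ref):
    from bcellfate.simulate import simulate_cohort

    config, params, source = fm_ref
    return simulate_cohort(compact_design(5, seed=11), config, params, source)
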