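import numpy as np
import pytest

from mdpmm.electronic import UnperturbedSet
from mdpmm.fixtures import FixtureSpec, mock_unperturbed_set
from mdpmm.pmm import PerturbingFrame


def make_two_level_set(e0=0.0, e1=0.25, mu_offdiag=0.8, mu_diag=(0.0, 0.0)):
    """Minimal 2-state set with one electric-dipole component populated."""
    elec = np.zeros((3, 2, 2))
    elec[0] = [[mu_diag[0], mu_offdiag], [mu_offdiag, mu_diag[1]]]
    mag = np.zeros((3, 2, 2), complex)
    mag[0] = 1j * np.array([[0.0, 0.5], [-0.5, 0.0]])
    return UnperturbedSet(
        state_energies=[e0, e1], elec_dipole=elec, mag_dipole=mag,
        qc_charges=[0.4, -0.4], qc_masses=[12.0, 16.0],
        qc_positions=[[0.0, 0.0, 0.0], [0.15, 0.0, 0.0]],
        total_charge=0.0, label="two-level").validate()


@pytest.fixture
def two_level_set():
    return make_two_level_set()


@pytest.fixture(scope="session")
def mock17():
    """A 17-state randomized set, the standard basis-set size."""
    return mock_unperturbed_set(FixtureSpec(n_states=17, seed=42))


@pytest.fixture(scope="session")
def small_set():
    return mock_unperturbed_set(FixtureSpec(n_states=5, seed=7))


def empty_frame(uset, index=0):
    return PerturbingFrame(env_positions=np.zeros((0, 3)),
                           env_charges=np.zeros(0),
                           qc_positions=uset.qc_positions,
                           frame_index=index)
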