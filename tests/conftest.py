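import numpy as np
import pytest

from bindmode.energetics import select_key_waters
from bindmode.reference import system_states
from bindmode.simulate import GeneratorConfig, StateSpec, ToyComplexSpec, gen_toy_complex
from bindmode.structures import BindingPartition


@pytest.fixture(scope="session")
def atp_complex():
    """Toy natural-ligand system: 2 ions, 3 key waters, contacts 1000-1002,
    ion-anchoring acidic residues 1003-1004."""
    spec = ToyComplexSpec(n_frames=40, n_bulk_waters=20)
    structure, traj = gen_toy_complex(spec, seed=11)
    return structure, traj


@pytest.fixture(scope="session")
def inhibitor_complex():
    """Toy inhibitor system: no ions, 1 key water, contacts 1000/1005/1006."""
    spec = ToyComplexSpec(
        n_frames=40, n_bulk_waters=20,
        contact_residues=(0, 5, 6), acidic_residues=(), n_ions=0, n_key_waters=1,
    )
    structure, traj = gen_toy_complex(spec, seed=12)
    return structure, traj


@pytest.fixture(scope="session")
def atp_partition(atp_complex):
    _, traj = atp_complex
    return BindingPartition(ligand_water_residues=frozenset(select_key_waters(traj)))


@pytest.fixture()
def egfr_atp_states():
    return [StateSpec.from_reference_row(r) for _, r in system_states("EGFRa-ATP").iterrows()]


@pytest.fixture()
def small_two_state_config():
    states = (
        StateSpec("low", (-20.0, -30.0, 25.0, -5.0), (2.0, 3.0, 2.0, 0.2), 0.5, total_sd=2.0),
        StateSpec("high", (-15.0, -25.0, 22.0, -4.0), (2.0, 3.0, 2.0, 0.2), 0.5, total_sd=2.0),
    )
    return GeneratorConfig(states=states, n_replicates=2, n_frames=600, mean_dwell=80.0, seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
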