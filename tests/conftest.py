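import numpy as np
import pytest

from ensdyn.ensemble_io import Atom, StructuralEnsemble
from ensdyn.synthetic_data import SyntheticEnsembleSpec, generate_two_domain_ensemble


def make_atoms(n, name="CA", resname="ALA", chain="A", start_resid=1, element="C"):
    return [
        Atom(
            serial=i + 1,
            name=name,
            resname=resname,
            chain=chain,
            resid=start_resid + i,
            element=element,
        )
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_ensemble(rng):
    """3 models x 5 CA atoms with random (non-degenerate) coordinates."""
    coords = rng.normal(0, 5, size=(3, 5, 3))
    return StructuralEnsemble(coords=coords, atoms=make_atoms(5), source_id="toy")


@pytest.fixture
def default_spec():
    return SyntheticEnsembleSpec(seed=42)


@pytest.fixture
def synthetic_ensemble(default_spec):
    return generate_two_domain_ensemble(default_spec)


@pytest.fixture
def bimodal_spec():
    """Planted open/closed fixture used by the masking analyses."""
    return SyntheticEnsembleSpec(
        n_models=20,
        twist_amplitude_sd=0.05,
        bend_amplitude_sd=0.25,
        noise_sd=0.1,
        bimodal_bend=True,
        seed=1,
    )
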