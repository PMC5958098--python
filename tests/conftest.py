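import numpy as np
import pytest

from prismfold.model_core import SymmetryModel
from prismfold.restraint_engine import (
    InterfacePin,
    RestraintSet,
    find_hbond_donors,
    hbond_restraints,
    restraints_from_peaks,
    symmetrize,
)
from prismfold.synthetic_data import (
    NoeSimSpec,
    ToyTrimerSpec,
    make_toy_trimer,
    simulate_noes,
    toy_interfaces,
    toy_torsion_restraints,
)


@pytest.fixture(scope="session")
def sym():
    return SymmetryModel()


@pytest.fixture(scope="session")
def toy_trimer():
    """The default strand-swapped prism surrogate (19 residues/chain)."""
    return make_toy_trimer(ToyTrimerSpec())


@pytest.fixture(scope="session")
def small_trimer():
    """A smaller prism for fast annealing unit tests."""
    return make_toy_trimer(ToyTrimerSpec(n_res=16))


@pytest.fixture(scope="session")
def toy_peaks(toy_trimer):
    return simulate_noes(toy_trimer, NoeSimSpec())


@pytest.fixture(scope="session")
def toy_pins():
    return [
        InterfacePin(v["regions"][0], v["regions"][1], v["true_label"])
        for v in toy_interfaces(19).values()
    ]


@pytest.fixture(scope="session")
def toy_restraints(toy_trimer, toy_peaks, toy_pins, sym):
    """The full blinded restraint set of the default toy: NOE + hydrogen
    bonds + strand torsions, symmetrized."""
    distance = restraints_from_peaks(toy_peaks, toy_pins)
    distance += hbond_restraints(find_hbond_donors(toy_trimer, sym))
    return symmetrize(
        RestraintSet(distance=distance, torsion=toy_torsion_restraints(19)),
        sym,
    )
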