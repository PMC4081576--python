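import numpy as np
import pytest

from qsarkit.chemio import Compound, ic50_to_pic50
from qsarkit.synthdata import SynthConfig, generate_dataset


def make_compound(cid: str, smiles: str, ic50: float, target_class: str = "wild") -> Compound:
    return Compound(
        compound_id=cid,
        smiles=smiles,
        ic50=ic50,
        pic50=ic50_to_pic50(ic50),
        target_class=target_class,
    )


@pytest.fixture
def small_compounds() -> list[Compound]:
    """Six hand-written molecules, two classes, nM-scale potencies."""
    return [
        make_compound("w1", "c1ccc2ncncc2c1", 12.0, "wild"),
        make_compound("w2", "Cc1nc(Nc2ccccc2)c3ccccc3n1", 55.0, "wild"),
        make_compound("w3", "COc1ccc2ncnc(Nc3ccccc3)c2c1", 3.0, "wild"),
        make_compound("m1", "Nc1ncnc2[nH]ncc12", 480.0, "mutant"),
        make_compound("m2", "Cc1nn(C)c2nc(C)nc(N)c12", 150.0, "mutant"),
        make_compound("m3", "CCc1nn(C)c2ncnc(N)c12", 920.0, "mutant"),
    ]


@pytest.fixture(scope="session")
def synth_small():
    """A 32+32 two-class synthetic dataset shared across tests."""
    cfg = SynthConfig(n_per_class=32, seed=7)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def synth_wild_128():
    """The 128-compound single-class (quinazoline) study set."""
    cfg = SynthConfig(n_per_class=128, n_class_b=0, seed=1)
    return generate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
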