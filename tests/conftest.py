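import numpy as np
import pytest

from hdxscreen.uptake import Peptide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190607)


@pytest.fixture(scope="session")
def toy_peptides():
    """Three overlapping peptides on a 30-residue toy construct (1-based)."""
    return [
        Peptide(id="1-10(2)", sequence="ACDEFGHIKL", start=1, end=10, charge=2),
        Peptide(id="8-17(1)", sequence="IKLMNQRSTV", start=8, end=17, charge=1),
        Peptide(id="15-24(2)", sequence="TVWYACDEFG", start=15, end=24, charge=2),
    ]


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete simulated screen (12 compounds) shared by tests."""
    from hdxscreen.exchange_model import simulate_screen_study

    return simulate_screen_study(seed=7, n_compounds=12)
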