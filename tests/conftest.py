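import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from nmakit import energetics as en
from nmakit import modes as md
from nmakit import synthetic as syn
from nmakit.structure import select


@pytest.fixture(scope="session")
def chain10():
    """10-bead harmonic chain: (potential, coords, longitudinal oracle)."""
    return syn.harmonic_chain(10, k=1.0, m=1.0)


@pytest.fixture(scope="session")
def chain10_modes(chain10):
    pot, coords, _ = chain10
    H = en.mass_weight(en.numerical_hessian(pot, coords))
    return md.diagonalize_full(H)


@pytest.fixture(scope="session")
def folded100():
    """100-node connected Cα toy with its full-diagonalization mode set."""
    s = syn.folded_chain_structure(100, seed=3)
    sel = select(s, "name CA")
    H = en.mass_weight(en.anm_hessian(s, sel, en.ANMParameters(cutoff=10.0)))
    return s, sel, H, md.diagonalize_full(H)


@pytest.fixture(scope="session")
def hinge_toy():
    """Committed-seed open/closed hinge pair with open-form ANM modes."""
    open_s, closed_s = syn.hinge_pair(seed=0)
    sel = select(open_s, "name CA")
    H = en.mass_weight(en.anm_hessian(open_s, sel, en.ANMParameters(cutoff=12.0)))
    return open_s, closed_s, sel, md.diagonalize_full(H)
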