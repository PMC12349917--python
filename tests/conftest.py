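import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pisrank import (
    FixtureRecipe,
    InterfaceSet,
    PaeMatrix,
    Token,
    make_complex,
)


@pytest.fixture
def dimer():
    """A touching two-chain fixture (gap 4.4 Å < 4.5 Å cutoff)."""
    structure, spec = make_complex(FixtureRecipe(seed=1))
    return structure, spec


@pytest.fixture
def dimer_structure(dimer):
    return dimer[0]


@pytest.fixture
def dimer_jobspec(dimer):
    return dimer[1]


@pytest.fixture
def separated_dimer():
    """Two chains 20 Å apart: no interface at the default cutoff."""
    structure, _ = make_complex(FixtureRecipe(seed=2, inter_chain_gap=20.0))
    return structure


def two_residue_interface(e01: float, e10: float = None):
    """A minimal 2-token PAE + interface over one residue per chain."""
    if e10 is None:
        e10 = e01
    tokens = [Token("A", 1), Token("B", 1)]
    pae = PaeMatrix(values=[[0.0, e01], [e10, 0.0]], token_map=tokens)
    interface = InterfaceSet(
        residues=(("A", 1), ("B", 1)),
        by_chain={"A": (("A", 1),), "B": (("B", 1),)},
        cutoff_used=4.5,
    )
    return pae, interface
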