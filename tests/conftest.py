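import numpy as np
import pytest

from pepscreen.structio import Atom, Structure, annotate
from pepscreen.synth import build_peptide


def make_atom(serial=1, name="CA", element="C", resname="ALA", resseq=1, chain="A",
              pos=(0.0, 0.0, 0.0), **kw):
    return Atom(
        serial=serial, name=name, element=element, residue_name=resname,
        residue_seq=resseq, insertion_code="", chain_id=chain,
        position=np.array(pos, dtype=float), **kw,
    )


@pytest.fixture
def helical_peptide():
    """Tetra-alanine at canonical helical torsions, annotated."""
    return build_peptide("AAAA", [(-60.0, -45.0, 180.0)] * 4)


@pytest.fixture
def single_carbon():
    s = Structure(atoms=[make_atom()], label="one-carbon")
    return annotate(s)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
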