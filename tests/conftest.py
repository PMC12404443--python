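import numpy as np
import pytest

import ardscan as a
from ardscan import synth


@pytest.fixture(scope="session")
def helix_pdb(tmp_path_factory):
    """20-residue poly-Ala ideal helix written as a PDB file."""
    path = tmp_path_factory.mktemp("structures") / "helix20.pdb"
    path.write_text(synth.generate_helix_structure(20))
    return path


@pytest.fixture(scope="session")
def helix_residue_sasa(helix_pdb):
    atoms = a.read_structure(helix_pdb)
    per_atom = a.shrake_rupley(atoms)
    return a.residue_sasa(per_atom, atoms), atoms, per_atom


@pytest.fixture()
def m308_spectrum():
    """The published M308 missense spectrum (gnomAD 4.1, rat numbering)."""
    return a.VariantSpectrum(308, "M", {"V": 121, "T": 8, "I": 2, "R": 2})


@pytest.fixture(scope="session")
def ard_like_residues():
    """251 residues (positions 111–361) with sorted random fractional SASA."""
    rng = np.random.default_rng(0)
    fsasa = np.sort(rng.beta(1.2, 2.0, 251))
    return [
        a.ResidueSASA("A", 111 + i, "A", float(f) * 129.0, float(f))
        for i, f in enumerate(fsasa)
    ]
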