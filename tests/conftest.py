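import numpy as np
import pytest

from pocketome.interactions import detect_interactions
from pocketome.motif_builder import Motif
from pocketome.synthetic import make_complex


@pytest.fixture(scope="session")
def fx_complex():
    """Deterministic pseudo-protein/ligand complex with designed contacts."""
    return make_complex(0)


@pytest.fixture(scope="session")
def fx_records(fx_complex):
    return detect_interactions(fx_complex.receptor, fx_complex.ligand,
                               ligand_chemistry=fx_complex.chemistry)


@pytest.fixture(scope="session")
def fx_motif(fx_complex, fx_records):
    wanted = {r.residue_id[:3] for r in fx_records}
    residues = sorted((r for r in fx_complex.receptor.residues if r.id in wanted),
                      key=lambda r: r.id)
    return Motif(centroid_index=0, residues=residues,
                 interactions=list(fx_records), label="motif_0")


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00  0.00           C
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p
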