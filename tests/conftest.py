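import gemmi
import numpy as np
import pytest

from pairpssm import bundled_potential
from pairpssm.fixtures import FixtureSpec, make_toy_dimer


@pytest.fixture(scope="session")
def potential():
    return bundled_potential()


@pytest.fixture(scope="session")
def toy_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def toy_dimer(toy_spec):
    return make_toy_dimer(toy_spec)


@pytest.fixture(scope="session")
def toy_structure(toy_dimer):
    st = gemmi.read_pdb_string(toy_dimer.pdb_text)
    st.setup_entities()
    return st


def brute_force_contacts(structure, chain_a, chain_b, cutoff=4.5):
    """Independent O(n^2) atom-pair scan used as the geometry oracle."""
    model = structure[0]

    def atoms(chain_id):
        out = []
        for res in model.find_chain(chain_id):
            if res.is_water():
                continue
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            for atom in res:
                if atom.is_hydrogen():
                    continue
                out.append(((res.seqid.num, res.seqid.icode.strip()),
                            np.array([atom.pos.x, atom.pos.y, atom.pos.z])))
        return out

    best = {}
    for ra, pa in atoms(chain_a):
        for rb, pb in atoms(chain_b):
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                key = (ra, rb)
                if key not in best or d < best[key]:
                    best[key] = d
    return best
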