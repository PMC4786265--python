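import numpy as np
import pytest

from gosbm.contacts import cutoff_contact_map, map_contacts_to_cg
from gosbm.structure_io import make_fixture
from gosbm.templates import bundled_template_dir, parse_template_set
from gosbm.topology_builder import assemble_topology, coarse_grain


@pytest.fixture(scope="session")
def ca_templates():
    return parse_template_set(bundled_template_dir("SBM_CA"))


@pytest.fixture(scope="session")
def aa_templates():
    return parse_template_set(bundled_template_dir("SBM_AA"))


@pytest.fixture(scope="session")
def enm_templates():
    return parse_template_set(bundled_template_dir("ENM"))


@pytest.fixture(scope="session")
def helix10():
    return make_fixture("ca_helix", 10)


@pytest.fixture(scope="session")
def helix_topology(ca_templates, helix10):
    return assemble_topology(helix10, ca_templates)


@pytest.fixture(scope="session")
def ci2_cg(ca_templates):
    """Synthetic CI2-scale fold coarse-grained to C-alpha beads, with its
    residue-level native contact map and assembled topology."""
    atomistic = make_fixture("synthetic_ci2")
    cg = coarse_grain(atomistic, ca_templates)
    atomic_contacts = cutoff_contact_map(atomistic)
    cg_contacts = map_contacts_to_cg(atomic_contacts, atomistic, cg.structure)
    topology = assemble_topology(cg.structure, ca_templates, cg_contacts)
    return {
        "atomistic": atomistic,
        "structure": cg.structure,
        "contacts": cg_contacts,
        "topology": topology,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
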