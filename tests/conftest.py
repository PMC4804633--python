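import pytest

from obanlink.fixtures import FixtureSpec, FixtureSet, generate
from obanlink.oban import BiologicalEntity, ProvenanceRecord, ECO_MANUAL_ASSERTION

EFO = "http://www.ebi.ac.uk/efo/EFO_"
ORDO = "http://www.orpha.net/ORDO/Orphanet_"
HP = "http://purl.obolibrary.org/obo/HP_"


def disease(num: int, label: str = "", rare: bool = False) -> BiologicalEntity:
    base = ORDO if rare else EFO
    return BiologicalEntity(f"{base}{num}", label or f"disease {num}", "disease")


def phenotype(num: int, label: str = "") -> BiologicalEntity:
    return BiologicalEntity(f"{HP}{num}", label or f"phenotype {num}", "phenotype")


def provenance(name: str = "p1", evidence: str = ECO_MANUAL_ASSERTION,
               **attrs) -> ProvenanceRecord:
    return ProvenanceRecord(
        prov_id=f"http://purl.example.org/obanlink/provenance/{name}",
        evidence_type=evidence,
        attributes=frozenset((f"http://purl.example.org/obanlink/{k}", v)
                             for k, v in attrs.items()))


@pytest.fixture(scope="session")
def small_spec() -> FixtureSpec:
    """Desk-scale study conditions shared across tests."""
    return FixtureSpec(seed=11, n_bridge_phenotypes=40,
                       n_nonbridge_phenotypes=15, n_linked_common=6,
                       n_linked_rare=12)


@pytest.fixture(scope="session")
def small_fixture(small_spec) -> FixtureSet:
    return generate(small_spec)
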