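import pytest

from pathweaver import (
    InteractionRecord,
    ParticipantRef,
    Pathway,
    PathwayCollection,
)


def gp(entity, role="participant"):
    return ParticipantRef(f"ensembl:{entity}", "gene_product", role)


def directed(local_id, pathway, source, target, itype="directed"):
    return InteractionRecord(
        local_id,
        itype,
        [gp(source, "source"), gp(target, "target")],
        pathway,
    )


@pytest.fixture
def two_pathway_collection():
    """Two pathways stating three interaction records; the A->B record
    appears in both pathways and must merge at build time."""
    return PathwayCollection(
        pathways=[
            Pathway("P1", "First pathway", "wikipathways"),
            Pathway("P2", "Second pathway", "reactome"),
        ],
        interactions=[
            directed("I1", "P1", "A", "B"),
            directed("I1", "P2", "A", "B"),
            directed("I2", "P2", "B", "D"),
        ],
    )
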