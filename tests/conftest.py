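import pytest

from pgdbcompare import (
    Compound,
    Gene,
    Pathway,
    Pgdb,
    Protein,
    Reaction,
    SynthesisConfig,
    generate,
)


def build_tiny_pgdb(name="tiny"):
    """Hand-built two-gene resource with one pathway, for targeted tests."""
    p = Pgdb(name=name)
    p.genes = {
        "G1": Gene("G1", protein_ids={"G1-P1", "G1-P2"}, go_terms={"GO:0008150"}),
        "G2": Gene("G2", protein_ids={"G2-P1"}),
    }
    p.proteins = {
        "G1-P1": Protein("G1-P1", "G1", {"R1"}),
        "G1-P2": Protein("G1-P2", "G1", {"R1", "R2"}),
        "G2-P1": Protein("G2-P1", "G2"),
    }
    p.reactions = {
        "R1": Reaction("R1", "1.1.1.1", {"C1"}, {"C2"}),
        "R2": Reaction("R2", None, {"C2"}, {"C1"}),
    }
    p.compounds = {
        "C1": Compound("C1", "small-molecule"),
        "C2": Compound("C2", "small-molecule"),
        "C3": Compound("C3", "macromolecule"),
    }
    p.pathways = {"PWY-1": Pathway("PWY-1", {"R1", "R2"})}
    return p


@pytest.fixture
def tiny_pgdb():
    return build_tiny_pgdb()


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down synthesis config used across tests (fast, still planted)."""
    return SynthesisConfig(
        seed=11,
        n_genes=600,
        n_gold_genes=200,
        n_gold_annotations=210,
        missing_gold_genes_a=15,
        missing_gold_genes_b=3,
        n_reactions=150,
        n_compounds=120,
        n_pathways=24,
        n_background_predictions=50,
    )


@pytest.fixture(scope="session")
def small_output(small_config):
    return generate(small_config)
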