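import pytest

from neopseudo.classify import FunctionalityCall, Status
from neopseudo.io import ExpressionMatrix, GeneModel, OrthologGroup
from neopseudo.pipeline import PipelineConfig, run_all
from neopseudo.simulate import SimulationParams, simulate_study


def make_gene(gene_id="g1", slot="Dpse", cds_length=900, start=True, stop=True,
              flank_amb=False, source="transcriptome", species=None):
    return GeneModel(
        gene_id=gene_id,
        species=species or ("Dmir" if slot in ("neoX", "neoY") else slot),
        lineage_slot=slot,
        element="C",
        cds_length=cds_length,
        has_start_codon=start,
        has_stop_codon=stop,
        flank_has_ambiguity=flank_amb,
        annotation_source=source,
    )


def make_group(group_id="og1", **lengths):
    """Group with complete-ORF members of the given CDS lengths, e.g.
    make_group(Dobs=900, Dpse=900, neoX=900, neoY=None)."""
    members = {}
    for slot in ("Dobs", "Dpse", "neoX", "neoY"):
        length = lengths.get(slot, 900)
        if length is None:
            members[slot] = None
        elif isinstance(length, GeneModel):
            members[slot] = length
        else:
            members[slot] = make_gene(f"{group_id}_{slot}", slot, length)
    return OrthologGroup(group_id=group_id, members=members)


def make_call(status, rule=None):
    return FunctionalityCall(Status(status), rule=rule)


def make_expr(entries):
    """ExpressionMatrix from {(gene, tissue, sex): fpkm}."""
    return ExpressionMatrix(entries)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small simulated study bundle shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    params = SimulationParams(seed=20260926, n_groups=150, n_codons=40)
    return simulate_study(params, outdir)


@pytest.fixture(scope="session")
def small_results(small_bundle):
    """Full pipeline results on the small bundle."""
    return run_all(small_bundle.directory, PipelineConfig(bootstrap_reps=200))
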