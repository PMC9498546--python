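import warnings

import pytest

warnings.filterwarnings("ignore", message=".*Bio.codonalign.*")

from ugtfam import motif
from ugtfam.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def pspg():
    return motif.parse_pattern(motif.PSPG_PATTERN)


@pytest.fixture()
def cfg():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """Default synthetic scenario, generated once per session."""
    outdir = tmp_path_factory.mktemp("scenario")
    import json

    truth = generate_scenario(ScenarioConfig(), seed=20260, outdir=outdir)
    return outdir, truth


def pipeline_config(scenario_dir, seed=20260, stages=None):
    names = {
        "proteome": "proteome.faa",
        "alignment": "alignment.faa",
        "anchors_map": "anchors.tsv",
        "species_map": "species.tsv",
        "loci_bed": "loci.bed",
        "cds_fasta": "cds.fna",
        "pairs": "pairs_in.tsv",
        "gff3": "gene_models.gff3",
        "struct_alignment": "struct_alignment.faa",
        "counts": "expression_counts.tsv",
        "conditions": "conditions.tsv",
        "lengths": "gene_lengths.tsv",
        "expression_groups": "expression_groups.tsv",
    }
    cfg = {
        "schema_version": 1,
        "seed": seed,
        "inputs": {k: str(scenario_dir / v) for k, v in names.items()},
    }
    if stages is not None:
        cfg["stages"] = list(stages)
    return cfg
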