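import json

import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic reference + planted-variant bundle shared across tests."""
    from pyfaidx import Fasta

    from utr5var import load_reference
    from utr5var.fixtures import FixtureConfig, generate_reference, generate_variants
    from utr5var.tracks import ConservationTrack, EvidenceCatalog, GeneConstraint

    root = tmp_path_factory.mktemp("bundle")
    paths = generate_reference(FixtureConfig(seed=1, n_genes=20), root)
    paths.update(generate_variants(paths, seed=1))
    return {
        "paths": paths,
        "catalog": load_reference(paths["fasta"], paths["gtf"]),
        "genome": Fasta(paths["fasta"]),
        "evidence": EvidenceCatalog.from_tsv(paths["evidence"]),
        "conservation": ConservationTrack.from_files(paths["phylop"], paths["phastcons"]),
        "constraint": GeneConstraint.from_tsv(paths["constraint"]),
        "truth": json.load(open(paths["truth"])),
    }
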