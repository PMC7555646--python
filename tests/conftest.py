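from pathlib import Path

import pytest

from lrrkit.simulate import SimConfig, simulate_genome

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle(tmp_path_factory) -> tuple[dict, object]:
    """One default synthetic bundle shared by the whole session."""
    outdir = tmp_path_factory.mktemp("bundle")
    cfg = SimConfig(seed=BUNDLE_SEED)
    paths, truth = simulate_genome(cfg, outdir)
    return paths, truth


@pytest.fixture(scope="session")
def bundle_paths(bundle):
    return bundle[0]


@pytest.fixture(scope="session")
def bundle_truth(bundle):
    return bundle[1]


@pytest.fixture(scope="session")
def bundle_annotation(bundle_paths):
    from lrrkit.io import read_gff3

    return read_gff3(bundle_paths["gff3"])


@pytest.fixture(scope="session")
def bundle_family(bundle_paths):
    """The family set recovered by the identification cascade."""
    from lrrkit import identify
    from lrrkit import io as lio

    hits = lio.read_domain_hits(bundle_paths["domains"])
    kept = identify.filter_domain_hits(hits)
    proteins = lio.fasta_dict(lio.read_fasta(bundle_paths["proteins"], alphabet="protein"))
    calls = identify.call_architectures(kept, proteins)
    hmm_set = {h.gene_id for h in kept if h.domain_class == "LRR"}
    rescue = {
        line.strip()
        for line in Path(bundle_paths["rescue"]).read_text().splitlines()
        if line.strip()
    }
    return identify.merge_candidates(hmm_set, rescue, calls)
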