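import numpy as np
import pytest

from emsnv.models import ReferenceSequence, TranscriptModel
from emsnv.simulate import SimConfig, generate_reference, simulate_lineages


@pytest.fixture
def simple_ref():
    # 60 bp scaffold: 10 bp flank | 39 bp CDS | flank
    #                 0123456789
    residues = "AAAAATTTTT" + "ATGGCTAGTTGGCATCCCGATTTAAAAGGGCGCTCATAA" + "CCCCCGGGGGTT"
    return ReferenceSequence(seq_id="chr1", residues=residues)


@pytest.fixture
def plus_model():
    return TranscriptModel(
        gene_id="g1", transcript_id="g1.t1", seq_id="chr1",
        strand="+", cds_intervals=((10, 49),),
    )


@pytest.fixture
def minus_ref(simple_ref):
    from emsnv.models import reverse_complement

    return ReferenceSequence(
        seq_id="chr1m", residues=reverse_complement(simple_ref.residues)
    )


@pytest.fixture
def minus_model(simple_ref):
    n = len(simple_ref.residues)
    return TranscriptModel(
        gene_id="g1m", transcript_id="g1m.t1", seq_id="chr1m",
        strand="-", cds_intervals=((n - 49, n - 10),),
    )


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared across tests (fixed seed)."""
    cfg = SimConfig(n_genes=60, cds_length=300, n_isoform_genes=10, seed=11)
    rng = np.random.default_rng(cfg.seed)
    refs, models = generate_reference(cfg, rng)
    wt, mut, truth = simulate_lineages(refs, models, cfg, rng)
    return cfg, refs, models, wt, mut, truth
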