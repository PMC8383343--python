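import numpy as np
import pytest

from ptvburden.gene_models import GenomeReference, Transcript
from ptvburden.synthetic_data import SimulationConfig, simulate_bundle

# A hand-specified four-exon plus-strand transcript used across test modules.
# 1-based inclusive exons: 101-200, 301-400, 501-590, 701-800; CDS 151-550.
# Exon 4 is entirely 3'UTR; the 3'UTR tail on exon 3 spans c.*1..*40.
TOY1_EXONS = [(100, 200), (300, 400), (500, 590), (700, 800)]
TOY1_CDS = (150, 550)


def make_toy1(seq_overrides: dict[int, str] | None = None) -> tuple[Transcript, GenomeReference]:
    """TOY1 over a deterministic random contig; overrides are 1-based."""
    rng = np.random.default_rng(20260919)
    seq = list("".join(rng.choice(list("ACGT"), size=900)))
    for pos, base in (seq_overrides or {}).items():
        seq[pos - 1] = base
    ref = GenomeReference({"chrT": "".join(seq)})
    tx = Transcript(
        id="TOY1", gene="TOYGENE", contig="chrT", strand="+",
        exons=list(TOY1_EXONS), cds_start=TOY1_CDS[0], cds_end=TOY1_CDS[1],
    )
    return tx, ref


@pytest.fixture(scope="session")
def toy1():
    return make_toy1()


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """A small simulated cohort bundle shared by integration tests."""
    cfg = SimulationConfig(seed=11, n_genes=6, n_case_samples=60)
    outdir = tmp_path_factory.mktemp("bundle")
    paths = simulate_bundle(cfg, outdir)
    return cfg, paths
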