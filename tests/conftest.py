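import numpy as np
import pytest

from mitocomp.genome_io import CircularGenome, GeneLocus, GenomeSet
from mitocomp.pipeline import RunConfig, run_pipeline
from mitocomp.simulate import headline_scenario, simulate


def build_tiny_genome(seed: int = 5) -> CircularGenome:
    """1,000 bp circle with one 2-exon CDS (+) and one tRNA (-)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=1000))
    # CDS: exons 101..250 and 301..400 (spliced 250 nt + 2 = not multiple; fix)
    # use exons 101..250 (150) and 301..450 (150): spliced 300 nt
    seq = seq[:100] + "ATG" + seq[103:]
    cds = GeneLocus("cox1", "CDS", "+", exons=[(101, 250), (301, 450)], introns=[(251, 300)])
    trna = GeneLocus("trnA", "tRNA", "-", exons=[(601, 672)])
    return CircularGenome("tiny1", seq, topology="circular", features=[cds, trna])


@pytest.fixture
def tiny_genome() -> CircularGenome:
    return build_tiny_genome()


@pytest.fixture(scope="session")
def headline_sim():
    """The scripted 16-isolate scenario (10 distinct sequences) plus truth."""
    return simulate(headline_scenario(seed=1))


@pytest.fixture(scope="session")
def headline_report(headline_sim):
    gs, _ = headline_sim
    return run_pipeline(RunConfig(), genome_set=gs)


@pytest.fixture(scope="session")
def headline_table(headline_report):
    return headline_report.locus_table


def identical_pair_set(seed: int = 3) -> GenomeSet:
    """Two isolates with byte-identical genomes (degenerate comparison)."""
    from mitocomp.simulate import SimConfig, default_plan

    cfg = SimConfig(
        seed=seed,
        tree="(A:0.0,B:0.0);",
        plan=default_plan(),
    )
    gs, _ = simulate(cfg)
    return gs
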