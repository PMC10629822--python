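import warnings

import pytest

from crypticsplice import (
    GeneModel,
    SimulationConfig,
    SpliceJunction,
    simulate_cohort,
    write_cohort,
)

warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def small_cohort():
    """40-gene default-signature cohort shared by read-only tests."""
    return simulate_cohort(SimulationConfig(n_genes=40), seed=101)


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory, small_cohort):
    d = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, d)
    return d


def mirror_cohort(cohort):
    """Reverse-complement every contig and mirror all coordinates/strands.

    Used by the strand-mirror invariance tests: the event set and all
    sequence characterizations must be identical up to the coordinate map
    ``pos -> L - pos + 1`` and strand flip.
    """
    from Bio.Seq import reverse_complement

    genome = {c: reverse_complement(s) for c, s in cohort.sim.genome.items()}
    lengths = {c: len(s) for c, s in cohort.sim.genome.items()}

    def mpos(chrom, p):
        return lengths[chrom] - p + 1

    def mint(chrom, iv):
        return (mpos(chrom, iv[1]), mpos(chrom, iv[0]))

    flip = {"+": "-", "-": "+"}
    genes = [
        GeneModel(
            gene_id=g.gene_id,
            transcript_id=g.transcript_id,
            chrom=g.chrom,
            strand=flip[g.strand],
            exons=tuple(sorted(mint(g.chrom, e) for e in g.exons)),
            cds=tuple(sorted(mint(g.chrom, e) for e in g.cds)) if g.cds else None,
        )
        for g in cohort.sim.genes
    ]
    junctions = [
        SpliceJunction(
            chrom=j.chrom,
            intron_start=mpos(j.chrom, j.intron_end),
            intron_end=mpos(j.chrom, j.intron_start),
            strand=flip[j.strand],
            unique_reads=j.unique_reads,
            sample_id=j.sample_id,
        )
        for j in cohort.junctions
    ]
    return genome, genes, junctions, mpos
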