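from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from rtscan.genome_model import GeneModel, GenomicInterval, TranscriptModel
from rtscan.synthetic_data import SimulationConfig, simulate


def make_gene(
    gene_id,
    chrom="chr1",
    start=100,
    end=500,
    cds=((150, 450),),
    strand="+",
    biotype="protein_coding",
):
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval(chrom, start, end, strand),
        cds_intervals=tuple(GenomicInterval(chrom, s, e, strand) for s, e in cds),
        biotype=biotype,
    )


def make_transcript(tid, exons, strand="+", chrom="chr1", sample="s1", count=1):
    return TranscriptModel(
        transcript_id=tid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        sample_id=sample,
        read_count=count,
    )


@pytest.fixture
def tandem_pair():
    """Gene A (span 100-500, CDS 150-450) then B (700-1100, CDS 750-1050), '+'."""
    a = make_gene("A", start=100, end=500, cds=((150, 450),))
    b = make_gene("B", start=700, end=1100, cds=((750, 1050),))
    return a, b


def random_annotation(rng: np.random.Generator, n_genes: int, chrom_len: int = 3000):
    """Random small annotation plus random transcripts, for oracle tests."""
    genes = []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_len - 320))
        length = int(rng.integers(60, 300))
        end = start + length
        cds_s = start + int(rng.integers(0, max(1, length // 4)))
        cds_e = end - int(rng.integers(0, max(1, length // 4)))
        if cds_e <= cds_s:
            cds_e = cds_s + 1
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            make_gene(f"g{i}", start=start, end=end, cds=((cds_s, cds_e),), strand=strand)
        )
    transcripts = []
    for j in range(12):
        start = int(rng.integers(0, chrom_len - 700))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_exons):
            ex_len = int(rng.integers(40, 250))
            exons.append((pos, pos + ex_len))
            pos += ex_len + int(rng.integers(20, 120))
        transcripts.append(make_transcript(f"t{j}", exons, strand=strand))
    return genes, transcripts


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """Decoy-free seeded simulation used across test modules."""
    outdir = tmp_path_factory.mktemp("sim")
    config = SimulationConfig(seed=7, n_gene_pairs=10)
    truth = simulate(config, outdir)
    return truth, outdir


@pytest.fixture(scope="session")
def sim_result(sim_bundle):
    from rtscan.pipeline import PipelineConfig, run_pipeline

    truth, d = sim_bundle
    config = PipelineConfig(
        annotation=str(d / "annotation.gff3"),
        transcripts={"sim": str(d / "transcripts.bed")},
        genome_fasta=str(d / "genome.fa"),
        cage=str(d / "cage.tsv"),
        orf_counts=str(d / "orf_counts.tsv"),
        localization=str(d / "localization.tsv"),
        nue_hexamers=str(d / "nue_hexamers.txt"),
        ce_hexamers=str(d / "ce_hexamers.txt"),
        outdir=str(d / "out"),
    )
    return run_pipeline(config)
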