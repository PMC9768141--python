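"""Readthrough (RT) locus calling and per-sample count summaries.

A transcript is an RT candidate when its exonic bases overlap the merged CDS
of two or more distinct same-strand protein-coding genes, each by at least
``min_cds_overlap_bp``, and no two of those genes have overlapping annotated
spans.  Candidates are grouped into loci by their ordered gene tuple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .genome_model import GeneModel, TranscriptModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_CDS_OVERLAP_BP = 30

# locus flags
FLAG_FIRST_MONO = "has_first_monocistronic"
FLAG_SECOND_MONO = "has_second_monocistronic"
FLAG_SECOND_TSS = "second_gene_tss_supported"
FLAG_POLYA_IN_IS = "polya_in_is_intron"


@dataclass
class RTLocus:
    """An ordered set of >= 2 genes co-spanned by at least one transcript."""

    locus_id: str
    genes: tuple[GeneModel, ...]
    supporting_transcripts: dict[str, list[TranscriptModel]] = field(default_factory=dict)
    is_introns: list = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"{self.locus_id}: an RT locus needs >= 2 genes")
        chroms = {g.chrom for g in self.genes}
        strands = {g.strand for g in self.genes}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"{self.locus_id}: genes on mixed chrom/strand")

    @property
    def chrom(self) -> str:
        return self.genes[0].chrom

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    @property
    def start(self) -> int:
        return min(g.span.start for g in self.genes)

    @property
    def end(self) -> int:
        return max(g.span.end for g in self.genes)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g.gene_id for g in self.genes)

    @property
    def first_gene(self) -> GeneModel:
        return self.genes[0]

    @property
    def second_gene(self) -> GeneModel:
        return self.genes[1]

    def all_supporting(self) -> list[TranscriptModel]:
        return [t for ts in self.supporting_transcripts.values() for t in ts]


@dataclass(frozen=True)
class RTCountSummary:
    """Per-sample RT tallies: variants (structures) <= RTs (reads), loci, totals."""

    sample_id: str
    n_rt_variants: int
    n_rts: int
    n_rt_loci: int
    n_total_transcripts: int
    proportion_pct: float


def _cds_overlap_bp(t: TranscriptModel, gene: GeneModel) -> int:
    return sum(t.exonic_overlap(cds) for cds in gene.cds_intervals)


def call_rt_transcripts(
    transcripts: Iterable[TranscriptModel],
    genes: Sequence[GeneModel],
    min_cds_overlap_bp: int = DEFAULT_MIN_CDS_OVERLAP_BP,
) -> dict[TranscriptModel, tuple[GeneModel, ...]]:
    """Map each readthrough transcript to its ordered (5'->3') gene tuple.

    Only same-strand protein-coding genes count; a gene qualifies when the
    transcript's exons cover >= ``min_cds_overlap_bp`` of its merged CDS.
    Genes whose annotated spans overlap another same-strand protein-coding
    gene are excluded as RT partners up front (overlapping annotations
    co-span trivially and are not readthrough); the static exclusion keeps
    RT calls monotone in the overlap threshold.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if min_cds_overlap_bp < 1:
        raise ValueError("min_cds_overlap_bp must be >= 1")

    by_loc: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        by_loc.setdefault((g.chrom, g.strand), []).append(g)
    for key, bucket in by_loc.items():
        excluded = {
            g.gene_id
            for i, g in enumerate(bucket)
            for other in bucket[i + 1 :]
            if g.span.overlaps(other.span)
        } | {
            other.gene_id
            for i, g in enumerate(bucket)
            for other in bucket[i + 1 :]
            if g.span.overlaps(other.span)
        }
        if excluded:
            logger.debug("excluding overlapping-span genes as RT partners: %s", sorted(excluded))
        by_loc[key] = sorted(
            (g for g in bucket if g.gene_id not in excluded), key=lambda g: g.span.start
        )

    known_chroms = {chrom for chrom, _ in by_loc}
    assignments: dict[TranscriptModel, tuple[GeneModel, ...]] = {}
    for t in transcripts:
        if t.chrom not in known_chroms:
            logger.debug(
                "transcript %s on chromosome %s absent from annotation", t.transcript_id, t.chrom
            )
            continue
        bucket = by_loc.get((t.chrom, t.strand), ())
        hits = [
            g
            for g in bucket
            if g.span.start < t.end
            and t.start < g.span.end
            and _cds_overlap_bp(t, g) >= min_cds_overlap_bp
        ]
        if len(hits) < 2:
            continue
        hits.sort(key=lambda g: g.span.start, reverse=(t.strand == "-"))
        assignments[t] = tuple(hits)
    logger.info("called %d RT transcript(s)", len(assignments))
    return assignments


def group_rt_loci(
    rt_assignments: Mapping[TranscriptModel, tuple[GeneModel, ...]],
    samples: Sequence[str] | None = None,
) -> list[RTLocus]:
    """Group RT transcript assignments into loci keyed by the ordered gene tuple."""
    by_key: dict[tuple[str, ...], tuple[tuple[GeneModel, ...], list[TranscriptModel]]] = {}
    for t, gene_tuple in rt_assignments.items():
        key = tuple(g.gene_id for g in gene_tuple)
        if key not in by_key:
            by_key[key] = (gene_tuple, [])
        by_key[key][1].append(t)

    sample_universe = list(samples) if samples is not None else sorted(
        {t.sample_id for t in rt_assignments}
    )

    raw = sorted(
        by_key.values(),
        key=lambda pair: (pair[0][0].chrom, min(g.span.start for g in pair[0])),
    )
    loci = []
    for i, (gene_tuple, ts) in enumerate(raw, start=1):
        per_sample: dict[str, list[TranscriptModel]] = {s: [] for s in sample_universe}
        for t in ts:
            per_sample.setdefault(t.sample_id, []).append(t)
        loci.append(
            RTLocus(
                locus_id=f"RTL{i:04d}",
                genes=gene_tuple,
                supporting_transcripts=per_sample,
            )
        )
    return loci


def summarize_counts(
    loci: Sequence[RTLocus], total_transcripts_per_sample: Mapping[str, int]
) -> list[RTCountSummary]:
    """Per-sample RT summary: reads, distinct structures, loci and proportion.

    ``proportion_pct`` is 100 * n_rts / n_total rounded to 3 decimals.  An RT
    "variant" is a distinct (locus, intron-chain) signature within the sample.
    """
    summaries = []
    for sample_id in sorted(total_transcripts_per_sample):
        total = total_transcripts_per_sample[sample_id]
        if total <= 0:
            raise ValueError(f"sample {sample_id}: total transcript count must be > 0")
        n_rts = 0
        n_loci = 0
        signatures: set[tuple] = set()
        for locus in loci:
            ts = locus.supporting_transcripts.get(sample_id, [])
            if not ts:
                continue
            n_loci += 1
            for t in ts:
                n_rts += t.read_count
                signatures.add((locus.locus_id, t.intron_chain()))
        summaries.append(
            RTCountSummary(
                sample_id=sample_id,
                n_rt_variants=len(signatures),
                n_rts=n_rts,
                n_rt_loci=n_loci,
                n_total_transcripts=total,
                proportion_pct=round(100.0 * n_rts / total, 3),
            )
        )
    return summaries


def detect_monocistronic_counterparts(
    locus: RTLocus,
    transcripts: Iterable[TranscriptModel],
    min_cds_overlap_bp: int = DEFAULT_MIN_CDS_OVERLAP_BP,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Find transcripts covering only the first (resp. only the second) gene.

    A first monocistronic transcript overlaps the first gene's CDS by at
    least the threshold and overlaps no other locus gene's CDS at all (a
    transcript straddling another CDS by even a few bases is neither
    monocistronic nor RT).  Sets the corresponding locus flags.
    """
    first_monos: list[TranscriptModel] = []
    second_monos: list[TranscriptModel] = []
    for t in transcripts:
        if t.chrom != locus.chrom or t.strand != locus.strand:
            continue
        overlaps = [_cds_overlap_bp(t, g) for g in locus.genes]
        if overlaps[0] >= min_cds_overlap_bp and all(o == 0 for o in overlaps[1:]):
            first_monos.append(t)
        elif overlaps[1] >= min_cds_overlap_bp and all(
            o == 0 for i, o in enumerate(overlaps) if i != 1
        ):
            second_monos.append(t)
    if first_monos:
        locus.flags.add(FLAG_FIRST_MONO)
    if second_monos:
        locus.flags.add(FLAG_SECOND_MONO)
    return first_monos, second_monos
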