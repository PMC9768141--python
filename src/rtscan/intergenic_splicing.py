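"""Intergenic-splicing (IS) intron detection and termination-class assignment.

An IS intron of an RT joins the 3' region of one locus gene to the 5' region
of the next: its donor lies at or after the upstream gene's CDS end and its
acceptor at or before the downstream gene's CDS start (all in transcription
direction).  Loci are classified by whether the first gene's monocistronic
polyadenylation falls inside an IS intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    fetch_sequence,
    polya_site,
    reverse_complement,
)
from .rt_detection import FLAG_POLYA_IN_IS, RTLocus

logger = logging.getLogger(__name__)

DEFAULT_CLUSTER_RADIUS_NT = 10

CLASS_IS_WITH_POLYA = "IS_with_internal_polyA"
CLASS_IS_WITHOUT_POLYA = "IS_without_internal_polyA"
CLASS_NO_IS = "no_IS"


@dataclass
class ISIntron:
    """A merged intergenic-splicing intron with read support."""

    interval: GenomicInterval
    donor_pos: int
    acceptor_pos: int
    supporting_reads: int
    gene_pair: tuple[str, str]
    contained_polya_sites: list[tuple[int, int]] = field(default_factory=list)
    major: bool = False

    def contains_strictly(self, pos: int) -> bool:
        """True when ``pos`` is an intron base other than the two terminal ones."""
        return self.interval.start < pos < self.interval.end - 1


@dataclass(frozen=True)
class LocusTerminationClass:
    locus_id: str
    class_label: str


class SpliceSites(NamedTuple):
    donor_seq: str
    acceptor_seq: str
    canonical: bool


def find_is_introns(locus: RTLocus) -> list[ISIntron]:
    """Collect IS introns from a locus's supporting transcripts.

    Identical introns across reads are merged with summed support; per
    adjacent gene pair the best-supported intron (ties broken by 5'-most
    donor) is flagged ``major``.  The result is also stored on
    ``locus.is_introns``.
    """
    minus = locus.strand == "-"
    merged: dict[tuple[int, tuple[int, int]], ISIntron] = {}
    for pair_idx, (up, down) in enumerate(zip(locus.genes, locus.genes[1:])):
        # genomic bounds of the inter-CDS region between the adjacent genes
        if minus:
            lo, hi = down.cds_end, up.cds_start
        else:
            lo, hi = up.cds_end, down.cds_start
        for t in locus.all_supporting():
            for intron in t.introns():
                if intron.start >= lo and intron.end <= hi:
                    key = (pair_idx, (intron.start, intron.end))
                    if key in merged:
                        merged[key].supporting_reads += t.read_count
                    else:
                        donor = intron.end - 1 if minus else intron.start
                        acceptor = intron.start if minus else intron.end - 1
                        merged[key] = ISIntron(
                            interval=intron,
                            donor_pos=donor,
                            acceptor_pos=acceptor,
                            supporting_reads=t.read_count,
                            gene_pair=(up.gene_id, down.gene_id),
                        )

    introns = sorted(
        merged.items(), key=lambda kv: (kv[0][0], kv[0][1][0], kv[0][1][1])
    )
    result = [iv for _, iv in introns]
    for pair_idx in {k[0] for k in merged}:
        group = [iv for (pi, _), iv in introns if pi == pair_idx]
        # best support first; 5'-most donor breaks ties deterministically
        group.sort(
            key=lambda iv: (
                -iv.supporting_reads,
                -iv.donor_pos if minus else iv.donor_pos,
            )
        )
        group[0].major = True
    locus.is_introns = result
    return result


def cluster_polya_sites(
    positions_with_support: Sequence[tuple[int, int]], cluster_radius_nt: int
) -> list[tuple[int, int]]:
    """Single-linkage clustering of 3'-end positions on one strand.

    Sorted positions whose consecutive gaps are <= radius join one cluster.
    Returns (representative_position, total_support) per cluster, where the
    representative is the best-supported position (smallest on ties).
    """
    if cluster_radius_nt < 0:
        raise ValueError("cluster_radius_nt must be >= 0")
    pts = sorted(positions_with_support)
    clusters: list[list[tuple[int, int]]] = []
    for pos, sup in pts:
        if clusters and pos - clusters[-1][-1][0] <= cluster_radius_nt:
            clusters[-1].append((pos, sup))
        else:
            clusters.append([(pos, sup)])
    out = []
    for cl in clusters:
        total = sum(s for _, s in cl)
        rep = min(cl, key=lambda ps: (-ps[1], ps[0]))[0]
        out.append((rep, total))
    return out


def classify_termination(
    locus: RTLocus,
    first_monos: Sequence[TranscriptModel],
    cluster_radius_nt: int = DEFAULT_CLUSTER_RADIUS_NT,
) -> LocusTerminationClass:
    """Assign one termination class per locus.

    First-monocistronic polyA sites are clustered; the locus is
    ``IS_with_internal_polyA`` when any cluster representative lies strictly
    inside any IS intron, ``IS_without_internal_polyA`` when IS introns
    exist without such a site, ``no_IS`` otherwise.  Contained sites are
    recorded on the harboring introns and the locus flag is set.
    """
    introns: list[ISIntron] = list(locus.is_introns)
    if not introns:
        return LocusTerminationClass(locus.locus_id, CLASS_NO_IS)

    sites = [(polya_site(t)[2], t.read_count) for t in first_monos]
    reps = cluster_polya_sites(sites, cluster_radius_nt)

    internal = False
    for rep_pos, support in reps:
        for intron in introns:
            if intron.contains_strictly(rep_pos):
                intron.contained_polya_sites.append((rep_pos, support))
                internal = True
    if internal:
        locus.flags.add(FLAG_POLYA_IN_IS)
        return LocusTerminationClass(locus.locus_id, CLASS_IS_WITH_POLYA)
    return LocusTerminationClass(locus.locus_id, CLASS_IS_WITHOUT_POLYA)


def splice_site_dinucleotides(intron: ISIntron | GenomicInterval, genome) -> SpliceSites:
    """First and last 3 intron bases in transcription direction.

    Canonical means GT at intron positions 1-2 and AG at the last two
    (GT..AG rule on the coding strand).
    """
    interval = intron.interval if isinstance(intron, ISIntron) else intron
    if interval.length < 6:
        raise ValueError(f"intron {interval} too short for splice-site extraction")
    seq = fetch_sequence(genome, interval.chrom, interval.start, interval.end)
    if interval.strand == "-":
        seq = reverse_complement(seq)
    donor, acceptor = seq[:3], seq[-3:]
    canonical = donor.startswith("GT") and acceptor.endswith("AG")
    return SpliceSites(donor, acceptor, canonical)
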