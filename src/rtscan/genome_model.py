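"""Core genomic data types and readers/writers for GFF3, BED12 and TSV tracks.

Coordinate convention
---------------------
All coordinates are 0-based, half-open ``[start, end)`` internally.  GFF3
input (1-based, closed) is converted once at the parsing boundary; BED12 is
already 0-based half-open.  Positions in TSV tracks (CAGE) are 1-based in
the file and converted on read.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse-complement a DNA string (IUPAC beyond ACGTN not supported)."""
    return seq.translate(COMPLEMENT)[::-1]


class Gff3ParseError(ValueError):
    """Raised for a malformed GFF3 line; message names the offending line."""


class Bed12Error(ValueError):
    """Raised when BED12 block arithmetic is internally inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Union of intervals (sweep over sorted starts); all must share chrom/strand."""
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return ()
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("cannot merge intervals across chromosomes or strands")
    merged: list[list[int]] = [[ivs[0].start, ivs[0].end]]
    for iv in ivs[1:]:
        if iv.start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], iv.end)
        else:
            merged.append([iv.start, iv.end])
    chrom, strand = ivs[0].chrom, ivs[0].strand
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding (or other) gene with isoform-collapsed CDS intervals."""

    gene_id: str
    span: GenomicInterval
    cds_intervals: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"
    localization: str | None = None

    def __post_init__(self) -> None:
        if self.biotype == "protein_coding" and not self.cds_intervals:
            raise ValueError(f"protein-coding gene {self.gene_id} has no CDS")
        prev_end = -1
        for iv in self.cds_intervals:
            if iv.chrom != self.span.chrom or iv.strand != self.span.strand:
                raise ValueError(f"{self.gene_id}: CDS chrom/strand differs from span")
            if iv.start < self.span.start or iv.end > self.span.end:
                raise ValueError(f"{self.gene_id}: CDS {iv} outside gene span {self.span}")
            if iv.start < prev_end:
                raise ValueError(f"{self.gene_id}: CDS intervals overlap or are unsorted")
            prev_end = iv.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def cds_start(self) -> int:
        """Genomic (leftmost) start of the merged CDS region."""
        return self.cds_intervals[0].start

    @property
    def cds_end(self) -> int:
        """Genomic (rightmost) end of the merged CDS region."""
        return self.cds_intervals[-1].end

    def cds_3p_boundary(self) -> int:
        """Half-open boundary just downstream of the CDS in transcription direction."""
        return self.cds_end if self.strand == "+" else self.cds_start

    def cds_5p_boundary(self) -> int:
        """Half-open boundary just upstream of the CDS in transcription direction."""
        return self.cds_start if self.strand == "+" else self.cds_end

    def tss_position(self) -> int:
        """Annotated 5' end (first transcribed base) of the gene span."""
        return self.span.start if self.strand == "+" else self.span.end - 1


@dataclass(frozen=True, eq=False)
class TranscriptModel:
    """One full-length transcript model (a read or a collapsed isoform).

    Identity (hash/eq) is per object so that duplicate records in the input
    remain distinct observations.
    """

    transcript_id: str
    exons: tuple[GenomicInterval, ...]
    sample_id: str = "sample"
    read_count: int = 1

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if self.read_count < 0:
            raise ValueError(f"transcript {self.transcript_id}: negative read_count")
        first = self.exons[0]
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != first.chrom or ex.strand != first.strand:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons on mixed chrom/strand"
                )
            if ex.start <= prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons overlap, touch or are unsorted"
                )
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def intron_chain(self) -> tuple:
        """Hashable splice-structure signature (chrom, strand, intron coords)."""
        return (
            self.chrom,
            self.strand,
            tuple((iv.start, iv.end) for iv in self.introns()),
        )

    def exonic_overlap(self, interval: GenomicInterval) -> int:
        """Exonic bases shared with ``interval`` (chrom-aware, strand-agnostic)."""
        return sum(ex.overlap_len(interval) for ex in self.exons)


def polya_site(t: TranscriptModel) -> tuple[str, str, int]:
    """Genomic position of the transcript's 3' terminal (polyadenylated) base."""
    pos = t.end - 1 if t.strand == "+" else t.start
    return (t.chrom, t.strand, pos)


def polya_boundary(t: TranscriptModel) -> int:
    """Half-open boundary just past the 3' end in transcription direction.

    On ``+`` this is the last exon's ``end``; on ``-`` the first exon's
    ``start``.  Window construction in :mod:`rtscan.polya_signals` uses this
    convention so that the polyadenylated base itself is inside the window.
    """
    return t.end if t.strand == "+" else t.start


@dataclass
class CageTrack:
    """Sparse CAGE TSS signal: (chrom, strand, 0-based position) -> TPM."""

    entries: dict[tuple[str, str, int], float]
    _index: dict[tuple[str, str], tuple[list[int], list[float]]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        for (chrom, strand, pos), tpm in self.entries.items():
            if strand not in STRANDS:
                raise ValueError(f"bad strand {strand!r} in CAGE entry")
            if tpm < 0:
                raise ValueError(f"negative TPM at {chrom}:{pos}")
        by_key: dict[tuple[str, str], list[tuple[int, float]]] = {}
        for (chrom, strand, pos), tpm in self.entries.items():
            by_key.setdefault((chrom, strand), []).append((pos, tpm))
        for key, pairs in by_key.items():
            pairs.sort()
            self._index[key] = ([p for p, _ in pairs], [t for _, t in pairs])

    def max_tpm_in(self, chrom: str, strand: str, lo: int, hi: int) -> float:
        """Maximum TPM among positions in [lo, hi] on the given strand; 0 if none."""
        idx = self._index.get((chrom, strand))
        if idx is None:
            return 0.0
        positions, tpms = idx
        i = bisect.bisect_left(positions, lo)
        j = bisect.bisect_right(positions, hi)
        return max(tpms[i:j], default=0.0)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_BIOTYPE_KEYS = ("biotype", "gene_biotype", "locus_type")


def _validate_gff3_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: non-integer start/end"
                ) from exc
            if start < 1 or end < start:
                raise Gff3ParseError(
                    f"{path}: line {lineno}: invalid 1-based span {start}-{end}"
                )


def _gff3_db(path: Path):
    import gffutils

    return gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )


def read_gff3_genes(path: str | Path, biotype_filter: str = "protein_coding") -> list[GeneModel]:
    """Read gene models from GFF3, collapsing all isoforms to a CDS union.

    GFF3 1-based closed coordinates are converted to the internal 0-based
    half-open convention.  A gene's biotype is taken from a
    ``biotype``/``gene_biotype``/``locus_type`` attribute when present,
    otherwise inferred as ``protein_coding`` iff the gene has CDS descendants.
    CDS features without a resolvable parent gene are skipped with a warning.
    """
    path = Path(path)
    _validate_gff3_lines(path)
    db = _gff3_db(path)

    parented_cds_ids: set[str] = set()
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds_feats = list(db.children(gene, featuretype="CDS"))
        for c in cds_feats:
            parented_cds_ids.add(c.id)
        biotype = None
        for key in _BIOTYPE_KEYS:
            if key in gene.attributes:
                biotype = gene.attributes[key][0]
                break
        if biotype is None:
            biotype = "protein_coding" if cds_feats else "other"
        if biotype != biotype_filter:
            continue
        strand = gene.strand if gene.strand in STRANDS else "+"
        span = GenomicInterval(gene.seqid, gene.start - 1, gene.end, strand)
        cds = merge_intervals(
            GenomicInterval(c.seqid, c.start - 1, c.end, strand) for c in cds_feats
        )
        genes.append(GeneModel(gene_id=gene.id, span=span, cds_intervals=cds, biotype=biotype))

    n_orphans = sum(
        1 for c in db.features_of_type("CDS") if c.id not in parented_cds_ids
    )
    if n_orphans:
        logger.warning("%s: skipped %d CDS feature(s) without a parent gene", path, n_orphans)
    logger.info("%s: read %d gene(s) with biotype %s", path, len(genes), biotype_filter)
    return genes


# ---------------------------------------------------------------------------
# Transcripts (BED12 / GFF3)
# ---------------------------------------------------------------------------


def _parse_bed12_line(line: str, lineno: int, sample_id: str, source: str) -> TranscriptModel:
    fields = line.split("\t")
    if len(fields) < 12:
        raise Bed12Error(f"{source}: line {lineno}: expected 12 BED fields, got {len(fields)}")
    chrom = fields[0]
    name = fields[3]
    try:
        chrom_start, chrom_end = int(fields[1]), int(fields[2])
        score = int(float(fields[4]))
        strand = fields[5]
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise Bed12Error(f"{source}: record {name!r} (line {lineno}): bad field") from exc
    if len(sizes) != block_count or len(starts) != block_count:
        raise Bed12Error(
            f"{source}: record {name!r}: blockCount={block_count} but "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    if starts[0] != 0 or chrom_start + starts[-1] + sizes[-1] != chrom_end:
        raise Bed12Error(
            f"{source}: record {name!r}: block arithmetic inconsistent with "
            f"chromStart/chromEnd"
        )
    exons = tuple(
        GenomicInterval(chrom, chrom_start + st, chrom_start + st + sz, strand)
        for st, sz in zip(starts, sizes)
    )
    return TranscriptModel(
        transcript_id=name,
        exons=exons,
        sample_id=sample_id,
        read_count=score if score > 0 else 1,
    )


def read_transcripts(
    path: str | Path, format: str = "bed12", sample_id: str = "sample"
) -> list[TranscriptModel]:
    """Read transcript models from BED12 (score column = read support) or GFF3.

    Records with identical coordinates are kept as distinct models;
    deduplication/collapsing is a downstream decision.
    """
    path = Path(path)
    transcripts: list[TranscriptModel] = []
    if format == "bed12":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                transcripts.append(_parse_bed12_line(line, lineno, sample_id, str(path)))
    elif format == "gff3":
        _validate_gff3_lines(path)
        db = _gff3_db(path)
        for ftype in ("mRNA", "transcript"):
            for feat in db.features_of_type(ftype):
                strand = feat.strand if feat.strand in STRANDS else "+"
                exon_feats = sorted(
                    db.children(feat, featuretype="exon"), key=lambda f: f.start
                )
                if exon_feats:
                    exons = tuple(
                        GenomicInterval(e.seqid, e.start - 1, e.end, strand)
                        for e in exon_feats
                    )
                else:
                    exons = (GenomicInterval(feat.seqid, feat.start - 1, feat.end, strand),)
                count = 1
                if "read_count" in feat.attributes:
                    count = int(feat.attributes["read_count"][0])
                transcripts.append(
                    TranscriptModel(
                        transcript_id=feat.id,
                        exons=exons,
                        sample_id=sample_id,
                        read_count=count,
                    )
                )
    else:
        raise ValueError(f"unknown transcript format {format!r}")
    logger.info("%s: read %d transcript model(s) for sample %s", path, len(transcripts), sample_id)
    return transcripts


def write_transcripts_bed12(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as BED12; the score column carries read support."""
    with open(path, "w") as fh:
        for t in transcripts:
            sizes = ",".join(str(ex.length) for ex in t.exons)
            starts = ",".join(str(ex.start - t.start) for ex in t.exons)
            fh.write(
                "\t".join(
                    [
                        t.chrom,
                        str(t.start),
                        str(t.end),
                        t.transcript_id,
                        str(t.read_count),
                        t.strand,
                        str(t.start),
                        str(t.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tracks
# ---------------------------------------------------------------------------


def read_cage(path: str | Path) -> CageTrack:
    """Read a CAGE TSV (chrom, strand, position [1-based], tpm) into a CageTrack."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"chrom", "strand", "position", "tpm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: CAGE TSV missing columns {sorted(missing)}")
    entries: dict[tuple[str, str, int], float] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, row.strand, int(row.position) - 1)
        if key in entries:
            raise ValueError(f"{path}: duplicate CAGE position {key}")
        entries[key] = float(row.tpm)
    logger.info("%s: read %d CAGE position(s)", path, len(entries))
    return CageTrack(entries=entries)


def write_cage(track: CageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstrand\tposition\ttpm\n")
        for (chrom, strand, pos), tpm in sorted(track.entries.items()):
            fh.write(f"{chrom}\t{strand}\t{pos + 1}\t{tpm:g}\n")


def read_localization(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping gene_id -> localization label."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError(f"{path}: localization TSV needs >= 2 columns")
    mapping = dict(zip(df[cols[0]], df[cols[1]]))
    logger.info("%s: read localization for %d gene(s)", path, len(mapping))
    return mapping


# ---------------------------------------------------------------------------
# Sequence access
# ---------------------------------------------------------------------------


def fetch_sequence(genome, chrom: str, start: int, end: int) -> str:
    """Fetch an uppercase sequence slice from a dict-of-str or pyfaidx.Fasta.

    Raises ``KeyError`` for an unknown chromosome and ``ValueError`` when the
    requested slice runs outside the sequence bounds.
    """
    if start < 0:
        raise ValueError(f"{chrom}:{start}-{end}: negative start")
    record = genome[chrom]  # KeyError propagates for unknown chromosomes
    sub = record[start:end]
    seq = str(getattr(sub, "seq", sub))
    if len(seq) != end - start:
        raise ValueError(
            f"{chrom}:{start}-{end}: slice runs outside sequence bounds "
            f"(got {len(seq)} nt)"
        )
    return seq.upper()
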