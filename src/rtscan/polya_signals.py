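"""Hexamer scanning for polyadenylation-signal (NUE) and cleavage (CE) elements.

Windows run upstream from a first-gene polyadenylation boundary, capped at
``max_len_nt`` or at the IS-intron donor site, whichever is closer (an
optional donor-anchored mode extends the window all the way to the donor).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

from .genome_model import GenomicInterval, fetch_sequence, reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LEN_NT = 150

# Literature-style defaults, user-overridable: the canonical plant
# polyadenylation signal plus common single-substitution variants (NUE), and
# a small YA-centred, U-rich-flanked set (CE).  Analyses that need an exact
# published dictionary should supply their own hexamer files.
DEFAULT_NUE_HEXAMERS = frozenset(
    {
        "AATAAA",
        "AATAAT",
        "AATAAG",
        "AATACA",
        "AATATA",
        "AATGAA",
        "ATTAAA",
        "TATAAA",
        "GATAAA",
        "CATAAA",
        "AAGAAA",
        "AACAAA",
    }
)
DEFAULT_CE_HEXAMERS = frozenset(
    "".join(p)
    for p in itertools.product(["T"], ["T", "G"], ["C", "T"], ["A"], ["T"], ["T", "G"])
)


@dataclass(frozen=True)
class HexamerDictionary:
    nue_hexamers: frozenset[str]
    ce_hexamers: frozenset[str]

    def __post_init__(self) -> None:
        for name, hexset in (("NUE", self.nue_hexamers), ("CE", self.ce_hexamers)):
            for h in hexset:
                if len(h) != 6 or set(h) - set("ACGT"):
                    raise ValueError(f"{name} entry {h!r} is not an uppercase ACGT 6-mer")

    @classmethod
    def literature_defaults(cls) -> "HexamerDictionary":
        return cls(DEFAULT_NUE_HEXAMERS, DEFAULT_CE_HEXAMERS)

    @classmethod
    def from_files(cls, nue_path: str | Path, ce_path: str | Path) -> "HexamerDictionary":
        return cls(read_hexamer_file(nue_path), read_hexamer_file(ce_path))


def read_hexamer_file(path: str | Path) -> frozenset[str]:
    """One hexamer per line; blank lines and '#' comments ignored."""
    entries = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip().upper()
            if line and not line.startswith("#"):
                entries.add(line)
    return frozenset(entries)


def write_hexamer_file(hexamers, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in sorted(hexamers):
            fh.write(h + "\n")


@dataclass
class SignalScanResult:
    locus_id: str
    window: GenomicInterval
    nue_hits: list[tuple[str, int]]
    ce_hits: list[tuple[str, int]]

    @property
    def has_nue(self) -> bool:
        return bool(self.nue_hits)

    @property
    def has_ce(self) -> bool:
        return bool(self.ce_hits)


def build_scan_window(
    polya_pos: int,
    donor_pos: int | None,
    strand: str,
    chrom: str = "chr",
    max_len_nt: int = DEFAULT_WINDOW_LEN_NT,
    donor_anchored: bool = False,
) -> GenomicInterval:
    """Window upstream of a polyA boundary, bounded by the IS donor if closer.

    ``polya_pos`` is the half-open 3' boundary in transcription direction
    (last exon end on '+', first exon start on '-'; see
    :func:`rtscan.genome_model.polya_boundary`), so the polyadenylated base
    itself falls inside the window.  With ``donor_anchored`` the window runs
    from the donor even when that exceeds ``max_len_nt``.
    """
    if max_len_nt < 1:
        raise ValueError("max_len_nt must be >= 1")
    if strand == "+":
        lo = polya_pos - max_len_nt
        if donor_pos is not None:
            if donor_pos >= polya_pos:
                raise ValueError(
                    f"donor position {donor_pos} not upstream of polyA boundary {polya_pos}"
                )
            lo = donor_pos if donor_anchored else max(lo, donor_pos)
        lo = max(lo, 0)
        if lo >= polya_pos:
            raise ValueError("zero-length scan window")
        return GenomicInterval(chrom, lo, polya_pos, "+")
    else:
        hi = polya_pos + max_len_nt
        if donor_pos is not None:
            # on '-' the donor base sits at a higher genomic coordinate
            if donor_pos < polya_pos:
                raise ValueError(
                    f"donor position {donor_pos} not upstream of polyA boundary {polya_pos}"
                )
            hi = donor_pos + 1 if donor_anchored else min(hi, donor_pos + 1)
        if hi <= polya_pos:
            raise ValueError("zero-length scan window")
        return GenomicInterval(chrom, polya_pos, hi, "-")


def scan_hexamers(
    window: GenomicInterval,
    genome,
    dictionary: HexamerDictionary,
    locus_id: str = "",
) -> SignalScanResult:
    """Test every overlapping 6-mer of the window against both hexamer sets.

    Offsets are in transcription direction (0 = window 5' end).  Positions
    containing ambiguous bases never match because dictionaries are ACGT-only.
    """
    seq = fetch_sequence(genome, window.chrom, window.start, window.end)
    if window.strand == "-":
        seq = reverse_complement(seq)
    nue_hits: list[tuple[str, int]] = []
    ce_hits: list[tuple[str, int]] = []
    for i in range(len(seq) - 5):
        kmer = seq[i : i + 6]
        if kmer in dictionary.nue_hexamers:
            nue_hits.append((kmer, i))
        if kmer in dictionary.ce_hexamers:
            ce_hits.append((kmer, i))
    return SignalScanResult(locus_id=locus_id, window=window, nue_hits=nue_hits, ce_hits=ce_hits)
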