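"""Seeded synthetic datasets with planted ground truth for every pipeline stage.

The generator emits a toy genome FASTA, a tandem-gene-pair GFF3 annotation,
per-read transcript models (BED12), a CAGE TSV, ORF count tables and a
localization table, plus ``ground_truth.json`` recording what was planted.
All randomness flows from a single integer seed; identical configs produce
byte-identical files.

Geometry (per pair, genomic left to right): 400 nt genes (50 nt UTRs around
a 300 nt CDS) separated by a seeded 200-600 nt gap; the IS intron runs from
40 nt past the upstream CDS to 40 nt before the downstream CDS.  On '-'
pairs the first (5'-most in transcription direction) gene is the right one.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_model import (
    GenomicInterval,
    TranscriptModel,
    CageTrack,
    reverse_complement,
    write_cage,
    write_transcripts_bed12,
)
from .expression_support import ORFCounts
from .polya_signals import build_scan_window, write_hexamer_file

logger = logging.getLogger(__name__)

UTR_LEN = 50
CDS_LEN = 300
GENE_LEN = 2 * UTR_LEN + CDS_LEN
INTRON_MARGIN = 40  # IS intron offset from CDS boundaries
PAIR_SPACER = 1000
CHROM = "chr1"
SAMPLE_ID = "sim"

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_gene_pairs: int = 10
    fraction_rt_loci: float = 0.5
    fraction_is: float = 0.5
    fraction_polya_in_intron: float = 0.5
    reads_rt: int = 5
    reads_first_mono: int = 4
    reads_second_mono: int = 3
    nue_hexamers: tuple[str, ...] = ("AATAAA",)
    ce_hexamers: tuple[str, ...] = ("TGTATT",)
    fraction_nue: float = 1.0
    fraction_ce: float = 1.0
    te_first: float = 5.0
    te_second: float = 0.1
    rna_mean: float = 200.0
    n_replicates: int = 3
    noise_model: str = "poisson"  # "poisson" | "nb"
    nb_dispersion: float = 0.1
    tss_tpm_range: tuple[float, float] = (0.5, 5.0)
    tss_unsupported_tpm: float = 0.05
    fraction_tss_supported: float = 1.0
    fraction_organelle_first: float = 0.5
    antisense_decoys: bool = False
    utr_overlap_decoys: bool = False
    alternate_strands: bool = True

    def __post_init__(self) -> None:
        fracs = {
            "fraction_rt_loci": self.fraction_rt_loci,
            "fraction_is": self.fraction_is,
            "fraction_polya_in_intron": self.fraction_polya_in_intron,
            "fraction_nue": self.fraction_nue,
            "fraction_ce": self.fraction_ce,
            "fraction_tss_supported": self.fraction_tss_supported,
            "fraction_organelle_first": self.fraction_organelle_first,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_gene_pairs < 1:
            raise ConfigError("n_gene_pairs must be >= 1")
        if self.noise_model not in ("poisson", "nb"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        n_rt = _planted_count(self.fraction_rt_loci, self.n_gene_pairs)
        if self.fraction_is > 0 and n_rt == 0:
            raise ConfigError("fraction_is > 0 but the config plants zero RT loci")
        for h in (*self.nue_hexamers, *self.ce_hexamers):
            if len(h) != 6 or set(h) - set("ACGT"):
                raise ConfigError(f"planted hexamer {h!r} is not an ACGT 6-mer")


def _planted_count(fraction: float, n: int) -> int:
    return int(round(fraction * n))


@dataclass
class LocusTruth:
    pair_id: str
    gene_ids: tuple[str, str]  # (first, second) in transcription direction
    strand: str
    is_rt: bool
    has_is: bool
    is_intron: tuple[int, int] | None
    polya_in_intron: bool
    first_mono_emitted: bool
    polya_boundary: int | None
    window: tuple[int, int] | None
    planted_nue: list[tuple[str, int]]
    planted_ce: list[tuple[str, int]]
    tss_tpm: float | None
    tss_supported: bool | None
    te_first: float | None
    te_second: float | None
    localization_first: str
    localization_second: str


@dataclass
class GroundTruth:
    seed: int
    sample_id: str
    n_transcripts: int
    loci: list[LocusTruth] = field(default_factory=list)

    def rt_gene_tuples(self) -> set[tuple[str, ...]]:
        return {t.gene_ids for t in self.loci if t.is_rt}

    def gene_universe(self) -> set[str]:
        return {g for t in self.loci for g in t.gene_ids}

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        loci = []
        for d in payload["loci"]:
            d = dict(d)
            d["gene_ids"] = tuple(d["gene_ids"])
            if d["is_intron"] is not None:
                d["is_intron"] = tuple(d["is_intron"])
            if d["window"] is not None:
                d["window"] = tuple(d["window"])
            d["planted_nue"] = [tuple(x) for x in d["planted_nue"]]
            d["planted_ce"] = [tuple(x) for x in d["planted_ce"]]
            loci.append(LocusTruth(**d))
        return cls(
            seed=payload["seed"],
            sample_id=payload["sample_id"],
            n_transcripts=payload["n_transcripts"],
            loci=loci,
        )


# ---------------------------------------------------------------------------
# genome editing helpers
# ---------------------------------------------------------------------------


def _set_seq(genome: list[str], start: int, seq: str) -> None:
    genome[start : start + len(seq)] = list(seq)


def _plant_td(genome: list[str], strand: str, win_start: int, win_end: int, offset: int, seq: str) -> int:
    """Plant ``seq`` at a transcription-direction offset inside [win_start, win_end).

    Returns the genomic start of the planted motif.
    """
    if strand == "+":
        g = win_start + offset
        _set_seq(genome, g, seq)
    else:
        g = win_end - offset - len(seq)
        _set_seq(genome, g, reverse_complement(seq))
    return g


def _scrub_region(
    genome: list[str],
    start: int,
    end: int,
    strand: str,
    forbidden: frozenset[str],
    protected: set[int],
    max_passes: int = 60,
) -> None:
    """Mutate bases so no forbidden 6-mer survives in the region (td sense).

    Positions in ``protected`` (genomic) are never mutated.  Deterministic:
    offending bases cycle A->C->G->T.
    """
    order = "ACGT"
    for _ in range(max_passes):
        seq = "".join(genome[start:end])
        if strand == "-":
            seq = reverse_complement(seq)
        dirty = False
        for i in range(len(seq) - 5):
            if seq[i : i + 6] in forbidden:
                # genomic coordinates of the offending 6-mer
                if strand == "+":
                    span = range(start + i, start + i + 6)
                else:
                    span = range(end - i - 6, end - i)
                for gpos in span:
                    if gpos not in protected:
                        genome[gpos] = order[(order.index(genome[gpos]) + 1) % 4]
                        dirty = True
                        break
                break
        if not dirty:
            return
    raise RuntimeError("hexamer scrubbing did not converge")


# ---------------------------------------------------------------------------
# count models
# ---------------------------------------------------------------------------


def _draw_count(rng: np.random.Generator, mean: float, noise_model: str, nb_dispersion: float) -> int:
    if noise_model == "poisson":
        return int(rng.poisson(mean))
    n = 1.0 / nb_dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def simulate_orf_counts(
    rng: np.random.Generator,
    te_first: float,
    te_second: float,
    n_replicates: int = 3,
    rna_mean: float = 200.0,
    noise_model: str = "poisson",
    nb_dispersion: float = 0.1,
    construct_id: str = "construct",
    libsize: int = 1_000_000,
) -> list[ORFCounts]:
    """Draw one construct's first/second ORF count table at planted TE ratios."""
    orfs = []
    for role, te in (("first", te_first), ("second", te_second)):
        rna = [max(1, _draw_count(rng, rna_mean, noise_model, nb_dispersion)) for _ in range(n_replicates)]
        fp = [_draw_count(rng, te * r, noise_model, nb_dispersion) for r in rna]
        orfs.append(
            ORFCounts(
                orf_id=f"{construct_id}_{role}",
                role=role,
                construct_id=construct_id,
                footprint_counts=tuple(fp),
                rna_counts=tuple(rna),
                fp_libsizes=(libsize,) * n_replicates,
                rna_libsizes=(libsize,) * n_replicates,
            )
        )
    return orfs


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------


def simulate(config: SimulationConfig, outdir: str | Path) -> GroundTruth:
    """Write the full synthetic bundle to ``outdir`` and return ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n = config.n_gene_pairs
    n_rt = _planted_count(config.fraction_rt_loci, n)
    rt_idx = set(rng.permutation(n)[:n_rt].tolist())
    rt_list = sorted(rt_idx)
    n_is = _planted_count(config.fraction_is, n_rt)
    is_idx = set(np.array(rt_list)[rng.permutation(n_rt)[:n_is]].tolist()) if n_rt else set()
    is_list = sorted(is_idx)
    n_pin = _planted_count(config.fraction_polya_in_intron, n_is)
    pin_idx = set(np.array(is_list)[rng.permutation(n_is)[:n_pin]].tolist()) if n_is else set()
    pin_list = sorted(pin_idx)
    n_nue = _planted_count(config.fraction_nue, n_pin)
    nue_idx = set(np.array(pin_list)[rng.permutation(n_pin)[:n_nue]].tolist()) if n_pin else set()
    n_ce = _planted_count(config.fraction_ce, n_pin)
    ce_idx = set(np.array(pin_list)[rng.permutation(n_pin)[:n_ce]].tolist()) if n_pin else set()
    n_tss = _planted_count(config.fraction_tss_supported, n_rt)
    tss_idx = set(np.array(rt_list)[rng.permutation(n_rt)[:n_tss]].tolist()) if n_rt else set()
    n_org = _planted_count(config.fraction_organelle_first, n_rt)
    org_idx = set(np.array(rt_list)[rng.permutation(n_rt)[:n_org]].tolist()) if n_rt else set()

    gaps = rng.integers(200, 601, size=n)

    # genomic layout
    pair_left = []
    cursor = 500
    for i in range(n):
        pair_left.append(cursor)
        cursor += 2 * GENE_LEN + int(gaps[i]) + PAIR_SPACER
    genome_len = cursor + 500
    genome = list(BASES[rng.integers(0, 4, size=genome_len)])

    truth = GroundTruth(seed=config.seed, sample_id=SAMPLE_ID, n_transcripts=0)
    transcripts: list[TranscriptModel] = []
    gff_lines: list[str] = ["##gff-version 3"]
    cage_entries: dict[tuple[str, str, int], float] = {}
    orf_rows: list[str] = []
    loc_rows: list[str] = []
    nue_cycle = list(config.nue_hexamers)
    ce_cycle = list(config.ce_hexamers)

    for i in range(n):
        pid = f"pair{i:03d}"
        strand = "-" if (config.alternate_strands and i % 2 == 1) else "+"
        gap = int(gaps[i])
        lx = pair_left[i]
        left = (lx, lx + GENE_LEN)
        right = (lx + GENE_LEN + gap, lx + 2 * GENE_LEN + gap)
        left_cds = (left[0] + UTR_LEN, left[1] - UTR_LEN)
        right_cds = (right[0] + UTR_LEN, right[1] - UTR_LEN)
        if strand == "+":
            first_span, second_span = left, right
        else:
            first_span, second_span = right, left
        first_id, second_id = f"gene{i:03d}a", f"gene{i:03d}b"

        # annotation rows (left-to-right genomic order, ids in transcription order)
        for gid, span, cds in (
            (first_id if strand == "+" else second_id, left, left_cds),
            (second_id if strand == "+" else first_id, right, right_cds),
        ):
            gff_lines.append(
                f"{CHROM}\trtscan_sim\tgene\t{span[0] + 1}\t{span[1]}\t.\t{strand}\t.\tID={gid}"
            )
            gff_lines.append(
                f"{CHROM}\trtscan_sim\tmRNA\t{span[0] + 1}\t{span[1]}\t.\t{strand}\t.\t"
                f"ID={gid}.1;Parent={gid}"
            )
            gff_lines.append(
                f"{CHROM}\trtscan_sim\texon\t{span[0] + 1}\t{span[1]}\t.\t{strand}\t.\t"
                f"ID={gid}.1.exon1;Parent={gid}.1"
            )
            gff_lines.append(
                f"{CHROM}\trtscan_sim\tCDS\t{cds[0] + 1}\t{cds[1]}\t.\t{strand}\t0\t"
                f"ID={gid}.1.cds1;Parent={gid}.1"
            )

        is_rt = i in rt_idx
        has_is = i in is_idx
        pin = i in pin_idx
        intron = (left_cds[1] + INTRON_MARGIN, right_cds[0] - INTRON_MARGIN) if has_is else None

        protected: set[int] = set()
        if intron is not None:
            s, e = intron
            if strand == "+":
                _set_seq(genome, s, "GTA")
                _set_seq(genome, e - 3, "CAG")
            else:
                _set_seq(genome, s, reverse_complement("CAG"))
                _set_seq(genome, e - 3, reverse_complement("GTA"))
            protected.update(range(s, s + 3))
            protected.update(range(e - 3, e))

        # transcript emission -------------------------------------------------
        def add_reads(prefix: str, exons: list[tuple[int, int]], n_reads: int, t_strand: str) -> None:
            for r in range(n_reads):
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{pid}_{prefix}_{r}",
                        exons=tuple(GenomicInterval(CHROM, a, b, t_strand) for a, b in exons),
                        sample_id=SAMPLE_ID,
                        read_count=1,
                    )
                )

        first_mono_emitted = False
        polya_bound: int | None = None
        if is_rt:
            if has_is:
                assert intron is not None
                add_reads("rt", [(left[0], intron[0]), (intron[1], right[1])], config.reads_rt, strand)
            else:
                add_reads("rt", [(left[0], right[1])], config.reads_rt, strand)
            if has_is and pin:
                mid = (intron[0] + intron[1]) // 2
                if strand == "+":
                    add_reads("mono1", [(left[0], mid)], config.reads_first_mono, strand)
                    polya_bound = mid
                else:
                    add_reads("mono1", [(mid, right[1])], config.reads_first_mono, strand)
                    polya_bound = mid
                first_mono_emitted = config.reads_first_mono > 0
            elif not has_is:
                # weak-terminator locus without IS still shows first monos
                mono_span = left if strand == "+" else right
                add_reads("mono1", [mono_span], config.reads_first_mono, strand)
                first_mono_emitted = config.reads_first_mono > 0
                polya_bound = mono_span[1] if strand == "+" else mono_span[0]
            # IS loci without internal polyA dominantly produce only RTs
            second_span_g = right if strand == "+" else left
            add_reads("mono2", [second_span_g], config.reads_second_mono, strand)
        else:
            add_reads("mono1", [left if strand == "+" else right], config.reads_first_mono, strand)
            add_reads("mono2", [right if strand == "+" else left], config.reads_second_mono, strand)

        if is_rt and config.antisense_decoys:
            anti = "-" if strand == "+" else "+"
            add_reads("anti", [(left[0], right[1])], 1, anti)
        if is_rt and config.utr_overlap_decoys:
            if strand == "+":
                add_reads("utrdecoy", [(left[0], right[0] + INTRON_MARGIN)], 1, strand)
            else:
                add_reads("utrdecoy", [(left[1] - INTRON_MARGIN, right[1])], 1, strand)

        # hexamer planting -----------------------------------------------------
        window = None
        planted_nue: list[tuple[str, int]] = []
        planted_ce: list[tuple[str, int]] = []
        if is_rt and has_is and pin and polya_bound is not None:
            assert intron is not None
            donor = intron[0] if strand == "+" else intron[1] - 1
            win = build_scan_window(polya_bound, donor, strand, chrom=CHROM)
            window = (win.start, win.end)
            wlen = win.length
            scrub_lo = max(0, win.start - 30)
            scrub_hi = min(genome_len, win.end + 30)
            forbidden = frozenset((*config.nue_hexamers, *config.ce_hexamers))
            _scrub_region(genome, scrub_lo, scrub_hi, strand, forbidden, protected)
            if i in nue_idx:
                hexamer = nue_cycle[i % len(nue_cycle)]
                off = wlen - 50
                g = _plant_td(genome, strand, win.start, win.end, off, hexamer)
                protected.update(range(g, g + 6))
                planted_nue.append((hexamer, off))
            if i in ce_idx:
                hexamer = ce_cycle[i % len(ce_cycle)]
                off = wlen - 20
                g = _plant_td(genome, strand, win.start, win.end, off, hexamer)
                protected.update(range(g, g + 6))
                planted_ce.append((hexamer, off))
            # decoy just outside the window (upstream in transcription direction)
            decoy = nue_cycle[0]
            _plant_td(genome, strand, win.start, win.end, -26, decoy)
            # planting may have created accidental matches at the junctions
            _scrub_region_keep_planted(genome, win, strand, forbidden, planted_nue + planted_ce, protected)

        # CAGE -----------------------------------------------------------------
        tss_tpm: float | None = None
        tss_ok: bool | None = None
        if is_rt:
            second_tss_pos = right[0] if strand == "+" else left[1] - 1
            tss_ok = i in tss_idx
            if tss_ok:
                lo, hi = config.tss_tpm_range
                tss_tpm = round(float(lo + (hi - lo) * rng.random()), 3)
            else:
                tss_tpm = config.tss_unsupported_tpm
            cage_entries[(CHROM, strand, second_tss_pos)] = tss_tpm

        # ORF counts -----------------------------------------------------------
        te_f = te_s = None
        if is_rt:
            te_f, te_s = config.te_first, config.te_second
            for orf in simulate_orf_counts(
                rng,
                te_f,
                te_s,
                n_replicates=config.n_replicates,
                rna_mean=config.rna_mean,
                noise_model=config.noise_model,
                nb_dispersion=config.nb_dispersion,
                construct_id=pid,
            ):
                for r in range(orf.n_replicates):
                    orf_rows.append(
                        f"{orf.orf_id}\t{orf.role}\t{orf.construct_id}\t{r}\t"
                        f"{orf.footprint_counts[r]}\t{orf.rna_counts[r]}\t"
                        f"{orf.fp_libsizes[r]}\t{orf.rna_libsizes[r]}"
                    )

        # localization ---------------------------------------------------------
        if i in org_idx:
            loc_first = "mitochondrion" if (i % 2 == 0) else "chloroplast"
        else:
            loc_first = "other"
        loc_second = "other"
        loc_rows.append(f"{first_id}\t{loc_first}")
        loc_rows.append(f"{second_id}\t{loc_second}")

        truth.loci.append(
            LocusTruth(
                pair_id=pid,
                gene_ids=(first_id, second_id),
                strand=strand,
                is_rt=is_rt,
                has_is=has_is,
                is_intron=intron,
                polya_in_intron=pin,
                first_mono_emitted=first_mono_emitted,
                polya_boundary=polya_bound,
                window=window,
                planted_nue=planted_nue,
                planted_ce=planted_ce,
                tss_tpm=tss_tpm,
                tss_supported=tss_ok,
                te_first=te_f,
                te_second=te_s,
                localization_first=loc_first,
                localization_second=loc_second,
            )
        )

    truth.n_transcripts = sum(t.read_count for t in transcripts)

    # emit files ---------------------------------------------------------------
    seq = "".join(genome)
    with open(outdir / "genome.fa", "w") as fh:
        fh.write(f">{CHROM}\n")
        for j in range(0, len(seq), 80):
            fh.write(seq[j : j + 80] + "\n")
    with open(outdir / "annotation.gff3", "w") as fh:
        fh.write("\n".join(gff_lines) + "\n")
    write_transcripts_bed12(transcripts, outdir / "transcripts.bed")
    write_cage(CageTrack(entries=cage_entries), outdir / "cage.tsv")
    header = "orf_id\trole\tconstruct\treplicate\tfootprint_count\trna_count\tfp_libsize\trna_libsize"
    with open(outdir / "orf_counts.tsv", "w") as fh:
        fh.write(header + "\n")
        if orf_rows:
            fh.write("\n".join(orf_rows) + "\n")
    with open(outdir / "localization.tsv", "w") as fh:
        fh.write("gene_id\tlocalization\n")
        fh.write("\n".join(loc_rows) + "\n")
    write_hexamer_file(config.nue_hexamers, outdir / "nue_hexamers.txt")
    write_hexamer_file(config.ce_hexamers, outdir / "ce_hexamers.txt")
    truth.to_json(outdir / "ground_truth.json")
    logger.info(
        "simulated %d pairs (%d RT, %d IS, %d polyA-in-intron) -> %s",
        n, n_rt, n_is, n_pin, outdir,
    )
    return truth


def _scrub_region_keep_planted(
    genome: list[str],
    win: GenomicInterval,
    strand: str,
    forbidden: frozenset[str],
    planted: list[tuple[str, int]],
    protected: set[int],
) -> None:
    """Remove dictionary matches inside the window except at planted offsets."""
    planted_offsets = {off for _, off in planted}
    order = "ACGT"
    for _ in range(60):
        seq = "".join(genome[win.start : win.end])
        if strand == "-":
            seq = reverse_complement(seq)
        dirty = False
        for i in range(len(seq) - 5):
            if i in planted_offsets:
                continue
            if seq[i : i + 6] in forbidden:
                if strand == "+":
                    span = range(win.start + i, win.start + i + 6)
                else:
                    span = range(win.end - i - 6, win.end - i)
                for gpos in span:
                    if gpos not in protected:
                        genome[gpos] = order[(order.index(genome[gpos]) + 1) % 4]
                        dirty = True
                        break
                break
        if not dirty:
            return
    raise RuntimeError("hexamer scrubbing did not converge")


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------


def _sens_prec(true_set: set, pred_set: set) -> dict[str, float]:
    tp = len(true_set & pred_set)
    sens = tp / len(true_set) if true_set else 1.0
    prec = tp / len(pred_set) if pred_set else 1.0
    return {"sensitivity": sens, "precision": prec}


def evaluate_recovery(
    truth: GroundTruth,
    loci: Sequence | None = None,
    termination_classes: dict[tuple[str, ...], str] | None = None,
    hexamer_flags: dict[tuple[str, ...], tuple[bool, bool]] | None = None,
    tss_flags: dict[str, bool] | None = None,
) -> dict:
    """Sensitivity/precision of pipeline output against planted truth.

    ``loci`` are RTLocus objects; other stages are keyed by the locus's
    ordered gene-id tuple (termination class label, (has_nue, has_ce)) or by
    the second gene id (TSS support).  Predicted loci naming genes unknown
    to the truth raise ``ValueError``.
    """
    from .intergenic_splicing import CLASS_IS_WITH_POLYA

    report: dict = {}
    universe = truth.gene_universe()
    truth_by_genes = {t.gene_ids: t for t in truth.loci}

    if loci is not None:
        pred = set()
        for locus in loci:
            ids = locus.gene_ids
            if not set(ids) <= universe:
                raise ValueError(f"predicted locus references unknown genes: {ids}")
            pred.add(ids)
        report["rt_loci"] = _sens_prec(truth.rt_gene_tuples(), pred)

        true_introns = {
            (t.gene_ids, t.is_intron) for t in truth.loci if t.is_rt and t.has_is
        }
        pred_introns = {
            (locus.gene_ids, (iv.interval.start, iv.interval.end))
            for locus in loci
            for iv in locus.is_introns
        }
        report["is_introns"] = _sens_prec(true_introns, pred_introns)

    if termination_classes is not None:
        true_pin = {
            t.gene_ids
            for t in truth.loci
            if t.is_rt and t.has_is and t.polya_in_intron and t.first_mono_emitted
        }
        pred_pin = {
            ids for ids, label in termination_classes.items() if label == CLASS_IS_WITH_POLYA
        }
        report["polya_in_intron"] = _sens_prec(true_pin, pred_pin)

    if hexamer_flags is not None:
        n_match = 0
        n_total = 0
        for ids, (has_nue, has_ce) in hexamer_flags.items():
            t = truth_by_genes.get(ids)
            if t is None:
                raise ValueError(f"hexamer flags for unknown locus {ids}")
            if t.window is None:
                continue
            n_total += 1
            if has_nue == bool(t.planted_nue) and has_ce == bool(t.planted_ce):
                n_match += 1
        report["hexamer_flags"] = {
            "n": n_total,
            "exact_match_fraction": n_match / n_total if n_total else 1.0,
        }

    if tss_flags is not None:
        n_match = 0
        n_total = 0
        for t in truth.loci:
            if not t.is_rt or t.tss_supported is None:
                continue
            if t.gene_ids[1] in tss_flags:
                n_total += 1
                if tss_flags[t.gene_ids[1]] == t.tss_supported:
                    n_match += 1
        report["tss_support"] = {
            "n": n_total,
            "exact_match_fraction": n_match / n_total if n_total else 1.0,
        }

    return report
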