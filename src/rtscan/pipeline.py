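"""End-to-end pipeline driver: RT calling -> IS classification -> polyA-signal
scanning -> expression support, with TSV outputs and a JSON run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genome_model import (
    polya_site,
    read_cage,
    read_gff3_genes,
    read_localization,
    read_transcripts,
)
from .rt_detection import (
    RTLocus,
    call_rt_transcripts,
    detect_monocistronic_counterparts,
    group_rt_loci,
    summarize_counts,
)
from .intergenic_splicing import (
    LocusTerminationClass,
    classify_termination,
    cluster_polya_sites,
    find_is_introns,
    splice_site_dinucleotides,
)
from .polya_signals import (
    HexamerDictionary,
    SignalScanResult,
    build_scan_window,
    scan_hexamers,
)
from .expression_support import (
    ORGANELLE_LABELS,
    EnrichmentInput,
    TEComparison,
    compare_orf_te,
    hypergeom_enrichment,
    localization_distribution,
    read_orf_counts,
    tss_supported,
)

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    annotation: str
    transcripts: dict[str, str]  # sample_id -> path
    transcript_format: str = "bed12"
    genome_fasta: str | None = None
    cage: str | None = None
    orf_counts: str | None = None
    localization: str | None = None
    nue_hexamers: str | None = None
    ce_hexamers: str | None = None
    outdir: str = "rtscan_out"
    min_cds_overlap_bp: int = 30
    cluster_radius_nt: int = 10
    window_max_len_nt: int = 150
    donor_anchored_window: bool = False
    tpm_threshold: float = 0.2
    tss_window_nt: int = 100
    normalize_te: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.min_cds_overlap_bp < 1:
            raise PipelineConfigError("min_cds_overlap_bp must be >= 1")
        if self.window_max_len_nt < 1:
            raise PipelineConfigError("window_max_len_nt must be >= 1")
        if self.cluster_radius_nt < 0 or self.tss_window_nt < 0:
            raise PipelineConfigError("radii/windows must be >= 0")
        if self.tpm_threshold < 0:
            raise PipelineConfigError("tpm_threshold must be >= 0")
        if not self.transcripts:
            raise PipelineConfigError("at least one transcript input is required")
        for path in [self.annotation, *self.transcripts.values()]:
            if not Path(path).exists():
                raise PipelineConfigError(f"input file not found: {path}")
        for path in (
            self.genome_fasta,
            self.cage,
            self.orf_counts,
            self.localization,
            self.nue_hexamers,
            self.ce_hexamers,
        ):
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    loci: list[RTLocus]
    summaries: list
    termination_classes: list[LocusTerminationClass]
    scans: list[SignalScanResult]
    tss_flags: dict[str, bool]
    te_comparison: TEComparison | None
    enrichment_p: float | None
    manifest: dict
    first_monos: dict[str, list] = field(default_factory=dict)


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; every output lands as TSV/JSON under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    genes = read_gff3_genes(config.annotation)
    transcripts = []
    totals: dict[str, int] = {}
    for sample_id, path in sorted(config.transcripts.items()):
        ts = read_transcripts(path, format=config.transcript_format, sample_id=sample_id)
        transcripts.extend(ts)
        totals[sample_id] = sum(t.read_count for t in ts)

    genome = None
    if config.genome_fasta:
        from pyfaidx import Fasta

        genome = Fasta(config.genome_fasta)

    # --- RT calling ---------------------------------------------------------
    assignments = call_rt_transcripts(
        transcripts, genes, min_cds_overlap_bp=config.min_cds_overlap_bp
    )
    loci = group_rt_loci(assignments, samples=sorted(totals))
    summaries = summarize_counts(loci, totals)

    # --- IS detection and termination classes ------------------------------
    classes: list[LocusTerminationClass] = []
    first_monos_by_locus: dict[str, list] = {}
    for locus in loci:
        first_monos, _ = detect_monocistronic_counterparts(
            locus, transcripts, min_cds_overlap_bp=config.min_cds_overlap_bp
        )
        first_monos_by_locus[locus.locus_id] = first_monos
        find_is_introns(locus)
        classes.append(
            classify_termination(locus, first_monos, cluster_radius_nt=config.cluster_radius_nt)
        )

    # --- polyA-signal scanning ----------------------------------------------
    scans: list[SignalScanResult] = []
    if genome is not None and config.nue_hexamers and config.ce_hexamers:
        dictionary = HexamerDictionary.from_files(config.nue_hexamers, config.ce_hexamers)
        for locus in loci:
            monos = first_monos_by_locus[locus.locus_id]
            if not monos:
                continue
            sites = [(polya_site(t)[2], t.read_count) for t in monos]
            reps = cluster_polya_sites(sites, config.cluster_radius_nt)
            rep = max(reps, key=lambda ps: (ps[1], -ps[0]))[0]
            boundary = rep + 1 if locus.strand == "+" else rep
            donor = None
            for intron in locus.is_introns:
                if intron.contains_strictly(rep):
                    donor = intron.donor_pos
                    break
            window = build_scan_window(
                boundary,
                donor,
                locus.strand,
                chrom=locus.chrom,
                max_len_nt=config.window_max_len_nt,
                donor_anchored=config.donor_anchored_window,
            )
            scans.append(scan_hexamers(window, genome, dictionary, locus_id=locus.locus_id))
    else:
        warnings.append("polyA-signal scan skipped (genome or hexamer dictionaries missing)")

    # --- CAGE TSS support ----------------------------------------------------
    tss_flags: dict[str, bool] = {}
    if config.cage:
        cage = read_cage(config.cage)
        from .rt_detection import FLAG_SECOND_TSS

        for locus in loci:
            ok = tss_supported(
                locus.second_gene,
                cage,
                tpm_threshold=config.tpm_threshold,
                window_nt=config.tss_window_nt,
            )
            tss_flags[locus.second_gene.gene_id] = ok
            if ok:
                locus.flags.add(FLAG_SECOND_TSS)
    else:
        warnings.append("TSS support skipped (no CAGE input); columns emitted as NA")

    # --- translation efficiency ---------------------------------------------
    te_comparison = None
    if config.orf_counts:
        orfs = read_orf_counts(config.orf_counts)
        if orfs:
            te_comparison = compare_orf_te(orfs, normalize=config.normalize_te)
    else:
        warnings.append("TE comparison skipped (no ORF count input)")

    # --- localization & enrichment ------------------------------------------
    enrichment_p = None
    if config.localization:
        table = read_localization(config.localization)
        localization_distribution(loci, table).to_csv(
            outdir / "localization_distribution.tsv", sep="\t", index=False
        )
        if loci:
            sample_successes = sum(
                1 for locus in loci if table.get(locus.first_gene.gene_id) in ORGANELLE_LABELS
            )
            enrichment_p = hypergeom_enrichment(
                EnrichmentInput(
                    population_size=len(table),
                    population_successes=sum(
                        1 for v in table.values() if v in ORGANELLE_LABELS
                    ),
                    sample_size=len(loci),
                    sample_successes=sample_successes,
                )
            )
    else:
        warnings.append("enrichment skipped (no localization input)")

    _write_outputs(
        outdir, config, loci, summaries, classes, scans, tss_flags, te_comparison,
        enrichment_p, genome, totals,
    )

    manifest = {
        "rtscan_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "transcripts"
        },
        "transcript_inputs": {
            s: {"path": p, "md5": _checksum(p)} for s, p in sorted(config.transcripts.items())
        },
        "input_checksums": {
            name: _checksum(path)
            for name, path in (
                ("annotation", config.annotation),
                ("genome_fasta", config.genome_fasta),
                ("cage", config.cage),
                ("orf_counts", config.orf_counts),
                ("localization", config.localization),
            )
            if path
        },
        "n_rt_loci": len(loci),
        "warnings": warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return PipelineResult(
        loci=loci,
        summaries=summaries,
        termination_classes=classes,
        scans=scans,
        tss_flags=tss_flags,
        te_comparison=te_comparison,
        enrichment_p=enrichment_p,
        manifest=manifest,
        first_monos=first_monos_by_locus,
    )


def _write_outputs(
    outdir: Path,
    config: PipelineConfig,
    loci,
    summaries,
    classes,
    scans,
    tss_flags,
    te_comparison,
    enrichment_p,
    genome,
    totals,
) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in summaries]).to_csv(
        outdir / "summary.tsv", sep="\t", index=False
    )

    class_by_locus = {c.locus_id: c.class_label for c in classes}
    scan_by_locus = {s.locus_id: s for s in scans}

    locus_rows = []
    intron_rows = []
    for locus in loci:
        row = {
            "locus_id": locus.locus_id,
            "chrom": locus.chrom,
            "strand": locus.strand,
            "start": locus.start,
            "end": locus.end,
            "gene_ids": ",".join(locus.gene_ids),
            "n_genes": len(locus.genes),
        }
        for sample in sorted(totals):
            row[f"reads_{sample}"] = sum(
                t.read_count for t in locus.supporting_transcripts.get(sample, [])
            )
        row["flags"] = ";".join(sorted(locus.flags))
        row["termination_class"] = class_by_locus.get(locus.locus_id, "NA")
        scan = scan_by_locus.get(locus.locus_id)
        row["has_nue"] = scan.has_nue if scan else "NA"
        row["has_ce"] = scan.has_ce if scan else "NA"
        second_id = locus.second_gene.gene_id
        row["second_tss_supported"] = tss_flags.get(second_id, "NA")
        locus_rows.append(row)

        for intron in locus.is_introns:
            irow = {
                "locus_id": locus.locus_id,
                "chrom": intron.interval.chrom,
                "start": intron.interval.start,
                "end": intron.interval.end,
                "strand": intron.interval.strand,
                "donor_pos": intron.donor_pos,
                "acceptor_pos": intron.acceptor_pos,
                "supporting_reads": intron.supporting_reads,
                "major": intron.major,
                "gene_pair": ",".join(intron.gene_pair),
                "contained_polya_sites": ";".join(
                    f"{p}:{s}" for p, s in intron.contained_polya_sites
                ),
            }
            if genome is not None:
                sites = splice_site_dinucleotides(intron, genome)
                irow["donor_seq"] = sites.donor_seq
                irow["acceptor_seq"] = sites.acceptor_seq
                irow["canonical"] = sites.canonical
            intron_rows.append(irow)

    pd.DataFrame(locus_rows).to_csv(outdir / "master_table.tsv", sep="\t", index=False)
    pd.DataFrame(intron_rows).to_csv(outdir / "is_introns.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"locus_id": c.locus_id, "class_label": c.class_label} for c in classes]
    ).to_csv(outdir / "termination_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "locus_id": s.locus_id,
                "chrom": s.window.chrom,
                "window_start": s.window.start,
                "window_end": s.window.end,
                "strand": s.window.strand,
                "n_nue_hits": len(s.nue_hits),
                "n_ce_hits": len(s.ce_hits),
                "has_nue": s.has_nue,
                "has_ce": s.has_ce,
                "nue_hits": ";".join(f"{h}@{o}" for h, o in s.nue_hits),
                "ce_hits": ";".join(f"{h}@{o}" for h, o in s.ce_hits),
            }
            for s in scans
        ]
    ).to_csv(outdir / "polya_scan.tsv", sep="\t", index=False)

    if te_comparison is not None:
        te_comparison.group_stats.to_csv(outdir / "te_groups.tsv", sep="\t", index=False)
        te_comparison.pairwise.to_csv(outdir / "te_pairwise.tsv", sep="\t", index=False)
    if enrichment_p is not None:
        with open(outdir / "enrichment.tsv", "w") as fh:
            fh.write("test\tp_value\n")
            fh.write(f"organelle_first_genes\t{enrichment_p:.6g}\n")
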