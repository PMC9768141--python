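"""CAGE TSS support, translation efficiency, Tukey contrasts and enrichment.

Translation efficiency (TE) of an ORF is ribosome-footprint count divided by
RNA-seq count over the same region; groupwise contrasts are run on log TE.
Enrichment of organelle-localized first genes uses an upper-tail
hypergeometric probability computed in log-factorial arithmetic.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import tukey_hsd

from .genome_model import CageTrack, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_TPM_THRESHOLD = 0.2
DEFAULT_TSS_WINDOW_NT = 100

ORGANELLE_LABELS = frozenset({"mitochondrion", "chloroplast"})
LOCALIZATION_CATEGORIES = ("mitochondrion", "chloroplast", "other", "unknown")


@dataclass(frozen=True)
class ORFCounts:
    """Per-ORF Ribo-seq footprint and RNA-seq counts across replicates.

    Footprint counts are assumed pre-filtered to 27-29 nt read lengths by the
    upstream counting step; this module only consumes the per-ORF tallies.
    """

    orf_id: str
    role: str  # "first" | "second"
    construct_id: str
    footprint_counts: tuple[int, ...]
    rna_counts: tuple[int, ...]
    fp_libsizes: tuple[int, ...]
    rna_libsizes: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.footprint_counts)
        if not (len(self.rna_counts) == len(self.fp_libsizes) == len(self.rna_libsizes) == n):
            raise ValueError(f"{self.orf_id}: replicate index sets differ between assays")
        if n == 0:
            raise ValueError(f"{self.orf_id}: no replicates")
        for v in (*self.footprint_counts, *self.rna_counts):
            if v < 0:
                raise ValueError(f"{self.orf_id}: negative count")
        for v in (*self.fp_libsizes, *self.rna_libsizes):
            if v <= 0:
                raise ValueError(f"{self.orf_id}: library sizes must be positive")

    @property
    def n_replicates(self) -> int:
        return len(self.footprint_counts)


@dataclass(frozen=True)
class EnrichmentInput:
    population_size: int
    population_successes: int
    sample_size: int
    sample_successes: int

    def __post_init__(self) -> None:
        ok = (
            0 <= self.population_successes <= self.population_size
            and 0 <= self.sample_successes <= self.sample_size
            and self.sample_size <= self.population_size
            and self.sample_successes <= self.population_successes
        )
        if not ok:
            raise ValueError(f"impossible enrichment configuration: {self}")


def tss_supported(
    gene: GeneModel,
    cage: CageTrack,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    window_nt: int = DEFAULT_TSS_WINDOW_NT,
) -> bool:
    """True iff a same-strand CAGE position within +-window_nt of the gene's
    annotated 5' end has TPM strictly greater than the threshold."""
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    tss = gene.tss_position()
    best = cage.max_tpm_in(gene.chrom, gene.strand, tss - window_nt, tss + window_nt)
    return best > tpm_threshold


def translation_efficiency(
    orf: ORFCounts, replicate: int, normalize: bool = False
) -> float | None:
    """Footprints / RNA reads for one replicate; ``None`` when RNA count is 0.

    With ``normalize`` both counts are scaled to per-million of their library
    sizes first (the ratio is then invariant to joint libsize rescaling).
    """
    fp = orf.footprint_counts[replicate]
    rna = orf.rna_counts[replicate]
    if rna == 0:
        logger.warning("%s replicate %d: RNA count 0, TE undefined", orf.orf_id, replicate)
        return None
    if normalize:
        fp_v = 1e6 * fp / orf.fp_libsizes[replicate]
        rna_v = 1e6 * rna / orf.rna_libsizes[replicate]
        return fp_v / rna_v
    return fp / rna


def _group_label(construct_id: str, role: str) -> str:
    return f"{construct_id}:{role}"


@dataclass
class TEComparison:
    group_stats: pd.DataFrame  # group, n, mean_te, sd_te, mean_log_te
    pairwise: pd.DataFrame  # group_a, group_b, diff_log_te, p_adj


def compare_orf_te(
    orfs: Sequence[ORFCounts], normalize: bool = False
) -> TEComparison:
    """Tukey HSD over construct x role groups on log-transformed TE.

    Undefined TEs (RNA count 0) are dropped; zero TEs are floored to half the
    smallest positive TE before the log transform so they stay in the test.
    Groups left with < 2 usable values are excluded with a warning.  Output
    rows are ordered by group label.
    """
    values: dict[str, list[float]] = {}
    for orf in orfs:
        label = _group_label(orf.construct_id, orf.role)
        bucket = values.setdefault(label, [])
        for r in range(orf.n_replicates):
            te = translation_efficiency(orf, r, normalize=normalize)
            if te is not None:
                bucket.append(te)

    positives = [v for vs in values.values() for v in vs if v > 0]
    floor = min(positives) / 2 if positives else 1.0

    groups: dict[str, np.ndarray] = {}
    for label in sorted(values):
        vs = values[label]
        if len(vs) < 2:
            logger.warning("TE group %s has < 2 defined values; excluded", label)
            continue
        groups[label] = np.log([v if v > 0 else floor for v in vs])

    if len(groups) < 2:
        raise ValueError("need >= 2 usable groups for a Tukey comparison")

    labels = list(groups)
    stats = pd.DataFrame(
        {
            "group": labels,
            "n": [len(groups[g]) for g in labels],
            "mean_te": [float(np.mean(np.exp(groups[g]))) for g in labels],
            "sd_te": [float(np.std(np.exp(groups[g]), ddof=1)) for g in labels],
            "mean_log_te": [float(np.mean(groups[g])) for g in labels],
        }
    )

    samples = [groups[g] for g in labels]
    means = [float(np.mean(s)) for s in samples]
    mse = float(np.mean([np.var(s, ddof=1) for s in samples]))
    if mse == 0.0:
        # degenerate zero within-group variance: identical values give p=1,
        # any mean difference is infinitely significant
        rows = [
            {
                "group_a": a,
                "group_b": b,
                "diff_log_te": means[i] - means[j],
                "p_adj": 1.0 if math.isclose(means[i], means[j]) else 0.0,
            }
            for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2)
        ]
        return TEComparison(group_stats=stats, pairwise=pd.DataFrame(rows))

    res = tukey_hsd(*samples)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "diff_log_te": means[i] - means[j],
                "p_adj": float(res.pvalue[i, j]),
            }
        )
    return TEComparison(group_stats=stats, pairwise=pd.DataFrame(rows))


def hypergeom_enrichment(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= sample_successes), log-factorial arithmetic."""
    N, K, n, k = (
        inp.population_size,
        inp.population_successes,
        inp.sample_size,
        inp.sample_successes,
    )
    if k == 0:
        return 1.0
    k_max = min(n, K)
    log_terms = []
    log_denom = _log_comb(N, n)
    for x in range(k, k_max + 1):
        log_terms.append(_log_comb(K, x) + _log_comb(N - K, n - x) - log_denom)
    p = float(np.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def _log_comb(n: int, r: int) -> float:
    return float(gammaln(n + 1) - gammaln(r + 1) - gammaln(n - r + 1))


def localization_distribution(
    loci, localization_table: Mapping[str, str]
) -> pd.DataFrame:
    """Counts and fractions per localization category for first genes, second
    genes, and the all-genes background (the whole localization table).

    Genes absent from the table count as 'unknown'; labels outside the known
    categories collapse to 'other'.
    """

    def norm(label: str | None) -> str:
        if label is None:
            return "unknown"
        return label if label in LOCALIZATION_CATEGORIES else "other"

    role_labels: dict[str, list[str]] = {"first": [], "second": [], "all_genes": []}
    for locus in loci:
        role_labels["first"].append(norm(localization_table.get(locus.genes[0].gene_id)))
        role_labels["second"].append(norm(localization_table.get(locus.genes[1].gene_id)))
    role_labels["all_genes"] = [norm(v) for v in localization_table.values()]

    rows = []
    for role in ("first", "second", "all_genes"):
        labels = role_labels[role]
        total = len(labels)
        for cat in LOCALIZATION_CATEGORIES:
            count = sum(1 for v in labels if v == cat)
            rows.append(
                {
                    "role": role,
                    "category": cat,
                    "count": count,
                    "total": total,
                    "fraction": count / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def read_orf_counts(path: str | Path) -> list[ORFCounts]:
    """Read an ORF count TSV (long format, one row per ORF x replicate)."""
    df = pd.read_csv(path, sep="\t")
    required = {
        "orf_id",
        "role",
        "construct",
        "replicate",
        "footprint_count",
        "rna_count",
        "fp_libsize",
        "rna_libsize",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: ORF count TSV missing columns {sorted(missing)}")
    orfs = []
    for (orf_id, role, construct), sub in df.groupby(["orf_id", "role", "construct"], sort=True):
        sub = sub.sort_values("replicate")
        orfs.append(
            ORFCounts(
                orf_id=str(orf_id),
                role=str(role),
                construct_id=str(construct),
                footprint_counts=tuple(int(v) for v in sub["footprint_count"]),
                rna_counts=tuple(int(v) for v in sub["rna_count"]),
                fp_libsizes=tuple(int(v) for v in sub["fp_libsize"]),
                rna_libsizes=tuple(int(v) for v in sub["rna_libsize"]),
            )
        )
    logger.info("%s: read counts for %d ORF(s)", path, len(orfs))
    return orfs
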