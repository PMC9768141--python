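from __future__ import annotations

import math

import numpy as np
import pytest

from rtscan.expression_support import (
    EnrichmentInput,
    ORFCounts,
    compare_orf_te,
    hypergeom_enrichment,
    localization_distribution,
    read_orf_counts,
    translation_efficiency,
    tss_supported,
)
from rtscan.genome_model import CageTrack
from rtscan.rt_detection import RTLocus

from conftest import make_gene
from oracles import hypergeom_upper_by_draws, hypergeom_upper_exact, permutation_pvalue


def _orf(orf_id, role, construct, fps, rnas, fp_lib=None, rna_lib=None):
    n = len(fps)
    return ORFCounts(
        orf_id=orf_id,
        role=role,
        construct_id=construct,
        footprint_counts=tuple(fps),
        rna_counts=tuple(rnas),
        fp_libsizes=tuple(fp_lib or [1_000_000] * n),
        rna_libsizes=tuple(rna_lib or [1_000_000] * n),
    )


class TestTSS:
    def _gene(self):
        return make_gene("G", start=1000, end=1400, cds=((1050, 1350),))

    def test_tpm_above_threshold_supported(self):
        cage = CageTrack({("chr1", "+", 1000): 0.3})
        assert tss_supported(self._gene(), cage)

    def test_tpm_exactly_at_threshold_unsupported(self):
        cage = CageTrack({("chr1", "+", 1000): 0.2})
        assert not tss_supported(self._gene(), cage)

    def test_no_entries_on_strand_unsupported(self):
        cage = CageTrack({("chr1", "-", 1000): 5.0})
        assert not tss_supported(self._gene(), cage)

    def test_window_respected(self):
        cage = CageTrack({("chr1", "+", 1200): 5.0})
        assert not tss_supported(self._gene(), cage, window_nt=100)
        assert tss_supported(self._gene(), cage, window_nt=200)


class TestTE:
    def test_plain_ratio(self):
        orf = _orf("o", "first", "c", [30], [10])
        assert translation_efficiency(orf, 0) == 3.0

    def test_zero_footprints(self):
        orf = _orf("o", "first", "c", [0], [10])
        assert translation_efficiency(orf, 0) == 0.0

    def test_zero_rna_undefined(self):
        orf = _orf("o", "first", "c", [30], [0])
        assert translation_efficiency(orf, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _orf("o", "first", "c", [-1], [10])

    def test_normalized_scale_invariance(self):
        orf1 = _orf("o", "first", "c", [30], [10], fp_lib=[1000], rna_lib=[2000])
        orf2 = _orf("o", "first", "c", [30], [10], fp_lib=[5000], rna_lib=[10000])
        assert math.isclose(
            translation_efficiency(orf1, 0, normalize=True),
            translation_efficiency(orf2, 0, normalize=True),
        )


class TestCompareTE:
    def test_identical_groups_p_one(self):
        orfs = [
            _orf("a", "first", "c", [10, 20, 30], [10, 10, 10]),
            _orf("b", "second", "c", [10, 20, 30], [10, 10, 10]),
        ]
        cmp = compare_orf_te(orfs)
        assert cmp.pairwise["p_adj"].tolist() == [1.0]

    def test_planted_fold_change_significant_and_permutation_consistent(self):
        rng = np.random.default_rng(3)
        fps_hi = [1000 + int(rng.integers(-30, 30)) for _ in range(3)]
        fps_lo = [20 + int(rng.integers(-3, 3)) for _ in range(3)]
        rnas = [200, 210, 190]
        orfs = [
            _orf("a", "first", "c", fps_hi, rnas),
            _orf("b", "second", "c", fps_lo, rnas),
        ]
        cmp = compare_orf_te(orfs)
        row = cmp.pairwise.iloc[0]
        assert row["diff_log_te"] > 0
        assert row["p_adj"] < 0.01
        # a crude permutation oracle agrees the difference is extreme
        a = [f / r for f, r in zip(fps_hi, rnas)]
        b = [f / r for f, r in zip(fps_lo, rnas)]
        p_perm = permutation_pvalue(a, b, 500, np.random.default_rng(0))
        assert p_perm <= 0.15  # 3v3 permutation floor is 0.1

    def test_three_groups_three_pairs(self):
        orfs = [
            _orf("a", "first", "c1", [10, 12, 14], [10, 10, 10]),
            _orf("b", "second", "c1", [5, 6, 7], [10, 10, 10]),
            _orf("c", "first", "c2", [20, 22, 24], [10, 10, 10]),
        ]
        cmp = compare_orf_te(orfs)
        assert len(cmp.pairwise) == 3
        assert list(cmp.group_stats["group"]) == sorted(cmp.group_stats["group"])

    def test_all_undefined_group_excluded(self, caplog):
        orfs = [
            _orf("a", "first", "c", [10, 12, 14], [10, 10, 10]),
            _orf("b", "second", "c", [5, 6, 7], [10, 9, 11]),
            _orf("z", "first", "dead", [5, 6, 7], [0, 0, 0]),
        ]
        with caplog.at_level("WARNING"):
            cmp = compare_orf_te(orfs)
        assert len(cmp.group_stats) == 2
        assert any("excluded" in r.message for r in caplog.records)


class TestHypergeom:
    def test_zero_successes_p_one(self):
        assert hypergeom_enrichment(EnrichmentInput(100, 30, 10, 0)) == 1.0

    def test_worked_example_11_over_42(self):
        p = hypergeom_enrichment(EnrichmentInput(10, 4, 5, 3))
        assert math.isclose(p, 11 / 42, rel_tol=1e-12)
        # exhaustive enumeration of all C(10,5) draws
        assert math.isclose(p, float(hypergeom_upper_by_draws(10, 4, 5, 3)), rel_tol=1e-12)

    def test_single_extreme_outcome(self):
        # draw size equals the number of successes; all successes drawn
        p = hypergeom_enrichment(EnrichmentInput(12, 5, 5, 5))
        assert math.isclose(p, 1 / math.comb(12, 5), rel_tol=1e-12)

    def test_impossible_configuration_errors(self):
        with pytest.raises(ValueError):
            EnrichmentInput(10, 4, 5, 6)
        with pytest.raises(ValueError):
            EnrichmentInput(10, 12, 5, 3)

    def test_full_grid_against_exact_enumeration(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(1, N + 1):
                    for k in range(min(n, K) + 1):
                        got = hypergeom_enrichment(EnrichmentInput(N, K, n, k))
                        want = float(hypergeom_upper_exact(N, K, n, k))
                        assert math.isclose(got, want, rel_tol=1e-9, abs_tol=1e-12), (
                            N, K, n, k,
                        )


class TestLocalization:
    def _loci(self, labels_first, labels_second, table):
        loci = []
        for i, (lf, ls) in enumerate(zip(labels_first, labels_second)):
            a = make_gene(f"f{i}", start=100, end=500, cds=((150, 450),))
            b = make_gene(f"s{i}", start=700, end=1100, cds=((750, 1050),))
            loci.append(RTLocus(locus_id=f"L{i}", genes=(a, b)))
            table.setdefault(f"f{i}", lf)
            table.setdefault(f"s{i}", ls)
        return loci

    def test_fraction_of_first_genes(self):
        table: dict[str, str] = {}
        loci = self._loci(
            ["mitochondrion", "chloroplast", "other"], ["other"] * 3, table
        )
        df = localization_distribution(loci, table)
        first = df[df.role == "first"].set_index("category")
        assert first.loc["mitochondrion", "count"] == 1
        assert first.loc["chloroplast", "count"] == 1
        assert first["fraction"].sum() == pytest.approx(1.0)

    def test_empty_locus_list(self):
        df = localization_distribution([], {"g": "other"})
        assert (df[df.role == "first"]["count"] == 0).all()

    def test_missing_gene_counts_as_unknown(self):
        table: dict[str, str] = {}
        loci = self._loci(["other"], ["other"], table)
        del table["f0"]
        df = localization_distribution(loci, table)
        first = df[df.role == "first"].set_index("category")
        assert first.loc["unknown", "count"] == 1


def test_read_orf_counts_round_structure(tmp_path):
    p = tmp_path / "orf.tsv"
    p.write_text(
        "orf_id\trole\tconstruct\treplicate\tfootprint_count\trna_count\tfp_libsize\trna_libsize\n"
        "o1\tfirst\tc\t0\t30\t10\t1000000\t1000000\n"
        "o1\tfirst\tc\t1\t40\t20\t1000000\t1000000\n"
    )
    (orf,) = read_orf_counts(p)
    assert orf.footprint_counts == (30, 40)
    assert orf.n_replicates == 2
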