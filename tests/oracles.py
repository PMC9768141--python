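"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (per-base sets, exhaustive draw
enumeration, union-find) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def rt_assignments_oracle(transcripts, genes, min_bp):
    """Exhaustive per-base overlap counter for RT calling.

    Mirrors the contract: genes whose spans share bases with another
    same-strand protein-coding gene are statically excluded as partners.
    """
    coding = [g for g in genes if g.biotype == "protein_coding"]
    excluded = set()
    for a, b in itertools.combinations(coding, 2):
        if a.chrom != b.chrom or a.strand != b.strand:
            continue
        a_span = set(range(a.span.start, a.span.end))
        if a_span & set(range(b.span.start, b.span.end)):
            excluded.add(a.gene_id)
            excluded.add(b.gene_id)
    eligible = [g for g in coding if g.gene_id not in excluded]

    out = {}
    for t in transcripts:
        tbases = set()
        for ex in t.exons:
            tbases.update(range(ex.start, ex.end))
        hits = []
        for g in eligible:
            if g.chrom != t.chrom or g.strand != t.strand:
                continue
            gbases = set()
            for c in g.cds_intervals:
                gbases.update(range(c.start, c.end))
            if len(tbases & gbases) >= min_bp:
                hits.append(g)
        if len(hits) < 2:
            continue
        hits.sort(key=lambda g: g.span.start, reverse=(t.strand == "-"))
        out[t] = tuple(g.gene_id for g in hits)
    return out


def interval_union_oracle(intervals):
    """Boolean-mask union of (start, end) pairs -> sorted merged runs."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    mask = [False] * hi
    for s, e in intervals:
        for i in range(s, e):
            mask[i] = True
    runs = []
    i = 0
    while i < hi:
        if mask[i]:
            j = i
            while j < hi and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def sliding_hexamer_oracle(seq, hexamers):
    """All (hexamer, offset) matches by direct substring comparison."""
    return [
        (h, i)
        for i in range(len(seq) - 5)
        for h in sorted(hexamers)
        if seq[i : i + 6] == h
    ]


def hypergeom_upper_exact(N, K, n, k):
    """Exact upper tail P(X >= k) as a Fraction via binomial coefficients."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def hypergeom_upper_by_draws(N, K, n, k):
    """P(X >= k) by literally enumerating every size-n draw from the population."""
    population = list(range(N))  # items < K are the successes
    hits = 0
    total = 0
    for draw in itertools.combinations(population, n):
        total += 1
        if sum(1 for item in draw if item < K) >= k:
            hits += 1
    return Fraction(hits, total)


def single_linkage_clusters_oracle(positions, radius):
    """Union-find over all pairs within the radius; returns sorted clusters."""
    parent = list(range(len(positions)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(positions)), 2):
        if abs(positions[i] - positions[j]) <= radius:
            parent[find(i)] = find(j)
    groups = {}
    for i, pos in enumerate(positions):
        groups.setdefault(find(i), []).append(pos)
    return sorted(sorted(g) for g in groups.values())


def permutation_pvalue(a, b, n_perm, rng):
    """Two-sided permutation test on the difference of means."""
    import numpy as np

    a, b = list(a), list(b)
    observed = abs(sum(a) / len(a) - sum(b) / len(b))
    pooled = np.array(a + b, dtype=float)
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        pa, pb = pooled[: len(a)], pooled[len(a) :]
        if abs(pa.mean() - pb.mean()) >= observed - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
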