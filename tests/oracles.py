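"""Independent brute-force oracles used to cross-check the vectorized code.

These deliberately avoid the package's interval trees and sparse products:
overlap is decided on explicit base sets, the matrices are built by triple
loops over genes, peaks and cells, and the agreement metrics are computed
straight from their contingency-table formulas.
"""

import math
import random

import numpy as np

from gagam import (
    Gene,
    GenomeAnnotation,
    GenomicInterval,
    RegulatoryRegion,
    derive_promoter_window,
    derive_tss,
    tss_position,
)

D_TH = 30_000
DECAY = 5000.0


import functools


@functools.lru_cache(maxsize=None)
def bases(iv):
    return frozenset(range(iv.start, iv.end))


def oracle_label(peak_iv, genes, regions, mode="literal_containment", strand_aware=True):
    """Per-base-set evaluation of the four-way labeling rule."""
    pb = bases(peak_iv)

    def region_hit(r):
        if r.region.chrom != peak_iv.chrom:
            return False
        rb = bases(r.region)
        return rb <= pb if mode == "literal_containment" else bool(rb & pb)

    tss_hits = set()
    for g in genes:
        t = derive_tss(g, 2, strand_aware)
        if t.chrom == peak_iv.chrom and bases(t) <= pb:
            tss_hits.add(g.gene_id)
    if any(region_hit(r) for r in regions if r.label == "promoter") or tss_hits:
        return "prom", tss_hits
    if any(region_hit(r) for r in regions if r.label == "enhancer_distal"):
        return "enhD", tss_hits
    for g in genes:
        for e in g.exons:
            if e.chrom != peak_iv.chrom:
                continue
            eb = bases(e)
            if (pb <= eb) if mode == "literal_containment" else bool(pb & eb):
                return "exon", tss_hits
    return "empty", tss_hits


def oracle_matrices(
    genes,
    regions,
    peaks,
    D,
    connections,
    weights=(1, 1, 1),
    upstream_bp=500,
    strand_aware=True,
    mode="literal_containment",
):
    """Triple-loop evaluation of the labeling rule plus the P/C/E components
    and their weighted combination (pre-normalization).

    ``connections`` is a list of (peak_id_1, peak_id_2, ca, d) tuples.
    Returns (gene_ids, labels, P, C, E, combined) with genes restricted to
    those owning at least one promoter peak.
    """
    D = np.asarray(D)
    n_cells = D.shape[1]
    labels, hits = [], []
    for p in peaks:
        lab, h = oracle_label(p.interval, genes, regions, mode, strand_aware)
        labels.append(lab)
        hits.append(h)

    # gene -> associated promoter peak indices
    assoc = {g.gene_id: set() for g in genes}
    for i, p in enumerate(peaks):
        if labels[i] != "prom":
            continue
        if hits[i]:
            for gid in hits[i]:
                assoc[gid].add(i)
        else:
            pb = bases(p.interval)
            for g in genes:
                w = derive_promoter_window(g, upstream_bp, strand_aware)
                if w.chrom == p.interval.chrom and bases(w) & pb:
                    assoc[g.gene_id].add(i)
    gp_genes = [g for g in genes if assoc[g.gene_id]]

    # connection filtering
    label_of = {p.id: labels[i] for i, p in enumerate(peaks)}
    index_of = {p.id: i for i, p in enumerate(peaks)}
    pos = [ca for (_, _, ca, _) in connections if ca > 0]
    kept = []
    if pos:
        cam = sum(pos) / len(pos)
        for p1, p2, ca, d in connections:
            l1, l2 = label_of.get(p1), label_of.get(p2)
            if {l1, l2} == {"prom", "enhD"} and ca >= cam and d <= D_TH:
                if l1 == "enhD":
                    p1, p2 = p2, p1
                kept.append((p1, p2, ca))

    nG = len(gp_genes)
    P = np.zeros((nG, n_cells))
    C = np.zeros((nG, n_cells))
    E = np.zeros((nG, n_cells))
    for r, g in enumerate(gp_genes):
        tss = tss_position(g, strand_aware)
        for c in range(n_cells):
            if any(D[i, c] for i in assoc[g.gene_id]):
                P[r, c] = 1.0
            for p1, p2, ca in kept:
                if index_of[p1] in assoc[g.gene_id] and D[index_of[p2], c]:
                    C[r, c] += ca
            for i, p in enumerate(peaks):
                if labels[i] != "exon" or not D[i, c]:
                    continue
                pb = bases(p.interval)
                in_exon = any(
                    (pb <= bases(e)) if mode == "literal_containment" else bool(pb & bases(e))
                    for e in g.exons
                    if e.chrom == p.interval.chrom
                )
                if in_exon:
                    E[r, c] += math.exp(-abs(p.interval.center - tss) / DECAY)
    wp, wc, we = weights
    return (
        [g.gene_id for g in gp_genes],
        labels,
        P,
        C,
        E,
        wp * P + wc * C + we * E,
    )


# ---------------------------------------------------------------------------
# Metric oracles


def oracle_gini(x):
    x = list(map(float, x))
    n = len(x)
    if n == 0 or sum(x) == 0:
        return 0.0
    total = sum(abs(a - b) for a in x for b in x)
    return total / (2 * n * n * (sum(x) / n))


def _comb2(n):
    return n * (n - 1) // 2


def oracle_ari(a, b):
    """Permutation-model adjusted Rand index from the contingency table."""
    a, b = list(a), list(b)
    n = len(a)
    la, lb = sorted(set(a)), sorted(set(b))
    table = [[sum(1 for x, y in zip(a, b) if x == i and y == j) for j in lb] for i in la]
    sum_ij = sum(_comb2(v) for row in table for v in row)
    sum_a = sum(_comb2(sum(row)) for row in table)
    sum_b = sum(_comb2(sum(row[j] for row in table)) for j in range(len(lb)))
    expected = sum_a * sum_b / _comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def oracle_ami(a, b):
    """Adjusted mutual information with the hypergeometric expected-MI
    correction and arithmetic-mean normalization."""
    a, b = list(a), list(b)
    n = len(a)
    la, lb = sorted(set(a)), sorted(set(b))
    nij = {(i, j): sum(1 for x, y in zip(a, b) if x == i and y == j) for i in la for j in lb}
    ai = {i: sum(nij[i, j] for j in lb) for i in la}
    bj = {j: sum(nij[i, j] for i in la) for j in lb}

    mi = 0.0
    for i in la:
        for j in lb:
            if nij[i, j]:
                mi += (nij[i, j] / n) * math.log(n * nij[i, j] / (ai[i] * bj[j]))

    def entropy(counts):
        return -sum((c / n) * math.log(c / n) for c in counts if c)

    ha, hb = entropy(ai.values()), entropy(bj.values())

    emi = 0.0
    for i in la:
        for j in lb:
            lo = max(1, ai[i] + bj[j] - n)
            hi = min(ai[i], bj[j])
            for k in range(lo, hi + 1):
                p = (
                    math.comb(bj[j], k)
                    * math.comb(n - bj[j], ai[i] - k)
                    / math.comb(n, ai[i])
                )
                emi += p * (k / n) * math.log(n * k / (ai[i] * bj[j]))
    denom = (ha + hb) / 2 - emi
    if denom == 0:
        return 1.0 if mi == emi else 0.0
    return (mi - emi) / denom


# ---------------------------------------------------------------------------
# Random micro-fixture generator


def random_micro_fixture(seed, max_genes=10, max_peaks=30, max_cells=10):
    """A small random genome + peaks + binary matrix + connections for
    oracle-equivalence fuzzing."""
    rng = random.Random(seed)
    span = 60_000
    n_genes = rng.randint(1, max_genes)
    genes = []
    for i in range(n_genes):
        start = rng.randrange(500, span - 3000)
        length = rng.randrange(800, 3000)
        body = GenomicInterval("chrF", start, start + length)
        e1_len = rng.randrange(100, length // 2)
        e2_len = rng.randrange(50, max(51, length // 4))
        exons = (
            GenomicInterval("chrF", start, start + e1_len),
            GenomicInterval("chrF", start + length - e2_len, start + length),
        )
        genes.append(
            Gene(f"g{i}", f"g{i}", body, rng.choice("+-"), exons)
        )
    regions = []
    for _ in range(rng.randint(0, 8)):
        s = rng.randrange(0, span)
        w = rng.randrange(50, 400)
        label = rng.choice(["promoter", "enhancer_distal", "other"])
        regions.append(RegulatoryRegion(GenomicInterval("chrF", s, s + w), label))
    # promoter signatures near some gene starts so prom labels actually occur
    for g in genes[: rng.randint(1, n_genes)]:
        s = max(0, g.body.start - rng.randrange(100, 400))
        regions.append(
            RegulatoryRegion(GenomicInterval("chrF", s, s + rng.randrange(60, 200)), "promoter")
        )

    from gagam import Peak

    # targeted peaks first, so the promoter/TSS/exon machinery is exercised:
    # peaks containing a regulatory signature, covering a TSS, or inside exons
    candidates = []
    for r in regions:
        if rng.random() < 0.6:
            pad_l, pad_r = rng.randrange(10, 300), rng.randrange(10, 300)
            candidates.append(
                (max(0, r.region.start - pad_l), r.region.end + pad_r)
            )
    for g in genes:
        if rng.random() < 0.5:
            t = derive_tss(g)
            candidates.append(
                (max(0, t.start - rng.randrange(5, 250)), t.end + rng.randrange(5, 250))
            )
        if rng.random() < 0.5:
            e = g.exons[rng.randrange(len(g.exons))]
            if e.length > 60:
                s = e.start + rng.randrange(0, e.length - 50)
                candidates.append((s, min(e.end, s + rng.randrange(40, e.length))))
    rng.shuffle(candidates)

    n_peaks = rng.randint(4, max_peaks)
    peaks, seen = [], set()
    for s, e in candidates[: n_peaks - 2]:
        if e > s and (s, e) not in seen:
            seen.add((s, e))
            peaks.append(Peak(GenomicInterval("chrF", s, e), len(peaks)))
    while len(peaks) < n_peaks:
        s = rng.randrange(0, span)
        w = rng.randrange(100, 700)
        iv = GenomicInterval("chrF", s, s + w)
        key = (iv.start, iv.end)
        if key in seen:
            continue
        seen.add(key)
        peaks.append(Peak(iv, len(peaks)))

    n_cells = rng.randint(2, max_cells)
    D = np.array(
        [[rng.random() < 0.4 for _ in range(n_cells)] for _ in range(n_peaks)],
        dtype=np.int8,
    )

    connections = []
    pairs = set()
    for _ in range(rng.randint(0, 25)):
        i, j = rng.sample(range(n_peaks), 2)
        key = tuple(sorted((i, j)))
        if key in pairs:
            continue
        pairs.add(key)
        ca = rng.uniform(-1, 1)
        d = abs(peaks[i].interval.center - peaks[j].interval.center)
        connections.append((peaks[i].id, peaks[j].id, ca, d))

    annotation = GenomeAnnotation(genes, regions, ["chrF"])
    return annotation, peaks, D, connections
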