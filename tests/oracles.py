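"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: boolean per-base arrays for
interval arithmetic, exact rational enumeration for the discrete tests,
transitive closure for clustering. None of it shares code with the
package paths it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def per_base_mask(intervals, length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s, e in intervals:
        mask[max(0, s):max(0, e)] = True
    return mask


def mask_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            in_run = False
            out.append((start, i))
    if in_run:
        out.append((start, len(mask)))
    return out


def brute_force_noncoding_flanks(gene_start, gene_end, cds_intervals, flank_len, chrom_len):
    """Per-base flank extraction: windows around the gene minus all CDS bases."""
    mask = np.zeros(chrom_len, dtype=bool)
    mask[max(0, gene_start - flank_len):gene_start] = True
    mask[gene_end:min(chrom_len, gene_end + flank_len)] = True
    mask &= ~per_base_mask(cds_intervals, chrom_len)
    return mask_to_intervals(mask)


def brute_force_resolve(records):
    """Score-priority overlap resolution by pairwise checks against kept set.

    records: (start, end, score) tuples on one chromosome. Returns kept
    tuples in start order.
    """
    ranked = sorted(records, key=lambda r: (-r[2], r[0], -(r[1] - r[0])))
    kept = []
    for r in ranked:
        if all(r[1] <= k[0] or k[1] <= r[0] for k in kept):
            kept.append(r)
    return sorted(kept)


def brute_force_coverage(flanks, repeat_intervals, chrom_len) -> int:
    """Per-base count of flank positions covered by any repeat."""
    return int(
        (per_base_mask(flanks, chrom_len) & per_base_mask(repeat_intervals, chrom_len)).sum()
    )


def hypergeom_table_prob(a, row1, col1, n) -> Fraction:
    b = row1 - a
    c = col1 - a
    d = n - row1 - c
    if min(b, c, d) < 0:
        return Fraction(0)
    return Fraction(comb(row1, a) * comb(n - row1, c), comb(n, col1))


def fisher_two_sided_enum(a, b, c, d) -> float:
    """Exact two-sided Fisher p by enumerating all tables with the margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom_table_prob(a, row1, col1, n)
    total = Fraction(0)
    for x in range(0, min(row1, col1) + 1):
        p_x = hypergeom_table_prob(x, row1, col1, n)
        if p_x > 0 and float(p_x) <= float(p_obs) * (1 + 1e-7):
            total += p_x
    return float(total)


def bh_direct(pvals):
    """q_i = min_{j >= i} p_(j) * m / j over the sorted p-values, unsorted back."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q_sorted[rank - 1] = running
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out


def binom_two_sided_enum(k, n) -> float:
    """Exact two-sided binomial(n, 1/2) p by direct summation."""
    probs = [Fraction(comb(n, j), 2**n) for j in range(n + 1)]
    p_obs = probs[k]
    return float(sum(p for p in probs if float(p) <= float(p_obs) * (1 + 1e-7)))


def single_linkage_clusters(items, linked) -> list[set]:
    """Transitive closure of the pairwise `linked` predicate."""
    clusters = [{i} for i in range(len(items))]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if any(linked(items[a], items[b]) for a in clusters[i] for b in clusters[j]):
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return clusters


def percentile_linear(values, pct) -> float:
    """Linear-interpolation percentile between order statistics."""
    xs = sorted(values)
    h = (len(xs) - 1) * pct / 100
    lo = int(h)
    if lo == len(xs) - 1:
        return xs[-1]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])
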