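"""Chromosomal-context analyses of compartment calls.

Covers the subtelomere permutation test (terminal 10% of each
chromosome, 1000 label resamplings), per-species GC/recombination
rank-sum comparisons, and the cross-species sign binomial test used to
ask whether any per-species trend is consistent across lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

TERMINAL_FRAC = 0.10
N_PERMUTATIONS = 1000


@dataclass
class SubtelomereTestResult:
    chrom: str
    n_genes: int
    n_called: int
    observed_prop: float
    null_props: np.ndarray
    p_two_sided: float
    direction: str  # enriched | depleted | ns


def subtelomere_permutation_test(
    gene_midpoints: Mapping[str, float],
    called: set[str],
    chrom_len: int,
    chrom: str = "chrom",
    terminal_frac: float = TERMINAL_FRAC,
    n_perm: int = N_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> SubtelomereTestResult:
    """Is the called set over/underrepresented in the chromosome ends?

    A gene is subtelomeric iff its midpoint lies in the first or last
    `terminal_frac` of bases. The null resamples |called| genes without
    replacement from the chromosome's genes n_perm times (drawn as
    hypergeometric counts, which is distributionally identical); the
    two-sided p doubles the smaller tail with a +1 pseudocount and is
    capped at 1.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    called_here = [g for g in gene_midpoints if g in called]
    n_genes = len(gene_midpoints)
    n_called = len(called_here)
    if n_called == 0:
        raise ValueError(f"{chrom}: no called genes; test skipped")
    lo, hi = terminal_frac * chrom_len, (1 - terminal_frac) * chrom_len
    is_term = {g: (m < lo or m >= hi) for g, m in gene_midpoints.items()}
    n_term = sum(is_term.values())
    obs = sum(1 for g in called_here if is_term[g])
    null_counts = rng.hypergeometric(n_term, n_genes - n_term, n_called, size=n_perm)
    p_hi = (1 + int(np.sum(null_counts >= obs))) / (n_perm + 1)
    p_lo = (1 + int(np.sum(null_counts <= obs))) / (n_perm + 1)
    p = min(1.0, 2 * min(p_hi, p_lo))
    if p <= alpha:
        direction = "enriched" if obs > null_counts.mean() else "depleted"
    else:
        direction = "ns"
    return SubtelomereTestResult(
        chrom=chrom,
        n_genes=n_genes,
        n_called=n_called,
        observed_prop=obs / n_called,
        null_props=null_counts / n_called,
        p_two_sided=p,
        direction=direction,
    )


def context_group_comparison(
    values: Mapping[str, float],
    called: set[str],
    background: set[str],
) -> tuple[float, float, float, int]:
    """Two-sided Mann-Whitney U comparison of a per-gene numeric context
    feature (GC fraction, recombination rate) between groups.

    Returns (median_called, median_background, p, sign) where sign is
    the sign of the median difference (+1, -1, or 0).
    """
    x = np.array([values[g] for g in sorted(called) if g in values])
    y = np.array([values[g] for g in sorted(background) if g in values])
    if len(x) < 4 or len(y) < 4:
        raise ValueError("need >= 4 values per group")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return med_x, med_y, 1.0, 0  # fully degenerate: no information
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    sign = int(np.sign(med_x - med_y))
    return med_x, med_y, p, sign


def bp_weighted_gene_values(
    genes,
    track,
    chrom_lengths: Mapping[str, int],
    flank_len: int = 50_000,
) -> dict[str, float]:
    """Average a bedGraph track over each gene's span plus its flanks,
    weighting each track interval by its bp overlap with the region.

    `genes` is a list of GeneRecord; `track` a DataFrame with columns
    chrom, start, end, value. Genes with no track overlap are omitted.
    """
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for row in track.itertuples(index=False):
        by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end), float(row.value)))
    for ivs in by_chrom.values():
        ivs.sort()
    out: dict[str, float] = {}
    for g in genes:
        ivs = by_chrom.get(g.chrom)
        if not ivs:
            continue
        s = max(0, g.start - flank_len)
        e = min(chrom_lengths[g.chrom], g.end + flank_len)
        starts = np.array([iv[0] for iv in ivs])
        ends = np.array([iv[1] for iv in ivs])
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        wsum = vsum = 0.0
        for ts, te, val in ivs[lo:hi]:
            ov = min(te, e) - max(ts, s)
            if ov > 0:
                wsum += ov
                vsum += ov * val
        if wsum > 0:
            out[g.gene_id] = vsum / wsum
    return out


def cross_species_binomial(signs: Sequence[int]) -> float:
    """Exact two-sided binomial test of per-species signs against 0.5.

    Zeros (ties) are dropped; an empty sign list after dropping is an
    error. This is the cross-species trend test applied to GC,
    recombination, multigene-fold and selection-proportion signs.
    """
    nonzero = [s for s in signs if s != 0]
    if not nonzero:
        raise ValueError("no non-zero signs: cross-species test undefined")
    k = sum(1 for s in nonzero if s > 0)
    return float(stats.binomtest(k, len(nonzero), 0.5, alternative="two-sided").pvalue)
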