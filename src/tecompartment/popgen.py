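"""TE-associated SV filtering/merging and folded-AFS group comparison.

Population variants come from haploid genome assemblies (n_samples =
number of genomes). Per-sample SV calls are merged by breakpoint
vicinity (single linkage, both breakpoints within 500 bp), filtered to
TE-associated events (> 50 bp, >= 50% TE coverage), assigned to the
noncoding flank (TE SVs) or CDS (SNVs) of compartmentalized vs other
genes, and compared via a chi-square test on the folded allele-
frequency spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .compartmentalization import CompartmentCallSet
from .intervals import Interval
from .io_formats import VariantRecord

log = logging.getLogger(__name__)

SV_MERGE_DIST = 500
SV_MIN_LEN = 50
SV_MIN_TE_COV = 0.5


@dataclass
class FoldedAFS:
    """Histogram of minor-allele counts 1..floor(n/2) over biallelic variants."""

    n_samples: int
    bins: np.ndarray  # bins[i-1] = number of variants with minor count i

    @property
    def n_variants(self) -> int:
        return int(self.bins.sum())

    @property
    def mean_minor_freq(self) -> float:
        if self.n_variants == 0:
            return float("nan")
        i = np.arange(1, len(self.bins) + 1)
        return float((i * self.bins).sum() / self.bins.sum() / self.n_samples)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_sv_calls(svs: list[VariantRecord], max_dist: int = SV_MERGE_DIST) -> list[VariantRecord]:
    """Single-linkage merge of redundant per-sample SV calls.

    Two same-type calls on the same chromosome link when both their
    start and end breakpoints are within max_dist. Each cluster keeps
    one representative (leftmost start, then longest); its alt_count
    becomes the number of contributing samples.
    """
    groups: dict[tuple[str, str], list[int]] = {}
    for i, v in enumerate(svs):
        groups.setdefault((v.chrom, v.vtype), []).append(i)
    merged: list[VariantRecord] = []
    for key in sorted(groups):
        idx = sorted(groups[key], key=lambda i: (svs[i].pos, svs[i].variant_id))
        uf = _UnionFind(len(idx))
        for a in range(len(idx)):
            va = svs[idx[a]]
            for b in range(a + 1, len(idx)):
                vb = svs[idx[b]]
                if vb.pos - va.pos > max_dist:
                    break
                if abs(vb.end - va.end) <= max_dist:
                    uf.union(a, b)
        clusters: dict[int, list[VariantRecord]] = {}
        for a in range(len(idx)):
            clusters.setdefault(uf.find(a), []).append(svs[idx[a]])
        for members in clusters.values():
            rep = min(members, key=lambda v: (v.pos, -(v.length or 0)))
            samples = {v.sample_id for v in members if v.sample_id is not None}
            count = len(samples) if samples else len(members)
            merged.append(
                replace(
                    rep,
                    alt_count=min(count, rep.n_samples),
                    sample_id=None,
                )
            )
    merged.sort(key=lambda v: (v.chrom, v.pos, v.variant_id))
    return merged


def filter_te_svs(
    svs: list[VariantRecord],
    min_len: int = SV_MIN_LEN,
    min_te_cov: float = SV_MIN_TE_COV,
) -> list[VariantRecord]:
    """Keep TE-associated SVs: length strictly > min_len and TE coverage
    >= min_te_cov; ambiguous-sequence calls are dropped first."""
    out = []
    for v in svs:
        if v.ambiguous:
            continue
        if v.te_coverage is None or v.length is None:
            raise ValueError(f"SV {v.variant_id}: te_coverage/length missing")
        if v.length > min_len and v.te_coverage >= min_te_cov:
            out.append(v)
    return out


def assign_variants(
    variants: list[VariantRecord],
    flanks: Mapping[str, list[Interval]],
    cds: Mapping[str, list[Interval]],
    calls: CompartmentCallSet,
    chrom_of_gene: Mapping[str, str],
) -> dict[str, tuple[str, str]]:
    """variant_id -> (group in {called, other}, context in {flank, cds}).

    TE SVs are assigned by position within a gene's noncoding flank,
    SNVs within a gene's CDS. A variant hitting both a called and an
    other gene goes to `called`; unassignable variants are dropped. A
    variant in flanks of several genes of one group still yields a
    single assignment (no double counting within a spectrum).
    """
    from .intervals import IntervalIndex

    indexes: dict[tuple[str, str, str], IntervalIndex] = {}
    for context, intervals_of in (("flank", flanks), ("cds", cds)):
        pooled: dict[tuple[str, str], list] = {}
        for group, gene_ids in (("called", calls.called_gene_ids), ("other", calls.background_gene_ids)):
            for gid in gene_ids:
                chrom = chrom_of_gene.get(gid)
                if chrom is None:
                    continue
                pooled.setdefault((group, chrom), []).extend(intervals_of.get(gid, []))
        for (group, chrom), ivs in pooled.items():
            indexes[(context, group, chrom)] = IntervalIndex(ivs)

    out: dict[str, tuple[str, str]] = {}
    for v in variants:
        if v.vtype in ("TE_SV_INS", "TE_SV_DEL"):
            context = "flank"
        elif v.vtype in ("SNV_SYN", "SNV_NONSYN"):
            context = "cds"
        else:
            continue
        for group in ("called", "other"):  # called-gene priority
            idx = indexes.get((context, group, v.chrom))
            if idx is not None and idx.overlap_length(v.pos, v.pos + 1) > 0:
                out[v.variant_id] = (group, context)
                break
    return out


def folded_afs(variants: list[VariantRecord], n_samples: int) -> FoldedAFS:
    """Fold biallelic alt counts to minor-allele counts and histogram them.

    Monomorphic records (alt_count 0 or n) are excluded and counted in
    a log message.
    """
    k = n_samples // 2
    bins = np.zeros(k, dtype=np.int64)
    n_mono = 0
    for v in variants:
        if v.n_samples != n_samples:
            raise ValueError(f"variant {v.variant_id}: n_samples mismatch")
        if v.alt_count == 0 or v.alt_count == n_samples:
            n_mono += 1
            continue
        minor = min(v.alt_count, n_samples - v.alt_count)
        bins[minor - 1] += 1
    if n_mono:
        log.info("excluded %d monomorphic variants from folded AFS", n_mono)
    return FoldedAFS(n_samples=n_samples, bins=bins)


def compare_afs_chi2(afs_a: FoldedAFS, afs_b: FoldedAFS) -> tuple[float, int, float]:
    """Chi-square homogeneity test between two folded spectra.

    The 2xK count table is pooled from the high-frequency tail until
    every expected cell is >= 5 (empty columns are dropped first);
    df = K_pooled - 1. Identical spectra give (0, df, 1).
    """
    if afs_a.n_samples != afs_b.n_samples:
        raise ValueError("spectra have different sample sizes")
    if afs_a.n_variants == 0 or afs_b.n_variants == 0:
        raise ValueError("both spectra must contain at least one variant")
    table = np.vstack([afs_a.bins, afs_b.bins]).astype(float)
    table = table[:, table.sum(axis=0) > 0]

    def min_expected(t: np.ndarray) -> float:
        exp = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
        return float(exp.min())

    while table.shape[1] > 2 and min_expected(table) < 5:
        table = np.hstack([table[:, :-2], table[:, -2:].sum(axis=1, keepdims=True)])
    if table.shape[1] < 2 or min_expected(table) < 5:
        raise ValueError("too few variants for a chi-square comparison after pooling")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)
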