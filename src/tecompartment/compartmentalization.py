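"""Flanking-region TE density and percentile-based compartment calls.

The core statistic: for each gene, take the 50 kb windows up- and
downstream of the gene span, remove every annotated CDS genome-wide
(not only the focal gene's), and measure the fraction of the remaining
noncoding positions covered by resolved TE annotations. Genes whose
flank density falls at or above the species-level 90th (or 95th)
percentile are "TE-compartmentalized". Introns of neighboring genes
remain in flanks; only CDS is subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import Interval, IntervalIndex, merge_intervals, subtract_intervals, total_length
from .io_formats import TE_CLASSES, ChromosomeSpec, GeneRecord, RepeatRecord

log = logging.getLogger(__name__)

DEFAULT_FLANK_LEN = 50_000
MIN_ELIGIBLE_GENES = 10


@dataclass
class FlankProfile:
    """Per-gene noncoding flank and its TE coverage per class (plus 'ALL')."""

    gene_id: str
    flank_intervals: list[Interval]
    noncoding_len: int
    te_covered_len: dict[str, int] = field(default_factory=dict)
    density: dict[str, float] = field(default_factory=dict)

    @property
    def eligible(self) -> bool:
        return self.noncoding_len > 0


@dataclass
class CompartmentCallSet:
    species_id: str
    te_class: str
    percentile: float
    cutoff_value: float
    called_gene_ids: set[str]
    background_gene_ids: set[str]


def extract_noncoding_flanks(
    gene: GeneRecord,
    cds_by_chrom: dict[str, list[Interval]],
    flank_len: int = DEFAULT_FLANK_LEN,
    chrom_len: int | None = None,
) -> list[Interval]:
    """Noncoding flank intervals for one gene: +/- flank_len around the gene
    span, truncated at chromosome boundaries, minus the union of all CDS.

    `cds_by_chrom` must hold the merged CDS intervals of *every* gene on
    each chromosome, mirroring a genome-wide subtraction.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    left = (max(0, gene.start - flank_len), gene.start)
    right_end = gene.end + flank_len if chrom_len is None else min(chrom_len, gene.end + flank_len)
    right = (gene.end, right_end)
    raw = [iv for iv in (left, right) if iv[1] > iv[0]]
    return subtract_intervals(raw, cds_by_chrom.get(gene.chrom, []))


def resolve_repeat_overlaps(repeats: list[RepeatRecord]) -> list[RepeatRecord]:
    """Resolve overlapping repeat annotations: higher score survives intact.

    Greedy per chromosome by descending score (ties: leftmost start,
    then longer record); a record is kept iff it overlaps no
    already-kept record. Matches score-priority overlap resolution of
    RepeatMasker-style annotation cleanup.
    """
    out: list[RepeatRecord] = []
    by_chrom: dict[str, list[RepeatRecord]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom in sorted(by_chrom):
        ranked = sorted(
            by_chrom[chrom], key=lambda r: (-r.score, r.start, -(r.end - r.start))
        )
        kept_starts: list[int] = []
        kept_ends: list[int] = []
        kept: list[RepeatRecord] = []
        for r in ranked:
            i = np.searchsorted(kept_starts, r.start)
            # overlap possible only with predecessor or successor in start order
            if i > 0 and kept_ends[i - 1] > r.start:
                continue
            if i < len(kept_starts) and kept_starts[i] < r.end:
                continue
            kept_starts.insert(i, r.start)
            kept_ends.insert(i, r.end)
            kept.append(r)
        out.extend(sorted(kept, key=lambda r: r.start))
    return out


def _check_resolved(repeats: list[RepeatRecord]) -> None:
    by_chrom: dict[str, list[RepeatRecord]] = {}
    for r in repeats:
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: r.start)
        for a, b in zip(rs, rs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"repeat annotations on {chrom} overlap ({a.start}-{a.end} vs "
                    f"{b.start}-{b.end}); resolve_repeat_overlaps them first"
                )


class RepeatCoverage:
    """Per-(chromosome, class) overlap-length indexes over resolved repeats."""

    def __init__(self, repeats: list[RepeatRecord], check: bool = True):
        if check:
            _check_resolved(repeats)
        grouped: dict[tuple[str, str], list[Interval]] = {}
        for r in repeats:
            if r.te_class == "Simple":
                continue  # simple/low-complexity repeats never count as TE
            grouped.setdefault((r.chrom, r.te_class), []).append((r.start, r.end))
        self._index = {key: IntervalIndex(ivs) for key, ivs in grouped.items()}
        self.classes = sorted({k for _, k in grouped})

    def covered(self, chrom: str, intervals: list[Interval], te_class: str) -> int:
        idx = self._index.get((chrom, te_class))
        return idx.overlap_with(intervals) if idx else 0


def compute_te_density(
    gene_id: str,
    chrom: str,
    flanks: list[Interval],
    coverage: RepeatCoverage,
    te_classes: tuple[str, ...] = TE_CLASSES,
) -> FlankProfile:
    """TE density = covered bp / noncoding flank bp, per class and pooled.

    Repeats must be resolved (non-overlapping), so per-class covered
    lengths are disjoint and sum exactly to the 'ALL' coverage.
    """
    noncoding = total_length(flanks)
    prof = FlankProfile(gene_id=gene_id, flank_intervals=flanks, noncoding_len=noncoding)
    covered_all = 0
    for klass in te_classes + ("Other",):
        c = coverage.covered(chrom, flanks, klass)
        prof.te_covered_len[klass] = c
        covered_all += c
    prof.te_covered_len["ALL"] = covered_all
    if noncoding > 0:
        for k, v in prof.te_covered_len.items():
            prof.density[k] = v / noncoding
    return prof


def flank_profiles(
    genes: list[GeneRecord],
    resolved_repeats: list[RepeatRecord],
    chroms: list[ChromosomeSpec],
    flank_len: int = DEFAULT_FLANK_LEN,
) -> list[FlankProfile]:
    """Profiles for every gene, subtracting all genes' CDS genome-wide."""
    chrom_len = {c.name: c.length for c in chroms}
    cds_by_chrom: dict[str, list[Interval]] = {}
    for g in genes:
        cds_by_chrom.setdefault(g.chrom, []).extend(g.cds)
    cds_by_chrom = {c: merge_intervals(ivs) for c, ivs in cds_by_chrom.items()}
    coverage = RepeatCoverage(resolved_repeats)
    out = []
    for g in genes:
        flanks = extract_noncoding_flanks(g, cds_by_chrom, flank_len, chrom_len[g.chrom])
        out.append(compute_te_density(g.gene_id, g.chrom, flanks, coverage))
    return out


def call_compartmentalized(
    profiles: list[FlankProfile],
    te_class: str = "ALL",
    percentile: float = 90,
    species_id: str = "species",
) -> CompartmentCallSet:
    """Call genes at/above the given percentile of the species' density distribution.

    The cutoff is the linear-interpolation percentile of densities over
    eligible genes (noncoding_len > 0); genes exactly at the cutoff are
    called. Fewer than 10 eligible genes makes the species unusable.
    """
    eligible = [p for p in profiles if p.eligible]
    if len(eligible) < MIN_ELIGIBLE_GENES:
        raise ValueError(
            f"only {len(eligible)} genes have noncoding flank sequence; need "
            f">= {MIN_ELIGIBLE_GENES} for a percentile call"
        )
    dens = np.array([p.density.get(te_class, 0.0) for p in eligible])
    cutoff = float(np.percentile(dens, percentile))
    if np.all(dens == dens[0]):
        log.warning("degenerate density distribution (all equal): every gene is called")
    called = {p.gene_id for p, d in zip(eligible, dens) if d >= cutoff}
    background = {p.gene_id for p in eligible} - called
    return CompartmentCallSet(
        species_id=species_id,
        te_class=te_class,
        percentile=percentile,
        cutoff_value=cutoff,
        called_gene_ids=called,
        background_gene_ids=background,
    )
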