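"""Synthetic multi-species fixtures with planted compartmentalization signals.

No nucleotide sequence is generated: a species is a set of chromosome
lengths, gene/CDS intervals, repeat intervals, annotation tables,
population variants and per-site selection posteriors. A subset of gene
families is marked "labile"; their genes get elevated flanking TE
density, a planted GO term, optional subtelomeric placement, an excess
of high-frequency polymorphic TE insertions in their flanks, and an
elevated per-site rate of positive-selection signal — the signals the
downstream stages are supposed to recover.

TE placement is a Boolean (Poisson-interval) process per flank and TE
class: insertion count ~ Poisson, lengths ~ exponential, truncated at
the flank. The intensity is chosen as lambda = -ln(1 - r)/mean_len so
the expected *union* coverage equals the target rate r despite
self-overlap. Neutral allele counts follow the standard 1/i spectrum;
a coalescent simulation is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    ChromosomeSpec,
    GeneRecord,
    RepeatRecord,
    VariantRecord,
    write_bedgraph,
    write_chroms,
    write_gene_family_map,
    write_gene_term_map,
    write_genes,
    write_repeats,
    write_site_posteriors,
    write_variants,
)

_STREAM_SPECIES = 1
_STREAM_POPULATION = 2
_STREAM_POSTERIORS = 3
_STREAM_TRACKS = 4


def _default_class_mix() -> dict[str, float]:
    return {"LINE": 0.40, "SINE": 0.20, "LTR": 0.25, "DNA": 0.15}


def _default_labile_mix() -> dict[str, float]:
    # long, high-impact elements (LINEs/LTRs) dominate planted compartments
    return {"LINE": 0.45, "SINE": 0.05, "LTR": 0.45, "DNA": 0.05}


def _default_te_lengths() -> dict[str, float]:
    # RepeatMasker-style annotations are fragment-dominated: mean interval
    # lengths sit well below full element length
    return {"LINE": 900.0, "SINE": 250.0, "LTR": 1500.0, "DNA": 600.0}


@dataclass
class SimulationConfig:
    """One synthetic species; every planted signal has a knob here.

    Defaults describe the reference study condition: a compact
    fly-sized genome (5 x 25 Mb, 1,000 genes) with 5% of genes in
    labile families whose flanks carry a 10x elevated TE rate, a
    planted GO term at 90% specificity, 50 haploid genomes, and a
    strong high-frequency skew for TE insertions near labile genes.
    """

    seed: int = 0
    n_chroms: int = 5
    chrom_length: int = 25_000_000
    n_genes: int = 1000
    gene_length: int = 3000
    n_families: int = 300
    family_size_exponent: float = 2.2
    max_family_size: int = 60
    frac_labile: float = 0.05
    te_rate_background: float = 0.05
    te_rate_labile: float = 0.50
    te_class_mix: dict[str, float] = field(default_factory=_default_class_mix)
    labile_te_class_mix: dict[str, float] = field(default_factory=_default_labile_mix)
    te_length_mean: dict[str, float] = field(default_factory=_default_te_lengths)
    te_flank_len: int = 50_000
    n_go_terms: int = 50
    go_annotation_fraction: float = 0.8
    mean_terms_per_gene: float = 3.0
    planted_term_specificity: float = 0.9
    planted_term_background: float = 0.02
    subtelomere_bias: str = "none"  # none | enriched | depleted
    subtelomere_frac: float = 0.10
    subtelomere_strength: float = 0.85
    n_samples: int = 50
    n_te_variants: int = 5000
    n_snvs: int = 4000
    afs_skew: float = 0.5
    selection_base: float = 0.01
    selection_effect: float = 0.04
    constraint_base: float = 0.20
    constraint_effect: float = 0.05
    n_sites_per_family: int = 200

    def validate(self) -> None:
        fracs = {
            "frac_labile": self.frac_labile,
            "te_rate_background": self.te_rate_background,
            "te_rate_labile": self.te_rate_labile,
            "go_annotation_fraction": self.go_annotation_fraction,
            "planted_term_specificity": self.planted_term_specificity,
            "planted_term_background": self.planted_term_background,
            "afs_skew": self.afs_skew,
            "selection_base": self.selection_base,
            "selection_effect": self.selection_effect,
            "constraint_base": self.constraint_base,
            "constraint_effect": self.constraint_effect,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.te_rate_labile >= 1.0 or self.te_rate_background >= 1.0:
            raise ValueError("TE rates must be < 1")
        if self.subtelomere_bias not in ("none", "enriched", "depleted"):
            raise ValueError(f"unknown subtelomere_bias {self.subtelomere_bias!r}")
        for mix in (self.te_class_mix, self.labile_te_class_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("TE class mix must sum to 1")


@dataclass
class GroundTruth:
    labile_gene_ids: set[str]
    planted_go_term: str
    labile_family_ids: set[str]


def _stream(config: SimulationConfig, key: int) -> np.random.Generator:
    """Independent, reproducible stream per simulation stage."""
    return np.random.default_rng([int(config.seed), key])


def _family_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    sizes = np.minimum(
        rng.zipf(config.family_size_exponent, size=config.n_families), config.max_family_size
    ).astype(np.int64)
    # rebalance to exactly n_genes
    while sizes.sum() < config.n_genes:
        sizes[rng.integers(config.n_families)] += 1
    while sizes.sum() > config.n_genes:
        i = int(np.argmax(sizes))
        if sizes[i] <= 1:
            break
        sizes[i] -= 1
    return sizes


def _pick_labile_families(
    sizes: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> set[int]:
    """Select families until ~frac_labile of genes are labile, preferring
    multigene families (size >= 10) so calls reproduce the multigene-family
    enrichment the analysis looks for."""
    budget = int(round(config.frac_labile * config.n_genes))
    if budget == 0:
        return set()
    multi = [i for i in range(len(sizes)) if sizes[i] >= 10]
    small = [i for i in range(len(sizes)) if 0 < sizes[i] < 10]
    rng.shuffle(multi)
    rng.shuffle(small)
    chosen: set[int] = set()
    count = 0
    for i in multi + small:
        if count >= budget:
            break
        if count + int(sizes[i]) <= budget:  # never overshoot the gene budget
            chosen.add(i)
            count += int(sizes[i])
    return chosen


def simulate_species(
    config: SimulationConfig, species_id: str = "sim"
) -> tuple[list[ChromosomeSpec], list[GeneRecord], list[RepeatRecord], GroundTruth]:
    """Chromosomes, genes (with family/GO annotations) and repeat intervals.

    Genes occupy one slot each on an even grid per chromosome, keeping a
    flank-sized margin inside the slot where the slot permits, so each
    gene's planted flank signal stays local to that gene. Deterministic
    for a fixed config (including seed).
    """
    config.validate()
    rng = _stream(config, _STREAM_SPECIES)

    chroms = [
        ChromosomeSpec(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chroms)
    ]
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1

    # slot grid; terminal slots live in the first/last subtelomere_frac of bases
    slots: list[tuple[str, int, int]] = []  # (chrom, slot_start, slot_width)
    terminal_mask: list[bool] = []
    for c, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        width = c.length // n
        if width < config.gene_length:
            raise ValueError(
                f"infeasible packing: {n} genes of {config.gene_length} bp do not fit on "
                f"{c.name} ({c.length} bp)"
            )
        for j in range(n):
            start = j * width
            center = start + width / 2
            slots.append((c.name, start, width))
            terminal_mask.append(
                center < config.subtelomere_frac * c.length
                or center >= (1 - config.subtelomere_frac) * c.length
            )

    sizes = _family_sizes(config, rng)
    labile_fams = _pick_labile_families(sizes, config, rng)
    fam_of_gene: list[int] = []
    for i, s in enumerate(sizes):
        fam_of_gene.extend([i] * int(s))
    fam_of_gene = fam_of_gene[: config.n_genes]
    rng.shuffle(fam_of_gene)

    # slot assignment; labile genes steered to/away from terminal slots if biased
    n = config.n_genes
    order = list(rng.permutation(n))
    slot_of_gene: dict[int, int] = {}
    if config.subtelomere_bias == "none":
        for g, s in zip(range(n), order):
            slot_of_gene[g] = s
    else:
        terminal = [s for s in order if terminal_mask[s]]
        interior = [s for s in order if not terminal_mask[s]]
        prefer_terminal = config.subtelomere_bias == "enriched"
        labile_genes = [g for g in range(n) if fam_of_gene[g] in labile_fams]
        other_genes = [g for g in range(n) if fam_of_gene[g] not in labile_fams]
        for g in labile_genes:
            pools = (terminal, interior) if prefer_terminal else (interior, terminal)
            primary, fallback = pools
            use_primary = rng.random() < config.subtelomere_strength and primary
            pool = primary if use_primary else (fallback or primary)
            slot_of_gene[g] = pool.pop()
        rest = terminal + interior
        rng.shuffle(rest)
        for g, s in zip(other_genes, rest):
            slot_of_gene[g] = s

    genes: list[GeneRecord] = []
    repeats: list[RepeatRecord] = []
    go_terms = [f"GO:{i:07d}" for i in range(1, config.n_go_terms + 1)]
    planted_term = go_terms[0]
    other_terms = np.array(go_terms[1:])

    for g in range(n):
        chrom, slot_start, width = slots[slot_of_gene[g]]
        margin = min(config.te_flank_len, max(0, (width - config.gene_length) // 2))
        lo = slot_start + margin
        hi = slot_start + width - margin - config.gene_length
        start = int(lo if hi <= lo else lo + rng.integers(hi - lo))
        end = start + config.gene_length
        gl = config.gene_length
        cds = [
            (start + max(1, gl // 30), start + 2 * gl // 5),
            (start + 3 * gl // 5, end - max(1, gl // 30)),
        ]
        fam = fam_of_gene[g]
        labile = fam in labile_fams
        gene_id = f"g{g + 1:04d}"
        rec = GeneRecord(
            gene_id=gene_id,
            chrom=chrom,
            start=start,
            end=end,
            strand="+" if rng.random() < 0.5 else "-",
            cds=cds,
            family_id=f"fam{fam + 1:04d}",
        )
        # GO annotation: planted term for labile genes, random terms otherwise
        if labile and rng.random() < config.planted_term_specificity:
            rec.go_terms.add(planted_term)
        elif not labile and rng.random() < config.planted_term_background:
            rec.go_terms.add(planted_term)
        if rng.random() < config.go_annotation_fraction:
            k = 1 + rng.poisson(max(0.0, config.mean_terms_per_gene - 1))
            k = min(k, len(other_terms))
            rec.go_terms.update(rng.choice(other_terms, size=k, replace=False))
        genes.append(rec)

        rate = config.te_rate_labile if labile else config.te_rate_background
        mix = config.labile_te_class_mix if labile else config.te_class_mix
        if rate > 0:
            chrom_len = config.chrom_length
            flanks = [
                (max(0, start - config.te_flank_len), start),
                (end, min(chrom_len, end + config.te_flank_len)),
            ]
            for klass in ("LINE", "SINE", "LTR", "DNA"):
                r_c = rate * mix.get(klass, 0.0)
                if r_c <= 0:
                    continue
                mean_len = config.te_length_mean[klass]
                lam = -np.log1p(-r_c) / mean_len  # union coverage expectation = r_c
                for fs, fe in flanks:
                    if fe <= fs:
                        continue
                    count = rng.poisson(lam * (fe - fs))
                    for _ in range(count):
                        ts = int(rng.integers(fs, fe))
                        tl = max(30, int(rng.exponential(mean_len)))
                        te = min(ts + tl, chrom_len)
                        if te <= ts:
                            continue
                        repeats.append(
                            RepeatRecord(
                                chrom=chrom,
                                start=ts,
                                end=te,
                                te_class=klass,
                                family_name=f"{klass}/fam{int(rng.integers(1, 20))}",
                                score=float(rng.integers(100, 10000)),
                            )
                        )

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    repeats.sort(key=lambda r: (r.chrom, r.start, r.end))
    truth = GroundTruth(
        labile_gene_ids={g.gene_id for g in genes if g.family_id in {f"fam{i + 1:04d}" for i in labile_fams}},
        planted_go_term=planted_term,
        labile_family_ids={f"fam{i + 1:04d}" for i in labile_fams},
    )
    return chroms, genes, repeats, truth


def _neutral_counts(rng: np.random.Generator, n_samples: int, size: int) -> np.ndarray:
    """Allele counts from the neutral 1/i spectrum over 1..n-1."""
    i = np.arange(1, n_samples)
    w = 1.0 / i
    return rng.choice(i, size=size, p=w / w.sum())


def simulate_population(
    genes: list[GeneRecord],
    truth: GroundTruth,
    config: SimulationConfig,
) -> list[VariantRecord]:
    """Polymorphic TE insertions/deletions in gene flanks and syn/nonsyn SNVs in CDS.

    Allele counts are neutral (1/i) everywhere except TE variants in
    labile-gene flanks, which with probability afs_skew come from a
    high-frequency component uniform over counts > n/2.
    """
    if config.n_samples < 4:
        raise ValueError("need n_samples >= 4")
    rng = _stream(config, _STREAM_POPULATION)
    n = config.n_samples
    variants: list[VariantRecord] = []

    if config.n_te_variants > 0 and genes:
        gene_idx = rng.integers(len(genes), size=config.n_te_variants)
        for v, gi in enumerate(gene_idx):
            g = genes[int(gi)]
            flanks = [
                (max(0, g.start - config.te_flank_len), g.start),
                (g.end, min(config.chrom_length, g.end + config.te_flank_len)),
            ]
            flanks = [f for f in flanks if f[1] > f[0]]
            fs, fe = flanks[int(rng.integers(len(flanks)))]
            pos = int(rng.integers(fs, fe))
            is_ins = rng.random() < 0.7
            labile = g.gene_id in truth.labile_gene_ids
            if labile and rng.random() < config.afs_skew:
                alt = int(rng.integers(n // 2 + 1, n))
            else:
                alt = int(_neutral_counts(rng, n, 1)[0])
            variants.append(
                VariantRecord(
                    variant_id=f"te{v + 1:06d}",
                    chrom=g.chrom,
                    pos=pos,
                    vtype="TE_SV_INS" if is_ins else "TE_SV_DEL",
                    alt_count=alt,
                    n_samples=n,
                    length=51 + int(rng.exponential(1500)),
                    te_coverage=float(rng.uniform(0.5, 1.0)),
                )
            )

    if config.n_snvs > 0 and genes:
        gene_idx = rng.integers(len(genes), size=config.n_snvs)
        counts = _neutral_counts(rng, n, config.n_snvs)
        for v, (gi, alt) in enumerate(zip(gene_idx, counts)):
            g = genes[int(gi)]
            cs, ce = g.cds[int(rng.integers(len(g.cds)))]
            variants.append(
                VariantRecord(
                    variant_id=f"snv{v + 1:06d}",
                    chrom=g.chrom,
                    pos=int(rng.integers(cs, ce)),
                    vtype="SNV_SYN" if rng.random() < 0.5 else "SNV_NONSYN",
                    alt_count=int(alt),
                    n_samples=n,
                )
            )
    variants.sort(key=lambda v: (v.chrom, v.pos, v.variant_id))
    return variants


def simulate_site_posteriors(
    family_sizes: Mapping[str, int],
    truth: GroundTruth,
    config: SimulationConfig,
    species_id: str = "sim",
) -> pd.DataFrame:
    """Per-site selection posteriors with a planted group difference.

    For each site one of {positive, constrained, neither} is drawn; the
    chosen signal's posterior is pushed above 0.95 and the other kept
    below, so no site carries both signals. Labile families get
    selection_base + selection_effect as their positive-site rate.
    """
    rng = _stream(config, _STREAM_POSTERIORS)
    frames: list[pd.DataFrame] = []
    for fam in sorted(family_sizes):
        labile = fam in truth.labile_family_ids
        p_pos = config.selection_base + (config.selection_effect if labile else 0.0)
        p_con = config.constraint_base + (config.constraint_effect if labile else 0.0)
        m = config.n_sites_per_family
        u = rng.random(m)
        a = rng.random(m)
        b = rng.random(m)
        is_pos = u < p_pos
        is_con = ~is_pos & (u < p_pos + p_con)
        prob_pos = np.where(is_pos, 0.951 + 0.049 * a, np.where(is_con, 0.5 * a, 0.94 * a))
        prob_neg = np.where(is_con, 0.951 + 0.049 * b, np.where(is_pos, 0.5 * b, 0.94 * b))
        frames.append(
            pd.DataFrame(
                {
                    "species": species_id,
                    "family": fam,
                    "site": np.arange(1, m + 1),
                    "prob_pos": np.round(prob_pos, 6),
                    "prob_neg": np.round(prob_neg, 6),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["species", "family", "site", "prob_pos", "prob_neg"])
    return pd.concat(frames, ignore_index=True)


def simulate_context_tracks(
    genes: list[GeneRecord], config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null per-gene GC and recombination bedGraph tracks (no planted effect:
    the chromosomal-context stage is expected to find nothing here)."""
    rng = _stream(config, _STREAM_TRACKS)
    rows_gc, rows_rec = [], []
    for g in genes:
        span_start = max(0, g.start - config.te_flank_len)
        span_end = min(config.chrom_length, g.end + config.te_flank_len)
        gc = float(np.clip(rng.normal(0.41, 0.03), 0.25, 0.65))
        rec = float(rng.exponential(2.0))
        rows_gc.append({"chrom": g.chrom, "start": span_start, "end": span_end, "value": round(gc, 5)})
        rows_rec.append({"chrom": g.chrom, "start": span_start, "end": span_end, "value": round(rec, 5)})
    return pd.DataFrame(rows_gc), pd.DataFrame(rows_rec)


def write_species_fixtures(
    outdir: str | Path,
    config: SimulationConfig,
    species_id: str = "sim",
) -> dict[str, Path]:
    """Simulate one species and write every fixture file the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chroms, genes, repeats, truth = simulate_species(config, species_id)
    variants = simulate_population(genes, truth, config)
    fam_sizes: dict[str, int] = {}
    for g in genes:
        fam_sizes[g.family_id] = fam_sizes.get(g.family_id, 0) + 1
    posteriors = simulate_site_posteriors(fam_sizes, truth, config, species_id)
    gc, rec = simulate_context_tracks(genes, config)

    paths = {
        "chroms": outdir / "chroms.tsv",
        "genes": outdir / "genes.gff3",
        "repeats": outdir / "repeats.bed",
        "variants": outdir / "variants.vcf",
        "go": outdir / "gene_go.tsv",
        "families": outdir / "gene_family.tsv",
        "posteriors": outdir / "site_posteriors.tsv",
        "gc": outdir / "gc.bedgraph",
        "recomb": outdir / "recomb.bedgraph",
        "truth": outdir / "ground_truth.tsv",
    }
    write_chroms(paths["chroms"], chroms)
    write_genes(paths["genes"], genes, chroms)
    write_repeats(paths["repeats"], repeats)
    write_variants(paths["variants"], variants, chroms, config.n_samples)
    write_gene_term_map(paths["go"], {g.gene_id: g.go_terms for g in genes if g.go_terms})
    write_gene_family_map(paths["families"], {g.gene_id: g.family_id for g in genes})
    write_site_posteriors(paths["posteriors"], posteriors)
    write_bedgraph(paths["gc"], gc)
    write_bedgraph(paths["recomb"], rec)
    with open(paths["truth"], "w") as fh:
        fh.write(f"#planted_go_term\t{truth.planted_go_term}\n")
        for gid in sorted(truth.labile_gene_ids):
            fh.write(f"labile_gene\t{gid}\n")
        for fid in sorted(truth.labile_family_ids):
            fh.write(f"labile_family\t{fid}\n")
    return paths
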