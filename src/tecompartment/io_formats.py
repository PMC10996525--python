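"""Readers, writers and domain records for every external format the pipeline touches.

Internally everything is BED-style 0-based half-open; conversion to each
format's native convention (GFF3/VCF 1-based) happens only here, at the
I/O boundary. Strand is carried through but never used by the density
computations, which are strand-symmetric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

log = logging.getLogger(__name__)

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA")
ALL_CLASSES = TE_CLASSES + ("Other", "Simple")

_SIMPLE_LABELS = {"Simple", "Simple_repeat", "Low_complexity", "Satellite"}


def normalize_te_class(label: str) -> str:
    """Map a RepeatMasker-style class/family label onto the closed vocabulary.

    Classification is by slash prefix ("LINE/L1" -> LINE); simple and
    low-complexity repeats map to Simple and are excluded from TE
    density downstream; anything unrecognized becomes Other.
    """
    head = label.split("/", 1)[0].strip()
    if head in TE_CLASSES:
        return head
    if head in _SIMPLE_LABELS:
        return "Simple"
    return "Other"


# ---------------------------------------------------------------------------
# domain records


@dataclass(frozen=True)
class ChromosomeSpec:
    name: str
    length: int

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"chromosome {self.name}: length must be >= 1")


@dataclass
class GeneRecord:
    """A gene with its CDS intervals, all 0-based half-open."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds: list[tuple[int, int]] = field(default_factory=list)
    family_id: str | None = None
    go_terms: set[str] = field(default_factory=set)

    def validate(self, chrom_len: int | None = None) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if chrom_len is not None and self.end > chrom_len:
            raise ValueError(f"gene {self.gene_id}: extends past chromosome end")
        prev = self.start
        for s, e in self.cds:
            if s < prev or e > self.end or s >= e:
                raise ValueError(
                    f"gene {self.gene_id}: CDS ({s},{e}) not sorted/contained in gene span"
                )
            prev = e

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class RepeatRecord:
    chrom: str
    start: int
    end: int
    te_class: str
    family_name: str = "."
    score: float = 0.0

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"repeat {self.family_name}@{self.chrom}:{self.start}-{self.end}: bad coordinates"
            )
        if self.te_class not in ALL_CLASSES:
            raise ValueError(f"unknown te_class {self.te_class!r}")


VTYPES = ("TE_SV_INS", "TE_SV_DEL", "SNV_SYN", "SNV_NONSYN", "OTHER")


@dataclass
class VariantRecord:
    """One biallelic variant; alt_count over n_samples haploid genomes."""

    variant_id: str
    chrom: str
    pos: int
    vtype: str
    alt_count: int
    n_samples: int
    length: int | None = None
    te_coverage: float | None = None
    sample_id: str | None = None
    ambiguous: bool = False

    def __post_init__(self):
        if not 0 <= self.alt_count <= self.n_samples:
            raise ValueError(f"variant {self.variant_id}: alt_count out of range")
        if self.vtype not in VTYPES:
            raise ValueError(f"variant {self.variant_id}: unknown vtype {self.vtype!r}")

    @property
    def end(self) -> int:
        """Second breakpoint: pos for insertions, pos+length for deletions."""
        if self.vtype == "TE_SV_DEL" and self.length:
            return self.pos + self.length
        return self.pos


# ---------------------------------------------------------------------------
# GFF3 genes


def read_genes(path: str | Path, chroms: Sequence[ChromosomeSpec]) -> list[GeneRecord]:
    """Read gene and CDS features (linked by ID/Parent) from GFF3.

    Coordinates are converted from GFF3 1-based inclusive to 0-based
    half-open. Records on chromosomes not in `chroms` are a hard error,
    as is a CDS outside its parent's span.
    """
    path = Path(path)
    chrom_len = {c.name: c.length for c in chroms}
    if path.stat().st_size == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        if feat.seqid not in chrom_len:
            raise ValueError(f"gene {feat.id}: unknown chromosome {feat.seqid!r}")
        cds = sorted(
            (c.start - 1, c.end) for c in db.children(feat.id, featuretype="CDS")
        )
        rec = GeneRecord(
            gene_id=feat.id,
            chrom=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            cds=cds,
        )
        rec.validate(chrom_len[rec.chrom])
        genes.append(rec)
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_genes(path: str | Path, genes: Iterable[GeneRecord], chroms: Sequence[ChromosomeSpec]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in chroms:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\ttecompartment\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\ttecompartment\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# BED6+1 repeats (chrom, start, end, family_name, score, strand, class)


def read_repeats(path: str | Path) -> list[RepeatRecord]:
    out: list[RepeatRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{ln}: expected 7 BED columns, got {len(parts)}")
            chrom, start, end, name, score, _strand, klass = parts[:7]
            start_i, end_i = int(start), int(end)
            if start_i < 0 or start_i >= end_i:
                raise ValueError(f"{path}:{ln}: bad repeat coordinates {start}-{end}")
            out.append(
                RepeatRecord(
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    family_name=name,
                    score=float(score),
                    te_class=normalize_te_class(klass),
                )
            )
    return out


def write_repeats(path: str | Path, repeats: Iterable[RepeatRecord]) -> None:
    with open(path, "w") as fh:
        for r in sorted(repeats, key=lambda r: (r.chrom, r.start, r.end)):
            score = int(r.score) if float(r.score).is_integer() else r.score
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.family_name}\t{score}\t+\t{r.te_class}\n"
            )


# ---------------------------------------------------------------------------
# VCF variants


def _classify_variant(info: Mapping) -> tuple[str, int | None, float | None]:
    keys = set(info.keys())
    if "SVTYPE" in keys:
        svtype = info["SVTYPE"]
        length = abs(int(info["SVLEN"])) if "SVLEN" in keys else None
        tecov = float(info["TECOV"]) if "TECOV" in keys else None
        vtype = {"INS": "TE_SV_INS", "DEL": "TE_SV_DEL"}.get(str(svtype), "OTHER")
        return vtype, length, tecov
    if "EFF" in keys:
        eff = info["EFF"]
        eff = eff[0] if isinstance(eff, tuple) else str(eff)
        vtype = {"synonymous": "SNV_SYN", "missense": "SNV_NONSYN"}.get(eff, "OTHER")
        return vtype, None, None
    return "OTHER", None, None


def read_variants(path: str | Path) -> list[VariantRecord]:
    """Read biallelic variants from VCF; multi-allelic sites are dropped.

    alt_count is the number of alt alleles over the haploid sample
    columns; a site with any missing genotype is skipped with a warning.
    """
    out: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        n_samples = len(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            alleles = []
            missing = False
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or any(a is None for a in gt):
                    missing = True
                    break
                alleles.extend(gt)
            if missing:
                log.warning("site %s:%d skipped: missing genotype", rec.chrom, rec.pos)
                continue
            vtype, length, tecov = _classify_variant(rec.info)
            out.append(
                VariantRecord(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.start,
                    vtype=vtype,
                    alt_count=sum(1 for a in alleles if a == 1),
                    n_samples=n_samples,
                    length=length,
                    te_coverage=tecov,
                )
            )
    return out


def write_variants(
    path: str | Path, variants: Sequence[VariantRecord], chroms: Sequence[ChromosomeSpec], n_samples: int
) -> None:
    """Write variants as haploid VCF; alt alleles go to the first alt_count samples."""
    header = pysam.VariantHeader()
    for c in chroms:
        header.contigs.add(c.name, length=c.length)
    header.info.add("SVTYPE", 1, "String", "Structural variant type")
    header.info.add("SVLEN", 1, "Integer", "Structural variant length")
    header.info.add("TECOV", 1, "Float", "Fraction of SV sequence covered by TE annotation")
    header.info.add("EFF", 1, "String", "Coding effect (synonymous/missense)")
    header.formats.add("GT", 1, "String", "Genotype")
    sample_names = [f"s{i:03d}" for i in range(n_samples)]
    for s in sample_names:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.variant_id)):
            rec = vcf.new_record(contig=v.chrom, start=v.pos, stop=v.pos + 1, id=v.variant_id)
            if v.vtype in ("TE_SV_INS", "TE_SV_DEL"):
                rec.alleles = ("N", "<INS>" if v.vtype == "TE_SV_INS" else "<DEL>")
                rec.info["SVTYPE"] = "INS" if v.vtype == "TE_SV_INS" else "DEL"
                if v.length is not None:
                    rec.info["SVLEN"] = -v.length if v.vtype == "TE_SV_DEL" else v.length
                if v.te_coverage is not None:
                    rec.info["TECOV"] = v.te_coverage
            else:
                rec.alleles = ("A", "T")
                if v.vtype == "SNV_SYN":
                    rec.info["EFF"] = "synonymous"
                elif v.vtype == "SNV_NONSYN":
                    rec.info["EFF"] = "missense"
            for i, s in enumerate(sample_names):
                rec.samples[s]["GT"] = (1,) if i < v.alt_count else (0,)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# flat TSV tables


def read_chroms(path: str | Path) -> list[ChromosomeSpec]:
    df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"], dtype={"name": str})
    return [ChromosomeSpec(r.name, int(r.length)) for r in df.itertuples(index=False)]


def write_chroms(path: str | Path, chroms: Sequence[ChromosomeSpec]) -> None:
    with open(path, "w") as fh:
        for c in chroms:
            fh.write(f"{c.name}\t{c.length}\n")


def read_gene_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV, one (gene, GO term) pair per line -> gene -> term set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, term = line.split("\t")
            out.setdefault(gene, set()).add(term)
    return out


def write_gene_term_map(path: str | Path, go_map: Mapping[str, set[str]]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(go_map):
            for term in sorted(go_map[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gene_family_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            gene, fam = line.split("\t")
            out[gene] = fam
    return out


def write_gene_family_map(path: str | Path, fam_map: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for gene in sorted(fam_map):
            fh.write(f"{gene}\t{fam_map[gene]}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], dtype={"chrom": str}
    )


def write_bedgraph(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "start", "end", "value"])


POSTERIOR_COLUMNS = ["species", "family", "site", "prob_pos", "prob_neg"]


def read_site_posteriors(path: str | Path) -> pd.DataFrame:
    """Per-site selection posteriors (FUBAR-style): P(positive) and P(constraint)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(POSTERIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing posterior columns {sorted(missing)}")
    bad = df[(df.prob_pos < 0) | (df.prob_pos > 1) | (df.prob_neg < 0) | (df.prob_neg > 1)]
    if len(bad):
        raise ValueError(f"{path}: posteriors outside [0,1]")
    return df


def write_site_posteriors(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, columns=POSTERIOR_COLUMNS)
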