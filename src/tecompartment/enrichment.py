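"""GO enrichment/purification of compartment calls and related fold statistics.

GO terms are treated as flat labels (no DAG propagation); the
population for each species is its GO-annotated gene set, and the study
set is the annotated compartmentalized genes. Species with under 20%
of genes annotated are refused outright. A species with no FDR-
significant term at the 90th-percentile call threshold is retried at
the 95th.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .compartmentalization import CompartmentCallSet, FlankProfile, call_compartmentalized

log = logging.getLogger(__name__)

MIN_ANNOTATION_FRACTION = 0.20
MIN_STUDY_GENES = 4
MULTIGENE_SIZE = 10


@dataclass
class EnrichmentRecord:
    term_id: str
    study_hits: int
    study_n: int
    pop_hits: int
    pop_n: int
    fold: float
    p: float
    q: float
    direction: str  # enriched | purified


@dataclass
class SpeciesGOQuality:
    species_id: str
    n_genes: int
    n_annotated: int

    @property
    def fraction_annotated(self) -> float:
        return self.n_annotated / self.n_genes if self.n_genes else 0.0

    @property
    def passes(self) -> bool:
        return self.fraction_annotated >= MIN_ANNOTATION_FRACTION


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on [[a, b], [c, d]].

    Returns (odds_ratio, p). The two-sided p sums hypergeometric
    probabilities of all tables with the observed margins that are no
    more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("Fisher table counts must be non-negative")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def bh_fdr(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0,1]")
    return list(multipletests(p, method="fdr_bh")[1])


def species_go_quality(
    all_gene_ids: set[str], go_map: Mapping[str, set[str]], species_id: str = "species"
) -> SpeciesGOQuality:
    annotated = sum(1 for g in all_gene_ids if go_map.get(g))
    return SpeciesGOQuality(species_id, len(all_gene_ids), annotated)


def go_enrichment(
    calls: CompartmentCallSet,
    go_map: Mapping[str, set[str]],
    min_study: int = MIN_STUDY_GENES,
) -> list[EnrichmentRecord]:
    """Per-term Fisher tests of annotated called genes against the annotated population.

    Both directions are reported: fold > 1 is enrichment, fold < 1
    purification (underrepresentation). Fewer than `min_study`
    annotated called genes yields an empty result.
    """
    population = sorted(
        g for g in calls.called_gene_ids | calls.background_gene_ids if go_map.get(g)
    )
    study = [g for g in population if g in calls.called_gene_ids]
    pop_n, study_n = len(population), len(study)
    if study_n < min_study:
        log.warning(
            "species %s: only %d annotated called genes (< %d); no enrichment test",
            calls.species_id, study_n, min_study,
        )
        return []
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    study_set = set(study)
    for g in population:
        for t in go_map[g]:
            term_pop[t] = term_pop.get(t, 0) + 1
            if g in study_set:
                term_study[t] = term_study.get(t, 0) + 1
    records = []
    for term in sorted(term_pop):
        a = term_study.get(term, 0)
        b = study_n - a
        c = term_pop[term] - a
        d = (pop_n - study_n) - c
        _, p = fisher_exact_2x2(a, b, c, d)
        study_frac = a / study_n
        pop_frac = term_pop[term] / pop_n
        fold = study_frac / pop_frac if pop_frac > 0 else math.inf
        records.append(
            EnrichmentRecord(
                term_id=term,
                study_hits=a,
                study_n=study_n,
                pop_hits=term_pop[term],
                pop_n=pop_n,
                fold=fold,
                p=p,
                q=math.nan,
                direction="enriched" if fold >= 1 else "purified",
            )
        )
    qs = bh_fdr([r.p for r in records])
    for r, q in zip(records, qs):
        r.q = float(q)
    records.sort(key=lambda r: (r.q, r.p, r.term_id))
    return records


def go_enrichment_with_fallback(
    profiles: list[FlankProfile],
    go_map: Mapping[str, set[str]],
    te_class: str = "ALL",
    species_id: str = "species",
    alpha: float = 0.05,
    min_study: int = MIN_STUDY_GENES,
) -> tuple[list[EnrichmentRecord], CompartmentCallSet]:
    """Enrichment at the 90th-percentile calls; if no term passes FDR,
    recompute calls at the 95th percentile and retest."""
    calls = call_compartmentalized(profiles, te_class, 90, species_id)
    records = go_enrichment(calls, go_map, min_study)
    if not any(r.q < alpha for r in records):
        calls95 = call_compartmentalized(profiles, te_class, 95, species_id)
        records95 = go_enrichment(calls95, go_map, min_study)
        if records95:
            return records95, calls95
    return records, calls


def multigene_fold(
    calls: CompartmentCallSet,
    family_sizes: Mapping[str, int],
    size_threshold: int = MULTIGENE_SIZE,
) -> float:
    """Fold enrichment of multigene-family membership among called genes.

    fold = (fraction of called genes whose family has >= size_threshold
    members) / (same fraction among background genes). Returns +inf if
    the background fraction is zero while the called fraction is not.
    """
    if not calls.background_gene_ids:
        raise ValueError("empty background set")
    if not calls.called_gene_ids:
        raise ValueError("empty call set")

    def frac(gene_ids: set[str]) -> float:
        hits = sum(1 for g in gene_ids if family_sizes.get(g, 1) >= size_threshold)
        return hits / len(gene_ids)

    f_called = frac(calls.called_gene_ids)
    f_back = frac(calls.background_gene_ids)
    if f_back == 0:
        return math.inf if f_called > 0 else 1.0
    return f_called / f_back


def compare_te_class_profiles(
    per_species_class_calls: Mapping[str, Mapping[str, CompartmentCallSet]],
    go_maps: Mapping[str, Mapping[str, set[str]]],
    alpha: float = 0.05,
) -> dict[tuple[str, str], dict]:
    """Per-GO-term Fisher tests between TE-class call sets, pooled across species.

    For each class pair and term, the 2x2 table counts annotated called
    genes with/without the term in each class, summed over species.
    Returns per pair: records (term, p, q) and the fraction of terms
    with q < alpha.
    """
    classes = sorted({k for calls in per_species_class_calls.values() for k in calls})
    if len(classes) < 2:
        raise ValueError("need calls for at least two TE classes")
    out: dict[tuple[str, str], dict] = {}
    for ca, cb in itertools.combinations(classes, 2):
        with_term: dict[str, list[int]] = {}
        totals = [0, 0]
        for sp, calls in per_species_class_calls.items():
            go_map = go_maps[sp]
            for gi, klass in enumerate((ca, cb)):
                if klass not in calls:
                    continue
                genes = [g for g in calls[klass].called_gene_ids if go_map.get(g)]
                totals[gi] += len(genes)
                for g in genes:
                    for t in go_map[g]:
                        with_term.setdefault(t, [0, 0])[gi] += 1
        if totals[0] == 0 or totals[1] == 0:
            log.warning("class pair (%s,%s): a class has no annotated called genes", ca, cb)
            out[(ca, cb)] = {"records": [], "fraction_significant": 0.0}
            continue
        terms = sorted(t for t, (x, y) in with_term.items() if x + y > 0)
        pvals = []
        for t in terms:
            x, y = with_term[t]
            _, p = fisher_exact_2x2(x, totals[0] - x, y, totals[1] - y)
            pvals.append(p)
        qs = bh_fdr(pvals)
        records = [
            {"term_id": t, "p": p, "q": q} for t, p, q in zip(terms, pvals, qs)
        ]
        frac_sig = (
            sum(1 for r in records if r["q"] < alpha) / len(records) if records else 0.0
        )
        out[(ca, cb)] = {"records": records, "fraction_significant": frac_sig}
    return out


def aggregate_term_frequencies(
    per_species_records: Mapping[str, Sequence[EnrichmentRecord]],
    alpha: float = 0.05,
) -> dict[str, tuple[int, int]]:
    """term -> (n species where the term is FDR-significantly enriched,
    n species where the term was tested at all)."""
    out: dict[str, list[int]] = {}
    for records in per_species_records.values():
        for r in records:
            counts = out.setdefault(r.term_id, [0, 0])
            counts[1] += 1
            if r.q < alpha and r.direction == "enriched":
                counts[0] += 1
    return {t: (c[0], c[1]) for t, c in out.items()}
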