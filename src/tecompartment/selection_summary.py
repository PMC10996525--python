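"""Aggregate per-site selection posteriors into group-level proportions.

Consumes FUBAR-style per-site posteriors of positive selection and
constraint for each gene family, restricted to multigene families
(>= 10 genes), splits families into TE-compartmentalized vs other
(a family counts as compartmentalized if >= 1 member gene is called,
or a strict majority under the "majority" rule), and pools sites per
group. The cross-species trend is an exact two-sided binomial test on
per-species signs of the group difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .compartmentalization import CompartmentCallSet
from .genomic_context import cross_species_binomial

log = logging.getLogger(__name__)

POSTERIOR_CUTOFF = 0.95
MIN_FAMILY_SIZE = 10


@dataclass
class SelectionSummary:
    species_id: str
    group: str  # called_families | other_families
    n_sites: int
    n_pos_sites: int
    n_con_sites: int

    @property
    def prop_pos(self) -> float:
        return self.n_pos_sites / self.n_sites if self.n_sites else float("nan")

    @property
    def prop_con(self) -> float:
        return self.n_con_sites / self.n_sites if self.n_sites else float("nan")


def _called_families(
    calls: CompartmentCallSet, gene_families: Mapping[str, str], rule: str
) -> set[str]:
    members: dict[str, int] = {}
    hits: dict[str, int] = {}
    for gene, fam in gene_families.items():
        members[fam] = members.get(fam, 0) + 1
        if gene in calls.called_gene_ids:
            hits[fam] = hits.get(fam, 0) + 1
    if rule == "any":
        return set(hits)
    if rule == "majority":
        return {f for f, h in hits.items() if h * 2 > members[f]}
    raise ValueError(f"unknown family rule {rule!r}")


def summarize_selection(
    table: pd.DataFrame,
    calls: CompartmentCallSet,
    gene_families: Mapping[str, str],
    min_family: int = MIN_FAMILY_SIZE,
    cutoff: float = POSTERIOR_CUTOFF,
    family_rule: str = "any",
    species_id: str | None = None,
) -> tuple[SelectionSummary, SelectionSummary]:
    """Pooled site proportions above the posterior cutoff, per group.

    `table` holds columns family, prob_pos, prob_neg (one row per
    site). Families smaller than min_family are excluded; a group left
    with no eligible family makes the species unusable.
    """
    species_id = species_id or calls.species_id
    fam_sizes: dict[str, int] = {}
    for fam in gene_families.values():
        fam_sizes[fam] = fam_sizes.get(fam, 0) + 1
    eligible = {f for f, s in fam_sizes.items() if s >= min_family}
    called_fams = _called_families(calls, gene_families, family_rule) & eligible
    other_fams = eligible - called_fams

    sub = table[table["family"].isin(eligible)]
    both = sub[(sub.prob_pos > cutoff) & (sub.prob_neg > cutoff)]
    if len(both):
        raise ValueError(
            f"{len(both)} sites claim both positive selection and constraint above "
            f"{cutoff}; posterior table is inconsistent"
        )

    summaries = []
    for group, fams in (("called_families", called_fams), ("other_families", other_fams)):
        rows = sub[sub["family"].isin(fams)]
        if not len(rows):
            raise ValueError(
                f"species {species_id}: no eligible {group} with posterior sites; skipped"
            )
        summaries.append(
            SelectionSummary(
                species_id=species_id,
                group=group,
                n_sites=len(rows),
                n_pos_sites=int((rows.prob_pos > cutoff).sum()),
                n_con_sites=int((rows.prob_neg > cutoff).sum()),
            )
        )
    return summaries[0], summaries[1]


def cross_species_selection_test(
    summaries: Sequence[tuple[SelectionSummary, SelectionSummary]],
) -> tuple[float, float]:
    """(p_pos, p_con): binomial tests on per-species signs of the
    called-minus-other difference in positive-selection and constraint
    site proportions. Ties are dropped; all-ties is an error."""
    if not summaries:
        raise ValueError("no species summaries")

    def signs(attr: str) -> list[int]:
        out = []
        for called, other in summaries:
            diff = getattr(called, attr) - getattr(other, attr)
            out.append(0 if diff == 0 else (1 if diff > 0 else -1))
        return out

    return cross_species_binomial(signs("prop_pos")), cross_species_binomial(signs("prop_con"))
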