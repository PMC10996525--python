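"""End-to-end orchestration over one species: simulate/load -> compartmentalize
-> enrich -> context -> popgen -> selection, with one manifest per run.

Every stage writes one TSV under the run directory; stages whose inputs
are absent are marked skipped. All stochastic stages derive child
streams from the single run seed, so a rerun from the same manifest is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartmentalization import (
    call_compartmentalized,
    flank_profiles,
    resolve_repeat_overlaps,
)
from .enrichment import (
    go_enrichment_with_fallback,
    multigene_fold,
    species_go_quality,
)
from .genomic_context import (
    bp_weighted_gene_values,
    context_group_comparison,
    subtelomere_permutation_test,
)
from .intervals import merge_intervals
from .io_formats import (
    TE_CLASSES,
    read_bedgraph,
    read_chroms,
    read_gene_family_map,
    read_gene_term_map,
    read_genes,
    read_repeats,
    read_site_posteriors,
    read_variants,
)
from .popgen import assign_variants, compare_afs_chi2, filter_te_svs, folded_afs
from .selection_summary import summarize_selection
from .synthetic_data import SimulationConfig, write_species_fixtures

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All thresholds of the analysis, defaulting to the standard protocol."""

    flank_len: int = 50_000
    percentile: float = 90
    fallback_percentile: float = 95
    alpha: float = 0.05
    min_study: int = 4
    min_annotation_fraction: float = 0.20
    multigene_size: int = 10
    min_family: int = 10
    selection_cutoff: float = 0.95
    terminal_frac: float = 0.10
    n_perm: int = 1000
    sv_min_len: int = 50
    sv_min_te_cov: float = 0.5
    sv_merge_dist: int = 500
    family_rule: str = "any"
    seed: int = 0


@dataclass
class RunConfig:
    outdir: str
    species_id: str = "sim"
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    inputs: dict[str, str] = field(default_factory=dict)


@dataclass
class RunManifest:
    species_id: str
    seed: int
    version: str
    config: dict
    stages: dict[str, dict]
    outputs: dict[str, str]

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _load_inputs(config: RunConfig) -> dict:
    paths = {k: Path(v) for k, v in config.inputs.items()}
    if config.simulate:
        fixdir = Path(config.outdir) / "fixtures"
        paths = write_species_fixtures(fixdir, config.sim, config.species_id)
    chroms = read_chroms(paths["chroms"])
    genes = read_genes(paths["genes"], chroms)
    fam_map = read_gene_family_map(paths["families"]) if "families" in paths else {}
    go_map = read_gene_term_map(paths["go"]) if "go" in paths else {}
    for g in genes:
        g.family_id = fam_map.get(g.gene_id)
        g.go_terms = set(go_map.get(g.gene_id, set()))
    data = {
        "paths": paths,
        "chroms": chroms,
        "genes": genes,
        "repeats": read_repeats(paths["repeats"]),
        "go_map": go_map,
        "fam_map": fam_map,
    }
    for opt, reader in (
        ("variants", read_variants),
        ("posteriors", read_site_posteriors),
        ("gc", read_bedgraph),
        ("recomb", read_bedgraph),
    ):
        data[opt] = reader(paths[opt]) if opt in paths and paths[opt].exists() else None
    return data


def run_species(config: RunConfig) -> RunManifest:
    """Execute the full pipeline for one species; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ana = config.analysis
    data = _load_inputs(config)
    chroms, genes, go_map, fam_map = (
        data["chroms"], data["genes"], data["go_map"], data["fam_map"],
    )
    stages: dict[str, dict] = {}
    outputs: dict[str, str] = {}

    # --- compartmentalization -------------------------------------------------
    resolved = resolve_repeat_overlaps(data["repeats"])
    profiles = flank_profiles(genes, resolved, chroms, ana.flank_len)
    calls = call_compartmentalized(
        profiles, "ALL", ana.percentile, config.species_id
    )
    class_calls = {"ALL": calls}
    for klass in TE_CLASSES:
        class_calls[klass] = call_compartmentalized(
            profiles, klass, ana.percentile, config.species_id
        )
    rows = []
    for p in profiles:
        row = {
            "gene_id": p.gene_id,
            "noncoding_len": p.noncoding_len,
            "density_ALL": round(p.density.get("ALL", float("nan")), 6),
            "called_ALL": int(p.gene_id in calls.called_gene_ids),
        }
        for klass in TE_CLASSES:
            row[f"density_{klass}"] = round(p.density.get(klass, float("nan")), 6)
            row[f"called_{klass}"] = int(p.gene_id in class_calls[klass].called_gene_ids)
        rows.append(row)
    comp_path = outdir / "compartments.tsv"
    pd.DataFrame(rows).to_csv(comp_path, sep="\t", index=False)
    outputs["compartments"] = str(comp_path)
    stages["compartmentalize"] = {
        "status": "ok",
        "n_genes": len(genes),
        "n_repeats_resolved": len(resolved),
        "n_called": len(calls.called_gene_ids),
        "cutoff": calls.cutoff_value,
    }

    # --- GO enrichment + multigene fold --------------------------------------
    quality = species_go_quality({g.gene_id for g in genes}, go_map, config.species_id)
    if not quality.passes:
        stages["enrich"] = {
            "status": "skipped",
            "reason": f"only {quality.fraction_annotated:.1%} of genes GO-annotated (< 20%)",
        }
    else:
        records, used_calls = go_enrichment_with_fallback(
            profiles, go_map, "ALL", config.species_id, ana.alpha, ana.min_study
        )
        enr_path = outdir / "enrichment.tsv"
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "study_hits": r.study_hits,
                    "study_n": r.study_n,
                    "pop_hits": r.pop_hits,
                    "pop_n": r.pop_n,
                    "fold": round(r.fold, 6),
                    "p": r.p,
                    "q": r.q,
                    "direction": r.direction,
                }
                for r in records
            ]
        ).to_csv(enr_path, sep="\t", index=False)
        outputs["enrichment"] = str(enr_path)
        fam_gene_sizes: dict[str, int] = {}
        fam_counts: dict[str, int] = {}
        for g in genes:
            if g.family_id:
                fam_counts[g.family_id] = fam_counts.get(g.family_id, 0) + 1
        for g in genes:
            fam_gene_sizes[g.gene_id] = fam_counts.get(g.family_id, 1)
        fold = multigene_fold(calls, fam_gene_sizes, ana.multigene_size) if fam_map else None
        stages["enrich"] = {
            "status": "ok",
            "percentile_used": used_calls.percentile,
            "n_terms_tested": len(records),
            "n_significant": sum(1 for r in records if r.q < ana.alpha),
            "multigene_fold": fold,
        }

    # --- chromosomal context --------------------------------------------------
    rng = np.random.default_rng([ana.seed, 10])
    ctx_rows = []
    by_chrom: dict[str, dict[str, float]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, {})[g.gene_id] = g.midpoint
    chrom_len = {c.name: c.length for c in chroms}
    for chrom in sorted(by_chrom):
        mids = by_chrom[chrom]
        if not (set(mids) & calls.called_gene_ids):
            continue
        res = subtelomere_permutation_test(
            mids, calls.called_gene_ids, chrom_len[chrom], chrom,
            ana.terminal_frac, ana.n_perm, rng, ana.alpha,
        )
        ctx_rows.append(
            {
                "chrom": chrom, "kind": "subtelomere", "n_genes": res.n_genes,
                "n_called": res.n_called, "observed_prop": round(res.observed_prop, 6),
                "p": res.p_two_sided, "direction": res.direction,
            }
        )
    for kind in ("gc", "recomb"):
        track = data[kind]
        if track is None:
            continue
        values = bp_weighted_gene_values(genes, track, chrom_len, ana.flank_len)
        try:
            med_c, med_b, p, sign = context_group_comparison(
                values, calls.called_gene_ids, calls.background_gene_ids
            )
        except ValueError as exc:
            log.warning("%s comparison skipped: %s", kind, exc)
            continue
        ctx_rows.append(
            {
                "chrom": "genome", "kind": kind, "n_genes": len(values),
                "n_called": len(calls.called_gene_ids),
                "observed_prop": round(med_c - med_b, 6), "p": p,
                "direction": {1: "+", -1: "-", 0: "0"}[sign],
            }
        )
    ctx_path = outdir / "context.tsv"
    pd.DataFrame(ctx_rows).to_csv(ctx_path, sep="\t", index=False)
    outputs["context"] = str(ctx_path)
    stages["context"] = {"status": "ok", "n_tests": len(ctx_rows)}

    # --- population genetics --------------------------------------------------
    variants = data["variants"]
    if variants is None:
        stages["popgen"] = {"status": "skipped", "reason": "no variant input"}
    else:
        stages["popgen"] = _popgen_stage(
            variants, genes, profiles, calls, chroms, ana, outdir, outputs
        )

    # --- selection summary ----------------------------------------------------
    posteriors = data["posteriors"]
    if posteriors is None or not fam_map:
        stages["selection"] = {"status": "skipped", "reason": "no posterior/family input"}
    else:
        try:
            called_s, other_s = summarize_selection(
                posteriors, calls, fam_map, ana.min_family, ana.selection_cutoff,
                ana.family_rule, config.species_id,
            )
            sel_path = outdir / "selection.tsv"
            pd.DataFrame(
                [
                    {
                        "species": s.species_id, "group": s.group, "n_sites": s.n_sites,
                        "n_pos_sites": s.n_pos_sites, "n_con_sites": s.n_con_sites,
                        "prop_pos": round(s.prop_pos, 6), "prop_con": round(s.prop_con, 6),
                    }
                    for s in (called_s, other_s)
                ]
            ).to_csv(sel_path, sep="\t", index=False)
            outputs["selection"] = str(sel_path)
            stages["selection"] = {
                "status": "ok",
                "prop_pos_called": called_s.prop_pos,
                "prop_pos_other": other_s.prop_pos,
            }
        except ValueError as exc:
            stages["selection"] = {"status": "skipped", "reason": str(exc)}

    manifest = RunManifest(
        species_id=config.species_id,
        seed=ana.seed,
        version=__version__,
        config={
            "analysis": asdict(ana),
            "sim": asdict(config.sim) if config.simulate else None,
            "inputs": {k: str(v) for k, v in data["paths"].items()},
        },
        stages=stages,
        outputs=outputs,
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _popgen_stage(variants, genes, profiles, calls, chroms, ana, outdir, outputs) -> dict:
    n_samples = variants[0].n_samples if variants else 0
    te_svs = [v for v in variants if v.vtype in ("TE_SV_INS", "TE_SV_DEL")]
    snvs = [v for v in variants if v.vtype in ("SNV_SYN", "SNV_NONSYN")]
    te_svs = filter_te_svs(te_svs, ana.sv_min_len, ana.sv_min_te_cov)
    flanks = {p.gene_id: p.flank_intervals for p in profiles}
    cds = {g.gene_id: merge_intervals(g.cds) for g in genes}
    chrom_of = {g.gene_id: g.chrom for g in genes}
    assign = assign_variants(te_svs + snvs, flanks, cds, calls, chrom_of)
    spectra_rows, test_rows = [], []
    by_id = {v.variant_id: v for v in te_svs + snvs}
    for label, vtypes, context in (
        ("te_flank", ("TE_SV_INS", "TE_SV_DEL"), "flank"),
        ("snv_syn", ("SNV_SYN",), "cds"),
        ("snv_nonsyn", ("SNV_NONSYN",), "cds"),
    ):
        groups = {}
        for grp in ("called", "other"):
            members = [
                by_id[vid]
                for vid, (g, ctx) in assign.items()
                if g == grp and ctx == context and by_id[vid].vtype in vtypes
            ]
            afs = folded_afs(members, n_samples)
            groups[grp] = afs
            for i, count in enumerate(afs.bins, start=1):
                spectra_rows.append(
                    {"spectrum": label, "group": grp, "minor_count": i, "n": int(count)}
                )
        try:
            chi2, df, p = compare_afs_chi2(groups["called"], groups["other"])
            test_rows.append({"spectrum": label, "chi2": chi2, "df": df, "p": p})
        except ValueError as exc:
            log.warning("AFS comparison for %s skipped: %s", label, exc)
    afs_path = outdir / "afs_spectra.tsv"
    pd.DataFrame(spectra_rows).to_csv(afs_path, sep="\t", index=False)
    tests_path = outdir / "afs_tests.tsv"
    pd.DataFrame(test_rows).to_csv(tests_path, sep="\t", index=False)
    outputs["afs_spectra"] = str(afs_path)
    outputs["afs_tests"] = str(tests_path)
    return {
        "status": "ok",
        "n_te_svs": len(te_svs),
        "n_snvs": len(snvs),
        "n_assigned": len(assign),
        "tests": {r["spectrum"]: r["p"] for r in test_rows},
    }
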