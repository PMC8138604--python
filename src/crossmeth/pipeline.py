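"""End-to-end orchestration of the synthetic cross-species study.

``run_all`` simulates an RRBS tumour/control study plus linked human
array datasets, pushes them through every analysis stage — locus
filtering, global methylation comparison, per-CpG moderated-t calls,
beta-binomial DMRs, clustering, ortholog resolution, cross-species
enrichment/concordance and the clinical risk-group check — and writes
the artifact set to an output directory. Everything is deterministic for
a fixed seed, and the simulated data pass through the real file writers
and readers on their way in.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cross_species as xs
from . import io_formats as iof
from .clustering import hierarchical_cluster, select_top_variance_loci
from .config import PipelineConfig
from .dm_cpg import call_dm_cpgs
from .dmr import call_dmrs
from .methylation import (
    array_to_meth_matrix,
    average_methylation,
    build_meth_matrix,
    filter_array_probes,
    filter_loci,
)
from .orthology import resolve_orthologs
from .simulate import (
    SimulationConfig,
    simulate_array,
    simulate_ortholog_candidates,
    simulate_rrbs,
)

logger = logging.getLogger(__name__)

__all__ = ["run_all", "write_simulated_inputs", "load_samples_manifest"]

#: Direction-concordance probabilities used for the two simulated human
#: subtypes, emulating the strong (stem-cell-like) vs weaker
#: (keratinocyte-like) agreement with the mouse model.
SUBTYPE_CONCORDANCE = {"stem": 0.825, "keratinocyte": 0.657}


def write_simulated_inputs(sim, outdir: Path) -> pd.DataFrame:
    """Write the simulated RRBS study as on-disk inputs; returns the manifest."""
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    rows = []
    for t in sim.tables:
        path = datadir / f"{t.sample_id}.cov"
        iof.write_bismark_coverage(t, path)
        # paths relative to the manifest's directory keep the artifact set
        # byte-identical wherever it is written
        rows.append({"sample": t.sample_id, "group": sim.groups[t.sample_id], "path": path.name})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(datadir / "samples.tsv", sep="\t", index=False)
    iof.write_gene_annotation_bed(sim.annotation, datadir / "genes.bed")
    sim.truth.regions.to_csv(datadir / "truth_regions.tsv", sep="\t", index=False)
    return manifest


def load_samples_manifest(path: str | Path):
    """Read a samples manifest (sample, group, path) and its coverage files."""
    path = Path(path)
    manifest = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str, "path": str})
    required = {"sample", "group", "path"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}")
    base = path.parent
    tables = [
        iof.read_bismark_coverage(
            p if (p := Path(row.path)).is_absolute() else base / p, row.sample
        )
        for row in manifest.itertuples(index=False)
    ]
    groups = dict(zip(manifest["sample"], manifest["group"]))
    return tables, groups


def _simulate_human_side(sim_cfg: SimulationConfig, mouse_truth, ortholog_map):
    """Two human subtype arrays plus a risk-stratified array, deterministic."""
    arrays = {}
    for i, (subtype, conc) in enumerate(sorted(SUBTYPE_CONCORDANCE.items())):
        cfg = dataclasses.replace(
            sim_cfg, concordance_probability=conc, seed=sim_cfg.seed + 101 + i
        )
        arrays[subtype] = simulate_array(cfg, mouse_truth, ortholog_map)
    risk_cfg = dataclasses.replace(
        sim_cfg,
        concordance_probability=0.9,
        array_n_control=10,  # low-risk group
        array_n_tumour=8,  # high-risk group
        seed=sim_cfg.seed + 201,
    )
    risk = simulate_array(risk_cfg, mouse_truth, ortholog_map)
    risk.groups = {
        s: ("low_risk" if g == "control" else "high_risk") for s, g in risk.groups.items()
    }
    return arrays, risk


def run_all(
    sim_cfg: SimulationConfig,
    pipe_cfg: PipelineConfig,
    outdir: str | Path,
) -> dict:
    """Run the full synthetic study; returns the report dict (also written
    as ``report.json`` along with all stage artifacts)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- simulate and round-trip through the real readers -----------------
    sim = simulate_rrbs(sim_cfg)
    manifest = write_simulated_inputs(sim, outdir)
    tables, groups = load_samples_manifest(outdir / "data" / "samples.tsv")
    annotation = iof.read_gene_annotation_bed(outdir / "data" / "genes.bed")

    # --- mouse side -------------------------------------------------------
    matrix = build_meth_matrix(tables, groups)
    n_loci_raw = matrix.n_loci
    matrix = filter_loci(matrix, pipe_cfg.min_coverage, pipe_cfg.min_meth_reads)

    global_summary = average_methylation(matrix)
    design = ("control", "tumour")
    dm = call_dm_cpgs(matrix, design, fdr_threshold=pipe_cfg.rrbs_fdr)
    dm.table.to_csv(outdir / "dm_cpgs.tsv", sep="\t")
    tumour_mean = matrix.beta[matrix.group_samples("tumour")].mean(axis=1)
    iof.write_signed_bedgraph(dm, tumour_mean, outdir / "dm_cpgs.bedgraph")

    regions = call_dmrs(
        matrix,
        design,
        annotation=annotation,
        min_cpgs=pipe_cfg.dmr_min_cpgs,
        max_span_bp=pipe_cfg.dmr_max_span_bp,
        min_presence=pipe_cfg.dmr_min_presence,
        fdr_threshold=pipe_cfg.dmr_fdr,
        promoter_window_bp=pipe_cfg.promoter_window_bp,
        cpg_p_values=dm.table["p_value"],
    )
    iof.write_dmr_table(regions, outdir / "dmr_table.tsv")

    top = select_top_variance_loci(matrix, pipe_cfg.top_k_loci)
    clust = hierarchical_cluster(top, linkage_method=pipe_cfg.linkage_method)
    (outdir / "dendrogram.nwk").write_text(clust.to_newick() + "\n")
    clust.cut(2).to_csv(outdir / "clusters.tsv", sep="\t")

    # --- orthologs and human side ----------------------------------------
    candidates = simulate_ortholog_candidates(sim.annotation, seed=sim_cfg.seed + 50)
    iof.write_ortholog_candidates(candidates, outdir / "ortholog_candidates.tsv")
    candidates = iof.read_ortholog_candidates(outdir / "ortholog_candidates.tsv")
    omap = resolve_orthologs(candidates)
    omap.pairs.to_csv(outdir / "ortholog_map.tsv", sep="\t", index=False)

    arrays, risk_sim = _simulate_human_side(sim_cfg, sim.truth, omap)

    mouse_assign = xs.annotate_loci_to_genes(dm, annotation, pipe_cfg.promoter_window_bp)
    mouse_summary = xs.summarize_genes(dm, mouse_assign, pipe_cfg.clear_delta)

    human_summaries = {}
    human_dms = {}
    for subtype, arr in arrays.items():
        ds = filter_array_probes(arr.dataset, pipe_cfg.max_detection_p)
        amat = array_to_meth_matrix(ds, arr.groups)
        adm = call_dm_cpgs(amat, ("control", "tumour"), fdr_threshold=pipe_cfg.array_fdr)
        human_dms[subtype] = adm
        assign = pd.DataFrame(
            {
                "chrom": ds.probe_annotation["chrom"].to_numpy(),
                "pos": ds.probe_annotation["pos"].to_numpy(),
                "gene": ds.probe_annotation["gene"].to_numpy(),
            }
        )
        probe_table = adm.table.copy()
        probe_table.insert(0, "pos", ds.probe_annotation["pos"].to_numpy())
        probe_table.insert(0, "chrom", ds.probe_annotation["chrom"].to_numpy())
        probe_table = probe_table.set_index(["chrom", "pos"])
        probe_dm = dataclasses.replace(adm, table=probe_table)
        human_summaries[subtype] = xs.summarize_genes(
            probe_dm, assign, pipe_cfg.clear_delta
        )

    enrich = xs.enrichment_test(mouse_summary, human_summaries, omap)
    direction = xs.direction_concordance(mouse_summary, human_summaries, omap)
    enrich.enrichment.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    direction.direction.to_csv(outdir / "direction_concordance.tsv", sep="\t", index=False)

    major = xs.major_relevance_genes(mouse_summary, human_summaries["stem"], omap)
    major.to_csv(outdir / "major_relevance_genes.tsv", sep="\t", index=False)

    # --- clinical risk concordance ---------------------------------------
    risk_ds = filter_array_probes(risk_sim.dataset, pipe_cfg.max_detection_p)
    risk_mat = array_to_meth_matrix(risk_ds, risk_sim.groups)
    risk_dm = call_dm_cpgs(risk_mat, ("low_risk", "high_risk"), fdr_threshold=pipe_cfg.array_fdr)
    tumour_adm = human_dms["stem"]
    shared_genes = sorted(sim.truth.shared_genes())
    if shared_genes and len(major):
        target_gene = major.iloc[0]["human_gene"]
    elif shared_genes:
        target_gene = shared_genes[0].upper()
    else:
        target_gene = None
    if target_gene is not None:
        stem_annot = filter_array_probes(
            arrays["stem"].dataset, pipe_cfg.max_detection_p
        ).probe_annotation
        gene_probes_tumour = stem_annot.index[stem_annot["gene"] == target_gene]
        gene_probes_risk = risk_ds.probe_annotation.index[
            risk_ds.probe_annotation["gene"] == target_gene
        ]
        gene_loci = gene_probes_tumour.intersection(gene_probes_risk)
        risk_res = xs.risk_concordance(
            risk_dm, tumour_adm, gene_loci, risk_fdr=pipe_cfg.array_fdr,
            clear_threshold=pipe_cfg.clear_delta,
        )
    else:
        risk_res = None

    # --- report -----------------------------------------------------------
    two_group = global_summary.contrasts.iloc[0]
    n_sig_regions = sum(1 for r in regions if r.significant)
    report = {
        "n_loci_raw": int(n_loci_raw),
        "n_loci_filtered": int(matrix.n_loci),
        "mean_beta_control": float(global_summary.group_means["control"]),
        "mean_beta_tumour": float(global_summary.group_means["tumour"]),
        "mean_beta_difference": float(two_group["difference"]),
        "anova_p": float(global_summary.anova_p),
        "n_significant_cpgs": int(dm.n_significant),
        "n_genes_with_dm_cpg": int(len(mouse_summary.genes_with_dm())),
        "n_candidate_regions": int(len(regions)),
        "n_significant_regions": int(n_sig_regions),
        "top_region": (
            {
                "chrom": regions[0].chrom,
                "start": int(regions[0].start),
                "end": int(regions[0].end),
                "width": int(regions[0].width),
                "median_difference": float(regions[0].median_difference),
                "genes": regions[0].gene_symbols,
            }
            if regions
            else None
        ),
        "cluster_leaf_order": clust.leaf_order,
        "n_ortholog_pairs": int(len(omap)),
        "enrichment": enrich.enrichment.to_dict(orient="records"),
        "direction_concordance": direction.direction.to_dict(orient="records"),
        "direction_chi2_p": float(direction.direction_p),
        "n_major_relevance_genes": int(len(major)),
        "risk_concordance": (
            {
                "target_gene": target_gene,
                "n_shared": risk_res.n_shared,
                "n_concordant": risk_res.n_concordant,
                "p_value": risk_res.p_value,
            }
            if risk_res is not None and risk_res.testable
            else None
        ),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
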