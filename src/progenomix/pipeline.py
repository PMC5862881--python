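"""End-to-end orchestration of the analysis stages and summary reports.

``run_full_analysis`` executes the full flow on a cohort bundle —
normalization, replicate QC, differential expression at protein and
mRNA level for both disease comparisons, cross-level overlaps,
copy-number and methylation correlation densities, mutation metrics,
miRNA screens, and (when reads are provided) structural-variant calling
— writing a TSV report set plus a machine-readable run-metadata JSON
recording every threshold and seed used.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from progenomix import breakfast, correlation, de, mirna, mutation
from progenomix.io import (ExpressionMatrix, SampleSheet, copy_number_matrix,
                           dmr_sample_columns)
from progenomix.simulate import SyntheticCohort


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults are the production values."""

    p_adj_threshold: float = 0.05
    fold_threshold: float = 1.5
    negative_rho_threshold: float = -0.50
    dmr_proximal_bp: int = 10_000
    dmr_distal_bp: int = 250_000
    meth_rho_threshold: float = 0.3
    mirna_min_count: int = 8
    min_mapq: int = 20
    max_span: int = 100_000
    anchor_len: int = 25
    max_identity: float = 0.70
    cluster_window: int = 1_000
    blacklist_margin: int = 1_000
    cin_block_bp: int = 500
    n_perm: int = 1_000
    seed: int = 0
    comparisons: tuple = (("PC", "BPH"), ("CRPC", "PC"))


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def _log2_matrix(mat: ExpressionMatrix) -> ExpressionMatrix:
    if mat.scale == "log2":
        return mat
    return dataclasses.replace(mat, values=np.log2(mat.values), scale="log2")


def run_full_analysis(cohort: SyntheticCohort, outdir: str | Path,
                      config: PipelineConfig | None = None,
                      sv_sam: str | Path | None = None,
                      sv_reference: dict[str, str] | None = None) -> dict:
    """Run every stage on a cohort bundle; returns a summary dict and
    writes the report TSVs under ``outdir``."""
    cfg = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    rng = np.random.default_rng(cfg.seed)
    substream = {name: int(s) for name, s in zip(
        ("qc", "mutation"), rng.integers(0, 2 ** 31 - 1, size=2))}

    # --- normalization + QC -------------------------------------------
    _log("normalize", "log2 + quantile normalization of the protein layer")
    protein_norm = de.normalize(cohort.protein)
    qc = de.replicate_icc(protein_norm, cohort.sheet)
    for i, item in enumerate(qc):
        orig, rep = item.pair_id.split("|")
        item.perm_p = de.replicate_permutation_test(
            protein_norm.values[orig].to_numpy(),
            protein_norm.values[rep].to_numpy(),
            n_perm=cfg.n_perm, seed=substream["qc"] + i)
        item.n_perm = cfg.n_perm
    summary["mean_icc"] = de.mean_icc(qc) if qc else float("nan")
    summary["qc_frac_perm_significant"] = (
        float(np.mean([q.perm_p < 0.05 for q in qc])) if qc else float("nan"))
    pd.DataFrame([q.__dict__ for q in qc]).to_csv(
        outdir / "replicate_qc.tsv", sep="\t", index=False)
    protein_avg = de.average_replicates(protein_norm, cohort.sheet)
    mrna_log2 = _log2_matrix(cohort.mrna)

    # --- differential expression --------------------------------------
    de_results: dict[tuple[str, str], dict[str, list[de.DEResult]]] = {}
    for group_a, group_b in cfg.comparisons:
        comp = f"{group_a}_vs_{group_b}"
        _log("de", f"differential expression {comp}")
        res_p = de.differential_expression(
            protein_avg, cohort.sheet, group_a, group_b,
            p_threshold=cfg.p_adj_threshold, fold_threshold=cfg.fold_threshold)
        res_m = de.differential_expression(
            mrna_log2, cohort.sheet, group_a, group_b,
            p_threshold=cfg.p_adj_threshold, fold_threshold=cfg.fold_threshold)
        de_results[(group_a, group_b)] = {"protein": res_p, "mrna": res_m}
        de.de_results_frame(res_p).to_csv(outdir / f"de_protein_{comp}.tsv",
                                          sep="\t")
        de.de_results_frame(res_m).to_csv(outdir / f"de_mrna_{comp}.tsv",
                                          sep="\t")
        summary[f"n_de_protein_{comp}"] = len(de.significant_features(res_p))
        summary[f"n_de_mrna_{comp}"] = len(de.significant_features(res_m))
        overlap = de.de_overlap(res_m, res_p)
        summary[f"de_overlap_{comp}"] = overlap
    comps = list(cfg.comparisons)
    if len(comps) == 2:
        cross = de.de_overlap(
            de_results[tuple(comps[0])]["protein"],
            de_results[tuple(comps[1])]["protein"])
        summary["n_de_protein_common_between_comparisons"] = cross["both"]

    # --- copy-number / methylation correlation densities ---------------
    _log("correlate", "per-sample copy-number correlation densities")
    cn_mat = copy_number_matrix(cohort.copy_number)
    cn_expr = ExpressionMatrix(cn_mat, layer="mrna", scale="linear")
    dens = {}
    for name, expr in (("mrna", mrna_log2), ("protein", protein_avg)):
        d = correlation.correlation_density(cn_expr, expr)
        dens[name] = d
        summary[f"cn_{name}_rho_mean"] = float(np.mean(d.rho))
        summary[f"cn_{name}_density_mode"] = d.mode()
        pd.DataFrame({"grid": d.grid, "pdf": d.pdf}).to_csv(
            outdir / f"cn_{name}_density.tsv", sep="\t", index=False)

    _log("methylation", "DMR-gene linking and methylation screen")
    links = correlation.link_dmrs_to_genes(cohort.dmrs, cohort.tss,
                                           zone="proximal_10kb")
    sig_m = de.significant_features(
        de_results[tuple(comps[0])]["mrna"]) if comps else set()
    sig_p = de.significant_features(
        de_results[tuple(comps[0])]["protein"]) if comps else set()
    meth = correlation.methylation_expression_screen(
        links, cohort.dmrs, mrna_log2, protein_avg,
        de_mrna=sig_m, de_protein=sig_p,
        rho_threshold=cfg.meth_rho_threshold)
    meth.to_csv(outdir / "methylation_screen.tsv", sep="\t", index=False)
    summary["n_meth_links_correlated"] = int(len(meth))
    summary["n_meth_links_de"] = int(
        (meth["de_mrna"] | meth["de_protein"]).sum()) if len(meth) else 0

    # --- mRNA-protein coupling -----------------------------------------
    _log("coupling", "per-gene mRNA-protein correlation")
    coupling = correlation.mrna_protein_coupling(mrna_log2, protein_avg,
                                                 cohort.sheet)
    coupling.to_csv(outdir / "mrna_protein_coupling.tsv", sep="\t")
    for col in coupling.columns:
        summary[f"coupling_mu_{col}"] = float(np.nanmean(coupling[col]))

    # --- mutation metrics ----------------------------------------------
    _log("mutation", "mutation impact and burden metrics")
    impacts = mutation.mutation_impact(mrna_log2, protein_avg,
                                       cohort.mutations)
    contrast = {layer: mutation.somatic_germline_contrast(impacts, layer)
                for layer in ("mrna", "protein")}
    summary["mutation_fisher_p_mrna"] = contrast["mrna"]["p"]
    summary["mutation_fisher_p_protein"] = contrast["protein"]["p"]
    pd.DataFrame([i.__dict__ for i in impacts]).to_csv(
        outdir / "mutation_impact.tsv", sep="\t", index=False)

    # --- miRNA screens ---------------------------------------------------
    _log("mirna", "miRNA filtering, DE and negative-correlation screen")
    expressed = mirna.filter_expressed_mirnas(cohort.mirna,
                                              min_count=cfg.mirna_min_count)
    summary["n_mirnas_expressed"] = len(expressed.feature_ids)
    mirna_log = mirna.log2_cpm(expressed)
    mirna_de_res = mirna.mirna_de(expressed, cohort.sheet, "CRPC", "PC")
    summary["n_mirnas_de"] = len(de.significant_features(mirna_de_res))
    tumour_samples = (cohort.sheet.samples_in_group("PC")
                      + cohort.sheet.samples_in_group("CRPC"))
    targets = mirna.consensus_targets(cohort.mirna_targets)
    pairs = mirna.negative_correlation_screen(
        mirna_log.subset_samples(tumour_samples),
        cohort.mrna and _log2_matrix(cohort.mrna).subset_samples(
            tumour_samples),
        protein_avg.subset_samples(
            [s for s in tumour_samples if s in protein_avg.values.columns]),
        targets, threshold=cfg.negative_rho_threshold,
        de_mrna=de.significant_features(de_results[tuple(comps[-1])]["mrna"]),
        de_protein=de.significant_features(
            de_results[tuple(comps[-1])]["protein"]),
        de_mirna=de.significant_features(mirna_de_res))
    mirna.pairs_frame(pairs).to_csv(outdir / "mirna_pairs.tsv", sep="\t",
                                    index=False)
    levels = mirna.level_comparison(pairs)
    summary["mirna_level_comparison"] = levels

    # --- structural variants --------------------------------------------
    if sv_sam is not None and sv_reference is not None:
        _log("sv", f"structural-variant calling on {sv_sam}")
        calls = breakfast.call_structural_variants(
            sv_sam, sv_reference, min_mapq=cfg.min_mapq,
            max_span=cfg.max_span, anchor_len=cfg.anchor_len,
            window=cfg.cluster_window, max_identity=cfg.max_identity)
        breakfast.calls_frame(calls).to_csv(outdir / "sv_calls.tsv",
                                            sep="\t", index=False)
        summary["n_sv_calls"] = len(calls)

    # --- run metadata ----------------------------------------------------
    meta = {"config": dataclasses.asdict(cfg) | {
        "comparisons": [list(c) for c in cfg.comparisons]},
        "substreams": substream}
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    return summary


# ---------------------------------------------------------------------------
# TCA-style three-class categorization
# ---------------------------------------------------------------------------

def tca_class_report(de_mrna_a: list, de_protein_a: list,
                     de_mrna_b: list, de_protein_b: list,
                     gene_set: list[str]) -> pd.DataFrame:
    """Classify genes by concordance of mRNA and protein regulation
    across two comparisons (e.g. PC vs BPH and CRPC vs PC).

    * class 1 — protein DE with concordant mRNA DE in at least one
      comparison (expression changes go hand in hand);
    * class 2 — protein not DE in either comparison;
    * class 3 — protein DE without matching mRNA DE (same comparison,
      same direction): regulation at the protein level only.

    Genes absent from a layer are reported unclassifiable.
    """
    def _index(res):
        return {r.feature_id: r for r in res}

    layers = [(_index(de_mrna_a), _index(de_protein_a)),
              (_index(de_mrna_b), _index(de_protein_b))]
    rows = []
    for gene in gene_set:
        if any(gene not in m or gene not in p for m, p in layers):
            rows.append({"gene_id": gene, "tca_class": "unclassifiable"})
            continue
        protein_sig = [p[gene].significant for _, p in layers]
        concordant = [
            p[gene].significant and m[gene].significant
            and p[gene].direction == m[gene].direction
            for m, p in layers]
        if not any(protein_sig):
            cls = "2"
        elif any(concordant):
            cls = "1"
        else:
            cls = "3"
        rows.append({"gene_id": gene, "tca_class": cls})
    return pd.DataFrame(rows)
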