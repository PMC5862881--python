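"""miRNA-target consensus prediction, expression filtering, differential
expression of miRNAs, negative-correlation screening at mRNA vs protein
level, and hypergeometric target enrichment.

A gene is a consensus target of a miRNA when at least two of the three
prediction databases agree. miRNAs whose read count stays below 8 in
every sample are treated as unexpressed and excluded. The screen flags
a pair as a hit when the Spearman correlation between miRNA expression
(log2 counts-per-million) and target expression is <= -0.50; comparing
hits at the mRNA vs protein level separates degradation-mode targeting
from translation-only repression, which is invisible in transcriptomes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from progenomix.de import DEResult, differential_expression
from progenomix.io import ExpressionMatrix, SampleSheet

EXPRESSION_MIN_COUNT = 8
NEGATIVE_RHO_THRESHOLD = -0.50


@dataclass
class MirnaTargetPair:
    mirna_id: str
    gene_id: str
    rho_mrna: float
    rho_protein: float
    hit_mrna: bool
    hit_protein: bool
    measured_mrna: bool = True
    measured_protein: bool = True
    target_de_mrna: bool = False
    target_de_protein: bool = False
    mirna_de: bool = False


@dataclass
class EnrichmentResult:
    mirna_id: str
    population_n: int
    targets_k: int
    correlated_n: int
    overlap_k: int
    p_hypergeom: float


# ---------------------------------------------------------------------------
# Target consensus and expression filter
# ---------------------------------------------------------------------------

def consensus_targets(table: pd.DataFrame,
                      min_databases: int = 2) -> set[tuple[str, str]]:
    """(miRNA, gene) pairs predicted by >= ``min_databases`` of the three
    databases."""
    flag_cols = [c for c in table.columns if c.startswith("db_")]
    votes = table[flag_cols].astype(bool).sum(axis=1)
    keep = table.loc[votes >= min_databases]
    return {(str(r["mirna_id"]), str(r["gene_id"]))
            for _, r in keep.iterrows()}


def filter_expressed_mirnas(counts: ExpressionMatrix,
                            min_count: int = EXPRESSION_MIN_COUNT,
                            ) -> ExpressionMatrix:
    """Drop miRNAs whose read count is below ``min_count`` in every
    sample (a single sample at the threshold keeps the miRNA)."""
    if counts.layer != "mirna_counts":
        raise ValueError("expects a mirna_counts layer")
    arr = counts.values.to_numpy()
    if (arr < 0).any():
        raise ValueError("negative counts")
    keep = (arr >= min_count).any(axis=1)
    return replace(counts, values=counts.values.loc[keep])


def log2_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """log2(counts-per-million + 1) normalization of a count matrix."""
    arr = counts.values.to_numpy(dtype=float)
    libsize = arr.sum(axis=0)
    if (libsize <= 0).any():
        raise ValueError("sample with zero total counts")
    cpm = arr / libsize * 1e6
    values = pd.DataFrame(np.log2(cpm + 1), index=counts.values.index,
                          columns=counts.values.columns)
    return ExpressionMatrix(values, layer="mrna", scale="log2")


def mirna_de(counts: ExpressionMatrix, sheet: SampleSheet,
             group_a: str, group_b: str) -> list[DEResult]:
    """Differential expression of miRNAs: log2-CPM then the standard
    Wilcoxon/Benjamini-Hochberg DE with the median-ratio filter."""
    return differential_expression(log2_cpm(counts), sheet, group_a, group_b)


# ---------------------------------------------------------------------------
# Negative-correlation screen
# ---------------------------------------------------------------------------

def negative_correlation_screen(mirna_expr: ExpressionMatrix,
                                mrna_expr: ExpressionMatrix | None,
                                protein_expr: ExpressionMatrix | None,
                                pairs: set[tuple[str, str]],
                                threshold: float = NEGATIVE_RHO_THRESHOLD,
                                de_mrna: set[str] | None = None,
                                de_protein: set[str] | None = None,
                                de_mirna: set[str] | None = None,
                                ) -> list[MirnaTargetPair]:
    """Spearman correlation between each predicted miRNA-target pair at
    each available target layer; hits are pairs with rho <= threshold
    (inclusive). Targets unmeasured in a layer are flagged, not dropped.
    """
    de_mrna = de_mrna or set()
    de_protein = de_protein or set()
    de_mirna = de_mirna or set()
    out: list[MirnaTargetPair] = []
    for mirna, gene in sorted(pairs):
        if mirna not in mirna_expr.values.index:
            continue
        rhos = {}
        measured = {}
        for layer, expr in (("mrna", mrna_expr), ("protein", protein_expr)):
            rho = float("nan")
            ok = expr is not None and gene in expr.values.index
            if ok:
                shared = [s for s in mirna_expr.sample_ids
                          if s in expr.values.columns]
                if len(shared) >= 3:
                    x = mirna_expr.values.loc[mirna, shared].to_numpy(float)
                    y = expr.values.loc[gene, shared].to_numpy(float)
                    if np.ptp(x) > 0 and np.ptp(y) > 0:
                        rho = float(stats.spearmanr(x, y).statistic)
            rhos[layer] = rho
            measured[layer] = bool(ok)
        out.append(MirnaTargetPair(
            mirna_id=mirna, gene_id=gene,
            rho_mrna=rhos["mrna"], rho_protein=rhos["protein"],
            hit_mrna=bool(np.isfinite(rhos["mrna"])
                          and rhos["mrna"] <= threshold + 1e-12),
            hit_protein=bool(np.isfinite(rhos["protein"])
                             and rhos["protein"] <= threshold + 1e-12),
            measured_mrna=measured["mrna"],
            measured_protein=measured["protein"],
            target_de_mrna=gene in de_mrna,
            target_de_protein=gene in de_protein,
            mirna_de=mirna in de_mirna,
        ))
    return out


def pairs_frame(pairs: list[MirnaTargetPair]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in pairs])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def hypergeom_upper_tail(population_n: int, targets_k: int,
                         draws_n: int, overlap_k: int) -> float:
    """P(X >= overlap_k) for X ~ Hypergeom(N, K, n)."""
    return float(stats.hypergeom.sf(overlap_k - 1, population_n,
                                    targets_k, draws_n))


def correlated_genes_by_mirna(mirna_expr: ExpressionMatrix,
                              target_expr: ExpressionMatrix,
                              universe: set[str],
                              threshold: float = NEGATIVE_RHO_THRESHOLD,
                              ) -> dict[str, set[str]]:
    """For each miRNA, the universe genes whose expression at this layer
    correlates with the miRNA at rho <= threshold (the population-level
    'negatively correlating' set of the enrichment test)."""
    genes = [g for g in universe if g in target_expr.values.index]
    shared = [s for s in mirna_expr.sample_ids
              if s in target_expr.values.columns]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    ranks_t = target_expr.values.loc[genes, shared].rank(axis=1)
    out: dict[str, set[str]] = {}
    for mirna in mirna_expr.values.index:
        x = mirna_expr.values.loc[mirna, shared].to_numpy(float)
        if np.ptp(x) == 0:
            out[str(mirna)] = set()
            continue
        rx = stats.rankdata(x)
        rx = (rx - rx.mean()) / rx.std()
        rt = ranks_t.to_numpy(float)
        rt_sd = rt.std(axis=1)
        ok = rt_sd > 0
        rho = np.full(len(genes), np.nan)
        centered = (rt[ok] - rt[ok].mean(axis=1, keepdims=True)) / \
            rt_sd[ok][:, None]
        rho[ok] = centered @ rx / len(shared)
        out[str(mirna)] = {genes[i] for i in range(len(genes))
                           if np.isfinite(rho[i])
                           and rho[i] <= threshold + 1e-12}
    return out


def enrichment(pairs: list[MirnaTargetPair],
               universe: set[str],
               layer: str = "protein",
               correlated_by_mirna: dict[str, set[str]] | None = None,
               ) -> list[EnrichmentResult]:
    """Per-miRNA hypergeometric enrichment of negatively correlating
    genes among its predicted targets.

    With N = measured genes in the prediction universe, K = the miRNA's
    consensus targets among them, n = universe genes negatively
    correlating with the miRNA, and k = their overlap, the p-value is
    the upper tail P(X >= k). When the universe-wide correlated sets are
    not supplied, the screen's own hits stand in for them (n = k), the
    most conservative population choice.
    """
    if not universe:
        raise ValueError("empty population universe")
    hit_attr = f"hit_{layer}"
    measured_attr = f"measured_{layer}"
    by_mirna: dict[str, list[MirnaTargetPair]] = {}
    for p in pairs:
        by_mirna.setdefault(p.mirna_id, []).append(p)
    results = []
    for mirna, plist in sorted(by_mirna.items()):
        measured = [p for p in plist if getattr(p, measured_attr)
                    and p.gene_id in universe]
        population_n = len(universe)
        targets_k = len({p.gene_id for p in measured})
        hits = {p.gene_id for p in measured if getattr(p, hit_attr)}
        if correlated_by_mirna is not None:
            correlated = correlated_by_mirna.get(mirna, set()) & universe
            overlap_k = len(correlated & {p.gene_id for p in measured})
        else:
            correlated = hits
            overlap_k = len(hits)
        correlated_n = len(correlated)
        p_val = hypergeom_upper_tail(population_n, targets_k,
                                     correlated_n, overlap_k)
        results.append(EnrichmentResult(
            mirna_id=mirna, population_n=population_n, targets_k=targets_k,
            correlated_n=correlated_n, overlap_k=overlap_k,
            p_hypergeom=p_val))
    return results


def enrichment_from_counts(mirna_id: str, population_n: int, targets_k: int,
                           correlated_n: int, overlap_k: int,
                           ) -> EnrichmentResult:
    """Hypergeometric enrichment from explicit counts (population size,
    predicted targets among it, negatively-correlating genes among it,
    and their overlap)."""
    if population_n <= 0:
        raise ValueError("empty population")
    if overlap_k > min(targets_k, correlated_n):
        raise ValueError("overlap exceeds its margins")
    return EnrichmentResult(
        mirna_id=mirna_id, population_n=population_n, targets_k=targets_k,
        correlated_n=correlated_n, overlap_k=overlap_k,
        p_hypergeom=hypergeom_upper_tail(population_n, targets_k,
                                         correlated_n, overlap_k))


# ---------------------------------------------------------------------------
# mRNA vs protein level comparison
# ---------------------------------------------------------------------------

def level_comparison(pairs: list[MirnaTargetPair]) -> dict:
    """Collapse hit pairs to genes and compare the mRNA-level and
    protein-level hit sets (Venn counts) plus the fraction of hit genes
    that are differentially expressed at each level."""
    genes_mrna = {p.gene_id for p in pairs if p.hit_mrna}
    genes_protein = {p.gene_id for p in pairs if p.hit_protein}
    both = genes_mrna & genes_protein
    de_m = {p.gene_id for p in pairs if p.target_de_mrna}
    de_p = {p.gene_id for p in pairs if p.target_de_protein}
    return {
        "mrna_only": len(genes_mrna - genes_protein),
        "protein_only": len(genes_protein - genes_mrna),
        "both": len(both),
        "n_genes_mrna": len(genes_mrna),
        "n_genes_protein": len(genes_protein),
        "de_fraction_mrna": (len(genes_mrna & de_m) / len(genes_mrna)
                             if genes_mrna else float("nan")),
        "de_fraction_protein": (len(genes_protein & de_p) / len(genes_protein)
                                if genes_protein else float("nan")),
    }
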