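"""Point-mutation impact on expression, mutation-burden metrics and the
burden-protein correlation screen.

Mutation impact is operationalized as an expression z-score of the
mutated sample against the unmutated samples of the same gene, with an
|z| > 2 outlier rule and a 2x2 Fisher contrast of somatic vs germline
outlier rates. The chromosomal-instability score (CIN) of a sample is
the mean integer copy number over non-overlapping 500 bp blocks tiling
the genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from progenomix.io import ExpressionMatrix

CIN_BLOCK_BP = 500


@dataclass
class MutationImpact:
    gene_id: str
    sample_id: str
    origin: str                      # somatic | germline
    z_mrna: float
    z_protein: float
    outlier_mrna: bool
    outlier_protein: bool


# ---------------------------------------------------------------------------
# Mutation impact
# ---------------------------------------------------------------------------

def _zscore(value: float, others: np.ndarray) -> float:
    sd = float(np.std(others, ddof=1))
    if sd == 0:
        return float("nan")
    return float((value - float(np.mean(others))) / sd)


def mutation_impact(expr_mrna: ExpressionMatrix | None,
                    expr_protein: ExpressionMatrix | None,
                    mutations: pd.DataFrame,
                    z_threshold: float = 2.0) -> list[MutationImpact]:
    """Expression z-score of each mutated (gene, sample) against the
    unmutated samples of that gene, at mRNA and/or protein level.

    Genes mutated in all samples (no null reference) or with fewer than
    3 unmutated samples are skipped.
    """
    impacts: list[MutationImpact] = []
    mutated_by_gene = mutations.groupby("gene_id")["sample_id"].apply(set)
    for _, row in mutations.iterrows():
        gene, sample, origin = row["gene_id"], row["sample_id"], row["origin"]
        zs = {}
        for layer, expr in (("mrna", expr_mrna), ("protein", expr_protein)):
            z = float("nan")
            if expr is not None and gene in expr.values.index \
                    and sample in expr.values.columns:
                mutated = mutated_by_gene[gene]
                unmut = [s for s in expr.values.columns if s not in mutated]
                if len(unmut) >= 3:
                    z = _zscore(float(expr.values.at[gene, sample]),
                                expr.values.loc[gene, unmut].to_numpy(float))
            zs[layer] = z
        if np.isnan(zs["mrna"]) and np.isnan(zs["protein"]):
            continue
        impacts.append(MutationImpact(
            gene_id=str(gene), sample_id=str(sample), origin=str(origin),
            z_mrna=zs["mrna"], z_protein=zs["protein"],
            outlier_mrna=bool(abs(zs["mrna"]) > z_threshold)
            if np.isfinite(zs["mrna"]) else False,
            outlier_protein=bool(abs(zs["protein"]) > z_threshold)
            if np.isfinite(zs["protein"]) else False,
        ))
    return impacts


def somatic_germline_contrast(impacts: list[MutationImpact],
                              layer: str = "mrna") -> dict:
    """Fisher's exact test on the 2x2 table origin x expression-outlier."""
    attr = f"outlier_{layer}"
    zattr = f"z_{layer}"
    table = np.zeros((2, 2), dtype=int)
    for imp in impacts:
        if not np.isfinite(getattr(imp, zattr)):
            continue
        i = 0 if imp.origin == "somatic" else 1
        j = 0 if getattr(imp, attr) else 1
        table[i, j] += 1
    if table.sum() == 0:
        return {"table": table, "p": float("nan")}
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {"table": table, "p": p}


def null_impact_zscores(expr: ExpressionMatrix, genes: list[str],
                        n_draws: int, seed: int = 0) -> np.ndarray:
    """Null z-score distribution from pseudo-mutations: for each draw a
    random gene and a random sample are treated as mutated and compared
    against the remaining samples."""
    rng = np.random.default_rng(seed)
    cols = list(expr.values.columns)
    out = []
    genes = [g for g in genes if g in expr.values.index]
    if not genes or len(cols) < 4:
        raise ValueError("need measurable genes and >= 4 samples")
    for _ in range(n_draws):
        gene = genes[rng.integers(len(genes))]
        k = int(rng.integers(len(cols)))
        sample = cols[k]
        others = [c for c in cols if c != sample]
        z = _zscore(float(expr.values.at[gene, sample]),
                    expr.values.loc[gene, others].to_numpy(float))
        if np.isfinite(z):
            out.append(z)
    return np.array(out)


# ---------------------------------------------------------------------------
# Chromosomal instability
# ---------------------------------------------------------------------------

def compute_cin(segments: pd.DataFrame, genome_size: int,
                block_bp: int = CIN_BLOCK_BP) -> float:
    """Mean integer copy number over non-overlapping ``block_bp`` blocks.

    ``segments`` has columns start, end (0-based half-open) and
    integer_cn covering (part of) a genome of ``genome_size`` bp. Each
    block takes the copy number of the segment covering its midpoint;
    blocks whose midpoint falls in a gap are excluded from the mean.
    Overlapping segments with conflicting calls are an error.
    """
    seg = segments.sort_values("start").reset_index(drop=True)
    prev_end = -1
    prev_cn = None
    for _, row in seg.iterrows():
        if row["start"] < prev_end and row["integer_cn"] != prev_cn:
            raise ValueError("overlapping segments with conflicting calls")
        prev_end = max(prev_end, int(row["end"]))
        prev_cn = row["integer_cn"]
    starts = seg["start"].to_numpy(int)
    ends = seg["end"].to_numpy(int)
    cns = seg["integer_cn"].to_numpy(float)
    n_blocks = int(np.ceil(genome_size / block_bp))
    block_starts = np.arange(n_blocks) * block_bp
    block_ends = np.minimum(block_starts + block_bp, genome_size)
    midpoints = (block_starts + block_ends) // 2
    # midpoint-in-segment lookup
    idx = np.searchsorted(starts, midpoints, side="right") - 1
    valid = (idx >= 0) & (midpoints < ends[np.clip(idx, 0, None)])
    assigned = cns[idx[valid]]
    if len(assigned) == 0:
        raise ValueError("no block midpoint covered by any segment")
    return float(np.mean(assigned))


def burden_profiles(point_mutations: pd.DataFrame,
                    rearrangement_counts: pd.Series,
                    cn_segments_by_sample: dict[str, pd.DataFrame],
                    genome_size: int,
                    block_bp: int = CIN_BLOCK_BP) -> pd.DataFrame:
    """Per-sample burden table: somatic point-mutation count,
    rearrangement count, and CIN."""
    samples = sorted(set(point_mutations["sample_id"])
                     | set(rearrangement_counts.index)
                     | set(cn_segments_by_sample))
    somatic = point_mutations[point_mutations["origin"] == "somatic"]
    counts = somatic.groupby("sample_id").size()
    rows = []
    for s in samples:
        cin = float("nan")
        if s in cn_segments_by_sample:
            cin = compute_cin(cn_segments_by_sample[s], genome_size, block_bp)
        rows.append({
            "sample_id": s,
            "n_point_mutations": int(counts.get(s, 0)),
            "n_rearrangements": int(rearrangement_counts.get(s, 0)),
            "cin": cin,
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Burden-protein screen
# ---------------------------------------------------------------------------

def burden_protein_screen(protein: ExpressionMatrix,
                          burdens: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each protein with each burden metric
    across samples, ranked by |rho| within metric.

    Metrics that are constant across samples are skipped. Returns a
    frame with columns feature_id, metric, rho, abs_rank (1 = strongest).
    """
    samples = [s for s in protein.sample_ids if s in burdens.index]
    if len(samples) < 5:
        raise ValueError("need >= 5 samples with burden and protein data")
    rows = []
    expr = protein.values[samples]
    for metric in burdens.columns:
        vec = burdens.loc[samples, metric].to_numpy(float)
        if not np.isfinite(vec).all() or np.ptp(vec) == 0:
            continue
        for gene in expr.index:
            x = expr.loc[gene].to_numpy(float)
            if np.ptp(x) == 0:
                continue
            rho = float(stats.spearmanr(x, vec).statistic)
            rows.append({"feature_id": str(gene), "metric": metric,
                         "rho": rho})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["abs_rank"] = out.groupby("metric")["rho"].transform(
        lambda r: r.abs().rank(ascending=False, method="min").astype(int))
    return out.sort_values(["metric", "abs_rank"]).reset_index(drop=True)
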