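"""Proteome QC and differential expression.

The processing chain mirrors a SWATH-MS quantification workflow:
log2 transform and quantile normalization, technical-replicate agreement
(intraclass correlation and a Spearman permutation test), averaging of
replicate MS runs, then per-feature two-sided Wilcoxon rank-sum tests
with Benjamini-Hochberg adjustment. A feature is significant when the
adjusted p-value is below 0.05 and the fold change (ratio of group
medians, taken two-sidedly) exceeds 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from progenomix.io import ExpressionMatrix, SampleSheet

P_ADJ_THRESHOLD = 0.05
FOLD_THRESHOLD = 1.5


@dataclass
class DEResult:
    feature_id: str
    median_ratio: float      # linear-scale group-A / group-B median ratio
    p_raw: float
    p_adj: float
    direction: str           # "up" if A > B else "down"
    significant: bool


@dataclass
class ReplicateQC:
    pair_id: str
    icc: float
    perm_p: float
    n_perm: int


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Bolstad-style quantile normalization: every column receives the
    mean-of-sorted-columns reference distribution; ties within a column
    get the average of the reference values they span."""
    arr = df.to_numpy(dtype=float)
    order = np.sort(arr, axis=0)
    reference = order.mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        ranks = stats.rankdata(arr[:, j], method="average")  # 1-based, ties avg
        out[:, j] = np.interp(ranks, np.arange(1, arr.shape[0] + 1), reference)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform then quantile-normalize a linear-scale matrix."""
    if matrix.scale != "linear":
        raise ValueError("normalize expects a linear-scale matrix")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        bad = matrix.values.index[(arr <= 0).any(axis=1)].tolist()
        raise ValueError(f"non-positive values, cannot log2: {bad[:5]}")
    logged = np.log2(matrix.values)
    return replace(matrix, values=quantile_normalize(logged), scale="log2")


# ---------------------------------------------------------------------------
# Replicate QC
# ---------------------------------------------------------------------------

def icc_oneway(x: np.ndarray, y: np.ndarray) -> float:
    """One-way random-effects, single-measure ICC(1,1) for paired runs.

    Each feature is a subject measured twice (original and replicate run).
    ICC = (MSB - MSW) / (MSB + (k-1) MSW) with k = 2.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired vectors required")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 features")
    data = np.stack([x, y], axis=1)     # n subjects x k=2 measurements
    k = 2
    subj_means = data.mean(axis=1)
    grand = data.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((data - subj_means[:, None]) ** 2) / (n * (k - 1))
    return float((msb - msw) / (msb + (k - 1) * msw))


def replicate_icc(matrix: ExpressionMatrix, sheet: SampleSheet) -> list[ReplicateQC]:
    """ICC(1,1) over all features for each technical replicate pair.

    The permutation p-value slot is left NaN; use
    :func:`replicate_permutation_test` to fill it.
    """
    out = []
    for original, rep in sheet.replicate_pairs():
        icc = icc_oneway(matrix.values[original].to_numpy(),
                         matrix.values[rep].to_numpy())
        out.append(ReplicateQC(pair_id=f"{original}|{rep}", icc=icc,
                               perm_p=float("nan"), n_perm=0))
    return out


def mean_icc(qc: list[ReplicateQC]) -> float:
    return float(np.mean([q.icc for q in qc]))


def replicate_permutation_test(x: np.ndarray, y: np.ndarray,
                               n_perm: int = 1000, seed: int = 0) -> float:
    """Permutation p-value for the Spearman correlation of two runs.

    One vector is permuted ``n_perm`` times; the add-one estimator
    p = (1 + #{rho_perm >= rho_obs}) / (1 + n_perm) avoids p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need equal-length vectors with >= 5 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(ry)
        if np.corrcoef(rx, perm)[0, 1] >= obs:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def average_replicates(matrix: ExpressionMatrix,
                       sheet: SampleSheet) -> ExpressionMatrix:
    """Collapse each technical replicate pair to the mean of the two runs
    (on the current scale); samples without replicates pass through."""
    df = matrix.values.copy()
    for original, rep in sheet.replicate_pairs():
        if original in df.columns and rep in df.columns:
            df[original] = (df[original] + df[rep]) / 2.0
            df = df.drop(columns=[rep])
    return replace(matrix, values=df)


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact null when the combined sample is small (n <= 30) and tie-free;
    otherwise the normal approximation with tie and continuity correction.
    An all-constant feature carries no information and is assigned p = 1.
    """
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 30 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def differential_expression(matrix: ExpressionMatrix, sheet: SampleSheet,
                            group_a: str, group_b: str,
                            p_threshold: float = P_ADJ_THRESHOLD,
                            fold_threshold: float = FOLD_THRESHOLD,
                            ) -> list[DEResult]:
    """Per-feature Wilcoxon rank-sum DE between two disease groups.

    The matrix must be on log2 scale; median ratios are reported on the
    linear scale as ``2 ** (median_A - median_B)``. Significance requires
    BH-adjusted p < ``p_threshold`` and max(r, 1/r) > ``fold_threshold``.
    """
    if matrix.scale != "log2":
        raise ValueError("differential_expression expects log2-scale data")
    samples_a = [s for s in sheet.samples_in_group(group_a)
                 if s in matrix.values.columns]
    samples_b = [s for s in sheet.samples_in_group(group_b)
                 if s in matrix.values.columns]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs at least 2 samples in the matrix")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    p_raw = np.array([_wilcoxon_p(a[i], b[i]) for i in range(a.shape[0])])
    p_adj = multipletests(p_raw, method="fdr_bh")[1]
    med_a = np.median(a, axis=1)
    med_b = np.median(b, axis=1)
    ratio = np.exp2(med_a - med_b)
    out = []
    for i, fid in enumerate(matrix.values.index):
        r = float(ratio[i])
        fold = max(r, 1.0 / r) if r > 0 else np.inf
        out.append(DEResult(
            feature_id=str(fid),
            median_ratio=r,
            p_raw=float(p_raw[i]),
            p_adj=float(p_adj[i]),
            direction="up" if r > 1 else "down",
            significant=bool(p_adj[i] < p_threshold and fold > fold_threshold),
        ))
    return out


def de_results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results]).set_index("feature_id")


def significant_features(results: list[DEResult]) -> set[str]:
    return {r.feature_id for r in results if r.significant}


def de_overlap(de_a: list[DEResult], de_b: list[DEResult]) -> dict:
    """Venn counts of the significant sets of two DE analyses over the
    same feature universe, plus the direction concordance of the shared
    significant features (NaN when the intersection is empty)."""
    universe_a = {r.feature_id for r in de_a}
    universe_b = {r.feature_id for r in de_b}
    if not (universe_a & universe_b):
        raise ValueError("DE results have disjoint feature universes")
    sig_a = significant_features(de_a)
    sig_b = significant_features(de_b)
    both = sig_a & sig_b
    dir_a = {r.feature_id: r.direction for r in de_a}
    dir_b = {r.feature_id: r.direction for r in de_b}
    if both:
        concordance = sum(dir_a[f] == dir_b[f] for f in both) / len(both)
    else:
        concordance = float("nan")
    return {
        "only_a": len(sig_a - sig_b),
        "only_b": len(sig_b - sig_a),
        "both": len(both),
        "direction_concordance": concordance,
    }
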