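"""Per-sample correlation of expression layers, kernel-density summaries
and the DMR-methylation / expression screens.

The central object is a vector of per-sample Spearman correlations
(e.g. copy number vs mRNA across genes, computed within each sample)
summarized by a Gaussian kernel density estimate with Scott's-rule
bandwidth, together with a background null built from all cross-sample
pairings. A right-shifted mRNA density relative to the protein density
is the signature of genomic dosage effects that do not propagate to the
proteome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from progenomix.io import ExpressionMatrix, SampleSheet, dmr_sample_columns


@dataclass
class CorrelationDensity:
    sample_ids: list[str]
    rho: np.ndarray                  # per-sample Spearman values (finite only)
    grid: np.ndarray
    pdf: np.ndarray
    bandwidth: float
    background_rho: np.ndarray | None = None
    background_pdf: np.ndarray | None = None

    def mode(self) -> float:
        """Grid point of maximal density."""
        return float(self.grid[int(np.argmax(self.pdf))])


@dataclass
class DmrGeneLink:
    dmr_id: str
    gene_id: str
    distance: int                    # bp from interval to TSS; 0 if inside
    zone: str                        # proximal_10kb | within_250kb
    rho_mrna: float = float("nan")
    rho_protein: float = float("nan")


PROXIMAL_BP = 10_000
DISTAL_BP = 250_000


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.spearmanr(x, y).statistic)


# ---------------------------------------------------------------------------
# Per-sample correlations and densities
# ---------------------------------------------------------------------------

def per_sample_correlation(expr_a: ExpressionMatrix,
                           expr_b: ExpressionMatrix) -> pd.Series:
    """Spearman rho across shared genes, computed within each shared
    sample, between two layers (e.g. copy number vs protein).

    Samples where either layer is constant across genes yield NaN with a
    warning (undefined correlation), and are excluded from densities.
    """
    genes = [g for g in expr_a.feature_ids if g in set(expr_b.feature_ids)]
    samples = [s for s in expr_a.sample_ids if s in set(expr_b.sample_ids)]
    if len(genes) < 10:
        raise ValueError("need at least 10 shared genes")
    if not samples:
        raise ValueError("no shared samples")
    a = expr_a.values.loc[genes, samples]
    b = expr_b.values.loc[genes, samples]
    rho = {}
    for s in samples:
        r = _spearman(a[s].to_numpy(float), b[s].to_numpy(float))
        if np.isnan(r):
            warnings.warn(f"sample {s}: constant layer, rho undefined")
        rho[s] = r
    return pd.Series(rho, name="rho")


def scott_bandwidth(values: np.ndarray) -> float:
    """Scott's rule for d = 1: h = sd(x) * n^(-1/5) (sample sd, ddof=1)."""
    values = np.asarray(values, dtype=float)
    sd = float(np.std(values, ddof=1))
    return sd * len(values) ** (-1 / 5)


def gaussian_kde_curve(values: np.ndarray, grid: np.ndarray,
                       bandwidth: float) -> np.ndarray:
    """Gaussian-kernel density of ``values`` evaluated on ``grid``."""
    values = np.asarray(values, dtype=float)
    z = (grid[:, None] - values[None, :]) / bandwidth
    return np.exp(-0.5 * z ** 2).sum(axis=1) / (
        len(values) * bandwidth * np.sqrt(2 * np.pi))


def estimate_pdf(rho: np.ndarray, grid_size: int = 512,
                 sample_ids: list[str] | None = None,
                 background_rho: np.ndarray | None = None,
                 ) -> CorrelationDensity:
    """Gaussian KDE with Scott's-rule bandwidth on an equispaced grid
    spanning [min - 3h, max + 3h]."""
    rho = np.asarray(rho, dtype=float)
    rho = rho[np.isfinite(rho)]
    if len(rho) < 2 or np.ptp(rho) == 0:
        raise ValueError("need >= 2 distinct finite correlations "
                         "(degenerate input)")
    h = scott_bandwidth(rho)
    grid = np.linspace(rho.min() - 3 * h, rho.max() + 3 * h, grid_size)
    pdf = gaussian_kde_curve(rho, grid, h)
    bg_pdf = None
    bg = None
    if background_rho is not None:
        bg = np.asarray(background_rho, dtype=float)
        bg = bg[np.isfinite(bg)]
        if len(bg) >= 2 and np.ptp(bg) > 0:
            bg_pdf = gaussian_kde_curve(bg, grid, scott_bandwidth(bg))
    return CorrelationDensity(
        sample_ids=sample_ids or [], rho=rho, grid=grid, pdf=pdf,
        bandwidth=h, background_rho=bg, background_pdf=bg_pdf)


def background_distribution(expr_a: ExpressionMatrix,
                            expr_b: ExpressionMatrix) -> np.ndarray:
    """Null correlations from mismatched samples: for every ordered pair
    (i, j), i != j, the Spearman rho of layer A in sample i against layer
    B in sample j, pooled into one vector of up to n(n-1) values."""
    genes = [g for g in expr_a.feature_ids if g in set(expr_b.feature_ids)]
    samples = [s for s in expr_a.sample_ids if s in set(expr_b.sample_ids)]
    if len(samples) < 3:
        raise ValueError("background needs >= 3 shared samples")
    a = expr_a.values.loc[genes, samples].to_numpy(float)
    b = expr_b.values.loc[genes, samples].to_numpy(float)
    # rank once per sample, then correlate rank vectors pairwise
    ra = np.apply_along_axis(stats.rankdata, 0, a)
    rb = np.apply_along_axis(stats.rankdata, 0, b)
    out = []
    for i in range(len(samples)):
        for j in range(len(samples)):
            if i == j:
                continue
            if np.ptp(a[:, i]) == 0 or np.ptp(b[:, j]) == 0:
                continue
            out.append(float(np.corrcoef(ra[:, i], rb[:, j])[0, 1]))
    return np.array(out)


def correlation_density(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix,
                        grid_size: int = 512,
                        with_background: bool = True) -> CorrelationDensity:
    """Convenience wrapper: per-sample correlations + KDE + background."""
    rho = per_sample_correlation(expr_a, expr_b)
    bg = background_distribution(expr_a, expr_b) if with_background else None
    return estimate_pdf(rho.to_numpy(), grid_size=grid_size,
                        sample_ids=list(rho.index), background_rho=bg)


# ---------------------------------------------------------------------------
# DMR-gene linking and methylation screen
# ---------------------------------------------------------------------------

def tss_position(row: pd.Series) -> int:
    """TSS coordinate of a gene: interval start for '+' strand genes,
    last base (end - 1) for '-' strand genes when given as start/end,
    or the explicit 'position' column when present."""
    return int(row["position"])


def interval_point_distance(start: int, end: int, point: int) -> int:
    """Minimal distance from 0-based half-open [start, end) to a point;
    0 when the point lies inside the interval."""
    if start <= point < end:
        return 0
    return min(abs(point - start), abs(point - (end - 1)))


def link_dmrs_to_genes(dmrs: pd.DataFrame, tss: pd.DataFrame,
                       zone: str = "proximal_10kb") -> list[DmrGeneLink]:
    """Assign DMRs to genes by TSS distance on the same chromosome.

    ``proximal_10kb`` keeps links with distance <= 10 kb (inclusive, per
    the 'within 10 kb' rule); ``within_250kb`` keeps distance < 250 kb.
    Unknown chromosomes on either side skip the pair with a warning.
    """
    if zone not in ("proximal_10kb", "within_250kb"):
        raise ValueError(f"unknown zone {zone!r}")
    known_chroms = set(dmrs["chrom"]) | set(tss["chrom"])
    links: list[DmrGeneLink] = []
    tss_by_chrom = dict(tuple(tss.groupby("chrom")))
    for _, d in dmrs.iterrows():
        if d["chrom"] not in tss_by_chrom:
            warnings.warn(f"DMR {d['dmr_id']}: no TSS on chrom {d['chrom']}")
            continue
        for _, g in tss_by_chrom[d["chrom"]].iterrows():
            dist = interval_point_distance(int(d["start"]), int(d["end"]),
                                           tss_position(g))
            if zone == "proximal_10kb" and dist <= PROXIMAL_BP:
                links.append(DmrGeneLink(str(d["dmr_id"]), str(g["gene_id"]),
                                         dist, zone))
            elif zone == "within_250kb" and dist < DISTAL_BP:
                links.append(DmrGeneLink(str(d["dmr_id"]), str(g["gene_id"]),
                                         dist, zone))
    return links


def methylation_expression_screen(links: list[DmrGeneLink],
                                  dmrs: pd.DataFrame,
                                  expr_mrna: ExpressionMatrix,
                                  expr_protein: ExpressionMatrix,
                                  de_mrna: set[str] | None = None,
                                  de_protein: set[str] | None = None,
                                  rho_threshold: float = 0.3) -> pd.DataFrame:
    """Correlate DMR fragment counts with target-gene expression.

    For each DMR-gene link, the Spearman correlation across shared
    samples between the DMR's normalized fragment counts and the gene's
    mRNA and protein expression is computed; links with |rho| above the
    threshold at either level are retained and annotated with the gene's
    differential-expression status.
    """
    sample_cols = dmr_sample_columns(dmrs)
    dmr_rows = dmrs.set_index("dmr_id")
    de_mrna = de_mrna or set()
    de_protein = de_protein or set()
    records = []
    for link in links:
        counts = dmr_rows.loc[link.dmr_id, sample_cols].astype(float)
        for expr, attr in ((expr_mrna, "rho_mrna"),
                           (expr_protein, "rho_protein")):
            if link.gene_id not in expr.values.index:
                continue
            shared = [s for s in sample_cols if s in expr.values.columns]
            if len(shared) != len(sample_cols):
                missing = set(sample_cols) - set(shared)
                raise ValueError(f"DMR samples missing from expression "
                                 f"matrix: {sorted(missing)}")
            rho = _spearman(counts[shared].to_numpy(float),
                            expr.values.loc[link.gene_id, shared]
                            .to_numpy(float))
            setattr(link, attr, rho)
        best = np.nanmax([abs(link.rho_mrna), abs(link.rho_protein)])
        if np.isnan(best) or best <= rho_threshold:
            continue
        records.append({
            "dmr_id": link.dmr_id, "gene_id": link.gene_id,
            "distance": link.distance, "zone": link.zone,
            "rho_mrna": link.rho_mrna, "rho_protein": link.rho_protein,
            "de_mrna": link.gene_id in de_mrna,
            "de_protein": link.gene_id in de_protein,
        })
    cols = ["dmr_id", "gene_id", "distance", "zone", "rho_mrna",
            "rho_protein", "de_mrna", "de_protein"]
    return pd.DataFrame(records, columns=cols)


# ---------------------------------------------------------------------------
# mRNA-protein coupling
# ---------------------------------------------------------------------------

def mrna_protein_coupling(expr_mrna: ExpressionMatrix,
                          expr_protein: ExpressionMatrix,
                          sheet: SampleSheet | None = None) -> pd.DataFrame:
    """Per-gene Spearman correlation between mRNA and protein expression
    across samples, overall and within each disease group.

    Returns a genes x columns frame with an ``all`` column and one
    column per group with >= 3 samples; the mean of each column is the
    coupling summary mu reported for the cohort.
    """
    genes = [g for g in expr_protein.feature_ids
             if g in set(expr_mrna.feature_ids)]
    samples = [s for s in expr_protein.sample_ids
               if s in set(expr_mrna.sample_ids)]
    if len(genes) == 0 or len(samples) < 3:
        raise ValueError("need shared genes and >= 3 shared samples")
    m = expr_mrna.values.loc[genes, samples].to_numpy(float)
    p = expr_protein.values.loc[genes, samples].to_numpy(float)

    def _per_gene(cols: list[int]) -> np.ndarray:
        return np.array([_spearman(m[i, cols], p[i, cols])
                         for i in range(len(genes))])

    data = {"all": _per_gene(list(range(len(samples))))}
    if sheet is not None:
        for group in ("BPH", "PC", "CRPC"):
            members = [samples.index(s) for s in sheet.samples_in_group(group)
                       if s in samples]
            if len(members) < 3:
                warnings.warn(f"group {group}: fewer than 3 samples, skipped")
                continue
            data[group] = _per_gene(members)
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
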