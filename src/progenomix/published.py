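"""Reproduction of the published proteome-level results from the
study's open supplementary quantification matrix.

The quantified 3,394-protein matrix is distributed with the original
publication (and via Peptide Atlas, PASS01126); it is not bundled here.
To reproduce the published differential-expression counts and fold
changes, export the quantification matrix to
``data/published/protein_matrix.tsv`` (proteins x samples, first column
feature ids, raw linear-scale intensities, technical replicate columns
included) with the matching ``data/published/samples.tsv`` sample sheet,
then run :func:`published_de_counts`.
"""

from __future__ import annotations

from pathlib import Path

from progenomix import de
from progenomix.io import read_expression_matrix, read_sample_sheet

PUBLISHED_DIR = Path("data/published")
MATRIX_FILE = PUBLISHED_DIR / "protein_matrix.tsv"
SHEET_FILE = PUBLISHED_DIR / "samples.tsv"


def published_inputs_available(base: Path | None = None) -> bool:
    base = Path(base) if base is not None else Path(".")
    return (base / MATRIX_FILE).exists() and (base / SHEET_FILE).exists()


def published_de_analysis(base: Path | None = None) -> dict:
    """Full published-proteome DE analysis: normalization, replicate
    averaging, PC vs BPH and CRPC vs PC differential expression.

    Returns the two DE result lists, their significant-set sizes and
    overlap, and the linear-scale median ratios of every protein.
    """
    base = Path(base) if base is not None else Path(".")
    matrix = read_expression_matrix(base / MATRIX_FILE, layer="protein",
                                    scale="linear")
    sheet = read_sample_sheet(base / SHEET_FILE)
    norm = de.normalize(matrix)
    avg = de.average_replicates(norm, sheet)
    pc_bph = de.differential_expression(avg, sheet, "PC", "BPH")
    crpc_pc = de.differential_expression(avg, sheet, "CRPC", "PC")
    sig_a = de.significant_features(pc_bph)
    sig_b = de.significant_features(crpc_pc)
    return {
        "pc_vs_bph": pc_bph,
        "crpc_vs_pc": crpc_pc,
        "n_pc_vs_bph": len(sig_a),
        "n_crpc_vs_pc": len(sig_b),
        "n_common": len(sig_a & sig_b),
    }


def published_de_counts(base: Path | None = None) -> dict[str, int]:
    out = published_de_analysis(base)
    return {k: out[k] for k in ("n_pc_vs_bph", "n_crpc_vs_pc", "n_common")}


def fold_change(results: list[de.DEResult], gene: str) -> float:
    for r in results:
        if r.feature_id == gene:
            return r.median_ratio
    raise KeyError(gene)
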