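"""Synthetic multi-omic prostate-cancer cohort with known ground truth.

The generator emulates the statistical structure of the study cohort —
10 BPH, 17 PC and 11 CRPC samples with ~3,000 genes measured at both
mRNA and protein level — so that every pipeline stage can be tested
against planted effects:

* per-gene mRNA/protein values are bivariate Gaussian on the log2 scale
  with a group-specific Spearman correlation (coupling weakens in CRPC);
* a subset of genes carries group mean shifts (the differentially
  expressed genes), concordant at both levels;
* gene copy number influences mRNA with a configurable slope and protein
  with an attenuated slope; DMR methylation acts analogously with
  negative slopes;
* miRNAs repress their targets either by mRNA degradation (both layers
  drop) or translation-only inhibition (protein drops, mRNA untouched);
* somatic point mutations perturb the mutated sample's mRNA, germline
  variants do not;
* technical replicate MS runs are generated for protein samples with
  low-variance noise;
* a two-chromosome toy genome carries planted deletions, inversions and
  translocations, from which 90 bp paired-end reads at configurable
  coverage and base-error rate are simulated and aligned back to the
  reference with the built-in seed aligner.

All randomness flows from a single integer seed; identical config+seed
yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from progenomix.align import Hit, ToyAligner, revcomp
from progenomix.io import ExpressionMatrix, SampleSheet

GROUP_ORDER = ("BPH", "PC", "CRPC")


@dataclass
class SyntheticCohortConfig:
    """Study conditions for the simulated cohort.

    Group sizes and read geometry follow the emulated study design
    (10/17/11 samples, 90 bp paired reads); mRNA-protein coupling per
    group reflects the decreased coupling observed in CRPC. Effect
    slopes without an empirical anchor are chosen for testability: the
    copy-number and methylation slopes at protein level are attenuated
    five-fold relative to mRNA, planting the dosage-does-not-propagate
    contrast the density comparison is designed to expose.
    """

    n_genes: int = 3000
    n_bph: int = 10
    n_pc: int = 17
    n_crpc: int = 11
    mrna_protein_rho: dict = field(default_factory=lambda: {
        "BPH": 0.45, "PC": 0.5, "CRPC": 0.3})
    # differential expression
    de_fraction: float = 0.1
    de_shift: float = 1.5               # log2 group mean shift
    # copy number: a quarter of genes lie in copy-number-altered
    # regions, aberrant more often in tumours - progressed prostate
    # cancers carry a large fraction of the genome copy-altered, and the
    # per-sample dosage-expression correlation is driven by that fraction
    cn_gene_fraction: float = 0.25
    cn_effect_mrna: float = 0.5         # log2 expression per copy
    cn_effect_protein: float = 0.1
    cn_aberration_prob: dict = field(default_factory=lambda: {
        "BPH": 0.05, "PC": 0.3, "CRPC": 0.5})
    # methylation
    n_dmrs: int = 60
    meth_effect_mrna: float = -0.5
    meth_effect_protein: float = -0.1
    # miRNA
    n_mirnas: int = 20
    targets_per_mirna: int = 10
    mirna_effect: float = 1.0           # log2 drop per latent-sd of miRNA
    mirna_dispersion: float = 10.0      # negative-binomial size parameter
    unexpressed_mirna_fraction: float = 0.1
    # mutations
    mutation_rate_somatic: float = 0.002    # per gene per tumour sample
    mutation_rate_germline: float = 0.002
    somatic_impact_prob: float = 0.5
    somatic_impact_shift: float = 3.0   # log2 shift of the mutated sample
    # noise
    noise_sd: float = 1.0               # within-group log2 sd per layer
    replicate_noise_sd: float = 0.1
    # genome / reads
    genome_length: int = 100_000
    n_chromosomes: int = 2
    n_rearrangements: int = 3
    read_length: int = 90
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    base_error_rate: float = 0.001

    def __post_init__(self) -> None:
        if min(self.n_bph, self.n_pc, self.n_crpc) < 2:
            raise ValueError("group sizes must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("degenerate config: noise_sd must be > 0")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        for g, rho in self.mrna_protein_rho.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"rho out of range for {g}")


@dataclass
class GroundTruth:
    """Planted parameters for recovery tests."""

    de_genes: dict                      # comparison -> {gene: direction}
    cn_genes: list[str]
    meth_gene_of_dmr: dict              # dmr_id -> gene_id
    mirna_targets: dict                 # mirna -> {"mode": ..., "genes": [...]}
    expressed_mirnas: list[str]
    mutation_impacts: list              # (gene, sample, layer, shift)
    group_rho: dict
    breakends: list = field(default_factory=list)  # (chromA,posA,chromB,posB,type)


@dataclass
class SyntheticCohort:
    protein: ExpressionMatrix           # linear scale, includes replicates
    mrna: ExpressionMatrix              # linear scale
    mirna: ExpressionMatrix             # raw counts
    sheet: SampleSheet
    copy_number: pd.DataFrame           # long form gene/sample dosage
    dmrs: pd.DataFrame                  # BED3+ with per-sample counts
    tss: pd.DataFrame
    mutations: pd.DataFrame
    mirna_targets: pd.DataFrame         # prediction table with db flags
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Expression cohort
# ---------------------------------------------------------------------------

def _spearman_to_pearson(rho_s: float) -> float:
    """For bivariate Gaussians, Spearman rho_s = (6/pi) asin(r/2);
    invert to get the Pearson r that realizes a target Spearman."""
    if abs(rho_s) == 1.0:
        return float(rho_s)
    return float(2 * np.sin(np.pi * rho_s / 6))


def simulate_expression(config: SyntheticCohortConfig,
                        seed: int = 0) -> SyntheticCohort:
    rng = np.random.default_rng(seed)
    n = config.n_genes
    genes = [f"G{i:04d}" for i in range(n)]
    samples = ([f"BPH{i:02d}" for i in range(config.n_bph)]
               + [f"PC{i:02d}" for i in range(config.n_pc)]
               + [f"CRPC{i:02d}" for i in range(config.n_crpc)])
    groups = (["BPH"] * config.n_bph + ["PC"] * config.n_pc
              + ["CRPC"] * config.n_crpc)
    n_samples = len(samples)

    # --- gene role assignment (disjoint special sets) -------------------
    perm = rng.permutation(n)
    n_de = int(round(config.de_fraction * n))
    n_cn = int(round(config.cn_gene_fraction * n))
    n_mir = config.n_mirnas * config.targets_per_mirna
    n_dmr = config.n_dmrs
    if n_de + n_cn + n_mir + n_dmr > n:
        raise ValueError("special gene sets exceed n_genes")
    cursor = 0
    de_idx = perm[cursor:cursor + n_de]; cursor += n_de
    cn_idx = perm[cursor:cursor + n_cn]; cursor += n_cn
    mir_idx = perm[cursor:cursor + n_mir]; cursor += n_mir
    dmr_idx = perm[cursor:cursor + n_dmr]; cursor += n_dmr

    # --- baseline means and DE shifts ------------------------------------
    mu = rng.normal(8.0, 2.0, size=n)
    shift = np.zeros((n, 3))            # per group column (BPH, PC, CRPC)
    de_truth: dict[str, dict[str, str]] = {"PC_vs_BPH": {}, "CRPC_vs_PC": {}}
    for j, gi in enumerate(de_idx):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        which = j % 3   # shift in PC only, CRPC only, or both
        if which in (0, 2):
            shift[gi, 1] += sign * config.de_shift
            de_truth["PC_vs_BPH"][genes[gi]] = "up" if sign > 0 else "down"
        if which in (1, 2):
            shift[gi, 2] = shift[gi, 1] + sign * config.de_shift
            de_truth["CRPC_vs_PC"][genes[gi]] = "up" if sign > 0 else "down"
        elif which == 0:
            shift[gi, 2] = shift[gi, 1]

    group_index = np.array([GROUP_ORDER.index(g) for g in groups])

    # --- copy number ------------------------------------------------------
    integer_cn = np.full((n, n_samples), 2, dtype=int)
    for gi in cn_idx:
        for sj, g in enumerate(groups):
            if rng.random() < config.cn_aberration_prob[g]:
                integer_cn[gi, sj] = rng.choice([0, 1, 3, 4],
                                                p=[0.05, 0.45, 0.4, 0.1])
    # expression responds to the true dosage; the reported copy-number
    # table additionally carries measurement noise
    dosage = integer_cn + rng.normal(0, 0.05, size=integer_cn.shape)
    dosage = np.clip(dosage, 0.0, None)
    cn_term = integer_cn - 2.0

    # --- methylation ------------------------------------------------------
    # latent per-DMR, per-sample methylation deviation (z-scale); tumour
    # groups get a DMR-specific directional shift
    meth_latent = rng.normal(0, 1.0, size=(n_dmr, n_samples))
    dmr_shift = rng.choice([-1.5, 1.5], size=n_dmr)
    meth_latent += np.where(group_index[None, :] > 0,
                            dmr_shift[:, None], 0.0)
    frag_counts = np.clip(20.0 + 5.0 * meth_latent
                          + rng.normal(0, 1.0, size=meth_latent.shape),
                          0.0, None)

    # --- miRNAs -----------------------------------------------------------
    n_mirnas = config.n_mirnas
    mirna_ids = [f"miR-{100 + i}" for i in range(n_mirnas)]
    n_low = int(round(config.unexpressed_mirna_fraction * n_mirnas))
    base_l2 = rng.uniform(6.0, 11.0, size=n_mirnas)
    base_l2[:n_low] = 1.0               # below the count-8 floor everywhere
    mirna_de_shift = np.zeros(n_mirnas)
    # half of the expressed miRNAs shift between PC and CRPC
    expressed = list(range(n_low, n_mirnas))
    for j, mi in enumerate(expressed):
        if j % 2 == 0:
            mirna_de_shift[mi] = 2.0 if (j // 2) % 2 == 0 else -2.0
    mirna_latent = (base_l2[:, None]
                    + np.where(group_index[None, :] == 2,
                               mirna_de_shift[:, None], 0.0)
                    + rng.normal(0, 0.7, size=(n_mirnas, n_samples)))
    mean_expr = np.exp2(mirna_latent)
    r = config.mirna_dispersion
    p = r / (r + mean_expr)
    mirna_counts = rng.negative_binomial(r, p)
    # standardized latent drives target repression
    lat_c = mirna_latent - mirna_latent.mean(axis=1, keepdims=True)
    lat_sd = lat_c.std(axis=1, ddof=0)
    lat_z = lat_c / np.where(lat_sd > 0, lat_sd, 1.0)[:, None]

    mirna_targets: dict[str, dict] = {}
    repress_mrna = np.zeros((n, n_samples))
    repress_protein = np.zeros((n, n_samples))
    for mi in range(n_mirnas):
        mode = "degradation" if mi % 2 == 0 else "translation_only"
        tgt = mir_idx[mi * config.targets_per_mirna:
                      (mi + 1) * config.targets_per_mirna]
        mirna_targets[mirna_ids[mi]] = {
            "mode": mode, "genes": [genes[t] for t in tgt]}
        if mi < n_low:
            continue                    # unexpressed: no planted effect
        effect = config.mirna_effect * lat_z[mi]
        for t in tgt:
            repress_protein[t] += -effect
            if mode == "degradation":
                repress_mrna[t] += -effect

    # --- correlated noise and assembly ------------------------------------
    pearson = {g: _spearman_to_pearson(config.mrna_protein_rho[g])
               for g in GROUP_ORDER}
    z_m = rng.normal(size=(n, n_samples))
    z_w = rng.normal(size=(n, n_samples))
    r_vec = np.array([pearson[g] for g in groups])
    z_p = r_vec[None, :] * z_m + np.sqrt(1 - r_vec[None, :] ** 2) * z_w

    base = mu[:, None] + shift[:, group_index]
    mrna_log2 = (base
                 + config.cn_effect_mrna * cn_term
                 + repress_mrna
                 + config.noise_sd * z_m)
    protein_log2 = (base
                    + config.cn_effect_protein * cn_term
                    + repress_protein
                    + config.noise_sd * z_p)
    # methylation acts on the DMR-linked genes
    for d, gi in enumerate(dmr_idx):
        mrna_log2[gi] += config.meth_effect_mrna * meth_latent[d]
        protein_log2[gi] += config.meth_effect_protein * meth_latent[d]

    # --- mutations --------------------------------------------------------
    mut_rows = []
    mutation_impacts = []
    for sj, (sample, g) in enumerate(zip(samples, groups)):
        n_som = rng.binomial(n, config.mutation_rate_somatic) if g != "BPH" else 0
        n_ger = rng.binomial(n, config.mutation_rate_germline)
        som_genes = rng.choice(n, size=n_som, replace=False) if n_som else []
        ger_pool = [i for i in range(n) if i not in set(som_genes)]
        ger_genes = rng.choice(ger_pool, size=min(n_ger, len(ger_pool)),
                               replace=False) if n_ger else []
        for gi in som_genes:
            mut_rows.append({"gene_id": genes[gi], "sample_id": sample,
                             "origin": "somatic", "effect": "missense"})
            if rng.random() < config.somatic_impact_prob:
                delta = config.somatic_impact_shift * (
                    1.0 if rng.random() < 0.5 else -1.0)
                mrna_log2[gi, sj] += delta
                mutation_impacts.append((genes[gi], sample, "mrna", delta))
        for gi in ger_genes:
            mut_rows.append({"gene_id": genes[gi], "sample_id": sample,
                             "origin": "germline", "effect": "missense"})
    mutations = pd.DataFrame(mut_rows, columns=["gene_id", "sample_id",
                                                "origin", "effect"])

    # --- technical replicates (protein layer) -----------------------------
    rep_samples = [f"{s}_rep" for s in samples]
    rep_log2 = protein_log2 + rng.normal(0, config.replicate_noise_sd,
                                         size=protein_log2.shape)
    protein_cols = samples + rep_samples
    protein_vals = np.concatenate([protein_log2, rep_log2], axis=1)

    # --- tables -----------------------------------------------------------
    protein = ExpressionMatrix(
        pd.DataFrame(np.exp2(protein_vals), index=genes,
                     columns=protein_cols),
        layer="protein", scale="linear")
    mrna = ExpressionMatrix(
        pd.DataFrame(np.exp2(mrna_log2), index=genes, columns=samples),
        layer="mrna", scale="linear")
    mirna = ExpressionMatrix(
        pd.DataFrame(mirna_counts, index=mirna_ids, columns=samples),
        layer="mirna_counts", scale="linear")

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": samples + rep_samples,
        "group": groups + groups,
        "replicate_of": [None] * n_samples + samples,
    }))

    cn_long = pd.DataFrame({
        "gene_id": np.repeat(genes, n_samples),
        "sample_id": np.tile(samples, n),
        "copy_number": dosage.ravel(),
        "integer_cn": integer_cn.ravel(),
    })

    # toy annotation genome for DMR linking: every gene's TSS on chrA,
    # spaced 20 kb so only the planted DMR falls within 10 kb
    tss = pd.DataFrame({
        "gene_id": genes,
        "chrom": "chrA",
        "position": np.arange(n) * 20_000 + 5_000,
        "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
    })
    dmr_rows = {
        "chrom": ["chrA"] * n_dmr,
        "start": [int(tss["position"][gi] - 800) for gi in dmr_idx],
        "end": [int(tss["position"][gi] - 200) for gi in dmr_idx],
        "dmr_id": [f"DMR{d:03d}" for d in range(n_dmr)],
    }
    dmrs = pd.DataFrame(dmr_rows)
    for sj, s in enumerate(samples):
        dmrs[s] = frag_counts[:, sj]

    # prediction table: true targets agree in >= 2 databases; decoys with
    # a single database vote exercise the consensus rule; a few confident
    # false predictions (no planted effect) keep the screen honest
    pred_rows = []
    for mi, (mirna_id, info) in enumerate(mirna_targets.items()):
        for t, gene in enumerate(info["genes"]):
            flags = [True, True, t % 2 == 0]
            pred_rows.append({"mirna_id": mirna_id, "gene_id": gene,
                              "db_a": flags[0], "db_b": flags[1],
                              "db_c": flags[2]})
        decoys = rng.choice(perm[cursor:], size=4, replace=False)
        for k, gi in enumerate(decoys):
            n_flags = 1 if k < 2 else 2
            flags = [True] * n_flags + [False] * (3 - n_flags)
            pred_rows.append({"mirna_id": mirna_id, "gene_id": genes[gi],
                              "db_a": flags[0], "db_b": flags[1],
                              "db_c": flags[2]})
    pred = pd.DataFrame(pred_rows)

    truth = GroundTruth(
        de_genes=de_truth,
        cn_genes=[genes[i] for i in cn_idx],
        meth_gene_of_dmr={f"DMR{d:03d}": genes[gi]
                          for d, gi in enumerate(dmr_idx)},
        mirna_targets=mirna_targets,
        expressed_mirnas=[mirna_ids[i] for i in expressed],
        mutation_impacts=mutation_impacts,
        group_rho=dict(config.mrna_protein_rho),
    )
    return SyntheticCohort(protein=protein, mrna=mrna, mirna=mirna,
                           sheet=sheet, copy_number=cn_long, dmrs=dmrs,
                           tss=tss, mutations=mutations, mirna_targets=pred,
                           truth=truth)


# ---------------------------------------------------------------------------
# Rearranged genomes
# ---------------------------------------------------------------------------

@dataclass
class Rearrangement:
    kind: str                            # deletion | inversion | translocation
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int


def default_rearrangements(config: SyntheticCohortConfig) -> list[Rearrangement]:
    """A deletion, an inversion and a reciprocal translocation placed at
    fixed fractions of the two-chromosome genome."""
    L = config.genome_length // config.n_chromosomes
    plan = [
        Rearrangement("deletion", "chr1", int(0.4 * L), "chr1", int(0.56 * L)),
        Rearrangement("inversion", "chr2", int(0.3 * L), "chr2", int(0.5 * L)),
        Rearrangement("translocation", "chr1", int(0.8 * L),
                      "chr2", int(0.7 * L)),
    ]
    return plan[:config.n_rearrangements]


def random_genome(config: SyntheticCohortConfig, rng: np.random.Generator,
                  ) -> dict[str, str]:
    L = config.genome_length // config.n_chromosomes
    bases = np.array(list("ACGT"))
    return {f"chr{i + 1}": "".join(bases[rng.integers(0, 4, size=L)])
            for i in range(config.n_chromosomes)}


_Segment = tuple[str, int, int, str]          # (source chrom, start, end, strand)


def _split_segments(segments: list[_Segment], chrom: str,
                    pos: int) -> tuple[list[_Segment], list[_Segment], int]:
    """Split a donor-chromosome segment list at reference position
    ``pos`` of source ``chrom``; the position must fall inside a
    forward-strand segment that still maps colinearly to the reference."""
    for i, (c, s, e, strand) in enumerate(segments):
        if c == chrom and strand == "+" and s <= pos < e:
            prefix = segments[:i] + ([(c, s, pos, "+")] if pos > s else [])
            suffix = ([(c, pos, e, "+")] if pos < e else []) + segments[i + 1:]
            return prefix, suffix, i
    raise ValueError(f"breakpoint {chrom}:{pos} falls in an already "
                     f"rearranged or out-of-range region")


def _junctions(donor_segments: dict[str, list[_Segment]],
               reference: dict[str, str]) -> list[tuple]:
    """Novel adjacencies between consecutive donor segments, skipping
    the ones that reproduce the reference."""
    out = []
    for segs in donor_segments.values():
        for left, right in zip(segs, segs[1:]):
            cl, sl, el, stl = left
            cr, sr, er, str_ = right
            if cl == cr and stl == "+" and str_ == "+" and el == sr:
                continue                           # reference adjacency
            bl = el if stl == "+" else sl          # left-flank boundary
            br = sr if str_ == "+" else er         # right-flank boundary
            out.append(((cl, bl, stl), (cr, br, str_)))
    return out


def _break_junction_homology(reference: dict[str, list],
                             junctions: list[tuple]) -> None:
    """Mutate single reference bases so that no junction carries
    microhomology: the exact breakpoint of every planted junction is
    then unique, making breakend ground truth well defined.

    ``reference`` maps chrom -> mutable list of bases (edited in place).
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def walk(flank: tuple, step: int) -> tuple[str, int, bool]:
        """Reference position ``step`` bases across/behind the boundary
        in the flank's reading direction; returns (chrom, idx, flip)."""
        chrom, boundary, strand = flank
        if strand == "+":
            return chrom, boundary + step, False
        return chrom, boundary - 1 - step, True

    def base_at(chrom: str, idx: int, flip: bool) -> str | None:
        seq = reference[chrom]
        if not 0 <= idx < len(seq):
            return None
        b = seq[idx]
        return comp[b] if flip else b

    for _ in range(3):                   # shared bases may need a re-pass
        dirty = False
        for left, right in junctions:
            # block a +1 shift: continuation of the left flank must not
            # equal the first base of the right flank
            lc, li, lf = walk(left, 0)
            rc, ri, rf = walk(right, 0)
            cont_l = base_at(lc, li, lf)
            first_r = base_at(rc, ri, rf)
            if cont_l is not None and cont_l == first_r:
                reference[rc][ri] = (comp[cont_l] if not rf
                                     else cont_l)  # any base != cont_l
                dirty = True
            # block a -1 shift: last base of the left flank must not
            # equal the base preceding the right flank
            lc, li, lf = walk(left, -1)
            rc, ri, rf = walk(right, -1)
            last_l = base_at(lc, li, lf)
            pre_r = base_at(rc, ri, rf)
            if last_l is not None and last_l == pre_r:
                reference[rc][ri] = (comp[last_l] if not rf else last_l)
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not resolve junction homologies")


def simulate_rearranged_genome(config: SyntheticCohortConfig, seed: int = 0,
                               rearrangements: list[Rearrangement] | None = None,
                               ) -> tuple[dict[str, str], dict[str, str], list]:
    """Build a random reference and a donor genome carrying the planted
    rearrangements; returns (reference, donor, breakends).

    All rearrangement positions are reference coordinates; each planted
    breakpoint must lie in a region not touched by an earlier event.
    Breakends are (chromA, posA, chromB, posB, kind) tuples on reference
    coordinates, ordered so the lower (chrom, pos) comes first; a
    deletion of [s, e) yields the pair (s, e), as does an inversion of
    [s, e) (both of its junctions share that coordinate pair). Single
    reference bases flanking each junction are adjusted so junctions
    carry no microhomology, keeping the exact breakpoint unambiguous.
    """
    if config.genome_length < 10_000:
        raise ValueError("genome_length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    reference = random_genome(config, rng)
    if rearrangements is None:
        rearrangements = default_rearrangements(config)
    segments: dict[str, list[_Segment]] = {
        c: [(c, 0, len(s), "+")] for c, s in reference.items()}
    breakends = []
    for r in rearrangements:
        for chrom, pos in ((r.chrom_a, r.pos_a), (r.chrom_b, r.pos_b)):
            if chrom not in reference:
                raise ValueError(f"unknown chromosome {chrom}")
            if not 0 <= pos <= len(reference[chrom]):
                raise ValueError(f"breakpoint {pos} outside {chrom}")
        if r.kind in ("deletion", "inversion"):
            if r.chrom_a != r.chrom_b or r.pos_b <= r.pos_a:
                raise ValueError(f"{r.kind} needs pos_a < pos_b on one chrom")
            if r.pos_b - r.pos_a >= len(reference[r.chrom_a]):
                raise ValueError("rearrangement longer than chromosome")
            for donor_chrom, segs in segments.items():
                try:
                    prefix, rest, _ = _split_segments(segs, r.chrom_a, r.pos_a)
                except ValueError:
                    continue
                mid, suffix, _ = _split_segments(rest, r.chrom_a, r.pos_b)
                if r.kind == "deletion":
                    segments[donor_chrom] = prefix + suffix
                else:
                    flipped = [(c, s, e, "-" if st == "+" else "+")
                               for c, s, e, st in reversed(mid)]
                    segments[donor_chrom] = prefix + flipped + suffix
                break
            else:
                raise ValueError(f"breakpoint {r.chrom_a}:{r.pos_a} not in "
                                 f"any colinear donor region")
            breakends.append((r.chrom_a, r.pos_a, r.chrom_b, r.pos_b, r.kind))
        elif r.kind == "translocation":
            if r.chrom_a == r.chrom_b:
                raise ValueError("translocation needs two chromosomes")
            donor_a = donor_b = None
            for donor_chrom, segs in segments.items():
                for c, s, e, st in segs:
                    if c == r.chrom_a and st == "+" and s <= r.pos_a < e:
                        donor_a = donor_chrom
                    if c == r.chrom_b and st == "+" and s <= r.pos_b < e:
                        donor_b = donor_chrom
            if donor_a is None or donor_b is None or donor_a == donor_b:
                raise ValueError("translocation breakpoints unavailable")
            pa, sa, _ = _split_segments(segments[donor_a], r.chrom_a, r.pos_a)
            pb, sb, _ = _split_segments(segments[donor_b], r.chrom_b, r.pos_b)
            segments[donor_a] = pa + sb
            segments[donor_b] = pb + sa
            (ca, p1), (cb, p2) = sorted([(r.chrom_a, r.pos_a),
                                         (r.chrom_b, r.pos_b)])
            breakends.append((ca, p1, cb, p2, "translocation"))
        else:
            raise ValueError(f"unknown rearrangement kind {r.kind!r}")
    # remove microhomology at the planted junctions, then assemble
    mutable = {c: list(s) for c, s in reference.items()}
    _break_junction_homology(mutable, _junctions(segments, reference))
    reference = {c: "".join(s) for c, s in mutable.items()}
    donor = {}
    for donor_chrom, segs in segments.items():
        parts = []
        for c, s, e, st in segs:
            piece = reference[c][s:e]
            parts.append(piece if st == "+" else revcomp(piece))
        donor[donor_chrom] = "".join(parts)
    return reference, donor, breakends


# ---------------------------------------------------------------------------
# Read simulation + SAM
# ---------------------------------------------------------------------------

def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = b"ACGT"
    for i in hits:
        cur = arr[i]
        choices = [b for b in bases if bytes([b]) != cur]
        arr[i] = bytes([choices[rng.integers(3)]])
    return arr.tobytes().decode()


def simulate_reads(donor: dict[str, str], config: SyntheticCohortConfig,
                   seed: int = 0) -> list[tuple[str, str, str]]:
    """Sample paired 90 bp reads from the donor genome.

    Returns (read_id, seq1, seq2) with read 2 reverse-complemented, as
    sequenced from the opposite fragment end. Expected pair count is
    coverage * genome / (2 * read_length).
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    rl = config.read_length
    chroms = sorted(donor)
    lengths = np.array([len(donor[c]) for c in chroms], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(config.coverage * total / (2 * rl)))
    weights = lengths / total
    out = []
    for i in range(n_pairs):
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        L = len(donor[chrom])
        insert = int(round(rng.normal(config.insert_mean, config.insert_sd)))
        insert = max(rl, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        frag = donor[chrom][start:start + insert]
        r1 = _apply_errors(frag[:rl], config.base_error_rate, rng)
        r2 = _apply_errors(revcomp(frag[-rl:]), config.base_error_rate, rng)
        out.append((f"rp{i:06d}", r1, r2))
    return out


def align_and_write_sam(pairs: list[tuple[str, str, str]],
                        reference: dict[str, str], path: str | Path,
                        max_mismatches: int = 5) -> None:
    """Align simulated pairs to the reference with the toy aligner and
    write a name-sorted SAM (mapq 60 unique, 0 ambiguous, unmapped reads
    kept with their sequence for split-read analysis)."""
    aligner = ToyAligner(reference)
    lines = ["@HD\tVN:1.6\tSO:queryname"]
    for chrom in sorted(reference):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{len(reference[chrom])}")

    def _fmt(read_id: str, seq: str, hit: Hit | None, mate: Hit | None,
             first: bool) -> str:
        flag = 0x1 | (0x40 if first else 0x80)
        if hit is None:
            flag |= 0x4
        elif hit.strand == "-":
            flag |= 0x10
        if mate is None:
            flag |= 0x8
        elif mate.strand == "-":
            flag |= 0x20
        rname = hit.chrom if hit else "*"
        pos = hit.pos + 1 if hit else 0
        mapq = hit.mapq if hit else 0
        cigar = f"{len(seq)}M" if hit else "*"
        rnext = mate.chrom if mate else "*"
        pnext = mate.pos + 1 if mate else 0
        out_seq = revcomp(seq) if (hit and hit.strand == "-") else seq
        return "\t".join([read_id, str(flag), rname, str(pos), str(mapq),
                          cigar, rnext, str(pnext), "0", out_seq,
                          "*"])

    for read_id, s1, s2 in pairs:
        h1 = aligner.align(s1, max_mismatches=max_mismatches)
        h2 = aligner.align(s2, max_mismatches=max_mismatches)
        lines.append(_fmt(read_id, s1, h1, h2, True))
        lines.append(_fmt(read_id, s2, h2, h1, False))
    Path(path).write_text("\n".join(lines) + "\n")


def cohort_config_to_dict(config: SyntheticCohortConfig) -> dict:
    return dataclasses.asdict(config)
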