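"""Per-sample correlations, kernel densities (vs a direct Gaussian-sum
oracle), DMR-gene linking and the mRNA-protein coupling summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from progenomix import correlation
from progenomix.io import ExpressionMatrix, SampleSheet


def _matrix(arr, genes=None, samples=None, scale="log2", layer="mrna"):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            layer=layer, scale=scale)


class TestPerSampleCorrelation:
    def test_monotone_transform_gives_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 4))
        rho = correlation.per_sample_correlation(
            _matrix(a), _matrix(np.exp(a) + 5))
        np.testing.assert_allclose(rho.to_numpy(), 1.0)

    def test_negated_layer_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(15, 3))
        rho = correlation.per_sample_correlation(_matrix(a), _matrix(-a))
        np.testing.assert_allclose(rho.to_numpy(), -1.0)

    def test_tied_values_match_rank_formula(self):
        # 12 genes in one sample, one tie in layer B; compare against the
        # Pearson correlation of average ranks computed by hand
        a = np.arange(12, dtype=float)
        b = np.array([3., 1., 4., 4., 5., 2., 9., 7., 6., 8., 11., 10.])
        from scipy.stats import rankdata

        expected = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        rho = correlation.per_sample_correlation(
            _matrix(a[:, None], samples=["S0"]),
            _matrix(b[:, None], samples=["S0"]))
        assert rho["S0"] == pytest.approx(expected, abs=1e-12)

    def test_constant_sample_is_nan_with_warning(self):
        a = np.random.default_rng(2).normal(size=(12, 2))
        b = a.copy()
        b[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            rho = correlation.per_sample_correlation(_matrix(a), _matrix(b))
        assert math.isnan(rho["S1"]) and not math.isnan(rho["S0"])


def _kde_oracle(values, grid, h):
    """Naive direct-sum Gaussian kernel density."""
    out = np.zeros_like(grid)
    for i, g in enumerate(grid):
        s = sum(math.exp(-0.5 * ((g - v) / h) ** 2) for v in values)
        out[i] = s / (len(values) * h * math.sqrt(2 * math.pi))
    return out


class TestEstimatePdf:
    def test_two_point_value_matches_kernel_sum_oracle(self):
        rho = np.array([0.2, 0.4])
        dens = correlation.estimate_pdf(rho, grid_size=64)
        h = np.std(rho, ddof=1) * 2 ** (-1 / 5)
        assert dens.bandwidth == pytest.approx(h)
        expected = _kde_oracle(rho, dens.grid, h)
        np.testing.assert_allclose(dens.pdf, expected, atol=1e-12)

    @pytest.mark.parametrize("n", [5, 23, 50])
    def test_matches_oracle_on_random_draws(self, n):
        rng = np.random.default_rng(n)
        rho = np.clip(rng.normal(0.2, 0.3, size=n), -1, 1)
        dens = correlation.estimate_pdf(rho)
        expected = _kde_oracle(rho, dens.grid, dens.bandwidth)
        assert np.max(np.abs(dens.pdf - expected)) < 1e-10

    def test_symmetric_input_symmetric_density(self):
        dens = correlation.estimate_pdf(np.array([-1.0, 1.0]), grid_size=101)
        assert np.max(np.abs(dens.pdf - dens.pdf[::-1])) < 1e-12

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(9)
        dens = correlation.estimate_pdf(rng.uniform(-0.8, 0.8, 30))
        integral = np.trapezoid(dens.pdf, dens.grid)
        assert 0.98 <= integral <= 1.02

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation.estimate_pdf(np.array([0.3, 0.3, 0.3]))


class TestBackgroundDistribution:
    def test_three_samples_give_six_values(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(12, 3)), rng.normal(size=(12, 3))
        bg = correlation.background_distribution(_matrix(a), _matrix(b))
        assert len(bg) == 6

    def test_sample_reordering_preserves_pooled_multiset(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=(15, 4)), rng.normal(size=(15, 4))
        bg1 = correlation.background_distribution(_matrix(a), _matrix(b))
        order = [2, 0, 3, 1]
        bg2 = correlation.background_distribution(
            _matrix(a[:, order], samples=[f"S{j}" for j in order]),
            _matrix(b[:, order], samples=[f"S{j}" for j in order]))
        np.testing.assert_allclose(sorted(bg1), sorted(bg2), atol=1e-12)

    def test_independent_layers_centered_at_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(200, 12))
        b = rng.normal(size=(200, 12))
        bg = correlation.background_distribution(_matrix(a), _matrix(b))
        assert abs(np.mean(bg)) < 0.05


class TestDmrLinking:
    def _tss(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "position",
                                           "strand"])

    def test_tss_inside_interval_distance_zero(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [1000],
                             "end": [2000], "dmr_id": ["D1"]})
        tss = self._tss([("G1", "chr1", 1500, "+")])
        links = correlation.link_dmrs_to_genes(dmrs, tss)
        assert links[0].distance == 0

    def test_proximal_boundary_inclusive_at_10kb(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                             "dmr_id": ["D1"]})
        tss = self._tss([("G1", "chr1", 10_099, "+"),
                         ("G2", "chr1", 10_100, "+")])
        links = correlation.link_dmrs_to_genes(dmrs, tss,
                                               zone="proximal_10kb")
        assert [l.gene_id for l in links] == ["G1"]
        assert links[0].distance == 10_000

    def test_distal_zone_excludes_250kb(self):
        dmrs = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100],
                             "dmr_id": ["D1"]})
        tss = self._tss([("G1", "chr1", 100_000, "+"),
                         ("G2", "chr1", 260_099, "+")])
        links = correlation.link_dmrs_to_genes(dmrs, tss,
                                               zone="within_250kb")
        assert [l.gene_id for l in links] == ["G1"]

    def test_unknown_chromosome_skipped_with_warning(self):
        dmrs = pd.DataFrame({"chrom": ["chrZ"], "start": [0], "end": [100],
                             "dmr_id": ["D1"]})
        tss = self._tss([("G1", "chr1", 50, "+")])
        with pytest.warns(UserWarning, match="chrZ"):
            links = correlation.link_dmrs_to_genes(dmrs, tss)
        assert links == []


class TestMethylationScreen:
    def test_planted_negative_coupling_recovered(self, cohort):
        links = correlation.link_dmrs_to_genes(cohort.dmrs, cohort.tss)
        mrna = ExpressionMatrix(np.log2(cohort.mrna.values), layer="mrna",
                                scale="log2")
        prot_cols = cohort.mrna.sample_ids
        protein = ExpressionMatrix(
            np.log2(cohort.protein.values[prot_cols]), layer="protein",
            scale="log2")
        screen = correlation.methylation_expression_screen(
            links, cohort.dmrs, mrna, protein)
        # every DMR is linked to its planted gene; the mRNA slope (-0.5)
        # should push most linked genes past the |rho| > 0.3 filter with
        # a negative sign
        truth = cohort.truth.meth_gene_of_dmr
        planted = screen[[truth.get(r.dmr_id) == r.gene_id
                          for r in screen.itertuples()]]
        assert len(planted) >= 0.7 * len(truth)
        assert (planted["rho_mrna"] < -0.3).all()

    def test_no_de_genes_annotation_empty(self, cohort):
        links = correlation.link_dmrs_to_genes(cohort.dmrs, cohort.tss)
        mrna = ExpressionMatrix(np.log2(cohort.mrna.values), layer="mrna",
                                scale="log2")
        screen = correlation.methylation_expression_screen(
            links, cohort.dmrs, mrna, mrna, de_mrna=set(), de_protein=set())
        if len(screen):
            assert not screen["de_mrna"].any()
            assert not screen["de_protein"].any()


class TestCoupling:
    def test_identical_layers_mu_one(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(10, 6))
        out = correlation.mrna_protein_coupling(_matrix(a), _matrix(a))
        np.testing.assert_allclose(out["all"].to_numpy(), 1.0)

    def test_independent_layers_half_positive(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(800, 10))
        b = rng.normal(size=(800, 10))
        out = correlation.mrna_protein_coupling(_matrix(a), _matrix(b))
        frac_pos = float((out["all"] > 0).mean())
        assert 0.4 < frac_pos < 0.6
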