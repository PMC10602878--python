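import time

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genedomains.accessibility import border_score, site_accessibility
from genedomains.contact_matrix import kr_balance, observed_over_expected
from genedomains.pileup import PileupImage, domain_score, gene_raster, group_by_value
from genedomains.simulator import SimParams
from genedomains.synthetic_data import (
    AccessSpec,
    GenomeSpec,
    generate_accessibility,
    generate_contacts,
    generate_expression,
    generate_genome,
    recovery_dataset,
)


def per_gene_domain_scores(oe, genes):
    dense = oe.to_dense()
    coverage = np.zeros(dense.shape, dtype=bool)
    coverage[oe.row, oe.col] = True
    coverage[oe.col, oe.row] = True
    out = {}
    for g in genes:
        raster = gene_raster(oe, g, dense=dense, coverage=coverage)
        if raster is None:
            continue
        ds = domain_score(PileupImage(raster, 1, 0.5))
        if ds.defined:
            out[g.gene_id] = ds.value
    return out


class TestGenerateGenome:
    def test_deterministic(self):
        spec = GenomeSpec(seed=9)
        a_genes, a_map = generate_genome(spec)
        b_genes, b_map = generate_genome(spec)
        assert a_genes == b_genes
        assert np.array_equal(a_map.starts, b_map.starts)

    def test_empty_annotation(self):
        genes, fmap = generate_genome(GenomeSpec(n_genes=0))
        assert genes == []
        assert fmap.length == 400_000

    def test_genes_sorted_non_overlapping(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=60, seed=2))
        for a, b in zip(genes, genes[1:]):
            assert a.end <= b.start

    def test_density_matches_spec(self):
        spec = GenomeSpec(n_genes=500, chromosome_length=2_500_000, seed=4)
        genes, fmap = generate_genome(spec)
        density = len(genes) / fmap.length
        assert density == pytest.approx(500 / 2_500_000, rel=0.10)

    def test_infeasible_packing(self):
        with pytest.raises(ValueError):
            generate_genome(GenomeSpec(n_genes=500, chromosome_length=10_000))

    def test_fragment_lengths(self):
        _, fmap = generate_genome(GenomeSpec(seed=1))
        mean_len = np.mean(fmap.ends - fmap.starts)
        assert mean_len == pytest.approx(500, rel=0.2)


class TestGenerateAccessibility:
    def test_flat_background_when_no_peaks(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=5, seed=1))
        spec = AccessSpec(tss_height_mean=1e-9, tes_height_mean=1e-9)
        track, _ = generate_accessibility(genes, spec, chrom_length=400_000)
        arr = track.to_array("chr1", 400_000)
        assert np.allclose(arr, spec.background)

    def test_site_accessibility_recovers_height(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=20, seed=3))
        track, truth = generate_accessibility(genes, chrom_length=400_000, seed=3)
        for g in genes[:10]:
            h = truth.loc[g.gene_id, "tss_height"]
            if h > 0.2:  # above background
                measured = site_accessibility(track, "chr1", g.tss)
                assert measured == pytest.approx(h, rel=1e-6)

    def test_monotone_height_scale(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=30, seed=5))
        products = []
        for scale in (0.5, 1.0, 2.0):
            track, _ = generate_accessibility(
                genes, AccessSpec(height_scale=scale), chrom_length=400_000, seed=5)
            products.append(np.mean([border_score(g, track).product
                                     for g in genes]))
        assert products[0] < products[1] < products[2]

    def test_deterministic(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=10, seed=1))
        a, ta = generate_accessibility(genes, chrom_length=400_000, seed=7)
        b, tb = generate_accessibility(genes, chrom_length=400_000, seed=7)
        pd.testing.assert_frame_equal(ta, tb)


@pytest.fixture(scope="module")
def small_world():
    genes, fmap = generate_genome(GenomeSpec(
        n_genes=20, chromosome_length=120_000, seed=6))
    track, truth = generate_accessibility(genes, chrom_length=120_000, seed=6)
    return genes, fmap, track, truth


class TestGenerateContacts:
    def test_deterministic(self, small_world):
        genes, fmap, track, _ = small_world
        a, _, _ = generate_contacts(genes, track, fmap, seed=8)
        b, _, _ = generate_contacts(genes, track, fmap, seed=8)
        assert np.array_equal(a.value, b.value)

    def test_depth_convergence_to_mean_field(self, small_world):
        """OE of generated counts approaches lambda / expected as depth grows."""
        genes, fmap, track, _ = small_world
        errors = []
        for depth in (1.0, 30.0, 1000.0):
            m, _, lam = generate_contacts(genes, track, fmap,
                                          depth_scale=depth, seed=9)
            oe = observed_over_expected(m)
            dense_oe = oe.to_dense()
            # expected OE from the mean field itself
            n = fmap.n_fragments
            lam_oe = np.zeros_like(lam)
            for d in range(1, 120):
                diag = np.diagonal(lam, offset=d)
                if diag.mean() > 0:
                    vals = diag / diag.mean()
                    idx = np.arange(n - d)
                    lam_oe[idx, idx + d] = vals
                    lam_oe[idx + d, idx] = vals
            band = np.triu(np.ones((n, n), dtype=bool), 1) & ~np.triu(
                np.ones((n, n), dtype=bool), 60)
            errors.append(np.abs(dense_oe[band] - lam_oe[band]).mean())
        assert errors[2] < errors[1] < errors[0]
        assert errors[2] < 0.05

    def test_invalid_depth(self, small_world):
        genes, fmap, track, _ = small_world
        with pytest.raises(ValueError):
            generate_contacts(genes, track, fmap, depth_scale=0.0)

    def test_band_limit(self, small_world):
        genes, fmap, track, _ = small_world
        m, _, _ = generate_contacts(genes, track, fmap, band_limit=50, seed=1)
        assert (m.col - m.row).max() <= 50


class TestControlGeneration:
    def test_a2_zero_ds_centered_near_one(self):
        """Without the accessibility term, domain scores sit near 1."""
        data = recovery_dataset(seed=3, n_genes=60)
        genes, fmap, track = data["genes"], data["fragment_map"], data["track"]
        m, pairs, _ = generate_contacts(
            genes, track, fmap, SimParams(a2=0.0), depth_scale=30.0,
            band_limit=120, seed=3)
        # pair detection is independent of a2; with a2=0 pairs add nothing
        oe = observed_over_expected(kr_balance(m))
        ds = per_gene_domain_scores(oe, genes)
        assert np.median(list(ds.values())) == pytest.approx(1.0, abs=0.1)

    def test_strong_cohort_beats_weak(self):
        """One-sided rank test: strong-anchor genes have higher DS."""
        data = recovery_dataset(seed=2)
        oe = observed_over_expected(kr_balance(data["matrix"]))
        ds = per_gene_domain_scores(oe, data["genes"])
        truth = data["truth"]
        prods = truth.loc[list(ds.keys()), "height_product"].to_numpy()
        values = np.array(list(ds.values()))
        median = np.median(prods)
        strong = values[prods > median]
        weak = values[prods <= median]
        res = stats.mannwhitneyu(strong, weak, alternative="greater")
        assert res.pvalue < 1e-3


class TestRecovery:
    def test_per_gene_ds_tracks_truth(self, recovery_data, recovery_oe):
        """Ground-truth recovery: rho(border product, per-gene DS) >= 0.5."""
        ds = per_gene_domain_scores(recovery_oe, recovery_data["genes"])
        truth = recovery_data["truth"]
        prods = truth.loc[list(ds.keys()), "height_product"].to_numpy()
        rho = stats.spearmanr(list(ds.values()), prods).statistic
        assert rho >= 0.5

    def test_quantile_gradient(self, recovery_data, recovery_oe):
        """Q1..Q10 cohorts by border product: mean DS follows cohort strength."""
        ds = per_gene_domain_scores(recovery_oe, recovery_data["genes"])
        truth = recovery_data["truth"]
        ids = list(ds.keys())
        labels = group_by_value(ids, truth.loc[ids, "height_product"].to_numpy(), 10)
        frame = pd.DataFrame({"ds": [ds[i] for i in ids], "q": labels})
        mean_ds = frame.groupby("q")["ds"].mean().reindex(
            [f"Q{k}" for k in range(1, 11)])
        # Q1 is the strongest cohort; DS should fall along Q1 -> Q10
        strength_rank = np.arange(10, 0, -1)
        rho = stats.spearmanr(strength_rank, mean_ds.to_numpy()).statistic
        assert rho >= 0.9


class TestGenerateExpression:
    def test_proportional_noise_free_matches_rank(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=40, seed=4))
        track, _ = generate_accessibility(genes, chrom_length=400_000, seed=4)
        expr = generate_expression(genes, track, noise_sd=0.0)
        prods = [border_score(g, track).product for g in genes]
        rho = stats.spearmanr(expr["expression"].to_numpy(), prods).statistic
        assert rho == pytest.approx(1.0)

    def test_decoupled_mode(self):
        genes, _ = generate_genome(GenomeSpec(
            n_genes=500, chromosome_length=2_500_000, seed=4))
        track, _ = generate_accessibility(genes, chrom_length=2_500_000, seed=4)
        expr = generate_expression(genes, track, mode="decoupled", seed=4)
        prods = [border_score(g, track).product for g in genes]
        rho = stats.spearmanr(expr["expression"].to_numpy(), prods).statistic
        assert abs(rho) < 0.2

    def test_deterministic(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=10, seed=4))
        track, _ = generate_accessibility(genes, chrom_length=400_000, seed=4)
        a = generate_expression(genes, track, seed=1)
        b = generate_expression(genes, track, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_nonnegative(self):
        genes, _ = generate_genome(GenomeSpec(n_genes=30, seed=4))
        track, _ = generate_accessibility(genes, chrom_length=400_000, seed=4)
        expr = generate_expression(genes, track, noise_sd=2.0, seed=2)
        assert (expr["expression"] >= 0).all()


class TestFullPipelineSmoke:
    def test_end_to_end_300_genes(self):
        """Genome -> contacts -> balance -> OE -> DI -> pile-up -> quantiles."""
        from genedomains.directionality import di_track, metagene
        from genedomains.pileup import pileup

        start = time.monotonic()
        spec = GenomeSpec(n_genes=300, chromosome_length=1_300_000, seed=11)
        genes, fmap = generate_genome(spec)
        track, _ = generate_accessibility(
            genes, chrom_length=spec.chromosome_length, seed=11)
        matrix, _, _ = generate_contacts(genes, track, fmap, depth_scale=2.0,
                                         band_limit=200, seed=11)
        balanced = kr_balance(matrix)
        oe = observed_over_expected(balanced)
        profile = di_track(oe)
        assert profile.di.size == fmap.n_fragments
        cohort = [g for g in genes if g.length >= 2000]
        image = pileup(cohort, oe)
        assert image.raster.shape == (80, 80)
        scores = [border_score(g, track).product for g in cohort]
        labels = group_by_value(cohort, scores, 10)
        assert len(set(labels)) == 10
        assert time.monotonic() - start < 300
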