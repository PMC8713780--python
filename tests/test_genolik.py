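"""Genotype likelihoods, EM frequencies, SNP test, filters, heterozygosity."""

import numpy as np
import pytest
from scipy import integrate, stats

import trawlscan as ts
from trawlscan.genolik import (
    SiteFilterConfig,
    em_maf,
    estimate_maf,
    expected_het,
    saf_loglik,
    sfs_em,
    site_loglik,
    snp_lrt,
)


def triple_oracle(n_ref, n_alt, err):
    """Direct arithmetic evaluation of the per-read error model."""
    p_alt = np.array([err, 0.5, 1.0 - err])
    lik = p_alt**n_alt * (1.0 - p_alt) ** n_ref
    return lik / lik.max()


class TestGenotypeLikelihoods:
    def test_zero_reads_flagged_missing_with_flat_triple(self):
        gl = ts.genotype_likelihoods(np.array([[0]]), np.array([[0]]), 0.01)
        assert gl.missing[0, 0]
        assert np.allclose(gl.logl[0, 0], 0.0)

    def test_error_free_limit_single_alt_read(self):
        gl = ts.genotype_likelihoods(np.array([[0]]), np.array([[1]]), 1e-9)
        lik = np.exp(gl.logl[0, 0])
        assert lik[2] == pytest.approx(1.0)
        assert lik[1] == pytest.approx(0.5)
        assert lik[0] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize(
        "n_ref,n_alt,err",
        [(2, 0, 0.01), (3, 1, 0.05), (0, 4, 0.002), (5, 5, 0.1)],
    )
    def test_triples_match_hand_arithmetic(self, n_ref, n_alt, err):
        gl = ts.genotype_likelihoods(
            np.array([[n_ref]]), np.array([[n_alt]]), err
        )
        assert np.allclose(np.exp(gl.logl[0, 0]), triple_oracle(n_ref, n_alt, err))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ts.genotype_likelihoods(np.array([[-1]]), np.array([[0]]), 0.01)
        with pytest.raises(ValueError):
            ts.genotype_likelihoods(np.array([[1]]), np.array([[0]]), 0.0)


def random_gl(rng, n_sites, n_ind, depth, p=None, err=0.01):
    """Simulated GL matrix for testing, returning truth alongside."""
    p = rng.uniform(0.05, 0.95, size=n_sites) if p is None else p
    geno = rng.binomial(2, p, size=(n_ind, n_sites)).astype(np.int8)
    counts = ts.simulate_read_counts(geno, depth, 0.0, err, seed=rng)
    gl = ts.genotype_likelihoods(counts.ref, counts.alt, err)
    return gl, geno, p


class TestEstimateMaf:
    def test_homozygous_panel_gives_zero_frequency(self, rng):
        geno = np.zeros((20, 5), dtype=np.int8)
        counts = ts.simulate_read_counts(geno, 30.0, 0.0, 0.001, seed=rng)
        gl = ts.genotype_likelihoods(counts.ref, counts.alt, 0.001)
        p, _, _ = em_maf(gl.logl, gl.missing)
        assert np.all(p < 1e-4)

    def test_swap_symmetric_triples_give_half(self):
        # two individuals whose triples are mirror images force p = 0.5
        logl = np.log(np.array([[[1.0, 0.5, 1e-4], [1e-4, 0.5, 1.0]]]))
        missing = np.zeros((1, 2), dtype=bool)
        p, _, _ = em_maf(logl, missing)
        assert p[0] == pytest.approx(0.5, abs=1e-6)

    def test_all_missing_site_rejected(self):
        triples = np.zeros((4, 3))
        with pytest.raises(ValueError, match="missing"):
            estimate_maf(triples)

    def test_em_matches_grid_search(self, rng):
        # independent oracle: dense likelihood evaluation on a 1e-4 grid
        gl, _, _ = random_gl(rng, 50, 12, 2.0)
        p_em, _, _ = em_maf(gl.logl, gl.missing)
        grid = np.arange(0.0, 1.0 + 1e-9, 1e-4)
        for s in range(gl.n_sites):
            ll = site_loglik(
                np.repeat(gl.logl[s][None], len(grid), axis=0),
                np.repeat(gl.missing[s][None], len(grid), axis=0),
                grid,
            )
            p_grid = grid[np.argmax(ll)]
            assert abs(p_em[s] - p_grid) < 1e-3

    def test_likelihood_ascent_per_iteration(self, rng):
        gl, _, _ = random_gl(rng, 30, 10, 1.5)
        prev = None
        for k in range(1, 12):
            p, _, ll = em_maf(gl.logl, gl.missing, max_iter=k)
            total = np.sum(ll)
            if prev is not None:
                assert total >= prev - 1e-9
            prev = total

    def test_allele_swap_equivariance(self, rng):
        gl, _, _ = random_gl(rng, 40, 15, 2.0)
        p, _, _ = em_maf(gl.logl, gl.missing)
        p_swap, _, _ = em_maf(gl.logl[:, :, ::-1], gl.missing)
        assert np.allclose(p_swap, 1.0 - p, atol=1e-4)

    def test_high_depth_matches_sample_frequency(self, rng):
        gl, geno, _ = random_gl(rng, 1000, 24, 30.0)
        p, _, _ = em_maf(gl.logl, gl.missing)
        realized = geno.mean(axis=0) / 2.0
        assert np.max(np.abs(p - realized)) < 0.02


class TestSnpLrt:
    def test_monomorphic_estimate_gives_p_one(self):
        logl = np.zeros((1, 5, 3))
        logl[:, :, 1:] = -5.0
        missing = np.zeros((1, 5), dtype=bool)
        p = snp_lrt(logl, missing, np.array([0.0]))
        assert p[0] == pytest.approx(1.0)

    def test_fixed_instance_matches_numeric_tail_integral(self, rng):
        gl, _, _ = random_gl(rng, 1, 10, 4.0)
        maf, _, _ = em_maf(gl.logl, gl.missing)
        lam = 2.0 * (
            site_loglik(gl.logl, gl.missing, maf)
            - site_loglik(gl.logl, gl.missing, np.array([0.0]))
        )
        p = snp_lrt(gl.logl, gl.missing, maf)[0]
        tail, _ = integrate.quad(stats.chi2(df=1).pdf, float(lam[0]), np.inf)
        assert p == pytest.approx(tail, rel=1e-6, abs=1e-12)


class TestSiteFilters:
    def test_default_thresholds_are_the_standard_seven(self):
        c = SiteFilterConfig()
        assert (
            c.snp_pval,
            c.min_total_depth,
            c.max_total_depth,
            c.min_individuals,
            c.min_base_q,
            c.min_map_q,
            c.min_maf,
        ) == (1e-6, 48, 600, 48, 20, 20, 0.05)

    def test_all_zero_counts_give_zero_survivors(self):
        ref = np.zeros((10, 50), dtype=int)
        alt = np.zeros((10, 50), dtype=int)
        gl = ts.genotype_likelihoods(ref + 1, alt, 0.01)  # placeholder GLs
        gl.logl[:] = 0.0
        gl.missing[:] = True
        panel, report = ts.apply_site_filters(
            ref, alt, gl, maf_hat=np.zeros(10), lrt_pvalue=np.ones(10)
        )
        assert report["pass_all"] == 0

    def test_toy_matrix_matches_hand_enumeration(self, rng):
        # manual application of each rule on a 20-site toy
        n_sites, n_ind = 20, 6
        ref = rng.integers(0, 6, size=(n_sites, n_ind))
        alt = rng.integers(0, 6, size=(n_sites, n_ind))
        gl = ts.genotype_likelihoods(ref, alt, 0.01)
        maf = rng.uniform(0, 0.5, size=n_sites)
        pval = rng.uniform(0, 1e-4, size=n_sites)
        config = SiteFilterConfig(
            snp_pval=5e-5, min_total_depth=20, max_total_depth=45,
            min_individuals=5, min_maf=0.1,
        )
        panel, report = ts.apply_site_filters(
            ref, alt, gl, config, maf_hat=maf, lrt_pvalue=pval
        )
        expected = []
        for s in range(n_sites):
            depth = ref[s].sum() + alt[s].sum()
            covered = np.sum((ref[s] + alt[s]) > 0)
            ok = (
                20 <= depth <= 45
                and covered >= 5
                and pval[s] < 5e-5
                and maf[s] >= 0.1
            )
            expected.append(ok)
        assert list(panel["pass"]) == expected
        assert report["pass_all"] == sum(expected)

    @pytest.mark.parametrize(
        "relaxed",
        [
            {"snp_pval": 1e-2},
            {"min_total_depth": 0},
            {"max_total_depth": 10_000},
            {"min_individuals": 0},
            {"min_maf": 0.0},
        ],
    )
    def test_relaxing_one_threshold_is_monotone(self, sequenced, relaxed):
        base = SiteFilterConfig()
        loose = SiteFilterConfig(**{**base.__dict__, **relaxed})
        counts = sequenced["counts"]
        _, rep_base = ts.apply_site_filters(
            counts.ref, counts.alt, sequenced["gl"], base, maf_hat=sequenced["maf"]
        )
        _, rep_loose = ts.apply_site_filters(
            counts.ref, counts.alt, sequenced["gl"], loose, maf_hat=sequenced["maf"]
        )
        assert rep_loose["pass_all"] >= rep_base["pass_all"]


class TestExpectedHet:
    def test_single_site_half(self):
        assert expected_het(np.array([0.5])).he == pytest.approx(0.5)

    def test_monomorphic_panel(self):
        assert expected_het(np.zeros(10)).he == 0.0

    def test_freq_mode_matches_hand_mean(self):
        p = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        hand = np.mean([2 * x * (1 - x) for x in p])
        assert expected_het(p, mode="freq").he == pytest.approx(hand)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            expected_het(np.array([]))

    def test_sfs_mode_consistent_with_frequencies_at_high_depth(self, rng):
        gl, geno, _ = random_gl(rng, 300, 16, 25.0)
        res = expected_het(gl, mode="sfs")
        realized = geno.mean(axis=0) / 2.0
        he_freq = np.mean(2 * realized * (1 - realized))
        assert res.mode == "sfs"
        assert res.sfs == pytest.approx(res.sfs)  # finite
        assert res.he == pytest.approx(he_freq, abs=0.02)

    def test_saf_peaks_at_true_count_when_depth_is_high(self, rng):
        gl, geno, _ = random_gl(rng, 20, 8, 40.0)
        saf = saf_loglik(gl.logl, gl.missing)
        truth = geno.sum(axis=0)
        assert np.array_equal(np.argmax(saf, axis=1), truth)

    def test_sfs_em_recovers_spectrum_shape(self, rng):
        gl, geno, _ = random_gl(rng, 400, 10, 30.0)
        phi = sfs_em(saf_loglik(gl.logl, gl.missing))
        counts = np.bincount(geno.sum(axis=0), minlength=21) / 400
        assert np.max(np.abs(phi - counts)) < 0.05
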