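"""Cohort generator: founders, NC II breeding, liability, trawl, reads."""

import numpy as np
import pandas as pd
import pytest

import trawlscan as ts
from trawlscan.synthetic_cohort import DENSITIES


class TestFounderPanel:
    def test_shape_and_range_contract(self, founder_panel):
        p = founder_panel
        assert p.n_founders == 24
        assert (p.sex == "M").sum() == 12 and (p.sex == "F").sum() == 12
        assert p.n_sites == 1500
        assert set(np.unique(p.genotypes)) <= {0, 1, 2}
        assert np.all((p.anc_maf >= 0.05) & (p.anc_maf <= 0.5))
        # coordinates: 1-based, sorted within chromosome
        df = pd.DataFrame({"chrom": p.chrom, "pos": p.pos})
        assert (df["pos"] >= 1).all()
        assert df.groupby("chrom", sort=False)["pos"].apply(
            lambda s: s.is_monotonic_increasing
        ).all()

    def test_zero_maf_gives_monomorphic_founders(self):
        p = ts.draw_founder_panel(50, maf_low=0.0, maf_high=0.0, seed=1)
        assert np.all(p.genotypes == 0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ts.draw_founder_panel(10, maf_low=0.4, maf_high=0.2, seed=1)
        with pytest.raises(ValueError):
            ts.draw_founder_panel(10, maf_low=0.1, maf_high=0.7, seed=1)

    def test_founder_frequency_matches_ancestral_maf(self):
        # binomial sampling oracle: mean deviation of the realised founder
        # frequency from the ancestral MAF is 0 within 3 standard errors
        p = ts.draw_founder_panel(10_000, seed=3)
        obs = p.genotypes.mean(axis=0) / 2.0
        diff = obs - p.anc_maf
        se = diff.std(ddof=1) / np.sqrt(diff.size)
        assert abs(diff.mean()) < 3 * se


class TestBreeding:
    def test_default_design_gives_36_families(self, trawl_cohort):
        assert trawl_cohort.table["family_id"].nunique() == 36
        sizes = trawl_cohort.table.groupby(["family_id", "density"]).size()
        assert (sizes == 10).all()

    def test_single_pair_block_gives_one_family(self):
        p = ts.draw_founder_panel(20, seed=1, n_founders=2)
        cohort = ts.breed_nc2(
            p, 5, seed=2, n_blocks=1, males_per_block=1, females_per_block=1
        )
        assert cohort.table["family_id"].nunique() == 1
        assert cohort.n == 10

    def test_mendelian_fixed_cross(self):
        # dosage-2 x dosage-0 parents must give all-heterozygous offspring
        p = ts.draw_founder_panel(30, seed=1, n_founders=2)
        p.genotypes[0, :] = 2
        p.genotypes[1, :] = 0
        cohort = ts.breed_nc2(
            p, 8, seed=2, n_blocks=1, males_per_block=1, females_per_block=1
        )
        assert np.all(cohort.genotypes == 1)

    def test_insufficient_founders_rejected(self):
        p = ts.draw_founder_panel(10, seed=1, n_founders=6)
        with pytest.raises(ValueError, match="males"):
            ts.breed_nc2(p, 2, seed=2)

    def test_offspring_frequency_matches_mid_parent(self, founder_panel):
        cohort = ts.breed_nc2(founder_panel, 40, seed=9)
        fam = cohort.table["family_id"].to_numpy()
        one_family = fam == fam[0]
        geno = cohort.genotypes[one_family]
        # recover the parents of that family from the design
        b, mi, fi = 0, 0, 0  # family B1M1F1 is the first bred
        dad = founder_panel.genotypes[np.flatnonzero(founder_panel.sex == "M")[mi]]
        mum = founder_panel.genotypes[np.flatnonzero(founder_panel.sex == "F")[fi]]
        mid_parent = (dad + mum) / 4.0  # expected offspring allele frequency
        obs = geno.mean(axis=0) / 2.0
        n_off = geno.shape[0]
        se = np.sqrt(np.maximum(mid_parent * (1 - mid_parent), 1e-3) / (2 * n_off))
        assert np.mean(np.abs(obs - mid_parent) < 4 * se) > 0.95


class TestLiabilityAndPhenotypes:
    def test_zero_effects_zero_noise_gives_zero_liability(self, founder_panel):
        cohort = ts.breed_nc2(founder_panel, 2, seed=1)
        model = ts.EffectModel.null(env_sd=0.0)
        out = ts.assign_liability_and_phenotypes(cohort, model, seed=2)
        assert np.all(out.table["liability"] == 0.0)

    def test_single_locus_liability_equals_genotype(self, founder_panel):
        cohort = ts.breed_nc2(founder_panel, 2, seed=1)
        locus = np.array([5])
        model = ts.EffectModel(locus, locus, np.array([1.0]), np.array([1.0]), env_sd=0.0)
        out = ts.assign_liability_and_phenotypes(cohort, model, seed=2)
        assert np.allclose(out.table["liability"], cohort.genotypes[:, 5])

    def test_phenotype_directions_follow_loadings(self, trawl_cohort):
        # escaped-advantage loadings: vulnerability (high liability) goes with
        # slower growth, lower aerobic scope, more bites, shorter distance
        t = trawl_cohort.table
        z = t["liability_z"]
        assert np.corrcoef(z, t["sgr"])[0, 1] < 0
        assert np.corrcoef(z, t["aerobic_scope"])[0, 1] < 0
        assert np.corrcoef(z, t["aggression_bites"])[0, 1] > 0
        assert np.corrcoef(z, t["sociability_distance"])[0, 1] < 0

    def test_aerobic_scope_identity_holds(self, trawl_cohort):
        t = trawl_cohort.table
        assert np.allclose(t["aerobic_scope"], t["mmr"] - t["smr"])
        assert (t["smr"] <= t["mmr"]).all()

    def test_out_of_range_locus_rejected(self, founder_panel):
        cohort = ts.breed_nc2(founder_panel, 1, seed=1)
        bad = np.array([founder_panel.n_sites + 10])
        model = ts.EffectModel(bad, bad, np.array([1.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="locus"):
            ts.assign_liability_and_phenotypes(cohort, model, seed=2)


class TestTrawlSelection:
    def test_selection_bookkeeping(self, trawl_cohort):
        # 360 fish per density with the 20% rule: 72 captured, 72 escaped
        t = trawl_cohort.table
        for density in DENSITIES:
            sub = t[t["density"] == density]
            assert len(sub) == 360
            counts = sub["vulnerability"].value_counts()
            assert counts["captured"] == 72
            assert counts["escaped"] == 72

    def test_first_trial_has_22_events(self, trawl_cohort):
        report = trawl_cohort.meta["trawl_report"]["densities"]
        for density in DENSITIES:
            assert report[density]["events_per_trial"][0] == 22

    def test_conservation_of_individuals(self, trawl_cohort):
        t = trawl_cohort.table
        for density in DENSITIES:
            sub = t[t["density"] == density]
            counts = sub["vulnerability"].value_counts()
            total = sum(counts.get(k, 0) for k in ("captured", "escaped", "intermediate", "none"))
            assert total == 360

    def test_captured_and_escaped_exclusive(self, trawl_cohort):
        t = trawl_cohort.table
        esc = t[t["vulnerability"] == "escaped"]
        assert not esc["ever_captured"].any()
        cap = t[t["vulnerability"] == "captured"]
        assert (cap["removed_in_trial"] == 1).all()

    def test_zero_noise_captures_top_liability_fraction(self, founder_panel, effect_model):
        cohort = ts.breed_nc2(founder_panel, 10, seed=3)
        cohort = ts.assign_liability_and_phenotypes(cohort, effect_model, seed=4)
        config = ts.TrawlConfig(event_noise_sd=0.0)
        out = ts.run_trawl_selection(cohort, config, seed=5)
        t = out.table
        for density in DENSITIES:
            sub = t[t["density"] == density]
            top = set(sub.nlargest(72, "liability_z")["individual_id"])
            captured = set(sub[sub["vulnerability"] == "captured"]["individual_id"])
            assert captured == top

    def test_fixed_count_exhaustion_names_trial(self, founder_panel, effect_model):
        cohort = ts.breed_nc2(founder_panel, 1, seed=3)  # 36 per density
        cohort = ts.assign_liability_and_phenotypes(cohort, effect_model, seed=4)
        config = ts.TrawlConfig(
            removal_policy="fixed_count", removal_count=20, capture_threshold=-10.0
        )
        with pytest.raises(RuntimeError, match="trial 2"):
            ts.run_trawl_selection(cohort, config, seed=5)

    def test_single_selected_locus_dominates_group_difference(self, founder_panel):
        # heritability sanity: with no environmental noise and one selected
        # locus, the captured-escaped frequency difference peaks at that locus
        cohort = ts.breed_nc2(founder_panel, 10, seed=6)
        locus = np.array([123])
        model = ts.EffectModel(locus, locus, np.array([1.0]), np.array([1.0]), env_sd=0.0)
        cohort = ts.assign_liability_and_phenotypes(cohort, model, seed=7)
        out = ts.run_trawl_selection(cohort, ts.TrawlConfig(), seed=8)
        t = out.table
        m = (t["density"] == "baseline").to_numpy()
        cap = m & (t["vulnerability"] == "captured").to_numpy()
        esc = m & (t["vulnerability"] == "escaped").to_numpy()
        daf = np.abs(
            out.genotypes[cap].mean(axis=0) - out.genotypes[esc].mean(axis=0)
        )
        assert np.argmax(daf) == 123

    def test_determinism(self, founder_panel, effect_model):
        def build(seed):
            c = ts.breed_nc2(founder_panel, 5, seed=seed)
            c = ts.assign_liability_and_phenotypes(c, effect_model, seed=seed + 1)
            return ts.run_trawl_selection(c, ts.TrawlConfig(), seed=seed + 2)

        a, b = build(11), build(11)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert np.array_equal(a.genotypes, b.genotypes)


class TestSequencingPanel:
    def test_group_sizes(self, sample_sheet):
        sizes = sample_sheet.groupby(["density", "group"]).size()
        assert (sizes == 24).all()
        assert len(sample_sheet) == 96
        assert sample_sheet["individual_id"].is_unique


class TestReadCounts:
    def test_depth_distribution(self, rng):
        genotypes = rng.integers(0, 3, size=(96, 10_000)).astype(np.int8)
        counts = ts.simulate_read_counts(genotypes, 2.0, 0.5, 0.01, seed=1)
        grand = counts.depth.mean()
        assert 1.8 < grand < 2.2

    def test_error_free_homozygote_reads(self, rng):
        genotypes = np.full((4, 200), 2, dtype=np.int8)
        counts = ts.simulate_read_counts(genotypes, 5.0, 0.0, 0.0, seed=2)
        assert np.all(counts.ref == 0)

    def test_error_boundary_rejected(self, rng):
        genotypes = np.zeros((2, 10), dtype=np.int8)
        with pytest.raises(ValueError):
            ts.simulate_read_counts(genotypes, 2.0, 0.5, 0.5, seed=1)
        with pytest.raises(ValueError):
            ts.simulate_read_counts(genotypes, 0.0, 0.5, 0.01, seed=1)

    def test_determinism(self, rng):
        genotypes = rng.integers(0, 3, size=(10, 500)).astype(np.int8)
        a = ts.simulate_read_counts(genotypes, 2.0, 0.5, 0.01, seed=42)
        b = ts.simulate_read_counts(genotypes, 2.0, 0.5, 0.01, seed=42)
        assert np.array_equal(a.ref, b.ref) and np.array_equal(a.alt, b.alt)


class TestGeneAnnotation:
    def test_empty_annotation(self):
        ann = ts.make_gene_annotation(0, {"chr1": 10_000}, seed=1)
        assert len(ann) == 0

    def test_disjoint_intervals(self):
        ann = ts.make_gene_annotation(
            100, {"chr1": 2_000_000, "chr2": 2_000_000}, seed=2, mean_length=5_000
        )
        assert len(ann) == 100
        for _, g in ann.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            ts.make_gene_annotation(
                50, {"chr1": 10_000}, seed=3, mean_length=10_000, sd_log=0.01
            )

    def test_genic_snp_fraction_tracks_gene_span(self, rng):
        genome = {"chr1": 1_000_000}
        ann = ts.make_gene_annotation(40, genome, seed=4, mean_length=8_000)
        span = (ann["end"] - ann["start"]).sum()
        pos = rng.integers(1, 1_000_001, size=5_000)
        sites = pd.DataFrame({"chrom": "chr1", "pos": pos})
        assigned = ts.map_sites_to_genes(sites, ann)
        frac = assigned["annotated"].mean()
        expect = span / 1_000_000
        se = np.sqrt(expect * (1 - expect) / 5_000)
        assert abs(frac - expect) < 4 * se
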