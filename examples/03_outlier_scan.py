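"""The zdAF outlier scan with its permutation-derived thresholds.

Computes captured-vs-escaped allele-frequency differences per density,
standardises them genome-wide (zdAF), builds the empirical null from 625
pairings of 25 random 24-fish groups, compiles per-SNP Bonferroni
quantiles into global 0.5% cutoffs, and calls outlier SNPs.
"""

import warnings

import numpy as np

import trawlscan as ts

# build the sequenced dataset (as in example 02, condensed)
panel = ts.draw_founder_panel(4000, seed=1)
cohort = ts.breed_nc2(panel, 10, seed=2)
effects = ts.EffectModel.gxe(panel, seed=3)
cohort = ts.assign_liability_and_phenotypes(cohort, effects, seed=4)
cohort = ts.run_trawl_selection(cohort, ts.TrawlConfig(), seed=5)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sheet = ts.select_sequencing_panel(cohort, 24, seed=6)
idx = sheet["cohort_index"].to_numpy()
counts = ts.simulate_read_counts(cohort.genotypes[idx], seed=7,
                                 chrom=cohort.chrom, pos=cohort.pos)
gl = ts.genotype_likelihoods(counts.ref, counts.alt, 0.01,
                             chrom=counts.chrom, pos=counts.pos)
freq, _, _ = ts.em_maf(gl.logl, gl.missing)
gl_pol, maf, _ = ts.polarize_to_minor(gl, freq)
panel_df, _ = ts.apply_site_filters(counts.ref, counts.alt, gl_pol, maf_hat=maf)
mask = panel_df["pass"].to_numpy()

plan = ts.build_permutation_groups(np.arange(96), G=25, size=24, seed=8)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    null = ts.null_zdaf_distribution(gl_pol, plan, site_mask=mask)
print(f"permutation null: {null.shape[1]} pairings x {null.shape[0]} SNPs")

for density in ("baseline", "reduced"):
    cap = np.flatnonzero(((sheet["density"] == density)
                          & (sheet["group"] == "captured")).to_numpy())
    esc = np.flatnonzero(((sheet["density"] == density)
                          & (sheet["group"] == "escaped")).to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        daf, outliers, report = ts.scan_density(
            gl_pol, cap, esc, plan, site_mask=mask, null_matrix=null
        )
    print(f"\n{density}: global cutoffs "
          f"[{report.z_lo:.2f}, {report.z_hi:.2f}] "
          f"(Bonferroni level {report.alpha_bonf:.2e} per tail)")
    print(f"  {len(outliers)} outlier SNPs of {len(daf)} tested")
    if len(outliers):
        print(outliers[["chrom", "pos", "daf", "zdaf", "tail"]].to_string(index=False))

print("\nOutliers are SNPs whose captured-escaped frequency difference, "
      "standardised genome-wide, exceeds what 625 random group pairings produce.")
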