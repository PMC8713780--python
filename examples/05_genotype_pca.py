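"""Genotype-likelihood PCA and the analysis PC.

Computes posterior expected dosages from likelihood triples under a
Hardy-Weinberg prior, runs the normalised-dosage PCA, and picks the
component that separates captured from escaped fish.
"""

import numpy as np

import trawlscan as ts
from trawlscan.genolik import em_maf

rng = np.random.default_rng(11)
# two diverged 24-fish groups at 200 "outlier-like" sites, sequenced at 2x
p_cap, p_esc = 0.75, 0.25
geno = np.vstack(
    [rng.binomial(2, p_cap, (24, 200)), rng.binomial(2, p_esc, (24, 200))]
).astype(np.int8)
labels = np.array(["captured"] * 24 + ["escaped"] * 24)
counts = ts.simulate_read_counts(geno, mean_depth=2.0,
                                 depth_sd_between_individuals=0.5,
                                 err=0.01, seed=12)
gl = ts.genotype_likelihoods(counts.ref, counts.alt, 0.01)
maf, _, _ = em_maf(gl.logl, gl.missing)

dosages = ts.posterior_dosages(gl, maf)
result = ts.genotype_pca(dosages, maf, n_components=6, analysis_pc=2)
print("variance explained (%):",
      np.round(100 * result.variance_explained[:4], 1))

idx, scores = ts.select_analysis_pc(result, "max_group_separation", labels=labels)
cap, esc = scores[labels == "captured"], scores[labels == "escaped"]
print(f"separating component: PC{idx}")
print(f"mean PC score  captured {cap.mean():+.3f}   escaped {esc.mean():+.3f}")
print("\nEven at 2x coverage the posterior-dosage PCA separates the groups; "
      "the per-fish PC score summarises their outlier-locus genotype and is "
      "the quantity correlated with phenotypes downstream.")
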