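"""Shared fixtures: a small end-to-end synthetic experiment, built once."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import trawlscan as ts

N_SITES = 1500
SEED = 7


@pytest.fixture(scope="session")
def founder_panel():
    return ts.draw_founder_panel(N_SITES, seed=SEED)


@pytest.fixture(scope="session")
def effect_model(founder_panel):
    return ts.EffectModel.gxe(founder_panel, seed=SEED + 1)


@pytest.fixture(scope="session")
def trawl_cohort(founder_panel, effect_model):
    """Full 720-fish cohort: bred, phenotyped, and trawl-selected."""
    cohort = ts.breed_nc2(founder_panel, 10, seed=SEED + 2)
    cohort = ts.assign_liability_and_phenotypes(cohort, effect_model, seed=SEED + 3)
    return ts.run_trawl_selection(cohort, ts.TrawlConfig(), seed=SEED + 4)


@pytest.fixture(scope="session")
def sample_sheet(trawl_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ts.select_sequencing_panel(trawl_cohort, 24, seed=SEED + 5)


@pytest.fixture(scope="session")
def sequenced(trawl_cohort, sample_sheet):
    """Read counts and polarised GL matrix for the 96 sequenced fish."""
    idx = sample_sheet["cohort_index"].to_numpy()
    counts = ts.simulate_read_counts(
        trawl_cohort.genotypes[idx],
        seed=SEED + 6,
        chrom=trawl_cohort.chrom,
        pos=trawl_cohort.pos,
        sample_ids=list(sample_sheet["individual_id"]),
    )
    gl = ts.genotype_likelihoods(
        counts.ref,
        counts.alt,
        counts.err,
        chrom=counts.chrom,
        pos=counts.pos,
        sample_ids=counts.sample_ids,
    )
    freq, _, _ = ts.em_maf(gl.logl, gl.missing)
    gl_pol, maf, _ = ts.polarize_to_minor(gl, freq)
    panel, report = ts.apply_site_filters(counts.ref, counts.alt, gl_pol, maf_hat=maf)
    return {
        "counts": counts,
        "gl": gl_pol,
        "maf": maf,
        "panel": panel,
        "report": report,
        "mask": panel["pass"].to_numpy(),
        "genotypes": trawl_cohort.genotypes[idx],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
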