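"""Genotype likelihoods and allele-frequency inference for low-coverage data.

This module works directly on per-site, per-individual read counts from
~2x whole-genome sequencing, where calling hard genotypes is unreliable.
Instead of genotypes it carries, for every site and individual, the
likelihood of the read data under each diploid dosage g in {0, 1, 2} of a
reference/alternate biallelic site, and estimates population allele
frequencies by maximum likelihood under Hardy-Weinberg equilibrium with an
EM algorithm.  On top of that sit a likelihood-ratio SNP test, the standard
site filters used for low-coverage scans (depth, number of covered
individuals, SNP p-value, minor-allele frequency), and expected
heterozygosity either from frequencies or from a maximum-likelihood site
frequency spectrum.

The per-read error model is symmetric: a read reports the true allele with
probability 1 - err.  Base- and mapping-quality screening is modelled as
applied upstream (reads below quality never enter the count matrix), which
is exact for simulated counts and mirrors how quality filters act before
likelihood computation in standard callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

__all__ = [
    "GLMatrix",
    "SiteFilterConfig",
    "genotype_likelihoods",
    "em_maf",
    "estimate_maf",
    "polarize_to_minor",
    "snp_lrt",
    "apply_site_filters",
    "expected_het",
    "HeResult",
    "saf_loglik",
    "sfs_em",
]

_DOSAGES = np.array([0.0, 1.0, 2.0])


@dataclass
class GLMatrix:
    """Per-site x per-individual genotype log-likelihoods for dosages 0/1/2.

    ``logl`` is shaped (L, N, 3) and normalised so the maximum of each
    triple is 0 in log space (likelihoods are defined up to a per-triple
    constant).  Site-individuals with no reads are flagged in ``missing``
    and carry flat triples.  The dosage axis counts copies of the allele in
    ``allele_minor`` once the matrix has been polarised (see
    :func:`polarize_to_minor`); before polarisation it counts the simulated
    alternate allele.
    """

    logl: np.ndarray
    missing: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    sample_ids: list[str] | None = None
    allele_major: np.ndarray | None = None
    allele_minor: np.ndarray | None = None
    polarized: bool = False

    @property
    def n_sites(self) -> int:
        return self.logl.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.logl.shape[1]

    def subset_individuals(self, idx: np.ndarray) -> "GLMatrix":
        idx = np.asarray(idx)
        return GLMatrix(
            logl=self.logl[:, idx, :],
            missing=self.missing[:, idx],
            chrom=self.chrom,
            pos=self.pos,
            sample_ids=None
            if self.sample_ids is None
            else [self.sample_ids[i] for i in idx],
            allele_major=self.allele_major,
            allele_minor=self.allele_minor,
            polarized=self.polarized,
        )

    def subset_sites(self, mask: np.ndarray) -> "GLMatrix":
        mask = np.asarray(mask)
        return GLMatrix(
            logl=self.logl[mask],
            missing=self.missing[mask],
            chrom=None if self.chrom is None else self.chrom[mask],
            pos=None if self.pos is None else self.pos[mask],
            sample_ids=self.sample_ids,
            allele_major=None if self.allele_major is None else self.allele_major[mask],
            allele_minor=None if self.allele_minor is None else self.allele_minor[mask],
            polarized=self.polarized,
        )


@dataclass
class SiteFilterConfig:
    """Site-filter thresholds for the low-coverage SNP panel.

    Defaults follow common practice for a 96-individual, ~2x dataset:
    SNP LRT p-value below 1e-6, summed depth across individuals within
    [48, 600], at least 48 individuals covered by >= 1 read, base and
    mapping quality >= 20 (applied upstream of the count matrix), and
    minor-allele frequency >= 0.05.
    """

    snp_pval: float = 1e-6
    min_total_depth: int = 48
    max_total_depth: int = 600
    min_individuals: int = 48
    min_base_q: int = 20
    min_map_q: int = 20
    min_maf: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "snp_pval",
            "min_total_depth",
            "max_total_depth",
            "min_individuals",
            "min_base_q",
            "min_map_q",
            "min_maf",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_total_depth > self.max_total_depth:
            raise ValueError("min_total_depth must be <= max_total_depth")


def genotype_likelihoods(
    ref: np.ndarray,
    alt: np.ndarray,
    err: float,
    *,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> GLMatrix:
    """Genotype log-likelihood triples from per-site/individual read counts.

    Under a symmetric per-read error ``err``, a read is the alternate
    allele with probability p_alt(g) = (g/2)(1-err) + (1-g/2) err for true
    dosage g, so L(g) is binomial in the observed counts.  Triples are
    normalised to max 0 in log space; zero-read entries are flagged
    missing with flat triples.
    """
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if ref.shape != alt.shape:
        raise ValueError("ref and alt count matrices must share a shape")
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    if not 0.0 < err < 0.5:
        raise ValueError("err must be in (0, 0.5)")

    p_alt = (_DOSAGES / 2.0) * (1.0 - err) + (1.0 - _DOSAGES / 2.0) * err  # (3,)
    logl = (
        alt[..., None] * np.log(p_alt)
        + ref[..., None] * np.log1p(-p_alt)
    )
    logl -= logl.max(axis=-1, keepdims=True)
    missing = (ref + alt) == 0
    logl[missing] = 0.0
    return GLMatrix(
        logl=logl, missing=missing, chrom=chrom, pos=pos, sample_ids=sample_ids
    )


def em_maf(
    logl: np.ndarray,
    missing: np.ndarray,
    *,
    init: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, int, np.ndarray]:
    """EM allele-frequency estimate per site, vectorised over sites.

    E-step: posterior over dosage g given the current frequency p under
    Hardy-Weinberg priors {(1-p)^2, 2p(1-p), p^2}; M-step: p <- mean
    posterior dosage / 2 over individuals with data.  Iterates until the
    largest |delta p| < ``tol`` or ``max_iter`` iterations.  Sites where no
    individual has data come back NaN.

    Returns (p_hat, n_iterations, per-site log-likelihood at p_hat).
    """
    logl = np.asarray(logl, dtype=float)
    missing = np.asarray(missing, dtype=bool)
    L, N, _ = logl.shape
    lik = np.exp(logl)
    observed = ~missing
    n_obs = observed.sum(axis=1)  # (L,)
    any_obs = n_obs > 0

    p = np.full(L, float(init))
    n_iter = 0
    # only iterate the sites that have not converged yet
    active = any_obs.copy()
    for n_iter in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        pa = p[idx]
        lik_a = lik[idx]
        priors = np.stack(
            [(1.0 - pa) ** 2, 2.0 * pa * (1.0 - pa), pa**2], axis=-1
        )  # (l, 3)
        w = lik_a * priors[:, None, :]
        denom = w.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            e_dos = (w[..., 1] + 2.0 * w[..., 2]) / denom
        e_dos = np.where(observed[idx], e_dos, 0.0)
        p_new = e_dos.sum(axis=1) / (2.0 * n_obs[idx])
        delta = np.abs(p_new - pa)
        p[idx] = p_new
        active[idx] = delta >= tol

    loglik = site_loglik(logl, missing, p)
    p = np.where(any_obs, p, np.nan)
    loglik = np.where(any_obs, loglik, np.nan)
    return p, n_iter, loglik


def site_loglik(logl: np.ndarray, missing: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Log-likelihood of frequency vector ``p`` per site under HWE priors."""
    p = np.asarray(p, dtype=float)
    pc = np.clip(p, 0.0, 1.0)
    priors = np.stack([(1.0 - pc) ** 2, 2.0 * pc * (1.0 - pc), pc**2], axis=-1)
    with np.errstate(divide="ignore"):
        log_priors = np.log(priors)
    per_ind = logsumexp(logl + log_priors[:, None, :], axis=-1)
    per_ind = np.where(missing, 0.0, per_ind)
    return per_ind.sum(axis=1)


def estimate_maf(
    gl_triples: np.ndarray,
    missing: np.ndarray | None = None,
    *,
    init: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float, int, float]:
    """Single-site EM allele-frequency estimate.

    ``gl_triples`` is (N, 3) log-likelihoods; raises if every individual is
    missing.
    """
    gl_triples = np.asarray(gl_triples, dtype=float)
    if missing is None:
        missing = np.all(gl_triples == gl_triples[:, :1], axis=1)
    missing = np.asarray(missing, dtype=bool)
    if missing.all():
        raise ValueError("cannot estimate a frequency with all individuals missing")
    p, n_iter, ll = em_maf(
        gl_triples[None], missing[None], init=init, tol=tol, max_iter=max_iter
    )
    return float(p[0]), n_iter, float(ll[0])


def polarize_to_minor(
    gl: GLMatrix, freq: np.ndarray
) -> tuple[GLMatrix, np.ndarray, np.ndarray]:
    """Re-index dosages so they count the globally minor allele.

    ``freq`` is the pooled-sample frequency of the allele the dosage axis
    currently counts.  Sites with freq > 0.5 have their triples reversed
    and frequency mapped to 1 - freq.  Fixing major/minor once from the
    pooled sample keeps group frequencies on a common allele so that
    between-group frequency differences cannot flip sign site-by-site.

    Returns (polarised GLMatrix, minor-allele frequency, flip mask).
    """
    freq = np.asarray(freq, dtype=float)
    flip = freq > 0.5
    logl = gl.logl.copy()
    logl[flip] = logl[flip][:, :, ::-1]
    maf = np.where(flip, 1.0 - freq, freq)
    major = np.where(flip, "1", "0")
    minor = np.where(flip, "0", "1")
    out = GLMatrix(
        logl=logl,
        missing=gl.missing.copy(),
        chrom=gl.chrom,
        pos=gl.pos,
        sample_ids=gl.sample_ids,
        allele_major=major,
        allele_minor=minor,
        polarized=True,
    )
    return out, maf, flip


def snp_lrt(
    logl: np.ndarray, missing: np.ndarray, maf_hat: np.ndarray
) -> np.ndarray:
    """Likelihood-ratio SNP test p-values per site.

    Lambda = 2 [l(maf_hat) - l(0)] against a chi-square with 1 df; the
    per-individual normalising constants cancel in the difference.  The
    boundary mixture at p = 0 is ignored (conservative by a factor of two
    at the boundary), matching the usual convention for this test.
    """
    maf_hat = np.asarray(maf_hat, dtype=float)
    ll_hat = site_loglik(logl, missing, maf_hat)
    ll_null = np.where(missing, 0.0, logl[..., 0]).sum(axis=1)
    lam = np.clip(2.0 * (ll_hat - ll_null), 0.0, None)
    return stats.chi2.sf(lam, df=1)


def apply_site_filters(
    ref: np.ndarray,
    alt: np.ndarray,
    gl: GLMatrix,
    config: SiteFilterConfig | None = None,
    *,
    maf_hat: np.ndarray | None = None,
    lrt_pvalue: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Apply the SNP-panel site filters; return the panel and a report.

    Filters: summed depth across individuals within
    [min_total_depth, max_total_depth]; >= min_individuals individuals with
    at least one read; SNP LRT p-value < snp_pval; polarised minor-allele
    frequency >= min_maf.  Base/mapping-quality thresholds act upstream of
    the count matrix and are recorded as pre-applied.  If ``maf_hat`` /
    ``lrt_pvalue`` are not supplied they are computed from ``gl`` pooled
    over all individuals (polarising to the minor allele first).
    """
    if config is None:
        config = SiteFilterConfig()
    ref = np.asarray(ref)
    alt = np.asarray(alt)
    if ref.shape != gl.logl.shape[:2]:
        raise ValueError("count matrix and GL matrix dimensions disagree")

    if maf_hat is None or lrt_pvalue is None:
        freq, _, _ = em_maf(gl.logl, gl.missing)
        gl_pol, maf_hat_c, _ = polarize_to_minor(gl, freq)
        if maf_hat is None:
            maf_hat = maf_hat_c
        if lrt_pvalue is None:
            lrt_pvalue = snp_lrt(gl_pol.logl, gl_pol.missing, maf_hat)

    depth = (ref + alt).sum(axis=1)
    n_covered = ((ref + alt) > 0).sum(axis=1)

    pass_depth = (depth >= config.min_total_depth) & (depth <= config.max_total_depth)
    pass_ind = n_covered >= config.min_individuals
    with np.errstate(invalid="ignore"):
        pass_snp = np.nan_to_num(lrt_pvalue, nan=1.0) < config.snp_pval
        pass_maf = np.nan_to_num(maf_hat, nan=0.0) >= config.min_maf
    overall = pass_depth & pass_ind & pass_snp & pass_maf

    panel = pd.DataFrame(
        {
            "chrom": gl.chrom if gl.chrom is not None else np.repeat("1", len(depth)),
            "pos": gl.pos if gl.pos is not None else np.arange(1, len(depth) + 1),
            "major": gl.allele_major if gl.allele_major is not None else "0",
            "minor": gl.allele_minor if gl.allele_minor is not None else "1",
            "maf_hat": maf_hat,
            "lrt_pvalue": lrt_pvalue,
            "total_depth": depth,
            "n_covered": n_covered,
            "pass_depth": pass_depth,
            "pass_individuals": pass_ind,
            "pass_snp_pval": pass_snp,
            "pass_maf": pass_maf,
            "pass": overall,
        }
    )
    report = {
        "n_sites": int(len(depth)),
        "pass_depth": int(pass_depth.sum()),
        "pass_individuals": int(pass_ind.sum()),
        "pass_snp_pval": int(pass_snp.sum()),
        "pass_maf": int(pass_maf.sum()),
        "pass_all": int(overall.sum()),
        "pre_applied": {
            "min_base_q": config.min_base_q,
            "min_map_q": config.min_map_q,
            "note": "quality screening acts upstream of the count matrix",
        },
        "thresholds": {
            "snp_pval": config.snp_pval,
            "min_total_depth": config.min_total_depth,
            "max_total_depth": config.max_total_depth,
            "min_individuals": config.min_individuals,
            "min_maf": config.min_maf,
        },
    }
    return panel, report


@dataclass
class HeResult:
    """Expected heterozygosity with the estimation mode recorded."""

    he: float
    mode: str
    sfs: np.ndarray | None = None

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.he


def expected_het(data, mode: str = "freq") -> HeResult:
    """Expected heterozygosity across a site panel.

    mode="freq" (default): ``data`` is a vector of minor-allele
    frequencies; He is the mean of 2 p (1 - p).  mode="sfs": ``data`` is a
    :class:`GLMatrix`; the maximum-likelihood sample site frequency
    spectrum is fit by EM over the genotype likelihoods and He is the
    expected heterozygosity 2 p (1 - p) averaged under that spectrum.
    """
    if mode == "freq":
        p = np.asarray(data, dtype=float)
        p = p[~np.isnan(p)]
        if p.size == 0:
            raise ValueError("expected_het needs at least one site")
        he = float(np.mean(2.0 * p * (1.0 - p)))
        return HeResult(he=he, mode="freq")
    if mode == "sfs":
        if not isinstance(data, GLMatrix):
            raise TypeError("mode='sfs' expects a GLMatrix")
        if data.n_sites == 0:
            raise ValueError("expected_het needs at least one site")
        saf = saf_loglik(data.logl, data.missing)
        sfs = sfs_em(saf)
        n_chrom = saf.shape[1] - 1
        p = np.arange(n_chrom + 1) / n_chrom
        he = float(np.sum(sfs * 2.0 * p * (1.0 - p)))
        return HeResult(he=he, mode="sfs", sfs=sfs)
    raise ValueError(f"unknown mode {mode!r}")


def saf_loglik(logl: np.ndarray, missing: np.ndarray) -> np.ndarray:
    """Per-site log-likelihood of each sample allele frequency (SAF).

    For j copies of the allele among 2N chromosomes, P(data | j) is the
    coefficient of x^j in prod_i [L_i(0) + 2 L_i(1) x + L_i(2) x^2]
    divided by C(2N, j) (genotype configurations given j are multivariate
    hypergeometric).  Computed by a site-vectorised polynomial convolution
    with per-step renormalisation; no-data individuals contribute flat
    triples.  O(N^2 L), intended for modest panels.
    """
    logl = np.asarray(logl, dtype=float)
    L, N, _ = logl.shape
    lik = np.exp(logl)
    lik[np.asarray(missing, dtype=bool)] = 1.0

    poly = np.zeros((L, 2 * N + 1))
    poly[:, 0] = 1.0
    logscale = np.zeros(L)
    width = 1  # number of occupied coefficients so far
    for i in range(N):
        a0 = lik[:, i, 0][:, None]
        a1 = lik[:, i, 1][:, None]
        a2 = lik[:, i, 2][:, None]
        seg = poly[:, :width]
        new = np.zeros((L, width + 2))
        new[:, :width] += seg * a0
        new[:, 1 : width + 1] += seg * (2.0 * a1)
        new[:, 2 : width + 2] += seg * a2
        norm = new.max(axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        new /= norm
        logscale += np.log(norm[:, 0])
        width += 2
        poly[:, :width] = new
    with np.errstate(divide="ignore"):
        log_poly = np.log(poly)
    j = np.arange(2 * N + 1)
    log_binom = gammaln(2 * N + 1) - gammaln(j + 1) - gammaln(2 * N - j + 1)
    return log_poly + logscale[:, None] - log_binom[None, :]


def sfs_em(
    saf: np.ndarray, *, tol: float = 1e-8, max_iter: int = 200
) -> np.ndarray:
    """Maximum-likelihood site frequency spectrum by EM over SAF likelihoods."""
    saf = np.asarray(saf, dtype=float)
    L, K = saf.shape
    saf = saf - saf.max(axis=1, keepdims=True)
    lik = np.exp(saf)
    phi = np.full(K, 1.0 / K)
    for _ in range(max_iter):
        w = lik * phi[None, :]
        w /= w.sum(axis=1, keepdims=True)
        phi_new = w.mean(axis=0)
        if np.max(np.abs(phi_new - phi)) < tol:
            phi = phi_new
            break
        phi = phi_new
    return phi
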