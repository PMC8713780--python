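"""Genotype-likelihood PCA on outlier sites.

Hard genotype calls are unreliable at ~2x coverage, so individual scores
are computed from posterior expected dosages: the genotype likelihood
triple at each site is combined with a Hardy-Weinberg prior at the
site's minor-allele frequency, and the posterior mean dosage (2p for
missing data) is used in place of the genotype.  Dosages are centred by
2p and scaled by sqrt(2p(1-p)), the individual-by-individual covariance
is averaged over sites, and its eigendecomposition gives eigenvalues,
individual scores and site loadings.  An optional iterative refinement
re-estimates individual allele frequencies from the top components and
recomputes dosages until the covariance stabilises; the default is a
single pass, which is sufficient when the analysed sites already separate
the groups strongly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genolik import GLMatrix

__all__ = ["PCAResult", "posterior_dosages", "genotype_pca", "select_analysis_pc"]


@dataclass
class PCAResult:
    """Eigenvalues (descending), individual scores and site loadings.

    Component indices are 1-based everywhere (``analysis_pc`` = 2 means the
    second component).  Each component's sign is fixed so that its
    largest-magnitude site loading is positive.
    """

    eigenvalues: np.ndarray  # (k,)
    scores: np.ndarray  # (n_individuals, k)
    loadings: np.ndarray  # (n_sites, k)
    analysis_pc: int
    n_iterations: int
    converged: bool
    kept_sites: np.ndarray  # mask of sites with 0 < p < 1 actually used
    covariance: np.ndarray  # (n, n) averaged over sites

    @property
    def variance_explained(self) -> np.ndarray:
        tot = self.eigenvalues.sum()
        return self.eigenvalues / tot if tot > 0 else self.eigenvalues * 0.0


def posterior_dosages(gl: GLMatrix, maf: np.ndarray) -> np.ndarray:
    """Posterior expected dosage per individual and site.

    HWE prior {(1-p)^2, 2p(1-p), p^2} times the likelihood triple,
    normalised; the expected dosage is sum_g g * posterior(g).  Missing
    site-individuals get the prior mean 2p.  Returns (n_individuals,
    n_sites).
    """
    maf = np.asarray(maf, dtype=float)
    if np.any((maf < 0) | (maf > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    lik = np.exp(gl.logl)  # (L, N, 3)
    priors = np.stack(
        [(1.0 - maf) ** 2, 2.0 * maf * (1.0 - maf), maf**2], axis=-1
    )  # (L, 3)
    w = lik * priors[:, None, :]
    denom = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dos = (w[..., 1] + 2.0 * w[..., 2]) / denom
    dos = np.where(gl.missing, 2.0 * maf[:, None], dos)
    return dos.T  # (N, L)


def _fix_signs(eigvecs: np.ndarray, loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            eigvecs[:, k] *= -1.0
    return eigvecs, loadings


def genotype_pca(
    dosages: np.ndarray,
    maf: np.ndarray,
    n_components: int | None = None,
    iterate: bool = False,
    *,
    gl: GLMatrix | None = None,
    analysis_pc: int = 2,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> PCAResult:
    """PCA of normalised posterior dosages.

    Entries are centred by 2p and scaled by sqrt(2p(1-p)); the n x n
    covariance is the average over sites of the outer products.  Sites
    fixed in the sample (p = 0 or 1) carry no variance and are dropped
    with a warning.  With ``iterate`` (and ``gl`` supplied), individual
    allele frequencies are re-estimated from the top components and the
    dosages recomputed until the covariance changes by less than ``tol``.
    """
    dosages = np.asarray(dosages, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n, L = dosages.shape
    if n < 2 or L < 1:
        raise ValueError("need at least 2 individuals and 1 site")

    keep = (maf > 0.0) & (maf < 1.0) & ~np.isnan(maf)
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance sites from the PCA",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no polymorphic sites left for the PCA")
    X = dosages[:, keep]
    p = maf[keep]
    k = n_components or min(n, 10)
    k = min(k, n)

    def normalised(Xd: np.ndarray) -> np.ndarray:
        return (Xd - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]

    Z = normalised(X)
    cov = (Z @ Z.T) / Z.shape[1]
    n_iter = 0
    converged = True
    if iterate:
        if gl is None:
            raise ValueError("iterate=True needs the GL matrix to recompute dosages")
        gl_kept = gl.subset_sites(keep)
        lik = np.exp(gl_kept.logl)  # (L, N, 3)
        converged = False
        for n_iter in range(1, max_iter + 1):
            vals, vecs = np.linalg.eigh(cov)
            order = np.argsort(vals)[::-1]
            top = vecs[:, order[:k]]
            # individual allele frequencies from the low-rank reconstruction
            resid = X / 2.0 - p[None, :]
            pi = p[None, :] + top @ (top.T @ resid)
            pi = np.clip(pi, 1e-4, 1.0 - 1e-4)  # (N, L)
            pri = np.stack(
                [(1.0 - pi) ** 2, 2.0 * pi * (1.0 - pi), pi**2], axis=-1
            )  # (N, L, 3)
            w = lik.transpose(1, 0, 2) * pri
            dos = (w[..., 1] + 2.0 * w[..., 2]) / w.sum(axis=-1)
            miss = gl_kept.missing.T
            X = np.where(miss, 2.0 * pi, dos)
            Z = normalised(X)
            cov_new = (Z @ Z.T) / Z.shape[1]
            delta = np.max(np.abs(cov_new - cov))
            cov = cov_new
            if delta < tol:
                converged = True
                break

    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    eigvals = np.clip(vals[order], 0.0, None)
    eigvecs = vecs[:, order]
    scores = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        loadings = Z.T @ eigvecs / (np.sqrt(np.maximum(eigvals, 1e-12)) * Z.shape[1])
    eigvecs, loadings = _fix_signs(scores, loadings)
    scores = eigvecs

    full_loadings = np.zeros((len(maf), scores.shape[1]))
    full_loadings[keep] = loadings
    if not 1 <= analysis_pc <= scores.shape[1]:
        raise ValueError(
            f"analysis_pc {analysis_pc} out of range 1..{scores.shape[1]}"
        )
    return PCAResult(
        eigenvalues=eigvals,
        scores=scores,
        loadings=full_loadings,
        analysis_pc=analysis_pc,
        n_iterations=n_iter,
        converged=converged,
        kept_sites=keep,
        covariance=cov,
    )


def select_analysis_pc(
    result: PCAResult,
    strategy: str = "fixed_index",
    *,
    index: int | None = None,
    labels: np.ndarray | None = None,
) -> tuple[int, np.ndarray]:
    """Pick the component used for downstream statistics.

    ``fixed_index`` (default) returns the configured component — index 2
    unless overridden, matching the convention of taking the second
    component when the first one absorbs within-group variability.
    ``max_group_separation`` picks the component with the largest
    between-group to within-group variance ratio for the supplied labels.
    Returns (1-based component index, score vector).
    """
    k = result.scores.shape[1]
    if strategy == "fixed_index":
        idx = index if index is not None else result.analysis_pc
        if not 1 <= idx <= k:
            raise ValueError(f"component index {idx} out of range 1..{k}")
        return idx, result.scores[:, idx - 1]
    if strategy == "max_group_separation":
        if labels is None:
            raise ValueError("max_group_separation needs group labels")
        labels = np.asarray(labels)
        best, best_ratio = 1, -np.inf
        for c in range(k):
            s = result.scores[:, c]
            groups = [s[labels == g] for g in np.unique(labels)]
            within = np.sum([len(g) * np.var(g) for g in groups])
            grand = s.mean()
            between = np.sum([len(g) * (g.mean() - grand) ** 2 for g in groups])
            ratio = between / within if within > 0 else np.inf
            if ratio > best_ratio:
                best, best_ratio = c + 1, ratio
        return best, result.scores[:, best - 1]
    raise ValueError(f"unknown strategy {strategy!r}")
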