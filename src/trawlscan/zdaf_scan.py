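"""zdAF outlier scan: group allele frequencies, permutation null, thresholds.

The scan statistic is the z-transformed difference in minor-allele
frequency between captured and escaped fish at each SNP:

    dAF  = p_captured - p_escaped
    zdAF = (dAF - mean(dAF)) / sd(dAF)

with the moments taken over all SNPs in the comparison (sample SD, n-1
denominator).  Significance comes from an empirical null: G random
permutation groups of fixed size are drawn from the sequenced individuals,
zdAF is recomputed for every pairing of permutation groups (G^2 = 625
ordered pairings for the default G = 25, self-pairings included and
defined as exactly zero), and each SNP receives upper/lower null quantile
thresholds at a Bonferroni-corrected per-tail level tail_p / L.  The
per-SNP thresholds are then compiled into a single global pair of cutoffs
at the 0.5% quantile, and outliers are the SNPs whose observed zdAF
strictly exceeds a global cutoff.

With 625 null values per site and a Bonferroni level far below 1/625 the
per-site quantiles clamp to the null sample extremes; this degeneracy is
inherent to the design and is surfaced in the threshold report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genolik import GLMatrix, em_maf

__all__ = [
    "PermutationPlan",
    "ThresholdReport",
    "group_freqs",
    "compute_zdaf",
    "build_permutation_groups",
    "null_zdaf_distribution",
    "per_site_null_quantiles",
    "global_thresholds",
    "call_outliers",
    "scan_density",
]

PAIRING_SCHEMES = ("ordered_with_self", "ordered_no_self", "unordered")


@dataclass
class PermutationPlan:
    """G random groups of ``size`` individuals used to build the null.

    Groups are drawn without replacement within themselves and
    independently of each other, so they may overlap when G x size exceeds
    the pool (as for the default 25 x 24 from 96 fish).
    """

    groups: list[np.ndarray]
    size: int
    seed: int | None
    pool: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class ThresholdReport:
    """Per-site null quantile thresholds and the derived global cutoffs."""

    lower: np.ndarray
    upper: np.ndarray
    z_lo: float
    z_hi: float
    tail_p: float
    l_total: int
    alpha_bonf: float
    global_q: float
    clamped_fraction: float
    scheme: str = "ordered_with_self"
    notes: list[str] = field(default_factory=list)


def group_freqs(gl: GLMatrix, members: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site within a group of individuals.

    EM maximum-likelihood estimate restricted to ``members`` (indices into
    the GL individual axis).  Polarisation must already be fixed globally:
    the dosage axis counts the pooled-sample minor allele, so frequencies
    from different groups are comparable.  Sites where no member has data
    come back NaN and are excluded from downstream moments.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("group_freqs needs a non-empty member list")
    sub = gl.subset_individuals(members)
    p, _, _ = em_maf(sub.logl, sub.missing)
    return p


def compute_zdaf(p_a: np.ndarray, p_b: np.ndarray) -> np.ndarray:
    """z-transformed allele-frequency difference between two groups.

    zdAF = (dAF - mean(dAF)) / sd(dAF) with dAF = p_a - p_b and sample
    moments (ddof=1) over all sites in the comparison.  NaN frequencies
    propagate and are excluded from the moments.  A comparison with zero
    dAF variance (e.g. a group against itself) is degenerate and raises.
    """
    p_a = np.asarray(p_a, dtype=float)
    p_b = np.asarray(p_b, dtype=float)
    if p_a.shape != p_b.shape:
        raise ValueError("frequency vectors must have equal length")
    if p_a.size < 2:
        raise ValueError("need at least two sites to standardise")
    daf = p_a - p_b
    valid = ~np.isnan(daf)
    sd = np.std(daf[valid], ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError("degenerate comparison: dAF has zero variance")
    return (daf - np.mean(daf[valid])) / sd


def build_permutation_groups(
    individual_ids: np.ndarray, G: int = 25, size: int = 24, seed=None
) -> PermutationPlan:
    """Draw G permutation groups of ``size`` individuals from the pool."""
    pool = np.asarray(individual_ids)
    if size > pool.size:
        raise ValueError(f"group size {size} exceeds pool of {pool.size}")
    rng = np.random.default_rng(seed)
    groups = [rng.choice(pool, size=size, replace=False) for _ in range(G)]
    return PermutationPlan(
        groups=groups,
        size=size,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        pool=pool,
    )


def null_zdaf_distribution(
    gl: GLMatrix,
    plan: PermutationPlan,
    scheme: str = "ordered_with_self",
    *,
    site_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Null zdAF matrix (sites x pairings) from the permutation groups.

    Group frequencies are estimated once per group; zdAF is standardised
    within each pairing.  Pairing counts: G^2 (ordered_with_self, the
    default), G(G-1) (ordered_no_self) or G(G-1)/2 (unordered).
    Self-pairings have dAF identically zero; their 0/0 standardisation is
    defined as 0 at every site.
    """
    if scheme not in PAIRING_SCHEMES:
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    use = gl if site_mask is None else gl.subset_sites(site_mask)
    G = plan.n_groups
    freqs = np.stack([group_freqs(use, g) for g in plan.groups])  # (G, L)
    L = freqs.shape[1]

    if scheme == "ordered_with_self":
        pairs = [(i, j) for i in range(G) for j in range(G)]
    elif scheme == "ordered_no_self":
        pairs = [(i, j) for i in range(G) for j in range(G) if i != j]
    else:
        pairs = [(i, j) for i in range(G) for j in range(i + 1, G)]

    null = np.empty((L, len(pairs)))
    for k, (i, j) in enumerate(pairs):
        if i == j:
            null[:, k] = 0.0
        else:
            null[:, k] = compute_zdaf(freqs[i], freqs[j])
    return null


def per_site_null_quantiles(
    null_matrix: np.ndarray, tail_p: float, l_total: int
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-site (lower, upper) null quantiles at the Bonferroni level.

    The per-tail level is alpha_bonf = tail_p / l_total (``l_total`` =
    total number of SNPs tested).  Quantiles use linear interpolation
    (type 7).  When alpha_bonf is below the resolution of the null sample
    the quantiles clamp to the per-site min/max; the returned info dict
    records the level and the clamping.
    """
    null_matrix = np.asarray(null_matrix, dtype=float)
    if null_matrix.size == 0:
        raise ValueError("empty null matrix")
    if not 0.0 < tail_p < 0.5:
        raise ValueError("tail_p must be in (0, 0.5)")
    if l_total < 1:
        raise ValueError("l_total must be >= 1")
    alpha = tail_p / l_total
    n_null = null_matrix.shape[1]
    lower = np.quantile(null_matrix, alpha, axis=1, method="linear")
    upper = np.quantile(null_matrix, 1.0 - alpha, axis=1, method="linear")
    clamped = alpha < 1.0 / (n_null - 1) if n_null > 1 else True
    info = {
        "alpha_bonf": alpha,
        "n_null_per_site": int(n_null),
        "clamped_to_extremes": bool(clamped),
    }
    if clamped:
        warnings.warn(
            f"Bonferroni level {alpha:.3g} is below the resolution of "
            f"{n_null} null values; per-site quantiles clamp to the null extremes",
            stacklevel=2,
        )
    return lower, upper, info


def global_thresholds(
    per_site_uppers: np.ndarray,
    per_site_lowers: np.ndarray,
    global_q: float = 0.005,
) -> tuple[float, float]:
    """Compile per-site thresholds into one global (z_lo, z_hi) pair.

    z_hi is the (1 - global_q) quantile of the per-site upper thresholds
    and z_lo the global_q quantile of the lower ones (type-7 quantiles).
    """
    uppers = np.asarray(per_site_uppers, dtype=float)
    lowers = np.asarray(per_site_lowers, dtype=float)
    if uppers.size == 0 or lowers.size == 0:
        raise ValueError("empty threshold vectors")
    if not 0.0 < global_q < 0.5:
        raise ValueError("global_q must be in (0, 0.5)")
    z_hi = float(np.quantile(uppers, 1.0 - global_q, method="linear"))
    z_lo = float(np.quantile(lowers, global_q, method="linear"))
    return z_lo, z_hi


def call_outliers(
    daf_table: pd.DataFrame, z_lo: float, z_hi: float
) -> pd.DataFrame:
    """Outlier SNPs: zdAF strictly beyond a global cutoff.

    ``daf_table`` needs chrom/pos/zdaf columns; equality with a cutoff is
    not an outlier ("exceeding" is strict).  The result carries the tail
    label.
    """
    if not (np.isfinite(z_lo) and np.isfinite(z_hi)):
        raise ValueError("thresholds must be finite")
    z = daf_table["zdaf"].to_numpy()
    hi = z > z_hi
    lo = z < z_lo
    out = daf_table.loc[hi | lo].copy()
    out["tail"] = np.where(out["zdaf"].to_numpy() > z_hi, "upper", "lower")
    return out.reset_index(drop=True)


def scan_density(
    gl: GLMatrix,
    captured: np.ndarray,
    escaped: np.ndarray,
    plan: PermutationPlan,
    *,
    tail_p: float = 0.0005,
    global_q: float = 0.005,
    scheme: str = "ordered_with_self",
    site_mask: np.ndarray | None = None,
    null_matrix: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ThresholdReport]:
    """Full per-density scan: dAF table, outlier list, threshold report.

    ``captured`` / ``escaped`` are indices into the GL individual axis.
    The permutation null (which may be shared between densities — pass it
    via ``null_matrix``) sets per-site Bonferroni quantiles and the global
    cutoffs; outliers are called on the observed captured-vs-escaped zdAF.
    """
    use = gl if site_mask is None else gl.subset_sites(site_mask)
    p_cap = group_freqs(use, captured)
    p_esc = group_freqs(use, escaped)
    zdaf = compute_zdaf(p_cap, p_esc)
    daf_table = pd.DataFrame(
        {
            "chrom": use.chrom if use.chrom is not None else "1",
            "pos": use.pos if use.pos is not None else np.arange(1, use.n_sites + 1),
            "p_captured": p_cap,
            "p_escaped": p_esc,
            "daf": p_cap - p_esc,
            "zdaf": zdaf,
        }
    )
    if null_matrix is None:
        null_matrix = null_zdaf_distribution(gl, plan, scheme, site_mask=site_mask)
    l_total = daf_table.shape[0]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lower, upper, info = per_site_null_quantiles(null_matrix, tail_p, l_total)
    z_lo, z_hi = global_thresholds(upper, lower, global_q)
    report = ThresholdReport(
        lower=lower,
        upper=upper,
        z_lo=z_lo,
        z_hi=z_hi,
        tail_p=tail_p,
        l_total=l_total,
        alpha_bonf=info["alpha_bonf"],
        global_q=global_q,
        clamped_fraction=1.0 if info["clamped_to_extremes"] else 0.0,
        scheme=scheme,
        notes=[str(w.message) for w in caught],
    )
    outliers = call_outliers(daf_table, z_lo, z_hi)
    return daf_table, outliers, report
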