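"""Between-density outlier overlap: SNP and gene level, exact tests.

Given the outlier SNP sets detected independently in the two density
populations, this module quantifies how many are shared, what overlap
chance alone predicts (n_A n_B / N for a universe of N items), and the
hypergeometric/Fisher exact significance in both directions.  SNPs are
mapped to genes through a GFF3/BED annotation so the same comparison can
be run at gene level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OverlapResult",
    "exact_overlap_test",
    "map_sites_to_genes",
    "compare_densities",
]


@dataclass
class OverlapResult:
    """Observed vs expected overlap of two sets in a common universe."""

    n_a: int
    n_b: int
    universe: int
    observed: int
    expected: float
    p_enrichment: float  # one-sided: overlap at least this large
    p_depletion: float  # one-sided: overlap at most this large
    p_two_sided: float  # minimum-likelihood exact test
    table: tuple[tuple[int, int], tuple[int, int]]

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "universe": self.universe,
            "observed": self.observed,
            "expected": self.expected,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "p_two_sided": self.p_two_sided,
            "table": [list(r) for r in self.table],
        }


def exact_overlap_test(n_a: int, n_b: int, k: int, n_universe: int) -> OverlapResult:
    """Hypergeometric exact test of the overlap of two sets.

    ``k`` shared items between sets of ``n_a`` and ``n_b`` drawn from a
    universe of ``n_universe``.  Expected overlap is n_a n_b / N.
    One-sided p-values are hypergeometric tails; the two-sided p is the
    minimum-likelihood sum (all tables with probability <= the observed
    one), the convention of Fisher's exact test.
    """
    if k > min(n_a, n_b):
        raise ValueError("overlap cannot exceed the smaller set")
    if n_a + n_b - k > n_universe:
        raise ValueError("sets cannot fit in the universe")
    if min(n_a, n_b, k, n_universe) < 0:
        raise ValueError("counts must be non-negative")

    table = ((k, n_a - k), (n_b - k, n_universe - n_a - n_b + k))
    expected = n_a * n_b / n_universe if n_universe else float("nan")
    p_enr = float(stats.hypergeom.sf(k - 1, n_universe, n_a, n_b))
    p_dep = float(stats.hypergeom.cdf(k, n_universe, n_a, n_b))
    p_two = float(stats.fisher_exact(np.array(table), alternative="two-sided")[1])
    return OverlapResult(
        n_a=n_a,
        n_b=n_b,
        universe=n_universe,
        observed=k,
        expected=expected,
        p_enrichment=p_enr,
        p_depletion=p_dep,
        p_two_sided=min(p_two, 1.0),
        table=table,
    )


def map_sites_to_genes(
    sites: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Assign each SNP to every gene interval containing it.

    ``sites`` needs ``chrom`` and 1-based ``pos`` columns; ``annotation``
    carries 0-based half-open ``start``/``end`` (the package's internal
    convention — the GFF3 reader converts on input).  A site at 1-based
    position p lies in a gene iff start <= p - 1 < end.  Returns one row
    per site with the (possibly empty) list of overlapping gene IDs;
    sites in no gene are labelled unannotated.
    """
    for col in ("chrom", "pos"):
        if col not in sites.columns:
            raise ValueError(f"sites frame needs a {col!r} column")
    genes_out: list[list[str]] = []
    ann_by_chrom = {c: g for c, g in annotation.groupby("chrom")}
    for chrom, pos in zip(sites["chrom"], sites["pos"]):
        g = ann_by_chrom.get(chrom)
        if g is None:
            genes_out.append([])
            continue
        p0 = int(pos) - 1
        hit = (g["start"].to_numpy() <= p0) & (p0 < g["end"].to_numpy())
        genes_out.append(list(g.loc[hit, "gene_id"]))
    out = sites.copy().reset_index(drop=True)
    out["genes"] = genes_out
    out["annotated"] = [len(g) > 0 for g in genes_out]
    return out


def compare_densities(
    outliers_baseline: pd.DataFrame,
    outliers_reduced: pd.DataFrame,
    universe_sites: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
) -> dict:
    """SNP-level (and, with an annotation, gene-level) overlap report.

    The SNP universe is the full filtered site panel; the gene universe is
    every gene containing at least one filtered SNP.  Shared SNPs/genes
    are listed alongside the exact-test results in every orientation
    (enrichment, depletion, two-sided) — the orientation question is left
    to the reader of the report.
    """
    def keys(df: pd.DataFrame) -> set:
        return set(zip(df["chrom"], df["pos"]))

    set_a = keys(outliers_baseline)
    set_b = keys(outliers_reduced)
    universe = keys(universe_sites)
    shared = sorted(set_a & set_b)
    snp_result = exact_overlap_test(
        len(set_a), len(set_b), len(shared), len(universe)
    )
    report: dict = {
        "snp": snp_result.to_dict(),
        "shared_snps": [{"chrom": c, "pos": int(p)} for c, p in shared],
    }

    if annotation is not None:
        uni_genes = set(
            g
            for gs in map_sites_to_genes(universe_sites, annotation)["genes"]
            for g in gs
        )
        genes_a = set(
            g
            for gs in map_sites_to_genes(outliers_baseline, annotation)["genes"]
            for g in gs
        )
        genes_b = set(
            g
            for gs in map_sites_to_genes(outliers_reduced, annotation)["genes"]
            for g in gs
        )
        shared_genes = sorted(genes_a & genes_b)
        gene_result = exact_overlap_test(
            len(genes_a), len(genes_b), len(shared_genes), max(len(uni_genes), 1)
        )
        report["gene"] = gene_result.to_dict()
        report["shared_genes"] = shared_genes
    return report
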