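"""Stage orchestration: configuration, per-stage runners, end-to-end run.

The pipeline mirrors the experiment's analysis order on synthetic data:

    simulate -> likelihoods -> scan (per density) -> overlap -> pca -> phenostats

Every stage reads its inputs from files written by earlier stages (so
stages can be re-run individually and produce byte-identical artifacts
for equal configs and seeds) and appends an entry to the run manifest.
One master seed is split deterministically into per-stage child seeds,
all recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from . import overlap_sets, pca_gl, phenostats, zdaf_scan
from .genolik import (
    SiteFilterConfig,
    apply_site_filters,
    em_maf,
    expected_het,
    genotype_likelihoods,
    polarize_to_minor,
)
from .synthetic_cohort import (
    EffectModel,
    TrawlConfig,
    assign_liability_and_phenotypes,
    breed_nc2,
    draw_founder_panel,
    make_gene_annotation,
    run_trawl_selection,
    select_sequencing_panel,
    simulate_read_counts,
)

__all__ = ["RunConfig", "run_stage", "run_all", "STAGES"]

STAGES = ("simulate", "likelihoods", "scan", "overlap", "pca", "phenostats")


@dataclass
class CohortParams:
    n_sites: int = 20_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    offspring_per_family_per_density: int = 10
    n_chrom: int = 25
    chrom_length: int = 1_000_000
    growth_days: int = 90


@dataclass
class EffectParams:
    mode: str = "gxe"  # gxe | shared | null
    n_loci: int = 2
    beta: float = 2.5
    h2: float = 0.85
    min_selected_maf: float = 0.40


@dataclass
class SequencingParams:
    n_per_group: int = 24
    mean_depth: float = 2.0
    depth_sd: float = 0.5
    err: float = 0.01


@dataclass
class ScanParams:
    n_groups: int = 25
    group_size: int = 24
    tail_p: float = 0.0005
    global_q: float = 0.005
    scheme: str = "ordered_with_self"


@dataclass
class PcaParams:
    n_components: int = 10
    analysis_pc: int = 2
    iterate: bool = False
    # when fewer outlier SNPs than this cleared the global cutoff, the PCA
    # falls back to the strongest-|zdAF| sites per density to stay defined
    min_sites: int = 20


@dataclass
class AnnotationParams:
    n_genes: int = 300
    mean_length: float = 10_000.0


@dataclass
class RunConfig:
    """Full run configuration; serialises losslessly to/from YAML."""

    seed: int = 1
    out_dir: str = "trawlscan_run"
    cohort: CohortParams = field(default_factory=CohortParams)
    effects: EffectParams = field(default_factory=EffectParams)
    trawl: TrawlConfig = field(default_factory=TrawlConfig)
    sequencing: SequencingParams = field(default_factory=SequencingParams)
    filters: SiteFilterConfig = field(default_factory=SiteFilterConfig)
    scan: ScanParams = field(default_factory=ScanParams)
    pca: PcaParams = field(default_factory=PcaParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        for name, sub in (
            ("cohort", CohortParams),
            ("effects", EffectParams),
            ("trawl", TrawlConfig),
            ("sequencing", SequencingParams),
            ("filters", SiteFilterConfig),
            ("scan", ScanParams),
            ("pca", PcaParams),
            ("annotation", AnnotationParams),
        ):
            if name in kwargs and isinstance(kwargs[name], dict):
                kwargs[name] = sub(**kwargs[name])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def stage_seeds(self) -> dict[str, int]:
        """Deterministic child seed per stage from the master seed."""
        words = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {s: int(w % (2**31)) for s, w in zip(STAGES, words)}


def _require(out: Path, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage input missing: {out / name} (run the earlier stage first)"
            )


def _append_manifest(out: Path, stage: str, payload: dict) -> None:
    path = out / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = payload
    tio.write_manifest(manifest, path)


def _stage_simulate(config: RunConfig, out: Path, seed: int) -> dict:
    c = config.cohort
    ss = np.random.SeedSequence(seed)
    seeds = [int(w % (2**31)) for w in ss.generate_state(8)]

    panel = draw_founder_panel(
        c.n_sites,
        c.maf_low,
        c.maf_high,
        seed=seeds[0],
        n_chrom=c.n_chrom,
        chrom_length=c.chrom_length,
    )
    cohort = breed_nc2(panel, c.offspring_per_family_per_density, seed=seeds[1])
    e = config.effects
    if e.mode == "null":
        effects = EffectModel.null()
    else:
        effects = EffectModel.gxe(
            panel,
            n_loci=e.n_loci,
            beta=e.beta,
            h2=e.h2,
            disjoint=(e.mode == "gxe"),
            min_selected_maf=e.min_selected_maf,
            seed=seeds[2],
        )
    cohort = assign_liability_and_phenotypes(
        cohort, effects, seed=seeds[3], growth_days=c.growth_days
    )
    cohort = run_trawl_selection(cohort, config.trawl, seed=seeds[4])
    sheet = select_sequencing_panel(
        cohort, config.sequencing.n_per_group, seed=seeds[5]
    )
    idx = sheet["cohort_index"].to_numpy()
    counts = simulate_read_counts(
        cohort.genotypes[idx],
        config.sequencing.mean_depth,
        config.sequencing.depth_sd,
        config.sequencing.err,
        seed=seeds[6],
        chrom=cohort.chrom,
        pos=cohort.pos,
        sample_ids=list(sheet["individual_id"]),
    )
    annotation = make_gene_annotation(
        config.annotation.n_genes,
        panel.genome(),
        seed=seeds[7],
        mean_length=config.annotation.mean_length,
    )

    sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
    cohort.table.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    sites = pd.DataFrame(
        {"chrom": cohort.chrom, "pos": cohort.pos, "anc_maf": cohort.anc_maf}
    )
    sites.to_csv(out / "sites.tsv", sep="\t", index=False)
    geno = pd.DataFrame(
        cohort.genotypes[idx].T, columns=list(sheet["individual_id"])
    )
    geno.insert(0, "chrom", cohort.chrom)
    geno.insert(1, "pos", cohort.pos)
    geno.to_csv(out / "genotypes_sequenced.tsv", sep="\t", index=False)
    np.savetxt(out / "counts_ref.tsv", counts.ref, fmt="%d", delimiter="\t")
    np.savetxt(out / "counts_alt.tsv", counts.alt, fmt="%d", delimiter="\t")
    tio.write_gff3(annotation, out / "annotation.gff3")
    tio.write_bed(annotation, out / "annotation.bed")
    pd.DataFrame(
        {
            "locus": np.concatenate([effects.loci_baseline, effects.loci_reduced]),
            "density": ["baseline"] * len(effects.loci_baseline)
            + ["reduced"] * len(effects.loci_reduced),
            "beta": np.concatenate([effects.beta_baseline, effects.beta_reduced]),
        }
    ).to_csv(out / "selected_loci.tsv", sep="\t", index=False)

    report = cohort.meta.get("trawl_report", {})
    return {
        "seeds": seeds,
        "n_families": int(cohort.meta.get("n_families", 0)),
        "n_individuals": int(cohort.n),
        "n_sequenced": int(len(sheet)),
        "trawl_report": report,
        "err": config.sequencing.err,
    }


def _load_counts(out: Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, pd.DataFrame]:
    _require(out, "counts_ref.tsv", "counts_alt.tsv", "sites.tsv", "sample_sheet.tsv")
    ref = np.loadtxt(out / "counts_ref.tsv", dtype=int, delimiter="\t", ndmin=2)
    alt = np.loadtxt(out / "counts_alt.tsv", dtype=int, delimiter="\t", ndmin=2)
    sites = pd.read_csv(out / "sites.tsv", sep="\t")
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    return ref, alt, sites, sheet


def _stage_likelihoods(config: RunConfig, out: Path, seed: int) -> dict:
    ref, alt, sites, sheet = _load_counts(out)
    manifest = json.loads((out / "manifest.json").read_text())
    err = manifest["stages"]["simulate"]["err"]
    gl = genotype_likelihoods(
        ref,
        alt,
        max(err, 1e-6),
        chrom=sites["chrom"].to_numpy(),
        pos=sites["pos"].to_numpy(),
        sample_ids=list(sheet["individual_id"]),
    )
    freq, _, _ = em_maf(gl.logl, gl.missing)
    gl_pol, maf, _ = polarize_to_minor(gl, freq)
    panel, report = apply_site_filters(ref, alt, gl_pol, config.filters, maf_hat=maf)

    keep = panel["pass"].to_numpy()
    gl_pass = gl_pol.subset_sites(keep)
    tio.write_beagle(gl_pass, out / "genolik.beagle.txt")
    panel.to_csv(out / "site_panel.tsv", sep="\t", index=False)
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    he = expected_het(maf[keep], mode="freq")
    return {"seed": seed, "he_freq": he.he, "n_pass": int(keep.sum()), **report}


def _scan_inputs(out: Path):
    _require(out, "genolik.beagle.txt", "sample_sheet.tsv", "site_panel.tsv")
    gl = tio.read_beagle(out / "genolik.beagle.txt")
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    return gl, sheet


def _stage_scan(config: RunConfig, out: Path, seed: int) -> dict:
    gl, sheet = _scan_inputs(out)
    plan = zdaf_scan.build_permutation_groups(
        np.arange(gl.n_individuals),
        G=config.scan.n_groups,
        size=config.scan.group_size,
        seed=seed,
    )
    null = zdaf_scan.null_zdaf_distribution(gl, plan, config.scan.scheme)

    info: dict = {"seed": seed, "pairings": int(null.shape[1]), "densities": {}}
    for density in ("baseline", "reduced"):
        cap = np.flatnonzero(
            ((sheet["density"] == density) & (sheet["group"] == "captured")).to_numpy()
        )
        esc = np.flatnonzero(
            ((sheet["density"] == density) & (sheet["group"] == "escaped")).to_numpy()
        )
        daf, outliers, report = zdaf_scan.scan_density(
            gl,
            cap,
            esc,
            plan,
            tail_p=config.scan.tail_p,
            global_q=config.scan.global_q,
            scheme=config.scan.scheme,
            null_matrix=null,
        )
        daf.to_csv(out / f"daf_{density}.tsv", sep="\t", index=False)
        tio.write_outliers(
            outliers, out / f"outliers_{density}.tsv", out / f"outliers_{density}.bed"
        )
        info["densities"][density] = {
            "n_outliers": int(len(outliers)),
            "z_lo": report.z_lo,
            "z_hi": report.z_hi,
            "alpha_bonf": report.alpha_bonf,
            "l_total": report.l_total,
            "notes": report.notes,
        }
    with open(out / "thresholds.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return info


def _stage_overlap(config: RunConfig, out: Path, seed: int) -> dict:
    _require(
        out,
        "outliers_baseline.tsv",
        "outliers_reduced.tsv",
        "site_panel.tsv",
        "annotation.gff3",
    )
    out_b = pd.read_csv(out / "outliers_baseline.tsv", sep="\t")
    out_r = pd.read_csv(out / "outliers_reduced.tsv", sep="\t")
    panel = pd.read_csv(out / "site_panel.tsv", sep="\t")
    universe = panel.loc[panel["pass"], ["chrom", "pos"]]
    annotation = tio.read_gff3(out / "annotation.gff3")
    report = overlap_sets.compare_densities(out_b, out_r, universe, annotation)
    pd.DataFrame(
        report["shared_snps"], columns=["chrom", "pos"]
    ).to_csv(out / "shared_outliers.tsv", sep="\t", index=False)
    with open(out / "overlap.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"seed": seed, "snp_overlap": report["snp"]["observed"]}


def _stage_pca(config: RunConfig, out: Path, seed: int) -> dict:
    gl, sheet = _scan_inputs(out)
    _require(out, "outliers_baseline.tsv", "outliers_reduced.tsv")
    out_b = pd.read_csv(out / "outliers_baseline.tsv", sep="\t")
    out_r = pd.read_csv(out / "outliers_reduced.tsv", sep="\t")
    keys = set(zip(out_b["chrom"], out_b["pos"])) | set(
        zip(out_r["chrom"], out_r["pos"])
    )
    fallback = False
    if len(keys) < config.pca.min_sites:
        # too few SNPs cleared the global cutoff at this scale; fall back to
        # the strongest-|zdAF| sites of each density so the PC is defined
        fallback = True
        per_density = max(config.pca.min_sites // 2, 1)
        for density in ("baseline", "reduced"):
            daf = pd.read_csv(out / f"daf_{density}.tsv", sep="\t")
            top = daf.reindex(
                daf["zdaf"].abs().sort_values(ascending=False).index
            ).head(per_density)
            keys |= set(zip(top["chrom"], top["pos"]))
    mask = np.array(
        [(c, p) in keys for c, p in zip(gl.chrom, gl.pos)], dtype=bool
    )
    if mask.sum() == 0:
        raise RuntimeError("no outlier sites available for the PCA")
    gl_out = gl.subset_sites(mask)
    maf, _, _ = em_maf(gl_out.logl, gl_out.missing)
    dosages = pca_gl.posterior_dosages(gl_out, maf)
    k = min(config.pca.n_components, gl_out.n_individuals)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pca_gl.genotype_pca(
            dosages,
            maf,
            n_components=k,
            iterate=config.pca.iterate,
            gl=gl_out if config.pca.iterate else None,
            analysis_pc=min(config.pca.analysis_pc, k),
        )
    idx, scores = pca_gl.select_analysis_pc(result, "fixed_index")
    scores_df = pd.DataFrame(
        result.scores, columns=[f"PC{i + 1}" for i in range(result.scores.shape[1])]
    )
    scores_df.insert(0, "individual_id", sheet["individual_id"])
    scores_df["analysis_pc_score"] = scores
    scores_df.to_csv(out / "pca_scores.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "component": np.arange(1, len(result.eigenvalues) + 1),
            "eigenvalue": result.eigenvalues,
            "variance_fraction": result.variance_explained,
        }
    ).to_csv(out / "pca_eigenvalues.tsv", sep="\t", index=False)
    return {
        "seed": seed,
        "n_outlier_sites": int(mask.sum()),
        "topk_fallback": fallback,
        "analysis_pc": int(idx),
        "variance_fraction_pc": float(result.variance_explained[idx - 1]),
    }


def _stage_phenostats(config: RunConfig, out: Path, seed: int) -> dict:
    _require(out, "pca_scores.tsv", "phenotypes.tsv", "sample_sheet.tsv")
    scores = pd.read_csv(out / "pca_scores.tsv", sep="\t")
    pheno = pd.read_csv(out / "phenotypes.tsv", sep="\t")
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t")
    df = sheet.merge(
        pheno, on="individual_id", suffixes=("", "_cohort"), how="left"
    ).merge(scores[["individual_id", "analysis_pc_score"]], on="individual_id")
    df = df.rename(columns={"group": "vulnerability_group"})
    df["mass"] = df["mass_9mo"]

    traits = {
        "mass": "mass_9mo",
        "sgr": "sgr",
        "aerobic_scope": "aerobic_scope",
        "aggression": "aggression_bites",
        "sociability": "sociability_distance",
    }
    correlations = {}
    for name, col in traits.items():
        correlations[name] = phenostats.pc_trait_correlation(
            df["analysis_pc_score"], df[col], df["density"]
        )
    corr_rows = []
    for name, c in correlations.items():
        corr_rows.append(
            {
                "trait": name,
                "r_combined": c["combined"]["r"],
                "r2_combined": c["combined"]["r2"],
                "p_combined": c["combined"]["p"],
                "p_interaction": c["interaction_p"],
                "r_baseline": c["baseline"]["r"],
                "r2_baseline": c["baseline"]["r2"],
                "p_baseline": c["baseline"]["p"],
                "r_reduced": c["reduced"]["r"],
                "r2_reduced": c["reduced"]["r2"],
                "p_reduced": c["reduced"]["p"],
            }
        )
    pd.DataFrame(corr_rows).to_csv(out / "pc_correlations.tsv", sep="\t", index=False)

    glm_df = df.drop(columns=["vulnerability"], errors="ignore").rename(
        columns={"vulnerability_group": "vulnerability"}
    )
    pc_model = phenostats.factorial_glm(
        glm_df,
        "analysis_pc_score",
        factors=("sex", "density", "vulnerability"),
        covariate=None,
        rank_response=True,
    )
    group_means = (
        df.groupby(["density", "vulnerability_group"])["analysis_pc_score"]
        .mean()
        .unstack()
        .to_dict()
    )
    models = {
        "pc_score_glm": {
            "formula": pc_model.attrs["formula"],
            "table": pc_model.reset_index().to_dict(orient="records"),
        },
        "correlations": correlations,
        "pc_group_means": {
            str(k): {str(kk): float(vv) for kk, vv in v.items()}
            for k, v in group_means.items()
        },
    }
    with open(out / "models.json", "w") as fh:
        json.dump(models, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")

    # summary report assembled from the stage artifacts
    thresholds = json.loads((out / "thresholds.json").read_text())
    overlap = json.loads((out / "overlap.json").read_text())
    summary = {
        "outliers": {
            d: thresholds["densities"][d]["n_outliers"]
            for d in ("baseline", "reduced")
        },
        "thresholds": {
            d: [
                thresholds["densities"][d]["z_lo"],
                thresholds["densities"][d]["z_hi"],
            ]
            for d in ("baseline", "reduced")
        },
        "overlap": overlap["snp"],
        "pc_group_means": models["pc_group_means"],
        "correlation_table": corr_rows,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return {"seed": seed, "n_models": len(models)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "likelihoods": _stage_likelihoods,
    "scan": _stage_scan,
    "overlap": _stage_overlap,
    "pca": _stage_pca,
    "phenostats": _stage_phenostats,
}


def run_stage(stage_name: str, config: RunConfig, out_dir=None) -> dict:
    """Run one pipeline stage; inputs come from earlier stages' files.

    Raises FileNotFoundError naming the missing artifact when a dependency
    has not been produced yet.  Returns the manifest entry.
    """
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; choose from {STAGES}")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seeds()[stage_name]
    entry = _STAGE_FUNCS[stage_name](config, out, seed)
    entry["stage_seed"] = seed
    _append_manifest(out, stage_name, entry)
    return entry


def run_all(config: RunConfig, out_dir=None) -> dict:
    """Run the full pipeline in order and return the summary report."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    for stage in STAGES:
        run_stage(stage, config, out)
    return json.loads((out / "summary.json").read_text())
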