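"""Synthetic harvest-selection experiment: founders, families, trawling, reads.

Generates the full experimental system end to end so every downstream
analysis stage can be exercised without any external data:

* a founder panel of 24 adults genotyped at L biallelic SNPs,
* 36 full-sib families from a North Carolina II design (4 blocks in which
  3 males are reciprocally crossed to 3 females), each family split
  equally between a baseline- and a reduced-density population,
* a polygenic, density-dependent liability for vulnerability to trawl
  capture (the G-by-E structure: the selected loci and/or their effects
  may differ between densities),
* phenotypes (growth, metabolic rates, aggression, sociability) loaded on
  that liability so that, by default, escaped fish grow faster, have a
  higher aerobic scope, and are less aggressive and less social than
  captured fish,
* six iterated trawl trials that each remove the most vulnerable fish,
  yielding captured (removed in trial 1) and escaped (never captured)
  vulnerability groups of 20% of the starting population each,
* low-coverage sequencing read counts (~2x +/- 0.5 per individual) with a
  symmetric per-read base error,
* a synthetic non-overlapping gene annotation for SNP-to-gene assignment.

All randomness flows through a single ``numpy`` Generator per operation;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "FounderPanel",
    "Cohort",
    "EffectModel",
    "TrawlConfig",
    "AlleleCountMatrix",
    "draw_founder_panel",
    "breed_nc2",
    "assign_liability_and_phenotypes",
    "run_trawl_selection",
    "select_sequencing_panel",
    "simulate_read_counts",
    "make_gene_annotation",
]

DENSITIES = ("baseline", "reduced")
PHENOTYPES = (
    "mass_6mo",
    "mass_9mo",
    "length",
    "sgr",
    "smr",
    "mmr",
    "aerobic_scope",
    "aggression_bites",
    "sociability_distance",
)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class FounderPanel:
    """24 founding adults genotyped at L biallelic sites."""

    founder_id: np.ndarray
    sex: np.ndarray  # 'M' / 'F'
    genotypes: np.ndarray  # (n_founders, L) dosage of the alternate allele
    anc_maf: np.ndarray  # (L,) ancestral minor-allele frequency
    chrom: np.ndarray  # (L,) chromosome labels
    pos: np.ndarray  # (L,) 1-based positions
    chrom_length: int = 1_000_000

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_founders(self) -> int:
        return self.genotypes.shape[0]

    def genome(self) -> dict[str, int]:
        """Chromosome name -> length mapping implied by the panel."""
        return {str(c): self.chrom_length for c in pd.unique(self.chrom)}


@dataclass
class Cohort:
    """Experimental individuals with genotypes and per-individual metadata.

    ``table`` holds one row per fish (identity, family, density, sex, then
    liability, phenotypes and capture records as stages add them);
    ``genotypes`` is aligned row-for-row with ``table``.
    """

    table: pd.DataFrame
    genotypes: np.ndarray  # (n, L) int8
    chrom: np.ndarray
    pos: np.ndarray
    anc_maf: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            table=self.table.iloc[idx].reset_index(drop=True),
            genotypes=self.genotypes[idx],
            chrom=self.chrom,
            pos=self.pos,
            anc_maf=self.anc_maf,
            meta=dict(self.meta),
        )


def draw_founder_panel(
    n_sites: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    seed=None,
    *,
    n_founders: int = 24,
    n_chrom: int = 25,
    chrom_length: int = 1_000_000,
) -> FounderPanel:
    """Draw a founder panel with Hardy-Weinberg genotypes.

    Ancestral minor-allele frequencies are uniform on
    [``maf_low``, ``maf_high``]; founder dosages are Binomial(2, maf) per
    site.  Sites are spread evenly over ``n_chrom`` chromosomes with
    sorted, distinct 1-based positions.  Half the founders are male, half
    female.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if not (0.0 <= maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 <= maf_low <= maf_high <= 0.5")
    if n_founders < 2 or n_founders % 2:
        raise ValueError("n_founders must be a positive even number")
    rng = _rng(seed)

    maf = rng.uniform(maf_low, maf_high, size=n_sites)
    genotypes = rng.binomial(2, maf, size=(n_founders, n_sites)).astype(np.int8)

    per_chrom = np.full(n_chrom, n_sites // n_chrom)
    per_chrom[: n_sites % n_chrom] += 1
    chrom_labels: list[str] = []
    positions: list[np.ndarray] = []
    for c, k in enumerate(per_chrom, start=1):
        if k == 0:
            continue
        pos = np.sort(rng.choice(chrom_length, size=k, replace=False)) + 1
        chrom_labels.extend([f"chr{c}"] * k)
        positions.append(pos)
    sex = np.array(["M"] * (n_founders // 2) + ["F"] * (n_founders // 2))
    return FounderPanel(
        founder_id=np.array([f"F{i + 1:02d}" for i in range(n_founders)]),
        sex=sex,
        genotypes=genotypes,
        anc_maf=maf,
        chrom=np.array(chrom_labels),
        pos=np.concatenate(positions),
        chrom_length=chrom_length,
    )


def breed_nc2(
    panel: FounderPanel,
    offspring_per_family_per_density: int = 10,
    seed=None,
    *,
    n_blocks: int = 4,
    males_per_block: int = 3,
    females_per_block: int = 3,
) -> Cohort:
    """Breed a North Carolina II cohort from the founder panel.

    Each of ``n_blocks`` blocks crosses ``males_per_block`` males
    reciprocally with ``females_per_block`` females (all pairwise
    combinations), giving 4 x 3 x 3 = 36 families by default.  Every
    family contributes ``offspring_per_family_per_density`` offspring to
    each density.  Offspring genotypes follow independent Mendelian
    segregation per site (one allele drawn from each parent; no linkage).
    """
    males = np.flatnonzero(panel.sex == "M")
    females = np.flatnonzero(panel.sex == "F")
    need_m = n_blocks * males_per_block
    need_f = n_blocks * females_per_block
    if len(males) < need_m or len(females) < need_f:
        raise ValueError(
            f"panel has {len(males)} males / {len(females)} females; "
            f"need {need_m} / {need_f} for {n_blocks} blocks"
        )
    rng = _rng(seed)
    L = panel.n_sites
    n_off = offspring_per_family_per_density

    rows = []
    geno_blocks = []
    uid = 0
    for b in range(n_blocks):
        block_m = males[b * males_per_block : (b + 1) * males_per_block]
        block_f = females[b * females_per_block : (b + 1) * females_per_block]
        for mi, m in enumerate(block_m):
            for fi, f in enumerate(block_f):
                family_id = f"B{b + 1}M{mi + 1}F{fi + 1}"
                total = n_off * len(DENSITIES)
                p_dad = panel.genotypes[m] / 2.0
                p_mum = panel.genotypes[f] / 2.0
                gametes_dad = rng.binomial(1, p_dad, size=(total, L))
                gametes_mum = rng.binomial(1, p_mum, size=(total, L))
                geno = (gametes_dad + gametes_mum).astype(np.int8)
                sexes = rng.choice(["M", "F"], size=total)
                for d, density in enumerate(DENSITIES):
                    for k in range(n_off):
                        uid += 1
                        rows.append(
                            {
                                "individual_id": f"Z{uid:05d}",
                                "family_id": family_id,
                                "block_id": b + 1,
                                "sex": sexes[d * n_off + k],
                                "density": density,
                            }
                        )
                geno_blocks.append(geno)

    table = pd.DataFrame(rows)
    genotypes = np.concatenate(geno_blocks, axis=0)
    return Cohort(
        table=table,
        genotypes=genotypes,
        chrom=panel.chrom,
        pos=panel.pos,
        anc_maf=panel.anc_maf,
        meta={"n_families": table["family_id"].nunique()},
    )


# Default phenotype generation constants (zebrafish-scaled):
# base level, loading per liability SD (sign encodes the capture-vulnerable
# direction: captured fish grow slower, have lower aerobic scope, bite more,
# and stay closer to conspecifics), and residual noise SD.
_TRAIT_BASE = {
    "mass_6mo": 0.25,  # g
    "sgr": 0.50,  # % body mass / day
    "smr": 0.08,  # mg O2 / h
    "aerobic_scope": 0.25,  # mg O2 / h
    "aggression_bites": 20.0,  # bites / 10 min
    "sociability_distance": 10.0,  # cm (larger = less social)
}
_TRAIT_LOADINGS = {
    "mass_6mo": -0.010,
    "sgr": -0.15,
    "smr": 0.0,
    "aerobic_scope": -0.020,
    "aggression_bites": 4.0,
    "sociability_distance": -1.2,
}
_TRAIT_NOISE = {
    "mass_6mo": 0.030,
    "sgr": 0.10,
    "smr": 0.008,
    "aerobic_scope": 0.020,
    "aggression_bites": 5.0,
    "sociability_distance": 1.5,
}


@dataclass
class EffectModel:
    """Density-specific polygenic architecture of capture vulnerability.

    Liability of individual i is sum over selected loci of
    beta_density(l) * dosage(i, l) plus Normal(0, env_sd) noise; each
    phenotype is base + loading * standardised liability + trait noise.
    Disjoint per-density locus sets plant a G-by-E signal; identical sets
    remove it.
    """

    loci_baseline: np.ndarray
    loci_reduced: np.ndarray
    beta_baseline: np.ndarray
    beta_reduced: np.ndarray
    env_sd: float = 1.0
    trait_base: dict = field(default_factory=lambda: dict(_TRAIT_BASE))
    trait_loadings: dict = field(default_factory=lambda: dict(_TRAIT_LOADINGS))
    trait_noise_sd: dict = field(default_factory=lambda: dict(_TRAIT_NOISE))

    def __post_init__(self) -> None:
        self.loci_baseline = np.asarray(self.loci_baseline, dtype=int)
        self.loci_reduced = np.asarray(self.loci_reduced, dtype=int)
        self.beta_baseline = np.asarray(self.beta_baseline, dtype=float)
        self.beta_reduced = np.asarray(self.beta_reduced, dtype=float)
        if len(self.loci_baseline) != len(self.beta_baseline):
            raise ValueError("loci_baseline and beta_baseline lengths differ")
        if len(self.loci_reduced) != len(self.beta_reduced):
            raise ValueError("loci_reduced and beta_reduced lengths differ")
        for arr in (self.beta_baseline, self.beta_reduced):
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError("liability effects must be finite")
        if not np.isfinite(self.env_sd) or self.env_sd < 0:
            raise ValueError("env_sd must be finite and >= 0")

    @classmethod
    def null(cls, env_sd: float = 1.0) -> "EffectModel":
        """No genetic effect on vulnerability: liability is pure noise."""
        empty = np.empty(0, dtype=int)
        return cls(empty, empty, np.empty(0), np.empty(0), env_sd=env_sd)

    @classmethod
    def gxe(
        cls,
        panel: FounderPanel,
        n_loci: int = 2,
        beta: float = 2.5,
        h2: float = 0.85,
        disjoint: bool = True,
        min_selected_maf: float = 0.40,
        seed=None,
    ) -> "EffectModel":
        """Random polygenic model with density-specific selected loci.

        Selected loci are drawn among sites with ancestral MAF >=
        ``min_selected_maf`` (effects planted at common variants are the
        ones iterated truncation selection can move far enough to detect
        in 24-fish groups at ~2x coverage).  Effects are +/- ``beta`` with
        random signs.  ``env_sd`` is set so the planted liability
        heritability is ``h2`` given the panel's ancestral frequencies
        (genic variance sum beta^2 2p(1-p)).  With ``disjoint`` the two
        densities use non-overlapping locus sets (the G-by-E
        configuration); otherwise both use the same set and effects.
        """
        rng = _rng(seed)
        eligible = np.flatnonzero(panel.anc_maf >= min_selected_maf)
        if len(eligible) < (2 * n_loci if disjoint else n_loci):
            raise ValueError(
                f"only {len(eligible)} sites have MAF >= {min_selected_maf}; "
                "cannot place the selected loci"
            )
        if disjoint:
            chosen = rng.choice(eligible, size=2 * n_loci, replace=False)
            loci_b, loci_r = chosen[:n_loci], chosen[n_loci:]
        else:
            loci_b = rng.choice(eligible, size=n_loci, replace=False)
            loci_r = loci_b.copy()
        beta_b = rng.choice([-beta, beta], size=n_loci)
        beta_r = beta_b.copy() if not disjoint else rng.choice([-beta, beta], size=n_loci)
        p = panel.anc_maf
        vg = float(
            np.sum(beta_b**2 * 2 * p[loci_b] * (1 - p[loci_b]))
            + np.sum(beta_r**2 * 2 * p[loci_r] * (1 - p[loci_r]))
        ) / 2.0
        env_sd = np.sqrt(vg * (1.0 - h2) / h2) if vg > 0 and h2 > 0 else 1.0
        return cls(loci_b, loci_r, beta_b, beta_r, env_sd=env_sd)


def assign_liability_and_phenotypes(
    cohort: Cohort,
    effect_model: EffectModel,
    seed=None,
    *,
    growth_days: int = 90,
) -> Cohort:
    """Attach capture-vulnerability liability and phenotypes to a cohort.

    Raw liability is the density-specific weighted dosage sum plus
    environmental noise.  For the phenotype loadings (and later for trawl
    capture) liability is standardised within density, so loading and
    noise SDs are expressed per liability SD and are invariant to the
    effect-size scale; a zero-variance liability standardises to 0.
    Aerobic scope is generated and MMR defined as SMR + AS, so
    AS = MMR - SMR holds exactly.
    """
    for loci in (effect_model.loci_baseline, effect_model.loci_reduced):
        if loci.size and loci.max() >= cohort.n_sites:
            raise ValueError("effect model locus index outside the site panel")
    rng = _rng(seed)
    table = cohort.table.copy()
    n = cohort.n

    liab = np.zeros(n)
    for density, loci, beta in (
        ("baseline", effect_model.loci_baseline, effect_model.beta_baseline),
        ("reduced", effect_model.loci_reduced, effect_model.beta_reduced),
    ):
        m = (table["density"] == density).to_numpy()
        if loci.size:
            liab[m] = cohort.genotypes[np.ix_(m, loci)] @ beta
    liab = liab + rng.normal(0.0, effect_model.env_sd, size=n)

    liab_z = np.zeros(n)
    for density in DENSITIES:
        m = (table["density"] == density).to_numpy()
        sd = liab[m].std()
        if sd > 0:
            liab_z[m] = (liab[m] - liab[m].mean()) / sd
    table["liability"] = liab
    table["liability_z"] = liab_z

    base = effect_model.trait_base
    load = effect_model.trait_loadings
    noise = effect_model.trait_noise_sd

    def draw(trait):
        return (
            base[trait]
            + load[trait] * liab_z
            + rng.normal(0.0, noise[trait], size=n)
        )

    mass_6 = np.clip(draw("mass_6mo"), 0.05, None)
    sgr = draw("sgr")
    mass_9 = mass_6 * np.exp(sgr * growth_days / 100.0)
    length = 30.0 * np.cbrt(mass_9 / 0.3) + rng.normal(0.0, 0.8, size=n)
    smr = np.clip(draw("smr"), 0.01, None)
    aerobic = np.clip(draw("aerobic_scope"), 0.01, None)
    aggression = np.clip(np.rint(draw("aggression_bites")), 0, None)
    sociability = np.clip(draw("sociability_distance"), 0.5, None)

    table["mass_6mo"] = mass_6
    table["mass_9mo"] = mass_9
    table["length"] = length
    table["sgr"] = sgr
    table["smr"] = smr
    table["aerobic_scope"] = aerobic
    table["mmr"] = smr + aerobic
    table["aggression_bites"] = aggression
    table["sociability_distance"] = sociability
    return replace(cohort, table=table)


@dataclass
class TrawlConfig:
    """Iterated trawl-harvest schedule.

    Six weekly trials by default; each trial splits the current population
    into events of ~``fish_per_event`` fish swimming against the model
    trawl, and removes the most vulnerable fraction by capture time.
    Within an event a fish falls back into the net when its noisy
    vulnerability exceeds ``capture_threshold`` (an absolute swim-
    performance criterion in liability-SD units, mimicking the fixed
    water velocity of an event); fish below it escape the event and get
    no capture time.  ``removal_policy`` controls how many fish each
    trial removes: a fraction of the current population (default), a
    fraction of the original population, or a fixed count.
    """

    fish_per_event: int = 16
    n_trials: int = 6
    removal_policy: str = "fraction_of_current"
    removal_fraction: float = 0.2
    removal_count: int | None = None
    event_noise_sd: float = 0.5
    capture_threshold: float = 0.25
    event_duration_s: float = 600.0

    def __post_init__(self) -> None:
        if not 0.0 < self.removal_fraction < 1.0:
            raise ValueError("removal_fraction must be in (0, 1)")
        if self.fish_per_event < 1:
            raise ValueError("fish_per_event must be >= 1")
        if self.removal_policy not in (
            "fraction_of_current",
            "fraction_of_original",
            "fixed_count",
        ):
            raise ValueError(f"unknown removal_policy {self.removal_policy!r}")
        if self.removal_policy == "fixed_count" and not self.removal_count:
            raise ValueError("fixed_count policy needs removal_count")
        if not np.isfinite(self.capture_threshold):
            raise ValueError("capture_threshold must be finite")


def run_trawl_selection(cohort: Cohort, config: TrawlConfig, seed=None) -> Cohort:
    """Run the iterated trawl harvest and label vulnerability groups.

    Per density and per trial, fish are shuffled into events of
    ``fish_per_event`` (remainder merged into the final events, so 360
    fish give 22 first-trial events); within an event, fish whose noisy
    liability v = liability_z + noise exceeds ``capture_threshold`` are
    captured with times t = duration * expit(-v), a strictly increasing
    function of minus the noisy liability.  The removal quota of fish with
    the shortest capture times is removed after each trial.  Labels:
    ``captured`` = removed in trial 1 (the removal-fraction most
    vulnerable); ``escaped`` = never captured across all trials, lowest
    liability first, up to the removal fraction of the original
    population; ``intermediate`` = other survivors; ``none`` = fish
    removed in trials 2+.
    """
    if "liability_z" not in cohort.table.columns:
        raise ValueError("cohort has no liability; run assign_liability_and_phenotypes first")
    rng = _rng(seed)
    table = cohort.table.copy()
    n = cohort.n

    label = np.array(["intermediate"] * n, dtype=object)
    removed_in_trial = np.zeros(n, dtype=int)
    ever_captured = np.zeros(n, dtype=bool)
    cap_trial = np.full(n, -1)
    cap_event = np.full(n, -1)
    cap_time = np.full(n, np.nan)
    trial1_time = np.full(n, np.nan)
    report: dict = {"densities": {}}

    for density in DENSITIES:
        ids = np.flatnonzero((table["density"] == density).to_numpy())
        if len(ids) < config.fish_per_event:
            raise ValueError(
                f"density {density!r} has {len(ids)} fish; "
                f"need at least one event of {config.fish_per_event}"
            )
        liab_z = table["liability_z"].to_numpy()[ids]
        n_orig = len(ids)
        active = np.arange(n_orig)
        events_per_trial = []
        removed_per_trial = []

        for trial in range(1, config.n_trials + 1):
            if config.removal_policy == "fraction_of_current":
                quota = int(round(config.removal_fraction * len(active)))
            elif config.removal_policy == "fraction_of_original":
                quota = int(round(config.removal_fraction * n_orig))
            else:
                quota = int(config.removal_count)
                if len(active) < quota:
                    raise RuntimeError(
                        f"population exhausted at trial {trial} "
                        f"({len(active)} fish left, removal_count={quota})"
                    )

            perm = rng.permutation(active)
            n_ev = max(1, len(perm) // config.fish_per_event)
            sizes = np.full(n_ev, len(perm) // n_ev)
            sizes[n_ev - (len(perm) % n_ev) :] += 1 if len(perm) % n_ev else 0
            events_per_trial.append(int(n_ev))

            trial_fish: list[int] = []
            trial_times: list[float] = []
            offset = 0
            for ev in range(n_ev):
                members = perm[offset : offset + sizes[ev]]
                offset += sizes[ev]
                v = liab_z[members] + rng.normal(
                    0.0, config.event_noise_sd, size=len(members)
                )
                caught_mask = v > config.capture_threshold
                caught = members[caught_mask]
                times = config.event_duration_s * expit(-v[caught_mask])
                for fish, t in zip(caught, times):
                    g = ids[fish]
                    if not ever_captured[g]:
                        cap_trial[g] = trial
                        cap_event[g] = ev + 1
                        cap_time[g] = t
                    ever_captured[g] = True
                    if trial == 1:
                        trial1_time[g] = t
                trial_fish.extend(caught)
                trial_times.extend(times)

            trial_fish_arr = np.array(trial_fish, dtype=int)
            trial_times_arr = np.array(trial_times)
            k_remove = min(quota, len(trial_fish_arr))
            order = np.argsort(trial_times_arr, kind="stable")[:k_remove]
            removed = trial_fish_arr[order]
            removed_per_trial.append(int(len(removed)))
            for fish in removed:
                g = ids[fish]
                removed_in_trial[g] = trial
                label[g] = "captured" if trial == 1 else "none"
            active = np.setdiff1d(active, removed, assume_unique=False)

        n_escape = int(round(config.removal_fraction * n_orig))
        never = active[~ever_captured[ids[active]]]
        if len(never) < n_escape:
            warnings.warn(
                f"density {density!r}: only {len(never)} never-captured fish "
                f"available for {n_escape} escaped labels",
                stacklevel=2,
            )
        order = np.argsort(liab_z[never], kind="stable")
        escaped = never[order[: min(n_escape, len(never))]]
        label[ids[escaped]] = "escaped"

        report["densities"][density] = {
            "n_start": int(n_orig),
            "events_per_trial": events_per_trial,
            "total_events": int(sum(events_per_trial)),
            "removed_per_trial": removed_per_trial,
            "n_captured": int(np.sum(label[ids] == "captured")),
            "n_escaped": int(np.sum(label[ids] == "escaped")),
            "n_remaining": int(len(active)),
        }

    table["vulnerability"] = label
    table["removed_in_trial"] = removed_in_trial
    table["ever_captured"] = ever_captured
    table["capture_trial"] = cap_trial
    table["capture_event"] = cap_event
    table["capture_time_s"] = cap_time
    table["trial1_capture_time_s"] = trial1_time
    meta = dict(cohort.meta)
    meta["trawl_report"] = report
    return replace(cohort, table=table, meta=meta)


def select_sequencing_panel(
    cohort: Cohort, n_per_group: int = 24, seed=None
) -> pd.DataFrame:
    """Choose the fish to sequence: n per vulnerability x density group.

    Individuals are drawn balanced across the families represented in all
    four groups (round-robin, one fish per family per pass); when the
    shared families cannot fill a group the remainder is drawn from the
    group's other members with a warning.  Returns a sample sheet with the
    cohort row index of each chosen fish.
    """
    rng = _rng(seed)
    t = cohort.table
    groups = [
        (density, vuln)
        for density in DENSITIES
        for vuln in ("captured", "escaped")
    ]
    members = {
        g: t.index[(t["density"] == g[0]) & (t["vulnerability"] == g[1])].to_numpy()
        for g in groups
    }
    shared_families = set(t["family_id"].unique())
    for g in groups:
        shared_families &= set(t.loc[members[g], "family_id"])
    shared = sorted(shared_families)

    rows = []
    for g in groups:
        pool = members[g]
        if len(pool) < n_per_group:
            raise ValueError(
                f"group {g} has only {len(pool)} fish; cannot sequence {n_per_group}"
            )
        by_family: dict[str, list[int]] = {}
        for i in pool:
            by_family.setdefault(t.at[i, "family_id"], []).append(int(i))
        for fam in by_family:
            by_family[fam] = list(rng.permutation(by_family[fam]))
        chosen: list[int] = []
        fams = list(rng.permutation(shared)) if shared else []
        while len(chosen) < n_per_group and fams:
            progressed = False
            for fam in fams:
                if len(chosen) >= n_per_group:
                    break
                bucket = by_family.get(fam)
                if bucket:
                    chosen.append(bucket.pop())
                    progressed = True
            if not progressed:
                break
        if len(chosen) < n_per_group:
            warnings.warn(
                f"group {g}: exact family balance impossible; "
                f"filling {n_per_group - len(chosen)} slots from remaining fish",
                stacklevel=2,
            )
            rest = [i for i in pool if i not in set(chosen)]
            extra = rng.permutation(rest)[: n_per_group - len(chosen)]
            chosen.extend(int(i) for i in extra)
        for i in chosen:
            rows.append(
                {
                    "individual_id": t.at[i, "individual_id"],
                    "family_id": t.at[i, "family_id"],
                    "density": g[0],
                    "sex": t.at[i, "sex"],
                    "group": g[1],
                    "cohort_index": int(i),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AlleleCountMatrix:
    """Per-site x per-individual reference/alternate read counts."""

    ref: np.ndarray  # (L, N)
    alt: np.ndarray  # (L, N)
    indiv_mean_depth: np.ndarray  # (N,) realised per-individual target depth
    err: float
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    sample_ids: list[str] | None = None

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt


def simulate_read_counts(
    genotypes: np.ndarray,
    mean_depth: float = 2.0,
    depth_sd_between_individuals: float = 0.5,
    err: float = 0.01,
    seed=None,
    *,
    chrom: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> AlleleCountMatrix:
    """Simulate low-coverage sequencing reads over hard genotypes.

    Per-individual mean depth is Normal(mean_depth, sd) truncated at 0;
    per-site depth is Poisson around that mean; each read reports the true
    allele with probability 1 - ``err``.  ``genotypes`` is (N individuals,
    L sites) alternate-allele dosage.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    if not 0.0 <= err < 0.5:
        raise ValueError("err must be in [0, 0.5)")
    genotypes = np.asarray(genotypes)
    rng = _rng(seed)
    n_ind, n_sites = genotypes.shape

    if depth_sd_between_individuals > 0:
        a = (0.0 - mean_depth) / depth_sd_between_individuals
        mu = truncnorm.rvs(
            a,
            np.inf,
            loc=mean_depth,
            scale=depth_sd_between_individuals,
            size=n_ind,
            random_state=rng,
        )
    else:
        mu = np.full(n_ind, float(mean_depth))

    depth = rng.poisson(np.broadcast_to(mu[None, :], (n_sites, n_ind)))
    g = genotypes.T  # (L, N)
    p_alt = (g / 2.0) * (1.0 - err) + (1.0 - g / 2.0) * err
    alt = rng.binomial(depth, p_alt)
    ref = depth - alt
    return AlleleCountMatrix(
        ref=ref.astype(np.int32),
        alt=alt.astype(np.int32),
        indiv_mean_depth=mu,
        err=err,
        chrom=chrom,
        pos=pos,
        sample_ids=sample_ids,
    )


def make_gene_annotation(
    n_genes: int,
    genome: dict[str, int],
    seed=None,
    *,
    mean_length: float = 10_000.0,
    sd_log: float = 0.5,
    min_length: int = 200,
    allow_overlap: bool = False,
) -> pd.DataFrame:
    """Place synthetic gene intervals on the genome.

    Lengths are log-normal around ``mean_length``; genes are spread over
    chromosomes round-robin and placed uniformly at random without overlap
    (unless ``allow_overlap``).  Returns a frame with 0-based half-open
    ``start``/``end`` coordinates.  Raises if the genes cannot be packed
    into a chromosome.
    """
    rng = _rng(seed)
    if n_genes == 0:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "gene_id", "strand"]
        ).astype({"start": int, "end": int})
    chroms = list(genome)
    lengths = np.maximum(
        rng.lognormal(np.log(mean_length), sd_log, size=n_genes), min_length
    ).astype(int)
    assignment = np.array([chroms[i % len(chroms)] for i in range(n_genes)])

    rows = []
    gid = 0
    for c in chroms:
        idx = np.flatnonzero(assignment == c)
        if idx.size == 0:
            continue
        clen = genome[c]
        glens = lengths[idx]
        if allow_overlap:
            starts = rng.integers(0, np.maximum(clen - glens, 1), size=len(idx))
        else:
            free = clen - int(glens.sum())
            if free < 0:
                raise ValueError(
                    f"cannot pack {len(idx)} genes ({glens.sum()} bp) into "
                    f"chromosome {c} ({clen} bp)"
                )
            gaps = np.sort(rng.uniform(0, free, size=len(idx))).astype(int)
            starts = gaps + np.concatenate([[0], np.cumsum(glens[:-1])])
        for s, ln in zip(starts, glens):
            gid += 1
            rows.append(
                {
                    "chrom": c,
                    "start": int(s),
                    "end": int(s + ln),
                    "gene_id": f"gene{gid:04d}",
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    return pd.DataFrame(rows)
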