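"""Phenotype derivations and the experiment's statistical models.

Trait derivations: specific growth rate from the two mass measurements,
oxygen uptake from respirometry slopes, standard metabolic rate as the
0.2 quantile of the overnight series, maximum metabolic rate as the
post-exercise peak within a 30-minute window, aerobic scope as their
difference.  Statistics: rank transforms for non-normal responses,
factorial ordinary-least-squares models with Type-III (sum-to-zero)
F tests for sex x density x vulnerability designs with a mass or length
covariate, a multivariate test (Pillai's trace) across all traits, and
Pearson correlations between a genomic PC score and each trait with a
density-interaction test.

Quantiles are type-7 (linear interpolation) throughout, the same
convention used by the scan thresholds.

Two variants of the specific growth rate are exposed.  The ``as_printed``
variant, SGR = ln(m_f - m_i) / T, is dimensionally odd (the log of a mass
difference, negative for sub-unit differences) but is retained verbatim;
the default ``conventional`` variant is the standard
100 (ln m_f - ln m_i) / T in % body mass per day, the only form
consistent with positive reported growth rates.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "sgr",
    "mo2_from_slope",
    "smr_mmr",
    "rank_transform",
    "factorial_glm",
    "multivariate_glm",
    "pc_trait_correlation",
]


def sgr(m_i: float, m_f: float, days: float, variant: str = "conventional") -> float:
    """Specific growth rate between two mass measurements.

    conventional (default): 100 (ln m_f - ln m_i) / days, % body mass per
    day.  as_printed: ln(m_f - m_i) / days, kept for fidelity to the
    originally printed formula; it requires m_f > m_i.
    """
    if days <= 0:
        raise ValueError("days must be > 0")
    if variant == "conventional":
        if m_i <= 0 or m_f <= 0:
            raise ValueError("masses must be positive")
        return 100.0 * (np.log(m_f) - np.log(m_i)) / days
    if variant == "as_printed":
        if m_f <= m_i:
            raise ValueError("as_printed variant requires m_f > m_i")
        return float(np.log(m_f - m_i) / days)
    raise ValueError(f"unknown SGR variant {variant!r}")


def mo2_from_slope(
    slope: float,
    chamber_vol: float,
    fish_vol: float,
    blank_slope: float = 0.0,
    *,
    per_hour_factor: float = 1.0,
) -> float:
    """Oxygen uptake (mg O2 / h) from a respirometry decline slope.

    MO2 = (slope - blank_slope) * (chamber volume - fish volume), with the
    blank slope correcting for background bacterial respiration.  Slopes
    are mg O2 / L per unit time; ``per_hour_factor`` converts that time
    unit to hours (60 for per-minute slopes, 1 for per-hour slopes).
    """
    if fish_vol >= chamber_vol:
        raise ValueError("fish volume must be smaller than the chamber volume")
    if fish_vol < 0:
        raise ValueError("fish volume must be >= 0")
    return (slope - blank_slope) * (chamber_vol - fish_vol) * per_hour_factor


def smr_mmr(
    mo2_series,
    post_exercise_series,
    window: float = 30.0,
    *,
    post_exercise_times=None,
) -> tuple[float, float, float]:
    """SMR, MMR and aerobic scope from oxygen-uptake series.

    SMR is the type-7 0.2 quantile of the overnight MO2 series; MMR is the
    maximum MO2 within the first ``window`` minutes after exercise (all
    supplied values if no times are given); AS = MMR - SMR.
    """
    mo2 = np.asarray(mo2_series, dtype=float)
    post = np.asarray(post_exercise_series, dtype=float)
    if mo2.size == 0 or post.size == 0:
        raise ValueError("oxygen-uptake series must be non-empty")
    if post_exercise_times is not None:
        t = np.asarray(post_exercise_times, dtype=float)
        post = post[t <= window]
        if post.size == 0:
            raise ValueError("no post-exercise measurements inside the window")
    smr = float(np.quantile(mo2, 0.2, method="linear"))
    mmr = float(post.max())
    return smr, mmr, mmr - smr


def rank_transform(values) -> np.ndarray:
    """Average ranks (ties share their mean rank), order-preserving."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty vector")
    return stats.rankdata(values, method="average")


def _check_full_rank(design: pd.DataFrame, formula: str) -> None:
    import patsy

    mat = patsy.dmatrix(formula.split("~", 1)[1], design, return_type="dataframe")
    rank = np.linalg.matrix_rank(mat.to_numpy())
    if rank < mat.shape[1]:
        # find an aliased column: first column whose removal keeps the rank
        for col in mat.columns:
            rest = mat.drop(columns=[col]).to_numpy()
            if np.linalg.matrix_rank(rest) == rank:
                raise ValueError(f"rank-deficient design: term {col!r} is aliased")
        raise ValueError("rank-deficient design")


def factorial_glm(
    data: pd.DataFrame,
    response: str,
    *,
    factors: tuple[str, ...] = ("sex", "density", "vulnerability"),
    covariate: str | None = "mass",
    interactions: bool = True,
    rank_response: bool = False,
) -> pd.DataFrame:
    """Factorial OLS with marginal (Type-III) F tests, sum-to-zero coding.

    Fits ``response`` on the crossed factors (full interaction structure
    when ``interactions``), optionally with a covariate, optionally on the
    rank-transformed response.  Returns the ANOVA table with F, df pair
    and p per term.
    """
    df = data.copy()
    y = response
    if rank_response:
        df["_rank_y"] = rank_transform(df[response])
        y = "_rank_y"
    terms = [f"C({f}, Sum)" for f in factors]
    rhs = " * ".join(terms) if interactions else " + ".join(terms)
    if covariate:
        rhs = f"{rhs} + {covariate}"
    formula = f"{y} ~ {rhs}"
    _check_full_rank(df, formula)
    model = ols(formula, data=df).fit()
    table = sm.stats.anova_lm(model, typ=3)
    table = table.rename(
        columns={"F": "F", "PR(>F)": "p_value", "sum_sq": "sum_sq", "df": "df"}
    )
    table.attrs["formula"] = formula
    table.attrs["rank_response"] = rank_response
    table.attrs["resid_df"] = float(model.df_resid)
    return table


def multivariate_glm(
    data: pd.DataFrame,
    responses: tuple[str, ...],
    *,
    factors: tuple[str, ...] = ("sex", "density", "vulnerability"),
    covariate: str | None = "mass",
    interactions: bool = True,
    rank_responses: bool = False,
) -> pd.DataFrame:
    """Multivariate linear model; Pillai's trace per term with F approximation.

    Complete cases only; raises when the within-group covariance of the
    responses is singular.
    """
    if len(responses) < 1:
        raise ValueError("need at least one response trait")
    cols = list(responses) + list(factors) + ([covariate] if covariate else [])
    df = data[cols].dropna().copy()
    if rank_responses:
        for r in responses:
            df[r] = rank_transform(df[r])
    resid = df[list(responses)] - df.groupby(list(factors))[list(responses)].transform(
        "mean"
    )
    if len(responses) > 1:
        cov = np.cov(resid.to_numpy().T)
        if np.linalg.matrix_rank(cov) < len(responses):
            raise ValueError("singular within-groups covariance of the responses")
    if len(responses) == 1:
        # one response: Pillai reduces to SSH/(SSH+SSE) and the F test to the
        # univariate marginal F, so delegate to the factorial model
        uni = factorial_glm(
            df,
            responses[0],
            factors=factors,
            covariate=covariate,
            interactions=interactions,
        )
        rows = []
        df_den = uni.attrs["resid_df"]
        for term in uni.index:
            if term in ("Intercept", "Residual"):
                continue
            f_val = float(uni.loc[term, "F"])
            df_num = float(uni.loc[term, "df"])
            pillai = f_val * df_num / (f_val * df_num + df_den)
            rows.append(
                {
                    "term": term.replace(", Sum)", ")").replace("C(", "").replace(")", ""),
                    "pillai": pillai,
                    "F": f_val,
                    "df_num": df_num,
                    "df_den": df_den,
                    "p_value": float(uni.loc[term, "p_value"]),
                }
            )
        out = pd.DataFrame(rows).set_index("term")
        out.attrs["responses"] = list(responses)
        return out
    terms = [f"C({f}, Sum)" for f in factors]
    rhs = " * ".join(terms) if interactions else " + ".join(terms)
    if covariate:
        rhs = f"{rhs} + {covariate}"
    lhs = " + ".join(responses)
    mv = MANOVA.from_formula(f"{lhs} ~ {rhs}", data=df)
    res = mv.mv_test()
    rows = []
    for term, payload in res.results.items():
        stat = payload["stat"]
        pillai = stat.loc["Pillai's trace"]
        rows.append(
            {
                "term": term,
                "pillai": float(pillai["Value"]),
                "F": float(pillai["F Value"]),
                "df_num": float(pillai["Num DF"]),
                "df_den": float(pillai["Den DF"]),
                "p_value": float(pillai["Pr > F"]),
            }
        )
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["responses"] = list(responses)
    return out


def pc_trait_correlation(
    pc_scores: np.ndarray,
    trait: np.ndarray,
    density_labels: np.ndarray,
) -> dict:
    """Pearson correlation of a genomic PC score with a trait, by density.

    Reports r, r^2 and two-sided p for each density stratum and for the
    densities combined, plus the p-value of the score x density
    interaction from an OLS model of the trait.  Requires >= 3 complete
    pairs per stratum and non-zero variance in both variables.
    """
    pc_scores = np.asarray(pc_scores, dtype=float)
    trait = np.asarray(trait, dtype=float)
    density_labels = np.asarray(density_labels)
    ok = ~(np.isnan(pc_scores) | np.isnan(trait))
    pc_scores, trait, density_labels = pc_scores[ok], trait[ok], density_labels[ok]

    def corr(x, y):
        if len(x) < 3:
            raise ValueError("need at least 3 pairs per stratum")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero variance in a correlation input")
        r, p = stats.pearsonr(x, y)
        return {"r": float(r), "r2": float(r * r), "p": float(p), "n": int(len(x))}

    out = {"combined": corr(pc_scores, trait)}
    for d in pd.unique(density_labels):
        m = density_labels == d
        out[str(d)] = corr(pc_scores[m], trait[m])

    df = pd.DataFrame(
        {"trait": trait, "score": pc_scores, "density": density_labels}
    )
    model = ols("trait ~ score * C(density, Sum)", data=df).fit()
    inter = [t for t in model.pvalues.index if "score:" in t]
    out["interaction_p"] = float(model.pvalues[inter].min()) if inter else float("nan")
    return out
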