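"""Group-level statistics for four-arm injury/treatment cohorts.

Implements the study's statistical layer on per-animal outcomes:

- descriptive summaries as mean +/- SEM,
- Kruskal-Wallis omnibus with Dunn's multiple-comparison post hoc test for
  urethral/pudendal function metrics,
- two-way (between-group x within-strain-level) repeated-measures ANOVA with
  Bonferroni-adjusted pairwise group contrasts for tangent moduli,
- a linear mixed model (random intercept per specimen) with Bonferroni
  contrasts for the anisotropy index, and
- the two-sample t-test sample-size calculation (30% stiffness difference,
  alpha 0.05, power 0.9).

Omnibus machinery is delegated to scipy / pingouin / statsmodels; Dunn's
test is implemented here (rank-based z-tests with tie correction).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.power import TTestIndPower

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "PairwiseComparison",
    "StatResult",
    "summarize",
    "kruskal_dunn",
    "rm_anova_bonferroni",
    "mixed_model_ai",
    "sample_size",
]

AdjustMethod = Literal["bonferroni", "holm", "none"]
_ADJUST_MAP = {"bonferroni": "bonferroni", "holm": "holm", "none": None}


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- SEM descriptive summary of one metric in one group."""

    group: str
    metric: str
    n: int
    mean: float
    sem: float  # NaN when n < 2


@dataclass
class PairwiseComparison:
    pair: tuple
    estimate: float
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str
    label: str = ""


@dataclass
class StatResult:
    """Omnibus test plus its family of pairwise comparisons."""

    test: str
    statistic: float
    p_value: float
    comparisons: List[PairwiseComparison] = field(default_factory=list)
    alpha: float = 0.05
    details: Dict = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "comparisons": [
                {
                    "pair": list(c.pair),
                    "label": c.label,
                    "estimate": c.estimate,
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "method": c.method,
                }
                for c in self.comparisons
            ],
            "details": self.details,
        }


def _adjust(p_raw: Sequence[float], method: AdjustMethod) -> np.ndarray:
    p = np.asarray(p_raw, dtype=float)
    if len(p) == 0:
        return p
    if method == "none":
        return p
    return multipletests(p, method=_ADJUST_MAP[method])[1]


def summarize(outcomes: pd.DataFrame, metric: str) -> List[GroupSummary]:
    """Per-group mean and SEM of ``metric`` from a tidy outcomes table.

    Accepts either long format (columns metric/value) or wide format (one
    column per metric). NaN values are treated as missing; a group with no
    non-missing values raises.
    """
    if {"metric", "value"}.issubset(outcomes.columns):
        df = outcomes[outcomes["metric"] == metric][["group", "value"]]
    elif metric in outcomes.columns:
        df = outcomes[["group", metric]].rename(columns={metric: "value"})
    else:
        raise ValueError(f"metric {metric!r} not found in outcomes table")

    out: List[GroupSummary] = []
    for group, sub in df.groupby("group", sort=False):
        vals = sub["value"].dropna().to_numpy()
        if len(vals) == 0:
            raise ValueError(f"group {group!r} has no non-missing values for {metric!r}")
        sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else math.nan
        out.append(GroupSummary(group=str(group), metric=metric, n=len(vals),
                                mean=float(np.mean(vals)), sem=sem))
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------


def _dunn_pairs(
    samples: Dict[str, np.ndarray], method: AdjustMethod
) -> List[PairwiseComparison]:
    """Dunn's post hoc z-tests on mean ranks, with tie correction."""
    groups = list(samples)
    pooled = np.concatenate([samples[g] for g in groups])
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)

    mean_ranks, start = {}, 0
    for g in groups:
        n_g = len(samples[g])
        mean_ranks[g] = float(np.mean(ranks[start:start + n_g]))
        start += n_g

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    comps, p_raw = [], []
    for g1, g2 in itertools.combinations(groups, 2):
        se = math.sqrt(var_base * (1.0 / len(samples[g1]) + 1.0 / len(samples[g2])))
        diff = mean_ranks[g1] - mean_ranks[g2]
        z = diff / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        comps.append(PairwiseComparison(pair=(g1, g2), estimate=diff, statistic=z,
                                        p_raw=p, p_adjusted=p, method=method))
        p_raw.append(p)
    for c, p_adj in zip(comps, _adjust(p_raw, method)):
        c.p_adjusted = float(p_adj)
    return comps


def kruskal_dunn(
    outcomes: pd.DataFrame,
    metric: str,
    method: AdjustMethod = "bonferroni",
    alpha: float = 0.05,
) -> StatResult:
    """Kruskal-Wallis omnibus (tie-corrected) with Dunn's post hoc test.

    All-identical data degenerate to H=0, p=1 rather than erroring.
    """
    if {"metric", "value"}.issubset(outcomes.columns):
        df = outcomes[outcomes["metric"] == metric]
        value_col = "value"
    else:
        df, value_col = outcomes, metric
    samples = {
        str(g): sub[value_col].dropna().to_numpy()
        for g, sub in df.groupby("group", sort=False)
    }
    samples = {g: v for g, v in samples.items() if len(v) > 0}
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 non-empty groups")

    pooled = np.concatenate(list(samples.values()))
    if np.all(pooled == pooled[0]):
        h_stat, p = 0.0, 1.0
        comps = [
            PairwiseComparison(pair=(g1, g2), estimate=0.0, statistic=0.0,
                               p_raw=1.0, p_adjusted=1.0, method=method)
            for g1, g2 in itertools.combinations(samples, 2)
        ]
    else:
        h_stat, p = sps.kruskal(*samples.values())
        comps = _dunn_pairs(samples, method)
    return StatResult(
        test="kruskal_wallis_dunn", statistic=float(h_stat), p_value=float(p),
        comparisons=comps, alpha=alpha, details={"metric": metric},
    )


# ---------------------------------------------------------------------------
# Two-way repeated-measures (mixed) ANOVA for tangent moduli
# ---------------------------------------------------------------------------


def rm_anova_bonferroni(
    moduli: pd.DataFrame,
    dv: str = "tangent_modulus_MPa",
    subject: str = "specimen_id",
    within: str = "strain_level_pct",
    between: str = "group",
    method: AdjustMethod = "bonferroni",
    alpha: float = 0.05,
) -> StatResult:
    """Between-group x within-strain-level ANOVA on one axis's moduli.

    Subjects missing any strain level are excluded with a logged warning
    (the within factor must be complete). Pairwise group contrasts are
    two-sample t-tests within each strain level, adjusted over the whole
    family of (pair x level) comparisons.
    """
    import pingouin as pg

    df = moduli.dropna(subset=[dv]).copy()
    n_levels = df[within].nunique()
    counts = df.groupby(subject)[within].nunique()
    incomplete = counts[counts < n_levels].index.tolist()
    if incomplete:
        logger.warning(
            "excluding %d subject(s) missing strain levels: %s", len(incomplete), incomplete
        )
        df = df[~df[subject].isin(incomplete)]
    if df[between].nunique() < 2:
        raise ValueError("need at least 2 groups")

    if float(df[dv].std()) == 0.0:
        # fully degenerate data: no variance anywhere -> F = 0, p = 1
        f_stat, p = 0.0, 1.0
        details = {"degenerate": True}
    else:
        aov = pg.mixed_anova(data=df, dv=dv, within=within, between=between, subject=subject)
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        row = aov[aov["Source"] == between].iloc[0]
        f_stat, p = float(row["F"]), float(row[p_col])
        details = {
            "anova_table": aov.to_dict(orient="records"),
            "interaction_p": float(aov[aov["Source"] == "Interaction"][p_col].iloc[0]),
        }

    comps, p_raw = [], []
    groups = sorted(df[between].unique())
    for level in sorted(df[within].unique()):
        sub = df[df[within] == level]
        for g1, g2 in itertools.combinations(groups, 2):
            a = sub[sub[between] == g1][dv].to_numpy()
            b = sub[sub[between] == g2][dv].to_numpy()
            est = float(np.mean(a) - np.mean(b)) if len(a) and len(b) else math.nan
            if len(a) >= 2 and len(b) >= 2 and (np.std(a) > 0 or np.std(b) > 0):
                t_stat, p_t = sps.ttest_ind(a, b)
            else:
                t_stat, p_t = 0.0, 1.0
            comps.append(
                PairwiseComparison(pair=(g1, g2), estimate=est, statistic=float(t_stat),
                                   p_raw=float(p_t), p_adjusted=float(p_t), method=method,
                                   label=f"{within}={level}")
            )
            p_raw.append(float(p_t))
    for c, p_adj in zip(comps, _adjust(p_raw, method)):
        c.p_adjusted = float(p_adj)

    return StatResult(
        test="two_way_rm_anova", statistic=f_stat, p_value=p, comparisons=comps,
        alpha=alpha, details=details,
    )


# ---------------------------------------------------------------------------
# Mixed model for the anisotropy index
# ---------------------------------------------------------------------------


def mixed_model_ai(
    ai: pd.DataFrame,
    dv: str = "ai",
    subject: str = "specimen_id",
    within: str = "strain_level_pct",
    between: str = "group",
    method: AdjustMethod = "bonferroni",
    alpha: float = 0.05,
) -> StatResult:
    """AI ~ group x strain level with a per-specimen random intercept.

    Pairwise group contrasts within each strain level are Wald z-tests on
    the fixed effects, Bonferroni-adjusted over the whole family. A singular
    fit (zero random-intercept variance) falls back to an ordinary
    fixed-effects (OLS) model with a logged warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from patsy import build_design_matrices

    df = ai.dropna(subset=[dv]).copy()
    df["_level"] = df[within].astype(str)
    formula = f"{dv} ~ C({between}) * C(_level)"

    used_ols = False
    if float(df[dv].std()) == 0.0:
        used_ols = True  # constant response: OLS gives the exact zero contrasts
        result = smf.ols(formula, data=df).fit()
    else:
        model = smf.mixedlm(formula, data=df, groups=df[subject])
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True)
        re_var = float(np.asarray(result.cov_re).ravel()[0])
        if not np.isfinite(re_var) or re_var < 1e-10:
            logger.warning("singular mixed-model fit (random-intercept variance ~ 0); "
                           "falling back to a fixed-effects model")
            used_ols = True
            result = smf.ols(formula, data=df).fit()

    design_info = result.model.data.design_info
    groups = sorted(df[between].unique())
    levels = sorted(df[within].unique())

    comps, p_raw = [], []
    k_fe = len(result.fe_params) if not used_ols else len(result.params)
    for level in levels:
        for g1, g2 in itertools.combinations(groups, 2):
            rows = build_design_matrices(
                [design_info],
                pd.DataFrame({between: [g1, g2], "_level": [str(level)] * 2}),
            )[0]
            L = (np.asarray(rows)[0] - np.asarray(rows)[1]).reshape(1, -1)[:, :k_fe]
            params = result.fe_params if not used_ols else result.params
            cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
            est = (L @ np.asarray(params)).item()
            var = (L @ cov @ L.T).item()
            if var <= 0:
                z, p = 0.0, 1.0
            else:
                z = est / math.sqrt(var)
                p = 2.0 * sps.norm.sf(abs(z))
            comps.append(
                PairwiseComparison(pair=(g1, g2), estimate=est, statistic=z,
                                   p_raw=p, p_adjusted=p, method=method,
                                   label=f"{within}={level}")
            )
            p_raw.append(p)
    for c, p_adj in zip(comps, _adjust(p_raw, method)):
        c.p_adjusted = float(p_adj)

    # omnibus: Wald test that all group-involving fixed effects are zero
    params = np.asarray(result.fe_params if not used_ols else result.params)
    cov = np.asarray(result.cov_params())[:k_fe, :k_fe]
    group_ix = [i for i, name in enumerate(design_info.column_names[:k_fe]) if between in name]
    if group_ix and float(df[dv].std()) > 0.0:
        R = np.zeros((len(group_ix), k_fe))
        for r, i in enumerate(group_ix):
            R[r, i] = 1.0
        Rp = R @ params
        Rcov = R @ cov @ R.T
        try:
            w = float(Rp @ np.linalg.solve(Rcov, Rp))
            p_omni = float(sps.chi2.sf(w, df=len(group_ix)))
        except np.linalg.LinAlgError:
            w, p_omni = math.nan, math.nan
    else:
        w, p_omni = 0.0, 1.0

    return StatResult(
        test="mixed_model_ai", statistic=w, p_value=p_omni, comparisons=comps,
        alpha=alpha, details={"fallback_ols": used_ols},
    )


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------


def sample_size(
    relative_difference: float = 0.30,
    alpha: float = 0.05,
    power: float = 0.90,
    relative_sd: float | None = None,
) -> int:
    """Smallest per-group n for a two-sided two-sample t-test.

    The standardized effect is d = relative_difference / relative_sd;
    ``relative_sd`` (the assumed coefficient of variation of the outcome)
    must be supplied explicitly. With the study's 30% difference, alpha
    0.05, power 0.9 and relative_sd 0.15 (d = 2), this gives n = 7.
    """
    if relative_sd is None:
        raise ValueError("relative_sd must be supplied (no silent default)")
    if not (0 < relative_difference and 0 < alpha < 1 and 0 < power < 1):
        raise ValueError("arguments out of range")
    if relative_sd <= 0:
        raise ValueError("relative_sd must be > 0")
    d = relative_difference / relative_sd
    solver = TTestIndPower()
    try:
        n_frac = float(np.atleast_1d(
            solver.solve_power(effect_size=d, alpha=alpha, power=power, ratio=1.0,
                               alternative="two-sided")
        )[0])
    except Exception:
        n_frac = math.nan  # solver can fail for extreme effect sizes
    # smallest integer n (>= 2) whose achieved power meets the target;
    # power is monotone in n, so walk up from the solver's hint, then down
    def achieved(n: int) -> float:
        return solver.power(effect_size=d, nobs1=n, alpha=alpha, ratio=1.0,
                            alternative="two-sided")

    n = max(int(math.floor(n_frac)), 2) if math.isfinite(n_frac) else 2
    while n < 10_000_000 and not achieved(n) >= power - 1e-12:
        n += 1
    if n >= 10_000_000:
        raise ValueError("requested power is unattainable")
    while n > 2 and achieved(n - 1) >= power - 1e-12:
        n -= 1
    return n
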