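"""Group comparisons: scalar tests, mixed-effects models, effect sizes.

Animal-level scalars (event rates) are compared with an independent-samples
t-test when both groups pass Shapiro-Wilk normality, otherwise a Wilcoxon
rank-sum test; Cohen's d on the pooled SD is always reported. Channel-nested
outcomes (entropy summaries) are modelled with linear mixed effects:

    entropy ~ animal_group + (1 | channel) + (1 | animal)

and event-partitioned entropy with

    entropy ~ event_type + animal_group + coactivity_statistic
              + (1 | channel) + (1 | animal) + (1 | baseline_entropy_decile)

where the baseline-entropy random intercept groups each channel's session
baseline entropy into deciles (a continuous variable cannot index a random
intercept directly). Mixed-model results are reported in
(beta, +/-CI, d_RM, p) order with Wald 95% intervals; d_RM is the
repeated-measures Cohen effect size for the paired contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .errors import InsufficientDataError, InvalidInputError, InvalidParameterError

__all__ = [
    "ScalarTestResult",
    "LmeResult",
    "compare_scalar_by_group",
    "fit_entropy_lme",
    "fit_event_entropy_lme",
    "cohen_d",
    "cohen_d_rm",
]


@dataclass
class ScalarTestResult:
    test_name: str  # "t-test" | "wilcoxon-rank-sum"
    p: float
    effect_d: float
    group_means: tuple[float, float]  # (control, HF)
    normality_p: tuple[float, float]
    flagged: bool = False  # gate fell back (zero variance / tiny group)


@dataclass
class LmeResult:
    beta: dict[str, float]
    ci95: dict[str, float]  # +/- half-widths
    p: dict[str, float]
    d_rm: float
    formula_echo: str
    primary: str  # name of the coefficient of interest
    flags: list[str] = field(default_factory=list)

    def report(self, term: str | None = None) -> tuple[float, float, float, float]:
        """(beta, +/-CI, d_RM, p) for one coefficient."""
        term = term or self.primary
        return self.beta[term], self.ci95[term], self.d_rm, self.p[term]


def cohen_d(x: np.ndarray, y: np.ndarray) -> float:
    """Independent-samples Cohen's d with pooled SD; 0 when both spreads vanish."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    diff = x.mean() - y.mean()
    if pooled == 0:
        return 0.0 if diff == 0 else np.inf * np.sign(diff)
    return float(diff / pooled)


def cohen_d_rm(x: np.ndarray, y: np.ndarray) -> float:
    """Repeated-measures Cohen's d for paired samples.

    d_RM = mean(x - y) / sqrt(SDx^2 + SDy^2 - 2 r SDx SDy) * sqrt(2 (1 - r)),
    with r the Pearson correlation across units. Degenerate spread with a
    non-zero mean difference is an error; identical pairs give 0.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise InsufficientDataError("need at least two complete pairs")
    mean_diff = float(np.mean(x - y))
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        if mean_diff == 0:
            return 0.0
        raise InsufficientDataError("correlation undefined: a margin has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    denom = np.sqrt(max(sx**2 + sy**2 - 2 * r * sx * sy, 0.0))
    if denom == 0:
        if mean_diff == 0:
            return 0.0
        raise InsufficientDataError("degenerate denominator: constant paired difference")
    return float(mean_diff / denom * np.sqrt(2.0 * (1.0 - r)))


def _shapiro_p(v: np.ndarray) -> float:
    if v.size < 3 or np.ptp(v) == 0:
        return np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(v).pvalue)


def compare_scalar_by_group(
    values: np.ndarray,
    groups: np.ndarray,
    alpha_norm: float = 0.05,
    order: tuple[str, str] = ("control", "HF"),
) -> ScalarTestResult:
    """Normality-gated two-sided comparison of one scalar per animal.

    Both groups normal by Shapiro-Wilk (p >= alpha_norm) -> Student's pooled
    t-test; otherwise Wilcoxon rank-sum. A group with zero variance (where the
    t-test is ill-posed) also falls back to rank-sum, flagged. Cohen's d is
    reported as (second group - first group) / pooled SD.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    a = values[groups == order[0]]
    b = values[groups == order[1]]
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("need at least two animals per group")

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    flagged = False
    degenerate = np.ptp(a) == 0 or np.ptp(b) == 0
    both_normal = (np.isnan(pa) or pa >= alpha_norm) and (np.isnan(pb) or pb >= alpha_norm)
    if np.array_equal(np.sort(a), np.sort(b)):
        # identical groups: no evidence of difference
        test_name, p = "t-test", 1.0
    elif both_normal and not degenerate:
        test_name = "t-test"
        p = float(sps.ttest_ind(a, b, equal_var=True).pvalue)
    else:
        test_name = "wilcoxon-rank-sum"
        flagged = degenerate and both_normal
        p = float(sps.ranksums(a, b).pvalue)
    d = cohen_d(b, a)  # HF relative to control
    return ScalarTestResult(
        test_name=test_name,
        p=p,
        effect_d=d,
        group_means=(float(a.mean()), float(b.mean())),
        normality_p=(pa, pb),
        flagged=flagged,
    )


def _fit_mixedlm(formula: str, data: pd.DataFrame, groups: str, vc: dict[str, str]):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data[groups], re_formula="1", vc_formula=vc)
        return model.fit(reml=True, method=["lbfgs", "bfgs"])


def _extract(
    res,
    primary: str,
    d_rm: float,
    formula: str,
    flags: list[str],
    df_map: dict[str, float] | None = None,
) -> LmeResult:
    """Wald intervals with between/within t reference distributions.

    ``df_map`` assigns each coefficient its denominator degrees of freedom
    (animal-level effects get n_animals - #between-terms, within-animal
    effects the residual df); coefficients not listed use the residual df.
    """
    fe = res.fe_params
    se = res.bse_fe
    resid_df = max(float(res.nobs - len(fe)), 1.0)
    beta, ci, pvals = {}, {}, {}
    for k in fe.index:
        df = (df_map or {}).get(k, resid_df)
        tcrit = float(sps.t.ppf(0.975, df))
        beta[k] = float(fe[k])
        ci[k] = float(tcrit * se[k])
        tval = fe[k] / se[k] if se[k] > 0 else np.inf * np.sign(fe[k])
        pvals[k] = float(2.0 * sps.t.sf(abs(tval), df))
    return LmeResult(
        beta=beta, ci95=ci, p=pvals, d_rm=d_rm, formula_echo=formula, primary=primary, flags=flags
    )


def fit_entropy_lme(table: pd.DataFrame, outcome: str = "outcome") -> LmeResult:
    """Mixed model: outcome ~ group with random intercepts for channel and animal.

    ``table`` needs columns animal_id, group ("control"/"HF"), channel and the
    outcome. A singular channel variance component triggers a refit without it
    (flagged).
    """
    required = {"animal_id", "group", "channel", outcome}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"table must have columns {sorted(required)}")
    if table["animal_id"].nunique() < 4 or table["channel"].nunique() < 2:
        raise InsufficientDataError("need >= 2 animals per group and >= 2 channels")

    data = table.rename(columns={outcome: "_y"}).copy()
    if data["_y"].nunique() == 1:
        # constant outcome: no group effect, trivially
        beta = {"Intercept": float(data["_y"].iloc[0]), "group_hf": 0.0}
        return LmeResult(
            beta=beta,
            ci95={k: 0.0 for k in beta},
            p={"Intercept": 0.0, "group_hf": 1.0},
            d_rm=0.0,
            formula_echo="_y ~ group_hf + (1|channel) + (1|animal_id)",
            primary="group_hf",
            flags=["constant-outcome"],
        )
    data["group_hf"] = (data["group"] == "HF").astype(float)
    formula = "_y ~ group_hf"
    flags: list[str] = []
    try:
        res = _fit_mixedlm(formula, data, "animal_id", {"channel": "0 + C(channel)"})
        if not np.all(np.isfinite(res.bse_fe)):
            raise ValueError("non-finite standard errors")
    except Exception:
        flags.append("channel-intercept-dropped")
        res = _fit_mixedlm(formula, data, "animal_id", {})
    n_animals = data["animal_id"].nunique()
    df_map = {"Intercept": n_animals - 2.0, "group_hf": n_animals - 2.0}

    # d_RM: pair the two groups' channel-wise means across shared channels
    piv = data.pivot_table(index="channel", columns="group", values="_y", aggfunc="mean")
    d_rm = np.nan
    if {"control", "HF"}.issubset(piv.columns):
        piv = piv.dropna()
        if len(piv) >= 2:
            try:
                d_rm = cohen_d_rm(piv["HF"].to_numpy(), piv["control"].to_numpy())
            except InsufficientDataError:
                d_rm = np.nan
    return _extract(
        res, "group_hf", d_rm, "_y ~ group_hf + (1|channel) + (1|animal_id)", flags, df_map
    )


def fit_event_entropy_lme(table: pd.DataFrame, outcome: str = "outcome") -> LmeResult:
    """Mixed model for event-partitioned entropy.

    Fixed effects: event_type ("event"/"non_event"), group, statistic
    ("MEAN"/"STD"); random intercepts: channel, animal, and deciles of
    ``baseline_entropy`` (each channel's session-level entropy mean). The
    primary coefficient is the event-type contrast (event minus non-event).
    """
    required = {"animal_id", "group", "channel", "statistic", "event_type", "baseline_entropy", outcome}
    if not required.issubset(table.columns):
        raise InvalidInputError(f"table must have columns {sorted(required)}")
    n_units = table.groupby("animal_id")["event_type"].nunique()
    if table["animal_id"].nunique() < 2 or table["channel"].nunique() < 2:
        raise InsufficientDataError("need multiple animals and channels")
    if (n_units < 2).all():
        raise InsufficientDataError("need both event types for at least one animal")

    data = table.rename(columns={outcome: "_y"}).copy()
    data["is_event"] = (data["event_type"] == "event").astype(float)
    data["group_hf"] = (data["group"] == "HF").astype(float)
    data["stat_std"] = (data["statistic"] == "STD").astype(float)
    # decile bins of the baseline entropy (ties collapse duplicate edges)
    try:
        data["baseline_bin"] = pd.qcut(
            data["baseline_entropy"], 10, labels=False, duplicates="drop"
        )
    except ValueError:
        data["baseline_bin"] = 0
    if data["baseline_bin"].isna().any() or data["baseline_bin"].nunique() < 2:
        data["baseline_bin"] = 0

    terms = ["is_event"]
    if data["group_hf"].nunique() > 1:
        terms.append("group_hf")
    if data["stat_std"].nunique() > 1:
        terms.append("stat_std")
    formula = "_y ~ " + " + ".join(terms)
    vc = {"channel": "0 + C(channel)"}
    if data["baseline_bin"].nunique() > 1:
        vc["baseline_bin"] = "0 + C(baseline_bin)"
    flags: list[str] = []
    try:
        res = _fit_mixedlm(formula, data, "animal_id", vc)
        if not np.all(np.isfinite(res.bse_fe)):
            raise ValueError("non-finite standard errors")
    except Exception:
        flags.append("vc-dropped")
        res = _fit_mixedlm(formula, data, "animal_id", {})

    # d_RM pairs inside vs outside event values per (animal, channel, statistic)
    piv = data.pivot_table(
        index=["animal_id", "channel", "statistic"],
        columns="event_type",
        values="_y",
        aggfunc="mean",
    )
    d_rm = np.nan
    if {"event", "non_event"}.issubset(piv.columns):
        piv = piv.dropna()
        if len(piv) >= 2:
            try:
                d_rm = cohen_d_rm(piv["event"].to_numpy(), piv["non_event"].to_numpy())
            except InsufficientDataError:
                d_rm = np.nan
    echo = (
        "_y ~ is_event + group_hf + stat_std + (1|channel) + (1|animal_id) + (1|baseline_bin)"
    )
    n_animals = data["animal_id"].nunique()
    df_map = {"Intercept": n_animals - 2.0, "group_hf": n_animals - 2.0}
    return _extract(res, "is_event", d_rm, echo, flags, df_map)
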