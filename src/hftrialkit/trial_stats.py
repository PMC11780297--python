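"""Statistics for a small two-arm trial analyzed by intent-to-treat.

The analysis layer mirrors what a phase-1 feasibility trial reports:

* per-patient change scores from baseline and group summaries (mean, SD with
  the n-1 denominator);
* standardized mean differences (Cohen's d on change scores, pooled SD) with
  t-based confidence intervals:  se_d = sqrt((n1+n2)/(n1*n2) + d^2/(2(n1+n2)))
  and CI = d +/- t_{1-a/2, n1+n2-2} * se_d.  No small-sample (Hedges)
  correction by default.  Interpretation rests on direction, magnitude and CI
  rather than p values, but the pooled-variance two-sample t test is reported;
* multiple imputation by chained equations (normal linear model per
  incomplete column, predictive-mean-matching variant selectable), m=20 by
  default, pooled by Rubin's rules (total variance = within + (1+1/m) between);
* random-intercept linear mixed models for weekly trajectories (REML via
  statsmodels), with Wald t statistics at a configurable denominator df
  (default N_obs - N_subjects - 1);
* feasibility arithmetic: recruitment fraction, recruitment rate per month,
  retention per visit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import ValidationError


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean_change: float
    sd_change: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group size must be >= 2")
        if self.sd_change < 0:
            raise ValidationError("SD must be non-negative")


@dataclass(frozen=True)
class EffectSizeResult:
    d: float
    se_d: float
    ci_low: float
    ci_high: float
    df: int
    t_stat: float
    p_value: float


@dataclass
class ImputationSet:
    m: int
    datasets: list[pd.DataFrame]
    predictors: list[str]
    seed: int | None


@dataclass
class LMMResult:
    intercept: float
    intercept_se: float
    slope: float
    slope_se: float
    intercept_t: float
    slope_t: float
    df: int
    intercept_p: float
    slope_p: float
    random_intercept_var: float
    residual_var: float


@dataclass
class FeasibilityMetrics:
    n_screened: int
    n_eligible: int
    n_enrolled: int
    n_randomized: int
    n_completed: int
    recruitment_fraction_pct: float
    retention_pct: dict[str, float] = field(default_factory=dict)
    recruitment_rate_per_month: float | None = None


# ---------------------------------------------------------------------------
# change scores and effect sizes


def change_scores(
    baseline: pd.DataFrame,
    followup: pd.DataFrame,
    value_col: str = "score",
) -> pd.DataFrame:
    """Per-patient followup - baseline deltas on matched patient_ids.

    Unmatched patients are excluded (and reported in the ``n_dropped`` attr).
    """
    b = baseline.set_index("patient_id")[value_col]
    f = followup.set_index("patient_id")[value_col]
    common = b.index.intersection(f.index)
    out = pd.DataFrame(
        {"patient_id": common, "delta": (f.loc[common] - b.loc[common]).to_numpy()}
    )
    out.attrs["n_dropped"] = (len(b) - len(common)) + (len(f) - len(common))
    return out


def summarize_group(deltas: np.ndarray | pd.Series) -> GroupSummary:
    arr = np.asarray(deltas, dtype=float)
    arr = arr[~np.isnan(arr)]
    return GroupSummary(
        n=len(arr),
        mean_change=float(np.mean(arr)),
        sd_change=float(np.std(arr, ddof=1)),
    )


def cohen_d_from_summary(
    g1: GroupSummary,
    g2: GroupSummary,
    conf: float = 0.95,
    *,
    ci_method: str = "t",
) -> EffectSizeResult:
    """Cohen's d with pooled SD and a t-quantile confidence interval.

    ``ci_method='normal'`` swaps the t quantile for the normal one (the
    t-based interval is the canonical method here: it reproduces printed
    small-trial intervals that the normal interval does not).
    """
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd_change**2 + (n2 - 1) * g2.sd_change**2) / df
    sp = np.sqrt(sp2)
    diff = g1.mean_change - g2.mean_change
    if sp == 0.0:
        if diff != 0.0:
            raise ValidationError("zero pooled SD with unequal means: d undefined")
        d = 0.0
    else:
        d = diff / sp
    se_d = float(np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))))
    if ci_method == "t":
        q = stats.t.ppf(1 - (1 - conf) / 2, df)
    elif ci_method == "normal":
        q = stats.norm.ppf(1 - (1 - conf) / 2)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    t_stat, _, p = two_sample_t(g1, g2)
    return EffectSizeResult(
        d=float(d),
        se_d=se_d,
        ci_low=float(d - q * se_d),
        ci_high=float(d + q * se_d),
        df=df,
        t_stat=float(t_stat),
        p_value=float(p),
    )


def two_sample_t(g1: GroupSummary, g2: GroupSummary) -> tuple[float, int, float]:
    """Pooled-variance Student t test from group summaries: (t, df, p)."""
    n1, n2 = g1.n, g2.n
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * g1.sd_change**2 + (n2 - 1) * g2.sd_change**2) / df
    diff = g1.mean_change - g2.mean_change
    if sp2 == 0.0:
        if diff != 0.0:
            raise ValidationError("zero pooled variance with unequal means")
        return 0.0, df, 1.0
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    t = diff / se
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# multiple imputation


def _bayes_draw_imputation(
    X_obs: np.ndarray,
    y_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
    *,
    pmm: bool,
    pmm_k: int = 5,
) -> np.ndarray:
    """One proper imputation draw from a normal linear model.

    Draws sigma^2 from its scaled inverse-chi-square posterior and beta from
    N(beta_hat, sigma^2 (X'X)^-1), then either draws y ~ N(X beta, sigma) or
    (PMM) matches each predicted mean to its nearest observed donors.
    """
    n, p = X_obs.shape
    XtX = X_obs.T @ X_obs
    # ridge jitter keeps near-collinear predictor sets invertible
    XtX_inv = np.linalg.pinv(XtX + 1e-10 * np.eye(p))
    beta_hat = XtX_inv @ X_obs.T @ y_obs
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_draw = sigma2 * dof / rng.chisquare(dof) if sigma2 > 0 else 0.0
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta_draw = beta_hat + np.sqrt(sigma2_draw) * (L @ rng.standard_normal(p))
    mu_mis = X_mis @ beta_draw
    if pmm:
        mu_obs = X_obs @ beta_draw
        out = np.empty(len(mu_mis))
        for i, m in enumerate(mu_mis):
            donors = np.argsort(np.abs(mu_obs - m))[:pmm_k]
            out[i] = y_obs[donors[rng.integers(len(donors))]]
        return out
    return mu_mis + np.sqrt(sigma2_draw) * rng.standard_normal(len(mu_mis))


def mi_impute(
    data: pd.DataFrame,
    predictors: list[str],
    outcome_cols: list[str] | None = None,
    m: int = 20,
    seed: int | None = None,
    *,
    n_cycles: int = 10,
    method: str = "norm",
    max_missing_fraction: float = 0.8,
) -> ImputationSet:
    """Multiple imputation by chained equations.

    Missingness is expected only in ``outcome_cols`` (default: every
    non-predictor numeric column with missing cells); predictors must be
    complete.  Each incomplete column is imputed from the predictors plus the
    other outcome columns with a normal linear model and proper posterior
    draws (``method='pmm'`` uses predictive-mean matching on the same
    draws).  Deterministic given ``seed``.
    """
    if method not in ("norm", "pmm"):
        raise ValidationError(f"unknown imputation method {method!r}")
    for p in predictors:
        if data[p].isna().any():
            raise ValidationError(f"predictor {p!r} has missing values")
    if outcome_cols is None:
        outcome_cols = [
            c
            for c in data.columns
            if c not in predictors
            and pd.api.types.is_numeric_dtype(data[c])
            and data[c].isna().any()
        ]
    for c in outcome_cols:
        frac = data[c].isna().mean()
        if frac > max_missing_fraction:
            raise ValidationError(
                f"column {c!r} is {100 * frac:.0f}% missing; refusing to impute"
            )

    incomplete = [c for c in outcome_cols if data[c].isna().any()]
    rng = np.random.default_rng(seed)
    datasets: list[pd.DataFrame] = []
    X_pred = data[predictors].to_numpy(dtype=float)
    intercept = np.ones((len(data), 1))

    for _ in range(m):
        filled = data.copy()
        # initialize missing cells from observed-value draws
        for c in incomplete:
            obs = filled[c].dropna().to_numpy()
            mask = filled[c].isna()
            filled.loc[mask, c] = rng.choice(obs, size=int(mask.sum()))
        if incomplete:
            for _cycle in range(n_cycles):
                for c in incomplete:
                    mask = data[c].isna().to_numpy()
                    others = [o for o in outcome_cols if o != c]
                    X = np.hstack(
                        [intercept, X_pred, filled[others].to_numpy(dtype=float)]
                        if others
                        else [intercept, X_pred]
                    )
                    y = filled[c].to_numpy(dtype=float)
                    imputed = _bayes_draw_imputation(
                        X[~mask], y[~mask], X[mask], rng, pmm=(method == "pmm")
                    )
                    col = filled[c].to_numpy(dtype=float)
                    col[mask] = imputed
                    filled[c] = col
        datasets.append(filled)
    return ImputationSet(m=m, datasets=datasets, predictors=list(predictors), seed=seed)


def rubin_pool(
    estimates: list[float] | np.ndarray,
    variances: list[float] | np.ndarray,
) -> tuple[float, float]:
    """Pool point estimates and variances across imputations (Rubin's rules).

    Returns (pooled estimate, total SE) with total variance
    T = mean within-variance + (1 + 1/m) * between-variance.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if len(q) != len(u):
        raise ValidationError("estimates and variances must have equal length")
    m = len(q)
    if m < 2:
        raise ValidationError("need at least 2 imputations to pool")
    pooled = float(np.mean(q))
    b = float(np.var(q, ddof=1))
    t = float(np.mean(u)) + (1 + 1 / m) * b
    return pooled, float(np.sqrt(t))


# ---------------------------------------------------------------------------
# mixed models


def fit_random_intercept_lmm(
    long: pd.DataFrame,
    *,
    y_col: str = "y",
    week_col: str = "week",
    group_col: str = "patient_id",
    df_method: str = "inner",
) -> LMMResult:
    """REML random-intercept model: y ~ intercept + week, intercept | patient.

    ``df_method='inner'`` uses the within-subject denominator df
    N_obs - N_subjects - 1 for the Wald t tests; ``'residual'`` uses
    N_obs - 2.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    data = long.dropna(subset=[y_col, week_col]).copy()
    n_obs = len(data)
    groups = data[group_col]
    n_subj = groups.nunique()
    if n_subj < 2:
        raise ValidationError("need at least 2 subjects")
    y = data[y_col].to_numpy(dtype=float)
    X = sm.add_constant(data[week_col].to_numpy(dtype=float))

    if df_method == "inner":
        dof = n_obs - n_subj - 1
    elif df_method == "residual":
        dof = n_obs - 2
    else:
        raise ValidationError(f"unknown df_method {df_method!r}")

    max_group = groups.value_counts().max()
    ols = sm.OLS(y, X).fit()
    degenerate = max_group == 1 or float(np.var(ols.resid)) < 1e-12
    if degenerate:
        if max_group == 1:
            warnings.warn(
                "one observation per subject: random-intercept variance pinned to 0"
            )
        params = ols.params
        bse = ols.bse
        re_var = 0.0
        resid_var = float(ols.scale) if float(np.var(ols.resid)) >= 1e-12 else 0.0
        if resid_var == 0.0:
            bse = np.zeros_like(bse)
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = MixedLM(y, X, groups=groups.to_numpy())
            fit = None
            # near-degenerate variance structures can break an optimizer;
            # walk a fallback chain before giving up
            for opt in ("lbfgs", "powell", "nm"):
                try:
                    fit = model.fit(reml=True, method=opt)
                    break
                except (np.linalg.LinAlgError, ValueError):
                    continue
            if fit is None:
                raise ValidationError("mixed-model fit failed to converge")
        params = fit.fe_params
        bse = fit.bse_fe
        re_var = float(np.asarray(fit.cov_re).ravel()[0])
        resid_var = float(fit.scale)

    def tp(i: int) -> tuple[float, float]:
        if bse[i] == 0:
            return float("inf") if params[i] != 0 else 0.0, 0.0 if params[i] != 0 else 1.0
        t = params[i] / bse[i]
        return float(t), float(2 * stats.t.sf(abs(t), dof))

    it, ip = tp(0)
    st, sp = tp(1)
    return LMMResult(
        intercept=float(params[0]),
        intercept_se=float(bse[0]),
        slope=float(params[1]),
        slope_se=float(bse[1]),
        intercept_t=it,
        slope_t=st,
        df=dof,
        intercept_p=ip,
        slope_p=sp,
        random_intercept_var=re_var,
        residual_var=resid_var,
    )


# ---------------------------------------------------------------------------
# feasibility


def feasibility_metrics(
    screening_log: pd.DataFrame,
    *,
    months: float | None = None,
) -> FeasibilityMetrics:
    """Recruitment/retention arithmetic from a screening log.

    One row per screened candidate, with boolean columns ``eligible``,
    ``enrolled``, ``randomized``, and ``completed_week4``/``completed_week8``
    for visit completion.  Retention denominators use the ``analyzable``
    column (randomized patients who started their assigned care) when
    present, otherwise all randomized patients.
    """
    n_screened = len(screening_log)
    if n_screened == 0:
        raise ValidationError("empty screening log")
    n_eligible = int(screening_log["eligible"].sum())
    n_enrolled = int(screening_log["enrolled"].sum())
    n_randomized = int(screening_log["randomized"].sum())
    denom_col = "analyzable" if "analyzable" in screening_log.columns else "randomized"
    analyzable = screening_log[screening_log[denom_col]]
    retention = {}
    n_completed = n_randomized
    for col in screening_log.columns:
        if col.startswith("completed_"):
            visit = col.removeprefix("completed_")
            n_done = int(analyzable[col].sum())
            retention[visit] = (
                round(100.0 * n_done / len(analyzable), 1) if len(analyzable) else 0.0
            )
            n_completed = n_done
    return FeasibilityMetrics(
        n_screened=n_screened,
        n_eligible=n_eligible,
        n_enrolled=n_enrolled,
        n_randomized=n_randomized,
        n_completed=n_completed,
        recruitment_fraction_pct=round(100.0 * n_enrolled / n_screened, 1),
        retention_pct=retention,
        recruitment_rate_per_month=(
            n_enrolled / months if months else None
        ),
    )


# ---------------------------------------------------------------------------
# report tables


def build_results_tables(
    scored: pd.DataFrame | list[pd.DataFrame],
    *,
    arms: tuple[str, str] = ("intervention", "control"),
    value_col: str = "score",
) -> pd.DataFrame:
    """Tables-shaped report: one row per (scale, post-baseline visit).

    ``scored`` is a long table (patient_id, arm, scale_id, visit, score) —
    or a list of m completed copies from multiple imputation, in which case
    the effect sizes are pooled across copies by Rubin's rules.  Analysis is
    intent-to-treat: every patient appears under their assigned arm.
    """
    tables = scored if isinstance(scored, list) else [scored]
    base = tables[0]
    scales = sorted(base["scale_id"].unique())
    visits = [v for v in ("week4", "week8") if v in set(base["visit"])]
    rows = []
    for scale in scales:
        for visit in visits:
            per_copy: list[EffectSizeResult] = []
            summ: dict[str, GroupSummary] = {}
            for tab in tables:
                sub = tab[tab["scale_id"] == scale]
                b = sub[sub["visit"] == "baseline"]
                f = sub[sub["visit"] == visit]
                if f.empty or b.empty:
                    continue
                groups = {}
                for arm in arms:
                    deltas = change_scores(
                        b[b["arm"] == arm], f[f["arm"] == arm], value_col
                    )["delta"].dropna()
                    if len(deltas) < 2:
                        break
                    groups[arm] = summarize_group(deltas)
                if len(groups) == 2:
                    per_copy.append(cohen_d_from_summary(groups[arms[0]], groups[arms[1]]))
                    summ = groups
            if not per_copy:
                warnings.warn(f"{scale}/{visit}: no analyzable data; row omitted")
                continue
            if len(per_copy) > 1:
                d, se = rubin_pool(
                    [r.d for r in per_copy], [r.se_d**2 for r in per_copy]
                )
                q = stats.t.ppf(0.975, per_copy[0].df)
                ci_low, ci_high = d - q * se, d + q * se
                p = float(np.mean([r.p_value for r in per_copy]))
            else:
                r = per_copy[0]
                d, ci_low, ci_high, p = r.d, r.ci_low, r.ci_high, r.p_value
            rows.append(
                {
                    "scale_id": scale,
                    "visit": visit,
                    f"n_{arms[0]}": summ[arms[0]].n,
                    f"mean_change_{arms[0]}": summ[arms[0]].mean_change,
                    f"sd_change_{arms[0]}": summ[arms[0]].sd_change,
                    f"n_{arms[1]}": summ[arms[1]].n,
                    f"mean_change_{arms[1]}": summ[arms[1]].mean_change,
                    f"sd_change_{arms[1]}": summ[arms[1]].sd_change,
                    "cohen_d": round(d, 2),
                    "ci_low": round(ci_low, 2),
                    "ci_high": round(ci_high, 2),
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
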