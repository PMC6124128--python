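"""Model comparison and the staged hypothesis-winnowing pipeline.

Rather than testing each predictor against a straw-man null, the pipeline
culls hypotheses by strategic model comparison.  A candidate driver (e.g. a
parasite-load index) must explain variation in a cultural trait beyond

1. relatedness and proximity (stage 1: corrected univariate fits),
2. covariation with other cultural traits (stage 2: likelihood-ratio tests
   against models of the significantly correlated traits), and
3. external covariates such as biodiversity, climate or population (stage 3:
   LRT and AIC races against covariate-only models).

A variable dropped at any stage never re-enters a later one.  Nested models
are compared with likelihood-ratio tests (chi-squared, df = number of added
coefficients); non-nested models with AIC, a difference above 2 counting as
meaningful support.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gls_core import (
    FitOptions,
    GLSFit,
    ModelSpec,
    autocorrelation_contribution,
    fit_gls,
    fit_ols,
)

__all__ = [
    "ComparisonResult",
    "AICRanking",
    "CorrelationScreen",
    "StageResult",
    "WinnowConfig",
    "WinnowReport",
    "lr_test",
    "aic_rank",
    "kendall_screen",
    "stage1_univariate",
    "stage2_covariation",
    "stage3_external",
    "run_winnow",
]

BONFERRONI_ALPHA = 0.003  # 0.05 / 16 tests, to the precision used in reporting
_LR_SLACK = 1e-6


@dataclass(frozen=True)
class ComparisonResult:
    """A likelihood-ratio comparison of two nested fits."""

    nested_label: str
    full_label: str
    lr: float
    df: int
    p: float
    delta_aic: float | None = None
    significant_05: bool = False
    significant_bonferroni: bool = False


def lr_test(
    loglik_nested: float,
    loglik_full: float,
    df: int,
    nested_label: str = "nested",
    full_label: str = "full",
    bonferroni_alpha: float = BONFERRONI_ALPHA,
) -> ComparisonResult:
    """Likelihood-ratio test: ``LR = 2 (logLik_full - logLik_nested)``.

    Small negative LR values (within optimizer slack) are clamped to zero;
    larger negatives indicate the models are not actually nested and raise.
    """
    if df <= 0:
        raise ValueError(f"df must be >= 1, got {df}")
    lr = 2.0 * (loglik_full - loglik_nested)
    if lr < 0:
        if lr < -_LR_SLACK:
            raise ValueError(
                f"LR = {lr:.6g} < 0: full model fits worse than nested model; "
                "models are not nested or the optimizer failed"
            )
        lr = 0.0
    p = float(stats.chi2.sf(lr, df))
    return ComparisonResult(
        nested_label=nested_label,
        full_label=full_label,
        lr=float(lr),
        df=df,
        p=p,
        significant_05=p < 0.05,
        significant_bonferroni=p < bonferroni_alpha,
    )


@dataclass
class AICRanking:
    """AIC ranking of non-nested fits on a common case set."""

    table: pd.DataFrame  # model, loglik, n_params, aic, delta_aic (vs best)
    pairwise: pd.DataFrame  # delta_aic[i, j] = AIC_i - AIC_j
    threshold: float

    def better(self, a: str, b: str) -> bool:
        """True when model ``a`` beats model ``b`` by more than the threshold."""
        return self.pairwise.loc[b, a] > self.threshold


def aic_rank(fits: Sequence[GLSFit], threshold: float = 2.0) -> AICRanking:
    """Rank fits of the same response on the same cases by AIC.

    ``AIC = 2 * n_free_params - 2 * logLik``; a model whose AIC is lower by
    more than ``threshold`` (default 2) is flagged a significantly better
    fit, and ties within the threshold are read as equivalent explanatory
    power.
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to rank")
    responses = {f.spec.response for f in fits}
    if len(responses) > 1:
        raise ValueError(f"fits have different responses: {sorted(responses)}")
    case_sets = {f.societies for f in fits}
    if len(case_sets) > 1:
        raise ValueError("fits use different complete-case sets; AIC not comparable")
    labels = [f.spec.label for f in fits]
    aics = np.array([f.aic for f in fits])
    table = pd.DataFrame(
        {
            "model": labels,
            "loglik": [f.loglik for f in fits],
            "n_params": [f.n_free_params for f in fits],
            "aic": aics,
            "delta_aic": aics - aics.min(),
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    pairwise = pd.DataFrame(
        aics[:, None] - aics[None, :], index=labels, columns=labels
    )
    return AICRanking(table=table, pairwise=pairwise, threshold=threshold)


@dataclass
class CorrelationScreen:
    """Pairwise Kendall tau-b between variables, with z statistics and p."""

    tau: pd.DataFrame
    statistic: pd.DataFrame
    p: pd.DataFrame

    def significant_partners(self, var: str, alpha: float = 0.05) -> list[str]:
        row = self.p.loc[var].drop(var)
        return [v for v in row.index if np.isfinite(row[v]) and row[v] < alpha]


def kendall_screen(
    traits: pd.DataFrame, variables: Sequence[str], min_pairs: int = 8
) -> CorrelationScreen:
    """Tie-corrected Kendall rank correlation over pairwise-complete rows.

    Reports tau-b, the normal-approximation z statistic and the two-sided p
    for every pair.  Pairs with fewer than ``min_pairs`` complete rows or a
    constant variable are reported as missing (with a warning).
    """
    variables = list(variables)
    n = len(variables)
    tau = pd.DataFrame(np.full((n, n), np.nan), index=variables, columns=variables)
    z = tau.copy()
    p = tau.copy()
    for a, b in itertools.combinations(variables, 2):
        sub = traits[[a, b]].dropna()
        if len(sub) < min_pairs:
            warnings.warn(
                f"{a}/{b}: only {len(sub)} complete pairs (< {min_pairs}); skipped",
                stacklevel=2,
            )
            continue
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"{a}/{b}: constant variable, tau undefined", stacklevel=2)
            continue
        res = stats.kendalltau(x, y)
        tau.loc[a, b] = tau.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
        zval = np.sign(res.statistic) * stats.norm.isf(
            np.clip(res.pvalue / 2.0, 1e-300, 1.0)
        )
        z.loc[a, b] = z.loc[b, a] = zval
    return CorrelationScreen(tau=tau, statistic=z, p=p)


@dataclass
class StageResult:
    """Output of one winnowing stage: table, decisions, per-cell errors."""

    table: pd.DataFrame
    retained: list[str]
    dropped: list[str]
    sig_pairs: dict[str, list[str]] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    verdicts: dict[str, str] = field(default_factory=dict)


def _gls_options(mode: str, restarts: int, seed: int) -> FitOptions:
    return FitOptions(mode=mode, restarts=restarts, seed=seed)


def stage1_univariate(
    traits: pd.DataFrame,
    P: pd.DataFrame,
    D: pd.DataFrame,
    cultural_vars: Sequence[str],
    parasite_vars: Sequence[str],
    alpha: float = 0.05,
    bonferroni_m: int = 16,
    options: FitOptions = FitOptions(),
) -> StageResult:
    """Stage 1: does each trait correlate with a driver beyond relatedness
    and proximity?

    For every trait x driver pair an uncorrected (OLS) and a corrected (GLS)
    univariate fit is made, with the autocorrelation-contribution statistic
    ``1 - logLik_corrected / logLik_uncorrected``.  Traits with no corrected
    association significant at ``alpha`` against any driver are dropped.
    """
    bonf = alpha / bonferroni_m
    rows = []
    errors: list[str] = []
    sig_pairs: dict[str, list[str]] = {v: [] for v in cultural_vars}
    for trait in cultural_vars:
        for par in parasite_vars:
            spec = ModelSpec(response=trait, predictors=(par,))
            row: dict = {"y": trait, "x": par}
            try:
                unc = fit_ols(spec, traits)
                cor = fit_gls(spec, traits, P, D, options)
                c_unc, c_cor = unc.coef(par), cor.coef(par)
                contrib = autocorrelation_contribution(cor.loglik, unc.loglik)
                row.update(
                    n=cor.n,
                    df=cor.df_resid,
                    beta_unc=c_unc["beta"], se_unc=c_unc["se"],
                    t_unc=c_unc["t"], p_unc=c_unc["p"], loglik_unc=unc.loglik,
                    beta_cor=c_cor["beta"], se_cor=c_cor["se"],
                    t_cor=c_cor["t"], p_cor=c_cor["p"], loglik_cor=cor.loglik,
                    contribution=contrib,
                    significant_05=bool(c_cor["p"] < alpha),
                    significant_bonferroni=bool(c_cor["p"] < bonf),
                )
                if c_cor["p"] < alpha:
                    sig_pairs[trait].append(par)
            except Exception as exc:  # per-cell, not fatal
                row["error"] = f"{type(exc).__name__}: {exc}"
                errors.append(f"{trait} ~ {par}: {exc}")
            rows.append(row)
    table = pd.DataFrame(rows)
    retained = [v for v in cultural_vars if sig_pairs[v]]
    dropped = [v for v in cultural_vars if not sig_pairs[v]]
    return StageResult(
        table=table,
        retained=retained,
        dropped=dropped,
        sig_pairs={k: v for k, v in sig_pairs.items() if v},
        errors=errors,
    )


def _restricted(traits: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    """Rows complete for all of ``variables`` (for comparable fits)."""
    return traits.loc[traits[list(variables)].notna().all(axis=1)]


def stage2_covariation(
    traits: pd.DataFrame,
    P: pd.DataFrame,
    D: pd.DataFrame,
    retained_vars: Sequence[str],
    parasite_vars: Sequence[str],
    screen: CorrelationScreen,
    alpha: float = 0.05,
    sig_pairs: Mapping[str, Sequence[str]] | None = None,
    options: FitOptions = FitOptions(),
) -> StageResult:
    """Stage 2: does the driver explain a trait beyond trait covariation?

    For each retained trait, Model 1 is a corrected fit on the trait's
    significantly correlated cultural covariates (from the Kendall screen,
    restricted to the retained set); Model 2 adds the driver.  Only driver x
    trait combinations already significant at stage 1 are tested.  A trait
    with no significant covariates passes through untested.
    """
    sig_pairs = dict(sig_pairs or {v: list(parasite_vars) for v in retained_vars})
    rows = []
    errors: list[str] = []
    keep: dict[str, bool] = {}
    for trait in retained_vars:
        partners = [
            v
            for v in screen.significant_partners(trait, alpha)
            if v in retained_vars and v != trait
        ]
        if not partners:
            keep[trait] = True  # vacuous: no covariation to explain it away
            rows.append(
                {"y": trait, "covariates": "", "x": "", "note": "no covariates"}
            )
            continue
        keep[trait] = False
        for par in sig_pairs.get(trait, []):
            sub = _restricted(traits, [trait, *partners, par])
            m1_spec = ModelSpec(response=trait, predictors=tuple(partners))
            m2_spec = ModelSpec(response=trait, predictors=(par, *partners))
            row: dict = {"y": trait, "covariates": "+".join(partners), "x": par}
            try:
                m1 = fit_gls(m1_spec, sub, P, D, options)
                m2 = fit_gls(m2_spec, sub, P, D, options)
                cmp_ = lr_test(m1.loglik, m2.loglik, 1, m1_spec.label, m2_spec.label)
                row.update(
                    n=m1.n,
                    loglik_m1=m1.loglik,
                    loglik_m2=m2.loglik,
                    lr=cmp_.lr,
                    p=cmp_.p,
                    significant_05=cmp_.significant_05,
                )
                if cmp_.p < alpha:
                    keep[trait] = True
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
                errors.append(f"{trait} | {par}: {exc}")
            rows.append(row)
    retained = [v for v in retained_vars if keep.get(v, False)]
    dropped = [v for v in retained_vars if not keep.get(v, False)]
    return StageResult(
        table=pd.DataFrame(rows),
        retained=retained,
        dropped=dropped,
        sig_pairs={v: list(sig_pairs.get(v, [])) for v in retained},
        errors=errors,
    )


def stage3_external(
    traits: pd.DataFrame,
    P: pd.DataFrame,
    D: pd.DataFrame,
    retained_vars: Sequence[str],
    parasite_vars: Sequence[str],
    covariate_sets: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    aic_threshold: float = 2.0,
    sig_pairs: Mapping[str, Sequence[str]] | None = None,
    options: FitOptions = FitOptions(),
) -> StageResult:
    """Stage 3: do external covariates explain the trait as well as the driver?

    Two races per trait and covariate set: (a) an LRT asking whether the
    driver still improves a corrected model that already contains the
    covariates, and (b) an AIC comparison of the covariate-link model against
    the driver-link model on the same cases.  The driver is retained for a
    trait only if it survives every race; otherwise the verdict names the
    explaining covariate set.  With no covariate sets the stage reduces to
    the stage-1 outcome.
    """
    sig_pairs = dict(sig_pairs or {v: list(parasite_vars) for v in retained_vars})
    rows = []
    errors: list[str] = []
    verdicts: dict[str, str] = {}
    for trait in retained_vars:
        survives: dict[str, bool] = {}
        explained_by: list[str] = []
        for par in sig_pairs.get(trait, []):
            survives[par] = True
            for set_name, covs in covariate_sets.items():
                covs = [c for c in covs if c != trait and c != par]
                if not covs:
                    continue
                row: dict = {
                    "y": trait,
                    "x": par,
                    "covariate_set": set_name,
                    "covariates": "+".join(covs),
                }
                try:
                    sub = _restricted(traits, [trait, par, *covs])
                    m1 = fit_gls(
                        ModelSpec(trait, tuple(covs)), sub, P, D, options
                    )
                    m2 = fit_gls(
                        ModelSpec(trait, (par, *covs)), sub, P, D, options
                    )
                    cmp_ = lr_test(
                        m1.loglik, m2.loglik, 1, m1.spec.label, m2.spec.label
                    )
                    cov_only = fit_gls(ModelSpec(trait, tuple(covs)), sub, P, D, options)
                    par_only = fit_gls(ModelSpec(trait, (par,)), sub, P, D, options)
                    rank = aic_rank([cov_only, par_only], aic_threshold)
                    d_aic = float(
                        rank.pairwise.loc[par_only.spec.label, cov_only.spec.label]
                    )
                    cov_beats = rank.better(cov_only.spec.label, par_only.spec.label)
                    row.update(
                        n=m1.n,
                        loglik_m1=m1.loglik,
                        loglik_m2=m2.loglik,
                        lr=cmp_.lr,
                        p=cmp_.p,
                        significant_05=cmp_.significant_05,
                        delta_aic=d_aic,
                        aic_equivalent=bool(abs(d_aic) <= aic_threshold),
                    )
                    if cmp_.p >= alpha or cov_beats:
                        survives[par] = False
                        explained_by.append(set_name)
                except Exception as exc:
                    row["error"] = f"{type(exc).__name__}: {exc}"
                    errors.append(f"{trait} | {par} | {set_name}: {exc}")
                rows.append(row)
        if any(survives.values()):
            verdicts[trait] = "parasite retained"
        elif explained_by:
            verdicts[trait] = "explained by " + "+".join(
                sorted(set(explained_by))
            )
        else:
            verdicts[trait] = "parasite retained"  # no races ran
    retained = [v for v in retained_vars if verdicts.get(v) == "parasite retained"]
    dropped = [v for v in retained_vars if v not in retained]
    return StageResult(
        table=pd.DataFrame(rows),
        retained=retained,
        dropped=dropped,
        verdicts=verdicts,
        errors=errors,
    )


@dataclass
class WinnowConfig:
    """Everything :func:`run_winnow` needs: data, variable roles, thresholds."""

    traits: pd.DataFrame
    P: pd.DataFrame
    D: pd.DataFrame
    cultural_vars: tuple[str, ...]
    parasite_vars: tuple[str, ...]
    covariate_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    alpha: float = 0.05
    bonferroni_m: int = 16
    aic_threshold: float = 2.0
    mode: str = "nugget"
    restarts: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        known = set(self.traits.columns)
        for v in (*self.cultural_vars, *self.parasite_vars):
            if v not in known:
                raise KeyError(f"variable {v!r} not in trait table")


@dataclass
class WinnowReport:
    """Result of the full pipeline: stage tables, status trail, verdicts."""

    stage1: StageResult
    screen: CorrelationScreen | None
    stage2: StageResult
    stage3: StageResult
    trail: list[dict]
    final_retained: list[str]
    verdicts: dict[str, str]


def run_winnow(config: WinnowConfig) -> WinnowReport:
    """Run stages 1 -> 2 -> 3 with the drop-forward rule.

    A variable dropped at stage *k* is never fitted at stage *k+1*; the
    status trail records, for every input trait, where it was dropped (or
    that it survived) and by which test.  Deterministic for a given config.
    """
    opts = _gls_options(config.mode, config.restarts, config.seed)
    trail: list[dict] = []

    s1 = stage1_univariate(
        config.traits,
        config.P,
        config.D,
        config.cultural_vars,
        config.parasite_vars,
        config.alpha,
        config.bonferroni_m,
        opts,
    )
    for v in s1.dropped:
        trail.append(
            {
                "variable": v,
                "status": "dropped",
                "stage": 1,
                "test": "no corrected association with any driver",
            }
        )

    screen = None
    if s1.retained:
        screen = kendall_screen(config.traits, list(config.cultural_vars))
        s2 = stage2_covariation(
            config.traits,
            config.P,
            config.D,
            s1.retained,
            config.parasite_vars,
            screen,
            config.alpha,
            s1.sig_pairs,
            opts,
        )
    else:
        s2 = StageResult(table=pd.DataFrame(), retained=[], dropped=[])
    for v in s2.dropped:
        trail.append(
            {
                "variable": v,
                "status": "dropped",
                "stage": 2,
                "test": "association explained by covariation with other traits",
            }
        )

    if s2.retained:
        s3 = stage3_external(
            config.traits,
            config.P,
            config.D,
            s2.retained,
            config.parasite_vars,
            config.covariate_sets,
            config.alpha,
            config.aic_threshold,
            s2.sig_pairs,
            opts,
        )
    else:
        s3 = StageResult(table=pd.DataFrame(), retained=[], dropped=[])
    for v in s3.dropped:
        trail.append(
            {
                "variable": v,
                "status": "dropped",
                "stage": 3,
                "test": s3.verdicts.get(v, "explained by external covariates"),
            }
        )
    for v in s3.retained:
        trail.append(
            {
                "variable": v,
                "status": "retained",
                "stage": 3,
                "test": "driver explains variation beyond all covariate sets",
            }
        )

    trail.sort(key=lambda r: (r["stage"], r["variable"]))
    return WinnowReport(
        stage1=s1,
        screen=screen,
        stage2=s2,
        stage3=s3,
        trail=trail,
        final_retained=list(s3.retained),
        verdicts=dict(s3.verdicts),
    )
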