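"""One-sample Mendelian randomization by two-stage predictor substitution.

Stage 1 regresses medication-corrected BP on the genetic risk score plus
covariates (OLS); stage 2 regresses the three-level frailty category on the
stage-1 fitted BP plus the same covariates (maximum-likelihood multinomial
logit, non-frail as reference). The fitted-BP coefficient per contrast is a
log relative-risk ratio per mmHg, rescaled to the conventional units of a
10-mmHg decrement in systolic or 5-mmHg decrement in diastolic BP.

Wald standard errors from stage 2 are used as-is (no correction for
first-stage estimation uncertainty), the common predictor-substitution
practice; with a strong instrument this is a second-order effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .frailty import CATEGORIES
from .grs import FirstStageStats, first_stage_stats

__all__ = [
    "DEFAULT_COVARIATES",
    "AdjustedBp",
    "MrEstimate",
    "SecondStageFit",
    "adjust_bp",
    "build_design",
    "fit_first_stage",
    "fit_second_stage",
    "scale_to_rrr",
    "significance_flags",
    "run_two_stage_mr",
]

log = logging.getLogger(__name__)

SBP_MED_CORRECTION = 15.0  # mmHg added for medicated individuals
DBP_MED_CORRECTION = 10.0

# covariate name -> treat as categorical (one-hot, first level reference)?
DEFAULT_COVARIATES: dict[str, bool] = {
    "age": False,
    "sex": True,
    "center": True,
    "smoking": True,
    "alcohol": True,
    "bmi": False,
    "deprivation": True,
    "array": True,
    **{f"pc{i}": False for i in range(1, 11)},
}


@dataclass
class AdjustedBp:
    """Medication-corrected BP (mean of available readings, then +15/+10)."""

    values: pd.Series
    exposure: str  # "SBP" | "DBP"
    n_excluded: int = 0  # persons with zero readings


@dataclass
class MrEstimate:
    exposure: str
    drug_class: str
    contrast: str  # "pre_frail_vs_non" | "frail_vs_non"
    rrr: float
    ci_low: float
    ci_high: float
    p: float
    unit: float  # mmHg decrement the RRR refers to
    coef_per_mmhg: float
    se_per_mmhg: float
    flag: str = ""
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.rrr <= self.ci_high):
            raise ValueError("confidence bounds must bracket the point estimate")


@dataclass
class SecondStageFit:
    """Fitted-BP coefficients (log-RRR per mmHg) and SEs per contrast."""

    coef: dict[str, float]
    se: dict[str, float]
    converged: bool
    n: int
    llf: float
    diagnostics: dict = field(default_factory=dict)


def adjust_bp(readings: pd.DataFrame | np.ndarray, on_med, exposure: str = "SBP") -> AdjustedBp:
    """Average the available cuff readings, then add back the medication shift.

    ``readings``: one column per reading (second column NaN for
    single-measurement individuals). Persons with no readings at all get NaN
    and are counted in ``n_excluded``.
    """
    r = pd.DataFrame(readings)
    mean_bp = r.mean(axis=1, skipna=True)
    n_excluded = int(mean_bp.isna().sum())
    if n_excluded:
        log.warning("%d persons with no BP readings excluded", n_excluded)
    correction = SBP_MED_CORRECTION if exposure.upper() == "SBP" else DBP_MED_CORRECTION
    med = pd.Series(np.asarray(on_med, dtype=float), index=mean_bp.index)
    return AdjustedBp(values=mean_bp + correction * med, exposure=exposure.upper(), n_excluded=n_excluded)


def build_design(
    covariates: pd.DataFrame, spec: dict[str, bool] | None = None
) -> pd.DataFrame:
    """Covariate design matrix: continuous columns as-is, categorical columns
    one-hot encoded with the first (sorted) level as reference."""
    spec = DEFAULT_COVARIATES if spec is None else spec
    missing = [c for c in spec if c not in covariates.columns]
    if missing:
        raise KeyError(f"covariate columns absent from table: {missing}")
    parts: list[pd.DataFrame] = []
    for name, categorical in spec.items():
        col = covariates[name]
        if categorical:
            dummies = pd.get_dummies(col.astype("category"), prefix=name, drop_first=True)
            parts.append(dummies.astype(float))
        else:
            parts.append(col.astype(float).to_frame(name))
    return pd.concat(parts, axis=1)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by QR pivoting
        _, r = np.linalg.qr(X)
        dep = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")


def fit_first_stage(
    bp_adj: pd.Series | np.ndarray,
    grs: np.ndarray,
    covariates: pd.DataFrame | None = None,
    covariate_spec: dict[str, bool] | None = None,
):
    """OLS of adjusted BP on the risk score plus covariates.

    Rows with any missing value are dropped (count logged). Returns
    (fitted_bp: pd.Series aligned to the retained rows, stats:
    FirstStageStats from the simple BP~GRS regression, results: the
    statsmodels OLS results object).
    """
    y = pd.Series(np.asarray(bp_adj, dtype=float))
    parts = {"grs": np.asarray(grs, dtype=float)}
    if covariates is not None:
        design = build_design(covariates.reset_index(drop=True), covariate_spec)
        X = pd.concat([pd.DataFrame(parts), design], axis=1)
    else:
        X = pd.DataFrame(parts)
    X.insert(0, "const", 1.0)
    y = y.reset_index(drop=True)
    keep = ~(y.isna() | X.isna().any(axis=1))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning("first stage: dropped %d incomplete rows", n_dropped)
    Xk, yk = X[keep], y[keep]
    _check_full_rank(Xk.to_numpy(), list(Xk.columns))
    res = sm.OLS(yk.to_numpy(), Xk.to_numpy()).fit()
    fitted = pd.Series(res.fittedvalues, index=yk.index, name="fitted_bp")
    simple = first_stage_stats(yk.to_numpy(), Xk["grs"].to_numpy())
    return fitted, simple, res


def fit_second_stage(
    fitted_bp: pd.Series | np.ndarray,
    frailty_category,
    covariates: pd.DataFrame | None = None,
    covariate_spec: dict[str, bool] | None = None,
    maxiter: int = 100,
) -> SecondStageFit:
    """Multinomial logit of frailty category on stage-1 fitted BP.

    Non-frail is the reference outcome; coefficients are log-RRRs per mmHg
    of genetically predicted BP. Newton-Raphson maximum likelihood
    (statsmodels MNLogit, tolerance 1e-10, up to ``maxiter`` iterations);
    non-convergence or separation is flagged on the returned fit rather
    than raised.
    """
    cat = pd.Series(frailty_category).reset_index(drop=True)
    if isinstance(cat.dtype, pd.CategoricalDtype):
        codes = cat.cat.set_categories(CATEGORIES).cat.codes
    else:
        codes = cat.map({c: i for i, c in enumerate(CATEGORIES)}).fillna(-1).astype(int)
    present = sorted(set(codes[codes >= 0]))
    if present != [0, 1, 2]:
        raise ValueError(
            f"need all three frailty categories with non_frail as reference; present codes: {present}"
        )

    fb = pd.Series(np.asarray(fitted_bp, dtype=float), name="fitted_bp").reset_index(drop=True)
    if covariates is not None:
        design = build_design(covariates.reset_index(drop=True), covariate_spec)
        X = pd.concat([fb, design], axis=1)
    else:
        X = fb.to_frame()
    X.insert(0, "const", 1.0)
    keep = (codes >= 0) & ~(fb.isna() | X.isna().any(axis=1))
    Xk = X[keep]
    yk = codes[keep].to_numpy()
    _check_full_rank(Xk.to_numpy(), list(Xk.columns))

    model = sm.MNLogit(yk, Xk.to_numpy())
    with np.errstate(over="ignore"):
        res = model.fit(method="newton", maxiter=maxiter, tol=1e-10, disp=0, warn_convergence=False)
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        log.warning("second stage did not converge (possible separation)")

    j = list(Xk.columns).index("fitted_bp")
    params = np.asarray(res.params)  # (k_exog, 2): columns = pre_frail, frail vs non_frail
    bse = np.asarray(res.bse)
    coef = {"pre_frail_vs_non": float(params[j, 0]), "frail_vs_non": float(params[j, 1])}
    se = {"pre_frail_vs_non": float(bse[j, 0]), "frail_vs_non": float(bse[j, 1])}
    return SecondStageFit(
        coef=coef,
        se=se,
        converged=converged,
        n=int(keep.sum()),
        llf=float(res.llf),
        diagnostics={"iterations": res.mle_retvals.get("iterations")},
    )


def scale_to_rrr(
    coef_per_mmhg: float,
    se: float,
    unit: float,
    exposure: str = "SBP",
    drug_class: str = "",
    contrast: str = "",
    direction: str = "decrease",
    converged: bool = True,
) -> MrEstimate:
    """Convert a per-mmHg log-RRR to an RRR per ``unit`` mmHg decrement.

    decrease: RRR = exp(-unit * coef); increase: RRR = exp(+unit * coef).
    95% CI on the same scale with bounds ordered; two-sided Wald p from
    z = coef / se.
    """
    if unit <= 0:
        raise ValueError("unit must be positive")
    if se <= 0:
        raise ValueError("standard error must be positive")
    sign = -1.0 if direction == "decrease" else 1.0
    point = sign * unit * coef_per_mmhg
    half = 1.96 * unit * se
    lo, hi = np.exp(point - half), np.exp(point + half)
    z = coef_per_mmhg / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    est = MrEstimate(
        exposure=exposure,
        drug_class=drug_class,
        contrast=contrast,
        rrr=float(np.exp(point)),
        ci_low=float(min(lo, hi)),
        ci_high=float(max(lo, hi)),
        p=p,
        unit=unit,
        coef_per_mmhg=float(coef_per_mmhg),
        se_per_mmhg=float(se),
        converged=converged,
    )
    est.flag = significance_flags(p)
    return est


def significance_flags(p_values):
    """Multiple-testing flags for two BP exposures: p < 0.025 significant
    (0.05 Bonferroni-corrected for 2 tests), 0.025 <= p < 0.05 suggestive,
    otherwise null."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    flags = np.where(arr < 0.025, "significant", np.where(arr < 0.05, "suggestive", "null"))
    if np.isscalar(p_values) or getattr(p_values, "ndim", 1) == 0:
        return str(flags[0])
    return list(flags)


def run_two_stage_mr(
    bp_adj,
    grs: np.ndarray,
    frailty_category,
    covariates: pd.DataFrame | None,
    exposure: str,
    drug_class: str = "",
    unit: float | None = None,
    covariate_spec: dict[str, bool] | None = None,
) -> tuple[list[MrEstimate], FirstStageStats, SecondStageFit]:
    """Convenience wrapper: stage 1, stage 2, RRR scaling for both contrasts.

    ``unit`` defaults to the conventional 10 mmHg for SBP and 5 for DBP.
    """
    if unit is None:
        unit = 10.0 if exposure.upper() == "SBP" else 5.0
    fitted, fs, _ = fit_first_stage(bp_adj, grs, covariates, covariate_spec)
    cat = pd.Series(frailty_category).reset_index(drop=True).loc[fitted.index]
    cov = covariates.reset_index(drop=True).loc[fitted.index] if covariates is not None else None
    ss = fit_second_stage(fitted, cat, cov, covariate_spec)
    estimates = [
        scale_to_rrr(
            ss.coef[contrast],
            ss.se[contrast],
            unit=unit,
            exposure=exposure.upper(),
            drug_class=drug_class,
            contrast=contrast,
            converged=ss.converged,
        )
        for contrast in ("pre_frail_vs_non", "frail_vs_non")
    ]
    return estimates, fs, ss
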