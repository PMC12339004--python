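"""Probit dose-response analysis of acaricide bioassays.

Mortality at each concentration is corrected for control mortality
(Abbott's formula), then fitted by maximum-likelihood binomial
regression with a probit link on log10 concentration.  The LC50 is
10^(-alpha/beta) with a 95% confidence interval from the delta method
(Fieller's theorem available behind a flag).  Populations whose
corrected mortality never reaches the informative range are reported as
censored bounds (e.g. "LC50 > top dose"), never as silent numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

__all__ = [
    "ProbitFit",
    "abbott_correct",
    "fit_probit",
    "fold_change",
    "classify_population",
    "fit_populations",
    "summarize_group_lc50",
]

#: bimodal classification defaults (mg/L): susceptible ceiling is the top of
#: the observed susceptible range, resistant floor the bottom of the
#: resistant range.
SUSCEPTIBLE_MAX = 30.1
RESISTANT_MIN = 1498.6


def abbott_correct(p_treated: float, p_control: float) -> float:
    """Abbott's control-mortality correction.

    Returns max(0, (p_treated - p_control) / (1 - p_control)).
    """
    if not 0.0 <= p_control < 1.0:
        raise ValueError("control mortality must lie in [0, 1)")
    if not 0.0 <= p_treated <= 1.0:
        raise ValueError("treated mortality must lie in [0, 1]")
    return max(0.0, (p_treated - p_control) / (1.0 - p_control))


@dataclass
class ProbitFit:
    """Result of a probit dose-response fit.

    ``status`` is ``"ok"`` for a valid fit, ``"censored_high"`` /
    ``"censored_low"`` when the LC50 is not estimable and only a bound is
    reported (``lc50`` then holds the bound), or ``"failed"`` with a
    diagnostic message.
    """

    status: str
    alpha: float = np.nan
    beta: float = np.nan
    lc50: float = np.nan
    lc50_ci: tuple[float, float] = (np.nan, np.nan)
    deviance: float = np.nan
    n_doses: int = 0
    censored: bool = False
    message: str = ""
    cov: np.ndarray | None = field(default=None, repr=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _delta_ci(alpha: float, beta: float, cov: np.ndarray, level: float = 0.95):
    """Delta-method CI for LC50 on the log10 scale, mapped back to mg/L."""
    log_lc50 = -alpha / beta
    grad = np.array([-1.0 / beta, alpha / beta**2])
    var = float(grad @ cov @ grad)
    if var < 0 or not np.isfinite(var):
        return (np.nan, np.nan)
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    with np.errstate(over="ignore"):
        return (float(10.0 ** np.float64(log_lc50 - half)),
                float(10.0 ** np.float64(log_lc50 + half)))


def _fieller_ci(alpha: float, beta: float, cov: np.ndarray, level: float = 0.95):
    """Fieller's theorem CI for -alpha/beta, mapped back to mg/L."""
    z = norm.ppf(0.5 + level / 2.0)
    v11, v12, v22 = cov[0, 0], cov[0, 1], cov[1, 1]
    # ratio rho = -alpha/beta; solve (alpha + rho*beta)^2 = z^2 var(alpha + rho*beta)
    a = beta**2 - z**2 * v22
    b = 2 * (alpha * beta - z**2 * v12)
    c = alpha**2 - z**2 * v11
    disc = b**2 - 4 * a * c
    if a <= 0 or disc < 0:
        return (np.nan, np.nan)
    lo = (-b - np.sqrt(disc)) / (2 * a)
    hi = (-b + np.sqrt(disc)) / (2 * a)
    return (10 ** min(lo, hi), 10 ** max(lo, hi))


def fit_probit(
    records: pd.DataFrame,
    *,
    ci: str = "delta",
    link: str = "probit",
) -> ProbitFit:
    """Fit a probit (or logit) dose-mortality curve and report the LC50.

    ``records`` needs columns ``conc_mg_L``, ``n``, ``dead``; rows with
    concentration 0 are controls and are pooled into the Abbott
    correction.  Doses with 0% or 100% corrected mortality stay in the
    likelihood.  Requires >= 3 distinct positive concentrations with
    non-degenerate corrected mortality; all-dead tables are censored low,
    all-alive tables censored high (mirroring ">top dose" reporting).
    """
    df = records.copy()
    required = {"conc_mg_L", "n", "dead"}
    if not required.issubset(df.columns):
        raise ValueError(f"records must have columns {sorted(required)}")
    if ((df["dead"] < 0) | (df["dead"] > df["n"])).any():
        raise ValueError("dead counts must lie in [0, n]")
    controls = df[df["conc_mg_L"] == 0]
    p_control = float(controls["dead"].sum() / controls["n"].sum()) if len(controls) else 0.0
    if p_control >= 1.0:
        raise ValueError("control mortality of 1 leaves Abbott correction undefined")
    trt = df[df["conc_mg_L"] > 0].copy()
    n_doses = trt["conc_mg_L"].nunique()
    if n_doses < 3:
        return ProbitFit(status="failed", n_doses=n_doses,
                         message="fewer than 3 distinct concentrations")
    p_corr = np.array([abbott_correct(d / n, p_control)
                       for d, n in zip(trt["dead"], trt["n"])])
    if np.all(p_corr >= 1.0):
        return ProbitFit(status="censored_low", lc50=float(trt["conc_mg_L"].min()),
                         censored=True, n_doses=n_doses,
                         message="all doses fully lethal; LC50 below the lowest dose")
    if np.all(p_corr <= 0.0):
        return ProbitFit(status="censored_high", lc50=float(trt["conc_mg_L"].max()),
                         censored=True, n_doses=n_doses,
                         message="no corrected mortality; LC50 above the highest dose")
    if np.all((p_corr <= 0.0) | (p_corr >= 1.0)):
        return ProbitFit(status="failed", n_doses=n_doses,
                         message="complete separation: no dose with intermediate mortality")

    x = sm.add_constant(np.log10(trt["conc_mg_L"].to_numpy()))
    links = {"probit": sm.families.links.Probit(), "logit": sm.families.links.Logit()}
    family = sm.families.Binomial(link=links[link])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.GLM(p_corr, x, family=family, var_weights=trt["n"].to_numpy())
            res = model.fit(maxiter=200)
        except Exception as exc:  # noqa: BLE001 - fit failure is a reported state
            return ProbitFit(status="failed", n_doses=n_doses,
                             message=f"probit fit failed: {exc}")
    alpha, beta = float(res.params[0]), float(res.params[1])
    cov = np.asarray(res.cov_params())
    se = np.sqrt(np.diag(cov))
    if not res.converged or not np.all(np.isfinite(se)) or abs(beta) > 1e3:
        return ProbitFit(status="failed", n_doses=n_doses,
                         message="complete separation or non-convergent fit")
    if beta <= 0:
        return ProbitFit(status="failed", alpha=alpha, beta=beta, n_doses=n_doses,
                         message="non-positive slope; dose-response not monotone")
    lc50 = 10 ** (-alpha / beta)
    ci_fn = {"delta": _delta_ci, "fieller": _fieller_ci}[ci]
    return ProbitFit(
        status="ok",
        alpha=alpha,
        beta=beta,
        lc50=float(lc50),
        lc50_ci=ci_fn(alpha, beta, cov),
        deviance=float(res.deviance),
        n_doses=n_doses,
        cov=cov,
    )


def fold_change(lc50_num: float, lc50_den: float) -> float:
    """Resistance ratio LC50_num / LC50_den (reporting rounds to integer folds)."""
    if lc50_num <= 0 or lc50_den <= 0:
        raise ValueError("LC50 values must be positive")
    return lc50_num / lc50_den


def classify_population(
    lc50: float,
    *,
    censored_high: bool = False,
    susceptible_max: float = SUSCEPTIBLE_MAX,
    resistant_min: float = RESISTANT_MIN,
) -> str:
    """Bimodal susceptible/resistant call with an explicit unclassified band.

    A censored-high bound counts as resistant when the bound already
    exceeds the resistant floor (e.g. ">32,000 mg/L").
    """
    if censored_high:
        return "resistant" if lc50 >= resistant_min else "unclassified"
    if lc50 <= susceptible_max:
        return "susceptible"
    if lc50 >= resistant_min:
        return "resistant"
    return "unclassified"


def fit_populations(assays: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Fit every (population, compound) table in a long-format assay CSV."""
    rows = []
    for (pop, compound), grp in assays.groupby(["population", "compound"]):
        fit = fit_probit(grp, **kwargs)
        rows.append(dict(
            population=pop, compound=compound, status=fit.status,
            alpha=fit.alpha, beta=fit.beta, lc50=fit.lc50,
            lc50_ci_low=fit.lc50_ci[0], lc50_ci_high=fit.lc50_ci[1],
            censored=fit.censored, n_doses=fit.n_doses,
            classification=(classify_population(fit.lc50, censored_high=fit.status == "censored_high")
                            if np.isfinite(fit.lc50) else "unclassified"),
            message=fit.message,
        ))
    return pd.DataFrame(rows)


def summarize_group_lc50(fits: pd.DataFrame) -> tuple[float, bool]:
    """Group mean LC50 with a ">"-bound flag.

    The mean is taken over point estimates, with censored-high members
    entering at their bound; the returned flag marks the mean as a lower
    bound whenever any member is censored (mirroring "x > 5892.5 mg/L"
    style reporting).
    """
    usable = fits[fits["status"].isin(["ok", "censored_high"])]
    if usable.empty:
        return float("nan"), False
    return float(usable["lc50"].mean()), bool((usable["status"] == "censored_high").any())
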