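"""Regression forms relating visibility to behaviour, and mixed-effects fits.

Three candidate response forms are compared on (visibility, measure) scatter:
linear ``f(x) = a*x + b``, exponential ``f(x) = a*exp(b*x)``, and a threshold
step ``f(x) = a if x == 0 else b``.  Information criteria use a Gaussian
likelihood with the error variance profiled out, counting k = 3 parameters
(a, b, sigma) for every form so the comparison is on equal footing.

Mixed-effects regressions follow the study design: a fixed-effect structure
over visibility condition, atria type, block, and session, with a random
intercept per participant, reported as a Wald coefficient table
(coef, SE, z, p, 95% CI) plus the random-intercept variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
import statsmodels.formula.api as smf


@dataclass
class ModelFit:
    form: str  # "linear" | "exponential" | "threshold"
    a: float
    b: float
    sse: float
    log_likelihood: float
    aic: float
    bic: float
    n: int
    converged: bool = True
    flag: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.a * x + self.b
        if self.form == "exponential":
            return self.a * np.exp(self.b * x)
        return np.where(x == 0.0, self.a, self.b)


_N_PARAMS = 3  # a, b and the error SD


def _gaussian_ic(sse: float, n: int) -> tuple[float, float, float]:
    sigma2 = max(sse / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    aic = 2 * _N_PARAMS - 2 * ll
    bic = _N_PARAMS * np.log(n) - 2 * ll
    return ll, aic, bic


def fit_threshold(x: np.ndarray, y: np.ndarray) -> ModelFit:
    """Closed-form least squares step fit: group means at x==0 and x>0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    zero = x == 0.0
    flag = ""
    if zero.all() or (~zero).all():
        flag = "degenerate: all x on one side of the threshold"
    a = float(y[zero].mean()) if zero.any() else float("nan")
    b = float(y[~zero].mean()) if (~zero).any() else float("nan")
    pred = np.where(zero, a if zero.any() else 0.0, b if (~zero).any() else 0.0)
    sse = float(np.sum((y - pred) ** 2))
    ll, aic, bic = _gaussian_ic(sse, len(y))
    return ModelFit("threshold", a, b, sse, ll, aic, bic, len(y), flag=flag)


def fit_linear(x: np.ndarray, y: np.ndarray) -> ModelFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a, b = np.polyfit(x, y, 1)
    sse = float(np.sum((y - (a * x + b)) ** 2))
    ll, aic, bic = _gaussian_ic(sse, len(y))
    return ModelFit("linear", float(a), float(b), sse, ll, aic, bic, len(y))


def fit_exponential(x: np.ndarray, y: np.ndarray) -> ModelFit:
    """Nonlinear least squares for a*exp(b*x), log-linear initialisation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (y > 0).all():
        b0, loga = np.polyfit(x, np.log(y), 1)
        p0 = (float(np.exp(loga)), float(b0))
    else:
        p0 = (float(np.mean(y)), 0.0)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                lambda xx, a, b: a * np.exp(b * xx), x, y, p0=p0, maxfev=20000)
        a, b = (float(popt[0]), float(popt[1]))
        converged, flag = True, ""
    except (RuntimeError, optimize.OptimizeWarning):
        a, b = p0
        converged, flag = False, "nonlinear fit did not converge"
    pred = a * np.exp(b * x)
    sse = float(np.sum((y - pred) ** 2))
    ll, aic, bic = _gaussian_ic(sse, len(y))
    return ModelFit("exponential", a, b, sse, ll, aic, bic, len(y),
                    converged=converged, flag=flag)


def fit_visibility_response_models(x, y) -> list[ModelFit]:
    """Fit all three forms and return them ranked by AIC.

    Non-converged fits sort last regardless of their nominal AIC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need matching x/y with at least 3 points")
    if (x < 0).any():
        raise ValueError("visibility values must be non-negative")
    fits = [fit_threshold(x, y), fit_linear(x, y), fit_exponential(x, y)]
    return sorted(fits, key=lambda f: (not f.converged, f.aic))


def extrapolation_report(fits: list[ModelFit], x_max: float,
                         physical_max: float = 1.0,
                         x_probe_factor: float = 10.0) -> pd.DataFrame:
    """Where would each fitted curve exceed a physical bound beyond the data?

    Probes each (converged) linear/exponential fit at ``x_probe_factor`` times
    the observed maximum visibility and reports whether the prediction leaves
    the physically admissible range — the sanity check that disfavours the
    smooth forms for bounded measures such as cosine similarity.
    """
    probe = x_max * x_probe_factor
    rows = []
    for f in fits:
        if f.form == "threshold":
            continue
        pred = float(f.predict(np.array([probe]))[0])
        rows.append({"form": f.form, "x_probe": probe, "prediction": pred,
                     "physically_impossible": bool(pred > physical_max),
                     "converged": f.converged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mixed-effects regression
# ---------------------------------------------------------------------------

@dataclass
class LmerResult:
    formula: str
    table: pd.DataFrame  # index: term; columns coef, se, z, p, ci_low, ci_high
    group_var: float
    group_var_se: float
    n_obs: int
    n_groups: int
    converged: bool
    scale: float

    def coef(self, term: str) -> float:
        return float(self.table.loc[term, "coef"])

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]

    def to_markdown_table(self) -> str:
        df = self.table.round(3)
        lines = ["| term | Coef. | Std.Err. | z | p>|z| | [0.025 | 0.975] |",
                 "|---|---|---|---|---|---|---|"]
        for term, r in df.iterrows():
            lines.append(f"| {term} | {r.coef} | {r.se} | {r.z} | {r.p} "
                         f"| {r.ci_low} | {r.ci_high} |")
        lines.append(f"| Group var | {self.group_var:.3f} | {self.group_var_se:.3f} | | | | |")
        return "\n".join(lines)


def fit_lmer(table: pd.DataFrame, response: str, fixed: list[str],
             group: str, reml: bool = True) -> LmerResult:
    """Random-intercept mixed model ``response ~ fixed + (1 | group)``.

    ``fixed`` entries are patsy terms (e.g. ``C(condition)``); p-values come
    from the Wald z statistic and the CI is coef +/- 1.96 SE, matching the
    conventional coefficient-table layout.  A singular (boundary) fit is
    reported with ``converged=False`` rather than raised.
    """
    if table[response].isna().any():
        raise ValueError("missing values in the response")
    if table[group].nunique() < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{response} ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(formula, data=table, groups=table[group])
        try:
            mdf = md.fit(reml=reml)
        except np.linalg.LinAlgError:
            mdf = md.fit(reml=reml, method="powell")
    fe = mdf.fe_params
    se = mdf.bse_fe
    z = fe / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    tab = pd.DataFrame({
        "coef": fe, "se": se, "z": z, "p": p,
        "ci_low": fe - 1.959963984540054 * se,
        "ci_high": fe + 1.959963984540054 * se,
    })
    group_var = float(mdf.cov_re.iloc[0, 0])
    # SE of the variance component, on the reported (unscaled-by-sigma2) scale
    try:
        group_var_se = float(mdf.bse.iloc[len(fe)] * mdf.scale)
    except Exception:
        group_var_se = float("nan")
    return LmerResult(
        formula=f"{formula} + (1 | {group})",
        table=tab, group_var=group_var, group_var_se=group_var_se,
        n_obs=int(mdf.nobs), n_groups=int(md.n_groups),
        converged=bool(mdf.converged), scale=float(mdf.scale),
    )


#: measure column -> response name used in study-style model formulas
STUDY_RESPONSES = {
    "time_to_escalator": "TimeToEscalator",
    "avg_vertical_head_movement": "VerticalHeadMovement",
    "avg_cosine_similarity": "AvgCosineSimilarity",
}


def fit_study_model(segmented: pd.DataFrame, response: str,
                    reml: bool = True) -> LmerResult:
    """The study's per-measure model on a segmented measures table.

    Encoding: visibility condition NV is the reference (the reported
    coefficient is the V-minus-NV effect), block is numeric and 0-based so
    the intercept refers to non-visible trials in the first block, and atria
    type / session are 0/1 indicators (centralized and session 1 reference).
    """
    df = pd.DataFrame({
        "y": segmented[response].to_numpy(),
        "visible": (segmented["condition"] == "V").astype(float),
        "atria": (segmented["atria_type"] == "distributed").astype(float),
        "block0": segmented["block"].astype(float) - segmented["block"].min(),
        "session2": (segmented["session"].astype(int) > 1).astype(float),
        "participant": segmented["subject_id"],
    })
    res = fit_lmer(df, "y", ["atria", "block0", "visible", "session2"],
                   group="participant", reml=reml)
    res.table.index = ["Intercept", "AtriaType", "Block",
                       "VisibilityCondition(NV-V)", "Session"]
    return res


def corrected_alpha(alpha: float, n_tests: int) -> float:
    """Bonferroni-corrected significance threshold alpha / n_tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def significance_threshold(alpha: float, n_tests: int,
                           declared: float | None = None) -> float:
    """The effective threshold: the Bonferroni value, or a stricter declared one."""
    base = corrected_alpha(alpha, n_tests)
    if declared is not None:
        if declared > base:
            raise ValueError("a declared threshold must not be looser than "
                             "the Bonferroni correction")
        return declared
    return base
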