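"""Per-medication logistic screening (MWAS core).

Each retained medication is tested separately against the binary outcome
in a logistic model whose control group is every other delivery, under one
of three adjustment sets:

* model1 — unadjusted,
* model2 — adjusted for maternal age,
* model3 — adjusted for maternal age, ART-resulting pregnancy and
  infertility diagnosis.

Fitting is maximum likelihood by iteratively reweighted least squares
(IRLS); standard errors come from the inverse observed information.
Odds ratios carry Wald 95% CIs, exp(beta ± 1.96·se), with two-sided Wald
P values and Bonferroni adjustment over the retained medication family.
Complete or quasi-complete separation is detected and flagged rather than
penalised: the affected medication keeps its exposure counts but reports
no OR/CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .exposure import ExposureMatrix

Z_95 = 1.96  # normal quantile for the 95% Wald interval

_MODEL_COVARIATES = {
    "model1": (),
    "model2": ("maternal_age",),
    "model3": ("maternal_age", "art", "infertility"),
}

MAX_ITER = 100
TOL = 1e-8
#: hard |beta| cap beyond which the MLE is always treated as diverging
BETA_DIVERGENCE = 30.0
#: softer separation rule: |beta| above this with an exploding Wald SE
BETA_SUSPECT = 10.0
SE_EXPLODED = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Adjustment set for a screen: one of model1/model2/model3."""

    label: str = "model3"
    alpha: float = 0.05

    def __post_init__(self):
        if self.label not in _MODEL_COVARIATES:
            raise ValueError(f"unknown model label {self.label!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def covariates(self) -> tuple[str, ...]:
        return _MODEL_COVARIATES[self.label]


@dataclass
class LogitFit:
    """Raw output of the IRLS logistic fitter.

    ``params``/``bse`` are NaN for aliased (rank-deficient) columns;
    ``converged`` is False on iteration exhaustion.  ``diverged`` marks
    coefficients whose MLE is drifting to ±infinity (complete or
    quasi-complete separation in that column): the fit as a whole can
    still stabilise in deviance, matching R glm behaviour, but Wald
    inference on a diverged coefficient is meaningless.
    """

    params: np.ndarray
    bse: np.ndarray
    converged: bool
    n_iter: int
    estimable: np.ndarray = field(default=None)
    diverged: np.ndarray = field(default=None)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy left-to-right mask of linearly independent columns."""
    n, p = X.shape
    keep = np.zeros(p, dtype=bool)
    basis = np.empty((n, 0))
    rank = 0
    for j in range(p):
        trial = np.column_stack([basis, X[:, j]])
        if np.linalg.matrix_rank(trial) > rank:
            keep[j] = True
            basis = trial
            rank += 1
    return keep


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = MAX_ITER,
    tol: float = TOL,
) -> LogitFit:
    """Maximum-likelihood logistic regression via IRLS.

    ``X`` must include the intercept column.  Convergence is declared when
    the largest coefficient update falls below ``tol``, or — as in R's
    glm — when the deviance has stabilised while one coefficient drifts
    off under separation; drifting coefficients (large |beta| with an
    exploding or undefined Wald SE) are marked in ``diverged``.  Aliased
    columns (for instance a constant
    non-intercept column) are dropped from the fit and reported as NaN,
    leaving the remaining coefficients unaffected.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design/outcome shapes do not match")
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")

    p_full = X.shape[1]
    estimable = _independent_columns(X)
    Xr = X[:, estimable]
    p = Xr.shape[1]

    def deviance(beta):
        mu = np.clip(special.expit(np.clip(Xr @ beta, -35, 35)), 1e-15, 1 - 1e-15)
        return -2.0 * float(y @ np.log(mu) + (1 - y) @ np.log(1 - mu))

    beta = np.zeros(p)
    converged = False
    dev_old = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(Xr @ beta, -35, 35)
        mu = special.expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        info = (Xr * w[:, None]).T @ Xr
        score = Xr.T @ (y - mu)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.abs(step).max() < tol:
            converged = True
            break
        # deviance stop only applies when a coefficient is running off
        # under separation; ordinary fits converge on the step criterion
        dev = deviance(beta)
        if (np.abs(beta).max() > BETA_SUSPECT
                and abs(dev - dev_old) < 1e-12 * (abs(dev) + 0.1)):
            converged = True
            break
        dev_old = dev

    params = np.full(p_full, np.nan)
    bse = np.full(p_full, np.nan)
    params[estimable] = beta
    eta = np.clip(Xr @ beta, -35, 35)
    mu = special.expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (Xr * w[:, None]).T @ Xr
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    with np.errstate(invalid="ignore"):
        bse[estimable] = np.sqrt(np.diag(cov))
    # separation: the coefficient runs off while its Wald SE explodes
    with np.errstate(invalid="ignore"):
        diverged = (np.abs(params) > BETA_DIVERGENCE) | (
            (np.abs(params) > BETA_SUSPECT)
            & ((bse > SE_EXPLODED) | ~np.isfinite(bse)))
    diverged |= estimable & ~np.isfinite(params)
    diverged[~estimable] = False
    return LogitFit(params=params, bse=bse, converged=converged, n_iter=it,
                    estimable=estimable, diverged=diverged)


RESULT_COLUMNS = [
    "medication_id", "n_exposed", "n_exposed_mb", "beta", "se", "or_",
    "ci_low", "ci_high", "p", "p_bonf", "sig_nominal", "sig_bonf", "converged",
]


class MWASModel:
    """Medication-wide screen of a binary outcome.

    Parameters
    ----------
    cohort : DataFrame
        Per-delivery analysis table with columns delivery_id, mb and the
        model covariates (maternal_age, art, infertility).
    exposure : ExposureMatrix
        Filtered binary exposure matrix; its column count fixes the
        Bonferroni family size.
    model : str or ModelSpec
        Adjustment set, default ``model3``.
    """

    def __init__(self, cohort: pd.DataFrame, exposure: ExposureMatrix,
                 model: str | ModelSpec = "model3", alpha: float = 0.05):
        self.spec = model if isinstance(model, ModelSpec) else ModelSpec(model, alpha)
        self.cohort = cohort.reset_index(drop=True)
        self.exposure = exposure
        missing = [c for c in ("mb", *self.spec.covariates) if c not in cohort.columns]
        if missing:
            raise ValueError(f"cohort is missing columns {missing}")

    def fit(self) -> "MWASResults":
        cohort = self.cohort
        spec = self.spec
        frame = self.exposure.frame.reindex(cohort["delivery_id"], fill_value=0)
        y = cohort["mb"].to_numpy(dtype=float)
        covs = [cohort[c].to_numpy(dtype=float) for c in spec.covariates]
        n = len(cohort)
        m = self.exposure.m  # family size fixed before fitting

        rows = []
        covariate_rows = []
        for med in sorted(frame.columns):
            x = frame[med].to_numpy(dtype=float)
            X = np.column_stack([np.ones(n), x, *covs])
            fit = fit_logistic(y, X)
            beta, se = fit.params[1], fit.bse[1]
            # a medication is reportable when the fit stabilised and its
            # own exposure coefficient did not separate; a diverging
            # nuisance covariate does not invalidate the exposure OR
            ok = (fit.converged and not fit.diverged[1]
                  and np.isfinite(beta) and np.isfinite(se) and se > 0)
            row = {
                "medication_id": med,
                "n_exposed": int(x.sum()),
                "n_exposed_mb": int((x * y).sum()),
                "converged": int(ok),
            }
            if row["converged"]:
                p = 2.0 * stats.norm.sf(abs(beta / se))
                row.update(
                    beta=beta, se=se, or_=np.exp(beta),
                    ci_low=np.exp(beta - Z_95 * se), ci_high=np.exp(beta + Z_95 * se),
                    p=p, p_bonf=min(1.0, m * p),
                )
                row["sig_nominal"] = int(row["p"] < spec.alpha)
                row["sig_bonf"] = int(row["p_bonf"] < spec.alpha)
            else:
                row.update(beta=np.nan, se=np.nan, or_=np.nan, ci_low=np.nan,
                           ci_high=np.nan, p=np.nan, p_bonf=np.nan,
                           sig_nominal=0, sig_bonf=0)
            rows.append(row)
            cov_row = {"medication_id": med}
            for k, name in enumerate(spec.covariates, start=2):
                cov_row[f"beta_{name}"] = fit.params[k]
                cov_row[f"se_{name}"] = fit.bse[k]
            covariate_rows.append(cov_row)

        results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        cov_columns = ["medication_id"] + [f"{k}_{c}" for c in spec.covariates
                                           for k in ("beta", "se")]
        covariates = pd.DataFrame(covariate_rows, columns=cov_columns)
        return MWASResults(self, results, covariates, m=m)


class MWASResults:
    """Results of a medication-wide screen.

    ``frame`` has one row per medication (sorted by medication_id) with
    exposure counts, log-odds estimate, Wald SE, OR with 95% CI, nominal
    and Bonferroni P, significance flags and a convergence flag.
    """

    def __init__(self, model: MWASModel, frame: pd.DataFrame,
                 covariates: pd.DataFrame, m: int):
        self.model = model
        self.spec = model.spec
        self.frame = frame
        self.covariates = covariates
        self.m = m

    @property
    def significant_nominal(self) -> list[str]:
        return list(self.frame.loc[self.frame["sig_nominal"] == 1, "medication_id"])

    @property
    def significant_bonferroni(self) -> list[str]:
        return list(self.frame.loc[self.frame["sig_bonf"] == 1, "medication_id"])

    def summary(self) -> str:
        f = self.frame
        lines = [
            f"MWAS screen ({self.spec.label}, alpha={self.spec.alpha:g}, "
            f"m={self.m} medications)",
            f"  deliveries: {len(self.model.cohort)}   "
            f"outcome events: {int(self.model.cohort['mb'].sum())}",
            f"  significant (nominal): {int(f['sig_nominal'].sum())}   "
            f"significant (Bonferroni): {int(f['sig_bonf'].sum())}   "
            f"non-converged: {int((1 - f['converged']).sum())}",
            "",
            f["medication_id n_exposed n_exposed_mb or_ ci_low ci_high p p_bonf sig_bonf".split()]
            .to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def forest_frame(self, significant_only: bool = True) -> pd.DataFrame:
        return export_forest(self, significant_only=significant_only)


def run_mwas(cohort: pd.DataFrame, matrix: ExposureMatrix,
             spec: ModelSpec | str = "model3", alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper: screen every medication and return the result frame."""
    return MWASModel(cohort, matrix, model=spec, alpha=alpha).fit().frame


def export_forest(results: MWASResults, significant_only: bool = True) -> pd.DataFrame:
    """Long-format forest-plot table: OR and CI bounds per medication for
    the exposure term and each model covariate.

    Non-converged medications are excluded with a note column; when
    ``significant_only`` the table is restricted to nominally significant
    medications.
    """
    f = results.frame
    keep = f["converged"] == 1
    if significant_only:
        keep &= f["sig_nominal"] == 1
    rows = []
    cov = results.covariates.set_index("medication_id")
    for _, r in f[keep].iterrows():
        med = r["medication_id"]
        rows.append({"medication_id": med, "term": "exposure", "or_": r["or_"],
                     "ci_low": r["ci_low"], "ci_high": r["ci_high"]})
        for name in results.spec.covariates:
            b, s = cov.loc[med, f"beta_{name}"], cov.loc[med, f"se_{name}"]
            rows.append({
                "medication_id": med, "term": name, "or_": np.exp(b),
                "ci_low": np.exp(b - Z_95 * s), "ci_high": np.exp(b + Z_95 * s),
            })
    out = pd.DataFrame(rows, columns=["medication_id", "term", "or_", "ci_low", "ci_high"])
    out.attrs["excluded_nonconverged"] = list(f.loc[f["converged"] == 0, "medication_id"])
    return out
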