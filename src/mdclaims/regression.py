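"""Age-stratified binary logistic regression for predicting confirmed case
status from passively collected claims variables.

The model is fit from first principles by iteratively reweighted least
squares (Fisher scoring) with step-halving, so the binomial log-likelihood
is non-decreasing across iterations.  Inference is Wald: standard errors
from the inverse observed information, z against the standard normal,
two-sided p-values.  Complete separation is reported as an explicit
error, never papered over with a penalty.

The design mirrors the published predictor set, one model per age stratum
(first MD code at <=18 years vs >18 years): intercept, number of distinct
MD-coded dates (continuous), the robust-claim indicator, male (referent
female), race dummies for African American and other (referent white),
neurologist-coded and other-specialist-coded indicators, the
other-neurologic-syndrome-after-MD indicator, and age in years
(continuous).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "DESIGN_COLUMNS",
    "REFERENTS",
    "EmptyStratumError",
    "CollinearityError",
    "SeparationError",
    "FitError",
    "LogisticFit",
    "build_design",
    "fit_logistic",
    "significance_screen",
    "fit_table",
]

#: Fixed design-matrix column order.
DESIGN_COLUMNS = [
    "intercept",
    "n_md_codes",
    "robust_claim",
    "male",
    "race_african_american",
    "race_other",
    "neurologist_coded",
    "other_specialist_coded",
    "other_neuro_after",
    "age",
]

#: Referent level (or unit) per design column, for report layout.
REFERENTS = {
    "intercept": "",
    "n_md_codes": "number of encounters with MD codes, continuous",
    "robust_claim": "MD code used for only 1 outpatient claim or 2 claims < 30 days apart",
    "male": "female",
    "race_african_american": "white",
    "race_other": "white",
    "neurologist_coded": "no neurology specialist coded MD",
    "other_specialist_coded": "no other specialty physician coded MD",
    "other_neuro_after": "no other neurologic syndrome coded",
    "age": "in years, continuous",
}


class FitError(RuntimeError):
    """The model could not be fit on the supplied data."""


class EmptyStratumError(FitError):
    """The requested age stratum contains no persons."""


class CollinearityError(FitError):
    """The design columns are linearly dependent; names the columns."""


class SeparationError(FitError):
    """Divergence consistent with (quasi-)complete separation."""


@dataclasses.dataclass(frozen=True)
class LogisticFit:
    """Coefficients and Wald inference for one fitted model."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n_obs: int
    loglik: float
    n_iter: int

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.coef.tolist()))


def build_design(
    data: pd.DataFrame, stratum: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Assemble the stratified design matrix and confirmed-status labels.

    ``data`` is a feature table joined with a boolean ``confirmed`` column;
    rows are restricted to ``stratum`` ("le18" or "gt18").  Returns
    (X, y, column names) with X in :data:`DESIGN_COLUMNS` order.
    """
    if stratum not in ("le18", "gt18"):
        raise ValueError(f"unknown stratum {stratum!r}")
    sub = data.loc[data["age_group"].eq(stratum)]
    if sub.empty:
        raise EmptyStratumError(f"no persons in stratum {stratum!r}")
    n = len(sub)
    X = np.column_stack(
        [
            np.ones(n),
            sub["n_md_codes"].to_numpy(float),
            sub["robust_claim"].to_numpy(bool).astype(float),
            sub["sex"].eq("male").to_numpy(float),
            sub["race"].eq("african_american").to_numpy(float),
            sub["race"].eq("other").to_numpy(float),
            sub["neurologist_coded_md"].to_numpy(bool).astype(float),
            sub["other_specialist_coded_md"].to_numpy(bool).astype(float),
            sub["other_neuro_after"].to_numpy(bool).astype(float),
            sub["age_at_first_md"].to_numpy(float),
        ]
    )
    y = sub["confirmed"].to_numpy(bool).astype(float)
    return X, y, list(DESIGN_COLUMNS)


def _loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.flatnonzero(bad)]
        raise CollinearityError(f"linearly dependent design column(s): {', '.join(culprits)}")


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence requires the score vector's max-norm below ``tol * n``.
    Raises :class:`SeparationError` when coefficients diverge (the signature
    of complete separation) and :class:`CollinearityError` for a rank-
    deficient design, naming the offending columns.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be 2-D with one row per label")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be 0/1")
    if y.sum() == 0 or y.sum() == len(y):
        raise FitError("need at least one positive and one negative label")
    n, k = X.shape
    names = list(names) if names is not None else [f"x{i}" for i in range(k)]
    _check_rank(X, names)

    beta = np.zeros(k)
    ll = _loglik(X, y, beta)
    converged = False
    info = None
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        score = X.T @ (y - mu)
        if np.max(np.abs(score)) < tol * n:
            converged = True
            break
        if np.max(np.abs(beta)) > 40.0:
            raise SeparationError(
                "coefficients diverged (|beta| > 40): data are likely completely separated"
            )
        w = mu * (1.0 - mu)
        info = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "information matrix became singular during fitting "
                "(weights underflowed): likely separation"
            ) from exc
        # step-halving keeps the log-likelihood non-decreasing
        step = 1.0
        for _ in range(40):
            cand = beta + step * delta
            ll_new = _loglik(X, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta = beta + step * delta
        ll = ll_new
    if not converged:
        raise SeparationError(
            f"IRLS did not converge in {max_iter} iterations "
            "(possible quasi-complete separation)"
        )
    mu = expit(X @ beta)
    w = mu * (1.0 - mu)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SeparationError("singular information at the optimum") from exc
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p = np.clip(2.0 * norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
    return LogisticFit(
        names=tuple(names),
        coef=beta,
        se=se,
        z=z,
        p=p,
        converged=True,
        n_obs=n,
        loglik=ll,
        n_iter=it,
    )


def significance_screen(fit: LogisticFit, alpha: float = 0.05) -> pd.DataFrame:
    """Label each parameter significant iff p <= alpha (inclusive).

    Pure function of the fit; returns one row per parameter with the
    estimate, p-value, and the boolean flag.
    """
    return pd.DataFrame(
        {
            "parameter": list(fit.names),
            "estimate": fit.coef,
            "p_value": fit.p,
            "significant": fit.p <= alpha,
        }
    )


def fit_table(fit: LogisticFit) -> pd.DataFrame:
    """Report layout mirroring the published model table: parameter,
    referent group, estimate, standard error, p-value."""
    return pd.DataFrame(
        {
            "parameter": list(fit.names),
            "referent": [REFERENTS.get(n, "") for n in fit.names],
            "estimate": fit.coef,
            "std_error": fit.se,
            "p_value": fit.p,
        }
    )
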