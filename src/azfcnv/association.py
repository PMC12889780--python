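"""Case-control association: 2x2 analysis and Firth-penalized logistic fits.

The carrier-phenotype association is tested two ways:

* ``unadjusted_or`` — classical 2x2 odds ratio with a Woolf (log-scale)
  confidence interval and a Yates-corrected chi-square p-value.

* ``fit_firth`` — Firth's bias-reduced logistic regression, maximizing the
  Jeffreys-prior penalized log-likelihood

      pl(beta) = l(beta) + 1/2 * log det I(beta),

  by Newton iteration on the Firth-modified score

      U*(beta) = X' (y - pi + h * (1/2 - pi)),

  where h are the hat-matrix diagonals.  The penalty keeps estimates finite
  under complete or quasi-complete separation — exactly the regime produced
  by rare carriers and heavy case-control imbalance.  Confidence intervals
  default to profile penalized likelihood (Wald available); p-values are
  penalized likelihood-ratio tests.

Rows with identical covariate patterns may be aggregated via frequency
``weights``; the penalized likelihood, information and hat values are
identical to the expanded per-individual representation, so grouped and
ungrouped fits agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, log_expit

from .errors import CollinearDesignError

Z95 = 1.959964  # standard normal 97.5% quantile to printed-CI precision
_TOL = 1e-8
_MAX_ITER = 100


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier-by-phenotype counts.

    a: carriers among cases, b: non-carriers among cases,
    c: carriers among controls, d: non-carriers among controls.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    def to_design(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Aggregated design [intercept, carrier], outcome, weights."""
        X = np.array([[1.0, 1.0], [1.0, 0.0], [1.0, 1.0], [1.0, 0.0]])
        y = np.array([1.0, 1.0, 0.0, 0.0])
        w = np.array([self.a, self.b, self.c, self.d], dtype=float)
        keep = w > 0
        return X[keep], y[keep], w[keep]


@dataclass
class UnadjustedResult:
    or_point: float | None
    ci95: tuple[float, float] | None
    chi2_yates: float
    p_value: float
    flags: list[str]


def unadjusted_or(t: ContingencyTable) -> UnadjustedResult:
    """Woolf-interval odds ratio and Yates-corrected chi-square test.

    With any zero cell the OR is undefined and reported as ``None`` with a
    flag pointing at :func:`fit_firth`, which remains finite in that regime.
    """
    flags: list[str] = []
    table = np.array([[t.a, t.b], [t.c, t.d]], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    if min(t.a, t.b, t.c, t.d) == 0:
        flags.append("zero_cell_use_firth")
        return UnadjustedResult(None, None, float(chi2), float(p), flags)
    or_point = (t.a * t.d) / (t.b * t.c)
    se = np.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    lo, hi = np.exp(np.log(or_point) + np.array([-1, 1]) * Z95 * se)
    return UnadjustedResult(
        float(or_point), (float(lo), float(hi)), float(chi2), float(p), flags
    )


@dataclass
class FirthFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    or_adjusted: float | None
    ci95: tuple[float, float] | None
    ci_method: str
    p_value: float | None
    penalized_loglik: float
    converged: bool
    n_iter: int
    interest_index: int | None = None


def _pll(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    ll = float(np.sum(w * (y * log_expit(eta) + (1 - y) * log_expit(-eta))))
    pi = expit(eta)
    wvar = w * pi * (1 - pi)
    info = X.T @ (X * wvar[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _score_info(X, y, w, beta):
    pi = expit(X @ beta)
    wvar = w * pi * (1 - pi)
    info = X.T @ (X * wvar[:, None])
    # hat diagonals of the (weighted) covariate patterns
    solved = np.linalg.solve(info, X.T).T  # n x k
    h = wvar * np.einsum("ij,ij->i", X, solved)
    score = X.T @ (w * (y - pi) + h * (0.5 - pi))
    return score, info


def _firth_newton(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    beta0: np.ndarray,
    free: np.ndarray,
    tol: float = _TOL,
    max_iter: int = _MAX_ITER,
) -> tuple[np.ndarray, float, bool, int]:
    """Maximize the penalized likelihood over the ``free`` coordinates.

    Newton steps on the Firth-modified score with step-halving, guaranteeing
    the penalized log-likelihood never decreases across accepted steps.
    """
    beta = beta0.copy()
    pll = _pll(X, y, w, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info = _score_info(X, y, w, beta)
        sub = info[np.ix_(free, free)]
        try:
            step = np.linalg.solve(sub, score[free])
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(score[free])) < tol:
            converged = True
            break
        # step-halving: accept the first step that does not decrease pll
        factor = 1.0
        for _ in range(25):
            cand = beta.copy()
            cand[free] += factor * step
            cand_pll = _pll(X, y, w, cand)
            if cand_pll >= pll - 1e-12:
                break
            factor /= 2
        beta, new_pll = cand, cand_pll
        if abs(new_pll - pll) < 1e-14 and np.max(np.abs(factor * step)) < tol:
            pll = new_pll
            converged = True
            break
        pll = new_pll
    else:
        it = max_iter
    score, _ = _score_info(X, y, w, beta)
    if np.max(np.abs(score[free])) < 1e-4:
        converged = True
    return beta, _pll(X, y, w, beta), converged, it


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                raise CollinearDesignError(
                    f"design column {j} is collinear with the others"
                )
        raise CollinearDesignError("design matrix is rank-deficient")


def fit_firth(
    design: np.ndarray,
    outcome: np.ndarray,
    weights: np.ndarray | None = None,
    interest: int | None = 1,
    ci_method: str = "profile",
    alpha: float = 0.05,
) -> FirthFit:
    """Firth-penalized logistic regression.

    ``design`` is n x (k+1) with an intercept column; ``interest`` selects the
    coefficient (default: column 1, the carrier indicator) for which the OR,
    CI and penalized likelihood-ratio p-value are reported.  ``ci_method`` is
    ``"profile"`` (profile penalized likelihood, the default) or ``"wald"``.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("design and outcome shapes disagree")
    if w @ y == 0 or w @ (1 - y) == 0:
        raise ValueError("outcome is constant; nothing to fit")
    if (w > 0).sum() * 1.0 <= X.shape[1] and w.sum() <= X.shape[1]:
        raise ValueError("more parameters than observations")
    _check_design(X)

    free = np.ones(X.shape[1], dtype=bool)
    beta, pll, converged, n_iter = _firth_newton(X, y, w, np.zeros(X.shape[1]), free)
    _, info = _score_info(X, y, w, beta)
    cov = np.linalg.inv(info)
    ses = np.sqrt(np.diag(cov))

    or_adj = ci = p = None
    if interest is not None:
        j = interest
        or_adj = float(np.exp(beta[j]))
        # penalized likelihood-ratio test of beta_j = 0
        fixed = free.copy()
        fixed[j] = False
        b0 = beta.copy()
        b0[j] = 0.0
        _, pll0, _, _ = _firth_newton(X, y, w, b0, fixed)
        lr = max(0.0, 2 * (pll - pll0))
        p = float(stats.chi2.sf(lr, 1))
        if ci_method == "wald":
            ci = (
                float(np.exp(beta[j] - Z95 * ses[j])),
                float(np.exp(beta[j] + Z95 * ses[j])),
            )
        elif ci_method == "profile":
            lo = _profile_bound(X, y, w, beta, pll, j, alpha, direction=-1)
            hi = _profile_bound(X, y, w, beta, pll, j, alpha, direction=+1)
            ci = (float(np.exp(lo)), float(np.exp(hi)))
        else:
            raise ValueError(f"unknown ci_method {ci_method!r}")

    return FirthFit(
        coefficients=beta,
        standard_errors=ses,
        or_adjusted=or_adj,
        ci95=ci,
        ci_method=ci_method if interest is not None else "none",
        p_value=p,
        penalized_loglik=pll,
        converged=converged,
        n_iter=n_iter,
        interest_index=interest,
    )


def _profile_pll(X, y, w, beta_hat, j, value) -> float:
    free = np.ones(X.shape[1], dtype=bool)
    free[j] = False
    b0 = beta_hat.copy()
    b0[j] = value
    _, pll, _, _ = _firth_newton(X, y, w, b0, free)
    return pll


def _profile_bound(X, y, w, beta_hat, pll_max, j, alpha, direction) -> float:
    """One endpoint of the profile-penalized-likelihood CI by bracketing."""
    target = pll_max - stats.chi2.ppf(1 - alpha, 1) / 2

    def g(b: float) -> float:
        return _profile_pll(X, y, w, beta_hat, j, b) - target

    _, info = _score_info(X, y, w, beta_hat)
    se = float(np.sqrt(np.linalg.inv(info)[j, j]))
    step = max(se, 1e-2)
    inner = beta_hat[j]
    outer = inner + direction * step
    for _ in range(60):
        if g(outer) < 0:
            break
        inner = outer
        outer += direction * step
        step *= 1.6
    else:
        raise RuntimeError("profile CI bracket not found")
    lo, hi = sorted((inner, outer))
    return float(brentq(g, lo, hi, xtol=1e-6))


def assoc_with_covariates(
    table: pd.DataFrame, n_covariates: int, ci_method: str = "profile"
) -> FirthFit:
    """Firth fit of phenotype ~ carrier + cov1..covN from an association table.

    The table is the output of the caller's association filter: columns
    ``sample_id``, ``carrier``, ``phenotype``, plus covariate columns
    ``cov1``..``covN`` (typically principal components supplied externally).
    """
    cov_cols = [f"cov{i}" for i in range(1, n_covariates + 1)]
    missing_cols = [c for c in cov_cols if c not in table.columns]
    if missing_cols:
        raise ValueError(f"missing covariate columns: {missing_cols}")
    na_mask = table[["carrier", "phenotype"] + cov_cols].isna().any(axis=1)
    if na_mask.any():
        offenders = table.loc[na_mask, "sample_id"].tolist()
        raise ValueError(
            f"missing covariate/outcome values for samples: {offenders[:20]}"
        )
    n = len(table)
    # all-zero covariate columns carry no information and would only make
    # the design singular; drop them so the fit equals the covariate-free one
    cov_cols = [c for c in cov_cols if np.any(table[c].to_numpy(dtype=float) != 0)]
    X = np.column_stack(
        [np.ones(n), table["carrier"].to_numpy(dtype=float)]
        + [table[c].to_numpy(dtype=float) for c in cov_cols]
    )
    y = table["phenotype"].to_numpy(dtype=float)
    return fit_firth(X, y, interest=1, ci_method=ci_method)


def firth_from_table(t: ContingencyTable, ci_method: str = "profile") -> FirthFit:
    """Firth fit on a bare 2x2 table (aggregated rows; exact equivalence to
    the per-individual fit)."""
    X, y, w = t.to_design()
    return fit_firth(X, y, weights=w, interest=1, ci_method=ci_method)
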