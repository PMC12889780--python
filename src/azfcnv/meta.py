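"""Inverse-variance meta-analysis of per-dataset log odds ratios.

Per-study inputs are log-ORs with standard errors, either taken from a fitted
model or reconstructed from a printed OR and 95% CI:

    se = (ln CI_high - ln CI_low) / (2 * 1.959964)

Fixed-effect pooling uses weights w_i = 1/se_i^2.  The random-effects model
uses the DerSimonian-Laird moment estimator of the between-study variance

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)),

with Q the Cochran heterogeneity statistic on the fixed-effect weights, and
re-pools with starred weights w_i* = 1/(se_i^2 + tau^2).  When Q <= k-1 the
moment estimate truncates to zero and the random-effects result collapses
exactly onto the fixed-effect one.

I^2 = max(0, (Q - (k-1))/Q) * 100 expresses the share of total variability
attributable to between-study heterogeneity.  A test-based (log-H) confidence
interval for I^2 is reported where the formula is defined, but the method is
sensitive to convention at k = 2 and the interval is labeled accordingly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import StudyInputError

Z95 = 1.959964


class EstimateSource(str, Enum):
    FITTED = "FITTED"
    FROM_CI = "FROM_CI"


class MetaMethod(str, Enum):
    FIXED = "FIXED"
    RANDOM_DL = "RANDOM_DL"


@dataclass(frozen=True)
class StudyEstimate:
    label: str
    log_or: float
    se: float
    source: EstimateSource = EstimateSource.FITTED

    def __post_init__(self) -> None:
        if not (self.se > 0) or not math.isfinite(self.se):
            raise StudyInputError(f"study {self.label!r}: se must be positive")
        if not math.isfinite(self.log_or):
            raise StudyInputError(f"study {self.label!r}: log OR must be finite")


@dataclass(frozen=True)
class Heterogeneity:
    q_stat: float
    q_p: float
    tau2: float
    i2_percent: float
    i2_ci: tuple[float, float] | None
    i2_ci_method: str | None


@dataclass
class MetaResult:
    method: MetaMethod
    combined_log_or: float
    se: float
    or_point: float
    ci95: tuple[float, float]
    z: float
    p: float
    q_stat: float | None = None
    q_p: float | None = None
    tau2: float = 0.0
    i2_percent: float | None = None
    i2_ci: tuple[float, float] | None = None


def estimate_from_ci(
    or_point: float, ci_low: float, ci_high: float, label: str = "study"
) -> StudyEstimate:
    """Reconstruct a log-OR and its SE from a printed OR and 95% CI."""
    if not (0 < ci_low <= or_point <= ci_high):
        raise StudyInputError(
            f"study {label!r}: need 0 < ci_low <= or <= ci_high "
            f"(got {or_point}, [{ci_low}, {ci_high}])"
        )
    if ci_low == ci_high:
        raise StudyInputError(f"study {label!r}: degenerate CI (se would be 0)")
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z95)
    return StudyEstimate(label, math.log(or_point), se, EstimateSource.FROM_CI)


def _pool(thetas: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    combined = float((weights * thetas).sum() / weights.sum())
    se = float(1 / math.sqrt(weights.sum()))
    return combined, se


def _result(method: MetaMethod, combined: float, se: float, **extras) -> MetaResult:
    z = combined / se
    p = 2 * float(stats.norm.sf(abs(z)))
    ci = (math.exp(combined - Z95 * se), math.exp(combined + Z95 * se))
    return MetaResult(
        method=method,
        combined_log_or=combined,
        se=se,
        or_point=math.exp(combined),
        ci95=ci,
        z=z,
        p=p,
        **extras,
    )


def fixed_effect(studies: Sequence[StudyEstimate]) -> MetaResult:
    """Inverse-variance fixed-effect pooling."""
    if not studies:
        raise StudyInputError("at least one study required")
    th = np.array([s.log_or for s in studies])
    w = np.array([1 / s.se**2 for s in studies])
    combined, se = _pool(th, w)
    extras = {}
    if len(studies) >= 2:
        het = heterogeneity(studies)
        extras = {
            "q_stat": het.q_stat,
            "q_p": het.q_p,
            "i2_percent": het.i2_percent,
            "i2_ci": het.i2_ci,
        }
    return _result(MetaMethod.FIXED, combined, se, tau2=0.0, **extras)


def heterogeneity(studies: Sequence[StudyEstimate]) -> Heterogeneity:
    """Cochran's Q, DerSimonian-Laird tau^2 and I^2 (with test-based CI)."""
    k = len(studies)
    if k < 2:
        raise StudyInputError("heterogeneity needs at least two studies")
    th = np.array([s.log_or for s in studies])
    w = np.array([1 / s.se**2 for s in studies])
    theta_fixed = (w * th).sum() / w.sum()
    q = float((w * (th - theta_fixed) ** 2).sum())
    q_p = float(stats.chi2.sf(q, k - 1))
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    i2 = max(0.0, (q - (k - 1)) / q) * 100 if q > 0 else 0.0
    i2_ci, method = _i2_ci_log_h(q, k)
    return Heterogeneity(q, q_p, float(tau2), float(i2), i2_ci, method)


def _i2_ci_log_h(q: float, k: int) -> tuple[tuple[float, float] | None, str | None]:
    """Test-based (log-H) interval for I^2, truncated to [0, 100].

    The small-k branch of the Higgins-Thompson variance formula is undefined
    for k = 2 when Q is small; in that case no interval is reported.  The
    method is convention-sensitive and the interval is informational only.
    """
    if q > k:
        se_ln_h = 0.5 * (math.log(q) - math.log(k - 1)) / (
            math.sqrt(2 * q) - math.sqrt(2 * k - 3)
        )
    elif k > 2:
        se_ln_h = math.sqrt(1 / (2 * (k - 2)) * (1 - 1 / (3 * (k - 2) ** 2)))
    else:
        return None, None
    ln_h = 0.5 * max(0.0, math.log(q / (k - 1))) if q > 0 else 0.0

    def h_to_i2(h: float) -> float:
        return max(0.0, min(100.0, (h**2 - 1) / h**2 * 100 if h > 0 else 0.0))

    lo = h_to_i2(math.exp(ln_h - Z95 * se_ln_h))
    hi = h_to_i2(math.exp(ln_h + Z95 * se_ln_h))
    return (lo, hi), "test-based log-H (method-sensitive)"


def random_effects(studies: Sequence[StudyEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects inverse-variance pooling."""
    if len(studies) < 2:
        raise StudyInputError("random-effects meta-analysis needs >= 2 studies")
    het = heterogeneity(studies)
    th = np.array([s.log_or for s in studies])
    w_star = np.array([1 / (s.se**2 + het.tau2) for s in studies])
    combined, se = _pool(th, w_star)
    return _result(
        MetaMethod.RANDOM_DL,
        combined,
        se,
        q_stat=het.q_stat,
        q_p=het.q_p,
        tau2=het.tau2,
        i2_percent=het.i2_percent,
        i2_ci=het.i2_ci,
    )


def read_studies_tsv(path) -> dict[str, list[StudyEstimate]]:
    """Read a studies TSV (label, or, ci_low, ci_high[, stratum]).

    Returns estimates grouped by stratum (a single ``"all"`` stratum when the
    column is absent).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if "stratum" not in df.columns:
        df["stratum"] = "all"
    out: dict[str, list[StudyEstimate]] = {}
    for _, row in df.iterrows():  # itertuples would mangle the "or" column
        out.setdefault(str(row["stratum"]), []).append(
            estimate_from_ci(
                float(row["or"]),
                float(row["ci_low"]),
                float(row["ci_high"]),
                label=str(row["label"]),
            )
        )
    return out


def result_to_dict(r: MetaResult) -> dict:
    return {
        "method": r.method.value,
        "or": r.or_point,
        "ci95": list(r.ci95),
        "combined_log_or": r.combined_log_or,
        "se": r.se,
        "z": r.z,
        "p": r.p,
        "q_stat": r.q_stat,
        "q_p": r.q_p,
        "tau2": r.tau2,
        "i2_percent": r.i2_percent,
        "i2_ci": list(r.i2_ci) if r.i2_ci else None,
    }


def forest_frame(
    studies: Sequence[StudyEstimate], results: Sequence[MetaResult]
) -> pd.DataFrame:
    """Forest-plot-ready rows: per-study estimates then pooled rows."""
    rows = [
        {
            "label": s.label,
            "kind": "study",
            "or": math.exp(s.log_or),
            "ci_low": math.exp(s.log_or - Z95 * s.se),
            "ci_high": math.exp(s.log_or + Z95 * s.se),
        }
        for s in studies
    ]
    for r in results:
        rows.append(
            {
                "label": f"meta ({r.method.value})",
                "kind": "pooled",
                "or": r.or_point,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
            }
        )
    return pd.DataFrame(rows)
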