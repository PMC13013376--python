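"""Paired-design statistical battery.

Implements the inference layer of the pipeline: Shapiro-Wilk-routed paired
comparisons (Student t when the paired differences look normal, Wilcoxon
signed rank otherwise), paired-design effect sizes dz = t/sqrt(n) and
r = z/sqrt(n) with normal-theory confidence intervals, Benjamini-Hochberg
FDR over parallel node/target tests, Spearman brain-behavior correlations
with Fisher-transform CIs, and covariate-adjusted ordinary least squares
with variance-inflation-factor diagnostics.

Scalar machinery (Shapiro-Wilk, Student/normal tails, rank statistics,
OLS) is delegated to scipy and statsmodels; this module owns the routing,
effect-size, and table conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.linear_model import OLS
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateDataError

Method = Literal["paired_t", "wilcoxon"]


@dataclass(frozen=True)
class PairedSample:
    """Per-subject values under conditions A and B, aligned by subject."""

    x_A: np.ndarray
    x_B: np.ndarray
    subject_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        a, b = np.asarray(self.x_A, float), np.asarray(self.x_B, float)
        if a.shape != b.shape or a.ndim != 1 or a.size < 3:
            raise ConfigurationError("paired sample needs aligned 1-D arrays, n >= 3")

    @property
    def diffs(self) -> np.ndarray:
        """Condition differences B - A."""
        return np.asarray(self.x_B, float) - np.asarray(self.x_A, float)

    @property
    def n(self) -> int:
        return len(self.x_A)


@dataclass(frozen=True)
class StatResult:
    method: Method
    statistic: float  # t for paired_t, z for wilcoxon
    df: int | None
    p_raw: float
    effect_size: float  # Cohen's dz or matched-pairs r, sign = direction of B - A
    effect_ci: tuple[float, float]
    direction: int  # sign of the B - A effect
    p_adjusted: float | None = None
    degenerate: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    ci: tuple[float, float]
    n: int


# ---------------------------------------------------------------------------
# effect sizes


def cohens_d_from_t(t: float, n: int) -> float:
    """Paired-design Cohen's dz = t / sqrt(n), sign preserved."""
    if n < 2:
        raise ConfigurationError("need n >= 2")
    return t / math.sqrt(n)


def r_from_z(z: float, n: int) -> float:
    """Matched-pairs rank effect size r = z / sqrt(n), sign preserved."""
    if n < 2:
        raise ConfigurationError("need n >= 2")
    return z / math.sqrt(n)


def _d_ci(d: float, n: int) -> tuple[float, float]:
    # normal-theory CI for dz: d +/- 1.96 * sqrt(1/n + d^2 / (2n))
    se = math.sqrt(1.0 / n + d * d / (2.0 * n))
    return (d - 1.96 * se, d + 1.96 * se)


def _r_ci(r: float, n: int) -> tuple[float, float]:
    half = 1.96 / math.sqrt(n)
    return (max(r - half, -1.0), min(r + half, 1.0))


# ---------------------------------------------------------------------------
# paired comparisons


def shapiro_route(sample: PairedSample, alpha: float = 0.05) -> Method:
    """Choose the paired test from Shapiro-Wilk normality of the differences.

    p >= alpha keeps the t test; otherwise, or when the differences are
    constant (Shapiro undefined), the Wilcoxon signed-rank test is used.
    """
    d = sample.diffs
    if np.ptp(d) == 0:
        return "wilcoxon"
    p = stats.shapiro(d).pvalue
    return "paired_t" if p >= alpha else "wilcoxon"


def paired_t(sample: PairedSample) -> StatResult:
    """Paired Student t test on B - A with dz effect size."""
    d = sample.diffs
    n = sample.n
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("constant paired differences; t undefined")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    dz = cohens_d_from_t(t, n)
    return StatResult(
        method="paired_t",
        statistic=float(t),
        df=n - 1,
        p_raw=float(p),
        effect_size=float(dz),
        effect_ci=_d_ci(dz, n),
        direction=int(np.sign(d.mean())),
    )


def wilcoxon_signed_rank(sample: PairedSample) -> StatResult:
    """Wilcoxon signed-rank test, normal approximation.

    Convention: zero differences dropped, tie-corrected variance, no
    continuity correction; z is signed so that positive z means B > A.
    The effect size is r = |z|/sqrt(n) carrying the direction's sign, with
    n the full number of pairs.
    """
    d = sample.diffs
    n_full = sample.n
    d = d[d != 0.0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    if var <= 0:
        raise DegenerateDataError("zero variance in signed ranks")
    z = (w_pos - mu) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    direction = int(np.sign(z)) if z != 0 else 0
    r = abs(r_from_z(z, n_full)) * (direction if direction != 0 else 1)
    if direction == 0:
        r = 0.0
    return StatResult(
        method="wilcoxon",
        statistic=float(z),
        df=None,
        p_raw=float(min(p, 1.0)),
        effect_size=float(r),
        effect_ci=_r_ci(r, n_full),
        direction=direction,
    )


def compare_paired(sample: PairedSample, alpha: float = 0.05) -> StatResult:
    """Normality-routed paired comparison.

    All-zero difference vectors yield p = 1 with a degenerate flag rather
    than an error: conservative, and keeps FDR across parallel tests
    well defined.
    """
    d = sample.diffs
    if np.all(d == 0):
        return StatResult(
            method="paired_t",
            statistic=0.0,
            df=sample.n - 1,
            p_raw=1.0,
            effect_size=0.0,
            effect_ci=(0.0, 0.0),
            direction=0,
            degenerate=True,
        )
    method = shapiro_route(sample, alpha=alpha)
    if method == "paired_t" and d.std(ddof=1) > 0:
        return paired_t(sample)
    return wilcoxon_signed_rank(sample)


# ---------------------------------------------------------------------------
# multiplicity, correlation, regression


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, reject


def spearman_corr(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Spearman rank correlation with two-tailed p and Fisher-transform CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ConfigurationError("need aligned 1-D samples with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("constant vector; correlation undefined")
    rho, p = stats.spearmanr(x, y)
    n = x.size
    if abs(rho) < 1.0:
        zr = np.arctanh(rho)
        half = 1.96 / math.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (float(rho), float(rho))
    return CorrelationResult(rho=float(rho), p=float(p), ci=ci, n=n)


def linear_regression(
    y: np.ndarray,
    predictors: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of ``y`` on named predictors with an intercept.

    Returns one row per term: unstandardized B with se, t, two-tailed p and
    95% CI; standardized beta (from the z-scored fit, intercept excluded);
    tolerance = 1 - R^2 of the predictor on the remaining predictors, and
    VIF = 1/tolerance.
    """
    y = np.asarray(y, float)
    X = predictors.astype(float)
    n, k = X.shape
    if n <= k + 1:
        raise ConfigurationError("need n > number of predictors + 1")
    design = np.column_stack([np.ones(n), X.to_numpy()])
    if np.linalg.matrix_rank(design) < k + 1:
        raise ConfigurationError(
            f"rank-deficient design; check columns {list(X.columns)}"
        )
    fit = OLS(y, design).fit()

    # standardized coefficients from the z-scored problem
    Xz = (X - X.mean()) / X.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    beta = OLS(yz, np.column_stack([np.ones(n), Xz.to_numpy()])).fit().params[1:]

    rows = [
        {
            "term": "(Constant)", "B": fit.params[0], "se": fit.bse[0],
            "beta": np.nan, "t": fit.tvalues[0], "p": fit.pvalues[0],
            "ci_lo": fit.conf_int()[0][0], "ci_hi": fit.conf_int()[0][1],
            "tolerance": np.nan, "vif": np.nan,
        }
    ]
    for j, name in enumerate(X.columns):
        others = X.drop(columns=[name])
        aux = OLS(
            X[name].to_numpy(),
            np.column_stack([np.ones(n), others.to_numpy()]),
        ).fit()
        tol = 1.0 - aux.rsquared
        rows.append(
            {
                "term": name, "B": fit.params[j + 1], "se": fit.bse[j + 1],
                "beta": beta[j], "t": fit.tvalues[j + 1], "p": fit.pvalues[j + 1],
                "ci_lo": fit.conf_int()[j + 1][0], "ci_hi": fit.conf_int()[j + 1][1],
                "tolerance": tol, "vif": np.inf if tol == 0 else 1.0 / tol,
            }
        )
    return pd.DataFrame(rows)


def paired_table(
    samples: dict[str, PairedSample],
    alpha: float = 0.05,
    q: float | None = None,
) -> pd.DataFrame:
    """Routed paired comparisons for a family of named outcomes.

    With ``q`` set, BH-FDR adjusts across the family (the nodal/target
    convention); without, raw p-values stand (the global-metric convention,
    flagged exploratory).
    """
    rows = []
    for name, sample in samples.items():
        res = compare_paired(sample, alpha=alpha)
        rows.append(
            {
                "outcome": name, "method": res.method, "statistic": res.statistic,
                "df": res.df, "p_raw": res.p_raw, "effect_size": res.effect_size,
                "ci_lo": res.effect_ci[0], "ci_hi": res.effect_ci[1],
                "direction": res.direction,
            }
        )
    table = pd.DataFrame(rows)
    if q is not None:
        adjusted, signif = bh_fdr(table["p_raw"].to_numpy(), q=q)
        table["p_fdr"] = adjusted
        table["significant"] = signif
    else:
        table["exploratory"] = True
    return table


def spearman_table(
    pairs: Sequence[tuple[str, str, np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Spearman correlations for (metric name, behavior name, x, y) tuples."""
    rows = []
    for metric, behavior, x, y in pairs:
        res = spearman_corr(x, y)
        rows.append(
            {
                "network_attribute": metric, "behavior": behavior,
                "rho": res.rho, "p": res.p,
                "ci_lo": res.ci[0], "ci_hi": res.ci[1], "n": res.n,
                "exploratory": True,
            }
        )
    return pd.DataFrame(rows)
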