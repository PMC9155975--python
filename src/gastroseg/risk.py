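"""Recurrence risk-factor statistics: cross-tabs, chi-square, odds ratios, logistic.

The clinical question: which categorical covariates (age ≥ 60, tumor diameter
≥ 6 cm, TNM stage III/IV, chemotherapy, sex, tumor location) are associated
with post-operative recurrence?  Tables are oriented with rows =
(recurrence, no-recurrence) and columns = (factor level 1, level 0), where
"level 1" is the at-risk category of each factor; tumor location is a 2×3
table.

Chi-square uses the closed-form 2×2 Pearson statistic
n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d)) without continuity correction by default
(all published expected counts exceed 5); Yates correction is available by
flag.  Odds ratios are ad/bc with a Woolf (log-normal) 95% CI and the
Haldane–Anscombe +0.5 correction when a cell is empty.  The logistic model is
an ordinary maximum-likelihood fit with Wald statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from scipy import stats

from gastroseg.phantoms import PatientRecord

__all__ = [
    "ContingencyTable2x2",
    "RiskResult",
    "LogisticResult",
    "PerfectSeparationError",
    "FACTOR_LEVELS",
    "crosstab",
    "crosstab_location",
    "proportions",
    "chi_square",
    "odds_ratio",
    "logistic_fit",
    "logistic_fit_xy",
    "analyze",
]

#: For each binary factor: (record field, at-risk "level 1" value, level-0 value).
FACTOR_LEVELS: dict[str, tuple[str, object, object]] = {
    "age": ("age_group", "ge60", "under60"),
    "sex": ("sex", "male", "female"),
    "diameter": ("diameter_group", "ge6cm", "lt6cm"),
    "tnm": ("tnm_group", "III_IV", "I_II"),
    "chemo": ("chemo", True, False),
}

_LOCATION_LEVELS = ("esophagogastric", "distal", "whole")


class PerfectSeparationError(RuntimeError):
    """A covariate perfectly separates the outcomes; the MLE does not exist."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a..d: rows (recurrence, no-recurrence) × columns (level 1, level 0)."""

    a: int  # recurrence, level 1
    b: int  # recurrence, level 0
    c: int  # no recurrence, level 1
    d: int  # no recurrence, level 0
    factor: str = ""

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class RiskResult:
    """Univariate association of one factor with recurrence."""

    factor: str
    chi_square: float
    p_value: float
    odds_ratio: float
    ci95: tuple[float, float]
    proportions: dict[str, dict[str, float]]


@dataclass(frozen=True)
class LogisticResult:
    """One coefficient of a logistic fit with its Wald inference."""

    factor: str
    coefficient: float
    std_error: float
    wald_statistic: float
    p_value: float
    ci95: tuple[float, float]


def crosstab(records: Sequence[PatientRecord], factor: str) -> ContingencyTable2x2:
    """2×2 cross-tabulation of a binary factor against recurrence."""
    if len(records) == 0:
        raise ValueError("no records")
    if factor not in FACTOR_LEVELS:
        raise ValueError(
            f"unknown factor {factor!r}; binary factors: {sorted(FACTOR_LEVELS)} "
            "(use crosstab_location for tumor location)"
        )
    field, level1, _ = FACTOR_LEVELS[factor]
    a = b = c = d = 0
    for r in records:
        hit = getattr(r, field) == level1
        if r.recurrence:
            a, b = a + hit, b + (not hit)
        else:
            c, d = c + hit, d + (not hit)
    return ContingencyTable2x2(a, b, c, d, factor=factor)


def crosstab_location(records: Sequence[PatientRecord]) -> np.ndarray:
    """2×3 table: rows (recurrence, no-recurrence) × location categories."""
    if len(records) == 0:
        raise ValueError("no records")
    out = np.zeros((2, 3), dtype=int)
    for r in records:
        out[0 if r.recurrence else 1, _LOCATION_LEVELS.index(r.location)] += 1
    return out


def _pct(num: int, den: int) -> float:
    """Percentage rounded half-up to two decimals (as clinical tables print)."""
    if den == 0:
        return 0.0
    exact = Decimal(num) * 100 / Decimal(den)
    return float(exact.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def proportions(table: ContingencyTable2x2) -> dict[str, dict[str, float]]:
    """Per-arm row percentages (two decimals, round-half-up).

    Keys: arm → {"level1": %, "level0": %}; each row sums to 100 up to the
    rounding of its two cells.
    """
    n_rec = table.a + table.b
    n_no = table.c + table.d
    return {
        "recurrence": {"level1": _pct(table.a, n_rec), "level0": _pct(table.b, n_rec)},
        "no_recurrence": {"level1": _pct(table.c, n_no), "level0": _pct(table.d, n_no)},
    }


def chi_square(
    table: ContingencyTable2x2 | np.ndarray, continuity_correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value for a 2×2 (or 2×k) table.

    2×2 without correction uses the closed form
    n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with 1 df; wider tables use the general
    Pearson statistic with (k−1) df.  A zero row or column margin makes the
    test undefined and raises ValueError.
    """
    arr = table.as_array() if isinstance(table, ContingencyTable2x2) else np.asarray(table, float)
    if arr.sum() == 0:
        raise ValueError("empty table")
    if (arr.sum(axis=1) == 0).any() or (arr.sum(axis=0) == 0).any():
        raise ValueError("a zero margin makes the chi-square test undefined")
    if arr.shape == (2, 2) and not continuity_correction:
        (a, b), (c, d) = arr
        n = arr.sum()
        stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d)) / ((a + c) * (b + d))
        return float(stat), float(stats.chi2.sf(stat, df=1))
    stat, p, _, _ = stats.chi2_contingency(arr, correction=continuity_correction)
    return float(stat), float(p)


def odds_ratio(table: ContingencyTable2x2) -> tuple[float, tuple[float, float]]:
    """Odds ratio ad/bc with Woolf 95% CI.

    Applies the Haldane–Anscombe +0.5 continuity correction to every cell when
    any cell is zero.
    """
    a, b, c, d = float(table.a), float(table.b), float(table.c), float(table.d)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(oratio) - 1.959963984540054 * se))
    hi = float(np.exp(np.log(oratio) + 1.959963984540054 * se))
    return float(oratio), (lo, hi)


def logistic_fit_xy(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    penalized: bool = False,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> list[LogisticResult]:
    """Maximum-likelihood logistic regression of y on X (intercept added).

    Plain Newton/IRLS fit with convergence at max coefficient change < ``tol``;
    Wald statistics from the observed-information covariance.  Perfect (or
    quasi-) separation is detected from exploding coefficients and raises
    :class:`PerfectSeparationError`; ``penalized=True`` falls back to an
    L2-regularized fit (no p-values are invalidated on purpose — standard
    ridge-logistic Wald inference is reported).
    """
    import statsmodels.api as sm

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 records per outcome class")
    Xd = sm.add_constant(X, has_constant="add")

    if penalized:
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        params = np.concatenate(([clf.intercept_[0]], clf.coef_[0]))
        # Wald covariance from the penalized information matrix
        p = 1 / (1 + np.exp(-(Xd @ params)))
        W = p * (1 - p)
        info = Xd.T @ (W[:, None] * Xd) + np.eye(Xd.shape[1]) / 1.0
        cov = np.linalg.inv(info)
        bse = np.sqrt(np.diag(cov))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, Xd).fit(disp=0, method="newton", tol=tol, maxiter=maxiter)
            except Exception as exc:  # statsmodels raises on hard separation
                raise PerfectSeparationError(
                    f"logistic MLE failed ({exc}); retry with penalized=True"
                ) from exc
        params, bse = res.params, res.bse
        if not np.all(np.isfinite(bse)) or np.any(np.abs(params[1:]) > 20):
            raise PerfectSeparationError(
                "coefficients diverged (perfect separation); retry with penalized=True"
            )

    out = []
    z = 1.959963984540054
    for i, name in enumerate(names):
        beta, se = float(params[i + 1]), float(bse[i + 1])
        wald = (beta / se) ** 2 if se > 0 else np.inf
        pval = float(stats.chi2.sf(wald, df=1))
        out.append(
            LogisticResult(
                factor=name,
                coefficient=beta,
                std_error=se,
                wald_statistic=float(wald),
                p_value=pval,
                ci95=(beta - z * se, beta + z * se),
            )
        )
    return out


def logistic_fit(
    records: Sequence[PatientRecord],
    factors: Sequence[str],
    penalized: bool = False,
) -> list[LogisticResult]:
    """Multivariate logistic regression of recurrence on binary factors.

    Factors are coded 1 at their at-risk level (see :data:`FACTOR_LEVELS`).
    """
    bad = [f for f in factors if f not in FACTOR_LEVELS]
    if bad:
        raise ValueError(f"unknown factors {bad}; choose from {sorted(FACTOR_LEVELS)}")
    X = np.zeros((len(records), len(factors)))
    y = np.array([1.0 if r.recurrence else 0.0 for r in records])
    for j, f in enumerate(factors):
        field, level1, _ = FACTOR_LEVELS[f]
        X[:, j] = [1.0 if getattr(r, field) == level1 else 0.0 for r in records]
    return logistic_fit_xy(X, y, names=list(factors), penalized=penalized)


def analyze(
    records: Sequence[PatientRecord],
    factors: Sequence[str] = ("age", "sex", "diameter", "tnm", "chemo"),
    continuity_correction: bool = False,
) -> list[RiskResult]:
    """Univariate screen: chi-square + odds ratio + proportions per factor."""
    out = []
    for f in factors:
        t = crosstab(records, f)
        stat, p = chi_square(t, continuity_correction)
        oratio, ci = odds_ratio(t)
        out.append(
            RiskResult(
                factor=f,
                chi_square=stat,
                p_value=p,
                odds_ratio=oratio,
                ci95=ci,
                proportions=proportions(t),
            )
        )
    return out
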