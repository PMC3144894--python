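"""Adult-lifetime metric averaging and randomization regressions of longevity.

Each individual that died as an adult contributes one panel row: its
age at death and its group-level network metrics averaged over every
year from age two to death.  Because age at death is not normally
distributed, regression p-values come from a randomization test
(permuting the response and refitting).  Residual regression removes
the effect of group size or observation effort before a focal
predictor, and a fixed-effects group term checks robustness to
within-group dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import stats

from .errors import ConfigError, DegenerateInputError, DomainError

__all__ = [
    "LifeRecord",
    "RegressionResult",
    "average_adult_metrics",
    "fit_ols",
    "randomization_regression",
    "residual_control",
    "group_effect_model",
    "aggression_rate",
]


@dataclass
class LifeRecord:
    """Per-individual longevity row: one entry per adult year.

    ``yearly`` maps year label -> dict with keys ``group``,
    ``group_size`` and one entry per metric name; ``adult_years`` lists
    (year, age) pairs for ages >= 2.
    """

    individual_id: str
    sex: str
    age_at_death_years: float
    yearly: dict = field(default_factory=dict)
    adult_years: list = field(default_factory=list)

    def __post_init__(self):
        if self.age_at_death_years <= 0:
            raise DomainError("age at death must be positive")


def average_adult_metrics(record: LifeRecord, metric: str) -> float:
    """Mean of a metric over the record's adult years (ages 2..death).

    Years in which the metric is missing are skipped with a warning; a
    record with no adult year carrying the metric raises
    :class:`DegenerateInputError` (the individual is excluded).
    """
    values = []
    missing = []
    for year, _age in record.adult_years:
        entry = record.yearly.get(year, {})
        if metric in entry and entry[metric] is not None and not (
            isinstance(entry[metric], float) and np.isnan(entry[metric])
        ):
            values.append(entry[metric])
        else:
            missing.append(year)
    if not values:
        raise DegenerateInputError(
            f"{record.individual_id}: no adult year with metric {metric!r}"
        )
    if missing:
        warnings.warn(
            f"{record.individual_id}: metric {metric!r} missing in years {missing}; "
            "averaging the available years",
            stacklevel=2,
        )
    return float(np.mean(values))


def _design(x, add_intercept: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if add_intercept:
        x = np.column_stack([np.ones(len(x)), x])
    return x


def fit_ols(y, x, add_intercept: bool = True) -> tuple[np.ndarray, float]:
    """Ordinary least squares: returns (slopes excluding intercept, r^2).

    Raises on a rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    X = _design(x, add_intercept)
    n, p = X.shape
    if n <= p - (1 if add_intercept else 0):
        raise DegenerateInputError(f"need n > number of parameters ({n} rows, {p} columns)")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name a dependent column: the first whose removal restores full rank
        bad = [
            j for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DomainError(f"rank-deficient design; collinear column indices {bad}")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    slopes = beta[1:] if add_intercept else beta
    return slopes, r2


@dataclass
class RegressionResult:
    slope: float
    r_squared: float
    p_randomization: float
    n_permutations: int
    n: int
    tail: str = "two"


def randomization_regression(
    y,
    x,
    n_perm: int = 10_000,
    tail: str = "two",
    rng: np.random.Generator | int | None = None,
) -> RegressionResult:
    """Simple regression with a Manly-style randomization p-value.

    The response is permuted ``n_perm`` times and the slope refit; the
    p-value is (count of permuted slopes at least as extreme + 1) /
    (n_perm + 1).  ``tail`` is "two" (|slope|, default), "lower" or
    "upper".
    """
    if n_perm < 100:
        raise ConfigError("n_perm must be at least 100")
    if tail not in ("two", "lower", "upper"):
        raise ConfigError("tail must be 'two', 'lower' or 'upper'")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.ndim != 1 or x.ndim != 1 or len(y) != len(x):
        raise ConfigError("y and x must be 1-D and the same length")
    n = len(y)
    if n < 5:
        raise DegenerateInputError("randomization regression needs n >= 5")
    rng = np.random.default_rng(rng)

    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise DomainError("predictor is constant")
    yc = y - y.mean()
    syy = float(yc @ yc)
    slope = float(xc @ yc) / sxx
    r2 = (slope * slope * sxx / syy) if syy > 0 else 0.0

    # all permutations at once: slope_perm = xc . y_perm / sxx
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = rng.permutation(y)
    null_slopes = (perms - perms.mean(axis=1, keepdims=True)) @ xc / sxx
    if tail == "two":
        count = int(np.sum(np.abs(null_slopes) >= abs(slope) - 1e-15))
    elif tail == "lower":
        count = int(np.sum(null_slopes <= slope + 1e-15))
    else:
        count = int(np.sum(null_slopes >= slope - 1e-15))
    p = (count + 1) / (n_perm + 1)
    return RegressionResult(
        slope=slope, r_squared=float(r2), p_randomization=float(p),
        n_permutations=n_perm, n=n, tail=tail,
    )


def residual_control(y, controls) -> np.ndarray:
    """Residuals of y after OLS on the control design (with intercept).

    The standard device for removing group size / observation effort
    before testing a focal predictor; residuals sum to zero.
    """
    y = np.asarray(y, dtype=float)
    X = _design(controls, add_intercept=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DomainError("control design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


@dataclass
class GroupEffectResult:
    f_predictor: float
    df_predictor: tuple[int, int]
    p_predictor: float
    f_group: float
    df_group: tuple[int, int]
    p_group: float
    r_squared: float


def group_effect_model(y, predictor, group_labels) -> GroupEffectResult:
    """Fixed-effects check for within-group dependence.

    Fits y ~ predictor + group indicators and reports partial F tests
    for each term against the full model's residual.  (The group term
    plays the role of a random effect evaluated by its F statistic; the
    indicator parameterization reproduces the same F_{g-1, n-g-1}-style
    test without a mixed-model fit.)  Groups with a single member are
    retained with a warning.
    """
    y = np.asarray(y, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    labels = np.asarray(group_labels)
    groups = sorted(set(labels.tolist()), key=str)
    g = len(groups)
    if g < 2:
        raise DegenerateInputError("group effect model requires >= 2 groups")
    n = len(y)
    if n <= g + 2:
        raise DegenerateInputError("too few rows for the number of groups")
    for grp in groups:
        if int(np.sum(labels == grp)) == 1:
            warnings.warn(f"group {grp!r} has a single member; retained", stacklevel=2)

    dummies = np.column_stack([(labels == grp).astype(float) for grp in groups[1:]])
    X_full = np.column_stack([np.ones(n), predictor, dummies])

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    sse_full = sse(X_full)
    df_resid = n - X_full.shape[1]
    sst = float(np.sum((y - y.mean()) ** 2))

    sse_no_pred = sse(np.column_stack([np.ones(n), dummies]))
    f_pred = ((sse_no_pred - sse_full) / 1) / (sse_full / df_resid)
    p_pred = float(stats.f.sf(f_pred, 1, df_resid))

    sse_no_grp = sse(np.column_stack([np.ones(n), predictor]))
    df_grp = g - 1
    f_grp = ((sse_no_grp - sse_full) / df_grp) / (sse_full / df_resid)
    p_grp = float(stats.f.sf(f_grp, df_grp, df_resid))

    return GroupEffectResult(
        f_predictor=float(f_pred), df_predictor=(1, df_resid), p_predictor=p_pred,
        f_group=float(f_grp), df_group=(df_grp, df_resid), p_group=p_grp,
        r_squared=1.0 - sse_full / sst if sst > 0 else 0.0,
    )


def aggression_rate(counts, group_size, observed_days, level: str = "individual") -> np.ndarray:
    """Aggression rates controlled for group size and observation effort.

    The rate is the residual from OLS of agonistic-day counts on group
    size and days observed (with intercept): positive values mean more
    aggression than expected for that group size and effort.  ``level``
    is recorded only for bookkeeping ("individual" or "group").
    """
    if level not in ("individual", "group"):
        raise ConfigError("level must be 'individual' or 'group'")
    counts = np.asarray(counts, dtype=float)
    group_size = np.asarray(group_size, dtype=float)
    observed_days = np.asarray(observed_days, dtype=float)
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    if np.any(observed_days <= 0):
        raise DomainError("observed days must be positive")
    if not np.any(counts):
        return np.zeros_like(counts)
    return residual_control(counts, np.column_stack([group_size, observed_days]))
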