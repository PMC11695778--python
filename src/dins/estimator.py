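"""Plug-in estimation of the DINS measure zeta.

The measure compares the ordinary-least-squares prediction-error variance
of one device regressed on the other against the combined repeatability
variance of the pair,

    zeta = Var(y_new - y_hat) / (sigma_Y^2 + beta1^2 * sigma_X^2),

and equals 1 when the two devices differ only by their analytical noise.
Values above 1 quantify excess disagreement: differences in nonselectivity
(DINS).  The plug-in estimator replaces the numerator by the mean estimated
prediction-error variance over the observed design, S_P^2 = S^2*(nR+2)/nR,
and the denominator by pooled within-sample replicate variances and the
OLS slope.

All computations are unit-agnostic ratios; scaling both devices by a
common positive constant leaves the estimate unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import (
    ComparisonData,
    DegenerateDesignError,
    DomainError,
    InsufficientReplicationError,
)

__all__ = [
    "DinsEstimate",
    "pooled_within_sample_variance",
    "assign_roles",
    "fit_ols",
    "prediction_error_variance",
    "zeta_full",
    "zeta_simplified",
    "simplified_form_applicable",
    "zeta_batch",
]


@dataclass(frozen=True)
class DinsEstimate:
    """The estimate zeta-hat together with all of its ingredients."""

    zeta: float
    s2: float
    sp2: float
    var_x_pooled: float
    var_y_pooled: float
    beta1_hat: float
    beta0_hat: float
    roles_swapped: bool
    form: str  # "full" or "simplified"
    n_pairs: int

    def __post_init__(self) -> None:
        if self.zeta < 0 or self.s2 < 0:
            raise DomainError("zeta and S^2 must be non-negative")


def pooled_within_sample_variance(
    sample_ids: np.ndarray, values: np.ndarray
) -> float:
    """Pooled within-sample replicate variance of one device.

    The mean over samples of the per-sample unbiased replicate variance,
    (1/n) * sum_i (1/(R_i-1)) * sum_r (x_ir - xbar_i)^2.  Samples with
    fewer than two non-missing replicates carry no information about the
    repeatability and are skipped; the mean runs over contributing samples.
    """
    values = np.asarray(values, float)
    ok = np.isfinite(values)
    ids, inv = np.unique(np.asarray(sample_ids), return_inverse=True)
    counts = np.bincount(inv[ok], minlength=len(ids))
    use = counts >= 2
    if not use.any():
        raise InsufficientReplicationError(
            "pooled variance needs a sample with >= 2 non-missing replicates"
        )
    sums = np.bincount(inv[ok], weights=values[ok], minlength=len(ids))
    sqsums = np.bincount(inv[ok], weights=values[ok] ** 2, minlength=len(ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        ss = sqsums[use] - sums[use] ** 2 / counts[use]
        per_sample = ss / (counts[use] - 1)
    # guard tiny negative round-off on constant replicates
    per_sample = np.maximum(per_sample, 0.0)
    return float(per_sample.mean())


def assign_roles(data: ComparisonData) -> tuple[ComparisonData, bool]:
    """Make the device with the smaller pooled variance the predictor.

    OLS slope estimates attenuate when the predictor carries measurement
    error, so the less noisy device should sit on the x-axis.  If the
    pooled variance of x exceeds that of y the two devices are
    interchanged; exact ties keep the user-given order.
    """
    vx = pooled_within_sample_variance(data.sample_ids, data.x)
    vy = pooled_within_sample_variance(data.sample_ids, data.y)
    if vx > vy:
        return data.swapped(), True
    return data, False


def fit_ols(data: ComparisonData) -> tuple[float, float, float]:
    """OLS fit of y on x over all complete pairs.

    Returns
    -------
    (beta0_hat, beta1_hat, s2)
        Intercept, slope and the residual variance estimator
        S^2 = RSS / (nR - 2), with nR the number of complete pairs.
    """
    ok = np.isfinite(data.x) & np.isfinite(data.y)
    x, y = data.x[ok], data.y[ok]
    m = x.size
    if m < 3:
        raise DegenerateDesignError("OLS needs >= 3 complete (x, y) pairs")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateDesignError("constant predictor: OLS slope undefined")
    sxy = float(((x - xm) * (y - ym)).sum())
    b1 = sxy / sxx
    b0 = ym - b1 * xm
    rss = float(((y - b0 - b1 * x) ** 2).sum())
    s2 = rss / (m - 2)
    return b0, b1, s2


def prediction_error_variance(s2: float, n_pairs: int) -> float:
    """Mean estimated prediction-error variance S_P^2 = S^2 * (nR + 2) / nR.

    Averaging the pointwise OLS prediction-error variance over the nR
    observed design points collapses to this closed form.
    """
    return s2 * (n_pairs + 2) / n_pairs


def _zeta(data: ComparisonData, form: str, do_assign_roles: bool) -> DinsEstimate:
    swapped = False
    if do_assign_roles:
        data, swapped = assign_roles(data)
    vx = pooled_within_sample_variance(data.sample_ids, data.x)
    vy = pooled_within_sample_variance(data.sample_ids, data.y)
    if vx == 0.0 and vy == 0.0:
        raise DomainError("both pooled variances are zero: zeta undefined")
    b0, b1, s2 = fit_ols(data)
    ok = np.isfinite(data.x) & np.isfinite(data.y)
    n_pairs = int(ok.sum())
    sp2 = prediction_error_variance(s2, n_pairs)
    if form == "full":
        denom = vy + b1**2 * vx
    elif form == "simplified":
        denom = vx + vy
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown estimator form {form!r}")
    return DinsEstimate(
        zeta=sp2 / denom,
        s2=s2,
        sp2=sp2,
        var_x_pooled=vx,
        var_y_pooled=vy,
        beta1_hat=b1,
        beta0_hat=b0,
        roles_swapped=swapped,
        form=form,
        n_pairs=n_pairs,
    )


def zeta_full(data: ComparisonData, do_assign_roles: bool = True) -> DinsEstimate:
    """The full plug-in estimator zeta-hat = S_P^2 / (var_y + b1^2 var_x).

    This is the default form; it stays accurate when the fitted slope
    deviates from 1.
    """
    return _zeta(data, "full", do_assign_roles)


def zeta_simplified(data: ComparisonData, do_assign_roles: bool = True) -> DinsEstimate:
    """The simplified estimator zeta-hat = S_P^2 / (var_x + var_y).

    Assumes the slope is close to 1; see :func:`simplified_form_applicable`
    for the advisory rule of thumb.  Biased upward for slopes below 1 and
    downward for slopes above 1.
    """
    return _zeta(data, "simplified", do_assign_roles)


def simplified_form_applicable(beta1_hat: float, cv_x: float, cv_y: float) -> bool:
    """Rule of thumb for when the simplified form is acceptable.

    True iff the fitted slope lies in [0.75, 1.25], or it lies in the
    wider band [0.5, 2] while the CV ratio cv_y/cv_x is <= 1/4 or >= 4.
    The narrow band keeps the average relative discrepancy between the
    two estimator forms under about 20%.
    """
    if cv_x <= 0 or cv_y <= 0:
        raise DomainError("device CVs must be positive")
    if 0.75 <= beta1_hat <= 1.25:
        return True
    ratio = cv_y / cv_x
    return 0.5 <= beta1_hat <= 2.0 and (ratio <= 0.25 or ratio >= 4.0)


# -- vectorized engine --------------------------------------------------------


def zeta_batch(
    x: np.ndarray,
    y: np.ndarray,
    form: str = "full",
    do_assign_roles: bool = True,
) -> np.ndarray:
    """zeta-hat for a batch of balanced, complete datasets.

    Parameters
    ----------
    x, y
        Arrays of shape ``(batch, n, R)``: per-dataset measurements with n
        samples and R replicates and no missing cells.
    form
        "full" (slope-aware denominator) or "simplified".
    do_assign_roles
        Re-assign predictor/response per dataset from the pooled variances.

    This is the computational core behind the Monte Carlo simulator and
    the cluster bootstrap; it agrees with :func:`zeta_full` /
    :func:`zeta_simplified` to floating-point accuracy on any single
    dataset (see the test suite's equivalence property).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 3 or x.shape != y.shape:
        raise ValueError("x and y must both have shape (batch, n, R)")
    batch, n, R = x.shape
    if R < 2:
        raise InsufficientReplicationError("batch engine needs R >= 2")
    nR = n * R
    if nR < 3:
        raise DegenerateDesignError("OLS needs >= 3 pairs")
    vx = x.var(axis=2, ddof=1).mean(axis=1)
    vy = y.var(axis=2, ddof=1).mean(axis=1)
    if do_assign_roles:
        swap = vx > vy
        sw = swap[:, None, None]
        x, y = np.where(sw, y, x), np.where(sw, x, y)
        vx, vy = np.where(swap, vy, vx), np.where(swap, vx, vy)
    X = x.reshape(batch, nR)
    Y = y.reshape(batch, nR)
    xc = X - X.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", xc, xc)
    sxy = np.einsum("ij,ij->i", xc, yc)
    syy = np.einsum("ij,ij->i", yc, yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = sxy / sxx
        s2 = np.maximum(syy - b1 * sxy, 0.0) / (nR - 2)
        sp2 = s2 * (nR + 2) / nR
        denom = (vy + b1**2 * vx) if form == "full" else (vx + vy)
        return sp2 / denom
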