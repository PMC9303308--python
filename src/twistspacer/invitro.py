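"""Analysis of in vitro sigma-titration transcription data.

Activities of spacer-length mutant promoters measured across a range of
superhelical densities are normalized, at each sigma, by the reference
(17-nt) mutant.  The normalized log-ratios fall on lines in sigma whose
slopes are fixed by the DNA torsional stiffness -- proportional to
``n - n_ref`` with no free parameter -- so only the vertical intercept
``Q_sp`` is promoter-specific and fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, MissingReferenceError
from .torsion import (
    DEFAULT_PARAMS,
    TwistParameters,
    log_relative_expression,
    relative_expression_slope,
)

__all__ = [
    "REQUIRED_COLUMNS",
    "read_invitro_tsv",
    "normalize_to_reference",
    "fit_intercept",
    "slope_consistency_test",
    "InterceptFit",
    "SlopeTest",
]

REQUIRED_COLUMNS = ("promoter_id", "sigma", "spacer_len", "activity")


def read_invitro_tsv(path) -> pd.DataFrame:
    """Read an in vitro activity table (TSV) and validate its columns."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"in vitro table is missing columns {missing}")
    if (df["activity"] <= 0).any():
        raise ValueError("activities must be > 0")
    return df


def normalize_to_reference(
    data: pd.DataFrame,
    n_ref: int = 17,
    sigma_tol: float = 0.0,
) -> pd.DataFrame:
    """Log-ratio of each activity to the reference spacer at the same sigma.

    For every sigma in the data, the reference activity is the geometric mean
    of the ``n_ref`` measurements at that sigma (exact match by default;
    ``sigma_tol > 0`` allows nearest-sigma matching for digitized data).
    Reference points map to exactly zero when unreplicated.

    Returns the input frame with a ``log_ratio`` column added, reference rows
    included.

    Raises
    ------
    MissingReferenceError
        If any sigma has no reference measurement, listing the sigma values.
    """
    df = data.copy()
    ref = df[df["spacer_len"] == n_ref]
    if ref.empty:
        raise MissingReferenceError(
            f"no measurement with the reference spacer length {n_ref}"
        )
    # geometric-mean reference activity per sigma
    ref_by_sigma = (
        np.log(ref["activity"]).groupby(ref["sigma"]).mean().rename("log_ref")
    )
    ref_sigmas = ref_by_sigma.index.to_numpy(dtype=float)

    sigmas = df["sigma"].to_numpy(dtype=float)
    idx = np.abs(sigmas[:, None] - ref_sigmas[None, :]).argmin(axis=1)
    dist = np.abs(sigmas - ref_sigmas[idx])
    unmatched = dist > sigma_tol + 1e-12
    if unmatched.any():
        bad = sorted(set(np.round(sigmas[unmatched], 6)))
        raise MissingReferenceError(
            f"no reference ({n_ref}-nt) measurement at sigma values {bad}"
        )
    df["log_ratio"] = np.log(df["activity"].to_numpy()) - ref_by_sigma.to_numpy()[idx]
    return df


@dataclass(frozen=True)
class InterceptFit:
    """Fitted sigma-independent offset Q_sp (k_B*T) for one spacer length."""

    spacer_len: int
    q_sp: float
    se: float
    ci95: tuple[float, float]
    n_points: int


def fit_intercept(
    points: pd.DataFrame,
    params: TwistParameters = DEFAULT_PARAMS,
) -> InterceptFit:
    """Estimate Q_sp for one spacer length, holding the model slope fixed.

    The parameter-free orientational part of the log-ratio is subtracted from
    each point; the residual mean is the Q_sp estimate, with a Student 95% CI.
    The slope is *not* fitted.
    """
    lengths = points["spacer_len"].unique()
    if len(lengths) != 1:
        raise ValueError("fit_intercept expects points for a single spacer length")
    n = int(lengths[0])
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >= 2 points to fit an intercept, got {len(points)}"
        )
    predicted = log_relative_expression(points["sigma"].to_numpy(), n, params=params)
    resid = points["log_ratio"].to_numpy() - np.asarray(predicted)
    q = float(resid.mean())
    se = float(resid.std(ddof=1) / np.sqrt(len(resid)))
    tcrit = stats.t.ppf(0.975, len(resid) - 1)
    return InterceptFit(
        spacer_len=n,
        q_sp=q,
        se=se,
        ci95=(q - tcrit * se, q + tcrit * se),
        n_points=len(resid),
    )


@dataclass(frozen=True)
class SlopeTest:
    """Free-slope fit versus the parameter-free predicted slope."""

    spacer_len: int
    fitted_slope: float
    fitted_se: float
    predicted_slope: float
    predicted_slope_linearized: float
    z: float
    p_value: float
    n_points: int


def slope_consistency_test(
    points: pd.DataFrame,
    params: TwistParameters = DEFAULT_PARAMS,
) -> SlopeTest:
    """OLS slope of log-ratio on sigma, compared with the model prediction.

    The prediction carries no adjustable parameter: the exact derivative
    ``-k_theta*alpha0**2*(n - n_ref)*(1 + sigma)`` evaluated at the mean sigma
    of the points; the pure linearized constant is reported alongside.  The
    compatibility z-statistic is ``(fitted - predicted) / SE``.
    """
    lengths = points["spacer_len"].unique()
    if len(lengths) != 1:
        raise ValueError("slope_consistency_test expects a single spacer length")
    n = int(lengths[0])
    if len(points) < 3:
        raise InsufficientDataError(
            f"need >= 3 points for a slope fit, got {len(points)}"
        )
    x = sm.add_constant(points["sigma"].to_numpy())
    fit = sm.OLS(points["log_ratio"].to_numpy(), x).fit()
    fitted, se = float(fit.params[1]), float(fit.bse[1])
    predicted = relative_expression_slope(
        n, params, linearized=False, sigma=float(points["sigma"].mean())
    )
    linearized = relative_expression_slope(n, params, linearized=True)
    diff = fitted - predicted
    if se > 0:
        z = diff / se
    elif abs(diff) < 1e-10:
        z = 0.0
    else:
        z = np.inf if diff > 0 else -np.inf
    p = float(2 * stats.norm.sf(abs(z)))
    return SlopeTest(
        spacer_len=n,
        fitted_slope=fitted,
        fitted_se=se,
        predicted_slope=float(predicted),
        predicted_slope_linearized=float(linearized),
        z=float(z),
        p_value=p,
        n_points=len(points),
    )
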