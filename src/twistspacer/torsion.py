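"""Torsional-elasticity model of spacer orientation during closed-complex formation.

The spacer between the -35 and -10 hexamers of a sigma70 promoter must be
twisted so that both hexamers present RNA polymerase with its preferred
relative angle ``theta_P`` before the closed complex can form.  Treating the
spacer as ``n`` harmonic basepair steps of twist stiffness ``k_theta`` whose
relaxed twist is modulated by the superhelical density sigma, the elastic
cost of that alignment is

    dG_or(sigma, n) = (n / 2) * k_theta * (theta_P / n - alpha0 * (1 + sigma))**2

in units of k_B*T.  This single coupled term in (sigma, n) drives every
prediction in this package: relative expression of spacer-length mutants
across a sigma titration, fold-changes under superhelical shocks, and the
genome-scale selectivity of promoters by spacer length.

All angles are stored internally in radians; constructors and accessors that
carry ``_deg`` in their name convert at the boundary.  Natural logarithms are
used for every log fold-change.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEG",
    "TwistParameters",
    "PromoterEnergyTerms",
    "ShockCondition",
    "default_theta_p",
    "orientational_energy",
    "transcription_rate",
    "log_relative_expression",
    "relative_expression_slope",
    "logfc_under_shock",
    "spacer_logfc_difference",
    "DEFAULT_PARAMS",
]

#: radians per degree
DEG = math.pi / 180.0

#: DNA sequence-averaged twist stiffness, k_B*T per rad^2 per basepair step
K_THETA_DEFAULT = 71.4
#: mean twist angle between adjacent basepairs, degrees
ALPHA0_DEG_DEFAULT = 34.0
#: spacer length at which promoter activity peaks, nucleotides
N_REF_DEFAULT = 17
#: superhelical density at which the reference spacer is optimally phased
SIGMA_REF_DEFAULT = -0.06

#: model validity window for the spacer length, nucleotides
SPACER_VALID_RANGE = (15, 19)
#: hard domain bounds for the spacer length
SPACER_DOMAIN = (1, 30)


class SpacerRangeWarning(UserWarning):
    """Spacer length outside the 15-19 nt window where the model is tested."""


def default_theta_p(
    n_opt: float = N_REF_DEFAULT,
    sigma_opt: float = SIGMA_REF_DEFAULT,
    alpha0: float = ALPHA0_DEG_DEFAULT * DEG,
) -> float:
    """Optimal RNAP twist angle making spacer ``n_opt`` strain-free at ``sigma_opt``.

    Returns ``n_opt * alpha0 * (1 + sigma_opt)`` in radians.  With the default
    17-nt spacer at sigma = -0.06 and alpha0 = 34 deg this is 543.32 deg
    (conventionally quoted as 543 deg).  Most downstream predictions -- all
    slopes and fold-change differences -- are independent of this value.

    Parameters
    ----------
    n_opt : float
        Spacer length (nt) that should be optimally phased; must be >= 1.
    sigma_opt : float
        Superhelical density at which ``n_opt`` is optimal.
    alpha0 : float
        Mean twist per basepair step, radians.
    """
    if n_opt < 1:
        raise ValueError(f"n_opt must be >= 1, got {n_opt}")
    return n_opt * alpha0 * (1.0 + sigma_opt)


@dataclass(frozen=True)
class TwistParameters:
    """Physical constants of the orientational model.

    Attributes
    ----------
    k_theta : float
        Torsional stiffness, k_B*T per rad^2 per basepair step (default 71.4).
    alpha0 : float
        Mean twist per basepair step, radians (default equivalent of 34 deg).
    theta_p : float
        RNAP-imposed total spacer twist angle, radians.  Defaults to the
        strain-free angle of the reference spacer at ``sigma_ref``.
    n_ref : int
        Reference spacer length, nucleotides (default 17).
    sigma_ref : float
        Superhelical density at which the reference spacer is optimal.
    """

    k_theta: float = K_THETA_DEFAULT
    alpha0: float = ALPHA0_DEG_DEFAULT * DEG
    theta_p: float = field(default=float("nan"))
    n_ref: int = N_REF_DEFAULT
    sigma_ref: float = SIGMA_REF_DEFAULT

    def __post_init__(self) -> None:
        if self.k_theta <= 0:
            raise ValueError("k_theta must be > 0")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.n_ref < 1:
            raise ValueError("n_ref must be >= 1")
        if math.isnan(self.theta_p):
            object.__setattr__(
                self,
                "theta_p",
                default_theta_p(self.n_ref, self.sigma_ref, self.alpha0),
            )
        if self.theta_p <= 0:
            raise ValueError("theta_p must be > 0")

    @classmethod
    def from_degrees(
        cls,
        k_theta: float = K_THETA_DEFAULT,
        alpha0_deg: float = ALPHA0_DEG_DEFAULT,
        theta_p_deg: float | None = None,
        n_ref: int = N_REF_DEFAULT,
        sigma_ref: float = SIGMA_REF_DEFAULT,
    ) -> "TwistParameters":
        """Build parameters from degree-valued angles (user-facing convention)."""
        kwargs = dict(
            k_theta=k_theta, alpha0=alpha0_deg * DEG, n_ref=n_ref, sigma_ref=sigma_ref
        )
        if theta_p_deg is not None:
            kwargs["theta_p"] = theta_p_deg * DEG
        return cls(**kwargs)

    @property
    def alpha0_deg(self) -> float:
        return self.alpha0 / DEG

    @property
    def theta_p_deg(self) -> float:
        return self.theta_p / DEG

    @property
    def slope_scale(self) -> float:
        """The parameter-free slope constant ``k_theta * alpha0**2`` (~= 25.1)."""
        return self.k_theta * self.alpha0**2


DEFAULT_PARAMS = TwistParameters()


@dataclass(frozen=True)
class PromoterEnergyTerms:
    """Promoter-specific terms that do not couple sigma and spacer length.

    ``q_sp`` collects every sigma-independent effect of swapping the spacer
    (relative to the reference length) and shifts the normalized expression
    curve vertically.  ``r_sc`` collects every spacer-independent effect of a
    superhelical shift (promoter opening, etc.); its fold-change contribution
    is ``exp(-r_sc)``.
    """

    k0: float = 1.0
    q_sp: float = 0.0
    r_sc: float = 0.0

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValueError("basal rate k0 must be > 0")
        if not (math.isfinite(self.q_sp) and math.isfinite(self.r_sc)):
            raise ValueError("q_sp and r_sc must be finite")


@dataclass(frozen=True)
class ShockCondition:
    """A global superhelical shift sigma0 -> sigma0 + delta_sigma.

    ``delta_sigma > 0`` is DNA relaxation (e.g. gyrase inhibition by
    novobiocin); ``delta_sigma < 0`` is overtwisting (e.g. topoisomerase I
    inhibition by seconeolitsine).
    """

    sigma0: float = SIGMA_REF_DEFAULT
    delta_sigma: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.sigma0) >= 0.3:
            raise ValueError(f"|sigma0| must be < 0.3, got {self.sigma0}")
        if abs(self.sigma0 + self.delta_sigma) >= 0.3:
            raise ValueError("post-shock |sigma0 + delta_sigma| must be < 0.3")

    @property
    def sigma1(self) -> float:
        return self.sigma0 + self.delta_sigma


def _check_spacer_length(n) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if np.any(n < SPACER_DOMAIN[0]) or np.any(n > SPACER_DOMAIN[1]):
        raise ValueError(
            f"spacer length must lie in [{SPACER_DOMAIN[0]}, {SPACER_DOMAIN[1]}]"
        )
    lo, hi = SPACER_VALID_RANGE
    if np.any((n < lo) | (n > hi)):
        warnings.warn(
            f"spacer length outside the {lo}-{hi} nt range where the model "
            "has been validated",
            SpacerRangeWarning,
            stacklevel=3,
        )
    return n


def orientational_energy(sigma, n, params: TwistParameters = DEFAULT_PARAMS):
    """Elastic free energy (k_B*T) of twisting an ``n``-nt spacer to theta_P.

    ``(n/2) * k_theta * (theta_p/n - alpha0*(1 + sigma))**2``.  Non-negative
    everywhere; zero exactly where the torque-modulated relaxed twist matches
    the RNAP-imposed angle, i.e. at ``sigma* = theta_p / (n * alpha0) - 1``.
    Accepts scalars or broadcastable arrays for ``sigma`` and ``n``.
    """
    n = _check_spacer_length(n)
    sigma = np.asarray(sigma, dtype=float)
    dev = params.theta_p / n - params.alpha0 * (1.0 + sigma)
    out = 0.5 * n * params.k_theta * dev**2
    if out.ndim == 0:
        return float(out)
    return out


def transcription_rate(
    sigma,
    n,
    terms: PromoterEnergyTerms = PromoterEnergyTerms(),
    params: TwistParameters = DEFAULT_PARAMS,
):
    """Thermodynamic transcription rate ``k0 * exp(-dG_or(sigma, n))``.

    Spacer- and sigma-specific effects other than the orientational coupling
    are absorbed into ``k0`` (they cancel in every relative quantity the
    pipelines compute), so the rate is strictly positive and monotone
    decreasing in the orientational energy.
    """
    e = orientational_energy(sigma, n, params)
    out = terms.k0 * np.exp(-np.asarray(e))
    if np.ndim(out) == 0:
        return float(out)
    return out


def log_relative_expression(
    sigma,
    n,
    terms: PromoterEnergyTerms = PromoterEnergyTerms(),
    params: TwistParameters = DEFAULT_PARAMS,
):
    """Natural-log expression of spacer ``n`` relative to the reference spacer.

    ``dG_or(sigma, n_ref) - dG_or(sigma, n) + q_sp``: the normalization by the
    reference mutant removes ``k0`` and every spacer-independent sigma effect,
    leaving only the orientational coupling plus the sigma-independent offset
    ``q_sp``.
    """
    e_ref = orientational_energy(sigma, params.n_ref, params)
    e_n = orientational_energy(sigma, n, params)
    out = np.asarray(e_ref) - np.asarray(e_n) + terms.q_sp
    if out.ndim == 0:
        return float(out)
    return out


def relative_expression_slope(
    n,
    params: TwistParameters = DEFAULT_PARAMS,
    *,
    linearized: bool = True,
    sigma: float | None = None,
):
    """Slope d(log relative expression)/d(sigma) for spacer length ``n``.

    The linearized form is the parameter-free constant
    ``-k_theta * alpha0**2 * (n - n_ref)`` (about -25.1 per extra nucleotide);
    it consumes neither ``theta_p`` nor ``q_sp``.  The exact form is the
    analytic derivative ``-k_theta * alpha0**2 * (n - n_ref) * (1 + sigma)``
    evaluated at the supplied ``sigma``.
    """
    n = _check_spacer_length(n)
    base = -params.slope_scale * (n - params.n_ref)
    if linearized:
        out = base
    else:
        if sigma is None:
            raise ValueError("the exact slope requires a sigma value")
        out = base * (1.0 + sigma)
    if np.ndim(out) == 0:
        return float(out)
    return out


def logfc_under_shock(
    cond: ShockCondition,
    n,
    terms: PromoterEnergyTerms = PromoterEnergyTerms(),
    params: TwistParameters = DEFAULT_PARAMS,
):
    """Natural-log fold-change of one promoter under a superhelical shock.

    ``-r_sc - [dG_or(sigma0 + dsigma, n) - dG_or(sigma0, n)]``.  The
    orientational part is evaluated exactly (no linearization), so the small
    post-shock residual of the reference spacer is retained.
    """
    de = np.asarray(orientational_energy(cond.sigma1, n, params)) - np.asarray(
        orientational_energy(cond.sigma0, n, params)
    )
    out = -terms.r_sc - de
    if out.ndim == 0:
        return float(out)
    return out


def spacer_logfc_difference(
    delta_sigma: float,
    delta_n,
    params: TwistParameters = DEFAULT_PARAMS,
    *,
    linearized: bool = True,
    sigma0: float | None = None,
):
    """Shock log-fold-change of spacer ``n_ref + delta_n`` minus that of ``n_ref``.

    The linearized form is ``-k_theta * alpha0**2 * delta_n * delta_sigma``
    (the "-25 * dn * dsigma" rule); it is independent of sigma0, theta_p and
    every promoter-specific term.  The exact form differences
    :func:`logfc_under_shock` at the two lengths (``r_sc`` cancels) starting
    from ``sigma0`` (default ``params.sigma_ref``).
    """
    delta_n = np.asarray(delta_n, dtype=float)
    if linearized:
        out = -params.slope_scale * delta_n * delta_sigma
    else:
        s0 = params.sigma_ref if sigma0 is None else sigma0
        cond = ShockCondition(sigma0=s0, delta_sigma=delta_sigma)
        terms = PromoterEnergyTerms()
        out = np.asarray(
            logfc_under_shock(cond, params.n_ref + delta_n, terms, params)
        ) - logfc_under_shock(cond, params.n_ref, terms, params)
    if np.ndim(out) == 0:
        return float(out)
    return out
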