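"""Closed-form effort and choice models for force-loaded reaching.

The subjective cost (effort) of a single reach against a constant resistive
force ``F`` is modelled as a power law with an offset::

    E(F) = F**alpha + beta

with a per-subject force exponent ``alpha``, effort offset ``beta`` and an
effort sensitivity ``gamma`` that scales a probit choice rule.  Choices
between a reference action (``n`` repeats of a movement against ``F_R``) and
a single test movement against ``F_T`` follow

    P(reference) = Phi((U(n * E(F_R)) - U(E(F_T))) / gamma)

where ``Phi`` is the standard normal CDF and ``U`` is one of four competing
utility transforms of effort (negative log, negative identity, hyperbolic,
hyperbolic on log effort).  All four transforms share the same point of
subjective equality, the equivalent force

    F_Teq = (n * F_R**alpha + (n - 1) * beta)**(1/alpha)

at which the choice probability is exactly one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import ndtr

__all__ = [
    "PARAM_FLOOR",
    "EffortDomainError",
    "InvalidParameterError",
    "SubjectParams",
    "UtilityModel",
    "ForcePair",
    "Exp1GenParams",
    "effort",
    "utility",
    "choice_probability",
    "equivalent_force",
    "isoeffort_linear",
    "isoeffort_impulse",
    "generative_effort_exp1",
    "exp1_equivalent_force",
]

# Subject parameters are truncated to strict positivity so that effort is
# positive for the F = 0 N conditions and the log-based utilities stay finite.
PARAM_FLOOR = 1e-6


class EffortDomainError(ValueError):
    """Input outside the valid domain of an effort/utility function."""


class InvalidParameterError(ValueError):
    """Subject or model parameters violate their positivity constraints."""


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject parameters of the effort/choice model.

    alpha : force exponent (dimensionless, > 0)
    beta  : effort offset (effort units, > 0)
    gamma : effort sensitivity / probit scale (dimensionless, > 0)
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {v!r}")


class UtilityModel(str, Enum):
    """The four competing utility transforms of effort."""

    LOG_DIFFERENCE = "log_difference"   # U(E) = -log E
    DIFFERENCE = "difference"           # U(E) = -E
    HYPERBOLIC = "hyperbolic"           # U(E) = 1/E
    HYPERBOLIC_LOG = "hyperbolic_log"   # U(E) = 1/log E


@dataclass(frozen=True)
class ForcePair:
    """One binary comparison: reference force, test force, repeat count.

    ``n_ref_repeats`` is 1 for single-vs-single comparisons and 2 when the
    reference action is a doubled movement.
    """

    f_ref: float
    f_test: float
    n_ref_repeats: int = 2

    def __post_init__(self) -> None:
        if self.f_ref < 0 or self.f_test < 0:
            raise EffortDomainError("forces must be non-negative")
        if self.n_ref_repeats < 1:
            raise InvalidParameterError("n_ref_repeats must be >= 1")


def effort(force, p: SubjectParams):
    """Effort E(F) = F**alpha + beta of a movement against ``force`` (N).

    ``force`` may be a scalar or array; negative forces raise
    :class:`EffortDomainError`.  0**alpha is taken as 0 (continuous limit
    for alpha > 0).
    """
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise EffortDomainError("force must be non-negative")
    e = np.power(f, p.alpha) + p.beta
    if np.any(e <= 0):
        raise InvalidParameterError("effort must be positive; check parameters")
    return e if e.ndim else float(e)


def utility(e, model: UtilityModel | str):
    """Utility U(E) of an effort value under one of the four transforms.

    Monotonically decreasing in E over the valid domain.  Log-based models
    require E > 0; the hyperbolic-log model is singular at E = 1.
    """
    model = UtilityModel(model)
    ev = np.asarray(e, dtype=float)
    if model is UtilityModel.DIFFERENCE:
        u = -ev
    elif model is UtilityModel.HYPERBOLIC:
        if np.any(ev <= 0):
            raise EffortDomainError(f"hyperbolic utility needs E > 0, got {e!r}")
        u = 1.0 / ev
    elif model is UtilityModel.LOG_DIFFERENCE:
        if np.any(ev <= 0):
            raise EffortDomainError(f"log utility needs E > 0, got {e!r}")
        u = -np.log(ev)
    else:  # HYPERBOLIC_LOG
        if np.any(ev <= 0):
            raise EffortDomainError(f"log utility needs E > 0, got {e!r}")
        le = np.log(ev)
        if np.any(le == 0.0):
            raise EffortDomainError("hyperbolic_log utility singular at E = 1")
        u = 1.0 / le
    return u if u.ndim else float(u)


def choice_probability(pair: ForcePair, p: SubjectParams,
                       model: UtilityModel | str = UtilityModel.LOG_DIFFERENCE) -> float:
    """Probability of choosing the reference action over the test movement.

    Probit rule on the utility difference, with the reference effort scaled
    by the number of movement repetitions.
    """
    model = UtilityModel(model)
    e_ref = pair.n_ref_repeats * effort(pair.f_ref, p)
    e_test = effort(pair.f_test, p)
    try:
        du = utility(e_ref, model) - utility(e_test, model)
    except EffortDomainError as err:
        raise EffortDomainError(
            f"utility undefined for efforts ref={e_ref!r}, test={e_test!r}: {err}"
        ) from err
    return float(ndtr(du / p.gamma))


def equivalent_force(f_ref, p: SubjectParams, n_ref_repeats: int = 2):
    """Equivalent test force F_Teq with E(F_Teq) = n * E(F_R).

    Closed form ``(n * F_R**alpha + (n-1) * beta)**(1/alpha)``; identical for
    all four utility transforms, and the identity map for n = 1.
    """
    if p.alpha <= 0:
        raise InvalidParameterError("alpha must be positive")
    if n_ref_repeats < 1:
        raise InvalidParameterError("n_ref_repeats must be >= 1")
    f = np.asarray(f_ref, dtype=float)
    if np.any(f < 0):
        raise EffortDomainError("reference force must be non-negative")
    n = n_ref_repeats
    out = np.power(n * np.power(f, p.alpha) + (n - 1) * p.beta, 1.0 / p.alpha)
    return out if out.ndim else float(out)


def isoeffort_linear(f_ref: float, d_ref: float, d_test, alpha: float, beta: float):
    """Isoeffort force grid for a linear force-duration cost E = alpha*F + beta*d.

    F_T(d_T) = (alpha*F_R + beta*d_R)/alpha - (beta/alpha) * d_T — a straight
    line in the force-duration plane.
    """
    if alpha <= 0:
        raise InvalidParameterError("alpha must be positive")
    d = np.asarray(d_test, dtype=float)
    if d_ref <= 0 or np.any(d <= 0):
        raise EffortDomainError("durations must be positive")
    out = (alpha * f_ref + beta * d_ref) / alpha - (beta / alpha) * d
    return out if out.ndim else float(out)


def isoeffort_impulse(f_ref: float, d_ref: float, d_test):
    """Isoeffort force grid for a pure impulse cost E = F*d.

    F_T(d_T) = F_R * d_R / d_T — a convex inverse curve.
    """
    d = np.asarray(d_test, dtype=float)
    if d_ref <= 0 or np.any(d <= 0):
        raise EffortDomainError("durations must be positive")
    out = f_ref * d_ref / d
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class Exp1GenParams:
    """Generative effort parameters for single-movement comparisons.

    Extends the power-law cost with a multiplicative duration term and
    direction-specific scale factors (inward reaches toward the body midline
    are cheaper than outward ones).  This generative extension is used only
    to simulate single-vs-single choice sessions; it is not the model fitted
    to doubled-movement data.
    """

    alpha: float
    beta: float
    c_in: float = 1.0
    c_out: float = 1.15

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "c_in", "c_out"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")

    def coeff(self, direction: str) -> float:
        if direction == "inward":
            return self.c_in
        if direction == "outward":
            return self.c_out
        raise ValueError(f"unknown direction {direction!r}")


def generative_effort_exp1(force, duration: float, direction: str, g: Exp1GenParams):
    """Duration-integrated, direction-scaled effort c_dir * d * (F**alpha + beta).

    Reduces to the static power-law effort (up to scale) at fixed duration
    and direction; linear in duration.
    """
    if duration <= 0:
        raise EffortDomainError("duration must be positive")
    f = np.asarray(force, dtype=float)
    if np.any(f < 0):
        raise EffortDomainError("force must be non-negative")
    out = g.coeff(direction) * duration * (np.power(f, g.alpha) + g.beta)
    return out if out.ndim else float(out)


def exp1_equivalent_force(f_ref: float, d_ref: float, dir_ref: str,
                          d_test: float, dir_test: str, g: Exp1GenParams) -> float:
    """Test force solving c_T d_T (F_T**a + b) = c_R d_R (F_R**a + b).

    Returns the non-negative root; 0 if even a zero-force test movement is
    more effortful than the reference.
    """
    r = g.coeff(dir_ref) * d_ref / (g.coeff(dir_test) * d_test)
    rhs = r * (math.pow(f_ref, g.alpha) + g.beta) - g.beta
    if rhs <= 0:
        return 0.0
    return math.pow(rhs, 1.0 / g.alpha)
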