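"""Forward model of the RNA life cycle.

Mass balance: pre-mRNA P is produced by transcription (rate alpha) and
consumed by processing (rate gamma); the mature pool M = T - P is fed by
processing and drained by degradation (rate beta), all in amount units
(expression/min):

    dP/dt = alpha(t) - gamma(t)
    dM/dt = gamma(t) - beta(t)

so P, T and the labeled signal TL are linear combinations of pulse-curve
integrals.  RNA is assumed not to degrade during the short labeling
window tL, hence the labeled observation is a carryover fraction of the
total pool plus the nascent transcription integral over the window:

    TL(t) = c1 * T(t) + c2 * \\int_{t-tL}^{t} alpha(u) du

with the two identifiable scale-factor combinations c1 = w2/w and
c2 = w1 - w2 (pre-existing-RNA leak into the labeled library, and net
labeling capture efficiency).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pulse import PulseParams, pulse_eval, pulse_integral

__all__ = [
    "ScaleFactors",
    "TimeGrid",
    "GeneKinetics",
    "RateConstants",
    "predict_premrna",
    "predict_total",
    "predict_labeled",
    "steady_state_rates",
    "convert_rates",
]

#: positivity guard (expression-units) when dividing by P or T - P
EPS_EXPR = 1e-9


@dataclass(frozen=True)
class ScaleFactors:
    """Global labeling normalization constants, one pair per experiment.

    c1 = w2/w is the fraction of pre-existing RNA leaking into the labeled
    library relative to total (dimensionless, in [0, 1]); c2 = w1 - w2 is
    the net labeling capture efficiency (> 0 for informative data; 0 is
    permitted only as the degenerate output of an unidentifiable fit).
    """

    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.c1 <= 1.0):
            raise ValueError(f"c1 must lie in [0, 1], got {self.c1}")
        if self.c2 < 0.0:
            raise ValueError(f"c2 must be nonnegative, got {self.c2}")


@dataclass(frozen=True)
class TimeGrid:
    """Sampling times (min, strictly increasing, times[0] >= 0) and the
    4sU labeling duration ``tL`` (min, at most the smallest spacing)."""

    times: np.ndarray
    tL: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("times must be a 1-D vector with >= 2 entries")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with times[0] >= 0")
        if not (0 < self.tL <= float(np.min(np.diff(t)))):
            raise ValueError("tL must satisfy 0 < tL <= min spacing of times")

    @property
    def n(self) -> int:
        return int(self.times.size)


@dataclass
class GeneKinetics:
    """Fitted (or true) kinetics of one gene: the three pulse rate curves
    in amount units, the initial conditions, and fit diagnostics."""

    theta_alpha: PulseParams
    theta_gamma: PulseParams
    theta_beta: PulseParams
    P0: float = 0.0
    T0: float = 0.0
    J: float = float("nan")
    converged: bool = True
    chi2_stat: float = float("nan")
    chi2_p: float = float("nan")
    dof: int = 0
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.P0 < 0:
            raise ValueError("P0 must be nonnegative")
        if not math.isnan(self.J) and self.J < 0:
            raise ValueError("objective value J must be nonnegative")


@dataclass(frozen=True)
class RateConstants:
    """Rates at one time point: transcription in amount units, processing
    and degradation as first-order constants (1/min)."""

    alpha: float
    gamma_k: float
    beta_k: float
    flagged: bool = False


def _as_times(t) -> tuple[np.ndarray, bool]:
    ta = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(ta < 0) or not np.all(np.isfinite(ta)):
        raise ValueError("prediction times must be finite and >= 0")
    return ta, np.ndim(t) == 0


def predict_premrna(kin: GeneKinetics, t) -> np.ndarray | float:
    """Pre-mRNA level P(t) = P(0) + int_0^t alpha - int_0^t gamma.

    Valid beyond the last measured time point (this is the prediction
    feature).  A negative prediction is returned as-is but recorded in
    ``kin.flags``; the fit constraints make it rare.
    """
    ta, scalar = _as_times(t)
    out = np.array(
        [
            kin.P0
            + pulse_integral(kin.theta_alpha, 0.0, ti)
            - pulse_integral(kin.theta_gamma, 0.0, ti)
            for ti in ta
        ]
    )
    if np.any(out < 0) and "negative_P" not in kin.flags:
        kin.flags.append("negative_P")
    return float(out[0]) if scalar else out


def predict_total(kin: GeneKinetics, t) -> np.ndarray | float:
    """Total RNA level T(t) = T(0) + int_0^t alpha - int_0^t beta."""
    ta, scalar = _as_times(t)
    out = np.array(
        [
            kin.T0
            + pulse_integral(kin.theta_alpha, 0.0, ti)
            - pulse_integral(kin.theta_beta, 0.0, ti)
            for ti in ta
        ]
    )
    if np.any(out < 0) and "negative_T" not in kin.flags:
        kin.flags.append("negative_T")
    return float(out[0]) if scalar else out


def predict_labeled(kin: GeneKinetics, sf: ScaleFactors, t, tL: float) -> np.ndarray | float:
    """Labeled signal TL(t) = c1*T(t) + c2 * int_{max(0, t-tL)}^{t} alpha.

    The lower integration limit is clipped at 0: no transcription before
    the start of the experiment is attributed to the first sample.
    """
    if tL <= 0:
        raise ValueError("labeling duration tL must be positive")
    ta, scalar = _as_times(t)
    tot = np.atleast_1d(predict_total(kin, ta))
    nascent = np.array(
        [pulse_integral(kin.theta_alpha, max(0.0, ti - tL), ti) for ti in ta]
    )
    out = sf.c1 * tot + sf.c2 * nascent
    return float(out[0]) if scalar else out


def steady_state_rates(kin: GeneKinetics) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Initial and predicted-new steady-state rate triples.

    Returns ``((alpha0, gamma0, beta0), (alpha2, gamma2, beta2))`` — the
    ``h0`` and ``h2`` levels of the three fitted curves.  At steady state
    transcription, processing and degradation balance, so under the hard
    steady-state ties the members of each triple coincide.
    """
    initial = (kin.theta_alpha.h0, kin.theta_gamma.h0, kin.theta_beta.h0)
    final = (kin.theta_alpha.h2, kin.theta_gamma.h2, kin.theta_beta.h2)
    return initial, final


def convert_rates(kin: GeneKinetics, t: float) -> RateConstants:
    """Convert amount rates at time ``t`` to first-order constants.

    Processing is taken proportional to the pre-mRNA pool and degradation
    to the mature pool: gamma_k = gamma(t)/P(t), beta_k = beta(t)/(T-P).
    When a pool is (numerically) empty the corresponding constant is
    undefined and returned as NaN with ``flagged=True``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    alpha = pulse_eval(kin.theta_alpha, t)
    P = predict_premrna(kin, t)
    T = predict_total(kin, t)
    M = T - P
    flagged = False
    if P > EPS_EXPR:
        gamma_k = pulse_eval(kin.theta_gamma, t) / P
    else:
        warnings.warn(f"P(t) <= {EPS_EXPR} at t={t}: processing constant undefined")
        gamma_k, flagged = float("nan"), True
    if M > EPS_EXPR:
        beta_k = pulse_eval(kin.theta_beta, t) / M
    else:
        warnings.warn(f"T(t)-P(t) <= {EPS_EXPR} at t={t}: degradation constant undefined")
        beta_k, flagged = float("nan"), True
    return RateConstants(alpha=alpha, gamma_k=gamma_k, beta_k=beta_k, flagged=flagged)
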