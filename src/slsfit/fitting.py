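"""Nonlinear least-squares recovery of SLS parameters from hold curves.

Two estimator families per test kind:

* finite-rate fits use the ramp-corrected hold solutions with free
  parameters (E1, tau_R, tau_C, k), the loading rate and hold level held
  fixed at their protocol values; E2 and eta then follow from
  E2 = E1 (tau_C - tau_R)/tau_R, eta = tau_R E2;
* infinite-rate fits use the step-loading solutions with free parameters
  (E1, E2, tau_R) for relaxation or (E1, E2, tau_C) for creep.

Fits act on the hold phase only.  Inside the optimizer the time-constant
pair is parameterised as a base constant times (1 + delta), delta > 0, so
tau_C > tau_R holds by construction.  The amplitude of the fitted decay is
compared to the signal scale: when it falls below 1e-3 of it the transient
is essentially unidentifiable and ``condition_warning`` is set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .model import (
    CreepProtocol,
    RelaxationProtocol,
    SLSParameters,
    recover_E2_eta,
)
from .simulate import TestCurve

__all__ = [
    "FitResult",
    "ErrorReport",
    "estimate_protocol",
    "fit_relaxation_finite",
    "fit_relaxation_infinite",
    "fit_creep_finite",
    "fit_creep_infinite",
    "relative_error",
    "error_report",
]

_AMPLITUDE_IDENTIFIABILITY = 1e-3  # |amplitude| / signal scale below which E2 is ill-posed
_TINY = 1e-12


@dataclass(frozen=True)
class FitResult:
    """Recovered SLS parameters plus fit diagnostics.

    ``k`` is the stretch exponent (None for infinite-rate fits, which have
    no stretched decay).  ``residual_rms`` is in the units of the fitted
    channel (Pa for relaxation, dimensionless strain for creep).
    """

    form: str  # "finite" | "infinite"
    test: str  # "relaxation" | "creep"
    E1: float
    E2: float
    eta: float
    tau_R: float
    tau_C: float
    k: float | None
    residual_rms: float
    converged: bool
    condition_warning: bool
    message: str = ""

    @property
    def parameters(self) -> SLSParameters:
        return SLSParameters(self.E1, self.E2, self.eta)


@dataclass(frozen=True)
class ErrorReport:
    """Absolute relative errors of (E1, E2, eta) against known truth, as fractions."""

    E1: float
    E2: float
    eta: float

    def as_percent(self) -> dict[str, float]:
        return {"E1": 100 * self.E1, "E2": 100 * self.E2, "eta": 100 * self.eta}

    @property
    def max(self) -> float:
        return max(self.E1, self.E2, self.eta)


def relative_error(analyzed: float, true: float) -> float:
    """|analyzed - true| / |true|, the accuracy metric of the validation study."""
    if true == 0:
        raise ValueError("relative error undefined for a zero true value")
    return abs(analyzed - true) / abs(true)


def error_report(result: FitResult, truth: SLSParameters) -> ErrorReport:
    """Per-parameter relative errors of a fit against the generating material."""
    return ErrorReport(
        E1=relative_error(result.E1, truth.E1),
        E2=relative_error(result.E2, truth.E2),
        eta=relative_error(result.eta, truth.eta),
    )


def estimate_protocol(curve: TestCurve) -> RelaxationProtocol | CreepProtocol:
    """Recover the test protocol from the controlled channel of the data.

    The loading rate is the least-squares slope of the controlled channel
    over the ramp; the hold level is its mean over the hold.  Exact for
    noiseless synthetic curves.
    """
    loading = curve.loading_mask
    hold = curve.hold_mask
    if loading.sum() < 2 or hold.sum() < 2:
        raise ValueError(
            "protocol estimation needs >= 2 loading and >= 2 hold samples with "
            "phase labels; supply the protocol explicitly otherwise"
        )
    t_load = curve.time[loading]
    y_load = curve.controlled[loading]
    rate = float(np.polyfit(t_load, y_load, 1)[0])
    level = float(curve.controlled[hold].mean())
    t_hold = curve.time[hold]
    duration = float(t_hold[-1] - t_hold[0])
    if curve.kind == "relaxation":
        return RelaxationProtocol(rate, level, duration)
    return CreepProtocol(rate, level, duration)


def _hold_series(curve: TestCurve) -> tuple[np.ndarray, np.ndarray]:
    mask = curve.hold_mask
    t = curve.time[mask]
    return t - t[0], curve.measured[mask]


def _efold_time(t: np.ndarray, decay: np.ndarray) -> float:
    """Time at which a normalised decay (1 -> 0) crosses 1/e, by interpolation."""
    target = math.exp(-1.0)
    below = np.nonzero(decay < target)[0]
    if below.size == 0:
        return float(t[-1]) if t[-1] > 0 else 1.0
    i = below[0]
    if i == 0:
        return float(max(t[1] / 2.0, _TINY))
    t0, t1 = t[i - 1], t[i]
    d0, d1 = decay[i - 1], decay[i]
    if d0 == d1:
        return float(t1)
    return float(t0 + (d0 - target) * (t1 - t0) / (d0 - d1))


def _solve(residual, x0, lb, ub, restarts: int = 3):
    """Bounded trust-region least squares with deterministic multi-start."""
    x0 = np.clip(np.asarray(x0, dtype=float), lb, ub)
    factors = [None, 0.6, 1.6, 0.3]  # first run unperturbed
    best = None
    for i, f in enumerate(factors[: restarts + 1]):
        xi = x0 if f is None else np.clip(x0 * f, lb, ub)
        res = least_squares(
            residual,
            xi,
            bounds=(lb, ub),
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
            max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
        if res.success and i == 0:
            return best
    return best


def _resolve_protocol(curve, proto, expected_type):
    if proto is None:
        proto = curve.protocol
    if proto is None:
        proto = estimate_protocol(curve)
    if not isinstance(proto, expected_type):
        raise TypeError(f"expected a {expected_type.__name__}, got {type(proto).__name__}")
    return proto


def _equilibrium_and_amplitude(t, y):
    n_eq = max(1, y.size // 10)
    eq = float(y[-n_eq:].mean())
    amp = float(y[0] - eq)
    return eq, amp


def _finalize(form, test, E1, tau_R, tau_C, k, res, amp_fit, scale) -> FitResult:
    E2, eta = recover_E2_eta(E1, tau_C, tau_R)
    n = res.fun.size
    converged = bool(res.success) and all(
        math.isfinite(v) for v in (E1, E2, eta, tau_R, tau_C)
    )
    return FitResult(
        form=form,
        test=test,
        E1=E1,
        E2=E2,
        eta=eta,
        tau_R=tau_R,
        tau_C=tau_C,
        k=k,
        residual_rms=float(np.sqrt(2.0 * res.cost / n)),
        converged=converged,
        condition_warning=abs(amp_fit) < _AMPLITUDE_IDENTIFIABILITY * scale,
        message=str(res.message),
    )


def fit_relaxation_finite(
    curve: TestCurve,
    proto: RelaxationProtocol | None = None,
    fit_k: bool = True,
) -> FitResult:
    """Fit the finite-rate relaxation form to the hold phase.

    Free parameters (E1, tau_R, delta, k) with tau_C = tau_R (1 + delta);
    the strain rate and hold strain are fixed from the protocol.  With
    ``fit_k=False`` the stretch exponent is pinned at 1 (pure SLS decay).
    """
    proto = _resolve_protocol(curve, proto, RelaxationProtocol)
    t, y = _hold_series(curve)
    n_free = 4 if fit_k else 3
    if t.size < n_free:
        raise ValueError(f"finite-rate relaxation fit needs >= {n_free} hold samples")
    r, eps0 = proto.strain_rate, proto.hold_strain
    scale = float(np.max(np.abs(y)))

    eq, amp0 = _equilibrium_and_amplitude(t, y)
    E1_0 = max(eq / eps0, _TINY)
    tauR_0 = _efold_time(t, (y - eq) / amp0) if amp0 != 0 else float(np.median(t[1:]))
    sat = -math.expm1(-eps0 / (tauR_0 * r))
    dtc = amp0 / (E1_0 * r * sat) if sat > 0 else 0.0
    delta_0 = dtc / tauR_0 if dtc > 0 else 4.0
    x0 = [E1_0, tauR_0, delta_0, 1.0]
    lb = [_TINY, _TINY, _TINY, 1e-3]
    ub = [np.inf, np.inf, np.inf, 1.0]
    if not fit_k:
        x0, lb, ub = x0[:3], lb[:3], ub[:3]

    def model(x):
        E1, tauR, delta = x[0], x[1], x[2]
        k = x[3] if fit_k else 1.0
        amp = -E1 * r * tauR * delta * math.expm1(-eps0 / (tauR * r))
        return amp * np.exp(-((t / tauR) ** k)) + E1 * eps0

    res = _solve(lambda x: model(x) - y, x0, lb, ub)
    E1, tauR, delta = res.x[0], res.x[1], res.x[2]
    k = float(res.x[3]) if fit_k else 1.0
    amp_fit = -E1 * r * tauR * delta * math.expm1(-eps0 / (tauR * r))
    return _finalize(
        "finite", "relaxation", E1, tauR, tauR * (1.0 + delta), k, res, amp_fit, scale
    )


def fit_relaxation_infinite(
    curve: TestCurve, proto: RelaxationProtocol | None = None
) -> FitResult:
    """Fit the step-strain (infinite-rate) relaxation form to the hold phase.

    Free parameters (E1, E2, tau_R); eta = tau_R E2.  Accurate only when the
    ramp is fast relative to tau_R — the slow-ramp bias of this form is the
    motivation for the finite-rate estimator.
    """
    proto = _resolve_protocol(curve, proto, RelaxationProtocol)
    t, y = _hold_series(curve)
    if t.size < 3:
        raise ValueError("infinite-rate relaxation fit needs >= 3 hold samples")
    eps0 = proto.hold_strain
    scale = float(np.max(np.abs(y)))

    eq, amp0 = _equilibrium_and_amplitude(t, y)
    E1_0 = max(eq / eps0, _TINY)
    E2_0 = max(amp0 / eps0, _TINY)
    tauR_0 = _efold_time(t, (y - eq) / amp0) if amp0 != 0 else float(np.median(t[1:]))
    x0 = [E1_0, E2_0, tauR_0]
    lb = [_TINY] * 3
    ub = [np.inf] * 3

    def model(x):
        E1, E2, tauR = x
        return (E1 + E2 * np.exp(-t / tauR)) * eps0

    res = _solve(lambda x: model(x) - y, x0, lb, ub)
    E1, E2, tauR = res.x
    eta = tauR * E2
    tauC = eta * (E1 + E2) / (E1 * E2)
    n = res.fun.size
    return FitResult(
        form="infinite",
        test="relaxation",
        E1=float(E1),
        E2=float(E2),
        eta=float(eta),
        tau_R=float(tauR),
        tau_C=float(tauC),
        k=None,
        residual_rms=float(np.sqrt(2.0 * res.cost / n)),
        converged=bool(res.success),
        condition_warning=abs(E2 * eps0) < _AMPLITUDE_IDENTIFIABILITY * scale,
        message=str(res.message),
    )


def fit_creep_finite(
    curve: TestCurve,
    proto: CreepProtocol | None = None,
    fit_k: bool = True,
) -> FitResult:
    """Fit the finite-rate creep form to the hold phase.

    Free parameters (E1, tau_C, delta, k) with tau_R = tau_C / (1 + delta);
    the stress rate and hold stress are fixed from the protocol.  As the
    stress rate tends to zero the transient amplitude vanishes and E2
    becomes unidentifiable; ``condition_warning`` flags that regime.
    """
    proto = _resolve_protocol(curve, proto, CreepProtocol)
    t, y = _hold_series(curve)
    n_free = 4 if fit_k else 3
    if t.size < n_free:
        raise ValueError(f"finite-rate creep fit needs >= {n_free} hold samples")
    r, sigma0 = proto.stress_rate, proto.hold_stress
    scale = float(np.max(np.abs(y)))

    eq, amp0 = _equilibrium_and_amplitude(t, y)  # amp0 < 0 for creep
    E1_0 = max(sigma0 / eq, _TINY) if eq > 0 else _TINY
    tauC_0 = _efold_time(t, (y - eq) / amp0) if amp0 != 0 else float(np.median(t[1:]))
    sat = -math.expm1(-sigma0 / (tauC_0 * r))
    tauR_0 = tauC_0 + amp0 * E1_0 / (r * sat) if sat > 0 else 0.0
    delta_0 = tauC_0 / tauR_0 - 1.0 if 0 < tauR_0 < tauC_0 else 4.0
    x0 = [E1_0, tauC_0, delta_0, 1.0]
    lb = [_TINY, _TINY, _TINY, 1e-3]
    ub = [np.inf, np.inf, np.inf, 1.0]
    if not fit_k:
        x0, lb, ub = x0[:3], lb[:3], ub[:3]

    def model(x):
        E1, tauC, delta = x[0], x[1], x[2]
        k = x[3] if fit_k else 1.0
        # tau_R - tau_C = -tauC * delta / (1 + delta)
        amp = (r / E1) * (tauC * delta / (1.0 + delta)) * math.expm1(-sigma0 / (tauC * r))
        return amp * np.exp(-((t / tauC) ** k)) + sigma0 / E1

    res = _solve(lambda x: model(x) - y, x0, lb, ub)
    E1, tauC, delta = res.x[0], res.x[1], res.x[2]
    k = float(res.x[3]) if fit_k else 1.0
    tauR = tauC / (1.0 + delta)
    amp_fit = (r / E1) * (tauC * delta / (1.0 + delta)) * math.expm1(-sigma0 / (tauC * r))
    return _finalize("finite", "creep", E1, tauR, tauC, k, res, amp_fit, scale)


def fit_creep_infinite(curve: TestCurve, proto: CreepProtocol | None = None) -> FitResult:
    """Fit the step-stress (infinite-rate) creep form to the hold phase.

    Free parameters (E1, E2, tau_C); eta = tau_C E1 E2 / (E1 + E2).
    """
    proto = _resolve_protocol(curve, proto, CreepProtocol)
    t, y = _hold_series(curve)
    if t.size < 3:
        raise ValueError("infinite-rate creep fit needs >= 3 hold samples")
    sigma0 = proto.hold_stress
    scale = float(np.max(np.abs(y)))

    eq, amp0 = _equilibrium_and_amplitude(t, y)
    E1_0 = max(sigma0 / eq, _TINY) if eq > 0 else _TINY
    # initial strain ~ sigma0 / (E1 + E2) for a fast ramp
    E2_0 = max(sigma0 / y[0] - E1_0, _TINY) if y[0] > 0 else _TINY
    tauC_0 = _efold_time(t, (y - eq) / amp0) if amp0 != 0 else float(np.median(t[1:]))
    x0 = [E1_0, E2_0, tauC_0]
    lb = [_TINY] * 3
    ub = [np.inf] * 3

    def model(x):
        E1, E2, tauC = x
        return (sigma0 / E1) * (1.0 - (E2 / (E1 + E2)) * np.exp(-t / tauC))

    res = _solve(lambda x: model(x) - y, x0, lb, ub)
    E1, E2, tauC = res.x
    eta = tauC * E1 * E2 / (E1 + E2)
    tauR = eta / E2
    amp_fit = (sigma0 / E1) * (E2 / (E1 + E2))
    n = res.fun.size
    return FitResult(
        form="infinite",
        test="creep",
        E1=float(E1),
        E2=float(E2),
        eta=float(eta),
        tau_R=float(tauR),
        tau_C=float(tauC),
        k=None,
        residual_rms=float(np.sqrt(2.0 * res.cost / n)),
        converged=bool(res.success),
        condition_warning=abs(amp_fit) < _AMPLITUDE_IDENTIFIABILITY * scale,
        message=str(res.message),
    )
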