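"""Closed-form ramp-hold solutions for the standard linear solid (Zener) model.

The Maxwell form of the standard linear solid (SLS) is a spring ``E1`` in
parallel with a Maxwell arm: a spring ``E2`` in series with a dashpot ``eta``.
It is the simplest linear viscoelastic model with both a finite instantaneous
modulus (``E1 + E2``) and a finite equilibrium modulus (``E1``), which makes
it a workhorse for analysing stress relaxation and creep of polymers,
hydrogels and soft tissues.

Two solution families are provided for each test kind:

* infinite-rate ("textbook") forms, which assume the load is applied as a
  perfect step: ``sigma(t) = (E1 + E2 exp(-t/tau_R)) eps0`` for relaxation and
  the mirrored compliance form for creep;
* finite-rate forms, in which the loading phase is an explicit constant-rate
  ramp and the hold-phase solution carries the ramp history inside its
  amplitude term.  The hold-phase decay may optionally be stretched
  (Kohlrausch exponent ``k``, ``0 < k <= 1``) to fit real materials whose
  relaxation is broader than a single exponential.

Conventions
-----------
* All quantities are SI: stress in Pa, time in s, strain dimensionless,
  rates in 1/s (strain control) or Pa/s (stress control).
* Hold-phase functions take ``t = 0`` at the start of the hold; ramp
  functions take ``t = 0`` at the start of loading.
* ``tau_R = eta / E2`` is the relaxation time constant and
  ``tau_C = eta (E1 + E2) / (E1 E2)`` the creep (retardation) time constant;
  ``tau_C > tau_R`` for every physical parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SLSParameters",
    "PronyParameters",
    "RelaxationProtocol",
    "CreepProtocol",
    "make_sls",
    "sls_to_prony",
    "prony_to_sls",
    "recover_E2_eta",
    "relaxation_modulus_dimensionless",
    "relaxation_loading_stress",
    "stress_at_ramp_end",
    "relaxation_hold_amplitude",
    "relaxation_stress_finite",
    "relaxation_stress_infinite",
    "creep_loading_strain",
    "strain_at_ramp_end",
    "creep_hold_amplitude",
    "creep_strain_finite",
    "creep_strain_infinite",
]


def _require_positive(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v) or v <= 0.0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")
    return v


def _check_stretch_exponent(k: float) -> float:
    k = float(k)
    if not math.isfinite(k) or not 0.0 < k <= 1.0:
        raise ValueError(f"stretch exponent k must satisfy 0 < k <= 1, got {k!r}")
    return k


def _as_times(t, name: str = "t"):
    """Validate non-negative time input; returns (array, was_scalar)."""
    arr = np.asarray(t, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError(f"{name} must be non-negative")
    return arr, arr.ndim == 0


def _maybe_scalar(values: np.ndarray, scalar: bool):
    return float(values) if scalar else values


@dataclass(frozen=True)
class SLSParameters:
    """Material triple (E1, E2, eta) of the standard linear solid.

    ``E1`` is the equilibrium (long-time) modulus, ``E1 + E2`` the
    instantaneous modulus, ``eta`` the dashpot viscosity of the Maxwell arm.
    """

    E1: float
    E2: float
    eta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "E1", _require_positive("E1", self.E1))
        object.__setattr__(self, "E2", _require_positive("E2", self.E2))
        object.__setattr__(self, "eta", _require_positive("eta", self.eta))

    @property
    def tau_R(self) -> float:
        """Relaxation time constant eta / E2."""
        return self.eta / self.E2

    @property
    def tau_C(self) -> float:
        """Creep (retardation) time constant eta (E1 + E2) / (E1 E2)."""
        return self.eta * (self.E1 + self.E2) / (self.E1 * self.E2)


@dataclass(frozen=True)
class PronyParameters:
    """One-branch Prony parameterisation (E, g, tau_R).

    This is the native material parameterisation of FE packages: an elastic
    modulus ``E`` and a dimensionless one-branch relaxation modulus
    ``g_R(t) = 1 - g (1 - exp(-t/tau_R))`` with ``0 < g < 1``.
    """

    E: float
    g: float
    tau_R: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "E", _require_positive("E", self.E))
        object.__setattr__(self, "tau_R", _require_positive("tau_R", self.tau_R))
        g = float(self.g)
        if not math.isfinite(g) or not 0.0 < g < 1.0:
            raise ValueError(f"g must satisfy 0 < g < 1, got {self.g!r}")
        object.__setattr__(self, "g", g)


@dataclass(frozen=True)
class RelaxationProtocol:
    """Ramp-hold protocol for a strain-controlled stress-relaxation test.

    The strain is ramped at constant rate ``strain_rate`` (1/s) from zero to
    ``hold_strain`` and then held constant for ``hold_duration`` seconds.
    """

    strain_rate: float
    hold_strain: float
    hold_duration: float

    def __post_init__(self) -> None:
        _require_positive("strain_rate", self.strain_rate)
        _require_positive("hold_strain", self.hold_strain)
        _require_positive("hold_duration", self.hold_duration)

    @property
    def ramp_duration(self) -> float:
        """Loading-phase duration t' = hold_strain / strain_rate."""
        return self.hold_strain / self.strain_rate


@dataclass(frozen=True)
class CreepProtocol:
    """Ramp-hold protocol for a stress-controlled creep test.

    The stress is ramped at constant rate ``stress_rate`` (Pa/s) from zero to
    ``hold_stress`` and then held constant for ``hold_duration`` seconds.
    """

    stress_rate: float
    hold_stress: float
    hold_duration: float

    def __post_init__(self) -> None:
        _require_positive("stress_rate", self.stress_rate)
        _require_positive("hold_stress", self.hold_stress)
        _require_positive("hold_duration", self.hold_duration)

    @property
    def ramp_duration(self) -> float:
        """Loading-phase duration t' = hold_stress / stress_rate."""
        return self.hold_stress / self.stress_rate


def make_sls(E1: float, E2: float, eta: float) -> SLSParameters:
    """Construct validated SLS parameters from the three material constants."""
    return SLSParameters(E1=E1, E2=E2, eta=eta)


def sls_to_prony(p: SLSParameters) -> PronyParameters:
    """Convert (E1, E2, eta) to the FE-style (E, g, tau_R) triple.

    E = E1, g = E2 / (E1 + E2), tau_R = eta / E2.
    """
    return PronyParameters(E=p.E1, g=p.E2 / (p.E1 + p.E2), tau_R=p.tau_R)


def prony_to_sls(q: PronyParameters) -> SLSParameters:
    """Convert (E, g, tau_R) to SLS parameters.

    E1 = E, E2 = E g / (1 - g), eta = tau_R E g / (1 - g).
    """
    E2 = q.E * q.g / (1.0 - q.g)
    return SLSParameters(E1=q.E, E2=E2, eta=q.tau_R * E2)


def recover_E2_eta(E1: float, tau_C: float, tau_R: float) -> tuple[float, float]:
    """Solve tau_C = eta (E1+E2)/(E1 E2) and tau_R = eta/E2 for (E2, eta).

    This is the post-fit step of the finite-rate analysis: the curvefit
    yields (E1, tau_C, tau_R), and the Maxwell-arm constants follow from
    E2 = E1 (tau_C - tau_R) / tau_R and eta = tau_R E2.
    """
    E1 = _require_positive("E1", E1)
    tau_R = _require_positive("tau_R", tau_R)
    tau_C = float(tau_C)
    if not math.isfinite(tau_C) or tau_C <= tau_R:
        raise ValueError(
            f"tau_C must exceed tau_R for a physical SLS (got tau_C={tau_C!r}, tau_R={tau_R!r})"
        )
    E2 = E1 * (tau_C - tau_R) / tau_R
    return E2, tau_R * E2


def relaxation_modulus_dimensionless(t, q: PronyParameters):
    """One-branch dimensionless relaxation modulus g_R(t) = 1 - g (1 - e^{-t/tau_R})."""
    arr, scalar = _as_times(t)
    values = 1.0 + q.g * np.expm1(-arr / q.tau_R)
    return _maybe_scalar(values, scalar)


def _check_ramp_window(arr: np.ndarray, ramp_duration: float | None) -> None:
    if ramp_duration is not None:
        # allow the exact endpoint with a small relative slack
        if np.any(arr > ramp_duration * (1.0 + 1e-12) + 1e-300):
            raise ValueError("t outside the loading ramp window [0, t']")


def relaxation_loading_stress(t, p: SLSParameters, r: float, hold_strain: float | None = None):
    """Stress during the constant-strain-rate loading ramp of a relaxation test.

    sigma(t) = E1 r t + E1 r (tau_C - tau_R) (1 - e^{-t/tau_R}), valid on
    0 <= t <= t' = hold_strain / r.  The ramp window is enforced only when
    ``hold_strain`` is given.
    """
    r = _require_positive("r", r)
    arr, scalar = _as_times(t)
    _check_ramp_window(arr, None if hold_strain is None else hold_strain / r)
    values = p.E1 * r * arr - p.E1 * r * (p.tau_C - p.tau_R) * np.expm1(-arr / p.tau_R)
    return _maybe_scalar(values, scalar)


def relaxation_hold_amplitude(p: SLSParameters, proto: RelaxationProtocol) -> float:
    """Amplitude of the finite-rate relaxation decay, sigma0 - E1 eps0.

    E1 r (tau_C - tau_R) (1 - e^{-eps0/(tau_R r)}); evaluated with expm1 so
    fast ramps (r tau_R >> eps0) do not suffer catastrophic cancellation.
    Tends to E2 eps0 as r -> infinity and to 0 as r -> 0.
    """
    r = proto.strain_rate
    return -p.E1 * r * (p.tau_C - p.tau_R) * math.expm1(-proto.hold_strain / (p.tau_R * r))


def stress_at_ramp_end(p: SLSParameters, proto: RelaxationProtocol) -> float:
    """Stress sigma0 at the end of the loading ramp (t = t').

    sigma0 = E1 eps0 + E1 r (tau_C - tau_R)(1 - e^{-eps0/(tau_R r)}), i.e. the
    ramp solution evaluated at t' = eps0 / r.
    """
    return p.E1 * proto.hold_strain + relaxation_hold_amplitude(p, proto)


def relaxation_stress_finite(t, p: SLSParameters, proto: RelaxationProtocol, k: float = 1.0):
    """Finite-rate hold-phase stress of a relaxation test (t = 0 at hold start).

    sigma(t) = A e^{-(t/tau_R)^k} + E1 eps0 with ramp-history amplitude
    A = E1 r (tau_C - tau_R)(1 - e^{-eps0/(tau_R r)}).  ``k`` is the
    Kohlrausch stretch exponent; ``k = 1`` recovers the pure SLS solution.
    """
    k = _check_stretch_exponent(k)
    arr, scalar = _as_times(t)
    amp = relaxation_hold_amplitude(p, proto)
    values = amp * np.exp(-((arr / p.tau_R) ** k)) + p.E1 * proto.hold_strain
    return _maybe_scalar(values, scalar)


def relaxation_stress_infinite(t, p: SLSParameters, eps0: float):
    """Infinite-rate (step-strain) relaxation stress (E1 + E2 e^{-t/tau_R}) eps0."""
    eps0 = _require_positive("eps0", eps0)
    arr, scalar = _as_times(t)
    values = (p.E1 + p.E2 * np.exp(-arr / p.tau_R)) * eps0
    return _maybe_scalar(values, scalar)


def creep_loading_strain(t, p: SLSParameters, r: float, hold_stress: float | None = None):
    """Strain during the constant-stress-rate loading ramp of a creep test.

    eps(t) = (r/E1) t + (r/E1)(tau_R - tau_C)(1 - e^{-t/tau_C}), valid on
    0 <= t <= t' = hold_stress / r.  Because tau_R < tau_C the second term is
    negative: the strain lags the quasi-static line (r/E1) t.
    """
    r = _require_positive("r", r)
    arr, scalar = _as_times(t)
    _check_ramp_window(arr, None if hold_stress is None else hold_stress / r)
    values = (r / p.E1) * arr + (r / p.E1) * (p.tau_C - p.tau_R) * np.expm1(-arr / p.tau_C)
    return _maybe_scalar(values, scalar)


def creep_hold_amplitude(p: SLSParameters, proto: CreepProtocol) -> float:
    """Amplitude of the finite-rate creep transient, eps0 - sigma0/E1 (negative).

    (r/E1)(tau_R - tau_C)(1 - e^{-sigma0/(tau_C r)}); tends to
    -sigma0 E2 / (E1 (E1+E2)) as r -> infinity and to 0 as r -> 0 — the
    identifiability bottleneck of slow-ramp creep tests.
    """
    r = proto.stress_rate
    return (r / p.E1) * (p.tau_C - p.tau_R) * math.expm1(-proto.hold_stress / (p.tau_C * r))


def strain_at_ramp_end(p: SLSParameters, proto: CreepProtocol) -> float:
    """Strain eps0 at the end of the loading ramp (t = t' = sigma0 / r)."""
    return proto.hold_stress / p.E1 + creep_hold_amplitude(p, proto)


def creep_strain_finite(t, p: SLSParameters, proto: CreepProtocol, k: float = 1.0):
    """Finite-rate hold-phase strain of a creep test (t = 0 at hold start).

    eps(t) = A e^{-(t/tau_C)^k} + sigma0 / E1 with negative ramp-history
    amplitude A = (r/E1)(tau_R - tau_C)(1 - e^{-sigma0/(tau_C r)}), so the
    strain rises monotonically to the equilibrium compliance response.
    """
    k = _check_stretch_exponent(k)
    arr, scalar = _as_times(t)
    amp = creep_hold_amplitude(p, proto)
    values = amp * np.exp(-((arr / p.tau_C) ** k)) + proto.hold_stress / p.E1
    return _maybe_scalar(values, scalar)


def creep_strain_infinite(t, p: SLSParameters, sigma0: float):
    """Infinite-rate (step-stress) creep strain.

    eps(t) = (sigma0 / E1) (1 - (E2/(E1+E2)) e^{-t/tau_C}).
    """
    sigma0 = _require_positive("sigma0", sigma0)
    arr, scalar = _as_times(t)
    frac = p.E2 / (p.E1 + p.E2)
    values = (sigma0 / p.E1) * (1.0 - frac * np.exp(-arr / p.tau_C))
    return _maybe_scalar(values, scalar)
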