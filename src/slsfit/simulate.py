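"""Material-point ramp-hold test simulator and benchmark grid builder.

Simulates strain-controlled stress-relaxation and stress-controlled creep
tests of a standard-linear-solid material point.  For a linear, isotropic,
homogeneous specimen under uniform uniaxial ramp-hold loading every point of
the body follows the 1-D SLS constitutive relation

    sigma + tau_R dsigma/dt = E1 (eps + tau_C deps/dt),

so a material-point simulation is the desk-scale surrogate for a full
finite-element study of such a specimen.  Two generation methods are
provided: ``analytic`` evaluates the closed-form ramp/hold solutions, and
``ode`` integrates the governing relation with an adaptive solver — an
independent numerical oracle for validating the closed forms.

The benchmark grid mirrors a soft-tissue-mimicking hydrogel study design:
nine materials (E in {5, 10, 30} kPa crossed with tau_R in {0.5, 2, 5} s at
relaxation fraction g = 0.8) tested at seven decade-spaced loading rates,
holding 0.01 strain (relaxation) or 100 Pa (creep).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    CreepProtocol,
    PronyParameters,
    RelaxationProtocol,
    SLSParameters,
    creep_loading_strain,
    creep_strain_finite,
    prony_to_sls,
    relaxation_loading_stress,
    relaxation_stress_finite,
)

__all__ = [
    "SamplingPlan",
    "NoiseSpec",
    "TestCurve",
    "simulate_relaxation",
    "simulate_creep",
    "add_noise",
    "benchmark_materials",
    "build_benchmark_grid",
    "STRAIN_RATE_GRID",
    "STRESS_RATE_GRID",
    "RELAXATION_HOLD_STRAIN",
    "CREEP_HOLD_STRESS",
]

#: Strain rates (1/s) of the relaxation benchmark; ramp durations 100 .. 1e-4 s.
STRAIN_RATE_GRID: tuple[float, ...] = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0)
#: Stress rates (Pa/s) of the creep benchmark; ramp durations 100 .. 1e-4 s.
STRESS_RATE_GRID: tuple[float, ...] = (1.0, 10.0, 100.0, 1e3, 1e4, 1e5, 1e6)
#: Hold strain of the relaxation benchmark (0.1 mm on a 10 mm specimen).
RELAXATION_HOLD_STRAIN: float = 0.01
#: Hold stress of the creep benchmark, Pa.
CREEP_HOLD_STRESS: float = 100.0

#: Default hold duration as a multiple of the governing time constant
#: (tau_R for relaxation, tau_C for creep) so the plateau is reached.
DEFAULT_HOLD_MULTIPLIER: float = 8.0

_ODE_RTOL = 1e-9


@dataclass(frozen=True)
class SamplingPlan:
    """Uniform per-phase sampling: points on the ramp and on the hold."""

    ramp_points: int = 200
    hold_points: int = 1000

    def __post_init__(self) -> None:
        if self.ramp_points < 2 or self.hold_points < 2:
            raise ValueError("sampling requires at least 2 points per phase")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian noise on the measured channel, seeded."""

    relative_sd: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be non-negative")


@dataclass
class TestCurve:
    """A sampled ramp-hold test: time/stress/strain series with phase labels.

    ``time`` is the global clock (0 at load start); hold-phase model
    equations use ``time - time[first hold sample]``.  ``truth`` carries the
    generating material parameters when the curve is synthetic.
    """

    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest suite

    time: np.ndarray
    stress: np.ndarray
    strain: np.ndarray
    phase: np.ndarray
    kind: str  # "relaxation" | "creep"
    protocol: RelaxationProtocol | CreepProtocol | None = None
    truth: SLSParameters | None = None
    noise: NoiseSpec | None = None
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.strain = np.asarray(self.strain, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        n = len(self.time)
        if not (len(self.stress) == len(self.strain) == len(self.phase) == n):
            raise ValueError("time, stress, strain and phase must have equal length")
        if n and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not (np.all(np.isfinite(self.stress)) and np.all(np.isfinite(self.strain))):
            raise ValueError("stress and strain must be finite")
        if self.kind not in ("relaxation", "creep"):
            raise ValueError(f"unknown test kind {self.kind!r}")
        labels = set(self.phase.tolist())
        if not labels <= {"loading", "hold"}:
            raise ValueError(f"phase labels must be 'loading' or 'hold', got {labels}")
        is_hold = self.phase == "hold"
        if np.any(is_hold[:-1] & ~is_hold[1:]):
            raise ValueError("phase must be a 'loading' prefix followed by 'hold'")

    @property
    def loading_mask(self) -> np.ndarray:
        return self.phase == "loading"

    @property
    def hold_mask(self) -> np.ndarray:
        return self.phase == "hold"

    @property
    def measured(self) -> np.ndarray:
        """The monitored channel: stress for relaxation, strain for creep."""
        return self.stress if self.kind == "relaxation" else self.strain

    @property
    def controlled(self) -> np.ndarray:
        """The imposed channel: strain for relaxation, stress for creep."""
        return self.strain if self.kind == "relaxation" else self.stress


def _phase_times(proto, sampling: SamplingPlan) -> tuple[np.ndarray, np.ndarray, list[str]]:
    warnings: list[str] = []
    n_ramp = sampling.ramp_points
    if n_ramp < 10:
        warnings.append(
            f"ramp sampling of {n_ramp} points is too coarse; increased to 50"
        )
        n_ramp = 50
    tp = proto.ramp_duration
    t_ramp = np.linspace(0.0, tp, n_ramp, endpoint=False)
    t_hold = tp + np.linspace(0.0, proto.hold_duration, sampling.hold_points)
    return t_ramp, t_hold, warnings


def _integrate(rhs_ramp, rhs_hold, y0: float, t_ramp, t_hold, scale: float):
    """Piecewise adaptive integration of a scalar linear ODE across ramp+hold."""
    tp = t_hold[0]
    sol1 = solve_ivp(
        rhs_ramp,
        (0.0, tp),
        [y0],
        method="LSODA",
        t_eval=np.append(t_ramp, tp),
        rtol=_ODE_RTOL,
        atol=1e-12 * scale,
    )
    if not sol1.success:
        raise RuntimeError(f"ramp-phase ODE integration failed: {sol1.message}")
    sol2 = solve_ivp(
        rhs_hold,
        (tp, t_hold[-1]),
        [sol1.y[0, -1]],
        method="LSODA",
        t_eval=t_hold,
        rtol=_ODE_RTOL,
        atol=1e-12 * scale,
    )
    if not sol2.success:
        raise RuntimeError(f"hold-phase ODE integration failed: {sol2.message}")
    return sol1.y[0, :-1], sol2.y[0]


def simulate_relaxation(
    p: SLSParameters,
    proto: RelaxationProtocol,
    sampling: SamplingPlan | None = None,
    method: str = "analytic",
) -> TestCurve:
    """Simulate a strain-controlled ramp-hold stress-relaxation test.

    The strain is r*t on the ramp and eps0 on the hold; the stress follows
    the closed-form ramp/hold solutions (``analytic``) or an adaptive
    integration of sigma + tau_R sigma' = E1 (eps + tau_C eps')  (``ode``).
    """
    sampling = sampling or SamplingPlan()
    t_ramp, t_hold, warns = _phase_times(proto, sampling)
    r, eps0 = proto.strain_rate, proto.hold_strain
    strain = np.concatenate([r * t_ramp, np.full(t_hold.size, eps0)])
    if method == "analytic":
        s_ramp = relaxation_loading_stress(t_ramp, p, r)
        s_hold = relaxation_stress_finite(t_hold - t_hold[0], p, proto, k=1.0)
    elif method == "ode":
        def rhs_ramp(t, y):
            return [(p.E1 * (r * t + p.tau_C * r) - y[0]) / p.tau_R]

        def rhs_hold(t, y):
            return [(p.E1 * eps0 - y[0]) / p.tau_R]

        scale = (p.E1 + p.E2) * eps0
        s_ramp, s_hold = _integrate(rhs_ramp, rhs_hold, 0.0, t_ramp, t_hold, scale)
    else:
        raise ValueError(f"unknown method {method!r}; use 'analytic' or 'ode'")
    stress = np.concatenate([s_ramp, s_hold])
    phase = np.array(["loading"] * t_ramp.size + ["hold"] * t_hold.size, dtype=object)
    return TestCurve(
        time=np.concatenate([t_ramp, t_hold]),
        stress=stress,
        strain=strain,
        phase=phase,
        kind="relaxation",
        protocol=proto,
        truth=p,
        warnings=tuple(warns),
    )


def simulate_creep(
    p: SLSParameters,
    proto: CreepProtocol,
    sampling: SamplingPlan | None = None,
    method: str = "analytic",
) -> TestCurve:
    """Simulate a stress-controlled ramp-hold creep test (mirror of relaxation)."""
    sampling = sampling or SamplingPlan()
    t_ramp, t_hold, warns = _phase_times(proto, sampling)
    r, sigma0 = proto.stress_rate, proto.hold_stress
    stress = np.concatenate([r * t_ramp, np.full(t_hold.size, sigma0)])
    if method == "analytic":
        e_ramp = creep_loading_strain(t_ramp, p, r)
        e_hold = creep_strain_finite(t_hold - t_hold[0], p, proto, k=1.0)
    elif method == "ode":
        def rhs_ramp(t, y):
            return [(r * t + p.tau_R * r - p.E1 * y[0]) / (p.E1 * p.tau_C)]

        def rhs_hold(t, y):
            return [(sigma0 - p.E1 * y[0]) / (p.E1 * p.tau_C)]

        scale = sigma0 / p.E1
        e_ramp, e_hold = _integrate(rhs_ramp, rhs_hold, 0.0, t_ramp, t_hold, scale)
    else:
        raise ValueError(f"unknown method {method!r}; use 'analytic' or 'ode'")
    strain = np.concatenate([e_ramp, e_hold])
    phase = np.array(["loading"] * t_ramp.size + ["hold"] * t_hold.size, dtype=object)
    return TestCurve(
        time=np.concatenate([t_ramp, t_hold]),
        stress=stress,
        strain=strain,
        phase=phase,
        kind="creep",
        protocol=proto,
        truth=p,
        warnings=tuple(warns),
    )


def add_noise(curve: TestCurve, spec: NoiseSpec) -> TestCurve:
    """Apply seeded multiplicative Gaussian noise to the measured channel.

    Relaxation curves are noisy in stress, creep curves in strain (the
    controlled channel is assumed exact).  Reproducible from ``spec.seed``.
    """
    if spec.relative_sd == 0.0:
        return replace(curve, noise=spec)
    rng = np.random.default_rng(spec.seed)
    factor = 1.0 + spec.relative_sd * rng.standard_normal(curve.time.size)
    if curve.kind == "relaxation":
        return replace(curve, stress=curve.stress * factor, noise=spec)
    return replace(curve, strain=curve.strain * factor, noise=spec)


def benchmark_materials() -> list[SLSParameters]:
    """The nine benchmark hydrogel-like materials, in SI units.

    E in {5, 10, 30} kPa crossed with tau_R in {0.5, 2, 5} s at g = 0.8,
    i.e. E1 = E, E2 = 4 E, eta = tau_R E2 — moduli and relaxation times in
    the range reported for soft tissues.
    """
    materials = []
    for E_kpa in (5.0, 10.0, 30.0):
        for tau_R in (0.5, 2.0, 5.0):
            materials.append(prony_to_sls(PronyParameters(E=E_kpa * 1e3, g=0.8, tau_R=tau_R)))
    return materials


def build_benchmark_grid(
    kind: str,
    hold_multiplier: float = DEFAULT_HOLD_MULTIPLIER,
) -> list[tuple[SLSParameters, RelaxationProtocol | CreepProtocol]]:
    """Build the full 9-material x 7-rate trial list for one test kind.

    Relaxation trials hold eps0 = 0.01 and sweep strain rates 1e-4 .. 100 1/s;
    creep trials hold sigma0 = 100 Pa and sweep stress rates 1 .. 1e6 Pa/s.
    Hold durations are ``hold_multiplier`` governing time constants.
    """
    if kind == "relaxation":
        return [
            (p, RelaxationProtocol(r, RELAXATION_HOLD_STRAIN, hold_multiplier * p.tau_R))
            for p in benchmark_materials()
            for r in STRAIN_RATE_GRID
        ]
    if kind == "creep":
        return [
            (p, CreepProtocol(r, CREEP_HOLD_STRESS, hold_multiplier * p.tau_C))
            for p in benchmark_materials()
            for r in STRESS_RATE_GRID
        ]
    raise ValueError(f"unknown kind {kind!r}; use 'relaxation' or 'creep'")
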