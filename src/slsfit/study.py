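"""Batch validation pipeline: simulate benchmark grids, fit, tabulate errors.

Runs the 9-material x 7-rate ramp-hold benchmark for one test kind, fits
every curve with the requested equation forms, and collects per-parameter
relative errors against the generating materials.  Downstream utilities
locate the accuracy threshold of each error-vs-rate series (smallest grid
rate at which the error stays below the criterion at all faster rates) and
relate thresholds to the relaxation time constant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import (
    error_report,
    fit_creep_finite,
    fit_creep_infinite,
    fit_relaxation_finite,
    fit_relaxation_infinite,
)
from .model import CreepProtocol, RelaxationProtocol, SLSParameters, sls_to_prony
from .simulate import (
    CREEP_HOLD_STRESS,
    DEFAULT_HOLD_MULTIPLIER,
    RELAXATION_HOLD_STRAIN,
    STRAIN_RATE_GRID,
    STRESS_RATE_GRID,
    NoiseSpec,
    SamplingPlan,
    add_noise,
    benchmark_materials,
    simulate_creep,
    simulate_relaxation,
)

__all__ = [
    "SweepConfig",
    "SweepResult",
    "run_sweep",
    "detect_threshold",
    "threshold_table",
    "threshold_vs_tauR",
    "report",
    "ACCURACY_CRITERION",
]

#: Accuracy criterion of the validation study: a fit is accurate if the
#: relative error is below 5%.
ACCURACY_CRITERION = 0.05

_FITTERS = {
    ("relaxation", "finite"): fit_relaxation_finite,
    ("relaxation", "infinite"): fit_relaxation_infinite,
    ("creep", "finite"): fit_creep_finite,
    ("creep", "infinite"): fit_creep_infinite,
}

_SENTINEL = "none within grid"


@dataclass(frozen=True)
class SweepConfig:
    """Study conditions for one benchmark sweep.

    Defaults reproduce the benchmark design: all nine materials, the full
    decade rate grid of the test kind, hold levels 0.01 strain / 100 Pa,
    hold durations of 8 governing time constants, noiseless curves.
    """

    materials: tuple[SLSParameters, ...] | None = None
    rates: tuple[float, ...] | None = None
    hold_strain: float = RELAXATION_HOLD_STRAIN
    hold_stress: float = CREEP_HOLD_STRESS
    hold_multiplier: float = DEFAULT_HOLD_MULTIPLIER
    sampling: SamplingPlan = field(default_factory=SamplingPlan)
    noise_sd: float = 0.0
    seed: int | None = None
    fit_k: bool = True

    def resolve(self, kind: str) -> tuple[tuple[SLSParameters, ...], tuple[float, ...]]:
        materials = self.materials or tuple(benchmark_materials())
        default_rates = STRAIN_RATE_GRID if kind == "relaxation" else STRESS_RATE_GRID
        rates = self.rates or default_rates
        if self.noise_sd > 0 and self.seed is None:
            raise ValueError("a seed is required when noise_sd > 0")
        return materials, tuple(rates)

    def to_record(self, kind: str) -> dict:
        materials, rates = self.resolve(kind)
        return {
            "kind": kind,
            "materials": [[p.E1, p.E2, p.eta] for p in materials],
            "rates": list(rates),
            "hold_strain": self.hold_strain,
            "hold_stress": self.hold_stress,
            "hold_multiplier": self.hold_multiplier,
            "sampling": [self.sampling.ramp_points, self.sampling.hold_points],
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "fit_k": self.fit_k,
        }


@dataclass
class SweepResult:
    """Tidy error table for one sweep plus the configuration that made it.

    ``errors`` has one row per (material, rate, form, parameter) with the
    relative error in percent; failed fits appear as flagged rows with NaN
    errors, never as gaps.
    """

    kind: str
    forms: tuple[str, ...]
    config: SweepConfig
    errors: pd.DataFrame

    def error_series(self, form: str, parameter: str, model_id: int) -> tuple[np.ndarray, np.ndarray]:
        """(rates ascending, errors as fractions) for one model/form/parameter."""
        sel = self.errors[
            (self.errors["form"] == form)
            & (self.errors["parameter"] == parameter)
            & (self.errors["model_id"] == model_id)
        ].sort_values("rate")
        return sel["rate"].to_numpy(), sel["relative_error_pct"].to_numpy() / 100.0

    def model_ids(self) -> list[int]:
        return sorted(self.errors["model_id"].unique())


def _derive_seed(base: int, index: int) -> int:
    return (base * 100003 + index * 7919) % (2**31 - 1)


def run_sweep(
    kind: str,
    forms: tuple[str, ...] = ("finite", "infinite"),
    config: SweepConfig | None = None,
) -> SweepResult:
    """Simulate the benchmark grid of ``kind`` and fit with every requested form.

    Deterministic given the config (bitwise so for noiseless runs).  A fit
    that raises is recorded as a non-converged row with NaN errors.
    """
    if kind not in ("relaxation", "creep"):
        raise ValueError(f"unknown kind {kind!r}")
    if not forms:
        raise ValueError("at least one equation form is required")
    for form in forms:
        if form not in ("finite", "infinite"):
            raise ValueError(f"unknown form {form!r}")
    config = config or SweepConfig()
    materials, rates = config.resolve(kind)

    rows = []
    trial = 0
    for model_id, p in enumerate(materials, start=1):
        q = sls_to_prony(p)
        for rate in rates:
            if kind == "relaxation":
                proto = RelaxationProtocol(
                    rate, config.hold_strain, config.hold_multiplier * p.tau_R
                )
                curve = simulate_relaxation(p, proto, config.sampling)
            else:
                proto = CreepProtocol(
                    rate, config.hold_stress, config.hold_multiplier * p.tau_C
                )
                curve = simulate_creep(p, proto, config.sampling)
            if config.noise_sd > 0:
                curve = add_noise(
                    curve, NoiseSpec(config.noise_sd, _derive_seed(config.seed, trial))
                )
            trial += 1
            for form in forms:
                fitter = _FITTERS[(kind, form)]
                base = {
                    "model_id": model_id,
                    "E_kPa": p.E1 / 1e3,
                    "tau_R_s": p.tau_R,
                    "g": q.g,
                    "rate": rate,
                    "form": form,
                }
                try:
                    if form == "finite":
                        fit = fitter(curve, proto, fit_k=config.fit_k)
                    else:
                        fit = fitter(curve, proto)
                    rep = error_report(fit, p)
                    estimates = {"E1": fit.E1, "E2": fit.E2, "eta": fit.eta}
                    truths = {"E1": p.E1, "E2": p.E2, "eta": p.eta}
                    for param in ("E1", "E2", "eta"):
                        rows.append(
                            base
                            | {
                                "parameter": param,
                                "estimate": estimates[param],
                                "truth": truths[param],
                                "relative_error_pct": 100.0 * getattr(rep, param),
                                "converged": fit.converged,
                                "condition_warning": fit.condition_warning,
                                "error_message": "",
                            }
                        )
                except Exception as exc:  # failed fits become flagged rows
                    for param in ("E1", "E2", "eta"):
                        rows.append(
                            base
                            | {
                                "parameter": param,
                                "estimate": np.nan,
                                "truth": getattr(p, param if param != "eta" else "eta"),
                                "relative_error_pct": np.nan,
                                "converged": False,
                                "condition_warning": True,
                                "error_message": f"{type(exc).__name__}: {exc}",
                            }
                        )
    return SweepResult(kind=kind, forms=tuple(forms), config=config, errors=pd.DataFrame(rows))


def detect_threshold(rates, errors, criterion: float = ACCURACY_CRITERION):
    """Smallest rate at which the error is below ``criterion`` there and at
    every faster grid rate; ``None`` if no rate qualifies.

    ``errors`` are fractions aligned with ``rates`` (ascending); NaN entries
    count as failures.
    """
    rates = np.asarray(rates, dtype=float)
    errors = np.asarray(errors, dtype=float)
    if rates.size == 0:
        raise ValueError("empty rate series")
    if np.any(np.diff(rates) <= 0):
        raise ValueError("rates must be sorted ascending")
    below = (errors < criterion) & np.isfinite(errors)
    for i in range(rates.size):
        if below[i:].all():
            return float(rates[i])
    return None


def threshold_table(
    sweep: SweepResult,
    form: str,
    parameter: str,
    criterion: float = ACCURACY_CRITERION,
) -> pd.DataFrame:
    """Per-model accuracy thresholds for one form/parameter."""
    rows = []
    for model_id in sweep.model_ids():
        rates, errs = sweep.error_series(form, parameter, model_id)
        sel = sweep.errors[sweep.errors["model_id"] == model_id].iloc[0]
        rows.append(
            {
                "model_id": model_id,
                "E_kPa": sel["E_kPa"],
                "tau_R_s": sel["tau_R_s"],
                "form": form,
                "parameter": parameter,
                "threshold_rate": detect_threshold(rates, errs, criterion),
            }
        )
    return pd.DataFrame(rows)


def threshold_vs_tauR(
    sweep: SweepResult,
    form: str = "infinite",
    parameter: str = "E2",
    criterion: float = ACCURACY_CRITERION,
) -> pd.DataFrame:
    """Accuracy threshold pivoted by modulus (rows) and tau_R (columns).

    Expresses the observation that materials with shorter relaxation times
    need faster loading for the step-loading forms to be accurate: at fixed
    modulus the threshold is non-increasing in tau_R.
    """
    table = threshold_table(sweep, form, parameter, criterion)
    if table["tau_R_s"].nunique() < 2:
        raise ValueError("threshold-vs-tau_R analysis needs >= 2 distinct tau_R values")
    return table.pivot_table(
        index="E_kPa", columns="tau_R_s", values="threshold_rate", aggfunc="first"
    )


def _config_hash(record: dict) -> str:
    return hashlib.sha256(json.dumps(record, sort_keys=True).encode()).hexdigest()[:16]


def report(
    sweep: SweepResult,
    out_dir: str | Path,
    criterion: float = ACCURACY_CRITERION,
    plots: bool = False,
) -> dict[str, Path]:
    """Write the tidy error table, threshold tables and a run manifest.

    Returns a mapping of artifact names to paths.  With ``plots=True`` an
    error-vs-rate figure (log-rate axes; one panel grid of modulus x
    parameter, one line per tau_R) is written per form.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    errors_path = out_dir / f"errors_{sweep.kind}.csv"
    sweep.errors.to_csv(errors_path, index=False)
    paths["errors"] = errors_path

    tables = []
    for form in sweep.forms:
        for parameter in ("E1", "E2", "eta"):
            tables.append(threshold_table(sweep, form, parameter, criterion))
    thresholds = pd.concat(tables, ignore_index=True)
    thresholds["threshold_rate"] = thresholds["threshold_rate"].map(
        lambda v: _SENTINEL if v is None or (isinstance(v, float) and np.isnan(v)) else v
    )
    thresholds_path = out_dir / f"thresholds_{sweep.kind}.csv"
    thresholds.to_csv(thresholds_path, index=False)
    paths["thresholds"] = thresholds_path

    record = sweep.config.to_record(sweep.kind)
    manifest = {
        "kind": sweep.kind,
        "forms": list(sweep.forms),
        "criterion": criterion,
        "config": record,
        "config_hash": _config_hash(record),
        "n_rows": int(len(sweep.errors)),
    }
    manifest_path = out_dir / f"manifest_{sweep.kind}.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = manifest_path

    if plots:
        paths["plots"] = _plot_errors(sweep, out_dir, criterion)
    return paths


def _plot_errors(sweep: SweepResult, out_dir: Path, criterion: float) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rate_label = "strain rate (1/s)" if sweep.kind == "relaxation" else "stress rate (Pa/s)"
    moduli = sorted(sweep.errors["E_kPa"].unique())
    params = ("E1", "E2", "eta")
    last = None
    for form in sweep.forms:
        fig, axes = plt.subplots(
            len(moduli), len(params), figsize=(11, 8), sharex=True, squeeze=False
        )
        for i, E_kpa in enumerate(moduli):
            for j, param in enumerate(params):
                ax = axes[i][j]
                sub = sweep.errors[
                    (sweep.errors["form"] == form)
                    & (sweep.errors["parameter"] == param)
                    & (sweep.errors["E_kPa"] == E_kpa)
                ]
                for tau_R, grp in sub.groupby("tau_R_s"):
                    grp = grp.sort_values("rate")
                    ax.plot(grp["rate"], grp["relative_error_pct"], "o-", label=f"tau_R={tau_R} s")
                ax.axhline(100 * criterion, ls=":", color="green")
                ax.set_xscale("log")
                if i == len(moduli) - 1:
                    ax.set_xlabel(rate_label)
                if j == 0:
                    ax.set_ylabel(f"E = {E_kpa:g} kPa\nerror (%)")
                if i == 0:
                    ax.set_title(param)
        axes[0][0].legend(fontsize=8)
        fig.suptitle(f"{sweep.kind} — {form}-rate form")
        fig.tight_layout()
        last = out_dir / f"errors_{sweep.kind}_{form}.png"
        fig.savefig(last, dpi=120)
        plt.close(fig)
    return last
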