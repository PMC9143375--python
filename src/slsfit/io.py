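"""Plain-text I/O for test curves: CSV series plus a JSON metadata sidecar.

The CSV schema is ``time_s, stress_Pa, strain, phase`` with phase labels
``loading``/``hold``; the sidecar (``<stem>.meta.json`` next to the CSV)
records the test kind, protocol, generating parameters when known, the noise
spec and any simulator warnings, so a curve round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .model import CreepProtocol, RelaxationProtocol, SLSParameters
from .simulate import NoiseSpec, TestCurve

__all__ = ["write_curve", "read_curve", "sidecar_path"]


def sidecar_path(csv_path: str | Path) -> Path:
    csv_path = Path(csv_path)
    return csv_path.with_name(csv_path.stem + ".meta.json")


def _protocol_record(proto) -> dict | None:
    if proto is None:
        return None
    if isinstance(proto, RelaxationProtocol):
        return {
            "type": "relaxation",
            "strain_rate_per_s": proto.strain_rate,
            "hold_strain": proto.hold_strain,
            "hold_duration_s": proto.hold_duration,
        }
    return {
        "type": "creep",
        "stress_rate_Pa_per_s": proto.stress_rate,
        "hold_stress_Pa": proto.hold_stress,
        "hold_duration_s": proto.hold_duration,
    }


def _protocol_from_record(rec: dict | None):
    if rec is None:
        return None
    if rec["type"] == "relaxation":
        return RelaxationProtocol(
            rec["strain_rate_per_s"], rec["hold_strain"], rec["hold_duration_s"]
        )
    return CreepProtocol(
        rec["stress_rate_Pa_per_s"], rec["hold_stress_Pa"], rec["hold_duration_s"]
    )


def write_curve(curve: TestCurve, csv_path: str | Path) -> tuple[Path, Path]:
    """Write a curve as CSV plus JSON sidecar; returns both paths."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame(
        {
            "time_s": curve.time,
            "stress_Pa": curve.stress,
            "strain": curve.strain,
            "phase": curve.phase,
        }
    )
    frame.to_csv(csv_path, index=False, float_format="%.17g")
    meta = {
        "kind": curve.kind,
        "protocol": _protocol_record(curve.protocol),
        "truth": None
        if curve.truth is None
        else {"E1_Pa": curve.truth.E1, "E2_Pa": curve.truth.E2, "eta_Pa_s": curve.truth.eta},
        "noise": None
        if curve.noise is None
        else {"relative_sd": curve.noise.relative_sd, "seed": curve.noise.seed},
        "warnings": list(curve.warnings),
    }
    meta_path = sidecar_path(csv_path)
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    return csv_path, meta_path


def read_curve(csv_path: str | Path, kind: str | None = None) -> TestCurve:
    """Read a curve CSV; the sidecar is used when present, else ``kind`` is required."""
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path, float_precision="round_trip")
    required = {"time_s", "stress_Pa", "strain", "phase"}
    if not required <= set(frame.columns):
        raise ValueError(f"curve CSV must have columns {sorted(required)}")
    meta_path = sidecar_path(csv_path)
    protocol = truth = noise = None
    warnings: tuple[str, ...] = ()
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        kind = meta.get("kind", kind)
        protocol = _protocol_from_record(meta.get("protocol"))
        if meta.get("truth") is not None:
            t = meta["truth"]
            truth = SLSParameters(t["E1_Pa"], t["E2_Pa"], t["eta_Pa_s"])
        if meta.get("noise") is not None:
            noise = NoiseSpec(meta["noise"]["relative_sd"], meta["noise"]["seed"])
        warnings = tuple(meta.get("warnings", ()))
    if kind is None:
        raise ValueError(
            "test kind unknown: no metadata sidecar found and no kind given"
        )
    return TestCurve(
        time=frame["time_s"].to_numpy(),
        stress=frame["stress_Pa"].to_numpy(),
        strain=frame["strain"].to_numpy(),
        phase=frame["phase"].to_numpy(dtype=object),
        kind=kind,
        protocol=protocol,
        truth=truth,
        noise=noise,
        warnings=warnings,
    )
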