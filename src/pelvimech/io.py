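"""File formats, run configuration and reporting.

Interchange dialect: tidy UTF-8 CSV with a header row and '.' decimals,
units fixed in the column names (s, pct, N, MPa, cmH2O, uV, Hz), plus JSON
sidecars for everything that is not a time series (geometry, protocol,
markers, ground truth, statistics). Numeric payloads round-trip to 1e-9
relative precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .ephys import AnimalOutcome
from .synthetic import (
    CohortTruth,
    MechProtocol,
    MechTrace,
    NeuroTrace,
    PressureTrace,
    SpecimenGeometry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_mech_trace",
    "write_mech_trace",
    "read_pressure_trace",
    "write_pressure_trace",
    "read_neuro_trace",
    "write_neuro_trace",
    "read_outcomes",
    "write_outcomes",
    "write_truth",
    "read_truth_frame",
    "write_report",
]

_FLOAT_FMT = "%.12g"

MECH_COLUMNS = ["time_s", "strain_x_pct", "strain_y_pct", "force_x_N", "force_y_N"]


@dataclass
class RunConfig:
    """Serializable run configuration (YAML); unknown keys are rejected."""

    seed: int = 0
    k_last: int = 3
    window_pct: float = 1.0
    threshold_sd: float = 4.5
    noise_estimator: str = "mad"
    dunn_method: str = "bonferroni"
    alpha: float = 0.05
    fit_scope: str = "per_cycle"
    strain_levels: Tuple[float, ...] | None = None
    cycles_per_level: int | None = None
    n_per_group: Dict[str, int] | None = None
    between_animal_cv: float | None = None

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strain_levels" in data and data["strain_levels"] is not None:
            data["strain_levels"] = tuple(data["strain_levels"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        if data.get("strain_levels") is not None:
            data["strain_levels"] = list(data["strain_levels"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:12]


def _read_csv_checked(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def write_mech_trace(trace: MechTrace, csv_path: str | Path) -> None:
    """CSV of the five channels plus a JSON sidecar with geometry/protocol."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time_s": trace.time,
            "strain_x_pct": trace.strain_x,
            "strain_y_pct": trace.strain_y,
            "force_x_N": trace.force_x,
            "force_y_N": trace.force_y,
        }
    ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "specimen_id": trace.specimen_id,
        "geometry": dataclasses.asdict(trace.geometry),
        "protocol": dataclasses.asdict(trace.protocol),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=list))


def read_mech_trace(csv_path: str | Path) -> MechTrace:
    csv_path = Path(csv_path)
    df = _read_csv_checked(csv_path, MECH_COLUMNS)
    sidecar_path = csv_path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"{csv_path}: missing sidecar {sidecar_path.name}")
    meta = json.loads(sidecar_path.read_text())
    time = df["time_s"].to_numpy()
    if not np.all(np.diff(time) > 0):
        bad = int(np.flatnonzero(np.diff(time) <= 0)[0]) + 2  # 1-based data line
        raise ValueError(f"{csv_path}: time_s not strictly increasing at data row {bad}")
    proto = meta["protocol"]
    proto["strain_levels"] = tuple(proto["strain_levels"])
    return MechTrace(
        time=time,
        strain_x=df["strain_x_pct"].to_numpy(),
        strain_y=df["strain_y_pct"].to_numpy(),
        force_x=df["force_x_N"].to_numpy(),
        force_y=df["force_y_N"].to_numpy(),
        geometry=SpecimenGeometry(**meta["geometry"]),
        protocol=MechProtocol(**proto),
        specimen_id=meta.get("specimen_id", csv_path.stem),
    )


def write_pressure_trace(trace: PressureTrace, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time, "value": trace.pressure}).to_csv(
        csv_path, index=False, float_format=_FLOAT_FMT
    )
    markers = {
        "kind": "pressure_cmH2O",
        "baseline_window": list(trace.baseline_window),
        "peak_time": trace.peak_time,
        "ramp_onset": trace.ramp_onset,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(markers, indent=2))


def read_pressure_trace(csv_path: str | Path) -> PressureTrace:
    csv_path = Path(csv_path)
    df = _read_csv_checked(csv_path, ["time_s", "value"])
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    if meta.get("kind") != "pressure_cmH2O":
        raise ValueError(f"{csv_path}: sidecar does not describe a pressure trace")
    return PressureTrace(
        time=df["time_s"].to_numpy(),
        pressure=df["value"].to_numpy(),
        baseline_window=tuple(meta["baseline_window"]),
        peak_time=meta["peak_time"],
        ramp_onset=meta["ramp_onset"],
    )


def write_neuro_trace(trace: NeuroTrace, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.time, "value": trace.voltage}).to_csv(
        csv_path, index=False, float_format=_FLOAT_FMT
    )
    markers = {
        "kind": "voltage_uV",
        "channel": trace.channel,
        "sample_rate_Hz": trace.sample_rate,
        "baseline_window": list(trace.baseline_window),
        "stim_window": list(trace.stim_window),
        "raw": trace.raw,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(markers, indent=2))


def read_neuro_trace(csv_path: str | Path) -> NeuroTrace:
    csv_path = Path(csv_path)
    df = _read_csv_checked(csv_path, ["time_s", "value"])
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    if meta.get("kind") != "voltage_uV":
        raise ValueError(f"{csv_path}: sidecar does not describe a voltage trace")
    return NeuroTrace(
        time=df["time_s"].to_numpy(),
        voltage=df["value"].to_numpy(),
        sample_rate=meta["sample_rate_Hz"],
        channel=meta["channel"],
        baseline_window=tuple(meta["baseline_window"]),
        stim_window=tuple(meta["stim_window"]),
        raw=meta.get("raw", False),
    )


def write_outcomes(outcomes: pd.DataFrame, path: str | Path) -> None:
    """Tidy per-animal outcomes CSV (animal_id, group, metric, value)."""
    outcomes.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_outcomes(path: str | Path) -> pd.DataFrame:
    return _read_csv_checked(path, ["animal_id", "group", "metric", "value"])


def write_truth(truth: CohortTruth, path: str | Path) -> None:
    """Cohort ground truth as JSON (per-animal parameters and targets)."""
    payload = []
    for a in truth.animals:
        payload.append(
            {
                "animal_id": a.animal_id,
                "group": a.group,
                "mech_params": dataclasses.asdict(a.mech),
                "ephys_params": dataclasses.asdict(a.ephys),
                "tangent_modulus_MPa": {ax: {str(k): v for k, v in d.items()}
                                        for ax, d in a.tangent_modulus.items()},
                "window_slope_MPa": {ax: {str(k): v for k, v in d.items()}
                                     for ax, d in a.window_slope.items()},
                "anisotropy_index": {str(k): v for k, v in a.anisotropy_index.items()},
                "lpp_cmH2O": a.lpp,
                "d_rate_Hz": a.d_rate,
            }
        )
    Path(path).write_text(json.dumps({"animals": payload}, indent=2))


def read_truth_frame(path: str | Path) -> pd.DataFrame:
    """Ground-truth tangent moduli as a tidy frame for recovery checks."""
    data = json.loads(Path(path).read_text())
    rows = []
    for a in data["animals"]:
        for ax, d in a["tangent_modulus_MPa"].items():
            for level, v in d.items():
                rows.append(
                    {
                        "specimen_id": a["animal_id"],
                        "group": a["group"],
                        "axis": ax,
                        "strain_level_pct": float(level),
                        "true_tangent_modulus_MPa": v,
                    }
                )
    return pd.DataFrame(rows)


def write_report(report: Dict, out_dir: str | Path, make_plots: bool = False) -> Path:
    """Write the composed analysis report as JSON (optionally with plots).

    Returns the path of the JSON report. Plots are per-metric group bar
    charts (mean +/- SEM), written as PNG next to the report.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    if make_plots and "summaries" in report:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for metric, entries in report["summaries"].items():
            fig, ax = plt.subplots(figsize=(4, 3))
            names = [e["group"] for e in entries]
            means = [e["mean"] for e in entries]
            sems = [0.0 if e["sem"] is None or math.isnan(e["sem"]) else e["sem"]
                    for e in entries]
            ax.bar(range(len(names)), means, yerr=sems, capsize=3, color="0.4")
            ax.set_xticks(range(len(names)))
            ax.set_xticklabels(names, rotation=30, ha="right", fontsize=7)
            ax.set_ylabel(metric)
            fig.tight_layout()
            fig.savefig(out_dir / f"{metric}.png", dpi=100)
            plt.close(fig)
    return path
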