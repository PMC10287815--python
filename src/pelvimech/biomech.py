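"""Biaxial biomechanics analysis.

Turns a raw equibiaxial cyclic tension record into per-specimen stiffness
metrics: nominal stress/strain conversion, cycle segmentation, steady-cycle
selection (last 3 of 10), first-order-fit mean slope over loading and
unloading limbs, tangent modulus over the last 1% strain of the loading
limb, and the Anisotropy Index (longitudinal / transverse tangent modulus).

Conventions
-----------
- Nominal (engineering) stress: force divided by the *initial* cross-section
  thickness x width, in MPa (N/mm^2). Engineering strain, stored as % in raw
  traces and converted to a fraction for all fits.
- Metrics are computed per cycle and the per-cycle values averaged over the
  selected steady cycles ("per_cycle" scope); a "pooled" scope that fits one
  line through the concatenated points of the selected cycles is available
  as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Literal, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .synthetic import MechProtocol, MechTrace

__all__ = [
    "StressStrainSeries",
    "Cycle",
    "SpecimenMechanics",
    "compute_stress_strain",
    "segment_cycles",
    "select_steady_cycles",
    "mean_slope",
    "tangent_modulus",
    "anisotropy_index",
    "analyze_specimen",
    "mechanics_to_frames",
]

AXIS_NAMES = {"x": "longitudinal", "y": "transverse"}


@dataclass
class StressStrainSeries:
    """One axis of a biaxial test: strain (fraction), stress (MPa), time (s)."""

    axis: str
    strain: np.ndarray
    stress: np.ndarray
    time: np.ndarray

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if not (len(self.strain) == len(self.stress) == len(self.time)):
            raise ValueError("strain, stress and time must have equal lengths")
        if self.axis not in ("x", "y"):
            raise ValueError(f"unknown axis {self.axis!r}")


@dataclass
class Cycle:
    """One load/unload cycle assigned to a protocol strain level."""

    level: float  # protocol strain level, %
    index: int    # 1-based cycle index within its level
    loading_strain: np.ndarray
    loading_stress: np.ndarray
    unloading_strain: np.ndarray
    unloading_stress: np.ndarray

    @property
    def peak_strain(self) -> float:
        return float(np.max(self.loading_strain))


@dataclass
class SpecimenMechanics:
    """Per-specimen stiffness metrics.

    ``mean_slope`` and ``tangent_modulus`` map axis -> level% -> MPa;
    ``anisotropy_index`` maps level% -> longitudinal/transverse modulus ratio.
    """

    specimen_id: str
    mean_slope: Dict[str, Dict[float, float]] = field(default_factory=dict)
    tangent_modulus: Dict[str, Dict[float, float]] = field(default_factory=dict)
    anisotropy_index: Dict[float, float] = field(default_factory=dict)
    group: str | None = None


def compute_stress_strain(trace: MechTrace) -> Tuple[StressStrainSeries, StressStrainSeries]:
    """Convert a raw force/strain record to nominal stress-strain, both axes.

    Stress_a = force_a / (thickness * width_a) in MPa; strain % -> fraction.
    Returns (x=longitudinal, y=transverse).
    """
    geom = trace.geometry
    out = []
    for axis, strain_pct, force in (
        ("x", trace.strain_x, trace.force_x),
        ("y", trace.strain_y, trace.force_y),
    ):
        area = geom.area(axis)  # validated positive by SpecimenGeometry
        out.append(
            StressStrainSeries(
                axis=axis,
                strain=strain_pct / 100.0,
                stress=force / area,
                time=trace.time,
            )
        )
    return out[0], out[1]


def segment_cycles(series: StressStrainSeries, protocol: MechProtocol) -> List[Cycle]:
    """Split a stress-strain series into load/unload cycles per strain level.

    Cycles are delimited by strain minima (troughs of the triangle wave);
    each cycle splits into loading/unloading at its strain maximum and is
    assigned to the nearest protocol level (ties to the lower level).

    Raises ``ValueError`` naming the level if any protocol level ends up
    with fewer than 3 cycles.
    """
    strain = series.strain
    levels = np.asarray(protocol.strain_levels) / 100.0
    prominence = 0.5 * levels[0]
    troughs, _ = find_peaks(-strain, prominence=prominence)
    bounds = np.concatenate(([0], troughs, [len(strain) - 1]))

    cycles: List[Cycle] = []
    counts = {float(lv): 0 for lv in protocol.strain_levels}
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < 3:
            continue
        seg = slice(b0, b1 + 1)
        s = strain[seg]
        peak_rel = int(np.argmax(s))
        if peak_rel == 0 or peak_rel == len(s) - 1:
            continue  # boundary artefact, not a full cycle
        peak = float(s[peak_rel])
        # nearest level; exact ties go to the lower level
        dist = np.abs(levels - peak)
        level_idx = int(np.argmin(dist))  # argmin returns the first (lower) on ties
        level = float(protocol.strain_levels[level_idx])
        counts[level] += 1
        st = series.stress[seg]
        cycles.append(
            Cycle(
                level=level,
                index=counts[level],
                loading_strain=s[: peak_rel + 1],
                loading_stress=st[: peak_rel + 1],
                unloading_strain=s[peak_rel:],
                unloading_stress=st[peak_rel:],
            )
        )

    for lv in protocol.strain_levels:
        if counts[float(lv)] < 3:
            raise ValueError(
                f"strain level {lv}%: only {counts[float(lv)]} cycles detected (need >= 3); "
                "trace may be truncated or mislabelled"
            )
    return cycles


def select_steady_cycles(cycles: Sequence[Cycle], k: int = 3) -> List[Cycle]:
    """Keep the last ``k`` (steady-state) cycles of each strain level."""
    out: List[Cycle] = []
    for level in sorted({c.level for c in cycles}):
        at_level = [c for c in cycles if c.level == level]
        if len(at_level) < k:
            raise ValueError(
                f"strain level {level}%: {len(at_level)} cycles available, need {k}"
            )
        at_level.sort(key=lambda c: c.index)
        out.extend(at_level[-k:])
    return out


def _fit_slope(strain: np.ndarray, stress: np.ndarray) -> float:
    """First-order least-squares slope d(stress)/d(strain)."""
    if len(strain) < 2:
        raise ValueError("need at least 2 points for a first-order fit")
    if float(np.ptp(strain)) == 0.0:
        raise ValueError("degenerate segment: strain is constant")
    return float(np.polyfit(strain, stress, 1)[0])


def mean_slope(cycle: Cycle) -> float:
    """Mean of the loading-limb and unloading-limb first-order fit slopes (MPa)."""
    k_load = _fit_slope(cycle.loading_strain, cycle.loading_stress)
    k_unload = _fit_slope(cycle.unloading_strain, cycle.unloading_stress)
    return 0.5 * (k_load + k_unload)


def _window_points(cycle: Cycle, window: float) -> Tuple[np.ndarray, np.ndarray]:
    strain, stress = cycle.loading_strain, cycle.loading_stress
    # Turnaround artifact: when the reversal falls between samples, the
    # strain maximum is the first post-reversal sample and its stress sits on
    # the (lower) unloading branch. Trim it if stress breaks monotonicity.
    if len(strain) >= 3 and stress[-1] < stress[-2]:
        strain, stress = strain[:-1], stress[:-1]
    peak = float(np.max(strain))
    span = peak - float(np.min(strain))
    if span < window:
        raise ValueError(
            f"loading segment spans {span:.4f} strain, smaller than the {window:.4f} window"
        )
    mask = strain >= peak - window
    if int(np.sum(mask)) < 2:
        raise ValueError(
            "fewer than 2 samples inside the tangent-modulus window; "
            "sample rate is insufficient for this window"
        )
    return strain[mask], stress[mask]


def tangent_modulus(
    cycles_at_level: Sequence[Cycle],
    window_pct: float = 1.0,
    scope: Literal["per_cycle", "pooled"] = "per_cycle",
) -> float:
    """Slope over the last ``window_pct`` strain of the loading limb (MPa).

    ``per_cycle`` fits each cycle separately and averages the slopes (the
    default); ``pooled`` fits one line through the concatenated window
    points of all supplied cycles.
    """
    if not cycles_at_level:
        raise ValueError("no cycles supplied")
    window = window_pct / 100.0
    if scope == "per_cycle":
        slopes = []
        for c in cycles_at_level:
            s, st = _window_points(c, window)
            slopes.append(_fit_slope(s, st))
        return float(np.mean(slopes))
    if scope == "pooled":
        pts = [_window_points(c, window) for c in cycles_at_level]
        s = np.concatenate([p[0] for p in pts])
        st = np.concatenate([p[1] for p in pts])
        return _fit_slope(s, st)
    raise ValueError(f"unknown scope {scope!r}")


def anisotropy_index(specimen: SpecimenMechanics) -> Dict[float, float]:
    """AI per strain level: longitudinal / transverse tangent modulus."""
    tx, ty = specimen.tangent_modulus.get("x"), specimen.tangent_modulus.get("y")
    if not tx or not ty:
        raise ValueError("both axes' tangent moduli are required for the anisotropy index")
    ai: Dict[float, float] = {}
    for level in tx:
        if level not in ty:
            raise ValueError(f"transverse tangent modulus missing at level {level}%")
        if ty[level] <= 0:
            raise ValueError(f"transverse tangent modulus <= 0 at level {level}%")
        ai[level] = tx[level] / ty[level]
    specimen.anisotropy_index = ai
    return ai


def analyze_specimen(
    trace: MechTrace,
    k_last: int = 3,
    window_pct: float = 1.0,
    scope: Literal["per_cycle", "pooled"] = "per_cycle",
    group: str | None = None,
) -> SpecimenMechanics:
    """Full per-specimen chain: stress/strain, cycles, steady selection,
    mean slope and tangent modulus per axis and level, AI per level."""
    sx, sy = compute_stress_strain(trace)
    result = SpecimenMechanics(specimen_id=trace.specimen_id, group=group)
    for series in (sx, sy):
        try:
            cycles = segment_cycles(series, trace.protocol)
            steady = select_steady_cycles(cycles, k=k_last)
        except ValueError as err:
            raise ValueError(f"specimen {trace.specimen_id}, axis {series.axis}: {err}") from err
        slopes: Dict[float, float] = {}
        tangents: Dict[float, float] = {}
        for level in trace.protocol.strain_levels:
            at_level = [c for c in steady if c.level == float(level)]
            try:
                slopes[float(level)] = float(np.mean([mean_slope(c) for c in at_level]))
                tangents[float(level)] = tangent_modulus(at_level, window_pct=window_pct, scope=scope)
            except ValueError as err:
                raise ValueError(
                    f"specimen {trace.specimen_id}, axis {series.axis}, level {level}%: {err}"
                ) from err
        result.mean_slope[series.axis] = slopes
        result.tangent_modulus[series.axis] = tangents
    anisotropy_index(result)
    return result


def mechanics_to_frames(
    specimens: Sequence[SpecimenMechanics],
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy long tables: (moduli, AI).

    moduli: specimen_id, group, axis, strain_level_pct, mean_slope_MPa,
    tangent_modulus_MPa. AI: specimen_id, group, strain_level_pct, ai.
    """
    rows, ai_rows = [], []
    for sp in specimens:
        for axis, tangents in sp.tangent_modulus.items():
            for level, tmod in tangents.items():
                rows.append(
                    {
                        "specimen_id": sp.specimen_id,
                        "group": sp.group,
                        "axis": axis,
                        "strain_level_pct": level,
                        "mean_slope_MPa": sp.mean_slope[axis][level],
                        "tangent_modulus_MPa": tmod,
                    }
                )
        for level, ai in sp.anisotropy_index.items():
            ai_rows.append(
                {
                    "specimen_id": sp.specimen_id,
                    "group": sp.group,
                    "strain_level_pct": level,
                    "ai": ai,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(ai_rows)
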