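"""Synthetic cohort generator for pelvic-floor injury studies.

Generates raw biaxial tensile traces and urethral/pudendal electrophysiology
trials for a four-group rat cohort (sham, injury+vehicle, injury+MSC,
injury+RGTA) with fully known ground truth, so that every downstream analysis
step can be validated by parameter recovery.

The tissue material model is an exponential strain-stiffening law

    sigma_a(eps) = A_a * (exp(B_a * eps) - 1),   a in {x, y},

which reproduces the toe region plus quasi-linear high-strain region of soft
tissue and has the closed-form tangent d(sigma)/d(eps) = A*B*exp(B*eps).
Cyclic preconditioning is modelled as a geometric decay of a peak-stress
deficit, and hysteresis as an unloading limb scaled by ``eta`` relative to
loading (both limbs pass through zero stress at zero strain).

Neural activity is a homogeneous Poisson process with a 1 ms absolute
refractory period (a renewal process with dead time), so the realised mean
firing rate is lambda/(1 + lambda*tau) rather than lambda;
:func:`dead_time_rate` gives that closed form and is the truth used in
recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "TissueMechParams",
    "MechProtocol",
    "SpecimenGeometry",
    "MechTrace",
    "EphysParams",
    "PressureTrace",
    "NeuroTrace",
    "CohortConfig",
    "AnimalTruth",
    "CohortTruth",
    "AnimalData",
    "simulate_specimen_mech",
    "true_tangent_modulus",
    "true_window_slope",
    "dead_time_rate",
    "simulate_lpp_trial",
    "simulate_eng_trial",
    "simulate_cohort",
    "default_group_effects",
    "DEFAULT_GROUPS",
    "DEFAULT_N_PER_GROUP",
]

# Sphincter EMG / pudendal ENG are recorded at 10 kHz; bladder pressure is a
# slow channel and 100 Hz is ample for a manual ramp.
NEURO_SAMPLE_RATE = 10_000.0
PRESSURE_SAMPLE_RATE = 100.0

# Spike micro-structure (not described by the study; fixed by design).
TEMPLATE_DURATION_S = 0.002   # biphasic, one positive then one negative lobe
REFRACTORY_S = 0.001

DEFAULT_GROUPS = ("sham+VEH", "PNC+VD+VEH", "PNC+VD+MSC", "PNC+VD+RGTA")

# Biomechanics arm group sizes (animals with usable biaxial data).
DEFAULT_N_PER_GROUP = {
    "sham+VEH": 12,
    "PNC+VD+VEH": 7,
    "PNC+VD+MSC": 9,
    "PNC+VD+RGTA": 7,
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueMechParams:
    """Material parameters of one specimen's exponential stress-strain law.

    ``A_*`` (MPa) sets the stress scale per axis and ``B_*`` (dimensionless,
    strain as a fraction) the exponential stiffening rate. ``eta`` scales the
    unloading limb relative to loading (hysteresis), ``precond_drop`` and
    ``precond_rate`` govern the preconditioning transient (cycle c is scaled
    by 1 - precond_drop * precond_rate**(c-1)), and ``noise_sd`` is additive
    Gaussian force noise in N.
    """

    A_x: float = 0.04
    A_y: float = 0.04
    B_x: float = 10.0
    B_y: float = 10.0
    eta: float = 0.8
    precond_drop: float = 0.15
    precond_rate: float = 0.6
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        _require(self.A_x > 0 and self.A_y > 0, "stress scales A_x, A_y must be > 0")
        _require(self.B_x >= 0 and self.B_y >= 0, "stiffening exponents B_x, B_y must be >= 0")
        _require(0 < self.eta <= 1, "unloading ratio eta must be in (0, 1]")
        _require(0 <= self.precond_drop < 1, "precond_drop must be in [0, 1)")
        _require(0 < self.precond_rate < 1, "precond_rate must be in (0, 1)")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")

    def A(self, axis: str) -> float:
        return {"x": self.A_x, "y": self.A_y}[axis]

    def B(self, axis: str) -> float:
        return {"x": self.B_x, "y": self.B_y}[axis]


@dataclass(frozen=True)
class MechProtocol:
    """Cyclic equibiaxial loading protocol.

    Defaults mirror the standard vaginal-wall protocol: four strain levels
    (4.6, 10, 15.7, 21.6 %), 10 cycles per level, 100 %strain/min, 30 Hz
    sampling, after a 0.1 N preload (the preload defines the tared reference
    state; simulated forces are preload-referenced).
    """

    strain_levels: Tuple[float, ...] = (4.6, 10.0, 15.7, 21.6)
    cycles_per_level: int = 10
    strain_rate: float = 100.0  # % strain per minute
    sample_rate: float = 30.0   # Hz
    preload: float = 0.1        # N

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.strain_levels)
        object.__setattr__(self, "strain_levels", levels)
        _require(len(levels) >= 1 and all(v > 0 for v in levels), "strain levels must be positive")
        _require(all(b > a for a, b in zip(levels, levels[1:])), "strain levels must be strictly increasing")
        _require(self.cycles_per_level >= 3, "need at least 3 cycles per level")
        _require(self.sample_rate > 0, "sample_rate must be > 0")
        _require(self.strain_rate > 0, "strain_rate must be > 0")


@dataclass(frozen=True)
class SpecimenGeometry:
    """Initial specimen geometry (mm). Widths default to the 10 mm square cut."""

    thickness: float = 1.5
    width_x: float = 10.0
    width_y: float = 10.0
    gauge_length: float = 10.0

    def __post_init__(self) -> None:
        _require(
            min(self.thickness, self.width_x, self.width_y, self.gauge_length) > 0,
            "all geometry dimensions must be strictly positive",
        )

    def area(self, axis: str) -> float:
        """Initial cross-section (mm^2) loaded along ``axis``."""
        return self.thickness * {"x": self.width_x, "y": self.width_y}[axis]


@dataclass
class MechTrace:
    """Raw per-specimen biaxial record: time (s), strain (%), force (N)."""

    time: np.ndarray
    strain_x: np.ndarray
    strain_y: np.ndarray
    force_x: np.ndarray
    force_y: np.ndarray
    geometry: SpecimenGeometry
    protocol: MechProtocol
    specimen_id: str = "specimen"

    def __post_init__(self) -> None:
        arrays = [self.time, self.strain_x, self.strain_y, self.force_x, self.force_y]
        for name, arr in zip(["time", "strain_x", "strain_y", "force_x", "force_y"], arrays):
            setattr(self, name, np.asarray(arr, dtype=float))
        n = len(self.time)
        _require(all(len(a) == n for a in arrays), "all trace channels must have equal length")
        _require(bool(np.all(np.diff(self.time) > 0)), "time must be strictly increasing")
        tol = 0.05 * max(self.protocol.strain_levels)
        smax = max(self.protocol.strain_levels) + tol
        for s in (self.strain_x, self.strain_y):
            _require(
                float(np.min(s)) >= -tol and float(np.max(s)) <= smax,
                "strain outside [0, max level] (plus tolerance)",
            )


# ---------------------------------------------------------------------------
# Biaxial trace simulation
# ---------------------------------------------------------------------------


def _triangle_breakpoints(protocol: MechProtocol) -> Tuple[np.ndarray, np.ndarray]:
    """Breakpoint times/strains of the full triangle-wave strain profile (%)."""
    rate = protocol.strain_rate / 60.0  # %/s
    t, eps = [0.0], [0.0]
    now = 0.0
    for level in protocol.strain_levels:
        half = level / rate
        for _ in range(protocol.cycles_per_level):
            t += [now + half, now + 2 * half]
            eps += [level, 0.0]
            now += 2 * half
    return np.array(t), np.array(eps)


def simulate_specimen_mech(
    params: TissueMechParams,
    protocol: MechProtocol,
    geometry: SpecimenGeometry,
    seed: int,
    specimen_id: str = "specimen",
) -> MechTrace:
    """Simulate one equibiaxial cyclic tension test.

    Strain follows an exact triangle wave (constant |strain rate|) through
    ``cycles_per_level`` cycles at each protocol level in order. Loading
    stress is ``A (exp(B eps) - 1)`` scaled by the preconditioning factor of
    the cycle; unloading is the loading curve scaled by ``eta``. Force is
    stress times the initial cross-section, plus additive Gaussian noise.
    Identical seeds give bit-identical traces.
    """
    rng = np.random.default_rng(seed)
    bp_t, bp_eps = _triangle_breakpoints(protocol)
    total = bp_t[-1]
    n = int(math.floor(total * protocol.sample_rate)) + 1
    time = np.arange(n) / protocol.sample_rate
    strain_pct = np.interp(time, bp_t, bp_eps)

    # Per-sample segment bookkeeping: segments alternate loading/unloading.
    # side="left" keeps a sample that lands exactly on a peak breakpoint in
    # the loading segment, so loading stress is continuous up to the peak.
    seg = np.clip(np.searchsorted(bp_t, time, side="left") - 1, 0, len(bp_t) - 2)
    loading = seg % 2 == 0
    cycle_global = seg // 2
    cycle_in_level = (cycle_global % protocol.cycles_per_level) + 1
    precond = 1.0 - params.precond_drop * params.precond_rate ** (cycle_in_level - 1)

    eps = strain_pct / 100.0
    forces = {}
    for axis in ("x", "y"):
        sigma = params.A(axis) * np.expm1(params.B(axis) * eps)
        sigma = sigma * precond * np.where(loading, 1.0, params.eta)
        force = sigma * geometry.area(axis)
        if params.noise_sd > 0:
            force = force + rng.normal(0.0, params.noise_sd, size=n)
        forces[axis] = force

    return MechTrace(
        time=time,
        strain_x=strain_pct.copy(),
        strain_y=strain_pct.copy(),
        force_x=forces["x"],
        force_y=forces["y"],
        geometry=geometry,
        protocol=protocol,
        specimen_id=specimen_id,
    )


def true_tangent_modulus(params: TissueMechParams, axis: str, strain_level: float) -> float:
    """Closed-form steady-state tangent modulus A*B*exp(B*eps) in MPa.

    ``strain_level`` is in %, converted to a fraction internally; no
    preconditioning factor is applied (steady state).
    """
    if axis not in ("x", "y"):
        raise ValueError(f"unknown axis {axis!r}; expected 'x' or 'y'")
    eps = strain_level / 100.0
    return params.A(axis) * params.B(axis) * math.exp(params.B(axis) * eps)


def true_window_slope(
    params: TissueMechParams, axis: str, strain_level: float, window_pct: float = 1.0
) -> float:
    """Closed-form continuous least-squares slope over the last ``window_pct``
    strain of the loading curve ending at ``strain_level``.

    This is the estimand of the tangent-modulus estimator: the LS slope of
    A(exp(B eps)-1) over [eps_p - w, eps_p] equals
    A*exp(B*m) * 3(Bh cosh(Bh) - sinh(Bh)) / (B^2 h^3), with m the window
    midpoint and h = w/2, which tends to the true tangent at the midpoint as
    B*h -> 0.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"unknown axis {axis!r}; expected 'x' or 'y'")
    return _ls_window_slope(
        params.A(axis), params.B(axis), strain_level / 100.0, window_pct / 100.0
    )


def _ls_window_slope(A: float, B: float, eps_p: float, w: float) -> float:
    """Continuous LS slope of A(exp(B eps)-1) over [eps_p - w, eps_p]."""
    h = w / 2.0
    m = eps_p - h  # window midpoint
    if B == 0:
        return 0.0
    bh = B * h
    if bh < 1e-6:  # series limit, avoids 0/0
        return A * B * math.exp(B * m)
    return A * math.exp(B * m) * 3.0 * (bh * math.cosh(bh) - math.sinh(bh)) / (B * B * h**3)


# ---------------------------------------------------------------------------
# Electrophysiology simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EphysParams:
    """Parameters of one animal's urethral/pudendal electrophysiology.

    Rates are nominal Poisson intensities (Hz) at baseline/rest and during
    stimulation (peak bladder pressure for EUS EMG; genital brushing for
    pudendal ENG). Spike peak-to-peak amplitudes are Normal(amp_mean,
    amp_sd) in uV; ``noise_sd`` is the broadband recording noise in uV.
    Pressures are in cm H2O. Trial counts follow typical practice: 3-6 leak
    point pressure trials and 5-10 ENG trials per animal.
    """

    rate_baseline: float = 10.0
    rate_stim: float = 45.0
    amp_mean: float = 120.0
    amp_sd: float = 20.0
    noise_sd: float = 5.0
    p_baseline: float = 8.0
    p_leak: float = 42.0
    n_lpp_trials: int = 4
    n_eng_trials: int = 6

    def __post_init__(self) -> None:
        _require(self.rate_baseline >= 0 and self.rate_stim >= 0, "firing rates must be >= 0")
        _require(self.amp_mean > 0 and self.amp_sd >= 0, "amplitudes must be positive")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.p_leak > self.p_baseline, "p_leak must exceed p_baseline")
        _require(3 <= self.n_lpp_trials <= 6, "n_lpp_trials must be within 3-6")
        _require(5 <= self.n_eng_trials <= 10, "n_eng_trials must be within 5-10")


def dead_time_rate(rate: float, refractory: float = REFRACTORY_S) -> float:
    """Realised mean rate of a Poisson process with an absolute dead time."""
    if rate <= 0:
        return 0.0
    return rate / (1.0 + rate * refractory)


@dataclass
class PressureTrace:
    """Bladder pressure record (cm H2O) with annotations (seconds)."""

    time: np.ndarray
    pressure: np.ndarray
    baseline_window: Tuple[float, float]
    peak_time: float
    ramp_onset: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        _require(len(self.time) == len(self.pressure), "time/pressure length mismatch")
        _require(bool(np.all(np.isfinite(self.pressure))), "pressure must be finite")
        t0, t1 = float(self.time[0]), float(self.time[-1])
        _require(
            t0 <= self.baseline_window[0] < self.baseline_window[1] <= t1,
            "baseline window must lie inside the record",
        )
        _require(t0 <= self.peak_time <= t1, "peak marker must lie inside the record")


@dataclass
class NeuroTrace:
    """EMG/ENG voltage record (uV) at 10 kHz with baseline/stim windows."""

    time: np.ndarray
    voltage: np.ndarray
    sample_rate: float
    channel: str  # "EUS_EMG" or "pudendal_ENG"
    baseline_window: Tuple[float, float]
    stim_window: Tuple[float, float]
    raw: bool = False  # True if band-pass filtering is still required

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        _require(len(self.time) == len(self.voltage), "time/voltage length mismatch")
        _require(self.channel in ("EUS_EMG", "pudendal_ENG"), "unknown channel")
        if len(self.time) > 1:
            dt = float(np.median(np.diff(self.time)))
            _require(abs(dt * self.sample_rate - 1.0) < 1e-6, "sample_rate does not match time spacing")
        for w in (self.baseline_window, self.stim_window):
            _require(w[1] - w[0] >= 1.0 - 1e-9, "analysis windows must span at least 1 s")


def _spike_times(rng: np.random.Generator, rate: float, t0: float, t1: float) -> np.ndarray:
    """Renewal spike train with dead time: intervals = refractory + Exp(rate)."""
    if rate <= 0 or t1 <= t0:
        return np.empty(0)
    times = []
    t = t0 + rng.exponential(1.0 / rate)
    while t < t1:
        times.append(t)
        t += REFRACTORY_S + rng.exponential(1.0 / rate)
    return np.array(times)


def _biphasic_template(sample_rate: float) -> np.ndarray:
    """One full sine cycle over 2 ms; peak-to-peak amplitude 1."""
    n = max(int(round(TEMPLATE_DURATION_S * sample_rate)), 4)
    t = np.arange(n) / sample_rate
    return 0.5 * np.sin(2.0 * np.pi * t / TEMPLATE_DURATION_S)


def _render_spikes(
    rng: np.random.Generator,
    n_samples: int,
    sample_rate: float,
    segments: Sequence[Tuple[float, float, float]],
    amp_mean: float,
    amp_sd: float,
) -> np.ndarray:
    """Sum spike templates over rate segments (t0, t1, rate) onto a zero trace."""
    v = np.zeros(n_samples)
    template = _biphasic_template(sample_rate)
    for t0, t1, rate in segments:
        for st in _spike_times(rng, rate, t0, t1):
            amp = rng.normal(amp_mean, amp_sd)
            amp = max(amp, 0.05 * amp_mean)  # physical amplitudes stay positive
            i0 = int(round(st * sample_rate))
            i1 = min(i0 + len(template), n_samples)
            if i0 < n_samples:
                v[i0:i1] += amp * template[: i1 - i0]
    return v


# LPP trial timeline (s): baseline hold, manual ramp to leak, release, tail.
_LPP_BASELINE_END = 3.0
_LPP_PEAK_TIME = 7.0
_LPP_RELEASE_END = 7.5
_LPP_TOTAL = 8.0


def simulate_lpp_trial(params: EphysParams, seed: int) -> Tuple[PressureTrace, NeuroTrace]:
    """Simulate one leak-point-pressure trial with simultaneous EUS EMG.

    The pressure holds at ``p_baseline``, ramps to ``p_leak`` (the leak
    marker sits at the peak, which falls exactly on a sample), then drops.
    The EMG fires at ``rate_baseline`` outside the peak and at ``rate_stim``
    in the 1 s around the peak. With all noise parameters zero the pressure
    maximum equals ``p_leak`` exactly.
    """
    rng = np.random.default_rng(seed)

    n_p = int(round(_LPP_TOTAL * PRESSURE_SAMPLE_RATE)) + 1
    t_p = np.arange(n_p) / PRESSURE_SAMPLE_RATE
    pressure = np.interp(
        t_p,
        [0.0, _LPP_BASELINE_END, _LPP_PEAK_TIME, _LPP_RELEASE_END, _LPP_TOTAL],
        [params.p_baseline, params.p_baseline, params.p_leak, params.p_baseline, params.p_baseline],
    )
    p_noise_sd = 0.05 * params.noise_sd  # shared noise scale: 5 uV EMG ~ 0.25 cm H2O
    if p_noise_sd > 0:
        noise = rng.normal(0.0, p_noise_sd, size=n_p)
        noise[np.argmax(pressure)] = 0.0  # leak marker stays the true peak
        pressure = pressure + noise
    ptrace = PressureTrace(
        time=t_p,
        pressure=pressure,
        baseline_window=(0.5, 2.5),
        peak_time=_LPP_PEAK_TIME,
        ramp_onset=_LPP_BASELINE_END,
    )

    n_v = int(round(_LPP_TOTAL * NEURO_SAMPLE_RATE)) + 1
    t_v = np.arange(n_v) / NEURO_SAMPLE_RATE
    stim0, stim1 = _LPP_PEAK_TIME - 0.5, _LPP_PEAK_TIME + 0.5
    segments = [
        (0.0, stim0, params.rate_baseline),
        (stim0, stim1, params.rate_stim),
        (stim1, _LPP_TOTAL, params.rate_baseline),
    ]
    v = _render_spikes(rng, n_v, NEURO_SAMPLE_RATE, segments, params.amp_mean, params.amp_sd)
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=n_v)
    etrace = NeuroTrace(
        time=t_v,
        voltage=v,
        sample_rate=NEURO_SAMPLE_RATE,
        channel="EUS_EMG",
        baseline_window=(_LPP_BASELINE_END - 1.0, _LPP_BASELINE_END),
        stim_window=(stim0, stim1),
    )
    return ptrace, etrace


# ENG trial timeline (s): rest, pause, brushing, tail.
_ENG_REST = (0.25, 1.25)
_ENG_BRUSH = (2.25, 3.25)
_ENG_BRUSH_FULL = (2.0, 3.5)
_ENG_TOTAL = 4.0


def simulate_eng_trial(params: EphysParams, seed: int) -> NeuroTrace:
    """Simulate one pudendal sensory-nerve trial: rest, then genital brushing.

    Fires at ``rate_baseline`` at rest and ``rate_stim`` during the brushing
    interval (>= 1 s by construction); the analysis windows are annotated on
    the trace.
    """
    rng = np.random.default_rng(seed)
    n_v = int(round(_ENG_TOTAL * NEURO_SAMPLE_RATE)) + 1
    t_v = np.arange(n_v) / NEURO_SAMPLE_RATE
    b0, b1 = _ENG_BRUSH_FULL
    segments = [
        (0.0, b0, params.rate_baseline),
        (b0, b1, params.rate_stim),
        (b1, _ENG_TOTAL, params.rate_baseline),
    ]
    v = _render_spikes(rng, n_v, NEURO_SAMPLE_RATE, segments, params.amp_mean, params.amp_sd)
    if params.noise_sd > 0:
        v = v + rng.normal(0.0, params.noise_sd, size=n_v)
    return NeuroTrace(
        time=t_v,
        voltage=v,
        sample_rate=NEURO_SAMPLE_RATE,
        channel="pudendal_ENG",
        baseline_window=_ENG_REST,
        stim_window=_ENG_BRUSH,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def default_group_effects() -> Dict[str, Tuple[float, float, float, float]]:
    """Multiplicative group factors on (A_x, A_y, rate_stim, p_leak).

    Qualitative presets: injury lowers stiffness ~30% on both axes and
    degrades urethral/pudendal function; MSC restores stiffness (but not
    function); RGTA restores longitudinal stiffness only, raising anisotropy.
    These are modelling choices, not measured values.
    """
    return {
        "sham+VEH": (1.0, 1.0, 1.0, 1.0),
        "PNC+VD+VEH": (0.7, 0.7, 0.6, 0.75),
        "PNC+VD+MSC": (1.0, 1.0, 0.6, 0.75),
        "PNC+VD+RGTA": (1.0, 0.7, 0.6, 0.75),
    }


@dataclass(frozen=True)
class CohortConfig:
    """Study-design configuration of a synthetic cohort."""

    groups: Tuple[str, ...] = DEFAULT_GROUPS
    n_per_group: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_GROUP))
    group_effects: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=default_group_effects
    )
    between_animal_cv: float = 0.10
    seed: int = 0
    base_mech: TissueMechParams = field(default_factory=TissueMechParams)
    base_ephys: EphysParams = field(default_factory=EphysParams)
    protocol: MechProtocol = field(default_factory=MechProtocol)
    geometry: SpecimenGeometry = field(default_factory=SpecimenGeometry)

    def __post_init__(self) -> None:
        for g in self.groups:
            _require(g in self.n_per_group, f"missing n_per_group entry for group {g!r}")
            _require(self.n_per_group[g] >= 1, f"n_per_group must be >= 1 for group {g!r}")
            if g not in self.group_effects:
                raise ValueError(f"unknown group label {g!r}: no group_effects entry")
            _require(
                all(f > 0 for f in self.group_effects[g]),
                f"group factors must be > 0 for group {g!r}",
            )
        _require(self.between_animal_cv >= 0, "between_animal_cv must be >= 0")


@dataclass
class AnimalTruth:
    """Realised ground truth for one animal."""

    animal_id: str
    group: str
    mech: TissueMechParams
    ephys: EphysParams
    tangent_modulus: Dict[str, Dict[float, float]]  # axis -> level% -> MPa
    window_slope: Dict[str, Dict[float, float]]     # estimand of the last-1% fit
    anisotropy_index: Dict[float, float]            # level% -> AI
    lpp: float
    d_rate: float  # dead-time-corrected expected rate difference (Hz)


@dataclass
class CohortTruth:
    """Ground truth for every generated animal (parameter-recovery oracle)."""

    animals: List[AnimalTruth]
    config: CohortConfig

    def by_id(self, animal_id: str) -> AnimalTruth:
        for a in self.animals:
            if a.animal_id == animal_id:
                return a
        raise KeyError(animal_id)


@dataclass
class AnimalData:
    """Raw simulated records for one animal."""

    animal_id: str
    group: str
    mech: MechTrace | None
    lpp_trials: List[Tuple[PressureTrace, NeuroTrace]]
    eng_trials: List[NeuroTrace]


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean log-normal multiplicative noise with coefficient of variation cv."""
    if cv == 0:
        return 1.0
    s2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))


def simulate_cohort(
    config: CohortConfig,
    include_mech: bool = True,
    include_ephys: bool = True,
) -> Tuple[List[AnimalData], CohortTruth]:
    """Generate the full cohort: traces per animal plus ground truth.

    Per animal, group factors and one unit-mean log-normal draw per parameter
    family (a common stiffness scale shared by both axes, the stimulated
    firing rate, and the leak pressure excess over baseline) are applied to
    the base parameters. Deterministic under ``config.seed``.
    """
    animals: List[AnimalData] = []
    truths: List[AnimalTruth] = []
    base_m, base_e = config.base_mech, config.base_ephys
    levels = config.protocol.strain_levels

    counter = 0
    for group in config.groups:
        fA_x, fA_y, f_rate, f_pleak = config.group_effects[group]
        for i in range(config.n_per_group[group]):
            counter += 1
            animal_id = f"{group}_{i + 1:02d}"
            ss = np.random.SeedSequence((config.seed, counter))
            child = ss.generate_state(4, dtype=np.uint32) % (2**31)
            rng = np.random.default_rng(np.random.SeedSequence((config.seed, counter, 9)))

            scale_A = _lognormal_factor(rng, config.between_animal_cv)
            scale_rate = _lognormal_factor(rng, config.between_animal_cv)
            scale_leak = _lognormal_factor(rng, config.between_animal_cv)

            mech_params = replace(
                base_m,
                A_x=base_m.A_x * fA_x * scale_A,
                A_y=base_m.A_y * fA_y * scale_A,
            )
            leak_excess = (base_e.p_leak - base_e.p_baseline) * f_pleak * scale_leak
            ephys_params = replace(
                base_e,
                rate_stim=base_e.rate_stim * f_rate * scale_rate,
                p_leak=base_e.p_baseline + leak_excess,
            )

            mech_trace = None
            if include_mech:
                mech_trace = simulate_specimen_mech(
                    mech_params, config.protocol, config.geometry,
                    seed=int(child[0]), specimen_id=animal_id,
                )
            lpp_trials: List[Tuple[PressureTrace, NeuroTrace]] = []
            eng_trials: List[NeuroTrace] = []
            if include_ephys:
                for k in range(ephys_params.n_lpp_trials):
                    s = np.random.SeedSequence((config.seed, counter, 1, k))
                    lpp_trials.append(
                        simulate_lpp_trial(ephys_params, seed=int(s.generate_state(1)[0] % 2**31))
                    )
                for k in range(ephys_params.n_eng_trials):
                    s = np.random.SeedSequence((config.seed, counter, 2, k))
                    eng_trials.append(
                        simulate_eng_trial(ephys_params, seed=int(s.generate_state(1)[0] % 2**31))
                    )

            tangent = {
                ax: {lv: true_tangent_modulus(mech_params, ax, lv) for lv in levels}
                for ax in ("x", "y")
            }
            window = {
                ax: {lv: _ls_window_slope(mech_params.A(ax), mech_params.B(ax), lv / 100.0, 0.01) for lv in levels}
                for ax in ("x", "y")
            }
            ai = {lv: tangent["x"][lv] / tangent["y"][lv] for lv in levels}
            d_rate = dead_time_rate(ephys_params.rate_stim) - dead_time_rate(ephys_params.rate_baseline)

            animals.append(AnimalData(animal_id, group, mech_trace, lpp_trials, eng_trials))
            truths.append(
                AnimalTruth(
                    animal_id=animal_id,
                    group=group,
                    mech=mech_params,
                    ephys=ephys_params,
                    tangent_modulus=tangent,
                    window_slope=window,
                    anisotropy_index=ai,
                    lpp=ephys_params.p_leak - ephys_params.p_baseline,
                    d_rate=d_rate,
                )
            )

    return animals, CohortTruth(animals=truths, config=config)
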