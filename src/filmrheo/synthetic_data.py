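"""Seeded synthetic trough data with known ground truth.

No raw trough recordings are deposited with the study this package supports,
so every pipeline stage is exercised on synthetic inputs that reproduce the
statistical structure the analysis assumes:

* relaxation transients: multi-exponential decay plus a plateau after a ~5%
  area step (the generalized-Maxwell form the fitter assumes);
* isotherm pairs: hysteretic, cycle-converging pi(A) loops where the test
  condition is shifted to higher pressures, with an optional vanish pressure
  at which the shift dies off (squeeze-out phenomenology);
* penetration kinetics: a fast pressure rise followed by slow
  re-equilibration.

Each generator is deterministic under a fixed seed, adds iid Gaussian noise
on pi only, and records its true parameters under ``meta["truth"]`` so
recovery tests read truth from the sidecar, never from the analysis under
test.  Default parameter sets mirror the meibomian-film protocol: strain
0.05, baseline near 18 mN/m, two relaxation processes with well-separated
times, a ~15 mN/m kinetic rise peaking within 100 s and re-equilibrating
within ~1000 s.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ValidationError
from .transients_io import KineticsTrace, RelaxationTransient, TroughRecording

__all__ = [
    "gen_relaxation",
    "gen_isotherm_pair",
    "gen_kinetics",
    "logistic_shift",
    "base_isotherm_template",
    "mgs_relaxation_preset",
    "isotherm_preset",
    "kinetics_preset",
]

#: Default area waypoints (cm^2, decreasing pi with area) for the isotherm
#: template; shaped like a meibomian-film compression on a small trough.
DEFAULT_ISOTHERM_WAYPOINTS = ((40.0, 38.0), (60.0, 30.0), (80.0, 22.0),
                              (100.0, 15.0), (120.0, 9.0), (135.0, 5.0))


def mgs_relaxation_preset() -> dict:
    """Meibum-like relaxation parameters: two processes, times 33x apart.

    Two Cole-Cole peaks with a sizable equilibrium plateau give the
    predominantly elastic spectra measured on meibomian films.
    """
    return dict(components=((4.0, 15.0), (3.0, 500.0)), plateau=4.0,
                strain=0.05, pi0=18.0, noise_sd=0.0, seed=0,
                sampling=(1.0, 5000.0))


def isotherm_preset() -> dict:
    """Squeeze-out-like isotherm pair: +8 mN/m shift vanishing near 23 mN/m."""
    return dict(base_curve=DEFAULT_ISOTHERM_WAYPOINTS, shift_amplitude=8.0,
                vanish_pressure=23.0, vanish_width=1.0, hysteresis_gap=1.5,
                drift_amplitude=4.0, drift_decay=0.5, n_cycles=10,
                noise_sd=0.0, seed=0, n_per_branch=400, branch_duration=60.0)


def kinetics_preset() -> dict:
    """Penetration-kinetics parameters: 15 mN/m rise, peak ~55 s, return ~1000 s."""
    return dict(rise_tau=20.0, decay_tau=300.0, amplitude=15.0, pi0=18.0,
                noise_sd=0.0, seed=0, sampling=(1.0, 2000.0))


def gen_relaxation(components: Sequence[tuple[float, float]],
                   plateau: float,
                   strain: float = 0.05,
                   pi0: float = 18.0,
                   noise_sd: float = 0.0,
                   seed: int = 0,
                   sampling: tuple[float, float] = (1.0, 5000.0)) -> RelaxationTransient:
    """Generate pi(t) = pi0 + sum_i A_i exp(-t/tau_i) + dpi_EQ + noise.

    ``sampling`` is (dt, duration) in seconds; noise is iid Gaussian on pi.
    Identical seeds give bit-identical series.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    for _, tau in components:
        if tau <= 0:
            raise ValidationError("relaxation times must be positive")
    dt, duration = sampling
    if dt <= 0 or duration <= dt:
        raise ValidationError("need 0 < dt < duration")
    time = np.arange(0.0, duration + dt / 2, dt)
    dpi = np.full(time.shape, float(plateau))
    for amp, tau in components:
        dpi = dpi + amp * np.exp(-time / tau)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=time.shape) if noise_sd > 0 else 0.0
    truth = {"components": [(float(a), float(tau)) for a, tau in components],
             "plateau": float(plateau), "strain": float(strain),
             "pi0": float(pi0), "noise_sd": float(noise_sd), "seed": int(seed),
             "sampling": (float(dt), float(duration))}
    return RelaxationTransient(time=time, pi=pi0 + dpi + noise, pi0=pi0,
                               strain=strain, meta={"truth": truth})


def logistic_shift(pi_base: Union[float, np.ndarray], amplitude: float,
                   vanish_pressure: Optional[float] = None,
                   vanish_width: float = 1.0) -> Union[float, np.ndarray]:
    """Incorporation shift as a function of the base-film pressure.

    Constant ``amplitude`` when ``vanish_pressure`` is None (persistent,
    CKC-like incorporation); otherwise a logistic switch-off
    amplitude / (1 + exp((pi_base - vanish_pressure)/vanish_width)), so the
    shift fades as the film is compressed past the vanish pressure
    (P188-like squeeze-out).
    """
    pi_base = np.asarray(pi_base, dtype=float)
    if vanish_pressure is None:
        return np.full(pi_base.shape, float(amplitude)) if pi_base.ndim else float(amplitude)
    return amplitude / (1.0 + np.exp((pi_base - vanish_pressure) / vanish_width))


def base_isotherm_template(waypoints=DEFAULT_ISOTHERM_WAYPOINTS) -> Callable:
    """Monotone-cubic pi(A) through waypoints (no equation of state claimed)."""
    pts = sorted((float(a), float(p)) for a, p in waypoints)
    areas = np.array([a for a, _ in pts])
    pis = np.array([p for _, p in pts])
    if np.any(np.diff(pis) > 0):
        raise ValidationError("base isotherm must be non-increasing in area")
    return PchipInterpolator(areas, pis)


def gen_isotherm_pair(base_curve=DEFAULT_ISOTHERM_WAYPOINTS,
                      shift_amplitude: float = 8.0,
                      vanish_pressure: Optional[float] = 23.0,
                      vanish_width: float = 1.0,
                      hysteresis_gap: float = 1.5,
                      drift_amplitude: float = 4.0,
                      drift_decay: float = 0.5,
                      n_cycles: int = 10,
                      noise_sd: float = 0.0,
                      seed: int = 0,
                      n_per_branch: int = 400,
                      branch_duration: float = 60.0,
                      area_unit: str = "cm^2") -> tuple[TroughRecording, TroughRecording]:
    """Generate a (reference, test) pair of cycled trough recordings.

    The area trace is a triangular ramp between the template's area range,
    ``n_cycles`` periods.  The reference film follows the base pi(A)
    template; the test film adds :func:`logistic_shift` of the base
    pressure.  The expansion branch runs up to ``hysteresis_gap`` mN/m below
    the compression branch, with the gap tapering parabolically to zero at
    the turning points so the loop closes (branches share their endpoint
    pressures, as measured loops do).  The baseline drift decays
    exponentially in time, drift(t) = drift_amplitude *
    drift_decay**(t/cycle_period), so consecutive compression branches
    differ by drift_amplitude * (1 - drift_decay) * drift_decay**(k-1) at
    matching phase; both recordings drift identically, as both films
    equilibrate on the trough.

    All generator parameters are recorded under ``meta["truth"]`` on both
    recordings for oracle use.
    """
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    if not (0.0 <= drift_decay < 1.0):
        raise ValidationError("drift_decay must lie in [0, 1)")
    template = (base_curve if callable(base_curve)
                else base_isotherm_template(base_curve))
    waypoints = None if callable(base_curve) else [tuple(map(float, w)) for w in base_curve]
    a_lo, a_hi = float(template.x[0]), float(template.x[-1])

    down = np.linspace(a_hi, a_lo, n_per_branch)
    up = np.linspace(a_lo, a_hi, n_per_branch)[1:]
    # build cycle by cycle: first sample of each subsequent branch duplicates
    # the previous branch's last sample and is dropped
    segs = []
    for k in range(n_cycles):
        comp = down if k == 0 else down[1:]
        segs.append(("c", comp))
        segs.append(("e", up))
    area = np.concatenate([s[1] for s in segs])
    n_total = area.size
    dt = branch_duration / (n_per_branch - 1)
    time = np.arange(n_total) * dt

    pi_base = np.asarray(template(area), dtype=float)
    # hysteresis: expansion dips below compression, vanishing at the turns
    frac = (area - a_lo) / (a_hi - a_lo)
    taper = 4.0 * frac * (1.0 - frac)
    on_expansion = np.concatenate(
        [np.full(s[1].size, s[0] == "e") for s in segs])
    gap = np.where(on_expansion, -hysteresis_gap * taper, 0.0)
    period = 2.0 * branch_duration
    if drift_amplitude == 0.0 or drift_decay == 0.0:
        drift = np.zeros(n_total)
    else:
        drift = drift_amplitude * drift_decay ** (time / period)
    shift = logistic_shift(pi_base, shift_amplitude, vanish_pressure, vanish_width)

    rng = np.random.default_rng(seed)
    eps_ref = rng.normal(0.0, noise_sd, size=n_total) if noise_sd > 0 else 0.0
    eps_test = rng.normal(0.0, noise_sd, size=n_total) if noise_sd > 0 else 0.0

    truth = {"waypoints": waypoints, "shift_amplitude": float(shift_amplitude),
             "vanish_pressure": None if vanish_pressure is None else float(vanish_pressure),
             "vanish_width": float(vanish_width),
             "hysteresis_gap": float(hysteresis_gap),
             "drift_amplitude": float(drift_amplitude),
             "drift_decay": float(drift_decay), "n_cycles": int(n_cycles),
             "noise_sd": float(noise_sd), "seed": int(seed),
             "n_per_branch": int(n_per_branch),
             "branch_duration": float(branch_duration),
             "cycle_start_drifts": [
                 0.0 if (drift_amplitude == 0.0 or drift_decay == 0.0)
                 else float(drift_amplitude * drift_decay ** k)
                 for k in range(n_cycles)]}
    ref = TroughRecording(time=time, area=area, pi=pi_base + gap + drift + eps_ref,
                          area_unit=area_unit, meta={"truth": truth, "role": "reference"})
    test = TroughRecording(time=time, area=area,
                           pi=pi_base + shift + gap + drift + eps_test,
                           area_unit=area_unit, meta={"truth": truth, "role": "test"})
    return ref, test


def gen_kinetics(rise_tau: float = 20.0, decay_tau: float = 300.0,
                 amplitude: float = 15.0, pi0: float = 18.0,
                 noise_sd: float = 0.0, seed: int = 0,
                 sampling: tuple[float, float] = (1.0, 2000.0)) -> KineticsTrace:
    """Generate pi(t) = pi0 + amplitude (1 - e^(-t/rise_tau)) e^(-t/decay_tau) + noise.

    With the defaults the pressure peaks (+~12 mN/m of the nominal 15) near
    55 s and returns to within 0.5 mN/m of the baseline around 1000 s.
    """
    if rise_tau >= decay_tau:
        raise ValidationError("need rise_tau < decay_tau (fast rise, slow decay)")
    if amplitude <= 0:
        raise ValidationError("amplitude must be positive")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    dt, duration = sampling
    if dt <= 0 or duration <= dt:
        raise ValidationError("need 0 < dt < duration")
    time = np.arange(0.0, duration + dt / 2, dt)
    signal = amplitude * (1.0 - np.exp(-time / rise_tau)) * np.exp(-time / decay_tau)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=time.shape) if noise_sd > 0 else 0.0
    truth = {"rise_tau": float(rise_tau), "decay_tau": float(decay_tau),
             "amplitude": float(amplitude), "pi0": float(pi0),
             "noise_sd": float(noise_sd), "seed": int(seed),
             "sampling": (float(dt), float(duration))}
    return KineticsTrace(time=time, pi=pi0 + signal + noise, pi0=pi0,
                         meta={"truth": truth})
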