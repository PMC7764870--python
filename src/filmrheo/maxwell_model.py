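"""Generalized-Maxwell fitting of stress-relaxation transients.

The pressure response of a film to a small area step is modeled as a sum of
decaying exponentials plus a plateau,

    dpi(t) = sum_i A_i exp(-t/tau_i) + dpi_EQ,

the time-domain form of a generalized Maxwell material: each exponential term
is one spring-and-dashpot element with elasticity E_i = A_i/strain and
dilatational viscosity eta_i = tau_i * E_i (so tau_i = eta_i/E_i holds by
construction), and the plateau is an equilibrium spring E_eq = dpi_EQ/strain.
The number of terms is taken from the number of peaks in the Cole-Cole plot
of the transient's spectrum -- one peak per relaxation process.

Sum-of-exponentials least squares is notoriously ill-conditioned; the fitter
initializes relaxation times log-spaced across the record, solves amplitudes
by non-negative linear least squares at fixed times, then refines everything
jointly, restarting from jittered initializations if the first attempt fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import FitFailureError, ValidationError
from .rheology_spectrum import (DEFAULT_FMAX, cole_cole, compute_spectrum,
                                default_frequency_grid, resolvable_band,
                                spectrum_noise_sd)
from .transients_io import RelaxationTransient, log_bin_transient

__all__ = [
    "MaxwellFit",
    "MaxwellElements",
    "fit_relaxation",
    "predict_relaxation",
    "maxwell_elements",
    "estimate_noise_sd",
    "auto_model_order",
]

# Auto-order peak detection on measured spectra: the transient is averaged
# into log-time bins before transforming (white noise shrinks by sqrt(n) per
# bin exactly where slow processes live), and maxima must clear a 5-sigma
# propagated-noise floor in both height and prominence (with ~300 grid points
# and correlated spectrum noise, a 4-sigma cut still leaks occasional false
# peaks family-wise).
_AUTO_BINS_PER_DECADE = 40
_AUTO_NOISE_Z = 5.0
# For order counting the noise floor already rejects spurious wiggles, so the
# fractional prominence cut is kept low: a weak slow process next to a strong
# fast one has small prominence yet is genuinely present.
_AUTO_PROMINENCE_FRAC = 0.02
_MIN_TAU_SEPARATION = 3.0


@dataclass
class MaxwellFit:
    """A fitted sum-of-exponentials-plus-plateau relaxation model.

    ``components`` holds (amplitude mN/m, relaxation time s) pairs ordered by
    ascending tau; ``plateau`` is dpi_EQ.  Derived Maxwell elements are
    available via :func:`maxwell_elements` or the ``elements``/``e_eq``
    properties.
    """

    components: list  # of (amplitude, tau), tau strictly ascending
    plateau: float
    strain: float
    residual_rms: float = 0.0
    stderr: Optional[dict] = None
    resolvable: bool = True
    n_auto: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.components = [(float(a), float(tau)) for a, tau in self.components]
        taus = [tau for _, tau in self.components]
        if any(tau <= 0 for tau in taus):
            raise ValidationError("all relaxation times must be positive")
        if any(t2 <= t1 for t1, t2 in zip(taus, taus[1:])):
            raise ValidationError("relaxation times must be strictly ascending")
        if self.strain <= 0:
            raise ValidationError("strain must be positive")

    def predict(self, times) -> np.ndarray:
        return predict_relaxation(self, times)

    @property
    def e_eq(self) -> float:
        """Equilibrium elasticity dpi_EQ/strain, mN/m."""
        return self.plateau / self.strain

    @property
    def elements(self) -> list:
        """Maxwell elements [(E_i, eta_i, tau_i), ...] ordered by tau."""
        return [(a / self.strain, tau * a / self.strain, tau)
                for a, tau in self.components]


@dataclass
class MaxwellElements:
    """Spring-dashpot elements (E_i mN/m, eta_i mN s/m, tau_i s) plus E_eq."""

    elements: list
    e_eq: float


def predict_relaxation(fit: MaxwellFit, times) -> np.ndarray:
    """Evaluate dpi(t) = sum_i A_i exp(-t/tau_i) + dpi_EQ at the given times.

    dpi(0) = sum A_i + dpi_EQ and dpi -> dpi_EQ as t -> inf.
    """
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)) or (times.size and times.min() < 0):
        raise ValidationError("times must be finite and non-negative")
    out = np.full(times.shape, float(fit.plateau))
    for amp, tau in fit.components:
        out = out + amp * np.exp(-times / tau)
    return out


def maxwell_elements(fit: MaxwellFit) -> MaxwellElements:
    """Map a fit to its generalized-Maxwell elements.

    E_i = A_i/strain, eta_i = tau_i * E_i, E_eq = dpi_EQ/strain; the identity
    tau_i = eta_i/E_i is then exact by construction.
    """
    if fit.strain <= 0:
        raise ValidationError("strain must be positive")
    return MaxwellElements(elements=fit.elements, e_eq=fit.e_eq)


def estimate_noise_sd(t: RelaxationTransient) -> float:
    """Robust iid-noise estimate from first differences of the trace.

    For white noise on a smooth signal, successive differences have standard
    deviation sigma*sqrt(2); the median absolute difference (scaled by the
    normal consistency constant 0.6745) is insensitive to the deterministic
    trend and to outliers.
    """
    d = np.abs(np.diff(t.delta_pi))
    return float(np.median(d) / (0.6745 * np.sqrt(2.0)))


def auto_model_order(t: RelaxationTransient):
    """Choose the number of exponential terms from the Cole-Cole peak count.

    The step-response transform amplifies white pressure noise
    proportionally to frequency, so the raw spectrum of a noisy transient is
    noise-dominated at the top of the band.  The transient is therefore
    averaged into logarithmic time bins before transforming (noise shrinks
    by sqrt(n) per bin where slow processes live, early samples pass through
    at full resolution), and E_IM maxima must clear a 5-sigma noise floor --
    propagated exactly through the quadrature weights -- in both height and
    prominence.  Returns (n, ColeColeResult) with the spectrum evaluated on
    the default grid clipped to the record's resolvable band.
    """
    binned, counts = log_bin_transient(t, _AUTO_BINS_PER_DECADE)
    fmin, fmax = resolvable_band(t)
    # span the whole resolvable band: a peak just above the band edge would
    # otherwise lose its prominence to grid truncation
    grid = default_frequency_grid(fmin, min(DEFAULT_FMAX, fmax))
    spec = compute_spectrum(binned, grid, check_band=False)
    sigma = estimate_noise_sd(t)
    floor = None
    if sigma > 0:
        per_point = sigma / np.sqrt(counts)
        floor = _AUTO_NOISE_Z * spectrum_noise_sd(binned.time, grid,
                                                  t.strain, per_point)
    cc = cole_cole(spec, prominence_frac=_AUTO_PROMINENCE_FRAC,
                   min_height=floor, min_prominence=floor)
    return cc.peaks.count, cc


def _residuals(x, n, time, dpi, nonneg):
    amps = x[:n]
    taus = np.exp(x[n:2 * n])
    plateau = x[2 * n]
    model = np.full(time.shape, plateau)
    for j in range(n):
        model = model + amps[j] * np.exp(-time / taus[j])
    return model - dpi


def fit_relaxation(t: RelaxationTransient,
                   n_components: Union[int, str] = "auto",
                   *,
                   nonneg: bool = True,
                   restarts: int = 5,
                   seed: int = 0,
                   tail_fraction: float = 0.1) -> MaxwellFit:
    """Least-squares fit of a transient with n exponentials plus a plateau.

    Parameters
    ----------
    t : RelaxationTransient
    n_components : int >= 0 or "auto"
        Number of exponential terms.  "auto" counts Cole-Cole peaks of the
        transient's spectrum (see :func:`auto_model_order`).
    nonneg : bool
        Constrain amplitudes A_i >= 0 (a compression step relaxes downward);
        the plateau is always free.
    restarts : int
        Jittered re-initializations attempted if the first fit fails.
    seed : int
        Seed for the jitter; fits are deterministic for fixed inputs.
    tail_fraction : float
        Tail fraction used for the initial plateau estimate.

    Returns
    -------
    MaxwellFit
        With per-parameter standard errors from the fit covariance in
        ``stderr`` and ``resolvable=False`` if any two fitted relaxation
        times are closer than a factor of 3.

    Raises
    ------
    FitFailureError
        If no attempt converges; the error carries the best attempt.
    """
    time = t.time
    dpi = t.delta_pi
    n_auto = None
    if n_components == "auto":
        n_components, _ = auto_model_order(t)
        n_auto = n_components
    n = int(n_components)
    if n < 0:
        raise ValidationError("n_components must be >= 0")

    if n == 0:
        plateau = float(np.mean(dpi))
        rms = float(np.sqrt(np.mean((dpi - plateau) ** 2)))
        return MaxwellFit(components=[], plateau=plateau, strain=t.strain,
                          residual_rms=rms, n_auto=n_auto)

    dt = float(np.median(np.diff(time)))
    duration = max(t.duration, 2 * dt)
    tau_lo, tau_hi = dt, 10.0 * duration
    n_tail = max(1, int(round(tail_fraction * dpi.size)))
    plateau0 = float(np.mean(dpi[-n_tail:]))

    if n == 1:
        taus0 = np.array([np.sqrt(3.0 * dt * duration / 2.0)])
    else:
        taus0 = np.geomspace(3.0 * dt, duration / 2.0, n)
    taus0 = np.clip(taus0, tau_lo * 1.01, tau_hi * 0.99)

    rng = np.random.default_rng(seed)
    amp_lo = 0.0 if nonneg else -np.inf
    lower = np.concatenate([np.full(n, amp_lo), np.full(n, np.log(tau_lo)), [-np.inf]])
    upper = np.concatenate([np.full(n, np.inf), np.full(n, np.log(tau_hi)), [np.inf]])

    def initial_amplitudes(taus):
        design = np.exp(-time[:, None] / taus[None, :])
        target = dpi - plateau0
        if nonneg:
            amps, _ = nnls(design, target)
        else:
            amps, *_ = np.linalg.lstsq(design, target, rcond=None)
        return amps

    def attempt(taus):
        x0 = np.concatenate([initial_amplitudes(taus), np.log(taus), [plateau0]])
        x0 = np.clip(x0, lower, upper)
        return least_squares(_residuals, x0, args=(n, time, dpi, nonneg),
                             bounds=(lower, upper), method="trf",
                             xtol=1e-14, ftol=1e-14, gtol=1e-14,
                             max_nfev=400 * (2 * n + 1))

    best = attempt(taus0)
    tries = 0
    while not best.success and tries < restarts:
        tries += 1
        jitter = np.exp(rng.normal(0.0, 0.5, size=n))
        res = attempt(np.clip(taus0 * jitter, tau_lo * 1.01, tau_hi * 0.99))
        if res.cost < best.cost or (res.success and not best.success):
            best = res

    amps = best.x[:n]
    taus = np.exp(best.x[n:2 * n])
    plateau = float(best.x[2 * n])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]

    # merge numerically coincident relaxation times by amplitude summation
    merged = []
    for a, tau in zip(amps, taus):
        if merged and tau / merged[-1][1] < 1.005:
            merged[-1] = (merged[-1][0] + a, merged[-1][1])
        else:
            merged.append((float(a), float(tau)))

    resid = best.fun
    rms = float(np.sqrt(np.mean(resid ** 2)))
    stderr = _covariance_stderr(best, n, resid)

    resolvable = all(t2 / t1 >= _MIN_TAU_SEPARATION
                     for (_, t1), (_, t2) in zip(merged, merged[1:]))
    if not resolvable:
        warnings.warn("fitted relaxation times closer than 3x: model order may "
                      "exceed what the data resolve", stacklevel=2)

    fit = MaxwellFit(components=merged, plateau=plateau, strain=t.strain,
                     residual_rms=rms, stderr=stderr, resolvable=resolvable,
                     n_auto=n_auto, meta={"cost": float(best.cost),
                                          "status": int(best.status)})
    if not best.success:
        raise FitFailureError(
            f"relaxation fit did not converge after {restarts} restarts "
            f"(status {best.status})", best_fit=fit)
    return fit


def _covariance_stderr(result, n, resid):
    """Per-parameter standard errors from the Gauss-Newton covariance."""
    dof = resid.size - result.x.size
    if dof <= 0:
        return None
    s2 = 2.0 * result.cost / dof
    try:
        jtj = result.jac.T @ result.jac
        cov = s2 * np.linalg.pinv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return None
    taus = np.exp(result.x[n:2 * n])
    return {
        "amplitude": se[:n].tolist(),
        "tau": (taus * se[n:2 * n]).tolist(),  # delta method for tau = exp(x)
        "plateau": float(se[2 * n]),
    }
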