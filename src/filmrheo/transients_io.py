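"""Data model and delimited-text I/O for interfacial time series.

Three record types cover the inputs of a Langmuir-trough film study:

* :class:`RelaxationTransient` -- surface pressure pi(t) after a small, rapid
  area compression step (stress-relaxation experiment).  Time zero is the end
  of the step; the relative step size ``strain`` = dA/A0 and the pre-step
  baseline ``pi0`` are carried with the trace.
* :class:`TroughRecording` -- (time, area, pi) during repeated
  compression--expansion cycling of the trough barriers.
* :class:`KineticsTrace` -- pi(t) after injecting a surfactant beneath a
  pre-formed film (penetration kinetics), with the pre-injection baseline.

All readers and writers speak delimited text (CSV/TSV) through a configurable
:class:`Dialect`; writers emit a header row naming the units so files are
self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import DegenerateStepError, FormatError, ValidationError

__all__ = [
    "Dialect",
    "RelaxationTransient",
    "TroughRecording",
    "KineticsTrace",
    "NormalizedRelaxation",
    "read_timeseries",
    "write_timeseries",
    "normalize_relaxation",
    "log_bin_transient",
]


@dataclass(frozen=True)
class Dialect:
    """Column mapping and parsing options for delimited trough exports.

    Defaults describe the package's own export format: comma-separated,
    header row, SI-with-mN/m units.  Vendor exports that differ only need a
    different column mapping, separator or decimal mark.
    """

    sep: str = ","
    decimal: str = "."
    time_col: str = "time_s"
    pi_col: str = "pi_mn_per_m"
    area_col: str = "area"
    area_unit: str = "cm^2"

    def columns_for(self, kind: str) -> list[str]:
        if kind == "trough":
            return [self.time_col, self.area_col, self.pi_col]
        return [self.time_col, self.pi_col]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_strictly_increasing(t: np.ndarray, what: str) -> None:
    if t.size < 2:
        raise ValidationError(f"{what}: need at least 2 samples, got {t.size}")
    if not np.all(np.diff(t) > 0):
        raise ValidationError(f"{what}: time must be strictly increasing")


@dataclass
class RelaxationTransient:
    """pi(t) after a small rapid area-compression step.

    Parameters
    ----------
    time : array
        Seconds, strictly increasing, with t = 0 at the end of the area step.
    pi : array
        Surface pressure in mN/m at each time.
    pi0 : float
        Pre-step baseline surface pressure, mN/m.
    strain : float
        Relative area step dA/A0, dimensionless, in (0, 0.2].  The standard
        small-deformation protocol uses 0.05 +/- 0.01.
    meta : dict
        Free-form labels (sample, subphase, temperature ...).
    """

    time: np.ndarray
    pi: np.ndarray
    pi0: float
    strain: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_1d_float(self.time, "time")
        self.pi = _as_1d_float(self.pi, "pi")
        _check_strictly_increasing(self.time, "RelaxationTransient")
        if self.pi.size != self.time.size:
            raise ValidationError("time and pi must have equal length")
        if not np.all(np.isfinite(self.pi)):
            raise ValidationError("pi contains non-finite values")
        if not np.isfinite(self.pi0):
            raise ValidationError("pi0 must be finite")
        if not (0.0 < self.strain <= 0.2):
            raise ValidationError(f"strain must lie in (0, 0.2], got {self.strain}")
        if self.pi.max() < self.pi0:
            raise ValidationError(
                "pi_max < pi0: not a compression step (pressure must rise above baseline)"
            )

    @classmethod
    def from_measurement(cls, time, pi, strain, pi0=None, meta=None):
        """Build a transient from a raw recording that may include pre-step samples.

        Samples with t < 0 (before the end of the step) are used only to
        estimate ``pi0`` (their mean) and are dropped from the stored series.
        If no pre-step samples exist, ``pi0`` must be supplied.
        """
        time = _as_1d_float(time, "time")
        pi = _as_1d_float(pi, "pi")
        pre = time < 0.0
        if pi0 is None:
            if not pre.any():
                raise ValidationError(
                    "pi0 not given and no pre-step (t < 0) samples to estimate it from"
                )
            pi0 = float(np.mean(pi[pre]))
        return cls(time=time[~pre], pi=pi[~pre], pi0=float(pi0),
                   strain=float(strain), meta=dict(meta or {}))

    @property
    def delta_pi(self) -> np.ndarray:
        """Pressure response dpi(t) = pi(t) - pi0, mN/m."""
        return self.pi - self.pi0

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass
class TroughRecording:
    """(time, area, pi) over repeated compression--expansion barrier cycles."""

    time: np.ndarray
    area: np.ndarray
    pi: np.ndarray
    area_unit: str = "cm^2"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_1d_float(self.time, "time")
        self.area = _as_1d_float(self.area, "area")
        self.pi = _as_1d_float(self.pi, "pi")
        _check_strictly_increasing(self.time, "TroughRecording")
        if not (self.time.size == self.area.size == self.pi.size):
            raise ValidationError("time, area and pi must have equal length")
        if not np.all(self.area > 0):
            raise ValidationError("area must be positive everywhere")
        if not (np.all(np.isfinite(self.area)) and np.all(np.isfinite(self.pi))):
            raise ValidationError("area/pi contain non-finite values")


@dataclass
class KineticsTrace:
    """pi(t) after surfactant injection beneath a pre-formed film.

    ``time`` counts seconds since injection; samples with t < 0, if present,
    record the pre-injection equilibration and may be used to estimate
    ``pi0`` (the protocol pre-equilibrates films near 18 mN/m).
    """

    time: np.ndarray
    pi: np.ndarray
    pi0: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = _as_1d_float(self.time, "time")
        self.pi = _as_1d_float(self.pi, "pi")
        _check_strictly_increasing(self.time, "KineticsTrace")
        if self.pi.size != self.time.size:
            raise ValidationError("time and pi must have equal length")
        if not np.all(np.isfinite(self.pi)):
            raise ValidationError("pi contains non-finite values")
        if self.pi0 is not None and not np.isfinite(self.pi0):
            raise ValidationError("pi0 must be finite")


Record = Union[RelaxationTransient, TroughRecording, KineticsTrace]

_KINDS = ("relaxation", "trough", "kinetics")


def read_timeseries(path, kind: str, dialect: Dialect = Dialect(), *,
                    strain: Optional[float] = None,
                    pi0: Optional[float] = None,
                    meta: Optional[dict] = None) -> Record:
    """Read a delimited-text time series into a validated record.

    Parameters
    ----------
    path : path-like
        CSV/TSV file with a header row.
    kind : {"relaxation", "trough", "kinetics"}
        Which record type to build; determines the required columns.
    dialect : Dialect
        Column names, separator and decimal mark.
    strain : float, required for kind="relaxation"
        Relative area step dA/A0 of the experiment.
    pi0 : float, optional
        Baseline pressure; if omitted it is estimated from pre-step
        (t < 0) samples where the kind supports that.

    Rows with non-finite values in any declared column are dropped; their
    1-based file line numbers are reported in a warning and recorded under
    ``meta["dropped_lines"]``.
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep=dialect.sep, decimal=dialect.decimal,
                         float_precision="round_trip")
    except Exception as exc:  # malformed text, inconsistent row lengths ...
        raise FormatError(f"cannot parse {path}: {exc}") from exc

    cols = dialect.columns_for(kind)
    for col in cols:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    sub = df[cols].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(sub.to_numpy()).all(axis=1)
    meta = dict(meta or {})
    if not finite.all():
        # +2: 1-based numbering plus the header row
        dropped = [int(i) + 2 for i in np.nonzero(~finite)[0]]
        warnings.warn(
            f"{path}: dropped {len(dropped)} non-finite row(s) at line(s) {dropped}",
            stacklevel=2,
        )
        meta["dropped_lines"] = dropped
        sub = sub[finite]

    t = sub[dialect.time_col].to_numpy(float)
    p = sub[dialect.pi_col].to_numpy(float)
    if kind == "trough":
        return TroughRecording(time=t, area=sub[dialect.area_col].to_numpy(float),
                               pi=p, area_unit=dialect.area_unit, meta=meta)
    if kind == "relaxation":
        if strain is None:
            raise ValidationError("strain is required to read a relaxation transient")
        return RelaxationTransient.from_measurement(t, p, strain=strain, pi0=pi0, meta=meta)
    if pi0 is None and (t < 0).any():
        pi0 = float(np.mean(p[t < 0]))
    return KineticsTrace(time=t, pi=p, pi0=pi0, meta=meta)


def write_timeseries(record: Record, path, dialect: Dialect = Dialect()) -> None:
    """Write a record back to delimited text with a unit-bearing header."""
    path = Path(path)
    if isinstance(record, TroughRecording):
        d = replace(dialect, area_unit=record.area_unit)
        df = pd.DataFrame({d.time_col: record.time, d.area_col: record.area,
                           d.pi_col: record.pi})
    elif isinstance(record, (RelaxationTransient, KineticsTrace)):
        df = pd.DataFrame({dialect.time_col: record.time, dialect.pi_col: record.pi})
    else:
        raise TypeError(f"unsupported record type {type(record).__name__}")
    df.to_csv(path, sep=dialect.sep, decimal=dialect.decimal, index=False)


def log_bin_transient(t: RelaxationTransient,
                      bins_per_decade: int = 20) -> tuple[RelaxationTransient, np.ndarray]:
    """Average a transient into logarithmically spaced time bins.

    Relaxation information is distributed uniformly in log time, while a
    uniformly sampled record spends almost all its samples on the slow tail.
    Binning onto a log-time grid averages many samples exactly where slow
    processes live -- suppressing white measurement noise by sqrt(n) per
    bin -- while early samples (which carry the fast processes) fall into
    bins narrower than the sampling step and pass through untouched.

    Returns the binned transient and the per-point sample counts (for noise
    propagation).  Each binned point carries the mean time and mean pi of
    its samples; the result is suitable for the irregular-grid quadrature of
    :func:`~filmrheo.rheology_spectrum.compute_spectrum` (with band checking
    off, since the effective resolution varies along the record).
    """
    if bins_per_decade < 1:
        raise ValidationError("bins_per_decade must be >= 1")
    time, pi = t.time, t.pi
    pos = time > 0
    if pos.sum() < 2:
        return t, np.ones(time.size)
    t_lo, t_hi = time[pos].min(), time[pos].max()
    n_edges = max(2, int(np.ceil(np.log10(t_hi / t_lo) * bins_per_decade)) + 1)
    edges = np.geomspace(t_lo, t_hi, n_edges)
    edges[-1] = np.nextafter(t_hi, np.inf)
    idx = np.digitize(time[pos], edges) - 1
    idx = np.clip(idx, 0, n_edges - 2)
    counts = np.bincount(idx, minlength=n_edges - 1)
    keep = counts > 0
    mean_t = np.bincount(idx, weights=time[pos], minlength=n_edges - 1)[keep] / counts[keep]
    mean_pi = np.bincount(idx, weights=pi[pos], minlength=n_edges - 1)[keep] / counts[keep]
    head_t, head_pi = time[~pos], pi[~pos]
    out_t = np.concatenate([head_t, mean_t])
    out_pi = np.concatenate([head_pi, mean_pi])
    out_n = np.concatenate([np.ones(head_t.size), counts[keep].astype(float)])
    binned = RelaxationTransient(time=out_t, pi=out_pi, pi0=t.pi0,
                                 strain=t.strain,
                                 meta={**t.meta, "log_binned": True})
    return binned, out_n


@dataclass
class NormalizedRelaxation:
    """A relaxation transient in (pi_t - pi0)/(pi_max - pi0) coordinates."""

    time: np.ndarray
    value: np.ndarray


def normalize_relaxation(t: RelaxationTransient) -> NormalizedRelaxation:
    """Rescale a transient to the dimensionless (pi_t - pi0)/(pi_max - pi0) form.

    The normalized series equals 1 at the sample where pi attains its maximum
    (the starting value right after the step) and tends toward
    dpi_EQ/(pi_max - pi0) at long times.  The transform is invariant to adding
    a constant to pi and pi0 jointly and to rescaling (pi - pi0) by a positive
    factor.

    Raises
    ------
    DegenerateStepError
        If pi never rises above pi0 (no pressure response to the step).
    """
    span = t.pi.max() - t.pi0
    if span <= 0:
        raise DegenerateStepError("pi_max == pi0: degenerate step, nothing to normalize")
    return NormalizedRelaxation(time=t.time.copy(), value=(t.pi - t.pi0) / span)
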