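"""Compression--expansion isotherm analytics for Langmuir-trough recordings.

A trough recording of repeated barrier cycling is split into per-cycle pi(A)
isotherms (compression and expansion branches), which are then analyzed for:

* cycle-to-cycle stationarity (films typically converge to a stationary
  isotherm shape after a few cycles);
* replicate averaging on a common area grid, with the maximum pairwise
  relative deviation reported as a quality-control figure (replicate spread
  is typically below 2%);
* the pressure shift dpi(A) of a test condition against a control on the
  compression branch -- the signature of surfactant incorporation into the
  film;
* the squeeze-out pressure: the surface pressure above which the shift
  vanishes and stays vanished under further compression, indicating the
  incorporated surfactant is expelled from the film (P188-like behavior;
  a persistent shift, CKC-like, has no squeeze-out);
* the hysteresis loop area enclosed between compression and expansion.

Compression branches are used for shifts and squeeze-out by default, since
penetration is read off the compression leg; area units (cm^2 of trough area
or A^2 per molecule) are carried opaquely and must match between compared
branches -- no implicit conversion is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import OverlapError, ValidationError
from .transients_io import TroughRecording

__all__ = [
    "IsothermBranch",
    "IsothermCycle",
    "IsothermComparison",
    "AveragedIsotherm",
    "CycleList",
    "split_cycles",
    "stationarity_index",
    "average_isotherms",
    "pressure_shift",
    "squeeze_out_pressure",
    "hysteresis_area",
]


@dataclass
class IsothermBranch:
    """One monotone leg of a cycle: (area, pi) with area decreasing
    (compression) or increasing (expansion)."""

    area: np.ndarray
    pi: np.ndarray
    direction: str  # "compression" | "expansion"
    area_unit: str = "cm^2"

    def __post_init__(self):
        self.area = np.asarray(self.area, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.area.size != self.pi.size or self.area.size == 0:
            raise ValidationError("branch needs equally long, non-empty area and pi")
        if self.direction not in ("compression", "expansion"):
            raise ValidationError(f"bad branch direction {self.direction!r}")

    def as_increasing_area(self) -> tuple[np.ndarray, np.ndarray]:
        """(area, pi) sorted by increasing area, for interpolation."""
        if self.area.size > 1 and self.area[0] > self.area[-1]:
            return self.area[::-1], self.pi[::-1]
        return self.area, self.pi


@dataclass
class IsothermCycle:
    """One full compression--expansion excursion; ``index`` counts from 1."""

    index: int
    compression: IsothermBranch
    expansion: IsothermBranch


class CycleList(list):
    """List of cycles; ``partial_branches`` holds trailing incomplete legs."""

    def __init__(self, cycles=(), partial_branches=()):
        super().__init__(cycles)
        self.partial_branches = list(partial_branches)


@dataclass
class IsothermComparison:
    """Pointwise pressure shift of a test branch against a reference.

    ``shift`` = pi_test(A) - pi_ref(A) on ``area_grid`` (the overlap of the
    two compression branches); ``pi_test``/``pi_ref`` are the interpolated
    branch pressures on the same grid.  ``squeeze_out`` is filled by
    :func:`squeeze_out_pressure` (None until computed, and when the shift
    never vanishes).
    """

    area_grid: np.ndarray
    shift: np.ndarray
    pi_ref: np.ndarray
    pi_test: np.ndarray
    area_unit: str = "cm^2"
    squeeze_out: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.shift)):
            raise ValidationError("shift must be finite on the grid")

    @property
    def mean_shift(self) -> float:
        return float(np.mean(self.shift))

    @property
    def max_shift(self) -> float:
        return float(np.max(self.shift))


@dataclass
class AveragedIsotherm:
    """Replicate mean +/- sd on a common area grid, with a QC spread figure."""

    area_grid: np.ndarray
    pi_mean: np.ndarray
    pi_sd: np.ndarray
    max_pairwise_relative_deviation: float


def _turning_points(area: np.ndarray, min_excursion: float) -> np.ndarray:
    """Indices of alternating area extrema, jitter below min_excursion ignored."""
    maxima, _ = find_peaks(area, prominence=min_excursion)
    minima, _ = find_peaks(-area, prominence=min_excursion)
    return np.sort(np.concatenate([maxima, minima]))


def split_cycles(r: TroughRecording, min_excursion: Optional[float] = None) -> CycleList:
    """Split a trough recording into complete compression--expansion cycles.

    Cycles are delimited at local extrema of the area trace; excursions
    smaller than ``min_excursion`` (default 5% of the full area range) are
    treated as jitter, not turning points.  Each sample belongs to exactly
    one branch (branches own the half-open index range up to the next
    extremum; the final segment is closed), so re-concatenating all branches
    restores the recording.

    A trailing or leading leg that does not complete a cycle is returned in
    ``.partial_branches`` and reported with a warning.
    """
    area = r.area
    rng = float(area.max() - area.min())
    if min_excursion is None:
        min_excursion = 0.05 * rng
    if rng <= 0:
        warnings.warn("constant area trace: no cycles", stacklevel=2)
        return CycleList()

    turns = _turning_points(area, min_excursion)
    bounds = np.concatenate([[0], turns, [area.size - 1]])
    bounds = np.unique(bounds)

    branches = []
    for k in range(bounds.size - 1):
        i, j = bounds[k], bounds[k + 1]
        stop = area.size if k == bounds.size - 2 else j  # half-open, last closed
        seg_area = area[i:stop]
        seg_pi = r.pi[i:stop]
        direction = "compression" if area[j] < area[i] else "expansion"
        branches.append(IsothermBranch(seg_area, seg_pi, direction, r.area_unit))

    cycles = []
    partial = []
    k = 0
    while k < len(branches):
        b = branches[k]
        if (b.direction == "compression" and k + 1 < len(branches)
                and branches[k + 1].direction == "expansion"):
            cycles.append(IsothermCycle(index=len(cycles) + 1,
                                        compression=b, expansion=branches[k + 1]))
            k += 2
        else:
            partial.append(b)
            k += 1
    if not cycles:
        warnings.warn(f"no complete compression-expansion cycle found "
                      f"({len(partial)} partial branch(es))", stacklevel=2)
    elif partial:
        warnings.warn(f"{len(partial)} partial branch(es) outside complete cycles",
                      stacklevel=2)
    return CycleList(cycles, partial)


def _common_grid(branches: Sequence[IsothermBranch]) -> np.ndarray:
    """Intersection area range, sampled at the finest branch spacing."""
    lo = max(b.area.min() for b in branches)
    hi = min(b.area.max() for b in branches)
    if hi <= lo:
        raise OverlapError("branches share no common area range")
    step = min(float(np.median(np.abs(np.diff(b.area)))) for b in branches)
    n = max(2, int(round((hi - lo) / step)) + 1)
    return np.linspace(lo, hi, n)


def _interp_branch(b: IsothermBranch, grid: np.ndarray) -> np.ndarray:
    a, p = b.as_increasing_area()
    return np.interp(grid, a, p)


def stationarity_index(cycles: Sequence[IsothermCycle],
                       tol: Optional[float] = None) -> Optional[int]:
    """First cycle index from which the isotherm shape is stationary.

    Returns the smallest 1-based k such that every pair of consecutive
    compression branches from cycle k onward differs by less than ``tol``
    in maximum absolute pi difference on their common area grid; None if the
    recording never becomes stationary.  ``tol`` defaults to 2% of the
    maximum pi over all cycles (echoing typical replicate spread).
    """
    if len(cycles) < 2:
        raise ValidationError("need at least 2 cycles to assess stationarity")
    if tol is None:
        tol = 0.02 * max(float(c.compression.pi.max()) for c in cycles)
    dists = []
    for c1, c2 in zip(cycles, cycles[1:]):
        grid = _common_grid([c1.compression, c2.compression])
        d = np.max(np.abs(_interp_branch(c1.compression, grid)
                          - _interp_branch(c2.compression, grid)))
        dists.append(float(d))
    # smallest k (1-based) with all subsequent consecutive distances < tol
    for k in range(len(dists)):
        if all(d < tol for d in dists[k:]):
            return k + 1
    return None


def average_isotherms(branches: Sequence[IsothermBranch]) -> AveragedIsotherm:
    """Average replicate compression branches on a common area grid.

    Branches are linearly interpolated to the intersection of their area
    ranges (at the finest sampling), then averaged pointwise.  The maximum
    pairwise relative deviation max_ij max_A |pi_i - pi_j| / max|pi_mean|
    is reported for QC against the typical <2% replicate spread.
    """
    if len(branches) < 2:
        raise ValidationError("need at least 2 branches to average")
    grid = _common_grid(branches)
    mat = np.vstack([_interp_branch(b, grid) for b in branches])
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1)
    scale = float(np.max(np.abs(mean)))
    dev = 0.0
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            dev = max(dev, float(np.max(np.abs(mat[i] - mat[j]))))
    rel = dev / scale if scale > 0 else 0.0
    return AveragedIsotherm(area_grid=grid, pi_mean=mean, pi_sd=sd,
                            max_pairwise_relative_deviation=rel)


def pressure_shift(ref: IsothermBranch, test: IsothermBranch) -> IsothermComparison:
    """dpi(A) = pi_test(A) - pi_ref(A) on the overlap of two compression branches.

    A positive shift means the test film sits at higher pressure -- the
    incorporation signature.  Units must match; comparing cm^2 against
    per-molecule areas would be meaningless without molecule counts.
    """
    if ref.area_unit != test.area_unit:
        raise ValidationError(
            f"area units differ ({ref.area_unit} vs {test.area_unit}); "
            "convert explicitly before comparing")
    grid = _common_grid([ref, test])
    pi_ref = _interp_branch(ref, grid)
    pi_test = _interp_branch(test, grid)
    return IsothermComparison(area_grid=grid, shift=pi_test - pi_ref,
                              pi_ref=pi_ref, pi_test=pi_test,
                              area_unit=ref.area_unit)


def squeeze_out_pressure(cmp: IsothermComparison,
                         threshold: float = 0.5) -> Optional[float]:
    """Surface pressure at which the incorporation shift vanishes for good.

    Scanning the compression branch toward smaller area (higher pressure),
    returns the lowest pi on the test branch at and above which the shift
    stays below ``threshold`` for the whole remaining compression
    ("sustained", not a single noisy crossing).  Returns None if the shift
    never vanishes -- persistent incorporation.  If the shift is below
    threshold everywhere, the lowest pi of the branch is returned.

    The result is monotone in ``threshold``: a larger threshold never yields
    a larger pressure.  The detected value is also stored on
    ``cmp.squeeze_out``.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be positive")
    # compression order: decreasing area
    order = np.argsort(cmp.area_grid)[::-1]
    shift = cmp.shift[order]
    pi_test = cmp.pi_test[order]
    below = shift < threshold
    # suffix of samples that are all below threshold
    sustained_from = None
    for i in range(below.size - 1, -1, -1):
        if below[i]:
            sustained_from = i
        else:
            break
    if sustained_from is None:
        cmp.squeeze_out = None
        return None
    cmp.squeeze_out = float(pi_test[sustained_from])
    return cmp.squeeze_out


def hysteresis_area(cycle: IsothermCycle) -> float:
    """Absolute area enclosed between compression and expansion branches.

    Computed by trapezoidal integration of both branches over their common
    area range, i.e. the loop integral |oint pi dA| in mN/m x area-unit.
    The integration grid is the union of both branches' sample areas (clipped
    to the overlap), so the result is exact for the piecewise-linear
    interpolants of the recorded points.  Identical branches give 0.
    """
    comp, exp = cycle.compression, cycle.expansion
    lo = max(comp.area.min(), exp.area.min())
    hi = min(comp.area.max(), exp.area.max())
    if hi <= lo:
        raise OverlapError("compression and expansion branches do not overlap")
    knots = np.concatenate([comp.area, exp.area, [lo, hi]])
    grid = np.unique(np.clip(knots, lo, hi))
    pc = _interp_branch(comp, grid)
    pe = _interp_branch(exp, grid)
    return float(abs(np.trapezoid(pc - pe, grid)))
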