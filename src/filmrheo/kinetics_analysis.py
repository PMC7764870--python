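"""Penetration-kinetics feature extraction.

When a surface-active compound is injected beneath a pre-formed film, the
surface pressure first rises as the compound penetrates the film (for CKC
under a meibum film: by ~15 mN/m within the first ~100 s) and then slowly
relaxes back toward the initial value as the film re-equilibrates (on the
order of 1000 s).  This module reduces such a pi(t) trace to three
descriptive features; no adsorption model is fitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ValidationError
from .transients_io import KineticsTrace

__all__ = ["KineticsFeatures", "penetration_features"]


@dataclass
class KineticsFeatures:
    """Descriptive features of a post-injection pi(t) trace.

    delta_pi_max : max(pi) - pi0, mN/m (the penetration-induced rise)
    t_peak : time of the maximum, s
    t_requil : first time at/after the peak from which |pi - pi0| < tol holds
        for the rest of the record (None if the film never re-equilibrates
        within the recording)
    tol : the re-equilibration tolerance used, mN/m
    """

    delta_pi_max: float
    t_peak: float
    t_requil: Optional[float]
    tol: float
    pi0: float


def penetration_features(k: KineticsTrace, tol: float = 0.5,
                         pi0: Optional[float] = None) -> KineticsFeatures:
    """Extract rise and re-equilibration features from a kinetics trace.

    Parameters
    ----------
    k : KineticsTrace
    tol : float
        Band around pi0 (mN/m) within which the film counts as
        re-equilibrated; the condition must hold until the end of the record
        ("sustained"), not just at one crossing.
    pi0 : float, optional
        Pre-injection baseline; defaults to ``k.pi0``, or the mean of
        pre-injection (t < 0) samples if present.

    Notes
    -----
    Only post-injection samples (t >= 0) are scanned.  The sustained-return
    scan includes the peak sample itself, so a flat trace yields
    ``t_requil`` equal to its first sample time (and ``delta_pi_max`` 0).
    A warning is issued when no samples exist after the peak.
    """
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if pi0 is None:
        pi0 = k.pi0
        if pi0 is None:
            pre = k.time < 0
            if not pre.any():
                raise ValidationError(
                    "pi0 not given, not stored on the trace, and no pre-injection "
                    "samples to estimate it from")
            pi0 = float(np.mean(k.pi[pre]))
    post = k.time >= 0
    if not post.any():
        raise ValidationError("trace has no post-injection (t >= 0) samples")
    time = k.time[post]
    pi = k.pi[post]

    ipeak = int(np.argmax(pi))
    delta_pi_max = float(pi[ipeak] - pi0)
    t_peak = float(time[ipeak])
    if ipeak == pi.size - 1 and pi.size > 1:
        warnings.warn("pressure still rising at the end of the record: "
                      "re-equilibration time unavailable", stacklevel=2)

    inside = np.abs(pi - pi0) < tol
    t_requil = None
    # longest suffix of in-band samples starting at or after the peak
    start = None
    for i in range(pi.size - 1, ipeak - 1, -1):
        if inside[i]:
            start = i
        else:
            break
    if start is not None:
        t_requil = float(time[start])
    return KineticsFeatures(delta_pi_max=delta_pi_max, t_peak=t_peak,
                            t_requil=t_requil, tol=float(tol), pi0=float(pi0))
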