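"""Derivative-based melting analysis of GP curves.

The gel-to-fluid transition appears as a sigmoidal drop in GP with
temperature. Its negative derivative, -dGP/dT, computed by the central
finite difference, shows the transition as a positive peak from which three
quantities are read:

* T_M -- the temperature of the peak maximum (main transition temperature);
* FWHM -- the full width at half maximum of the peak, an inverse measure of
  transition cooperativity (narrower = more cooperative);
* AUC -- the trapezoidal area under the peak, an enthalpy proxy in GP units
  (equals the total GP drop across the measured range up to discretization
  error).

A transition is only reported where the derivative peak is prominent
(default: maximum at least 3x the median absolute derivative) and interior
to the measured range; flat or edge-peaked derivatives -- e.g. a lipid whose
transition lies outside the instrument's range -- yield
``transition_detected = False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    InsufficientPointsError,
    NoTransitionError,
    SpectrumValidationError,
    TruncatedPeakError,
)
from .gp import GPCurve, smooth_gp

DEFAULT_PROMINENCE_FACTOR = 3.0


@dataclass(frozen=True)
class DerivativeCurve:
    """-dGP/dT on the interior points of a GP curve's temperature grid."""

    temperatures_C: np.ndarray
    neg_dgp_dt: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_C, dtype=float)
        d = np.asarray(self.neg_dgp_dt, dtype=float)
        object.__setattr__(self, "temperatures_C", t)
        object.__setattr__(self, "neg_dgp_dt", d)
        if t.size != d.size:
            raise SpectrumValidationError("derivative arrays must match in length")
        if t.size and not np.all(np.diff(t) > 0):
            raise SpectrumValidationError("temperatures must be strictly increasing")

    def __len__(self) -> int:
        return int(self.temperatures_C.size)


@dataclass(frozen=True)
class MeltingSummary:
    """Per-sample melting metrics; None marks an unreportable quantity."""

    sample_id: str
    lipid: str
    assembly: str
    tm_C: Optional[float]
    fwhm_C: Optional[float]
    auc_gp: float
    gp_low: float   # GP at the highest measured temperature (fluid end)
    gp_high: float  # GP at the lowest measured temperature (gel end)
    transition_detected: bool
    delta_tm_C: Optional[float] = None
    reference_id: Optional[str] = None


def central_difference(curve: GPCurve) -> DerivativeCurve:
    """Central finite difference of -GP over temperature, endpoints dropped.

    At each interior point i the derivative is taken over the flanking
    neighbors, -(GP[i+1] - GP[i-1]) / (T[i+1] - T[i-1]), which also handles
    non-uniform ramps (exact for affine GP on any grid, second-order accurate
    on uniform grids). Endpoints are dropped rather than estimated one-sided.
    """
    if len(curve) < 3:
        raise InsufficientPointsError(
            f"central difference needs >= 3 temperatures, got {len(curve)}"
        )
    t = curve.temperatures_C
    gp = curve.gp_mean
    deriv = -(gp[2:] - gp[:-2]) / (t[2:] - t[:-2])
    return DerivativeCurve(temperatures_C=t[1:-1], neg_dgp_dt=deriv)


def detect_transition(
    deriv: DerivativeCurve,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> bool:
    """True iff the derivative shows a prominent, interior peak.

    The peak must reach at least ``prominence_factor`` times the median
    absolute derivative (guarding against broad noise), be strictly positive,
    and its argmax must be an interior point of the derivative grid (an edge
    maximum means the transition is truncated by the measured range).
    """
    d = deriv.neg_dgp_dt
    if d.size == 0:
        return False
    peak_idx = int(np.argmax(d))
    peak = d[peak_idx]
    if peak <= 0 or np.all(d == d[0]):
        return False
    if peak_idx == 0 or peak_idx == d.size - 1:
        return False
    return bool(peak >= prominence_factor * np.median(np.abs(d)))


def find_tm(deriv: DerivativeCurve, refine: bool = False) -> float:
    """Temperature of the -dGP/dT maximum (the main transition temperature).

    Ties break toward the lowest temperature. With ``refine=True`` a
    parabola through the peak and its two neighbors returns the vertex
    abscissa, clamped to the neighbor interval; the default reports the raw
    grid argmax for reproducibility at grid resolution.
    """
    d = deriv.neg_dgp_dt
    if d.size == 0:
        raise NoTransitionError("empty derivative curve")
    if d.size > 2 and np.all(d == d[0]):
        raise NoTransitionError("flat derivative: no transition peak")
    i = int(np.argmax(d))  # np.argmax returns the first (lowest-T) maximum
    tm = float(deriv.temperatures_C[i])
    if not refine or i == 0 or i == d.size - 1:
        return tm
    t0, t1, t2 = deriv.temperatures_C[i - 1 : i + 2]
    y0, y1, y2 = d[i - 1 : i + 2]
    denom = (t1 - t0) * (y1 - y2) - (t1 - t2) * (y1 - y0)
    if denom == 0:
        return tm
    vertex = t1 - 0.5 * (
        (t1 - t0) ** 2 * (y1 - y2) - (t1 - t2) ** 2 * (y1 - y0)
    ) / denom
    return float(np.clip(vertex, t0, t2))


def fwhm(deriv: DerivativeCurve) -> float:
    """Full width at half maximum of the derivative peak (degC).

    The two half-maximum crossings nearest the peak are located by linear
    interpolation between bracketing grid points; a peak that never falls
    below half maximum on either side within the range raises
    :class:`TruncatedPeakError` (the summary then reports no width).
    """
    d = deriv.neg_dgp_dt
    t = deriv.temperatures_C
    if d.size == 0:
        raise NoTransitionError("empty derivative curve")
    i = int(np.argmax(d))
    half = d[i] / 2.0

    def cross(j_from: int, step: int) -> float:
        j = j_from
        while 0 <= j + step < d.size:
            a, b = j, j + step
            if d[b] <= half:
                # linear interpolation between t[a] (above) and t[b] (below)
                frac = (d[a] - half) / (d[a] - d[b])
                return float(t[a] + frac * (t[b] - t[a]))
            j += step
        raise TruncatedPeakError(
            "derivative peak does not fall below half maximum inside the "
            "measured range"
        )

    left = cross(i, -1)
    right = cross(i, +1)
    return right - left


def auc(deriv: DerivativeCurve) -> float:
    """Trapezoidal area under -dGP/dT over its temperature span (GP units).

    Approximates the total GP drop across the transition; the enthalpy proxy.
    """
    if len(deriv) < 2:
        raise InsufficientPointsError("AUC needs >= 2 derivative points")
    return float(np.trapezoid(deriv.neg_dgp_dt, deriv.temperatures_C))


def delta_tm(sample: MeltingSummary, reference: MeltingSummary) -> Optional[float]:
    """T_M shift of a sample versus a reference bilayer (positive = right-shifted).

    Returns None with a warning when either transition was not detected.
    """
    if not (sample.transition_detected and reference.transition_detected):
        warnings.warn(
            f"delta_tm({sample.sample_id!r} vs {reference.sample_id!r}): "
            "transition not detected in at least one input; returning NA",
            stacklevel=2,
        )
        return None
    return float(sample.tm_C - reference.tm_C)


def analyze_curve(
    curve: GPCurve,
    *,
    smooth: Optional[int] = None,
    refine: bool = False,
    prominence_factor: float = DEFAULT_PROMINENCE_FACTOR,
) -> MeltingSummary:
    """Full melting analysis of one GP curve.

    Optional odd-window smoothing is applied to GP before differentiation;
    by default the raw curve is analyzed. When no transition is detected,
    T_M and FWHM are None but the endpoint GPs and AUC are still reported.
    """
    if smooth:
        curve = smooth_gp(curve, smooth)
    deriv = central_difference(curve)
    detected = detect_transition(deriv, prominence_factor)
    tm: Optional[float] = None
    width: Optional[float] = None
    if detected:
        tm = find_tm(deriv, refine=refine)
        try:
            width = fwhm(deriv)
        except TruncatedPeakError:
            width = None
    return MeltingSummary(
        sample_id=curve.sample_id,
        lipid=curve.lipid,
        assembly=curve.assembly,
        tm_C=tm,
        fwhm_C=width,
        auc_gp=auc(deriv),
        gp_low=float(curve.gp_mean[-1]),
        gp_high=float(curve.gp_mean[0]),
        transition_detected=detected,
    )
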