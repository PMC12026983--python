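"""Geometric models of rim-perturbed lipids in a nanodisc.

A nanodisc of diameter d carries a perturbed annulus of lipids at the
scaffold rim. Under the two-population (perturbed / unperturbed) picture
with a boundary annulus of width w measured inward from the rim, the
unperturbed area fraction is

    f = ((d/2 - w) / (d/2))^2        (0 when w >= d/2)

and the observed disc GP is the area-weighted mix
f * GP_core + (1 - f) * GP_boundary. Inverting the annulus formula
calibrates the boundary width implied by an observed unperturbed fraction:
w = (d/2) (1 - sqrt(f)).

The continuum alternative replaces the step annulus with a monotone
perturbation profile in distance from the rim (exponential with decay
length lambda by default) and averages GP over the disc area by adaptive
quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .errors import GridMismatchError
from .gp import GPCurve

#: nominal scaffold diameters (nm) of the four circularized nanodiscs
SCAFFOLD_DIAMETERS_NM = {
    "spMSP1D1": 11.0,
    "spNW15": 15.0,
    "spNW25": 25.0,
    "spNW50": 50.0,
}


@dataclass(frozen=True)
class DiscGeometry:
    """Nanodisc diameter, boundary annulus width, and unperturbed fraction."""

    diameter_nm: float
    boundary_width_nm: float

    def __post_init__(self) -> None:
        if self.diameter_nm <= 0:
            raise ValueError("diameter must be positive")
        if self.boundary_width_nm < 0:
            raise ValueError("boundary width must be non-negative")

    @property
    def unperturbed_fraction(self) -> float:
        return unperturbed_fraction(self.diameter_nm, self.boundary_width_nm)


def unperturbed_fraction(d: float, w: float) -> float:
    """Area fraction of lipids outside a rim annulus of width w in a disc of
    diameter d (both nm). Returns 0 when the annulus swallows the disc."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    if w < 0:
        raise ValueError("boundary width must be non-negative")
    r = d / 2.0
    return max(0.0, (r - w) / r) ** 2


def calibrate_boundary_width(d: float, f_observed: float) -> float:
    """Boundary width (nm) implied by an observed unperturbed fraction.

    Inverse of :func:`unperturbed_fraction`: w = (d/2)(1 - sqrt(f));
    round-trips through the forward formula to 1e-12.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if not 0.0 < f_observed <= 1.0:
        raise ValueError("observed fraction must lie in (0, 1]")
    return (d / 2.0) * (1.0 - np.sqrt(f_observed))


def two_population_gp(
    f: float, gp_core_curve: GPCurve, gp_boundary_curve: GPCurve
) -> GPCurve:
    """Disc GP as the area-weighted mix of core and boundary populations."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    a, b = gp_core_curve, gp_boundary_curve
    if len(a) != len(b) or not np.allclose(
        a.temperatures_C, b.temperatures_C, rtol=0, atol=1e-9
    ):
        raise GridMismatchError(
            "core and boundary curves must share a temperature grid"
        )
    mixed = f * a.gp_mean + (1.0 - f) * b.gp_mean
    return GPCurve(
        sample_id=f"{a.sample_id}+boundary",
        lipid=a.lipid,
        assembly=a.assembly,
        temperatures_C=a.temperatures_C,
        gp_mean=mixed,
        gp_sd=np.full(len(a), np.nan),
        n_replicates=np.ones(len(a), dtype=int),
    )


def continuum_gp(
    d: float,
    decay_length: float,
    gp_bulk: float,
    gp_rim: float,
    profile: Optional[Callable[[float], float]] = None,
) -> float:
    """Disc-averaged GP under a continuum rim-perturbation profile.

    The local GP at radius r is
    gp_bulk + (gp_rim - gp_bulk) * p(R - r), where p is the perturbation
    profile in distance from the rim (default p(x) = exp(-x / decay_length))
    and R = d/2. The area-weighted average (2/R^2) * int_0^R r GP(r) dr is
    evaluated by adaptive quadrature at 1e-8 relative tolerance. A step
    profile p(x) = 1{x < w} recovers the two-population mix exactly.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if profile is None:
        if decay_length <= 0:
            raise ValueError("decay length must be positive")
        lam = float(decay_length)

        def profile(x: float) -> float:
            return float(np.exp(-x / lam))

    R = d / 2.0

    def integrand(r: float) -> float:
        return r * (gp_bulk + (gp_rim - gp_bulk) * profile(R - r))

    val, _ = quad(integrand, 0.0, R, epsrel=1e-8, epsabs=1e-12, limit=200)
    return (2.0 / R**2) * val
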