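"""Laurdan generalized polarization (GP).

GP is the ratiometric order statistic

    GP = (I_440 - I_490) / (I_440 + I_490)

where I_440 and I_490 are the emission intensities at the ordered-phase
(440 nm) and disordered-phase (490 nm) band maxima. GP lies in [-1, 1];
higher values indicate tighter lipid packing. Channel intensities are read
at the exact grid wavelength -- no bandwidth integration, no interpolation.

GP is always computed on scan-averaged spectra; replicate aggregation
(mean and n-1 standard deviation across independent preparations) happens
on GP values, matching how melting curves are conventionally reported with
error bars from three independent measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DegenerateSpectrumError,
    GridMismatchError,
    MissingChannelError,
    SpectrumValidationError,
)
from .spectra import EmissionSpectrum, SpectrumSeries

LAMBDA_ORDERED_NM = 440.0
LAMBDA_DISORDERED_NM = 490.0


@dataclass(frozen=True)
class GPCurve:
    """Replicate-aggregated GP versus temperature for one sample.

    ``gp_sd`` is NaN wherever ``n_replicates == 1`` (no spread to report).
    """

    sample_id: str
    lipid: str
    assembly: str
    temperatures_C: np.ndarray
    gp_mean: np.ndarray
    gp_sd: np.ndarray
    n_replicates: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_C, dtype=float)
        m = np.asarray(self.gp_mean, dtype=float)
        sd = np.asarray(self.gp_sd, dtype=float)
        n = np.asarray(self.n_replicates, dtype=int)
        for name, arr in (("temperatures_C", t), ("gp_mean", m),
                          ("gp_sd", sd), ("n_replicates", n)):
            object.__setattr__(self, name, arr)
        if not (t.size == m.size == sd.size == n.size):
            raise SpectrumValidationError("GPCurve arrays must have equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise SpectrumValidationError("temperatures must be strictly increasing")
        if np.any(m < -1 - 1e-12) or np.any(m > 1 + 1e-12):
            raise SpectrumValidationError("gp_mean values must lie in [-1, 1]")
        with np.errstate(invalid="ignore"):
            if np.any(sd[~np.isnan(sd)] < 0):
                raise SpectrumValidationError("gp_sd must be non-negative")
        if np.any(n < 1):
            raise SpectrumValidationError("n_replicates must be positive")

    def __len__(self) -> int:
        return int(self.temperatures_C.size)


def _channel_intensity(spectrum: EmissionSpectrum, wavelength_nm: float) -> float:
    idx = np.flatnonzero(np.abs(spectrum.wavelengths_nm - wavelength_nm) < 1e-9)
    if idx.size == 0:
        raise MissingChannelError(
            f"wavelength {wavelength_nm} nm is not on the spectrum grid "
            f"(sample {spectrum.sample_id!r}, T={spectrum.temperature_C} degC); "
            "no interpolation is performed"
        )
    return float(spectrum.intensities[idx[0]])


def compute_gp(
    spectrum: EmissionSpectrum,
    lambda_ordered: float = LAMBDA_ORDERED_NM,
    lambda_disordered: float = LAMBDA_DISORDERED_NM,
) -> float:
    """GP of one spectrum from exact-grid channel reads.

    Raises :class:`MissingChannelError` if either wavelength is absent from
    the grid and :class:`DegenerateSpectrumError` if both channels are zero.
    """
    i_ord = _channel_intensity(spectrum, lambda_ordered)
    i_dis = _channel_intensity(spectrum, lambda_disordered)
    total = i_ord + i_dis
    if total <= 0:
        raise DegenerateSpectrumError(
            f"I({lambda_ordered:g}) + I({lambda_disordered:g}) = 0 for sample "
            f"{spectrum.sample_id!r} at T={spectrum.temperature_C} degC"
        )
    return (i_ord - i_dis) / total


def build_gp_curve(
    series: SpectrumSeries,
    lambda_ordered: float = LAMBDA_ORDERED_NM,
    lambda_disordered: float = LAMBDA_DISORDERED_NM,
) -> GPCurve:
    """Single-replicate GP curve from a scan-averaged temperature series."""
    first = series.spectra[0]
    gp_vals = []
    for s in series:
        try:
            gp_vals.append(compute_gp(s, lambda_ordered, lambda_disordered))
        except (MissingChannelError, DegenerateSpectrumError) as exc:
            raise type(exc)(f"at T={s.temperature_C} degC: {exc}") from exc
    n = len(gp_vals)
    return GPCurve(
        sample_id=first.sample_id,
        lipid=first.lipid,
        assembly=first.assembly,
        temperatures_C=series.temperatures_C,
        gp_mean=np.array(gp_vals),
        gp_sd=np.full(n, np.nan),
        n_replicates=np.ones(n, dtype=int),
    )


def aggregate_replicates(curves) -> GPCurve:
    """Mean and sample SD (n-1 denominator) of replicate GP curves.

    All curves must share the temperature grid and labels; a single curve is
    returned as-is (SD stays NaN). The SD convention matches error bars that
    report the standard deviation of independent measurements.
    """
    curves = list(curves)
    if not curves:
        raise SpectrumValidationError("aggregate_replicates: empty curve list")
    first = curves[0]
    for c in curves[1:]:
        if c.sample_id != first.sample_id or c.lipid != first.lipid \
                or c.assembly != first.assembly:
            raise SpectrumValidationError(
                "replicate curves must share sample labels"
            )
        if len(c) != len(first) or not np.allclose(
            c.temperatures_C, first.temperatures_C, rtol=0, atol=1e-9
        ):
            bad = sorted(
                set(np.round(c.temperatures_C, 2))
                ^ set(np.round(first.temperatures_C, 2))
            )
            raise GridMismatchError(
                f"replicate temperature grids differ for {first.sample_id!r}; "
                f"offending temperatures: {bad}"
            )
    if len(curves) == 1:
        return first
    stack = np.vstack([c.gp_mean for c in curves])
    n = stack.shape[0]
    return GPCurve(
        sample_id=first.sample_id,
        lipid=first.lipid,
        assembly=first.assembly,
        temperatures_C=first.temperatures_C,
        gp_mean=stack.mean(axis=0),
        gp_sd=stack.std(axis=0, ddof=1),
        n_replicates=np.full(len(first), n, dtype=int),
    )


def smooth_gp(curve: GPCurve, window: int) -> GPCurve:
    """Centered moving average of ``gp_mean`` with an odd window.

    Off by default throughout the pipeline (raw GP is reported); available
    for noisy curves. Edges average over the available part of the window,
    so curve length is preserved.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return curve
    half = window // 2
    gp = curve.gp_mean
    out = np.empty_like(gp)
    for i in range(gp.size):
        lo, hi = max(0, i - half), min(gp.size, i + half + 1)
        out[i] = gp[lo:hi].mean()
    return replace(curve, gp_mean=out)
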