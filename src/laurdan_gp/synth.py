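"""Synthetic Laurdan emission spectra with two-state melting.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised without instrument data:

* a two-state (van't Hoff-like) gel/fluid equilibrium with ordered fraction
  f(T) = 1 / (1 + exp((T - tm) / k)) -- tm is the transition midpoint, k the
  transition width in degC (small k = cooperative, sharp transition);
* two Gaussian emission bands peaking at 440 nm (ordered phase) and 490 nm
  (disordered phase) on the 400-540 nm, 1 nm acquisition grid, mixed in
  proportion f : (1 - f);
* additive Gaussian detector noise as a fraction of peak amplitude, clipped
  at zero;
* the acquisition structure of a melting experiment: 3 scans per spectrum
  (averaged downstream) and 3 independent replicates.

Presets encode literature transition temperatures for the four lipids in
large unilamellar vesicles (DMPC 24, DPPC 41, DSPC 54, POPC -2 degC) and the
size-dependent shifts and broadening seen in circularized nanodiscs: the
11 nm disc raises T_M by +5 (DMPC) and +2 (DPPC) degC and leaves DSPC
unshifted, while 50 nm discs match vesicles; transitions broaden as discs
shrink. Disc widths and GP plateaus are generator choices encoding those
qualitative orderings, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from .errors import UnknownPresetError
from .spectra import EmissionSpectrum, write_spectra

DEFAULT_GRID_NM = (400.0, 540.0, 1.0)  # start, stop (inclusive), step


@dataclass(frozen=True)
class TwoStateModel:
    """Two-state gel/fluid melting model.

    ``gp_gel``/``gp_fluid`` are the GP plateaus of the pure phases; they
    parameterize the idealized GP curve :func:`gp_truth` (the rendered
    spectra themselves depend only on the ordered fraction and the band
    model).
    """

    tm_C: float
    k_C: float
    gp_gel: float = 0.55
    gp_fluid: float = -0.15

    def __post_init__(self) -> None:
        if self.k_C <= 0:
            raise ValueError("transition width k_C must be positive")
        for v in (self.gp_gel, self.gp_fluid):
            if not -1.0 <= v <= 1.0:
                raise ValueError("GP plateaus must lie in [-1, 1]")
        if self.gp_fluid >= self.gp_gel:
            raise ValueError("gp_fluid must be below gp_gel")


@dataclass(frozen=True)
class BandModel:
    """Gaussian emission bands of the two phases.

    Default sigma of 18 nm keeps 440/490 channel cross-talk near 2%, i.e.
    realistic band overlap that still leaves the derivative peak of rendered
    data on the generating midpoint at 1 degC resolution.
    """

    center_ordered_nm: float = 440.0
    center_disordered_nm: float = 490.0
    sigma_nm: float = 18.0
    amplitude: float = 1000.0

    def __post_init__(self) -> None:
        if self.sigma_nm <= 0 or self.amplitude <= 0:
            raise ValueError("sigma_nm and amplitude must be positive")


@dataclass(frozen=True)
class Preset:
    lipid: str
    assembly: str
    model: TwoStateModel
    bands: BandModel = field(default_factory=BandModel)

    @property
    def key(self) -> str:
        return f"{self.lipid}:{self.assembly}"


def _preset_table() -> dict[str, Preset]:
    # (lipid, assembly) -> (tm_C, k_C). LUV midpoints are the literature
    # transition temperatures; 11 nm disc (spMSP1D1) midpoints carry the
    # +5 / +2 / 0 degC shifts for DMPC / DPPC / DSPC; spNW15 matches
    # spMSP1D1, spNW50 matches the LUV, spNW25 sits between. Widths encode
    # cooperativity increasing with disc size (LUV sharpest).
    rows = [
        ("DMPC", "LUV", 24.0, 0.4),
        ("DPPC", "LUV", 41.0, 0.4),
        ("DSPC", "LUV", 54.0, 0.4),
        ("POPC", "LUV", -2.0, 0.4),
        ("DMPC", "spMSP1D1", 29.0, 2.5),
        ("DPPC", "spMSP1D1", 43.0, 2.5),
        ("DSPC", "spMSP1D1", 54.0, 2.5),
        ("DMPC", "spNW15", 29.0, 2.5),
        ("DPPC", "spNW15", 43.0, 2.5),
        ("DSPC", "spNW15", 54.0, 2.5),
        ("DMPC", "spNW25", 26.0, 1.5),
        ("DPPC", "spNW25", 42.0, 1.5),
        ("DSPC", "spNW25", 54.0, 1.5),
        ("DMPC", "spNW50", 24.0, 0.8),
        ("DPPC", "spNW50", 41.0, 0.8),
        ("DSPC", "spNW50", 54.0, 0.8),
    ]
    return {
        f"{lipid}:{assembly}": Preset(
            lipid=lipid,
            assembly=assembly,
            model=TwoStateModel(tm_C=tm, k_C=k),
        )
        for lipid, assembly, tm, k in rows
    }


PRESETS: dict[str, Preset] = _preset_table()


def get_preset(key: str) -> Preset:
    try:
        return PRESETS[key]
    except KeyError:
        raise UnknownPresetError(
            f"unknown preset {key!r}; available presets: "
            + ", ".join(sorted(PRESETS))
        ) from None


def ordered_fraction(T: float, model: TwoStateModel) -> float:
    """Fraction of lipid in the ordered (gel) phase at temperature T.

    f = 1 / (1 + exp((T - tm) / k)); strictly decreasing in T, 0.5 at tm.
    """
    return float(expit(-(float(T) - model.tm_C) / model.k_C))


def gp_truth(T: float, model: TwoStateModel) -> float:
    """Idealized GP of the two-state mixture: plateau interpolation by f(T)."""
    f = ordered_fraction(T, model)
    return model.gp_fluid + (model.gp_gel - model.gp_fluid) * f


def _gaussian_peak(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def render_spectrum(
    T: float,
    model: TwoStateModel,
    bands: BandModel = BandModel(),
    noise_sd_frac: float = 0.0,
    seed: Optional[int] = None,
    *,
    ordered_fraction_override: Optional[float] = None,
    grid_nm: tuple[float, float, float] = DEFAULT_GRID_NM,
    sample_id: str = "synthetic",
    lipid: str = "synthetic",
    assembly: str = "other",
    replicate: int = 1,
    scan: int = 1,
) -> EmissionSpectrum:
    """Render one emission spectrum at temperature T.

    Intensity is the f-weighted mixture of the two peak-normalized Gaussian
    bands scaled by the band amplitude, plus i.i.d. Gaussian noise with
    SD = ``noise_sd_frac`` * amplitude, clipped at zero. Reproducible for a
    given seed. ``ordered_fraction_override`` pins f directly (e.g. 1.0 or
    0.0 for the pure-phase limits) instead of evaluating the melting model.
    """
    if noise_sd_frac < 0:
        raise ValueError("noise_sd_frac must be >= 0")
    start, stop, step = grid_nm
    wl = np.arange(start, stop + step / 2, step, dtype=float)
    f = (
        float(ordered_fraction_override)
        if ordered_fraction_override is not None
        else ordered_fraction(T, model)
    )
    if not 0.0 <= f <= 1.0:
        raise ValueError("ordered fraction must lie in [0, 1]")
    intensity = bands.amplitude * (
        f * _gaussian_peak(wl, bands.center_ordered_nm, bands.sigma_nm)
        + (1.0 - f) * _gaussian_peak(wl, bands.center_disordered_nm, bands.sigma_nm)
    )
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(
            0.0, noise_sd_frac * bands.amplitude, size=wl.size
        )
    intensity = np.clip(intensity, 0.0, None)
    return EmissionSpectrum(
        wavelengths_nm=wl,
        intensities=intensity,
        temperature_C=float(T),
        sample_id=sample_id,
        lipid=lipid,
        assembly=assembly,
        replicate=replicate,
        scan=scan,
    )


def rendered_gp_closed_form(f: float, bands: BandModel = BandModel()) -> float:
    """Closed-form GP of a noise-free rendered spectrum at ordered fraction f.

    With equal-width, equal-amplitude bands the 440/490 channel reads are
    I440 = f + (1-f) b and I490 = f b + (1-f) (per unit amplitude), where
    b = exp(-(50/sigma)^2 / 2) is the band cross-talk, so
    GP = (2f - 1)(1 - b)/(1 + b): exactly linear in f. Used as the oracle
    for generator/analysis consistency checks.
    """
    dist = bands.center_disordered_nm - bands.center_ordered_nm
    b = float(np.exp(-0.5 * (dist / bands.sigma_nm) ** 2))
    return (2.0 * f - 1.0) * (1.0 - b) / (1.0 + b)


def simulate_spectra(
    preset_key: str,
    t_min: float,
    t_max: float,
    step: float = 1.0,
    n_replicates: int = 3,
    n_scans: int = 3,
    noise_sd_frac: float = 0.01,
    seed: int = 0,
) -> list[EmissionSpectrum]:
    """Generate a full synthetic melting experiment in memory.

    One spectrum per (replicate, scan, temperature); sub-seeds are derived
    deterministically from the master seed so replicates, scans and
    temperatures draw independent noise but the whole experiment is
    reproducible.
    """
    preset = get_preset(preset_key)
    temps = np.arange(t_min, t_max + step / 2, step, dtype=float)
    if temps.size < 3:
        raise ValueError("temperature grid must contain at least 3 points")
    spectra = []
    sample_id = f"{preset.lipid}-{preset.assembly}"
    for rep in range(1, n_replicates + 1):
        for scan in range(1, n_scans + 1):
            for ti, T in enumerate(temps):
                sub = np.random.SeedSequence([int(seed), rep, scan, ti])
                spectra.append(
                    render_spectrum(
                        T,
                        preset.model,
                        preset.bands,
                        noise_sd_frac=noise_sd_frac,
                        seed=sub,
                        sample_id=sample_id,
                        lipid=preset.lipid,
                        assembly=preset.assembly,
                        replicate=rep,
                        scan=scan,
                    )
                )
    return spectra


def simulate_experiment(
    preset_key: str,
    t_min: float,
    t_max: float,
    step: float = 1.0,
    n_replicates: int = 3,
    n_scans: int = 3,
    noise_sd_frac: float = 0.01,
    seed: int = 0,
    out_path="spectra.csv",
):
    """Simulate a melting experiment and write it as a long-form CSV file.

    Identical arguments (including the seed) produce a byte-identical file.
    Returns the output path.
    """
    spectra = simulate_spectra(
        preset_key, t_min, t_max, step, n_replicates, n_scans,
        noise_sd_frac, seed,
    )
    write_spectra(spectra, out_path)
    return out_path
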