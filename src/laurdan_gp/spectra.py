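"""Emission-spectrum containers and text-format I/O.

The pipeline's native spectra format is a long-form CSV (one row per
wavelength) with the header::

    sample_id,lipid,assembly,replicate,scan,temperature_C,wavelength_nm,intensity

Lines starting with ``#`` are ignored. Intensities are arbitrary fluorescence
units; wavelengths are nm on the acquisition grid (nominally 400-540 nm in
1 nm steps); temperatures are degrees Celsius, compared at 2 decimal places
(Peltier resolution). Downstream tables are a TSV of GP versus temperature
and a JSON melting summary; both round-trip numerically at 6 significant
digits.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    GridMismatchError,
    SpectrumValidationError,
)

ASSEMBLIES = ("LUV", "spMSP1D1", "spNW15", "spNW25", "spNW50", "other")

LONG_CSV_COLUMNS = (
    "sample_id",
    "lipid",
    "assembly",
    "replicate",
    "scan",
    "temperature_C",
    "wavelength_nm",
    "intensity",
)

GP_TABLE_COLUMNS = (
    "sample_id",
    "lipid",
    "assembly",
    "temperature_C",
    "gp_mean",
    "gp_sd",
    "n_replicates",
)

#: temperatures are grouped/compared after rounding to this many decimals
TEMPERATURE_DECIMALS = 2

ScanLabel = Union[int, str]  # positive integer or the literal "averaged"


def _round_temp(t: float) -> float:
    return round(float(t), TEMPERATURE_DECIMALS)


@dataclass(frozen=True)
class EmissionSpectrum:
    """One wavelength-resolved intensity trace at a single temperature.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths, length >= 2.
    intensities
        Non-negative finite intensities, same length as the grid.
    temperature_C
        Sample temperature in degrees Celsius.
    sample_id, lipid, assembly
        Free-text sample label, lipid name (e.g. ``DPPC``) and assembly
        type (``LUV``, ``spMSP1D1``, ``spNW15``, ``spNW25``, ``spNW50`` or
        ``other``).
    replicate
        1-based independent-preparation index.
    scan
        1-based scan index, or the string ``"averaged"`` after scan
        averaging.
    """

    wavelengths_nm: np.ndarray
    intensities: np.ndarray
    temperature_C: float
    sample_id: str
    lipid: str
    assembly: str
    replicate: int
    scan: ScanLabel = 1

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "intensities", it)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise SpectrumValidationError(
                "wavelengths and intensities must be 1-D arrays of equal length"
            )
        if wl.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumValidationError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)) or np.any(it < 0):
            raise SpectrumValidationError(
                "intensities must be finite and non-negative"
            )
        if self.assembly not in ASSEMBLIES:
            raise SpectrumValidationError(
                f"unknown assembly {self.assembly!r}; expected one of {ASSEMBLIES}"
            )
        if not (isinstance(self.replicate, (int, np.integer)) and self.replicate >= 1):
            raise SpectrumValidationError("replicate must be a positive integer")
        if self.scan != "averaged" and not (
            isinstance(self.scan, (int, np.integer)) and self.scan >= 1
        ):
            raise SpectrumValidationError(
                'scan must be a positive integer or "averaged"'
            )

    def same_grid(self, other: "EmissionSpectrum") -> bool:
        return self.wavelengths_nm.size == other.wavelengths_nm.size and bool(
            np.allclose(self.wavelengths_nm, other.wavelengths_nm, rtol=0, atol=1e-9)
        )


@dataclass(frozen=True)
class SpectrumSeries:
    """Scan-averaged spectra of one (sample, replicate) over a temperature ramp.

    Spectra are sorted by temperature on construction; duplicate temperatures
    (at 0.01 degC resolution) within one series are an error.
    """

    spectra: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        spectra = tuple(
            sorted(self.spectra, key=lambda s: s.temperature_C)
        )
        object.__setattr__(self, "spectra", spectra)
        if not spectra:
            raise SpectrumValidationError("a series needs at least one spectrum")
        first = spectra[0]
        for s in spectra[1:]:
            if (
                s.sample_id != first.sample_id
                or s.lipid != first.lipid
                or s.assembly != first.assembly
                or s.replicate != first.replicate
            ):
                raise SpectrumValidationError(
                    "all spectra in a series must share sample_id/lipid/"
                    "assembly/replicate"
                )
        temps = [_round_temp(s.temperature_C) for s in spectra]
        if len(set(temps)) != len(temps):
            raise SpectrumValidationError(
                f"duplicate temperatures in series {first.sample_id!r}: {temps}"
            )

    @property
    def temperatures_C(self) -> np.ndarray:
        return np.array([s.temperature_C for s in self.spectra], dtype=float)

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)


def read_spectra(path, format: str = "long_csv") -> list[EmissionSpectrum]:
    """Read a long-form CSV spectra file into a list of spectra.

    One :class:`EmissionSpectrum` is produced per
    (sample_id, lipid, assembly, replicate, scan, temperature) group, with
    wavelengths sorted ascending. Duplicate (group, wavelength) rows, missing
    columns, non-numeric fields and negative intensities are errors.
    """
    if format != "long_csv":
        raise FormatError(f"unsupported spectra format {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    missing = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        return []

    def numeric(col: str) -> pd.Series:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based indexing
            line = int(df.index[bad][0]) + 2
            raise FormatError(
                f"{path}: non-numeric value in column {col!r} near line {line}"
            )
        if vals.isna().any():
            line = int(df.index[vals.isna()][0]) + 2
            raise FormatError(f"{path}: empty value in column {col!r} near line {line}")
        return vals

    df = df.assign(
        replicate=numeric("replicate").astype(int),
        temperature_C=numeric("temperature_C"),
        wavelength_nm=numeric("wavelength_nm"),
        intensity=numeric("intensity"),
    )
    if (df["intensity"] < 0).any():
        line = int(df.index[df["intensity"] < 0][0]) + 2
        raise SpectrumValidationError(
            f"{path}: negative intensity near line {line}"
        )

    def parse_scan(v: str) -> ScanLabel:
        v = str(v).strip()
        if v == "averaged":
            return "averaged"
        try:
            return int(v)
        except ValueError as exc:
            raise FormatError(
                f"{path}: scan must be an integer or 'averaged', got {v!r}"
            ) from exc

    df["scan"] = df["scan"].map(parse_scan)
    df["_tkey"] = df["temperature_C"].round(TEMPERATURE_DECIMALS)

    group_cols = ["sample_id", "lipid", "assembly", "replicate", "scan", "_tkey"]
    spectra: list[EmissionSpectrum] = []
    for key, grp in df.groupby(group_cols, sort=True):
        sample_id, lipid, assembly, replicate, scan, _ = key
        grp = grp.sort_values("wavelength_nm")
        wl = grp["wavelength_nm"].to_numpy()
        if np.any(np.diff(wl) == 0):
            raise FormatError(
                f"{path}: duplicated wavelength within group "
                f"(sample={sample_id!r}, replicate={replicate}, scan={scan!r}, "
                f"T={key[-1]})"
            )
        spectra.append(
            EmissionSpectrum(
                wavelengths_nm=wl,
                intensities=grp["intensity"].to_numpy(),
                temperature_C=float(grp["temperature_C"].iloc[0]),
                sample_id=str(sample_id),
                lipid=str(lipid),
                assembly=str(assembly),
                replicate=int(replicate),
                scan=scan,
            )
        )
    return spectra


def write_spectra(spectra: Iterable[EmissionSpectrum], path) -> None:
    """Write spectra to the long-form CSV dialect (deterministic formatting)."""
    path = Path(path)
    lines = [",".join(LONG_CSV_COLUMNS)]
    for s in spectra:
        for wl, it in zip(s.wavelengths_nm, s.intensities):
            lines.append(
                f"{s.sample_id},{s.lipid},{s.assembly},{s.replicate},{s.scan},"
                f"{s.temperature_C:.2f},{wl:g},{it:.6f}"
            )
    path.write_text("\n".join(lines) + "\n")


def average_scans(spectra: Sequence[EmissionSpectrum]) -> EmissionSpectrum:
    """Pointwise arithmetic mean of repeat scans of one spectrum.

    All inputs must share the sample, replicate, temperature and exactly the
    same wavelength grid (no interpolation). The result carries
    ``scan="averaged"``; averaging a single spectrum only relabels it, so the
    operation is idempotent and permutation-invariant.
    """
    spectra = list(spectra)
    if not spectra:
        raise SpectrumValidationError("average_scans needs at least one spectrum")
    first = spectra[0]
    for s in spectra[1:]:
        if not first.same_grid(s):
            raise GridMismatchError(
                f"scan wavelength grids differ for sample {first.sample_id!r}"
            )
        if _round_temp(s.temperature_C) != _round_temp(first.temperature_C):
            raise SpectrumValidationError(
                "cannot average scans taken at different temperatures "
                f"({first.temperature_C} vs {s.temperature_C})"
            )
        if (
            s.sample_id != first.sample_id
            or s.replicate != first.replicate
        ):
            raise SpectrumValidationError(
                "cannot average scans from different samples/replicates"
            )
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return replace(first, intensities=mean, scan="averaged")


# ---------------------------------------------------------------------------
# downstream tables

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return f"{float(x):.6g}"


def write_gp_table(curves, path) -> None:
    """Write GP-versus-temperature curves as a TSV (one row per temperature).

    ``gp_sd`` is emitted as ``NA`` where a point has a single replicate.
    Values are written at 6 significant digits and round-trip through
    :func:`read_gp_table` to 1e-6 relative tolerance.
    """
    curves = list(curves)
    if not curves:
        raise SpectrumValidationError("write_gp_table: empty curve list")
    path = Path(path)
    lines = ["\t".join(GP_TABLE_COLUMNS)]
    for c in curves:
        for i, t in enumerate(c.temperatures_C):
            lines.append(
                "\t".join(
                    [
                        c.sample_id,
                        c.lipid,
                        c.assembly,
                        f"{t:.2f}",
                        _fmt(c.gp_mean[i]),
                        _fmt(c.gp_sd[i]),
                        str(int(c.n_replicates[i])),
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def read_gp_table(path) -> list:
    """Read a GP table TSV back into :class:`~laurdan_gp.gp.GPCurve` objects."""
    from .gp import GPCurve  # local import to avoid a cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    missing = [c for c in GP_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    curves = []
    for (sample_id, lipid, assembly), grp in df.groupby(
        ["sample_id", "lipid", "assembly"], sort=True
    ):
        grp = grp.sort_values("temperature_C")
        curves.append(
            GPCurve(
                sample_id=str(sample_id),
                lipid=str(lipid),
                assembly=str(assembly),
                temperatures_C=grp["temperature_C"].to_numpy(float),
                gp_mean=grp["gp_mean"].to_numpy(float),
                gp_sd=grp["gp_sd"].to_numpy(float),
                n_replicates=grp["n_replicates"].to_numpy(int),
            )
        )
    return curves


def write_melting_summaries(summaries, path) -> None:
    """Write melting summaries as a JSON object keyed by sample_id.

    Unreported quantities (undetected transition, truncated peak, no
    reference) are JSON ``null``. Output is byte-deterministic for identical
    inputs (sorted keys, fixed float rounding at 6 significant digits).
    """
    summaries = list(summaries)
    if not summaries:
        raise SpectrumValidationError("write_melting_summaries: empty summary list")

    def jnum(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return None
        return float(f"{float(x):.6g}")

    obj = {}
    for s in summaries:
        obj[s.sample_id] = {
            "lipid": s.lipid,
            "assembly": s.assembly,
            "tm_C": jnum(s.tm_C),
            "fwhm_C": jnum(s.fwhm_C),
            "auc_gp": jnum(s.auc_gp),
            "gp_low": jnum(s.gp_low),
            "gp_high": jnum(s.gp_high),
            "transition_detected": bool(s.transition_detected),
            "delta_tm_C": jnum(s.delta_tm_C),
            "reference_id": s.reference_id,
        }
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def group_and_average(spectra: Iterable[EmissionSpectrum]) -> list[SpectrumSeries]:
    """Scan-average raw spectra and assemble per-(sample, replicate) series.

    This is the standard entry into the pipeline: scans are averaged per
    (sample, replicate, temperature) before any GP is computed.
    """
    by_scan_group: dict = {}
    for s in spectra:
        key = (s.sample_id, s.lipid, s.assembly, s.replicate,
               _round_temp(s.temperature_C))
        by_scan_group.setdefault(key, []).append(s)
    by_series: dict = {}
    for key, scans in sorted(by_scan_group.items()):
        avg = average_scans(scans)
        skey = key[:4]
        by_series.setdefault(skey, []).append(avg)
    return [SpectrumSeries(spectra=tuple(v)) for _, v in sorted(by_series.items())]
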