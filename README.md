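# laurdan-gp

Thermotropic analysis of lipid bilayer order from Laurdan fluorescence, for
membrane biophysicists comparing nanodisc-reconstituted bilayers against
large unilamellar vesicles (LUVs).

Laurdan is a solvatochromic membrane dye: its emission peaks near 440 nm
when lipids are tightly packed (gel/ordered phase) and red-shifts to
~490 nm as water penetrates a disordered (fluid) bilayer. The generalized
polarization

```
GP = (I440 − I490) / (I440 + I490)
```

therefore reports lipid packing, and a temperature ramp of GP traces the
gel→fluid melting transition. This package implements the full analysis
chain:

- **spectra I/O** — long-form CSV emission spectra (400–540 nm, 1 nm
  steps), scan averaging (3 scans per spectrum), replicate bookkeeping;
- **GP curves** — exact-channel GP per spectrum, replicate mean ± SD
  (n−1) per temperature;
- **melting analysis** — central finite difference −dGP/dT; the peak
  location is the main transition temperature T_M, the peak's full width at
  half maximum is an (inverse) cooperativity measure, and the area under
  the peak is an enthalpy proxy in GP units (≈ the total GP drop); ΔT_M
  against a reference sample (e.g. a nanodisc versus its LUV);
- **synthetic generator** — two-state (van't Hoff-style) melting with
  Gaussian 440/490 nm emission bands, scan/replicate structure, seeded
  detector noise, and presets for DMPC/DPPC/DSPC/POPC in LUVs and 11–50 nm
  circularized nanodiscs (vesicle midpoints 24/41/54/−2 °C; the 11 nm disc
  shifted +5/+2/0 °C for DMPC/DPPC/DSPC, transitions broadening as discs
  shrink);
- **boundary-lipid geometry** — rim-annulus unperturbed fraction
  f = ((d/2 − w)/(d/2))², boundary-width calibration w = (d/2)(1 − √f),
  two-population and continuum (exponential-profile) disc-averaged GP.

## Worked example

Simulate a noise-free DPPC vesicle melt and analyze it:

```
laurdan-gp simulate --preset DPPC:LUV --tmin 31 --tmax 51 --noise 0 \
    --seed 7 --out dppc.csv
laurdan-gp run --in dppc.csv --out-gp gp.tsv --out-summary melt.json
```

`melt.json` then contains

```json
"DPPC-LUV": {
  "tm_C": 41.0,
  "fwhm_C": 2.33093,
  "auc_gp": 1.91731,
  "gp_high": 0.958653,
  "gp_low": -0.958653,
  "transition_detected": true
}
```

i.e. the derivative peak sits at the generator's 41 °C midpoint; the
2.3 °C width reflects the sharp vesicle transition sampled at 1 °C (broad
nanodisc presets give 8–9 °C); and the area equals the GP drop across the
ramp. The same pipeline is available as a library
(`laurdan_gp.run_pipeline`), and `laurdan-gp boundary --diameter 11
--calibrate --fraction 0.77` prints the rim-annulus width (0.674 nm)
implied by a 77% unperturbed-lipid fraction.

The study itself lives in `analysis/`: `01_simulate_spectra.py` generates
every preset on a shared per-lipid ramp at 1% noise, `02_melting_curves.py`
writes GP tables, melting summaries and the ΔT_M table to `results/`, and
`03_boundary_geometry.py` writes the calibrated boundary widths and
continuum-model comparison. At 1 °C resolution with realistic noise the
broad (11–15 nm disc) transitions carry a ±1 °C wobble in their grid T_M;
vesicle transitions are exact.

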