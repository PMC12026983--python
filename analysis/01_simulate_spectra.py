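#!/usr/bin/env python
"""Simulate the full melting study: every lipid/assembly preset on one
shared temperature ramp per lipid.

Each lipid gets a single 1 degC ramp wide enough to cover the vesicle and
all disc transitions (mirroring how a real study ramps every assembly of a
lipid over the same range), with 3 scans x 3 replicates and 1% detector
noise. Spectra land under scratch/spectra/ (large, regenerated on demand);
downstream scripts read them from there.
"""

from pathlib import Path

import laurdan_gp as lg

SEED = 2026
NOISE = 0.01
# per-lipid shared ramps covering every preset transition +/- >= 10 degC
RAMPS = {"DMPC": (9, 45), "DPPC": (26, 59), "DSPC": (40, 70), "POPC": (-12, 8)}

OUT = Path(__file__).resolve().parents[1] / "scratch" / "spectra"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, key in enumerate(sorted(lg.PRESETS)):
        preset = lg.get_preset(key)
        lo, hi = RAMPS[preset.lipid]
        path = OUT / f"{preset.lipid}_{preset.assembly}.csv"
        lg.simulate_experiment(
            key, lo, hi, step=1.0, n_replicates=3, n_scans=3,
            noise_sd_frac=NOISE, seed=SEED + i, out_path=path,
        )
        print(f"{key:16s} tm={preset.model.tm_C:6.1f} degC  "
              f"k={preset.model.k_C:.1f} degC  -> {path.name}")
    print(f"\nwrote {len(lg.PRESETS)} synthetic experiments to {OUT}")


if __name__ == "__main__":
    main()
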