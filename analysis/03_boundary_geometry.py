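#!/usr/bin/env python
"""Boundary-lipid geometry of the four disc scaffolds.

Two questions:

1. What boundary width does each scaffold's reported unperturbed lipid
   fraction (77/83/90/95% for 11/15/25/50 nm) imply under the rim-annulus
   formula f = ((d/2 - w)/(d/2))^2 -- and is that width constant across
   sizes, as the fixed-boundary picture requires? (It is, at ~0.65 nm; the
   often-quoted ~1.5 nm annulus would instead give 53/62/77/88%.)

2. How does a continuum rim-perturbation profile (exponential decay of the
   perturbation with distance from the rim) change the disc-averaged GP
   relative to the sharp two-population annulus?

Writes results/boundary_widths.tsv and results/continuum_gp.tsv.
"""

from pathlib import Path

import laurdan_gp as lg

RESULTS = Path(__file__).resolve().parents[1] / "results"
OBSERVED = {"spMSP1D1": 0.77, "spNW15": 0.83, "spNW25": 0.90, "spNW50": 0.95}
GP_BULK, GP_RIM = 0.45, 0.05  # ordered core vs. rim-perturbed GP


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    rows = ["scaffold\tdiameter_nm\tf_observed\tw_calibrated_nm\tf_at_1p5nm"]
    widths = []
    print("scaffold   d/nm  f_obs  w_cal/nm  f(w=1.5nm)")
    for scaffold, f_obs in OBSERVED.items():
        d = lg.SCAFFOLD_DIAMETERS_NM[scaffold]
        w = lg.calibrate_boundary_width(d, f_obs)
        f15 = lg.unperturbed_fraction(d, 1.5)
        widths.append(w)
        print(f"{scaffold:10s} {d:4.0f}  {f_obs:.2f}   {w:.3f}     {f15:.3f}")
        rows.append(f"{scaffold}\t{d:g}\t{f_obs:.2f}\t{w:.4f}\t{f15:.4f}")
    spread = (max(widths) - min(widths)) / (sum(widths) / len(widths))
    print(f"\ncalibrated widths: {min(widths):.3f}-{max(widths):.3f} nm "
          f"(spread {100 * spread:.1f}% of mean) -> consistent with a fixed "
          "boundary annulus of ~0.65 nm under the area formula")
    (RESULTS / "boundary_widths.tsv").write_text("\n".join(rows) + "\n")

    rows = ["scaffold\tdiameter_nm\tgp_two_population\tgp_continuum"]
    print("\ndisc-averaged GP, two-population (w=0.65 nm) vs continuum "
          f"(lambda=0.65 nm), bulk GP {GP_BULK}, rim GP {GP_RIM}:")
    for scaffold, d in lg.SCAFFOLD_DIAMETERS_NM.items():
        f = lg.unperturbed_fraction(d, 0.65)
        two_pop = f * GP_BULK + (1 - f) * GP_RIM
        cont = lg.continuum_gp(d, 0.65, GP_BULK, GP_RIM)
        print(f"  {scaffold:10s} d={d:4.0f} nm  two-pop {two_pop:.4f}  "
              f"continuum {cont:.4f}")
        rows.append(f"{scaffold}\t{d:g}\t{two_pop:.5f}\t{cont:.5f}")
    (RESULTS / "continuum_gp.tsv").write_text("\n".join(rows) + "\n")
    print(f"\nwrote {RESULTS / 'boundary_widths.tsv'} and "
          f"{RESULTS / 'continuum_gp.tsv'}")


if __name__ == "__main__":
    main()
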