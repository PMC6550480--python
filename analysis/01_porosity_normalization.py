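"""Porosity normalization of the effective diffusivity.

Solves steady-state diffusion through the open model film (straight 1 nm
pores, square lattice at 28% areal coverage) and shows that the film-region
De/D_bulk equals the rasterized open pore fraction, i.e. the effective
diffusivity of a straight-channel film is its porosity.

Writes results/porosity_normalization.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from aqpflux.geometry import (FilmGeometry, areal_pore_fraction,
                              discrete_pore_fraction, voxelize)
from aqpflux.solver import effective_diffusivity, solve_steady_state

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for coverage in (0.1, 0.2, 0.28, 0.4):
        geom = FilmGeometry.from_coverage(coverage, n_pores_y=1,
                                          n_pores_z=1, reservoir_depth=1.0)
        dom = voxelize(geom, None, voxel_size=0.1)
        fld = solve_steady_state(dom, tol=1e-10)
        eff = effective_diffusivity(fld, dom)
        rows.append({
            "target_coverage": coverage,
            "areal_pore_fraction": areal_pore_fraction(geom),
            "discrete_pore_fraction": discrete_pore_fraction(dom),
            "de_ratio": eff.ratio,
            "residual": fld.residual,
        })
        print(f"coverage {coverage:.2f}: De/D = {eff.ratio:.5f}, "
              f"rasterized porosity = {discrete_pore_fraction(dom):.5f}")
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "porosity_normalization.csv", index=False,
              float_format="%.10g")
    worst = (df.de_ratio - df.discrete_pore_fraction).abs().max()
    print(f"\nDe/D matches the rasterized porosity to {worst:.2e} "
          f"across all coverages: for straight aligned channels the "
          f"effective diffusivity IS the open areal fraction.")


if __name__ == "__main__":
    sys.exit(main())
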