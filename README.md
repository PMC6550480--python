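# aqpflux

Continuum diffusion modelling of aquaporin-functionalized nanofiltration
membranes.

Biomimetic membranes decorate a nanoporous polymer film with aquaporin
water channels.  Because aquaporins pass water but not ions, the protein
layer acts as a set of impermeable caps over the film's solute-conducting
nanopores — and the measured *solute* flux becomes an indirect probe of how
much of the surface the protein actually covers.  `aqpflux` implements that
inference chain for membrane scientists:

* **geometry** — parametric reservoir–film–reservoir supercells with
  straight cylindrical pores (default: 1 nm pores on a square lattice
  tuned to 28% areal coverage), occluded by per-pore caps, a growing
  aggregate disk, or fixed-size monomer patches; voxelized into a
  diffusivity field.
* **solver** — conservative finite-volume discretization of steady-state
  Fickian diffusion, ∇·(D∇c) = 0, with Dirichlet reservoir concentrations
  c(L) = 1, c(R) = 0 and harmonic face averaging (solids are exactly
  impermeable).  The mean flux through the film,
  ⟨j⟩ = (1/A) Σ D ∂c/∂x ΔS, yields the effective diffusivity
  De = ⟨j⟩ · Δx / Δc, normalized by D_bulk = 1.  For straight aligned
  channels, De/D_bulk equals the open areal fraction SA_pore/SA_total.
* **packing** — sweeps occlusion density to build the monotone De(f)
  curve for aggregate and monomer occlusion models, and inverts a measured
  flux (or De) ratio into a capping/packing fraction with a bracketing
  interval.
* **characterization** — solute rejection R = (1 − C_p/C_f)·100%, the
  90%-rejection molecular-weight-cut-off rule, and the tabulated
  Stokes–Einstein radii of the standard PEG/sucrose series.
* **synthetic** — a generator for flux and rejection tables with the
  statistical structure of bench measurements, so the entire pipeline is
  testable with no external data, including full parameter-recovery
  experiments.

## Worked example

```python
from aqpflux import (FilmGeometry, PackingFraction, realize_packing,
                     voxelize, solve_steady_state, plane_flux,
                     mid_film_face, effective_diffusivity,
                     sweep_capping, estimate_packing)

geom = FilmGeometry.from_coverage(0.28)        # 1 nm pores, 5x5 supercell
dom = voxelize(geom, None, voxel_size=0.25)
field = solve_steady_state(dom)
print(effective_diffusivity(field, dom).ratio)  # 0.26531 (= rasterized porosity)

occ = realize_packing(geom, PackingFraction(0.64), seed=1)   # cap 16/25 pores
dom64 = voxelize(geom, occ, voxel_size=0.25)
j0 = plane_flux(field, dom, mid_film_face(dom))
j64 = plane_flux(solve_steady_state(dom64), dom64, mid_film_face(dom64))
print(100 * (1 - j64 / j0))                     # 63.65  (% flux reduction)

curve = sweep_capping(geom, [0, .1, .2, .3, .4, .5, .6, .64, .7, .8, .9, 1],
                      seed=1)
est = estimate_packing(curve, 0.36, kind="flux_ratio")
print(est.estimate.value, est.bracket)          # 0.643 (0.64, 0.72)
```

The first number says the open film transports like a homogeneous slab of
26.5% bulk diffusivity — its porosity as rasterized on the grid (28.03% at
0.1 nm resolution).  Capping 64% of the pores removes 63.65% of the flux:
flux reduction maps one-to-one onto the fraction of pores occluded, so the
observed 64% flux difference between membrane variants inverts to a capping
fraction of 0.64.

The same steps are available from the shell:

```bash
aqpflux pipeline --config examples/study.yaml --out results/study_run
```

which writes synthetic tables, the De(f) curve, the packing estimate and
the MWCO determination (plus a machine-readable manifest) into the output
directory.  The numbered scripts under `analysis/` run the individual
analyses (porosity normalization, capping law, packing curves, parameter
recovery, MWCO) and write their tables under `results/`.

## Layout

```
src/aqpflux/     library (geometry, solver, packing, characterization,
                 synthetic, io, cli)
analysis/        numbered narrative drivers writing results/
tests/           pytest suite (unit, property-based, acceptance)
scripts/         acceptance script
docs/methods.md  model assumptions, numerics, limitations
examples/        YAML run configurations
```
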