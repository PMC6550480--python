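# Methods

## Model

The membrane is idealized as a slab of impermeable polymer pierced by
straight cylindrical nanopores, bounded by two well-mixed reservoirs.
Solute transport is steady-state Fickian diffusion, ∇·(D∇c) = 0, with
Dirichlet concentrations on the outer reservoir faces (c = 1 on the feed
side, c = 0 on the permeate side) and no-flux lateral boundaries, which
are equivalent to periodic boundaries for the symmetric unit supercell.
All quantities are nondimensional: lengths in nm, D_bulk = 1, Δc = 1.
Aquaporins are impermeable obstructions placed flush on the feed-side
film face — the model deliberately ignores protein microstructure
(a cylinder/patch silhouette is all that matters for occlusion),
electrostatics (screened at the experimental ionic strengths), advection,
and transient dynamics.

The film's effective diffusivity is defined through the homogeneous-slab
equivalence ⟨j⟩ = De·Δc/Δx.  For a film of straight aligned channels this
gives De/D_bulk = open areal fraction exactly, which is the physical
anchor for the whole inference: a measured flux ratio between an
aquaporin-modified membrane and its unmodified reference is a direct
estimate of the fraction of pore area left open.

## Geometry and defaults

| parameter | default | meaning |
|---|---|---|
| pore_diameter | 1.0 nm | from the nanofiltration cutoff scale |
| lattice_spacing | 1.6748 nm | square lattice tuned to 28% areal pore coverage |
| film_thickness | 10 nm | test-scale slab; a ~50 nm selective layer is available by config |
| reservoir_depth | 1.0 nm | thin, because the bench cell is continuously stirred (see below) |
| n_pores_y × n_pores_z | 5 × 5 | supercell used for capping analyses (25 pores) |
| voxel_size | 0.25 nm | requested resolution; must be ≤ pore_diameter/4 |
| occlusion_thickness | one voxel layer | any impermeable thickness blocks a capped column identically in steady state |

The pore lattice is square — the simplest arrangement reproducing a stated
areal coverage; the lattice type, supercell extent, reservoir depth and
protein height are modelling choices, not measured quantities.

Voxelization snaps the grid to the geometry rather than the reverse: the
lateral spacing is the lattice spacing divided by a whole number of voxels
per cell (so every pore rasterizes identically — capping k of n pores then
removes exactly k/n of the open columns), and reservoir depths are snapped
to whole layers of the film's x spacing so both film faces lie on voxel
faces.  Membership is decided by the voxel-center test, with a center
exactly on a cylinder surface counting as open.  `discrete_pore_fraction`
audits the rasterization; at 0.1 nm voxels the 28% target is realized as
28.03%.

**Reservoir depth.**  The reservoirs exist to carry the Dirichlet planes.
They are kept thin (1 nm) because deep reservoirs let neighbouring pore
columns exchange flux laterally, which breaks the column decomposition
that makes flux reduction commensurate with capping: with 5 nm reservoirs
on the 10 nm film, capping 64% of pores reduces flux by only 59.7%
instead of 63.7%.  Physically, the dead-end filtration cell is
continuously stirred, so the bulk concentration is maintained close to
the membrane face; the thin-reservoir limit is the appropriate idealization
of that condition.

## Solver numerics

Finite-volume 7-point discretization on the voxel grid; face
transmissibilities use the harmonic mean of the adjacent voxel
diffusivities, so any face touching a solid voxel is exactly impermeable
and discrete flux is conserved cell-by-cell.  Dirichlet values enter
through half-cell transmissibilities on the two end faces.  The SPD system
is solved by conjugate gradients with diagonal preconditioning, relative
tolerance 1e-10, initialized at the linear interpolant of the boundary
values (fully deterministic).  Open regions with no path to either
Dirichlet face are physically indeterminate; they are excluded from the
solve and assigned the mean boundary value.  Non-convergence raises an
error carrying the residual history.

De extraction uses the film-only convention by default: mean flux on the
voxel face nearest mid-film, concentration drop between the open-voxel
means of the first and last film layers.  For straight channels this is
exact (De/D equals the rasterized porosity to solver tolerance) because
it excludes the reservoir access resistance.  The literal whole-domain
convention (Dirichlet values, full separation) is available via
`separation="domain"` and differs by that access resistance.  Within a
packing sweep, De(f) is anchored at the film-only De(0) and scaled by the
mean-flux ratio j(f)/j(0) — flux ratio and De ratio are identical under
fixed Δc and geometry, and this removes a bookkeeping artifact of the
face-mean when capped pores change the set of open face voxels.

Validation oracles: a uniform domain reproduces the linear profile and
Fick's law to 1e-8; homogenized layered stacks (per-layer effective
diffusivity φ·D, the laterally well-mixed continuum limit of aligned
channel layers) reproduce the harmonic series composite L/Σ(L_i/φ_i) to
<0.5% at default resolution, which discriminates harmonic from arithmetic
face averaging.  Explicit discrete channel stacks approach that composite
from below as the channel pitch shrinks — finite lateral mixing is real
physics, so the closed form is only asserted in its regime of validity.
Property tests cover the maximum principle, interior-plane flux
conservation, linearity in Δc, mirror symmetry, and <1% De drift under
voxel halving.

## Packing curves and inversion

Two occlusion models are swept over packing fraction f (fraction of
pore-opening area occluded — the quantity that directly scales flux;
fraction of film-surface coverage is carried as an alternative tagged
definition):

* **aggregate** — either k of n whole pores capped (`pore_cap`), or a
  single disk of growing radius centred on the supercell
  (`aggregate_disk`).  Disk radii are quantized to *ring-complete*
  coverages ({0, 0.04, 0.2, 0.36, 0.52, 0.84, 1} on the 5×5 lattice):
  a thin impermeable disk whose rim only partially covers a pore leaves a
  conducting orifice whose resistance is far below the area-proportional
  value (measured: De up to ~80% above the area law at intermediate f,
  persisting at 4 nm occlusion thickness), so intermediate radii do not
  realize their nominal packing cleanly.
* **monomer** — a fixed 0.4 nm × 0.4 nm protein patch centred in every
  pore; the per-pore flux is scaled proportionally to the remaining open
  area, De(f) = (1 − f)·De(0), anchored at the simulated uncapped De.
  The simulated patch configuration itself is solved once and kept with
  the curve as a consistency record.

At matched f the two models agree within ~5% — diffusion data alone
cannot discriminate dispersed monomers from aggregates, and the package
reports both without asserting either.  Inversion is piecewise-linear on
the monotone curve, returning the bracketing sweep interval; flat segments
resolve to their lowest-f bracket.  Measured input may be a De ratio or a
flux ratio (tagged explicitly; the latter is rescaled by De(0)).

## Synthetic data generator

The generator emulates the *shapes* of the bench data, not their absolute
values: four membrane variants (two open references, two aquaporin-capped)
with mean flux (1 − f_true)·reference for capped variants and
multiplicative Gaussian noise (default 5% relative — measurement error in
dead-end filtration scales with signal; the study reports ± spreads but no
error model); and per-solute rejection sigmoidal in Stokes radius
(midpoint 0.6 nm, width 0.03 nm, additive noise 2.5 percentage points,
matching typical reported spreads of 1–4 points) clamped to [0, 100].
Everything is a pure function of the spec including the seed.

What passing recovery tests show: the *inference chain* is unbiased and
tight (MAE ≈ 0.006 at the study noise level, well under 0.05) when the
data actually follow the capping model.  What they do not show: anything
about fouling, concentration polarization, charge effects, or partial
protein permeability in real membranes — none of which the generator
models.

## Characterization rules

Rejection R = (1 − C_p/C_f)·100%; negative computed rejections (permeate
above feed, possible with noise) clamp to 0 with a logged warning.  The
MWCO is the smallest tested molecular weight with R ≥ threshold (90% by
default; the comparison is inclusive, matching how borderline values like
91.3% are classified in practice).  If every tested solute passes, the
result is flagged "at or below the lightest tested solute"; if none does,
an explicit no-MWCO result is returned.  Stokes radii are exact lookups
for the tabulated PEG/sucrose series and log-log interpolations otherwise,
flagged by a warning; extrapolation beyond the table requires an explicit
override.

## Problem sizes

Default analyses run on the 5×5-pore supercell at 0.25 nm voxels
(~23k unknowns per solve, sub-second) and the unit supercell at 0.1 nm
voxels for porosity checks (~14k unknowns); a 12-point sweep takes a few
seconds.  These sizes preserve all the geometry ratios of the study film;
thickness 50 nm and finer grids are available by configuration and change
De by <1% (grid-convergence tests).

## Known limitations

* Straight, aligned, monodisperse pores; real phase-inversion films are
  tortuous and polydisperse, so the porosity–De identity is an idealization.
* The two packing-density definitions (pore capping vs surface coverage)
  are both reported but cannot be reconciled without an independent
  measurement of protein footprint per pore.
* Thin-rim aggregate configurations (partially covered pores) fall outside
  the area-proportional regime and are excluded from the packing curve by
  ring quantization.
* Charged-solute transport (Poisson–Nernst–Planck) and water flux are out
  of scope; the model addresses solute diffusion only.
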