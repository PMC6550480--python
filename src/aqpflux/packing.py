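"""Occlusion-density sweeps and inversion of flux data into packing fractions.

The De(f) curve relates the effective-to-bulk diffusivity ratio of the film
to the fraction f of pore-opening area occluded by aquaporins.  Two
occlusion models are swept: an *aggregate* model (impermeable caps or a
growing central disk) solved by full simulation, and a *monomer* model in
which a fixed-size protein patch sits in every pore and the per-pore flux
is scaled proportionally to the remaining open area.  A measured flux (or
De) ratio is inverted on the monotone curve by piecewise-linear
interpolation, with a bracketing interval from adjacent sweep points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (FilmGeometry, OcclusionMode, OcclusionSpec,
                       PackingDefinition, PackingFraction, GeometryError,
                       realize_packing, realized_pore_occlusion, voxelize)
from .solver import (BoundaryConditions, SolverError, effective_diffusivity,
                     solve_steady_state)

__all__ = [
    "PackingCurve",
    "PackingEstimate",
    "sweep_capping",
    "monomer_curve",
    "estimate_packing",
    "flux_reduction_to_capping",
]

_MONOTONE_TOL = 1e-6


@dataclass(frozen=True)
class PackingCurve:
    """Ordered (f, De/D_bulk) sweep for one occlusion model."""

    model: str                       # "aggregate" | "monomer"
    fractions: tuple[float, ...]
    de_ratios: tuple[float, ...]
    definition: PackingDefinition
    geometry_hash: str
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        d = np.asarray(self.de_ratios, dtype=float)
        if f.size != d.size or f.size < 2:
            raise ValueError("curve needs matching f / De arrays, >= 2 points")
        if np.any(np.diff(f) <= 0):
            raise ValueError("fractions must be strictly ascending")
        if abs(f[0]) > 1e-12 or abs(f[-1] - 1.0) > 1e-12:
            raise ValueError("curve must include the endpoints f=0 and f=1")
        if np.any(np.diff(d) > _MONOTONE_TOL):
            raise ValueError("De ratio must be non-increasing in f")

    @property
    def de_at_zero(self) -> float:
        return self.de_ratios[0]


@dataclass(frozen=True)
class PackingEstimate:
    estimate: PackingFraction
    measured_ratio: float
    bracket: tuple[float, float]
    model: str

    def __post_init__(self) -> None:
        lo, hi = self.bracket
        if not lo - 1e-12 <= self.estimate.value <= hi + 1e-12:
            raise ValueError("estimate must lie within its bracket")


def _solve_flux_and_de(geom: FilmGeometry, occ: OcclusionSpec | None,
                       voxel_size: float, tol: float) -> tuple[float, float]:
    from .solver import mid_film_face, plane_flux
    dom = voxelize(geom, occ, voxel_size)
    fld = solve_steady_state(dom, BoundaryConditions(), tol=tol)
    j = plane_flux(fld, dom, mid_film_face(dom))
    return j, effective_diffusivity(fld, dom).ratio


def _check_fractions(fractions) -> np.ndarray:
    f = np.unique(np.asarray(list(fractions), dtype=float))
    if f.size < 2 or np.any(f < 0) or np.any(f > 1):
        raise ValueError("fractions must lie in [0, 1]")
    if abs(f[0]) > 1e-12 or abs(f[-1] - 1.0) > 1e-12:
        raise ValueError("sweep fractions must include 0 and 1")
    return f


def sweep_capping(geom: FilmGeometry, fractions, mode: str | OcclusionMode =
                  OcclusionMode.PORE_CAP, seed: int = 0,
                  voxel_size: float = 0.25, tol: float = 1e-10) -> PackingCurve:
    """Solve one steady state per occlusion fraction (aggregate models).

    ``pore_cap`` caps round(f * n_pores) pores chosen from ``seed``;
    ``aggregate_disk`` grows a central disk, with each requested fraction
    snapped to the nearest coverage the disk can realize in whole rings of
    pores (a thin disk rim across a pore leaves a conducting orifice, so
    ring-complete radii are the cleanly attainable densities).  Any solve
    failure aborts with the offending fraction.

    Within a sweep De(f)/De(0) is taken as the mean-flux ratio
    j(f)/j(0) — the two are identical under fixed boundary difference and
    geometry — anchored at the film-only De(0) of the open film.
    """
    mode = OcclusionMode(mode)
    f = _check_fractions(fractions)
    if mode is OcclusionMode.PORE_CAP:
        # snap targets to the attainable k/n grid (keeps endpoints exact)
        n = geom.n_pores
        f = np.unique(np.round(f * n) / n)
    elif mode is OcclusionMode.AGGREGATE_DISK:
        from .geometry import attainable_disk_coverages
        attain, radii = attainable_disk_coverages(geom)
        picks = np.unique([int(np.argmin(np.abs(attain - fi))) for fi in f])
        f = attain[picks]
        disk_radii = radii[picks]
    fluxes = []
    de0 = None
    for k, fi in enumerate(f):
        try:
            if mode is OcclusionMode.PORE_CAP:
                occ = realize_packing(
                    geom, PackingFraction(
                        fi, PackingDefinition.FRACTION_OF_PORES_CAPPED), seed)
            elif mode is OcclusionMode.AGGREGATE_DISK:
                occ = OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                                    disk_radius=float(disk_radii[k]),
                                    placement_seed=seed)
            else:
                raise GeometryError(
                    "sweep_capping supports pore_cap and aggregate_disk; "
                    "use monomer_curve for the monomer model")
            j, de = _solve_flux_and_de(geom, occ, voxel_size, tol)
            fluxes.append(j)
            if fi == 0.0:
                de0 = de
        except (SolverError, GeometryError) as exc:
            raise SolverError(f"sweep failed at fraction {fi}: {exc}") from exc
    j0 = fluxes[0]
    des = np.array([de0 * (j / j0) for j in fluxes])
    return PackingCurve(model="aggregate", fractions=tuple(f),
                        de_ratios=tuple(des),
                        definition=PackingDefinition.FRACTION_OF_PORES_CAPPED,
                        geometry_hash=geom.content_hash(),
                        voxel_size=voxel_size,
                        meta={"mode": mode.value, "seed": seed})


def monomer_curve(geom: FilmGeometry, fractions, patch_side: float = 0.4,
                  voxel_size: float = 0.25, tol: float = 1e-10) -> PackingCurve:
    """De(f) for uniformly dispersed monomers of fixed size.

    One steady state is solved with a ``patch_side`` x ``patch_side``
    monomer patch centred in every pore; the curve is then generated by
    scaling the per-pore flux proportionally to the open-area fraction
    (1 - f), anchored at the simulated uncapped De.  The simulated patch
    point (realized occlusion g, De(g)) is kept in ``meta`` as an internal
    consistency record.
    """
    if patch_side > geom.pore_diameter:
        raise GeometryError("monomer patch larger than the pore opening")
    f = _check_fractions(fractions)

    dom0 = voxelize(geom, None, voxel_size)
    fld0 = solve_steady_state(dom0, BoundaryConditions(), tol=tol)
    de0 = effective_diffusivity(fld0, dom0).ratio

    occ = OcclusionSpec(mode=OcclusionMode.MONOMER_PATCH,
                        patch_side=patch_side)
    dom_p = voxelize(geom, occ, voxel_size)
    fld_p = solve_steady_state(dom_p, BoundaryConditions(), tol=tol)
    de_p = effective_diffusivity(fld_p, dom_p).ratio
    g = realized_pore_occlusion(dom_p, dom0)

    des = (1.0 - f) * de0
    return PackingCurve(model="monomer", fractions=tuple(f),
                        de_ratios=tuple(des),
                        definition=PackingDefinition.FRACTION_OF_PORES_CAPPED,
                        geometry_hash=geom.content_hash(),
                        voxel_size=voxel_size,
                        meta={"patch_side": patch_side,
                              "patch_occlusion": g,
                              "patch_de_ratio": de_p})


class RatioOutOfRangeError(ValueError):
    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side  # "above_max" | "below_min"


def estimate_packing(curve: PackingCurve, measured: float,
                     kind: str = "de_ratio") -> PackingEstimate:
    """Invert a measured ratio on the monotone De(f) curve.

    ``kind="de_ratio"`` takes De/D_bulk directly; ``kind="flux_ratio"``
    takes flux(occluded)/flux(open), which equals De(f)/De(0) under fixed
    boundary difference and geometry, and is rescaled internally.
    """
    if kind == "flux_ratio":
        measured_de = measured * curve.de_at_zero
    elif kind == "de_ratio":
        measured_de = measured
    else:
        raise ValueError(f"unknown measurement kind {kind!r}")

    f = np.asarray(curve.fractions)
    d = np.asarray(curve.de_ratios)
    tol = 1e-9 * max(1.0, d[0])
    if measured_de > d[0] + tol:
        raise RatioOutOfRangeError(
            f"measured ratio {measured_de:.6g} above curve maximum "
            f"{d[0]:.6g}", side="above_max")
    if measured_de < d[-1] - tol:
        raise RatioOutOfRangeError(
            f"measured ratio {measured_de:.6g} below curve minimum "
            f"{d[-1]:.6g}", side="below_min")
    measured_de = float(min(max(measured_de, d[-1]), d[0]))

    # first bracket (lowest f) containing the measured value
    i = 0
    for k in range(len(f) - 1):
        if d[k] >= measured_de >= d[k + 1]:
            i = k
            break
    lo_f, hi_f = float(f[i]), float(f[i + 1])
    if d[i] == d[i + 1]:
        est = lo_f
    else:
        w = (d[i] - measured_de) / (d[i] - d[i + 1])
        est = lo_f + w * (hi_f - lo_f)
    return PackingEstimate(
        estimate=PackingFraction(float(np.clip(est, 0.0, 1.0)),
                                 curve.definition),
        measured_ratio=float(measured_de),
        bracket=(lo_f, hi_f),
        model=curve.model)


def flux_reduction_to_capping(reduction_pct: float) -> PackingFraction:
    """The commensurate-capping identification: an X% steady-state flux
    reduction is attributed to capping X% of the available pores."""
    if not 0.0 <= reduction_pct <= 100.0:
        raise ValueError("reduction_pct must lie in [0, 100]")
    return PackingFraction(reduction_pct / 100.0,
                           PackingDefinition.FRACTION_OF_PORES_CAPPED)
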