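"""Parametric membrane geometries and their voxelization.

The model film is a slab pierced by straight cylindrical nanopores on a
square lattice, sandwiched between two well-mixed reservoirs.  Aquaporins
(or aggregates thereof) are represented as impermeable obstructions placed
flush on the feed-side film face: per-pore caps, a single aggregate disk of
varying radius, or a small square monomer patch centred in every pore.

Coordinates: ``x`` is the transport axis (left = feed), ``y``/``z`` are
lateral.  All lengths are in nanometres.  The bulk diffusivity is
normalized to 1; solids carry diffusivity 0.
"""

from __future__ import annotations

import enum
import hashlib
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "GeometryError",
    "RegionLabel",
    "FilmGeometry",
    "OcclusionMode",
    "OcclusionSpec",
    "PackingDefinition",
    "PackingFraction",
    "VoxelDomain",
    "areal_pore_fraction",
    "voxelize",
    "discrete_pore_fraction",
    "realize_packing",
    "build_layered_domain",
]


class GeometryError(ValueError):
    """A geometry or occlusion invariant is violated."""


class RegionLabel(enum.IntEnum):
    LEFT_RESERVOIR = 0
    FILM_PORE = 1
    FILM_SOLID = 2
    OCCLUSION = 3
    RIGHT_RESERVOIR = 4


SOLID_LABELS = (RegionLabel.FILM_SOLID, RegionLabel.OCCLUSION)


@dataclass(frozen=True)
class FilmGeometry:
    """Reservoir-film-reservoir supercell with cylindrical pores.

    Defaults realize the study film: 1 nm pores whose square-lattice
    spacing yields 28% areal nanopore coverage of the film face.  The
    test-scale film thickness is 10 nm (a ~50 nm selective layer is
    available by configuration).  Reservoirs are thin because the bench
    cell is continuously stirred: the bulk concentration is held close to
    the membrane face, so the Dirichlet planes sit near the film.
    """

    pore_diameter: float = 1.0
    lattice_spacing: float = math.sqrt(math.pi * 0.25 / 0.28)
    film_thickness: float = 10.0
    reservoir_depth: float = 1.0
    n_pores_y: int = 5
    n_pores_z: int = 5

    def __post_init__(self) -> None:
        for name in ("pore_diameter", "lattice_spacing", "film_thickness",
                     "reservoir_depth"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be strictly positive")
        for name in ("n_pores_y", "n_pores_z"):
            if int(getattr(self, name)) < 1:
                raise GeometryError(f"{name} must be a positive count")
        if not self.pore_diameter < self.lattice_spacing:
            raise GeometryError(
                "pore_diameter must be smaller than lattice_spacing")
        frac = areal_pore_fraction(self)
        if not 0.0 < frac < 1.0:
            raise GeometryError(
                f"areal pore fraction {frac:.4f} outside (0, 1)")

    @classmethod
    def from_coverage(cls, coverage: float = 0.28, pore_diameter: float = 1.0,
                      **kwargs) -> "FilmGeometry":
        """Choose the lattice spacing that realizes a given areal coverage."""
        if not 0.0 < coverage < 1.0:
            raise GeometryError("coverage must lie strictly in (0, 1)")
        spacing = math.sqrt(math.pi * (pore_diameter / 2.0) ** 2 / coverage)
        return cls(pore_diameter=pore_diameter, lattice_spacing=spacing,
                   **kwargs)

    @property
    def lateral_extent(self) -> tuple[float, float]:
        return (self.n_pores_y * self.lattice_spacing,
                self.n_pores_z * self.lattice_spacing)

    @property
    def n_pores(self) -> int:
        return self.n_pores_y * self.n_pores_z

    def pore_centers(self) -> np.ndarray:
        """(n_pores, 2) array of pore-axis positions on the film face."""
        s = self.lattice_spacing
        cy = (np.arange(self.n_pores_y) + 0.5) * s
        cz = (np.arange(self.n_pores_z) + 0.5) * s
        Y, Z = np.meshgrid(cy, cz, indexing="ij")
        return np.column_stack([Y.ravel(), Z.ravel()])

    def content_hash(self) -> str:
        payload = repr((self.pore_diameter, self.lattice_spacing,
                        self.film_thickness, self.reservoir_depth,
                        self.n_pores_y, self.n_pores_z)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def areal_pore_fraction(geom: FilmGeometry) -> float:
    """Continuous pore areal fraction pi (d/2)^2 / s^2 of the film face."""
    return (math.pi * (geom.pore_diameter / 2.0) ** 2
            / geom.lattice_spacing ** 2)


class OcclusionMode(str, enum.Enum):
    PORE_CAP = "pore_cap"
    AGGREGATE_DISK = "aggregate_disk"
    MONOMER_PATCH = "monomer_patch"


@dataclass(frozen=True)
class OcclusionSpec:
    """How aquaporins block pores.

    ``occlusion_thickness=None`` means a single voxel layer at the feed
    face: in steady state an impermeable layer of any thickness blocks
    flux identically, so the cylinder height (unstated for the protein)
    is immaterial.
    """

    mode: OcclusionMode = OcclusionMode.PORE_CAP
    cap_fraction: float = 0.0
    disk_radius: float = 0.0
    patch_side: float = 0.0
    occlusion_thickness: float | None = None
    placement_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", OcclusionMode(self.mode))
        if not 0.0 <= self.cap_fraction <= 1.0:
            raise GeometryError("cap_fraction must lie in [0, 1]")
        if self.disk_radius < 0:
            raise GeometryError("disk_radius must be nonnegative")
        if self.patch_side < 0:
            raise GeometryError("patch_side must be nonnegative")
        if self.occlusion_thickness is not None and \
                not self.occlusion_thickness > 0:
            raise GeometryError("occlusion_thickness must be positive")

    @staticmethod
    def none() -> "OcclusionSpec":
        return OcclusionSpec(mode=OcclusionMode.PORE_CAP, cap_fraction=0.0)


class PackingDefinition(str, enum.Enum):
    """Two distinct occlusion densities appear in the study.

    ``FRACTION_OF_PORES_CAPPED`` is the fraction of pore-opening area
    occluded (the quantity that directly scales flux in the model);
    ``FRACTION_OF_FILM_SURFACE_OCCLUDED`` is the fraction of the total
    film face covered by protein.
    """

    FRACTION_OF_PORES_CAPPED = "fraction_of_pores_capped"
    FRACTION_OF_FILM_SURFACE_OCCLUDED = "fraction_of_film_surface_occluded"


@dataclass(frozen=True)
class PackingFraction:
    value: float
    definition: PackingDefinition = PackingDefinition.FRACTION_OF_PORES_CAPPED

    def __post_init__(self) -> None:
        object.__setattr__(self, "definition",
                           PackingDefinition(self.definition))
        if not 0.0 <= self.value <= 1.0:
            raise GeometryError("packing fraction must lie in [0, 1]")


@dataclass(frozen=True)
class VoxelDomain:
    """Voxelized diffusivity field on a structured grid.

    The x spacing ``dx`` is uniform; reservoir depths are snapped to whole
    layers of ``dx`` so the film faces lie exactly on voxel faces.  Lateral
    spacings are the lattice spacing divided by a whole number of voxels
    per cell, so every pore rasterizes identically.
    """

    labels: np.ndarray          # (nx, ny, nz) int8 RegionLabel values
    dx: float
    hy: float
    hz: float
    film_layers: tuple[int, int]   # [lo, hi) x-layer index range of the film
    geometry: FilmGeometry
    d_bulk: float = 1.0
    d_field: np.ndarray | None = None   # optional per-voxel diffusivity
    # (homogenized layers); None means binary d_bulk/0 from the labels

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def open_mask(self) -> np.ndarray:
        if self.d_field is not None:
            return self.d_field > 0
        return (self.labels != RegionLabel.FILM_SOLID) & \
               (self.labels != RegionLabel.OCCLUSION)

    @property
    def diffusivity(self) -> np.ndarray:
        if self.d_field is not None:
            return self.d_field
        return np.where(self.open_mask, self.d_bulk, 0.0)

    @property
    def x_faces(self) -> np.ndarray:
        return np.arange(self.labels.shape[0] + 1) * self.dx

    @property
    def x_centers(self) -> np.ndarray:
        return (np.arange(self.labels.shape[0]) + 0.5) * self.dx

    @property
    def lateral_area(self) -> float:
        _, ny, nz = self.labels.shape
        return ny * self.hy * nz * self.hz

    @property
    def film_span(self) -> tuple[float, float]:
        lo, hi = self.film_layers
        return lo * self.dx, hi * self.dx

    def validate(self) -> None:
        lab = self.labels
        solid = np.isin(lab, [int(l) for l in SOLID_LABELS])
        if not np.all((self.diffusivity == 0) == solid):
            raise GeometryError("diffusivity must vanish exactly on solids")
        if not (np.all(lab[0] == RegionLabel.LEFT_RESERVOIR) and
                np.all(lab[-1] == RegionLabel.RIGHT_RESERVOIR)):
            raise GeometryError("domain end faces must be reservoir regions")


def _pore_lateral_mask(geom: FilmGeometry, ny: int, nz: int,
                       hy: float, hz: float) -> np.ndarray:
    """Voxel-center membership test against the pore cylinders.

    A center exactly on the cylinder surface counts as open.
    """
    s = geom.lattice_spacing
    yc = (np.arange(ny) + 0.5) * hy
    zc = (np.arange(nz) + 0.5) * hz
    # distance from each center to the nearest pore axis via the lattice
    dy = (yc % s) - s / 2.0
    dz = (zc % s) - s / 2.0
    DY, DZ = np.meshgrid(dy, dz, indexing="ij")
    r = geom.pore_diameter / 2.0
    return DY ** 2 + DZ ** 2 <= r ** 2 + 1e-12 * r ** 2


def _capped_pore_indices(n_pores: int, cap_fraction: float,
                         seed: int) -> np.ndarray:
    k = int(round(cap_fraction * n_pores))
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(n_pores, size=k, replace=False))


def voxelize(geom: FilmGeometry, occ: OcclusionSpec | None = None,
             voxel_size: float = 0.25) -> VoxelDomain:
    """Rasterize geometry + occlusion into a labelled diffusivity field.

    ``voxel_size`` is the requested resolution; realized spacings are
    snapped down so pores and film faces align with the grid.  Requires
    ``voxel_size <= pore_diameter / 4``.
    """
    if occ is None:
        occ = OcclusionSpec.none()
    if voxel_size > geom.pore_diameter / 4.0 + 1e-12:
        raise GeometryError(
            f"voxel_size {voxel_size} too coarse: must be <= "
            f"pore_diameter/4 = {geom.pore_diameter / 4.0}")

    s = geom.lattice_spacing
    m = math.ceil(s / voxel_size - 1e-9)
    hy = hz = s / m
    ny = m * geom.n_pores_y
    nz = m * geom.n_pores_z

    n_film = math.ceil(geom.film_thickness / voxel_size - 1e-9)
    dx = geom.film_thickness / n_film
    n_res = max(1, int(round(geom.reservoir_depth / dx)))
    nx = n_res + n_film + n_res
    film_layers = (n_res, n_res + n_film)

    labels = np.empty((nx, ny, nz), dtype=np.int8)
    labels[:n_res] = RegionLabel.LEFT_RESERVOIR
    labels[n_res + n_film:] = RegionLabel.RIGHT_RESERVOIR

    pore_mask = _pore_lateral_mask(geom, ny, nz, hy, hz)
    film = np.where(pore_mask, np.int8(RegionLabel.FILM_PORE),
                    np.int8(RegionLabel.FILM_SOLID))
    labels[n_res:n_res + n_film] = film[None, :, :]

    occ_mask = _occlusion_lateral_mask(geom, occ, ny, nz, hy, hz)
    if occ_mask is not None:
        if occ.occlusion_thickness is None:
            n_occ = 1
        else:
            n_occ = min(n_film,
                        max(1, math.ceil(occ.occlusion_thickness / dx - 1e-9)))
        sl = labels[n_res:n_res + n_occ]
        sl[:, occ_mask & pore_mask] = RegionLabel.OCCLUSION

    dom = VoxelDomain(labels=labels, dx=dx, hy=hy, hz=hz,
                      film_layers=film_layers, geometry=geom)
    dom.labels.setflags(write=False)
    return dom


def _occlusion_lateral_mask(geom: FilmGeometry, occ: OcclusionSpec,
                            ny: int, nz: int, hy: float,
                            hz: float) -> np.ndarray | None:
    """Lateral footprint of the occlusion, or None if empty."""
    Ly, Lz = ny * hy, nz * hz
    yc = (np.arange(ny) + 0.5) * hy
    zc = (np.arange(nz) + 0.5) * hz
    YC, ZC = np.meshgrid(yc, zc, indexing="ij")

    if occ.mode is OcclusionMode.PORE_CAP:
        if occ.cap_fraction == 0.0:
            return None
        capped = _capped_pore_indices(geom.n_pores, occ.cap_fraction,
                                      occ.placement_seed)
        centers = geom.pore_centers()[capped]
        r = geom.pore_diameter / 2.0
        mask = np.zeros((ny, nz), dtype=bool)
        for cy, cz in centers:
            mask |= (YC - cy) ** 2 + (ZC - cz) ** 2 <= r ** 2 + 1e-12 * r ** 2
        return mask

    if occ.mode is OcclusionMode.AGGREGATE_DISK:
        if occ.disk_radius == 0.0:
            return None
        half_diag = math.hypot(Ly, Lz) / 2.0
        max_r = max(half_diag,
                    _radius_covering_all_pores(geom))
        if occ.disk_radius > max_r + 1e-9:
            raise GeometryError(
                f"disk_radius {occ.disk_radius:.4f} exceeds the supercell "
                f"(max {max_r:.4f})")
        return (YC - Ly / 2.0) ** 2 + (ZC - Lz / 2.0) ** 2 \
            <= occ.disk_radius ** 2

    if occ.mode is OcclusionMode.MONOMER_PATCH:
        if occ.patch_side == 0.0:
            return None
        if occ.patch_side > geom.pore_diameter:
            raise GeometryError(
                "monomer patch_side exceeds the pore opening")
        s = geom.lattice_spacing
        half = occ.patch_side / 2.0
        return (np.abs((YC % s) - s / 2.0) <= half) & \
               (np.abs((ZC % s) - s / 2.0) <= half)

    raise GeometryError(f"unknown occlusion mode {occ.mode}")


def _radius_covering_all_pores(geom: FilmGeometry) -> float:
    centers = geom.pore_centers()
    Ly, Lz = geom.lateral_extent
    d = np.hypot(centers[:, 0] - Ly / 2.0, centers[:, 1] - Lz / 2.0)
    return float(d.max() + geom.pore_diameter / 2.0)


def discrete_pore_fraction(dom: VoxelDomain) -> float:
    """Open fraction of the film face, as rasterized.

    Measured on the permeate-side film layer, which is never occluded, so
    the value audits the pore rasterization itself.  This is the reference
    value for De/D_bulk checks; it differs from :func:`areal_pore_fraction`
    by rasterization error.
    """
    lo, hi = dom.film_layers
    face = dom.labels[hi - 1]
    return float((face == RegionLabel.FILM_PORE).mean())


def _disk_face_fraction(geom: FilmGeometry, radius: float) -> float:
    """Continuous fraction of the film face covered by a centred disk."""
    Ly, Lz = geom.lateral_extent
    if radius <= 0:
        return 0.0
    # integrate the chord width clipped to the face
    y = np.linspace(-Ly / 2.0, Ly / 2.0, 20001)
    inside = np.clip(radius ** 2 - y ** 2, 0.0, None)
    width = np.minimum(2.0 * np.sqrt(inside), Lz)
    return float(np.trapezoid(width, y) / (Ly * Lz))


def _circle_overlap_area(r1: float, r2: float, d: float) -> float:
    """Area of intersection of two circles with radii r1, r2 at distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        r = min(r1, r2)
        return math.pi * r * r
    a1 = r1 * r1 * math.acos((d * d + r1 * r1 - r2 * r2) / (2 * d * r1))
    a2 = r2 * r2 * math.acos((d * d + r2 * r2 - r1 * r1) / (2 * d * r2))
    tri = 0.5 * math.sqrt(max(0.0, (-d + r1 + r2) * (d + r1 - r2)
                              * (d - r1 + r2) * (d + r1 + r2)))
    return a1 + a2 - tri


def _disk_pore_fraction(geom: FilmGeometry, radius: float) -> float:
    """Continuous fraction of total pore-opening area under a centred disk."""
    if radius <= 0:
        return 0.0
    centers = geom.pore_centers()
    Ly, Lz = geom.lateral_extent
    r_pore = geom.pore_diameter / 2.0
    dist = np.hypot(centers[:, 0] - Ly / 2.0, centers[:, 1] - Lz / 2.0)
    covered = sum(_circle_overlap_area(radius, r_pore, float(d))
                  for d in dist)
    return covered / (geom.n_pores * math.pi * r_pore ** 2)


def realize_packing(geom: FilmGeometry, target: PackingFraction,
                    seed: int = 0) -> OcclusionSpec:
    """Construct an occlusion realizing a target packing fraction.

    Pore-capping targets select round(value * n_pores) pores
    pseudo-randomly from ``seed`` (realized fraction within half a
    1/n_pores quantum).  Surface-coverage targets solve for the radius of
    a centred aggregate disk covering the target fraction of the face.
    """
    v = target.value
    if target.definition is PackingDefinition.FRACTION_OF_PORES_CAPPED:
        n = geom.n_pores
        k = int(round(v * n))
        if abs(k / n - v) > 0.5 / n + 1e-12:
            raise GeometryError(
                f"target {v} unattainable; nearest attainable {k / n:.4f}")
        return OcclusionSpec(mode=OcclusionMode.PORE_CAP,
                             cap_fraction=k / n, placement_seed=seed)

    # surface-coverage target -> centred aggregate disk
    if v == 0.0:
        return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                             disk_radius=0.0, placement_seed=seed)
    Ly, Lz = geom.lateral_extent
    r_max = math.hypot(Ly, Lz) / 2.0
    if v >= 1.0:
        return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                             disk_radius=r_max, placement_seed=seed)
    radius = brentq(lambda r: _disk_face_fraction(geom, r) - v,
                    0.0, r_max, xtol=1e-10)
    return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                         disk_radius=float(radius), placement_seed=seed)


def disk_for_pore_coverage(geom: FilmGeometry, fraction: float,
                           seed: int = 0) -> OcclusionSpec:
    """Centred aggregate disk occluding a given fraction of pore area."""
    if not 0.0 <= fraction <= 1.0:
        raise GeometryError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                             disk_radius=0.0, placement_seed=seed)
    r_max = _radius_covering_all_pores(geom)
    if fraction >= 1.0:
        return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                             disk_radius=r_max, placement_seed=seed)
    radius = brentq(lambda r: _disk_pore_fraction(geom, r) - fraction,
                    0.0, r_max, xtol=1e-10)
    return OcclusionSpec(mode=OcclusionMode.AGGREGATE_DISK,
                         disk_radius=float(radius), placement_seed=seed)


def attainable_disk_coverages(geom: FilmGeometry
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Pore-coverage fractions a centred disk can realize cleanly.

    A thin impermeable disk whose rim only partially covers a pore leaves
    an orifice that still conducts, so the disk occludes pores effectively
    in whole *rings* of the lattice.  Returns the cumulative coverage
    fractions (including 0 and 1) and the disk radii realizing them: each
    radius fully covers its rings without touching the next.
    """
    centers = geom.pore_centers()
    Ly, Lz = geom.lateral_extent
    r_pore = geom.pore_diameter / 2.0
    d = np.round(np.hypot(centers[:, 0] - Ly / 2.0,
                          centers[:, 1] - Lz / 2.0), 9)
    dists, counts = np.unique(d, return_counts=True)
    n = geom.n_pores
    fracs = [0.0]
    radii = [0.0]
    cum = 0
    for k, (dist, cnt) in enumerate(zip(dists, counts)):
        cum += cnt
        if k + 1 < len(dists):
            lo = dist + r_pore
            hi = dists[k + 1] - r_pore
            radius = 0.5 * (lo + hi) if hi > lo else lo
        else:
            radius = dist + r_pore
        fracs.append(cum / n)
        radii.append(float(radius))
    return np.asarray(fracs), np.asarray(radii)


def realized_pore_occlusion(dom_occluded: VoxelDomain,
                            dom_open: VoxelDomain) -> float:
    """Fraction of rasterized pore-opening area occluded at the feed face."""
    lo, _ = dom_occluded.film_layers
    face = dom_occluded.labels[lo]
    lo0, _ = dom_open.film_layers
    face0 = dom_open.labels[lo0]
    n_open0 = (face0 == RegionLabel.FILM_PORE).sum()
    n_occ = (face == RegionLabel.OCCLUSION).sum()
    return float(n_occ / n_open0)


def build_layered_domain(layers: list[tuple[float, float]],
                         lateral_n: int = 20, h: float = 0.1,
                         n_reservoir: int = 1,
                         homogenized: bool = False,
                         geom: FilmGeometry | None = None) -> VoxelDomain:
    """Stack of planar layers of straight aligned channels (for oracles).

    Each layer is ``(thickness, open_fraction)``.  With
    ``homogenized=False`` channels are explicit: a fixed pseudo-random
    ordering of the lateral columns is thresholded at each layer's open
    fraction, so layer open sets are nested (aligned).  With
    ``homogenized=True`` each layer is the laterally well-mixed continuum
    limit of such channels: a uniform slab of effective diffusivity
    ``phi * D_bulk``, for which the series-resistance composite is exact.
    Thin reservoir layers bound the stack.
    """
    if geom is None:
        geom = FilmGeometry()
    order = np.random.default_rng(12345).permutation(lateral_n * lateral_n)
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    rank = rank.reshape(lateral_n, lateral_n)

    blocks = []
    d_blocks = []
    for thickness, phi in layers:
        if thickness <= 0:
            raise GeometryError("layer thickness must be positive")
        if not 0.0 < phi <= 1.0:
            raise GeometryError("layer open fraction must lie in (0, 1]")
        n_lay = max(1, int(round(thickness / h)))
        if homogenized:
            film = np.full((lateral_n, lateral_n),
                           np.int8(RegionLabel.FILM_PORE))
            d_blocks.append(np.full((n_lay, lateral_n, lateral_n), phi))
        else:
            k = int(round(phi * lateral_n * lateral_n))
            mask = rank < k
            film = np.where(mask, np.int8(RegionLabel.FILM_PORE),
                            np.int8(RegionLabel.FILM_SOLID))
        blocks.append(np.repeat(film[None, :, :], n_lay, axis=0))

    film_block = np.concatenate(blocks, axis=0)
    res = np.full((n_reservoir, lateral_n, lateral_n),
                  np.int8(RegionLabel.LEFT_RESERVOIR))
    res_r = np.full((n_reservoir, lateral_n, lateral_n),
                    np.int8(RegionLabel.RIGHT_RESERVOIR))
    labels = np.concatenate([res, film_block, res_r], axis=0)
    n_film = film_block.shape[0]
    d_field = None
    if homogenized:
        ones = np.ones((n_reservoir, lateral_n, lateral_n))
        d_field = np.concatenate([ones] + d_blocks + [ones], axis=0)
    dom = VoxelDomain(labels=labels, dx=h, hy=h, hz=h,
                      film_layers=(n_reservoir, n_reservoir + n_film),
                      geometry=geom, d_field=d_field)
    dom.labels.setflags(write=False)
    return dom
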