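"""Steady-state Fickian diffusion on a voxel domain.

Finite-volume discretization of div(D grad c) = 0 with harmonic averaging
of face diffusivities, so faces adjacent to a solid voxel are exactly
impermeable.  Dirichlet concentrations are imposed on the two reservoir
end faces of the transport axis; lateral faces are no-flux (equivalent to
periodic for the symmetric unit supercell).

The effective diffusivity De of the film is the diffusivity of the
homogeneous slab that would carry the same mean flux under the same
concentration difference: De = <j> * separation / delta_c.  With the
default film-only convention, separation and delta_c are taken between the
first and last film voxel layers (open-voxel mean concentrations), which
makes De/D_bulk equal to the open areal fraction exactly for straight
aligned channels.  The whole-domain convention (reservoir-boundary values,
full domain separation) is available via ``separation="domain"``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import VoxelDomain

__all__ = [
    "SolverError",
    "ConvergenceError",
    "BoundaryConditions",
    "ConcentrationField",
    "EffectiveDiffusivity",
    "solve_steady_state",
    "plane_flux",
    "mid_film_face",
    "effective_diffusivity",
    "series_resistance_oracle",
]


class SolverError(RuntimeError):
    pass


class ConvergenceError(SolverError):
    def __init__(self, message: str, residual_history: list[float]):
        super().__init__(message)
        self.residual_history = residual_history


@dataclass(frozen=True)
class BoundaryConditions:
    """Dirichlet reservoir concentrations (nondimensional)."""

    c_left: float = 1.0
    c_right: float = 0.0
    axis: str = "x"

    def __post_init__(self) -> None:
        if self.axis != "x":
            raise SolverError("only the x transport axis is supported")
        for v in (self.c_left, self.c_right):
            if not (math.isfinite(v) and v >= 0):
                raise SolverError("boundary concentrations must be finite "
                                  "and nonnegative")


@dataclass(frozen=True)
class ConcentrationField:
    """Converged concentration field; NaN marks solid voxels."""

    c: np.ndarray
    residual: float
    iterations: int
    bc: BoundaryConditions
    tol: float


@dataclass(frozen=True)
class EffectiveDiffusivity:
    mean_flux: float
    De: float
    ratio: float
    plane_position: float
    separation: float


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def _assemble(dom: VoxelDomain, bc: BoundaryConditions):
    """Sparse SPD system over open voxels reachable from the end faces."""
    D = dom.diffusivity
    nx, ny, nz = D.shape
    open_mask = dom.open_mask

    # open voxels with no path to either Dirichlet face are indeterminate;
    # they are excluded and later filled with the mean boundary value
    comp, _ = ndi.label(open_mask)
    reach = np.unique(np.concatenate([comp[0].ravel(), comp[-1].ravel()]))
    reach = reach[reach > 0]
    solvable = np.isin(comp, reach)
    isolated = open_mask & ~solvable

    idx = -np.ones(D.shape, dtype=np.int64)
    n = int(solvable.sum())
    idx[solvable] = np.arange(n)

    areas = (dom.hy * dom.hz, dom.dx * dom.hz, dom.dx * dom.hy)
    dists = (dom.dx, dom.hy, dom.hz)

    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        Da, Db = D[tuple(sl_a)], D[tuple(sl_b)]
        T = _harmonic(Da, Db) * areas[axis] / dists[axis]
        ia, ib = idx[tuple(sl_a)], idx[tuple(sl_b)]
        ok = (ia >= 0) & (ib >= 0) & (T > 0)
        ta, tb, tv = ia[ok], ib[ok], T[ok]
        rows.append(ta); cols.append(tb); vals.append(-tv)
        rows.append(tb); cols.append(ta); vals.append(-tv)
        np.add.at(diag, ta, tv)
        np.add.at(diag, tb, tv)

    # Dirichlet faces at the x ends: half-cell transmissibility
    b = np.zeros(n)
    for layer, c_bc in ((0, bc.c_left), (nx - 1, bc.c_right)):
        face_idx = idx[layer]
        ok = face_idx >= 0
        Tb = D[layer][ok] * areas[0] / (dists[0] / 2.0)
        np.add.at(diag, face_idx[ok], Tb)
        np.add.at(b, face_idx[ok], Tb * c_bc)

    rows.append(np.arange(n)); cols.append(np.arange(n)); vals.append(diag)
    A = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return A, b, idx, isolated


def solve_steady_state(dom: VoxelDomain, bc: BoundaryConditions | None = None,
                       tol: float = 1e-10,
                       maxiter: int = 50000) -> ConcentrationField:
    """Solve div(D grad c) = 0 with diagonally preconditioned CG.

    The iteration starts from the linear interpolant of the boundary
    values and is deterministic.  Raises :class:`ConvergenceError`
    carrying the residual history if the iteration cap is reached.
    """
    if bc is None:
        bc = BoundaryConditions()
    if not tol > 0:
        raise SolverError("tol must be positive")
    A, b, idx, isolated = _assemble(dom, bc)

    nx = dom.shape[0]
    lin = bc.c_left + (bc.c_right - bc.c_left) * \
        (dom.x_centers / (nx * dom.dx))
    x0_full = np.broadcast_to(lin[:, None, None], dom.shape)
    x0 = x0_full[idx >= 0]

    if np.allclose(b, 0.0) and bc.c_left == bc.c_right == 0.0:
        x = np.zeros_like(x0)
        iters, res = 0, 0.0
    else:
        diag = A.diagonal()
        M = spla.LinearOperator(A.shape, matvec=lambda v: v / diag)
        history: list[float] = []
        b_norm = float(np.linalg.norm(b)) or 1.0

        it_count = [0]

        def callback(xk):
            it_count[0] += 1
            if it_count[0] % 25 == 0:
                history.append(float(np.linalg.norm(b - A @ xk)) / b_norm)

        x, info = spla.cg(A, b, x0=x0, rtol=tol, atol=0.0,
                          maxiter=maxiter, M=M, callback=callback)
        res = float(np.linalg.norm(b - A @ x)) / b_norm
        history.append(res)
        if info > 0:
            raise ConvergenceError(
                f"CG failed to reach rtol={tol} within {maxiter} iterations "
                f"(residual {res:.3e})", history)
        iters = it_count[0]

    c = np.full(dom.shape, np.nan)
    c[idx >= 0] = x
    if isolated.any():
        c[isolated] = 0.5 * (bc.c_left + bc.c_right)
    c.setflags(write=False)
    return ConcentrationField(c=c, residual=res, iterations=iters,
                              bc=bc, tol=tol)


def mid_film_face(dom: VoxelDomain) -> float:
    """x position of the voxel face nearest the middle of the film."""
    lo, hi = dom.film_layers
    return (lo + (hi - lo) // 2) * dom.dx


def plane_flux(field: ConcentrationField, dom: VoxelDomain,
               plane_x: float) -> float:
    """Area-averaged diffusive flux through an interior x voxel face.

    Positive for transport from the left (feed) to the right reservoir.
    """
    faces = dom.x_faces
    j = int(round(plane_x / dom.dx))
    if not (0 < j < dom.shape[0]) or abs(faces[j] - plane_x) > 1e-9 * faces[-1]:
        raise SolverError(
            f"plane_x={plane_x} is not an interior voxel face")
    D = dom.diffusivity
    Dh = _harmonic(D[j - 1], D[j])
    with np.errstate(invalid="ignore"):
        dc = field.c[j - 1] - field.c[j]
    face_flux = np.where(Dh > 0, Dh * np.nan_to_num(dc) / dom.dx, 0.0)
    return float(face_flux.sum() * dom.hy * dom.hz / dom.lateral_area)


def effective_diffusivity(field: ConcentrationField, dom: VoxelDomain,
                          bc: BoundaryConditions | None = None,
                          separation: str = "film") -> EffectiveDiffusivity:
    """Extract De from a converged field via De = <j> separation / delta_c.

    ``separation="film"``: mean flux at the mid-film face, concentration
    drop between the open voxels of the first and last film layers.
    ``separation="domain"``: the literal reservoir-boundary form with the
    full domain separation.
    """
    if bc is None:
        bc = field.bc
    dc_bc = bc.c_left - bc.c_right
    if dc_bc == 0:
        raise SolverError("De extraction requires c_left != c_right")
    plane = mid_film_face(dom)
    j_mean = plane_flux(field, dom, plane)

    if separation == "domain":
        sep = float(dom.x_faces[-1] - dom.x_faces[0])
        dc = dc_bc
    elif separation == "film":
        lo, hi = dom.film_layers
        xc = dom.x_centers
        sep = float(xc[hi - 1] - xc[lo])
        if sep == 0.0:  # single-layer film: fall back to face span
            sep = float(dom.dx)
        first, last = field.c[lo], field.c[hi - 1]
        cL = float(np.nanmean(first)) if np.isfinite(first).any() else np.nan
        cR = float(np.nanmean(last)) if np.isfinite(last).any() else np.nan
        dc = cL - cR
        if not np.isfinite(dc) or abs(dc) < 1e-12 * abs(dc_bc):
            # fully occluded face or vanishing film drop: the flux is the
            # informative quantity; normalize by the imposed difference
            dc = dc_bc
    else:
        raise SolverError(f"unknown separation convention {separation!r}")

    De = j_mean * sep / dc
    ratio = De / dom.d_bulk
    if ratio < -1e-6 or ratio > 1.0 + 1e-6:
        raise SolverError(f"unphysical De/D_bulk = {ratio}")
    ratio = float(min(max(ratio, 0.0), 1.0))
    return EffectiveDiffusivity(mean_flux=j_mean, De=float(De), ratio=ratio,
                                plane_position=plane, separation=sep)


def series_resistance_oracle(layers: list[tuple[float, float]]) -> float:
    """Closed-form De/D_bulk for stacked layers of straight aligned channels.

    Harmonic composite L_total / sum(L_i / phi_i); returns 0 if any layer
    is fully closed.
    """
    total = 0.0
    resistance = 0.0
    for thickness, phi in layers:
        if thickness <= 0:
            raise SolverError("layer thickness must be positive")
        if not 0.0 <= phi <= 1.0:
            raise SolverError("open fraction must lie in [0, 1]")
        if phi == 0.0:
            return 0.0
        total += thickness
        resistance += thickness / phi
    return total / resistance
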