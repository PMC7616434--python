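"""Finite-difference electrostatic solver and analytic oracles.

The scenes are pure Dirichlet problems for Laplace's equation, solved on
regular grids:

* axisymmetric scenes use the 5-point cylindrical stencil (with the 1/r
  first-derivative term and the symmetry condition dV/dr = 0 on the axis),
  assembled sparse and solved directly;
* Cartesian 3-D scenes use the 7-point stencil solved by conjugate gradients
  preconditioned with a geometric multigrid V-cycle (red-black Gauss-Seidel
  smoothing, full-weighting restriction, trilinear prolongation, direct
  factorisation on the coarsest level).

Both support a two-level nested solve: a coarse pass over the whole domain
supplies Dirichlet boundary values (by multilinear interpolation) for a fine
pass restricted to a refinement box around the millimetre-scale air gap —
the scale separation between a 1 m scene and a 2.5 mm gap makes a single
uniform grid impractical.

Curved conductor boundaries are handled by first-order cut-cell assignment:
every grid node inside a conductor takes its potential.  The electric field
is the centred-difference negative gradient (one-sided on grid edges), and
probes interpolate it multilinearly; probe points must stay at least one
cell away from any conductor.

An independent image-charge series for the sphere-plane geometry
(:func:`sphere_plane_axis_field`) serves as the analytic oracle for the rig.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.interpolate import RegularGridInterpolator

from . import _kernels
from .scenes import AXISYMMETRIC, CARTESIAN3D, FieldScene, build_rig_scene
from .shapes import InvalidGeometryError


class SolverError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class OutOfDomainError(ValueError):
    """A probe point lies outside the solved region."""


class ProximityError(ValueError):
    """A probe point lies within one grid cell of a conductor."""


class ResolutionWarning(UserWarning):
    """The grid does not resolve the smallest air gap adequately."""


@dataclass(frozen=True)
class GridSpec:
    """Discretisation request: spacing, solver tolerance, optional fine box.

    ``refinement_box`` (pair of corner tuples, metres) marks the region for
    the fine level of a nested solve; it is interpreted by the solve drivers,
    which snap it outward to grid-compatible extents.
    """

    h: float
    tol: float = 1e-8
    refinement_box: Optional[Tuple[Tuple[float, ...], Tuple[float, ...]]] = None
    maxiter: int = 400

    def __post_init__(self):
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")
        if self.tol <= 0:
            raise ValueError("solver tolerance must be positive")


@dataclass(frozen=True)
class ProbeResult:
    position: Tuple[float, ...]
    E_vector: Tuple[float, ...]
    E_magnitude: float
    V: float


@dataclass
class FieldSolution:
    """Discrete potential and field on a regular grid.

    ``axes`` are the grid coordinate vectors — (r, z) for axisymmetric
    solutions, (x, y, z) for Cartesian ones.  ``E`` holds one component per
    axis (negative centred-difference gradient of ``V``).
    """

    axes: Tuple[np.ndarray, ...]
    V: np.ndarray
    E: Tuple[np.ndarray, ...]
    conductor_mask: np.ndarray
    scene: FieldScene
    residual: float = 0.0
    h: float = 0.0

    _interp: dict = field(default_factory=dict, repr=False)

    @property
    def E_magnitude(self) -> np.ndarray:
        return np.sqrt(sum(c**2 for c in self.E))

    def check_maximum_principle(self, rtol: float = 1e-9) -> None:
        """Assert min(boundary potentials) <= V <= max everywhere."""
        pots = self.scene.potentials
        lo, hi = pots.min(), pots.max()
        slack = rtol * max(1.0, np.abs(pots).max())
        vmin, vmax = float(self.V.min()), float(self.V.max())
        if vmin < lo - slack or vmax > hi + slack:
            raise AssertionError(
                f"maximum principle violated: V in [{vmin}, {vmax}], "
                f"boundaries in [{lo}, {hi}]"
            )

    # -- probing ----------------------------------------------------------
    def _interpolator(self, key: str, values: np.ndarray) -> RegularGridInterpolator:
        if key not in self._interp:
            self._interp[key] = RegularGridInterpolator(
                self.axes, values, method="linear", bounds_error=True
            )
        return self._interp[key]

    def probe(self, points: Sequence[Sequence[float]]) -> List[ProbeResult]:
        pts = np.atleast_2d(np.asarray(points, float))
        if pts.shape[1] != len(self.axes):
            raise OutOfDomainError(
                f"probe points must have {len(self.axes)} coordinates"
            )
        try:
            near = self._interpolator("mask", self.conductor_mask.astype(float))(pts)
        except ValueError as exc:
            raise OutOfDomainError(str(exc)) from None
        if np.any(near > 0):
            raise ProximityError(
                "probe point within one grid cell of a conductor"
            )
        comps = [self._interpolator(f"E{i}", c)(pts) for i, c in enumerate(self.E)]
        vvals = self._interpolator("V", self.V)(pts)
        out = []
        for n, p in enumerate(pts):
            vec = tuple(float(c[n]) for c in comps)
            out.append(
                ProbeResult(
                    position=tuple(p),
                    E_vector=vec,
                    E_magnitude=float(np.sqrt(sum(v * v for v in vec))),
                    V=float(vvals[n]),
                )
            )
        return out

    def probe_magnitude(self, point: Sequence[float]) -> float:
        return self.probe([point])[0].E_magnitude

    # -- export -----------------------------------------------------------
    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        names = ("r", "z") if len(self.axes) == 2 else ("x", "y", "z")
        sl = tuple(slice(None, None, stride) for _ in self.axes)
        grids = np.meshgrid(*(a[::stride] for a in self.axes), indexing="ij")
        data = {f"{n}_m": g.ravel() for n, g in zip(names, grids)}
        data["V"] = self.V[sl].ravel()
        for n, c in zip(names, self.E):
            data[f"E{n}"] = c[sl].ravel()
        data["Emag"] = self.E_magnitude[sl].ravel()
        return pd.DataFrame(data)

    def export_csv(self, path: str, stride: int = 1) -> None:
        self.to_frame(stride).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grid helpers
# ---------------------------------------------------------------------------

def _make_axis(lo: float, hi: float, h: float) -> np.ndarray:
    n = max(2, int(round((hi - lo) / h)) + 1)
    return np.linspace(lo, hi, n)


def _domain_axis_mult8(lo: float, hi: float, h: float) -> np.ndarray:
    """Full-domain axis with a multiple-of-8 cell count (multigrid coarsening).

    Keeps the exact domain extent; the effective spacing is the requested one
    rounded so that 8 divides the cell count.
    """
    cells = max(8, int(round((hi - lo) / h / 8)) * 8)
    return np.linspace(lo, hi, cells + 1)


def _box_axis_mult8(lo: float, hi: float, h: float) -> np.ndarray:
    """Refinement-box axis at exactly spacing ``h``, cell count rounded up
    to a multiple of 8 by extending the upper corner."""
    cells = int(np.ceil((hi - lo) / h - 1e-9))
    cells = max(8, ((cells + 7) // 8) * 8)
    return np.linspace(lo, lo + cells * h, cells + 1)


def _conductor_fields(scene: FieldScene, grids) -> Tuple[np.ndarray, np.ndarray]:
    """Boolean Dirichlet mask and value array from the scene's conductors."""
    X = grids
    mask = np.zeros(X[0].shape, dtype=bool)
    vals = np.zeros(X[0].shape, dtype=float)
    for c in scene.conductors:
        if len(X) == 2:  # axisymmetric: x=r, y=0
            inside = c.shape.contains(X[0], 0.0, X[1])
        else:
            inside = c.shape.contains(X[0], X[1], X[2])
        vals = np.where(inside, c.potential, vals)
        mask |= inside
    return mask, vals


def _check_resolution(scene: FieldScene, h: float) -> None:
    if scene.min_gap is not None and h > scene.min_gap / 20:
        warnings.warn(
            f"grid spacing {h:g} m resolves the {scene.min_gap:g} m gap with "
            "fewer than 20 cells",
            ResolutionWarning,
            stacklevel=3,
        )


def _field_from_potential(axes, V):
    grads = np.gradient(V, *axes, edge_order=1)
    if len(axes) == 2:
        return (-grads[0], -grads[1])
    return tuple(-g for g in grads)


# ---------------------------------------------------------------------------
# axisymmetric direct solver
# ---------------------------------------------------------------------------

def _solve_axisym_grid(
    r: np.ndarray,
    z: np.ndarray,
    dir_mask: np.ndarray,
    dir_vals: np.ndarray,
) -> np.ndarray:
    """Direct solve of the cylindrical 5-point Laplace system.

    Faces not covered by ``dir_mask`` get zero-flux (mirror) conditions; the
    r = 0 column, when present, gets the axis condition via the regularised
    stencil 4(V_1 - V_0)/h^2.
    """
    nr, nz = len(r), len(z)
    hr = r[1] - r[0]
    hz = z[1] - z[0]
    N = nr * nz
    idx = np.arange(N).reshape(nr, nz)
    rr = np.broadcast_to(r[:, None], (nr, nz))

    cE = np.empty((nr, nz))
    cW = np.empty((nr, nz))
    with np.errstate(divide="ignore", invalid="ignore"):
        cE[:] = 1.0 / hr**2 + 1.0 / (2.0 * rr * hr)
        cW[:] = 1.0 / hr**2 - 1.0 / (2.0 * rr * hr)
    if r[0] == 0.0:
        cE[0, :] = 4.0 / hr**2
        cW[0, :] = 0.0
    else:  # mirror at inner radial face (only used off-axis)
        cE[0, :] = cE[0, :] + cW[0, :]
        cW[0, :] = 0.0
    cW[-1, :] = 2.0 / hr**2  # mirror at outer radial face
    cE[-1, :] = 0.0
    # couplings to the j+1 ("up") and j-1 ("down") neighbours, with mirror
    # doubling on zero-flux z faces (overridden wherever the face is Dirichlet)
    cU = np.full((nr, nz), 1.0 / hz**2)
    cD = np.full((nr, nz), 1.0 / hz**2)
    cU[:, 0] = 2.0 / hz**2
    cD[:, 0] = 0.0
    cD[:, -1] = 2.0 / hz**2
    cU[:, -1] = 0.0

    diag = cE + cW + cU + cD
    free = ~dir_mask
    b = np.zeros(N)

    rows, cols, vals = [], [], []
    fidx = idx[free]
    rows.append(fidx)
    cols.append(fidx)
    vals.append(diag[free])

    def add_neighbor(coef, shift_r, shift_z):
        valid = np.zeros((nr, nz), dtype=bool)
        valid[
            max(0, -shift_r): nr - max(0, shift_r),
            max(0, -shift_z): nz - max(0, shift_z),
        ] = True
        has = valid & (coef != 0.0) & free
        rr_i = idx[has]
        cc = rr_i + shift_r * nz + shift_z
        cf = coef[has]
        nb_dir = dir_mask.ravel()[cc]
        np.add.at(b, rr_i[nb_dir], cf[nb_dir] * dir_vals.ravel()[cc[nb_dir]])
        rows.append(rr_i[~nb_dir])
        cols.append(cc[~nb_dir])
        vals.append(-cf[~nb_dir])

    add_neighbor(cE, +1, 0)
    add_neighbor(cW, -1, 0)
    add_neighbor(cU, 0, +1)
    add_neighbor(cD, 0, -1)

    didx = idx[dir_mask]
    rows.append(didx)
    cols.append(didx)
    vals.append(np.ones(len(didx)))
    b[didx] = dir_vals[dir_mask]

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(N, N),
    ).tocsc()
    V = spla.spsolve(A, b)
    return V.reshape(nr, nz)


def solve_axisymmetric(
    scene: FieldScene,
    grid: GridSpec,
    fine: Optional[GridSpec] = None,
) -> FieldSolution:
    """Solve an axisymmetric scene; optionally nested with a fine level.

    With ``fine`` given (its ``refinement_box`` is the (r, z) corner pair of
    the fine region), a coarse pass over the whole domain supplies Dirichlet
    boundary values for the fine pass, and the returned solution lives on the
    fine grid.
    """
    if scene.symmetry != AXISYMMETRIC:
        raise InvalidGeometryError("solve_axisymmetric requires an axisymmetric scene")
    lo, hi = scene.domain_lo, scene.domain_hi
    r = _make_axis(lo[0], hi[0], grid.h)
    z = _make_axis(lo[2], hi[2], grid.h)
    _check_resolution(scene, grid.h if fine is None else fine.h)
    R, Z = np.meshgrid(r, z, indexing="ij")
    mask, vals = _conductor_fields(scene, (R, Z))
    if scene.grounded_bottom:
        mask[:, 0] = True  # bottom face at domain ground
    V = _solve_axisym_grid(r, z, mask, vals)

    if fine is not None:
        if fine.refinement_box is None:
            raise ValueError("fine GridSpec must carry a refinement_box")
        (rlo, zlo), (rhi, zhi) = fine.refinement_box
        if not (lo[0] <= rlo < rhi <= hi[0] and lo[2] <= zlo < zhi <= hi[2]):
            raise InvalidGeometryError("refinement box outside the domain")
        rf = _make_axis(rlo, rhi, fine.h)
        zf = _make_axis(zlo, zhi, fine.h)
        Rf, Zf = np.meshgrid(rf, zf, indexing="ij")
        fmask, fvals = _conductor_fields(scene, (Rf, Zf))
        interp = RegularGridInterpolator((r, z), V, method="linear")
        edge = np.zeros_like(fmask)
        if rf[-1] < hi[0]:
            edge[-1, :] = True
        if zf[-1] < hi[2]:
            edge[:, -1] = True
        if zf[0] > lo[2]:
            edge[:, 0] = True
        elif scene.grounded_bottom:
            fmask[:, 0] = True
        if rf[0] > lo[0]:
            edge[0, :] = True
        edge &= ~fmask
        if np.any(edge):
            pts = np.column_stack([Rf[edge], Zf[edge]])
            fvals[edge] = interp(pts)
            fmask |= edge
        r, z, V, mask, vals = rf, zf, _solve_axisym_grid(rf, zf, fmask, fvals), fmask, fvals

    E = _field_from_potential((r, z), V)
    return FieldSolution(
        axes=(r, z),
        V=V,
        E=E,
        conductor_mask=_conductor_fields(scene, tuple(np.meshgrid(r, z, indexing="ij")))[0],
        scene=scene,
        residual=0.0,
        h=(fine.h if fine is not None else grid.h),
    )


# ---------------------------------------------------------------------------
# 3-D multigrid-preconditioned CG
# ---------------------------------------------------------------------------

def _restrict_full_weighting(r: np.ndarray) -> np.ndarray:
    # zero padding (not reflection) keeps the restriction exactly
    # proportional to the transpose of trilinear prolongation, which makes
    # the V-cycle a symmetric positive-definite preconditioner for CG
    for ax in range(3):
        pad = [(1, 1) if i == ax else (0, 0) for i in range(3)]
        ap = np.pad(r, pad, mode="constant")
        lo = [slice(None)] * 3
        mid = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -2)
        mid[ax] = slice(1, -1)
        hi[ax] = slice(2, None)
        r = 0.25 * ap[tuple(lo)] + 0.5 * ap[tuple(mid)] + 0.25 * ap[tuple(hi)]
    return r[::2, ::2, ::2]


def _prolong_trilinear(c: np.ndarray, fshape) -> np.ndarray:
    f = np.zeros(fshape)
    f[::2, ::2, ::2] = c
    f[1::2, ::2, ::2] = 0.5 * (f[:-1:2, ::2, ::2] + f[2::2, ::2, ::2])
    f[:, 1::2, ::2] = 0.5 * (f[:, :-1:2, ::2] + f[:, 2::2, ::2])
    f[:, :, 1::2] = 0.5 * (f[:, :, :-1:2] + f[:, :, 2::2])
    return f


def _assemble_weighted_7pt(mask: np.ndarray) -> sp.csc_matrix:
    """Sparse weighted 7-point operator (mirror faces, Dirichlet identity rows)."""
    sh = mask.shape
    n = int(np.prod(sh))
    idx = np.arange(n).reshape(sh)
    ws = []
    for m in sh:
        a = np.ones(m)
        a[0] = a[-1] = 0.5
        ws.append(a)
    w = ws[0][:, None, None] * ws[1][None, :, None] * ws[2][None, None, :]
    rows, cols, vals = [], [], []
    for ax in range(3):
        for sgn in (1, -1):
            src = [slice(None)] * 3
            dst = [slice(None)] * 3
            if sgn > 0:
                src[ax] = slice(0, -1)
                dst[ax] = slice(1, None)
            else:
                src[ax] = slice(1, None)
                dst[ax] = slice(0, -1)
            rows.append(idx[tuple(src)].ravel())
            cols.append(idx[tuple(dst)].ravel())
            vals.append(-w[tuple(src)].ravel())
            bsrc = [slice(None)] * 3
            bsrc[ax] = slice(0, 1) if sgn < 0 else slice(-1, None)
            binner = [slice(None)] * 3
            binner[ax] = slice(1, 2) if sgn < 0 else slice(-2, -1)
            rows.append(idx[tuple(bsrc)].ravel())
            cols.append(idx[tuple(binner)].ravel())
            vals.append(-w[tuple(bsrc)].ravel())
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    freef = ~mask.ravel()
    keep = freef[rows] & freef[cols]
    diag = np.where(freef, 6.0 * w.ravel(), 1.0)
    A = sp.coo_matrix(
        (
            np.concatenate([vals[keep], diag]),
            (
                np.concatenate([rows[keep], np.arange(n)]),
                np.concatenate([cols[keep], np.arange(n)]),
            ),
        ),
        shape=(n, n),
    )
    return A.tocsc()


class _Multigrid:
    """Geometric V-cycle preconditioner for the weighted 7-point operator."""

    def __init__(self, mask: np.ndarray, coarsest_max_nodes: int = 6_000):
        self.masks = [mask]
        sh = mask.shape
        m = mask
        while (
            all((n - 1) % 2 == 0 and n >= 5 for n in sh)
            and np.prod(sh) > coarsest_max_nodes
        ):
            m = m[::2, ::2, ::2]
            sh = m.shape
            self.masks.append(m)
        self.lu = spla.splu(_assemble_weighted_7pt(self.masks[-1]))

    def vcycle(self, b: np.ndarray, level: int = 0, nu: int = 1) -> np.ndarray:
        mask = self.masks[level]
        if level == len(self.masks) - 1:
            x = self.lu.solve(b.ravel()).reshape(mask.shape)
            x[mask] = 0.0
            return x
        x = np.zeros_like(b)
        for _ in range(nu):  # pre-smooth: red then black
            _kernels.rb_gauss_seidel(x, b, mask, 0)
            _kernels.rb_gauss_seidel(x, b, mask, 1)
        res = np.empty_like(b)
        _kernels.residual(x, b, mask, res)
        rc = 4.0 * _restrict_full_weighting(res)  # h^2 scaling between levels
        rc[self.masks[level + 1]] = 0.0
        corr = _prolong_trilinear(self.vcycle(rc, level + 1, nu), b.shape)
        corr[mask] = 0.0
        x += corr
        for _ in range(nu):  # post-smooth: black then red (symmetry)
            _kernels.rb_gauss_seidel(x, b, mask, 1)
            _kernels.rb_gauss_seidel(x, b, mask, 0)
        return x


def _solve_3d_grid(
    mask: np.ndarray,
    vals: np.ndarray,
    tol: float,
    maxiter: int,
) -> Tuple[np.ndarray, float]:
    """MG-preconditioned CG solve; returns (potential, relative residual)."""
    xd = np.where(mask, vals, 0.0)
    b = np.empty_like(xd)
    _kernels.apply_raw(xd, b)
    b = -b
    b[mask] = 0.0
    nb = float(np.sqrt(np.sum(b * b)))
    if nb == 0.0:  # all Dirichlet data zero -> zero field
        return xd.copy(), 0.0
    mg = _Multigrid(mask)
    x = np.zeros_like(b)
    r = b.copy()
    z = mg.vcycle(r)
    p = z.copy()
    rz = float(np.sum(r * z))
    Ap = np.empty_like(b)
    rel = 1.0
    for _ in range(maxiter):
        _kernels.apply_raw(p, Ap)
        Ap[mask] = 0.0
        alpha = rz / float(np.sum(p * Ap))
        x += alpha * p
        r -= alpha * Ap
        rel = float(np.sqrt(np.sum(r * r))) / nb
        if rel <= tol:
            break
        z = mg.vcycle(r)
        rz_new = float(np.sum(r * z))
        p = z + (rz_new / rz) * p
        rz = rz_new
    else:
        raise SolverError(
            f"CG did not reach tol={tol:g} in {maxiter} iterations", residual=rel
        )
    return x + xd, rel


def solve_cartesian_3d_nested(
    scene: FieldScene,
    coarse: GridSpec,
    fine: GridSpec,
) -> FieldSolution:
    """Two-level nested solve of a 3-D scene; returns the fine-level field.

    The coarse pass covers the full domain; the fine pass covers
    ``fine.refinement_box`` (snapped outward to a multigrid-friendly cell
    count) with Dirichlet boundary values interpolated from the coarse
    solution.  Conductors crossing the box boundary are pinned to their exact
    potentials, which overrides interpolation there.
    """
    if scene.symmetry != CARTESIAN3D:
        raise InvalidGeometryError("solve_cartesian_3d_nested requires a 3-D scene")
    if fine.refinement_box is None:
        raise ValueError("fine GridSpec must carry a refinement_box")
    lo = np.asarray(scene.domain_lo, float)
    hi = np.asarray(scene.domain_hi, float)
    _check_resolution(scene, fine.h)

    axes_c = tuple(_domain_axis_mult8(lo[d], hi[d], coarse.h) for d in range(3))
    hs = [a[1] - a[0] for a in axes_c]
    if max(hs) - min(hs) > 1e-9 * max(hs):
        raise InvalidGeometryError(
            "3-D solver requires an isotropic grid; choose a coarse spacing "
            "that divides all domain extents equally"
        )
    grids_c = np.meshgrid(*axes_c, indexing="ij")
    mask_c, vals_c = _conductor_fields(scene, grids_c)
    if scene.grounded_bottom:
        mask_c[:, :, 0] = True
    Vc, _ = _solve_3d_grid(mask_c, vals_c, coarse.tol, coarse.maxiter)
    interp = RegularGridInterpolator(axes_c, Vc, method="linear")

    blo = np.asarray(fine.refinement_box[0], float)
    bhi = np.asarray(fine.refinement_box[1], float)
    if np.any(blo < lo - 1e-12) or np.any(bhi > hi + 1e-12):
        raise InvalidGeometryError("refinement box outside the domain")
    axes_f = tuple(_box_axis_mult8(blo[d], bhi[d], fine.h) for d in range(3))
    for d in range(3):
        if axes_f[d][-1] > hi[d] + 1e-12:
            raise InvalidGeometryError(
                "refinement box (after snapping) exceeds the domain; "
                "shrink it or adjust the fine spacing"
            )
    grids_f = np.meshgrid(*axes_f, indexing="ij")
    mask_f, vals_f = _conductor_fields(scene, grids_f)

    edge = np.zeros(mask_f.shape, dtype=bool)
    for d in range(3):
        sl = [slice(None)] * 3
        if axes_f[d][0] > lo[d] + 1e-12:
            sl[d] = slice(0, 1)
            edge[tuple(sl)] = True
        if axes_f[d][-1] < hi[d] - 1e-12:
            sl[d] = slice(-1, None)
            edge[tuple(sl)] = True
    if scene.grounded_bottom and axes_f[2][0] <= lo[2] + 1e-12:
        mask_f[:, :, 0] = True
    edge &= ~mask_f
    if np.any(edge):
        pts = np.column_stack([g[edge] for g in grids_f])
        vals_f[edge] = interp(pts)
        mask_f |= edge

    Vf, rel = _solve_3d_grid(mask_f, vals_f, fine.tol, fine.maxiter)
    E = _field_from_potential(axes_f, Vf)
    cond_mask, _ = _conductor_fields(scene, grids_f)
    return FieldSolution(
        axes=axes_f,
        V=Vf,
        E=E,
        conductor_mask=cond_mask,
        scene=scene,
        residual=rel,
        h=fine.h,
    )


# ---------------------------------------------------------------------------
# convenience drivers for the two quantitative scenes
# ---------------------------------------------------------------------------

def rig_solution(
    gap: float,
    voltage: float,
    sphere_diameter: float = 0.015,
    h_coarse: float = 1e-3,
    h_fine: float = 5e-5,
    tol: float = 1e-8,
) -> FieldSolution:
    """Nested axisymmetric solve of the rig with a fine box around the gap."""
    scene = build_rig_scene(gap, voltage, sphere_diameter=sphere_diameter)
    z_top = 0.001 + gap + sphere_diameter + 0.005
    fine = GridSpec(
        h=h_fine, tol=tol, refinement_box=((0.0, 0.0), (0.02, z_top))
    )
    return solve_axisymmetric(scene, GridSpec(h=h_coarse, tol=tol), fine=fine)


def blade_solution(
    scene: FieldScene,
    coarse_h: float = 5e-3,
    fine_h: float = 1e-4,
    box_halfwidth: float = 0.0072,
    tol: float = 1e-8,
) -> FieldSolution:
    """Nested 3-D solve of a single-blade scene, refined around the blade tip."""
    blade = next(c for c in scene.conductors if c.name == "blade")
    blo, bhi = blade.shape.bounds()
    tip = np.array([(blo[0] + bhi[0]) / 2, 0.0, bhi[2]])
    w = box_halfwidth
    box_lo = (tip[0] - w / 2 - 0.0008, -w, tip[2] - w)
    box_hi = (tip[0] + w + (scene.min_gap or 0.0025), w, tip[2] + w)
    fine = GridSpec(h=fine_h, tol=tol, refinement_box=(box_lo, box_hi))
    return solve_cartesian_3d_nested(scene, GridSpec(h=coarse_h, tol=tol), fine)


# ---------------------------------------------------------------------------
# analytic oracles and verification utilities
# ---------------------------------------------------------------------------

def sphere_plane_axis_field(
    sphere_radius: float,
    gap: float,
    voltage: float,
    z: float,
    rel_tol: float = 1e-12,
    max_terms: int = 100_000,
) -> float:
    """On-axis field E_z of a charged sphere above a grounded plane.

    Classical image-charge construction: the sphere at potential V with its
    lowest point ``gap`` above the plane is replaced by a convergent series
    of point charges inside the sphere plus their plane images.  Returns the
    signed on-axis field component (negative of dV/dz is downward for V > 0;
    the sign follows the applied voltage) at height ``z`` above the plane,
    0 <= z <= gap.  Truncates when a term falls below ``rel_tol`` of the sum.
    """
    if not (0.0 <= z <= gap):
        raise ValueError("z must lie in the air gap [0, gap]")
    a = sphere_radius
    c = gap + a  # sphere centre height
    q = a * voltage  # k*q of the first charge (k factors cancel in E/V)
    p = c
    total = 0.0
    for _ in range(max_terms):
        term = q * (1.0 / (p - z) ** 2 + 1.0 / (p + z) ** 2)
        total += term
        if abs(total) > 0 and abs(term) <= rel_tol * abs(total):
            # dV/dz = +total, so the field component is -total: it points
            # from the sphere to the plane for V > 0 (sign follows voltage).
            return -total
        q, p = q * a / (c + p), c - a * a / (c + p)
    raise SolverError("image-charge series did not converge", residual=abs(term))


def grid_convergence_report(
    scene: FieldScene,
    probe_point: Sequence[float],
    spacings: Sequence[float],
    solve_fn: Optional[Callable[[float], FieldSolution]] = None,
) -> pd.DataFrame:
    """Probe |E| at a sequence of decreasing grid spacings.

    Returns a table (h, E_magnitude, change) with the estimated observed
    convergence order in ``df.attrs['order']``.  ``solve_fn`` maps a spacing
    to a solution; by default a single-level axisymmetric solve of ``scene``.
    """
    spacings = list(spacings)
    if len(spacings) < 3:
        raise ValueError("need at least 3 spacings for a convergence report")
    if any(b >= a for a, b in zip(spacings, spacings[1:])):
        raise ValueError("spacings must be strictly decreasing")
    if solve_fn is None:
        solve_fn = lambda h: solve_axisymmetric(scene, GridSpec(h=h))
    values = [solve_fn(h).probe_magnitude(probe_point) for h in spacings]
    changes = [np.nan] + [abs(b - a) for a, b in zip(values, values[1:])]
    df = pd.DataFrame({"h": spacings, "E_magnitude": values, "change": changes})
    e1, e2 = changes[-2], changes[-1]
    ratio = spacings[-2] / spacings[-1]
    df.attrs["order"] = (
        float(np.log(e1 / e2) / np.log(ratio)) if e2 > 0 and e1 > 0 else np.inf
    )
    return df
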