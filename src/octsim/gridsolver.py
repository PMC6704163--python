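"""Time-harmonic Helmholtz scattering on a 2D refractive-index grid.

Perpendicular polarisation is a scalar problem for the out-of-plane field,
``(laplace + k0^2 n^2(r)) E = 0``, solved with the preconditioned (convergent)
Born series: with a complex background ``kb^2 = k0^2 n_med^2 + i eps`` and
potential ``V = k0^2 n_eff^2 - kb^2`` where ``eps >= max|V|``, the fixed-point
iteration

    E <- E + (i/eps) V [ G (V E + S) - E ],      G = F^-1 (p^2 - kb^2)^-1 F

converges for arbitrary contrast.  Parallel polarisation on arbitrary maps is
the in-plane (H_z) problem ``div(1/n^2 grad H) + k0^2 H = 0``, discretized as
a sparse five-point FDFD system and solved directly (or by GMRES+ILU).

Open boundaries are modeled by an absorptive layer: a smooth polynomial ramp
of positive Im(n^2) inside ``boundary_width`` of the grid edge.  The solvers
use a scattered-field formulation with the source restricted to the physical
index contrast, so only outgoing scattered waves are absorbed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.interpolate import RectBivariateSpline
from scipy.sparse.linalg import splu

from .optics import Polarisation
from .scenes import Disc, Scene

__all__ = [
    "IndexMap",
    "SolverConfig",
    "ConvergenceError",
    "rasterize_scene",
    "helmholtz_solve",
    "born_series_solve",
    "born_series_source_solve",
    "fdfd_solve",
    "scattered_field_on_circle",
]


class ConvergenceError(RuntimeError):
    """Raised when a solver does not reach the residual tolerance."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (final relative residual {residual:.3e})")
        self.residual = residual


@dataclass
class SolverConfig:
    """Stopping and scheme controls for the Helmholtz solvers.

    ``absorption`` is the peak Im(n^2) of the boundary ramp and
    ``absorption_power`` its polynomial order; the defaults give a round-trip
    boundary reflection below 1e-4 at the design wavelength for the default
    10 um layer.
    """

    tolerance: float = 1e-6
    max_iterations: int = 10000
    scheme: str = "convergent_born"
    absorption: float = 1.2
    absorption_power: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.tolerance < 1):
            raise ValueError("tolerance must lie in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.scheme not in ("convergent_born", "gmres_fdfd"):
            raise ValueError("scheme must be 'convergent_born' or 'gmres_fdfd'")


@dataclass
class IndexMap:
    """Squared-refractive-index grid, row-major over (x, y), cell-centered.

    ``origin`` is the physical coordinate of the lower grid corner (edge of
    the first cell); cell centers sit at ``origin + (i + 1/2) dx``.
    ``boundary_width`` is the absorbing-layer thickness measured inward from
    each edge.
    """

    n2: np.ndarray
    dx: float
    origin: tuple[float, float]
    boundary_width: float
    n_med: float
    subsampling: int = 10

    @property
    def shape(self) -> tuple[int, int]:
        return self.n2.shape

    @property
    def x(self) -> np.ndarray:
        return self.origin[0] + (np.arange(self.n2.shape[0]) + 0.5) * self.dx

    @property
    def y(self) -> np.ndarray:
        return self.origin[1] + (np.arange(self.n2.shape[1]) + 0.5) * self.dx

    def boundary_ramp(self, power: int = 3) -> np.ndarray:
        """Normalized [0, 1] polynomial ramp rising inside the absorbing layer."""
        def ramp_1d(coords: np.ndarray) -> np.ndarray:
            lo, hi = coords[0] - 0.5 * self.dx, coords[-1] + 0.5 * self.dx
            d = np.minimum(coords - lo, hi - coords)
            t = np.clip(1.0 - d / max(self.boundary_width, 1e-300), 0.0, 1.0)
            return t**power

        rx = ramp_1d(self.x)
        ry = ramp_1d(self.y)
        return np.maximum.outer(rx, ry)

    def effective_n2(self, cfg: SolverConfig) -> np.ndarray:
        """Complex squared index including the absorbing boundary layer."""
        return self.n2 + 1j * cfg.absorption * self.boundary_ramp(cfg.absorption_power)

    def interior_mask(self) -> np.ndarray:
        return self.boundary_ramp(1) == 0.0

    def to_tiff(self, path: str) -> None:
        import tifffile

        tifffile.imwrite(path, self.n2.astype(np.float32))
        meta = {"dx": self.dx, "origin": list(self.origin),
                "boundary_width": self.boundary_width,
                "n_med": self.n_med, "subsampling": self.subsampling}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)

    @classmethod
    def from_tiff(cls, path: str) -> "IndexMap":
        import tifffile

        n2 = tifffile.imread(path).astype(float)
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        return cls(n2, meta["dx"], tuple(meta["origin"]),
                   meta["boundary_width"], meta["n_med"], meta["subsampling"])


def _coverage(primitive, xc: np.ndarray, yc: np.ndarray, dx: float,
              subsampling: int) -> tuple[slice, slice, np.ndarray]:
    """Sub-cell coverage fraction of a primitive over its bounding cells."""
    s = subsampling
    off = (np.arange(s) + 0.5) / s - 0.5  # sub-cell offsets in units of dx
    if isinstance(primitive, Disc):
        cx, cy = primitive.center
        x0, x1 = cx - primitive.radius, cx + primitive.radius
        y0, y1 = cy - primitive.radius, cy + primitive.radius
    else:
        x0, x1, y0, y1 = primitive.xmin, primitive.xmax, primitive.ymin, primitive.ymax
    i0 = max(0, int(np.searchsorted(xc, x0 - dx)))
    i1 = min(len(xc), int(np.searchsorted(xc, x1 + dx)))
    j0 = max(0, int(np.searchsorted(yc, y0 - dx)))
    j1 = min(len(yc), int(np.searchsorted(yc, y1 + dx)))
    if i0 >= i1 or j0 >= j1:
        raise ValueError("scene primitive outside grid")
    sx = (xc[i0:i1, None] + off[None, :] * dx).ravel()
    sy = (yc[j0:j1, None] + off[None, :] * dx).ravel()
    if isinstance(primitive, Disc):
        inside = ((sx[:, None] - cx) ** 2 + (sy[None, :] - cy) ** 2
                  <= primitive.radius**2)
    else:
        inside = ((sx[:, None] >= x0) & (sx[:, None] <= x1)
                  & (sy[None, :] >= y0) & (sy[None, :] <= y1))
    frac = inside.reshape(i1 - i0, s, j1 - j0, s).mean(axis=(1, 3))
    return slice(i0, i1), slice(j0, j1), frac


def rasterize_scene(
    scene: Scene,
    dx: float,
    subsampling: int = 10,
    boundary_width: float = 10e-6,
    padding: float = 0.0,
) -> IndexMap:
    """Permittivity-averaged rasterization of a scene onto a square-cell grid.

    Each cell's n^2 is the mean of n^2 over ``subsampling x subsampling``
    sub-cells, which reduces staircase artifacts at curved boundaries.  The
    grid covers the scene extent plus ``padding`` plus the absorbing layer on
    every side, so no primitive can touch the absorbing region.
    """
    if dx <= 0:
        raise ValueError("grid spacing must be positive")
    if subsampling < 1:
        raise ValueError("subsampling must be >= 1")
    (x0, x1), (y0, y1) = scene.extent
    pad = padding + boundary_width
    nx = int(np.ceil((x1 - x0 + 2 * pad) / dx))
    ny = int(np.ceil((y1 - y0 + 2 * pad) / dx))
    origin = (x0 - pad, y0 - pad)
    n2 = np.full((nx, ny), scene.n_med**2, dtype=float)
    imap = IndexMap(n2, dx, origin, boundary_width, scene.n_med, subsampling)
    xc, yc = imap.x, imap.y
    for p in scene.primitives:
        si, sj, frac = _coverage(p, xc, yc, dx, subsampling)
        n2[si, sj] = (1.0 - frac) * n2[si, sj] + frac * p.index**2
    return imap


def _spectral_laplacian_symbol(shape, dx: float) -> np.ndarray:
    px = 2 * np.pi * np.fft.fftfreq(shape[0], dx)
    py = 2 * np.pi * np.fft.fftfreq(shape[1], dx)
    return px[:, None] ** 2 + py[None, :] ** 2


def born_series_solve(
    imap: IndexMap,
    incident: np.ndarray,
    k0: float,
    cfg: SolverConfig | None = None,
) -> np.ndarray:
    """Convergent Born series for the scalar (perpendicular) channel.

    ``incident`` is the analytic incident field sampled on the full grid (a
    solution of the homogeneous background problem).  Returns the total
    field; the scattered part satisfies the stated relative residual of the
    (spectrally discretized) Helmholtz operator, else a
    :class:`ConvergenceError` is raised.
    """
    cfg = cfg or SolverConfig()
    if imap.dx > (2 * np.pi / k0) / 13:
        warnings.warn("grid spacing coarser than lambda/13 for this wavenumber",
                      stacklevel=2)
    source = k0**2 * (imap.n2 - imap.n_med**2) * incident
    if not np.any(source):
        return incident.astype(complex)
    return incident + born_series_source_solve(imap, source, k0, cfg)


def born_series_source_solve(
    imap: IndexMap,
    source: np.ndarray,
    k0: float,
    cfg: SolverConfig | None = None,
) -> np.ndarray:
    """Field radiated by a source density: ``(lap + k0^2 n_eff^2) E = -S``.

    The preconditioned Born iteration with the absorbing-boundary effective
    index; used both for scattering (``S = k0^2 (n^2-n_med^2) E_inc``) and
    for free sources such as line-source tests.
    """
    cfg = cfg or SolverConfig()
    n2_eff = imap.effective_n2(cfg)
    eps = 1.05 * float(np.max(np.abs(k0**2 * n2_eff - k0**2 * imap.n_med**2)))
    kb2 = k0**2 * imap.n_med**2 + 1j * eps
    v = k0**2 * n2_eff - kb2
    lap_symbol = _spectral_laplacian_symbol(imap.shape, imap.dx)
    g_symbol = 1.0 / (lap_symbol - kb2)
    gamma = (1j / eps) * v

    def green(f: np.ndarray) -> np.ndarray:
        return np.fft.ifft2(g_symbol * np.fft.fft2(f))

    e_s = np.zeros(imap.shape, dtype=complex)
    src_norm = np.linalg.norm(source)

    def residual(e: np.ndarray) -> float:
        r = (np.fft.ifft2(-lap_symbol * np.fft.fft2(e))
             + k0**2 * n2_eff * e + source)
        return float(np.linalg.norm(r) / src_norm)

    rel = np.inf
    for it in range(1, cfg.max_iterations + 1):
        e_s = e_s + gamma * (green(v * e_s + source) - e_s)
        if it % 25 == 0 or it == cfg.max_iterations:
            rel = residual(e_s)
            if rel <= cfg.tolerance:
                break
    if rel > cfg.tolerance:
        raise ConvergenceError(
            f"Born series did not converge in {cfg.max_iterations} iterations",
            rel)
    return e_s


def _fdfd_matrix(n2_eff: np.ndarray, dx: float, k0: float,
                 pol: Polarisation, n_med: float) -> sparse.csr_matrix:
    nx, ny = n2_eff.shape
    idx = np.arange(nx * ny).reshape(nx, ny)
    inv_dx2 = 1.0 / dx**2
    rows, cols, vals = [], [], []

    if pol is Polarisation.PERPENDICULAR:
        # standard 5-point Laplacian + k0^2 n^2
        diag = np.full((nx, ny), -4.0 * inv_dx2, dtype=complex)
        diag += k0**2 * n2_eff
        for shift, axis in (((1, 0), 0), ((-1, 0), 0), ((0, 1), 1), ((0, -1), 1)):
            src = np.roll(idx, (-shift[0], -shift[1]), axis=(0, 1))
            mask = np.ones((nx, ny), dtype=bool)
            if shift[0] == 1:
                mask[-1, :] = False
            if shift[0] == -1:
                mask[0, :] = False
            if shift[1] == 1:
                mask[:, -1] = False
            if shift[1] == -1:
                mask[:, 0] = False
            rows.append(idx[mask]); cols.append(src[mask])
            vals.append(np.full(mask.sum(), inv_dx2, dtype=complex))
        rows.append(idx.ravel()); cols.append(idx.ravel()); vals.append(diag.ravel())
    else:
        # div( (1/eps) grad H ) + k0^2 H, harmonic face averages of 1/eps
        def face(a: np.ndarray, b: np.ndarray) -> np.ndarray:
            return 2.0 / (a + b)  # harmonic mean of 1/eps_a, 1/eps_b

        cxp = np.zeros((nx, ny), dtype=complex)
        cxm = np.zeros((nx, ny), dtype=complex)
        cyp = np.zeros((nx, ny), dtype=complex)
        cym = np.zeros((nx, ny), dtype=complex)
        cxp[:-1, :] = face(n2_eff[:-1, :], n2_eff[1:, :]) * inv_dx2
        cxm[1:, :] = face(n2_eff[1:, :], n2_eff[:-1, :]) * inv_dx2
        cyp[:, :-1] = face(n2_eff[:, :-1], n2_eff[:, 1:]) * inv_dx2
        cym[:, 1:] = face(n2_eff[:, 1:], n2_eff[:, :-1]) * inv_dx2
        diag = -(cxp + cxm + cyp + cym) + k0**2
        for coeff, shift in ((cxp, (1, 0)), (cxm, (-1, 0)),
                             (cyp, (0, 1)), (cym, (0, -1))):
            src = np.roll(idx, (-shift[0], -shift[1]), axis=(0, 1))
            mask = coeff != 0
            rows.append(idx[mask]); cols.append(src[mask]); vals.append(coeff[mask])
        rows.append(idx.ravel()); cols.append(idx.ravel()); vals.append(diag.ravel())

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(nx * ny, nx * ny))


def fdfd_solve(
    imap: IndexMap,
    incident: np.ndarray,
    k0: float,
    pol: Polarisation,
    cfg: SolverConfig | None = None,
) -> np.ndarray:
    """Sparse frequency-domain solve, both polarisation channels.

    Scattered-field formulation: the discrete source is
    ``(A_background - A_physical) u_inc`` (supported on the index contrast),
    and the scattered field is obtained from the full absorbing-boundary
    operator by a direct sparse LU solve.
    """
    cfg = cfg or SolverConfig(scheme="gmres_fdfd")
    n2_eff = imap.effective_n2(cfg)
    n2_bg = np.full(imap.shape, imap.n_med**2, dtype=complex)
    a_full = _fdfd_matrix(n2_eff, imap.dx, k0, pol, imap.n_med)
    a_phys = _fdfd_matrix(imap.n2.astype(complex), imap.dx, k0, pol, imap.n_med)
    a_bg = _fdfd_matrix(n2_bg, imap.dx, k0, pol, imap.n_med)
    u_inc = incident.ravel().astype(complex)
    rhs = (a_bg - a_phys) @ u_inc
    if not np.any(rhs):
        return incident.astype(complex)
    lu = splu(a_full.tocsc())
    u_s = lu.solve(rhs)
    rel = float(np.linalg.norm(a_full @ u_s - rhs) / np.linalg.norm(rhs))
    if rel > max(cfg.tolerance, 1e-9):
        raise ConvergenceError("FDFD direct solve residual above tolerance", rel)
    return (u_inc + u_s).reshape(imap.shape)


def helmholtz_solve(
    imap: IndexMap,
    incident: np.ndarray,
    k0: float,
    cfg: SolverConfig | None = None,
    pol: Polarisation = Polarisation.PERPENDICULAR,
) -> np.ndarray:
    """Total field on the grid for vacuum wavenumber ``k0``.

    Dispatches to the convergent Born series (scalar, perpendicular channel)
    or the sparse FDFD solve; the parallel channel always uses FDFD.
    """
    cfg = cfg or SolverConfig()
    if incident.shape != imap.shape:
        raise ValueError("incident field must be sampled on the map grid")
    if pol is Polarisation.PARALLEL or cfg.scheme == "gmres_fdfd":
        return fdfd_solve(imap, incident, k0, pol, cfg)
    return born_series_solve(imap, incident, k0, cfg)


def scattered_field_on_circle(
    imap: IndexMap,
    scattered: np.ndarray,
    radius: float,
    center: tuple[float, float] = (0.0, 0.0),
    n_points: int | None = None,
    spline_order: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a grid field onto a circle for the near-to-far transform.

    The circle must stay inside the non-absorbing region and outside all
    index contrast; at least 8 sample points per in-medium wavelength of arc
    are used by default.
    """
    interior = imap.interior_mask()
    xs, ys = imap.x, imap.y
    if (center[0] - radius < xs[np.argmax(interior.any(axis=1))]
            or center[0] + radius > xs[::-1][np.argmax(interior.any(axis=1)[::-1])]
            or center[1] - radius < ys[np.argmax(interior.any(axis=0))]
            or center[1] + radius > ys[::-1][np.argmax(interior.any(axis=0)[::-1])]):
        raise ValueError("sampling circle intersects the absorbing layer")
    if n_points is None:
        n_points = int(2 ** np.ceil(np.log2(max(64, 16 * radius / imap.dx))))
    phi = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    px = center[0] + radius * np.cos(phi)
    py = center[1] + radius * np.sin(phi)
    sp_r = RectBivariateSpline(xs, ys, scattered.real, kx=spline_order, ky=spline_order)
    sp_i = RectBivariateSpline(xs, ys, scattered.imag, kx=spline_order, ky=spline_order)
    vals = sp_r.ev(px, py) + 1j * sp_i.ev(px, py)
    return phi, vals
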