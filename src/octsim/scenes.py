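"""Sample geometries: single/multiple cylinders, ziggurats, dentin-tubule slabs.

A :class:`Scene` is a background index plus a list of geometric primitives
(discs and axis-aligned rectangles) with their refractive indices.  Scenes are
consumed either by the analytic cylinder path (disc primitives only) or
rasterized onto a squared-index grid for the Helmholtz solvers.

The dentin phantoms emulate water-filled tubules (n = 1.33) in a dentin
matrix (n = 1.52); the background is dentin everywhere so the air-dentin
surface reflection is suppressed.  The mean-free-path diagnostic
``L = pi a^2 / (C_sca f)`` with area concentration ``f = N pi a^2/(Lx Ly)``
uses the exact infinite-cylinder scattering cross section at the in-medium
wavelength.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np

from .cylinder import cylinder_series_coefficients, scattering_cross_section
from .optics import Polarisation

__all__ = [
    "Disc",
    "Rectangle",
    "Scene",
    "PhantomSpec",
    "make_single_cylinder",
    "echo_separation",
    "make_cylinder_cluster",
    "make_ziggurat",
    "make_dentin_slab",
    "mean_free_path",
]


@dataclass(frozen=True)
class Disc:
    """Circular cylinder cross section: center (x, y) in m, radius in m."""

    center: tuple[float, float]
    radius: float
    index: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("disc radius must be positive")
        if self.index < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned rectangle: bounds in m."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    index: float

    def __post_init__(self) -> None:
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError("degenerate rectangle bounds")
        if self.index < 1:
            raise ValueError("refractive index must be >= 1")


@dataclass
class Scene:
    """Background medium plus a list of index primitives.

    ``extent`` is ((xmin, xmax), (ymin, ymax)); all primitives must lie
    inside.  ``metadata`` carries generator provenance (seed, achieved
    displacements, ...) and travels with JSON serialization.
    """

    primitives: list
    n_med: float
    extent: tuple[tuple[float, float], tuple[float, float]]
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_med < 1:
            raise ValueError("background index must be >= 1")
        (x0, x1), (y0, y1) = self.extent
        for p in self.primitives:
            if isinstance(p, Disc):
                cx, cy = p.center
                inside = (x0 <= cx - p.radius and cx + p.radius <= x1
                          and y0 <= cy - p.radius and cy + p.radius <= y1)
            else:
                inside = (x0 <= p.xmin and p.xmax <= x1
                          and y0 <= p.ymin and p.ymax <= y1)
            if not inside:
                raise ValueError("scene primitive outside the stated extent")

    @property
    def discs(self) -> list[Disc]:
        return [p for p in self.primitives if isinstance(p, Disc)]

    def to_json(self) -> str:
        def enc(p):
            if isinstance(p, Disc):
                return {"type": "disc", "center": list(p.center),
                        "radius": p.radius, "index": p.index}
            return {"type": "rectangle", "bounds": [p.xmin, p.xmax, p.ymin, p.ymax],
                    "index": p.index}

        return json.dumps({
            "n_med": self.n_med,
            "extent": [list(self.extent[0]), list(self.extent[1])],
            "primitives": [enc(p) for p in self.primitives],
            "metadata": self.metadata,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Scene":
        d = json.loads(text)
        prims = []
        for p in d["primitives"]:
            if p["type"] == "disc":
                prims.append(Disc(tuple(p["center"]), p["radius"], p["index"]))
            else:
                prims.append(Rectangle(*p["bounds"], p["index"]))
        ext = (tuple(d["extent"][0]), tuple(d["extent"][1]))
        return cls(prims, d["n_med"], ext, d.get("metadata", {}))


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a randomized multi-cylinder phantom.

    ``region`` is either ``("disc", cx, cy, R)`` or
    ``("rectangle", xmin, xmax, ymin, ymax)``.  ``jitter`` (per-axis maximum
    displacement, m) switches the cluster generator from the symmetric
    lattice to the jittered-lattice mode.
    """

    n_cyl_count: int
    region: tuple
    radius: float
    index: float
    seed: int = 0
    allow_overlap: bool = True
    jitter: tuple[float, float] | None = None
    arrangement: str = "lattice"  # "lattice" or "uniform"

    def __post_init__(self) -> None:
        if self.n_cyl_count < 0:
            raise ValueError("cylinder count must be >= 0")
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.region[0] not in ("disc", "rectangle"):
            raise ValueError("region must be a disc or a rectangle")
        if self.arrangement not in ("lattice", "uniform"):
            raise ValueError("arrangement must be 'lattice' or 'uniform'")


def make_single_cylinder(
    a: float,
    n_cyl: float,
    n_med: float,
    center: tuple[float, float] = (0.0, 0.0),
    margin: float | None = None,
) -> Scene:
    """Scene with one cylindrical scatterer centered at ``center``.

    The predicted optical separation of the front and back surface echoes,
    ``d = 2 a n_cyl/n_med``, is stored in ``scene.metadata['echo_separation']``.
    """
    if a <= 0:
        raise ValueError("cylinder radius must be positive")
    m = 2 * a if margin is None else margin
    ext = ((center[0] - a - m, center[0] + a + m),
           (center[1] - a - m, center[1] + a + m))
    return Scene([Disc(center, a, n_cyl)], n_med, ext,
                 {"echo_separation": echo_separation(a, n_cyl, n_med)})


def echo_separation(a: float, n_cyl: float, n_med: float) -> float:
    """Optical front-to-back echo distance ``2 a n_cyl / n_med`` (m)."""
    return 2.0 * a * n_cyl / n_med


def _hex_lattice_in_disc(count: int, cx: float, cy: float, big_r: float,
                         radius: float) -> np.ndarray:
    """Mirror-symmetric (about y = 0 through the center) hexagonal fill.

    Points are added in whole symmetry orbits (a point on the axis, or a
    ±y pair) in order of distance from the center, so the result is exactly
    symmetric for any count that the orbit structure can realize.
    """
    if count == 0:
        return np.zeros((0, 2))
    # pitch chosen so that the hex fill of the disc offers >= count sites
    pitch = max(2.05 * radius,
                np.sqrt(2 * np.pi / (np.sqrt(3) * max(count, 1))) * big_r * 0.95)
    pts = []
    nrow = int(np.ceil(big_r / (pitch * np.sqrt(3) / 2))) + 2
    ncol = int(np.ceil(big_r / pitch)) + 2
    for i in range(-nrow, nrow + 1):
        x = i * pitch * np.sqrt(3) / 2
        offset = 0.0 if i % 2 == 0 else 0.5
        for j in range(-ncol, ncol + 1):
            y = (j + offset) * pitch
            if np.hypot(x, y) <= big_r - radius:
                pts.append((x, y))
    pts = np.array(pts)
    if len(pts) < count:
        raise ValueError("phantom region too small for the requested count")
    # group into symmetry orbits about y = 0
    r2 = np.hypot(pts[:, 0], pts[:, 1])
    order = np.argsort(r2, kind="stable")
    pts = pts[order]
    used = np.zeros(len(pts), dtype=bool)
    chosen: list[np.ndarray] = []
    singles_backlog: list[int] = []
    for i in range(len(pts)):
        if used[i] or len(chosen) >= count:
            continue
        x, y = pts[i]
        if abs(y) < 1e-12 * max(big_r, 1e-9):
            chosen.append(pts[i])
            used[i] = True
            continue
        # find mirror partner
        d = np.hypot(pts[:, 0] - x, pts[:, 1] + y)
        j = int(np.argmin(d))
        if len(chosen) + 2 <= count:
            chosen.append(pts[i])
            chosen.append(pts[j])
            used[i] = used[j] = True
        else:
            singles_backlog.append(i)
    k = 0
    while len(chosen) < count and k < len(pts):
        # odd remainder: fill with on-axis sites further out
        if not used[k] and abs(pts[k, 1]) < 1e-12 * max(big_r, 1e-9):
            chosen.append(pts[k])
            used[k] = True
        k += 1
    if len(chosen) < count:
        raise ValueError("cannot realize a symmetric arrangement with this count")
    return np.array(chosen) + np.array([cx, cy])


def _no_overlap(centers: np.ndarray, radius: float) -> bool:
    if len(centers) < 2:
        return True
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return bool(np.min(d) >= 2 * radius)


def make_cylinder_cluster(spec: PhantomSpec) -> Scene:
    """Cluster of identical cylinders in a disc (or rectangular) region.

    Modes:

    * ``arrangement='lattice'``, no jitter: deterministic mirror-symmetric
      hexagonal arrangement (stand-in for the published symmetric
      83-cylinder figure, whose coordinates are not tabulated);
    * with ``jitter=(jx, jy)``: each lattice site is displaced by independent
      uniform draws in ``[-jx, jx] x [-jy, jy]`` (seeded);
    * ``arrangement='uniform'``: centers drawn uniformly in the region.

    Achieved displacement statistics are reported in ``scene.metadata``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.region[0] == "disc":
        _, cx, cy, big_r = spec.region
        ext = ((cx - big_r, cx + big_r), (cy - big_r, cy + big_r))
        area = np.pi * big_r**2
    else:
        _, x0, x1, y0, y1 = spec.region
        ext = ((x0, x1), (y0, y1))
        area = (x1 - x0) * (y1 - y0)
        cx, cy = 0.5 * (x0 + x1), 0.5 * (y0 + y1)
    if not spec.allow_overlap and spec.n_cyl_count * np.pi * spec.radius**2 > area:
        raise ValueError("region area too small for non-overlapping placement")

    meta: dict = {"seed": spec.seed, "count": spec.n_cyl_count}
    if spec.n_cyl_count == 0:
        return Scene([], spec_background(spec), ext, meta)

    if spec.arrangement == "uniform":
        centers = _uniform_centers(spec, rng, ext)
        disp = None
    else:
        if spec.region[0] == "disc":
            base = _hex_lattice_in_disc(spec.n_cyl_count, cx, cy, big_r, spec.radius)
        else:
            base = _rect_lattice(spec, ext)
        centers = base.copy()
        disp = None
        if spec.jitter is not None:
            jx, jy = spec.jitter
            for _ in range(200):
                shift = np.column_stack([
                    rng.uniform(-jx, jx, len(base)),
                    rng.uniform(-jy, jy, len(base)),
                ])
                centers = base + shift
                if spec.allow_overlap or _no_overlap(centers, spec.radius):
                    break
            else:
                raise RuntimeError("placement failed: could not avoid overlap")
            disp = np.linalg.norm(shift, axis=1)
            meta.update({
                "min_shift_x": float(np.min(np.abs(shift[:, 0]))),
                "max_shift_x": float(np.max(np.abs(shift[:, 0]))),
                "min_shift_y": float(np.min(np.abs(shift[:, 1]))),
                "max_shift_y": float(np.max(np.abs(shift[:, 1]))),
            })
    if disp is not None:
        meta.update({
            "min_shift": float(np.min(disp)),
            "max_shift": float(np.max(disp)),
            "mean_shift": float(np.mean(disp)),
        })
    # grow the extent if jitter pushed a disc over the edge
    (ex0, ex1), (ey0, ey1) = ext
    pad_x = max(0.0, np.max(centers[:, 0] + spec.radius - ex1, initial=0.0),
                np.max(ex0 - (centers[:, 0] - spec.radius), initial=0.0))
    pad_y = max(0.0, np.max(centers[:, 1] + spec.radius - ey1, initial=0.0),
                np.max(ey0 - (centers[:, 1] - spec.radius), initial=0.0))
    ext = ((ex0 - pad_x, ex1 + pad_x), (ey0 - pad_y, ey1 + pad_y))
    prims = [Disc((float(x), float(y)), spec.radius, spec.index) for x, y in centers]
    return Scene(prims, spec_background(spec), ext, meta)


def spec_background(spec: PhantomSpec, default: float = 1.35) -> float:
    """Background index attached to a phantom spec (default tissue-like 1.35)."""
    return getattr(spec, "n_med", default)


def _uniform_centers(spec: PhantomSpec, rng, ext) -> np.ndarray:
    (x0, x1), (y0, y1) = ext
    centers: list[np.ndarray] = []
    attempts = 0
    max_attempts = 1000 * max(spec.n_cyl_count, 1)
    while len(centers) < spec.n_cyl_count:
        if attempts > max_attempts:
            raise RuntimeError("placement failed after bounded retries")
        attempts += 1
        if spec.region[0] == "disc":
            _, cx, cy, big_r = spec.region
            r = (big_r - spec.radius) * np.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * np.pi)
            c = np.array([cx + r * np.cos(phi), cy + r * np.sin(phi)])
        else:
            c = np.array([rng.uniform(x0 + spec.radius, x1 - spec.radius),
                          rng.uniform(y0 + spec.radius, y1 - spec.radius)])
        if not spec.allow_overlap and centers:
            d = np.linalg.norm(np.array(centers) - c, axis=1)
            if np.min(d) < 2 * spec.radius:
                continue
        centers.append(c)
    return np.array(centers)


def _rect_lattice(spec: PhantomSpec, ext) -> np.ndarray:
    (x0, x1), (y0, y1) = ext
    n = spec.n_cyl_count
    aspect = (x1 - x0) / (y1 - y0)
    nx = max(1, int(np.round(np.sqrt(n * aspect))))
    ny = int(np.ceil(n / nx))
    gx = np.linspace(x0 + spec.radius * 2, x1 - spec.radius * 2, nx)
    gy = np.linspace(y0 + spec.radius * 2, y1 - spec.radius * 2, ny)
    pts = np.array([(x, y) for x in gx for y in gy])
    return pts[:n]


def make_ziggurat(
    plateau_widths,
    step_height: float,
    index: float,
    n_med: float,
    x_top: float = 0.0,
    margin: float | None = None,
) -> Scene:
    """Stepped (ziggurat) scatterer: stacked slabs, widest deepest.

    ``plateau_widths`` must be strictly decreasing (full lateral widths, m);
    the narrowest plateau faces the incident beam at depth ``x_top``, each
    subsequent slab of thickness ``step_height`` is wider.  Top surface
    normals are along the optical axis, mirror-symmetric about y = 0.
    """
    widths = np.asarray(plateau_widths, dtype=float)
    if np.any(np.diff(widths) >= 0):
        raise ValueError("plateau widths must be strictly decreasing")
    if step_height <= 0:
        raise ValueError("step height must be positive")
    rects = []
    for j, w in enumerate(widths[::-1]):
        rects.append(Rectangle(x_top + j * step_height,
                               x_top + (j + 1) * step_height,
                               -w / 2, w / 2, index))
    m = widths[0] if margin is None else margin
    depth = len(widths) * step_height
    ext = ((x_top - m, x_top + depth + m), (-widths[0] / 2 - m, widths[0] / 2 + m))
    return Scene(rects, n_med, ext, {"stepped_area": float(np.sum(widths) * step_height)})


def make_dentin_slab(
    spec: PhantomSpec,
    n_dentin: float = 1.52,
    n_tubule: float = 1.33,
) -> Scene:
    """Dentin slab with water-filled tubules as disc inclusions.

    The background is dentin (1.52) everywhere so that no air-dentin surface
    reflection appears; tubules (default radius from ``spec``, index 1.33)
    are placed uniformly at random in the slab, seeded and reproducible.
    """
    if spec.region[0] != "rectangle":
        raise ValueError("dentin slab requires a rectangular region")
    rng = np.random.default_rng(spec.seed)
    _, x0, x1, y0, y1 = spec.region
    ext = ((x0, x1), (y0, y1))
    meta = {"seed": spec.seed, "count": spec.n_cyl_count,
            "concentration": concentration_factor(spec.n_cyl_count, spec.radius,
                                                  x1 - x0, y1 - y0)}
    if spec.n_cyl_count == 0:
        return Scene([], n_dentin, ext, meta)
    centers = _uniform_centers(
        PhantomSpec(spec.n_cyl_count, spec.region, spec.radius, n_tubule,
                    spec.seed, spec.allow_overlap, arrangement="uniform"),
        rng, ext)
    prims = [Disc((float(x), float(y)), spec.radius, n_tubule) for x, y in centers]
    return Scene(prims, n_dentin, ext, meta)


def concentration_factor(count: int, a: float, lx: float, ly: float) -> float:
    """Area concentration ``f = N pi a^2/(Lx Ly)``."""
    return count * np.pi * a**2 / (lx * ly)


def mean_free_path(
    a: float,
    n_cyl: float,
    n_med: float,
    lambda0: float,
    count: int,
    lx: float,
    ly: float,
    pol: Polarisation = Polarisation.PERPENDICULAR,
) -> float:
    """Scattering mean free path ``L = pi a^2/(C_sca f)`` in a cylinder slab.

    ``C_sca`` is the exact infinite-cylinder scattering cross section at the
    in-medium wavelength ``lambda0/n_med``.
    """
    if min(a, n_cyl, n_med, lambda0, lx, ly) <= 0 or count <= 0:
        raise ValueError("all mean-free-path arguments must be positive")
    k_med = 2 * np.pi * n_med / lambda0
    if n_cyl == n_med:
        raise ZeroDivisionError("no index contrast: scattering cross section is zero")
    bn = cylinder_series_coefficients(n_cyl / n_med, k_med * a, pol)
    c_sca = scattering_cross_section(bn, k_med)
    f = concentration_factor(count, a, lx, ly)
    return float(np.pi * a**2 / (c_sca * f))
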