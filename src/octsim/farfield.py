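"""Far-field amplitudes on the collection circle and near-to-far transforms.

The far-field normalization throughout the package is

    E(l, phi) ~ A(phi) * sqrt(2/(pi k l)) * exp(i k l)      for k l >> 1,

the large-argument form of the outgoing 2D Green's function.  Two routes
produce ``A``:

* the source (volume) integral over the scattering potential, used for grid
  solutions because it is discretization-consistent and needs no derivatives;
* an angular-harmonic expansion of the outgoing field on a circle enclosing
  all contrast: on such a circle ``E_s = sum_n c_n H_n^(1)(kR) e^{in phi}``,
  so ``A(phi) = e^{-i pi/4} sum_n c_n e^{-i n pi/2} e^{in phi}`` — the
  Green's-function contour integral resummed, requiring field values only.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass

import numpy as np
from scipy import special

from .optics import Polarisation

__all__ = ["FarField", "near_to_far", "far_field_from_sources"]


@dataclass
class FarField:
    """Complex angular amplitudes on the collection circle for one wavenumber."""

    angles: np.ndarray
    amplitudes: np.ndarray
    k: float
    polarisation: Polarisation

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        if self.angles.shape != self.amplitudes.shape:
            raise ValueError("angles and amplitudes must have equal length")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("non-finite far-field amplitudes")
        if self.angles.size > 1 and np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    def to_csv(self) -> str:
        buf = io.StringIO()
        w = csv.writer(buf)
        w.writerow(["angle_rad", "re", "im"])
        for a, amp in zip(self.angles, self.amplitudes):
            w.writerow([repr(float(a)), repr(float(amp.real)), repr(float(amp.imag))])
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str, k: float,
                 pol: Polarisation = Polarisation.PERPENDICULAR) -> "FarField":
        rows = list(csv.reader(io.StringIO(text)))[1:]
        ang = np.array([float(r[0]) for r in rows])
        amp = np.array([float(r[1]) + 1j * float(r[2]) for r in rows])
        return cls(ang, amp, k, pol)


def near_to_far(
    values_on_circle: np.ndarray,
    radius: float,
    k_med: float,
    angles_out: np.ndarray | None = None,
    n_harmonics: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Far-field amplitudes from the scattered field sampled on a circle.

    ``values_on_circle`` are the scattered (total minus incident) field values
    at uniformly spaced polar angles ``phi_j = 2 pi j / n`` on a circle of
    ``radius`` enclosing all index contrast.  Returns ``(angles, A)``.

    Orders beyond ``kR`` plus a small evanescent margin are discarded: their
    Hankel functions are exponentially large on the circle, so dividing by
    them would amplify sampling noise while contributing nothing outgoing.
    """
    v = np.asarray(values_on_circle, dtype=complex)
    n = v.size
    if radius <= 0:
        raise ValueError("contour radius must be positive")
    kr = k_med * radius
    nmax_default = int(kr + 8 * kr ** (1 / 3) + 10)
    nmax = min(n // 2 - 1, nmax_default if n_harmonics is None else n_harmonics)
    c = np.fft.fft(v) / n  # c[m] multiplies e^{+i m phi} with m = fft order
    orders = np.fft.fftfreq(n, 1.0 / n).astype(int)
    keep = np.abs(orders) <= nmax
    m = orders[keep]
    cm = c[keep] / special.hankel1(m, kr)
    if angles_out is None:
        angles_out = np.linspace(0, 2 * np.pi, n, endpoint=False)
    angles_out = np.asarray(angles_out, dtype=float)
    phase = np.exp(1j * np.multiply.outer(angles_out, m))
    amps = phase @ (cm * np.exp(-1j * m * np.pi / 2))
    return angles_out, np.exp(-1j * np.pi / 4) * amps


def far_field_from_sources(
    potential_times_field: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    dx: float,
    k_med: float,
    angles: np.ndarray,
) -> np.ndarray:
    """Far-field amplitude from the volume source density ``V * E_total``.

    ``potential_times_field`` is ``k0^2 (n^2 - n_med^2) E_tot`` on the grid
    ``x[:, None] x y[None, :]``;  A(phi) = (i/4) e^{-i pi/4}
    sum V E exp(-i k_med q(phi).r) dx^2.
    """
    angles = np.asarray(angles, dtype=float)
    src = np.asarray(potential_times_field)
    ix, iy = np.nonzero(src)
    if ix.size == 0:
        return np.zeros_like(angles, dtype=complex)
    vals = src[ix, iy]
    xs, ys = x[ix], y[iy]
    phase = np.exp(-1j * k_med * (np.multiply.outer(np.cos(angles), xs)
                                  + np.multiply.outer(np.sin(angles), ys)))
    return 0.25j * np.exp(-1j * np.pi / 4) * (phase @ vals) * dx * dx
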