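"""Source, lens train and focusing optics of the two-dimensional interferometer.

The sample and reference arms share the same afocal, telecentric lens pair
(L1/L2 and L3/L4): a weakly guiding fiber emits a Gaussian mode, an angular
spectrum of plane waves propagates it to the first lens, a paraxial Fresnel
integral carries it through the lens to the common focal midplane (where the
aperture stop sits), and a one-dimensional (cylindrical-lens) Debye-Wolf
integral produces the rigorous focused field in the sample space.  The mirror
in the reference arm is handled in closed form: in the far-field limit every
angular component of the focused beam returns as exactly one outgoing
cylindrical wave per angle.

Conventions
-----------
* ``x`` is the optical axis, increasing into the sample; ``y`` is lateral.
  The beam focus is the origin of the sample-space coordinates.
* All quantities are SI (meters, rad/m); fields are in arbitrary linear units.
* A time dependence ``exp(-i omega t)`` is implied, so outgoing cylindrical
  waves carry ``exp(+ikl)``.
* Global lens-train phases (``exp(i k f)`` factors) are kept explicitly; they
  are common to both arms and cancel in the normalized tomogram.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT",
    "FiberMode",
    "Polarisation",
    "OpticalSystem",
    "FocusedBeam",
    "FocusedBeamSpectrum",
    "fiber_mode_field",
    "field_on_first_lens",
    "midplane_field",
    "aperture_half_angle",
    "angular_quadrature",
    "beam_angular_amplitude",
    "debye_wolf_prefactor",
    "focused_beam_spectrum",
    "debye_wolf_focus",
    "reference_arm_far_field",
    "reference_collection_amplitude",
]

SPEED_OF_LIGHT = 299_792_458.0


class Polarisation(str, Enum):
    """Incident polarisation channel.

    ``PERPENDICULAR`` is the out-of-plane field (E along the cylinder axis,
    a scalar Helmholtz problem for ``E_z``); ``PARALLEL`` is the in-plane
    field (tracked through the scalar ``H_z``).  The two channels do not mix
    in a two-dimensional geometry.
    """

    PERPENDICULAR = "perpendicular"
    PARALLEL = "parallel"


@dataclass(frozen=True)
class FiberMode:
    """Gaussian mode of the weakly guiding illumination/detection fiber.

    Parameters
    ----------
    w0 : float
        Half of the fiber's mode-field diameter (m).
    E0 : complex
        Peak field amplitude (arbitrary units).
    """

    w0: float = 4.6e-6
    E0: complex = 1.0

    def __post_init__(self) -> None:
        if not (self.w0 > 0):
            raise ValueError("fiber mode radius w0 must be positive")
        if not np.isfinite(self.E0) or self.E0 == 0:
            raise ValueError("fiber peak amplitude E0 must be finite and nonzero")


@dataclass(frozen=True)
class OpticalSystem:
    """Geometry of the matched lens trains in both interferometer arms.

    ``f1`` is the focal length of the fiber-side lenses L1/L3, ``f2`` that of
    the sample/mirror-side lenses L2/L4, ``h`` the radius of the aperture stop
    in the common focal midplane.  ``n_med`` is the background refractive
    index of the sample space.  ``n_debye`` is the index used when converting
    the aperture radius into the angular limits of the Debye-Wolf integral;
    the default 1 widens the angular window relative to ``arcsin(h/(f2 n))``
    and suppresses truncation side lobes of the focused beam.
    """

    f1: float = 25e-3
    f2: float = 36e-3
    h: float = 3.5e-3
    n_med: float = 1.35
    n_debye: float = 1.0

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 < self.h < self.f2 * self.n_debye):
            raise ValueError("invalid geometry: require 0 < h < f2*n_debye")
        if self.n_med < 1:
            raise ValueError("background index must be >= 1")

    @property
    def alpha_max(self) -> float:
        """Aperture half-angle in sample space (rad), via the sine condition."""
        return float(np.arcsin(self.h / (self.f2 * self.n_debye)))


@dataclass(frozen=True)
class FocusedBeamSpectrum:
    """Angular-spectrum representation of the focused beam for one wavenumber.

    The sample-space field is
    ``E(x, y) = sum_j weights_j * amplitude_j * exp(i k_sample (y sin th_j + x cos th_j))``
    where the Debye-Wolf prefactor is already folded into ``amplitude``.
    """

    theta: np.ndarray
    weights: np.ndarray
    amplitude: np.ndarray
    k: float          # vacuum wavenumber (rad/m)
    k_sample: float   # propagation constant in the sample medium (rad/m)
    polarisation: Polarisation

    def field(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Scalar channel field (E_z or H_z) at sample-space points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        phase = np.exp(
            1j * self.k_sample
            * (np.multiply.outer(y, np.sin(self.theta))
               + np.multiply.outer(x, np.cos(self.theta)))
        )
        return phase @ (self.weights * self.amplitude)

    def field_on_grid(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Field on the tensor grid ``x[:, None] × y[None, :]`` (row-major x, y)."""
        cx = np.exp(1j * self.k_sample * np.multiply.outer(np.asarray(x), np.cos(self.theta)))
        cy = np.exp(1j * self.k_sample * np.multiply.outer(np.asarray(y), np.sin(self.theta)))
        return np.einsum("j,xj,yj->xy", self.weights * self.amplitude, cx, cy)


@dataclass(frozen=True)
class FocusedBeam:
    """Sampled focused field: complex values on stated sample-space points."""

    k: float
    x: np.ndarray
    y: np.ndarray
    samples: np.ndarray
    polarisation: Polarisation


def fiber_mode_field(y, mode: FiberMode):
    """Field emitted at the fiber end face: ``E0 exp(-y^2/w0^2)``."""
    y = np.asarray(y, dtype=float)
    return mode.E0 * np.exp(-(y**2) / mode.w0**2)


def field_on_first_lens(y, k: float, mode: FiberMode, sys: OpticalSystem):
    """Closed-form field incident on L1/L3 after free propagation over f1.

    Gaussian with complex width ``2i f1/k + w0^2``; derives from the
    two-dimensional angular spectrum of plane waves in paraxial approximation.
    """
    y = np.asarray(y, dtype=float)
    q = 2j * sys.f1 / k + mode.w0**2
    return mode.E0 * mode.w0 / np.sqrt(q) * np.exp(1j * k * sys.f1 - y**2 / q)


def midplane_field(y, k: float, mode: FiberMode, sys: OpticalSystem):
    """Field in the common focal midplane of L1 and L2 (paraxial Fresnel focus).

    ``(1-i) w0 E0 sqrt(pi)/sqrt(2 f1 lambda) e^{2ikf1} e^{-(y k w0/(2 f1))^2}``;
    a Gaussian of 1/e half-width ``2 f1/(k w0)``.  Lens thickness is neglected.
    """
    y = np.asarray(y, dtype=float)
    lam = 2 * np.pi / k
    amp = (1 - 1j) * mode.w0 * mode.E0 * np.sqrt(np.pi) / np.sqrt(2 * sys.f1 * lam)
    return amp * np.exp(2j * k * sys.f1 - (y * k * mode.w0 / (2 * sys.f1)) ** 2)


def aperture_half_angle(sys: OpticalSystem) -> float:
    """Aperture half-angle ``arcsin(h/f2)`` from the sine condition.

    The tangent convention ``arctan(h/f2)`` differs by <0.5% at this NA and is
    not used.
    """
    if sys.h >= sys.f2:
        raise ValueError("invalid geometry: aperture radius must satisfy h < f2")
    return float(np.arcsin(sys.h / sys.f2))


def angular_quadrature(sys: OpticalSystem, n_nodes: int = 201):
    """Gauss-Legendre nodes/weights on the Debye-Wolf interval [-alpha, alpha]."""
    if n_nodes < 1:
        raise ValueError("empty angular grid")
    u, w = np.polynomial.legendre.leggauss(n_nodes)
    a = sys.alpha_max
    return u * a, w * a


def beam_angular_amplitude(theta, k: float, mode: FiberMode, sys: OpticalSystem):
    """Apodized angular weight ``W(theta, k) = sqrt(cos th) E3(f2 sin th, k)``.

    This is the midplane field mapped onto the reference sphere by the sine
    condition (ray height ``xi = f2 sin th``) with the aplanatic
    ``sqrt(cos th)`` apodization.  Same weight for emission and, by
    reciprocity, detection.
    """
    theta = np.asarray(theta, dtype=float)
    return np.sqrt(np.cos(theta)) * midplane_field(sys.f2 * np.sin(theta), k, mode, sys)


def debye_wolf_prefactor(k: float, sys: OpticalSystem) -> complex:
    """``sqrt(f2/lambda) e^{-i pi/4 + i k f2}`` in front of the focusing integral."""
    lam = 2 * np.pi / k
    return complex(np.sqrt(sys.f2 / lam) * np.exp(-1j * np.pi / 4 + 1j * k * sys.f2))


def focused_beam_spectrum(
    k: float,
    mode: FiberMode,
    sys: OpticalSystem,
    pol: Polarisation = Polarisation.PERPENDICULAR,
    n_nodes: int = 201,
    n_sample: float | None = None,
    aberration=None,
) -> FocusedBeamSpectrum:
    """Angular spectrum of the focused beam behind L2 for vacuum wavenumber k.

    ``n_sample`` is the propagation index used for the sample-space plane
    waves (default: the medium index, so that the components solve the medium
    Helmholtz equation).  ``aberration``, if given, is a hook
    ``phi(theta, k) -> rad`` applied as a pupil phase screen
    ``exp(i phi)``; the default optics are aberration-free.
    """
    theta, w = angular_quadrature(sys, n_nodes)
    amp = debye_wolf_prefactor(k, sys) * beam_angular_amplitude(theta, k, mode, sys)
    if aberration is not None:
        amp = amp * np.exp(1j * np.asarray(aberration(theta, k), dtype=float))
    ns = sys.n_med if n_sample is None else n_sample
    return FocusedBeamSpectrum(theta, w, amp, k, k * ns, pol)


def debye_wolf_focus(
    theta: np.ndarray,
    midplane: np.ndarray,
    weights: np.ndarray,
    k: float,
    x,
    y,
    pol: Polarisation,
    sys: OpticalSystem,
    n_sample: float | None = None,
) -> dict[str, np.ndarray]:
    """One-dimensional Debye-Wolf integral over the angular field ``midplane``.

    Parameters mirror the focusing step: ``midplane[j]`` is the (already
    sine-condition mapped) field at angle ``theta[j]``; ``weights`` are the
    quadrature weights.  Returns the field components at sample-space points
    ``(x, y)`` as a dict with keys ``Ex``, ``Ey``, ``Ez``.

    For perpendicular input only ``E_z`` is nonzero; for parallel input the
    lens rotation produces ``(E_x, E_y) = (-sin th, cos th) E(th)`` per
    angular component.
    """
    theta = np.asarray(theta, dtype=float)
    midplane = np.asarray(midplane)
    if theta.size == 0:
        raise ValueError("empty angular grid")
    if not np.all(np.isfinite(midplane)):
        raise ValueError("non-finite input field")
    if np.any(np.abs(theta) > sys.alpha_max + 1e-12):
        raise ValueError("angles exceed the aperture half-angle")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ns = sys.n_med if n_sample is None else n_sample
    ks = k * ns
    pref = debye_wolf_prefactor(k, sys)
    apod = np.sqrt(np.cos(theta)) * midplane * np.asarray(weights)
    phase = np.exp(1j * ks * (np.multiply.outer(y, np.sin(theta))
                              + np.multiply.outer(x, np.cos(theta))))
    zeros = np.zeros(np.broadcast_shapes(x.shape, y.shape), dtype=complex)
    if pol is Polarisation.PERPENDICULAR:
        ez = pref * (phase @ apod)
        return {"Ex": zeros, "Ey": zeros.copy(), "Ez": ez}
    ex = pref * (phase @ (-np.sin(theta) * apod))
    ey = pref * (phase @ (np.cos(theta) * apod))
    return {"Ex": ex, "Ey": ey, "Ez": zeros}


def reference_arm_far_field(
    alpha,
    l: float,
    k: float,
    pol: Polarisation,
    sys: OpticalSystem,
    mode: FiberMode,
    mirror_r: complex = 1.0,
) -> dict[str, np.ndarray]:
    """Closed-form reference-arm field at L4: one cylindrical wave per angle.

    The stationary-phase (Jacobi-Anger) reduction of the Debye-Wolf integral
    at large ``k l`` collapses each angular component of the focused beam onto
    its own observation angle; the mirror at the focus retro-reflects it with
    reflection coefficient ``mirror_r``.
    """
    if l <= 0:
        raise ValueError("radial distance l must be positive")
    alpha = np.asarray(alpha, dtype=float)
    if np.any(np.abs(alpha) > sys.alpha_max + 1e-12):
        raise ValueError("observation angle outside the collection aperture")
    e3 = midplane_field(sys.f2 * np.sin(alpha), k, mode, sys)
    radial = np.pi * np.sqrt(2 / (np.pi * k * l)) * np.exp(1j * k * l - 1j * np.pi / 4)
    common = (debye_wolf_prefactor(k, sys) * np.sqrt(np.cos(alpha)) * radial
              * complex(mirror_r))
    zeros = np.zeros_like(alpha, dtype=complex)
    if pol is Polarisation.PERPENDICULAR:
        return {"Ex": zeros, "Ey": zeros.copy(), "Ez": common * e3}
    return {"Ex": common * (-np.sin(alpha)) * e3,
            "Ey": common * np.cos(alpha) * e3,
            "Ez": zeros}


def reference_collection_amplitude(
    theta,
    k: float,
    mode: FiberMode,
    sys: OpticalSystem,
    mirror_r: complex = 1.0,
):
    """Reference-arm outgoing amplitude in far-field normalization.

    Amplitude ``A(theta)`` such that the field at the collection circle is
    ``A(theta) sqrt(2/(pi k l)) e^{ikl}``:  ``pi e^{-i pi/4} P(k) W(theta) r``.
    Directly comparable to the sample-arm far-field amplitudes.
    """
    return (np.pi * np.exp(-1j * np.pi / 4) * debye_wolf_prefactor(k, sys)
            * beam_angular_amplitude(theta, k, mode, sys) * complex(mirror_r))
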