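# Methods

`octsim` computes what a two-dimensional spectral-domain OCT interferometer
records for a known sample, by propagating every spectral component of the
source through the optical train, solving the scattering problem exactly or
numerically, and assembling the depth image by an inverse discrete Fourier
transform.  This note describes the model, the numerical choices, and what
the synthetic scenes do and do not represent.

## Geometry and conventions

`x` is the optical axis, increasing into the sample; `y` is lateral; the beam
focus is the origin.  The time convention is `exp(−iωt)`, so outgoing
cylindrical waves carry `exp(+ikl)` and decay as `1/√l`.  All internal units
are SI.  Far fields are stored in the normalization
`E(l, φ) ≈ A(φ) √(2/(πkl)) e^{ikl}`, the large-argument form of the 2D
Green's function `G = (i/4) H₀⁽¹⁾(k|r−r′|)`.

Restricting the model to two dimensions decouples the electromagnetic
problem into two scalar channels: the *perpendicular* polarisation (E along
the invariant axis, `E_z`, a scalar Helmholtz problem) and the *parallel*
polarisation (in-plane E, tracked through `H_z`).  The channels never mix;
any difference between their tomograms is a pure vector-scattering effect.

## Source and lens train

The fiber emits a Gaussian mode `E₁ = E₀ exp(−y²/w₀²)` (default
w₀ = 4.6 µm).  A 2D angular-spectrum propagation in paraxial approximation
gives the closed-form field on the first lens (a Gaussian of complex width
`2if₁/k + w₀²`), and the paraxial Fresnel integral with the thin-lens
transmission carries it to the common focal midplane:

    E₃(y) = (1−i) w₀E₀ √π / √(2f₁λ) · e^{2ikf₁} · e^{−(y k w₀ / 2f₁)²}.

Lens thickness is set to zero.  Both closed forms are verified in the test
suite against direct numeric quadrature of the underlying integrals to
better than 0.1%.

Focusing into the sample uses the one-dimensional (cylindrical-lens)
Debye–Wolf integral for aplanatic lenses satisfying the sine condition
(ray height ξ = f₂ sin θ on the midplane):

    E₄(x, y) = √(f₂/λ) e^{−iπ/4 + ikf₂} ∫_{−α}^{α} √cosθ · M(θ)
               e^{ik_s (y sinθ + x cosθ)} dθ,

where `M(θ)` contains the midplane field and, for the parallel channel, the
lens rotation `(−sinθ, cosθ)`.  Two index conventions deliberately coexist:

* the **angular limit** α = arcsin(h/f₂) is computed with index 1
  (`OpticalSystem.n_debye`, configurable).  Using the medium index would
  narrow the angular window, truncate the Gaussian pupil harder, and produce
  strong side lobes on the focused beam;
* the **plane-wave phases** always use the medium propagation constant
  `k_s = k·n_med`.  Anything else would make the angular components
  non-solutions of the medium's Helmholtz equation and break the optical
  depth mapping (see below).

The quadrature is Gauss–Legendre with 201 nodes by default; the tests verify
convergence against 10× refinement to 10⁻⁶ relative.  All global `e^{ikf}`
phases are retained; they are common to both arms and cancel in the
normalized tomogram.  An optional pupil phase screen
(`focused_beam_spectrum(..., aberration=phi)`) is provided as a hook for
aberrated systems; the shipped optics are aberration-free and the hook is
not exercised by the test suite.

## Reference arm

A mirror sits at the focus of L4.  In the far-field limit (kl ≫ 1, satisfied
at the lens distance of tens of millimeters) the Jacobi–Anger expansion of
the Debye–Wolf kernel collapses: each angular component of the focused beam
returns as exactly one outgoing cylindrical wave at its own angle, with
amplitude `π √cosα M(α)` times the mirror reflection coefficient.  The
default mirror is ideal (`r = 1`, angle- and polarisation-independent); a
Fresnel-coefficient model can be substituted through the `mirror_r` argument.
Because the tomogram is normalized by the reference intensity, the constant
choice is harmless.  The closed form is tested against brute-force numeric
propagation of the Debye–Wolf integral over three decades of kl (error
decreasing, <1% at kl ≈ 10⁴).

## Sample scattering

### Exact cylinder series

For an infinite circular cylinder at normal incidence the scattered field is
an outgoing Hankel series with coefficients obtained by matching the field
and its polarisation-dependent normal derivative at the surface
(perpendicular: `E` and `∂E/∂r` continuous; parallel: `H` and `(1/n²)∂H/∂r`
continuous).  The truncation order is `x + 4x^{1/3} + 4` (x the in-medium
size parameter); cross sections per unit length are
`C_sca = (4/k)(|b₀|² + 2Σ|b_n|²)` and are verified against angular
quadrature of the far-field intensity (10⁻⁸) and the optical theorem.

The **analytic imaging path** superposes this response over the focused
beam's angular spectrum: each incident plane-wave component is weighted by
the beam amplitude, phase-referenced to the cylinder center for incidence
and observation, scattered with the exact amplitude `T(φ_out − θ_in)`, and
summed.  With several cylinders the per-cylinder responses add linearly —
i.e. the analytic path is **single-scattering between cylinders** (exact per
cylinder).  Multiple scattering between scatterers is only captured by the
grid path; multi-cylinder analytic tomograms are therefore a fast
approximation, appropriate for channel-difference and symmetry studies.

### Grid solvers

Scenes are rasterized to a squared-index map by permittivity averaging over
10×10 sub-cells per cell (configurable), which suppresses staircase noise at
curved boundaries; the conserved contrast area is tested to the expected
`10/subsampling²` bound.  The solver grid adds an absorbing layer
(default 10 µm; the rasterizer guarantees primitives cannot touch it) built
from a cubic ramp of Im(n²) with peak 1.2.  Measured round-trip boundary
reflection at the design wavelength is below 10⁻⁴ (line-source test against
a large-domain reference).

*Perpendicular channel* — the preconditioned (convergent) Born series: with
`kb² = k₀²n_med² + iε`, `V = k₀²n_eff² − kb²`, and `ε ≥ max|k₀²n_eff² −
k₀²n_med²|`, the iteration `E ← E + (i/ε)V[G(VE+S) − E]` with the spectral
Green's operator `G = F⁻¹(p² − kb²)⁻¹F` converges for arbitrary contrast.
The source is `S = k₀²(n² − n_med²) E_inc` with the *physical* contrast only
(scattered-field formulation): the analytic incident beam, a solution of the
homogeneous background problem, passes the absorbing layer untouched while
only outgoing scattered waves are damped.  The returned solution satisfies a
spectral-residual contract (`≤ tolerance`, default 10⁻⁶) or raises.  Because
the operator is spectral, the scheme is free of grid dispersion; far fields
are extracted by the discretization-consistent source integral
`A(φ) = (i/4)e^{−iπ/4} Σ V·E_tot e^{−ik_m q̂·r} dx²`.

*Parallel channel* — `∇·(n⁻²∇H_z) + k₀²H_z = 0`, discretized with a
five-point stencil and harmonic face averages of `n⁻²`, solved directly by
sparse LU in the same scattered-field formulation (the discrete source
`(A_bg − A_phys)u_inc` makes the incident field's numerical dispersion
consistent).  Far fields come from an angular-harmonic expansion of the
scattered field on a circle (below).  The 5-point stencil carries
second-order grid dispersion; the plane-wave oracle error against the series
is ≈4% at λ₀/30 and halves at λ₀/45, so parallel-channel grid runs should
use the finest affordable grid.  For cylinder scenes both polarisations also
run through the exact series path.

### Near-to-far transform

Outside all contrast the scattered field on a circle of radius R is
`Σ c_n H_n⁽¹⁾(kR) e^{inφ}`; an FFT over the circle yields `c_n` and
`A(φ) = e^{−iπ/4} Σ c_n e^{−inπ/2} e^{inφ}` — the Green's-function contour
integral resummed so that only field *values* are needed.  Orders beyond
`kR` plus an evanescent margin are discarded (their Hankel functions are
exponentially large on the circle; dividing by them would only amplify
noise).  The transform is radius-independent and reproduces the analytic
series to 10⁻⁴, limited in grid use by spline interpolation onto the circle.

## Detection and reconstruction

Scanning shifts the beam laterally over the sample (equivalently, the sample
under the beam); the small lateral offset of the fiber during scanning is
neglected, so the beam always passes the lens centers.  Collection applies
the reciprocity form of the back-propagation: for this matched aplanatic
train, coupling an outgoing far field `A(θ)` into the fiber equals
`P(k)∫A(θ)W(θ)dθ` with the same apodized angular weight `W(θ) = √cosθ
E₃(f₂ sinθ)` as emission.  The explicit numeric chain (Fresnel back through
L2/L4, Debye–Wolf through L1/L3, Gaussian-mode overlap) is implemented
alongside and agrees with the reciprocity form up to a single k-dependent
constant (pattern-independent to ~1%, a few % under strong pupil tilts),
which cancels in the normalized tomogram.  Sample- and reference-arm far
fields are reduced to the same cylindrical-wave normalization before
detection — the arms are matched at the focus, and the unmodeled
medium-to-air path between the focus sphere and the lens is treated as
compensated; otherwise every echo would shift by a constant offset.

The source spectrum `S(ω) = (b/√2)exp(−((b/2)(ω−ω₀))²)` with
`b = 2√(ln2)λ₀²/(πcΔλ)` (amplitude-FWHM convention) is sampled at N uniform
frequencies between the points where it falls to ε·max(S).  The A-scan is
the inverse DFT of `α_sca·α_ref*`, weighted by the spectral **power** |S|²
(an amplitude option exists; the power choice pairs one field factor per
arm, at the cost of √2 coarser axial resolution — the small-cylinder echo
test uses the amplitude option for that reason).  DFT indices run
−N/2 … N/2−1; time maps to depth via `x = tc/(2n_med)`.  The full axis is
kept (front-surface echoes of centered scatterers lie at negative depths);
`AScan.positive()` gives the display view.  Intensities are magnitudes,
divided by the reference-arm intensity `(δω/2π)Σ|S α_ref|²`, so a
mirror-equivalent sample reads exactly 1 at depth 0.

Finite spectral sampling makes depths unambiguous only up to
`c·t_max = c/(2n_med)·(N/2 + 1/N − 3/2)·πb/(2√(ln 1/ε))` (≈92 µm for
N = 160, ε = 10⁻³, n_med = 1.35); deeper signals alias to DFT-wrapped bins,
which the tests check by exact bin arithmetic.

## Synthetic scenes

The generators reproduce the study conditions of the simulator's scenes:

* **single cylinders** (a = 5 and 20 µm, n_cyl = 1.42 in n_med = 1.35) with
  the optical echo-separation helper `d = 2a·n_cyl/n_med`;
* **cylinder clusters**: 83 cylinders of a = 0.5 µm in a disc.  The
  published symmetric arrangement is not tabulated, so the lattice mode is a
  mirror-symmetric hexagonal fill of a 10 µm disc with the same count and
  radius — a stand-in that preserves count, radius, symmetry and packing
  scale, not the exact coordinates.  Jitter mode displaces each site by
  independent per-axis uniform draws bounded by the stated maxima
  (230 nm in x, 192 nm in y); only achieved extrema were reported for the
  original, so the uniform law is this package's choice.  Overlap is allowed
  by default (and rarely occurs); a non-overlap mode with bounded retries
  exists;
* **ziggurats**: stacked slabs with strictly decreasing plateau widths,
  narrowest facing the beam;
* **dentin slabs**: water-filled tubules (n = 1.33, radius 1 µm) placed
  uniformly at random in a dentin background (n = 1.52 everywhere, so no
  air–dentin surface reflection).  The published slabs were derived from a
  microscopy image; the uniform-random generator reproduces count, region
  and concentration, not the anatomical arrangement.  The mean free path
  `L = πa²/(C_sca·f)`, `f = N πa²/(LxLy)`, uses the exact series cross
  section at the in-medium wavelength λ₀/n_med.

All generators are seeded and bit-reproducible.  What passing tests show is
that the *image-formation physics* is right (echo laws, aliasing, channel
separation, solver-oracle agreement); they do not certify agreement with any
particular biological tissue, whose index fluctuations are neither binary
nor two-dimensional.

## Problem sizes and defaults

The bundled examples and the test suite run at desk scale by choice:
analytic-path B-scans use the full N = 160 spectrum; grid-path oracle tests
use single-micrometer cylinders on λ₀/13–λ₀/45 grids (hundreds squared) with
6–10 µm boundaries; cluster property runs use N = 40 wavenumbers and ≤13
scan positions.  Tolerances: solver residual 10⁻⁶; Born-vs-series far-field
agreement 2% at λ₀/24 (0.4% typical at λ₀/13, 0.1% at λ₀/24); echo-position
checks one depth bin (≈1.16 µm at N = 160).

## Known limitations

* Two-dimensional only; no spherical-lens (3D) Debye–Wolf integral.
* Real refractive indices only — no dispersion, absorption in the sample, or
  noise model (shot/RIN), and no sensitivity roll-off beyond what the
  sampling itself produces.
* The analytic multi-cylinder path omits inter-cylinder multiple scattering.
* The parallel-channel grid solver is dispersion-limited by its second-order
  stencil and is the slow path on large maps.
* Tomogram display conventions (log/linear, magnitude) are configurable;
  magnitudes are used throughout because the phase of the complex
  reconstruction is arm-length dependent.
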