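# Methods

This note documents the models, estimators, numerical choices and known
limitations of the toolkit, in the package's own words. No number quoted
here is asserted anywhere without being recomputed by the test suite or
`scripts/acceptance.py` at run time.

## The measurement model

A probe particle of hydrodynamic radius `R_h` embedded in a dense
protein phase performs thermal motion governed by a generalized
Langevin equation (GLE),

    m_eff dv/dt = −∫₀ᵗ ζ(t−s) v(s) ds + F_B(t),

with a memory kernel `ζ(t)` set by the medium's linear viscoelasticity
and colored Brownian noise `F_B` obeying fluctuation–dissipation.
Passive microrheology inverts this: track the probe, measure its
mean-square displacement (MSD), move to the frequency domain and solve
a continuum force balance for the medium's complex modulus
`G*(ω) = G′(ω) + iG″(ω)`.

With the one-sided Fourier convention `x̂(ω) = ∫₀^∞ x(t) e^{−iωt} dt`,
equilibrium statistics give the frequency-dependent friction directly
from the transformed MSD:

    Z*(ω) = −2 d k_B T / (ω² · MSD(ω)) − iω m_eff,

where `d` is the number of tracked dimensions (3, or 2 for probes
restrained on a plane) and `m_eff = m_bare + m_add` includes the added
mass of displaced medium, `m_add = (2/3)π R_h³ ρ`. The friction is then
balanced against the unsteady-Stokes drag of a no-slip sphere in a
viscoelastic medium — generalized Stokes drag plus Basset
(medium-inertia) force:

    Z*(ω) = 6π R_h G*(ω)/(iω) + 6π R_h² √(ρ G*(ω)).

This is quadratic in `√G*`; the root with `Re √G* > 0` is the passive
(dissipative) branch. At low frequency both inertial corrections vanish
and the relation reduces to the classical generalized Stokes–Einstein
form. From `G*`: the crossover frequency `ω_c` (lowest frequency where
`G′` overtakes `G″`, located by log–log interpolation) defines the
relaxation time `τ = 1/ω_c`; the terminal viscosity is `η = ⟨G″/ω⟩`
over a window in which the log–log slope of `G″` is 1 within 0.05.

Everything is computed in real coarse-grained units (Å, ns, kcal/mol,
g/mol; `k_B = 1.987204259×10⁻³ kcal/(mol·K)`); masses and densities are
converted internally to the energy-consistent system
(1 (g/mol)(Å/ns)² = 2.39006×10⁻⁹ kcal/mol) so that moduli come out in
kcal/(mol·Å³) and viscosities in kcal·ns/(mol·Å³); converters to Pa and
Pa·s are provided.

## MSD estimation

The estimator is the all-origin time average, computed with the FFT
("order-N") decomposition and proven identical to the O(N²) double loop
in the tests. Multiple probes are averaged with equal weight; a probe
volume fraction above 0.1 raises a crowding flag, beyond which
probe–probe interactions are known to bias viscosities upward. Log
lag grids use 30 points per decade; lags beyond 10 % of the trajectory
are dropped by default because so few independent origins remain there
that the estimate is dominated by correlated noise (this cap measurably
biased terminal quantities when absent).

Asymptote fits: the ballistic coefficient `C` (MSD → Ct²) is obtained
by fitting the inertial-Langevin short-time form
`MSD = 2Cτ_v²(t/τ_v − 1 + e^{−t/τ_v})` over the first ~1.1 decades of
lag, which also yields the probe's velocity-relaxation time `τ_v` and
removes the O(t/τ_v) bias that a plain `MSD` vs `t²` slope suffers when
the first stored frame is not asymptotically short. The diffusion
coefficient `D` comes from a slope-with-intercept linear fit in the
diffusive window; the intercept absorbs the plateau offset that a
viscoelastic liquid adds to its diffusive asymptote.

## The relaxation-spectrum parametrization of the MSD

Numerical one-sided transforms of noisy MSD data are ill-conditioned,
so the MSD is first fitted by an analytic form whose transform is
closed-form: a Baumgaertel–Schausberger–Winter-like windowed power-law
retardation spectrum

    h(τ) = g_j τ^{α_j − 1}  on  τ_{j−1} < τ ≤ τ_j,  j = 1…n_max,

with weights chained by continuity of `h` at the knots,
`g_j = g_{j−1} τ_j^{α_{j−1}−α_j}`, and

    MSD(t) = ∫ h(τ) f¹(t/τ) dτ + g₀ f⁰(t),
    f¹(x) = 1 − e^{−x}(1 + x),
    f⁰(t) = Λ(t) − β (1 − e^{−t/τ_max})(1 − e^{−t/τ_v}),
    Λ(t)  = t/τ_max − (τ_v/τ_max)(1 − e^{−t/τ_v}),

where `g₀ = Σ_j g_j (τ_j^{α_j} − τ_{j−1}^{α_j})/α_j = ∫ h dτ` is the
total spectrum weight (the displacement plateau), `τ_max` is the
terminal relaxation time, and `β ∈ [0, 1)` is the fraction of the
plateau missing from the diffusive-asymptote offset (the
solvent-channel correction; for a single-mode medium without solvent
drag the offset equals the plateau and `β = 0`). Each mode kernel `f¹`
is ballistic (`x²/2`) at short times and saturates at 1; the terminal
kernel is inertially gated by `τ_v` so the ballistic limit is exact.
Consequences used as exact identities in the tests:

* short times: `MSD → C t²` with
  `C = ½ Σ_j g_j (τ_{j−1}^{α_j−2} − τ_j^{α_j−2})/(2−α_j) + g₀(½−β)/(τ_v τ_max)`,
  linear in `g₁`, so the measured ballistic slope fixes all weights
  once the exponents are chosen;
* long times: `MSD → (g₀/τ_max)·t + g₀(1−β)`, i.e. free diffusion with
  `D = g₀/(2 d τ_max)` offset by the plateau.

The closed forms: the time domain needs upper incomplete gamma
functions `Γ(−α, t/τ)`, `Γ(1−α, t/τ)` (the generalized
exponential-integral family, evaluated by a downward recurrence from
`scipy`'s regularized gamma, with `Γ(−n, x) = x^{−n}E_{n+1}(x)` at
non-positive integers); the frequency domain reduces to Gauss
hypergeometric `₂F₁` bracket evaluations `[x(τ)]` from `τ_{j−1}` to
`τ_j` per window (mpmath's analytic continuation, with a 10⁻⁶ nudge at
the removable parameter poles α = −1, −2, …), plus elementary rational
terms for `f⁰`. Removable singularities of the window integrals at
α = 2 and α = 0 switch to logarithmic forms within 10⁻⁶. Both closed
forms are validated in the test suite against direct quadrature
(time domain) and against a damped, Richardson-extrapolated numerical
one-sided transform (frequency domain).

### Fitting

`τ` knots are log-equidistant; exponents minimize the χ² of relative
residuals on the log lag grid (each decade weighted equally by
construction). Defaults chosen where the method itself is silent:

* the grid starts at half the ballistic-departure knee (the first lag
  where MSD < 0.5·Ct²) — spectrum weight below the inertial knee is
  unidentifiable and poisons the fit;
* the endpoint knots (τ₀, τ_max) and the offset fraction β are fitted
  along with the exponents: τ_max is the terminal relaxation time and
  fixing it a priori over-constrains the diffusive tail;
* α ∈ [−3, 3]: negative exponents are required because the chained
  spectrum must often decay faster than τ⁻¹ above the knee;
* a penalty `30·(D_model/D_data − 1)²` keeps the spectrum's implied
  diffusivity consistent with the measured long-time slope, which the
  in-range residuals constrain only weakly;
* optimizer: deterministic two-stage — bounded multi-start Powell,
  then seeded differential evolution (seed 0); `polish_only=True`
  skips the second stage for cheap fits. Reported `chi2` excludes the
  penalty.

## Green–Kubo route

The shear relaxation modulus from pressure-tensor fluctuations uses the
five-component isotropic estimator

    G(t) = V/(5k_BT) Σ_off ⟨P_ab(0)P_ab(t)⟩
         + V/(30k_BT) Σ ⟨N_ab(0)N_ab(t)⟩,   N_ab = P_aa − P_bb,

with FFT autocorrelations (unbiased normalization, de-meaned inputs)
truncated at half the series. The viscosity is the hybrid integral:
trapezoidal `∫₀^{t_switch} G dt` plus the analytic tail
`Σ G_i τ_i e^{−t_switch/τ_i}` of a non-negative least-squares fit of
`G(t)` to four Maxwell modes log-equidistant in time (`t_switch`
defaults to the first time `G` falls below 5 % of `G(0)`). Moduli from
the fitted modes are exact closed forms; raw `G(t)` can also be
transformed numerically with an exponential damping window.

## Synthetic ground truth

`microrheo.gle` integrates the passive GLE with kernels that are sums
of exponentials plus an optional instantaneous (solvent/thermostat)
drag — the Jeffreys class. Each Maxwell mode is embedded as an
auxiliary Ornstein–Uhlenbeck force, exact in distribution for frozen
velocity, inside a velocity-Verlet splitting with exact OU updates
(`dt ≤ τ_min/50` enforced); the fluctuation–dissipation theorem holds
by construction, checked by equipartition to 2 %. The medium's moduli
are exact: `G*(ω) = iω ζ̂(ω)/(6πR_h)` with
`ζ̂ = ζ_N + Σ c_i/(1+iωτ_i)`, so `η = (ζ_N + Σc_i)/(6πR_h)` and the
reference MSD/VACF follow from the rational-function pole
decomposition in closed form. The stress generator produces six
pressure-tensor channels as OU sums with isotropically consistent
variances (normal-difference autocorrelations equal 4× the
off-diagonal ones), so the five-component estimator returns
`Σ G_i e^{−t/τ_i}` exactly in expectation.

### Study conditions for the recovery benchmark

The end-to-end benchmark simulates a probe (`R_h = 10.6 Å`,
`m = 2510 g/mol`, T = 300 K) in a single-mode Maxwell medium
(`G₀ = 10⁻⁴ kcal/(mol·Å³)`, `τ_M = 1 ns`) plus a weak solvent drag
`ζ_N = ζ_slow/20` — the analogue of the Langevin-thermostat friction
in coarse-grained condensate simulations. The solvent term is what
makes the probe's velocity autocorrelation overdamped (all poles real);
without it the probe rings against the medium's elasticity and no
monotone retardation parametrization represents the MSD. It costs a 5 %
viscosity contribution and shifts the true crossover to
`τ_c ≈ 0.9 τ_M`, which is why recovered quantities are compared
against functionals of the exact moduli (crossover time, `G′` at
`5ω_c`, terminal `G″/ω`), not against raw kernel parameters. Sizes:
`dt = 10⁻³ ns` (resolving the velocity-relaxation time
`τ_v ≈ 5×10⁻³ ns`), 2×10⁶ steps, 8 independent probes, lags to 10 % of
the 2 μs trajectory. Five spectrum windows, full two-stage fit.

At these conditions the noise-free pipeline recovers the three
functionals to within ~5 %; with trajectory noise the seed-to-seed
scatter is a few percent for the plateau and crossover and somewhat
larger for the viscosity, dominated by the statistics of the diffusive
tail. The terminal window is placed at `(ω_c/30, ω_c/12)`: low enough
that `G″ ∝ ω` within the slope gate, high enough to be anchored by
in-band data rather than by the fitted spectrum's extrapolation.

### What the generator does and does not emulate

It reproduces the statistical structure the inversion assumes —
ballistic onset, mode relaxation, terminal diffusion, exact FDT, and
independent probes. It does **not** include Basset/added-mass
hydrodynamics (the kernel absorbs all drag, so the inertial IGSER
terms are exercised separately with algebraic fixtures), spatial
heterogeneity, probe–probe hydrodynamic coupling, or adsorption
physics; passing the recovery benchmark therefore demonstrates the
fidelity of the analysis chain, not the validity of the continuum
assumptions in any particular condensate.

## HPS medium utilities

Residue-level force-field terms follow the hydropathy-scale model:
harmonic bonds `U = ½k_b(r−r₀)²` (`k_b = 20 kcal/(mol·Å²)`,
`r₀ = 3.8 Å`); Ashbaugh–Hatch van der Waals,
`U = U_LJ + (1−λ)ε` inside the LJ minimum and `λU_LJ` outside, with
arithmetic mixing, `ε = 0.2 kcal/mol`, plain truncation at 4σ (the
discontinuity at the cutoff is the stated convention, not a bug); and
Debye–Hückel electrostatics `q_iq_j e²/(4πϵ₀ϵ_r r)·e^{−r/l}` with
`ϵ_r = 80`, `l = 10 Å`, truncated at 35 Å, with the Coulomb constant
built from CODATA values. Kapcha–Rossky and Urry hydropathy tables
ship as data; E/D carry −1, K/R +1, H is neutral by default.

Sequence charge patterning: `SCD = (1/N)Σ_{i<j} q_iq_j√(j−i)`,
normalized to `nSCD = (SCD − SCD_alt)/(SCD_diblock − SCD_alt)` using
the alternating and diblock arrangements of the same composition as
extremes. For equal-composition polyampholytes these constructions are
the exhaustive extremes (verified by enumeration for N ≤ 10 in the
tests) and `nSCD ∈ [0, 1]`; for strongly asymmetric compositions they
are not guaranteed extremal and values may leave [0, 1] — such
sequences are outside the descriptor's design.

Probe validity: the semidilute correlation length is
`ξ = R_e (ρ/ρ*)^{ν/(1−3ν)}` with overlap concentration
`ρ* = 3M_w/(4πR_e³)` in per-mole units and ideal-chain `ν = ½` by
default (so `ξ = R_e ρ*/ρ`). A probe is continuum-valid for
`R_h/ξ ≥ 1.5` with a recommended efficiency band `[1.5ξ, 2ξ]`, and its
protein attraction should sit in `1 ≤ ε/ε_HPS ≤ 1.5` — below ~0.75 the
medium slips at the surface, beyond ~1.75 chains adsorb.

## Probe construction

The rough sphere is carved from an FCC lattice (cubic cell edge
2.12 Å, i.e. nearest neighbors at 2.12/√2 ≈ 1.5 Å, just touching for
σ = 1.5 Å beads of 100 g/mol), centered on a lattice site so a carve
radius below the first shell keeps exactly one bead; neighbors within
1.05× the nearest-neighbor distance are bonded (`k_b = 250
kcal/(mol·Å²)`), giving a single connected body. Geometry diagnostics
use the gyration tensor: `R_g` from the trace and the relative shape
anisotropy `κ² = 1 − 3(λ₁λ₂+λ₁λ₃+λ₂λ₃)/(λ₁+λ₂+λ₃)²`; the carved
probe approaches the uniform-sphere `R_g = √(3/5)R_b` within 3 % by
`R_b = 20 Å` with `κ² < 0.01`. The hydrodynamic radius is the first
RDF peak (above a 1.1 noise guard) between probe center and protein
residues, refined by a parabola through the peak bin; the no-slip
diagnostic is the ratio of the first-bin residue velocity to the probe
velocity.

## Known limitations

* The spectrum family is a monotone retardation parametrization: media
  whose probes are underdamped against the medium elasticity (velocity
  autocorrelation with strong ringing) produce MSDs outside the family;
  the fit then reports large χ² rather than failing loudly.
* Frequencies trustworthy for `G*` are bounded by the fitted knots,
  roughly `[1/(3τ_max), 3/τ₀]`; the transform is analytic outside but
  extrapolated.
* Discrete-mode media expose kernel-shape mismatch at the few-percent
  level near the terminal handover; broad (power-law-like) spectra —
  the regime the method was designed for — fit much more tightly.
* Triclinic boxes, velocity storage beyond the no-slip check, active
  (driven-probe) and two-point microrheology are out of scope.
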