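# Methods

## Model

The induced first-order current density of a closed-shell molecule in a
static uniform field is computed from a restricted Hartree–Fock ground state
and its coupled-perturbed (CPHF) response. Both magnetic perturbations are
purely imaginary one-electron operators, H′ = iλÔ with Ô a real antisymmetric
matrix: the angular momentum L about a common origin r₀ (per field component)
and the linear momentum P (per Cartesian component). For imaginary
perturbations the first-order density matrix is imaginary and antisymmetric,
the Coulomb response vanishes, and the CPHF equations close on the (A − B)
matrix

    Σ_bj [ (ε_a − ε_i) δ_ab δ_ij − (ab|ij) + (aj|ib) ] V_bj = −O_ai ,

solved densely (occupied–virtual dimensions here are tiny). Each solved
perturbation yields a per-point paramagnetic current kernel

    K(r) = −2 Σ_i [ ψ_i ∇ṽ_i − ṽ_i ∇ψ_i ],   ṽ_i = Σ_a V_ai ψ_a ,

and every CTOCD current is a pointwise contraction of the six cached kernels
(3 × L, 3 × P) with geometric coefficients:

* CO: Larmor term −(1/2c) ρ B×(r − r₀′) plus the L(r₀′) kernel;
* DZ1: L(r₀) kernel minus [B×(r − r₀)]·(P kernels) — the operator identity
  L(r) = L(r₀) − (r − r₀)×P evaluated pointwise;
* GRRO/GPRO: DZ1 plus the parameter times a *unit kernel*
  f̂(ρ)[B×∇ln ρ]·(P kernels) − (1/2c) f̂(ρ) B×∇ρ, with shape factor
  f̂ = 1 (GRRO) or ρ^(−2/3) (GPRO).

Because the origin change of L is linear and the CPHF solve is linear in its
right-hand side, CTOCD fields and shieldings are origin-independent to
solver roundoff (measured ~10⁻¹³ ppm for a 5-bohr shift), and totals are
exactly linear in α/β — the property the calibration exploits.

### The GPRO exponent

The shift d − r = −f(ρ)∇ln ρ must carry the dimension of a length. Since
[∇ln ρ] = L⁻¹, f must carry L²; with f = βρⁿ and [ρ] = L⁻³ this forces
n = −2/3. The merged diamagnetic term then reads −(3β/2c) B×∇ρ^{1/3}, which
is the Thomas–Fermi current-density approximation of Harris and Cina for
β = −1/(6(3π²)^{2/3}) = −0.017414 — the numerical agreement of this constant
is the cross-check that pins the exponent. (α is quoted in a₀ following the
field's convention for the GRRO parameter; in strict dimensional terms the
constant f carries a₀².)

### Shielding integration

σ_γλ^N = −(1/c) ε_γδν ∫ 𝒥_δλ (R_N − r)_ν/|R_N − r|³, reported in ppm
(×10⁶) with c = 137.035999. The sign/prefactor convention is pinned by an
exactness identity: for a closed-shell atom the pipeline must reproduce the
Lamb value (10⁶/3c²)⟨1/r⟩ computed directly from the same density (measured
agreement ~10⁻¹² ppm on He; the hydrogenic 1s closed form gives
10⁶/3c² = 17.750 ppm).

## Becke partition and grids

Fuzzy-cell weights use the k-fold iterated cutoff polynomial
p(x) = (3x − x³)/2 on the confocal elliptical coordinate, k = 3, with
Bragg–Slater size adjustment (|a_AB| ≤ 0.5 clip, hydrogen radius 0.35 Å).
The partition of unity is exact to machine precision, so single-center
decomposition introduces no error; per-atom parameter switching inside the
cells is the single-pass multi-parameter integration. Cross-talk on foreign
cells (suppressed by w_A) is accepted, not corrected; the uniform-parameter
mode remains available and is what calibration uses.

Radial quadrature: Gauss–Legendre nodes mapped by r = R(1 + x)/(1 − x) with
R the Bragg–Slater radius (min 0.4 a₀), 90 points per atom by default,
truncated at 30 a₀. Angular quadrature: product Gauss–Legendre(cos θ) ×
uniform(φ), default 18 × 36, exact for spherical harmonics to degree 35 —
chosen over tabulated Lebedev grids to keep the quadrature self-contained
and arbitrarily refinable; the Biot–Savart integrand is sharper than an XC
integrand near nuclei, which the radial map accommodates. Defaults hold the
observed grid-refinement drift of σ_Av below 0.05 ppm on the built-in
fixtures and integrate electron counts to 10⁻⁶.

## Numerical choices

* ∇ln ρ is evaluated as ∇ρ/ρ with the whole shift contribution zeroed where
  ρ < rho_cut (default 10⁻¹⁰ a₀⁻³): the GPRO factor ρ^(−2/3) diverges in
  density tails, and tail handling is otherwise arbitrary.
* Fields are stored as ∂J_δ/∂B_β tensors, so no field magnitude appears.
* Divergence checks use central differences; a 4th-order stencil (h = 10⁻³
  a₀) keeps the truncation error of the *check* near 10⁻⁸ relative, far
  below the 10⁻⁶ solenoidality tolerance — the GRRO/GPRO diamagnetic term is
  B×∇(scalar) and analytically divergence-free.
* A grid point coinciding with the probed nucleus has its integrand zeroed
  (measure-zero exclusion) and is logged.
* SCF: DIIS, energy tolerance 10⁻¹⁰; response solved by dense LU. Both are
  deterministic; identical inputs give identical outputs bit for bit.

## Calibration

Probes default to {0, −0.01} for α and {0, −0.05} for β — inside the
physically sensible negative range and far enough apart for slope stability;
by exact linearity the fitted parameter is probe-independent (tested to
10⁻⁸). Aggregation reports the arithmetic mean and the sample (n − 1)
standard deviation per element or per environment key. The predicted error
of using a pooled mean is |slope| × std. Environment keys: heavy atoms are
typed by element + sorted first-shell neighbour elements; hydrogens carry
the attached element and the sorted second-shell elements, giving
transferable proton classes. Connectivity only — no aromaticity or
hybridization perception, so e.g. sp² versus aromatic nitrogen environments
may need richer keys.

## Electronic-structure level and what the tests show

The backend implements restricted Hartree–Fock with s/p Gaussian bases
(STO-3G data built in; an even-tempered matched s/p set `et-sp` for H/He in
which multiplying occupied orbitals by a coordinate stays inside the basis,
so the momentum response reproduces the Larmor kernel and DZ1 agrees with CO
to ~10⁻³ ppm on He). Hybrid-DFT response and richer basis sets are out of
scope; requesting a functional raises an explicit error. All structural
claims verified by the test suite — exact parameter linearity, the DZ1
limit, solenoidality, origin independence, Becke exactness, calibration
round trips — are level-independent: they hold for any consistent set of
density and response kernels, so they transfer to better electronic
structure unchanged. What does *not* transfer is chemistry: STO-3G slopes
and shieldings differ quantitatively from converged-basis values (the
slope for a carbon nucleus is ~−1.7×10⁴ ppm/a₀ here versus ~−2.4×10⁴ at a
polarized double-zeta level), and calibrated parameters are meaningful only
for the basis/method they were fitted with — they compensate basis-set
incompleteness, nothing else.

Fixture geometries are textbook equilibrium structures, not force-field
optimized conformers; the analytic Gaussian/hydrogenic states have zero
paramagnetic response by construction, exercising only the diamagnetic and
quadrature machinery.

## Limitations

* Closed-shell RHF only; no GIAO comparison path, no open shells, no DFT.
* Full shielding-tensor anisotropy is not a target: one scalar parameter can
  fix one number per nucleus (the isotropic average), not a tensor.
* Basis-set data ship only for H, He, C, N, O (STO-3G) and H, He (et-sp).
* Magnetizabilities and the damped nearest-nucleus origin variants
  (CSDGT/DZ2, PZ1/PZ2) are not implemented.
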