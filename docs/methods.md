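# Methods

## Model

The system is a single file of rectangular plant cells of length l̂,
width ŵ, separated by apoplast (cell wall) of thickness â, with a
centred vacuole occupying an area fraction φ of the symplast. Hormone
concentrations are tracked in five compartments per cell unit: cytoplasm
(c), vacuole (v), and the transverse (f), corner (g) and longitudinal
(h) pieces of the apoplast. All intra-compartment mixing is assumed fast
(valid while cells stay well below the ~1 mm length at which cytoplasmic
diffusion becomes rate-limiting), so each compartment carries a single
concentration.

Fluxes are linear:

* **Membrane transport.** A weak-acid hormone is protonated (neutral,
  membrane-permeant) with fraction 1/(1+10^(pH−pK)) in each compartment;
  the anion crosses only through transporters with
  Goldman–Hodgkin–Katz electrodiffusion weights q(φ̃) = φ̃/(e^φ̃−1),
  φ̃ = F·V/(R·T). Passive and facilitated contributions combine into four
  effective permeabilities P_ca, P_ac, P_cv, P_vc (cytoplasm↔apoplast,
  cytoplasm↔vacuole). Loss-of-function mutants are represented by
  zeroing the importer and/or tonoplast-exporter permeability *before*
  combining, so every mutant expression downstream is the wild-type
  formula under adjusted inputs.
* **Apoplastic diffusion** between adjacent wall compartments, with rate
  2·D_apo over the centre-to-centre distance.
* **Plasmodesmata**: direct cytoplasm-to-cytoplasm diffusion with
  permeability P_plas.

Concentrations are scaled with the upstream value, lengths with the
(average initial) cell length, permeabilities with D_apo/(l̂_av+â), and
time with L̂₀²/D_apo (apoplastic diffusion across the whole file). The
dimensionless groups are ε = 1/N, λ = â/l̂_av, ω = ŵ/l̂_av, φ, the four
scaled permeabilities, and the quasi-static partition ratios
𝒫_a = P_ca/P_ac and 𝒫_v = P_cv/P_vc.

### Discrete system

For T tracked cells the state has 5T−2 unknowns: c and h for cells 2..T,
v, f, g for cells 1..T. The upstream boundary fixes c₁ = 1 and
h₁ = 𝒫_a (its quasi-static value); downstream, a ghost reflection
c_{T+1} = c_{T−1}, h_{T+1} = h_{T−1} imposes no flux about the last
tracked cell. The continuum coordinate x ∈ [0, 1] runs between the
centres of the first and last cells, so a file of N cell units tracks
T = N+1 cells and the discrete no-flux plane coincides with the
continuum boundary x = 1. (Reflecting about cell N instead shifts the
no-flux plane one cell inward; for spatially graded files whose last
cells are long this visibly degrades the discrete–continuum agreement,
from ≲0.012 to ~0.07–0.10 maximum deviation at N = 20.)

Growing files evolve the conserved amounts (1−φᵢ)lᵢcᵢ, φᵢlᵢvᵢ and lᵢhᵢ
with Lagrangian (cell-following) time derivatives, so dilution enters
through the product rule and the hormone budget closes exactly: the
derivative of the capacitance-weighted total equals the boundary influx
identically (audited in the tests to 1e−10 relative).

### Continuum limit

With ε ≪ 1 the compartments equilibrate quasi-statically
(f, g, h → 𝒫_a·c, v → 𝒫_v·c) and the macroscopic cytoplasmic
concentration obeys

    C_t + (U_eff C)_x = (D_eff C_x)_x − Q_eff C,
    D_eff = (K(l+λ)+M)(l+λ)/V,

with K = (ωP_ca/2 + ωP_plas)/(1+λ), M = λ𝒫_a and
V = ω(1−φ)l + ωφl𝒫_v + λ(ω+λ+l)𝒫_a. U_eff collects the material growth
velocity u (from the continuity equation for cell density 1/(l+λ)) plus
terms in ∂l/∂x and ∂V/∂x; Q_eff is the dilution sink. The conserved
density is V·C/(l+λ) — concentration × capacitance × cell density — in
which weighting the static equation is exactly in divergence form with
flux −(K(l+λ)+M)C_x; the sealed-file mass-conservation test uses this
weighting.

Special cases used throughout:

* static identical cells — pure diffusion with the closed-form D_eff
  above at l = 1, solved either by method of lines or by the
  separation-of-variables series (the two agree to <1e−3, a cross-solver
  oracle);
* asymptotic limit regimes — for GA, 𝒫_a, λ = O(ε) and P_ca = O(ε²)
  (short cells; additionally ω = O(ε), λ = O(ε²) for long cells), giving
  scaled diffusivities on the slow time t̄ = ε²t. Each
  `LimitDiffusivity` carries a `time_scale` tag ("t" vs "tbar") so the
  dimensional conversion (D·D_apo vs D·ε²·D_apo) is unambiguous;
* identical linearly growing cells — solved on the fixed interval
  ξ = x(1+λ)/(l+λ), where advection cancels and
  Q = (1/V)dV/dt; with growth by vacuolar expansion ((1−φ)l constant)
  dV/dt = (ω𝒫_v+λ𝒫_a)dl/dt, and the large-time profile is
  C_eq = cosh(√β(1−ξ))/cosh(√β) with
  β = κ(ω𝒫_v+λ𝒫_a)/((1+λ)(ωP_ca/2+ωP_plas));
* static spatially varying cells — u = 0 but gradients of l and φ induce
  an effective velocity; the solver uses the equivalent form
  V C_t = (K(l+λ)+M)(l+λ)C_xx + K(l+λ)l_x C_x, which is algebraically
  identical to the U/D/Q form but avoids differentiating U_eff.

### Induced velocity diagnostics

The ratio of cytoplasmic to area-weighted average concentration is
C/𝒞 = 𝒱/V with 𝒱 = (l+λ)(ω+λ); U_eff(x) = (K(l+λ)+M)/(ω+λ)·d(𝒱/V)/dx
identically, so the sign of the ratio gradient is the sign of the
induced velocity. The closed-form general gradient is verified against
numerical differentiation of the ratio in the tests (both routes kept,
since a sign error here would invert the headline biological claim).
For constant cytoplasmic area σ = (1−φ)l, increasing-length files
advect forward iff 𝒫_v < (σ+λ𝒫_a)/(σ+λ) — satisfied when the tonoplast
importer is absent (𝒫_v ≈ B1/C1 ≈ 0.03).

### Growth and division

Cell lengths and vacuolar fractions are *prescribed* fields (no
mechanics): static uniform, linear in time (κt+1), linear in space
(αx+ν, discretised by a fixed-point iteration so each cell's length
equals the profile at its own centre), or exponential growth with
synchronous division. Dividing cells double in one inter-division time
T (µ = ln2/T) and split into two daughters plus a new wall; the
per-cell length follows
l_d = (1−λ(1−2^(−⌊t/T⌋)))·e^(µ(t−T⌊t/T⌋)). This law conserves total
file length exactly at the first division and to an O(λ/2) wall-
insertion correction at later ones, while keeping l_d — and hence
D_eff(t) — asymptotically T-periodic; the alternative bookkeeping that
conserves length exactly at every event (prefactor 1−nλ/2) loses the
periodicity, so the periodic form is used consistently in both the
discrete simulator and the continuum coefficients. At an event,
daughters inherit the mother's c, v, h; the new transverse/corner wall
compartments start at the quasi-static value 𝒫_a·c (mass error O(λc),
erased within the fast compartment transient). In the continuum solve
the ξ-map uses the *undivided* exponential growth for the domain length
(division repartitions the file but does not change its total growth)
while D_eff and Q_eff follow l_d.

## Parameters and defaults

The presets store dimensional primaries only; all dimensionless values
are derived at load time. GA in the *Arabidopsis* root: pK 4.2, pH 5.3
(apoplast) / 7.0 (cytoplasm) / 5.5 (vacuole), membrane potentials
−120 mV (plasma membrane) and −30 mV (tonoplast) at 300 K,
permeabilities P_pass 0.333, P_imp 0.017, P_exp 0.556, P_plas 0.81 µm/s,
D_apo 32 µm²/s; geometry 20 cells, width 10 µm, wall 0.5 µm, with
`ga_short` (l = 20 µm, φ = 0.1) and `ga_long` (l = 200 µm, φ = 0.91 —
the same cytoplasmic area as the short cells, elongation being by
vacuolar expansion). Simulation scenarios follow the same study
conditions: growth rates κ = 0.001–0.1, the 20→200 µm spatial file with
φ from 0.1 to 0.9, and division runs starting from two 5 µm cells with
a 10 h inter-division time (T ≈ 9.5×10³ in the 2-cell file's time
units, where one unit is L̂₀²/D_apo ≈ 3.8 s).

## Numerical choices

* GHK factor: series 1 − φ/2 + φ²/12 for |φ| < 1e−6 (removable
  singularity), φ/expm1(φ) otherwise; stable beyond |φ| = 50.
* Linear-file fixed point: iterate centre positions ↔ profile
  evaluation from a linear-in-index start; tolerance 1e−12 relative,
  max 1000 iterations (the map is a mild contraction for realistic
  gradients; non-convergence signals inconsistent inputs).
* Discrete integrator: BDF with the analytic Jacobian of the linear
  flux operator (the ε²-scaled capacitances make the system stiff);
  default rtol 1e−8, atol 1e−10. The operator is assembled by probing
  the vectorised right-hand side with unit vectors — exact for a linear
  system and rebuilt per Jacobian evaluation when coefficients are
  time-dependent.
* Continuum solver: method of lines with 100 grid points (second-order
  central differences; ghost-node reflection for no-flux ends), BDF in
  time. The upstream Dirichlet value jumps from 0 to 1 at t = 0⁺,
  matching the separation-of-variables solution.
* Profile derivatives are analytic per profile kind, never finite
  differences, so U_eff and Q_eff are exact; the only numerical
  differentiation is the optional dU/dx for general mixed profiles
  (central difference, h = 1e−6), which no solver path uses.
* Division instants t = nT evaluate to the post-division (right-limit)
  state: events carry the new cell count.

## Scope of the tests

The test suite generates every scenario programmatically from the
presets; there are no external data. What passing shows: the chemistry
chain reproduces the published reference values to their printed
precision; the discrete and continuum models — built from independent
formulations (compartment ODEs vs homogenised PDE) — agree within 0.05
at N = 20 across static, growing, spatially varying and dividing files;
conservation, linearity, quasi-static structure and the velocity-sign
criterion hold as exact identities. What it does not show: agreement
with living tissue. Real roots have asynchronous division, mechanically
regulated growth, hormone metabolism, radial transport between files
and transporter saturation, none of which are modelled.

## Known limitations

* Fluxes are linear (no Michaelis–Menten saturation of transporters).
* Growth is kinematic: lengths are inputs, not outputs of mechanics.
* The discrete solver supports uniform (possibly growing/dividing) and
  static spatially varying files; fully general l(x, t) is available in
  the coefficient/velocity analysis only.
* The division length law trades exact per-event length conservation
  (O(λ/2) error after many events) for asymptotic periodicity; both
  bookkeepings coincide for thin walls and at the first event.
* One radial cell file only; no exchange with neighbouring files.
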