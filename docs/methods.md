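# Methods

## Model

The simulator couples two univoltine insect populations through a seasonal
hybrid dynamical system. Within a year, adults and eggs of the parasitoid
(*Torymus sinensis*: p, q) and of the gall wasp (*Dryocosmus kuriphilus*:
u, v) obey ODEs (homogeneous form) or reaction-diffusion PDEs (spatial
form); across years, only the egg densities survive: the parasitoid phase of
year *n* starts from p_n(0) = q_{n−1}(ητ) and consumes the pest egg density
v_{n−1}(1), and the gall-wasp phase emerges at the constant rate
c = v_{n−1}(1) − q_n(ητ), the unparasitized fraction.

Assumptions inherited from the model's derivation:

- the parasitoid suffers no adult mortality within its season (no natural
  enemies; lifespan equals the season), and its oviposition is limited only
  by unparasitized host larvae;
- gall-wasp adults live a ≪ T_d days, emerge at a constant rate through the
  season, and lay into the remaining bud capacity;
- overwintering mortality is a constant fraction per species (η for the
  pest — thelytokous, so up to 1; γ < 0.5 for the sexual parasitoid);
- in the spatial form only *adults* disperse (eggs sit in galls), with
  constant diffusivities; the domain boundary is insulated (zero flux).

One printed equation is internally inconsistent in its source: the q̇
equation's driving term is written with the *current* season's end-of-season
pest density, which does not exist yet when the parasitoid flies. The
dimensional derivation and the ṗ row both use the previous season's density,
so we use v_{n−1}(1) in both parasitoid equations.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| η | pest overwintering survival | required, studied at 0.65/0.75/0.85 | – |
| γ | parasitoid overwintering survival | 0.47 | – |
| N_d, N_t | max eggs per female | 150, 71 | eggs |
| T_d | pest season length | 40 | days |
| T_t | parasitoid season length | = T_d (then τ = 1/η) | days |
| a | pest adult lifespan | 4 | days |
| M, β_max | eggs per bud, bud density | 5, 2·10⁶ | –, buds/ha |
| D_d, D_t | diffusivities | 0.889, 0.016 | km²/day |

Derived: μ = T_d/a = 10, E_d = ηN_d, E_t = γN_t = 33.37, δ = D_t/D_d ≈ 0.018,
V_max = M·β_max = 10⁷ eggs/ha, survival threshold 1/V_max = 10⁻⁷ (one insect
per hectare; divided by the monitored area in hectares for larger woodlands).
The length unit is √(D_d·T_d) ≈ 5.96 km, so the canonical 4×4 domain is
roughly 24×24 km². (The figure of ≈5.5 km per unit sometimes quoted for this
parameter set is not recoverable from √(D_d·T_d) with these constants; we
document the discrepancy and use the defining expression.)

τ defaults to the equal-season simplification 1/η; supplying T_t switches to
the exact T_t/(η·T_d).

## Numerics

**Cancellation-free emergence.** After a crash season the emergence rate
c = v_prev − q(ητ) is the residual of near-total parasitism and decays like
exp(−E_t·p₀·t/τ): far below the 10⁻¹⁶ relative floor of double-precision
subtraction. Forming c as a difference makes every deep minimum an artifact
of solver noise (we verified the direct (p,q) integration does not converge
even at rtol = 10⁻¹³, with minima wandering by tens of decades). The
parasitoid phase is therefore integrated in the redundant variables
(p, q, s) with s = v_prev − q carried as an unknown (ṡ = −q̇): q is accurate
when q is small, s is accurate when s is small, and q + s = v_prev holds to
solver tolerance. The transformed phase is logistic with a closed form,

    p(t) = A·p₀ / (v_prev·e^{At/τ} − E_t·p₀),  A = v_prev − E_t·p₀,
    s(t) = A·v_prev·e^{At/τ} / (v_prev·e^{At/τ} − E_t·p₀),

used in the tests as an independent oracle. With this formulation the
300-year homogeneous minima are converged to two decimals in log₁₀ across
rtol = 10⁻⁸…10⁻¹¹.

**Integrators.** Adaptive Dormand–Prince 4(5) (scipy RK45) everywhere.
Homogeneous: rtol = 10⁻⁸, atol = 0 (pure relative control; exact-zero initial
states are handled by closed-form shortcuts, and an explicit first step
avoids the zero-state step heuristic), so densities spanning 60+ decades stay
resolved in relative terms. Spatial: rtol = 10⁻⁶, atol = 10⁻¹² — fields pass
through exact zeros there, and the reported spatial minima (≳10⁻¹⁰) sit well
above the absolute floor.

**Discretization.** Regular cell-centered grid, 5-point Laplacian, Neumann
closure by ghost-cell reflection (edge padding): constant fields map to
exactly zero and the operator conserves mass to rounding. Default spacing
h = 0.05 nondimensional units, half the coarsest admissible value (0.1).
Adequacy is enforced by tests rather than by replicating any particular
discretization: (i) spatially uniform runs reproduce the homogeneous engine
to 10⁻⁶; (ii) halving h from 0.1 to 0.05 in the corner-release experiment
moves probe log₁₀ v by < 0.04 (the convergence test uses a grid-independent
release footprint of radius 0.15 so both grids solve the same continuum
problem); (iii) the discrete Neumann eigenvalue of cos(πx/L) converges at
O(h²).

**Clipping and clamping.** Emergence is clipped at zero (absorbs solver
overshoot ≤ tolerance); end-of-season fields are clipped to [0, 1]. Optional
extinction clamping (densities below the effective threshold set to zero and
flagged) is off by default: reported series are the raw model output and
threshold crossings are a diagnostic, not a dynamical event.

## Scenarios and study conditions

Homogeneous runs: v₀ = 1 (fully infested), q₀ = 10⁻⁹ (a few parasitoids per
km²), 300 seasons. Spatial runs: 4×4-unit domain (≈ 24×24 km²), 35 seasons
(the canonical corner-release maps span 33), fully infested, parasitoid
introduced by releases. A release sets p to amplitude 1.0 on the single grid
cell nearest each station ("maximal" local density); the released amount
(amplitude × cell area) is logged. Lattice layouts place stations at the
(k+1)² vertices of a regular lattice spanning the domain — the only reading
consistent with the quoted spacings 4, 2, 4/3, 1 for k = 1…4 and with the
monitoring point (1,1) being a station of the finest lattice. The first
release happens at the start of season 1; outputs are labeled by seasons
since that release (all comparisons use gaps or minima, which are invariant
to the label origin).

**Release-footprint sensitivity.** The single-cell footprint ties the
released mass to the grid (amplitude × h²). For the corner-release probe
minimum this matters only at the factor-of-a-few level (probe minima with a
one-cell release at h = 0.05 vs a radius-0.15 disc differ by ≲0.3 decades;
both are order 10⁻⁴), because establishment is exponential in time and only
logarithmic in the released mass. Grid-convergence testing uses the disc
footprint for exactly this reason.

## Diagnostics

Threshold crossings are strict inequalities on end-of-season values;
`time_to_suppression` reports the gap from parasitoid establishment
(q > 0.1) to pest extinction (v < 10⁻⁷, scaled by monitored area).
"Implantation" is operationalized as consecutive seasons with v > 0.9
(near-saturation) after the first suppression below that level; the level is
a parameter because the concept is verbal, and results are
interpretation-sensitive at the ±1-season level. Front radii are medians over
radial transects of the first outward crossing of v through an iso-level
(default 0.5). Cycle periods are intervals between local maxima of log₁₀ v
above 10⁻² (plateau-aware, since v saturates at exactly 1 for whole years).

## Known limitations

- The deterministic model produces absurdly low deterministic minima
  (10⁻⁵⁰ and below); in reality demographic stochasticity and refugia
  dominate long before. The deep minima should be read as "locally extinct",
  and their printed decades depend on nothing observable.
- Any solver that forms the emergence rate as the direct difference
  v_prev − q at finite tolerance floors the deep minima at its own noise
  level (typically pest ~10⁻⁹…10⁻¹², parasitoid ~10⁻³⁰…10⁻⁵⁰, and ~10⁻⁶ for
  spatial runs at looser PDE tolerances) — such numbers are solver artifacts
  and differ, by many decades, from the converged residuals this
  implementation computes (pest ~10⁻¹⁷ at η = 0.85, parasitoid ~10⁻⁶⁶ at
  η = 0.65, spatial lattice minima ~10⁻¹⁰). Shallow minima (corner-release
  ~10⁻⁴) and establishment timing are insensitive to the formulation.
- No phenology or temperature dependence: all rates are season constants.
- No habitat heterogeneity, advection, or unstructured geometry; domains are
  rectangles with zero-flux boundaries.
- Synthetic initial conditions (uniform infestation, point releases) are the
  study conditions, not fits to survey data; passing tests demonstrate
  correctness of the numerics and the stated phenomenology, not predictive
  skill for any particular orchard.
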