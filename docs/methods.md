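# Methods

## The model in brief

The package implements a three-layer analytical description of 2D water.
Layer one is a variable-structure cell theory: each molecule has three
equivalent arms at q = 120°, each arm independently in a hydrogen-bond
(HB), Lennard-Jones (LJ), or noninteracting (0) pair state, with the
cooperative all-bonded hexagon (s state) added as a correction to the
six-arm expansion of the hexagon partition function

    Q1 = (Δ_HB + Δ_LJ + Δ_0)^6 − Δ_HB^6 + δ Δ_s^6,   δ = exp(−β ε_c).

Layer two converts the state populations f_i into a diffusion
coefficient through a state-resolved random walk.  Layer three grows
stochastic "snowflake" clusters whose bond types are sampled from the
same populations, giving access to radial, angular, and spatial
distribution functions that a partition function alone cannot provide.

## The statistical weight model

The hexagon skeleton above fixes only how per-arm weights combine, not
their functional forms.  This package constructs them as

    Δ_j = Ω_j(T) · exp(−β (u_j_min + p v_j))

with:

| state | Ω_j | v_j (cell area) |
|---|---|---|
| HB | a · ∫_{−π/3}^{π/3} e^{−β k_s θ²} dθ | x_v · (3√3/4) r_HB² |
| LJ | a · (2π/3) | (√3/2) σ_LJ² |
| 0  | T/p | T/p |
| s  | a · ∫_{−π/3}^{π/3} e^{−β k_s θ²} dθ | (3√3/4) r_HB² |

Rationale: (3√3/4) r_HB² is the exact area per site of an ideal honeycomb
with bond length r_HB (the all-bonded solid), the liquid HB cell is that
area rescaled by the preset factor x_v, the LJ cell is the hexagonally
close-packed cell of discs of diameter σ_LJ, and the noninteracting cell
is the 2D ideal-gas area T/p (which also makes Δ_0 = (T/p)·e^{−1}, the
exact isothermal–isobaric cell integral for a free particle).  The
radial well width a multiplies the HB/s angular integral and the free
2π/3 angular sector of an LJ contact.  With the shipped MB-rose
parameters this construction yields, at p* = 0.19: ground-state
dominance of the s state at low T, a melting step near T* ≈ 0.15, a
density maximum (sign change of α_p) inside T* ∈ [0.1, 0.3], and
HB-dominated populations in the cold liquid — the qualitative profile
the theory is meant to produce.  The weight model is pluggable
(`state_weights(..., model=...)`): any object returning `StateWeights`
drops in, and populations, thermodynamics, and the snowflake generator
follow it unchanged.  Absolute offsets of g and h depend on
normalization constants (thermal wavelengths) that cancel in all
reported response functions, so only derivatives of g are treated as
observables.

## Thermodynamics and diffusion

All response functions are centered finite differences of
g = −T ln Q1/6 with relative step 1e−4 (configurable): v = ∂g/∂p,
h = ∂(g/T)/∂(1/T), α_p, κ_T, c_p as second differences.  The identity
v = Σ f_i v_i holds analytically for the default weight model and is
enforced as a consistency test at the 5% level (finite-difference error
only).  Near the melting step the weights switch over a narrow
temperature interval; derivatives there are reported as computed, never
smoothed, and the step-stability property (halving the step changes
responses by <1%) is only asserted away from that region.

Diffusion: λ_HB = λ_s = r_HB, λ_LJ = σ_LJ, λ_0 = √(T/p) (a distance must
scale as the square root of the 2D cell area), ν_i = C exp(β⟨u_i⟩) with
⟨u_HB⟩ = −ε_HB − ε_LJ + k_s⟨θ²⟩ computed by adaptive quadrature on the
truncated window (−π/3, π/3), ⟨u_s⟩ = ⟨u_HB⟩ + ε_c (a cooperative HB is
an HB plus the cooperative energy), and ⟨u_i⟩ taken as energy-only (no
pV contribution).

## The snowflake generator

Growth starts from a central molecule at the origin with arm 0 along
0°; the lab frame therefore *is* the body frame in which all
distributions are accumulated.  Randomizing the central orientation
would only rotate each replica rigidly and change no distribution.  Per
arm (three for the center, two thereafter) a bond type is sampled with
probabilities (f_HB + f_s, f_LJ, f_0) — the cooperative energy already
acted through the populations, so the s state simply counts as HB here.
Bond lengths: r_HB; r_LJ = σ_LJ·2^{1/6}; r_0 = √(T/p) + r_LJ (again the
square-root reading of the 2D cell area, consistent with λ_0).

Placement noise uses standard deviations (not variances)
σ_r = A√(T/(m_1 k_j)) and, for HB only, σ_θ = A√(T/(m_3 k_HB)); LJ and
noninteracting contacts have no angular spring and draw Z_θ uniformly on
(−π/3, π/3).  This is the equipartition spread √(T/k) of each harmonic
well with the empirical mass/inertia and scale factors inserted under
the root; it gives σ_r ≈ 0.05 for an HB at T* = 0.2, a physically
sensible bond-length jitter, and vanishes as T → 0 so the zero-noise
limit is exact.  A draw with r_j + Z_r ≤ 0 counts as a failed attempt
(the Gaussian tail would otherwise invert the bond); k_0 = 0.001 makes
σ_r for the 0 state so large that noninteracting neighbors are scattered
broadly, which is what keeps the RDF from decaying at high T.

Each placement is retried up to 10 times with fresh noise while keeping
the same source molecule, arm, and bond type; on failure only that arm's
branch terminates — siblings keep growing.  The hard-core rule rejects
candidates within σ_LJ − 0.05 of any existing molecule; the single
exception is a shell ≥ 2 candidate within r_LJ of the *central* molecule,
accepted with probability exp(−k_LJ(r − r_LJ)²/T), which keeps the RDF
continuous at small r.  The exception is checked against the central
molecule only, as the distributions are central-referenced.

Two engines implement the identical algorithm: a pure-Python reference
built from the documented operation functions, and a numba kernel used
for production ensembles (~10^4 replicas in well under a minute on one
core).  Their random streams differ, so reproducibility is per engine
and seed; tests verify they coincide exactly in the deterministic
zero-noise limit and statistically at finite temperature.

## Structure estimators

All distributions are referenced to the central molecule, not all pairs:
the body frame is defined there, and central referencing removes
cluster-edge bias.  The RDF divides the pooled distance histogram by
(replicas × ρ_ref × annulus area), with ρ_ref the cell-theory density at
(T, p) and an optional plateau rescaling; its support is restricted to
r ≤ 4 r_HB by default because a 9-shell cluster only surrounds the
center out to roughly that radius.  ADFs histogram atan2(y, x) for
molecules in a radial window (default half-width 0.05 r_HB, 2° bins)
normalized to unit circular mean, over the full circle by default.  The
model has exact C3 and mirror symmetry, so an optional folding maps
angles into the fundamental [0°, 60°] sector, a six-fold variance
reduction used when locating peak positions.  The SDF is a plain 2D
histogram normalized per replica, cell area, and ρ_ref.  Peak finding
reports strict local maxima above a prominence threshold at bin centers,
ties toward smaller location.

## Problem sizes and defaults

Default growth configuration follows the production settings: 9 shells,
10 attempts, overlap margin 0.05, and 100,000 replicas.  The shipped
analyses and the acceptance script use 10,000 replicas, which locates
every reported peak to well within its quoted tolerance (seed-to-seed
scatter ≈ 1 bin); trend tests use 1,500 replicas per temperature.

## Known limitations

* The molecule has only three interaction sites: hexagonal interstitial
  sites are never directly occupied, so the LJ first-shell peak at low T
  and the 0° ADF feature at r = 2.0 seen in disc simulations with
  half-bonds are intentionally absent.
* The solid is an idealized perfect honeycomb; densities and response
  functions below the melting step underestimate the disorder (and
  density) of a real 2D ice with filled interstitials.
* The weight model above is this package's documented construction of
  the per-arm cell integrals; alternative constructions can be swapped
  in through the `WeightModel` interface without touching callers.
* The generator is a direct sampler — no periodic boundaries, cluster
  energies, or Metropolis dynamics — and parameter fitting (e.g. of the
  density curve) is out of scope; parameters come from the shipped
  presets.
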