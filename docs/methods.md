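# Methods

## The model

`socioclimate` couples two deterministic subsystems through two scalar
channels.

### Rumor contagion on a heterogeneous network

Nodes are grouped into degree classes k with probabilities p_k (a
`DegreeDistribution`). Per class, four compartments (fractions of the
class): susceptible s_k, hesitator h_k, believer i_B,k, rejector i_R,k.
Transitions:

* **Individual channel** — rates proportional to c̄·k times the contact
  sum Θ_x = Σ_j p(j|k)·x_j. With the uncorrelated closure
  p(j|k) = j·p_j/⟨k⟩ the sum is class-independent. Exposure
  (β, against Θ_{i_B}), resolution of hesitators (η and ε, against Θ_h),
  believer forgetting (α, against Θ_{i_B}) and rejector forgetting
  (γ, against the class's own i_R,k).
* **Group channel** — broadcast coefficient Ḡ·m̄·d̄ acting on local class
  densities: exposure ς·s_k·i_B,k, believing ω·h_k, rejecting ζ·h_k,
  forgetting ρ·i_B,k and σ·i_R,k.
* **Turnover** — joining flow B into s only; exit rate μ from every
  compartment. Fractions are not renormalized, so B ≠ μ lets per-class
  totals drift; the baseline uses B = μ so totals are conserved.

Two structural quirks of the governing equations are implemented exactly
as stated and deserve attention:

1. The hesitator-resolution and believer-forgetting outflows are driven
   by the *neighborhood* densities Θ_h and Θ_{i_B}, not by the class's
   own density. Per class these are not mass-action fluxes; summed over
   classes they coincide with the own-state form because
   Σ_k p_k·k·x_k = ⟨k⟩·Θ_x.
2. Rejector forgetting (γ·c̄·k·i_R,k) carries no contact sum.

Consequences, verified numerically: the system conserves per-class mass
when B = μ = 0 (all fluxes cancel in pairs within a class), but it is
**not positivity-preserving** on multi-class networks — at the baseline
the transient dips to about −0.03 in individual classes, and for very
low forgetting rates (γ = σ ≈ 10⁻³) trajectories blow up in finite time.
On a single degree class the closure collapses to own-state terms and
the system is a proper compartment model with nonnegative trajectories.
The sensitivity instruments therefore record NaN for grid cells whose
integration fails rather than aborting.

The contact sum supports a `literal` mode carrying an additional p_j
factor (matching one reading of the degree-block sums); the default is
the standard row-normalized closure. Population aggregates are
p_k-weighted (Σ_k p_k·x_k, bounded in [0, 1] regardless of the class
count); a literal unweighted `sum` mode exists for sensitivity checks.

### Climate

One carbon stock and one temperature box:

* dC/dt = E(t) for t ≤ 2021 (historical emissions, linearly
  interpolated); afterwards dC/dt = E₂₀₂₁·e^(−Ψ·i_R) − δ·C. C is carried
  in GtCO₂ and converted to concentration inside the forcing via
  `gt_per_ppm` (7.82 GtCO₂ per ppm).
* F = (F₂ₓ/ln 2)·ln(C_atm/C₀) with C_atm = C₀ + C/gt_per_ppm.
* dT/dt = (q·F − T)/d: relaxation toward the equilibrium anomaly q·F
  with e-folding time d years. A `literal` mode dT/dt = q·F − T·d (d as
  a rate) is selectable for sensitivity to the alternative reading of
  the governing equation; the box form is the default because it is
  dimensionally consistent and matches the cited one-box emulator.

The historical spin-up integrates both from zero state over the
emission series (default 1850–2021). The default applies no sink before
2021 — the letter of the carbon law, implying a 100% airborne fraction —
with `sink_in_spinup` available to subtract δ·C throughout.

### Coupling

η(T) = η₀·e^(−v·T) and ω(T) = ω₀·e^(−v·T), re-evaluated continuously
inside the integrator (the coupled equations carry no lag), with T the
instantaneous anomaly. A cooling (T < 0) can push the value above the
base probability; it is capped at 1 with a logged warning. The rejector
aggregate entering the emission law is the p_k-weighted i_R.

## Baseline study conditions

Rumor side (rates per year; probabilities dimensionless):

| parameter | value | notes |
|---|---|---|
| B, μ | 0.01, 0.01 | balanced slow turnover |
| β, ς | 0.3, 0.3 | hesitating probabilities (individual, group) |
| η₀, ω₀ | 0.2, 0.2 | baseline believing probabilities |
| ε, ζ | 0.3, 0.3 | rejecting probabilities |
| α, ρ | 0.05, 0.05 | believer forgetting (individual, group) |
| γ, σ | 0.01, 0.01 | rejector forgetting — low, see below |
| c̄ | 27 | contacts per individual |
| d̄ | 1.0 | messages per group |
| X, m̄ | 40, 70 | groups and mean group size |
| Ḡ | 0.28 | = X·m̄/N with N = 10 000 |
| v | 0.2 per °C | temperature sensitivity of believing |

Climate side: q = 0.33 °C/(W m⁻²), d = 4.1 yr, F₂ₓ = 3.74 W m⁻²,
C₀ = 278 ppm (standard one-box emulator constants), δ = 0.01 yr⁻¹
(century-scale dissipation of the carbon deviation), Ψ = 11 (strong
baseline mitigation), E₂₀₂₁ = 37 GtCO₂ yr⁻¹.

Network: truncated power law on degrees 1–20 with the exponent solved so
⟨k⟩ = 10 (20 degree classes; class count trades closure accuracy against
ODE dimension). X and m̄ reach the dynamics only through Ḡ = X·m̄/N, so
varying either in a sweep recomputes Ḡ; ⟨k⟩ is itself a sweepable
parameter (`k`) that re-solves the exponent.

Two baseline choices are deliberate deviations from a literal reading:

* **Rumor seed.** The all-susceptible state is an exact equilibrium — a
  rumor with no believers never ignites. Scenarios therefore seed 1% of
  each class as believers at the 2021 onset (`rumor_seed = 0.01`;
  setting 0 recovers the literal frozen state).
* **Rejector forgetting.** Very low γ, σ push the long-run rejector
  share toward ~0.8 but sit inside the blow-up regime described above;
  0.01 keeps the model stable and yields a majority-rejector population
  (i_R ≈ 0.47–0.49) with the same qualitative structure (temperature
  ordered by Ψ, below 1.5 °C under strong mitigation).

Note that q = 0.33 °C/(W m⁻²) is the *fast* upper-ocean response; the
implied equilibrium warming per CO₂ doubling (≈ 1.2 °C) is below
consensus central estimates, so absolute temperatures are conservative.
The structure, not the absolute calibration, is the object of study.

## Numerical choices

* Default integrator: LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰, sampled on the
  annual grid via the solver interpolant. Compartments are never clipped
  inside the integrator.
* A fixed-step classic RK4 (`method="rk4"`, default 200 steps/year where
  used) exists for exact step-for-step reproducibility; with v = 0 and
  Ψ = 0 the coupled system is block-diagonal, so a fixed-step joint run
  equals the separately integrated components bit for bit — the
  decoupling check in the test suite uses this.
* Equilibria: Powell hybrid root-find on the packed state, residual
  tolerance 10⁻¹⁰; stability read off the leading eigenvalue of a
  central finite-difference Jacobian (step 10⁻⁷).
* ABC distances: Euclidean after scaling each summary by the target's
  magnitude (prior-predictive spread for exactly-zero entries);
  quantile acceptance (default best 1%) so a run always returns an
  ensemble. Spin-up is reused across draws whenever no sampled parameter
  reaches the historical window.
* Tornado: probabilities perturbed past [0, 1] are clamped with a logged
  warning. "Peak" in sweep records is the post-onset maximum with its
  (earliest) year; for monotone series this is an endpoint.

## What the synthetic data does and does not emulate

`make_emission_ramp` produces a logistic industrial-era ramp — slow
nineteenth-century take-off, rapid twentieth-century growth, modern
plateau — anchored exactly at a configurable 2021 value (default
37 GtCO₂ yr⁻¹). Under the default constants it lands the 2021 anomaly at
≈ 0.94 °C, inside the sanity band 0.5–2.0 °C asserted by the tests. It
does not reproduce year-to-year variability, wars/recessions, or
land-use accounting of real emission records; any real annual CSV with
`year, GtCO2_per_year` columns drops in via the same reader. Passing
tests on the ramp therefore validate model mechanics and code, not
historical fidelity.

`make_abc_fixture` generates calibration targets from a known parameter
set, so ABC tests measure parameter *recovery* under the model's own
dynamics — the favorable case; with real observational targets,
identifiability would also be limited by model misspecification.

## Validation strategy

The agent-based fidelity check simulates 2,000 agents in three degree
classes with per-contact rules whose aggregate mean field is the
governing system: exposure gated on believer contacts, resolution and
forgetting at rates proportional to own degree (aggregate-equivalent to
the neighborhood-driven fluxes, see above). Partners are drawn per
contact with the edge-following probability ∝ j·p_j — the annealed
setting in which the degree-block closure is exact as N → ∞ — and the
measured gap in final rejector share is ≈ 0.3 percentage points. On a
static (quenched) configuration-model graph the gap grows to ~10–13
points; that difference measures the pair correlations the closure
neglects, a known property of heterogeneous mean-field approximations,
not an implementation error. Both contact structures live in the test
harness (`tests/abm_oracle.py`).

## Known limitations

* The positivity failure and low-forgetting blow-up described above are
  properties of the governing equations as stated; results in those
  corners of parameter space should not be interpreted physically.
* One carbon stock and one thermal box: no ocean heat uptake layers, no
  non-CO₂ forcings, no explicit land/ocean partition (all collapsed
  into δ), and a fast-box-only q that understates equilibrium warming.
* No rumor content, no competing rumors, no demographic or attitudinal
  structure beyond network degree.
* The ABC implementation is plain rejection sampling with quantile
  tolerance; no sequential refinement, no posterior density estimation
  beyond histograms of the accepted ensemble.
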