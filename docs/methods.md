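# Methods

## Model and assumptions

The package studies a deterministic two-gene activator–inhibitor motif:
protein P_b activates transcription of gene *a*, protein P_a represses
gene *b*, neither gene regulates itself. Regulation is sigmoidal (Hill
functions with threshold θ and integer coefficient n); transcription and
translation are single delayed steps with discrete delays; degradation is
first order. Concentrations are in arbitrary concentration units and rates
in inverse time units; all benchmark sets use O(1) rates, so "time" is of
order the protein half-life.

Two descriptions are maintained side by side:

* the **complete model** (four variables, four delays τ_ra, τ_rb, τ_pa,
  τ_pb), and
* the **reduced model** (two proteins, one lumped delay
  τ = τ_ra + τ_pa + τ_rb + τ_pb), obtained by the quasi-steady-state
  assumption ṙ_i ≈ 0, valid when mRNA turnover is much faster than protein
  turnover.

Delays do not move fixed points, so both models share their equilibria.
Solutions from nonnegative histories (with strictly positive initial mRNA
in the complete model) remain nonnegative; the integrator treats this as
an enforced runtime invariant, not an assumption.

## Equilibria

Eliminating r_a, r_b and p_b from the stationarity conditions leaves one
polynomial in p̄_a. With S = θ_a^{n_a} + p̄_a^{n_a} and equilibrium scales
φ_i = m_i k_i/(γ_i δ_i):

θ_b^{n_b} · p̄_a · S^{n_b} + φ_b^{n_b} θ_a^{n_a n_b} (p̄_a − φ_a) = 0.

Its left side is strictly increasing on p̄_a ≥ 0 and negative at 0 for
fully positive parameters, so exactly one positive equilibrium exists
there; the solver nevertheless returns *all* nonnegative real roots (the
degenerate p̄_a = 0 branch appears when a transcription rate is zero) and
runs the stability analysis per equilibrium. One derivation subtlety: the
linear and constant terms carry the common factor φ_b^{n_b} θ_a^{n_a n_b};
a simplified form sometimes quoted for this motif drops that factor and
does not satisfy the stationarity conditions — the implementation keeps
the full expression and every returned equilibrium is verified against the
raw fixed-point equations (residual ≤ 1e−9, default, overridable).

Roots come from companion-matrix eigenvalues (`numpy.roots`) with a Newton
polish on the exact coefficients; a root counts as real-nonnegative when
|Im| ≤ 1e−8·max(1, |Re|) and Re ≥ −1e−12 (clamped to 0). The degree is at
most n_a·n_b + 1 ≤ 65 for n ≤ 8, well inside what the companion matrix
handles accurately after polishing.

## Stability analysis

**Reduced model.** The characteristic equation is
(λ+δ_a)(λ+δ_b) + D e^{−λτ} = 0 with coupling strength
D = k′_a k′_b |dh⁺/dp_b| |dh⁻/dp_a| evaluated at the equilibrium, which
the fixed-point relations simplify to
D = n_a n_b δ_a δ_b · [p̄_a^{n_a}/S_a] · [θ_b^{n_b}/S_b]. Both forms are
computed and must agree to 1e−10 — a built-in consistency check that also
catches non-equilibrium inputs. At τ = 0 the quadratic is always stable.
Purely imaginary roots require z = ω² to solve
h(z) = z² + (δ_a²+δ_b²) z + δ_a²δ_b² − D² = 0, which has a positive root
iff δ_a δ_b < D; that inequality is the exact stable-for-all-delays /
Hopf dichotomy. Crossing delays satisfy the pair
ω² − δ_aδ_b = D cos ωτ, (δ_a+δ_b)ω = D sin ωτ.

**Quadrant handling.** The crossing angle is computed as
atan2(sin, cos) mapped to (0, 2π], not as a principal arctangent of the
ratio: the ratio alone is quadrant-ambiguous when ω² − δ_aδ_b < 0, and
adding π to fix the tangent produces delays at which the *pair* of
conditions fails (the characteristic function does not vanish there).
Consequently consecutive genuine crossings are spaced by a full period
2π/ω₀, and each reported delay is verified by the characteristic residual
|char(iω₀, τ₀,ₙ)| ≤ 1e−9. The crossing speed has the sign of h′(ω₀²) > 0,
so eigenvalues only ever move rightward: the first crossing decides.

**Complete model.** The quartic-plus-delay characteristic equation uses
(A, B, C, D) = elementary symmetric polynomials of (γ_a, γ_b, δ_a, δ_b)
and D_c = m_a m_b k_a k_b |dh⁺||dh⁻| = γ_a γ_b D. The γ_a γ_b factor
matters: a simplified form of D_c that coincides with D is only valid when
γ_a γ_b = 1, and the implementation was checked against direct Jacobian
eigenvalues at τ = 0 with unequal rates. Stability at τ = 0 is decided by
the standard Hurwitz minors of λ⁴+Aλ³+Bλ²+Cλ+E, E = D + D_c:
Δ₁ = A, Δ₂ = AB−C, Δ₃ = ABC−C²−A²E, Δ₄ = E·Δ₃; for positive rates Δ₁, Δ₂
and E are automatically positive, so Δ₃ > 0 alone decides. Crossing
frequencies are positive roots of g(z) = z⁴+az³+bz²+cz+d (a = A²−2B,
b = B²+2D−2AC, c = C²−2BD, d = D²−D_c²), each resolved to its delay by the
same atan2 quadrant rule; τ₀ is the minimum over roots, and the crossing
speed there has the sign of g′(z₀). When the τ=0 check fails the crossing
analysis is skipped (the first-crossing theorem's hypotheses do not hold)
and the verdict is "unstable at τ=0". With several positive roots of g the
full delay table is retained, because opposite-direction crossings can
produce stability switches beyond τ₀ — the classifier's verdict covers
only the interval up to and immediately after the first crossing.

## Simulation

Method of steps with classical fixed-step RK4; lagged values are read from
the stored solution through cubic Hermite interpolation (locally O(h⁴), so
the scheme retains fourth order — confirmed by step-halving, error ratio
≈ 16). Every positive delay must be at least one step wide, which
guarantees the interpolation never reads ahead of the computed solution.
Zero delays short-circuit to the current RK4 stage value, making the τ = 0
runs exactly classical RK4 (validated against `scipy.integrate.solve_ivp`
at tolerance 1e−10 to within 1e−6). Undershoots below −1e−9 abort the run
with advice to shrink the step; smaller ones are clamped to 0 before the
Hill functions, preserving the positivity property rather than integrating
unphysical states.

Long-term classification inspects the trailing half of a run:
"converged" needs final distance to the equilibrium below 1e−4 of its
scale; "sustained oscillation" needs at least five consecutive peaks whose
heights — measured from the signal mean, so a slowly decaying transient is
not mistaken for a limit cycle — vary by less than 2%. Default histories
are constant at 10% of the equilibrium; the attractor verdicts tested are
history-independent for this motif at the benchmark parameters (checked
across random histories), though multistability in general delay systems
is not ruled out by this package.

Benchmark run sizes: the reduced-model runs use t_end = 200, step 0.005;
the complete-model convergence run below threshold uses t_end = 1000,
step 0.01, because the slowest eigenvalue just below the bifurcation
decays at only ~0.014 per time unit and the run must traverse that
transient to exhibit convergence.

## Verification oracle

`oracle_rightmost_root` approximates the rightmost characteristic root
independently of the analytic pipeline: damped multi-start Newton over
Re ∈ [−5R, 2R], Im ∈ [0, 10R] (R the largest decay rate), then an
argument-principle count over the rectangle strictly to the right of the
best candidate to certify no root was missed. The contour is sampled at a
density proportional to the delay-induced phase rate (τ radians per unit
length) before adaptive refinement — endpoint phases alone cannot detect a
full 2π loop inside one segment, which matters for large delays where
root chains crowd the imaginary axis. If the certificate finds missed
roots, Newton restarts densify inside the offending rectangle; persistent
inconsistency raises an oracle error rather than returning a guess. The
oracle is test infrastructure: slower and less precise than the analytic
path it checks, and deliberately independent of it.

## Randomised fixtures

`generate_fixture_params` draws kinetic rates log-uniformly on [0.3, 3],
transcription rates on [0.5, 5], thresholds on [0.2, 2] and Hill
coefficients from {2, 3, 4} — the O(1) regime in which the benchmark sets
live — and enforces a requested stability regime by rejection against the
reduced model's classifier. These draws exercise the code across the
dichotomy boundary but are not a model of any measured rate distribution;
passing the randomised suites demonstrates internal consistency of
analysis, oracle and simulation, not agreement with experimental GRN data
(no noise, no transcriptional bursting, no distributed delays).

## Known limitations

* Discrete delays only; distributed delays and stochastic (birth–death or
  delayed-SSA) dynamics are out of scope.
* No centre-manifold computation: the direction/criticality of the Hopf
  bifurcation is not derived, only the crossing and its transversality.
* No continuation: boundary grids recompute each point independently,
  which is robust at fold points but spends effort proportional to grid
  size.
* The integrator is fixed-step without error control; it is meant for the
  non-stiff O(1)-rate regime of this motif.
* Hill coefficients are restricted to integers ≥ 1 by construction;
  non-integer exponents are rejected rather than silently accepted.
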