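# Methods

## Model

The package implements a discrete-time, discrete-space neural field on a
bounded interval Ω = [a, b] with L layers. The update rule

V_{i,n+1}^(k) = α V_{i,n}^(k) + (1−α) Σ_{ℓ∈L_k} Σ_j β_ℓ W_ij^(k,ℓ) G(V_{j,n}^(ℓ)) + (1−α) S_i^(k)

is an exact-leak discretization of the continuous field equation: the
memory factor α = e^(−h) reproduces the membrane relaxation over a step h
exactly (not to first order as an Euler scheme would), and the interaction
integral is replaced by a midpoint Riemann sum with per-layer cell width
β_ℓ = |Ω|/M_ℓ. The factor (1−α) multiplies both the interaction sum and
the stimulus; this is the form consistent with the equilibrium condition
V = ΓG(V) + S (dropping it from the stimulus would shift every fixed
point). Layers form a line graph: L_k = {k−1, k, k+1} clipped at the ends,
and weight blocks between non-adjacent layers are exact zeros. Ragged
layer sizes are zero-padded to an L × M matrix; padded entries are masked
out of the update and stay zero. The step h is constant across the run;
time-varying steps and time-varying stimuli are not supported.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| h | time step, units of the membrane time constant | 0.8 (scenarios) |
| α | per-step memory, e^(−h); override in (0,1] for sweeps | derived |
| Ω | field domain | [−20, 20] (scenarios) |
| M | neurons per layer (midpoint grid) | 200 (scenarios) |
| σ⁺, σ⁻, σ₁, σ₂ | difference-of-Gaussians amplitudes/widths | 4, 1.5, 1, 4.5 |
| θ, v₀ | sigmoid steepness and threshold | 1, 0 |
| ν | resting level (S = ν + U) | −0.5 (scenarios) |
| V₀ | uniform initial field | −1.5 (scenarios) |

The sigmoid steepness and threshold have no canonical published values for
the scenario family; θ = 1, v₀ = 0 are the package defaults and both are
configurable, so scenario reproduction for sigmoid gains is qualitative
(regime-level: settling, excitation location, oscillation counts) rather
than bit-wise. The Gaussian external input is U(x) = (2π)^(−1/2)e^(−x²/2)
(negative exponent; the positive-exponent variant that sometimes appears in
transcriptions diverges and is rejected on plausibility). The multilayer
chain scenarios default to L = 200 single-neuron layers (the source
material is inconsistent between 200 and 250; the count is configurable).
The hard threshold uses the open-interval convention G(v) = 1 iff v > v₀,
so the threshold itself emits nothing; its derivative is 0 off-threshold
and a Dirac mass at v₀, guarded by an absolute tolerance of 1e−9 —
Jacobian construction errors out rather than silently linearizing on the
singular point.

## Stability analysis

`build_jacobian` returns the exact Jacobian of the one-step map: diagonal
blocks αI + (1−α)β_k W^(k,k)∘G′, off-diagonal blocks (1−α)β_m W^(k,m)∘G′
for adjacent layers, zero otherwise. Note that the compact "product"
expansion Φ·Δ sometimes quoted for the off-diagonal blocks of such
multilayer chain systems multiplies an extra intra-layer factor
[α + (1−α)β_k K^(k,k)] into the inter-layer derivative; the package keeps
that convention only inside the *closed-form reductions* (below), where it
is part of the published parameterization, while the Jacobian itself is the
true derivative — it is validated against central finite differences of
the step map on randomized models in the test suite.

Classification uses the dense non-symmetric eigensolver (the
super-adjacency matrix is not symmetric in general) with an inconclusive
band of ±1e−9 around ρ = 1; the linearization theorem is silent on the
unit circle and the package does not attempt a marginal analysis.

Closed forms, each cross-checked against a dense oracle in the tests:

* **Single layer**: μ_i = (|Ω|/M)Σ_j W_ij G′(V_{j,*}); max|μ_i| < 1 bounds
  the row norm by α + (1−α)max|μ_i| < 1 and hence the spectral radius.
* **One-neuron-per-layer chain** (`mu_multilayer`,
  `tridiagonal_eigenvalues`): diagonal a = α + (1−α)|Ω|K₀ and hoppings
  b = a|Ω|K₂, c = a|Ω|K₁ give eigenvalues
  μ_k = a[1 − 2|Ω|√(K₁K₂)cos(πk/(L+1))], with the L-independent bound
  a[1 + 2|Ω|√(K₁K₂)] reported alongside. The closed form requires
  K₁K₂ ≥ 0 (real spectrum); mixed signs are routed to the dense solver.
* **Transfer-matrix determinants** (`transfer_matrix_det`): the open-chain
  det(A − λI) is the trace of a product of 2×2 transfer matrices. For the
  ring-closed chain (corner entries c₀ at (1, L) and b_L at (L, 1)) the
  correct corner expansion is
  det = D₁..L − c₀b_L·D₂..L−1 + (−1)^(L+1)(Πb_i + Πc_i), with both inner
  determinants taken from the same 2×2 recursion. Compact typeset variants
  of this formula circulate with garbled corner matrices; the
  implementation was derived from the cofactor expansion and is validated
  against dense determinants on random open and closed chains.
* **Two layers** (`two_layer_stability`): with θ = 1 − |Ω|²K₁₂K₂₁,
  μ₀ = |Ω|(K₁₁+K₂₂), μ = α(K₁₁+K₂₂) + (1−α)|Ω|K₁₁K₂₂, the identities
  det(A) = [α² + (1−α)|Ω|μ]θ and tr(A) = 2α + (1−α)μ₀ turn the Schur–Cohn
  test |tr| − 1 < det < 1 into exact scalar conditions
  (`theorem_flags["two_layer_conditions"]`). The compact published-style
  triple (0 < θ < 1, μ < 1, discriminant < 0) is also reported
  (`printed_sufficient`); it is provably sufficient for stability under
  nonnegative gain rates but conservative — about one in ten random stable
  draws fails it — so the exact form is the one the equivalence tests use.
  Negative connectivity values pass through all dense numeric paths; the
  closed-form hypotheses assume positivity.

## Fixed points and the averaged iteration

`mann_iterate` runs the update loop with a sup-norm stopping rule and
reports the contraction product C·W₀·|Ω| (sigmoid Lipschitz constant
C = θ/4 times weight bound W₀ times domain size); when it does not exceed
one, the interaction map is nonexpansive and convergence of the averaged
scheme is guaranteed. The diagnostic is a sup-norm bound for a single
layer's Riemann weights; it is reported as unavailable for the hard
threshold (no Lipschitz constant). Exhausting the iteration budget returns
a diagnosed non-converged result rather than raising. `fixed_point_residual`
measures ‖V − T(V)‖∞ directly and is the convergence ground truth.

For hard-threshold fields with zero input that stay strictly sub-threshold,
the trajectory is exactly αⁿV₀ + ν(1 − αⁿ) (`heaviside_closed_form`; the
geometric sum of the per-step innovations — a transcription that omits the
(1 − αⁿ) factor on ν has the same limit but disagrees at finite n and with
the simulator). `trajectory_bound` provides the a-priori envelope
αⁿmax|V₀| + Yₘ(1 − α^(n+1))/(1 − α), Yₘ = (1−α)(S̄ + |Ω|W̄), valid for any
bounded weights and stimulus under a bounded gain.

## Synthetic fixtures

`generate_fixture` draws models from explicit parameter ranges with a
seeded `numpy` generator (identical seed ⇒ bit-identical model). The
`stable` regime rescales weights so the single-layer row criterion at the
zero field stays below 0.9. `fixture_with_fixed_point` plants an *exact*
equilibrium by solving the fixed-point condition for the stimulus
(S := V* − ΓG(V*)) and bisects a global weight scale until the Jacobian
spectral radius at V* reaches the requested side of the unit circle
(≤ 0.75 stable, ≥ 1.2 unstable). This is the only honest way to get
ground-truth equilibria for generic nonlinear models, and it is how the
stability-versus-dynamics consistency tests obtain their instances. What
the fixtures do **not** emulate: heterogeneous per-synapse noise,
time-varying input, conduction delays, or 2-D domains — passing tests
say nothing about those regimes.

## Numerical conventions

* Grids are midpoint rules; coordinates x_i = a + (i − ½)|Ω|/M.
* All trajectory/report serialization uses `repr` doubles (shortest
  round-trip form): write-then-read is bit-exact and reruns are
  byte-identical.
* The cosine eigenvalue formula is tested against the similarity-
  symmetrized chain (hopping √(bc)) because the nonsymmetric Toeplitz
  matrix itself has exponentially ill-conditioned eigenvalues when b and c
  differ strongly — the symmetric form is the numerically faithful oracle
  with the identical exact spectrum.
* Scenario problem sizes (M = 200, N = 100, L ≤ 200, 50-point α sweep) are
  the package defaults and run in well under a minute in total.

## Known limitations

* One-dimensional domains only (the kernel interface keeps coordinates
  extensible, but no 2-D grid machinery ships).
* No continuous-time integrator; the discrete map is the object of study.
* Stability verdicts are local (linearization); no basins of attraction or
  bifurcation tracking.
* The closed-form criteria inherit their positivity hypotheses; outside
  them the dense spectral route is authoritative.
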