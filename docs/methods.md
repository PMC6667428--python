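# Methods

## Model

The package studies Markovian SIR dynamics on a static, undirected, regular
network of `N` nodes with common degree `n`: infection crosses each
susceptible–infected link at rate `τ` (1/time) and infected nodes recover at
rate `γ` (1/time).  Clustering is summarised by the single global
coefficient `φ = trace(G³)/(‖G²‖ − trace(G²))` of the adjacency matrix `G`
(six times the triangle count over twice the connected-triple count), so all
triangles are treated as statistically equivalent; no degree heterogeneity,
weights, direction or rewiring.

The pairwise hierarchy tracks expected counts of singles and pairs,

    [S]' = −τ[SI]                       [SS]' = −2τ[SSI]
    [I]' = τ[SI] − γ[I]                 [II]' = 2τ([ISI]+[SI]) − 2γ[II]
    [SI]' = τ([SSI]−[ISI]−[SI]) − γ[SI]

with pairs counted in both directions ([AB] = [BA], [AA] even).  All counts
are continuous mean-field expectations; no integrality anywhere.  The system
is closed by expressing the triples [ASI], A ∈ {S, I}, through pairs and
singles.  Two closures are wired into ODE systems:

* **simple** — the tree-like estimate `((n−1)/n)[AS][SI]/[S]` times
  `(1−φ) + φ C_AI`, where `C_AB = N[AB]/(n[A][B])` is the observed-to-random
  pair ratio.  Transparent, but it breaks the pair-level conservation
  `Σ_A [ASI] = (n−1)[SI]` when φ > 0.
* **compact improved** — the clustered correction renormalised over the
  states {S, I}:
  `[ASI] = (n−1)((1−φ)[AS][SI]/(n[S]) + φ[AS][SI][IA]/([A]([SS][SI]/[S]+[SI][II]/[I])))`.
  Its clustered part sums to exactly `φ(n−1)[SI]` over A ∈ {S, I} for any
  admissible state; adding the tree-like [RSI] term restores the full
  conservation identity exactly.  A fully renormalised variant over
  {S, I, R} (`closure_improved_full`) is provided for conservation analysis
  only and is not integrated: the closed clustered system of record is the
  compact one, whose right-hand side is obtained by substituting the closure
  into the exact pair equations above.  That reconstruction is validated
  dynamically rather than against a printed system: at the standard initial
  conditions the time derivative of [SI]/[I] computed from the full
  five-equation system converges linearly in `I0/N` to the planar
  fast-variable field (checked at N = 10⁶, I0 ∈ {1, 0.1, 0.01}).

## Fast variables and thresholds

The ratios `α = [SI]/[I]` and `δ = [II]/[I]` equilibrate on the time scale
`1/(τ+γ)`, much faster than prevalence evolves, and their quasi-equilibrium
`(α*, δ*)` fixes the early growth rate: the epidemic grows iff
`R = τα*/γ > 1`.  For each closure the planar fast system is analysed on the
closed triangle `D = {0 ≤ α ≤ n, 0 ≤ δ ≤ n − α}` (closed boundaries, exact
membership, no tolerance):

* null clines, with evaluation within 1e−9 of a pole raising an error
  rather than returning a huge float (plotting code windows poles
  explicitly);
* the Bendixson divergence of the field scaled by 1/α, whose negativity on
  D excludes limit cycles and upgrades local to global stability;
* the closed-form parameter conditions: interior steady state of the simple
  system iff `φ < (n−2)/(n−1)`; Bendixson negativity iff
  `φ < 2n/(3(n−1))` (the two bounds cross at n = 6, so below degree six the
  whole feasible range is certified); sign condition `2φ < (n−2)/(n−1)` in
  the compact system's invariance argument.  Outside the certified Bendixson
  range the stability report simply flags the bound; no global-stability
  claim is made even though numerics suggest it holds.

`quasi_equilibrium` offers two independent routes that must agree: (a)
relaxation of the fast ODEs from the image of the standard initial
conditions `(α, δ)(0) = (nS0/N, nI0/N)`, declared converged when the field's
sup-norm drops below 1e−10, and (b) a 2-D root find seeded by the asymptotic
expansion, rejected unless the root lies in D.  The relaxation horizon is
2000/γ, integrated in 20/γ chunks with early exit: near the die-out boundary
`φ → (n−2)/(n−1)` the slow eigenvalue of the fast system approaches zero and
convergence to 1e−10 can take 500–1000/γ (e.g. n = 3, τ = 0.25, φ = 0.45),
so a tight horizon would spuriously reject feasible parameters while costing
nothing elsewhere.

Setting the fast field to zero reduces the steady state to one cubic per
closure: in α for the simple closure, in δ (with shorthands
`A = (n−2) − 2φ(n−1)`, `B = γ/τ`) for the compact improved closure, mapped
back through `α = (n−2) − 2(n−1)φδ/(n+δ)`.  Root selection: all polynomial
roots are computed (degree reduced when the leading coefficient is below
1e−12 relative — the simple cubic's leading coefficient vanishes identically
at φ = 0); the unique root in (0, n] is kept; should several fall there, the
one closest to the asymptotic expansion (continuity with the φ → 0 limit
n − 2) is chosen with a warning.  The first-order expansions are

    simple:  α ≈ (n−2) − φ (2(n−1)/n²)(2τ(n−1)(n−2)+γn)/(τ(n−2)+γ)
    compact: δ ≈ δ0 + φ 2τ(n−1)δ0(n−4+δ0)/(γ(n+3δ0)+τ(n−2)(n+3δ0−4)),
             δ0 = 2τ(n−2)/(γ+τ(n−2)),
             α ≈ (n−2) − φ 4τ(n−1)(n−2)/(τ(n+2)(n−2)+γn)

truncated at first order throughout (no second-order coefficients exist in
the underlying analysis) and never extrapolated beyond φ = 1.

## Comparison suite

* **Keeling's C*_SI** — the quasi-equilibrium of the early-time correlation
  ODE, with `β = τn`.  The root in (0, 1) is found by a bracketed search
  after clearing the (sign-monitored) denominator; via `C_SI = α/n` it is
  algebraically equivalent to the simple-closure cubic, and the two code
  paths agree to better than 1e−8 in α.
* **Next-generation matrix** — infected compartments ordered ([I], [SI]);
  new-infection matrix F and transition matrix V assembled at the
  disease-free state with the fast variables at quasi-equilibrium; R0 is the
  leading eigenvalue of FV⁻¹.  The reported expansion `R0 = r0 + φ r1` uses
  `r0 = τ(n−1)/(τ+γ)` and the exact first-order coefficient
  `r1 = r0(−2/n − τ(n−1)α0δ0/(n²(τ+γ)))`, verified against finite
  differences of the eigenvalue in φ; α1 and δ1 do not enter because F and V
  depend on them only through O(φ) terms.
* **Li et al. / Miller** — `R0 = (n−1)τ/(τ+γ+τφ)` and
  `R0 = (n−1)T − (n−1)φT²` with `T = τ/(τ+γ)` (a node belongs to
  `n(n−1)φ/2` triangles on a regular network).  Miller's formula equals the
  first-order expansion of Li's exactly as a function of (n, τ, γ, φ); the
  NGM first-order coefficient r1 is a genuinely different function and is
  reported without any equivalence claim.
* **Household R\*** — size-three households with regular global degree μ_D;
  `M(θ) = θ/(γ+θ)`, mean within-household outbreak
  `μ_T = 2[1−M(λ_L)² − M(2λ_L)(1−M(λ_L))]`,
  `R* = (1−M(λ_G))((1+μ_T)μ_D − 1)`, with the exact clustering map
  `φ = 2/(2+μ_D(3+μ_D))` and its inverse.  The exposed decomposition
  `R* = T1 + T2√(1+8/φ)` uses `T2 = ½(1−M(λ_G))(1+μ_T)`, the coefficient
  that makes the decomposition an identity (verified numerically against the
  direct formula).  φ = 0 is rejected: it corresponds to infinite global
  degree.  No other household sizes.

## Numerical choices

* Integrator: adaptive stiff-capable LSODA, rtol 1e−8, atol 1e−10 (the
  fast–slow structure makes the closed system mildly stiff near t = 0);
  horizon default `t_max = 1000`, long enough for extinction
  (`[I] < 10⁻⁶`, far below one individual) at rate-of-order-one parameters.
  The implied recovered count is integrated alongside as `R' = γ[I]`, so
  node conservation `S + I + R = N` is a genuine solver check (observed
  drift ~1e−11·N, asserted < 1e−6·N).
* Degenerate divisions: every closure term carrying 1/[I] or 1/[I]² is
  factored so it is multiplied by at least one power of [SI] or [II], and a
  0/0 is defined as 0 — the continuous limit of the closed equations, which
  keeps the solver stable through extinction.  The standalone closure
  functions, by contrast, raise explicit degenerate-state errors.
* Initial conditions: random-labelling values `[SI] = nI0S0/N`,
  `[SS] = nS0²/N`, `[II] = nI0²/N` with I0 = 1 by default, so all
  correlation factors start at exactly 1.
* Attack rate: `(N − S(t_max))/N`, seeds included (the alternative
  `(S(0)−S(t_max))/N` differs by I0/N = 10⁻⁴, immaterial).  Epidemic
  classification threshold for surfaces: attack rate 0.01, well above the
  seed fraction.
* Fast-variable plateau: read off a time course as the flattest point of
  α(t) between the relaxation transient (3/(τ+γ)) and the prevalence peak;
  at the illustration parameters it matches the quasi-equilibrium to
  0.1–0.6%.
* Edge lists: whitespace-separated 0-based integer pairs, undirected;
  duplicates and self-loops rejected.
* Sweeps and contours are fully deterministic (no randomness anywhere in
  the library); per-point failures are recorded in their row, never abort a
  sweep.  Contour extraction bisects R(τ) − 1 to 1e−8 after checking the
  bracket endpoints straddle the target.

## Problem sizes

The test suite and the reproduction script work at the study scale:
N = 10,000, I0 = 1, γ = 1, degrees n = 3…10, τ up to 2, clustering levels
φ ∈ {0, 0.15, 0.3, 0.45, 0.6} (filtered by feasibility for the simple
closure), with the full cubic-versus-relaxation comparison covering ~630
parameter combinations.  Everything runs in seconds on one core.

## Known limitations

* The closures are uncontrolled approximations of the exact Markov chain.
  In particular, the exact-process correlation inequalities
  `C_SI ≤ 1 ≤ C_II, C_SS` are reproduced by the closed systems during the
  epidemic growth phase, but the **simple closure transiently pushes C_SI a
  few percent above 1 around the prevalence peak** (≈1.03 at N = 10⁴,
  n = 5, φ = 0.5, τ = γ = 1); the compact improved closure respects all
  three signs throughout that scenario.
* The first-order expansions degrade with clustering: at n = 5, τ = γ = 1
  the simple-closure series is 1.5% off the cubic root at φ = 0.15 but 7%
  at φ = 0.3 and 21% at φ = 0.45; the compact-improved series roughly
  halves those errors.  Used as closed forms, they are early-φ
  approximations, not uniform ones.
* Near the threshold the deterministic final size is smoothed over a τ
  window of order `(dR/dτ)⁻¹ I0/(0.01 N)` (the attack rate just below
  threshold is ≈ (I0/N)/(1−R)), so the attack-rate-0.01 contour sits
  0.004–0.011 in τ below the R = 1 point at N = 10⁴, I0 = 1.  The analytic
  threshold marks the asymptotic transition, not a sharp finite-N edge.
* All results are mean-field ODE statements about regular clustered
  networks in which every triangle is statistically equivalent.  No
  stochastic network simulation is included, so the tests certify internal
  consistency of the closure analysis — not agreement with explicit
  epidemics on particular graphs, where degree heterogeneity, variance
  effects and early extinction matter.
* The ordering "compact improved predicts outbreaks more readily"
  (τ_critical(compact) ≤ τ_critical(simple)) is asserted only at the study
  parameter set n = 5, γ = 1; it is not claimed universally.
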