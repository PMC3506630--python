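# Methods

## Model

`prefnet` simulates the discrete-time SIS (susceptible–infected–susceptible)
process on a co-evolving contact network in which every node steers its
degree toward a *preferred degree* κ, and κ itself responds to the epidemic.

**Network dynamics.**  In one network Monte Carlo step (MCS), N elementary
attempts are made on uniformly random nodes (random sequential updating,
with replacement).  A selected node of degree k *adds* a link with the
Fermi probability

    w₊(k) = 1 / (1 + exp(β (k − κ)))

and *cuts* one otherwise (w₋ = 1 − w₊).  β is the population's
inflexibility; β = ∞ is the step function (always add below κ, always cut
above).  κ is stored as integer + 0.5 by default so the marginal case
k = κ never arises at β = ∞.  The partner of a move is drawn uniformly
from the eligible pool (non-neighbors for an add, neighbors for a cut) and
has no veto.  Degenerate attempts (add at degree N−1, cut at degree 0) are
silent no-ops counted in diagnostics; they never occur at κ ≪ N.  The
stationary degree distribution of this ensemble is a Laplace
(double-exponential) distribution at β = ∞; finite β rounds the peak over a
width ~1/β before crossing over to the same exponential tails.

**Epidemic dynamics.**  Each node is S or I.  One SIS MCS is N attempts on
random nodes; the time step is 1, so rates are probabilities.  An infected
node recovers with probability μ; a susceptible node with m infected
contacts is infected with probability 1 − (1 − λ)^m (simultaneous
exposure).  Finite systems would fall into the absorbing all-S state, so
the *immortal node* device is used: no node is special, but the last
infected node is never allowed to recover.  Steady-state time averages then
stand in for ensemble averages; in the inactive phase ⟨x⟩ sits at the 1/N
floor rather than at zero.

**Two timescales.**  Network adaptation is a *response* to the epidemic and
is normally slower: for every network MCS the scheduler performs w SIS MCS
(default w = 10; w = ∞ freezes the network).  For selective-adaptation
studies the link update can also be *faster* than the disease: w < 1 with
integer 1/w performs 1/w network MCS per SIS MCS, i.e. an adaptation rate
of 1/w on the epidemic clock.  The global prevalence x used by the adaptive
rules is re-read at the start of every network MCS.

**Fear factors.**  The preferred degree responds to the global infected
fraction x through κ(x) = κ₀ · f(x) with f(0) = 1 and f nonincreasing:

* *reckless*: f = 1 until x reaches x_c, then drops to κ∞/κ₀ (Heaviside);
* *typical*: linear decrease with slope s, s·x_c = 1 − κ∞/κ₀, clamped at
  κ∞ for all higher x;
* *nosophobic*: f = exp(−a·x), an exponential collapse of contacts.

The Fermi rule is evaluated with the real-valued κ(x) directly (no
rounding).

**Blind vs selective adaptation.**  Blind: partners are chosen with no
regard to disease state (an invisible disease).  Selective (a visible
disease): a susceptible updater weights the favoured class by odds
(1 + σ) — a cut is routed to an infected contact with probability
(1+σ)k_I / ((1+σ)k_I + k_S) and an addition to a susceptible partner with
probability (1+σ)n_S / ((1+σ)n_S + n_I), where k_I/k_S are the node's
infected/susceptible contacts and n_S/n_I the eligible non-neighbor pools;
the choice within the routed class is uniform.  σ = 0 is exactly the
unbiased (proportional) choice; σ → ∞ makes the favoured class certain.
Infected updaters always adapt blindly.  If a routed class turns out empty
the move falls back to the other class (counted in diagnostics) so that
exactly one link changes whenever the pools are nonempty.  An I node's
add pool is the full non-neighbor set, identical to the non-adaptive pool.

## Theory stack

**Simple mean field.**  With homogeneous degree κ and well-mixed contacts,

    dx/dt = −μ x + (1 − x)(1 − (1 − λ)^{κx}),

whose active stationary branch inverts in closed form:

    λ(x) = 1 − (1 − μx/(1−x))^{1/(κx)},     0 < x < 1/(1+μ).

At λ = 1 the stationary infected fraction is exactly x_max = 1/(1+μ).  The
package exposes two onset values: the printed threshold formula
λ_c = 1 − (1−μ)^{1/κ} (`mf_threshold`, the per-infected balance of
recovery μ against infecting at least one of κ neighbors) and the x → 0
limit of the λ(x) curve itself, 1 − exp(−μ/κ) (`mf_onset_lambda`).  The
two agree to leading order μ/κ and differ at relative order μ/2 (≈5% at
μ = 0.1); continuity checks against the curve use `mf_onset_lambda`.
Near onset the order parameter grows linearly, x ∝ (λ − λ_c).

**Adaptive mean field.**  With a fear factor, the only change is κ → κ₀f(x)
in the stationarity relation; the threshold is unchanged because f(0) = 1.
Equivalently, producing the same x requires λ enhanced by a factor
involving 1/f(x).

**Heterogeneous mean field.**  λ_c = 1 − (1−μ)^{⟨k⟩/⟨k²⟩}; because the
preferred-degree P(k) is narrow this is within a few percent of the simple
MF value, which is why the simple theory suffices over the phase diagram.

**Annealed adjacency matrix (AAM).**  The fluctuating adjacency is replaced
by pairwise connection probabilities ā_nl (either the homogeneous rank-1
form κ/(N−1), or a time-averaged empirical adjacency over snapshots) and
per-node infection probabilities are iterated through

    ρ_n(t+1) = (1−μ) ρ_n + (1−ρ_n) (1 − Π_l (1 − λ ā_nl ρ_l))

to a fixed point (sup-norm change < 10⁻¹⁰ by default); x = mean ρ.

**Local mean-field theory (LMFT).**  For selective adaptation the state is
(x, ℓ_SS, ℓ_SI, ℓ_II): infected fraction and mean links per node by
endpoint type.  Local degrees are closed with global class averages
(k_SS = 2ℓ_SS/(1−x), k_SI = ℓ_SI/(1−x), k_II = 2ℓ_II/x, k_IS = ℓ_SI/x).
The node equation is driven by the mean infected contacts per susceptible:

    dx/dt = −μ x + (1−x)(1 − (1−λ)^{k_SI}).

Link equations combine (i) epidemic conversions — a recovery relabels the
node's SI links to SS and II links to SI; an infection relabels SS → SI and
SI → II, at the class-average multiplicities — and (ii) adaptation fluxes
at rate 1/w: susceptible updaters add/cut with the Fermi decision at
κ(x) evaluated on k_S = k_SS + k_SI and route partners with the selective
probabilities above (pool fractions (1−x) and x for additions); infected
updaters adapt blindly.  Two structural properties anchor the closure:
the healthy state (x = ℓ_SI = ℓ_II = 0, ℓ_SS = κ₀/2) is an exact fixed
point, and at σ = 0 the random-mixing composition at the simple-MF fixed
point is itself exactly stationary for any w — the LMFT collapses onto the
(adaptive) simple MF when the bias is switched off.  Both are verified in
the test suite.

LMFT numerics: the ODE is integrated with LSODA (rtol 10⁻⁹);
stationarity is declared when the max-norm of the right-hand side drops
below 10⁻⁹, stability via the eigenvalues of a finite-difference Jacobian,
and a bounded trajectory that keeps swinging past the relaxation horizon is
flagged oscillatory.  Because the mean-field degree is one continuous
number per class, the simulation's β = ∞ step decision is represented by a
finite Fermi slope β_eff = 1 — the step function averaged over the ~unit
spread of the stationary degree distribution.  The reckless f(x)
discontinuity is optionally regularized by a steep sigmoid (width 10⁻³ in
x; off by default, enabled inside `lmft_phase_scan`), which turns the
x ≈ x_c sliding state into a genuine fixed point a smooth solver can find.
Phase scans integrate from user initial conditions *and* by continuation
(sweeping λ up and down re-using the previous fixed point), then deduplicate
branches at 10⁻³ resolution in x; a λ with ≥ 2 (≥ 3) distinct stable
branches is a bistable (tristable) window.

With strong bias and fast adaptation (σ ≈ 10, rate 1/w ≈ 4) the LMFT
reproduces the qualitative selective phenomenology: a bistable window for
typical fear (discontinuous transition), and for reckless fear three
branches — inactive, pinned at x ≈ x_c (a consequence of the f
discontinuity), and endemic, the latter approaching the homogeneous-κ∞
mean-field curve at high λ.  At weak bias (σ ≈ 2) the transition is
continuous in both the theory and the simulation.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| μ | 0.1 | recovery probability per attempt |
| κ₀ | 20.5 | baseline preferred degree (integer + 0.5 offset) |
| β | ∞ | inflexibility; 1 for "flexible" blind-adaptation studies |
| w | 10 | SIS MCS per network MCS (∞ = static; <1 = faster network) |
| x₀ | 0.1 | initial infected fraction (distinct uniform nodes) |
| x_c | 0.4 (blind), 0.6/(1+μ) ≈ 0.545 (selective) | fear threshold |
| κ∞ | 12.5 (blind, 60% of κ₀), 10.5 (selective) | minimal preferred degree |
| a | 25 | nosophobic severity; κ(x) < 1 beyond x ≈ 0.12 |
| σ | 2 | selective bias (odds 3:1) for structure studies; 10 for phase-diagram demonstrations |
| thermalization | 1000 MCS | plus 600–2000 MCS disease-free network growth |
| sampling | every 10 MCS | ⟨x⟩ and link-type counts |

Where a quantity has no canonical published value the default is the
package's own choice: κ∞ at 60% of κ₀ keeps a substantial but not drastic
distancing response; a = 25 makes nosophobic contact collapse effectively
complete at moderate prevalence; σ = 2 models strong-but-imperfect
discrimination of a visible disease, while σ = 10 (with adaptation rate 4)
is used where the sharply discontinuous regime itself is the object of
study.  Desk-scale protocols use N = 500–1000, 5–10 realizations,
10³-scale MCS; the degree-distribution study uses the full 10⁴ + 10⁴ MCS
protocol at N = 1000.

## What the simulator does and does not emulate

The generator produces homogeneous populations with a single behavioural
response driven by the *global* prevalence, exactly known at every network
step.  Real contact networks are heterogeneous (extroverts/introverts),
perceive prevalence locally and with noise and delay, and carry structure
(households, assortativity, clustering) that the preferred-degree ensemble
does not create.  Passing tests therefore validate the model stack's
internal consistency and its stated phenomenology — not quantitative
prediction for empirical epidemics.

## Numerical choices

* Random numbers inside the jit kernels come from an explicit xorshift128+
  stream (seeded via splitmix64).  Network and SIS dynamics consume two
  independent streams derived from the run seed, so a w = ∞ run is
  bit-identical to an explicitly frozen-network run, and every record can
  be replayed exactly from its manifest.
* The adjacency is a fixed-capacity neighbor-list matrix of width N−1;
  membership tests scan the row (k ≈ κ ≪ N), partner sampling uses
  rejection for large pools and an indexed scan for small ones, so the
  uniform-partner contract holds even when a class is nearly exhausted.
* Steady-state standard errors use pair-blocking, climbing levels while the
  estimate grows by >5% and stopping at the plateau; for uncorrelated data
  this reduces to σ/√n.
* Exponential-tail fits weight log-bins by √count (Poisson weighting) and
  drop bins with fewer than 5 samples, whose log values are shot-noise
  dominated.
* The threshold estimator reports the largest grid λ whose steady ⟨x⟩ is
  statistically indistinguishable from the immortal floor 1/N (midpointed
  to the next grid value), with a bootstrap-over-realizations confidence
  interval; grids that do not bracket the transition are flagged.
* Plateau detection fits every window of ≥ 4 consecutive grid points and
  accepts those whose slope is statistically consistent with zero (|t| < 2),
  preferring longer, then flatter windows.

## Known limitations

* The LMFT closure replaces local degrees by class averages and assumes the
  degree distribution adapts instantaneously to κ(x); its transition
  locations are only qualitatively reliable, and the effective β_eff = 1
  smoothing is a modelling choice, not derived.
* The bistable windows of the LMFT are narrow at moderate σ; stochastic
  simulations show metastable switching rather than true coexistence.
* Near-threshold critical properties (exponents, finite-size scaling) are
  outside the package's scope; the estimator resolution is set by the λ
  grid.
* Excursion-duration statistics are sampled on the MCS grid and are
  discrete; the exponential check dequantizes them before testing.
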