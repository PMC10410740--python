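# Methods

## Model

The network is a discrete-time rate model of a small piece of basal ganglia
learning to reproduce a fixed d-dimensional periodic trajectory. Five
populations: thalamus (rates imposed), cortex (recurrent reservoir, static
weights), striatum (dSPN + iSPN, all afferent and recurrent synapses
plastic), SNr/GPi (memoryless readout, plastic striatofugal input) and SNc
(d dopaminergic units whose rates equal the output-error vector
ε_k = (r_k − T_k) r_k (1 − r_k); negative values are read as dips below a
baseline rate). Membrane dynamics are leaky integrators
τ_m dV/dt = −V + Σ w r with logistic transfer φ(V) = 1/(1+exp(−V+b)); the
offset b shifts the sigmoid so balanced inputs produce sparse rates.

Assumptions inherited from the modeling idealization: the error vector is
available to SNc and SNr by construction (no critic or reward machinery is
modeled); the indirect pathway is collapsed to a direct excitatory iSPN→SNr
projection; cortex does not learn; no delays, spiking, or conductance
synapses.

### Dopamine field

Each SNc unit releases dopamine from N_var varicosities placed i.i.d.
uniformly in the unit cube of tissue; concentration decays exponentially
with Euclidean distance with spatial constant λ (measured in cube sides).
Summing varicosities gives the static effective feedback matrix
D[j,k] = Σ_v (1/λ)·exp(−‖p_j − q_kv‖/λ), and SPN j receives
C_j(t) = Σ_k ε_k(t) D[j,k]. Feedback variants used by the control
experiments:

- `heterogeneous` — D as built (the model proper);
- `shuffled` — one fixed elementwise permutation of D's entries;
- `homogeneous` — every entry replaced by mean(D): all SPNs share one scalar
  signal with the same total gain (the λ→∞ limit);
- `ideal` — the class-sign-adjusted readout transpose s_j·w_kj(t),
  re-evaluated every step. The sign adjustment (dSPN readout weights are
  negative) is what makes the three-factor rule with the class-signed rates
  α_j reduce exactly to the derived gradient rule; without it the dSPN half
  of the striatum would ascend the loss.
- `none` — zero feedback; striatal plasticity silent, only the readout
  learns (echo-state-like baseline).

### Plasticity

Striatal afferent and recurrent synapses: eligibility
τ_Str dp_ji/dt = −p_ji + r_j(1−r_j) r_i, weight update
dw_ji/dt = −α_j p_ji C_j, with α_j = −2.5e−2 (dSPN) / +2.5e−2 (iSPN).
Striatofugal: dw_kj/dt = −β ε_k r_j with β = 1e−3 — the exact negative
gradient of the instantaneous loss, and the projection whose plasticity
produces feedback alignment (w_kj drifts toward ±d_jk). Sign constraints
(Dale's law) are enforced by clamping any weight that crosses zero back to
zero; the synapse keeps its mask entry and may regrow. Updates are applied
online every time step with the same Euler dt as the dynamics; α and β are
per-ms rates.

### Slow dopamine and compensation

Temporal dopamine dynamics are collapsed into an exponential low-pass with
time constant τ_DA. The discrete filter is normalized
(C′ ← ξC′ + (1−ξ)C, ξ = e^(−dt/τ_DA)) so that a constant input passes with
unit gain; the literal unnormalized convolution (gain τ_DA/dt) is available
behind `unnormalized_lowpass` for comparison, but the normalized form is the
one under which the high-pass compensation
a(t) = A(t) − ξA(t−Δt), A = C′/(1−ξ) reconstructs C(t) *exactly* (a
telescoping identity, verified to machine precision in the tests). With
compensation on, training trajectories are bit-for-bit those of the
instantaneous model.

## Task generator

Targets are d independent draws from a Gaussian process with mean 0.5 and
covariance 0.15²·exp(−δ(t₁,t₂)²/(2τ_task²)) on the *circular* distance
δ(t₁,t₂)=min(|t₁−t₂|, |t₁−t₂±T|), with T = 200 ms, τ_task = 20 ms, on the
half-open grid t = 0…T−dt so consecutive trials tile time without
discontinuity. One target set is drawn per run and repeated for all trials;
trials are concatenated with no state reset. Trial time is signaled by
thalamic units r_m(t) = φ(A_m cos(2πt/T) + B_m sin(2πt/T)) with (A_m, B_m)
uniform on the circle of radius 4 — a clock with no trial index, identical
across trials.

What the generator does *not* emulate: sensory noise, trial-to-trial target
variability, reward delivery, or any nonstationarity. Passing tests
therefore demonstrate the learning mechanics under a fixed, noiseless,
periodic supervised task — not robustness of the mechanism to the
variability of real behavioral data.

## Parameters

| parameter | default | units | meaning / rationale |
|---|---|---|---|
| τ_m | 10 | ms | membrane time constant |
| b | 2 | — | sigmoid offset (sparse baseline rates) |
| dt | 1 | ms | forward-Euler step |
| T | 200 | ms | trial duration |
| τ_task | 20 | ms | target GP correlation time |
| α | ∓2.5e−2 | /ms | striatal learning rate, sign by SPN class |
| β | 1e−3 | /ms | striatofugal learning rate |
| τ_Str | 10 | ms | eligibility time constant (set equal to τ_m, the value the online-gradient derivation pairs with the membrane dynamics) |
| λ | 0.1 | cube sides | dopamine spatial constant (1/e at 10% of the cube) |
| N_var | 10 | — | varicosities per SNc unit |
| d | 4 | — | output/error dimensionality; N_SNr = N_SNc = d |
| connection p | 0.5 (readout 1.0) | — | sparse projections; dense readout |

Structural defaults (population sizes, per-projection weight caps w_max)
are config-driven. The shipped defaults — 100 cortical units (half
inhibitory, interneurons projecting only within cortex), 50+50 SPNs,
40 thalamic units, w_max = {thal_ctx 15, ctx_ctx 20, thal_str 15,
ctx_str 15, str_str 20, str_snr 2} — were chosen once by two criteria:
(i) a perturbation-growth check on the untrained balanced network gives a
slightly positive exponent (rich, near-chaotic dynamics) without widespread
rate saturation, and (ii) the readout operates in the sensitive range of
its sigmoid (a large str_snr cap saturates the readout and cripples the
delta rule). Initial weights are Uniform[0, w_max/N_post] times the
projection sign, then each neuron's incoming excitation/inhibition is
scaled to sum exactly to zero (neurons with a single sign class of input
are logged and left unbalanced).

Profiles: `SimConfig.paper()` (100 SPNs, 5,000 trials),
`SimConfig.desk()` (60 SPNs, 600 trials — the default experiment and test
profile), `SimConfig.correlation()` (100 SPNs, 1,000 trials — the
spatial-correlation analysis). Desk-scale experiment summaries use the
median of the last 10 per-trial losses and ≥10 paired seeds; "similar
performance" is operationalized as overlapping interquartile boxes, since
no formal test is defined for these comparisons.

## Numerical choices

- **Update order per step** (fixed convention): rates from current V
  (thalamic clock imposed) → readout, loss, ε → dopamine feedback
  (optionally filtered) → eligibility and weight updates with sign clamp →
  synchronous Euler membrane update driven by this step's rates (and the
  just-updated weights). A scalar-loop reference implementation in the test
  suite pins this convention.
- **Kernel factorization**: the squared-exponential kernel on circular
  distance is only approximately positive semidefinite; after adding 1e−8
  jitter it is factored by eigendecomposition with negative eigenvalues
  clipped at zero. Kernels whose smallest eigenvalue is below −1% of the
  largest are rejected as a numerical failure.
- **Ties and degenerate data**: preferred-dimension ties break toward the
  lowest index; constant rate traces (undefined correlation) are excluded
  and counted; zero-norm weight snapshots yield NaN alignment.
- **Instability**: any non-finite state aborts the run with the trial index.
- The trial loop is numba-compiled; the public per-operation functions are
  plain numpy and are cross-checked against the compiled loop.

## Spatial-correlation analysis

Pairwise Pearson correlations of post-training SPN rate traces (the last
five recorded trials), binned by Euclidean distance (bin width 0.05 cube
sides), pooled across repeated simulations at the pair level. Pairs are
pooled **within SPN class**: dSPNs and iSPNs carry opposite-signed dopamine
plasticity, so cross-class pairs carry no shared spatially structured
signal and would cancel the curve; the experimental analog likewise only
ever measures within-class pairs (each imaging session labels one SPN
class). Position information enters the model *only* through D, so any
distance dependence of the correlations is dopamine-induced.

## Known limitations

- With the shipped (non-published) structural scales, the near-distance
  within-class correlation of the trained model computes to ≈ 0.2–0.27 at
  the reduced analysis scale — the right shape (monotone decay to a ≈ 0.02
  far field) but somewhat stronger than the ≈ 0.15 the mechanism is
  expected to produce; the ratio of learned (dopamine-shared) to random
  (reservoir) striatal drive, set by the unpublished weight scales, governs
  this magnitude.
- Freezing the striatofugal projection leaves the model strongly impaired
  (an order of magnitude above intact) yet still better than a fully static
  network: two random nonnegative matrices (initial readout and D) have an
  appreciable cosine overlap, so striatal updates remain partially aligned
  even without readout plasticity.
- Under the normalized low-pass, slow uncompensated dopamine degrades
  learning toward — but not beyond — the no-striatal-plasticity level, even
  for τ_DA hundreds of times the task time constant: on a periodic task the
  trial-smoothed error remains weakly informative. The amplitude blow-up of
  the unnormalized filter (gain τ_DA/dt) is the regime in which slow
  dopamine becomes actively destructive.
- The model omits dopamine reuptake kinetics, receptor saturation,
  cholinergic-triggered release, GPe/STN circuitry and striosome/matrix
  structure; conclusions concern the feasibility of the feedback scheme,
  not biophysical realism.
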