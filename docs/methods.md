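# Methods

## Model and assumptions

The driver network is modeled as a conservative steady-state flow network
rather than a kinetic ODE system. The assumptions this buys and their cost:

- **Steady state, linear limit.** Readouts are taken after the network flow
  has equilibrated; each node's outflow equals its inflow. There is no
  signal amplification (kinase amounts are assumed beyond the
  ultrasensitivity threshold) and no spatial effect. Consequently flows are
  dimensionless fractions of the total input Σ = 1 and the untreated output
  is exactly 1 by the algebraic identity Υ_out = Ω₃ + Ω₅ + Ω₇ = 1 — the
  package checks this to 1e-12 (pure float cancellation, no solver
  tolerance involved).
- **Phenomenological dose response.** The constants K map dose fraction to
  output loss; they absorb pharmacology (binding, turnover) that the model
  does not resolve. The fraction-of-maximal-dose x is the only dose axis;
  there is no mg/kg conversion.
- **Additive combinations.** Multi-drug effects add in removed signal,
  ϕ = max(0, 1 − Σᵢ Kᵢx/(1+Kᵢx)), a first approximation with no
  synergy/antagonism (no Bliss or Loewe scoring).
- **Repression as a no-op on mass flow.** The JNK⊣ERK and TAOK⊣ERK
  repression edges are modifiers. Because TAOK represses ERK maximally
  under saturating stress, ERK activity is held constant under JNK
  inhibition; the associated strength constants (γ₁, γ₂) are stored but
  unused. Repression edges therefore carry zero mass and are excluded from
  conservation bookkeeping.

## Parameters

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| α₁ | 0.2 | fraction of Σ | source split into the RAF pathway (measured) |
| α₂ | 0.2 | fraction of Σ | source split into the MLK pathway (package default) |
| α₃…α₆ | 0.5 | fraction | pathway-vs-crosstalk splits at MLK, TAOK, p38, ERK (package defaults) |
| K₁, K₂, K₃, K₄ | 2, 0.4, 0.475628, 0.1 | dimensionless | dose-response constants of p38i, MEKi, JNKi, MLKi |
| γ₃, γ₄ | 1.520908, 1.435780 | 1/flow | Hill constants of the MLK→p38 and TAOK→p38 redirection gates |
| θ | 0.3 | fraction of Σ | compensatory-network activation threshold |
| 4D dose cap | 0.3 | dose fraction | per-kinase ceiling of the low-dose regimen |

Only α₁ and the K/γ constants are anchored values; α₂–α₆ are this package's
defaults, chosen symmetric (0.5) where nothing distinguishes the branches
and α₂ = α₁ so the two measured-pathway splits match. Every number the
acceptance script reports is independent of the α₂–α₆ defaults: the
untreated output is 1 for *any* valid splits (the script draws them at
random to demonstrate this), and the suppression/surplus closed forms
depend only on the K's.

θ = 0.3 operationalizes the observed threshold behavior of AKT activation
(minimal response until ERK inhibition reaches roughly 30%); it is a policy
parameter of the activation rule, configurable per run, not a fitted
constant.

## Numerical choices

- **Propagation vs. oracle.** The production path computes flows by a
  single pass in topological order (networkx toposort); the test oracle
  independently assembles the node-balance equations into a dense linear
  system and solves it directly. They must agree to 1e-9 on random
  topologies up to 50 nodes; observed agreement is at machine precision.
- **JNKi model conventions.** The redirection gate is the Hill form on the
  product, Γ = 1/(1 + (γ·Υ₆(x))⁴), and the output is ϕ = 1 − ε₆ with
  ε₆ = ⅓[Γ₃(x) + Γ₄(x) − Γ₃(0) − Γ₄(0)] ≥ 0 — the sign convention under
  which JNK inhibition suppresses (never raises) the output and
  ϕ + ε₆ = 1 holds. Υ₆(x) is computed through the propagation engine (with
  MLK activity scaled by 1/(1 + K₄x) when MLKi is co-applied), not from a
  transcribed closed form, so it stays correct for non-default splits. On
  a crosstalk-free topology there is no redirection route; the whole
  removed signal K₃x/(1 + K₃x) is exported and the output collapses to the
  hyperbolic 1/(1 + K₃x).
- **Coherence warnings, not rescaling.** With the shipped constants the
  raw activity reduction ξ = Δx/(1+Kx) can exceed 1 (e.g. MEKi at full
  dose on a branch carrying 0.2 of the input), and the summed 4D surplus
  can exceed 1 at high dose. The engine warns and clamps only node
  activities and ϕ to [0, 1]; it never rescales ξ or the surplus closed
  forms, which are reproduced as stated.
- **Monotonicity.** ϕ is non-increasing and every surplus component
  non-decreasing in dose, with one analytic exception: under single-agent
  JNKi the TAOK allocation share ε₆(1 − Γ₃) eventually declines as the
  redirection gate saturates (Γ₃ → 1), although the conserved sum
  ε_MLK + ε_TAOK = ε₆ + ε₈ keeps growing. The tests assert exactly this.
- **Calibration.** K is estimated by bounded nonlinear least squares
  (scipy `least_squares`, box constraint K ≥ 0, tolerances 1e-10) on the
  per-dose mean expression, with multi-start from K ∈ {0, 0.1, 1, 10} so
  the estimator is deterministic given the data; a log-scale loss is
  available behind a flag. Joint multi-K fits of the additive combination
  model initialize free constants at their preset values: the additive
  objective is symmetric under permuting the K's, so the start anchors
  each estimate to its drug. Identifiability requires at least as many
  nonzero doses as free constants (and ≥3 distinct doses for the
  single-K fit); violations raise rather than returning garbage.
- **Tolerances.** 1e-12 for pure algebraic identities (untreated
  conservation, ϕ + ε = 1), 1e-9 for propagation-vs-oracle and
  conservation under treatment.

## Synthetic data

The generator emulates the statistical structure of relative-expression
dose-response experiments: an 11-point dose grid on [0, 1], three
independent replicates, and multiplicative lognormal noise (median 1,
log-sd `noise_sd`, default 0.05; 0.02 for the parameter-recovery study)
applied to the model output — relative qPCR readouts are ratio-scale, so
noise is multiplicative; an additive-Gaussian alternative sits behind a
flag. Readouts are floored at a tiny positive value (detection floor),
which matters only where ϕ = 0. Random topologies are parallel kinase
chains with Dirichlet-sampled split fractions (concentration 1, uniform on
the simplex) and optional shallower-to-deeper crosstalk, so every sample
is acyclic and conservation-valid by construction. Random-number streams
are keyed by (seed, purpose): topology sampling, split sampling and
readout noise never share a stream.

What the generator does **not** emulate: real qPCR between-batch effects,
dose-dependent heteroscedasticity beyond the multiplicative model,
receptor-level saturation, or any transcriptome-wide structure (no RNA-seq
counts, no kinome capture). Passing the recovery tests therefore shows the
estimator is correct and well-conditioned under the stated noise model —
not that K's fitted to a particular laboratory's readouts would carry the
same precision.

Problem sizes used by the shipped studies: conservation is swept over
1000 sampled parameterizations/topologies; oracle equivalence over ~100
random networks up to 50 nodes; parameter recovery over 100 seeds at
11 doses × 3 replicates. These sizes make every property estimate stable
at the asserted tolerances while the full suite stays fast.

## Known limitations

- The model is phenomenological throughout: no kinetics, no feedback
  dynamics, no mechanistic PI3K/AKT model (the compensatory network is a
  threshold abstraction), and no inference of topology from data —
  topologies are inputs.
- γ₃, γ₄ and K₃ are configuration constants, not fittable from readout
  tables; only the hyperbolic K's are calibrated.
- On the crosstalk-free topology the JNKi variant exports the full removed
  signal, predicting modest (≈32% at full dose) rather than null
  suppression; the model offers no mechanism that would null it entirely.
- Per-drug dose vectors are supported only through the common-dose
  interface (one x per scenario), matching how the dose-response figures
  are parameterized.
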