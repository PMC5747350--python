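# Methods

## Model

The model is a hybrid continuous-logic / kinetic ODE system over a curated
prior-knowledge network of cellular cholesterol regulation. Node levels are
dimensionless: regulatory nodes (proteins, enzymatic activities,
intracellular drug pools) live on [0, 1], metabolite pools are non-negative
and interpreted on the same unit scale.

Regulatory influence passes through the normalized Hill transfer
`f(x; k, n) = x^n (1+k^n) / (x^n + k^n)`, which is anchored at f(0)=0 and
f(1)=1, has its half-effect near `x = k` and steepness `n`. Sources on one
(hyper)edge combine conjunctively — activators as `f`, inhibitors as
`1 − f` (AND-NOT) — and parallel edges onto the same node combine as a
noisy-OR, `B = 1 − Π(1 − g_e)`. Smooth AND/OR semantics were chosen over
max/min semantics for differentiability. Each regulated node relaxes as
`dx/dt = τ (B − x)`, so `B ∈ [0,1]` makes [0, 1] forward-invariant for
regulatory states.

Metabolite nodes carry explicit mass balances assembled from
mechanism-tagged reaction edges, each balance multiplied by the node's τ:

* constant source (positive mass-action self-loop): rate `0.5·k`, a pool
  fed at its resting level 0.5;
* first-order drain (negative self-loop): rate `k·x`;
* mass action: `k · Π(source levels)`; protein/activity sources are
  catalysts, metabolite sources are consumed (once per distinct species,
  matching the model's unit-free bookkeeping rather than stoichiometric
  mole counting);
* Michaelis–Menten with competitive inhibition:
  `k·E·S / (kM·(1 + I/kI) + S)`;
* uptake product: `k · Π(source levels)` without consuming its sources —
  the medium pool is treated as effectively unlimited.

The packaged cholesterol network has 44 edges over 21 protein nodes, two
activity nodes (ACAT2, HMGCS1 — activity can deviate from abundance), 11
distinct metabolite/drug species (cholesterol and the three drugs appear as
two pools each), and 25 measured nodes. Choices a reader should know about:

* siRNA perturbations enter as knockdown-input nodes folded into the
  target's activating edge as an AND-NOT source with a fixed steep
  transfer (k = 0.5, n = 4); the knockdown efficiency is the condition's
  input level.
* Lipoprotein-deficient medium is represented by clamping the
  extracellular cholesterol pool (`CholMedia`, 0.5 in full medium, 0.05
  under LPDS) rather than by a separate stimulus node: a dynamic
  `CholMedia` with only an inhibitory input would drift to 1 in the
  untreated condition under noisy-OR semantics, contradicting the
  resting-level penalty applied to it.
* The transcription-factor nodes (SREBP precursor, SREBP1, SREBP2, LXR)
  are modeled as unmeasured: TF abundance is a poor proxy for TF activity
  and low-abundance TFs are routinely missed by DIA proteomics. The
  SREBP precursor drives SREBP1 and SREBP2 through fixed edges
  (k = 0.5, n = 2), and a hypothetical SREBP1 ⊣ SREBP edge provides the
  simplest mechanism by which SREBP1 loss is compensated through SREBP2.

## Parameters

All parameters are dimensionless (time in model units). Shared box
constraints, identical across cell lines:

| kind | meaning | default | bounds |
| --- | --- | --- | --- |
| `k_<src>_<tgt>` | Hill half-effect | 0.5 | [0.01, 1] |
| `n_<src>_<tgt>` | Hill steepness | 2 | [1, 10] |
| `tau_<node>` | relaxation rate | 1 | [0.01, 10] |
| `k1…k8` | metabolic rate constants | 0.5 | [0, 10] |
| `kM4`, `kI_atorvastatin` | saturation / inhibition constants | 0.5 / 1 | [0.01, 10] |

Fixed entries (excluded from optimization): both SREBP→SREBP1/2 edges and
every knockdown transfer. The cholesterol template has 126 parameters, 112
free; the reduced toy model has 19, all free.

Conditions clamp input nodes and select a horizon: 100 time units for
48-hour-class (drug) treatments, 150 for 72-hour-class (siRNA) treatments,
with steady state declared at max |dx/dt| < 1e-6 (reported, never forced).
The packaged roster holds the 23-condition design: two doses per drug
(atorvastatin, T0901317, GW3965, 25-hydroxycholesterol), LPDS alone and
with two statin doses, two independent siRNAs per target gene (SREBF1,
SREBF2, LDLR, NPC1, HMGCS1), the combined SREBF1/2 knockdown, and the
untreated control; vehicle controls are input-identical to untreated and
are not duplicated.

## Data scaling and container

Raw signals are scaled per analyte over the pooled range of all cell lines
and conditions: proteins and drugs min–max, endogenous metabolites 0-to-max
(so small steady-state wiggle does not explode into large scaled variance).
Analytes with a degenerate range become uninformative (level 0.5, weight 0)
instead of raising. Scaled replicate-level values, weights and
differential flags live in a long-format table with the condition roster
attached, serialized to a MIDAS-style CSV (`TR:` treatments, `DA:ALL`
acquisition time, `DV:` values, plus `ID:` columns for condition/replicate/
cell line, which plain MIDAS would force us to re-derive).

## Objective

`loss = Σ w_i (sim_i − obs_i)² / Σ w_i + λ · mean[(x_p(t) − 0.5)²]`

* Observations are replicate means at the horizon; differentially abundant
  (node, condition) cells (mean shift > 0.2 vs. untreated) carry weight 2,
  others 1.
* The second term (λ = 1) averages over the four unquantified nodes and
  the untreated trajectory on a 33-point grid.
* Pseudo-timepoints: per measured pair, three anchors at 0.5/0.8/0.9 of
  the baseline-to-endpoint difference, weight 0.5, probed at the node's
  own e-folding times `t_f = −ln(1−f)/τ` — where a first-order relaxation
  attains exactly fraction f, so monotone trajectories are near-free and
  oscillatory ones are penalized. Because cascade and metabolite nodes are
  not single-exponential, the anchors retain a small irreducible residual
  on any data they did not generate; they are therefore a regularizer, and
  ground-truth-recovery experiments fit with `pseudo_weight = 0`.
* A condition whose integration fails contributes 10× the residual share
  of the all-0.5 constant predictor — large, finite, and not masking the
  failure (the failed fraction is reported per fit).

## Fitting

Per ensemble member: a fresh bootstrap of the biological replicates
(resampling with replacement within each (node, condition) cell, seeded,
shape-preserving), then seeded differential evolution over the free
parameters within bounds (population ≈ 2·d individuals, budget-limited),
followed by a bounded L-BFGS-B polish of the incumbent (≤ 600 extra
evaluations, reported in the evaluation count). Member seeds derive from
the base seed through a `SeedSequence`, so results are independent of
execution order. Presets: `desk` (10 models × 2,000 evaluations, minutes)
and `paper_scale` (100 × 50,000, hours of CPU).

## Cross-cell-line comparison

Per free parameter: Kruskal–Wallis across all cell-line ensembles
(tie-corrected, χ² p-value; all-identical input returns H = 0, p = 1),
Benjamini–Hochberg adjustment across parameters, and the maximum pairwise
Cohen's d (pooled-SD form; a zero pooled SD yields 0 for equal means and
an `inf` sentinel otherwise). One-vs-rest effect sizes are available
behind a flag. A parameter is divergent when d > 4 and adjusted
p < 1e-10; an edge is divergent when any of its parameters is (edge k and
n are tested separately). Transfer-function curves per ensemble member,
with 0.1/0.25/0.5/0.75/0.9 quantile bands, export to CSV for plotting.

## Synthetic data

The generator draws free parameters uniformly within bounds, rejecting
draws whose untreated condition misses quasi-steady state or whose
measured terminal levels leave [0, 1] (the latter keeps class-based scaling
exactly invertible — the zero-noise dataset reproduces the simulated
states to machine precision). Replicate noise is multiplicative lognormal,
mean-preserving, at CV 0.20 by default (the replicate-CV scale of both MS
platforms); metabolite-class analytes get 3 biological × 2 technical
replicates with nested technical noise at CV/4, proteins 3 biological.
Unlike the real study, every analyte class is measured in every condition,
and signals carry no batch structure, missingness, shared-peptide
ambiguity or limit-of-detection censoring — so passing recovery tests
demonstrates the estimation machinery, not robustness to those artifacts.
Planted-divergence scenarios clone a ground truth across cell lines and
shift chosen parameters in one line; ensembles for power analyses are
drawn as clipped Gaussians around each line's truth, emulating
member-to-member spread without the cost of refitting (the full
fit-ensembles-then-compare experiment at study scale is out of desk reach).

## Numerics and problem sizes

The derivative is compiled once per network into a numba kernel (a
readable reference implementation is kept and tested equal). Public
simulation uses `solve_ivp`/LSODA (rtol 1e-7, atol 1e-9); the objective
uses low-overhead `odeint`/LSODA at merged output times (rtol 1e-6).
States are clipped at 0 inside rate laws; metabolite non-negativity and
regulatory boundedness hold analytically and are tested. Ties in top-k
peptide selection break lexicographically; annotation ties break by
smaller mass error, then adduct name. Test problem sizes: the 8-node toy
model (4 conditions) for fitting and oracle checks, with the brute-force
check a fixed-step Euler integration at dt = 1e-4; divergence power uses
4 lines × 100-member ensembles × 100 repeats; the full 44-edge network is
simulated directly in fixture and flux tests.

## Limitations

* The fixture topology realizes every printed count and narrative
  constraint, but where the figure artwork was the only source of an
  edge's routing, the encoding documents one defensible choice.
* Terminal-state (quasi-steady-state) fitting with pseudo-timepoint
  anchors is not time-course fitting; kinetic constants are functional
  descriptions, not biochemical rate constants, and are only identified
  up to the observable surface.
* The desk-scale budgets recover the toy model; training the full network
  to the study's residuals requires the `paper_scale` preset and real
  data.
* The MS statistics operate on identification/quantification tables;
  feature extraction, alignment and raw-spectra processing are upstream
  and out of scope.
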