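# Methods

This note records the models, the stimulus statistics, the parameter
choices that matter, and what the synthetic benchmarks do and do not show.

## Stimuli

Images are 30×30 binary rasters containing N ∈ [1, 32] disjoint axis-aligned
rectangles (4-connected components; objects never touch, not even
diagonally, so the count is unambiguous). Ground-truth metadata —
numerosity, cumulative area A (on-pixel count), contour length C (object
pixels with an off 4-neighbour), per-item areas — is recomputed from the
pixels at construction, never trusted from the generator. Placement is
rejection sampling with a retry cap; infeasible requests raise an explicit
error rather than silently delivering the wrong count.

**Item-size distribution.** In the *free* (natural) regime every item's area
is drawn uniformly from [1, 16] pixels. The upper bound is the widest spread
that still packs reliably at N = 32 on this grid. Under this regime
cumulative area and contour covary with numerosity statistically, as they do
in typical behavioural stimulus sets.

**Unsupervised corpus.** The generative layer trains on images whose
cumulative area is drawn from the levels {32, 64, 96} crossed with
numerosity, decorrelating total area from count across the corpus, so that
numerosity remains a latent statistical regularity rather than a proxy for
brightness.

**Comparison pairs.** Task pairs are drawn from the free regime.
*Congruent* pairs are rejection-sampled until area, contour and mean item
size are all strictly larger on the more numerous side; *incongruent* pairs
reverse all three signs by the minimal sufficient perturbation (the
less-numerous side receives 5–30 % more cumulative area), keeping the
manipulation as close to the natural regime as the reversal allows. All sign
constraints are verified from the pixels. Pair ratios default to
{1:2, 2:3, 3:4, 4:5, 5:6, 6:7}.

## Deep network

* **Filter layer (fixed).** One on-centre and one off-centre
  difference-of-Gaussians prototype (σ_c = 1, σ_s = 2, 9×9 support, exact
  zero weight sum), tiled at stride 2 → 2 × 225 = 450 channels. Responses to
  binary images are gain-normalized into [−1, 1] and half-wave rectified.
  These weights never change.
* **Generative layer.** A 450×400 restricted Boltzmann machine, weights
  initialized N(0, 0.1²). Training is single-step contrastive divergence,
  learning rate 0.05, momentum 0.5→0.9 (switch at epoch 5), weight decay
  2·10⁻⁴, batch 100, plus a sparsity constraint pulling each unit's running
  mean activation toward 0.05 (cost 0.5). Sparsity drives units toward
  local item-detector features rather than dense area-like codes and is
  what lets acuity converge (without it the mature Weber fraction stalls
  near 0.28). Checkpoints are stored every 30 epochs; the default schedule
  is 150 epochs on 5 000 images (scaled profile). No label, metadata or
  task signal reaches this stage — the training function consumes pixels
  only.
* **Read-out.** A single logistic unit over the concatenated mean-field
  hidden codes of the two images, trained by the delta rule on a random
  25 % of the available pairs (each in both left/right orders, so no side
  bias is learnable). The per-trial learning rate anneals as
  0.1/(1 + 0.2·epoch) over 40 epochs and the returned weights average the
  final half of the iterates — the standard stochastic-approximation recipe;
  a constant learning rate leaves the estimate oscillating and inflates the
  fitted Weber fraction. Analyses always use deterministic mean-field
  encodings, so every neuron-level statistic is exactly reproducible.

## Psychometrics

Accuracy is tallied per exact numerosity ratio; the Weber fraction is the
weighted least-squares fit of p(r) = Φ(|ln r|/(√2 w)) (lapse rate 0 by
default). Fits require ≥ 3 ratios with ≥ 20 trials each; tables that are
entirely at chance or at ceiling are fitted but flagged unreliable.
Learning trajectories retrain the read-out with an identical protocol
(fixed seed, fixed pair subset) at every checkpoint, on pairs disjoint from
the evaluation set.

With these defaults the untrained network yields w ≈ 0.34 and the trained
network w ≈ 0.22, with the trajectory 0.34 → 0.25 → 0.23 → 0.21 over
checkpoints — a developmental refinement driven purely by unsupervised
experience.

## Neuronal coding analyses

Probes cross numerosity with cumulative area (summation analysis: N = 1…32
× A ∈ {32, 64} × 20 replicates; selectivity analysis: N = 1…5 ×
A ∈ {16, 32} × 50 replicates). Per unit:

* **Summation coding** — OLS of activation on standardized log₂N and log₂A
  (response standardized as well); *sensitive* iff |B_N| ≥ 0.10,
  |B_A| ≤ 0.05 and R² ≥ 0.50, with the sign of B_N separating increasing
  from decreasing profiles.
* **Selectivity** — balanced two-factor ANOVA with interaction (closed-form,
  vectorized over units; verified against statsmodels in the tests);
  *selective* iff the numerosity main effect is significant at α = 0.01
  while the area main effect and the interaction are not. Preferred
  numerosity is the peak of the area-averaged tuning curve; curves of units
  sharing a preferred level are min–max normalized and pooled. Selection is
  per-neuron with no correction across neurons, matching the
  electrophysiology convention this mirrors.

**Limitation.** In this substrate cumulative-area modulation pervades
essentially every hidden unit (median standardized |B_A| ≈ 0.2–0.6), so
*area-invariant* units under the absolute thresholds above are rare: the
summation-coding census returns counts near zero in both network stages,
and the ANOVA census returns a handful of units in the initial network,
growing several-fold after learning. The qualitative direction
(more numerosity-driven units after unsupervised experience) is robust; the
absolute census sizes are not a strength of this implementation. Relatedly,
the read-out of the *initial* network leans more heavily on continuous
cues than on numerosity — congruent pairs at ratio 1:2 are solved at ~99 %
while minimally cue-reversed pairs fall well below chance-symmetric
performance — and unsupervised learning reduces but does not abolish this
cue dependence. A richer (multi-scale, deeper, or jointly developed) visual
front end would be needed for full cue invariance; the filter layer is
deliberately fixed here.

## Artificial-life simulation

100×100 toroidal grid, food 0–9 per cell; 200 agents; each update lets every
agent sense (current cell + the three cells directly ahead, each quantity as
a 9-unit random binary code) and act (turn left/right, move forward, eat).
Eating transfers the cell's food and empties it; a grazed cell regrows once,
1 000 iterations later, with a fresh uniform {0..9} draw (a pending flag
prevents repeated eating from queueing extra refills). The slow regrowth is
deliberate: with fast regrowth, straight-lane grazing (revisiting each cell
after it has refilled) is optimal and no food-directed steering — hence no
quantity sensitivity — evolves. Under scarcity, steering toward richer
sensed cells pays, and the 3×3 comparison battery shows strong distance
effects.

Controllers are recurrent: 36 inputs → up to 20 tanh hidden units
(asymmetric recurrence) → 4 effectors, argmax action selection with random
tie-breaks. Genomes store padded weight arrays plus the active hidden size
(2–20); the steady-state GA samples two parents uniformly among agents older
than 500 steps and replaces the weaker (lifetime collection rate) by their
child: uniform per-gene crossover, Gaussian mutation (σ = 0.05, per-gene
rate 0.01), hidden-size mutation ±1 at rate 0.02, weights clamped to ±10.

The 3×3 test arena is walled; the agent starts at the centre facing the
baited row and a trial ends when it walks onto a corner (step cap 50;
timeouts are logged and excluded from accuracy). Every ordered pair of
distinct quantities 1–9 × 50 repetitions = 3600 trials per agent.

**What emerges, and what does not.** At the scaled budget (200 000
iterations ≈ 1 000 population turnovers) mean fitness rises in nearly every
seed and evolved populations show accuracy strongly increasing with
numerical distance and response time decreasing with it. A *size* effect
(worse accuracy at larger magnitudes for equal distance) does **not**
emerge: the n-of-9 binary code delivers quantity as a linear sum, so the
evolved discrimination depends on the absolute difference only. The
proportion of at-chance agents is highly seed-dependent at this budget
(roughly 0–60 %; convergence to a stable mix of discriminators and
non-discriminators would require the multi-million-iteration regime).
Marginal accuracy-by-magnitude tables are also confounded with distance
(the largest distances only occur at large maxima) and should be read
jointly with the by-distance table.

## Problem sizes

Library defaults (scaled profile): 5 000-image corpus, 150 unsupervised
epochs, 400 training + 200 evaluation pairs per ratio, 200
congruency-controlled pairs per condition, full-range coding probes,
200 000 ecosystem iterations with the complete 200-agent battery. The test
suite exercises the same pipelines at reduced sizes (3 500-image corpus, 60
epochs, 3 seeds; 40-agent battery; ten 15 000-iteration fitness-trend runs),
chosen so the whole suite completes in minutes while preserving each
phenomenon's direction and approximate magnitude. The full profile
(51 200 images, 300 epochs, millions of iterations) uses the same code
paths.

## Numerical conventions

4-connectivity everywhere; contour counts pixels with ≥ 1 off 4-neighbour
(outside the grid counts as off). Filter kernels are differences of two
unit-mass Gaussians, hence exactly zero-sum; gains normalize binary-image
responses into [−1, 1]. Sigmoids are clipped at ±30 before exponentiation.
Action-selection ties break uniformly at random from the trial's stream.
Zero-variance units are flagged and excluded from both coding censuses.
All stage seeds derive deterministically from one master seed
(`experiments.derive_seeds`); every experiment writes a manifest from which
it can be re-run bit-identically.
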