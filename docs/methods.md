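# Methods

## The propagation model

The interactome is a directed graph whose edges carry a sign (+1 activation,
−1 inhibition) and a confidence weight in [0, 1]. A pair of proteins may be
linked by one activating and one inhibiting edge simultaneously (conflicting
evidence is real in curated interactomes); their contributions sum in the
adjacency, so equal-weight opposing edges cancel. Self-loops are allowed.

Node activities evolve by the synchronous update
`v_i ← tanh(Σ_j A_ij v_j)` with `A_ij = w_ij · s_ij` and clamped nodes reset
to their clamp value after every step. tanh was chosen as the squashing
function because it is bounded, smooth, odd (so inverting every stimulus
inverts every response exactly — an invariant the tests assert to 1e−12) and
approximately linear near zero, which makes the small-signal regime
checkable against an independent path-sum oracle: on acyclic graphs with
clamp magnitudes ≈ 0.01 the fixed point equals the sum over directed paths
of the products of signed weights times the clamp, to 1e−3 relative error.

Iteration starts from the zero state, so nodes with no directed path from a
clamped node stay exactly 0 (locality). Convergence is declared when the
largest per-node change falls below `tol` (default 1e−6, ≤ 200 iterations).
Feedback loops can oscillate instead of converging; the engine detects limit
cycles up to period 64 by comparing the current state against the trailing
window, reports the average over one period, and flags the result
`converged=False`. This keeps oscillating systems deterministic and bounded
rather than erroring out.

A drug acts as a *sustained clamp* (its pharmacology is maintained, not a
transient pulse): each target is fixed at +1 or −1 for the whole
propagation. When several clamps land on one protein — a drug inhibiting
what a candidate mutation activates — the values sum and clip to [−1, 1], so
+1 against −1 cancels to 0. This represents competing pharmacology without
an arbitrary precedence rule.

## Ensembles and fitting

Edge weights are under-determined by any realistic restraint set, so the
model is always used as an ensemble of M solutions. Each solution starts
from weights drawn uniformly in [0, 1] and, when restraints are supplied, is
refined by simulated annealing: a proposal perturbs 4 randomly chosen
weights by N(0, 0.15) (clipped to [0, 1]), the per-restraint fixed points
are recomputed (warm-started from the incumbent state, since a few-weight
move barely shifts them), and the move is accepted by the Metropolis rule
with geometric cooling (T₀ = 1.0, factor 0.995, 2000 steps). The loss is
the fraction of expected effector signs violated, where a sign counts as
satisfied only when `expected · signal > 0.2` — the margin forces confident,
not borderline, agreement during fitting.

Two accuracy figures are reported. Per solution: the fraction of restraints
whose expected signs all hold (strict sign test, margin 0) under that
solution's weights. For the ensemble: the same fraction evaluated on the
*consensus* signals (the mean across solutions per restraint). The consensus
is the headline number because the ensemble, not any single draw, is the
model. On 200-node synthetic networks with 20 noise-free restraints
generated from a known ground-truth weight assignment, a 20-solution
ensemble recovers ≥ 90% of the restraints — the parameter-recovery check
that a known answer makes possible.

With no restraints the weights stay at their uniform draws and accuracy is
1.0 by convention. The head-to-head comparison uses exactly this mode: the
solution-to-solution weight variability is the noise model over which the
statistics are computed, and the difference between drugs comes only from
their target sets.

## TSignal and the mechanism-of-action subnetwork

TSignal is reversal-positive: each signed effector contributes
`−pathological_state · signal`, so a drug that drives a
pathologically-activated effector negative scores positively. Effectors with
a complex role (state 9) carry no sign to reverse; they are excluded from
TSignal but retained in the heatmap export. An effector removed from the
network (by a deletion scan) contributes signal 0.

The MoA subnetwork is the set of proteins whose |mean signal across
solutions| exceeds ε (default 1e−6 — "non-null" up to float noise) plus all
induced edges. Clamped targets are always members.

## Head-to-head statistics

Per motive, the per-solution TSignal samples of the two drugs are compared
with a Welch (unequal-variance) t-test and BH-adjusted across motives. A
winner is declared only at q < α (default 0.05). Per effector, the same test
runs on per-solution reversal values with BH across the effector list, and a
"more reversed by" call additionally requires a relative TSignal change
above 20%, computed as `|rA − rB| / max(|rA|, |rB|) × 100` (0 when both are
0 — the max-denominator avoids blow-ups near zero). Everything else is a
tie, reported as its own category; the per-motive percentage triple is
computed on exact counts and sums to 100 by construction. Degenerate tests
(both samples constant) report p = 1 when equal and p = 0 when not, so
comparing an ensemble against itself yields all-ties rather than NaNs.

Across-solutions (rather than across-effectors) testing is the adopted
reading for the motive comparison; the alternative would confound effector
heterogeneity with ensemble uncertainty.

## Perturbation scans

The resistance universe is deliberately reduced to the neighborhood
(undirected, radius configurable, default 1) of the disease effectors and
drug targets; "around" is read undirected as the inclusive interpretation.
Each protein contributes three modifications — activation (clamp +1),
inhibition (clamp −1), deletion (node and incident edges removed) — giving
exactly 3 × |universe| scan points. For each, every solution's global
TSignal is recomputed and compared to baseline with a *paired* t-test
(perturbed and baseline share solutions). Selection requires p ≤ 0.022 and
delta < 0: a resistance must weaken the reversal, not merely change it. The
0.022 default is adopted as the field-reported convention for this scan;
lowering α can only remove selections (monotonicity is tested).

Interference scans add the co-treatment's own target clamps (its profile's
stated actions; +1 for bare protein lists) on top of the primary drug's,
with the same paired test, tiered strong (p < 0.05) / weak (p < 0.1).
Co-drug targets absent from the network are skipped with a warning; a
co-drug with no resolvable targets is reported inert. Scans never mutate
their inputs and are deterministic given the ensemble.

## Relation classifier

The relation between a protein set and a motive is scored by a feed-forward
classifier (one hidden layer of 16 units, standardized inputs) on an
8-dimensional proximity vector: min and mean directed distance to the
effector set, fraction of effectors reachable, propagation overlap (mean
|signal| at the effectors when the sources are clamped +1), mean source
out-degree, mean effector in-degree, and the two set sizes. Disconnected
pairs use the finite sentinel `undirected diameter + 1` so "far" and
"unreachable" stay on one monotone scale. Accuracy is estimated by
stratified k-fold cross-validation (default 5 folds, seeded shuffling) and
the model is refit on all rows afterwards. Scores bin into "+"…"++++" at
0.25/0.5/0.75 with upper-inclusive boundaries (a score of exactly 0.25 is
"+"); the cutoffs are fixed quartiles — the qualitative grades have no
field-standard definition, so an explicit, monotone rule was chosen.
Per-target scoring (one column per target, not whole-profile marginals) is
the adopted reading for the target × motive grid.

## Sobol sensitivity

Factors for a drug model: each target's clamp magnitude in [0.5, 1]
(partial-to-full target engagement) and one multiplicative scale on all
edge weights in [0.5, 1.5] (global confidence in the network). The analysis
uses Saltelli's scheme on a scrambled Sobol sequence — N·(k+2) model
evaluations for k factors — with Jansen's estimators for S1 and ST and 100
bootstrap resamples for 95% half-widths. The estimators reproduce the
closed-form indices of additive test models (Y = X1 + 2X2 → S1 = 0.2/0.8)
within ±0.05 at N = 1024, report ≈ 0 for factors the output ignores, and
satisfy ST ≥ S1 up to estimator tolerance. Base sample sizes that are powers
of two keep the sequence balanced. Evaluations use the ensemble's mean
weight vector; second-order indices are out of scope.

## Synthetic data: what it emulates and what it does not

The generators stand in for three unavailable curated inputs: the
interactome, the disease characterization, and the restraint/relation
training compendium.

*Interactome*: preferential attachment, oldest-first, with new nodes
receiving edges from existing nodes chosen ∝ out-degree + 1, a feedback
edge from 10% of nodes, 25% inhibitory signs, unit weights. This yields
hub-dominated, mostly feed-forward topology — the shape that makes "drug
targets are upstream hubs" meaningful. Defaults: 500 nodes, mean out-degree
3.

*Disease*: five motives totalling exactly 174 unique effectors
(40/30/35/39/30), placed on nodes downstream of the drug targets.
Pathological states are assigned from a reference propagation with all
targets inhibited: an effector driven negative is recorded as
pathologically activated (+1), and vice versa, so treatment reverses
pathology by construction; inhibitory paths produce a natural minority of
−1 states, and 6 effectors are recoded to the complex-role state 9. An
8-protein brain-metastasis panel is drawn from the invasion/metastasis
motive, preferring nodes reachable only from the broad drug's exclusive
targets.

*Drugs*: the broad profile clamps the top six out-degree hubs at −1, the
narrow profile two, sharing the single top hub as anchor — the engineered
analogue of a multi-kinase inhibitor versus a selective one sharing ALK. In
the packaged study-scale bundle the target nodes carry the kinase labels
(ALK, FLT3, FER, ROS1, IGF1R, EGFR, RET) and the panel carries the
brain-metastasis effector labels; all other identifiers are synthetic.

*Truth table and restraints*: positives pair a stimulus protein with 3–6
effectors within 3 hops; negatives use distal/unreachable proteins;
restraint expected signs come from propagating the stimulus through a known
ground-truth weight assignment, keeping only confidently signed effectors
(|signal| > 0.05). Label noise (default 5%) flips truth-table labels.

What passing tests on these data do **not** show: real interactomes have
curated edge confidences, dense feedback, and hub structure that does not
coincide with drug-target identity; real disease characterizations are not
placed downstream of the drugs by construction; and effector placement here
is engineered so the broad drug reaches more of every motive — at this
scale the broad drug wins all five motives, including the immune-evasion
analogue whose effectors are drawn preferring the narrow drug's territory
(the narrow target's downstream set is nested inside the broad drug's in
hub-dominated graphs). The statistics, invariants and recovery properties
transfer; the biological directions of specific motives do not.

## Problem sizes and numerical defaults

Default study scale: 500-node network, M = 100 solutions per ensemble for
comparisons, 20 solutions for restraint-recovery runs, 200-row truth tables,
Sobol N = 256 (1024 in the estimator tests). These sizes keep a full
end-to-end run and the whole test suite in the minutes range on a single
CPU while leaving every statistic well-powered. Other defaults: propagation
tol 1e−6 and 200 iterations (60 inside the annealing loop); MoA ε 1e−6;
annealing 2000 steps, T₀ 1.0, cooling 0.995, margin 0.2, 4 moves/step;
comparison α 0.05 and 20% change threshold; resistance α 0.022;
interference tiers 0.05/0.1; grade cutoffs 0.25/0.5/0.75. All of them live
in the config dataclasses and the YAML run config (strict: unknown keys are
fatal before any stage runs).

## Known limitations

* The annealing objective is sign-satisfaction only; it does not regularize
  weights, so fitted ensembles are families of sign-consistent models, not
  posterior samples.
* Per-solution restraint accuracy is typically well below the consensus
  accuracy — individual anneals get stuck; the ensemble mean is the reliable
  object.
* The tanh update is one defensible semantics among several (Boolean,
  piecewise-linear, ODE); conclusions that depend on the squashing shape
  rather than on signs and reachability should be treated cautiously.
* Limit-cycle averaging makes oscillatory outputs deterministic but hides
  amplitude information.
* The relation classifier's features are purely topological/dynamical;
  it cannot encode biological annotation a curated compendium would carry.
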