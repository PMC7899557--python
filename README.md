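# netmoa

In silico head-to-head comparison of drug mechanisms of action over a signed
human protein-interaction network.

Targeted therapies with overlapping indications are rarely compared directly
in trials. `netmoa` provides a mechanistic, network-based alternative: each
drug is modelled as a sustained clamp on its target proteins (+1 activation,
−1 inactivation), the clamp is propagated over a signed, weighted, directed
interactome, and the drug's predicted effect on a disease is summarized over
the effector proteins that molecularly define its pathophysiological
processes ("motives"). The archetypal use case is comparing a broad-spectrum
multi-kinase inhibitor (six targets) with a selective two-target inhibitor
that shares one anchor target — the brigatinib-versus-alectinib situation in
ALK-positive non-small-cell lung cancer.

## The model

Signal spreads by the synchronous update

```
v_i ← tanh( Σ_{j→i} w_ji · s_ji · v_j ),      s_ji ∈ {+1, −1},  w_ji ∈ [0, 1]
```

with drug-target nodes held at their clamp value. Because the edge weights
`w` are under-determined, the model is an **ensemble**: M independent
stochastic fits (simulated annealing against sign restraints), each giving
one *model solution* with its own node-signal vector in [−1, 1]^N.

The effect on a disease is the **TSignal**: for effectors with pathological
state `p_e ∈ {+1, −1}` (state 9 = complex role, excluded),

```
TSignal = mean_e ( −p_e · v_e )        ∈ [−1, 1]
```

so +1 means full reversal of every effector's pathological direction.
Per-solution TSignal distributions feed the downstream statistics:

* **Head-to-head comparison** — per-motive Welch t-tests across solutions,
  Benjamini–Hochberg FDR across motives; per-effector calls require the dual
  criterion *q* < 0.05 **and** relative TSignal change > 20%, with explicit
  ties; a brain-metastasis effector panel is reported separately.
* **Resistance scan** — every protein in a neighborhood of the effectors and
  targets is activated, inhibited and deleted (3 modifications each); a
  modification is a candidate bypass resistance when the paired t-test gives
  *p* ≤ 0.022 and the TSignal drops.
* **Interference scan** — each co-treatment's target clamps are added to the
  model; interference is tiered strong (*p* < 0.05) or weak (*p* < 0.1).
* **Relation classifier** — a single-hidden-layer network on proximity
  features (distances, reachability, propagation overlap, degrees) scores
  target↔motive relatedness, graded "+" to "++++".
* **Sobol sensitivity** — Saltelli sampling + Jansen estimators of first-
  and total-order indices of the TSignal with respect to per-target clamp
  magnitudes and a global weight scale.

Because curated interactomes, disease characterizations and training
compendia of this kind are proprietary, the package ships seeded generators
that emulate all of them at the study's scale (500-node scale-free signed
network; 5 motives totalling 174 effectors; 6-target vs 2-target inhibitors
sharing one anchor; an 8-protein brain-metastasis panel; restraints derived
from a known ground-truth model).

## Worked example

```python
import netmoa as nm

bundle = nm.paper_mimic(seed=1)          # network + drugs + disease + panel
ensA = nm.fit_ensemble(bundle.net, [], M=100, seed=2, drug=bundle.broad)
ensB = nm.fit_ensemble(bundle.net, [], M=100, seed=3, drug=bundle.narrow)

for m in nm.compare_motives(ensA, ensB, bundle.disease):
    print(f"{m.motive:34s} TSignal {m.mean_tsignal_a:+.3f} vs "
          f"{m.mean_tsignal_b:+.3f}  q={m.q_value:.2e}  winner={m.winner}")
```

prints

```
cell_growth_and_proliferation      TSignal +0.472 vs +0.117  q=4.18e-104  winner=brigatinib
sustained_angiogenesis             TSignal +0.428 vs +0.206  q=2.62e-62  winner=brigatinib
evading_apoptosis                  TSignal +0.445 vs +0.118  q=4.18e-104  winner=brigatinib
tissue_invasion_and_metastasis     TSignal +0.493 vs +0.145  q=5.87e-83  winner=brigatinib
immune_evasion                     TSignal +0.417 vs +0.163  q=2.41e-81  winner=brigatinib
```

The broad 6-target inhibitor reverses every motive's effectors more strongly
than the narrow 2-target one, and every per-motive difference is significant
after FDR adjustment — the mean TSignal is the average reversal of that
motive's effectors, and `q` is the BH-adjusted Welch p-value across the 100
solutions of each ensemble.

The same pipeline is scriptable end-to-end from the shell:

```
netmoa run --seed 1 --outdir results_run      # simulate → fit → … → sobol
netmoa compare --outdir results_run           # restart a single stage
```

Each stage writes plain TSV/JSON artifacts plus a manifest with seeds and
file digests; reruns with the same seed are byte-identical.

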