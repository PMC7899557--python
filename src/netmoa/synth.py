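"""Seeded generators for every input the pipeline consumes.

Real drug/disease modelling of this kind runs on a proprietary curated human
interactome, a literature-derived disease characterization and a training
compendium, none of which can ship with a package.  These generators emulate
each of them at the study's scale so the whole pipeline is exercisable and
testable offline:

* a preferential-attachment signed directed network (hubs first, mostly
  feed-forward with a configurable fraction of feedback edges and of
  inhibitory signs);
* a disease characterization of 5 motives totalling 174 unique effector
  proteins, placed downstream of the drug targets, with pathological
  directions consistent with a reference propagation (plus a configurable
  few complex-role entries) and an 8-protein brain-metastasis panel;
* a broad 6-target inhibitor versus a narrow 2-target inhibitor sharing one
  anchor target — the structure of a multi-kinase versus a selective ALK
  inhibitor;
* a relation truth table (proximal positives, distal negatives) and sign
  restraints propagated through a known ground-truth weight assignment, so
  parameter-recovery is checkable against a known answer.

Everything is deterministic under ``SynthConfig.seed``.  The ``paper_mimic``
bundle applies the study's gene labels to the drug-target and brain-panel
nodes (ALK, FLT3, FER, ROS1, IGF1R, EGFR, RET; FGFR1, MKI67, ROBO1, S100A7,
S100B, SIRT1, SLIT2, VEGFA); all other proteins keep synthetic identifiers.

Engineered, and deliberate: effector placement favours nodes reachable from
the broad drug's exclusive targets for four of the five motives and from the
narrow drug's exclusive target for the immune-evasion motive, so the two
ensembles genuinely differ per motive in the direction the head-to-head
statistics are designed to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    BrainPanel,
    DiseaseCharacterization,
    DrugTargetProfile,
    Edge,
    Effector,
    Interactome,
    Restraint,
    ValidationError,
)
from .engine import propagate
from .relations import TruthTable, TruthTableRow

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "generate_interactome",
    "generate_drugs",
    "generate_disease",
    "generate_ground_truth_weights",
    "generate_truth_table",
    "paper_mimic",
    "BROAD_TARGET_LABELS",
    "NARROW_TARGET_LABELS",
    "PANEL_LABELS",
]

# gene labels used in the mimic bundle: 6 broad-drug targets, 2 narrow-drug
# targets (sharing the first), and the 8 brain-metastasis panel effectors
BROAD_TARGET_LABELS = ("ALK", "FLT3", "FER", "ROS1", "IGF1R", "EGFR")
NARROW_TARGET_LABELS = ("ALK", "RET")
PANEL_LABELS = (
    "FGFR1", "MKI67", "ROBO1", "S100A7", "S100B", "SIRT1", "SLIT2", "VEGFA",
)

MOTIVE_NAMES = (
    "cell_growth_and_proliferation",
    "sustained_angiogenesis",
    "evading_apoptosis",
    "tissue_invasion_and_metastasis",
    "immune_evasion",
)


@dataclass(frozen=True)
class SynthConfig:
    n_nodes: int = 500
    mean_out_degree: float = 3.0
    negative_edge_fraction: float = 0.25
    feedback_fraction: float = 0.1          # chance a new node sends an edge back
    n_motives: int = 5
    effectors_per_motive: tuple[int, ...] = (40, 30, 35, 39, 30)  # unique, sums to 174
    n_complex_role: int = 6                 # effectors recoded as state 9
    n_panel: int = 8
    n_targets_broad: int = 6
    n_targets_narrow: int = 2
    n_shared_targets: int = 1
    n_positive_rows: int = 100
    n_negative_rows: int = 100
    label_noise: float = 0.05
    n_restraints: int = 20
    restraint_noise: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_nodes < 10:
            raise ValidationError("n_nodes must be >= 10")
        for name in ("mean_out_degree",):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("negative_edge_fraction", "feedback_fraction",
                     "label_noise", "restraint_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if len(self.effectors_per_motive) != self.n_motives:
            raise ValidationError(
                "effectors_per_motive must have n_motives entries"
            )
        if any(c <= 0 for c in self.effectors_per_motive):
            raise ValidationError("effector counts must be positive")
        if sum(self.effectors_per_motive) > self.n_nodes:
            raise ValidationError("total effectors exceed n_nodes")
        if not (1 <= self.n_shared_targets
                <= min(self.n_targets_broad, self.n_targets_narrow)):
            raise ValidationError("n_shared_targets out of range")


@dataclass
class SynthBundle:
    """Everything one seeded study run needs."""

    config: SynthConfig
    net: Interactome
    broad: DrugTargetProfile
    narrow: DrugTargetProfile
    disease: DiseaseCharacterization
    panel: BrainPanel


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_interactome(cfg: SynthConfig) -> Interactome:
    """Preferential-attachment signed digraph, oldest nodes becoming hubs.

    Each new node receives edges from existing nodes chosen proportionally to
    their current out-degree (+1), so early nodes accumulate large downstream
    trees — the shape drug targets need.  A configurable fraction of new
    nodes sends one edge back upstream, adding feedback loops.
    """
    rng = _rng(cfg, 0)
    width = len(str(cfg.n_nodes - 1))
    names = [f"P{i:0{width}d}" for i in range(cfg.n_nodes)]
    m0 = max(3, int(round(cfg.mean_out_degree)))
    edges: set[tuple[str, str, int]] = set()
    out_deg = np.zeros(cfg.n_nodes)

    def sign() -> int:
        return -1 if rng.random() < cfg.negative_edge_fraction else 1

    def add(i: int, j: int) -> None:
        key = (names[i], names[j], sign())
        if (key[0], key[1], key[2]) not in edges:
            edges.add(key)
            out_deg[i] += 1

    for i in range(1, m0):            # seed chain
        add(i - 1, i)
    for v in range(m0, cfg.n_nodes):
        d = 1 + rng.poisson(max(cfg.mean_out_degree - 1.0, 0.0))
        d = min(d, v)
        probs = out_deg[:v] + 1.0
        probs /= probs.sum()
        sources = rng.choice(v, size=d, replace=False, p=probs)
        for s in sources:
            add(int(s), v)
        if rng.random() < cfg.feedback_fraction:
            back = int(rng.integers(0, v))
            add(v, back)
    edge_tuples = tuple(
        Edge(s, t, sg, 1.0) for s, t, sg in sorted(edges)
    )
    return Interactome(nodes=tuple(names), edges=edge_tuples)


def _select_target_nodes(net: Interactome, cfg: SynthConfig) -> list[str]:
    """Deterministic target choice: the highest out-degree hubs.

    Order: shared anchor(s) first, then broad-exclusive, then narrow-exclusive.
    """
    n_needed = (cfg.n_targets_broad + cfg.n_targets_narrow
                - cfg.n_shared_targets)
    ranked = sorted(net.nodes, key=lambda n: (-net.out_degree(n), n))
    return ranked[:n_needed]


def generate_drugs(net: Interactome, cfg: SynthConfig):
    """(broad, narrow) inhibitor profiles sharing the anchor target(s)."""
    picks = _select_target_nodes(net, cfg)
    shared = picks[: cfg.n_shared_targets]
    broad_excl = picks[cfg.n_shared_targets: cfg.n_targets_broad]
    narrow_excl = picks[cfg.n_targets_broad:]
    broad = DrugTargetProfile(
        "brigatinib", {p: -1 for p in shared + broad_excl}
    )
    narrow = DrugTargetProfile(
        "alectinib", {p: -1 for p in shared + narrow_excl}
    )
    return broad, narrow


def generate_disease(net: Interactome, cfg: SynthConfig):
    """(DiseaseCharacterization, BrainPanel) with engineered drug asymmetry.

    Pathological states are the sign a combined-inhibition propagation works
    against: with every target clamped -1 at reference weights, an effector
    pushed to a negative signal is recorded as pathologically activated (+1),
    and vice versa — so successful treatment reverses the pathology.
    """
    picks = _select_target_nodes(net, cfg)
    shared = set(picks[: cfg.n_shared_targets])
    broad_excl = set(picks[cfg.n_shared_targets: cfg.n_targets_broad])
    narrow_excl = set(picks[cfg.n_targets_broad:])
    targets = shared | broad_excl | narrow_excl

    down_broad = net.descendants(broad_excl) - targets
    down_narrow = net.descendants(narrow_excl) - targets
    down_shared = net.descendants(shared) - targets
    reachable = down_broad | down_narrow | down_shared

    rng = _rng(cfg, 1)
    ref = propagate(net, None, {t: -1.0 for t in targets}, max_iter=200, tol=1e-9)
    ref_values = {n: ref[n] for n in reachable}
    # effectors need a definite reference signal to carry a pathological sign
    usable = sorted(n for n, v in ref_values.items() if abs(v) > 1e-9)
    if len(usable) < sum(cfg.effectors_per_motive):
        raise ValidationError(
            f"network too sparse: {len(usable)} usable downstream nodes for "
            f"{sum(cfg.effectors_per_motive)} effectors"
        )
    broad_pool = [n for n in usable if n in down_broad]
    narrow_pool = [n for n in usable if n in down_narrow]

    used: set[str] = set()

    def draw(pool: Sequence[str], k: int) -> list[str]:
        avail = [n for n in pool if n not in used]
        take = min(k, len(avail))
        chosen = [str(c) for c in rng.choice(avail, size=take, replace=False)] if take else []
        if take < k:        # fall back to any usable node
            rest = [n for n in usable if n not in used and n not in chosen]
            chosen += [str(c) for c in rng.choice(rest, size=k - take, replace=False)]
        used.update(chosen)
        return chosen

    motives: dict[str, tuple[Effector, ...]] = {}
    immune_idx = cfg.n_motives - 1
    for i, name in enumerate(MOTIVE_NAMES[: cfg.n_motives]):
        count = cfg.effectors_per_motive[i]
        # prefer narrow-drug territory for the immune motive, broad elsewhere
        pool = narrow_pool if i == immune_idx else broad_pool
        chosen = draw(pool, count)
        motives[name] = tuple(
            Effector(p, 1 if ref_values[p] < 0 else -1) for p in chosen
        )

    # brain panel: from the metastasis motive, preferring broad-only nodes
    meta_name = MOTIVE_NAMES[3] if cfg.n_motives >= 4 else MOTIVE_NAMES[0]
    meta_effs = list(motives[meta_name])
    broad_only = down_broad - down_narrow - down_shared
    meta_effs.sort(key=lambda e: (e.protein not in broad_only, e.protein))
    panel_proteins = tuple(e.protein for e in meta_effs[: cfg.n_panel])

    # recode a few non-panel effectors as complex-role (state 9)
    flat = [
        (m, j) for m, effs in motives.items()
        for j, e in enumerate(effs) if e.protein not in panel_proteins
    ]
    n_complex = min(cfg.n_complex_role, len(flat))
    if n_complex:
        for sel in rng.choice(len(flat), size=n_complex, replace=False):
            m, j = flat[int(sel)]
            effs = list(motives[m])
            effs[j] = Effector(effs[j].protein, 9)
            motives[m] = tuple(effs)

    disease = DiseaseCharacterization(motives=motives)
    panel = BrainPanel(proteins=panel_proteins)
    panel.validate_against(disease)
    return disease, panel


def generate_ground_truth_weights(net: Interactome, cfg: SynthConfig) -> np.ndarray:
    """A known weight assignment, the oracle for parameter-recovery tests."""
    rng = _rng(cfg, 2)
    return rng.uniform(0.3, 1.0, size=net.n_edges)


def generate_truth_table(net: Interactome, ground_truth_weights: np.ndarray,
                         cfg: SynthConfig):
    """(TruthTable, restraints) from the ground-truth model.

    Positives pair a stimulus set with effectors it demonstrably drives
    (downstream within 3 hops, confident propagated sign); negatives pair it
    with distal or unreachable proteins.  ``label_noise`` flips truth-table
    labels; ``restraint_noise`` flips expected restraint signs.
    """
    w = np.asarray(ground_truth_weights, dtype=float)
    if w.shape != (net.n_edges,):
        raise ValidationError("ground-truth weights do not match the network")
    rng = _rng(cfg, 3)
    g = net._digraph
    nodes = list(net.nodes)

    import networkx as nx

    def near(src: str, radius: int = 3) -> list[str]:
        d = nx.single_source_shortest_path_length(g, src, cutoff=radius)
        d.pop(src, None)
        return sorted(d)

    rows: list[TruthTableRow] = []
    restraints: list[Restraint] = []
    attempts = 0
    while len([r for r in rows if r.label == "related"]) < cfg.n_positive_rows:
        attempts += 1
        if attempts > 50 * cfg.n_positive_rows:
            raise ValidationError("could not place enough proximal positives")
        src = nodes[int(rng.integers(0, len(nodes)))]
        cand = near(src)
        if len(cand) < 3:
            continue
        k = int(rng.integers(3, min(6, len(cand)) + 1))
        effs = [str(e) for e in rng.choice(cand, size=k, replace=False)]
        rows.append(TruthTableRow(frozenset([src]), frozenset(effs), "related"))
        if len(restraints) < cfg.n_restraints:
            value = int(rng.choice([-1, 1]))
            res = propagate(net, w, {src: float(value)}, max_iter=200, tol=1e-9)
            conf = [(e, res[e]) for e in effs if abs(res[e]) > 0.05]
            if conf:
                expected = {}
                for e, v in conf[:4]:
                    s = 1 if v > 0 else -1
                    if rng.random() < cfg.restraint_noise:
                        s = -s
                    expected[e] = s
                restraints.append(
                    Restraint({src: value}, expected, "positive")
                )

    n_neg = 0
    attempts = 0
    while n_neg < cfg.n_negative_rows:
        attempts += 1
        if attempts > 50 * cfg.n_negative_rows:
            raise ValidationError("could not place enough distal negatives")
        src = nodes[int(rng.integers(0, len(nodes)))]
        near_set = set(near(src)) | {src}
        far = [n for n in nodes if n not in near_set]
        if len(far) < 3:
            continue
        k = int(rng.integers(3, min(6, len(far)) + 1))
        effs = [str(e) for e in rng.choice(far, size=k, replace=False)]
        rows.append(TruthTableRow(frozenset([src]), frozenset(effs), "unrelated"))
        n_neg += 1

    if cfg.label_noise > 0:
        flipped = []
        for r in rows:
            if rng.random() < cfg.label_noise:
                other = "unrelated" if r.label == "related" else "related"
                flipped.append(TruthTableRow(r.source, r.effectors, other))
            else:
                flipped.append(r)
        rows = flipped
    return TruthTable(rows), restraints


def paper_mimic(seed: int = 1, cfg: SynthConfig | None = None) -> SynthBundle:
    """The packaged study-scale fixture, with gene labels applied.

    Builds the interactome, selects drug targets and the disease
    characterization, then renames the target nodes to the study's kinase
    labels and the panel nodes to the brain-metastasis effector labels.
    """
    cfg = replace(cfg or SynthConfig(), seed=seed)
    net = generate_interactome(cfg)
    broad, narrow = generate_drugs(net, cfg)
    disease, panel = generate_disease(net, cfg)

    target_order = _select_target_nodes(net, cfg)
    labels = (
        list(BROAD_TARGET_LABELS[: cfg.n_targets_broad])
        + list(NARROW_TARGET_LABELS[cfg.n_shared_targets: cfg.n_targets_narrow])
    )
    mapping = dict(zip(target_order, labels))
    mapping.update(dict(zip(panel.proteins, PANEL_LABELS[: cfg.n_panel])))

    rename = lambda p: mapping.get(p, p)
    net = net.relabel(mapping)
    broad = DrugTargetProfile(
        broad.drug_name, {rename(p): a for p, a in broad.targets.items()}
    )
    narrow = DrugTargetProfile(
        narrow.drug_name, {rename(p): a for p, a in narrow.targets.items()}
    )
    disease = DiseaseCharacterization(
        motives={
            m: tuple(Effector(rename(e.protein), e.pathological_state) for e in effs)
            for m, effs in disease.motives.items()
        }
    )
    panel = BrainPanel(proteins=tuple(rename(p) for p in panel.proteins))
    panel.validate_against(disease)
    return SynthBundle(cfg, net, broad, narrow, disease, panel)
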