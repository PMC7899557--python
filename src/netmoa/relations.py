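"""Network-proximity relation scoring between protein sets and motives.

A small feed-forward classifier decides whether a source protein set (for
example a drug's targets) is mechanistically related to an effector set (a
motive's molecular definition).  The inputs are topological and dynamical
proximity features computed on the interactome: shortest-path distances,
reachable fraction, propagation overlap and degree statistics.  Scores in
[0, 1] are binned into the qualitative grades "+" to "++++".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import RelateConfig
from .core import DiseaseCharacterization, DrugTargetProfile, Interactome, ValidationError
from .engine import propagate

__all__ = [
    "TruthTableRow",
    "TruthTable",
    "RelationScore",
    "featurize",
    "train_cv",
    "score_and_bin",
    "relation_grid",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "min_distance",
    "mean_distance",
    "reachable_fraction",
    "propagation_overlap",
    "source_mean_out_degree",
    "effector_mean_in_degree",
    "source_size",
    "effector_size",
)

BINS = ("+", "++", "+++", "++++")


@dataclass(frozen=True)
class TruthTableRow:
    source: frozenset
    effectors: frozenset
    label: str      # "related" | "unrelated"

    def __post_init__(self) -> None:
        if not self.source or not self.effectors:
            raise ValidationError("truth-table sets must be non-empty")
        if self.label not in ("related", "unrelated"):
            raise ValidationError(f"bad truth-table label {self.label!r}")


@dataclass
class TruthTable:
    rows: list[TruthTableRow]

    def labels(self) -> np.ndarray:
        return np.array([r.label == "related" for r in self.rows], dtype=int)


@dataclass
class RelationScore:
    source: frozenset
    motive: str
    score: float
    bin: str


def featurize(source: Iterable[str], targets_of_interest: Iterable[str],
              net: Interactome) -> np.ndarray:
    """Fixed-length proximity feature vector for a (source, effector-set) pair.

    Disconnected pairs get the finite distance sentinel ``diameter + 1`` so
    that "far" and "unreachable" stay on one monotone scale.
    """
    source = sorted(set(source))
    effs = sorted(set(targets_of_interest))
    unknown = [p for p in source + effs if p not in net.node_index]
    if unknown:
        raise ValidationError(f"proteins not in network: {sorted(set(unknown))}")
    sentinel = net.undirected_diameter + 1
    g = net._digraph
    # distance from any source to each effector (directed)
    per_eff = []
    reached = 0
    for e in effs:
        best = None
        for s in source:
            if s == e:
                best = 0
                break
            try:
                d = nx.shortest_path_length(g, s, e)
            except nx.NetworkXNoPath:
                continue
            best = d if best is None else min(best, d)
        if best is None:
            per_eff.append(sentinel)
        else:
            per_eff.append(best)
            reached += 1
    clamps = {s: 1.0 for s in source}
    res = propagate(net, None, clamps, max_iter=100, tol=1e-6)
    overlap = float(np.mean([abs(res[e]) for e in effs]))
    return np.array(
        [
            float(min(per_eff)),
            float(np.mean(per_eff)),
            reached / len(effs),
            overlap,
            float(np.mean([g.out_degree(s) for s in source])),
            float(np.mean([g.in_degree(e) for e in effs])),
            float(len(source)),
            float(len(effs)),
        ]
    )


def _make_classifier(cfg: RelateConfig, seed: int) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "ann",
                MLPClassifier(
                    hidden_layer_sizes=(cfg.hidden_units,),
                    max_iter=cfg.max_epochs,
                    random_state=seed,
                ),
            ),
        ]
    )


def train_cv(table: TruthTable, net: Interactome, folds: int = 5,
             seed: int = 0, cfg: RelateConfig | None = None):
    """Train the relation classifier with stratified k-fold cross-validation.

    Returns ``(model, cv_accuracy)`` where the model is refit on all rows and
    cv_accuracy is the mean held-out accuracy across folds.
    """
    cfg = cfg or RelateConfig()
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    y = table.labels()
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValidationError(
            "truth table needs at least 2 rows of each class "
            f"(got related={counts[1]}, unrelated={counts[0]})"
        )
    X = np.array([featurize(r.source, r.effectors, net) for r in table.rows])
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    model = _make_classifier(cfg, seed)
    scores = cross_val_score(model, X, y, cv=skf, scoring="accuracy")
    model.fit(X, y)
    return model, float(scores.mean())


def score_and_bin(model, source: Iterable[str], motive_effectors: Iterable[str],
                  net: Interactome, motive: str = "",
                  thresholds: Sequence[float] = (0.25, 0.5, 0.75)) -> RelationScore:
    """Classifier probability of relatedness, binned into "+" .. "++++".

    Bins are upper-inclusive: a score exactly on a threshold takes the lower
    grade (0.25 -> "+").
    """
    t1, t2, t3 = thresholds
    if not (0 < t1 < t2 < t3 < 1):
        raise ValidationError("thresholds must be strictly ascending within (0, 1)")
    x = featurize(source, motive_effectors, net).reshape(1, -1)
    score = float(model.predict_proba(x)[0, 1])
    if score <= t1:
        grade = "+"
    elif score <= t2:
        grade = "++"
    elif score <= t3:
        grade = "+++"
    else:
        grade = "++++"
    return RelationScore(frozenset(source), motive, score, grade)


def relation_grid(model, profiles: Sequence[DrugTargetProfile],
                  disease: DiseaseCharacterization, net: Interactome,
                  thresholds: Sequence[float] = (0.25, 0.5, 0.75)):
    """Per-target x per-motive grade table (plus an overall disease row).

    Rows are the disease overall and each motive; columns one per target of
    each profile.  Returns (grades DataFrame, scores DataFrame).
    """
    import pandas as pd

    rows = [("overall", [e.protein for e in disease.all_effectors])]
    rows += [
        (m, [e.protein for e in effs]) for m, effs in disease.motives.items()
    ]
    cols = []
    for prof in profiles:
        for t in prof.targets:
            cols.append((prof.drug_name, t))
    grades = pd.DataFrame(index=[r[0] for r in rows],
                          columns=pd.MultiIndex.from_tuples(cols, names=["drug", "target"]),
                          dtype=object)
    scores = grades.copy()
    for rname, effs in rows:
        effs_in_net = [p for p in effs if p in net.node_index]
        for drug, t in cols:
            rs = score_and_bin(model, {t}, effs_in_net, net, rname, thresholds)
            grades.loc[rname, (drug, t)] = rs.bin
            scores.loc[rname, (drug, t)] = rs.score
    return grades, scores
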