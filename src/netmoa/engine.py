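"""Clamp-and-propagate mechanistic model and its ensemble fit.

A drug is modelled as a sustained clamp on its target proteins (+1 for
activation, -1 for inactivation).  Signal spreads over the signed interactome
by the synchronous update

    v_i  <-  tanh( sum_{j -> i}  weight_ji * sign_ji * v_j ),

with clamped nodes held fixed at their clamp value on every iteration.  tanh
keeps all node activities in [-1, 1] and is odd, so flipping every clamp
flips every signal.  Iteration stops when the largest per-node change drops
below ``tol``; oscillating feedback loops are detected as limit cycles (up to
period 64) and reported as the cycle average with ``converged=False``.

Because edge weights are under-determined, the model is used as an ensemble:
M independent stochastic fits of the weight vector against sign restraints
(simulated annealing), each yielding one "model solution".  Distributions
across solutions are what the downstream statistics operate on.

The drug's effect on a disease is summarized by the TSignal: the mean of the
pathology-sign-flipped effector signals, so +1 means full reversal of every
effector's pathological direction and -1 means full reinforcement.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import EngineConfig, OptimizerConfig
from .core import (
    DiseaseCharacterization,
    DrugTargetProfile,
    Effector,
    Interactome,
    NetmoaError,
    Restraint,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationResult",
    "ModelSolution",
    "ModelEnsemble",
    "MoASubnetwork",
    "propagate",
    "fit_ensemble",
    "tsignal",
    "tsignal_per_solution",
    "moa_subnetwork",
    "save_ensemble",
    "load_ensemble",
]

_MAX_CYCLE = 64


# ---------------------------------------------------------------------------
# Propagation
# ---------------------------------------------------------------------------

class PropagationResult(Mapping):
    """Node-signal map produced by :func:`propagate` (read-only)."""

    def __init__(self, nodes: tuple[str, ...], values: np.ndarray, converged: bool):
        self._nodes = nodes
        self._index = {n: i for i, n in enumerate(nodes)}
        self.values = values
        self.converged = converged

    def __getitem__(self, node: str) -> float:
        return float(self.values[self._index[node]])

    def __iter__(self):
        return iter(self._nodes)

    def __len__(self) -> int:
        return len(self._nodes)

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(self._nodes, self.values)}


def _clamp_arrays(net: Interactome, clamps: Mapping[str, float]):
    idx = net.node_index
    missing = sorted(set(clamps) - set(idx))
    if missing:
        raise ValidationError(f"clamp proteins not in network: {missing}")
    ci = np.array([idx[p] for p in clamps], dtype=np.int64)
    cv = np.array([float(v) for v in clamps.values()], dtype=float)
    if ci.size and (np.abs(cv) > 1).any():
        raise ValidationError("clamp values must lie in [-1, 1]")
    return ci, cv


def _iterate(A, clamp_idx, clamp_vals, max_iter: int, tol: float,
             v0: np.ndarray | None = None, detect_cycles: bool = True):
    """Run the synchronous tanh update; returns (signals, converged).

    With ``detect_cycles`` the trailing window of states is scanned for a
    repeat up to period 64; a period-k repeat (k > 1) is resolved to the
    cycle average and flagged non-converged.
    """
    n = A.shape[0]
    if v0 is None:
        v = np.zeros(n)
    else:
        v = v0.copy()
    if clamp_idx.size:
        v[clamp_idx] = clamp_vals
    if clamp_idx.size == 0:
        return np.zeros_like(v), True
    history: list[np.ndarray] = [v.copy()] if detect_cycles else []
    for _ in range(max_iter):
        v_new = np.tanh(A @ v)
        if clamp_idx.size:
            v_new[clamp_idx] = clamp_vals
        if np.max(np.abs(v_new - v)) < tol:
            return v_new, True
        if detect_cycles:
            for k in range(2, min(_MAX_CYCLE, len(history)) + 1):
                if np.max(np.abs(v_new - history[-k + 1])) < tol:
                    cycle = history[-k + 1:] + [v_new]
                    return np.mean(cycle, axis=0), False
            history.append(v_new.copy())
            if len(history) > _MAX_CYCLE + 1:
                history.pop(0)
        v = v_new
    tail = history[-_MAX_CYCLE:] if detect_cycles and history else [v]
    return np.mean(tail, axis=0), False


def propagate(net: Interactome, weights: np.ndarray | Mapping | None,
              clamps: Mapping[str, float], max_iter: int = 200,
              tol: float = 1e-6) -> PropagationResult:
    """Propagate clamp values over the signed network to a fixed point.

    ``weights`` may be an array aligned with ``net.edges``, a mapping from
    (source, target, sign) to weight, or None to use the stored edge weights.
    An empty clamp map yields the all-zero signal.
    """
    if max_iter < 1:
        raise ValidationError("max_iter must be >= 1")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    if weights is not None and not isinstance(weights, np.ndarray):
        weights = np.array(
            [weights[(e.source, e.target, e.sign)] for e in net.edges], dtype=float
        )
    A = net.signed_adjacency(weights)
    ci, cv = _clamp_arrays(net, clamps)
    values, converged = _iterate(A, ci, cv, max_iter, tol)
    return PropagationResult(net.nodes, values, converged)


def _propagate_columns(A, clamp_cols: Sequence[tuple[np.ndarray, np.ndarray]],
                       max_iter: int, tol: float,
                       V0: np.ndarray | None = None) -> np.ndarray:
    """Propagate several clamp scenarios at once (one per column).

    Used inside the annealing loop where per-restraint fixed points are
    recomputed thousands of times; no cycle averaging, the last iterate is
    close enough for a loss evaluation.
    """
    n = A.shape[0]
    r = len(clamp_cols)
    V = np.zeros((n, r)) if V0 is None else V0.copy()
    rows = np.concatenate([ci for ci, _ in clamp_cols]).astype(np.int64)
    cols = np.concatenate(
        [np.full(len(ci), c, dtype=np.int64) for c, (ci, _) in enumerate(clamp_cols)]
    )
    vals = np.concatenate([cv for _, cv in clamp_cols])
    V[rows, cols] = vals
    for _ in range(max_iter):
        V_new = np.tanh(A @ V)
        V_new[rows, cols] = vals
        if np.max(np.abs(V_new - V)) < tol:
            return V_new
        V = V_new
    return V


# ---------------------------------------------------------------------------
# TSignal
# ---------------------------------------------------------------------------

def tsignal(signals: Mapping[str, float], effectors: Sequence[Effector]) -> float:
    """Mean pathology-reversal of the signed effectors, in [-1, 1].

    Each effector contributes ``-pathological_state * signal``: positive when
    the model drives the effector against its pathological direction.
    Complex-role (state 9) effectors carry no sign to reverse and are
    excluded.
    """
    signed = [e for e in effectors if e.pathological_state in (1, -1)]
    if not signed:
        raise ValidationError("no signed effectors (all complex-role)")
    total = 0.0
    for e in signed:
        sig = signals[e.protein] if e.protein in signals else 0.0
        total += -e.pathological_state * sig
    return total / len(signed)


# ---------------------------------------------------------------------------
# Solutions and ensembles
# ---------------------------------------------------------------------------

@dataclass
class ModelSolution:
    """One fitted parameterization: edge weights and the drug-clamped signals."""

    weights: np.ndarray          # aligned with net.edges, in [0, 1]
    signals: np.ndarray          # aligned with net.nodes, in [-1, 1]
    converged: bool
    seed: int
    restraint_accuracy: float = 1.0

    def signal_map(self, net: Interactome) -> dict[str, float]:
        return {n: float(v) for n, v in zip(net.nodes, self.signals)}


@dataclass
class ModelEnsemble:
    """M model solutions for one drug on one interactome."""

    net: Interactome
    solutions: list[ModelSolution]
    restraint_accuracy: float
    drug: DrugTargetProfile | None = None

    def __post_init__(self) -> None:
        if not self.solutions:
            raise ValidationError("ensemble must contain at least one solution")

    @property
    def M(self) -> int:
        return len(self.solutions)

    def signal_matrix(self) -> np.ndarray:
        """(n_nodes, M) array of per-solution node signals."""
        return np.column_stack([s.signals for s in self.solutions])

    def mean_signals(self) -> np.ndarray:
        return self.signal_matrix().mean(axis=1)

    def effector_signals(self, proteins: Sequence[str]) -> np.ndarray:
        """(len(proteins), M) signals; proteins absent from the net read as 0."""
        idx = self.net.node_index
        mat = self.signal_matrix()
        out = np.zeros((len(proteins), self.M))
        for r, p in enumerate(proteins):
            if p in idx:
                out[r] = mat[idx[p]]
        return out


@dataclass
class MoASubnetwork:
    """Proteins carrying non-null consensus signal, with their induced edges."""

    nodes: dict[str, float]      # node -> mean signal
    edges: tuple
    epsilon: float


# ---------------------------------------------------------------------------
# Ensemble fitting
# ---------------------------------------------------------------------------

def _restraint_satisfaction(V: np.ndarray, restraints: Sequence[Restraint],
                            node_index: dict[str, int], margin: float):
    """(violated_sign_count, total_signs, fully_satisfied_restraints)."""
    violated = 0
    total = 0
    full = 0
    for c, r in enumerate(restraints):
        ok = True
        for protein, expected in r.expected.items():
            total += 1
            if expected * V[node_index[protein], c] <= margin:
                violated += 1
                ok = False
        full += ok
    return violated, total, full


def _check_restraints(net: Interactome, restraints: Sequence[Restraint]) -> None:
    known = set(net.nodes)
    for i, r in enumerate(restraints):
        bad = sorted((set(r.stimulus) | set(r.expected)) - known)
        if bad:
            raise ValidationError(
                f"restraint {i} references unknown proteins: {bad}"
            )


def fit_ensemble(net: Interactome, restraints: Sequence[Restraint], M: int,
                 optimizer_cfg: OptimizerConfig | None = None, seed: int = 0,
                 drug: DrugTargetProfile | None = None,
                 engine_cfg: EngineConfig | None = None) -> ModelEnsemble:
    """Fit M independent weight solutions against sign restraints.

    Each solution runs simulated annealing over the edge-weight vector with
    geometric cooling; the loss is the fraction of expected effector signs
    violated (margin ``optimizer_cfg.margin``).  With no restraints the
    weights are sampled uniformly and the accuracy is 1.0 by convention.
    Reproducible: solution m uses a child seed derived from ``seed``.

    When ``drug`` is given, each solution's stored signals are the fixed
    point under that drug's target clamps; otherwise signals are zero.
    """
    if M < 1:
        raise ValidationError("M must be >= 1")
    cfg = optimizer_cfg or OptimizerConfig()
    eng = engine_cfg or EngineConfig()
    _check_restraints(net, restraints)
    if drug is not None:
        missing = sorted(set(drug.targets) - set(net.nodes))
        if missing:
            raise ValidationError(
                f"drug {drug.drug_name!r} targets not in network: {missing}"
            )

    node_index = net.node_index
    n_edges = net.n_edges
    clamp_cols = [
        _clamp_arrays(net, {p: float(v) for p, v in r.stimulus.items()})
        for r in restraints
    ]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(M)

    solutions: list[ModelSolution] = []
    for m in range(M):
        rng = np.random.default_rng(children[m])
        sol_seed = int(children[m].generate_state(1)[0] % (2**31))
        w = rng.uniform(0.0, 1.0, size=n_edges)
        if restraints:
            w = _anneal(net, w, restraints, clamp_cols, node_index, cfg, eng, rng)
        if drug is not None:
            res = propagate(net, w, drug.clamps(), eng.max_iter, eng.tol)
            signals, converged = res.values, res.converged
        else:
            signals, converged = np.zeros(net.n_nodes), True
        if restraints:
            A = net.signed_adjacency(w)
            V = _propagate_columns(A, clamp_cols, eng.max_iter, eng.tol)
            _, _, full = _restraint_satisfaction(V, restraints, node_index, 0.0)
            acc = full / len(restraints)
        else:
            acc = 1.0
        solutions.append(ModelSolution(w, signals, converged, sol_seed, acc))

    if restraints:
        # consensus: mean per-restraint signals over solutions
        V_sum = np.zeros((net.n_nodes, len(restraints)))
        for s in solutions:
            A = net.signed_adjacency(s.weights)
            V_sum += _propagate_columns(A, clamp_cols, eng.max_iter, eng.tol)
        V_mean = V_sum / M
        _, _, full = _restraint_satisfaction(V_mean, restraints, node_index, 0.0)
        consensus = full / len(restraints)
    else:
        consensus = 1.0
    return ModelEnsemble(net, solutions, consensus, drug)


def _anneal(net, w0, restraints, clamp_cols, node_index, cfg: OptimizerConfig,
            eng: EngineConfig, rng) -> np.ndarray:
    """Simulated annealing over edge weights; returns the best weights seen."""
    A = net.signed_adjacency(w0)
    V = _propagate_columns(A, clamp_cols, eng.max_iter, eng.tol)

    def loss_of(V):
        violated, total, _ = _restraint_satisfaction(
            V, restraints, node_index, cfg.margin
        )
        return violated / total if total else 0.0

    w = w0.copy()
    loss = loss_of(V)
    best_w, best_loss = w.copy(), loss
    T = cfg.t0
    n_edges = w.size
    k = min(cfg.moves_per_step, n_edges)
    for _ in range(cfg.steps):
        if best_loss == 0.0:
            break
        picks = rng.choice(n_edges, size=k, replace=False)
        old_vals = w[picks].copy()
        w[picks] = np.clip(w[picks] + rng.normal(0.0, cfg.step_size, size=k), 0.0, 1.0)
        A = net.signed_adjacency(w)
        # warm start from the incumbent state: a few-edge move barely shifts
        # the fixed point, so re-convergence is fast
        V_new = _propagate_columns(A, clamp_cols, eng.fit_max_iter, eng.tol, V0=V)
        new_loss = loss_of(V_new)
        accept = new_loss <= loss or rng.random() < np.exp(
            -(new_loss - loss) / max(T, 1e-12)
        )
        if accept:
            loss, V = new_loss, V_new
            if new_loss < best_loss:
                best_loss, best_w = new_loss, w.copy()
        else:
            w[picks] = old_vals
        T *= cfg.cooling
    return best_w


def tsignal_per_solution(ens: ModelEnsemble,
                         effectors: Sequence[Effector]) -> np.ndarray:
    """TSignal of every solution in the ensemble, as an (M,) array."""
    signed = [e for e in effectors if e.pathological_state in (1, -1)]
    if not signed:
        raise ValidationError("no signed effectors (all complex-role)")
    sigs = ens.effector_signals([e.protein for e in signed])   # (E, M)
    states = np.array([e.pathological_state for e in signed], dtype=float)
    return (-states[:, None] * sigs).mean(axis=0)


def moa_subnetwork(ens: ModelEnsemble, epsilon: float = 1e-6) -> MoASubnetwork:
    """Proteins with |mean signal| above ``epsilon``, plus induced edges."""
    if epsilon < 0:
        raise ValidationError("epsilon must be non-negative")
    mean = ens.mean_signals()
    keep = {
        n: float(v) for n, v in zip(ens.net.nodes, mean) if abs(v) > epsilon
    }
    edges = tuple(
        e for e in ens.net.edges if e.source in keep and e.target in keep
    )
    return MoASubnetwork(nodes=keep, edges=edges, epsilon=epsilon)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_ensemble(ens: ModelEnsemble, json_path: str | Path,
                  signals_path: str | Path, include_weights: bool = True) -> None:
    """Write the ensemble as JSON (metadata + weights) and a node x solution TSV."""
    meta = {
        "drug": ens.drug.drug_name if ens.drug else None,
        "targets": dict(ens.drug.targets) if ens.drug else None,
        "restraint_accuracy": ens.restraint_accuracy,
        "M": ens.M,
        "solutions": [
            {
                "seed": s.seed,
                "converged": bool(s.converged),
                "restraint_accuracy": s.restraint_accuracy,
                **({"weights": s.weights.tolist()} if include_weights else {}),
            }
            for s in ens.solutions
        ],
    }
    Path(json_path).write_text(json.dumps(meta) + "\n")
    df = pd.DataFrame(
        ens.signal_matrix(),
        index=list(ens.net.nodes),
        columns=[f"solution_{i:03d}" for i in range(ens.M)],
    )
    df.index.name = "protein"
    df.to_csv(signals_path, sep="\t", float_format="%.12g")


def load_ensemble(net: Interactome, json_path: str | Path,
                  signals_path: str | Path) -> ModelEnsemble:
    meta = json.loads(Path(json_path).read_text())
    df = pd.read_csv(signals_path, sep="\t", index_col="protein")
    df = df.reindex(list(net.nodes))
    if df.isna().any().any():
        raise ValidationError("signal matrix does not cover the network's nodes")
    sols = []
    for i, srec in enumerate(meta["solutions"]):
        w = np.array(srec.get("weights", [e.weight for e in net.edges]), dtype=float)
        sols.append(
            ModelSolution(
                weights=w,
                signals=df.iloc[:, i].to_numpy(),
                converged=srec["converged"],
                seed=srec["seed"],
                restraint_accuracy=srec.get("restraint_accuracy", 1.0),
            )
        )
    drug = None
    if meta.get("drug"):
        drug = DrugTargetProfile(meta["drug"], {k: int(v) for k, v in meta["targets"].items()})
    return ModelEnsemble(net, sols, meta["restraint_accuracy"], drug)
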