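"""Systematic in silico resistance and co-treatment interference scans.

A candidate resistance mutation is modelled as one of three modifications of
a protein — sustained activation (clamp +1), sustained inhibition (clamp -1)
or deletion (node removed with its edges).  For every modification the
drug-clamped model is re-propagated in each solution of the fitted ensemble,
the global TSignal is recomputed, and a paired t-test across solutions
compares perturbed against baseline.  A modification is selected as a
potential resistance when p <= alpha (default 0.022) and the TSignal drops
(delta < 0, efficacy loss).

Co-treatment interference works the same way, but the perturbation is the
co-drug's own target clamps added on top of the primary drug's; candidates
are tiered strong (p < 0.05) or weak (p < 0.1).

Simultaneous clamps on one protein (a drug inhibiting what a modification
activates, say) sum and clip to [-1, 1], so +1 against -1 cancels to 0 —
competing pharmacology without an arbitrary precedence rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DiseaseCharacterization,
    DrugTargetProfile,
    Interactome,
    ValidationError,
)
from .engine import ModelEnsemble, _clamp_arrays, _iterate, tsignal_per_solution

logger = logging.getLogger(__name__)

__all__ = [
    "MODIFICATION_KINDS",
    "Modification",
    "ScanResult",
    "enumerate_modifications",
    "combine_clamps",
    "apply_modification",
    "resistance_scan",
    "interference_scan",
    "scan_table",
]

MODIFICATION_KINDS = ("activation", "inhibition", "deletion")


class Modification(NamedTuple):
    protein: str
    kind: str


@dataclass
class ScanResult:
    name: str                    # "protein:kind" or co-drug name
    protein: str | None
    kind: str | None
    baseline_tsignal: float
    perturbed_tsignal: float
    delta: float
    p_value: float
    selected: bool
    tier: str | None = None      # interference only: "strong" | "weak"


def enumerate_modifications(universe: Iterable[str]) -> list[Modification]:
    """All 3 modifications for every protein, in deterministic order."""
    return [
        Modification(p, kind)
        for p in sorted(set(universe))
        for kind in MODIFICATION_KINDS
    ]


def combine_clamps(*clamp_maps: Mapping[str, float]) -> dict[str, float]:
    """Merge concurrent clamps: values on the same protein sum, clipped to [-1, 1]."""
    out: dict[str, float] = {}
    for cm in clamp_maps:
        for p, v in cm.items():
            out[p] = out.get(p, 0.0) + float(v)
    return {p: float(np.clip(v, -1.0, 1.0)) for p, v in out.items()}


def apply_modification(net: Interactome, clamps: Mapping[str, float],
                       mod: Modification):
    """Return (net', clamps') with the modification applied; inputs untouched."""
    if mod.kind not in MODIFICATION_KINDS:
        raise ValidationError(f"unknown modification kind {mod.kind!r}")
    if mod.protein not in net.node_index:
        raise ValidationError(f"modification protein not in network: {mod.protein}")
    if mod.protein in clamps:
        logger.info(
            "modification %s targets a drug-clamped protein %s (target-level "
            "resistance)", mod.kind, mod.protein
        )
    if mod.kind == "deletion":
        net2, kept = net.without_node(mod.protein)
        clamps2 = {p: v for p, v in clamps.items() if p != mod.protein}
        return net2, clamps2, kept
    value = 1.0 if mod.kind == "activation" else -1.0
    clamps2 = combine_clamps(clamps, {mod.protein: value})
    return net, clamps2, None


def _paired_p(base: np.ndarray, pert: np.ndarray) -> float:
    """Paired two-sided t-test across solutions; all-zero differences give p = 1."""
    diff = pert - base
    if np.ptp(diff) == 0:
        return 1.0 if diff[0] == 0 else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_rel(pert, base)
    return 1.0 if np.isnan(p) else float(p)


def _per_solution_tsignals(net: Interactome, ens: ModelEnsemble,
                           clamps: Mapping[str, float],
                           effectors, kept: np.ndarray | None,
                           max_iter: int = 200, tol: float = 1e-6) -> np.ndarray:
    """Global TSignal of each solution under modified net/clamps.

    ``kept`` maps the (possibly reduced) edge set back into the original
    solutions' weight vectors.  Effectors no longer in the network contribute
    signal 0.
    """
    signed = [e for e in effectors if e.pathological_state in (1, -1)]
    idx = net.node_index
    rows = np.array([idx.get(e.protein, -1) for e in signed])
    states = np.array([e.pathological_state for e in signed], dtype=float)
    ci, cv = _clamp_arrays(net, dict(clamps))
    out = np.empty(ens.M)
    for m, sol in enumerate(ens.solutions):
        w = sol.weights if kept is None else sol.weights[kept]
        A = net.signed_adjacency(w)
        values, _ = _iterate(A, ci, cv, max_iter, tol)
        sigs = np.where(rows >= 0, values[np.clip(rows, 0, None)], 0.0)
        out[m] = float((-states * sigs).mean())
    return out


def _baseline(ens: ModelEnsemble, disease: DiseaseCharacterization) -> np.ndarray:
    return tsignal_per_solution(ens, disease.all_effectors)


def resistance_scan(ens: ModelEnsemble, universe: Iterable[str],
                    disease: DiseaseCharacterization,
                    alpha: float = 0.022) -> list[ScanResult]:
    """Scan activation/inhibition/deletion of every universe protein.

    ``universe`` is normally a :func:`netmoa.core.neighborhood` around the
    disease effectors and the drug targets.  Selection requires p <= alpha
    AND delta < 0 (the modification weakens the reversal).
    """
    universe = sorted(set(universe))
    if not universe:
        raise ValidationError("resistance-scan universe is empty")
    if ens.drug is None:
        raise ValidationError("ensemble has no drug attached")
    missing = sorted(set(universe) - set(ens.net.nodes))
    if missing:
        raise ValidationError(f"universe proteins not in network: {missing}")
    base = _baseline(ens, disease)
    drug_clamps = ens.drug.clamps()
    effectors = disease.all_effectors
    results = []
    for mod in enumerate_modifications(universe):
        net2, clamps2, kept = apply_modification(ens.net, drug_clamps, mod)
        pert = _per_solution_tsignals(net2, ens, clamps2, effectors, kept)
        p = _paired_p(base, pert)
        delta = float(pert.mean() - base.mean())
        results.append(
            ScanResult(
                name=f"{mod.protein}:{mod.kind}",
                protein=mod.protein,
                kind=mod.kind,
                baseline_tsignal=float(base.mean()),
                perturbed_tsignal=float(pert.mean()),
                delta=delta,
                p_value=p,
                selected=bool(p <= alpha and delta < 0),
            )
        )
    return results


def interference_scan(ens: ModelEnsemble,
                      cotreatments: Sequence[DrugTargetProfile],
                      disease: DiseaseCharacterization,
                      alphas: tuple[float, float] = (0.05, 0.1)) -> list[ScanResult]:
    """Add each co-drug's target clamps to the model and retest the TSignal.

    Tier "strong" when p < alphas[0], "weak" when p < alphas[1].  Co-drug
    targets absent from the network are skipped with a warning.
    """
    strong_a, weak_a = alphas
    if not (0 < strong_a <= weak_a < 1):
        raise ValidationError("alphas must satisfy 0 < strong <= weak < 1")
    if ens.drug is None:
        raise ValidationError("ensemble has no drug attached")
    base = _baseline(ens, disease)
    drug_clamps = ens.drug.clamps()
    effectors = disease.all_effectors
    results = []
    for prof in cotreatments:
        resolvable = {
            p: float(a) for p, a in prof.targets.items()
            if p in ens.net.node_index
        }
        skipped = set(prof.targets) - set(resolvable)
        if skipped:
            warnings.warn(
                f"co-treatment {prof.drug_name}: targets not in network "
                f"skipped: {sorted(skipped)}"
            )
        if not resolvable:
            results.append(
                ScanResult(
                    name=prof.drug_name, protein=None, kind=None,
                    baseline_tsignal=float(base.mean()),
                    perturbed_tsignal=float(base.mean()),
                    delta=0.0, p_value=1.0, selected=False, tier=None,
                )
            )
            continue
        clamps2 = combine_clamps(drug_clamps, resolvable)
        pert = _per_solution_tsignals(ens.net, ens, clamps2, effectors, None)
        p = _paired_p(base, pert)
        tier = "strong" if p < strong_a else ("weak" if p < weak_a else None)
        results.append(
            ScanResult(
                name=prof.drug_name, protein=None, kind=None,
                baseline_tsignal=float(base.mean()),
                perturbed_tsignal=float(pert.mean()),
                delta=float(pert.mean() - base.mean()),
                p_value=p,
                selected=tier is not None,
                tier=tier,
            )
        )
    return results


def scan_table(results: Sequence[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name for r in results],
            "protein": [r.protein for r in results],
            "kind": [r.kind for r in results],
            "baseline_tsignal": [r.baseline_tsignal for r in results],
            "perturbed_tsignal": [r.perturbed_tsignal for r in results],
            "delta": [r.delta for r in results],
            "p_value": [r.p_value for r in results],
            "selected": [r.selected for r in results],
            "tier": [r.tier for r in results],
        }
    )
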