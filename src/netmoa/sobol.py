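"""Variance-based global sensitivity analysis of the fitted model's TSignal.

Implements the Saltelli sampling scheme on a scrambled Sobol low-discrepancy
sequence and the Jansen estimators for first-order (S1) and total-order (ST)
indices, with bootstrap confidence half-widths.  For k factors and a base
sample of N points the model is evaluated N*(k + 2) times.

The declared factor space for a drug ensemble is the clamp magnitude of each
target (how completely the drug engages that target, in [0.5, 1]) and one
multiplicative scale on all edge weights (global confidence in the network,
in [0.5, 1.5]).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .config import SobolConfig
from .core import DiseaseCharacterization, ValidationError
from .engine import ModelEnsemble, _clamp_arrays, _iterate, tsignal

__all__ = [
    "SobolFactors",
    "SobolResult",
    "sobol_analysis",
    "ensemble_factors",
    "ensemble_evaluator",
    "sobol_table",
]


@dataclass(frozen=True)
class SobolFactors:
    names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.names:
            raise ValidationError("at least one factor is required")
        if len(self.names) != len(self.bounds):
            raise ValidationError("names and bounds must align")
        if len(set(self.names)) != len(self.names):
            raise ValidationError("factor names must be unique")
        for name, (lo, hi) in zip(self.names, self.bounds):
            if not lo < hi:
                raise ValidationError(f"factor {name}: lo must be < hi")

    @property
    def k(self) -> int:
        return len(self.names)


@dataclass
class SobolResult:
    factors: SobolFactors
    S1: np.ndarray
    ST: np.ndarray
    S1_ci: np.ndarray        # bootstrap 95% half-widths
    ST_ci: np.ndarray
    n_base: int
    seed: int


def _jansen(YA: np.ndarray, YB: np.ndarray, YAB: np.ndarray):
    """Jansen estimators on (N,), (N,), (N, k) evaluations."""
    var = np.var(np.concatenate([YA, YB]))
    if var == 0:
        k = YAB.shape[1]
        return np.zeros(k), np.zeros(k)
    S1 = 1.0 - np.mean((YB[:, None] - YAB) ** 2, axis=0) / (2.0 * var)
    ST = np.mean((YA[:, None] - YAB) ** 2, axis=0) / (2.0 * var)
    return S1, ST


def sobol_analysis(evaluator: Callable[[np.ndarray], float],
                   factors: SobolFactors, n_base: int = 256,
                   seed: int = 0, bootstrap: int = 100) -> SobolResult:
    """Saltelli-sampled Sobol indices of ``evaluator`` over the factor space.

    ``evaluator`` maps one factor vector (length k, already scaled to the
    factor bounds) to a scalar output.  A power-of-two ``n_base`` keeps the
    Sobol sequence balanced.  A non-finite evaluator output is an error
    naming the offending sample.
    """
    if n_base < 64:
        raise ValidationError("n_base must be >= 64")
    k = factors.k
    sampler = qmc.Sobol(d=2 * k, scramble=True, rng=np.random.default_rng(seed))
    m = math.log2(n_base)
    if m.is_integer():
        base = sampler.random_base2(int(m))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            base = sampler.random(n_base)
    lows = np.array([b[0] for b in factors.bounds])
    highs = np.array([b[1] for b in factors.bounds])
    A = lows + base[:, :k] * (highs - lows)
    B = lows + base[:, k:] * (highs - lows)

    def run(X: np.ndarray, tag: str) -> np.ndarray:
        out = np.empty(len(X))
        for i, x in enumerate(X):
            y = float(evaluator(x))
            if not np.isfinite(y):
                raise ValidationError(
                    f"evaluator returned non-finite value at sample {tag}[{i}] "
                    f"(factors {dict(zip(factors.names, x))})"
                )
            out[i] = y
        return out

    YA = run(A, "A")
    YB = run(B, "B")
    YAB = np.empty((n_base, k))
    for j in range(k):
        ABj = A.copy()
        ABj[:, j] = B[:, j]
        YAB[:, j] = run(ABj, f"AB{j}")

    S1, ST = _jansen(YA, YB, YAB)
    rng = np.random.default_rng(seed + 1)
    s1_bs = np.empty((bootstrap, k))
    st_bs = np.empty((bootstrap, k))
    for b in range(bootstrap):
        idx = rng.integers(0, n_base, size=n_base)
        s1_bs[b], st_bs[b] = _jansen(YA[idx], YB[idx], YAB[idx])
    return SobolResult(
        factors=factors,
        S1=S1,
        ST=ST,
        S1_ci=1.96 * s1_bs.std(axis=0),
        ST_ci=1.96 * st_bs.std(axis=0),
        n_base=n_base,
        seed=seed,
    )


def ensemble_factors(ens: ModelEnsemble,
                     cfg: SobolConfig | None = None) -> SobolFactors:
    """Default factor space: per-target clamp magnitude + global weight scale."""
    cfg = cfg or SobolConfig()
    if ens.drug is None:
        raise ValidationError("ensemble has no drug attached")
    names = tuple(f"clamp_{t}" for t in ens.drug.targets) + ("weight_scale",)
    bounds = tuple(cfg.clamp_range for _ in ens.drug.targets) + (
        cfg.weight_scale_range,
    )
    return SobolFactors(names, bounds)


def ensemble_evaluator(ens: ModelEnsemble, disease: DiseaseCharacterization,
                       max_iter: int = 200, tol: float = 1e-6):
    """TSignal evaluator over (clamp magnitudes..., weight_scale) factors.

    Uses the ensemble's consensus (mean) weight vector; the weight-scale
    factor multiplies it wholesale.
    """
    if ens.drug is None:
        raise ValidationError("ensemble has no drug attached")
    targets = list(ens.drug.targets.items())
    effectors = [
        e for e in disease.all_effectors if e.pathological_state in (1, -1)
    ]
    if not effectors:
        raise ValidationError("no signed effectors (all complex-role)")
    mean_w = np.mean([s.weights for s in ens.solutions], axis=0)
    net = ens.net
    idx = net.node_index
    rows = np.array([idx[e.protein] for e in effectors if e.protein in idx])
    states = np.array(
        [e.pathological_state for e in effectors if e.protein in idx], dtype=float
    )

    def evaluate(x: np.ndarray) -> float:
        mags, wscale = x[:-1], x[-1]
        clamps = {
            t: float(action) * float(m) for (t, action), m in zip(targets, mags)
        }
        A = net.signed_adjacency(mean_w * wscale)
        ci, cv = _clamp_arrays(net, clamps)
        values, _ = _iterate(A, ci, cv, max_iter, tol)
        return float((-states * values[rows]).mean())

    return evaluate


def sobol_table(result: SobolResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "factor": list(result.factors.names),
            "S1": result.S1,
            "ST": result.ST,
            "S1_ci95_halfwidth": result.S1_ci,
            "ST_ci95_halfwidth": result.ST_ci,
        }
    )
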