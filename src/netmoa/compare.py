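"""Head-to-head statistics between two drug ensembles.

For each pathophysiological motive, the per-solution TSignal distributions of
the two drugs are compared with a Welch two-sample t-test, and p-values are
Benjamini-Hochberg adjusted across motives.  At the level of individual
effectors the same test runs on the per-solution reversal values, and an
effector is called "more reversed" by a drug only under the dual criterion
FDR q < alpha AND relative TSignal change > 20% — the criterion also used to
flag the brain-metastasis panel.  Ties are an explicit third category, which
is why the per-motive percentage pairs need not sum to 100 on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import CompareConfig
from .core import (
    BrainPanel,
    DiseaseCharacterization,
    Effector,
    ValidationError,
)
from .engine import ModelEnsemble, tsignal_per_solution

__all__ = [
    "MotiveComparison",
    "EffectorComparison",
    "BrainPanelReport",
    "bh_adjust",
    "welch_p",
    "compare_motives",
    "compare_effectors",
    "brain_panel_report",
    "heatmap_matrix",
    "motives_table",
    "effectors_table",
]


def bh_adjust(p: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """False-discovery-rate adjustment (Benjamini-Hochberg by default)."""
    return multipletests(np.asarray(p, dtype=float), method=method)[1]


def welch_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test returning (t, p) with degenerate conventions.

    When both samples are constant the t statistic is undefined: equal
    constants give p = 1 (no evidence of a difference), different constants
    give p = 0 (the distributions are disjoint points).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, (1.0 if a[0] == b[0] else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=False)
    if np.isnan(p):
        return 0.0, 1.0
    return float(t), float(p)


@dataclass
class MotiveComparison:
    motive: str
    mean_tsignal_a: float
    mean_tsignal_b: float
    t_statistic: float
    p_value: float
    q_value: float
    winner: str | None          # drug with the higher TSignal, q < alpha only
    pct_more_reversed_a: float
    pct_more_reversed_b: float
    pct_tie: float


@dataclass
class EffectorComparison:
    protein: str
    pathological_state: int
    mean_reversal_a: float
    mean_reversal_b: float
    p_value: float
    q_value: float
    relative_change_pct: float
    more_reversed_by: str       # drug name or "tie"


@dataclass
class BrainPanelReport:
    rows: list[EffectorComparison]
    count_a: int
    count_b: int
    count_tie: int
    drug_a: str
    drug_b: str


def _drug_names(ensA: ModelEnsemble, ensB: ModelEnsemble) -> tuple[str, str]:
    a = ensA.drug.drug_name if ensA.drug else "drugA"
    b = ensB.drug.drug_name if ensB.drug else "drugB"
    return a, b


def compare_effectors(ensA: ModelEnsemble, ensB: ModelEnsemble,
                      effectors: Sequence[Effector],
                      cfg: CompareConfig | None = None) -> list[EffectorComparison]:
    """Per-effector reversal comparison across solutions (signed effectors only)."""
    cfg = cfg or CompareConfig()
    nameA, nameB = _drug_names(ensA, ensB)
    signed = [e for e in effectors if e.pathological_state in (1, -1)]
    if not signed:
        return []
    proteins = [e.protein for e in signed]
    states = np.array([e.pathological_state for e in signed], dtype=float)
    revA = -states[:, None] * ensA.effector_signals(proteins)   # (E, M_A)
    revB = -states[:, None] * ensB.effector_signals(proteins)
    raw = np.array([welch_p(revA[i], revB[i])[1] for i in range(len(signed))])
    qs = bh_adjust(raw, cfg.fdr_method)
    out = []
    for i, e in enumerate(signed):
        rA, rB = float(revA[i].mean()), float(revB[i].mean())
        denom = max(abs(rA), abs(rB))
        rel = 0.0 if denom == 0 else abs(rA - rB) / denom * 100.0
        label = "tie"
        if qs[i] < cfg.alpha and rel > cfg.relative_change_threshold and rA != rB:
            label = nameA if rA > rB else nameB
        out.append(
            EffectorComparison(
                protein=e.protein,
                pathological_state=e.pathological_state,
                mean_reversal_a=rA,
                mean_reversal_b=rB,
                p_value=float(raw[i]),
                q_value=float(qs[i]),
                relative_change_pct=rel,
                more_reversed_by=label,
            )
        )
    return out


def compare_motives(ensA: ModelEnsemble, ensB: ModelEnsemble,
                    disease: DiseaseCharacterization,
                    alpha: float | None = None,
                    cfg: CompareConfig | None = None) -> list[MotiveComparison]:
    """Per-motive TSignal comparison (Welch across solutions, BH across motives)."""
    cfg = cfg or CompareConfig()
    if alpha is not None:
        cfg = CompareConfig(
            alpha=alpha,
            relative_change_threshold=cfg.relative_change_threshold,
            fdr_method=cfg.fdr_method,
        )
    if not (0 < cfg.alpha < 1):
        raise ValidationError("alpha must lie in (0, 1)")
    nameA, nameB = _drug_names(ensA, ensB)
    motives, tA, tB, raw = [], [], [], []
    for motive in disease.motives:
        signed = disease.signed_effectors(motive)
        if not signed:
            warnings.warn(f"motive {motive!r} has no signed effectors; skipped")
            continue
        a = tsignal_per_solution(ensA, signed)
        b = tsignal_per_solution(ensB, signed)
        _, p = welch_p(a, b)
        motives.append(motive)
        tA.append(a)
        tB.append(b)
        raw.append(p)
    if not motives:
        return []
    qs = bh_adjust(np.array(raw), cfg.fdr_method)
    out = []
    for i, motive in enumerate(motives):
        effcomp = compare_effectors(
            ensA, ensB, disease.signed_effectors(motive), cfg
        )
        n = len(effcomp)
        nA = sum(c.more_reversed_by == nameA for c in effcomp)
        nB = sum(c.more_reversed_by == nameB for c in effcomp)
        pctA = Fraction(100 * nA, n)
        pctB = Fraction(100 * nB, n)
        pct_tie = Fraction(100) - pctA - pctB
        meanA, meanB = float(tA[i].mean()), float(tB[i].mean())
        winner = None
        if qs[i] < cfg.alpha and meanA != meanB:
            winner = nameA if meanA > meanB else nameB
        tstat, _ = welch_p(tA[i], tB[i])
        out.append(
            MotiveComparison(
                motive=motive,
                mean_tsignal_a=meanA,
                mean_tsignal_b=meanB,
                t_statistic=tstat,
                p_value=float(raw[i]),
                q_value=float(qs[i]),
                winner=winner,
                pct_more_reversed_a=float(pctA),
                pct_more_reversed_b=float(pctB),
                pct_tie=float(pct_tie),
            )
        )
    return out


def brain_panel_report(comparisons: Sequence[EffectorComparison],
                       panel: BrainPanel,
                       drug_a: str = "drugA", drug_b: str = "drugB") -> BrainPanelReport:
    """Restrict an effector comparison to the brain-metastasis panel."""
    by_protein = {c.protein: c for c in comparisons}
    missing = [p for p in panel.proteins if p not in by_protein]
    if missing:
        raise ValidationError(f"panel proteins absent from comparison: {missing}")
    rows = [by_protein[p] for p in panel.proteins]
    nA = sum(r.more_reversed_by == drug_a for r in rows)
    nB = sum(r.more_reversed_by == drug_b for r in rows)
    return BrainPanelReport(
        rows=rows,
        count_a=nA,
        count_b=nB,
        count_tie=len(rows) - nA - nB,
        drug_a=drug_a,
        drug_b=drug_b,
    )


def heatmap_matrix(ensA: ModelEnsemble, ensB: ModelEnsemble,
                   effectors: Sequence[Effector]) -> pd.DataFrame:
    """Effector x solution signal matrix with a pathological-state sidebar.

    Rows are effectors (complex-role ones retained), columns are every
    solution of both drugs; the first column carries the state code
    {1, -1, 9} so the matrix can be rendered as an annotated heatmap.
    """
    nameA, nameB = _drug_names(ensA, ensB)
    proteins = [e.protein for e in effectors]
    sigA = ensA.effector_signals(proteins)
    sigB = ensB.effector_signals(proteins)
    cols = (
        [f"{nameA}_s{i:03d}" for i in range(ensA.M)]
        + [f"{nameB}_s{i:03d}" for i in range(ensB.M)]
    )
    df = pd.DataFrame(np.hstack([sigA, sigB]), index=proteins, columns=cols)
    df.insert(0, "pathological_state",
              [e.pathological_state for e in effectors])
    df.index.name = "protein"
    return df


def motives_table(comparisons: Sequence[MotiveComparison],
                  drug_a: str, drug_b: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "motive": [c.motive for c in comparisons],
            f"pct_more_reversed_{drug_a}": [c.pct_more_reversed_a for c in comparisons],
            f"pct_more_reversed_{drug_b}": [c.pct_more_reversed_b for c in comparisons],
            "pct_tie": [c.pct_tie for c in comparisons],
            f"mean_tsignal_{drug_a}": [c.mean_tsignal_a for c in comparisons],
            f"mean_tsignal_{drug_b}": [c.mean_tsignal_b for c in comparisons],
            "drug_with_highest_tsignal": [c.winner or "n.s." for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "fdr_q": [c.q_value for c in comparisons],
        }
    )


def effectors_table(comparisons: Sequence[EffectorComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [c.protein for c in comparisons],
            "pathological_state": [c.pathological_state for c in comparisons],
            "mean_reversal_a": [c.mean_reversal_a for c in comparisons],
            "mean_reversal_b": [c.mean_reversal_b for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "fdr_q": [c.q_value for c in comparisons],
            "relative_change_pct": [c.relative_change_pct for c in comparisons],
            "more_reversed_by": [c.more_reversed_by for c in comparisons],
        }
    )
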