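"""Config-driven end-to-end orchestration.

A run is described by one YAML file with a block per stage; unknown keys are
fatal so misconfiguration fails before anything executes.  Stages exchange
data only through serialized files in the output directory, so a run can be
restarted at any stage, and a manifest (stage order, file digests, seed,
version) makes two runs byte-comparable.

Stage order: simulate -> fit -> moa -> compare -> relate -> resist ->
interfere -> sobol.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    CompareConfig,
    EngineConfig,
    RelateConfig,
    ScanConfig,
    SobolConfig,
    from_mapping,
)
from .core import (
    NetmoaError,
    load_disease,
    load_drug_profiles,
    load_interactome,
    load_panel,
    load_restraints,
    neighborhood,
    write_disease,
    write_drug_profiles,
    write_interactome,
    write_panel,
    write_restraints,
)
from .compare import (
    brain_panel_report,
    compare_effectors,
    compare_motives,
    effectors_table,
    heatmap_matrix,
    motives_table,
)
from .engine import fit_ensemble, load_ensemble, moa_subnetwork, save_ensemble
from .relations import TruthTable, TruthTableRow, relation_grid, train_cv
from .scans import interference_scan, resistance_scan, scan_table
from .sobol import ensemble_evaluator, ensemble_factors, sobol_analysis, sobol_table
from .synth import (
    SynthConfig,
    generate_ground_truth_weights,
    generate_truth_table,
    paper_mimic,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "fit", "moa", "compare", "relate", "resist", "interfere", "sobol",
)

__all__ = ["RunConfig", "run_pipeline", "load_run_config", "STAGES"]


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "netmoa_run"
    stages: tuple[str, ...] = STAGES
    simulate: SynthConfig = field(default_factory=SynthConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    compare: CompareConfig = field(default_factory=CompareConfig)
    relate: RelateConfig = field(default_factory=RelateConfig)
    scans: ScanConfig = field(default_factory=ScanConfig)
    sobol: SobolConfig = field(default_factory=SobolConfig)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise NetmoaError(f"unknown stages: {sorted(unknown)}")


_BLOCKS = {
    "simulate": SynthConfig,
    "engine": EngineConfig,
    "compare": CompareConfig,
    "relate": RelateConfig,
    "scans": ScanConfig,
    "sobol": SobolConfig,
}


def load_run_config(path: str | Path) -> RunConfig:
    """Parse a YAML run config with strict key validation."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise NetmoaError(f"{path}: run config must be a mapping")
    unknown = set(data) - set(_BLOCKS) - {"seed", "outdir", "stages"}
    if unknown:
        raise NetmoaError(f"{path}: unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _BLOCKS:
            try:
                kwargs[key] = from_mapping(_BLOCKS[key], value or {})
            except (TypeError, ValueError) as exc:
                raise NetmoaError(f"{path}: bad block {key!r}: {exc}") from exc
        elif key == "stages":
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, seed: int, params: str,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} {params}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages end-to-end and return the run manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": [],
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in cfg.stages:
            continue
        runner = _STAGE_RUNNERS[stage]
        try:
            outputs = runner(cfg, out, state)
        except Exception as exc:
            manifest["failed_stage"] = stage
            _write_manifest(manifest, out)
            raise NetmoaError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {"name": stage, "outputs": {p.name: _sha256(p) for p in outputs}}
        )
        logger.info("stage %s complete (%d outputs)", stage, len(outputs))
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Stage runners: each loads its inputs from disk, writes its outputs to disk
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    scfg = dataclasses.replace(cfg.simulate, seed=cfg.seed)
    bundle = paper_mimic(cfg.seed, scfg)
    gt = generate_ground_truth_weights(bundle.net, scfg)
    table, restraints = generate_truth_table(bundle.net, gt, scfg)
    paths = []

    p = out / "interactome.tsv"
    write_interactome(bundle.net, p)
    paths.append(p)
    p = out / "drugs.tsv"
    write_drug_profiles([bundle.broad, bundle.narrow], p)
    paths.append(p)
    p = out / "disease.tsv"
    write_disease(bundle.disease, p)
    paths.append(p)
    p = out / "brain_panel.tsv"
    write_panel(bundle.panel, p)
    paths.append(p)
    p = out / "restraints.json"
    write_restraints(restraints, p)
    paths.append(p)
    p = out / "truth_table.tsv"
    rows = pd.DataFrame(
        {
            "source": [";".join(sorted(r.source)) for r in table.rows],
            "effectors": [";".join(sorted(r.effectors)) for r in table.rows],
            "label": [r.label for r in table.rows],
        }
    )
    _write_tsv(rows, p, cfg.seed, f"n_rows={len(table.rows)}")
    paths.append(p)
    state["bundle"] = bundle
    return paths


def _load_inputs(out: Path, state: dict):
    if "net" not in state:
        state["net"] = load_interactome(out / "interactome.tsv")
        profiles = load_drug_profiles(out / "drugs.tsv")
        state["broad"], state["narrow"] = profiles[0], profiles[1]
        state["disease"] = load_disease(out / "disease.tsv")
        state["panel"] = load_panel(out / "brain_panel.tsv")
    return state


def _stage_fit(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(out, state)
    paths = []
    for which, offset in (("broad", 0), ("narrow", 1)):
        drug = state[which]
        ens = fit_ensemble(
            state["net"], [], M=cfg.engine.M,
            optimizer_cfg=cfg.engine.optimizer,
            seed=cfg.seed * 2 + offset, drug=drug, engine_cfg=cfg.engine,
        )
        jp = out / f"ensemble_{which}.json"
        sp = out / f"ensemble_{which}_signals.tsv"
        save_ensemble(ens, jp, sp)
        paths += [jp, sp]
        state[f"ens_{which}"] = ens
    return paths


def _load_ensembles(cfg: RunConfig, out: Path, state: dict):
    _load_inputs(out, state)
    for which in ("broad", "narrow"):
        if f"ens_{which}" not in state:
            state[f"ens_{which}"] = load_ensemble(
                state["net"],
                out / f"ensemble_{which}.json",
                out / f"ensemble_{which}_signals.tsv",
            )
    return state


def _stage_moa(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_ensembles(cfg, out, state)
    paths = []
    for which in ("broad", "narrow"):
        sub = moa_subnetwork(state[f"ens_{which}"], cfg.engine.epsilon)
        df = pd.DataFrame(
            {"protein": list(sub.nodes), "mean_signal": list(sub.nodes.values())}
        )
        p = out / f"moa_{which}.tsv"
        _write_tsv(df, p, cfg.seed, f"epsilon={cfg.engine.epsilon}")
        paths.append(p)
    return paths


def _stage_compare(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_ensembles(cfg, out, state)
    ensA, ensB = state["ens_broad"], state["ens_narrow"]
    disease, panel = state["disease"], state["panel"]
    nameA = ensA.drug.drug_name
    nameB = ensB.drug.drug_name
    mot = compare_motives(ensA, ensB, disease, cfg=cfg.compare)
    eff = compare_effectors(ensA, ensB, disease.all_effectors, cfg.compare)
    report = brain_panel_report(eff, panel, nameA, nameB)
    heat = heatmap_matrix(ensA, ensB, disease.all_effectors)
    paths = []
    p = out / "motive_comparison.tsv"
    _write_tsv(motives_table(mot, nameA, nameB), p, cfg.seed,
               f"alpha={cfg.compare.alpha}")
    paths.append(p)
    p = out / "effector_comparison.tsv"
    _write_tsv(effectors_table(eff), p, cfg.seed,
               f"alpha={cfg.compare.alpha} "
               f"rel_change={cfg.compare.relative_change_threshold}")
    paths.append(p)
    p = out / "brain_panel_report.tsv"
    _write_tsv(effectors_table(report.rows), p, cfg.seed,
               f"more_reversed_{nameA}={report.count_a} "
               f"more_reversed_{nameB}={report.count_b} tie={report.count_tie}")
    paths.append(p)
    p = out / "heatmap_matrix.tsv"
    _write_tsv(heat, p, cfg.seed, f"M={ensA.M}+{ensB.M}", index=True)
    paths.append(p)
    return paths


def _read_truth_table(path: Path) -> TruthTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    rows = [
        TruthTableRow(
            frozenset(str(r.source).split(";")),
            frozenset(str(r.effectors).split(";")),
            r.label,
        )
        for r in df.itertuples()
    ]
    return TruthTable(rows)


def _stage_relate(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_inputs(out, state)
    table = _read_truth_table(out / "truth_table.tsv")
    model, cv_acc = train_cv(
        table, state["net"], folds=cfg.relate.folds, seed=cfg.seed,
        cfg=cfg.relate,
    )
    grades, scores = relation_grid(
        model, [state["broad"], state["narrow"]], state["disease"],
        state["net"], cfg.relate.bin_thresholds,
    )
    long = grades.stack(level=[0, 1], future_stack=True).rename("grade").reset_index()
    long.columns = ["motive", "drug", "target", "grade"]
    long["score"] = scores.stack(level=[0, 1], future_stack=True).reset_index(drop=True)
    p = out / "relation_scores.tsv"
    _write_tsv(long, p, cfg.seed, f"cv_accuracy={cv_acc:.4f}")
    return [p]


def _stage_resist(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_ensembles(cfg, out, state)
    disease = state["disease"]
    paths = []
    for which in ("broad", "narrow"):
        ens = state[f"ens_{which}"]
        seeds = set(disease.effector_proteins) & set(state["net"].nodes)
        seeds |= set(ens.drug.targets)
        universe = neighborhood(state["net"], seeds, cfg.scans.universe_radius)
        results = resistance_scan(
            ens, universe, disease, alpha=cfg.scans.resistance_alpha
        )
        p = out / f"resistance_{which}.tsv"
        _write_tsv(scan_table(results), p, cfg.seed,
                   f"alpha={cfg.scans.resistance_alpha} "
                   f"radius={cfg.scans.universe_radius}")
        paths.append(p)
    return paths


def _stage_interfere(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_ensembles(cfg, out, state)
    # co-treatments: each drug is the other's candidate interference, the
    # simplest self-contained co-treatment list
    pairs = (
        ("broad", state["narrow"]),
        ("narrow", state["broad"]),
    )
    paths = []
    for which, co in pairs:
        results = interference_scan(
            state[f"ens_{which}"], [co], state["disease"],
            alphas=cfg.scans.interference_alphas,
        )
        p = out / f"interference_{which}.tsv"
        _write_tsv(scan_table(results), p, cfg.seed,
                   f"alphas={cfg.scans.interference_alphas}")
        paths.append(p)
    return paths


def _stage_sobol(cfg: RunConfig, out: Path, state: dict) -> list[Path]:
    _load_ensembles(cfg, out, state)
    paths = []
    for which in ("broad", "narrow"):
        ens = state[f"ens_{which}"]
        factors = ensemble_factors(ens, cfg.sobol)
        evaluator = ensemble_evaluator(ens, state["disease"])
        result = sobol_analysis(
            evaluator, factors, n_base=cfg.sobol.n_base, seed=cfg.seed,
            bootstrap=cfg.sobol.bootstrap,
        )
        p = out / f"sobol_{which}.tsv"
        _write_tsv(sobol_table(result), p, cfg.seed,
                   f"n_base={cfg.sobol.n_base}")
        paths.append(p)
    return paths


_STAGE_RUNNERS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "moa": _stage_moa,
    "compare": _stage_compare,
    "relate": _stage_relate,
    "resist": _stage_resist,
    "interfere": _stage_interfere,
    "sobol": _stage_sobol,
}
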