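"""Default parameter blocks for the modelling pipeline.

Every tunable that the engine, statistics, scans, classifier or sensitivity
analysis consumes lives here rather than being hard-coded at call sites, so
a run is fully described by one configuration object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class OptimizerConfig:
    """Simulated-annealing settings for ensemble fitting.

    ``margin`` is the satisfaction margin: an expected effector sign counts
    as met during fitting only when ``expected_sign * signal > margin``.
    """

    steps: int = 2000
    t0: float = 1.0
    cooling: float = 0.995
    margin: float = 0.2
    step_size: float = 0.15
    moves_per_step: int = 4


@dataclass
class EngineConfig:
    M: int = 100                  # solutions per ensemble
    max_iter: int = 200           # propagation iterations
    tol: float = 1e-6             # propagation convergence tolerance
    epsilon: float = 1e-6         # |mean signal| threshold for the MoA subnetwork
    fit_max_iter: int = 60        # propagation cap inside the annealing loop
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)


@dataclass
class CompareConfig:
    alpha: float = 0.05                 # FDR level for motive/effector winners
    relative_change_threshold: float = 20.0   # % TSignal change for a per-effector call
    fdr_method: str = "fdr_bh"
    test: str = "welch"


@dataclass
class ScanConfig:
    resistance_alpha: float = 0.022     # selection threshold for resistance scans
    interference_alphas: tuple[float, float] = (0.05, 0.1)  # strong/weak tiers
    universe_radius: int = 1            # neighborhood radius around effectors+targets


@dataclass
class RelateConfig:
    folds: int = 5
    hidden_units: int = 16
    max_epochs: int = 600
    bin_thresholds: tuple[float, float, float] = (0.25, 0.5, 0.75)


@dataclass
class SobolConfig:
    n_base: int = 256
    bootstrap: int = 100
    clamp_range: tuple[float, float] = (0.5, 1.0)
    weight_scale_range: tuple[float, float] = (0.5, 1.5)


def from_mapping(cls, data: dict):
    """Build a config dataclass strictly: unknown keys are fatal."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if isinstance(value, dict):
            sub = {"optimizer": OptimizerConfig}.get(key)
            if sub is None:
                raise ValueError(f"unexpected mapping for {cls.__name__}.{key}")
            value = from_mapping(sub, value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
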