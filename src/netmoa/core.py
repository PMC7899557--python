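"""Domain types and file I/O for signed protein-interaction modelling.

The central container is :class:`Interactome`, a directed graph whose edges
carry an activation/inhibition sign (+1/-1) and a confidence weight in
[0, 1].  Drugs are represented by :class:`DrugTargetProfile` (which proteins
a drug activates or inactivates), diseases by :class:`DiseaseCharacterization`
(pathophysiological motives, each molecularly defined by effector proteins
with a pathological direction), and model-training constraints by
:class:`Restraint` (a stimulus and the effector signs it is expected to
produce).

Supported on-disk dialects: SIF (``source<TAB>sign<TAB>target``), TSV edge
lists (``source, target, sign, weight``) and GraphML with ``sign``/``weight``
edge attributes.  Profiles, characterizations and panels are plain TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "NetmoaError",
    "ParseError",
    "ValidationError",
    "Edge",
    "Interactome",
    "DrugTargetProfile",
    "Effector",
    "DiseaseCharacterization",
    "Restraint",
    "BrainPanel",
    "load_interactome",
    "write_interactome",
    "load_drug_profile",
    "load_drug_profiles",
    "write_drug_profiles",
    "load_disease",
    "write_disease",
    "load_panel",
    "write_panel",
    "load_restraints",
    "write_restraints",
    "neighborhood",
]


class NetmoaError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NetmoaError):
    """A file could not be parsed in the declared dialect."""


class ValidationError(NetmoaError):
    """Input parsed but violated a domain invariant."""


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

class Edge(NamedTuple):
    source: str
    target: str
    sign: int
    weight: float = 1.0


@dataclass(frozen=True)
class Interactome:
    """A signed, weighted, directed protein-interaction network.

    Self-loops are permitted, and a pair of proteins may be linked by two
    edges of opposite sign (activation and inhibition evidence can coexist),
    but the (source, target, sign) triple must be unique.
    """

    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    directed: bool = True

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValidationError("interactome has no nodes")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node identifiers")
        for n in self.nodes:
            if not isinstance(n, str) or not n:
                raise ValidationError(f"invalid node identifier: {n!r}")
        nodeset = set(self.nodes)
        seen: set[tuple[str, str, int]] = set()
        for e in self.edges:
            if e.source not in nodeset or e.target not in nodeset:
                raise ValidationError(
                    f"edge {e.source}->{e.target} has a dangling endpoint"
                )
            if e.sign not in (1, -1):
                raise ValidationError(f"edge sign must be +1 or -1, got {e.sign}")
            if not (0.0 <= e.weight <= 1.0):
                raise ValidationError(
                    f"edge weight must be in [0, 1], got {e.weight}"
                )
            key = (e.source, e.target, e.sign)
            if key in seen:
                raise ValidationError(
                    f"duplicate edge (source, target, sign) triple: {key}"
                )
            seen.add(key)

    @classmethod
    def from_edges(
        cls, edges: Iterable[Edge], extra_nodes: Iterable[str] = ()
    ) -> "Interactome":
        edges = tuple(edges)
        nodes: dict[str, None] = {}
        for e in edges:
            nodes.setdefault(e.source)
            nodes.setdefault(e.target)
        for n in extra_nodes:
            nodes.setdefault(n)
        return cls(nodes=tuple(nodes), edges=edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @cached_property
    def node_index(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def signed_adjacency(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        """Matrix A with A[i, j] = sum of sign*weight over edges j -> i.

        Multi-edges between the same pair sum, so opposing evidence of equal
        weight cancels.  ``weights`` overrides the stored per-edge weights
        (aligned with :attr:`edges`).
        """
        idx = self.node_index
        if weights is None:
            w = np.array([e.weight for e in self.edges], dtype=float)
        else:
            w = np.asarray(weights, dtype=float)
            if w.shape != (self.n_edges,):
                raise ValidationError(
                    f"weight vector has shape {w.shape}, expected ({self.n_edges},)"
                )
        rows = np.array([idx[e.target] for e in self.edges], dtype=np.int64)
        cols = np.array([idx[e.source] for e in self.edges], dtype=np.int64)
        signs = np.array([e.sign for e in self.edges], dtype=float)
        n = self.n_nodes
        return sp.csr_matrix((w * signs, (rows, cols)), shape=(n, n))

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, weight=e.weight)
        return g

    @cached_property
    def _undirected(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    @cached_property
    def _digraph(self) -> nx.DiGraph:
        # sign-collapsed simple digraph, for reachability/distance queries
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from((e.source, e.target) for e in self.edges)
        return g

    @cached_property
    def undirected_diameter(self) -> int:
        """Diameter of the largest connected component (undirected)."""
        comps = list(nx.connected_components(self._undirected))
        if not comps:
            return 0
        largest = max(comps, key=len)
        if len(largest) == 1:
            return 0
        return nx.diameter(self._undirected.subgraph(largest))

    def descendants(self, sources: Iterable[str]) -> set[str]:
        """Nodes reachable (directed) from any of ``sources``, excluding them."""
        out: set[str] = set()
        for s in sources:
            out |= nx.descendants(self._digraph, s)
        return out

    def out_degree(self, node: str) -> int:
        return self._digraph.out_degree(node)

    def without_node(self, node: str) -> tuple["Interactome", np.ndarray]:
        """Delete ``node`` and incident edges.

        Returns the reduced network and the indices (into the original edge
        tuple) of the surviving edges, so that per-edge weight vectors can be
        restricted consistently.
        """
        if node not in self.node_index:
            raise ValidationError(f"unknown node: {node}")
        kept = np.array(
            [i for i, e in enumerate(self.edges)
             if e.source != node and e.target != node],
            dtype=np.int64,
        )
        return (
            Interactome(
                nodes=tuple(n for n in self.nodes if n != node),
                edges=tuple(self.edges[i] for i in kept),
            ),
            kept,
        )

    def relabel(self, mapping: Mapping[str, str]) -> "Interactome":
        """Rename nodes; identifiers not in ``mapping`` are unchanged."""
        f = lambda n: mapping.get(n, n)
        return Interactome(
            nodes=tuple(f(n) for n in self.nodes),
            edges=tuple(
                Edge(f(e.source), f(e.target), e.sign, e.weight) for e in self.edges
            ),
        )


# ---------------------------------------------------------------------------
# Drug profiles, disease characterization, restraints, panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTargetProfile:
    """Targets of a drug with its action on each: +1 activation, -1 inactivation."""

    drug_name: str
    targets: dict[str, int]

    def __post_init__(self) -> None:
        if not self.drug_name:
            raise ValidationError("drug name must be non-empty")
        if not self.targets:
            raise ValidationError(f"drug {self.drug_name!r} has no targets")
        for p, a in self.targets.items():
            if a not in (1, -1):
                raise ValidationError(
                    f"action for {p} must be +1 or -1, got {a}"
                )

    def clamps(self) -> dict[str, float]:
        """The sustained clamp this drug applies to the network."""
        return {p: float(a) for p, a in self.targets.items()}


class Effector(NamedTuple):
    """A protein defining a motive: +1 activated in pathology, -1 inhibited, 9 complex."""

    protein: str
    pathological_state: int


VALID_STATES = (1, -1, 9)


@dataclass(frozen=True)
class DiseaseCharacterization:
    motives: dict[str, tuple[Effector, ...]]

    def __post_init__(self) -> None:
        if not self.motives:
            raise ValidationError("disease characterization has no motives")
        for m, effs in self.motives.items():
            seen = set()
            for e in effs:
                if e.pathological_state not in VALID_STATES:
                    raise ValidationError(
                        f"pathological state must be one of {VALID_STATES}, "
                        f"got {e.pathological_state} for {e.protein} in {m}"
                    )
                if e.protein in seen:
                    raise ValidationError(
                        f"effector {e.protein} duplicated within motive {m}"
                    )
                seen.add(e.protein)

    @property
    def all_effectors(self) -> tuple[Effector, ...]:
        """Unique effectors over all motives (first occurrence wins)."""
        out: dict[str, Effector] = {}
        for effs in self.motives.values():
            for e in effs:
                out.setdefault(e.protein, e)
        return tuple(out.values())

    @property
    def effector_proteins(self) -> tuple[str, ...]:
        return tuple(e.protein for e in self.all_effectors)

    def signed_effectors(self, motive: str | None = None) -> tuple[Effector, ...]:
        """Effectors with a definite pathological direction (state 9 excluded)."""
        effs = self.motives[motive] if motive is not None else self.all_effectors
        return tuple(e for e in effs if e.pathological_state in (1, -1))


@dataclass(frozen=True)
class Restraint:
    """A training constraint: a stimulus and the effector signs it should yield."""

    stimulus: dict[str, int]
    expected: dict[str, int]
    label: str = "positive"

    def __post_init__(self) -> None:
        if not self.stimulus or not self.expected:
            raise ValidationError("restraint stimulus and expected must be non-empty")
        for d in (self.stimulus, self.expected):
            for p, v in d.items():
                if v not in (1, -1):
                    raise ValidationError(f"restraint value for {p} must be +/-1")
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"restraint label must be positive/negative")


@dataclass(frozen=True)
class BrainPanel:
    """An ordered panel of effectors with a prominent role in brain metastasis."""

    proteins: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.proteins)) != len(self.proteins):
            raise ValidationError("brain panel entries must be unique")

    def validate_against(self, disease: DiseaseCharacterization) -> None:
        known = set(disease.effector_proteins)
        missing = [p for p in self.proteins if p not in known]
        if missing:
            raise ValidationError(
                f"panel proteins not effectors of any motive: {missing}"
            )


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

_SIGN_TOKENS = {"+1": 1, "1": 1, "-1": -1, "−1": -1}


def _parse_sign(tok: str, path: Path, lineno: int) -> int:
    try:
        return _SIGN_TOKENS[tok.strip()]
    except KeyError:
        raise ParseError(
            f"{path}:{lineno}: unknown sign token {tok!r} (expected +1 or -1)"
        ) from None


def _data_lines(path: Path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def load_interactome(path: str | Path, format: str | None = None) -> Interactome:
    """Read a network in SIF, TSV edge-list or GraphML dialect.

    ``format`` defaults to the file extension (.sif/.tsv/.graphml).
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("sif", "tsv", "graphml"):
        raise ParseError(f"unknown interactome format: {fmt!r}")
    if fmt == "graphml":
        return _load_graphml(path)
    edges: list[Edge] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if fmt == "sif":
            if len(parts) != 3:
                raise ParseError(
                    f"{path}:{lineno}: SIF requires 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            src, sign_tok, tgt = parts
            weight = 1.0
        else:  # tsv: source target sign [weight]
            if parts[0] == "source" and lineno == 1:
                continue
            if len(parts) not in (3, 4):
                raise ParseError(
                    f"{path}:{lineno}: TSV edge list requires 3 or 4 fields, "
                    f"got {len(parts)}"
                )
            src, tgt, sign_tok = parts[:3]
            try:
                weight = float(parts[3]) if len(parts) == 4 else 1.0
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: bad weight {parts[3]!r}"
                ) from None
        sign = _parse_sign(sign_tok, path, lineno)
        edges.append(Edge(src.strip(), tgt.strip(), sign, weight))
    if not edges:
        raise ParseError(f"{path}: no edges")
    return Interactome.from_edges(edges)


def _load_graphml(path: Path) -> Interactome:
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # noqa: BLE001 - rewrap parser errors uniformly
        raise ParseError(f"{path}: not valid GraphML ({exc})") from exc
    edges = []
    for u, v, data in g.edges(data=True):
        sign = int(data.get("sign", 1))
        weight = float(data.get("weight", 1.0))
        edges.append(Edge(str(u), str(v), sign, weight))
    if not edges:
        raise ParseError(f"{path}: no edges")
    return Interactome(
        nodes=tuple(str(n) for n in g.nodes), edges=tuple(edges)
    )


def write_interactome(net: Interactome, path: str | Path,
                      format: str | None = None) -> None:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.source}\t{e.sign:+d}\t{e.target}\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tsign\tweight\n")
            for e in net.edges:
                fh.write(f"{e.source}\t{e.target}\t{e.sign:+d}\t{e.weight!r}\n")
    elif fmt == "graphml":
        g = net.to_networkx()
        nx.write_graphml(g, path)
    else:
        raise ParseError(f"unknown interactome format: {fmt!r}")


def load_drug_profiles(path: str | Path) -> list[DrugTargetProfile]:
    """Read one or more drug target profiles from a TSV (drug, protein, action)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    drugs: dict[str, dict[str, int]] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if not header_seen:
            header_seen = True
            if parts[:3] == ["drug", "protein", "action"]:
                continue
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 fields (drug, protein, action)"
            )
        drug, protein, action_tok = parts
        action = _parse_sign(action_tok, path, lineno)
        targets = drugs.setdefault(drug, {})
        if protein in targets and targets[protein] != action:
            raise ValidationError(
                f"{path}:{lineno}: conflicting actions for {drug}/{protein}"
            )
        targets[protein] = action
    if not drugs:
        raise ParseError(f"{path}: no target rows")
    return [DrugTargetProfile(name, targets) for name, targets in drugs.items()]


def load_drug_profile(path: str | Path) -> DrugTargetProfile:
    profiles = load_drug_profiles(path)
    if len(profiles) != 1:
        raise ValidationError(
            f"{path}: expected a single drug, found {len(profiles)}"
        )
    return profiles[0]


def write_drug_profiles(profiles: Sequence[DrugTargetProfile],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\tprotein\taction\n")
        for prof in profiles:
            for protein, action in prof.targets.items():
                fh.write(f"{prof.drug_name}\t{protein}\t{action:+d}\n")


def load_disease(path: str | Path) -> DiseaseCharacterization:
    """Read a disease characterization TSV (motive, protein, state)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    motives: dict[str, list[Effector]] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        parts = [p.strip() for p in line.split("\t")]
        if not header_seen:
            header_seen = True
            if parts[:3] == ["motive", "protein", "state"]:
                continue
        if len(parts) != 3:
            raise ParseError(
                f"{path}:{lineno}: expected 3 fields (motive, protein, state)"
            )
        motive, protein, state_tok = parts
        try:
            state = int(state_tok)
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad state {state_tok!r}") from None
        if state not in VALID_STATES:
            raise ValidationError(
                f"{path}:{lineno}: state must be one of {VALID_STATES}, got {state}"
            )
        motives.setdefault(motive, []).append(Effector(protein, state))
    if not motives:
        raise ParseError(f"{path}: no effector rows")
    return DiseaseCharacterization(
        motives={m: tuple(effs) for m, effs in motives.items()}
    )


def write_disease(disease: DiseaseCharacterization, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("motive\tprotein\tstate\n")
        for motive, effs in disease.motives.items():
            for e in effs:
                fh.write(f"{motive}\t{e.protein}\t{e.pathological_state}\n")


def load_panel(path: str | Path) -> BrainPanel:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    proteins = []
    for lineno, line in _data_lines(path):
        tok = line.split("\t")[0].strip()
        if tok == "protein" and lineno == 1:
            continue
        proteins.append(tok)
    if not proteins:
        raise ParseError(f"{path}: empty panel")
    return BrainPanel(proteins=tuple(proteins))


def write_panel(panel: BrainPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\n")
        for p in panel.proteins:
            fh.write(p + "\n")


def load_restraints(path: str | Path) -> list[Restraint]:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not valid JSON ({exc})") from exc
    out = []
    for row in payload:
        out.append(
            Restraint(
                stimulus={str(k): int(v) for k, v in row["stimulus"].items()},
                expected={str(k): int(v) for k, v in row["expected"].items()},
                label=row.get("label", "positive"),
            )
        )
    return out


def write_restraints(restraints: Sequence[Restraint], path: str | Path) -> None:
    payload = [
        {"stimulus": r.stimulus, "expected": r.expected, "label": r.label}
        for r in restraints
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# ---------------------------------------------------------------------------
# Neighborhood
# ---------------------------------------------------------------------------

def neighborhood(net: Interactome, seeds: Iterable[str], radius: int) -> set[str]:
    """All nodes within undirected shortest-path distance ``radius`` of a seed.

    Used to narrow a perturbation-scan universe to the proteins around the
    disease effectors and the drug targets.  Seeds are always included.
    """
    seeds = set(seeds)
    missing = sorted(seeds - set(net.nodes))
    if missing:
        raise ValidationError(f"seed proteins not in network: {missing}")
    if radius < 0:
        raise ValidationError("radius must be non-negative")
    g = net._undirected
    out: set[str] = set()
    for s in seeds:
        out.update(nx.single_source_shortest_path_length(g, s, cutoff=radius))
    return out
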