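"""Regulatory-network topology, shifted-Hill kinetics and ODE assembly.

A circuit is a small signed, typed gene regulatory network (transcription
factors and microRNAs).  Every regulation acts multiplicatively on the
target's production rate through a *shifted Hill function*

    H^S(A; A0, n, lam) = lam + (1 - lam) / (1 + (A / A0)^n)

which equals 1 when the regulator A is absent and saturates at the
fold-change ``lam`` (lam > 1: activation, lam < 1: inhibition).  Each
species X then follows

    dX/dt = g_X * prod_i H^S(A_i) - k_X * X

with basal production g_X (molecules/time) and first-order degradation
k_X (1/time).  An optional external signal (e.g. an EMT-inducing stimulus
``Iext``) is a constant-level pseudo-node: it regulates its targets but has
no equation of its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "ACTIVATION",
    "INHIBITION",
    "TRANSCRIPTIONAL",
    "MICRORNA",
    "CircuitError",
    "ConfigurationError",
    "SchemaError",
    "Edge",
    "HillParams",
    "RegulatoryNetwork",
    "KineticParameterSet",
    "shifted_hill",
    "build_rhs",
    "load_network",
    "save_network",
    "load_parameters",
    "save_parameters",
    "load_fixture",
    "fixture_names",
]

ACTIVATION = "activation"
INHIBITION = "inhibition"
SIGNS = (ACTIVATION, INHIBITION)

TRANSCRIPTIONAL = "transcriptional"
MICRORNA = "microRNA"
MECHANISMS = (TRANSCRIPTIONAL, MICRORNA)


class CircuitError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(CircuitError):
    """A network/parameter combination is incomplete or inconsistent."""


class SchemaError(ConfigurationError):
    """A config file does not conform to the expected schema."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Edge:
    """A signed, typed regulation from ``source`` onto ``target``.

    ``mechanism`` distinguishes transcriptional regulation from
    microRNA-mediated regulation (e.g. miR-200 silencing ZEB mRNA).  Both
    use the same shifted-Hill multiplier by default; the distinction is
    retained so that a dedicated microRNA form can be substituted.
    """

    source: str
    target: str
    sign: str
    mechanism: str = TRANSCRIPTIONAL

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise SchemaError(f"edge {self.source}->{self.target}: sign must be one of {SIGNS}, got {self.sign!r}")
        if self.mechanism not in MECHANISMS:
            raise SchemaError(
                f"edge {self.source}->{self.target}: mechanism must be one of {MECHANISMS}, got {self.mechanism!r}"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.source, self.target)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        glyph = "->" if self.sign == ACTIVATION else "-|"
        return f"{self.source} {glyph} {self.target}"


@dataclass(frozen=True)
class HillParams:
    """Shifted-Hill parameters of one edge.

    fold_change
        Saturating multiplier ``lam`` (> 1 activation, < 1 inhibition,
        = 1 neutral).  Must be positive.
    threshold
        Half-effect regulator level ``A0`` in molecules.  Must be positive.
    coefficient
        Hill coefficient ``n`` (positive integer).
    """

    fold_change: float
    threshold: float
    coefficient: int

    def __post_init__(self) -> None:
        if not (self.fold_change > 0 and math.isfinite(self.fold_change)):
            raise SchemaError(f"fold_change must be positive and finite, got {self.fold_change}")
        if not (self.threshold > 0 and math.isfinite(self.threshold)):
            raise SchemaError(f"threshold must be positive and finite, got {self.threshold}")
        if int(self.coefficient) != self.coefficient or self.coefficient < 1:
            raise SchemaError(f"Hill coefficient must be an integer >= 1, got {self.coefficient}")


@dataclass(frozen=True)
class RegulatoryNetwork:
    """Nodes plus signed, typed edges; self-loops permitted.

    ``signal`` optionally names an external-input pseudo-node (constant
    level, no incoming edges, no ODE of its own).
    """

    name: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    signal: str | None = None

    def __init__(
        self,
        name: str,
        nodes: Iterable[str],
        edges: Iterable[Edge | tuple],
        signal: str | None = None,
    ) -> None:
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "nodes", tuple(nodes))
        object.__setattr__(self, "edges", tuple(e if isinstance(e, Edge) else Edge(*e) for e in edges))
        object.__setattr__(self, "signal", signal)
        self._validate()

    def _validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            dup = [n for n in self.nodes if self.nodes.count(n) > 1]
            raise SchemaError(f"network {self.name!r}: duplicate node names {sorted(set(dup))}")
        declared = set(self.nodes)
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in declared:
                    raise SchemaError(f"network {self.name!r}: edge {e} references undeclared node {endpoint!r}")
        keys = [e.key for e in self.edges]
        if len(set(keys)) != len(keys):
            dup_keys = sorted({k for k in keys if keys.count(k) > 1})
            raise SchemaError(f"network {self.name!r}: duplicate edges {dup_keys}")
        if self.signal is not None:
            if self.signal not in declared:
                raise SchemaError(f"network {self.name!r}: signal node {self.signal!r} not declared")
            incoming = [e for e in self.edges if e.target == self.signal]
            if incoming:
                raise SchemaError(
                    f"network {self.name!r}: signal node {self.signal!r} must have no incoming edges, got {incoming}"
                )

    # -- views ------------------------------------------------------------

    @property
    def dynamic_nodes(self) -> tuple[str, ...]:
        """Nodes carrying an ODE (everything except the signal node)."""
        return tuple(n for n in self.nodes if n != self.signal)

    def incoming(self, node: str) -> tuple[Edge, ...]:
        return tuple(e for e in self.edges if e.target == node)

    def edge(self, source: str, target: str) -> Edge:
        for e in self.edges:
            if e.key == (source, target):
                return e
        raise KeyError(f"no edge {source}->{target} in network {self.name!r}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(name=self.name)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign, mechanism=e.mechanism)
        return g

    # -- editing (returns new objects; used to derive circuit variants) ---

    def without_node(self, node: str, name: str | None = None) -> "RegulatoryNetwork":
        """Drop ``node`` and every edge touching it."""
        if node not in self.nodes:
            raise KeyError(f"node {node!r} not in network {self.name!r}")
        return RegulatoryNetwork(
            name or f"{self.name}-minus-{node}",
            tuple(n for n in self.nodes if n != node),
            tuple(e for e in self.edges if node not in e.key),
            signal=None if node == self.signal else self.signal,
        )


@dataclass
class KineticParameterSet:
    """Per-node production/degradation rates plus per-edge Hill parameters.

    ``provenance`` records where the numbers came from: "manual",
    "reconstructed-calibrated" (fixtures rebuilt from the modelling
    lineage) or "sampled(seed=S, index=I)" for ensemble draws.
    """

    production: dict[str, float]
    degradation: dict[str, float]
    hill: dict[tuple[str, str], HillParams]
    provenance: str = "manual"

    def __post_init__(self) -> None:
        for node, g in self.production.items():
            if not (g >= 0 and math.isfinite(g)):
                raise SchemaError(f"production rate of {node!r} must be >= 0 and finite, got {g}")
        for node, k in self.degradation.items():
            if not (k > 0 and math.isfinite(k)):
                raise SchemaError(f"degradation rate of {node!r} must be > 0 and finite, got {k}")

    def copy(self) -> "KineticParameterSet":
        return KineticParameterSet(
            dict(self.production), dict(self.degradation), dict(self.hill), self.provenance
        )

    # -- flat parameter naming, used by sweeps and sensitivity analysis ---
    #    "g:NODE", "k:NODE", "lambda:SRC->TGT", "threshold:SRC->TGT",
    #    "n:SRC->TGT"

    def parameter_names(self, include_hill_coefficients: bool = False) -> list[str]:
        names = [f"g:{n}" for n in self.production]
        names += [f"k:{n}" for n in self.degradation]
        for (s, t) in self.hill:
            names += [f"lambda:{s}->{t}", f"threshold:{s}->{t}"]
            if include_hill_coefficients:
                names.append(f"n:{s}->{t}")
        return names

    @staticmethod
    def _parse(name: str) -> tuple[str, object]:
        try:
            kind, rest = name.split(":", 1)
        except ValueError as exc:
            raise KeyError(f"malformed parameter name {name!r}") from exc
        if kind in ("g", "k"):
            return kind, rest
        if kind in ("lambda", "threshold", "n"):
            src, tgt = rest.split("->")
            return kind, (src, tgt)
        raise KeyError(f"unknown parameter kind in {name!r}")

    def get(self, name: str) -> float:
        kind, key = self._parse(name)
        if kind == "g":
            return self.production[key]
        if kind == "k":
            return self.degradation[key]
        hp = self.hill[key]
        return {"lambda": hp.fold_change, "threshold": hp.threshold, "n": hp.coefficient}[kind]

    def set(self, name: str, value: float) -> "KineticParameterSet":
        """Return a copy with one named parameter replaced."""
        kind, key = self._parse(name)
        out = self.copy()
        if kind == "g":
            if key not in out.production:
                raise KeyError(f"no node {key!r} in parameter set")
            out.production[key] = float(value)
        elif kind == "k":
            if key not in out.degradation:
                raise KeyError(f"no node {key!r} in parameter set")
            out.degradation[key] = float(value)
        else:
            hp = out.hill[key]
            if kind == "lambda":
                out.hill[key] = replace(hp, fold_change=float(value))
            elif kind == "threshold":
                out.hill[key] = replace(hp, threshold=float(value))
            else:
                out.hill[key] = replace(hp, coefficient=int(value))
        return out


# ---------------------------------------------------------------------------
# Shifted Hill function and RHS assembly
# ---------------------------------------------------------------------------


def shifted_hill(level, params: HillParams):
    """Shifted-Hill regulation multiplier ``H^S(level; A0, n, lam)``.

    Equals 1 at level 0 (unregulated baseline), ``(1 + lam)/2`` at the
    threshold, and tends to the fold-change ``lam`` as the level grows.
    Accepts scalars or arrays; negative levels are a domain error.
    """
    level = np.asarray(level, dtype=float)
    if np.any(level < 0):
        raise ValueError("regulator level must be non-negative")
    lam = params.fold_change
    ratio = (level / params.threshold) ** params.coefficient
    out = lam + (1.0 - lam) / (1.0 + ratio)
    return float(out) if out.ndim == 0 else out


def _check_coverage(network: RegulatoryNetwork, params: KineticParameterSet) -> None:
    for node in network.dynamic_nodes:
        if node not in params.production:
            raise ConfigurationError(f"missing production rate for node {node!r}")
        if node not in params.degradation:
            raise ConfigurationError(f"missing degradation rate for node {node!r}")
    for e in network.edges:
        if e.key not in params.hill:
            raise ConfigurationError(f"missing Hill parameters for edge {e}")


def build_rhs(
    network: RegulatoryNetwork,
    params: KineticParameterSet,
    external_signal: float = 0.0,
):
    """Build ``f(x) -> dx/dt`` over ``network.dynamic_nodes`` (in order).

    Each node's rate is its basal production times the product of the
    shifted-Hill multipliers of its incoming edges, minus first-order
    degradation.  The external signal (if the network declares one) enters
    as a fixed level acting through its outgoing edges.
    """
    _check_coverage(network, params)
    nodes = network.dynamic_nodes
    index = {n: i for i, n in enumerate(nodes)}
    g = np.array([params.production[n] for n in nodes], dtype=float)
    k = np.array([params.degradation[n] for n in nodes], dtype=float)

    # (target index, source index or -1 for the signal node, HillParams)
    terms: list[tuple[int, int, HillParams]] = []
    for e in network.edges:
        src = -1 if e.source == network.signal else index[e.source]
        terms.append((index[e.target], src, params.hill[e.key]))
    signal_level = float(external_signal)

    def rhs(x: np.ndarray) -> np.ndarray:
        # clamp to the physical domain: root-finders probe small negative
        # excursions that the Hill form does not accept
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        prod = g.copy()
        for tgt, src, hp in terms:
            level = signal_level if src < 0 else x[src]
            prod[tgt] *= shifted_hill(level, hp)
        return prod - k * x

    rhs.nodes = nodes  # type: ignore[attr-defined]
    rhs.production = g  # type: ignore[attr-defined]
    rhs.degradation = k  # type: ignore[attr-defined]
    return rhs


# ---------------------------------------------------------------------------
# Config IO (YAML) and shipped fixtures
# ---------------------------------------------------------------------------


def _network_to_dict(network: RegulatoryNetwork) -> dict:
    d: dict = {
        "name": network.name,
        "nodes": list(network.nodes),
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign, "mechanism": e.mechanism}
            for e in network.edges
        ],
    }
    if network.signal is not None:
        d["signal"] = network.signal
    return d


def _network_from_dict(d: Mapping) -> RegulatoryNetwork:
    try:
        edges = [
            Edge(e["source"], e["target"], e["sign"], e.get("mechanism", TRANSCRIPTIONAL))
            for e in d.get("edges", [])
        ]
        return RegulatoryNetwork(d["name"], d["nodes"], edges, signal=d.get("signal"))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed network config: {exc}") from exc


def _params_to_dict(params: KineticParameterSet) -> dict:
    return {
        "provenance": params.provenance,
        "production": {n: float(v) for n, v in params.production.items()},
        "degradation": {n: float(v) for n, v in params.degradation.items()},
        "hill": [
            {
                "source": s,
                "target": t,
                "lambda": float(hp.fold_change),
                "threshold": float(hp.threshold),
                "n": int(hp.coefficient),
            }
            for (s, t), hp in params.hill.items()
        ],
    }


def _params_from_dict(d: Mapping) -> KineticParameterSet:
    try:
        hill = {
            (h["source"], h["target"]): HillParams(float(h["lambda"]), float(h["threshold"]), int(h["n"]))
            for h in d.get("hill", [])
        }
        return KineticParameterSet(
            {n: float(v) for n, v in d.get("production", {}).items()},
            {n: float(v) for n, v in d.get("degradation", {}).items()},
            hill,
            provenance=str(d.get("provenance", "manual")),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed parameter config: {exc}") from exc


def load_network(path: str | Path) -> RegulatoryNetwork:
    """Read a network block (optionally the ``network:`` key of a combined file)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return _network_from_dict(doc.get("network", doc))


def save_network(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"network": _network_to_dict(network)}, fh, sort_keys=False)


def load_parameters(path: str | Path) -> KineticParameterSet:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError(f"{path}: expected a mapping at top level")
    return _params_from_dict(doc.get("parameters", doc))


def save_parameters(params: KineticParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": _params_to_dict(params)}, fh, sort_keys=False)


def save_model(network: RegulatoryNetwork, params: KineticParameterSet, path: str | Path) -> None:
    """Write a combined network+parameters config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"network": _network_to_dict(network), "parameters": _params_to_dict(params)},
            fh,
            sort_keys=False,
        )


_FIXTURE_DIR = Path(__file__).parent / "fixtures"


def fixture_names() -> list[str]:
    return sorted(p.stem for p in _FIXTURE_DIR.glob("*.yaml"))


def load_fixture(name: str) -> tuple[RegulatoryNetwork, KineticParameterSet | None]:
    """Load one of the shipped circuits by name (see :func:`fixture_names`).

    Returns the network and, when the fixture carries a calibrated kinetic
    parameter set, that set (ensemble-only fixtures ship topology only).
    """
    path = _FIXTURE_DIR / f"{name}.yaml"
    if not path.exists():
        raise KeyError(f"unknown fixture {name!r}; available: {fixture_names()}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    network = _network_from_dict(doc["network"])
    params = _params_from_dict(doc["parameters"]) if "parameters" in doc else None
    return network, params
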