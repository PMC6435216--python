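"""Network graphs of cortical sources with typed extrinsic connections.

A network is a set of sources (nodes) at given MNI locations, arranged in
a cortical hierarchy, and a set of directed extrinsic connections typed as
forward, backward or lateral.  Forward connections run up the hierarchy,
backward connections run down it, and lateral connections join sources at
the same level.  Connection type determines which neuronal subpopulations
a connection targets in the neural mass model, so the graph fixes both
the coupling structure and the dimension of the free parameter vector.

Two canonical resting-state networks are built in:

* ``"dmn"`` -- default mode network: bilateral lateral parietal cortex,
  precuneus and medial prefrontal cortex (5 forward, 5 backward,
  2 lateral connections).
* ``"sal"`` -- saliency network: bilateral lateral parietal cortex,
  bilateral anterior prefrontal cortex and dorsal anterior cingulate
  (6 forward, 6 backward, 4 lateral connections).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

EDGE_TYPES = ("forward", "backward", "lateral")

#: number of non-connectivity free parameters that do not scale with the
#: number of sources: shared innovation 1/f exponent amplitude, and the
#: white and 1/f observation-noise log-amplitudes
N_FIXED_GLOBAL = 3


@dataclass(frozen=True)
class Node:
    label: str
    mni: tuple[float, float, float]
    level: int


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    type: str


@dataclass
class NetworkSpec:
    """Sources plus typed directed extrinsic connections.

    Edges are stored grouped by type, forward then backward then lateral;
    this ordering defines the layout of the extrinsic log-gain block of
    the parameter vector.
    """

    nodes: list[Node]
    edges: list[Edge]
    n_modes: int = 0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.n_modes <= 0:
            self.n_modes = len(self.nodes)
        self._validate()
        # canonical ordering: forward, backward, lateral, stable within type
        order = {t: i for i, t in enumerate(EDGE_TYPES)}
        self.edges = sorted(
            self.edges, key=lambda e: (order[e.type], self.node_index(e.source), self.node_index(e.target))
        )

    def _validate(self) -> None:
        labels = [n.label for n in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate node labels")
        seen = set()
        for e in self.edges:
            if e.type not in EDGE_TYPES:
                raise ValueError(f"unknown edge type {e.type!r}")
            if e.source not in labels or e.target not in labels:
                raise ValueError(f"edge {e.source}->{e.target} references an undeclared node")
            if e.source == e.target:
                raise ValueError(f"self-connection on {e.source} (intrinsic coupling is not an edge)")
            key = (e.source, e.target, e.type)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        fwd = {(e.source, e.target) for e in self.edges if e.type == "forward"}
        bwd = {(e.source, e.target) for e in self.edges if e.type == "backward"}
        if {(t, s) for s, t in fwd} != bwd:
            raise ValueError("forward and backward edge sets must be mutually reciprocal")

    # -- bookkeeping -------------------------------------------------------

    def node_index(self, label: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.label == label:
                return i
        raise KeyError(label)

    @property
    def n_sources(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edges_of_type(self, type: str) -> list[Edge]:
        return [e for e in self.edges if e.type == type]

    def edge_counts(self) -> tuple[int, int, int]:
        """(forward, backward, lateral) connection counts."""
        return tuple(len(self.edges_of_type(t)) for t in EDGE_TYPES)

    @property
    def n_params(self) -> int:
        """Dimension B of the free parameter vector.

        One log-gain per extrinsic connection, one innovation
        log-amplitude per source, plus the global spectral/noise
        parameters.
        """
        return self.n_edges + self.n_sources + N_FIXED_GLOBAL

    def param_labels(self) -> list[str]:
        lab = [f"{e.type[0].upper()}:{e.source}->{e.target}" for e in self.edges]
        lab += [f"a0:{n.label}" for n in self.nodes]
        lab += ["a1:shared", "b0:white", "b1:pink"]
        return lab

    def edge_indices(self, type: str) -> list[int]:
        """Positions of a connection type's log-gains in the parameter vector."""
        if type not in EDGE_TYPES:
            raise ValueError(f"unknown edge type {type!r}")
        return [i for i, e in enumerate(self.edges) if e.type == type]

    # -- serialization -----------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "n_modes": self.n_modes,
            "nodes": [{"label": n.label, "mni": list(n.mni), "level": n.level} for n in self.nodes],
            "edges": [{"source": e.source, "target": e.target, "type": e.type} for e in self.edges],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "NetworkSpec":
        doc = yaml.safe_load(text)
        nodes = [Node(d["label"], tuple(d["mni"]), int(d["level"])) for d in doc["nodes"]]
        edges = [Edge(d["source"], d["target"], d["type"]) for d in doc["edges"]]
        return cls(nodes, edges, n_modes=int(doc.get("n_modes", 0)), name=doc.get("name", "custom"))


def _reciprocal_network(
    name: str,
    nodes: list[Node],
    forward: list[tuple[str, str]],
    lateral_pairs: list[tuple[str, str]],
    n_modes: int = 0,
) -> NetworkSpec:
    edges = [Edge(s, t, "forward") for s, t in forward]
    edges += [Edge(t, s, "backward") for s, t in forward]
    for a, b in lateral_pairs:
        edges += [Edge(a, b, "lateral"), Edge(b, a, "lateral")]
    return NetworkSpec(nodes, edges, n_modes=n_modes, name=name)


def dmn_network(n_modes: int = 0) -> NetworkSpec:
    """Default mode network: 4 sources, connection counts (5, 5, 2)."""
    nodes = [
        Node("lLP", (-46.0, -66.0, 30.0), 1),
        Node("rLP", (49.0, -63.0, 33.0), 1),
        Node("Prec", (0.0, -58.0, 0.0), 2),
        Node("mPFC", (-1.0, 54.0, 27.0), 3),
    ]
    forward = [("lLP", "Prec"), ("rLP", "Prec"), ("lLP", "mPFC"), ("rLP", "mPFC"), ("Prec", "mPFC")]
    return _reciprocal_network("dmn", nodes, forward, [("lLP", "rLP")], n_modes)


def sal_network(n_modes: int = 0) -> NetworkSpec:
    """Saliency network: 5 sources, connection counts (6, 6, 4)."""
    nodes = [
        Node("lLP", (-62.0, -45.0, 30.0), 1),
        Node("rLP", (62.0, -45.0, 30.0), 1),
        Node("laPFC", (-35.0, 45.0, 30.0), 2),
        Node("raPFC", (32.0, 45.0, 30.0), 2),
        Node("dACC", (0.0, 21.0, 36.0), 3),
    ]
    forward = [
        ("lLP", "dACC"),
        ("rLP", "dACC"),
        ("lLP", "laPFC"),
        ("rLP", "raPFC"),
        ("laPFC", "dACC"),
        ("raPFC", "dACC"),
    ]
    return _reciprocal_network("sal", nodes, forward, [("lLP", "rLP"), ("laPFC", "raPFC")], n_modes)


def chain_network(n_sources: int = 2, n_modes: int = 0) -> NetworkSpec:
    """A minimal hierarchical chain (forward up, backward down, no lateral).

    The 2-node chain is the standard small test bed for recovery studies.
    """
    if n_sources < 1:
        raise ValueError("need at least one source")
    nodes = [Node(f"S{i + 1}", (0.0, 0.0, 10.0 * i), i + 1) for i in range(n_sources)]
    forward = [(f"S{i + 1}", f"S{i + 2}") for i in range(n_sources - 1)]
    return _reciprocal_network(f"chain{n_sources}", nodes, forward, [], n_modes)


_PRESETS = {"dmn": dmn_network, "sal": sal_network, "chain2": chain_network}


def build_network(preset_or_edges, n_modes: int = 0, nodes: list[Node] | None = None) -> NetworkSpec:
    """Build a :class:`NetworkSpec` from a preset name or an explicit edge list.

    Parameters
    ----------
    preset_or_edges : str or list
        Either a preset name (``"dmn"``, ``"sal"``, ``"chain2"``) or a
        list of ``(source, target, type)`` tuples (requires `nodes`).
    n_modes : int
        Observation mode count; defaults to the number of sources.
    nodes : list of Node
        Node declarations when an explicit edge list is given.
    """
    if isinstance(preset_or_edges, str):
        key = preset_or_edges.lower()
        if key not in _PRESETS:
            raise ValueError(f"unknown network preset {preset_or_edges!r}; known: {sorted(_PRESETS)}")
        return _PRESETS[key](n_modes=n_modes)
    if nodes is None:
        raise ValueError("explicit edge lists require node declarations")
    edges = [Edge(s, t, k) for s, t, k in preset_or_edges]
    return NetworkSpec(nodes, edges, n_modes=n_modes)
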