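"""Cross-omics differential-network assembly, hub calling and export.

Per-omics differential edge sets (JDINAC for expression, LGCDG for the
binary CNV/mutation layers) are combined by keeping gene pairs supported by
at least ``min_layers`` omics layers. Genes with degree >= 3 in the combined
network are called hub genes; hubs recurring across survival-horizon
networks form the hub consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

__all__ = [
    "EdgeSet",
    "DifferentialNetwork",
    "combine_layers",
    "call_hubs",
    "hub_consensus",
    "export_network",
    "read_network",
]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-loop on gene {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class EdgeSet:
    """Weighted undirected gene-pair edges for one omics layer."""

    layer: str
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    horizon_years: float | None = None

    def add(self, gene_a: str, gene_b: str, weight: float = 1.0) -> None:
        if weight < 0:
            raise ValueError("edge weights must be nonnegative")
        self.edges[canonical_pair(gene_a, gene_b)] = float(weight)

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class DifferentialNetwork:
    """Combined cross-omics differential network at one survival horizon."""

    edges: dict[tuple[str, str], list[str]]  # pair -> supporting layers
    weights: dict[tuple[str, str], dict[str, float]]  # pair -> layer -> weight
    horizon_years: float | None = None

    def nodes(self) -> list[str]:
        out: set[str] = set()
        for a, b in self.edges:
            out.add(a)
            out.add(b)
        return sorted(out)

    def degree(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for a, b in self.edges:
            deg[a] = deg.get(a, 0) + 1
            deg[b] = deg.get(b, 0) + 1
        return deg

    def __len__(self) -> int:
        return len(self.edges)


def combine_layers(edge_sets: list[EdgeSet], min_layers: int = 2) -> DifferentialNetwork:
    """Keep gene pairs present in at least ``min_layers`` omics layers.

    Order-invariant in its layer arguments; supporting layers are recorded
    (sorted) per retained edge, with per-layer weights kept as attributes.
    """
    if len(edge_sets) < min_layers:
        raise ValueError(
            f"{len(edge_sets)} layers supplied but min_layers={min_layers}"
        )
    support: dict[tuple[str, str], list[str]] = {}
    weights: dict[tuple[str, str], dict[str, float]] = {}
    for es in sorted(edge_sets, key=lambda e: e.layer):
        for pair, w in es.edges.items():
            support.setdefault(pair, []).append(es.layer)
            weights.setdefault(pair, {})[es.layer] = w
    kept = {p: layers for p, layers in support.items() if len(layers) >= min_layers}
    horizons = {es.horizon_years for es in edge_sets}
    return DifferentialNetwork(
        edges={p: sorted(kept[p]) for p in sorted(kept)},
        weights={p: weights[p] for p in sorted(kept)},
        horizon_years=horizons.pop() if len(horizons) == 1 else None,
    )


def call_hubs(network: DifferentialNetwork, hub_degree: int = 3) -> list[str]:
    """Genes with degree >= ``hub_degree`` in the combined network."""
    deg = network.degree()
    return sorted(g for g, d in deg.items() if d >= hub_degree)


def hub_consensus(
    hubs_by_horizon: dict[float, list[str]], min_networks: int = 2
) -> dict[str, list[float]]:
    """Hub genes appearing in >= ``min_networks`` horizon networks.

    Returns each consensus gene with the (sorted) horizons it was a hub in.
    """
    seen: dict[str, list[float]] = {}
    for t in sorted(hubs_by_horizon):
        for g in hubs_by_horizon[t]:
            seen.setdefault(g, []).append(t)
    return {g: ts for g, ts in sorted(seen.items()) if len(ts) >= min_networks}


def _to_graph(network: DifferentialNetwork) -> nx.Graph:
    g = nx.Graph()
    for (a, b), layers in network.edges.items():
        attrs = {"layers": ",".join(layers)}
        for layer, w in network.weights.get((a, b), {}).items():
            attrs[f"weight_{layer}"] = float(w)
        g.add_edge(a, b, **attrs)
    return g


def export_network(network: DifferentialNetwork, path: str | Path, fmt: str = "graphml") -> Path:
    """Write the network as GraphML or SIF (Cytoscape-ingestible)."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(_to_graph(network), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for (a, b), layers in sorted(network.edges.items()):
                fh.write(f"{a}\t{'|'.join(layers)}\t{b}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'graphml' or 'sif'")
    return path


def read_network(path: str | Path, fmt: str = "graphml") -> DifferentialNetwork:
    """Round-trip reader for :func:`export_network` output."""
    path = Path(path)
    edges: dict[tuple[str, str], list[str]] = {}
    weights: dict[tuple[str, str], dict[str, float]] = {}
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for a, b, data in g.edges(data=True):
            pair = canonical_pair(str(a), str(b))
            edges[pair] = data.get("layers", "").split(",") if data.get("layers") else []
            weights[pair] = {
                k[len("weight_"):]: float(v)
                for k, v in data.items()
                if k.startswith("weight_")
            }
    elif fmt == "sif":
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    continue
                a, rel, b = parts
                pair = canonical_pair(a, b)
                edges[pair] = rel.split("|")
                weights[pair] = {}
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return DifferentialNetwork(
        edges=dict(sorted(edges.items())), weights=weights
    )
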