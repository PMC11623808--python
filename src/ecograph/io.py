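"""Graph and configuration I/O.

Graphs are exchanged as plain whitespace-delimited edge lists ("u v" per
line, 0-based integer labels, written sorted) or GraphML.  Reading
canonicalises labels to contiguous 0-based integers and enforces the
population-graph invariants (simple, undirected, connected); the original-
label mapping is available on the returned graph.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import yaml

from .graphs import PopulationGraph

__all__ = ["read_graph", "write_graph", "load_config", "GraphParseError"]


class GraphParseError(ValueError):
    """Malformed graph file; carries the offending line number when known."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix.lower() in {".graphml", ".xml"}:
        return "graphml"
    return "edgelist"


def read_graph(path, fmt: str | None = None) -> PopulationGraph:
    """Read an edge list or GraphML file into a :class:`PopulationGraph`."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        g = nx.Graph(g)  # drop potential multi-edge/directed wrappers
        try:
            return PopulationGraph(g)
        except ValueError as e:
            raise GraphParseError(f"{path}: {e}") from e
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise GraphParseError(f"{path}:{lineno}: expected 'u v', got {line!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as e:
                raise GraphParseError(
                    f"{path}:{lineno}: node labels must be integers"
                ) from e
            if u == v:
                raise GraphParseError(f"{path}:{lineno}: self-loop {u}-{v} rejected")
            g.add_edge(u, v)
    try:
        return PopulationGraph(g)
    except ValueError as e:
        raise GraphParseError(f"{path}: {e}") from e


def write_graph(graph: PopulationGraph, path, fmt: str | None = None) -> None:
    """Write a graph as a sorted 0-based edge list or GraphML."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "graphml":
        nx.write_graphml(graph.nx_graph, path)
        return
    with open(path, "w") as fh:
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")


def load_config(path) -> dict:
    """Load a YAML or JSON parameter mapping ({N, s, alpha, supply, D, ...})."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)
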