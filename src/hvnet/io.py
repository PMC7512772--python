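"""Edge-list I/O and run configuration.

Reads SNAP-dialect edge lists ('#' comment lines, two whitespace-separated
integer node ids per line) and the weighted "i j w" dialect this package
writes.  Graphs are symmetrized, de-duplicated, stripped of self-loops, and
relabelled to a dense 1..N index; the original ids are kept in the graph
attribute ``id_map`` (new label -> original id).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import networkx as nx
import pandas as pd
import yaml

__all__ = ["read_edge_list", "write_edge_list", "RunConfig"]


class EdgeListError(ValueError):
    pass


def _scan_for_bad_line(path, n_fields_ok) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split()
            if len(parts) not in n_fields_ok or not all(
                p.lstrip("-").isdigit() for p in parts[:2]
            ):
                raise EdgeListError(f"{path}: malformed line {lineno}: {stripped!r}")


def read_edge_list(path, dialect: str = "snap") -> nx.Graph:
    """Read an edge list as an undirected simple graph with dense labels 1..N.

    Directed duplicates collapse to one undirected edge, self-loops are
    dropped, and '#' lines are ignored.  ``dialect='weighted'`` accepts an
    optional third column (the multiedge weight), stored as edge attribute
    ``weight``.
    """
    n_fields = {2, 3} if dialect == "weighted" else {2}
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         dtype=np.int64)
    except Exception:
        _scan_for_bad_line(path, n_fields)
        raise EdgeListError(f"{path}: unreadable edge list")
    if df.empty:
        raise EdgeListError(f"{path}: no edges found")
    if df.shape[1] not in n_fields:
        _scan_for_bad_line(path, n_fields)
        raise EdgeListError(f"{path}: expected {sorted(n_fields)} columns")
    src, dst = df[0].to_numpy(), df[1].to_numpy()
    if np.any(src < 0) or np.any(dst < 0):
        raise EdgeListError(f"{path}: negative node ids")

    original_ids = np.unique(np.concatenate([src, dst]))
    dense = {orig: new for new, orig in enumerate(original_ids, start=1)}
    graph = nx.Graph()
    graph.add_nodes_from(range(1, len(original_ids) + 1))
    has_w = dialect == "weighted" and df.shape[1] == 3
    for row in range(len(df)):
        a, b = dense[src[row]], dense[dst[row]]
        if a == b:
            continue
        if has_w:
            w = int(df[2].iloc[row])
            graph.add_edge(a, b, weight=graph.edges.get((a, b), {}).get("weight", 0) + w)
        else:
            graph.add_edge(a, b)
    if graph.number_of_edges() == 0:
        raise EdgeListError(f"{path}: no valid edges after cleaning")
    graph.graph["id_map"] = {new: int(orig) for orig, new in dense.items()}
    return graph


def write_edge_list(graph: nx.Graph, path, header: dict | None = None) -> None:
    """Write a graph in SNAP dialect, with metadata in '#' header lines."""
    with open(path, "w") as fh:
        fh.write(f"# hvnet edge list N={graph.number_of_nodes()} "
                 f"L={graph.number_of_edges()}\n")
        if header:
            for key, val in header.items():
                fh.write(f"# {key}={val}\n")
        for i, j in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{i} {j}\n")


@dataclass
class RunConfig:
    """Configuration of one CLI run; the seed is recorded in every output."""

    command: str = "simulate"
    family: str = "bounded_power_law"
    gamma: float = 2.5
    theta_min: float = 1.0
    theta_max: float = 100.0
    n: int = 1000
    seed: int = 0
    subsample_fraction: float = 1.0
    output: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)
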