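"""Edge-list I/O, experiment configuration, and result serialisation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import networkx as nx
import numpy as np

from .errors import ParameterError

__all__ = [
    "read_edgelist",
    "write_edgelist",
    "ExperimentConfig",
    "config_hash",
]

log = logging.getLogger("motifresponse")


def read_edgelist(path: str | Path, one_based: bool = False) -> tuple[nx.Graph, dict[int, int]]:
    """Read a two-column integer TSV edge list.

    Lines starting with ``#`` are comments.  Node ids are normalised to
    contiguous 0-based integers; the returned mapping sends each new id to
    the original one.  Duplicate rows and self-loops are dropped (counts
    are logged).
    """
    path = Path(path)
    edges: list[tuple[int, int]] = []
    dupes = loops = 0
    seen: set[frozenset] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if len(parts) < 2:
                raise ParameterError(f"{path}:{lineno}: expected two columns, got {s!r}")
            try:
                u, v = int(parts[0]), int(parts[1])
            except ValueError as exc:
                raise ParameterError(f"{path}:{lineno}: non-integer token in {s!r}") from exc
            if one_based:
                u, v = u - 1, v - 1
            if u == v:
                loops += 1
                continue
            key = frozenset((u, v))
            if key in seen:
                dupes += 1
                continue
            seen.add(key)
            edges.append((u, v))
    if dupes or loops:
        log.info("read_edgelist: dropped %d duplicate rows, %d self-loops", dupes, loops)
    ids = sorted({u for e in edges for u in e})
    remap = {orig: new for new, orig in enumerate(ids)}
    G = nx.Graph()
    G.add_nodes_from(range(len(ids)))
    G.add_edges_from((remap[u], remap[v]) for u, v in edges)
    return G, {new: orig for orig, new in remap.items()}


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    """Write a graph as a two-column 0-based TSV edge list."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in sorted(tuple(sorted(e)) for e in G.edges()):
            fh.write(f"{u}\t{v}\n")


@dataclass
class ExperimentConfig:
    """Fully serialisable description of one perturbation experiment."""

    model: str
    params: dict[str, float]
    topology: dict[str, Any]  # {"generator": name, "args": {...}} or {"path": ...}
    source: int = 0
    epsilon: float = 0.01
    eta: float = 0.5
    seed: int = 0
    label: str = ""
    extras: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ExperimentConfig":
        return cls(**dict(d))

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable hash of a config; identical configs byte-reproduce outputs."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def dump_json(obj: Any, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))
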