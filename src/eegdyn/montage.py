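"""Built-in 32-channel 10-20 montage and electrode adjacency graphs.

The montage mirrors a standard 32-channel actiCAP/EasyCap label set.  The
2-D positions are a schematic head-disc layout (nose up, +x right, unit
head radius) with near-uniform nearest-neighbor spacing, chosen so that
the distance-threshold adjacency rule produces a sensible neighborhood
structure (midline neighbors such as Fz-Cz are adjacent; electrodes on
opposite ends of the scalp are not).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# Schematic 2-D positions on the unit head disc.
_COORDS_32: dict[str, tuple[float, float]] = {
    "Fp1": (-0.20, 0.93), "Fp2": (0.20, 0.93),
    "F7": (-0.65, 0.70), "F3": (-0.28, 0.62), "Fz": (0.0, 0.38),
    "F4": (0.28, 0.62), "F8": (0.65, 0.70),
    "FT9": (-0.95, 0.38), "FC5": (-0.60, 0.30), "FC1": (-0.27, 0.27),
    "FC2": (0.27, 0.27), "FC6": (0.60, 0.30), "FT10": (0.95, 0.38),
    "T7": (-0.92, 0.0), "C3": (-0.38, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.38, 0.0), "T8": (0.92, 0.0),
    "TP9": (-0.95, -0.38), "CP5": (-0.60, -0.30), "CP1": (-0.27, -0.27),
    "CP2": (0.27, -0.27), "CP6": (0.60, -0.30), "TP10": (0.95, -0.38),
    "P7": (-0.65, -0.70), "P3": (-0.28, -0.60), "Pz": (0.0, -0.38),
    "P4": (0.28, -0.60), "P8": (0.65, -0.70),
    "O1": (-0.31, -0.90), "Oz": (0.0, -0.88), "O2": (0.31, -0.90),
}

MONTAGE_32_LABELS = tuple(_COORDS_32)

#: electrodes on the very outer rim of the cap (barely over the scalp)
RIM_ELECTRODES = frozenset(
    ["Fp1", "Fp2", "F7", "F8", "FT9", "FT10", "TP9", "TP10", "T7", "T8"]
)

_KNOWN_MONTAGES = ("standard-32", "easycap-32")


def montage_positions(montage_name: str = "standard-32") -> dict[str, tuple[float, float]]:
    """Return 2-D electrode positions for a built-in montage."""
    if montage_name not in _KNOWN_MONTAGES:
        raise ValueError(f"unknown montage: {montage_name!r}")
    return dict(_COORDS_32)


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected electrode-neighborhood graph keyed by channel label.

    Edges are stored as frozensets of two labels, so the graph is
    symmetric by construction and independent of label order.
    """

    nodes: tuple[str, ...]
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        edges = set()
        for e in self.edges:
            a, b = tuple(e) if isinstance(e, frozenset) else e
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            edges.add(frozenset((a, b)))
        object.__setattr__(self, "edges", frozenset(edges))

    def neighbors(self, label: str) -> set[str]:
        return self.neighbor_map()[label]

    def neighbor_map(self) -> dict[str, set[str]]:
        nm: dict[str, set[str]] = {n: set() for n in self.nodes}
        for e in self.edges:
            a, b = tuple(e)
            nm[a].add(b)
            nm[b].add(a)
        return nm

    def is_adjacent(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def subgraph(self, labels) -> "AdjacencyGraph":
        keep = set(labels)
        edges = frozenset(e for e in self.edges if set(e) <= keep)
        return AdjacencyGraph(tuple(labels), edges)


def default_adjacency(
    montage_name: str = "standard-32", threshold_factor: float = 1.3
) -> AdjacencyGraph:
    """Distance-rule adjacency for a built-in montage.

    Two electrodes are neighbors when their 2-D distance is below
    ``threshold_factor`` times the median nearest-neighbor distance of
    the layout.
    """
    pos = montage_positions(montage_name)
    labels = list(pos)
    xy = np.array([pos[lab] for lab in labels])
    d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    thresh = threshold_factor * float(np.median(d.min(axis=1)))
    edges = set()
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < thresh:
                edges.add(frozenset((labels[i], labels[j])))
    return AdjacencyGraph(tuple(labels), frozenset(edges))


def read_adjacency(path, labels) -> AdjacencyGraph:
    """Read a two-column TSV edge list, restrict to *labels*, symmetrize.

    Raises ``ValueError`` if an edge names a label not in *labels*.  An
    empty file yields an empty edge set (with a logged warning).
    """
    known = set(labels)
    edges = set()
    n_rows = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{ln}: expected two tab-separated labels")
            a, b = parts[0].strip(), parts[1].strip()
            if ln == 1 and (a.lower(), b.lower()) in {("source", "target"), ("a", "b")}:
                continue
            for lab in (a, b):
                if lab not in known:
                    raise ValueError(f"{path}:{ln}: unknown electrode label {lab!r}")
            if a != b:
                edges.add(frozenset((a, b)))
            n_rows += 1
    if n_rows == 0:
        logger.warning("adjacency file %s contains no edges", path)
    return AdjacencyGraph(tuple(labels), frozenset(edges))


def write_adjacency(graph: AdjacencyGraph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")
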