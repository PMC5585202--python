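"""Data model and file I/O for anatomical networks.

An anatomical network represents the parts of a musculoskeletal system
(bones and muscles) as nodes and their physical contacts (articulations,
muscle attachments) as links.  Networks are simple, undirected and
unweighted: a contact is present or absent, nothing more.  On disk they
are coded as square binary adjacency matrices (CSV, labels in the first
row and first column) or as two-column edge lists.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "Tissue",
    "AnatomicalNode",
    "AnatomicalNetwork",
    "NetworkValidationError",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "read_edge_list",
    "write_edge_list",
    "read_tissue_map",
    "write_graphml",
    "degree_sequence",
    "is_connected",
]


class NetworkValidationError(ValueError):
    """Raised when an input violates the anatomical-network contract."""


class Tissue(str, Enum):
    """Tissue class of an anatomical node."""

    BONE = "bone"
    MUSCLE = "muscle"
    UNKNOWN = "unknown"


# Label prefixes that encode the tissue class directly in the node id,
# e.g. "bone:humerus".  The prefix is part of the id (ids stay unique even
# if a bone and a muscle share a bare name).
_TISSUE_PREFIXES = {"bone": Tissue.BONE, "muscle": Tissue.MUSCLE}


@dataclass(frozen=True)
class AnatomicalNode:
    """A single anatomical part.

    Parameters
    ----------
    id : str
        Unique, non-empty label within a network.
    tissue : Tissue
        ``bone`` or ``muscle``; ``unknown`` when the input carries no
        tissue annotation.
    region : str, optional
        Free-text anatomical region tag (e.g. ``"forearm"``).
    """

    id: str
    tissue: Tissue = Tissue.UNKNOWN
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.id or not self.id.strip():
            raise NetworkValidationError("node id must be a non-empty string")


def _infer_tissue(label: str, tissue_map: Mapping[str, Tissue | str] | None) -> Tissue:
    if tissue_map is not None:
        for key in (label, label.strip(), label.strip().lower()):
            if key in tissue_map:
                return Tissue(tissue_map[key])
    prefix, _, rest = label.partition(":")
    if rest and prefix.strip().lower() in _TISSUE_PREFIXES:
        return _TISSUE_PREFIXES[prefix.strip().lower()]
    return Tissue.UNKNOWN


@dataclass
class AnatomicalNetwork:
    """Simple undirected binary graph of typed anatomical nodes.

    Edges are stored as a canonical sorted set of unordered id pairs so
    equality and hashing are independent of insertion order; node order is
    preserved separately because file round-trips keep it.
    """

    nodes: list[AnatomicalNode]
    edges: set[tuple[str, str]] = field(default_factory=set)
    name: str = ""

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise NetworkValidationError(f"duplicate node labels: {sorted(dupes)}")
        known = set(ids)
        canonical: set[tuple[str, str]] = set()
        for a, b in self.edges:
            if a == b:
                raise NetworkValidationError(f"self-loop on node {a!r}")
            if a not in known or b not in known:
                missing = a if a not in known else b
                raise NetworkValidationError(f"edge endpoint {missing!r} is not a node")
            canonical.add((a, b) if a < b else (b, a))
        self.edges = canonical

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> AnatomicalNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def has_edge(self, a: str, b: str) -> bool:
        return ((a, b) if a < b else (b, a)) in self.edges

    def degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if node_id in e)

    def neighbors(self, node_id: str) -> set[str]:
        out = set()
        for a, b in self.edges:
            if a == node_id:
                out.add(b)
            elif b == node_id:
                out.add(a)
        return out

    def tissues(self) -> dict[str, Tissue]:
        return {n.id: n.tissue for n in self.nodes}

    def to_networkx(self) -> nx.Graph:
        """Export as a :class:`networkx.Graph` (node order preserved)."""
        g = nx.Graph(name=self.name)
        for n in self.nodes:
            g.add_node(n.id, tissue=n.tissue.value, region=n.region or "")
        g.add_edges_from(sorted(self.edges))
        return g

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return self.node_ids == other.node_ids and self.edges == other.edges

    def __hash__(self) -> int:
        return hash((tuple(self.node_ids), tuple(sorted(self.edges))))


# ---------------------------------------------------------------------------
# adjacency-matrix CSV dialect
# ---------------------------------------------------------------------------

def read_adjacency_csv(
    path: str | Path | io.TextIOBase,
    tissue_map: Mapping[str, Tissue | str] | None = None,
    name: str | None = None,
) -> AnatomicalNetwork:
    """Read a binary adjacency matrix CSV into a network.

    The first row and first column hold node labels (the top-left cell is
    ignored); every other cell must be 0 or 1, the matrix must be square
    and symmetric, and the diagonal must be all zero (a part is never in
    contact with itself).  Labels are stripped of surrounding whitespace;
    tissue classes come from ``tissue_map`` or a ``bone:``/``muscle:``
    label prefix, defaulting to ``unknown``.

    Raises
    ------
    NetworkValidationError
        Non-square matrix, asymmetric cell, non-binary cell, nonzero
        diagonal or duplicate label — each message names the offending
        cell or label.
    """
    if isinstance(path, (str, Path)):
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.reader(fh))
        default_name = Path(path).stem
    else:
        rows = list(csv.reader(path))
        default_name = ""
    rows = [r for r in rows if any(c.strip() for c in r)]
    if not rows:
        raise NetworkValidationError("empty adjacency file")

    header = [c.strip() for c in rows[0][1:]]
    n = len(header)
    if len(rows) - 1 != n:
        raise NetworkValidationError(
            f"matrix is not square: {n} columns but {len(rows) - 1} data rows"
        )
    dupes = {h for h in header if header.count(h) > 1}
    if dupes:
        raise NetworkValidationError(f"duplicate labels: {sorted(dupes)}")

    cells = [[0] * n for _ in range(n)]
    for i, row in enumerate(rows[1:]):
        row_label = row[0].strip()
        if row_label != header[i]:
            raise NetworkValidationError(
                f"row label {row_label!r} at row {i + 1} does not match "
                f"column label {header[i]!r}"
            )
        if len(row) - 1 != n:
            raise NetworkValidationError(
                f"row {row_label!r} has {len(row) - 1} cells, expected {n}"
            )
        for j, raw in enumerate(row[1:]):
            val = raw.strip()
            if val not in ("0", "1"):
                raise NetworkValidationError(
                    f"non-binary cell ({row_label}, {header[j]}): {raw!r}"
                )
            cells[i][j] = int(val)

    edges: set[tuple[str, str]] = set()
    for i in range(n):
        if cells[i][i] != 0:
            raise NetworkValidationError(
                f"nonzero diagonal at ({header[i]}, {header[i]})"
            )
        for j in range(i + 1, n):
            if cells[i][j] != cells[j][i]:
                raise NetworkValidationError(
                    f"asymmetric matrix: cell ({header[i]}, {header[j]})="
                    f"{cells[i][j]} but ({header[j]}, {header[i]})={cells[j][i]}"
                )
            if cells[i][j]:
                edges.add((header[i], header[j]))

    nodes = [AnatomicalNode(h, _infer_tissue(h, tissue_map)) for h in header]
    return AnatomicalNetwork(nodes, edges, name=name if name is not None else default_name)


def write_adjacency_csv(net: AnatomicalNetwork, path: str | Path | io.TextIOBase) -> None:
    """Write the network as an adjacency matrix CSV (round-trips exactly)."""
    ids = net.node_ids
    index = {v: i for i, v in enumerate(ids)}
    n = len(ids)
    cells = [[0] * n for _ in range(n)]
    for a, b in net.edges:
        i, j = index[a], index[b]
        cells[i][j] = cells[j][i] = 1

    def _dump(fh) -> None:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow([""] + ids)
        for i, label in enumerate(ids):
            writer.writerow([label] + cells[i])

    if isinstance(path, (str, Path)):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            _dump(fh)
    else:
        _dump(path)


# ---------------------------------------------------------------------------
# edge lists and side-cars
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path | io.TextIOBase,
    tissue_map: Mapping[str, Tissue | str] | None = None,
    name: str | None = None,
) -> AnatomicalNetwork:
    """Read a two-column delimited edge list (tab or comma separated).

    A third column, if present, is ignored.  Duplicate pairs — in either
    orientation — collapse to one undirected edge.  Self-loop rows and
    blank node ids are rejected.
    """
    if isinstance(path, (str, Path)):
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
        default_name = Path(path).stem
    else:
        lines = path.read().splitlines()
        default_name = ""

    order: list[str] = []
    seen: set[str] = set()
    edges: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise NetworkValidationError(f"line {lineno}: expected two node ids, got {line!r}")
        a, b = parts[0], parts[1]
        if a == b:
            raise NetworkValidationError(f"line {lineno}: self-loop on {a!r}")
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                order.append(v)
        edges.add((a, b) if a < b else (b, a))

    nodes = [AnatomicalNode(v, _infer_tissue(v, tissue_map)) for v in order]
    return AnatomicalNetwork(nodes, edges, name=name if name is not None else default_name)


def write_edge_list(net: AnatomicalNetwork, path: str | Path | io.TextIOBase) -> None:
    """Write edges as a two-column TSV, sorted for byte stability."""
    text = "".join(f"{a}\t{b}\n" for a, b in net.sorted_edges())
    if isinstance(path, (str, Path)):
        Path(path).write_text(text, encoding="utf-8")
    else:
        path.write(text)


def read_tissue_map(path: str | Path) -> dict[str, Tissue]:
    """Read a two-column side-car CSV of node id → tissue class."""
    out: dict[str, Tissue] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            label = row[0].strip()
            if label.lower() in ("id", "node", "label"):  # header row
                continue
            if len(row) < 2:
                raise NetworkValidationError(f"tissue map row for {label!r} lacks a class")
            out[label] = Tissue(row[1].strip().lower())
    return out


def write_graphml(net: AnatomicalNetwork, path: str | Path) -> None:
    """Export to GraphML for external visualization tools."""
    nx.write_graphml(net.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# elementary structural queries
# ---------------------------------------------------------------------------

def degree_sequence(net: AnatomicalNetwork) -> list[tuple[str, int]]:
    """Per-node link counts, in node order; sums to twice the link count."""
    counts = {v: 0 for v in net.node_ids}
    for a, b in net.edges:
        counts[a] += 1
        counts[b] += 1
    return [(v, counts[v]) for v in net.node_ids]


def is_connected(net: AnatomicalNetwork) -> tuple[bool, list[int]]:
    """Whether one component spans all nodes, plus component sizes.

    Returns ``(True, [N])`` for a connected network, otherwise
    ``(False, sizes)`` with component sizes in descending order.
    """
    if net.n_nodes == 0:
        return True, [0]
    g = net.to_networkx()
    sizes = sorted((len(c) for c in nx.connected_components(g)), reverse=True)
    return len(sizes) == 1, sizes
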