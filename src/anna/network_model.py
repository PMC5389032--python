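"""Typed data model for anatomical networks.

An anatomical network represents the musculoskeletal system of a body part as a
simple undirected graph: nodes are anatomical units (bones, cartilages, muscles)
and edges are their physical contacts (sutures, synchondroses, synovial joints,
muscle fiber fusions, tendinous attachments).  The module ships the 181-unit
registry of the adult human head together with the published 10-module reference
partition, plus delimited-text and GraphML readers/writers.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

TISSUE_CLASSES = frozenset({"bone", "cartilage", "muscle"})
SIDES = frozenset({"left", "right", "median"})
CONTACT_TYPES = frozenset(
    {"suture", "synchondrosis", "synovial", "muscle_fusion", "tendon",
     "attachment", "unspecified"}
)

#: tissue classes forming the skeletal subnetwork
SKELETAL_CLASSES = frozenset({"bone", "cartilage"})
#: tissue classes forming the muscular subnetwork
MUSCULAR_CLASSES = frozenset({"muscle"})


class InputError(ValueError):
    """A malformed or inconsistent input table."""


@dataclass(frozen=True)
class NodeRecord:
    """One anatomical unit: a bone, cartilage, or muscle, with body side."""

    node_id: int
    name: str
    tissue_class: str
    side: str

    def __post_init__(self) -> None:
        if self.node_id <= 0:
            raise InputError(f"node_id must be positive, got {self.node_id}")
        if self.tissue_class not in TISSUE_CLASSES:
            raise InputError(
                f"unknown tissue_class {self.tissue_class!r} for node {self.node_id}"
            )
        if self.side not in SIDES:
            raise InputError(f"unknown side {self.side!r} for node {self.node_id}")


@dataclass(frozen=True)
class ConnectionRecord:
    """One physical contact between two distinct anatomical units."""

    node_a: int
    node_b: int
    contact_type: str = "unspecified"

    def __post_init__(self) -> None:
        if self.node_a == self.node_b:
            raise InputError(f"self-loop on node {self.node_a} is not allowed")
        if self.contact_type not in CONTACT_TYPES:
            raise InputError(f"unknown contact_type {self.contact_type!r}")

    @property
    def pair(self) -> tuple[int, int]:
        """The unordered endpoint pair in canonical (sorted) order."""
        a, b = self.node_a, self.node_b
        return (a, b) if a < b else (b, a)


class AnatomicalNetwork:
    """Simple undirected, unweighted graph of anatomical units with typed contacts.

    Backed by a :class:`networkx.Graph`; node attributes hold the
    :class:`NodeRecord` fields, edge attribute ``contact_type`` the contact kind.
    Isolated nodes (units with no contact in the chosen tissue subset) are kept.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()

    # -- basic queries -----------------------------------------------------
    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def node_record(self, node_id: int) -> NodeRecord:
        d = self.graph.nodes[node_id]
        return NodeRecord(node_id, d["name"], d["tissue_class"], d["side"])

    def node_records(self) -> list[NodeRecord]:
        return [self.node_record(i) for i in self.node_ids]

    def connection_records(self) -> list[ConnectionRecord]:
        recs = [
            ConnectionRecord(min(a, b), max(a, b), d.get("contact_type", "unspecified"))
            for a, b, d in self.graph.edges(data=True)
        ]
        return sorted(recs, key=lambda r: r.pair)

    def isolates(self) -> set[int]:
        """Degree-zero units, e.g. muscles with no muscle-muscle contact."""
        return set(nx.isolates(self.graph))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnatomicalNetwork):
            return NotImplemented
        return (
            self.node_records() == other.node_records()
            and self.connection_records() == other.connection_records()
        )


@dataclass
class ReferencePartition:
    """A published node -> module assignment, with multiply-listed nodes flagged.

    ``assignments`` maps every unambiguous node to one module label; nodes the
    source table lists under more than one module go to ``ambiguous_nodes``
    instead, since a hard partition cannot honor a double listing.
    """

    assignments: dict[int, int]
    ambiguous_nodes: set[int] = field(default_factory=set)

    def covered_nodes(self) -> set[int]:
        return set(self.assignments) | set(self.ambiguous_nodes)

    def module_members(self) -> dict[int, set[int]]:
        out: dict[int, set[int]] = {}
        for node, mod in self.assignments.items():
            out.setdefault(mod, set()).add(node)
        return out


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _open_rows(path_or_buf, delimiter: str):
    if hasattr(path_or_buf, "read"):
        return csv.reader(path_or_buf, delimiter=delimiter)
    fh = open(path_or_buf, newline="")
    return csv.reader(fh, delimiter=delimiter)


def _clean_rows(reader) -> Iterable[list[str]]:
    for row in reader:
        if not row or (row[0].lstrip().startswith("#")):
            continue
        yield [c.strip() for c in row]


def load_nodes(path, delimiter: str = ",") -> list[NodeRecord]:
    """Read a node table (header ``node_id,name,tissue_class,side``).

    Lines starting with ``#`` are comments.  Raises :class:`InputError` on a
    missing/duplicate id or an unknown tissue class or side, naming the row.
    """
    rows = list(_clean_rows(_open_rows(path, delimiter)))
    if not rows:
        raise InputError(f"node table {path} is empty")
    header = [h.lower() for h in rows[0]]
    required = ["node_id", "name", "tissue_class", "side"]
    if not set(required) <= set(header):
        raise InputError(f"node table header must name {required}, got {header}")
    idx = {k: header.index(k) for k in required}
    records: list[NodeRecord] = []
    seen: set[int] = set()
    for row in rows[1:]:
        try:
            nid = int(row[idx["node_id"]])
        except (ValueError, IndexError) as exc:
            raise InputError(f"bad node row {row!r}: {exc}") from None
        if nid in seen:
            raise InputError(f"duplicate node_id {nid} in node table")
        seen.add(nid)
        try:
            records.append(
                NodeRecord(nid, row[idx["name"]], row[idx["tissue_class"]],
                           row[idx["side"]])
            )
        except InputError as exc:
            raise InputError(f"row for node {nid}: {exc}") from None
    return records


def load_edges(path, delimiter: str = ",") -> list[ConnectionRecord]:
    """Read an edge table (``node_a,node_b[,contact_type]``; header optional contact).

    A missing third column becomes ``unspecified``.  Duplicate unordered pairs
    collapse to one record with a warning (hand-curated anatomical tables often
    repeat contacts); a self-loop row is an error.
    """
    rows = list(_clean_rows(_open_rows(path, delimiter)))
    if not rows:
        raise InputError(f"edge table {path} is empty")
    start = 1 if not rows[0][0].lstrip("-").isdigit() else 0  # tolerate headerless
    records: dict[tuple[int, int], ConnectionRecord] = {}
    for row in rows[start:]:
        if len(row) < 2:
            raise InputError(f"edge row {row!r} needs two endpoint ids")
        try:
            a, b = int(row[0]), int(row[1])
        except ValueError as exc:
            raise InputError(f"bad edge row {row!r}: {exc}") from None
        ctype = row[2] if len(row) > 2 and row[2] else "unspecified"
        rec = ConnectionRecord(a, b, ctype)
        if rec.pair in records:
            warnings.warn(
                f"duplicate contact {rec.pair} collapsed to a single edge",
                stacklevel=2,
            )
            logger.warning("duplicate contact %s collapsed", rec.pair)
            continue
        records[rec.pair] = rec
    return [records[k] for k in sorted(records)]


def build_network(
    nodes: Iterable[NodeRecord], edges: Iterable[ConnectionRecord]
) -> AnatomicalNetwork:
    """Assemble an :class:`AnatomicalNetwork`, validating edge endpoints."""
    g = nx.Graph()
    for rec in nodes:
        if rec.node_id in g:
            raise InputError(f"duplicate node_id {rec.node_id}")
        g.add_node(rec.node_id, name=rec.name, tissue_class=rec.tissue_class,
                   side=rec.side)
    for rec in edges:
        for endpoint in (rec.node_a, rec.node_b):
            if endpoint not in g:
                raise InputError(f"edge {rec.pair} references unknown node id {endpoint}")
        g.add_edge(rec.node_a, rec.node_b, contact_type=rec.contact_type)
    return AnatomicalNetwork(g)


# ---------------------------------------------------------------------------
# packaged head data
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("anna.data").joinpath(name)


def load_head_registry() -> list[NodeRecord]:
    """The packaged 181-unit head registry (45 bones/cartilages + 136 muscles)."""
    with _data_path("head_nodes.csv").open() as fh:
        return load_nodes(fh)


def load_head_edges(path: str | Path | None = None) -> list[ConnectionRecord]:
    """Load the head contact (edge) table.

    The published contact list is distributed as the source article's
    supplementary information and is not redistributed inside this package.
    Pass the path to a transcription of it (``node_a,node_b[,contact_type]``),
    or drop it into the package data directory as ``head_edges.csv``.
    """
    if path is None:
        candidate = _data_path("head_edges.csv")
        if not candidate.is_file():
            raise FileNotFoundError(
                "head contact table not packaged: supply a transcription of the "
                "published supplementary edge list, either as an explicit path or "
                "as anna/data/head_edges.csv"
            )
        with candidate.open() as fh:
            return load_edges(fh)
    return load_edges(path)


def load_reference_partition() -> ReferencePartition:
    """The packaged 10-module reference decomposition of the head registry.

    Paired units printed without a side in modules 1-4 are expanded to both
    sides in the same module; modules 5-10 keep their printed left/right split.
    The hyoid bone is flagged ambiguous (printed under two modules).
    """
    assignments: dict[int, int] = {}
    ambiguous: set[int] = set()
    with _data_path("table1_partition.csv").open() as fh:
        rows = list(_clean_rows(csv.reader(fh)))
    header = rows[0]
    idx = {k: header.index(k) for k in ("node_id", "module_id", "ambiguous")}
    for row in rows[1:]:
        nid = int(row[idx["node_id"]])
        if int(row[idx["ambiguous"]]):
            ambiguous.add(nid)
        else:
            assignments[nid] = int(row[idx["module_id"]])
    return ReferencePartition(assignments, ambiguous)


# ---------------------------------------------------------------------------
# subsetting and writers
# ---------------------------------------------------------------------------

def subset_by_tissue(
    network: AnatomicalNetwork, classes: Iterable[str]
) -> AnatomicalNetwork:
    """Induced subnetwork on the given tissue classes.

    Edges survive only if both endpoints survive; nodes left without any
    contact stay in as isolates (in the muscular network most muscles attach
    only to bone, so they become isolated when bones are removed).
    """
    classes = set(classes)
    unknown = classes - TISSUE_CLASSES
    if unknown:
        raise InputError(f"unknown tissue classes {sorted(unknown)}")
    keep = [
        n for n, d in network.graph.nodes(data=True) if d["tissue_class"] in classes
    ]
    return AnatomicalNetwork(network.graph.subgraph(keep).copy())


def write_network(
    network: AnatomicalNetwork, path: str | Path, format: str = "edge-table"
) -> None:
    """Write a network as paired node+edge tables or as GraphML.

    ``edge-table`` writes ``<path>`` as the edge table and ``<path>`` with a
    ``.nodes.csv`` suffix as the node table, so that ``load_nodes`` /
    ``load_edges`` / ``build_network`` round-trip the network exactly.
    """
    path = Path(path)
    if format == "edge-table":
        nodes_path = path.with_suffix(path.suffix + ".nodes.csv") \
            if path.suffix != ".nodes.csv" else path
        with open(nodes_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "name", "tissue_class", "side"])
            for rec in network.node_records():
                w.writerow([rec.node_id, rec.name, rec.tissue_class, rec.side])
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["node_a", "node_b", "contact_type"])
            for rec in network.connection_records():
                w.writerow([rec.node_a, rec.node_b, rec.contact_type])
    elif format.lower() == "graphml":
        nx.write_graphml(network.graph, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(edge_path: str | Path, node_path: str | Path | None = None
                 ) -> AnatomicalNetwork:
    """Load a network written by :func:`write_network` in edge-table format."""
    edge_path = Path(edge_path)
    if node_path is None:
        node_path = edge_path.with_suffix(edge_path.suffix + ".nodes.csv")
    return build_network(load_nodes(node_path), load_edges(edge_path))


def read_graphml(path: str | Path) -> AnatomicalNetwork:
    g = nx.read_graphml(path, node_type=int)
    return AnatomicalNetwork(g)
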