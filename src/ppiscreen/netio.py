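"""Readers and writers for interaction networks, action tables and node tables.

File dialects
-------------
* Edge list: 2–3 whitespace/tab-separated columns per line
  (``proteinA  proteinB  [score]``).  Lines starting with ``#`` are comments.
  The optional third column is a confidence score; it is parsed and ignored
  for topology (no score threshold is ever applied).
* STRING export: the same, but with a header row whose first two columns name
  the interacting proteins (``node1``/``node2`` style) and whose remaining
  columns are numeric scores.
* Action table: 4 columns ``source  target  mode  directed`` where ``mode``
  is one of ``activation``, ``inhibition``, ``expression``.

Networks are simple undirected graphs: self-loops are dropped (with a
warning) and parallel edges collapse to one undirected edge.  Protein symbols
are case-sensitive and never remapped.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .errors import ParseError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .centrality import CentralityRecord

logger = logging.getLogger(__name__)

#: The three regulatory action layers.
ACTION_MODES = ("activation", "inhibition", "expression")

# header comment used by write_edge_list to preserve isolated nodes
_NODE_DIRECTIVE = "#%"

_TRUTHY = {"true", "t", "1", "yes", "y", "directed"}
_FALSY = {"false", "f", "0", "no", "n", "undirected"}

# column names that identify a headered STRING-style export
_HEADER_TOKENS = {"node1", "node2", "protein1", "protein2", "source", "target",
                  "#node1", "item_id_a", "item_id_b"}


def _edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (u, v) if u <= v else (v, u)


@dataclass(frozen=True)
class Network:
    """A simple undirected labelled graph for one disease interactome.

    ``edges`` holds canonically ordered node pairs; there are no self-loops
    and no duplicates, and every endpoint is in ``nodes``.
    """

    disease_id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]

    @classmethod
    def from_edges(
        cls,
        disease_id: str,
        edges: Iterable[tuple[str, str]],
        extra_nodes: Iterable[str] = (),
    ) -> "Network":
        """Build a network, dropping self-loops and collapsing duplicates."""
        edge_set: set[tuple[str, str]] = set()
        nodes: set[str] = set(extra_nodes)
        dropped = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                nodes.add(u)
                continue
            edge_set.add(_edge_key(u, v))
            nodes.add(u)
            nodes.add(v)
        if dropped:
            logger.warning("%s: dropped %d self-loop(s)", disease_id, dropped)
        return cls(disease_id, frozenset(nodes), frozenset(edge_set))

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> dict[str, set[str]]:
        """Adjacency sets, including entries for isolated nodes."""
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj

    def has_node(self, label: str) -> bool:
        return label in self.nodes


@dataclass(frozen=True)
class ActionEdge:
    """One typed, possibly directed, regulatory relation between proteins."""

    source: str
    target: str
    mode: str
    directed: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ACTION_MODES:
            raise ValidationError(
                f"unknown action mode {self.mode!r}; allowed modes are "
                f"{set(ACTION_MODES)}"
            )
        if self.source == self.target:
            raise ValidationError(
                f"self-action {self.source!r} -> {self.target!r} is not allowed"
            )


def _iter_data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            yield lineno, line


def read_edge_list(path: str | Path, disease_id: str) -> Network:
    """Read a 2–3 column undirected edge list into a :class:`Network`.

    ``#``-prefixed lines are comments, except ``#% node <label>`` directives
    (written by :func:`write_edge_list`) which declare isolated nodes so that
    write→read round-trips preserve the node set exactly.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    extra_nodes: list[str] = []
    n_lines = 0
    for lineno, line in _iter_data_lines(path):
        if line.startswith("#"):
            if line.startswith(_NODE_DIRECTIVE):
                tokens = line[len(_NODE_DIRECTIVE):].split()
                if len(tokens) == 2 and tokens[0] == "node":
                    extra_nodes.append(tokens[1])
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 columns, got "
                f"{len(tokens)} ({line!r})"
            )
        # tokens[2], when present, is a confidence score: tolerated, unused
        edges.append((tokens[0], tokens[1]))
        n_lines += 1
    if n_lines == 0 and not extra_nodes:
        logger.warning("%s: empty edge list for %s", path, disease_id)
    return Network.from_edges(disease_id, edges, extra_nodes)


def _looks_like_header(tokens: Sequence[str]) -> bool:
    if len(tokens) >= 3:
        try:
            float(tokens[2])
        except ValueError:
            return True  # third column non-numeric => score header
        return False
    return tokens[0].lower() in _HEADER_TOKENS or tokens[1].lower() in _HEADER_TOKENS


def read_string_links(path: str | Path, disease_id: str) -> Network:
    """Read a STRING-style export (headered TSV, scores from column 3).

    Falls back to plain headerless edge-list parsing, with a logged note,
    when no header row is detected.  Dedup contract is identical to
    :func:`read_edge_list`.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    extra_nodes: list[str] = []
    header_checked = False
    n_lines = 0
    for lineno, line in _iter_data_lines(path):
        if line.startswith("#"):
            if line.startswith(_NODE_DIRECTIVE):
                tokens = line[len(_NODE_DIRECTIVE):].split()
                if len(tokens) == 2 and tokens[0] == "node":
                    extra_nodes.append(tokens[1])
            continue
        tokens = line.split()
        if len(tokens) < 2:
            raise ParseError(
                f"{path}:{lineno}: expected at least 2 columns, got "
                f"{len(tokens)} ({line!r})"
            )
        if not header_checked:
            header_checked = True
            if _looks_like_header(tokens):
                continue
            logger.info("%s: no header row detected; parsing as plain edge list", path)
        edges.append((tokens[0], tokens[1]))
        n_lines += 1
    if n_lines == 0 and not extra_nodes:
        logger.warning("%s: empty STRING export for %s", path, disease_id)
    return Network.from_edges(disease_id, edges, extra_nodes)


def write_edge_list(
    net: Network,
    path: str | Path,
    scores: dict[tuple[str, str], float] | None = None,
    header: bool = False,
) -> None:
    """Write a network as a deterministic, sorted edge-list TSV.

    Isolated nodes are preserved via ``#% node`` directives.  With ``header``
    (and optionally ``scores``) the output follows the STRING export dialect.
    """
    path = Path(path)
    adj = net.adjacency()
    isolated = sorted(v for v, nb in adj.items() if not nb)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            cols = ["node1", "node2"] + (["combined_score"] if scores is not None else [])
            fh.write("\t".join(cols) + "\n")
        for v in isolated:
            fh.write(f"{_NODE_DIRECTIVE} node {v}\n")
        for u, v in sorted(net.edges):
            if scores is not None:
                fh.write(f"{u}\t{v}\t{scores.get((u, v), 0.0):.3f}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_action_table(path: str | Path) -> list[ActionEdge]:
    """Read a 4-column ``source target mode directed`` action table.

    An optional header row (first two columns named like identifiers) is
    skipped.  Unknown modes raise :class:`ValidationError` listing the
    allowed layer names.  An empty table is a valid, empty list.
    """
    path = Path(path)
    out: list[ActionEdge] = []
    first = True
    for lineno, line in _iter_data_lines(path):
        if line.startswith("#"):
            continue
        tokens = line.split()
        if first:
            first = False
            if tokens[0].lower() in _HEADER_TOKENS | {"src"}:
                continue
        if len(tokens) < 4:
            raise ParseError(
                f"{path}:{lineno}: expected 4 columns "
                f"(source target mode directed), got {len(tokens)}"
            )
        src, tgt, mode, flag = tokens[:4]
        if mode not in ACTION_MODES:
            raise ValidationError(
                f"{path}:{lineno}: unknown action mode {mode!r}; allowed "
                f"modes are {set(ACTION_MODES)}"
            )
        low = flag.lower()
        if low in _TRUTHY:
            directed = True
        elif low in _FALSY:
            directed = False
        else:
            raise ParseError(
                f"{path}:{lineno}: cannot parse directed flag {flag!r}"
            )
        try:
            out.append(ActionEdge(src, tgt, mode, directed))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_action_table(edges: Iterable[ActionEdge], path: str | Path) -> None:
    """Write action edges as a sorted 4-column TSV with a header row."""
    rows = sorted(
        (e.source, e.target, e.mode, "true" if e.directed else "false")
        for e in edges
    )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("source\ttarget\tmode\tdirected\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def write_node_table(
    records: Sequence["CentralityRecord"],
    path: str | Path,
    full_precision: bool = False,
) -> None:
    """Write centrality records as CSV: node, degree, betweenness, closeness, stress.

    Rows are sorted by degree descending then node label ascending.  Real
    values are printed with 3 decimals by default (display convention); pass
    ``full_precision=True`` for an unrounded machine-readable variant.
    """
    if not records:
        raise ValidationError("write_node_table requires at least one record")
    ordered = sorted(records, key=lambda r: (-r.degree, r.node))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["node", "degree", "betweenness", "closeness", "stress"])
        for r in ordered:
            if full_precision:
                writer.writerow([r.node, r.degree, repr(r.betweenness),
                                 repr(r.closeness), r.stress])
            else:
                writer.writerow([r.node, r.degree, f"{r.betweenness:.3f}",
                                 f"{r.closeness:.3f}", r.stress])
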