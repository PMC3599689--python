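"""Network representations of a molecule record.

Three mutually consistent views of the same molecular graph:

* :func:`adjacency_matrix` — symmetric vertex×vertex numpy matrix, binary
  or bond-order weighted (aromatic code 4 maps to order 1.5);
* :func:`connection_table` — one row per bond with normalized ascending
  atom indices and the two element symbols;
* :func:`to_labeled_graph` — an undirected :class:`networkx.Graph` with
  ``symbol``/``charge_code``/``mass_diff`` vertex attributes and a
  ``bond_type`` edge attribute, the input format expected by
  topological-descriptor packages.

All three accept a hydrogen policy: ``keep`` exports the atom block as
is; ``suppress`` removes explicit hydrogens and their bonds and reindexes
the survivors contiguously (the conventional hydrogen-suppressed graph of
topological indices).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import StructuralIntegrityError
from .model import MolEntry, check_entry

__all__ = [
    "AdjacencyMatrix",
    "ConnectionTable",
    "adjacency_matrix",
    "connection_table",
    "to_labeled_graph",
    "BOND_ORDER",
]

#: Bond-type code → bond order used in weighted adjacency matrices.
#: Query bond types (5-8) have no defined order and are rejected in
#: weighted mode.
BOND_ORDER: dict[int, float] = {1: 1.0, 2: 2.0, 3: 3.0, 4: 1.5}


@dataclass
class AdjacencyMatrix:
    """Symmetric adjacency matrix with index-aligned vertex labels.

    ``index_map`` maps original 1-based atom indices to the exported
    1-based vertex indices (identity under ``keep``; gaps closed under
    hydrogen suppression).
    """

    n: int
    values: np.ndarray
    mode: str
    vertex_labels: list[str]
    index_map: dict[int, int]


@dataclass
class ConnectionTable:
    """Edge list: (first_atom, second_atom, bond_type, first_symbol,
    second_symbol) with first_atom < second_atom, rows in bond-block
    order."""

    rows: list[tuple[int, int, int, str, str]]


def _surviving(entry: MolEntry, hydrogen_policy: str
               ) -> tuple[list[int], dict[int, int]]:
    """Old 1-based indices kept by the policy, and the old→new map."""
    if hydrogen_policy not in ("keep", "suppress"):
        raise ValueError(f"hydrogen_policy must be 'keep' or 'suppress', "
                         f"got {hydrogen_policy!r}")
    if hydrogen_policy == "keep":
        kept = list(range(1, len(entry.atoms) + 1))
    else:
        kept = [i for i, a in enumerate(entry.atoms, start=1)
                if a.symbol != "H"]
    return kept, {old: new for new, old in enumerate(kept, start=1)}


def _validated_bonds(entry: MolEntry, index_map: dict[int, int]
                     ) -> list[tuple[int, int, int]]:
    """Surviving bonds as (new_u, new_v, bond_type), u < v, block order.

    Structural check violations and duplicate bonds between one atom pair
    are export errors, never silently merged.
    """
    hard = [v for v in check_entry(entry) if v.severity == "error"]
    if hard:
        raise StructuralIntegrityError(
            "entry fails structural checks: "
            + "; ".join(v.message for v in hard))
    out: list[tuple[int, int, int]] = []
    for b in entry.bonds:
        if b.first_atom not in index_map or b.second_atom not in index_map:
            continue  # bond to a suppressed hydrogen
        u, v = index_map[b.first_atom], index_map[b.second_atom]
        if u > v:
            u, v = v, u
        out.append((u, v, b.bond_type))
    return out


def adjacency_matrix(entry: MolEntry, mode: str = "binary",
                     hydrogen_policy: str = "keep") -> AdjacencyMatrix:
    """Build the (binary or bond-order-weighted) adjacency matrix.

    Binary mode writes 1 wherever a bond exists, whatever its type;
    weighted mode writes the bond order (1, 2, 3, or 1.5 for aromatic)
    and rejects query bond types 5-8, whose order is undefined.
    """
    if mode not in ("binary", "weighted"):
        raise ValueError(f"mode must be 'binary' or 'weighted', got {mode!r}")
    kept, index_map = _surviving(entry, hydrogen_policy)
    bonds = _validated_bonds(entry, index_map)
    n = len(kept)
    values = np.zeros((n, n), dtype=float)
    for u, v, btype in bonds:
        if mode == "weighted":
            if btype not in BOND_ORDER:
                raise StructuralIntegrityError(
                    f"bond type {btype} is a query type with no defined "
                    f"bond order; weighted adjacency is undefined")
            w = BOND_ORDER[btype]
        else:
            w = 1.0
        values[u - 1, v - 1] = w
        values[v - 1, u - 1] = w
    labels = [entry.atoms[old - 1].symbol for old in kept]
    return AdjacencyMatrix(n=n, values=values, mode=mode,
                           vertex_labels=labels, index_map=index_map)


def connection_table(entry: MolEntry,
                     hydrogen_policy: str = "keep") -> ConnectionTable:
    """Edge list of the (possibly hydrogen-suppressed) molecular graph."""
    kept, index_map = _surviving(entry, hydrogen_policy)
    symbols = {index_map[old]: entry.atoms[old - 1].symbol for old in kept}
    rows = [(u, v, btype, symbols[u], symbols[v])
            for u, v, btype in _validated_bonds(entry, index_map)]
    return ConnectionTable(rows=rows)


def to_labeled_graph(entry: MolEntry,
                     hydrogen_policy: str = "keep") -> nx.Graph:
    """Attribute-labeled undirected graph of the molecule.

    Vertices are 1-based integers carrying ``symbol``, ``charge_code``
    and ``mass_diff``; edges carry ``bond_type``.  This is the labeled
    graph object downstream network-measure packages consume.
    """
    kept, index_map = _surviving(entry, hydrogen_policy)
    g = nx.Graph()
    for old in kept:
        atom = entry.atoms[old - 1]
        g.add_node(index_map[old], symbol=atom.symbol,
                   charge_code=atom.charge_code, mass_diff=atom.mass_diff)
    for u, v, btype in _validated_bonds(entry, index_map):
        g.add_edge(u, v, bond_type=btype)
    return g


def adjacency_to_tsv(matrix: AdjacencyMatrix) -> str:
    """TSV rendering: header row of vertex labels, then matrix rows."""
    lines = ["\t".join(matrix.vertex_labels)]
    for row in matrix.values:
        lines.append("\t".join(f"{v:g}" for v in row))
    return "\n".join(lines) + "\n"


def connection_table_to_tsv(table: ConnectionTable) -> str:
    lines = ["first_atom\tsecond_atom\tbond_type\tfirst_symbol\t"
             "second_symbol"]
    for u, v, t, su, sv in table.rows:
        lines.append(f"{u}\t{v}\t{t}\t{su}\t{sv}")
    return "\n".join(lines) + "\n"


def edge_list_to_tsv(graph: nx.Graph) -> str:
    lines = ["u\tv\tbond_type"]
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f"{u}\t{v}\t{data['bond_type']}")
    return "\n".join(lines) + "\n"
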