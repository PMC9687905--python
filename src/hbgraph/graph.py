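"""Molecular graphs: donor/acceptor atoms as nodes, feasible hydrogen bonds
as undirected edges.

Two weighting modes exist. ``coordinate_free`` graphs record a weight of
1.0 per bond, so only topology enters downstream analysis;
``coordinate_based`` graphs weight each edge by the donor-acceptor
Euclidean distance in angstroms. Both share the same edge set. Atoms that
donate or accept but form no feasible bond remain in the graph as degree-0
singleton nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hbonds import HBond
from .roles import ACCEPTOR, BOTH, DONOR, RoleAtom

COORDINATE_FREE = "coordinate_free"
COORDINATE_BASED = "coordinate_based"

FORMAT_VERSION = 1


@dataclass
class MolecularGraph:
    """Undirected weighted graph G = (V, E, A) over donor/acceptor atoms.

    ``roles[i]`` labels node i as donor/acceptor/both; ``adjacency`` is the
    symmetric N x N weight matrix with zero diagonal. ``node_info`` holds
    optional per-node provenance (atom serial, residue, atom name) and
    ``edge_records`` the stored hydrogen-bond geometry for each edge.
    """

    roles: list[str]
    adjacency: np.ndarray
    mode: str = COORDINATE_FREE
    label: int | str | None = None
    node_info: list[dict] = field(default_factory=list)
    edge_records: list[dict] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return len(self.roles)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency)))

    def edges(self) -> list[tuple[int, int, float]]:
        ii, jj = np.nonzero(np.triu(self.adjacency))
        return [(int(i), int(j), float(self.adjacency[i, j])) for i, j in zip(ii, jj)]

    def validate(self) -> None:
        A = self.adjacency
        n = self.n_nodes
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} does not match {n} nodes")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(A < 0):
            raise ValueError("adjacency weights must be nonnegative")
        bad = set(self.roles) - {DONOR, ACCEPTOR, BOTH}
        if bad:
            raise ValueError(f"unknown node roles: {sorted(bad)}")
        weights = A[np.nonzero(A)]
        if self.mode == COORDINATE_FREE:
            if weights.size and not np.all(weights == 1.0):
                raise ValueError("coordinate-free weights must all be 1.0")
        elif self.mode == COORDINATE_BASED:
            if weights.size and np.any(weights > 3.9):
                raise ValueError("coordinate-based weights must lie in (0, 3.9]")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Graph with nodes reordered by ``perm`` (new index i = old perm[i])."""
        perm = np.asarray(perm)
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        return MolecularGraph(
            roles=[self.roles[p] for p in perm],
            adjacency=self.adjacency[np.ix_(perm, perm)],
            mode=self.mode,
            label=self.label,
            node_info=[self.node_info[p] for p in perm] if self.node_info else [],
            edge_records=[
                {**e, "i": int(inv[e["i"]]), "j": int(inv[e["j"]])} for e in self.edge_records
            ],
        )


def build_molecular_graph(
    roles: list[RoleAtom],
    bonds: list[HBond],
    mode: str = COORDINATE_FREE,
    label=None,
) -> MolecularGraph:
    """Assemble the molecular graph from role atoms and detected bonds.

    Node order follows the input role order; every role atom becomes a node
    whether or not it is bonded. Each donor-acceptor pair contributes one
    undirected edge, weighted 1.0 (coordinate-free) or by its D-A distance
    (coordinate-based).
    """
    if mode not in (COORDINATE_FREE, COORDINATE_BASED):
        raise ValueError(f"unknown mode {mode!r}")
    index = {r.atom.serial: i for i, r in enumerate(roles)}
    n = len(roles)
    A = np.zeros((n, n))
    edge_records: list[dict] = []
    seen: set[tuple[int, int]] = set()
    for b in bonds:
        try:
            i = index[b.donor.atom.serial]
            j = index[b.acceptor.atom.serial]
        except KeyError:
            raise ValueError(
                f"bond references atom serial not present in the node set: {b.key}"
            ) from None
        pair = (min(i, j), max(i, j))
        if pair in seen:
            continue
        seen.add(pair)
        w = 1.0 if mode == COORDINATE_FREE else b.d_da
        A[i, j] = A[j, i] = w
        edge_records.append(
            {
                "i": pair[0],
                "j": pair[1],
                "weight": w,
                "d_DA": b.d_da,
                "d_HA": b.d_ha,
                "ang_DHA": b.ang_dha,
                "ang_HAAA": b.ang_haaa,
                "ang_DAAA": b.ang_daaa,
            }
        )
    node_info = [
        {
            "index": i,
            "serial": r.atom.serial,
            "residue": f"{r.atom.residue_name}{r.atom.residue_seq}{r.atom.icode}",
            "atom": r.atom.name,
            "role": r.role,
        }
        for i, r in enumerate(roles)
    ]
    g = MolecularGraph(
        roles=[r.role for r in roles],
        adjacency=A,
        mode=mode,
        label=label,
        node_info=node_info,
        edge_records=edge_records,
    )
    g.validate()
    return g


# --- serialization ---------------------------------------------------------


def graph_to_json(g: MolecularGraph) -> str:
    doc = {
        "format_version": FORMAT_VERSION,
        "mode": g.mode,
        "label": g.label,
        "n_nodes": g.n_nodes,
        "roles": g.roles,
        "nodes": g.node_info,
        "edges": g.edge_records
        if g.edge_records
        else [{"i": i, "j": j, "weight": w} for i, j, w in g.edges()],
    }
    return json.dumps(doc, indent=1)


def graph_from_json(text: str) -> MolecularGraph:
    doc = json.loads(text)
    n = doc["n_nodes"]
    A = np.zeros((n, n))
    for e in doc["edges"]:
        A[e["i"], e["j"]] = A[e["j"], e["i"]] = e["weight"]
    g = MolecularGraph(
        roles=list(doc["roles"]),
        adjacency=A,
        mode=doc["mode"],
        label=doc.get("label"),
        node_info=doc.get("nodes", []),
        edge_records=doc.get("edges", []),
    )
    g.validate()
    return g


def write_tsv_tables(g: MolecularGraph, nodes_path: str, edges_path: str) -> None:
    """Write the node and edge tables as TSV files."""
    with open(nodes_path, "w") as fh:
        fh.write("index\tserial\tresidue\tatom\trole\n")
        if g.node_info:
            for info in g.node_info:
                fh.write(
                    f"{info['index']}\t{info.get('serial', '')}\t{info.get('residue', '')}"
                    f"\t{info.get('atom', '')}\t{info['role']}\n"
                )
        else:
            for i, role in enumerate(g.roles):
                fh.write(f"{i}\t\t\t\t{role}\n")
    with open(edges_path, "w") as fh:
        fh.write("i\tj\tweight\td_DA\td_HA\tang_DHA\tang_HAAA\tang_DAAA\n")
        records = g.edge_records or [{"i": i, "j": j, "weight": w} for i, j, w in g.edges()]
        for e in records:
            fh.write(
                "\t".join(
                    _fmt(e.get(k))
                    for k in ("i", "j", "weight", "d_DA", "d_HA", "ang_DHA", "ang_HAAA", "ang_DAAA")
                )
                + "\n"
            )


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)
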