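"""Synthetic inputs for building and testing the pipeline without any
external structure downloads.

Three generators:

* :func:`make_ideal_helix` — a poly-alanine alpha-helix built from ideal
  internal coordinates (phi = -57, psi = -47 degrees, textbook bond lengths
  and angles), whose O(i)...N(i+4) geometry falls inside the hydrogen-bond
  feasibility envelope. The known bond pattern makes it an end-to-end
  oracle for detection.
* :func:`make_random_structure` — rigid standard-residue templates dropped
  at random positions/orientations with a minimum inter-atomic separation;
  a substrate for comparing the lattice search against brute force. The
  arrangement is deliberately non-physical apart from per-residue geometry.
* :func:`make_graph_family` — labelled families of molecular graphs whose
  classes differ only in edge-topology statistics while node roles are
  identically distributed, so any classifier signal must come from
  topology.

All generators take explicit seeds and touch no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import place_atom
from .graph import COORDINATE_FREE, MolecularGraph
from .pdb import AtomRecord, Structure, write_pdb
from .roles import ACCEPTOR, BOTH, DONOR

# ideal backbone internal coordinates (lengths A, angles degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_A_C_N_CA, _A_N_CA_C, _A_CA_C_N = 121.7, 111.2, 116.2
_B_C_O, _A_CA_C_O = 1.229, 120.8
_B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB = 1.521, 110.4, -122.6
_OMEGA = 180.0


@dataclass
class HelixSpec:
    """Ideal right-handed alpha-helix: phi = -57, psi = -47 degrees."""

    n_residues: int = 20
    phi: float = -57.0
    psi: float = -47.0


def make_ideal_helix(spec: HelixSpec | None = None, n_residues: int | None = None) -> str:
    """PDB text for an ideal poly-Ala helix (backbone N, CA, C, O, CB).

    Requires at least 5 residues so an i -> i+4 donor-acceptor pair exists.
    """
    if spec is None:
        spec = HelixSpec()
    if n_residues is not None:
        spec = HelixSpec(n_residues=n_residues, phi=spec.phi, psi=spec.psi)
    n = spec.n_residues
    if n < 5:
        raise ValueError(f"need >= 5 residues for an i->i+4 pair, got {n}")

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    c0 = place_atom(np.array([0.0, 1.0, 0.0]), N[0], CA[0], _B_CA_C, _A_N_CA_C, 0.0)
    C = [c0]
    for _ in range(1, n):
        N.append(place_atom(N[-1], CA[-1], C[-1], _B_C_N, _A_CA_C_N, spec.psi))
        CA.append(place_atom(CA[-1], C[-1], N[-1], _B_N_CA, _A_C_N_CA, _OMEGA))
        C.append(place_atom(C[-1], N[-1], CA[-1], _B_CA_C, _A_N_CA_C, spec.phi))
    O = []
    for i in range(n):
        if i + 1 < n:
            O.append(place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0))
        else:
            O.append(place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, spec.psi + 180.0))
    CB = [
        place_atom(C[i], N[i], CA[i], _B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB) for i in range(n)
    ]

    atoms: list[AtomRecord] = []
    serial = 0
    for i in range(n):
        for name, pos, elem in (
            ("N", N[i], "N"),
            ("CA", CA[i], "C"),
            ("C", C[i], "C"),
            ("O", O[i], "O"),
            ("CB", CB[i], "C"),
        ):
            serial += 1
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name,
                    element=elem,
                    residue_name="ALA",
                    chain_id="A",
                    residue_seq=i + 1,
                    icode="",
                    position=pos,
                )
            )
    return write_pdb(Structure(atoms=atoms, chain_id="A"))


# --- random rigid-template structures --------------------------------------


def _backbone_template() -> dict[str, np.ndarray]:
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_B_N_CA, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, _B_CA_C, _A_N_CA_C, 0.0)
    o = place_atom(n, ca, c, _B_C_O, _A_CA_C_O, -45.0)
    return {"N": n, "CA": ca, "C": c, "O": o}


def _residue_templates() -> dict[str, dict[str, np.ndarray]]:
    t: dict[str, dict[str, np.ndarray]] = {}
    for resname in ("GLY", "ALA", "SER", "ASN", "LYS", "ASP"):
        atoms = dict(_backbone_template())
        if resname != "GLY":
            atoms["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"], _B_CA_CB, _A_N_CA_CB, _T_C_N_CA_CB)
        if resname == "SER":
            atoms["OG"] = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.417, 110.8, 180.0)
        elif resname == "ASN":
            atoms["CG"] = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.516, 112.6, 180.0)
            atoms["OD1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.231, 120.8, 0.0)
            atoms["ND2"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.328, 116.4, 180.0)
        elif resname == "LYS":
            prev3 = (atoms["N"], atoms["CA"], atoms["CB"])
            for name, length in (("CG", 1.52), ("CD", 1.52), ("CE", 1.52), ("NZ", 1.489)):
                atoms[name] = place_atom(*prev3, length, 111.0, 180.0)
                prev3 = (prev3[1], prev3[2], atoms[name])
        elif resname == "ASP":
            atoms["CG"] = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.516, 112.6, 180.0)
            atoms["OD1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.249, 118.4, 0.0)
            atoms["OD2"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.249, 118.4, 180.0)
        t[resname] = atoms
    return t


_TEMPLATES = _residue_templates()
_RESIDUE_POOL = ("ALA", "GLY", "SER", "SER", "ASN", "ASN", "LYS", "ASP")
_MIN_SEPARATION = 1.5


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_random_structure(n_residues: int, seed: int = 0) -> str:
    """PDB text of randomly placed rigid residues with polar side chains.

    Residues are internally ideal but mutually unconnected; inter-atomic
    separation is kept >= 1.5 A. Deterministic per seed. Synthetic: an
    oracle-test substrate, not a protein model.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    n_atoms_est = n_residues * 7
    side = (n_atoms_est / 0.040) ** (1.0 / 3.0)

    placed: list[np.ndarray] = []
    atoms: list[AtomRecord] = []
    serial = 0
    occupied = np.zeros((0, 3))
    for res_i in range(n_residues):
        resname = _RESIDUE_POOL[rng.integers(len(_RESIDUE_POOL))]
        template = _TEMPLATES[resname]
        names = list(template)
        local = np.array([template[nm] for nm in names])
        local = local - local.mean(axis=0)
        for attempt in range(400):
            R = _random_rotation(rng)
            t = rng.uniform(0.0, side, size=3)
            coords = local @ R.T + t
            if occupied.shape[0]:
                d2 = ((coords[:, None, :] - occupied[None, :, :]) ** 2).sum(axis=2)
                if d2.min() < _MIN_SEPARATION**2:
                    if attempt == 399:
                        side *= 1.05  # relieve crowding deterministically
                    continue
            occupied = np.vstack([occupied, coords])
            for nm, pos in zip(names, coords):
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=nm,
                        element=nm[0],
                        residue_name=resname,
                        chain_id="A",
                        residue_seq=res_i + 1,
                        icode="",
                        position=pos,
                    )
                )
            placed.append(coords)
            break
    return write_pdb(Structure(atoms=atoms, chain_id="A"))


# --- labelled graph families ------------------------------------------------


@dataclass
class ClassSpec:
    """One class of a synthetic graph family."""

    label: str
    n_graphs: int = 60
    n_nodes: tuple[int, int] = (40, 70)
    edge_probability: float = 0.1
    role_probs: tuple[float, float, float] = (0.4, 0.4, 0.2)  # donor, acceptor, both


@dataclass
class GraphFamilySpec:
    classes: list[ClassSpec] = field(default_factory=list)
    seed: int = 0


@dataclass
class GraphDataset:
    graphs: list[MolecularGraph]
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))


def _random_role_graph(
    rng: np.random.Generator, n_nodes: int, p_edge: float, role_probs
) -> MolecularGraph:
    roles = [
        (DONOR, ACCEPTOR, BOTH)[k]
        for k in rng.choice(3, size=n_nodes, p=np.asarray(role_probs) / np.sum(role_probs))
    ]
    can_donate = np.array([r in (DONOR, BOTH) for r in roles])
    can_accept = np.array([r in (ACCEPTOR, BOTH) for r in roles])
    A = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            feasible = (can_donate[i] and can_accept[j]) or (can_donate[j] and can_accept[i])
            if feasible and rng.random() < p_edge:
                A[i, j] = A[j, i] = 1.0
    g = MolecularGraph(roles=roles, adjacency=A, mode=COORDINATE_FREE)
    g.validate()
    return g


def make_graph_family(spec: GraphFamilySpec) -> GraphDataset:
    """Labelled molecular-graph families differing only in edge topology.

    Node roles are drawn from each class's role distribution (identical
    distributions across classes keep the roles uninformative); edges are
    donor-acceptor-respecting random attachments at the class's edge
    probability. Degenerate specs (identical classes) are permitted but
    flagged in the metadata. The metadata records a chi-square test of
    role-count homogeneity across classes.
    """
    if len(spec.classes) < 2:
        raise ValueError("need >= 2 classes")
    for c in spec.classes:
        if c.n_graphs < 10:
            raise ValueError(f"class {c.label!r}: need >= 10 graphs, got {c.n_graphs}")
    rng = np.random.default_rng(spec.seed)
    graphs: list[MolecularGraph] = []
    labels: list[str] = []
    role_counts = []
    for c in spec.classes:
        counts = {DONOR: 0, ACCEPTOR: 0, BOTH: 0}
        for _ in range(c.n_graphs):
            n = int(rng.integers(c.n_nodes[0], c.n_nodes[1] + 1))
            g = _random_role_graph(rng, n, c.edge_probability, c.role_probs)
            g.label = c.label
            graphs.append(g)
            labels.append(c.label)
            for r in g.roles:
                counts[r] += 1
        role_counts.append([counts[DONOR], counts[ACCEPTOR], counts[BOTH]])

    table = np.array(role_counts)
    chi2_p = float(stats.chi2_contingency(table[:, table.sum(axis=0) > 0]).pvalue)
    signatures = {
        (c.n_nodes, c.edge_probability, tuple(c.role_probs)) for c in spec.classes
    }
    metadata = {
        "seed": spec.seed,
        "role_chi2_pvalue": chi2_p,
        "degenerate_identical_classes": len(signatures) < len(spec.classes),
        "class_labels": [c.label for c in spec.classes],
    }
    return GraphDataset(graphs=graphs, labels=np.array(labels), metadata=metadata)


def two_density_family(
    p_low: float = 0.05,
    p_high: float = 0.15,
    n_graphs: int = 60,
    seed: int = 0,
    n_nodes: tuple[int, int] = (40, 70),
) -> GraphDataset:
    """The canonical two-class benchmark: identical role distributions,
    edge densities ``p_low`` vs ``p_high``."""
    spec = GraphFamilySpec(
        classes=[
            ClassSpec(label="sparse", n_graphs=n_graphs, n_nodes=n_nodes, edge_probability=p_low),
            ClassSpec(label="dense", n_graphs=n_graphs, n_nodes=n_nodes, edge_probability=p_high),
        ],
        seed=seed,
    )
    return make_graph_family(spec)
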