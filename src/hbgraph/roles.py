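"""Donor/acceptor role assignment.

The chemistry lives in a data file (``data/roles.yaml``) so the polar-atom
table can be edited without code changes. A role atom is any heavy atom
that can donate a hydrogen bond (it carries at least one attached
hydrogen), accept one (it has at least one covalently bonded heavy-atom
antecedent), or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .pdb import AtomRecord, Structure

DONOR = "donor"
ACCEPTOR = "acceptor"
BOTH = "both"

#: maximum covalent H-parent distance when inferring attachment, angstroms
_H_ATTACH_CUTOFF = 1.3


@dataclass
class RoleAtom:
    """A heavy atom participating in hydrogen bonds, with its context atoms."""

    atom: AtomRecord
    role: str  # donor | acceptor | both
    donor_hydrogens: list[AtomRecord] = field(default_factory=list)
    acceptor_antecedents: list[AtomRecord] = field(default_factory=list)

    @property
    def is_donor(self) -> bool:
        return self.role in (DONOR, BOTH)

    @property
    def is_acceptor(self) -> bool:
        return self.role in (ACCEPTOR, BOTH)


def load_role_table(path: str | None = None) -> dict:
    """Load the role table, from ``path`` or the packaged default."""
    if path is None:
        text = resources.files("hbgraph.data").joinpath("roles.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return yaml.safe_load(text)


def assign_roles(s: Structure, table: dict | None = None) -> list[RoleAtom]:
    """Identify every donor/acceptor heavy atom of a protonated structure.

    Hydrogens are attached to their parent either through the recorded
    parent serial (structures protonated here) or, for pre-protonated
    input, to the nearest heavy atom within 1.3 A. Atoms outside the role
    table are silently not nodes.
    """
    if table is None:
        table = load_role_table()

    heavy = [a for a in s.atoms if not a.is_hydrogen]
    hydrogens = [a for a in s.atoms if a.is_hydrogen]

    by_serial = {a.serial: a for a in heavy}
    attached: dict[int, list[AtomRecord]] = {}
    for h in hydrogens:
        parent = by_serial.get(h.parent_serial) if h.parent_serial is not None else None
        if parent is None:
            parent = _nearest_heavy(h, heavy)
        if parent is not None:
            attached.setdefault(parent.serial, []).append(h)

    by_res: dict[tuple, dict[str, AtomRecord]] = {}
    for a in heavy:
        by_res.setdefault(a.residue_id, {})[a.name] = a

    backbone_donors = {d["atom"]: set(d.get("exclude_residues", [])) for d in table["backbone"]["donors"]}
    backbone_acceptors = {d["atom"]: d["antecedents"] for d in table["backbone"]["acceptors"]}
    sidechain = table.get("sidechain", {})

    out: list[RoleAtom] = []
    for a in heavy:
        residue_atoms = by_res[a.residue_id]
        donor = False
        antecedents: list[AtomRecord] = []
        if a.name in backbone_donors and a.residue_name not in backbone_donors[a.name]:
            donor = True
        if a.name in backbone_acceptors:
            antecedents = [residue_atoms[n] for n in backbone_acceptors[a.name] if n in residue_atoms]
        entry = sidechain.get(a.residue_name, {}).get(a.name)
        if entry is not None:
            if DONOR in entry["roles"]:
                donor = True
            if ACCEPTOR in entry["roles"]:
                antecedents = [residue_atoms[n] for n in entry.get("antecedents", []) if n in residue_atoms]

        donor_hs = attached.get(a.serial, []) if donor else []
        is_donor = donor and bool(donor_hs)
        is_acceptor = bool(antecedents)
        if not (is_donor or is_acceptor):
            continue
        role = BOTH if (is_donor and is_acceptor) else (DONOR if is_donor else ACCEPTOR)
        out.append(RoleAtom(atom=a, role=role, donor_hydrogens=donor_hs, acceptor_antecedents=antecedents))
    return out


def _nearest_heavy(h: AtomRecord, heavy: list[AtomRecord]) -> AtomRecord | None:
    best, best_d = None, _H_ATTACH_CUTOFF
    for a in heavy:
        d = float(sum((h.position - a.position) ** 2)) ** 0.5
        if d <= best_d:
            best, best_d = a, d
    return best
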