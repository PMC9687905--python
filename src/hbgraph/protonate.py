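"""Placement of polar hydrogens at idealized covalent geometry.

Hydrogens are added only where they matter for hydrogen-bond detection:
the donors of the role table (backbone amides, hydroxyls, side-chain
amides/ammonium/guanidinium, His NE2, Trp indole, the N-terminal amine).
Protonation states assume pH ~7: Asp/Glu carboxylates unprotonated,
Lys/Arg charged, His neutral with the NE2-H tautomer.

sp2 donors get in-plane hydrogens; sp3 donors (hydroxyls, ammonium, the
N-terminal amine) get staggered hydrogens, with rotatable hydroxyls placed
at the staggered torsion that maximizes clearance from nearby atoms.
N-H bonds are 1.00 A and O-H bonds 0.96 A.
"""

from __future__ import annotations

import logging
import numpy as np

from .geometry import place_atom
from .pdb import AtomRecord, Structure

logger = logging.getLogger(__name__)

NH_LENGTH = 1.00
OH_LENGTH = 0.96

# sidechain sp2 amide/guanidinium donors: donor atom -> (frame a, frame b, H names)
_SP2_PLANAR = {
    ("ASN", "ND2"): ("OD1", "CG", ("HD21", "HD22")),
    ("GLN", "NE2"): ("OE1", "CD", ("HE21", "HE22")),
    ("ARG", "NH1"): ("NE", "CZ", ("HH11", "HH12")),
    ("ARG", "NH2"): ("NE", "CZ", ("HH21", "HH22")),
}

# sp2 donors with two in-ring/in-plane heavy neighbors: donor -> (nbr1, nbr2, H name)
_SP2_BISECTOR = {
    ("ARG", "NE"): ("CD", "CZ", "HE"),
    ("HIS", "NE2"): ("CD2", "CE1", "HE2"),
    ("TRP", "NE1"): ("CD1", "CE2", "HE1"),
}

# rotatable hydroxyls: donor -> (frame a, frame b, H name)
_HYDROXYL = {
    ("SER", "OG"): ("CA", "CB", "HG"),
    ("THR", "OG1"): ("CA", "CB", "HG1"),
    ("TYR", "OH"): ("CE1", "CZ", "HH"),
}


def place_hydrogens(s: Structure) -> Structure:
    """Return a copy of ``s`` with idealized polar hydrogens added.

    Each hydrogen records its parent donor via ``parent_serial``. Residues
    missing the heavy atoms needed to frame a placement have that hydrogen
    skipped with a warning.
    """
    residues = s.residues()
    out: list[AtomRecord] = []
    next_serial = max((a.serial for a in s.atoms), default=0)

    def new_h(name: str, pos: np.ndarray, parent: AtomRecord) -> AtomRecord:
        nonlocal next_serial
        next_serial += 1
        return AtomRecord(
            serial=next_serial,
            name=name,
            element="H",
            residue_name=parent.residue_name,
            chain_id=parent.chain_id,
            residue_seq=parent.residue_seq,
            icode=parent.icode,
            position=pos,
            occupancy=1.0,
            is_hetero=False,
            parent_serial=parent.serial,
        )

    for idx, (res_id, atoms) in enumerate(residues):
        by_name = {a.name: a for a in atoms}
        resname = atoms[0].residue_name
        added: list[AtomRecord] = []

        def get(*names: str) -> list[AtomRecord] | None:
            got = [by_name.get(n) for n in names]
            return None if any(g is None for g in got) else got  # type: ignore[return-value]

        def skip(what: str) -> None:
            logger.warning("%s %s: missing frame atoms, %s hydrogen skipped", resname, res_id, what)

        # --- backbone amide nitrogen ---
        n_atom = by_name.get("N")
        if n_atom is not None and resname != "PRO":
            if idx == 0 or residues[idx - 1][1][0].chain_id != n_atom.chain_id:
                prev_c = None
            else:
                prev_c = next((a for a in residues[idx - 1][1] if a.name == "C"), None)
            if prev_c is not None:
                frame = get("CA")
                if frame is None:
                    skip("backbone amide")
                else:
                    ca = frame[0]
                    u1 = _unit(prev_c.position - n_atom.position)
                    u2 = _unit(ca.position - n_atom.position)
                    direction = -(u1 + u2)
                    direction /= np.linalg.norm(direction)
                    added.append(new_h("H", n_atom.position + NH_LENGTH * direction, n_atom))
            else:
                # chain start: sp3 ammonium, three staggered hydrogens
                frame = get("CA", "C")
                if frame is None:
                    skip("N-terminal amine")
                else:
                    ca, c = frame
                    for k, tor in enumerate((60.0, 180.0, 300.0), start=1):
                        pos = place_atom(c.position, ca.position, n_atom.position, NH_LENGTH, 109.5, tor)
                        added.append(new_h(f"H{k}", pos, n_atom))

        # --- sidechain sp2 amide / guanidinium (two in-plane hydrogens) ---
        key2 = [(k, v) for k, v in _SP2_PLANAR.items() if k[0] == resname and k[1] in by_name]
        for (_, donor_name), (a_name, b_name, h_names) in key2:
            donor = by_name[donor_name]
            frame = get(a_name, b_name)
            if frame is None:
                skip(donor_name)
                continue
            fa, fb = frame
            for h_name, tor in zip(h_names, (180.0, 0.0)):
                pos = place_atom(fa.position, fb.position, donor.position, NH_LENGTH, 120.0, tor)
                added.append(new_h(h_name, pos, donor))

        # --- sp2 donors framed by two heavy neighbors (bisector placement) ---
        for (rn, donor_name), (n1, n2, h_name) in _SP2_BISECTOR.items():
            if rn != resname or donor_name not in by_name:
                continue
            donor = by_name[donor_name]
            frame = get(n1, n2)
            if frame is None:
                skip(donor_name)
                continue
            u1 = _unit(frame[0].position - donor.position)
            u2 = _unit(frame[1].position - donor.position)
            direction = -(u1 + u2)
            direction /= np.linalg.norm(direction)
            added.append(new_h(h_name, donor.position + NH_LENGTH * direction, donor))

        # --- rotatable hydroxyls: staggered torsion with maximal clearance ---
        for (rn, donor_name), (a_name, b_name, h_name) in _HYDROXYL.items():
            if rn != resname or donor_name not in by_name:
                continue
            donor = by_name[donor_name]
            frame = get(a_name, b_name)
            if frame is None:
                skip(donor_name)
                continue
            fa, fb = frame
            others = [a.position for a in atoms if a.name not in (donor_name, b_name)]
            best_pos, best_clearance = None, -1.0
            for tor in (60.0, 180.0, 300.0):
                pos = place_atom(fa.position, fb.position, donor.position, OH_LENGTH, 109.5, tor)
                clearance = min((float(np.linalg.norm(pos - p)) for p in others), default=np.inf)
                if clearance > best_clearance:
                    best_pos, best_clearance = pos, clearance
            assert best_pos is not None
            added.append(new_h(h_name, best_pos, donor))

        # --- lysine ammonium ---
        if resname == "LYS" and "NZ" in by_name:
            donor = by_name["NZ"]
            frame = get("CD", "CE")
            if frame is None:
                skip("NZ")
            else:
                cd, ce = frame
                for k, tor in enumerate((60.0, 180.0, 300.0), start=1):
                    pos = place_atom(cd.position, ce.position, donor.position, NH_LENGTH, 109.5, tor)
                    added.append(new_h(f"HZ{k}", pos, donor))

        out.extend(atoms)
        out.extend(added)

    n_added = len(out) - len(s.atoms)
    logger.info("place_hydrogens: added %d polar hydrogens", n_added)
    return Structure(atoms=out, chain_id=s.chain_id, model_number=s.model_number, protonated=True)


def expected_donor_hydrogens(resname: str, is_nterm: bool, is_pro: bool | None = None) -> int:
    """Polar-hydrogen count the placement rules add for one complete residue."""
    if is_pro is None:
        is_pro = resname == "PRO"
    n = 0
    if not is_pro:
        n += 3 if is_nterm else 1
    n += {
        "SER": 1, "THR": 1, "TYR": 1, "CYS": 0, "TRP": 1, "HIS": 1,
        "ASN": 2, "GLN": 2, "LYS": 3, "ARG": 5,
    }.get(resname, 0)
    return n


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError("degenerate geometry: coincident atoms")
    return v / n
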