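"""Geometric hydrogen-bond detection.

A donor D (with covalent hydrogen H) and an acceptor A (with covalent
antecedent AA) form a feasible hydrogen bond when

* d(D, A) <= 3.9 A  and  d(H, A) <= 2.5 A  (inclusive), and
* the angles D-H-A, H-A-AA and D-A-AA each strictly exceed 90 degrees,
  the middle atom being the vertex.

Distance bounds are inclusive; angle bounds are strict. Donor and acceptor
must belong to different residues. A donor-acceptor pair is reported once
no matter how many hydrogen/antecedent combinations satisfy the criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .grid import build_grid, radius_query
from .pdb import AtomRecord, Structure
from .roles import RoleAtom, assign_roles

__all__ = [
    "HBondCriteria",
    "HBond",
    "evaluate_candidate",
    "find_hbonds",
    "brute_force_hbond_search",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Feasibility thresholds; defaults are the standard detection envelope."""

    max_da: float = 3.9  # D-A distance ceiling, A (inclusive)
    max_ha: float = 2.5  # H-A distance ceiling, A (inclusive)
    min_angle: float = 90.0  # D-H-A, H-A-AA, D-A-AA floor, degrees (strict)
    cell_size: float = 3.9  # lattice cell for the neighbor search, A


@dataclass(frozen=True)
class HBond:
    donor: RoleAtom
    hydrogen: AtomRecord
    acceptor: RoleAtom
    antecedent: AtomRecord
    d_da: float
    d_ha: float
    ang_dha: float
    ang_haaa: float
    ang_daaa: float

    @property
    def key(self) -> tuple[int, int]:
        """(donor serial, acceptor serial) identity of the bond."""
        return (self.donor.atom.serial, self.acceptor.atom.serial)


def _dist(p, q) -> float:
    dx, dy, dz = p[0] - q[0], p[1] - q[1], p[2] - q[2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


def _angle(p, vertex, q) -> float | None:
    """Angle p-vertex-q in degrees; None when an arm is degenerate."""
    ux, uy, uz = p[0] - vertex[0], p[1] - vertex[1], p[2] - vertex[2]
    vx, vy, vz = q[0] - vertex[0], q[1] - vertex[1], q[2] - vertex[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    if nu < 1e-9 or nv < 1e-9:
        return None
    c = (ux * vx + uy * vy + uz * vz) / (nu * nv)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def evaluate_candidate(
    d_pos, h_pos, a_pos, aa_pos, criteria: HBondCriteria = HBondCriteria()
) -> tuple[bool, dict]:
    """Test one D/H/A/AA geometry against the feasibility criteria.

    Returns ``(accept, record)`` where ``record`` carries all five
    measurements regardless of the outcome, plus a ``degenerate`` flag set
    when coincident atoms make an angle undefined (always rejected).
    """
    d_da = _dist(d_pos, a_pos)
    d_ha = _dist(h_pos, a_pos)
    ang_dha = _angle(d_pos, h_pos, a_pos)
    ang_haaa = _angle(h_pos, a_pos, aa_pos)
    ang_daaa = _angle(d_pos, a_pos, aa_pos)
    degenerate = ang_dha is None or ang_haaa is None or ang_daaa is None
    record = {
        "d_DA": d_da,
        "d_HA": d_ha,
        "ang_DHA": ang_dha,
        "ang_HAAA": ang_haaa,
        "ang_DAAA": ang_daaa,
        "degenerate": degenerate,
    }
    if degenerate:
        return False, record
    accept = (
        d_da <= criteria.max_da
        and d_ha <= criteria.max_ha
        and ang_dha > criteria.min_angle
        and ang_haaa > criteria.min_angle
        and ang_daaa > criteria.min_angle
    )
    return accept, record


def _check_pair(donor: RoleAtom, acceptor: RoleAtom, criteria: HBondCriteria) -> HBond | None:
    """First passing H/AA combination for a donor-acceptor pair, if any."""
    if donor.atom.residue_id == acceptor.atom.residue_id:
        return None
    d_pos = donor.atom.position
    a_pos = acceptor.atom.position
    for h in donor.donor_hydrogens:
        for aa in acceptor.acceptor_antecedents:
            accept, rec = evaluate_candidate(d_pos, h.position, a_pos, aa.position, criteria)
            if accept:
                return HBond(
                    donor=donor,
                    hydrogen=h,
                    acceptor=acceptor,
                    antecedent=aa,
                    d_da=rec["d_DA"],
                    d_ha=rec["d_HA"],
                    ang_dha=rec["ang_DHA"],
                    ang_haaa=rec["ang_HAAA"],
                    ang_daaa=rec["ang_DAAA"],
                )
    return None


def _require_protonated(s: Structure) -> None:
    if not s.protonated and not any(a.is_hydrogen for a in s.atoms):
        raise ValueError(
            "structure carries no hydrogens; run place_hydrogens (or pass a "
            "pre-protonated structure) before hydrogen-bond detection"
        )


def find_hbonds(
    s: Structure,
    roles: list[RoleAtom] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """All feasible hydrogen bonds, via the lattice-accelerated search.

    For every donor, acceptors within the D-A ceiling are pulled from a
    cell-list radius query and each is tested with every donor hydrogen and
    antecedent; a pair is emitted once as soon as any combination passes.
    """
    _require_protonated(s)
    if roles is None:
        roles = assign_roles(s)
    acceptors = [r for r in roles if r.is_acceptor]
    donors = [r for r in roles if r.is_donor]
    grid = build_grid(acceptors, criteria.cell_size, position_of=lambda r: r.atom.position)
    bonds: list[HBond] = []
    for donor in donors:
        for acceptor in radius_query(grid, donor.atom.position, criteria.max_da):
            if acceptor.atom.serial == donor.atom.serial:
                continue
            bond = _check_pair(donor, acceptor, criteria)
            if bond is not None:
                bonds.append(bond)
    return bonds


def brute_force_hbond_search(
    s: Structure,
    roles: list[RoleAtom] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Exhaustive all-pairs reference search; same contract as find_hbonds."""
    _require_protonated(s)
    if roles is None:
        roles = assign_roles(s)
    bonds: list[HBond] = []
    for donor in roles:
        if not donor.is_donor:
            continue
        for acceptor in roles:
            if not acceptor.is_acceptor or acceptor.atom.serial == donor.atom.serial:
                continue
            bond = _check_pair(donor, acceptor, criteria)
            if bond is not None:
                bonds.append(bond)
    return bonds
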