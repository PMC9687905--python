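"""Reading, writing and cleaning of PDB-format protein structures.

The reader is deliberately strict about the fixed-column coordinate fields:
a malformed coordinate raises immediately with the offending line number,
rather than silently dropping or mis-reading the atom. Only the first MODEL
of multi-model (e.g. NMR) files is read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

import numpy as np

logger = logging.getLogger(__name__)

#: Three-letter codes of the 20 standard amino acids.
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBError(ValueError):
    """Raised for unreadable or structurally unusable PDB input."""


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM record.

    ``residue_seq`` keeps the author numbering; ``icode`` the insertion code
    (empty string when absent). ``parent_serial`` links a hydrogen to the
    serial of the heavy atom it is covalently attached to, when known.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_seq: int
    icode: str
    position: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    is_hetero: bool = False
    parent_serial: int | None = None

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, sequence number, insertion code) identifying the residue."""
        return (self.chain_id, self.residue_seq, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class Structure:
    """An ordered collection of atoms, optionally restricted to one chain."""

    atoms: list[AtomRecord] = field(default_factory=list)
    chain_id: str | None = None
    model_number: int = 1
    protonated: bool = False

    def __len__(self) -> int:
        return len(self.atoms)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residues(self) -> list[tuple[tuple[str, int, str], list[AtomRecord]]]:
        """Atoms grouped by residue, in file order."""
        order: list[tuple[str, int, str]] = []
        groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            key = a.residue_id
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(a)
        return [(k, groups[k]) for k in order]

    def find(self, residue_id: tuple[str, int, str], name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_id == residue_id and a.name == name:
                return a
        return None


def _infer_element(name_field: str) -> str:
    """Derive the element from columns 13-16 when columns 77-78 are blank."""
    stripped = name_field.strip()
    if not stripped:
        return ""
    # Hydrogens may be named like 1HB2 / HG11; digits lead only for H.
    if stripped[0].isdigit():
        stripped = stripped.lstrip("0123456789")
    if not stripped:
        return ""
    if stripped[0] in ("H", "D") and name_field[:1] != " ":
        # four-character names starting in column 13 are hydrogens
        return "H"
    two = name_field[:2].strip()
    if two in ("FE", "ZN", "MG", "MN", "CA", "NA", "CL", "BR", "SE"):
        return two[0] + two[1].lower()
    return stripped[0]


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise PDBError(f"line {lineno}: malformed {what} field {text.strip()!r}") from None
    if not np.isfinite(value):
        raise PDBError(f"line {lineno}: non-finite {what} field {text.strip()!r}")
    return value


def parse_pdb(stream: IO[str] | str) -> Structure:
    """Parse fixed-column PDB text into a :class:`Structure`.

    Returns every ATOM/HETATM record of the first model, in file order.
    Raises :class:`PDBError` for input without atoms or with malformed
    coordinate columns (the error names the line).
    """
    if isinstance(stream, str):
        lines: Iterable[str] = stream.splitlines()
    else:
        lines = stream

    atoms: list[AtomRecord] = []
    model_number = 1
    in_first_model = True
    for lineno, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            fields = line.split()
            if atoms:
                in_first_model = False
            elif len(fields) > 1:
                model_number = int(fields[1])
        elif rec.startswith("ENDMDL"):
            if atoms:
                in_first_model = False
        elif rec in ("ATOM  ", "HETATM") and in_first_model:
            if len(line.rstrip("\n")) < 54:
                raise PDBError(f"line {lineno}: truncated coordinate record")
            x = _parse_float(line[30:38], "x coordinate", lineno)
            y = _parse_float(line[38:46], "y coordinate", lineno)
            z = _parse_float(line[46:54], "z coordinate", lineno)
            occ_field = line[54:60]
            occupancy = _parse_float(occ_field, "occupancy", lineno) if occ_field.strip() else 1.0
            try:
                serial = int(line[6:11])
            except ValueError:
                serial = len(atoms) + 1
            name_field = line[12:16]
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = _infer_element(name_field)
            element = element[0].upper() + element[1:].lower() if element else ""
            try:
                residue_seq = int(line[22:26])
            except ValueError:
                raise PDBError(f"line {lineno}: malformed residue number {line[22:26]!r}") from None
            atoms.append(
                AtomRecord(
                    serial=serial,
                    name=name_field.strip(),
                    element=element,
                    residue_name=line[17:20].strip(),
                    chain_id=line[21].strip() or " ",
                    residue_seq=residue_seq,
                    icode=line[26].strip(),
                    position=np.array([x, y, z], dtype=float),
                    occupancy=occupancy,
                    altloc=line[16].strip(),
                    is_hetero=rec == "HETATM",
                )
            )
    if not atoms:
        raise PDBError("no atoms: input contains no ATOM/HETATM records")
    return Structure(atoms=atoms, model_number=model_number)


def strip_nonprotein(s: Structure, chain: str | None = None) -> Structure:
    """Keep one chain of standard amino-acid ATOM records, no hydrogens.

    Waters, ions and ligands (HETATM), hydrogens/deuteriums, and nonstandard
    residues are removed. For alternate locations the highest-occupancy
    conformer is kept (ties broken toward altloc 'A'). ``chain=None`` selects
    the first chain in the file.
    """
    available = s.chains()
    if chain is None:
        chain = available[0]
    if chain not in available:
        raise PDBError(f"chain {chain!r} not present; available chains: {', '.join(available)}")

    n_water = n_het = n_hydro = 0
    dropped_res: set[str] = set()
    kept: list[AtomRecord] = []
    for a in s.atoms:
        if a.chain_id != chain:
            continue
        if a.residue_name in _WATER_NAMES:
            n_water += 1
            continue
        if a.is_hetero or a.residue_name not in STANDARD_RESIDUES:
            if a.residue_name not in STANDARD_RESIDUES and not a.is_hetero:
                dropped_res.add(a.residue_name)
            n_het += 1
            continue
        if a.is_hydrogen:
            n_hydro += 1
            continue
        kept.append(a)

    # alternate locations: one conformer per (residue, atom name)
    best: dict[tuple, AtomRecord] = {}
    order: list[tuple] = []
    for a in kept:
        key = (a.residue_id, a.name)
        if key not in best:
            best[key] = a
            order.append(key)
        else:
            b = best[key]
            if (a.occupancy, _altloc_rank(a.altloc)) > (b.occupancy, _altloc_rank(b.altloc)):
                best[key] = a
    deduped = [replace(best[k], altloc="") for k in order]

    if dropped_res:
        logger.warning("dropped nonstandard residues: %s", ", ".join(sorted(dropped_res)))
    logger.info(
        "strip_nonprotein: removed %d water, %d hetero/nonstandard, %d hydrogen atoms; kept %d",
        n_water, n_het, n_hydro, len(deduped),
    )
    return Structure(atoms=deduped, chain_id=chain, model_number=s.model_number, protonated=False)


def _altloc_rank(altloc: str) -> int:
    # ties at equal occupancy prefer 'A' (then blank, then later letters inverted)
    if altloc == "A":
        return 2
    if altloc == "":
        return 1
    return -ord(altloc)


def write_pdb(s: Structure, stream: IO[str] | None = None) -> str:
    """Serialize a Structure as fixed-column PDB text."""
    out: list[str] = []
    for i, a in enumerate(s.atoms, start=1):
        rec = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name
        # standard alignment: element in columns 13-14 for 1/2-letter elements
        if len(name) < 4:
            name = f" {name:<3s}" if len(a.element) == 1 else f"{name:<4s}"
        x, y, z = a.position
        out.append(
            f"{rec}{i:5d} {name:<4.4s}{a.altloc or ' ':1.1s}{a.residue_name:>3s} "
            f"{a.chain_id:1.1s}{a.residue_seq:4d}{a.icode or ' ':1.1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2.2s}"
        )
    out.append("END")
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text
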