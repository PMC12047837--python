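"""PDB coordinate I/O and a light atomic container.

Parsing is delegated to :mod:`gemmi`; on top of it this module enforces the
single-conformer policy used throughout the structural screen (keep blank
altlocs, otherwise the highest-occupancy conformer, ties broken by altloc
letter) and exposes the handful of views the analysis needs: chains, per-chain
Cα traces with one-letter sequences, and single-atom HETATM metal ions.

Coordinates are Cartesian Å. Residue numbering is kept exactly as printed in
the file; nothing is renumbered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

#: elements treated as metal ions when they appear as single-atom HETATM groups
METAL_ELEMENTS = frozenset(
    {"ZN", "CA", "MG", "MN", "FE", "CU", "NI", "CO", "NA", "K", "CD"}
)


class StructureError(ValueError):
    """Raised for malformed or invalid coordinate files."""


@dataclass(frozen=True)
class Atom:
    record_kind: str  # "ATOM" or "HETATM"
    serial: int
    name: str
    altloc: str
    resname: str
    chain: str
    resseq: int
    icode: str
    x: float
    y: float
    z: float
    element: str

    def __post_init__(self) -> None:
        if self.record_kind not in ("ATOM", "HETATM"):
            raise StructureError(f"bad record kind {self.record_kind!r}")
        if self.serial < 1:
            raise StructureError(f"atom serial must be >= 1, got {self.serial}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise StructureError(f"non-finite coordinates for atom {self.serial}")
        if not self.element:
            raise StructureError(f"atom {self.serial} has no element")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Residue:
    chain: str
    resname: str
    resseq: int
    icode: str
    atoms: list[Atom]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    """An ordered list of atoms with chain / residue / metal views."""

    id: str
    atoms: list[Atom] = field(default_factory=list)

    # -- views ------------------------------------------------------------

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain not in seen:
                seen.append(a.chain)
        return seen

    def chain_atoms(self, chain: str) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain]

    def residues(self, chain: str | None = None, polymer_only: bool = True) -> list[Residue]:
        """Residues in file order, grouped by (chain, resseq, icode)."""
        out: list[Residue] = []
        key = None
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if polymer_only and a.record_kind != "ATOM":
                continue
            k = (a.chain, a.resseq, a.icode, a.resname)
            if k != key:
                out.append(Residue(a.chain, a.resname, a.resseq, a.icode, []))
                key = k
            out[-1].atoms.append(a)
        return out

    def metal_ions(self) -> list[Atom]:
        """Single-atom HETATM groups whose element is a metal."""
        ions: list[Atom] = []
        groups: dict[tuple, list[Atom]] = {}
        for a in self.atoms:
            if a.record_kind != "HETATM":
                continue
            groups.setdefault((a.chain, a.resseq, a.icode, a.resname), []).append(a)
        for atoms in groups.values():
            if len(atoms) == 1 and atoms[0].element.upper() in METAL_ELEMENTS:
                ions.append(atoms[0])
        return ions

    def chain_sequence(self, chain: str) -> tuple[str, list[Residue]]:
        """One-letter sequence of a chain's polymer residues (X if unknown)."""
        residues = self.residues(chain=chain)
        letters = []
        for r in residues:
            info = gemmi.find_tabulated_residue(r.resname)
            one = info.one_letter_code.upper() if info and info.is_amino_acid() else "X"
            letters.append(one if one.isalpha() else "X")
        return "".join(letters), residues

    # -- operations -------------------------------------------------------

    def subset(
        self,
        chains: Sequence[str] | None = None,
        resseq_range: tuple[int, int] | None = None,
        polymer_only: bool = False,
    ) -> "Structure":
        """Restrict to the given chains and/or residue-number range.

        ``resseq_range`` is inclusive and applies to polymer residues only;
        HETATM records are kept unless ``polymer_only`` is set.
        """
        kept = []
        for a in self.atoms:
            if chains is not None and a.chain not in chains:
                continue
            if polymer_only and a.record_kind != "ATOM":
                continue
            if (
                resseq_range is not None
                and a.record_kind == "ATOM"
                and not (resseq_range[0] <= a.resseq <= resseq_range[1])
            ):
                continue
            kept.append(a)
        return Structure(id=self.id, atoms=kept)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to ``R @ x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_atoms = []
        for a in self.atoms:
            v = R @ a.xyz + t
            new_atoms.append(replace(a, x=float(v[0]), y=float(v[1]), z=float(v[2])))
        return Structure(id=self.id, atoms=new_atoms)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)


def _validate_coordinate_columns(path: Path) -> None:
    # gemmi is forgiving about garbled numeric fields; fail loudly instead,
    # naming the offending line.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    try:
                        float(fld)
                    except ValueError:
                        raise StructureError(
                            f"{path}: malformed coordinate field {fld!r} on line {lineno}"
                        ) from None


def _pick_conformers(atoms: list[Atom]) -> list[Atom]:
    # keep blank altlocs; among lettered altlocs for the same atom keep the
    # one the policy prefers (they arrive occupancy-sorted from the caller)
    return atoms


def read_structure(path: str | Path, id: str | None = None) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Alternate locations are collapsed to a single conformer: blank altlocs are
    kept as-is; where a residue's atom appears with several altloc letters the
    highest-occupancy copy wins, ties broken by altloc letter.
    """
    path = Path(path)
    _validate_coordinate_columns(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: {exc}") from exc
    st.setup_entities()

    atoms: list[Atom] = []
    for model in st:
        for chain in model:
            for res in chain:
                # collapse altlocs per atom name
                by_name: dict[str, gemmi.Atom] = {}
                for at in res:
                    altloc = at.altloc if at.altloc != "\x00" else ""
                    prev = by_name.get(at.name)
                    if prev is None:
                        by_name[at.name] = at
                        continue
                    prev_alt = prev.altloc if prev.altloc != "\x00" else ""
                    if altloc == "":
                        by_name[at.name] = at
                    elif prev_alt != "" and (
                        at.occ > prev.occ or (at.occ == prev.occ and altloc < prev_alt)
                    ):
                        by_name[at.name] = at
                kind = "HETATM" if res.het_flag == "H" else "ATOM"
                for at in by_name.values():
                    elem = at.element.name.upper() if at.element else ""
                    if not elem or elem == "X":
                        elem = "".join(c for c in at.name if c.isalpha())[:2].upper()
                    atoms.append(
                        Atom(
                            record_kind=kind,
                            serial=max(at.serial, 1),
                            name=at.name,
                            altloc=(at.altloc if at.altloc != "\x00" else ""),
                            resname=res.name,
                            chain=chain.name,
                            resseq=res.seqid.num,
                            icode=(res.seqid.icode.strip() or ""),
                            x=at.pos.x,
                            y=at.pos.y,
                            z=at.pos.z,
                            element=elem,
                        )
                    )
        break  # first model only
    if not atoms:
        raise StructureError(f"{path}: no ATOM/HETATM records found")
    return Structure(id=id or path.stem, atoms=atoms)


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a Structure as fixed-column PDB (coordinates to 0.001 Å)."""
    lines = []
    for a in structure.atoms:
        name = a.name
        if len(name) < 4 and len(a.element) == 1:
            name = " " + name
        lines.append(
            f"{a.record_kind:<6}{a.serial:>5} {name:<4}{a.altloc or ' ':1}"
            f"{a.resname:>3} {a.chain:1}{a.resseq:>4}{a.icode or ' ':1}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
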