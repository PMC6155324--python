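"""Structure model and PDB I/O.

A :class:`Structure` is a flat list of residues carrying heavy (and
optionally hydrogen) atoms, plus a two-sided chain partition that defines
which chains form each binding partner.  Parsing is delegated to
Biopython's PDB parser; only the first model is kept, alternate locations
are resolved to the highest-occupancy conformer, and waters/hetero
ligands are excluded by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Partition",
    "read_pdb",
    "extract_monomer",
    "write_pdb",
    "parse_partition",
    "VDW_RADII",
    "THREE_TO_ONE",
    "NONSTANDARD_PARENT",
]

#: Van der Waals radii in Angstrom (fixed published set; configurable via
#: the ``vdw_radii`` argument of read_pdb).  Unknown elements fall back to
#: the carbon radius.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Common nonstandard residues mapped to their parent standard type.
NONSTANDARD_PARENT: dict[str, str] = {
    "MSE": "MET", "SEC": "CYS", "PYL": "LYS", "HYP": "PRO",
    "SEP": "SER", "TPO": "THR", "PTR": "TYR", "CSO": "CYS",
    "MLY": "LYS", "M3L": "LYS",
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray
    vdw_radius: float

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    icode: str
    aa_type: str  # one-letter code, or "X" for unmapped nonstandard
    resname: str  # original three-letter name
    atoms: list[Atom] = field(default_factory=list)
    is_standard: bool = True

    @property
    def rid(self) -> tuple[str, int, str]:
        """Unique residue key within a structure."""
        return (self.chain_id, self.seq_number, self.icode)

    @property
    def label(self) -> str:
        ic = self.icode.strip()
        return f"{self.resname}{self.seq_number}{ic}:{self.chain_id}"

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.heavy_atoms], dtype=float)


@dataclass(frozen=True)
class Partition:
    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self):
        if not self.side_a or not self.side_b:
            raise ValueError("each partition side needs at least one chain")
        if self.side_a & self.side_b:
            raise ValueError("partition sides must be disjoint")

    def side_of(self, chain_id: str) -> str:
        if chain_id in self.side_a:
            return "A"
        if chain_id in self.side_b:
            return "B"
        raise KeyError(f"chain {chain_id!r} not in partition")

    @property
    def chains(self) -> frozenset[str]:
        return self.side_a | self.side_b


def parse_partition(spec: str) -> Partition:
    """Parse a CLI partition spec like ``"A:C"`` or ``"A,B:C,D"``."""
    try:
        left, right = spec.split(":")
    except ValueError as exc:
        raise ValueError(f"partition spec {spec!r} must contain one ':'") from exc
    return Partition(
        frozenset(c.strip() for c in left.split(",") if c.strip()),
        frozenset(c.strip() for c in right.split(",") if c.strip()),
    )


@dataclass
class Structure:
    residues: list[Residue]
    partition: Partition | None = None
    name: str = ""

    def __post_init__(self):
        seen = set()
        for r in self.residues:
            if r.rid in seen:
                raise ValueError(f"duplicate residue id {r.rid}")
            seen.add(r.rid)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if r.chain_id not in out:
                out.append(r.chain_id)
        return out

    def by_rid(self) -> dict[tuple[str, int, str], Residue]:
        return {r.rid: r for r in self.residues}

    def chain(self, chain_id: str) -> list[Residue]:
        return [r for r in self.residues if r.chain_id == chain_id]

    def heavy_atom_count(self) -> int:
        return sum(len(r.heavy_atoms) for r in self.residues)

    def side_of(self, residue: Residue) -> str:
        if self.partition is None:
            raise ValueError("structure has no partition")
        return self.partition.side_of(residue.chain_id)


def _residue_from_biopdb(bres, chain_id: str, vdw_radii: dict[str, float],
                         keep_hydrogens: bool) -> Residue | None:
    resname = bres.get_resname().strip()
    hetflag, seqnum, icode = bres.get_id()
    standard = True
    if resname in THREE_TO_ONE:
        aa = THREE_TO_ONE[resname]
    elif resname in NONSTANDARD_PARENT:
        aa = THREE_TO_ONE[NONSTANDARD_PARENT[resname]]
    elif is_aa(bres, standard=False):
        aa, standard = "X", False
    else:
        return None  # ligand/water handled by caller
    atoms = []
    for batom in bres.get_atoms():
        # Biopython's DisorderedAtom iterates conformers; selected child is
        # the highest-occupancy altloc.
        element = (batom.element or "").strip().upper() or batom.get_name()[0]
        if element == "H" and not keep_hydrogens:
            continue
        atoms.append(Atom(
            name=batom.get_name(),
            element=element,
            coord=np.asarray(batom.get_coord(), dtype=float),
            vdw_radius=vdw_radii.get(element, vdw_radii["C"]),
        ))
    heavy = [a for a in atoms if a.is_heavy]
    if not heavy:
        warnings.warn(
            f"residue {resname}{seqnum}:{chain_id} has no heavy atoms; skipped")
        return None
    if not np.isfinite(np.array([a.coord for a in atoms])).all():
        raise ValueError(f"non-finite coordinates in {resname}{seqnum}:{chain_id}")
    return Residue(chain_id=chain_id, seq_number=seqnum, icode=icode,
                   aa_type=aa, resname=resname, atoms=atoms,
                   is_standard=standard)


def read_pdb(path, partition_spec: str | Partition, *,
             include_hetero: bool = False,
             keep_hydrogens: bool = True,
             vdw_radii: dict[str, float] | None = None,
             name: str = "") -> Structure:
    """Read a PDB file into a partitioned :class:`Structure`.

    Only the first model is used; altlocs resolve to highest occupancy;
    waters are always dropped and other hetero ligands are dropped unless
    ``include_hetero``.  Hydrogens are retained on the atom lists if
    present but excluded from every heavy-atom view.

    Raises ``ValueError`` if a partition chain is absent from the file.
    """
    partition = (partition_spec if isinstance(partition_spec, Partition)
                 else parse_partition(partition_spec))
    radii = dict(VDW_RADII)
    if vdw_radii:
        radii.update(vdw_radii)
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("s", str(path)).get_models())
    residues: list[Residue] = []
    for chain in model:
        for bres in chain:
            hetflag = bres.get_id()[0]
            if hetflag == "W":
                continue
            if hetflag.startswith("H_") and not include_hetero \
                    and bres.get_resname().strip() not in NONSTANDARD_PARENT:
                continue
            res = _residue_from_biopdb(bres, chain.id, radii, keep_hydrogens)
            if res is not None:
                residues.append(res)
    present = {r.chain_id for r in residues}
    missing = partition.chains - present
    if missing:
        raise ValueError(f"partition chains {sorted(missing)} not present in "
                         f"{path} (found {sorted(present)})")
    residues = [r for r in residues if r.chain_id in partition.chains]
    return Structure(residues=residues, partition=partition,
                     name=name or str(path))


def extract_monomer(structure: Structure, side: str) -> Structure:
    """Return the single-side sub-structure (chains of ``side`` only).

    Residue identities and atom records are shared, not copied; the
    monomer keeps a degenerate partition mapping all its chains to the
    requested side so downstream code can still ask for chain sides.
    """
    if side not in ("A", "B"):
        raise ValueError("side must be 'A' or 'B'")
    if structure.partition is None:
        raise ValueError("structure has no partition")
    chains = (structure.partition.side_a if side == "A"
              else structure.partition.side_b)
    residues = [r for r in structure.residues if r.chain_id in chains]
    return Structure(residues=residues, partition=structure.partition,
                     name=f"{structure.name}|side{side}")


def write_pdb(structure: Structure, path) -> None:
    """Write ATOM records (minimal PDB) suitable for round-tripping."""
    serial = 1
    with open(path, "w") as fh:
        for res in structure.residues:
            for atom in res.atoms:
                name = atom.name
                # PDB column convention: 1-char elements start at col 14
                pad = f" {name:<3s}" if len(name) < 4 and len(atom.element) == 1 else f"{name:<4s}"
                x, y, z = atom.coord
                fh.write(
                    f"ATOM  {serial:5d} {pad}{'':1s}{res.resname:<3s} "
                    f"{res.chain_id:1s}{res.seq_number:4d}{res.icode or ' ':1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {atom.element:>2s}\n")
                serial += 1
        fh.write("END\n")
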