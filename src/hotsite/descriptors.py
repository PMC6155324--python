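"""Per-residue site descriptors: amino-acid property tables, PSSM /
DSSP / disorder / generic-track readers, conservation entropy,
secondary-structure encoding and residue-pair contact potentials.

The canonical ordered site-feature list (:data:`SITE_FEATURES`, 102
names) is fixed here; the assembled table carries 6x that many columns
(raw/weighted x site/Euclidean/Voronoi contexts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .neighbors import NeighborGraph
from .structure import Residue, Structure

__all__ = [
    "AA_ORDER",
    "PHYSCHEM_NAMES",
    "SITE_FEATURES",
    "PLUGGABLE_FEATURES",
    "MISSING",
    "PSSMProfile",
    "physicochemical",
    "pka_values",
    "conservation_score",
    "blosum_row",
    "pssm_row",
    "secondary_structure",
    "assign_secondary_structure",
    "disorder_scores",
    "pair_potential",
    "default_pair_potential_matrix",
    "read_pssm",
    "read_dssp",
    "read_disopred",
    "read_disembl",
    "read_residue_tsv",
    "read_hb2",
    "dihedral",
]

#: Alphabetical one-letter ordering used for every 20-vector block.
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST column ordering in ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"

#: Missing-value sentinel (never silently zero).
MISSING = float("nan")

PHYSCHEM_NAMES = [
    "Hydrophobicity",   # Kyte-Doolittle
    "Hydrophilicity",   # Hopp-Woods
    "Polarity",         # Grantham
    "Polarizability",   # Charton-Charton
    "Propensity",       # Chou-Fasman helix propensity
    "AvgASA",           # mean standard-state accessible area
    "NumAtoms",         # heavy atoms per residue
    "NEC",              # electrostatic charge count
    "NPHB",             # potential hydrogen-bonding groups
    "Mass",             # residue mass
    "EIIP",             # electron-ion interaction pseudopotential
    "PSHP",             # pseudo hydrophobicity (min-max rescaled KD)
]

# fmt: off
_PHYSCHEM: dict[str, list[float]] = {
    #      KD     HW    Pol  Polz   Pa    ASA    At NEC NPHB   Mass    EIIP
    "A": [ 1.8, -0.5,  8.1, 0.046, 1.42, 118.1,  5, 0, 0,  71.08, 0.0373],
    "C": [ 2.5, -1.0,  5.5, 0.128, 0.70, 146.1,  6, 0, 1, 103.14, 0.0829],
    "D": [-3.5,  3.0, 13.0, 0.105, 1.01, 158.7,  8, 1, 4, 115.09, 0.1263],
    "E": [-3.5,  3.0, 12.3, 0.151, 1.51, 186.2,  9, 1, 4, 129.12, 0.0058],
    "F": [ 2.8, -2.5,  5.2, 0.290, 1.13, 222.8, 11, 0, 0, 147.18, 0.0946],
    "G": [-0.4,  0.0,  9.0, 0.000, 0.57,  88.1,  4, 0, 0,  57.05, 0.0050],
    "H": [-3.2, -0.5, 10.4, 0.230, 1.00, 202.5, 10, 1, 2, 137.14, 0.0242],
    "I": [ 4.5, -1.8,  5.2, 0.186, 1.08, 181.0,  8, 0, 0, 113.16, 0.0000],
    "K": [-3.9,  3.0, 11.3, 0.219, 1.16, 225.8,  9, 1, 2, 128.17, 0.0371],
    "L": [ 3.8, -1.8,  4.9, 0.186, 1.21, 193.1,  8, 0, 0, 113.16, 0.0000],
    "M": [ 1.9, -1.3,  5.7, 0.221, 1.45, 203.4,  8, 0, 1, 131.19, 0.0823],
    "N": [-3.5,  0.2, 11.6, 0.134, 0.67, 165.5,  8, 0, 4, 114.10, 0.0036],
    "P": [-1.6,  0.0,  8.0, 0.131, 0.57, 146.8,  7, 0, 0,  97.12, 0.0198],
    "Q": [-3.5,  0.2, 10.5, 0.180, 1.11, 193.2,  9, 0, 4, 128.13, 0.0761],
    "R": [-4.5,  3.0, 10.5, 0.291, 0.98, 256.0, 11, 1, 4, 156.19, 0.0959],
    "S": [-0.8,  0.3,  9.2, 0.062, 0.77, 129.8,  6, 0, 2,  87.08, 0.0829],
    "T": [-0.7, -0.4,  8.6, 0.108, 0.83, 152.5,  7, 0, 2, 101.10, 0.0941],
    "V": [ 4.2, -1.5,  5.9, 0.140, 1.06, 164.5,  7, 0, 0,  99.13, 0.0057],
    "W": [-0.9, -3.4,  5.4, 0.409, 1.08, 266.3, 14, 0, 1, 186.21, 0.0548],
    "Y": [-1.3, -2.3,  6.2, 0.298, 0.69, 236.8, 12, 0, 2, 163.18, 0.0516],
}

#: Free-amino-acid pKa1 (alpha-carboxyl) and pKa2 (alpha-amino),
#: Lehninger-style side-chain environment table.
PKA_TABLE: dict[str, tuple[float, float]] = {
    "A": (2.34, 9.69), "C": (1.96, 10.28), "D": (1.88, 9.60),
    "E": (2.19, 9.67), "F": (1.83, 9.13), "G": (2.34, 9.60),
    "H": (1.82, 9.17), "I": (2.36, 9.68), "K": (2.18, 8.95),
    "L": (2.36, 9.60), "M": (2.28, 9.21), "N": (2.02, 8.80),
    "P": (1.99, 10.96), "Q": (2.17, 9.13), "R": (2.17, 9.04),
    "S": (2.21, 9.15), "T": (2.11, 9.62), "V": (2.32, 9.62),
    "W": (2.38, 9.39), "Y": (2.20, 9.11),
}
# fmt: on

_KD = {aa: v[0] for aa, v in _PHYSCHEM.items()}
_KD_MIN, _KD_MAX = min(_KD.values()), max(_KD.values())


def physicochemical(aa_type: str) -> np.ndarray:
    """12-vector of physicochemical properties (order in
    :data:`PHYSCHEM_NAMES`); all-NaN for nonstandard types."""
    if aa_type not in _PHYSCHEM:
        return np.full(12, MISSING)
    base = list(_PHYSCHEM[aa_type])
    pshp = (_KD[aa_type] - _KD_MIN) / (_KD_MAX - _KD_MIN)
    return np.array(base + [pshp], dtype=float)


def pka_values(aa_type: str) -> np.ndarray:
    if aa_type not in PKA_TABLE:
        return np.full(2, MISSING)
    return np.array(PKA_TABLE[aa_type], dtype=float)


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum_row(aa_type: str) -> np.ndarray:
    """BLOSUM62 substitution row in :data:`AA_ORDER` ordering."""
    if aa_type not in AA_ORDER:
        return np.full(20, MISSING)
    return np.array([_BLOSUM62[aa_type, b] for b in AA_ORDER], dtype=float)


# --------------------------------------------------------------------------
# PSSM

@dataclass
class PSSMProfile:
    """Parsed PSI-BLAST position-specific scoring matrix.

    ``scores`` and ``freqs`` are (L, 20) arrays in :data:`AA_ORDER`
    column order; ``freqs`` are in [0, 1].  Positions are 1-based.
    """

    sequence: str
    scores: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        if self.freqs.min() < 0 or self.freqs.max() > 1 + 1e-9:
            raise ValueError("PSSM frequencies must lie in [0, 1]")
        if (self.freqs.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("PSSM frequency rows must sum to <= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def read_pssm(path) -> PSSMProfile:
    """Read a PSI-BLAST ``-out_ascii_pssm`` file.

    Percent frequencies are normalized to [0, 1]; columns are reordered
    from PSI-BLAST order to alphabetical :data:`AA_ORDER`.
    """
    seq, score_rows, freq_rows = [], [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 42 or not parts[0].isdigit():
                continue
            seq.append(parts[1])
            score_rows.append([float(x) for x in parts[2:22]])
            freq_rows.append([float(x) / 100.0 for x in parts[22:42]])
    if not seq:
        raise ValueError(f"no PSSM rows found in {path}")
    reorder = [PSIBLAST_ORDER.index(a) for a in AA_ORDER]
    scores = np.array(score_rows)[:, reorder]
    freqs = np.array(freq_rows)[:, reorder]
    return PSSMProfile(sequence="".join(seq), scores=scores, freqs=freqs)


def pssm_row(pssm: PSSMProfile, position: int) -> np.ndarray:
    """Log-odds 20-vector at 1-based ``position`` (:data:`AA_ORDER` order)."""
    if not 1 <= position <= len(pssm):
        raise IndexError(f"position {position} out of range 1..{len(pssm)}")
    return pssm.scores[position - 1].copy()


def conservation_score(pssm: PSSMProfile, position: int) -> float:
    """Shannon entropy of the frequency row: -sum p log2 p, in
    [0, log2 20]; lower means more conserved.  0*log0 counts as 0."""
    if not 1 <= position <= len(pssm):
        raise IndexError(f"position {position} out of range 1..{len(pssm)}")
    p = pssm.freqs[position - 1]
    if p.sum() <= 0:
        raise ValueError(f"all-zero frequency row at position {position}")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


# --------------------------------------------------------------------------
# Secondary structure

_HELIX, _SHEET = "GHI", "BE"


def _ss_class(letter: str) -> str:
    if letter in _HELIX:
        return "H"
    if letter in _SHEET:
        return "E"
    return "C"  # T, S and blank


def secondary_structure(ss_class: str) -> np.ndarray:
    """One-hot (helix, sheet, coil) for a 'H'/'E'/'C' class letter."""
    return np.array({
        "H": (1.0, 0.0, 0.0),
        "E": (0.0, 1.0, 0.0),
        "C": (0.0, 0.0, 1.0),
    }[ss_class])


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


def _phi_psi(chain: list[Residue], idx: int) -> tuple[float | None, float | None]:
    res = chain[idx]
    n, ca, c = res.atom("N"), res.atom("CA"), res.atom("C")
    phi = psi = None
    if n is not None and ca is not None and c is not None:
        if idx > 0:
            prev_c = chain[idx - 1].atom("C")
            if prev_c is not None:
                phi = dihedral(prev_c.coord, n.coord, ca.coord, c.coord)
        if idx + 1 < len(chain):
            next_n = chain[idx + 1].atom("N")
            if next_n is not None:
                psi = dihedral(n.coord, ca.coord, c.coord, next_n.coord)
    return phi, psi


def _fallback_ss(phi: float | None, psi: float | None) -> str:
    def helixish(a, lo, hi):
        return a is not None and lo < a < hi

    phi_h = helixish(phi, -100, -30)
    psi_h = helixish(psi, -80, -5)
    if (phi_h and psi_h) or (phi is None and psi_h) or (psi is None and phi_h):
        return "H"
    phi_e = helixish(phi, -180, -70)
    psi_e = psi is not None and (psi > 90 or psi < -150)
    if (phi_e and psi_e) or (phi is None and psi_e) \
            or (psi is None and phi_e):
        return "E"
    return "C"


def assign_secondary_structure(structure: Structure,
                               dssp_track: dict | None = None,
                               ) -> dict[tuple, str]:
    """'H'/'E'/'C' per residue, from a DSSP track when supplied, else
    from backbone phi/psi geometry."""
    out: dict[tuple, str] = {}
    for chain_id in structure.chain_ids:
        chain = structure.chain(chain_id)
        for idx, res in enumerate(chain):
            if dssp_track is not None and res.rid in dssp_track:
                out[res.rid] = _ss_class(dssp_track[res.rid][0])
            else:
                out[res.rid] = _fallback_ss(*_phi_psi(chain, idx))
    return out


# --------------------------------------------------------------------------
# External track readers

def read_dssp(path) -> dict[tuple, tuple[str, float]]:
    """Minimal DSSP reader: {rid: (ss_letter, accessibility)}.

    Parses the fixed-column data section after the '#  RESIDUE' header.
    """
    out: dict[tuple, tuple[str, float]] = {}
    in_data = False
    with open(path) as fh:
        for line in fh:
            if line.lstrip().startswith("#  RESIDUE"):
                in_data = True
                continue
            if not in_data or len(line) < 38:
                continue
            if line[13] == "!":  # chain break
                continue
            try:
                resnum = int(line[5:10])
            except ValueError:
                continue
            icode = line[10].strip() or " "
            chain = line[11]
            ss = line[16].strip() or " "
            acc = float(line[34:38])
            out[(chain, resnum, icode)] = (ss, acc)
    if not out:
        raise ValueError(f"no DSSP records found in {path}")
    return out


def read_disopred(path) -> list[tuple[str, str, float]]:
    """DISOPRED-style track: per sequence position (aa, state, score).

    Lines: ``<idx> <aa> <mark> <score>`` with mark '*' = disordered.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4 or not parts[0].isdigit():
                continue
            rows.append((parts[1], parts[2], float(parts[3])))
    if not rows:
        raise ValueError(f"no disorder records found in {path}")
    return rows


def read_disembl(path) -> list[tuple[str, float, float, float]]:
    """DisEMBL-style TSV: per position (aa, coils, rem465, hotloops)."""
    rows: list[tuple[str, float, float, float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 5 or not parts[0].isdigit():
                continue
            rows.append((parts[1], float(parts[2]), float(parts[3]),
                         float(parts[4])))
    if not rows:
        raise ValueError(f"no disorder records found in {path}")
    return rows


def disorder_scores(disopred_rows, disembl_rows, position: int,
                    chain_length: int | None = None) -> np.ndarray:
    """6-vector for a 1-based chain ``position``:
    (disopred score, disopred state, coils, rem465, hotloops, mean).

    Positions beyond either track get NaN sentinels with a warning.
    """
    vec = np.full(6, MISSING)
    idx = position - 1
    if 0 <= idx < len(disopred_rows):
        _, state, score = disopred_rows[idx]
        vec[0] = score
        vec[1] = 1.0 if state == "*" else 0.0
    else:
        warnings.warn(f"position {position} beyond disorder track "
                      f"({len(disopred_rows)} rows)")
    if 0 <= idx < len(disembl_rows):
        vec[2:5] = disembl_rows[idx][1:4]
    else:
        warnings.warn(f"position {position} beyond disorder track "
                      f"({len(disembl_rows)} rows)")
    known = vec[[0, 2, 3, 4]]
    if not np.isnan(known).any():
        vec[5] = known.mean()
    return vec


def read_residue_tsv(path) -> dict[tuple, dict[str, float]]:
    """Generic per-residue value file: header line
    ``chain resnum icode <name>...``, keyed by residue id so row order
    is irrelevant."""
    out: dict[tuple, dict[str, float]] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if header[:3] != ["chain", "resnum", "icode"]:
            raise ValueError(f"{path}: expected 'chain resnum icode ...' header")
        names = header[3:]
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            chain, resnum, icode = parts[0], int(parts[1]), parts[2]
            icode = " " if icode == "-" else icode
            values = {n: float(v) for n, v in zip(names, parts[3:])}
            out[(chain, resnum, icode)] = values
    return out


def read_hb2(path) -> dict[tuple, float]:
    """HBPLUS ``.hb2`` reader: hydrogen-bond count per residue.

    Donor/acceptor fields look like ``A0042-LYS NZ``; each bond
    increments both partners.
    """
    counts: dict[tuple, float] = {}

    def bump(field: str) -> None:
        chain = field[0]
        resnum = int(field[1:5])
        icode = field[5] if field[5] != "-" else " "
        rid = (chain, resnum, icode)
        counts[rid] = counts.get(rid, 0.0) + 1.0

    with open(path) as fh:
        for line in fh:
            if len(line) < 27 or line[5] not in "- ABCDEFGHIJKLMNOPQRSTUVWXYZ":
                continue
            donor, acceptor = line[0:9], line[14:23]
            if donor[6:9].strip().isalpha() and acceptor[6:9].strip().isalpha():
                try:
                    bump(donor)
                    bump(acceptor)
                except (ValueError, IndexError):
                    continue
    return counts


# --------------------------------------------------------------------------
# Pair potentials

def default_pair_potential_matrix() -> dict[tuple[str, str], float]:
    """Shipped symmetric residue-contact potential.

    A documented hydrophobicity-derived stand-in,
    e(a, b) = -(h_a + h_b) / 20 on the Kyte-Doolittle scale (favorable,
    i.e. negative, for hydrophobic pairs); the matrix is a configuration
    point of :func:`pair_potential` and can be replaced wholesale.
    """
    return {(a, b): -(_KD[a] + _KD[b]) / 20.0
            for a in AA_ORDER for b in AA_ORDER}


def pair_potential(structure: Structure, graph: NeighborGraph,
                   residue: Residue,
                   matrix: dict[tuple[str, str], float] | None = None,
                   ) -> np.ndarray:
    """(Ppm, Ppc, Delpp): summed contact potentials over the residue's
    graph neighbors in its own monomer, in the complex, and their
    difference.

    Distance-based adjacency is unchanged by splitting the complex, so
    the monomer sum is the same-side restriction of the complex sum.
    """
    mat = matrix if matrix is not None else default_pair_potential_matrix()
    if residue.aa_type not in AA_ORDER:
        return np.full(3, MISSING)
    by_rid = structure.by_rid()
    own_side = structure.side_of(residue) if structure.partition else None
    ppc = ppm = 0.0
    for nb_rid in graph.neighbors(residue.rid):
        nb = by_rid.get(nb_rid)
        if nb is None or nb.aa_type not in AA_ORDER:
            continue
        e = mat[(residue.aa_type, nb.aa_type)]
        ppc += e
        if own_side is None or structure.side_of(nb) == own_side:
            ppm += e
    return np.array([ppm, ppc, ppc - ppm])


# --------------------------------------------------------------------------
# Canonical site-feature list

PLUGGABLE_FEATURES = (
    ["Cscore", "TOP", "FourBody"]
    + [f"SCE{i}" for i in range(1, 7)]
    + [f"LSE{i}" for i in range(1, 4)]
    + ["NearbyInterface"]
)

_ASA_BLOCK = ["AsaComplex", "AsaMonomer", "DeltaAsa",
              "RelAsaComplex", "RelAsaMonomer", "Wfb"]
_CONTACT_BLOCK = ["Nacc", "Nacm", "Delnac", "Ncrc", "Ncrm", "Delncr"]
_EXPOSURE_BLOCK = ["HSEAU", "HSEAD", "HSEBU", "HSEBD", "CN", "RD", "RDa"]

#: Fixed, documented ordering of the 102 site features.  The source
#: feature inventory nominally totals 100 blocks x contexts = 600
#: columns but its enumerated blocks sum to 102; the canonical list is
#: fixed here (102 -> 612 assembled columns) and the discrepancy is
#: deliberate and documented.
SITE_FEATURES: list[str] = (
    PHYSCHEM_NAMES
    + ["Pka1", "Pka2"]
    + [f"Pssm{a}" for a in AA_ORDER]
    + ["Cscore"]
    + _ASA_BLOCK
    + _CONTACT_BLOCK
    + ["Ppm", "Ppc", "Delpp"]
    + ["TOP", "FourBody"]
    + [f"SCE{i}" for i in range(1, 7)]
    + [f"LSE{i}" for i in range(1, 4)]
    + ["NearbyInterface"]
    + ["VorSame", "VorCross"]
    + ["SS1", "SS2", "SS3"]
    + [f"Disorder{i}" for i in range(1, 7)]
    + [f"Blosum{a}" for a in AA_ORDER]
    + _EXPOSURE_BLOCK
    + ["Conservation", "Hb"]
)

assert len(SITE_FEATURES) == 102
assert len(set(SITE_FEATURES)) == 102
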