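"""Accessibility-derived geometry: SASA, interface weights, exposure,
depth, contacts and geometric hydrogen bonds.

SASA uses a Shrake–Rupley scheme with a deterministic golden-section
spiral point lattice, so repeated runs are bit-identical.  All other
quantities are direct pairwise geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import Residue, Structure, extract_monomer

__all__ = [
    "SasaResult",
    "SurfaceProfile",
    "ExposureProfile",
    "ContactProfile",
    "shrake_rupley_sasa",
    "surface_profile",
    "half_sphere_exposure",
    "residue_depth",
    "contacts",
    "hydrogen_bonds",
    "pseudo_cbeta",
    "ideal_cbeta",
    "sphere_points",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_HSE_RADIUS",
    "DEFAULT_ATOM_CONTACT_CUTOFF",
    "DEFAULT_RESIDUE_CONTACT_CUTOFF",
    "DEFAULT_INTERFACE_DASA_MIN",
    "DEFAULT_CONTACT_REFERENCE",
]

DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_SPHERE_POINTS = 960
DEFAULT_HSE_RADIUS = 13.0
DEFAULT_ATOM_CONTACT_CUTOFF = 4.5
DEFAULT_RESIDUE_CONTACT_CUTOFF = 6.5
DEFAULT_INTERFACE_DASA_MIN = 0.1

Rid = tuple[str, int, str]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral lattice of ``n`` unit vectors."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


@dataclass
class SasaResult:
    """Per-atom SASA for the heavy atoms of one structure."""

    atom_areas: dict[tuple[Rid, str], float]
    probe_radius: float
    n_points: int

    def residue_area(self, rid: Rid) -> float:
        return sum(a for (r, _), a in self.atom_areas.items() if r == rid)

    def residue_totals(self) -> dict[Rid, float]:
        totals: dict[Rid, float] = {}
        for (rid, _), area in self.atom_areas.items():
            totals[rid] = totals.get(rid, 0.0) + area
        return totals


def shrake_rupley_sasa(structure: Structure,
                       probe_radius: float = DEFAULT_PROBE_RADIUS,
                       n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                       ) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area per heavy atom."""
    if probe_radius <= 0:
        raise ValueError("probe_radius must be > 0")
    if n_sphere_points < 50:
        raise ValueError("n_sphere_points must be >= 50")
    atoms: list[tuple[Rid, str, np.ndarray, float]] = []
    for res in structure.residues:
        for a in res.heavy_atoms:
            atoms.append((res.rid, a.name, a.coord, a.vdw_radius))
    if not atoms:
        raise ValueError("empty structure: no heavy atoms")
    coords = np.array([a[2] for a in atoms])
    radii = np.array([a[3] for a in atoms]) + probe_radius
    pts = sphere_points(n_sphere_points)
    tree = cKDTree(coords)
    max_r = radii.max()
    areas: dict[tuple[Rid, str], float] = {}
    for i, (rid, name, _, _) in enumerate(atoms):
        ri = radii[i]
        test = coords[i] + ri * pts
        buried = np.zeros(n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], ri + max_r):
            if j == i:
                continue
            rj = radii[j]
            if np.linalg.norm(coords[j] - coords[i]) >= ri + rj:
                continue
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            buried |= d2 < rj * rj
        frac = 1.0 - buried.sum() / n_sphere_points
        areas[(rid, name)] = 4.0 * math.pi * ri * ri * frac
    return SasaResult(atom_areas=areas, probe_radius=probe_radius,
                      n_points=n_sphere_points)


@dataclass
class SurfaceProfile:
    """Burial bookkeeping for a partitioned complex.

    ``W`` and ``W_FB`` are zero for non-interface residues; over the
    interface, ``sum(W) == 1``.
    """

    asa_complex: dict[Rid, float]
    asa_monomer: dict[Rid, float]
    delta_asa: dict[Rid, float]
    interface: set[Rid]
    W: dict[Rid, float]
    W_FB: dict[Rid, float]
    interface_dasa_min: float

    def is_interface(self, rid: Rid) -> bool:
        return rid in self.interface


def surface_profile(structure: Structure,
                    probe_radius: float = DEFAULT_PROBE_RADIUS,
                    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                    interface_dasa_min: float = DEFAULT_INTERFACE_DASA_MIN,
                    complex_sasa: SasaResult | None = None,
                    ) -> SurfaceProfile:
    """ASA in complex and monomer, ΔASA, interface set and the burial
    weights W(i) = ΔASA_i / Σ_j ΔASA_j (interface j) and
    W_FB(i) = W(i)·ΔASA_i / ASA_i(monomer)."""
    if structure.partition is None:
        raise ValueError("structure needs a two-side partition")
    if complex_sasa is None:
        complex_sasa = shrake_rupley_sasa(structure, probe_radius,
                                          n_sphere_points)
    asa_c = complex_sasa.residue_totals()
    asa_m: dict[Rid, float] = {}
    for side in ("A", "B"):
        mono = extract_monomer(structure, side)
        asa_m.update(shrake_rupley_sasa(mono, probe_radius,
                                        n_sphere_points).residue_totals())
    delta = {rid: asa_m[rid] - asa_c[rid] for rid in asa_c}
    interface = {rid for rid, d in delta.items() if d > interface_dasa_min}
    if not interface:
        raise ValueError("no interface: no residue buries more than "
                         f"{interface_dasa_min} A^2 on binding")
    total = sum(delta[rid] for rid in interface)
    W = {rid: (delta[rid] / total if rid in interface else 0.0)
         for rid in delta}
    W_FB = {}
    for rid in delta:
        if rid in interface and asa_m[rid] > 0:
            W_FB[rid] = W[rid] * delta[rid] / asa_m[rid]
        else:
            W_FB[rid] = 0.0
    return SurfaceProfile(asa_complex=asa_c, asa_monomer=asa_m,
                          delta_asa=delta, interface=interface, W=W,
                          W_FB=W_FB, interface_dasa_min=interface_dasa_min)


def ideal_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal L-configuration Cβ position from backbone N, Cα, C.

    Frame components (−0.605 along the N/C bisector, +0.796 along the
    N×C normal) match an energy-minimized L-alanine."""
    v_n = n - ca
    v_c = c - ca
    v_n = v_n / np.linalg.norm(v_n)
    v_c = v_c / np.linalg.norm(v_c)
    bisector = v_n + v_c
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(v_n, v_c)
    normal /= np.linalg.norm(normal)
    direction = -0.605 * bisector + 0.796 * normal
    return ca + 1.53 * direction / np.linalg.norm(direction)


def pseudo_cbeta(residue: Residue) -> np.ndarray | None:
    """Cβ position; for glycine (or missing Cβ) an ideal tetrahedral
    pseudo-Cβ built from N, Cα and C."""
    cb = residue.atom("CB")
    if cb is not None:
        return cb.coord
    n, ca, c = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if n is None or ca is None or c is None:
        return None
    return ideal_cbeta(n.coord, ca.coord, c.coord)


@dataclass
class ExposureProfile:
    """Half-sphere exposure counts, coordination number and depths.

    Missing values (no Cα, or depth unavailable) are NaN."""

    HSEAU: dict[Rid, float] = field(default_factory=dict)
    HSEAD: dict[Rid, float] = field(default_factory=dict)
    HSEBU: dict[Rid, float] = field(default_factory=dict)
    HSEBD: dict[Rid, float] = field(default_factory=dict)
    CN: dict[Rid, float] = field(default_factory=dict)
    RD: dict[Rid, float] = field(default_factory=dict)
    RDa: dict[Rid, float] = field(default_factory=dict)


def _pseudo_sidechain_direction(chain: list[Residue], idx: int) -> np.ndarray | None:
    """Hamelryck HSEα direction: -(d_prev + d_next) over chain-adjacent Cα."""
    res = chain[idx]
    ca = res.atom("CA")
    if ca is None:
        return None
    prev_ca = chain[idx - 1].atom("CA") if idx > 0 else None
    next_ca = chain[idx + 1].atom("CA") if idx + 1 < len(chain) else None
    if prev_ca is None or next_ca is None:
        return None
    d = -((prev_ca.coord - ca.coord) + (next_ca.coord - ca.coord))
    norm = np.linalg.norm(d)
    return d / norm if norm > 0 else None


def half_sphere_exposure(structure: Structure,
                         radius: float = DEFAULT_HSE_RADIUS,
                         ) -> ExposureProfile:
    """HSEα/HSEβ up/down counts of neighbor Cα atoms within ``radius``.

    Both measures count neighboring Cα atoms; they differ in the
    side-chain direction that defines the half-sphere plane: HSEB uses
    the Cα→Cβ vector (pseudo-Cβ for glycine), HSEA uses the chain-based
    pseudo direction, falling back to the Cβ vector at chain termini.
    Hence HSEAU+HSEAD == HSEBU+HSEBD == CN for every residue with a Cα.
    """
    prof = ExposureProfile()
    entries = []  # (residue, ca_coord, dir_a, dir_b)
    for chain_id in structure.chain_ids:
        chain = structure.chain(chain_id)
        for idx, res in enumerate(chain):
            ca = res.atom("CA")
            if ca is None:
                entries.append((res, None, None, None))
                continue
            cb = pseudo_cbeta(res)
            dir_b = None
            if cb is not None:
                v = cb - ca.coord
                n = np.linalg.norm(v)
                dir_b = v / n if n > 0 else None
            dir_a = _pseudo_sidechain_direction(chain, idx)
            if dir_a is None:
                dir_a = dir_b
            entries.append((res, ca.coord, dir_a, dir_b))
    ca_list = [(i, e[1]) for i, e in enumerate(entries) if e[1] is not None]
    for i, (res, ca, dir_a, dir_b) in enumerate(entries):
        if ca is None:
            for d in (prof.HSEAU, prof.HSEAD, prof.HSEBU, prof.HSEBD,
                      prof.CN):
                d[res.rid] = float("nan")
            continue
        cn = au = bu = 0
        for j, other_ca in ca_list:
            if j == i:
                continue
            rel = other_ca - ca
            if np.linalg.norm(rel) > radius:
                continue
            cn += 1
            if dir_a is not None and float(np.dot(dir_a, rel)) > 0:
                au += 1
            if dir_b is not None and float(np.dot(dir_b, rel)) > 0:
                bu += 1
        prof.CN[res.rid] = float(cn)
        if dir_a is None:
            prof.HSEAU[res.rid] = prof.HSEAD[res.rid] = float("nan")
        else:
            prof.HSEAU[res.rid] = float(au)
            prof.HSEAD[res.rid] = float(cn - au)
        if dir_b is None:
            prof.HSEBU[res.rid] = prof.HSEBD[res.rid] = float("nan")
        else:
            prof.HSEBU[res.rid] = float(bu)
            prof.HSEBD[res.rid] = float(cn - bu)
    return prof


def residue_depth(structure: Structure,
                  sasa: SasaResult | None = None,
                  probe_radius: float = DEFAULT_PROBE_RADIUS,
                  n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
                  ) -> tuple[dict[Rid, float], dict[Rid, float]]:
    """(RD, RDa): mean / Cα distance to the nearest solvent-exposed atom
    plus the probe-radius offset.  An exposed atom has depth equal to the
    offset itself."""
    if sasa is None:
        sasa = shrake_rupley_sasa(structure, probe_radius, n_sphere_points)
    exposed_coords = []
    for res in structure.residues:
        for a in res.heavy_atoms:
            if sasa.atom_areas.get((res.rid, a.name), 0.0) > 0:
                exposed_coords.append(a.coord)
    if not exposed_coords:
        raise ValueError("no solvent-exposed atom: cannot define depth")
    tree = cKDTree(np.array(exposed_coords))
    rd: dict[Rid, float] = {}
    rda: dict[Rid, float] = {}
    for res in structure.residues:
        depths = []
        for a in res.heavy_atoms:
            if sasa.atom_areas.get((res.rid, a.name), 0.0) > 0:
                d = 0.0
            else:
                d, _ = tree.query(a.coord)
            depths.append(d + sasa.probe_radius)
            if a.name == "CA":
                rda[res.rid] = d + sasa.probe_radius
        rd[res.rid] = float(np.mean(depths)) if depths else float("nan")
        rda.setdefault(res.rid, float("nan"))
    return rd, rda


#: Per-amino-acid mean contact counts used to normalize raw counts
#: (atom-pair contacts, residue contacts).  Frozen once from the packaged
#: poly-alanine helix-dimer fixture set (five seeds, 14 residues/chain:
#: mean 58.79 atom-pair and 3.86 residue contacts for alanine), with the
#: atom reference scaled by each type's heavy-atom count relative to
#: alanine.  Override via the ``reference`` argument of :func:`contacts`.
_ALA_ATOM_MEAN, _ALA_RES_MEAN = 58.79, 3.86
_HEAVY_ATOMS = {"A": 5, "C": 6, "D": 8, "E": 9, "F": 11, "G": 4, "H": 10,
                "I": 8, "K": 9, "L": 8, "M": 8, "N": 8, "P": 7, "Q": 9,
                "R": 11, "S": 6, "T": 7, "V": 7, "W": 14, "Y": 12}
DEFAULT_CONTACT_REFERENCE: dict[str, tuple[float, float]] = {
    aa: (_ALA_ATOM_MEAN * n / 5.0, _ALA_RES_MEAN)
    for aa, n in _HEAVY_ATOMS.items()
}


@dataclass
class ContactProfile:
    atom_complex: dict[Rid, float] = field(default_factory=dict)
    atom_monomer: dict[Rid, float] = field(default_factory=dict)
    residue_complex: dict[Rid, float] = field(default_factory=dict)
    residue_monomer: dict[Rid, float] = field(default_factory=dict)
    # normalized variants
    Nacc: dict[Rid, float] = field(default_factory=dict)
    Nacm: dict[Rid, float] = field(default_factory=dict)
    Delnac: dict[Rid, float] = field(default_factory=dict)
    Ncrc: dict[Rid, float] = field(default_factory=dict)
    Ncrm: dict[Rid, float] = field(default_factory=dict)
    Delncr: dict[Rid, float] = field(default_factory=dict)


def _atom_contact_counts(structure: Structure, cutoff: float) -> dict[Rid, float]:
    """Number of inter-residue heavy-atom pairs within ``cutoff`` per residue."""
    coords, owner = [], []
    for idx, res in enumerate(structure.residues):
        for a in res.heavy_atoms:
            coords.append(a.coord)
            owner.append(idx)
    counts = {res.rid: 0.0 for res in structure.residues}
    if not coords:
        return counts
    arr = np.array(coords)
    owner_arr = np.array(owner)
    tree = cKDTree(arr)
    for i, j in tree.query_pairs(cutoff):
        oi, oj = owner_arr[i], owner_arr[j]
        if oi == oj:
            continue
        counts[structure.residues[oi].rid] += 1
        counts[structure.residues[oj].rid] += 1
    return counts


def _residue_contact_counts(structure: Structure, cutoff: float) -> dict[Rid, float]:
    """Number of other residues whose (pseudo-)Cβ lies within ``cutoff``."""
    pts, rids = [], []
    for res in structure.residues:
        cb = pseudo_cbeta(res)
        if cb is not None:
            pts.append(cb)
            rids.append(res.rid)
    counts = {res.rid: 0.0 for res in structure.residues}
    if pts:
        tree = cKDTree(np.array(pts))
        for i, j in tree.query_pairs(cutoff):
            counts[rids[i]] += 1
            counts[rids[j]] += 1
    return counts


def contacts(structure: Structure,
             atom_cutoff: float = DEFAULT_ATOM_CONTACT_CUTOFF,
             residue_cutoff: float = DEFAULT_RESIDUE_CONTACT_CUTOFF,
             reference: dict[str, tuple[float, float]] | None = None,
             ) -> ContactProfile:
    """Atom-pair and residue contact counts in the complex and in each
    residue's own monomer, normalized by the per-amino-acid reference
    mean counts; Del* = normalized(complex) − normalized(monomer)."""
    if atom_cutoff <= 0 or residue_cutoff <= 0:
        raise ValueError("contact cutoffs must be > 0")
    ref = reference or DEFAULT_CONTACT_REFERENCE
    prof = ContactProfile()
    ac = _atom_contact_counts(structure, atom_cutoff)
    rc = _residue_contact_counts(structure, residue_cutoff)
    am: dict[Rid, float] = {}
    rm: dict[Rid, float] = {}
    if structure.partition is not None:
        for side in ("A", "B"):
            mono = extract_monomer(structure, side)
            am.update(_atom_contact_counts(mono, atom_cutoff))
            rm.update(_residue_contact_counts(mono, residue_cutoff))
    else:
        am, rm = dict(ac), dict(rc)
    for res in structure.residues:
        rid = res.rid
        ref_atom, ref_res = ref.get(res.aa_type, (1.0, 1.0))
        prof.atom_complex[rid] = ac[rid]
        prof.atom_monomer[rid] = am[rid]
        prof.residue_complex[rid] = rc[rid]
        prof.residue_monomer[rid] = rm[rid]
        prof.Nacc[rid] = ac[rid] / ref_atom
        prof.Nacm[rid] = am[rid] / ref_atom
        prof.Delnac[rid] = prof.Nacc[rid] - prof.Nacm[rid]
        prof.Ncrc[rid] = rc[rid] / ref_res
        prof.Ncrm[rid] = rm[rid] / ref_res
        prof.Delncr[rid] = prof.Ncrc[rid] - prof.Ncrm[rid]
    return prof


# Donor atom -> antecedent atom, per residue type ("*" = any).
_DONORS: dict[str, dict[str, str]] = {
    "*": {"N": "CA"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "LYS": {"NZ": "CE"},
    "HIS": {"ND1": "CG", "NE2": "CD2"},
    "TRP": {"NE1": "CD1"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "CYS": {"SG": "CB"},
}

_ACCEPTORS: dict[str, set[str]] = {
    "*": {"O", "OXT"},
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
    "MET": {"SD"},
}


def _donor_atoms(res: Residue):
    table = dict(_DONORS["*"])
    if res.resname == "PRO":
        table.pop("N", None)  # proline backbone N has no polar H
    table.update(_DONORS.get(res.resname, {}))
    for name, ante in table.items():
        a = res.atom(name)
        if a is not None:
            yield a, res.atom(ante)


def _acceptor_atoms(res: Residue):
    names = set(_ACCEPTORS["*"]) | _ACCEPTORS.get(res.resname, set())
    for name in names:
        a = res.atom(name)
        if a is not None:
            yield a


def hydrogen_bonds(structure: Structure,
                   max_distance: float = 3.5,
                   min_angle_deg: float = 90.0) -> dict[Rid, float]:
    """Geometric donor–acceptor hydrogen-bond count per residue.

    A bond requires D–A distance <= ``max_distance`` and, when the
    donor's antecedent heavy atom is present, an antecedent–D–A angle
    >= ``min_angle_deg``.  Backbone–backbone pairs between
    sequence-adjacent residues of one chain are excluded (covalent
    neighborhood).  Each bond increments both participants.
    """
    counts = {res.rid: 0.0 for res in structure.residues}
    donors = []
    for res in structure.residues:
        for d, ante in _donor_atoms(res):
            donors.append((res, d, ante))
    acceptors = []
    for res in structure.residues:
        for a in _acceptor_atoms(res):
            acceptors.append((res, a))
    for dres, datom, ante in donors:
        for ares, aatom in acceptors:
            if dres.rid == ares.rid:
                continue
            if (dres.chain_id == ares.chain_id
                    and abs(dres.seq_number - ares.seq_number) == 1
                    and datom.name == "N" and aatom.name in ("O", "OXT")):
                continue
            vec = aatom.coord - datom.coord
            dist = float(np.linalg.norm(vec))
            if dist > max_distance or dist < 1e-6:
                continue
            if ante is not None:
                v1 = ante.coord - datom.coord
                cosang = float(np.dot(v1, vec)
                               / (np.linalg.norm(v1) * dist))
                angle = math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))
                if angle < min_angle_deg:
                    continue
            counts[dres.rid] += 1
            counts[ares.rid] += 1
    return counts
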