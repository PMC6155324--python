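"""Synthetic desk-scale inputs: ideal poly-alanine helix dimers, PSSM /
disorder / DSSP-style track files, and labeled feature matrices with
planted class-shifted columns.

Every reader in :mod:`hotsite.descriptors` has a writer counterpart
here, so the test suite needs no downloads and no binary data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .structure import Atom, Partition, Residue, Structure, VDW_RADII, write_pdb
from .surface import ideal_cbeta
from .descriptors import AA_ORDER, PSIBLAST_ORDER

__all__ = [
    "FixtureSpec",
    "make_dimer",
    "make_feature_matrix",
    "make_tracks",
    "build_helix",
    "write_pssm",
    "write_disopred",
    "write_disembl",
    "write_dssp",
    "write_hb2",
]


@dataclass
class FixtureSpec:
    seed: int = 0
    n_residues_per_chain: int = 12
    gap: float = 4.0
    n_samples: int = 300
    n_features: int = 600
    n_informative: int = 4
    effect_size: float = 1.5
    class_balance: float = 0.5
    n_duplicate: int = 0


# Ideal backbone internal coordinates.
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_CA_CB = 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.4
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF: position of d bonded to c with angle b-c-d and torsion a-b-c-d."""
    ang, tor = math.radians(angle_deg), math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.cos(tor) * math.sin(ang),
        bond * math.sin(tor) * math.sin(ang),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_helix(n_residues: int, chain_id: str = "A",
                phi: float = _PHI, psi: float = _PSI,
                ) -> list[Residue]:
    """Ideal poly-alanine helix backbone (N, CA, C, O, CB) from internal
    coordinates."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    ncac: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_B_N_CA, 0.0, 0.0])
    ang = math.radians(_A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])
    ncac.append((n0, ca0, c0))
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = ncac[-1]
        n_i = _place(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psi)
        ca_i = _place(ca_prev, c_prev, n_i, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_i = _place(c_prev, n_i, ca_i, _B_CA_C, _A_N_CA_C, phi)
        ncac.append((n_i, ca_i, c_i))
    residues: list[Residue] = []
    for i, (n, ca, c) in enumerate(ncac):
        if i + 1 < n_residues:
            n_next = ncac[i + 1][0]
            o = _place(n_next, ca, c, _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = _place(n, ca, c, _B_C_O, _A_CA_C_O, psi + 180.0)
        cb = ideal_cbeta(n, ca, c)
        atoms = [Atom("N", "N", n, VDW_RADII["N"]),
                 Atom("CA", "C", ca, VDW_RADII["C"]),
                 Atom("C", "C", c, VDW_RADII["C"]),
                 Atom("O", "O", o, VDW_RADII["O"]),
                 Atom("CB", "C", cb, VDW_RADII["C"])]
        residues.append(Residue(chain_id=chain_id, seq_number=i + 1,
                                icode=" ", aa_type="A", resname="ALA",
                                atoms=atoms))
    return residues


def _min_interchain_distance(chain_a: list[Residue],
                             chain_b: list[Residue]) -> float:
    ca = np.vstack([r.heavy_coords() for r in chain_a])
    cb = np.vstack([r.heavy_coords() for r in chain_b])
    d = np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2).sum(-1))
    return float(d.min())


def _translate(residues: list[Residue], offset: np.ndarray) -> list[Residue]:
    out = []
    for r in residues:
        atoms = [Atom(a.name, a.element, a.coord + offset, a.vdw_radius)
                 for a in r.atoms]
        out.append(Residue(chain_id=r.chain_id, seq_number=r.seq_number,
                           icode=r.icode, aa_type=r.aa_type,
                           resname=r.resname, atoms=atoms))
    return out


def make_dimer(spec: FixtureSpec, pdb_path=None) -> Structure:
    """Two parallel ideal poly-alanine helices packed so the minimum
    inter-chain heavy-atom distance equals ``spec.gap`` (~1e-3 A).

    A seeded sub-0.01 A coordinate jitter breaks exact geometric
    degeneracies while leaving the backbone ideal for phi/psi purposes.
    """
    if spec.gap <= 0:
        raise ValueError("gap must be > 0")
    if spec.n_residues_per_chain < 4:
        raise ValueError("need at least 4 residues per chain")
    rng = np.random.default_rng(spec.seed)
    chain_a = build_helix(spec.n_residues_per_chain, "A")
    chain_b = build_helix(spec.n_residues_per_chain, "B")
    # helix axis: first-to-last CA direction; pack along a perpendicular
    cas = np.array([r.atom("CA").coord for r in chain_a])
    axis = cas[-1] - cas[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(perp) < 1e-6:
        perp = np.cross(axis, [0.0, 1.0, 0.0])
    perp /= np.linalg.norm(perp)
    offset = 10.0
    chain_b_t = _translate(chain_b, offset * perp)
    for _ in range(12):
        d = _min_interchain_distance(chain_a, chain_b_t)
        if abs(d - spec.gap) < 1e-4:
            break
        offset += spec.gap - d
        chain_b_t = _translate(chain_b, offset * perp)
    residues = chain_a + chain_b_t
    jitter = rng.normal(0.0, 0.005, size=(sum(len(r.atoms) for r in residues), 3))
    k = 0
    jittered = []
    for r in residues:
        atoms = []
        for a in r.atoms:
            atoms.append(Atom(a.name, a.element, a.coord + jitter[k],
                              a.vdw_radius))
            k += 1
        jittered.append(Residue(chain_id=r.chain_id, seq_number=r.seq_number,
                                icode=r.icode, aa_type=r.aa_type,
                                resname=r.resname, atoms=atoms))
    structure = Structure(residues=jittered,
                          partition=Partition(frozenset("A"), frozenset("B")),
                          name=f"dimer(seed={spec.seed},gap={spec.gap})")
    if pdb_path is not None:
        write_pdb(structure, pdb_path)
    return structure


def make_feature_matrix(spec: FixtureSpec) -> tuple[pd.DataFrame, np.ndarray]:
    """Labeled matrix: ``n_informative`` columns get a class-mean shift
    of ``effect_size`` (in sigma units); the rest are standard normal
    noise.  ``n_duplicate`` appends exact copies of the first
    informative columns (mRMR redundancy probes).

    Informative columns are named ``INF001..``, noise ``NSE001..``,
    duplicates ``DUP001..``; column order is randomized (seeded) so
    position carries no information.
    """
    if spec.n_samples < 40:
        raise ValueError("need n_samples >= 40")
    if spec.n_informative > spec.n_features:
        raise ValueError("n_informative cannot exceed n_features")
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_samples * spec.class_balance))
    y = np.array([1] * n_pos + [0] * (spec.n_samples - n_pos))
    X = rng.normal(size=(spec.n_samples, spec.n_features))
    shift = spec.effect_size
    for j in range(spec.n_informative):
        X[y == 1, j] += shift / 2.0
        X[y == 0, j] -= shift / 2.0
    names = ([f"INF{j + 1:03d}" for j in range(spec.n_informative)]
             + [f"NSE{j + 1:03d}" for j in range(spec.n_features
                                                 - spec.n_informative)])
    if spec.n_duplicate:
        dup = X[:, :spec.n_duplicate].copy()
        X = np.hstack([X, dup])
        names += [f"DUP{j + 1:03d}" for j in range(spec.n_duplicate)]
    order = rng.permutation(len(names))
    df = pd.DataFrame(X[:, order], columns=[names[i] for i in order])
    return df, y


# --------------------------------------------------------------------------
# Track writers (reader counterparts)

def write_pssm(path, sequence: str, freqs: np.ndarray | None = None,
               seed: int = 0, uniform: bool = False) -> np.ndarray:
    """Write a PSI-BLAST-layout ASCII PSSM for ``sequence``.

    ``freqs`` (L, 20, alphabetical order, rows summing to <= 1) may be
    given explicitly; otherwise rows are random integer percentages
    (``uniform=True`` gives exactly 5% everywhere, i.e. maximum
    entropy).  Returns the (L, 20) frequency matrix actually written.
    """
    L = len(sequence)
    rng = np.random.default_rng(seed)
    if freqs is None:
        if uniform:
            pct = np.full((L, 20), 5, dtype=int)
        else:
            pct = np.array([rng.multinomial(100, np.ones(20) / 20)
                            for _ in range(L)])
    else:
        pct = np.rint(np.asarray(freqs) * 100).astype(int)
    # reorder alphabetical -> PSI-BLAST column order
    to_psi = [AA_ORDER.index(a) for a in PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted, "
                 "observed percentages rounded down\n")
        fh.write("            " + "   ".join(PSIBLAST_ORDER) + "    "
                 + "   ".join(PSIBLAST_ORDER) + "\n")
        for i, aa in enumerate(sequence):
            row_pct = pct[i][to_psi]
            p = row_pct / 100.0
            with np.errstate(divide="ignore"):
                lo = np.where(p > 0, np.rint(2 * np.log2(p / 0.05)), -4)
            fields = [f"{int(v):3d}" for v in lo] + \
                     [f"{int(v):4d}" for v in row_pct]
            fh.write(f"{i + 1:5d} {aa} " + "".join(fields)
                     + "  0.36 0.09\n")
        fh.write("\n")
    return pct / 100.0


def write_disopred(path, sequence: str, scores=None, seed: int = 0,
                   threshold: float = 0.5) -> np.ndarray:
    """DISOPRED-style track; state mark '*' where score >= threshold."""
    rng = np.random.default_rng(seed)
    if scores is None:
        scores = rng.uniform(0, 1, size=len(sequence))
    scores = np.asarray(scores, dtype=float)
    with open(path, "w") as fh:
        fh.write("#         ----- DISORDER PREDICTION -----\n")
        for i, aa in enumerate(sequence):
            mark = "*" if scores[i] >= threshold else "."
            fh.write(f"{i + 1:5d} {aa} {mark} {scores[i]:.2f}\n")
    return scores


def write_disembl(path, sequence: str, tracks=None, seed: int = 0) -> np.ndarray:
    """DisEMBL-style TSV with (coils, rem465, hotloops) columns."""
    rng = np.random.default_rng(seed)
    if tracks is None:
        tracks = rng.uniform(0, 1, size=(len(sequence), 3))
    tracks = np.asarray(tracks, dtype=float)
    with open(path, "w") as fh:
        fh.write("# pos aa coils rem465 hotloops\n")
        for i, aa in enumerate(sequence):
            c, r, h = tracks[i]
            fh.write(f"{i + 1:5d} {aa} {c:.3f} {r:.3f} {h:.3f}\n")
    return tracks


def write_dssp(path, structure: Structure,
               ss: dict | None = None,
               acc: dict | None = None) -> None:
    """Minimal DSSP-layout file covering every residue of ``structure``.

    ``ss`` maps rid -> DSSP letter (default 'H'); ``acc`` maps rid ->
    accessibility (default 0).
    """
    with open(path, "w") as fh:
        fh.write("==== Secondary Structure Definition (synthetic) ====\n")
        fh.write("  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n")
        serial = 1
        for res in structure.residues:
            letter = (ss or {}).get(res.rid, "H")
            a = (acc or {}).get(res.rid, 0.0)
            line = (f"{serial:5d}{res.seq_number:5d}"
                    f"{res.icode.strip() or ' ':1s}{res.chain_id:1s} "
                    f"{res.aa_type:1s}  {letter:1s}")
            fh.write(line.ljust(34) + f"{a:4.0f}\n")
            serial += 1


def write_hb2(path, bonds: list[tuple[tuple, str, tuple, str]],
              structure: Structure | None = None) -> None:
    """HBPLUS-style ``.hb2``: one (donor_rid, donor_atom, acceptor_rid,
    acceptor_atom) line per bond."""
    names = {}
    if structure is not None:
        names = {r.rid: r.resname for r in structure.residues}

    def fmt(rid: tuple) -> str:
        chain, num, icode = rid
        ic = icode.strip() or "-"
        return f"{chain}{num:04d}{ic}{names.get(rid, 'ALA'):>3s}"

    with open(path, "w") as fh:
        fh.write("# HBPLUS-style hydrogen bond records (synthetic)\n")
        for drid, datom, arid, aatom in bonds:
            fh.write(f"{fmt(drid):9s} {datom:<4s}{fmt(arid):9s} "
                     f"{aatom:<4s} 2.90\n")


def make_tracks(spec: FixtureSpec, structure: Structure, outdir,
                uniform_pssm: bool = False,
                disorder_value: float | None = None) -> dict[str, dict[str, Path]]:
    """Write one PSSM / DISOPRED / DisEMBL / DSSP file per chain (DSSP
    covers the whole structure once).  Returns {chain: {kind: path}}."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, dict[str, Path]] = {}
    for k, chain_id in enumerate(structure.chain_ids):
        seq = "".join(r.aa_type for r in structure.chain(chain_id))
        paths = {
            "pssm": outdir / f"chain_{chain_id}.pssm",
            "disopred": outdir / f"chain_{chain_id}.diso",
            "disembl": outdir / f"chain_{chain_id}.disembl",
        }
        write_pssm(paths["pssm"], seq, seed=spec.seed + 11 * k,
                   uniform=uniform_pssm)
        if disorder_value is not None:
            const = np.full(len(seq), disorder_value)
            write_disopred(paths["disopred"], seq, scores=const)
            write_disembl(paths["disembl"], seq,
                          tracks=np.full((len(seq), 3), disorder_value))
        else:
            write_disopred(paths["disopred"], seq, seed=spec.seed + 11 * k + 1)
            write_disembl(paths["disembl"], seq, seed=spec.seed + 11 * k + 2)
        out[chain_id] = paths
    dssp_path = outdir / "structure.dssp"
    write_dssp(dssp_path, structure)
    for chain_id in structure.chain_ids:
        out[chain_id]["dssp"] = dssp_path
    return out
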