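"""Feature-table assembly.

Per-residue site descriptors (102 named features) are expanded into six
contexts — raw and burial-weighted versions of the site value, the
Euclidean-neighborhood sum and the Voronoi-neighborhood sum — giving a
612-column table over labeled interface residues.

Neighborhood aggregation is a sum that includes the central residue
(switchable); weighting multiplies each residue's site vector by its own
W_FB *before* aggregation, so a weighted context sums the neighbors' own
weighted values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import descriptors as D
from . import neighbors as N
from . import surface as S
from .structure import Structure

__all__ = [
    "ComplexInput",
    "FeatureTable",
    "FeatureConfig",
    "COLUMNS",
    "aggregate_neighborhood",
    "apply_weighting",
    "site_descriptor_matrix",
    "build_feature_table",
    "read_labels",
    "HOTSPOT_DDG",
]

#: Training-set hot-spot convention: ΔΔG >= 2.0 kcal/mol.
HOTSPOT_DDG = 2.0

Rid = tuple[str, int, str]

#: Canonical 612-column ordering: six context variants per site feature.
COLUMNS: list[str] = [
    variant
    for f in D.SITE_FEATURES
    for variant in (f, f + "_EN", f + "_VN",
                    "W_" + f, "W_" + f + "_EN", "W_" + f + "_VN")
]


@dataclass
class FeatureConfig:
    probe_radius: float = S.DEFAULT_PROBE_RADIUS
    n_sphere_points: int = S.DEFAULT_N_SPHERE_POINTS
    interface_dasa_min: float = S.DEFAULT_INTERFACE_DASA_MIN
    hse_radius: float = S.DEFAULT_HSE_RADIUS
    atom_contact_cutoff: float = S.DEFAULT_ATOM_CONTACT_CUTOFF
    residue_contact_cutoff: float = S.DEFAULT_RESIDUE_CONTACT_CUTOFF
    euclidean_cutoff: float = N.DEFAULT_EUCLIDEAN_CUTOFF
    voronoi_max_edge: float | None = N.DEFAULT_VORONOI_MAX_EDGE
    include_center: bool = True


@dataclass
class ComplexInput:
    """One parsed complex plus its optional external tracks."""

    structure: Structure
    pdb_id: str
    pssm: dict[str, D.PSSMProfile] = field(default_factory=dict)
    disopred: dict[str, list] = field(default_factory=dict)
    disembl: dict[str, list] = field(default_factory=dict)
    dssp: dict[Rid, tuple] | None = None
    hb2: dict[Rid, float] | None = None
    pluggable: dict[Rid, dict[str, float]] = field(default_factory=dict)


def site_descriptor_matrix(cx: ComplexInput,
                           config: FeatureConfig | None = None):
    """Compute the (n_residues, 102) site matrix for every residue of a
    complex, plus the surface profile and the two neighbor graphs.

    Missing external tracks yield NaN sentinels (flagged downstream),
    never silent zeros.
    """
    cfg = config or FeatureConfig()
    st = cx.structure
    sasa = S.shrake_rupley_sasa(st, cfg.probe_radius, cfg.n_sphere_points)
    prof = S.surface_profile(st, cfg.probe_radius, cfg.n_sphere_points,
                             cfg.interface_dasa_min, complex_sasa=sasa)
    hse = S.half_sphere_exposure(st, cfg.hse_radius)
    rd, rda = S.residue_depth(st, sasa=sasa)
    con = S.contacts(st, cfg.atom_contact_cutoff, cfg.residue_contact_cutoff)
    hb = cx.hb2 if cx.hb2 is not None else S.hydrogen_bonds(st)
    g_en = N.euclidean_neighbors(st, cfg.euclidean_cutoff)
    g_vn = N.voronoi_neighbors(st, cfg.voronoi_max_edge)
    vor = N.voronoi_contacts(st, g_vn)
    ss = D.assign_secondary_structure(st, cx.dssp)

    chain_pos: dict[Rid, int] = {}
    for chain_id in st.chain_ids:
        for i, res in enumerate(st.chain(chain_id)):
            chain_pos[res.rid] = i + 1

    rows = {}
    name_idx = {n: i for i, n in enumerate(D.SITE_FEATURES)}
    for res in st.residues:
        v = np.full(len(D.SITE_FEATURES), np.nan)

        def put(names, values):
            for n_, val in zip(names, np.atleast_1d(values)):
                v[name_idx[n_]] = val

        put(D.PHYSCHEM_NAMES, D.physicochemical(res.aa_type))
        put(["Pka1", "Pka2"], D.pka_values(res.aa_type))
        pssm = cx.pssm.get(res.chain_id)
        pos = chain_pos[res.rid]
        if pssm is not None and 1 <= pos <= len(pssm):
            put([f"Pssm{a}" for a in D.AA_ORDER], D.pssm_row(pssm, pos))
            put(["Conservation"], D.conservation_score(pssm, pos))
        asa_m = prof.asa_monomer[res.rid]
        ref_asa = D.physicochemical(res.aa_type)[D.PHYSCHEM_NAMES.index("AvgASA")]
        put(D._ASA_BLOCK, [
            prof.asa_complex[res.rid], asa_m, prof.delta_asa[res.rid],
            prof.asa_complex[res.rid] / ref_asa if ref_asa > 0 else np.nan,
            asa_m / ref_asa if ref_asa > 0 else np.nan,
            prof.W_FB[res.rid],
        ])
        put(D._CONTACT_BLOCK, [con.Nacc[res.rid], con.Nacm[res.rid],
                               con.Delnac[res.rid], con.Ncrc[res.rid],
                               con.Ncrm[res.rid], con.Delncr[res.rid]])
        put(["Ppm", "Ppc", "Delpp"], D.pair_potential(st, g_en, res))
        put(["VorSame", "VorCross"], list(vor[res.rid]))
        put(["SS1", "SS2", "SS3"], D.secondary_structure(ss[res.rid]))
        dis_o = cx.disopred.get(res.chain_id)
        dis_e = cx.disembl.get(res.chain_id)
        if dis_o is not None and dis_e is not None:
            put([f"Disorder{i}" for i in range(1, 7)],
                D.disorder_scores(dis_o, dis_e, pos))
        put([f"Blosum{a}" for a in D.AA_ORDER], D.blosum_row(res.aa_type))
        put(D._EXPOSURE_BLOCK, [
            hse.HSEAU[res.rid], hse.HSEAD[res.rid], hse.HSEBU[res.rid],
            hse.HSEBD[res.rid], hse.CN[res.rid], rd[res.rid], rda[res.rid]])
        put(["Hb"], hb.get(res.rid, 0.0))
        for name, value in cx.pluggable.get(res.rid, {}).items():
            if name in name_idx:
                v[name_idx[name]] = value
            else:
                warnings.warn(f"unknown pluggable column {name!r} ignored")
        rows[res.rid] = v
    site = pd.DataFrame.from_dict(rows, orient="index",
                                  columns=D.SITE_FEATURES)
    return site, prof, g_en, g_vn


def aggregate_neighborhood(site: pd.DataFrame, graph: N.NeighborGraph,
                           rid: Rid, include_center: bool = True,
                           ) -> np.ndarray:
    """Sum of site vectors over the residue's graph neighborhood.

    A residue absent from the graph is treated as having no neighbors,
    so its context equals its own site vector (when the center is
    included)."""
    total = site.loc[[rid]].to_numpy()[0].astype(float).copy() \
        if include_center else np.zeros(site.shape[1])
    for nb in graph.neighbors(rid):
        if nb in site.index:
            total = total + site.loc[[nb]].to_numpy()[0]
    return total


def apply_weighting(values: np.ndarray, profile: S.SurfaceProfile,
                    rid: Rid, strict: bool = True) -> np.ndarray:
    """Scale a residue's feature values by its W_FB.

    In strict mode a non-interface center (W_FB undefined by the burial
    weighting) is an error; non-strict callers get the zero-extended
    weight (0 for non-interface residues)."""
    if rid not in profile.W_FB:
        raise KeyError(f"residue {rid} not in surface profile")
    if strict and rid not in profile.interface:
        raise ValueError(f"residue {rid} is not an interface residue; "
                         "W_FB is undefined")
    return np.asarray(values, dtype=float) * profile.W_FB[rid]


@dataclass
class FeatureTable:
    """Samples x 612 named features plus labels and provenance."""

    data: pd.DataFrame
    labels: pd.Series
    ddg: pd.Series | None = None
    exclusions: list[str] = field(default_factory=list)
    missing_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.data.columns) != COLUMNS:
            raise ValueError("feature table columns deviate from the "
                             "canonical 612-column ordering")

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "label", self.labels.values)
        if self.ddg is not None:
            out.insert(1, "ddg", self.ddg.values)
        out.to_csv(path, sep="\t", index_label="residue",
                   float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, sep="\t", index_col="residue")
        labels = df.pop("label")
        ddg = df.pop("ddg") if "ddg" in df.columns else None
        return cls(data=df, labels=labels, ddg=ddg)


def read_labels(path) -> pd.DataFrame:
    """Label file: TSV with columns
    ``pdb_id  partition  chain  resnum  icode  ddg_or_annotation``.

    ``icode`` '-' means none.  The last column is either a ΔΔG in
    kcal/mol (hot spot iff >= 2.0) or a BID-style annotation (hot spot
    iff 'strong')."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["pdb_id", "partition", "chain", "resnum", "icode", "value"]
    if list(df.columns) != required:
        raise ValueError(f"label file needs columns {required}, "
                         f"got {list(df.columns)}")
    df["resnum"] = df["resnum"].astype(int)
    df["icode"] = df["icode"].replace("-", " ")
    return df


def _label_from_value(value: str) -> tuple[int, float | None]:
    try:
        ddg = float(value)
        return (1 if ddg >= HOTSPOT_DDG else 0), ddg
    except ValueError:
        return (1 if value.strip().lower() == "strong" else 0), None


def build_feature_table(complexes: list[ComplexInput],
                        labels: pd.DataFrame,
                        config: FeatureConfig | None = None,
                        ) -> FeatureTable:
    """One row per labeled residue, 612 canonical columns.

    Labeled residues that cannot be mapped to a structure residue are
    listed in ``exclusions`` (and warned about), never dropped silently.
    Feature names with NaN anywhere are listed in ``missing_features``.
    """
    cfg = config or FeatureConfig()
    by_id = {cx.pdb_id: cx for cx in complexes}
    rows, index, y, ddgs, exclusions = [], [], [], [], []
    for pdb_id in sorted(labels["pdb_id"].unique()):
        sub = labels[labels["pdb_id"] == pdb_id]
        cx = by_id.get(pdb_id)
        if cx is None:
            exclusions.extend(
                f"{pdb_id}/{r.chain}{r.resnum}: complex not provided"
                for r in sub.itertuples())
            continue
        site, prof, g_en, g_vn = site_descriptor_matrix(cx, cfg)
        wsite = site.mul(pd.Series({rid: prof.W_FB[rid]
                                    for rid in site.index}), axis=0)
        sub = sub.sort_values(["chain", "resnum", "icode"])
        for rec in sub.itertuples():
            rid = (rec.chain, int(rec.resnum), rec.icode)
            if rid not in site.index:
                exclusions.append(
                    f"{pdb_id}/{rec.chain}{rec.resnum}{rec.icode.strip()}: "
                    "residue not in structure")
                continue
            blocks = [
                site.loc[[rid]].to_numpy()[0],
                aggregate_neighborhood(site, g_en, rid, cfg.include_center),
                aggregate_neighborhood(site, g_vn, rid, cfg.include_center),
                wsite.loc[[rid]].to_numpy()[0],
                aggregate_neighborhood(wsite, g_en, rid, cfg.include_center),
                aggregate_neighborhood(wsite, g_vn, rid, cfg.include_center),
            ]
            # interleave per feature: f, f_EN, f_VN, W_f, W_f_EN, W_f_VN
            rows.append(np.column_stack(blocks).ravel())
            index.append(f"{pdb_id}/{rec.chain}/{int(rec.resnum)}/"
                         f"{rec.icode.strip() or '-'}")
            label, ddg = _label_from_value(rec.value)
            y.append(label)
            ddgs.append(np.nan if ddg is None else ddg)
    for e in exclusions:
        warnings.warn(f"excluded labeled residue: {e}")
    data = pd.DataFrame(rows, index=index, columns=COLUMNS, dtype=float)
    missing = sorted(data.columns[data.isna().any()].tolist()) if len(data) \
        else []
    return FeatureTable(data=data, labels=pd.Series(y, index=index),
                        ddg=pd.Series(ddgs, index=index),
                        exclusions=exclusions, missing_features=missing)
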