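"""Shared fixtures: everything is generated programmatically at test
time (no stored binary data)."""

import numpy as np
import pandas as pd
import pytest

from hotsite import assembly, descriptors
from hotsite.fixtures import FixtureSpec, make_dimer, make_tracks

#: Small boosted-tree configuration used wherever a test exercises the
#: Rc criterion / CV machinery; keeps the suite inside its time budget
#: while preserving the published defaults in the library API.
FAST_PARAMS = {"n_estimators": 25, "max_depth": 2}


@pytest.fixture(scope="session")
def dimer_spec():
    return FixtureSpec(seed=3, gap=4.0, n_residues_per_chain=12)


@pytest.fixture(scope="session")
def dimer(dimer_spec):
    return make_dimer(dimer_spec)


@pytest.fixture(scope="session")
def tracks_dir(dimer_spec, dimer, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("tracks")
    make_tracks(dimer_spec, dimer, outdir)
    return outdir


@pytest.fixture(scope="session")
def complex_input(dimer, tracks_dir):
    pssm, diso, dise = {}, {}, {}
    for chain_id in dimer.chain_ids:
        pssm[chain_id] = descriptors.read_pssm(
            tracks_dir / f"chain_{chain_id}.pssm")
        diso[chain_id] = descriptors.read_disopred(
            tracks_dir / f"chain_{chain_id}.diso")
        dise[chain_id] = descriptors.read_disembl(
            tracks_dir / f"chain_{chain_id}.disembl")
    dssp = descriptors.read_dssp(tracks_dir / "structure.dssp")
    return assembly.ComplexInput(structure=dimer, pdb_id="DIM1", pssm=pssm,
                                 disopred=diso, disembl=dise, dssp=dssp)


@pytest.fixture(scope="session")
def dimer_labels(dimer):
    ddgs = [2.5, 0.1, 3.0, 1.0, 2.2, 0.0, 4.0, 0.3, 2.1, 0.2]
    rows = [{"pdb_id": "DIM1", "partition": "A:B", "chain": r.chain_id,
             "resnum": r.seq_number, "icode": r.icode, "value": str(v)}
            for r, v in zip(dimer.residues, ddgs)]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def feature_table(complex_input, dimer_labels):
    return assembly.build_feature_table([complex_input], dimer_labels)


@pytest.fixture(scope="session")
def planted_matrix():
    """n=300 samples, 30 features, 3 planted at effect 1.5 sigma."""
    spec = FixtureSpec(seed=11, n_samples=300, n_features=30,
                       n_informative=3, effect_size=1.5)
    from hotsite.fixtures import make_feature_matrix
    return make_feature_matrix(spec)


def brute_force_min_distance(res_a, res_b) -> float:
    ca = res_a.heavy_coords()
    cb = res_b.heavy_coords()
    return float(np.sqrt(((ca[:, None, :] - cb[None, :, :]) ** 2
                          ).sum(-1)).min())
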