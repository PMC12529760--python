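"""Shared fixtures: tiny synthetic ensembles with known ground truth."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from deamidkit import synthetic_fixtures as sf
from deamidkit.ensemble_io import Topology, TrajectoryEnsemble, select_asn_sites


def bare_ensemble(coords, names, resnames, resids, elements=None, chains=None,
                  charges=None, box=5.0, replicate_id=None):
    """Hand-built ensemble without the fixture generator (for placed-geometry
    tests). ``coords``: (n_frames, n_atoms, 3) nm."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    if elements is None:
        elements = [nm[0] for nm in names]
    topo = Topology(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        resnames=np.array(resnames, dtype=object),
        resids=np.array(resids, dtype=int),
        chains=np.array(chains if chains is not None else ["A"] * n, dtype=object),
        charges=np.asarray(charges if charges is not None else np.zeros(n), dtype=float),
        masses=np.full(n, 12.0),
    )
    f = coords.shape[0]
    return TrajectoryEnsemble(
        topology=topo,
        coords=coords,
        box=np.full((f, 3), float(box)),
        replicate_id=np.asarray(
            replicate_id if replicate_id is not None else np.zeros(f, dtype=int)
        ),
    )


@pytest.fixture(scope="session")
def refs():
    return sf.make_reference_states()


@pytest.fixture(scope="session")
def toy():
    """Default small fixture: 3 shell waters, ideal N-H donor bond, 1 charge."""
    spec = sf.FixtureSpec(
        n_frames=25,
        n_replicates=2,
        water_shell=(3, 0.0),
        hbond_model={"N_donor": True, "N_acceptor": True},
        charge_layout=[(1.0, (0.5, 0.5, 0.5)), (-0.5, (2.5, 2.5, 2.5))],
        seed=7,
    )
    ensemble, truth = sf.make_toy_ensemble(spec)
    return ensemble, truth


@pytest.fixture(scope="session")
def toy_site(toy):
    ensemble, _ = toy
    ann = pd.DataFrame([{"protein_id": "p", "residue_number": 1, "label": "Yes"}])
    sites = select_asn_sites(ensemble.topology, ann, protein_id="p")
    assert len(sites) == 1
    return sites[0]
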