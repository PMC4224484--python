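import numpy as np
import pandas as pd
import pytest

import mdcc


def make_trajectory(coords, names=None, resids=None, resnames=None,
                    chains=None, elements=None):
    """Small helper to build a Trajectory from raw coordinate arrays."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    table = pd.DataFrame({
        "atom_name": names or [f"X{i}" for i in range(n)],
        "element": elements or ["C"] * n,
        "residue_seq": resids if resids is not None else list(range(1, n + 1)),
        "residue_name": resnames or ["UNK"] * n,
        "chain_id": chains or ["A"] * n,
    })
    table["is_heavy"] = table["element"].str.upper() != "H"
    table.index.name = "atom_id"
    return mdcc.Trajectory(coords, table, source="test fixture")


@pytest.fixture(scope="session")
def toy_traj():
    return mdcc.simulate_toy(seed=1)


@pytest.fixture(scope="session")
def toy_models(toy_traj):
    return mdcc.fit_all_atoms(toy_traj, mdcc.FitConfig(seed=11))


@pytest.fixture(scope="session")
def flip_traj():
    return mdcc.simulate_flip_system(seed=3)


@pytest.fixture(scope="session")
def flip_models(flip_traj):
    return mdcc.fit_all_atoms(flip_traj, mdcc.FitConfig(seed=7))


@pytest.fixture(scope="session")
def flip_pairs(flip_traj, flip_models):
    return mdcc.all_pairs(flip_traj, flip_models)
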