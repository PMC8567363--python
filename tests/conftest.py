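"""Shared fixtures: synthetic trajectories, receptor and helpers."""

import numpy as np
import pytest

from vcss import (Conformer, Trajectory, gen_distance_series, gen_toy_receptor,
                  gen_toy_trajectory, label_frames, TrajectoryParams)


def merge_trajectories(*trajectories: Trajectory) -> Trajectory:
    """Concatenate trajectories sharing one roster into one, renumbering frames."""
    conformers, i = [], 0
    for traj in trajectories:
        for c in traj:
            conformers.append(Conformer(i, i * 10.0, c.atom_names, c.res_ids,
                                        c.res_names, c.coords))
            i += 1
    return Trajectory(conformers)


@pytest.fixture(scope="session")
def receptor():
    return gen_toy_receptor(seed=0)


@pytest.fixture(scope="session")
def small_trans_traj():
    """A 400-frame synthetic trans trajectory with its hidden state labels."""
    params = TrajectoryParams(state="trans", n_frames=400, seed=11)
    series, hidden = gen_distance_series(params)
    return gen_toy_trajectory(series, "trans", seed=12), series, hidden


@pytest.fixture(scope="session")
def small_cis_traj():
    params = TrajectoryParams(state="cis", n_frames=200, seed=13)
    series, hidden = gen_distance_series(params)
    return gen_toy_trajectory(series, "cis", seed=14), series, hidden


@pytest.fixture(scope="session")
def mixed_labeled(small_trans_traj, small_cis_traj):
    """A labeled trajectory containing all three expected sub-ensembles."""
    merged = merge_trajectories(small_trans_traj[0], small_cis_traj[0])
    return label_frames(merged)


def rigid_transform(coords: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """A random rotation matrix and translation vector."""
    from scipy.spatial.transform import Rotation
    rng = np.random.default_rng(seed)
    return Rotation.random(rng=rng).as_matrix(), rng.normal(0, 2.0, 3)
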