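"""Shared fixtures: small simulated clusters reused across test modules."""

import numpy as np
import pytest

from disperseq import ClusterSimParams, generate_cluster_movie


@pytest.fixture(scope="session")
def wt_cluster_noiseless():
    """Small guided (radially oriented) cluster: noiseless, no attenuation."""
    params = ClusterSimParams(
        n_cells=8,
        cell_radius_um=2.0,
        cluster_radius_um=8.0,
        n_frames=1,
        noise="none",
        background_level=10.0,
        depth_attenuation_um=np.inf,
        seed=11,
    )
    movie, truth = generate_cluster_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def random_cluster_noiseless():
    """Small randomly oriented cluster, matched to wt_cluster_noiseless."""
    params = ClusterSimParams(
        n_cells=8,
        cell_radius_um=2.0,
        cluster_radius_um=8.0,
        orientation_mode="random",
        n_frames=1,
        noise="none",
        background_level=10.0,
        depth_attenuation_um=np.inf,
        seed=12,
    )
    movie, truth = generate_cluster_movie(params)
    return params, movie, truth


def background_voxels(truth, frame=0):
    return truth.label_movie.labels[frame] == 0
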