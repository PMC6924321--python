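import numpy as np
import pandas as pd
import pytest

from cvmove.cvm import Trajectory
from cvmove.synthetic import ExperimentConfig, gen_experiment, gen_genotype_panel


def straight_trajectory(speed=60.0, duration=40.0, dt=0.04, traj_id="straight", meta=None):
    """Noise-free straight path along x at the given speed."""
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    return Trajectory(traj_id, t, speed * t, np.zeros(n), meta=dict(meta or {}))


@pytest.fixture(scope="session")
def summary_experiment():
    """Default-scale experiment in summary mode (one tube row per system side)."""
    cfg = ExperimentConfig()
    panel = gen_genotype_panel(cfg, seed=11)
    return gen_experiment(panel, cfg, seed=12, render="summary"), cfg


@pytest.fixture(scope="session")
def summary_tubes(summary_experiment):
    """Tube table with dispersal rate joined, as the analyses consume it."""
    exp, _ = summary_experiment
    dens = exp.densities.copy()
    dens["dispersal_rate"] = dens["target_density"] / (
        dens["start_density"] + dens["target_density"]
    )
    tubes = exp.tubes.merge(
        dens[["genotype", "replicate", "dispersal_rate"]], on=["genotype", "replicate"]
    )
    return tubes.rename(columns={"size_um2": "size"})


@pytest.fixture(scope="session")
def small_rendered_experiment():
    """Small fully rendered experiment for pipeline-level tests."""
    cfg = ExperimentConfig(
        n_genotypes=8,
        n_replicates=2,
        cells_per_tube=30,
        frames=250,
        drop_systems=(),
    )
    panel = gen_genotype_panel(cfg, seed=21)
    return gen_experiment(panel, cfg, seed=22, render="trajectories"), cfg
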