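"""Trajectory screening and tube-level aggregation.

A two-patch dispersal system yields two tubes (start = residents,
target = dispersers).  Each tube's video yields many trajectories; this
module turns them into the tube-level summary the statistical analyses
run on: activity (fraction of moving cells), mean ln movement speed and
mean ln velocity-autocorrelation timescale over a random subsample of
moving trajectories after robust outlier exclusion, plus morphology and
density pass-throughs and the dispersal rate of the system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cvm import Trajectory

__all__ = [
    "TubeObservation",
    "DispersalRecord",
    "classify_moving",
    "activity",
    "subsample",
    "mad_filter",
    "aggregate_tube",
    "dispersal_rate",
]

logger = logging.getLogger(__name__)

#: MAD consistency constant for normal data.
MAD_SCALE = 1.4826

#: Defaults used throughout the pipeline (seconds, micrometres, counts).
MIN_DURATION_S = 1.0
MIN_DISPLACEMENT_UM = 50.0
SUBSAMPLE_N = 23
MAD_THRESHOLD = 3.0


@dataclass
class TubeObservation:
    """Aggregated record for one tube — the analysis' unit of replication."""

    genotype: str
    replicate: int
    status: str  # "disperser" | "resident"
    activity: float
    ln_speed: float
    ln_tau: float
    size: float  # mean cell area, um^2
    shape: float  # mean elongation (major/minor axis), >= 1
    density: float  # cells/mL

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError(f"activity {self.activity} outside [0, 1]")
        if self.shape < 1.0:
            raise ValueError(f"shape {self.shape} < 1")
        if self.density < 0.0:
            raise ValueError("density must be >= 0")


@dataclass
class DispersalRecord:
    """Densities and dispersal rate of one two-patch system."""

    genotype: str
    replicate: int
    start_density: float
    target_density: float

    @property
    def dispersal_rate(self) -> float:
        return dispersal_rate(self.start_density, self.target_density)


def classify_moving(
    traj: Trajectory,
    min_duration: float = MIN_DURATION_S,
    min_displacement: float = MIN_DISPLACEMENT_UM,
) -> bool:
    """True iff the cell counts as moving.

    A mover has trajectory duration strictly greater than ``min_duration``
    (s) and net first-to-last displacement strictly greater than
    ``min_displacement`` (um; the default 50 um is about one body length).
    Net rather than gross displacement is used so that cells jittering in
    place do not count as movers.
    """
    return traj.duration > min_duration and traj.net_displacement > min_displacement


def activity(
    trajs,
    min_duration: float = MIN_DURATION_S,
    min_displacement: float = MIN_DISPLACEMENT_UM,
) -> float:
    """Fraction of trajectories classified as moving, in [0, 1]."""
    trajs = list(trajs)
    if not trajs:
        raise ValueError("activity undefined for an empty trajectory collection")
    n_moving = sum(classify_moving(t, min_duration, min_displacement) for t in trajs)
    return n_moving / len(trajs)


def subsample(trajs, n: int = SUBSAMPLE_N, seed=None) -> list:
    """Uniform sample of ``n`` trajectories without replacement.

    If fewer than ``n`` are available all of them are returned and a
    warning is logged.  Reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    trajs = list(trajs)
    if len(trajs) <= n:
        if len(trajs) < n:
            logger.warning("only %d trajectories available, requested %d", len(trajs), n)
        return trajs
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(trajs), size=n, replace=False)
    return [trajs[i] for i in sorted(idx)]


def mad_filter(values, threshold: float = MAD_THRESHOLD) -> np.ndarray:
    """Keep mask from the scaled median-absolute-deviation rule.

    A value is kept iff ``|x - median| / (1.4826 * MAD) <= threshold``.
    If the scaled MAD is zero (at least half the values sit exactly on
    the median) the rule is degenerate and every value is kept.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad_filter needs at least one value")
    if not np.all(np.isfinite(x)):
        raise ValueError("mad_filter requires finite values")
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    if mad == 0.0:
        return np.ones(x.size, dtype=bool)
    return np.abs(x - med) / mad <= threshold


def aggregate_tube(
    fits: pd.DataFrame,
    activity: float,
    size: float,
    shape: float,
    density: float,
    genotype: str,
    replicate: int,
    status: str,
) -> TubeObservation:
    """Collapse retained per-trajectory fits into one TubeObservation.

    ``fits`` must hold the selected fits that survived outlier exclusion,
    with columns ``rms_speed_um_s`` and ``tau_s``; the tube summary is
    the mean of ln(rms speed) and ln(tau) over those trajectories.
    """
    if len(fits) == 0:
        raise ValueError(f"no retained fits for tube {genotype}/r{replicate}/{status}")
    return TubeObservation(
        genotype=genotype,
        replicate=int(replicate),
        status=status,
        activity=float(activity),
        ln_speed=float(np.mean(np.log(fits["rms_speed_um_s"].to_numpy()))),
        ln_tau=float(np.mean(np.log(fits["tau_s"].to_numpy()))),
        size=float(size),
        shape=float(shape),
        density=float(density),
    )


def dispersal_rate(start_density: float, target_density: float) -> float:
    """Proportion of the population found in the target tube.

    ``target / (start + target)``; densities must be non-negative with a
    positive sum.  Densities should each be averaged over their replicate
    images *before* taking the ratio (ratio of means, not mean of ratios).
    """
    if start_density < 0 or target_density < 0:
        raise ValueError("densities must be >= 0")
    total = start_density + target_density
    if total <= 0:
        raise ValueError("dispersal rate undefined for zero total density")
    return target_density / total
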