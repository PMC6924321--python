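"""In-silico two-patch dispersal experiments.

The generator produces complete experiments with the hierarchical
structure the analyses assume: genotype-level latent movement and
dispersal parameters, replicate- and tube-level noise, a disperser
vs. resident contrast with genotype-specific deviations (the
genotype x status interaction), morphology covarying with movement, and
per-cell trajectories rendered by the CVM simulator.

Default calibration anchors are the published ranges and contrasts for
*Tetrahymena thermophila* genotypes: activity 0.39–0.70, RMS speed
75–289 um/s, velocity-autocorrelation timescale tau 0.039–0.13 s,
dispersal rate 0.07–0.71; dispersers vs residents at activity
0.62 vs 0.57, speed 171 vs 139 um/s, tau 0.0804 vs 0.0602 s.  Genotype
draws are truncated to the observed ranges so a default panel always
lies inside them.

Two rendering fidelities are available: ``render="trajectories"``
emits every cell's positions (movers via the exact-discretization CVM
simulator, non-movers as sub-threshold jitter) for end-to-end pipeline
runs; ``render="summary"`` emits tube-level observations directly from
the latent model (binomial activity, Gaussian estimation noise at the
23-trajectory scale) for inference-level simulation studies where
per-trajectory fitting would be redundant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cvm import Trajectory, simulate_cvm_batch
from .metrics import dispersal_rate

__all__ = [
    "GenotypeParams",
    "ExperimentConfig",
    "SimulatedExperiment",
    "gen_genotype_panel",
    "gen_experiment",
    "truth_vs_estimate_report",
]

#: Observed genotype-level ranges used to truncate latent draws.
RANGES = {
    "activity": (0.39, 0.70),
    "speed": (75.0, 289.0),
    "tau": (0.039, 0.13),
    "dispersal": (0.07, 0.71),
}


@dataclass
class ExperimentConfig:
    """Design, calibration and noise settings of a simulated experiment."""

    # design
    n_genotypes: int = 44
    n_replicates: int = 3
    cells_per_tube: int = 100
    frames: int = 1000
    dt: float = 0.04
    initial_density: float = 300_000.0  # cells/mL in the start tube
    drop_systems: tuple = (("g32", 3),)  # (genotype, replicate) lost to failure

    # genotype-level latent distribution (resident scale)
    ln_speed_mean: float = math.log(139.0)
    ln_speed_sd: float = 0.28
    ln_tau_mean: float = math.log(0.0602)
    ln_tau_sd: float = 0.25
    act_logit_mean: float = float(logit(0.57))
    act_logit_sd: float = 0.30
    speed_tau_loading: float = 0.7  # corr(ln speed, ln tau) across genotypes
    act_speed_loading: float = 0.3
    size_speed_loading: float = 0.5  # larger cells move faster
    size_log_mean: float = math.log(1500.0)  # um^2
    size_log_sd: float = 0.15
    shape_mean: float = 2.0  # major/minor axis ratio
    shape_sd: float = 0.25

    # disperser - resident offsets (means; per-genotype deviations below)
    status_dln_speed: float = math.log(171.0 / 139.0)
    status_dln_tau: float = math.log(0.0804 / 0.0602)
    status_dact_logit: float = float(logit(0.62) - logit(0.57))
    interaction_sd: float = 0.08  # genotype-specific offset deviations

    # dispersal coupling: logit(dispersal) on standardized latent scores
    disp_logit_mean: float = float(logit(0.25))
    disp_act_coef: float = 0.40
    disp_speed_coef: float = 0.35
    disp_tau_coef: float = 0.15
    disp_noise_sd: float = 0.65
    disp_rep_sd: float = 0.15  # system-level dispersal noise (logit)

    # replicate / tube / trajectory noise
    rep_sd: float = 0.10  # replicate(genotype) stratum, per response
    tube_sd: float = 0.10  # replicate x status stratum, per response
    traj_ln_sd: float = 0.20  # per-trajectory lognormal scatter of speed, tau
    size_tube_sd: float = 0.05  # log-scale tube-level morphology noise
    shape_tube_sd: float = 0.08
    density_meas_sd: float = 0.03  # lognormal error of the 5-image density mean

    # within-tube morphology -> movement couplings
    within_size_elasticity: float = 1.0  # d ln speed / d ln size
    within_size_tau_elasticity: float = 0.5
    shape_speed_disperser: float = 0.10  # elongation helps dispersers ...
    shape_speed_resident: float = -0.10  # ... and hinders residents
    shape_tau_disperser: float = 0.10
    shape_tau_resident: float = 0.0

    # trajectory rendering
    model_mix: dict = field(
        default_factory=lambda: {"ACVM": 0.45, "UCVM": 0.35, "RCVM": 0.10, "RACVM": 0.10}
    )
    advection_frac: float = 0.7  # |mu| / RMS speed for advective movers
    omega_mean: float = 3.0  # rad/s for rotational movers
    omega_sd: float = 1.0
    jitter_um: float = 10.0  # non-mover net-displacement scale over the video
    field_um: tuple = (6300.0, 4500.0)  # imaged area

    def genotype_ids(self) -> list[str]:
        return [f"g{i + 1:02d}" for i in range(self.n_genotypes)]


@dataclass
class GenotypeParams:
    """Latent truth for one genotype (resident scale + disperser offsets)."""

    genotype: str
    mean_ln_speed: float
    mean_ln_tau: float
    activity_logit: float
    dispersal_logit: float
    size_mean: float
    shape_mean: float
    d_ln_speed: float  # disperser - resident offsets, incl. genotype deviation
    d_ln_tau: float
    d_act_logit: float

    @property
    def mid_speed(self) -> float:
        """Status-averaged RMS speed (um/s)."""
        return math.exp(self.mean_ln_speed + self.d_ln_speed / 2.0)

    @property
    def mid_tau(self) -> float:
        return math.exp(self.mean_ln_tau + self.d_ln_tau / 2.0)

    @property
    def mid_activity(self) -> float:
        return float(expit(self.activity_logit + self.d_act_logit / 2.0))

    @property
    def dispersal(self) -> float:
        return float(expit(self.dispersal_logit))


@dataclass
class SimulatedExperiment:
    """One rendered experiment plus its latent truth."""

    trajectories: list | None  # None in summary mode
    tubes: pd.DataFrame  # per-tube metadata (morphology, density; + measured responses in summary mode)
    densities: pd.DataFrame  # per-system start/target densities
    truth: dict


def _rng_from(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_genotype_panel(config: ExperimentConfig, seed=None) -> list[GenotypeParams]:
    """Draw the latent genotype panel.

    Latents come from a correlated Gaussian on transformed scales
    (ln speed, ln tau, logit activity, ln size): speed loads positively
    on size, tau and activity load positively on speed, and the
    dispersal logit is a linear combination of the three standardized
    movement scores plus noise.  Status-averaged back-transformed values
    are truncated to the observed genotype ranges.
    """
    rng = _rng_from(seed)
    c = config
    out = []
    for gid in c.genotype_ids():
        z_size = rng.standard_normal()
        u = rng.standard_normal(3)
        l_sz, l_st, l_as = c.size_speed_loading, c.speed_tau_loading, c.act_speed_loading
        z_speed = l_sz * z_size + math.sqrt(1 - l_sz**2) * u[0]
        z_tau = l_st * z_speed + math.sqrt(1 - l_st**2) * u[1]
        z_act = l_as * z_speed + math.sqrt(1 - l_as**2) * u[2]

        d_speed = c.status_dln_speed + c.interaction_sd * rng.standard_normal()
        d_tau = c.status_dln_tau + c.interaction_sd * rng.standard_normal()
        d_act = c.status_dact_logit + c.interaction_sd * rng.standard_normal()

        # truncate so the status midpoint stays inside the observed range
        lo, hi = RANGES["speed"]
        ln_speed = float(
            np.clip(
                c.ln_speed_mean + c.ln_speed_sd * z_speed,
                math.log(lo) - d_speed / 2,
                math.log(hi) - d_speed / 2,
            )
        )
        lo, hi = RANGES["tau"]
        ln_tau = float(
            np.clip(
                c.ln_tau_mean + c.ln_tau_sd * z_tau,
                math.log(lo) - d_tau / 2,
                math.log(hi) - d_tau / 2,
            )
        )
        lo, hi = RANGES["activity"]
        act = float(
            np.clip(
                c.act_logit_mean + c.act_logit_sd * z_act,
                logit(lo) - d_act / 2,
                logit(hi) - d_act / 2,
            )
        )
        lo, hi = RANGES["dispersal"]
        disp = float(
            np.clip(
                c.disp_logit_mean
                + c.disp_act_coef * z_act
                + c.disp_speed_coef * z_speed
                + c.disp_tau_coef * z_tau
                + c.disp_noise_sd * rng.standard_normal(),
                logit(lo),
                logit(hi),
            )
        )
        out.append(
            GenotypeParams(
                genotype=gid,
                mean_ln_speed=ln_speed,
                mean_ln_tau=ln_tau,
                activity_logit=act,
                dispersal_logit=disp,
                size_mean=float(math.exp(c.size_log_mean + c.size_log_sd * z_size)),
                shape_mean=float(max(1.0, c.shape_mean + c.shape_sd * rng.standard_normal())),
                d_ln_speed=d_speed,
                d_ln_tau=d_tau,
                d_act_logit=d_act,
            )
        )
    return out


def _mover_params(rng, n, rms, tau, mix, config):
    """Per-mover CVM parameter arrays; RMS speed sqrt(eta^2+|mu|^2) preserved."""
    models = rng.choice(list(mix), size=n, p=np.array(list(mix.values())) / sum(mix.values()))
    eta = rms.copy()
    mu = np.zeros(n, dtype=complex)
    omega = np.zeros(n)
    adv = np.isin(models, ("ACVM", "RACVM"))
    f = config.advection_frac
    theta = rng.uniform(0, 2 * math.pi, size=n)
    mu[adv] = f * rms[adv] * np.exp(1j * theta[adv])
    eta[adv] = rms[adv] * math.sqrt(1 - f**2)
    rot = np.isin(models, ("RCVM", "RACVM"))
    omega[rot] = rng.choice([-1.0, 1.0], size=int(rot.sum())) * rng.normal(
        config.omega_mean, config.omega_sd, size=int(rot.sum())
    )
    return models, tau, eta, omega, mu


def gen_experiment(
    panel: list[GenotypeParams],
    config: ExperimentConfig,
    seed=None,
    render: str = "trajectories",
) -> SimulatedExperiment:
    """Render one full experiment from a genotype panel.

    For every system (genotype x replicate) not on the drop list the
    generator draws replicate-level noise shared by the system's two
    tubes, splits the inoculated population by the realized dispersal
    rate into start/target densities, and produces a resident and a
    disperser tube with status offsets applied.  A truth record keeps
    every latent value for recovery tests.
    """
    if render not in ("trajectories", "summary"):
        raise ValueError("render must be 'trajectories' or 'summary'")
    if len(panel) != config.n_genotypes:
        raise ValueError(
            f"panel size {len(panel)} != configured n_genotypes {config.n_genotypes}"
        )
    rng = _rng_from(seed)
    c = config
    dropped = {(g, int(r)) for g, r in c.drop_systems}

    trajs: list[Trajectory] | None = [] if render == "trajectories" else None
    tube_rows = []
    density_rows = []
    truth_tubes = []

    for gp in panel:
        for rep in range(1, c.n_replicates + 1):
            if (gp.genotype, rep) in dropped:
                continue
            e_rep = rng.normal(0.0, c.rep_sd, size=3)  # ln_speed, ln_tau, act_logit
            d_sys = float(expit(gp.dispersal_logit + rng.normal(0.0, c.disp_rep_sd)))
            start_true = c.initial_density * (1.0 - d_sys)
            target_true = c.initial_density * d_sys
            start_obs = start_true * math.exp(rng.normal(0.0, c.density_meas_sd))
            target_obs = target_true * math.exp(rng.normal(0.0, c.density_meas_sd))
            density_rows.append(
                {
                    "genotype": gp.genotype,
                    "replicate": rep,
                    "start_density": start_obs,
                    "target_density": target_obs,
                }
            )
            for status in ("resident", "disperser"):
                disp = status == "disperser"
                size_tube = gp.size_mean * math.exp(rng.normal(0.0, c.size_tube_sd))
                shape_tube = max(1.0, gp.shape_mean + rng.normal(0.0, c.shape_tube_sd))
                dsize = math.log(size_tube / gp.size_mean)
                dshape = shape_tube - gp.shape_mean
                shape_speed = c.shape_speed_disperser if disp else c.shape_speed_resident
                shape_tau = c.shape_tau_disperser if disp else c.shape_tau_resident

                ln_speed = (
                    gp.mean_ln_speed
                    + (gp.d_ln_speed if disp else 0.0)
                    + e_rep[0]
                    + rng.normal(0.0, c.tube_sd)
                    + c.within_size_elasticity * dsize
                    + shape_speed * dshape
                )
                ln_tau = (
                    gp.mean_ln_tau
                    + (gp.d_ln_tau if disp else 0.0)
                    + e_rep[1]
                    + rng.normal(0.0, c.tube_sd)
                    + c.within_size_tau_elasticity * dsize
                    + shape_tau * dshape
                )
                p_act = float(
                    expit(
                        gp.activity_logit
                        + (gp.d_act_logit if disp else 0.0)
                        + e_rep[2]
                        + rng.normal(0.0, c.tube_sd)
                    )
                )
                n_mov = int(rng.binomial(c.cells_per_tube, p_act))
                row = {
                    "genotype": gp.genotype,
                    "replicate": rep,
                    "status": status,
                    "size_um2": size_tube,
                    "shape": shape_tube,
                    "density_cells_ml": target_obs if disp else start_obs,
                }
                truth_tubes.append(
                    {
                        "genotype": gp.genotype,
                        "replicate": rep,
                        "status": status,
                        "ln_speed": ln_speed,
                        "ln_tau": ln_tau,
                        "p_activity": p_act,
                        "n_movers": n_mov,
                        "n_cells": c.cells_per_tube,
                        "dispersal": d_sys,
                    }
                )
                if render == "summary":
                    n_eff = max(1, min(23, n_mov))
                    row["activity"] = n_mov / c.cells_per_tube
                    row["ln_speed"] = ln_speed + rng.normal(0.0, c.traj_ln_sd / math.sqrt(n_eff))
                    row["ln_tau"] = ln_tau + rng.normal(0.0, c.traj_ln_sd / math.sqrt(n_eff))
                else:
                    trajs.extend(
                        _render_tube(rng, gp.genotype, rep, status, ln_speed, ln_tau, n_mov, c)
                    )
                tube_rows.append(row)

    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(c).items()},
        "genotypes": {gp.genotype: asdict(gp) for gp in panel},
        "tubes": truth_tubes,
    }
    return SimulatedExperiment(
        trajectories=trajs,
        tubes=pd.DataFrame(tube_rows),
        densities=pd.DataFrame(density_rows),
        truth=truth,
    )


def _render_tube(rng, genotype, rep, status, ln_speed, ln_tau, n_mov, c) -> list[Trajectory]:
    """All trajectories of one tube: CVM movers plus sub-threshold jitter."""
    meta = {"genotype": genotype, "replicate": rep, "status": status}
    out = []
    n_non = c.cells_per_tube - n_mov
    fx, fy = c.field_um
    times = np.arange(c.frames) * c.dt
    if n_mov:
        rms = np.exp(ln_speed + c.traj_ln_sd * rng.standard_normal(n_mov))
        tau = np.exp(ln_tau + c.traj_ln_sd * rng.standard_normal(n_mov))
        models, tau, eta, omega, mu = _mover_params(rng, n_mov, rms, tau, c.model_mix, c)
        x0 = rng.uniform(0, fx, n_mov) + 1j * rng.uniform(0, fy, n_mov)
        pos = simulate_cvm_batch(tau, eta, omega, mu, c.frames, c.dt, x0, rng)
        for j in range(n_mov):
            out.append(
                Trajectory(
                    f"{genotype}_r{rep}_{status[0]}_m{j:03d}",
                    times,
                    pos[j].real,
                    pos[j].imag,
                    meta={**meta, "true_model": str(models[j])},
                )
            )
    # non-movers: random-walk jitter with net displacement ~ jitter_um
    step_sd = c.jitter_um / math.sqrt(c.frames)
    for j in range(n_non):
        steps = rng.normal(0.0, step_sd, size=(c.frames - 1, 2))
        x0 = (rng.uniform(0, fx), rng.uniform(0, fy))
        out.append(
            Trajectory(
                f"{genotype}_r{rep}_{status[0]}_n{j:03d}",
                times,
                x0[0] + np.concatenate([[0.0], np.cumsum(steps[:, 0])]),
                x0[1] + np.concatenate([[0.0], np.cumsum(steps[:, 1])]),
                meta={**meta, "true_model": "none"},
            )
        )
    return out


def truth_vs_estimate_report(truth: dict, tubes: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype comparison of latent truth and pipeline estimates.

    ``tubes`` is the estimated tube-level table; the report has one row
    per genotype with true and estimated activity, ln speed, ln tau and
    (when present) dispersal rate, and carries overall bias and RMSE per
    quantity in ``DataFrame.attrs["summary"]``.
    """
    rows = []
    for gid, gp in truth["genotypes"].items():
        sub = tubes[tubes["genotype"] == gid]
        if sub.empty:
            continue
        row = {
            "genotype": gid,
            "true_activity": float(
                expit(gp["activity_logit"] + gp["d_act_logit"] / 2.0)
            ),
            "true_ln_speed": gp["mean_ln_speed"] + gp["d_ln_speed"] / 2.0,
            "true_ln_tau": gp["mean_ln_tau"] + gp["d_ln_tau"] / 2.0,
            "true_dispersal": float(expit(gp["dispersal_logit"])),
            "est_activity": float(sub["activity"].mean()),
            "est_ln_speed": float(sub["ln_speed"].mean()),
            "est_ln_tau": float(sub["ln_tau"].mean()),
        }
        if "dispersal_rate" in sub.columns:
            row["est_dispersal"] = float(sub["dispersal_rate"].mean())
        rows.append(row)
    report = pd.DataFrame(rows)
    summary = {}
    for q in ("activity", "ln_speed", "ln_tau", "dispersal"):
        if f"est_{q}" in report.columns:
            err = report[f"est_{q}"] - report[f"true_{q}"]
            summary[q] = {"bias": float(err.mean()), "rmse": float(np.sqrt((err**2).mean()))}
    report.attrs["summary"] = summary
    return report
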