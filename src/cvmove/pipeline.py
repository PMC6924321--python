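"""End-to-end pipeline: generate/ingest -> fit -> aggregate -> infer.

The stages mirror the experimental workflow: every tube's video yields
trajectories; activity is computed over all of them; 23 moving
trajectories per tube are subsampled and fitted with the four CVM
variants; selected fits pass a pooled MAD outlier screen; tube-level
summaries join morphology and density; and the statistical battery
(nested ANOVA, ANCOVA selection, difference models, dispersal R^2,
covariation, model frequencies) runs on the tube table.

All randomness flows from one root seed, split per stage, so re-running
a configuration reproduces every output byte-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cvm, inference, metrics
from .synthetic import ExperimentConfig, gen_experiment, gen_genotype_panel

__all__ = ["RunConfig", "ValidationError", "run_pipeline", "fit_tubes", "build_tube_table", "analyze"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.10g"


class ValidationError(ValueError):
    """Malformed input data (missing columns, bad rows)."""


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "run"
    # input: either a generator config or paths to trajectory/morphology/density CSVs
    generate: bool = True
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    trajectories_csv: str | None = None
    tubes_csv: str | None = None  # morphology + density per tube
    densities_csv: str | None = None  # start/target density per system
    # screening thresholds (defaults reproduce the published constants)
    min_duration_s: float = 1.0
    min_displacement_um: float = 50.0
    subsample_n: int = 23
    mad_threshold: float = 3.0
    min_fit_points: int = 10
    write_trajectories: bool = False  # full-scale trajectory CSVs are large

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        exp = raw.pop("experiment", None)
        cfg = cls(**raw)
        if exp is not None:
            if "drop_systems" in exp:
                exp["drop_systems"] = tuple(tuple(x) for x in exp["drop_systems"])
            if "field_um" in exp:
                exp["field_um"] = tuple(exp["field_um"])
            cfg.experiment = ExperimentConfig(**exp)
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _tube_key(traj: cvm.Trajectory) -> tuple:
    m = traj.meta
    return (str(m.get("genotype")), int(m.get("replicate")), str(m.get("status")))


def fit_tubes(
    trajectories,
    seed,
    subsample_n: int = 23,
    min_duration_s: float = 1.0,
    min_displacement_um: float = 50.0,
    min_fit_points: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen, subsample and fit all tubes.

    Returns ``(fits, activities)``: the per-trajectory/per-model fit
    table (with tube keys and the selected flag) and the per-tube
    activity table computed over *all* trajectories of the tube.
    """
    rng = np.random.default_rng(seed)
    by_tube: dict[tuple, list] = {}
    for t in trajectories:
        by_tube.setdefault(_tube_key(t), []).append(t)

    act_rows = []
    fit_frames = []
    for key in sorted(by_tube):
        trajs = by_tube[key]
        movers = [
            t for t in trajs if metrics.classify_moving(t, min_duration_s, min_displacement_um)
        ]
        act_rows.append(
            {
                "genotype": key[0],
                "replicate": key[1],
                "status": key[2],
                "activity": len(movers) / len(trajs),
                "n_trajectories": len(trajs),
                "n_moving": len(movers),
            }
        )
        chosen = metrics.subsample(movers, subsample_n, seed=rng)
        rows = {}
        for t in chosen:
            best, fits = cvm.select_model(t, min_points=min_fit_points)
            rows[t.traj_id] = (best, fits)
        if rows:
            df = cvm.fits_to_frame(rows)
            df.insert(1, "genotype", key[0])
            df.insert(2, "replicate", key[1])
            df.insert(3, "status", key[2])
            fit_frames.append(df)
    fits = pd.concat(fit_frames, ignore_index=True) if fit_frames else pd.DataFrame()
    return fits, pd.DataFrame(act_rows)


def build_tube_table(
    fits: pd.DataFrame,
    activities: pd.DataFrame,
    tubes_meta: pd.DataFrame,
    densities: pd.DataFrame,
    mad_threshold: float = 3.0,
) -> pd.DataFrame:
    """Pooled MAD screen, per-tube aggregation, dispersal-rate join.

    The MAD mask is computed over the selected fits of the whole run,
    once for RMS speed and once for tau; a trajectory flagged on either
    parameter is dropped from both means.  The system's dispersal rate
    is replicated across its two tube rows.
    """
    sel = fits[fits["selected"]].copy()
    keep = metrics.mad_filter(sel["rms_speed_um_s"], mad_threshold) & metrics.mad_filter(
        sel["tau_s"], mad_threshold
    )
    sel = sel[keep]

    meta = tubes_meta.set_index(["genotype", "replicate", "status"])
    rows = []
    for _, arow in activities.iterrows():
        key = (arow["genotype"], arow["replicate"], arow["status"])
        grp = sel[
            (sel["genotype"] == key[0])
            & (sel["replicate"] == key[1])
            & (sel["status"] == key[2])
        ]
        m = meta.loc[key]
        obs = metrics.aggregate_tube(
            grp,
            activity=arow["activity"],
            size=m["size_um2"],
            shape=m["shape"],
            density=m["density_cells_ml"],
            genotype=key[0],
            replicate=key[1],
            status=key[2],
        )
        rows.append(
            {
                "genotype": obs.genotype,
                "replicate": obs.replicate,
                "status": obs.status,
                "activity": obs.activity,
                "ln_speed": obs.ln_speed,
                "ln_tau": obs.ln_tau,
                "size_um2": obs.size,
                "shape": obs.shape,
                "density_cells_ml": obs.density,
            }
        )
    tubes = pd.DataFrame(rows)
    dens = densities.copy()
    dens["dispersal_rate"] = [
        metrics.dispersal_rate(s, t)
        for s, t in zip(dens["start_density"], dens["target_density"])
    ]
    tubes = tubes.merge(
        dens[["genotype", "replicate", "dispersal_rate"]], on=["genotype", "replicate"], how="left"
    )
    return tubes.sort_values(["genotype", "replicate", "status"]).reset_index(drop=True)


def analyze(tubes: pd.DataFrame, fits: pd.DataFrame | None = None) -> dict:
    """Run the full statistical battery on a tube-level table."""
    data = tubes.rename(columns={"size_um2": "size"})
    results: dict = {}
    results["anova"] = {
        resp: inference.three_way_anova(data, resp) for resp in ("activity", "ln_speed", "ln_tau")
    }
    cands = inference.ancova_candidates()
    results["ancova"] = {
        resp: inference.aicc_select(cands, data, resp) for resp in ("ln_speed", "ln_tau")
    }
    results["delta"] = inference.delta_models(data)

    geno = (
        data.assign(speed=np.exp(data["ln_speed"]), tau=np.exp(data["ln_tau"]))
        .groupby("genotype", as_index=False)
        .agg({"dispersal_rate": "mean", "activity": "mean", "speed": "mean", "tau": "mean"})
    )
    results["genotype_table"] = geno
    results["r2"] = inference.dispersal_r2(geno)

    gs = (
        data.assign(speed=np.exp(data["ln_speed"]), tau=np.exp(data["ln_tau"]))
        .groupby(["genotype", "status"], as_index=False)
        .agg({"speed": "mean", "tau": "mean"})
    )
    results["covariation"] = inference.speed_linearity_covariation(gs)

    systems = data.drop_duplicates(["genotype", "replicate"])[
        ["genotype", "replicate", "dispersal_rate"]
    ]
    results["dispersal_anova"] = inference.one_way_anova(systems)

    if fits is not None and len(fits):
        results["model_frequencies"] = inference.model_frequency_table(fits)
    return results


# ---------------------------------------------------------------------------
# File-level driver


def _read_inputs(config: RunConfig):
    try:
        trajectories = cvm.read_trajectories(config.trajectories_csv)
    except ValueError as exc:
        raise ValidationError(str(exc)) from exc
    tubes_meta = pd.read_csv(config.tubes_csv)
    need = {"genotype", "replicate", "status", "size_um2", "shape", "density_cells_ml"}
    if not need <= set(tubes_meta.columns):
        raise ValidationError(
            f"{config.tubes_csv}: missing columns {sorted(need - set(tubes_meta.columns))}"
        )
    densities = pd.read_csv(config.densities_csv)
    need = {"genotype", "replicate", "start_density", "target_density"}
    if not need <= set(densities.columns):
        raise ValidationError(
            f"{config.densities_csv}: missing columns {sorted(need - set(densities.columns))}"
        )
    return trajectories, tubes_meta, densities


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and write the output tables to the run directory."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seed_gen, seed_sub = ss.spawn(2)

    truth = None
    if config.generate:
        panel = gen_genotype_panel(config.experiment, np.random.default_rng(seed_gen))
        exp = gen_experiment(
            panel, config.experiment, np.random.default_rng(seed_gen), render="trajectories"
        )
        trajectories, tubes_meta, densities, truth = (
            exp.trajectories,
            exp.tubes,
            exp.densities,
            exp.truth,
        )
        if config.write_trajectories:
            cvm.write_trajectories(trajectories, out / "trajectories.csv")
    else:
        trajectories, tubes_meta, densities = _read_inputs(config)

    fits, activities = fit_tubes(
        trajectories,
        seed=seed_sub,
        subsample_n=config.subsample_n,
        min_duration_s=config.min_duration_s,
        min_displacement_um=config.min_displacement_um,
        min_fit_points=config.min_fit_points,
    )
    tubes = build_tube_table(fits, activities, tubes_meta, densities, config.mad_threshold)
    results = analyze(tubes, fits)

    fits.to_csv(out / "fits.csv", index=False, float_format=FLOAT_FMT)
    tubes.to_csv(out / "tubes.csv", index=False, float_format=FLOAT_FMT)
    for resp, tab in results["anova"].items():
        tab.table.to_csv(out / f"anova_{resp}.csv", index=False, float_format=FLOAT_FMT)
    for resp, mst in results["ancova"].items():
        mst.table.to_csv(out / f"ancova_{resp}.csv", index=False, float_format=FLOAT_FMT)
    pd.concat(
        [m.table.assign(response=r) for r, m in results["delta"].items()], ignore_index=True
    ).to_csv(out / "delta_models.csv", index=False, float_format=FLOAT_FMT)
    results["r2"].table.to_csv(out / "r2_decomposition.csv", index=False, float_format=FLOAT_FMT)
    if "model_frequencies" in results:
        results["model_frequencies"].to_csv(
            out / "model_frequencies.csv", index=False, float_format=FLOAT_FMT
        )
    results["dispersal_anova"].table.to_csv(
        out / "dispersal_anova.csv", index=False, float_format=FLOAT_FMT
    )

    cov = results["covariation"]
    report = []
    for resp, tab in results["anova"].items():
        report.append(tab.report())
        report.append("")
    report.append(
        f"Speed-linearity covariation: b = {cov.slope:.6g} (t = {cov.t:.3f}, p = {cov.p:.3g}); "
        f"status intercept diff p = {cov.intercept_diff_p:.3g}, "
        f"slope diff p = {cov.slope_diff_p:.3g}"
    )
    report.append("")
    report.append("Dispersal-rate R^2 decomposition (genotype level):")
    report.append(results["r2"].table.to_string(index=False))
    report.append("")
    report.append(results["dispersal_anova"].report())
    (out / "report.txt").write_text("\n".join(report) + "\n")

    config.to_yaml(out / "config.yaml")
    if truth is not None:
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    logger.info("pipeline run complete: %s (seed %d)", out, config.seed)
    return out
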