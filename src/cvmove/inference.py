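"""Statistical analyses of tube-level movement and dispersal data.

Three questions drive the analysis of a two-patch dispersal experiment:

* Q1 — is there variation in movement (activity, ln speed, ln tau)
  among genotypes and between dispersers and residents?  Answered by a
  three-way ANOVA with genotype and dispersal status as crossed fixed
  effects and replicate as a random effect nested in genotype but
  crossed with status.  Because the design is saturated (one tube per
  genotype x replicate x status cell) the residual has zero df, and the
  F-tests use the appropriate random strata as error terms: genotype is
  tested over replicate(genotype); status and genotype x status over
  replicate x status(genotype).
* Q2 — can movement differences be explained by morphology?  Answered
  by ANCOVA candidate sets over {status, size, shape} with AICc and the
  delta-AICc < 2 parsimony rule, both across tubes and on
  within-replicate disperser-minus-resident differences.
* Q3 — how much of the genotype-level dispersal rate do activity,
  speed and linearity explain?  Answered by R^2 / AIC of four nested
  least-squares regressions at the genotype level.

Sums of squares are sequential (type I) in the fixed row order; the
single dropped system makes the design only mildly unbalanced, so the
SS type matters little, but the choice is recorded in the table
metadata.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "AnovaTable",
    "ModelSelectionTable",
    "R2Decomposition",
    "CovariationResult",
    "three_way_anova",
    "one_way_anova",
    "ancova_candidates",
    "aicc_select",
    "apply_parsimony",
    "delta_models",
    "dispersal_r2",
    "speed_linearity_covariation",
    "model_frequency_table",
]

logger = logging.getLogger(__name__)

RESPONSES = ("activity", "ln_speed", "ln_tau")


@dataclass
class AnovaTable:
    """ANOVA summary with explicit error-term bookkeeping."""

    table: pd.DataFrame  # effect, denominator, df, ss, ms, F, p
    response: str
    transform: str = "identity"
    n: int = 0
    ss_type: str = "sequential"

    @property
    def total_df(self) -> int:
        return int(self.table["df"].sum())

    def report(self) -> str:
        """Plain-text report in the effect / denominator / df / SS / MS / F / p layout."""
        lines = [
            f"ANOVA — response: {self.response} (transform: {self.transform}, "
            f"{self.ss_type} SS, n = {self.n})",
            f"{'Effect':<41}{'Denominator':<41}{'df':>4}{'SS':>12}{'MS':>10}{'F':>9}{'p':>10}",
        ]
        for _, r in self.table.iterrows():
            fval = f"{r['F']:.2f}" if pd.notna(r["F"]) else "-"
            pval = f"{r['p']:.4g}" if pd.notna(r["p"]) else "-"
            lines.append(
                f"{r['effect']:<41}{str(r['denominator']):<41}{int(r['df']):>4}"
                f"{r['ss']:>12.4f}{r['ms']:>10.4f}{fval:>9}{pval:>10}"
            )
        lines.append(f"{'Total':<41}{'':<41}{self.total_df:>4}{self.table['ss'].sum():>12.4f}")
        return "\n".join(lines)


@dataclass
class ModelSelectionTable:
    """AICc candidate-model comparison with the parsimony selection."""

    table: pd.DataFrame  # model, k, aicc, delta, weight, selected
    response: str

    @property
    def selected(self) -> str:
        return str(self.table.loc[self.table["selected"], "model"].iloc[0])


@dataclass
class R2Decomposition:
    """R^2 and AIC of the dispersal-rate regressions at genotype level."""

    table: pd.DataFrame  # model, predictors, k, r2, aic
    n: int

    def r2(self, model: str) -> float:
        return float(self.table.set_index("model").loc[model, "r2"])


@dataclass
class CovariationResult:
    """Speed–linearity regression: common slope and status-difference tests."""

    slope: float  # tau per (um/s)
    t: float
    p: float
    intercept_diff_t: float
    intercept_diff_p: float
    slope_diff_t: float
    slope_diff_p: float
    n: int = 0


# ---------------------------------------------------------------------------
# Sequential sums of squares on explicit design blocks


def _seq_ss(y: np.ndarray, blocks: list[tuple[str, np.ndarray]]) -> list[tuple[str, int, float]]:
    """Type-I SS: the RSS drop (and rank gain) as each block enters the model."""
    n = y.size
    X = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss_prev = float(np.sum((y - X @ beta) ** 2))
    rank_prev = 1
    out = []
    for name, B in blocks:
        X = np.hstack([X, B])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        rank = int(np.linalg.matrix_rank(X))
        out.append((name, rank - rank_prev, max(rss_prev - rss, 0.0)))
        rss_prev, rank_prev = rss, rank
    return out


def _dummies(labels: pd.Series) -> np.ndarray:
    return pd.get_dummies(labels.astype(str)).to_numpy(dtype=float)


def _drop_incomplete_systems(data: pd.DataFrame) -> pd.DataFrame:
    """Drop systems (genotype x replicate) lacking one of the two statuses."""
    counts = data.groupby(["genotype", "replicate"])["status"].nunique()
    bad = counts[counts < 2].index
    if len(bad):
        for g, r in bad:
            logger.warning("dropping unpaired system %s/replicate %s", g, r)
        mask = ~data.set_index(["genotype", "replicate"]).index.isin(bad)
        data = data.loc[mask.to_numpy() if hasattr(mask, "to_numpy") else mask]
    return data.reset_index(drop=True)


def three_way_anova(data: pd.DataFrame, response: str) -> AnovaTable:
    """Nested mixed-design ANOVA for one movement response.

    ``data`` holds one row per tube with columns genotype, replicate,
    status and the response.  Effects enter sequentially as genotype,
    status, genotype x status, replicate(genotype),
    replicate x status(genotype); the last stratum saturates the design
    so the residual df is zero and the two replicate strata carry no
    F-test of their own.
    """
    if response not in data.columns:
        raise ValueError(f"response {response!r} not in data")
    data = _drop_incomplete_systems(data)
    if data["genotype"].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    if data["status"].nunique() < 2:
        raise ValueError("both dispersal statuses must be present")

    y = data[response].to_numpy(dtype=float)
    g = data["genotype"].astype(str)
    s = data["status"].astype(str)
    r = data["replicate"].astype(str)
    blocks = [
        ("Genotype", _dummies(g)),
        ("Dispersal status", _dummies(s)),
        ("Genotype x dispersal status", _dummies(g + ":" + s)),
        ("Replicate (genotype)", _dummies(g + ":" + r)),
        ("Replicate x dispersal status (genotype)", _dummies(g + ":" + r + ":" + s)),
    ]
    ss_rows = _seq_ss(y, blocks)
    ss = {name: (df, val) for name, df, val in ss_rows}

    def ms(name):
        df, val = ss[name]
        return val / df if df > 0 else np.nan

    denom = {
        "Genotype": "Replicate (genotype)",
        "Dispersal status": "Replicate x dispersal status (genotype)",
        "Genotype x dispersal status": "Replicate x dispersal status (genotype)",
        "Replicate (genotype)": "Error",
        "Replicate x dispersal status (genotype)": "Error",
    }
    rows = []
    for name, df_i, ss_i in ss_rows:
        d = denom[name]
        if d != "Error" and ss[d][0] > 0 and ms(d) > 0:
            F = ms(name) / ms(d)
            p = float(stats.f.sf(F, df_i, ss[d][0]))
        else:
            F, p = np.nan, np.nan
        rows.append(
            {
                "effect": name,
                "denominator": d,
                "df": df_i,
                "ss": ss_i,
                "ms": ms(name),
                "F": F,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    return AnovaTable(table=table, response=response, n=len(data))


def one_way_anova(records: pd.DataFrame, value: str = "dispersal_rate") -> AnovaTable:
    """One-way between/within decomposition on per-system values."""
    groups = [g[value].to_numpy(dtype=float) for _, g in records.groupby("genotype")]
    if len(groups) < 2:
        raise ValueError("need >= 2 genotypes")
    y = records[value].to_numpy(dtype=float)
    n, k = y.size, len(groups)
    grand = y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    if ss_within == 0.0:
        F, p = math.inf, 0.0
    else:
        F = ms_b / (ss_within / df_w)
        p = float(stats.f.sf(F, df_b, df_w))
    table = pd.DataFrame(
        [
            {"effect": "Genotype", "denominator": "Error", "df": df_b, "ss": ss_between,
             "ms": ms_b, "F": F, "p": p},
            {"effect": "Error", "denominator": None, "df": df_w, "ss": ss_within,
             "ms": ss_within / df_w if df_w else np.nan, "F": np.nan, "p": np.nan},
        ]
    )
    return AnovaTable(table=table, response=value, n=n)


# ---------------------------------------------------------------------------
# AICc candidate-model selection (ANCOVA, Q2)


def ancova_candidates() -> list[str]:
    """All marginality-respecting formulas over status, size and shape.

    Returns right-hand sides: every additive combination of the three
    main effects, each optionally augmented with the status x size and
    status x shape interactions whose main effects are present, plus the
    intercept-only model.
    """
    mains = ["C(status)", "size", "shape"]
    out = []
    for m_mask in itertools.product([False, True], repeat=3):
        terms = [t for t, keep in zip(mains, m_mask) if keep]
        inters = []
        if "C(status)" in terms and "size" in terms:
            inters.append("C(status):size")
        if "C(status)" in terms and "shape" in terms:
            inters.append("C(status):shape")
        for i_mask in itertools.product([False, True], repeat=len(inters)):
            chosen = terms + [t for t, keep in zip(inters, i_mask) if keep]
            out.append(" + ".join(chosen) if chosen else "1")
    return out


def _ols_aicc(formula: str, data: pd.DataFrame):
    """OLS fit with AICc where k counts coefficients plus the variance."""
    with np.errstate(divide="ignore"):  # perfect fits yield llf = +inf
        fit = smf.ols(formula, data=data).fit()
    n = int(fit.nobs)
    rank = int(np.linalg.matrix_rank(fit.model.exog))
    if rank < fit.model.exog.shape[1]:
        raise np.linalg.LinAlgError(f"rank-deficient design for {formula!r}")
    k = rank + 1
    if n - k - 1 <= 0:
        raise ValueError(f"n = {n} too small for AICc with k = {k}")
    if not math.isfinite(fit.llf):
        # zero residual variance: the Gaussian likelihood is unbounded, so
        # the candidate is flagged as a perfect fit (AICc -> -inf) and the
        # parsimony rule falls back to the parameter count
        return fit, k, -math.inf
    aic = 2 * k - 2 * fit.llf
    aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    return fit, k, float(aicc)


def aicc_select(candidates, data: pd.DataFrame, response: str) -> ModelSelectionTable:
    """Fit each candidate by least squares and apply the parsimony rule.

    The selected model is the smallest-k candidate within 2 AICc units
    of the best, ties broken by lower AICc.  Akaike weights are computed
    over the full candidate set.  Rank-deficient candidates are dropped
    with a warning.
    """
    rows = []
    for rhs in candidates:
        formula = f"{response} ~ {rhs}"
        try:
            _, k, aicc = _ols_aicc(formula, data)
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.warning("candidate %r dropped: %s", rhs, exc)
            continue
        rows.append({"model": rhs, "k": k, "aicc": aicc})
    if not rows:
        raise ValueError("no fittable candidate models")
    table = pd.DataFrame(rows)
    table = apply_parsimony(table)
    return ModelSelectionTable(table=table, response=response)


def apply_parsimony(table: pd.DataFrame, delta_max: float = 2.0) -> pd.DataFrame:
    """Delta, Akaike weights and the delta-AICc < 2 parsimony selection.

    Among candidates within ``delta_max`` of the best AICc, the one with
    the fewest parameters is selected (ties by lower AICc).
    """
    table = table.copy()
    best = table["aicc"].min()
    if math.isinf(best):
        # perfect fits: every such candidate is "within delta" of the best
        table["delta"] = np.where(np.isinf(table["aicc"]), 0.0, np.inf)
    else:
        table["delta"] = table["aicc"] - best
    w = np.exp(-table["delta"] / 2.0)
    table["weight"] = w / w.sum()
    eligible = table[table["delta"] < delta_max]
    sel_idx = eligible.sort_values(["k", "aicc"]).index[0]
    table["selected"] = table.index == sel_idx
    return table.sort_values(["aicc", "k"]).reset_index(drop=True)


def delta_models(tubes: pd.DataFrame) -> dict[str, ModelSelectionTable]:
    """Within-replicate difference models.

    For each paired system, compute disperser-minus-resident differences
    of ln speed, ln tau, size and shape, then select among the four
    candidate regressions of each movement difference on the morphology
    differences.  Unpaired systems are dropped with a warning.
    """
    tubes = _drop_incomplete_systems(tubes)
    wide = tubes.pivot_table(
        index=["genotype", "replicate"],
        columns="status",
        values=["ln_speed", "ln_tau", "size", "shape"],
    )
    diffs = pd.DataFrame(
        {
            f"d_{v}": wide[(v, "disperser")] - wide[(v, "resident")]
            for v in ("ln_speed", "ln_tau", "size", "shape")
        }
    ).reset_index(drop=True)
    candidates = ["1", "d_size", "d_shape", "d_size + d_shape"]
    return {
        "ln_speed": aicc_select(candidates, diffs, "d_ln_speed"),
        "ln_tau": aicc_select(candidates, diffs, "d_ln_tau"),
    }


# ---------------------------------------------------------------------------
# Q3: dispersal rate vs genotype-level movement


def dispersal_r2(geno: pd.DataFrame) -> R2Decomposition:
    """R^2 / AIC decomposition of genotype-mean dispersal rate.

    ``geno`` has one row per genotype with columns dispersal_rate,
    activity, speed and tau (genotype means over statuses and
    replicates).  Four regressions are compared: each single movement
    predictor and all three jointly.
    """
    required = {"dispersal_rate", "activity", "speed", "tau"}
    missing = required - set(geno.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    n = len(geno)
    if n <= 5:
        raise ValueError("need > 5 genotypes for a stable decomposition")
    specs = [
        ("activity", "activity"),
        ("linearity", "tau"),
        ("speed", "speed"),
        ("full", "activity + speed + tau"),
    ]
    rows = []
    for label, rhs in specs:
        fit, k, _ = _ols_aicc(f"dispersal_rate ~ {rhs}", geno)
        rows.append(
            {
                "model": label,
                "predictors": rhs,
                "k": k,
                "r2": float(fit.rsquared),
                "aic": float(2 * k - 2 * fit.llf),
            }
        )
    return R2Decomposition(table=pd.DataFrame(rows), n=n)


def speed_linearity_covariation(data: pd.DataFrame) -> CovariationResult:
    """Regression of tau on RMS speed across genotype x status means.

    The common slope comes from the additive model
    ``tau ~ speed + status``; the status-difference tests (does the
    intercept or the slope differ between dispersers and residents?)
    come from the full interaction model.
    """
    for col in ("speed", "tau", "status"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    if data.groupby("status").size().min() < 3:
        raise ValueError("need >= 3 points per status")
    if float(np.var(data["speed"])) == 0.0:
        raise ValueError("zero variance in speed")
    add = smf.ols("tau ~ speed + C(status)", data=data).fit()
    full = smf.ols("tau ~ speed * C(status)", data=data).fit()
    status_term = [c for c in full.params.index if c.startswith("C(status)") and ":" not in c][0]
    inter_term = [c for c in full.params.index if ":" in c][0]
    return CovariationResult(
        slope=float(add.params["speed"]),
        t=float(add.tvalues["speed"]),
        p=float(add.pvalues["speed"]),
        intercept_diff_t=float(full.tvalues[status_term]),
        intercept_diff_p=float(full.pvalues[status_term]),
        slope_diff_t=float(full.tvalues[inter_term]),
        slope_diff_p=float(full.pvalues[inter_term]),
        n=len(data),
    )


def model_frequency_table(fits: pd.DataFrame) -> pd.DataFrame:
    """Per (genotype, status) relative frequencies of the selected CVM variant.

    ``fits`` needs columns genotype, status, model and selected; only
    selected rows are tabulated.  Each row of the result sums to 1 over
    the columns UCVM, RCVM, ACVM, RACVM.
    """
    from .cvm import MODELS

    sel = fits[fits["selected"]] if "selected" in fits.columns else fits
    freq = (
        sel.groupby(["genotype", "status"])["model"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
    )
    for m in MODELS:
        if m not in freq.columns:
            freq[m] = 0.0
    return freq[list(MODELS)].reset_index()
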