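"""Replicated simulate -> mask -> fit evaluation of the missing-label model.

For each replicate a campaign is simulated from a scenario's generative
truth, labels are masked, the Bayesian model is fitted, and the slope
parameters are summarized.  Two naive baselines are fitted alongside:

* LM1 — ordinary least squares of weight (or primary length) on day and year
  over *all* records, ignoring the age-sex classes entirely;
* LM2 — the same model restricted to records positively identified as young
  females (the one class that can be analyzed without imputation).

Aggregated over replicates the study reports, per parameter, the 95%
credible/confidence-interval coverage (proportion of replicates whose
interval contains the generating value), the mean bias (estimate - truth)
with its Monte-Carlo standard error, and the mean interval width.  Replicate
seeds are derived from the master seed with a counter-based scheme, so any
single replicate can be reproduced independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from redstart.bayes_model import SLOPE_NAMES, MCMCConfig, PriorSpec, run_mcmc
from redstart.capture_data import CaptureTable
from redstart.mcmc_diagnostics import summarize
from redstart.synthetic_data import ScenarioSpec, apply_missingness, simulate_captures

logger = logging.getLogger(__name__)

#: baseline (outcome, covariate) -> model slope name
BASELINE_PARAM = {
    ("weight", "day"): "w1",
    ("weight", "year"): "w2",
    ("primary", "day"): "p1",
    ("primary", "year"): "p2",
}


@dataclass
class StudyResult:
    """Aggregated outcome of one scenario study."""

    scenario: str
    n_reps: int
    master_seed: int
    coverage_bias: pd.DataFrame  # per Bayesian slope parameter
    baselines: pd.DataFrame  # per (model, outcome, covariate)
    per_replicate: pd.DataFrame  # long: every interval from every replicate
    n_nonconverged: int = 0
    mcmc_config: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
            "n_nonconverged": self.n_nonconverged,
            "mcmc_config": self.mcmc_config,
            "coverage_bias": self.coverage_bias.reset_index().to_dict("records"),
            "baselines": self.baselines.reset_index().to_dict("records"),
        }


def replicate_seed(master_seed: int, rep: int) -> np.random.SeedSequence:
    """Counter-based replicate seed: independent and individually reproducible."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(rep,))


def _ols_intervals(table: CaptureTable, mask: np.ndarray | None = None) -> list[dict]:
    """Day/year OLS slopes with 95% CIs for weight and primary length."""
    frame = table.frame if mask is None else table.frame.loc[mask]
    day_c = frame["day"].to_numpy(dtype=float) - table.season_midpoint_day
    year_c = frame["year"].to_numpy(dtype=float) - table.reference_year
    X = np.column_stack([np.ones(len(frame)), day_c, year_c])
    rows = []
    for outcome, col in (("weight", "weight_g"), ("primary", "primary_mm")):
        fit = sm.OLS(frame[col].to_numpy(dtype=float), X).fit()
        ci = np.asarray(fit.conf_int(alpha=0.05))
        for j, cov in ((1, "day"), (2, "year")):
            rows.append(
                dict(
                    outcome=outcome,
                    covariate=cov,
                    parameter=BASELINE_PARAM[(outcome, cov)],
                    est=float(fit.params[j]),
                    lo=float(ci[j, 0]),
                    hi=float(ci[j, 1]),
                )
            )
    return rows


def run_replicate(
    scenario: ScenarioSpec,
    seed_seq: np.random.SeedSequence,
    mcmc_config: MCMCConfig,
    priors: PriorSpec | None = None,
) -> pd.DataFrame:
    """One simulate -> mask -> fit replicate; returns the long interval table."""
    sim_ss, mask_ss, mcmc_ss = seed_seq.spawn(3)
    table = simulate_captures(scenario, np.random.default_rng(sim_ss))
    masked = apply_missingness(table, scenario, np.random.default_rng(mask_ss))
    cfg_seed = int(mcmc_ss.generate_state(1)[0] & 0x7FFFFFFF)
    cfg = MCMCConfig(
        n_chains=mcmc_config.n_chains,
        n_iter=mcmc_config.n_iter,
        n_burn=mcmc_config.n_burn,
        thin=mcmc_config.thin,
        seed=cfg_seed,
        target_accept=mcmc_config.target_accept,
        adapt_rate=mcmc_config.adapt_rate,
        init_jitter=mcmc_config.init_jitter,
        shared_rho=mcmc_config.shared_rho,
        rhat_threshold=mcmc_config.rhat_threshold,
    )
    draws = run_mcmc(masked, priors or PriorSpec(), cfg)
    summary = summarize(draws.scalar_frame(), parameters=SLOPE_NAMES)

    rows = []
    for name in SLOPE_NAMES:
        rows.append(
            dict(
                source="bayes",
                parameter=name,
                est=float(summary.loc[name, "mean"]),
                lo=float(summary.loc[name, "q2.5"]),
                hi=float(summary.loc[name, "q97.5"]),
                converged=bool(draws.converged),
            )
        )
    for row in _ols_intervals(masked):
        rows.append(
            dict(source="lm1", parameter=row["parameter"], est=row["est"], lo=row["lo"], hi=row["hi"], converged=True)
        )
    obs_yf = ((masked.frame["age"] == 0) & (masked.frame["sex"] == 0)).fillna(False)
    if int(obs_yf.sum()) >= 8:
        for row in _ols_intervals(masked, mask=obs_yf.to_numpy(dtype=bool)):
            rows.append(
                dict(source="lm2", parameter=row["parameter"], est=row["est"], lo=row["lo"], hi=row["hi"], converged=True)
            )
    else:
        logger.warning("LM2 skipped: only %d observed young females", int(obs_yf.sum()))
    return pd.DataFrame(rows)


def coverage_and_bias(per_replicate: pd.DataFrame, truth: dict[str, float]) -> pd.DataFrame:
    """Per-parameter coverage, bias (with MC standard error) and mean width.

    ``per_replicate`` holds one row per (replicate, parameter) with columns
    ``parameter``, ``est``, ``lo``, ``hi``; ``truth`` maps parameter names to
    generating values.  Parameters present in the frame but absent from
    ``truth`` raise.
    """
    names = list(dict.fromkeys(per_replicate["parameter"]))
    missing = [n for n in names if n not in truth]
    if missing:
        raise KeyError(f"no generating truth for parameters {missing}")
    rows = []
    for name in names:
        sub = per_replicate.loc[per_replicate["parameter"] == name]
        tv = truth[name]
        hits = (sub["lo"] <= tv) & (tv <= sub["hi"])
        err = sub["est"] - tv
        n = len(sub)
        rows.append(
            dict(
                parameter=name,
                truth=tv,
                n=n,
                coverage=float(hits.mean()),
                n_hits=int(hits.sum()),
                bias=float(err.mean()),
                mc_se_bias=float(err.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                mean_width=float((sub["hi"] - sub["lo"]).mean()),
            )
        )
    return pd.DataFrame(rows).set_index("parameter")


def run_study(
    scenario: ScenarioSpec,
    n_reps: int,
    mcmc_config: MCMCConfig | None = None,
    master_seed: int = 0,
    priors: PriorSpec | None = None,
) -> StudyResult:
    """Run the full replicated study for one scenario.

    Replicates whose sampler fails the Gelman-Rubin convergence check are
    recorded and excluded from the Bayesian coverage/bias aggregation (their
    intervals remain in ``per_replicate``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mcmc_config = mcmc_config or MCMCConfig()
    frames = []
    for rep in range(n_reps):
        result = run_replicate(scenario, replicate_seed(master_seed, rep), mcmc_config, priors)
        result.insert(0, "rep", rep)
        frames.append(result)
        logger.info("replicate %d/%d done", rep + 1, n_reps)
    per_replicate = pd.concat(frames, ignore_index=True)

    truth = scenario.truth.slopes()
    bayes = per_replicate[(per_replicate["source"] == "bayes") & per_replicate["converged"]]
    n_nonconverged = per_replicate.loc[per_replicate["source"] == "bayes", "rep"].nunique() - bayes["rep"].nunique()
    if n_nonconverged:
        logger.warning("%d replicate(s) excluded from coverage for non-convergence", n_nonconverged)
    coverage = coverage_and_bias(bayes, truth)

    base_rows = []
    for source in ("lm1", "lm2"):
        sub = per_replicate[per_replicate["source"] == source]
        if sub.empty:
            continue
        agg = coverage_and_bias(sub, truth)
        for name, row in agg.iterrows():
            s2 = sub[sub["parameter"] == name]
            base_rows.append(
                dict(
                    model=source,
                    parameter=name,
                    coverage=row["coverage"],
                    n_hits=row["n_hits"],
                    n=row["n"],
                    bias=row["bias"],
                    mc_se_bias=row["mc_se_bias"],
                    mean_width=row["mean_width"],
                    frac_reject_positive=float((s2["lo"] > 0).mean()),
                    frac_reject_negative=float((s2["hi"] < 0).mean()),
                )
            )
    baselines = pd.DataFrame(base_rows).set_index(["model", "parameter"]) if base_rows else pd.DataFrame()

    return StudyResult(
        scenario=scenario.name,
        n_reps=n_reps,
        master_seed=master_seed,
        coverage_bias=coverage,
        baselines=baselines,
        per_replicate=per_replicate,
        n_nonconverged=int(n_nonconverged),
        mcmc_config=dict(
            n_chains=mcmc_config.n_chains,
            n_iter=mcmc_config.n_iter,
            n_burn=mcmc_config.n_burn,
            thin=mcmc_config.thin,
        ),
    )


def reduced_mcmc_config(seed: int | None = None) -> MCMCConfig:
    """The documented desk-scale schedule: 2 chains x 3000, burn 1000, thin 2."""
    return MCMCConfig(n_chains=2, n_iter=3000, n_burn=1000, thin=2, seed=seed)
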