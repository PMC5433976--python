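"""Plumage-type effects on migration timing and body condition of young males.

Because many young males cannot be sexed in the field, "the young males" is
itself an uncertain subset of the captures.  The analysis therefore repeats,
for each saved posterior draw of the label-imputation model:

1. select the records whose (observed or imputed) labels say young male,
   tagging each as paradoxus (recorded paradoxus plumage) or cairei
   (any other/no plumage record — all female-like birds are female-colored);
2. fit a linear model of capture day on year and plumage type (timing), and
   linear mixed models of body weight / primary length on day, year and
   plumage type with a random year intercept (condition);
3. draw one coefficient vector from the estimated sampling distribution of
   each fit (the per-draw "sim" step).

Pooling the per-draw coefficient draws propagates both label uncertainty and
estimation uncertainty into one posterior sample per effect, summarized by
mean, 2.5%/97.5% quantiles and the probability that the effect lies in the
predicted direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from redstart.bayes_model import PosteriorDraws
from redstart.capture_data import CaptureTable, corrected_day

logger = logging.getLogger(__name__)


class InestimableDraw(ValueError):
    """Raised when a per-draw model cannot be fitted (e.g. one plumage level only)."""


def _sim_coefs(est: np.ndarray, cov: np.ndarray, rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Simulated coefficient vectors from the fit's sampling distribution, (size, k)."""
    cov = 0.5 * (cov + cov.T)  # numerical asymmetry from some optimizers
    return rng.multivariate_normal(est, cov, size=size, method="svd", check_valid="ignore")


@dataclass
class EffectSummary:
    """Pooled posterior summary of one scalar effect (paradoxus - cairei)."""

    mean: float
    q2_5: float
    q97_5: float
    support: float  # P(effect in the predicted direction)
    direction: int  # +1 or -1, the predicted sign
    n_draws_used: int
    n_draws_skipped: int

    def contains(self, value: float) -> bool:
        return bool(self.q2_5 <= value <= self.q97_5)


@dataclass
class TrendSummary:
    """Pooled yearly paradoxus-proportion trend among young males."""

    slope_mean: float
    slope_q2_5: float
    slope_q97_5: float
    support_increase: float
    first_year: int
    last_year: int
    first_frac_mean: float
    first_frac_q2_5: float
    first_frac_q97_5: float
    last_frac_mean: float
    last_frac_q2_5: float
    last_frac_q97_5: float
    n_draws_used: int
    n_draws_skipped: int


@dataclass
class PlumageEffects:
    """Pooled paradoxus-cairei contrasts for timing, weight and primary length."""

    timing: EffectSummary
    weight: EffectSummary
    primary: EffectSummary
    trend: TrendSummary | None
    paradoxus_fraction: np.ndarray  # per used draw, among selected young males

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {k: asdict(getattr(self, k)) for k in ("timing", "weight", "primary")}
        if self.trend is not None:
            from dataclasses import asdict as _a

            d["trend"] = _a(self.trend)
        d["paradoxus_fraction_mean"] = float(self.paradoxus_fraction.mean())
        d["paradoxus_fraction_range"] = [
            float(self.paradoxus_fraction.min()),
            float(self.paradoxus_fraction.max()),
        ]
        return d


def select_young_males(
    table: CaptureTable, draws: PosteriorDraws, draw_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Young-male subset under one posterior draw of the labels.

    Returns the selected record positions and, aligned with them, a boolean
    paradoxus indicator (cairei = recorded plumage other than paradoxus,
    including missing).  Records with an observed adult or female label are
    never selected: imputation only fills genuinely missing labels.
    """
    g = draws.class_g[draw_index]
    sel = np.flatnonzero(g == 2)  # class 2 = young male
    para = table.paradoxus()[sel]
    return sel, para


def _design(sub: pd.DataFrame, columns: list[str]) -> np.ndarray:
    return np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in columns])


def fit_timing_model(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """OLS of capture day on year and plumage type for one draw's young males.

    ``sub`` needs columns ``day`` (response), ``year_c`` and ``para`` (0/1).
    Returns the coefficient vector (intercept, year, plumage) and its
    estimated covariance.
    """
    para = sub["para"].to_numpy(dtype=float)
    if para.min() == para.max():
        raise InestimableDraw("only one plumage level in this draw's young males")
    X = _design(sub, ["year_c", "para"])
    fit = sm.OLS(sub["day"].to_numpy(dtype=float), X).fit()
    return np.asarray(fit.params), np.asarray(fit.cov_params())


def fit_condition_model(sub: pd.DataFrame, outcome: str) -> tuple[np.ndarray, np.ndarray]:
    """Random-year-intercept mixed model of a condition outcome on day, year, plumage.

    ``outcome`` is ``"weight"`` or ``"primary"``; fitted by REML.  If the
    variance-component optimization fails, falls back to the fixed-effects
    OLS with a logged warning.  Returns fixed-effect estimates (intercept,
    day, year, plumage) and their covariance.
    """
    col = {"weight": "weight_g", "primary": "primary_mm"}[outcome]
    para = sub["para"].to_numpy(dtype=float)
    if para.min() == para.max():
        raise InestimableDraw("only one plumage level in this draw's young males")
    y = sub[col].to_numpy(dtype=float)
    X = _design(sub, ["day_c", "year_c", "para"])
    groups = sub["year"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise InestimableDraw("mixed model needs at least two years")
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True, method="lbfgs")
        if any("singular" in str(w.message).lower() for w in caught):
            # year variance estimated at the zero boundary: the model reduces
            # to (and is correctly fitted by) the fixed-effects OLS
            raise ValueError("random-effects covariance at the singular boundary")
        k = X.shape[1]
        params = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:k, :k]
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(cov)):
            raise ValueError("non-finite mixed-model estimates")
        return params, cov
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.debug("mixed model degenerate (%s); using fixed-effects OLS", exc)
        fit = sm.OLS(y, X).fit()
        return np.asarray(fit.params), np.asarray(fit.cov_params())


def pool_over_draws(
    estimates: list[tuple[np.ndarray, np.ndarray]],
    seed,
    effect_index: int = -1,
    direction: int = 1,
    n_skipped: int = 0,
    n_sim_per_draw: int = 1,
) -> EffectSummary:
    """Pool per-draw (coefficients, covariance) fits into one posterior sample.

    For each draw, coefficient vectors are simulated from a multivariate
    normal at the fit with the fit's covariance, and the scalar effect
    (``effect_index``) collected; pooled mean, 2.5%/97.5% quantiles and the
    fraction of pooled samples with sign ``direction`` are reported.  With
    the full posterior one simulation per draw suffices; when pooling over a
    reduced set of draws, ``n_sim_per_draw`` > 1 keeps the pooled sample
    large enough for stable tail quantiles.
    """
    if not estimates:
        raise ValueError("no estimable draws to pool")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    samples = np.empty((len(estimates), n_sim_per_draw))
    for i, (est, cov) in enumerate(estimates):
        sim = _sim_coefs(est, cov, rng, n_sim_per_draw)
        samples[i] = sim[:, effect_index]
    samples = samples.ravel()
    return EffectSummary(
        mean=float(samples.mean()),
        q2_5=float(np.percentile(samples, 2.5)),
        q97_5=float(np.percentile(samples, 97.5)),
        support=float((direction * samples > 0).mean()),
        direction=direction,
        n_draws_used=len(estimates),
        n_draws_skipped=n_skipped,
    )


def _draw_indices(draws: PosteriorDraws, n_draws: int | None) -> np.ndarray:
    if n_draws is None or n_draws >= draws.n_draws:
        return np.arange(draws.n_draws)
    return np.unique(np.linspace(0, draws.n_draws - 1, n_draws).round().astype(int))


def paradoxus_trend(
    table: CaptureTable,
    draws: PosteriorDraws,
    seed,
    n_draws: int | None = None,
    n_sim_per_draw: int = 1,
) -> TrendSummary:
    """Yearly trend in the paradoxus proportion among young males.

    Per draw, a logistic regression of the paradoxus indicator on (centered)
    year over the selected young males; a simulated coefficient vector per
    draw propagates estimation uncertainty.  Reports the pooled year slope,
    the support for an increase, and pooled proportions at the first and
    last study year.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = _draw_indices(draws, n_draws)
    years = table.frame["year"].to_numpy()
    y_first = int(years.min())
    y_last = int(years.max())
    yc = table.centered_years()
    para_all = table.paradoxus().astype(float)
    slopes, first_frac, last_frac = [], [], []
    n_skipped = 0
    for i in idx:
        sel, _ = select_young_males(table, draws, i)
        para = para_all[sel]
        if para.min() == para.max():
            n_skipped += 1
            continue
        X = np.column_stack([np.ones(sel.size), yc[sel]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(para, X).fit(disp=0, maxiter=100)
            est, cov = np.asarray(fit.params), np.asarray(fit.cov_params())
            if not np.all(np.isfinite(cov)):
                raise ValueError("non-finite logistic covariance")
        except (np.linalg.LinAlgError, ValueError, sm.tools.sm_exceptions.PerfectSeparationError):
            n_skipped += 1
            continue
        sim = _sim_coefs(est, cov, rng, n_sim_per_draw)
        slopes.append(sim[:, 1])
        first_frac.append(expit(sim[:, 0] + sim[:, 1] * (y_first - table.reference_year)))
        last_frac.append(expit(sim[:, 0] + sim[:, 1] * (y_last - table.reference_year)))
    if not slopes:
        raise ValueError("paradoxus trend inestimable in every draw")
    slopes = np.concatenate(slopes)
    first_frac = np.concatenate(first_frac)
    last_frac = np.concatenate(last_frac)
    return TrendSummary(
        slope_mean=float(slopes.mean()),
        slope_q2_5=float(np.percentile(slopes, 2.5)),
        slope_q97_5=float(np.percentile(slopes, 97.5)),
        support_increase=float((slopes > 0).mean()),
        first_year=y_first,
        last_year=y_last,
        first_frac_mean=float(first_frac.mean()),
        first_frac_q2_5=float(np.percentile(first_frac, 2.5)),
        first_frac_q97_5=float(np.percentile(first_frac, 97.5)),
        last_frac_mean=float(last_frac.mean()),
        last_frac_q2_5=float(np.percentile(last_frac, 2.5)),
        last_frac_q97_5=float(np.percentile(last_frac, 97.5)),
        n_draws_used=int(len(slopes)) // n_sim_per_draw,
        n_draws_skipped=n_skipped,
    )


def analyze_plumage_effects(
    table: CaptureTable,
    draws: PosteriorDraws,
    seed,
    n_draws: int | None = None,
    use_corrected_day: bool = False,
    shift_per_year: float = 0.2,
    include_trend: bool = True,
) -> PlumageEffects:
    """Full per-draw selection / fit / sim / pool procedure.

    ``n_draws`` subsamples the saved posterior draws at evenly spaced indices
    (None = all).  When fewer than ~2000 draws are pooled, several
    coefficient vectors are simulated per fitted draw so the pooled 95%
    quantiles stay well resolved.  ``use_corrected_day`` switches the timing
    response to phenology-corrected days (default raw days; both give
    quantitatively similar answers on well-behaved data).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    idx = _draw_indices(draws, n_draws)
    n_sim = max(1, int(np.ceil(2000 / idx.size)))
    frame = table.frame
    day = frame["day"].to_numpy(dtype=float)
    if use_corrected_day:
        day = corrected_day(day, frame["year"].to_numpy(), table.reference_year, shift_per_year)
    base = pd.DataFrame(
        {
            "day": day,
            "day_c": table.centered_days(),
            "year_c": table.centered_years(),
            "year": frame["year"].to_numpy(),
            "weight_g": frame["weight_g"].to_numpy(dtype=float),
            "primary_mm": frame["primary_mm"].to_numpy(dtype=float),
        }
    )
    para_all = table.paradoxus()

    fits: dict[str, list] = {"timing": [], "weight": [], "primary": []}
    skipped = {"timing": 0, "weight": 0, "primary": 0}
    fractions = []
    for i in idx:
        sel, para = select_young_males(table, draws, i)
        sub = base.iloc[sel].copy()
        sub["para"] = para_all[sel].astype(float)
        fractions.append(float(sub["para"].mean()))
        try:
            fits["timing"].append(fit_timing_model(sub))
        except InestimableDraw:
            skipped["timing"] += 1
        for outcome in ("weight", "primary"):
            try:
                fits[outcome].append(fit_condition_model(sub, outcome))
            except InestimableDraw:
                skipped[outcome] += 1

    summaries = {}
    for key in ("timing", "weight", "primary"):
        summaries[key] = pool_over_draws(
            fits[key], rng, effect_index=-1, direction=1, n_skipped=skipped[key],
            n_sim_per_draw=n_sim,
        )
    trend = (
        paradoxus_trend(table, draws, rng, n_draws=n_draws, n_sim_per_draw=n_sim)
        if include_trend
        else None
    )
    return PlumageEffects(
        timing=summaries["timing"],
        weight=summaries["weight"],
        primary=summaries["primary"],
        trend=trend,
        paradoxus_fraction=np.asarray(fractions),
    )
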