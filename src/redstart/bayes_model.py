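"""Joint model for morphometrics and sex/age labels, and its MCMC sampler.

Model
-----
For capture i with age-sex class g(i) (young female, young male, adult female,
adult male), centered day ``d_i`` and centered year ``t_i``:

.. code-block:: text

    (Weight_i, Primary_i) ~ MVN( (w0_g + w1 d_i + w2 t_i,
                                  p0_g + p1 d_i + p2 t_i),  Sigma_g )
    Sex_i ~ Bernoulli( invlogit(s0 + s1 d_i + s2 t_i) )     (1 = male)
    Age_i ~ Bernoulli( invlogit(a0 + a1 d_i + a2 t_i) )     (1 = adult)

Records with unidentified sex and/or age have their labels treated as unknown
discrete quantities: every MCMC sweep draws each missing label from its full
conditional (morphometric likelihood of the candidate class times the two
Bernoulli label probabilities), then updates the parameters given the
completed labels.  Parameter updates are conjugate where possible (normal
linear-model draw for the mean structure, inverse-Wishart draws for the four
class covariance matrices) and adaptive random-walk Metropolis for the two
logistic blocks.

Recorded paradoxus plumage (an adult-male-like plumage only first-year males
carry) constrains a record's admissible classes to young male.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from redstart.capture_data import (
    CLASS_AGE,
    CLASS_SEX,
    PLUMAGE_PARADOXUS,
    CaptureTable,
)

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))

#: order of the mean-structure coefficient vector
BETA_NAMES = [
    "w0[1]", "w0[2]", "w0[3]", "w0[4]", "w1", "w2",
    "p0[1]", "p0[2]", "p0[3]", "p0[4]", "p1", "p2",
]
SLOPE_NAMES = ["w1", "w2", "p1", "p2", "s1", "s2", "a1", "a2"]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """All model parameters.

    ``w0``/``p0`` are length-4 class intercepts (g = 1..4); ``sigma`` holds the
    four 2x2 weight-primary covariance matrices.  Slopes are per centered day
    (``w1``, ``p1``, ``s1``, ``a1``) and per centered year (``w2``, ``p2``,
    ``s2``, ``a2``).
    """

    w0: np.ndarray
    w1: float
    w2: float
    p0: np.ndarray
    p1: float
    p2: float
    sigma: np.ndarray  # (4, 2, 2)
    s0: float
    s1: float
    s2: float
    a0: float
    a1: float
    a2: float

    def __post_init__(self) -> None:
        self.w0 = np.asarray(self.w0, dtype=float).reshape(4)
        self.p0 = np.asarray(self.p0, dtype=float).reshape(4)
        self.sigma = np.asarray(self.sigma, dtype=float).reshape(4, 2, 2)
        for g in range(4):
            S = self.sigma[g]
            if not np.allclose(S, S.T):
                raise ValueError(f"covariance for class {g + 1} is not symmetric")
            if np.linalg.eigvalsh(S)[0] <= 0:
                raise ValueError(f"covariance for class {g + 1} is not positive definite")

    @property
    def sigma_weight(self) -> np.ndarray:
        return np.sqrt(self.sigma[:, 0, 0])

    @property
    def sigma_primary(self) -> np.ndarray:
        return np.sqrt(self.sigma[:, 1, 1])

    @property
    def rho(self) -> np.ndarray:
        return self.sigma[:, 0, 1] / (self.sigma_weight * self.sigma_primary)

    @classmethod
    def from_sd_rho(
        cls,
        w0,
        w1,
        w2,
        p0,
        p1,
        p2,
        sigma_weight,
        sigma_primary,
        rho,
        s0,
        s1,
        s2,
        a0,
        a1,
        a2,
    ) -> "ModelParams":
        """Build from per-class standard deviations and correlations."""
        sw = np.broadcast_to(np.asarray(sigma_weight, dtype=float), (4,)).copy()
        sp = np.broadcast_to(np.asarray(sigma_primary, dtype=float), (4,)).copy()
        r = np.broadcast_to(np.asarray(rho, dtype=float), (4,)).copy()
        sigma = np.empty((4, 2, 2))
        sigma[:, 0, 0] = sw**2
        sigma[:, 1, 1] = sp**2
        sigma[:, 0, 1] = sigma[:, 1, 0] = r * sw * sp
        return cls(w0=w0, w1=w1, w2=w2, p0=p0, p1=p1, p2=p2, sigma=sigma,
                   s0=s0, s1=s1, s2=s2, a0=a0, a1=a1, a2=a2)

    def slopes(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in SLOPE_NAMES}

    def to_dict(self) -> dict:
        return {
            "w0": self.w0.tolist(),
            "w1": self.w1,
            "w2": self.w2,
            "p0": self.p0.tolist(),
            "p1": self.p1,
            "p2": self.p2,
            "sigma": self.sigma.tolist(),
            "s0": self.s0,
            "s1": self.s1,
            "s2": self.s2,
            "a0": self.a0,
            "a1": self.a1,
            "a2": self.a2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**{k: (np.asarray(v) if k in ("w0", "p0", "sigma") else v) for k, v in d.items()})


@dataclass
class PriorSpec:
    """Weakly informative priors.

    Class weight intercepts N(16, 5^2) g, class primary intercepts N(65, 5^2)
    mm, all day/year slopes N(0, 1), logistic intercepts N(0, 2^2), and an
    inverse-Wishart(scale = 1e-4 I, df = 3) on each class covariance matrix.
    """

    w0_mean: float = 16.0
    w0_sd: float = 5.0
    p0_mean: float = 65.0
    p0_sd: float = 5.0
    slope_sd: float = 1.0
    logit_intercept_sd: float = 2.0
    iw_scale: np.ndarray = field(default_factory=lambda: np.diag([1e-4, 1e-4]))
    iw_df: float = 3.0
    # shared-correlation variant: sigma_wg, sigma_pg ~ half-normal(sd), rho ~ U(-1, 1)
    sigma_halfnormal_sd: float = 5.0

    def __post_init__(self) -> None:
        self.iw_scale = np.asarray(self.iw_scale, dtype=float).reshape(2, 2)
        if self.iw_df < 3:
            raise ValueError("inverse-Wishart df must be >= dimension + 1 = 3")
        for sd in (self.w0_sd, self.p0_sd, self.slope_sd, self.logit_intercept_sd):
            if sd <= 0:
                raise ValueError("prior sds must be positive")

    def beta_mean_prec(self) -> tuple[np.ndarray, np.ndarray]:
        mean = np.array([self.w0_mean] * 4 + [0.0, 0.0] + [self.p0_mean] * 4 + [0.0, 0.0])
        prec = np.array(
            [1.0 / self.w0_sd**2] * 4
            + [1.0 / self.slope_sd**2] * 2
            + [1.0 / self.p0_sd**2] * 4
            + [1.0 / self.slope_sd**2] * 2
        )
        return mean, prec

    def logit_sds(self) -> np.ndarray:
        return np.array([self.logit_intercept_sd, self.slope_sd, self.slope_sd])


@dataclass
class MCMCConfig:
    """Sampler schedule and tuning.

    Defaults follow the production schedule (two chains of 6000 iterations,
    2000 burn-in, thinning by 2, i.e. 4000 saved draws).  ``shared_rho``
    switches the covariance parameterization from four free inverse-Wishart
    matrices to class sds with one correlation shared across classes.
    """

    n_chains: int = 2
    n_iter: int = 6000
    n_burn: int = 2000
    thin: int = 2
    seed: int | None = None
    target_accept: float = 0.35
    adapt_rate: float = 1.0
    init_jitter: float = 2.0  # chains start +/- this many complete-case SEs apart
    shared_rho: bool = False
    rhat_threshold: float = 1.1
    outlier_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n_iter <= self.n_burn:
            raise ValueError("n_iter must exceed n_burn")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_saved_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


@dataclass
class PosteriorDraws:
    """Saved post-burn-in draws from all chains.

    ``class_g`` stores, per saved draw, the completed age-sex class (1..4) of
    every record — constant for records with fully observed labels, imputed
    for the rest.
    """

    w0: np.ndarray  # (D, 4)
    w1: np.ndarray  # (D,)
    w2: np.ndarray
    p0: np.ndarray  # (D, 4)
    p1: np.ndarray
    p2: np.ndarray
    sigma: np.ndarray  # (D, 4, 2, 2)
    s: np.ndarray  # (D, 3)
    a: np.ndarray  # (D, 3)
    class_g: np.ndarray  # (D, N) int8, values 1..4
    chain: np.ndarray  # (D,)
    iteration: np.ndarray  # (D,)
    missing_any: np.ndarray  # (N,) bool: record had a missing label
    acceptance: dict = field(default_factory=dict)
    rhat: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def n_draws(self) -> int:
        return int(self.w1.shape[0])

    @property
    def n_records(self) -> int:
        return int(self.class_g.shape[1])

    def params_at(self, i: int) -> ModelParams:
        return ModelParams(
            w0=self.w0[i], w1=float(self.w1[i]), w2=float(self.w2[i]),
            p0=self.p0[i], p1=float(self.p1[i]), p2=float(self.p2[i]),
            sigma=self.sigma[i],
            s0=float(self.s[i, 0]), s1=float(self.s[i, 1]), s2=float(self.s[i, 2]),
            a0=float(self.a[i, 0]), a1=float(self.a[i, 1]), a2=float(self.a[i, 2]),
        )

    def scalar_frame(self) -> pd.DataFrame:
        """Named scalar parameters, one row per saved draw (chain column included)."""
        sw = np.sqrt(self.sigma[:, :, 0, 0])
        sp = np.sqrt(self.sigma[:, :, 1, 1])
        rho = self.sigma[:, :, 0, 1] / (sw * sp)
        cols: dict[str, np.ndarray] = {"chain": self.chain, "iteration": self.iteration}
        for g in range(4):
            cols[f"w0[{g + 1}]"] = self.w0[:, g]
            cols[f"p0[{g + 1}]"] = self.p0[:, g]
        cols.update({"w1": self.w1, "w2": self.w2, "p1": self.p1, "p2": self.p2})
        for j, name in enumerate(("s0", "s1", "s2")):
            cols[name] = self.s[:, j]
        for j, name in enumerate(("a0", "a1", "a2")):
            cols[name] = self.a[:, j]
        for g in range(4):
            cols[f"sigma_w[{g + 1}]"] = sw[:, g]
            cols[f"sigma_p[{g + 1}]"] = sp[:, g]
            cols[f"rho[{g + 1}]"] = rho[:, g]
        cols["rho"] = rho.mean(axis=1)
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------


def _mvn2_logpdf(dw: np.ndarray, dp: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Log-density of centered (weight, primary) residuals under a 2x2 covariance."""
    s11, s12, s22 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    det = s11 * s22 - s12 * s12
    if det <= 0:
        raise ValueError("covariance matrix is not positive definite")
    q11, q22, q12 = s22 / det, s11 / det, -s12 / det
    quad = q11 * dw * dw + 2.0 * q12 * dw * dp + q22 * dp * dp
    return -LOG2PI - 0.5 * np.log(det) - 0.5 * quad


def _bernoulli_logpmf(x: np.ndarray, logit_p: np.ndarray) -> np.ndarray:
    # log p = -softplus(-lp), log (1-p) = -softplus(lp)
    return -np.logaddexp(0.0, np.where(x == 1, -logit_p, logit_p))


def record_log_density(
    params: ModelParams,
    *,
    age,
    sex,
    weight,
    primary,
    day_c,
    year_c,
) -> np.ndarray | float:
    """Log joint density of one completed record given the parameters.

    Bivariate-normal log-density of (weight, primary) at the class mean plus
    the Bernoulli log-masses of the sex and age labels.  Accepts scalars or
    broadcastable arrays; ``age`` and ``sex`` must be observed (0/1).
    """
    age = np.asarray(age)
    sex = np.asarray(sex)
    if np.any((age != 0) & (age != 1)) or np.any((sex != 0) & (sex != 1)):
        raise ValueError("record_log_density requires observed binary labels")
    weight = np.asarray(weight, dtype=float)
    primary = np.asarray(primary, dtype=float)
    day_c = np.asarray(day_c, dtype=float)
    year_c = np.asarray(year_c, dtype=float)
    g = sex + 2 * age  # 0-based class index

    scalar = all(np.ndim(x) == 0 for x in (age, sex, weight, primary, day_c, year_c))
    age, sex, weight, primary, day_c, year_c, g = np.broadcast_arrays(
        age, sex, weight, primary, day_c, year_c, g
    )
    out = np.empty(g.shape, dtype=float)
    lp_s = params.s0 + params.s1 * day_c + params.s2 * year_c
    lp_a = params.a0 + params.a1 * day_c + params.a2 * year_c
    for j in range(4):
        m = g == j
        if not m.any():
            continue
        dw = weight[m] - (params.w0[j] + params.w1 * day_c[m] + params.w2 * year_c[m])
        dp = primary[m] - (params.p0[j] + params.p1 * day_c[m] + params.p2 * year_c[m])
        out[m] = _mvn2_logpdf(dw, dp, params.sigma[j])
    out = out + _bernoulli_logpmf(sex, lp_s) + _bernoulli_logpmf(age, lp_a)
    return float(out) if scalar else out


def admissible_classes(
    age: int | None, sex: int | None, plumage: str | None = None
) -> np.ndarray:
    """Boolean mask over classes g = 1..4 compatible with the observed labels.

    Paradoxus plumage forces young male (class 2); observed age/sex constrain
    the corresponding margin.
    """
    mask = np.ones(4, dtype=bool)
    if age is not None:
        mask &= CLASS_AGE == int(age)
    if sex is not None:
        mask &= CLASS_SEX == int(sex)
    if plumage == PLUMAGE_PARADOXUS:
        mask &= (CLASS_AGE == 0) & (CLASS_SEX == 1)
    if not mask.any():
        raise ValueError("contradictory label constraints: empty admissible set")
    return mask


def label_posterior(
    params: ModelParams,
    *,
    weight: float,
    primary: float,
    day_c: float,
    year_c: float,
    age: int | None = None,
    sex: int | None = None,
    plumage: str | None = None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Posterior over admissible (age, sex) completions of one record.

    Probabilities are proportional to P(sex | day, year) * P(age | day, year)
    * MVN(weight, primary | class) and normalized over the admissible set.
    Returns the list of (age, sex) completions and their probabilities.
    """
    if age is not None and sex is not None and plumage != PLUMAGE_PARADOXUS:
        raise ValueError("label_posterior requires at least one missing label")
    mask = admissible_classes(age, sex, plumage)
    classes = np.flatnonzero(mask)
    logw = np.array(
        [
            record_log_density(
                params,
                age=int(CLASS_AGE[j]),
                sex=int(CLASS_SEX[j]),
                weight=weight,
                primary=primary,
                day_c=day_c,
                year_c=year_c,
            )
            for j in classes
        ]
    )
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    completions = [(int(CLASS_AGE[j]), int(CLASS_SEX[j])) for j in classes]
    return completions, probs


# ---------------------------------------------------------------------------
# small samplers
# ---------------------------------------------------------------------------


def _chol2(m: np.ndarray) -> np.ndarray:
    l11 = np.sqrt(m[0, 0])
    l21 = m[1, 0] / l11
    l22 = np.sqrt(m[1, 1] - l21 * l21)
    return np.array([[l11, 0.0], [l21, l22]])


def _inv2(m: np.ndarray) -> np.ndarray:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def inv_wishart_rv(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One draw from the 2x2 inverse-Wishart(df, scale) via the Bartlett decomposition."""
    if df <= 1:
        raise ValueError("inverse-Wishart df must exceed dimension - 1")
    L = _chol2(_inv2(scale))  # chol of the Wishart scale matrix
    A = np.zeros((2, 2))
    A[0, 0] = np.sqrt(rng.chisquare(df))
    A[1, 1] = np.sqrt(rng.chisquare(df - 1.0))
    A[1, 0] = rng.standard_normal()
    LA = L @ A
    W = LA @ LA.T  # ~ Wishart(df, inv(scale))
    return _inv2(W)


# ---------------------------------------------------------------------------
# MCMC machinery
# ---------------------------------------------------------------------------


class _Data:
    """Preprocessed arrays for one table."""

    def __init__(self, table: CaptureTable, config: MCMCConfig):
        frame = table.frame
        self.n = len(frame)
        self.y = np.column_stack(
            [frame["weight_g"].to_numpy(dtype=float), frame["primary_mm"].to_numpy(dtype=float)]
        )
        day_c = table.centered_days()
        year_c = table.centered_years()
        self.U = np.column_stack([np.ones(self.n), day_c, year_c])
        self.day_c = day_c
        self.year_c = year_c
        obs_age = table.observed_age()
        obs_sex = table.observed_sex()
        para = table.paradoxus()
        adm = np.ones((self.n, 4), dtype=bool)
        adm &= (obs_age[:, None] < 0) | (CLASS_AGE[None, :] == obs_age[:, None])
        adm &= (obs_sex[:, None] < 0) | (CLASS_SEX[None, :] == obs_sex[:, None])
        adm[para] &= (CLASS_AGE[None, :] == 0) & (CLASS_SEX[None, :] == 1)
        if (~adm.any(axis=1)).any():
            bad = np.flatnonzero(~adm.any(axis=1))[:5]
            raise ValueError(f"records with contradictory label constraints, e.g. rows {bad.tolist()}")
        self.admissible = adm
        self.free = np.flatnonzero(adm.sum(axis=1) > 1)
        self.missing_any = adm.sum(axis=1) > 1
        self.obs_age = obs_age
        self.obs_sex = obs_sex
        # flag (but keep) gross morphometric outliers
        spread = np.where(self.y.std(axis=0) > 0, self.y.std(axis=0), 1.0)
        z = np.abs((self.y - self.y.mean(axis=0)) / spread)
        n_out = int((z > config.outlier_sd).any(axis=1).sum())
        if n_out:
            logger.warning("%d records are >%g pooled SD from the morphometric mean (kept)", n_out, config.outlier_sd)


def _ridge_logistic(U: np.ndarray, y: np.ndarray, prior_sd: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MAP logistic fit with normal priors; returns (coef, approximate SEs)."""
    k = U.shape[1]
    beta = np.zeros(k)
    prec = np.diag(1.0 / prior_sd**2)
    for _ in range(25):
        lp = U @ beta
        p = expit(lp)
        Wd = p * (1.0 - p) + 1e-10
        H = U.T @ (U * Wd[:, None]) + prec
        grad = U.T @ (y - p) - prec @ beta
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    H = U.T @ (U * (expit(U @ beta) * (1 - expit(U @ beta)))[:, None]) + prec
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


@dataclass
class _ChainState:
    beta: np.ndarray  # (12,)
    sigma: np.ndarray  # (4, 2, 2)
    s: np.ndarray  # (3,)
    a: np.ndarray  # (3,)
    g: np.ndarray  # (N,) 0-based class codes
    log_scale_s: np.ndarray
    log_scale_a: np.ndarray
    theta_scale: np.ndarray | None = None  # shared-rho variant proposal scales
    theta: np.ndarray | None = None  # shared-rho variant parameter vector


def _initialize(data: _Data, priors: PriorSpec, config: MCMCConfig, rng: np.random.Generator) -> _ChainState:
    both = (data.obs_age >= 0) & (data.obs_sex >= 0)
    g_obs = data.obs_sex + 2 * data.obs_age
    beta = np.zeros(12)
    pooled = np.zeros((2, 2))
    n_pooled = 0
    for j in range(4):
        m = both & (g_obs == j)
        if m.sum() >= 2:
            beta[j] = data.y[m, 0].mean()
            beta[6 + j] = data.y[m, 1].mean()
            e = data.y[m] - data.y[m].mean(axis=0)
            pooled += e.T @ e
            n_pooled += m.sum() - 1
        else:
            beta[j] = priors.w0_mean
            beta[6 + j] = priors.p0_mean
    if n_pooled >= 4:
        sigma0 = pooled / n_pooled
        if np.linalg.det(sigma0) <= 1e-8:
            sigma0 = np.diag([1.0, 2.0])
    else:
        sigma0 = np.diag([1.0, 2.0])
    sigma = np.repeat(sigma0[None], 4, axis=0).copy()

    logit_sds = priors.logit_sds()
    m_sex = data.obs_sex >= 0
    m_age = data.obs_age >= 0
    if m_sex.sum() >= 10:
        s_hat, s_se = _ridge_logistic(data.U[m_sex], data.obs_sex[m_sex].astype(float), logit_sds)
    else:
        s_hat, s_se = np.zeros(3), logit_sds * 0.25
    if m_age.sum() >= 10:
        a_hat, a_se = _ridge_logistic(data.U[m_age], data.obs_age[m_age].astype(float), logit_sds)
    else:
        a_hat, a_se = np.zeros(3), logit_sds * 0.25
    # overdisperse chain starting points relative to the complete-case fit
    s = s_hat + config.init_jitter * s_se * rng.standard_normal(3)
    a = a_hat + config.init_jitter * a_se * rng.standard_normal(3)

    # missing labels: admissible class nearest in Mahalanobis distance
    g = np.where(both, g_obs, -1)
    need = np.flatnonzero(g < 0)
    if need.size:
        Q = _inv2(sigma0)
        mu_w = beta[:4][None, :] + 0.0
        mu_p = beta[6:10][None, :] + 0.0
        dw = data.y[need, 0][:, None] - mu_w
        dp = data.y[need, 1][:, None] - mu_p
        dist = Q[0, 0] * dw**2 + 2 * Q[0, 1] * dw * dp + Q[1, 1] * dp**2
        dist[~data.admissible[need]] = np.inf
        g[need] = dist.argmin(axis=1)
    counts = np.bincount(g, minlength=4)
    if (counts == 0).any():
        empty = np.flatnonzero(counts == 0) + 1
        raise RuntimeError(f"age-sex class(es) {empty.tolist()} have no attributable records at initialization")

    return _ChainState(
        beta=beta,
        sigma=sigma,
        s=s,
        a=a,
        g=g,
        log_scale_s=np.log(np.maximum(2.4 * s_se, 1e-4)),
        log_scale_a=np.log(np.maximum(2.4 * a_se, 1e-4)),
        theta_scale=np.full(9, 0.05),
    )


def _class_log_weights_subset(
    idx: np.ndarray, data: _Data, beta: np.ndarray, sigma: np.ndarray, s: np.ndarray, a: np.ndarray
) -> np.ndarray:
    """(len(idx), 4) unnormalized log posterior weights of each class."""
    d = data.day_c[idx]
    t = data.year_c[idx]
    w = data.y[idx, 0]
    p = data.y[idx, 1]
    mu_w = beta[:4][None, :] + (beta[4] * d + beta[5] * t)[:, None]
    mu_p = beta[6:10][None, :] + (beta[10] * d + beta[11] * t)[:, None]
    dw = w[:, None] - mu_w
    dp = p[:, None] - mu_p
    s11 = sigma[:, 0, 0]
    s12 = sigma[:, 0, 1]
    s22 = sigma[:, 1, 1]
    det = s11 * s22 - s12 * s12
    q11, q22, q12 = s22 / det, s11 / det, -s12 / det
    logw = (
        -0.5 * np.log(det)[None, :]
        - 0.5 * (q11[None, :] * dw**2 + 2 * q12[None, :] * dw * dp + q22[None, :] * dp**2)
    )
    lp_s = s[0] + s[1] * d + s[2] * t
    lp_a = a[0] + a[1] * d + a[2] * t
    log_pm = -np.logaddexp(0.0, -lp_s)  # log P(male)
    log_pf = -np.logaddexp(0.0, lp_s)
    log_pa = -np.logaddexp(0.0, -lp_a)  # log P(adult)
    log_py = -np.logaddexp(0.0, lp_a)
    # class order g-1 = 0..3: (young,f), (young,m), (adult,f), (adult,m)
    logw[:, 0] += log_pf + log_py
    logw[:, 1] += log_pm + log_py
    logw[:, 2] += log_pf + log_pa
    logw[:, 3] += log_pm + log_pa
    return logw


def _sample_rows(logw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    logw = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    c = np.cumsum(w, axis=1)
    r = rng.random(w.shape[0]) * c[:, -1]
    return (c < r[:, None]).sum(axis=1)


def _class_suffstats(data: _Data, g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-class Gram matrices of (1, day, year) and cross products with (w, p)."""
    d, t = data.day_c, data.year_c
    w, p = data.y[:, 0], data.y[:, 1]
    bc = lambda wts: np.bincount(g, weights=wts, minlength=4)
    A = np.empty((4, 3, 3))
    A[:, 0, 0] = np.bincount(g, minlength=4)
    A[:, 0, 1] = A[:, 1, 0] = bc(d)
    A[:, 0, 2] = A[:, 2, 0] = bc(t)
    A[:, 1, 1] = bc(d * d)
    A[:, 1, 2] = A[:, 2, 1] = bc(d * t)
    A[:, 2, 2] = bc(t * t)
    bw = np.column_stack([bc(w), bc(d * w), bc(t * w)])
    bp = np.column_stack([bc(p), bc(d * p), bc(t * p)])
    return A, bw, bp


def _draw_beta(
    data: _Data, g: np.ndarray, sigma: np.ndarray, priors: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate draw of the 12 mean-structure coefficients given labels and covariances."""
    mean0, prec0 = priors.beta_mean_prec()
    P = np.diag(prec0)
    r = prec0 * mean0
    A, bw, bp = _class_suffstats(data, g)
    for j in range(4):
        det = sigma[j, 0, 0] * sigma[j, 1, 1] - sigma[j, 0, 1] ** 2
        q11 = sigma[j, 1, 1] / det
        q22 = sigma[j, 0, 0] / det
        q12 = -sigma[j, 0, 1] / det
        iw = (j, 4, 5)
        ip = (6 + j, 10, 11)
        for a_, ia in enumerate(iw):
            for b_, ib in enumerate(iw):
                P[ia, ib] += q11 * A[j, a_, b_]
            for b_, ib in enumerate(ip):
                P[ia, ib] += q12 * A[j, a_, b_]
        for a_, ia in enumerate(ip):
            for b_, ib in enumerate(ip):
                P[ia, ib] += q22 * A[j, a_, b_]
            for b_, ib in enumerate(iw):
                P[ia, ib] += q12 * A[j, a_, b_]
        for a_, (ia, ib) in enumerate(zip(iw, ip)):
            r[ia] += q11 * bw[j, a_] + q12 * bp[j, a_]
            r[ib] += q22 * bp[j, a_] + q12 * bw[j, a_]
    L = np.linalg.cholesky(P)
    mu = np.linalg.solve(L.T, np.linalg.solve(L, r))
    return mu + np.linalg.solve(L.T, rng.standard_normal(12))


def _residual_stats(data: _Data, g: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class residual scatter matrices (4, 2, 2) and counts (4,)."""
    mu_w = beta[g] + beta[4] * data.day_c + beta[5] * data.year_c
    mu_p = beta[6 + g] + beta[10] * data.day_c + beta[11] * data.year_c
    ew = data.y[:, 0] - mu_w
    ep = data.y[:, 1] - mu_p
    R = np.zeros((4, 2, 2))
    counts = np.bincount(g, minlength=4).astype(float)
    R[:, 0, 0] = np.bincount(g, weights=ew * ew, minlength=4)
    R[:, 1, 1] = np.bincount(g, weights=ep * ep, minlength=4)
    R[:, 0, 1] = R[:, 1, 0] = np.bincount(g, weights=ew * ep, minlength=4)
    return R, counts


def _draw_sigma_iw(
    R: np.ndarray, counts: np.ndarray, priors: PriorSpec, rng: np.random.Generator
) -> np.ndarray:
    sigma = np.empty((4, 2, 2))
    for j in range(4):
        sigma[j] = inv_wishart_rv(priors.iw_df + counts[j], priors.iw_scale + R[j], rng)
    return sigma


def _shared_rho_loglik(theta: np.ndarray, R: np.ndarray, counts: np.ndarray) -> float:
    """Total MVN log-likelihood from per-class residual stats.

    theta = (log sw_1..4, log sp_1..4, atanh rho)."""
    sw = np.exp(theta[:4])
    sp = np.exp(theta[4:8])
    rho = np.tanh(theta[8])
    det = (sw * sp) ** 2 * (1 - rho**2)
    ll = 0.0
    for j in range(4):
        q11 = 1.0 / (sw[j] ** 2 * (1 - rho**2))
        q22 = 1.0 / (sp[j] ** 2 * (1 - rho**2))
        q12 = -rho / (sw[j] * sp[j] * (1 - rho**2))
        tr = q11 * R[j, 0, 0] + q22 * R[j, 1, 1] + 2 * q12 * R[j, 0, 1]
        ll += -counts[j] * (LOG2PI + 0.5 * np.log(det[j])) - 0.5 * tr
    return float(ll)


def _shared_rho_logprior(theta: np.ndarray, priors: PriorSpec) -> float:
    sw = np.exp(theta[:4])
    sp = np.exp(theta[4:8])
    rho = np.tanh(theta[8])
    # half-normal on sds with log-scale Jacobian; uniform rho with tanh Jacobian
    lp = float(np.sum(-0.5 * sw**2 / priors.sigma_halfnormal_sd**2 + np.log(sw)))
    lp += float(np.sum(-0.5 * sp**2 / priors.sigma_halfnormal_sd**2 + np.log(sp)))
    lp += float(np.log1p(-rho**2))
    return lp


def _sigma_from_theta(theta: np.ndarray) -> np.ndarray:
    sw = np.exp(theta[:4])
    sp = np.exp(theta[4:8])
    rho = np.tanh(theta[8])
    sigma = np.empty((4, 2, 2))
    sigma[:, 0, 0] = sw**2
    sigma[:, 1, 1] = sp**2
    sigma[:, 0, 1] = sigma[:, 1, 0] = rho * sw * sp
    return sigma


def _sweep(
    data: _Data,
    state: _ChainState,
    priors: PriorSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
    adapt_it: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One full transition-kernel sweep; mutates ``state`` in place.

    ``adapt_it`` enables Robbins-Monro proposal-scale adaptation for the
    Metropolis blocks at that iteration count (None = frozen scales, the
    post-burn-in kernel, which leaves the posterior invariant).  Returns the
    Metropolis acceptance probabilities for the sex and age blocks.
    """
    logit_sds = priors.logit_sds()
    ap_s = np.zeros(3)
    ap_a = np.zeros(3)

    # (i) impute missing labels from their full conditional
    if data.free.size:
        logw = _class_log_weights_subset(data.free, data, state.beta, state.sigma, state.s, state.a)
        logw[~data.admissible[data.free]] = -np.inf
        state.g[data.free] = _sample_rows(logw, rng)

    # (ii) conjugate mean-structure draw
    state.beta = _draw_beta(data, state.g, state.sigma, priors, rng)

    # (iii) covariance update
    R, counts = _residual_stats(data, state.g, state.beta)
    if config.shared_rho:
        theta = state.theta
        ll = _shared_rho_loglik(theta, R, counts) + _shared_rho_logprior(theta, priors)
        for k in range(9):
            prop = theta.copy()
            prop[k] += state.theta_scale[k] * rng.standard_normal()
            ll_prop = _shared_rho_loglik(prop, R, counts) + _shared_rho_logprior(prop, priors)
            ap = min(1.0, np.exp(min(ll_prop - ll, 0.0)))
            if rng.random() < ap:
                theta, ll = prop, ll_prop
            if adapt_it is not None:
                lr = config.adapt_rate / (1.0 + adapt_it) ** 0.6
                state.theta_scale[k] = np.exp(
                    np.log(state.theta_scale[k]) + lr * (ap - config.target_accept)
                )
        state.theta = theta
        state.sigma = _sigma_from_theta(theta)
    else:
        state.sigma = _draw_sigma_iw(R, counts, priors, rng)

    # (iv) random-walk Metropolis for the two logistic blocks
    sex = CLASS_SEX[state.g].astype(float)
    age = CLASS_AGE[state.g].astype(float)
    for y, coef, log_scale, aps in (
        (sex, state.s, state.log_scale_s, ap_s),
        (age, state.a, state.log_scale_a, ap_a),
    ):
        lp = data.U @ coef
        sp_sum = np.logaddexp(0.0, lp).sum()
        yU = data.U.T @ y
        for k in range(3):
            delta = np.exp(log_scale[k]) * rng.standard_normal()
            lp_new = lp + delta * data.U[:, k]
            sp_new = np.logaddexp(0.0, lp_new).sum()
            new_k = coef[k] + delta
            dll = delta * yU[k] - (sp_new - sp_sum)
            dlprior = -0.5 * (new_k**2 - coef[k] ** 2) / logit_sds[k] ** 2
            ap = float(np.exp(min(dll + dlprior, 0.0)))
            aps[k] = ap
            if rng.random() < ap:
                coef[k] = new_k
                lp = lp_new
                sp_sum = sp_new
            if adapt_it is not None:
                lr = config.adapt_rate / (1.0 + adapt_it) ** 0.6
                log_scale[k] += lr * (ap - config.target_accept)
    return ap_s, ap_a


def _run_chain(
    data: _Data,
    priors: PriorSpec,
    config: MCMCConfig,
    rng: np.random.Generator,
    chain_id: int,
) -> dict:
    state = _initialize(data, priors, config, rng)
    n_save = config.n_saved_per_chain
    out = {
        "w0": np.empty((n_save, 4)),
        "w1": np.empty(n_save),
        "w2": np.empty(n_save),
        "p0": np.empty((n_save, 4)),
        "p1": np.empty(n_save),
        "p2": np.empty(n_save),
        "sigma": np.empty((n_save, 4, 2, 2)),
        "s": np.empty((n_save, 3)),
        "a": np.empty((n_save, 3)),
        "class_g": np.empty((n_save, data.n), dtype=np.int8),
        "iteration": np.empty(n_save, dtype=np.int64),
    }
    acc_s = np.zeros(3)
    acc_a = np.zeros(3)
    n_post = 0
    if config.shared_rho:
        sw0 = np.sqrt(state.sigma[:, 0, 0])
        sp0 = np.sqrt(state.sigma[:, 1, 1])
        rho0 = np.clip(state.sigma[:, 0, 1] / (sw0 * sp0), -0.9, 0.9).mean()
        state.theta = np.concatenate([np.log(sw0), np.log(sp0), [np.arctanh(rho0)]])
        state.sigma = _sigma_from_theta(state.theta)

    save_idx = 0
    for it in range(config.n_iter):
        ap_s, ap_a = _sweep(
            data, state, priors, config, rng, adapt_it=it if it < config.n_burn else None
        )
        if it >= config.n_burn:
            n_post += 1
            acc_s += ap_s
            acc_a += ap_a

        # save thinned post-burn-in draws
        if it >= config.n_burn and (it - config.n_burn) % config.thin == config.thin - 1:
            out["w0"][save_idx] = state.beta[:4]
            out["w1"][save_idx] = state.beta[4]
            out["w2"][save_idx] = state.beta[5]
            out["p0"][save_idx] = state.beta[6:10]
            out["p1"][save_idx] = state.beta[10]
            out["p2"][save_idx] = state.beta[11]
            out["sigma"][save_idx] = state.sigma
            out["s"][save_idx] = state.s
            out["a"][save_idx] = state.a
            out["class_g"][save_idx] = state.g + 1
            out["iteration"][save_idx] = it
            save_idx += 1

    out["acceptance"] = {
        "s": (acc_s / max(n_post, 1)).tolist(),
        "a": (acc_a / max(n_post, 1)).tolist(),
    }
    logger.info(
        "chain %d done: acceptance s=%s a=%s",
        chain_id,
        np.round(acc_s / max(n_post, 1), 2),
        np.round(acc_a / max(n_post, 1), 2),
    )
    return out


def run_mcmc(
    table: CaptureTable,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Fit the model by MCMC, imputing missing sex/age labels along the way.

    Runs ``config.n_chains`` chains with overdispersed starting points, saves
    post-burn-in thinned draws of all parameters plus the completed class of
    every record, and attaches Gelman-Rubin diagnostics for the scalar
    parameters (a non-convergence flag is set, not raised, when any R-hat
    exceeds the threshold).
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    data = _Data(table, config)
    root = np.random.SeedSequence(config.seed)
    chain_rngs = [np.random.default_rng(ss) for ss in root.spawn(config.n_chains)]
    chains = [_run_chain(data, priors, config, rng, c) for c, rng in enumerate(chain_rngs)]

    n_save = config.n_saved_per_chain
    draws = PosteriorDraws(
        w0=np.concatenate([c["w0"] for c in chains]),
        w1=np.concatenate([c["w1"] for c in chains]),
        w2=np.concatenate([c["w2"] for c in chains]),
        p0=np.concatenate([c["p0"] for c in chains]),
        p1=np.concatenate([c["p1"] for c in chains]),
        p2=np.concatenate([c["p2"] for c in chains]),
        sigma=np.concatenate([c["sigma"] for c in chains]),
        s=np.concatenate([c["s"] for c in chains]),
        a=np.concatenate([c["a"] for c in chains]),
        class_g=np.concatenate([c["class_g"] for c in chains]),
        chain=np.repeat(np.arange(config.n_chains), n_save),
        iteration=np.concatenate([c["iteration"] for c in chains]),
        missing_any=data.missing_any,
        acceptance={f"chain{c}": chains[c]["acceptance"] for c in range(config.n_chains)},
    )
    if config.n_chains >= 2:
        from redstart.mcmc_diagnostics import gelman_rubin

        frame = draws.scalar_frame()
        for name in frame.columns:
            if name in ("chain", "iteration"):
                continue
            per_chain = [
                frame.loc[frame["chain"] == c, name].to_numpy() for c in range(config.n_chains)
            ]
            if min(np.std(x) for x in per_chain) < 1e-12:
                continue
            draws.rhat[name] = gelman_rubin(np.array(per_chain))
        worst = max(draws.rhat.values(), default=1.0)
        draws.converged = bool(worst <= config.rhat_threshold)
        if not draws.converged:
            bad = {k: round(v, 3) for k, v in draws.rhat.items() if v > config.rhat_threshold}
            logger.warning("possible non-convergence, R-hat > %.2f for %s", config.rhat_threshold, bad)
    return draws


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_posterior(draws: PosteriorDraws, directory: str | Path) -> None:
    """Write draws to ``params.csv`` (long format), ``labels.csv`` and ``index.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = draws.scalar_frame()
    long = frame.melt(id_vars=["chain", "iteration"], var_name="parameter", value_name="value")
    long.to_csv(directory / "params.csv", index=False)
    np.savetxt(directory / "labels.csv", draws.class_g, fmt="%d", delimiter=",")
    index = {
        "n_draws": draws.n_draws,
        "n_records": draws.n_records,
        "chain": draws.chain.tolist(),
        "iteration": draws.iteration.tolist(),
        "missing_any": draws.missing_any.astype(int).tolist(),
        "acceptance": draws.acceptance,
        "rhat": draws.rhat,
        "converged": draws.converged,
        "sigma": draws.sigma.tolist(),
    }
    (directory / "index.json").write_text(json.dumps(index))


def load_posterior(directory: str | Path) -> PosteriorDraws:
    directory = Path(directory)
    index = json.loads((directory / "index.json").read_text())
    long = pd.read_csv(directory / "params.csv")
    frame = long.pivot_table(index=["chain", "iteration"], columns="parameter", values="value", sort=False)
    frame = frame.reset_index().sort_values(["chain", "iteration"], kind="stable")
    class_g = np.loadtxt(directory / "labels.csv", dtype=np.int8, delimiter=",", ndmin=2)
    get = lambda name: frame[name].to_numpy()
    return PosteriorDraws(
        w0=np.column_stack([get(f"w0[{g}]") for g in range(1, 5)]),
        w1=get("w1"),
        w2=get("w2"),
        p0=np.column_stack([get(f"p0[{g}]") for g in range(1, 5)]),
        p1=get("p1"),
        p2=get("p2"),
        sigma=np.asarray(index["sigma"], dtype=float),
        s=np.column_stack([get("s0"), get("s1"), get("s2")]),
        a=np.column_stack([get("a0"), get("a1"), get("a2")]),
        class_g=class_g,
        chain=np.asarray(index["chain"], dtype=np.int64),
        iteration=np.asarray(index["iteration"], dtype=np.int64),
        missing_any=np.asarray(index["missing_any"], dtype=bool),
        acceptance=index["acceptance"],
        rhat=index["rhat"],
        converged=bool(index["converged"]),
    )
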