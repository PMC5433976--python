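"""Convergence assessment and posterior summarization.

Convergence is judged with the potential scale reduction factor computed from
between- and within-chain variances, including the sampling-variability and
degrees-of-freedom corrections of the Brooks-Gelman form, as implemented in
the standard R diagnostic tooling.  Posterior point estimates are means and
interval estimates are the 2.5% and 97.5% empirical quantiles (linear
interpolation of order statistics).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


class DiagnosticUndefined(ValueError):
    """Raised when a diagnostic cannot be computed (single chain, zero variance)."""


def gelman_rubin(chains: np.ndarray) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    Parameters
    ----------
    chains : array (m, n)
        ``m`` >= 2 parallel chains of ``n`` >= 10 post-burn-in draws each.

    Returns
    -------
    float
        The corrected PSRF; values near 1 indicate the chains are sampling
        the same distribution.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise DiagnosticUndefined("gelman_rubin requires >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise DiagnosticUndefined("gelman_rubin requires >= 10 draws per chain")
    s2 = chains.var(axis=1, ddof=1)  # within-chain variances
    W = s2.mean()
    if W <= 0:
        raise DiagnosticUndefined("within-chain variance is zero")
    xbar = chains.mean(axis=1)
    mu = xbar.mean()
    B = n * xbar.var(ddof=1)  # between-chain variance (on the draw scale)
    sigma2_hat = (n - 1) / n * W + B / n
    V = sigma2_hat + B / (m * n)

    # sampling variance of V for the Brooks-Gelman df correction
    var_w = s2.var(ddof=1) / m
    var_b = 2.0 * B**2 / (m - 1)
    cov_wb = (n / m) * (np.cov(s2, xbar**2)[0, 1] - 2.0 * mu * np.cov(s2, xbar)[0, 1])
    var_V = (
        ((n - 1) / n) ** 2 * var_w
        + ((m + 1) / (m * n)) ** 2 * var_b
        + 2.0 * ((n - 1) * (m + 1) / (m * n**2)) * cov_wb
    )
    if var_V <= 0:
        return float(np.sqrt(V / W))
    d = 2.0 * V**2 / var_V
    return float(np.sqrt((d + 3.0) / (d + 1.0) * V / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Effective sample size of one parameter (delegates to arviz)."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    if chains.var() <= 0:
        raise DiagnosticUndefined("zero variance")
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        import arviz as az

        return float(az.ess(chains))


def summarize(
    frame: pd.DataFrame,
    parameters: list[str] | None = None,
    chain_col: str = "chain",
) -> pd.DataFrame:
    """Posterior summary table: mean, sd, 2.5%/97.5% quantiles, R-hat, ESS.

    ``frame`` holds one row per saved draw with a chain-id column (as produced
    by :meth:`PosteriorDraws.scalar_frame`).  R-hat and ESS are omitted (NaN)
    when fewer than two chains are present or a parameter is degenerate.
    """
    if frame.empty:
        raise ValueError("empty draw set")
    if parameters is None:
        parameters = [c for c in frame.columns if c not in (chain_col, "iteration")]
    chains = sorted(frame[chain_col].unique()) if chain_col in frame else [0]
    rows = []
    for name in parameters:
        x = frame[name].to_numpy(dtype=float)
        row = {
            "parameter": name,
            "mean": float(x.mean()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
            "q2.5": float(np.percentile(x, 2.5)),
            "q97.5": float(np.percentile(x, 97.5)),
            "rhat": np.nan,
            "ess": np.nan,
        }
        if len(chains) >= 2:
            per_chain = np.array([frame.loc[frame[chain_col] == c, name].to_numpy() for c in chains])
            try:
                row["rhat"] = gelman_rubin(per_chain)
                row["ess"] = effective_sample_size(per_chain)
            except DiagnosticUndefined:
                pass
        rows.append(row)
    return pd.DataFrame(rows).set_index("parameter")


def convergence_flag(summary: pd.DataFrame, threshold: float = 1.1) -> bool:
    """True when every defined R-hat in the summary is at or below the threshold."""
    rhats = summary["rhat"].dropna()
    if rhats.empty:
        warnings.warn("no R-hat values available; convergence not assessed")
        return True
    return bool((rhats <= threshold).all())
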