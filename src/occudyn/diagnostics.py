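"""Convergence diagnostics: Gelman-Rubin statistic and effective sample size.

The default R-hat is the classic between/within-chain potential scale
reduction factor of the BUGS era (no degrees-of-freedom correction, no rank
normalization), with the more conservative split-chain variant available
behind a flag.  Chains with zero within-chain variance get an undefined
(NaN) statistic and are flagged rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acovf

from .sampler import PosteriorSample

__all__ = ["ConvergenceReport", "gelman_rubin", "effective_sample_size"]

#: Conventional convergence threshold: chains with R-hat <= 1.1 are usually
#: regarded as converged.
RHAT_THRESHOLD = 1.1


@dataclass
class ConvergenceReport:
    """Per-parameter R-hat / ESS table plus the overall verdict."""

    table: pd.DataFrame  # columns: rhat, ess, converged; index: parameter
    threshold: float = RHAT_THRESHOLD

    @property
    def rhat(self) -> pd.Series:
        return self.table["rhat"]

    @property
    def ess(self) -> pd.Series:
        return self.table["ess"]

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())

    @property
    def converged(self) -> bool:
        """True iff every monitored parameter has a defined R-hat <= threshold."""
        r = self.table["rhat"]
        return bool(r.notna().all() and (r <= self.threshold).all())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="parameter")


def _psrf(x: np.ndarray) -> float:
    """Classic potential scale reduction factor for one parameter, x (C, N)."""
    C, N = x.shape
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = N * chain_means.var(ddof=1)
    if W <= 0.0:
        return np.nan
    var_hat = (N - 1) / N * W + B / N
    return float(np.sqrt(var_hat / W))


def gelman_rubin(
    sample: PosteriorSample,
    params: list[str] | None = None,
    threshold: float = RHAT_THRESHOLD,
    split: bool = False,
) -> ConvergenceReport:
    """Gelman-Rubin R-hat (and ESS) per monitored parameter.

    With ``split=True`` each chain is halved and the halves treated as
    chains, which additionally detects within-chain trends.  Requires at
    least two chains and at least 10 retained draws per chain.
    """
    if sample.n_chains < 2:
        raise ValueError("Gelman-Rubin diagnostic requires at least 2 chains")
    if sample.n_draws < 10:
        raise ValueError("need at least 10 retained draws per chain")
    names = params if params is not None else sample.parameter_names
    rhat = {}
    for name in names:
        x = sample.get(name)
        if split:
            half = x.shape[1] // 2
            x = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
        rhat[name] = _psrf(x)
    ess = effective_sample_size(sample, params=names)
    table = pd.DataFrame({"rhat": pd.Series(rhat), "ess": ess})
    table["converged"] = table["rhat"].notna() & (table["rhat"] <= threshold)
    return ConvergenceReport(table=table.loc[names], threshold=threshold)


def _ess_one(x: np.ndarray) -> float:
    """Geyer initial-positive-sequence ESS for one parameter, x (C, N)."""
    C, N = x.shape
    acovs = np.array([acovf(x[c], fft=True, demean=True, nlag=N - 1) for c in range(C)])
    acov = acovs.mean(axis=0)
    if acov[0] <= 0.0:
        return np.nan
    rho = acov / acov[0]
    # sums of adjacent autocorrelation pairs; truncate at the first negative
    max_pairs = (N - 1) // 2
    tau = 1.0  # contribution of rho_0 via -1 + 2*(rho_0/2 + ...)
    s = rho[0]  # running -1 + 2*sum starts from rho_0 = 1
    total = 2.0 * s - 1.0
    for k in range(max_pairs):
        pair = rho[2 * k + 1] + rho[2 * k + 2]
        if pair < 0.0:
            break
        total += 2.0 * pair
    tau = max(total, 1e-12)
    return float(min(C * N, C * N / tau))


def effective_sample_size(
    sample: PosteriorSample, params: list[str] | None = None
) -> pd.Series:
    """Per-parameter effective sample size (autocorrelation-adjusted draw count).

    Uses per-chain autocovariances averaged over chains and Geyer's initial
    positive sequence truncation; the result is capped at the total number of
    retained draws.  Constant chains get NaN.
    """
    names = params if params is not None else sample.parameter_names
    return pd.Series(
        {name: _ess_one(sample.get(name)) for name in names}, name="ess"
    ).loc[names]
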