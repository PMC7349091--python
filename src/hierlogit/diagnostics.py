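"""Convergence and prior-informativeness diagnostics that gate reported fits.

The reporting pipeline refuses to print estimates unless every parameter's
(split) Gelman–Rubin statistic is below the gate threshold (1.10 by default).
Geweke z-scores and effective sample sizes are computed alongside as
supporting evidence; a separate check compares posterior to prior standard
deviations (a fit is only considered prior-robust when every coefficient's
posterior SD is below 10% of its prior SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedStatisticError
from .model import PriorSpec
from .sampler import PosteriorDraws

__all__ = [
    "ConvergenceReport",
    "gelman_rubin",
    "geweke",
    "effective_sample_size",
    "check_convergence",
    "prior_informativeness_check",
]


def _as_chains(draws) -> np.ndarray:
    arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2:
        raise InvalidArgumentError("expected a (chains, draws) array for one parameter")
    return arr


def gelman_rubin(draws, split: bool = True) -> float:
    """Potential scale reduction factor for one parameter.

    With ``split=True`` each chain is halved first (detects within-chain
    trend). W is the mean within-chain variance, B/n the variance of chain
    means; the pooled variance estimate is ((n-1)/n) W + B/n and the statistic
    is sqrt(pooled / W).
    """
    arr = _as_chains(draws)
    if split:
        half = arr.shape[1] // 2
        if half < 2:
            raise InvalidArgumentError("need >= 4 draws per chain to split")
        arr = np.concatenate([arr[:, :half], arr[:, -half:]], axis=0)
    m, n = arr.shape
    if m < 2 or n < 2:
        raise InvalidArgumentError("need >= 2 chains with >= 2 draws each")
    within = float(np.mean(np.var(arr, axis=1, ddof=1)))
    if within == 0.0:
        raise UndefinedStatisticError("within-chain variance is zero (constant chains)")
    b_over_n = float(np.var(np.mean(arr, axis=1), ddof=1))
    pooled = (n - 1) / n * within + b_over_n
    return float(np.sqrt(pooled / within))


def _spectral_var_at_zero(x: np.ndarray) -> float:
    """Spectral density of x at frequency zero, via a Bartlett-windowed
    autocovariance sum (Newey–West). Used as the variance of the window mean
    in the Geweke z-score."""
    n = x.size
    x = x - x.mean()
    lag = min(n - 1, int(np.floor(4.0 * (n / 100.0) ** (2.0 / 9.0) + 4)))
    acov = np.correlate(x, x, mode="full")[n - 1:] / n
    weights = 1.0 - np.arange(1, lag + 1) / (lag + 1.0)
    return float(acov[0] + 2.0 * np.sum(weights * acov[1:lag + 1]))


def geweke(draws, first_frac: float = 0.1, last_frac: float = 0.5) -> float:
    """Geweke convergence z-score for a single chain.

    Compares the mean of the first ``first_frac`` of the chain with the mean
    of the last ``last_frac``, standardized by spectral-density-at-zero
    estimates of each window's variance of the mean.
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    if x.size < 100:
        raise InvalidArgumentError("geweke requires a single chain of >= 100 draws")
    if first_frac <= 0 or last_frac <= 0 or first_frac + last_frac > 1.0:
        raise InvalidArgumentError("geweke windows overlap: need first_frac + last_frac <= 1")
    n = x.size
    first = x[: int(np.floor(first_frac * n))]
    last = x[n - int(np.floor(last_frac * n)):]
    s_first = _spectral_var_at_zero(first)
    s_last = _spectral_var_at_zero(last)
    denom = np.sqrt(s_first / first.size + s_last / last.size)
    if denom == 0.0:
        if first.mean() == last.mean():
            return 0.0
        raise UndefinedStatisticError("zero spectral variance with unequal window means")
    return float((first.mean() - last.mean()) / denom)


def _autocorrelation(x: np.ndarray) -> np.ndarray:
    n = x.size
    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f))[:n].real / n
    if acov[0] == 0.0:
        raise UndefinedStatisticError("constant chain has no autocorrelation structure")
    return acov / acov[0]


def effective_sample_size(draws) -> float:
    """ESS via the autocorrelation-sum estimator with Geyer's pairwise-positive
    truncation, autocorrelations averaged (pooled) across chains."""
    arr = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = arr.shape
    if n < 4:
        raise InvalidArgumentError("need >= 4 draws per chain for an ESS estimate")
    rho = np.mean([_autocorrelation(arr[c]) for c in range(m)], axis=0)
    # Geyer initial positive sequence: sum consecutive pairs while positive
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        tau += 2.0 * pair
        t += 2
    total = m * n
    return float(total / max(tau, 1.0 / total))


@dataclass
class ConvergenceReport:
    """Per-parameter convergence diagnostics plus the overall gate decision."""

    parameters: list[str]
    rhat: np.ndarray
    geweke_z: np.ndarray
    ess: np.ndarray
    threshold: float
    passed: bool
    notes: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.parameters,
            "rhat": self.rhat,
            "geweke_z": self.geweke_z,
            "ess": self.ess,
        })

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_line(self) -> str:
        verdict = "PASS" if self.passed else "FAIL"
        return (f"convergence gate {verdict}: max rhat "
                f"{np.nanmax(self.rhat):.4f} vs threshold {self.threshold:.2f}"
                + (f" ({self.notes})" if self.notes else ""))


def check_convergence(draws: PosteriorDraws, threshold: float = 1.10) -> ConvergenceReport:
    """Evaluate split Gelman–Rubin for every parameter; pass iff all below threshold.

    Geweke (max |z| over chains, reported signed) and pooled ESS ride along
    for reporting. A parameter whose statistic is undefined (constant chains)
    fails the report with its cause recorded.
    """
    names = draws.constrained_names
    D = len(names)
    rhat = np.full(D, np.nan)
    gz = np.full(D, np.nan)
    ess = np.full(D, np.nan)
    notes = []
    for d, name in enumerate(names):
        chains = draws.constrained[:, :, d]
        try:
            rhat[d] = gelman_rubin(chains, split=True)
            zs = [geweke(chains[c]) for c in range(chains.shape[0])]
            gz[d] = zs[int(np.argmax(np.abs(zs)))]
            ess[d] = effective_sample_size(chains)
        except UndefinedStatisticError as exc:
            notes.append(f"{name}: {exc}")
    passed = (not notes) and bool(np.all(rhat < threshold))
    return ConvergenceReport(parameters=list(names), rhat=rhat, geweke_z=gz, ess=ess,
                             threshold=threshold, passed=passed,
                             notes="; ".join(notes))


def prior_informativeness_check(draws: PosteriorDraws, priors: PriorSpec,
                                limit: float = 0.10) -> tuple[pd.DataFrame, bool]:
    """Posterior-SD / prior-SD ratio for the intercept and every slope.

    The weak-prior rule requires every ratio below ``limit`` (10%): the data,
    not the prior, should drive the posterior spread.
    """
    rows = []
    for name in draws.constrained_names:
        if name == "alpha0":
            scale = priors.alpha_scale
        elif name.startswith("beta["):
            scale = priors.beta_scale
        else:
            continue
        post_sd = float(np.std(draws.pooled(name), ddof=1))
        rows.append({"parameter": name, "posterior_sd": post_sd,
                     "prior_sd": scale, "ratio": post_sd / scale})
    table = pd.DataFrame(rows)
    return table, bool((table["ratio"] < limit).all())
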