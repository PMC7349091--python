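"""Posterior reporting: coefficient summaries and the odds-ratio table.

The reporting surface mirrors standard practice for logit analyses: each
slope is shown as an odds ratio (exponentiated posterior mean), with the SD
of the exponentiated draws, an equal-tailed 95% credible interval on the
odds-ratio scale, the percentage change in odds (OR - 1) x 100, and a
significance flag that is set exactly when the interval excludes 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd

from .diagnostics import ConvergenceReport
from .errors import InvalidArgumentError
from .sampler import PosteriorDraws

__all__ = ["SummaryRow", "summarize_coefficients", "odds_ratio_table", "render_report"]

REPORT_COLUMNS = ["parameter", "odds_ratio", "or_sd", "ci_low", "ci_high",
                  "pct_effect", "significant"]


@dataclass(frozen=True)
class SummaryRow:
    """One reporting line for a slope coefficient, on the odds scale."""

    name: str
    odds_ratio: float
    or_sd: float
    ci_low: float
    ci_high: float
    pct_effect: float
    significant: bool

    def __post_init__(self):
        if not (0 < self.ci_low <= self.ci_high) or self.odds_ratio <= 0:
            raise InvalidArgumentError("odds-ratio quantities must be positive and ordered")
        if abs(self.pct_effect - (self.odds_ratio - 1.0) * 100.0) > 1e-9 * max(1.0, abs(self.pct_effect)):
            raise InvalidArgumentError("pct_effect must equal (odds_ratio - 1) * 100")
        if self.significant != (not (self.ci_low <= 1.0 <= self.ci_high)):
            raise InvalidArgumentError("significance flag must match interval-excludes-1")


def _coefficient_names(draws: PosteriorDraws) -> list[str]:
    return [n for n in draws.constrained_names
            if n == "alpha0" or n.startswith("beta[")]


def summarize_coefficients(draws: PosteriorDraws, level: float = 0.95,
                           parameters: list[str] | None = None) -> pd.DataFrame:
    """Coefficient-scale posterior mean, SD and equal-tailed interval bounds.

    Draws are pooled across chains; quantiles use linear interpolation between
    order statistics (numpy's default convention).
    """
    if draws.n_kept == 0:
        raise InvalidArgumentError("no retained draws to summarize")
    if not (0 < level < 1):
        raise InvalidArgumentError("credible level must lie in (0, 1)")
    names = parameters if parameters is not None else list(draws.constrained_names)
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in names:
        pooled = draws.pooled(name)
        rows.append({
            "parameter": name,
            "mean": float(np.mean(pooled)),
            "sd": float(np.std(pooled, ddof=1)),
            "q_low": float(np.quantile(pooled, lo_q)),
            "q_high": float(np.quantile(pooled, hi_q)),
        })
    return pd.DataFrame(rows)


def odds_ratio_table(draws: PosteriorDraws, level: float = 0.95,
                     point_estimate: str = "exp_mean") -> list[SummaryRow]:
    """Build the odds-ratio report for every slope coefficient.

    ``point_estimate="exp_mean"`` (default) reports exp(E[beta]) — the
    exponentiated posterior mean; ``"mean_exp"`` reports E[exp(beta)] instead.
    Interval bounds are the exponentiated coefficient-scale quantiles; by
    monotonicity these agree with quantiles of the exponentiated draws (exactly
    at order statistics, and within the interpolation gap between adjacent
    order statistics otherwise). The SD is
    taken on the odds scale (SD of exp(beta) draws), the only scale on which
    an odds-ratio dispersion is meaningful.
    """
    if point_estimate not in ("exp_mean", "mean_exp"):
        raise InvalidArgumentError("point_estimate must be 'exp_mean' or 'mean_exp'")
    slope_names = [n for n in draws.constrained_names if n.startswith("beta[")]
    if not slope_names:
        raise InvalidArgumentError("no slope coefficients found in draws")
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for name in slope_names:
        pooled = draws.pooled(name)
        exp_draws = np.exp(pooled)
        if point_estimate == "exp_mean":
            point = float(np.exp(np.mean(pooled)))
        else:
            point = float(np.mean(exp_draws))
        lo = float(np.exp(np.quantile(pooled, lo_q)))
        hi = float(np.exp(np.quantile(pooled, hi_q)))
        label = name[len("beta["):-1]
        rows.append(SummaryRow(
            name=label, odds_ratio=point,
            or_sd=float(np.std(exp_draws, ddof=1)),
            ci_low=lo, ci_high=hi,
            pct_effect=(point - 1.0) * 100.0,
            significant=not (lo <= 1.0 <= hi)))
    return rows


def rows_to_frame(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"parameter": r.name, "odds_ratio": r.odds_ratio, "or_sd": r.or_sd,
          "ci_low": r.ci_low, "ci_high": r.ci_high, "pct_effect": r.pct_effect,
          "significant": r.significant} for r in rows],
        columns=REPORT_COLUMNS)


def render_report(rows: list[SummaryRow], convergence: ConvergenceReport,
                  csv_path=None, force: bool = False) -> str:
    """Format the odds-ratio table with the convergence verdict above it.

    When the convergence gate failed and ``force`` is not set, the rendered
    report contains diagnostics only — no estimates are printed. ``csv_path``
    always writes the machine-readable table (full float precision, so a
    written table re-reads bit-for-bit); downstream consumers get the gate
    verdict from the convergence CSV.
    """
    frame = rows_to_frame(rows)
    if csv_path is not None:
        frame.to_csv(csv_path, index=False, float_format="%.17g")
    out = StringIO()
    out.write(convergence.summary_line() + "\n")
    if not convergence.passed and not force:
        out.write("estimates withheld: convergence gate failed "
                  "(re-run or pass force/--force-report to print anyway)\n")
        out.write(convergence.to_frame().to_string(index=False) + "\n")
        return out.getvalue()
    if frame.empty:
        out.write("  ".join(REPORT_COLUMNS) + "\n")
    else:
        display = frame.copy()
        for col in ("odds_ratio", "or_sd", "ci_low", "ci_high", "pct_effect"):
            display[col] = display[col].map(lambda v: f"{v:.3f}")
        out.write(display.to_string(index=False) + "\n")
    return out.getvalue()
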