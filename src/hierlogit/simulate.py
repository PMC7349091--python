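"""Synthetic survey-data generator for the varying-intercept logit analysis.

Emulates a GYTS-style school survey of adolescent smokers: ~40 binary and
ordinal covariates with specified marginal means, a three-level grade variable
with fixed shares, grade-varying intercepts with a between-grade scale, and a
Bernoulli outcome ("intends to quit smoking") generated from a linear logit
in the covariates. The default configuration reproduces the published
marginal means of the motivating Zambian sample (N = 640, grade shares
0.398/0.325/0.277, outcome prevalence 0.633) with effect sizes set to the
logs of the published odds ratios, so every stage of the pipeline is testable
without the (undeposited) survey micro-data.

Covariates are drawn independently unless a correlation is requested
(equicorrelated Gaussian copula hook, off by default), because the source
tables report marginals only. Mutually exclusive indicator sets (age groups,
parental smoking, cigarette brand) are drawn as single categoricals and
one-hot encoded with their reference levels dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import binom, norm

from .errors import InvalidArgumentError
from .model import Dataset

__all__ = [
    "CovariateSpec",
    "CategoricalSpec",
    "GeneratorConfig",
    "TruthRecord",
    "gyts_covariates",
    "gyts_true_beta",
    "gyts_config",
    "generate_covariates",
    "calibrate_intercept",
    "generate_dataset",
]

_FEASIBILITY_EPS = 1e-6


@dataclass(frozen=True)
class CovariateSpec:
    """One independently drawn covariate column.

    kind="binary": Bernoulli at ``target_mean``. kind="ordinal" or
    "count": integer codes on ``support`` = (low, high), drawn from a binomial
    on the support scaled so the mean matches ``target_mean`` (a bounded
    two-parameter family; the source tables give only means/SDs).
    """

    name: str
    kind: str = "binary"
    target_mean: float = 0.5
    support: tuple[int, int] = (0, 6)

    def __post_init__(self):
        if self.kind not in ("binary", "ordinal", "count"):
            raise InvalidArgumentError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary":
            if not (_FEASIBILITY_EPS <= self.target_mean <= 1 - _FEASIBILITY_EPS):
                raise InvalidArgumentError(
                    f"binary target_mean {self.target_mean} for {self.name!r} is infeasible")
        else:
            lo, hi = self.support
            if hi <= lo:
                raise InvalidArgumentError(f"empty support for {self.name!r}")
            if not (lo + _FEASIBILITY_EPS <= self.target_mean <= hi - _FEASIBILITY_EPS):
                raise InvalidArgumentError(
                    f"target_mean {self.target_mean} outside support {self.support} "
                    f"for {self.name!r}")


@dataclass(frozen=True)
class CategoricalSpec:
    """A mutually exclusive indicator set drawn as one categorical.

    ``levels`` maps one-hot column names to probabilities; ``reference_prob``
    is the probability of the dropped reference level (all columns zero).
    Probabilities are normalized if they drift from summing to one by rounding.
    """

    name: str
    levels: tuple[tuple[str, float], ...]
    reference_prob: float

    def __post_init__(self):
        probs = [p for _, p in self.levels] + [self.reference_prob]
        if min(probs) < 0:
            raise InvalidArgumentError(f"negative level probability in {self.name!r}")
        total = sum(probs)
        if abs(total - 1.0) > 0.05:
            raise InvalidArgumentError(
                f"level probabilities of {self.name!r} sum to {total:.3f}, not ~1")

    @property
    def column_names(self) -> list[str]:
        return [name for name, _ in self.levels]

    def normalized_probs(self) -> np.ndarray:
        probs = np.array([p for _, p in self.levels] + [self.reference_prob])
        return probs / probs.sum()


def gyts_covariates() -> list[CovariateSpec | CategoricalSpec]:
    """Default covariate battery: the published marginal means, in the
    published reporting order. Count-like items use integer codes 0..6."""
    cnt = {"kind": "count", "support": (0, 6)}
    return [
        CovariateSpec("gender", target_mean=0.492),
        CategoricalSpec("age_group",
                        levels=(("age_group_two", 0.577), ("age_group_three", 0.375)),
                        reference_prob=0.048),
        CovariateSpec("cigarettes_per_day", target_mean=1.792, **cnt),
        CovariateSpec("smokeless_tobacco_30d", target_mean=0.245),
        CovariateSpec("smoking_past_5_years", target_mean=0.230),
        CovariateSpec("difficult_to_quit", target_mean=0.528),
        CovariateSpec("smoking_harmful", target_mean=0.441),
        CovariateSpec("gained_weight", target_mean=0.209),
        CovariateSpec("lost_weight", target_mean=0.444),
        CovariateSpec("ask_permission", target_mean=0.358),
        CovariateSpec("safe_1_2_years", target_mean=0.291),
        CovariateSpec("times_smoked_in_house", target_mean=2.261, **cnt),
        CovariateSpec("times_smoked_enclosed", target_mean=2.319, **cnt),
        CovariateSpec("times_smoked_outdoor", target_mean=2.248, **cnt),
        CovariateSpec("favors_ban", target_mean=0.359),
        CovariateSpec("advised_stop", target_mean=0.809),
        CovariateSpec("owns_brand_logo", target_mean=0.313),
        CovariateSpec("attends_ad_events", target_mean=0.530),
        CovariateSpec("offered_free_cigs", target_mean=0.267),
        CovariateSpec("taught_dangers", target_mean=0.436),
        CovariateSpec("cigarettes_in_life", target_mean=2.289, **cnt),
        CovariateSpec("sold_near_home", target_mean=0.405),
        CovariateSpec("youth_groups_discourage", target_mean=0.356),
        CovariateSpec("health_workers_explained", target_mean=0.452),
        CovariateSpec("religious_discourage", target_mean=0.413),
        CovariateSpec("not_tried_stop", target_mean=0.111),
        CovariateSpec("tried_improve_health", target_mean=0.227),
        CovariateSpec("tried_save_money", target_mean=0.059),
        CovariateSpec("tried_family_dislikes", target_mean=0.209),
        CovariateSpec("friends_smoke", target_mean=0.603),
        CategoricalSpec("parents_smoke",
                        levels=(("both_parents_smoke", 0.069),
                                ("only_father_smokes", 0.213),
                                ("only_mother_smokes", 0.047)),
                        reference_prob=0.672),
        CategoricalSpec("brand",
                        levels=(("peter_stuyvesant", 0.077),
                                ("roth_man", 0.045),
                                ("consulate", 0.059),
                                ("safari", 0.006),
                                ("own_burns", 0.034)),
                        # "no usual brand" (0.230) and the unnamed remainder both
                        # code as all-zero brand indicators
                        reference_prob=0.779),
    ]


# Published odds ratios for the default effect sizes, keyed by column name,
# in the same order the columns are emitted.
_GYTS_ODDS_RATIOS = {
    "gender": 1.428, "age_group_two": 1.347, "age_group_three": 1.333,
    "cigarettes_per_day": 1.050, "smokeless_tobacco_30d": 2.035,
    "smoking_past_5_years": 1.387, "difficult_to_quit": 2.262,
    "smoking_harmful": 1.211, "gained_weight": 1.890, "lost_weight": 2.371,
    "ask_permission": 0.779, "safe_1_2_years": 1.294,
    "times_smoked_in_house": 1.125, "times_smoked_enclosed": 1.163,
    "times_smoked_outdoor": 0.994, "favors_ban": 2.633, "advised_stop": 2.884,
    "owns_brand_logo": 1.471, "attends_ad_events": 1.889,
    "offered_free_cigs": 1.031, "taught_dangers": 1.444,
    "cigarettes_in_life": 0.901, "sold_near_home": 0.679,
    "youth_groups_discourage": 1.209, "health_workers_explained": 1.591,
    "religious_discourage": 0.906, "not_tried_stop": 0.733,
    "tried_improve_health": 2.661, "tried_save_money": 1.812,
    "tried_family_dislikes": 2.013, "friends_smoke": 0.839,
    "both_parents_smoke": 0.984, "only_father_smokes": 1.324,
    "only_mother_smokes": 0.348, "peter_stuyvesant": 0.429, "roth_man": 1.407,
    "consulate": 1.001, "safari": 1.381, "own_burns": 3.486,
}


def covariate_column_names(covariates) -> list[str]:
    names: list[str] = []
    for spec in covariates:
        if isinstance(spec, CategoricalSpec):
            names.extend(spec.column_names)
        else:
            names.append(spec.name)
    return names


def gyts_true_beta() -> np.ndarray:
    """Default slope vector: natural logs of the published odds ratios."""
    return np.log([_GYTS_ODDS_RATIOS[n] for n in covariate_column_names(gyts_covariates())])


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of one synthetic survey draw.

    ``alpha0="auto"`` calibrates the intercept by bisection so the simulated
    prevalence hits ``target_prevalence``; ``sigma_mu`` is the between-grade
    intercept SD (a stipulated 0.3 by default — the source analysis never
    reports its group-scale posterior). ``latent_correlation`` switches on an
    equicorrelated Gaussian copula across covariates (off by default: the
    source reports marginals only).
    """

    n: int = 640
    grade_probs: tuple[float, float, float] = (0.398, 0.325, 0.277)
    covariates: tuple = field(default_factory=lambda: tuple(gyts_covariates()))
    true_beta: np.ndarray = field(default_factory=gyts_true_beta)
    sigma_mu: float = 0.3
    alpha0: float | str = "auto"
    target_prevalence: float = 0.633
    seed: int = 0
    latent_correlation: float = 0.0
    group_labels: tuple[str, ...] = ("grade7", "grade8", "grade9")

    def __post_init__(self):
        object.__setattr__(self, "true_beta", np.asarray(self.true_beta, dtype=float))
        if abs(sum(self.grade_probs) - 1.0) > 1e-12:
            raise InvalidArgumentError("grade_probs must sum to 1 within 1e-12")
        if min(self.grade_probs) <= 0:
            raise InvalidArgumentError("every grade share must be positive")
        if self.n < 10:
            raise InvalidArgumentError("need N >= 10 rows")
        if self.true_beta.size != len(covariate_column_names(self.covariates)):
            raise InvalidArgumentError("true_beta length must match covariate columns")
        if self.sigma_mu < 0 or not (0.0 <= self.latent_correlation < 1.0):
            raise InvalidArgumentError("sigma_mu >= 0 and latent_correlation in [0,1) required")
        if self.alpha0 == "auto" and not (0 < self.target_prevalence < 1):
            raise InvalidArgumentError("target_prevalence must lie in (0,1)")
        if len(self.grade_probs) != len(self.group_labels):
            raise InvalidArgumentError("one label per grade share required")

    @property
    def column_names(self) -> list[str]:
        return covariate_column_names(self.covariates)


@dataclass(frozen=True)
class TruthRecord:
    """The exact generating parameters of a simulated dataset, for recovery scoring."""

    alpha0: float
    group_deviations: np.ndarray   # mu_j on the logit scale, one per grade
    sigma_mu: float
    beta: np.ndarray
    covariate_names: tuple[str, ...]
    group_labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = [("alpha0", self.alpha0), ("sigma_mu", self.sigma_mu)]
        rows += [(f"mu[{lab}]", d) for lab, d in zip(self.group_labels, self.group_deviations)]
        rows += [(f"beta[{n}]", b) for n, b in zip(self.covariate_names, self.beta)]
        return pd.DataFrame(rows, columns=["parameter", "true_value"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _draw_one_spec(spec: CovariateSpec, u: np.ndarray) -> np.ndarray:
    """Map uniforms to one covariate column via its inverse CDF."""
    if spec.kind == "binary":
        return (u < spec.target_mean).astype(float)
    lo, hi = spec.support
    trials = hi - lo
    p = (spec.target_mean - lo) / trials
    return lo + binom.ppf(u, trials, p)


def generate_covariates(config: GeneratorConfig, rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Draw the covariate matrix and grade vector for ``config.n`` rows.

    Returns ``(X, grade)`` with grade in 1..J. Columns follow
    ``config.column_names``. Independent draws unless
    ``config.latent_correlation`` > 0, in which case a shared Gaussian factor
    induces equicorrelation across all non-categorical columns.
    """
    n = config.n
    grade = rng.choice(len(config.grade_probs), size=n, p=config.grade_probs) + 1
    columns: list[np.ndarray] = []
    rho = config.latent_correlation
    common = rng.normal(size=n) if rho > 0 else None
    for spec in config.covariates:
        if isinstance(spec, CategoricalSpec):
            draw = rng.choice(len(spec.levels) + 1, size=n, p=spec.normalized_probs())
            for level_idx in range(len(spec.levels)):
                columns.append((draw == level_idx).astype(float))
        else:
            if rho > 0:
                z = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.normal(size=n)
                u = norm.cdf(z)
            else:
                u = rng.random(n)
            columns.append(_draw_one_spec(spec, u))
    return np.column_stack(columns), grade


def _expected_prevalence(alpha0, eta_rest):
    return float(np.mean(expit(alpha0 + eta_rest)))


def calibrate_intercept(config: GeneratorConfig, rng: np.random.Generator | None = None,
                        group_deviations: np.ndarray | None = None,
                        n_mc: int = 100_000, tol: float = 0.002) -> float:
    """Bisect for the intercept that hits ``config.target_prevalence``.

    Uses a fixed Monte Carlo draw of ``n_mc`` covariate rows (seed-derived from
    ``config.seed`` when no rng is supplied, so the result is deterministic)
    and the expected outcome probability averaged over that draw. When
    ``group_deviations`` is given (one per grade, logit scale) the calibration
    conditions on those realized grade intercept deviations; otherwise
    deviations are drawn marginally from N(0, sigma_mu^2) per row.
    """
    if rng is None:
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([int(config.seed), 0x5EED])))
    mc_config = replace(config, n=n_mc)
    X, grade = generate_covariates(mc_config, rng)
    if group_deviations is not None:
        dev = np.asarray(group_deviations, dtype=float)[grade - 1]
    elif config.sigma_mu > 0:
        dev = rng.normal(scale=config.sigma_mu, size=n_mc)
    else:
        dev = 0.0
    eta_rest = dev + X @ config.true_beta
    lo, hi = -30.0, 30.0
    target = config.target_prevalence
    if _expected_prevalence(lo, eta_rest) > target or _expected_prevalence(hi, eta_rest) < target:
        strongest = config.column_names[int(np.argmax(np.abs(config.true_beta)))]
        raise InvalidArgumentError(
            f"target prevalence {target} unreachable for alpha0 in [-30, 30]; "
            f"largest effect size is on {strongest!r}")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = _expected_prevalence(mid, eta_rest)
        if abs(prev - target) < min(tol, 1e-4) or hi - lo < 1e-12:
            break
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_dataset(config: GeneratorConfig) -> tuple[Dataset, TruthRecord]:
    """Simulate one survey: grade deviations, covariates, calibrated intercept,
    Bernoulli outcomes. Deterministic given ``config.seed``."""
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(config.seed))))
    J = len(config.grade_probs)
    mu = (rng.normal(scale=config.sigma_mu, size=J) if config.sigma_mu > 0
          else np.zeros(J))
    X, grade = generate_covariates(config, rng)
    if config.alpha0 == "auto":
        alpha0 = calibrate_intercept(config, group_deviations=mu)
    else:
        alpha0 = float(config.alpha0)
    eta = alpha0 + mu[grade - 1] + X @ config.true_beta
    y = (rng.random(config.n) < expit(eta)).astype(float)
    data = Dataset(y=y, X=X, group=grade,
                   covariate_names=tuple(config.column_names),
                   group_labels=config.group_labels)
    truth = TruthRecord(alpha0=alpha0, group_deviations=mu, sigma_mu=config.sigma_mu,
                        beta=config.true_beta.copy(),
                        covariate_names=tuple(config.column_names),
                        group_labels=config.group_labels)
    return data, truth


def gyts_config(**overrides) -> GeneratorConfig:
    """The default GYTS-like configuration (N=640, published marginals), with
    keyword overrides."""
    return GeneratorConfig(**overrides)
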