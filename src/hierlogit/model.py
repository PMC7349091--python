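"""Varying-intercept Bayesian logistic regression: data model, priors, log-posterior.

The model is a hierarchical (partial-pooling) logit for a binary survey outcome
y_i observed on individuals nested in J groups (school grades in the motivating
application):

    logit Pr(y_i = 1) = alpha_0 + sigma_mu * mu_raw[g(i)] + x_i' beta

with a non-centered parameterization of the group intercept deviations:
mu_raw[j] ~ N(0, 1) a priori, so the group intercept is
alpha_0j = alpha_0 + sigma_mu * mu_raw[j] with between-group scale sigma_mu.

Priors: alpha_0 ~ N(0, alpha_scale), beta_k ~ N(0, beta_scale) (scales are
standard deviations), sigma_mu ~ half-Cauchy(0, sigma_scale). Sampling happens
on the unconstrained scale with theta = (alpha0, mu_raw, log sigma_mu, beta)
and an explicit log-Jacobian for the log transform of sigma_mu.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import InvalidArgumentError, NonFiniteGradientError

__all__ = [
    "Dataset",
    "PriorSpec",
    "ParamVector",
    "inverse_logit",
    "linear_predictor",
    "log_likelihood",
    "log_prior",
    "log_posterior",
    "grad_log_posterior",
    "HierarchicalLogitDensity",
]


@dataclass(frozen=True)
class Dataset:
    """A complete-case analytic sample for the varying-intercept logit.

    Attributes
    ----------
    y : (N,) array of 0/1 outcomes (1 = intends to quit in the motivating survey).
    X : (N, K) numeric covariate matrix; ordinal items enter as numeric codes.
    group : (N,) integer group index, contiguous values 1..J, every group non-empty.
    covariate_names : K unique column labels.
    group_labels : J labels (e.g. grade names).
    """

    y: np.ndarray
    X: np.ndarray
    group: np.ndarray
    covariate_names: tuple[str, ...]
    group_labels: tuple[str, ...]

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        group = np.asarray(self.group, dtype=int)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "covariate_names", tuple(self.covariate_names))
        object.__setattr__(self, "group_labels", tuple(self.group_labels))

        if y.ndim != 1 or X.shape[0] != y.size or group.shape != y.shape:
            raise InvalidArgumentError("y, X, group must share leading dimension N")
        if not np.isfinite(X).all() or not np.isfinite(y).all():
            raise InvalidArgumentError("missing or non-finite values are not allowed")
        if not np.isin(y, (0.0, 1.0)).all():
            raise InvalidArgumentError("outcome must be coded 0/1")
        J = len(self.group_labels)
        if sorted(set(group.tolist())) != list(range(1, J + 1)):
            raise InvalidArgumentError("group indices must cover a contiguous 1..J with every group non-empty")
        if y.size < J or X.shape[1] < 1:
            raise InvalidArgumentError("need N >= J rows and K >= 1 covariates")
        if len(self.covariate_names) != X.shape[1] or len(set(self.covariate_names)) != X.shape[1]:
            raise InvalidArgumentError("covariate_names must hold K unique labels")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, outcome: str, group: str,
                   covariates: list[str] | None = None) -> "Dataset":
        """Build a Dataset from a rectangular table.

        ``covariates=None`` uses every column other than outcome and group.
        Rows with any missing value in a used column are rejected (the analysis
        is complete-case by construction: non-response rows are dropped upstream).
        Group labels are sorted and mapped to contiguous indices 1..J.
        """
        if covariates is None:
            covariates = [c for c in frame.columns if c not in (outcome, group)]
        missing = [c for c in [outcome, group, *covariates] if c not in frame.columns]
        if missing:
            raise InvalidArgumentError(f"columns not found in input: {missing}")
        used = frame[[outcome, group, *covariates]]
        if used.isna().any().any():
            raise InvalidArgumentError("input contains missing values in used columns")
        try:
            X = used[covariates].astype(float).to_numpy()
            y = used[outcome].astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise InvalidArgumentError(f"non-numeric value in outcome/covariate columns: {exc}") from exc
        labels = sorted(used[group].unique().tolist())
        idx = used[group].map({lab: i + 1 for i, lab in enumerate(labels)}).to_numpy()
        return cls(y=y, X=X, group=idx,
                   covariate_names=tuple(covariates),
                   group_labels=tuple(str(lab) for lab in labels))

    @classmethod
    def from_csv(cls, path, outcome: str, group: str,
                 covariates: list[str] | None = None) -> "Dataset":
        """Load from a CSV file with a header row (see :meth:`from_frame`)."""
        return cls.from_frame(pd.read_csv(path), outcome, group, covariates)

    def to_frame(self, outcome: str = "intend_quit", group: str = "grade") -> pd.DataFrame:
        frame = pd.DataFrame(self.X, columns=list(self.covariate_names))
        frame.insert(0, group, [self.group_labels[g - 1] for g in self.group])
        frame.insert(0, outcome, self.y.astype(int))
        return frame


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales: normal SDs for coefficients, half-Cauchy scale for sigma_mu."""

    beta_scale: float = 10.0
    alpha_scale: float = 10.0
    sigma_scale: float = 2.5

    def __post_init__(self):
        if min(self.beta_scale, self.alpha_scale, self.sigma_scale) <= 0:
            raise InvalidArgumentError("all prior scales must be strictly positive")


@dataclass(frozen=True)
class ParamVector:
    """Unconstrained parameter state (alpha0, mu_raw[1..J], log sigma_mu, beta[1..K])."""

    alpha0: float
    mu_raw: np.ndarray
    log_sigma_mu: float
    beta: np.ndarray

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu_raw, dtype=float))
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "mu_raw", mu)
        object.__setattr__(self, "beta", beta)
        if not (np.isfinite(self.alpha0) and np.isfinite(self.log_sigma_mu)
                and np.isfinite(mu).all() and np.isfinite(beta).all()):
            raise InvalidArgumentError("all parameter entries must be finite")

    @property
    def sigma_mu(self) -> float:
        return float(np.exp(self.log_sigma_mu))

    @property
    def dim(self) -> int:
        return 1 + self.mu_raw.size + 1 + self.beta.size

    def to_array(self) -> np.ndarray:
        return np.concatenate(([self.alpha0], self.mu_raw, [self.log_sigma_mu], self.beta))

    @classmethod
    def from_array(cls, theta: np.ndarray, n_groups: int) -> "ParamVector":
        theta = np.asarray(theta, dtype=float)
        J = n_groups
        if theta.size < J + 3:
            raise InvalidArgumentError("parameter array too short for J groups and K >= 1 slopes")
        return cls(alpha0=float(theta[0]), mu_raw=theta[1:1 + J],
                   log_sigma_mu=float(theta[1 + J]), beta=theta[2 + J:])

    @staticmethod
    def names(n_groups: int, covariate_names) -> list[str]:
        """Unconstrained coordinate labels in packing order."""
        return (["alpha0"]
                + [f"mu_raw[{j + 1}]" for j in range(n_groups)]
                + ["log_sigma_mu"]
                + [f"beta[{c}]" for c in covariate_names])


def inverse_logit(eta):
    """Logistic function 1 / (1 + exp(-eta)), stable for |eta| up to overflow limits."""
    arr = np.asarray(eta, dtype=float)
    if not np.isfinite(arr).all():
        raise InvalidArgumentError("inverse_logit requires finite input")
    out = expit(arr)
    return float(out) if np.isscalar(eta) or arr.ndim == 0 else out


def _check_dims(params: ParamVector, data: Dataset) -> None:
    if params.mu_raw.size != data.n_groups or params.beta.size != data.n_covariates:
        raise InvalidArgumentError(
            f"parameter dimensions (J={params.mu_raw.size}, K={params.beta.size}) do not match "
            f"data (J={data.n_groups}, K={data.n_covariates})")


def linear_predictor(params: ParamVector, data: Dataset) -> np.ndarray:
    """Per-row logit: alpha0 + sigma_mu * mu_raw[group] + X beta."""
    _check_dims(params, data)
    sigma = params.sigma_mu
    return params.alpha0 + sigma * params.mu_raw[data.group - 1] + data.X @ params.beta


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), with the softplus evaluated stably.
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def log_likelihood(params: ParamVector, data: Dataset) -> float:
    """Bernoulli log-likelihood of the logit model, computed from logits directly."""
    eta = linear_predictor(params, data)
    return _bernoulli_loglik(data.y, eta)


_LOG_2PI = float(np.log(2.0 * np.pi))


def _normal_logpdf_sum(x: np.ndarray, scale: float) -> float:
    x = np.atleast_1d(x)
    return float(-0.5 * np.sum((x / scale) ** 2) - x.size * (np.log(scale) + 0.5 * _LOG_2PI))


def log_prior(params: ParamVector, priors: PriorSpec) -> float:
    """Joint log-prior on the unconstrained scale, including the sigma_mu Jacobian.

    Components: N(0, alpha_scale) on alpha0; N(0, beta_scale) on each beta;
    standard normal on each mu_raw (non-centered deviations); half-Cauchy
    (sigma_scale) on sigma_mu = exp(log_sigma_mu), plus the log-Jacobian
    log|d sigma_mu / d log_sigma_mu| = log_sigma_mu. All normalizing constants
    are included so the densities are proper.
    """
    s = priors.sigma_scale
    sigma = params.sigma_mu
    half_cauchy = float(np.log(2.0) - np.log(np.pi * s) - np.log1p((sigma / s) ** 2))
    return (_normal_logpdf_sum(np.array([params.alpha0]), priors.alpha_scale)
            + _normal_logpdf_sum(params.beta, priors.beta_scale)
            + _normal_logpdf_sum(params.mu_raw, 1.0)
            + half_cauchy
            + params.log_sigma_mu)


def log_posterior(params: ParamVector, data: Dataset, priors: PriorSpec) -> float:
    """Unnormalized log-posterior: log-likelihood plus log-prior."""
    return log_likelihood(params, data) + log_prior(params, priors)


def grad_log_posterior(params: ParamVector, data: Dataset, priors: PriorSpec) -> np.ndarray:
    """Analytic gradient of :func:`log_posterior` in packing order.

    The likelihood part uses the score identity d/d eta_i = y_i - pi_i; chain
    rule gives the alpha0, mu_raw, log_sigma_mu and beta components.
    """
    _check_dims(params, data)
    sigma = params.sigma_mu
    eta = linear_predictor(params, data)
    resid = data.y - expit(eta)

    g_alpha = np.sum(resid) - params.alpha0 / priors.alpha_scale ** 2
    g_mu = (sigma * np.bincount(data.group - 1, weights=resid, minlength=data.n_groups)
            - params.mu_raw)
    # d eta_i / d log_sigma = sigma * mu_raw[g(i)]; half-Cauchy + Jacobian score below.
    g_ls = (sigma * float(resid @ params.mu_raw[data.group - 1])
            + 1.0 - 2.0 * sigma ** 2 / (priors.sigma_scale ** 2 + sigma ** 2))
    g_beta = data.X.T @ resid - params.beta / priors.beta_scale ** 2

    grad = np.concatenate(([g_alpha], g_mu, [g_ls], g_beta))
    if not np.isfinite(grad).all():
        names = ParamVector.names(data.n_groups, data.covariate_names)
        bad = int(np.flatnonzero(~np.isfinite(grad))[0])
        raise NonFiniteGradientError(names[bad])
    return grad


class HierarchicalLogitDensity:
    """Callable log-density + gradient on the unconstrained scale, for the sampler.

    Exposes ``dim``, ``names`` (unconstrained), ``constrained_names`` and
    ``constrain`` (exponentiates log_sigma_mu); ``logp_and_grad`` never raises
    on non-finite intermediates — it returns (-inf, zeros) so the sampler can
    record a divergence instead of aborting a chain.
    """

    def __init__(self, data: Dataset, priors: PriorSpec):
        self.data = data
        self.priors = priors
        self.dim = 1 + data.n_groups + 1 + data.n_covariates
        self.names = ParamVector.names(data.n_groups, data.covariate_names)
        self.constrained_names = [n if n != "log_sigma_mu" else "sigma_mu" for n in self.names]
        self._sigma_index = 1 + data.n_groups
        self._J = data.n_groups
        self._gidx = data.group - 1
        self._X = data.X
        self._y = data.y

    def logp_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        a2 = self.priors.alpha_scale ** 2
        b2 = self.priors.beta_scale ** 2
        s2 = self.priors.sigma_scale ** 2
        J = self._J
        alpha0 = theta[0]
        mu_raw = theta[1:1 + J]
        ls = theta[1 + J]
        beta = theta[2 + J:]
        with np.errstate(over="ignore", invalid="ignore"):
            sigma = np.exp(ls)
            eta = alpha0 + sigma * mu_raw[self._gidx] + self._X @ beta
            lp = (float(self._y @ eta) - float(np.sum(np.logaddexp(0.0, eta)))
                  - 0.5 * alpha0 ** 2 / a2 - 0.5 * float(beta @ beta) / b2
                  - 0.5 * float(mu_raw @ mu_raw)
                  - float(np.log1p(sigma * sigma / s2)) + ls)
            resid = self._y - expit(eta)
            grad = np.empty_like(theta)
            grad[0] = np.sum(resid) - alpha0 / a2
            grad[1:1 + J] = sigma * np.bincount(self._gidx, weights=resid, minlength=J) - mu_raw
            grad[1 + J] = (sigma * float(resid @ mu_raw[self._gidx])
                           + 1.0 - 2.0 * sigma * sigma / (s2 + sigma * sigma))
            grad[2 + J:] = self._X.T @ resid - beta / b2
        if not (np.isfinite(lp) and np.isfinite(grad).all()):
            return -np.inf, np.zeros_like(theta)
        # constant prior normalizers are irrelevant to sampling but kept out here for speed
        return lp, grad

    def constrain(self, draws: np.ndarray) -> np.ndarray:
        """Map unconstrained draws to the constrained view (sigma_mu = exp(log_sigma_mu))."""
        out = np.array(draws, dtype=float, copy=True)
        out[..., self._sigma_index] = np.exp(out[..., self._sigma_index])
        return out
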