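"""Hamiltonian Monte Carlo with the No-U-Turn tree-doubling scheme.

This is the slice-sampling formulation of NUTS: a trajectory is grown by
repeated doubling with a leapfrog integrator until either end of the
trajectory starts to turn back toward the other (U-turn criterion), and the
next state is drawn uniformly from the slice-admissible points of the tree.
Step size is tuned during warmup by dual averaging toward a target acceptance
statistic; a diagonal mass matrix is estimated from warmup draws.

The sampler operates on any target exposing ``dim``, ``names``,
``constrained_names``, ``logp_and_grad`` and ``constrain`` (see
:class:`hierlogit.model.HierarchicalLogitDensity`); ``run_chains`` is the
high-level entry point for the hierarchical logit model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, SamplerError
from .model import Dataset, HierarchicalLogitDensity, PriorSpec

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "leapfrog",
    "nuts_step",
    "adapt",
    "sample_density",
    "run_chains",
]

# Energy-error bound beyond which a transition is flagged divergent and the
# doubling stops (standard HMC practice; configurable via SamplerConfig).
DIVERGENCE_ENERGY = 1000.0


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-run settings. Defaults follow the two-chain, 4000-iteration,
    2500-warmup protocol of the motivating analysis (warmup counts toward the
    total, leaving 1500 retained draws per chain)."""

    n_chains: int = 2
    n_iterations: int = 4000
    n_warmup: int = 2500
    target_accept: float = 0.8
    max_tree_depth: int = 10
    seed: int = 0
    init_jitter: float = 1.0
    divergence_energy: float = DIVERGENCE_ENERGY

    def __post_init__(self):
        if not (0 < self.n_warmup < self.n_iterations):
            raise InvalidArgumentError("need 0 < n_warmup < n_iterations")
        if self.n_chains < 2:
            raise InvalidArgumentError("need n_chains >= 2 (between-chain diagnostics require it)")
        if not (0.0 < self.target_accept < 1.0):
            raise InvalidArgumentError("target_accept must lie in (0, 1)")
        if self.max_tree_depth < 1 or self.init_jitter < 0:
            raise InvalidArgumentError("max_tree_depth >= 1 and init_jitter >= 0 required")

    @property
    def n_kept(self) -> int:
        return self.n_iterations - self.n_warmup


@dataclass
class PosteriorDraws:
    """Retained post-warmup draws with per-chain transition statistics.

    ``draws`` is (chains, kept, dim) on the unconstrained scale;
    ``constrained`` is the same array with scale parameters mapped back to
    their natural domain (sigma_mu exponentiated).
    """

    draws: np.ndarray
    constrained: np.ndarray
    parameter_names: list[str]
    constrained_names: list[str]
    divergences: np.ndarray          # per chain, post-warmup count
    tree_depth_saturations: np.ndarray
    step_size: np.ndarray            # per chain, frozen after warmup
    mass_diag: np.ndarray            # (chains, dim)
    accept_stat: np.ndarray          # per chain, mean over retained iterations
    seed: int = 0
    failed: bool = False
    failure_reason: str = ""

    def __post_init__(self):
        if self.draws.shape != self.constrained.shape or self.draws.ndim != 3:
            raise InvalidArgumentError("draws and constrained must be (chains, kept, dim)")
        if not np.isfinite(self.draws).all():
            raise InvalidArgumentError("retained draws must all be finite")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_kept(self) -> int:
        return self.draws.shape[1]

    def index_of(self, name: str) -> int:
        try:
            return self.constrained_names.index(name)
        except ValueError:
            return self.parameter_names.index(name)

    def get(self, name: str) -> np.ndarray:
        """(chains, kept) draws for one parameter, constrained scale."""
        return self.constrained[:, :, self.index_of(name)]

    def pooled(self, name: str) -> np.ndarray:
        """All chains concatenated, constrained scale."""
        return self.get(name).reshape(-1)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format (chain, iteration, parameter, value) table, constrained scale."""
        C, T, D = self.constrained.shape
        return pd.DataFrame({
            "chain": np.repeat(np.arange(1, C + 1), T * D),
            "iteration": np.tile(np.repeat(np.arange(1, T + 1), D), C),
            "parameter": np.tile(self.constrained_names, C * T),
            "value": self.constrained.reshape(-1),
        })

    def write_csv(self, path) -> None:
        self.to_long_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "PosteriorDraws":
        """Rebuild a draws object from the long-format CSV (diagnostic stats are
        not stored in the CSV and come back as zeros/NaN placeholders)."""
        frame = pd.read_csv(path)
        names = list(dict.fromkeys(frame["parameter"]))
        chains = sorted(frame["chain"].unique())
        C, D = len(chains), len(names)
        T = frame["iteration"].max()
        arr = np.empty((C, T, D))
        for ci, ch in enumerate(chains):
            sub = frame[frame["chain"] == ch]
            pivot = sub.pivot(index="iteration", columns="parameter", values="value")
            arr[ci] = pivot[names].to_numpy()
        return cls(draws=arr.copy(), constrained=arr, parameter_names=list(names),
                   constrained_names=list(names),
                   divergences=np.zeros(C, dtype=int),
                   tree_depth_saturations=np.zeros(C, dtype=int),
                   step_size=np.full(C, np.nan), mass_diag=np.full((C, D), np.nan),
                   accept_stat=np.full(C, np.nan))


def leapfrog(position, momentum, step_size, gradient_fn, mass_diag=None):
    """One leapfrog update: half momentum kick, full position drift, half kick.

    ``gradient_fn(q)`` returns the gradient of the log-density. The kinetic
    energy is 0.5 * p' M^{-1} p with diagonal M. Reversible (negate the
    momentum and step again to return) and volume-preserving by construction.
    """
    q = np.asarray(position, dtype=float)
    p = np.asarray(momentum, dtype=float)
    if step_size <= 0 or not (np.isfinite(q).all() and np.isfinite(p).all()):
        raise InvalidArgumentError("leapfrog requires finite inputs and step_size > 0")
    inv_mass = 1.0 if mass_diag is None else 1.0 / np.asarray(mass_diag, dtype=float)
    p_half = p + 0.5 * step_size * gradient_fn(q)
    q_new = q + step_size * inv_mass * p_half
    p_new = p_half + 0.5 * step_size * gradient_fn(q_new)
    return q_new, p_new


class _Target:
    """Caches the (logp, grad) pair per position for the tree recursion."""

    def __init__(self, logp_and_grad):
        self._f = logp_and_grad
        self.n_evals = 0

    def __call__(self, q):
        self.n_evals += 1
        return self._f(q)


def _kinetic(p, inv_mass):
    return 0.5 * float(p @ (inv_mass * p))


class _TreeState:
    __slots__ = ("q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
                 "q_prop", "n_valid", "keep_going", "sum_alpha", "n_alpha", "divergent")


def _build_tree(target, q, p, grad, log_u, direction, depth, step_size, inv_mass,
                h0, rng, div_energy):
    """Recursive tree doubling (slice-variant NUTS)."""
    st = _TreeState()
    if depth == 0:
        # single leapfrog step in the chosen direction, with cached endpoint grads
        eps = direction * step_size
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * inv_mass * p1
        lp1, g1 = target(q1)
        p1 = p1 + 0.5 * eps * g1
        h1 = -lp1 + _kinetic(p1, inv_mass)
        st.q_minus = st.q_plus = q1
        st.p_minus = st.p_plus = p1
        st.g_minus = st.g_plus = g1
        st.q_prop = q1
        joint = -h1
        st.n_valid = int(log_u <= joint)
        st.divergent = bool(log_u - joint > div_energy) or not np.isfinite(h1)
        st.keep_going = not st.divergent
        # acceptance statistic relative to the initial energy
        st.sum_alpha = float(min(1.0, np.exp(min(0.0, h0 - h1)))) if np.isfinite(h1) else 0.0
        st.n_alpha = 1
        return st

    left = _build_tree(target, q, p, grad, log_u, direction, depth - 1,
                       step_size, inv_mass, h0, rng, div_energy)
    st.q_minus, st.p_minus, st.g_minus = left.q_minus, left.p_minus, left.g_minus
    st.q_plus, st.p_plus, st.g_plus = left.q_plus, left.p_plus, left.g_plus
    st.q_prop = left.q_prop
    st.n_valid = left.n_valid
    st.sum_alpha, st.n_alpha = left.sum_alpha, left.n_alpha
    st.divergent = left.divergent
    st.keep_going = left.keep_going
    if not left.keep_going:
        return st

    if direction == -1:
        right = _build_tree(target, left.q_minus, left.p_minus, left.g_minus, log_u,
                            direction, depth - 1, step_size, inv_mass, h0, rng, div_energy)
        st.q_minus, st.p_minus, st.g_minus = right.q_minus, right.p_minus, right.g_minus
    else:
        right = _build_tree(target, left.q_plus, left.p_plus, left.g_plus, log_u,
                            direction, depth - 1, step_size, inv_mass, h0, rng, div_energy)
        st.q_plus, st.p_plus, st.g_plus = right.q_plus, right.p_plus, right.g_plus

    total = st.n_valid + right.n_valid
    if right.n_valid > 0 and rng.random() < right.n_valid / total:
        st.q_prop = right.q_prop
    st.n_valid = total
    st.sum_alpha += right.sum_alpha
    st.n_alpha += right.n_alpha
    st.divergent = st.divergent or right.divergent
    dq = st.q_plus - st.q_minus
    no_uturn = (float(dq @ (inv_mass * st.p_minus)) >= 0.0
                and float(dq @ (inv_mass * st.p_plus)) >= 0.0)
    st.keep_going = right.keep_going and not st.divergent and no_uturn
    return st


def nuts_step(position, step_size, mass_diag, rng, logp_and_grad,
              max_tree_depth=10, divergence_energy=DIVERGENCE_ENERGY):
    """One No-U-Turn transition from ``position``.

    Returns ``(new_position, stats)`` with stats keys ``accept_stat`` (mean
    Metropolis statistic over the tree), ``depth``, ``divergent``,
    ``saturated``, ``n_evals``.
    """
    target = _Target(logp_and_grad)
    q = np.asarray(position, dtype=float)
    mass = np.asarray(mass_diag, dtype=float)
    inv_mass = 1.0 / mass
    lp, grad = target(q)
    if not np.isfinite(lp):
        raise SamplerError("nuts_step started from a point of zero posterior density")
    p = rng.normal(size=q.size) * np.sqrt(mass)
    h0 = -lp + _kinetic(p, inv_mass)
    log_u = (-h0) + np.log1p(-rng.random())  # log of u ~ Uniform(0, exp(-h0))

    q_minus = q_plus = q
    p_minus = p_plus = p
    g_minus = g_plus = grad
    q_prop = q
    n_valid = 1
    depth = 0
    divergent = False
    sum_alpha, n_alpha = 0.0, 0
    keep_going = True
    while keep_going and depth < max_tree_depth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == -1:
            sub = _build_tree(target, q_minus, p_minus, g_minus, log_u, direction,
                              depth, step_size, inv_mass, h0, rng, divergence_energy)
            q_minus, p_minus, g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        else:
            sub = _build_tree(target, q_plus, p_plus, g_plus, log_u, direction,
                              depth, step_size, inv_mass, h0, rng, divergence_energy)
            q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        sum_alpha += sub.sum_alpha
        n_alpha += sub.n_alpha
        divergent = divergent or sub.divergent
        if sub.keep_going and sub.n_valid > 0 and rng.random() < min(1.0, sub.n_valid / n_valid):
            q_prop = sub.q_prop
        n_valid += sub.n_valid
        dq = q_plus - q_minus
        keep_going = (sub.keep_going
                      and float(dq @ (inv_mass * p_minus)) >= 0.0
                      and float(dq @ (inv_mass * p_plus)) >= 0.0)
        depth += 1
    stats = {
        "accept_stat": sum_alpha / max(n_alpha, 1),
        "depth": depth,
        "divergent": divergent,
        "saturated": depth >= max_tree_depth,
        "n_evals": target.n_evals,
    }
    return q_prop, stats


def _find_reasonable_epsilon(q, logp_and_grad, mass, rng):
    """Heuristic initial step size: double/halve until the one-step acceptance
    probability crosses 1/2."""
    inv_mass = 1.0 / mass
    eps = 1.0
    lp, grad = logp_and_grad(q)
    p = rng.normal(size=q.size) * np.sqrt(mass)
    h0 = -lp + _kinetic(p, inv_mass)

    def joint_after(eps):
        p1 = p + 0.5 * eps * grad
        q1 = q + eps * inv_mass * p1
        lp1, g1 = logp_and_grad(q1)
        p1 = p1 + 0.5 * eps * g1
        if not np.isfinite(lp1):
            return -np.inf
        return -(-lp1 + _kinetic(p1, inv_mass))

    log_ratio = joint_after(eps) + h0
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0 ** direction
        log_ratio = joint_after(eps) + h0
        if direction * log_ratio <= direction * np.log(0.5):
            break
    return eps


class _DualAveraging:
    """Nesterov dual averaging of log step size toward a target acceptance."""

    def __init__(self, eps0, target, gamma=0.05, t0=10.0, kappa=0.75):
        self.mu = float(np.log(10.0 * eps0))
        self.target = target
        self.gamma, self.t0, self.kappa = gamma, t0, kappa
        self.h_bar = 0.0
        self.log_eps = float(np.log(eps0))
        self.log_eps_bar = 0.0
        self.m = 0

    def update(self, accept_stat):
        self.m += 1
        frac = 1.0 / (self.m + self.t0)
        self.h_bar = (1.0 - frac) * self.h_bar + frac * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(self.m) / self.gamma * self.h_bar
        w = self.m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    @property
    def adapted(self):
        return float(np.exp(self.log_eps_bar))


def adapt(warmup_history, target_accept=0.8):
    """Summarize a warmup record into frozen (step_size, mass_diag).

    ``warmup_history`` is a dict with keys ``accept_stats`` (sequence of
    per-iteration acceptance statistics), ``positions`` (array of warmup draws
    from the window used for metric estimation) and ``step_sizes`` (per-
    iteration step sizes). The returned step size is the dual-averaged value
    implied by re-running the averaging over the recorded statistics; the mass
    diagonal is the inverse per-coordinate variance of the recorded positions
    (heavy masses pin down tight coordinates).
    """
    accept = np.asarray(warmup_history["accept_stats"], dtype=float)
    positions = np.asarray(warmup_history["positions"], dtype=float)
    if accept.size == 0 or positions.ndim != 2 or positions.shape[0] < 2:
        raise InvalidArgumentError("warmup history must hold accept stats and >= 2 positions")
    eps0 = float(warmup_history.get("eps0", np.median(warmup_history["step_sizes"])))
    da = _DualAveraging(eps0, target_accept)
    for a in accept:
        da.update(min(1.0, float(a)))
    step = da.adapted
    if step < 1e-10:
        raise SamplerError("adapted step size collapsed below 1e-10; "
                           "check parameter scaling of the target")
    var = np.var(positions, axis=0, ddof=1)
    mass = np.where(var > 0, 1.0 / np.maximum(var, 1e-300), 1.0)
    return step, mass


def _run_single_chain(density, config: SamplerConfig, rng: np.random.Generator):
    dim = density.dim
    q = rng.uniform(-config.init_jitter, config.init_jitter, size=dim)
    lp, _ = density.logp_and_grad(q)
    for _ in range(100):
        if np.isfinite(lp):
            break
        q = rng.uniform(-config.init_jitter, config.init_jitter, size=dim)
        lp, _ = density.logp_and_grad(q)
    else:
        raise SamplerError("could not find a finite-density initial point")

    mass = np.ones(dim)
    eps0 = _find_reasonable_epsilon(q, density.logp_and_grad, mass, rng)
    da = _DualAveraging(eps0, config.target_accept)
    step = eps0

    W = config.n_warmup
    metric_start = W // 2            # draws in (0.5 W, 0.75 W] feed the metric
    metric_end = max(metric_start + 2, int(0.75 * W))
    metric_end = min(metric_end, W)
    window = []

    kept = np.empty((config.n_kept, dim))
    divergences = 0
    saturations = 0
    accept_sum = 0.0

    for it in range(config.n_iterations):
        q, stats = nuts_step(q, step, mass, rng, density.logp_and_grad,
                             config.max_tree_depth, config.divergence_energy)
        if it < W:
            step = da.update(stats["accept_stat"])
            if step < 1e-10:
                raise SamplerError("step size collapsed below 1e-10 during adaptation; "
                                   "the target's parameter scales are pathological")
            if metric_start < it + 1 <= metric_end:
                window.append(q)
            if it + 1 == metric_end and len(window) >= 2:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                # mass is the inverse of the estimated posterior variance, so
                # wide coordinates get light masses and long drift steps
                mass = np.where(var > 1e-12, 1.0 / np.maximum(var, 1e-12), mass)
                # re-tune the step size for the remaining warmup under the new metric
                eps_restart = _find_reasonable_epsilon(q, density.logp_and_grad, mass, rng)
                da = _DualAveraging(eps_restart, config.target_accept)
                step = eps_restart
            if it + 1 == W:
                step = da.adapted
                if step < 1e-10:
                    raise SamplerError("adapted step size collapsed below 1e-10; "
                                       "the target's parameter scales are pathological")
        else:
            k = it - W
            kept[k] = q
            divergences += int(stats["divergent"])
            saturations += int(stats["saturated"])
            accept_sum += stats["accept_stat"]

    return kept, divergences, saturations, step, mass, accept_sum / config.n_kept


def sample_density(density, config: SamplerConfig) -> PosteriorDraws:
    """Run ``config.n_chains`` independent NUTS chains on an arbitrary density.

    Per-chain RNG streams are spawned deterministically from ``config.seed``,
    so identical configs give bit-identical draws.
    """
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    draws = np.empty((config.n_chains, config.n_kept, density.dim))
    div = np.zeros(config.n_chains, dtype=int)
    sat = np.zeros(config.n_chains, dtype=int)
    steps = np.zeros(config.n_chains)
    masses = np.zeros((config.n_chains, density.dim))
    acc = np.zeros(config.n_chains)
    for c in range(config.n_chains):
        rng = np.random.Generator(np.random.PCG64(seqs[c]))
        draws[c], div[c], sat[c], steps[c], masses[c], acc[c] = _run_single_chain(
            density, config, rng)

    out = PosteriorDraws(
        draws=draws, constrained=density.constrain(draws),
        parameter_names=list(density.names),
        constrained_names=list(density.constrained_names),
        divergences=div, tree_depth_saturations=sat,
        step_size=steps, mass_diag=masses, accept_stat=acc, seed=config.seed)
    frac = div.sum() / (config.n_chains * config.n_kept)
    if frac > 0.10:
        out.failed = True
        out.failure_reason = (f"{div.sum()} divergent transitions post-warmup "
                              f"({100 * frac:.1f}% > 10%); draws unreliable")
    return out


def run_chains(data: Dataset, priors: PriorSpec, config: SamplerConfig) -> PosteriorDraws:
    """Fit the varying-intercept logit to ``data`` and return posterior draws."""
    return sample_density(HierarchicalLogitDensity(data, priors), config)
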