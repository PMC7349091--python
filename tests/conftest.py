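import numpy as np
import pytest

import hierlogit as hl


def random_instance(seed, n_max=50, k_max=5, n_groups=3):
    """Small random model instance (data + params + priors) for oracle tests."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_groups * 2, n_max + 1))
    k = int(rng.integers(1, k_max + 1))
    group = np.concatenate([np.arange(1, n_groups + 1),
                            rng.integers(1, n_groups + 1, size=n - n_groups)])
    data = hl.Dataset(
        y=rng.integers(0, 2, size=n).astype(float),
        X=rng.normal(size=(n, k)),
        group=group,
        covariate_names=tuple(f"x{i}" for i in range(k)),
        group_labels=tuple(f"g{j}" for j in range(n_groups)),
    )
    params = hl.ParamVector(
        alpha0=float(rng.normal()),
        mu_raw=rng.normal(size=n_groups),
        log_sigma_mu=float(rng.normal(scale=0.5)),
        beta=rng.normal(size=k),
    )
    priors = hl.PriorSpec(
        beta_scale=float(rng.uniform(1, 12)),
        alpha_scale=float(rng.uniform(1, 12)),
        sigma_scale=float(rng.uniform(0.5, 4)),
    )
    return data, params, priors


@pytest.fixture(scope="session")
def small_dataset():
    data, truth = hl.generate_dataset(hl.recovery_generator_config(n=300, seed=7))
    return data, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One short two-chain fit shared by diagnostics/summaries tests."""
    data, truth = small_dataset
    config = hl.SamplerConfig(n_chains=2, n_iterations=1600, n_warmup=800, seed=21)
    draws = hl.run_chains(data, hl.PriorSpec(), config)
    return draws, data, truth
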