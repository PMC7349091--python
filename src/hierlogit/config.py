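"""Run configuration: file parsing (YAML/JSON) and resolved settings.

A run is fully described by a :class:`RunConfig`: where the data come from
(a survey CSV or generator settings), which columns play which role, prior
scales, sampler settings and reporting options. ``RunConfig.from_file``
accepts YAML or JSON with keys mirroring the dataclass fields; CLI flags
override file values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from .errors import InvalidArgumentError
from .model import PriorSpec
from .sampler import SamplerConfig
from .simulate import GeneratorConfig, gyts_config

__all__ = ["RunConfig"]

_GENERATOR_KEYS = {"n", "grade_probs", "sigma_mu", "alpha0", "target_prevalence",
                   "seed", "latent_correlation"}


def _build(cls, payload: dict, label: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise InvalidArgumentError(f"unknown {label} keys: {sorted(unknown)}")
    try:
        return cls(**payload)
    except TypeError as exc:
        raise InvalidArgumentError(f"bad {label} section: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one simulate/fit/recover run."""

    seed: int = 0
    output_dir: str = "out"
    input_csv: str | None = None
    outcome: str = "intend_quit"
    group: str = "grade"
    covariates: tuple[str, ...] | None = None
    generator: GeneratorConfig = field(default_factory=gyts_config)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    credible_level: float = 0.95
    rhat_threshold: float = 1.10
    force_report: bool = False
    replicates: int = 50

    def __post_init__(self):
        if not (0 < self.credible_level < 1):
            raise InvalidArgumentError("credible_level must lie in (0, 1)")
        if self.rhat_threshold <= 1.0:
            raise InvalidArgumentError("rhat_threshold must exceed 1")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.covariates is not None:
            object.__setattr__(self, "covariates", tuple(self.covariates))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a YAML or JSON config file; keys mirror the dataclass fields.

        The ``generator`` section accepts the scalar GeneratorConfig fields
        (n, grade_probs, sigma_mu, alpha0, target_prevalence, seed,
        latent_correlation); the covariate battery itself is the library
        default and is customized from Python, not from config files.
        """
        text = Path(path).read_text()
        try:
            payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise InvalidArgumentError(f"could not parse config {path}: {exc}") from exc
        if not isinstance(payload, dict):
            raise InvalidArgumentError(f"config {path} must be a mapping")
        return cls.from_mapping(payload)

    @classmethod
    def from_mapping(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        gen_payload = payload.pop("generator", {}) or {}
        unknown = set(gen_payload) - _GENERATOR_KEYS
        if unknown:
            raise InvalidArgumentError(f"unknown generator keys: {sorted(unknown)}")
        if "grade_probs" in gen_payload:
            gen_payload["grade_probs"] = tuple(gen_payload["grade_probs"])
        generator = replace(gyts_config(), **gen_payload)
        priors = _build(PriorSpec, payload.pop("priors", {}) or {}, "priors")
        sampler = _build(SamplerConfig, payload.pop("sampler", {}) or {}, "sampler")
        allowed = {f.name for f in dataclasses.fields(cls)} - {"generator", "priors", "sampler"}
        unknown = set(payload) - allowed
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=generator, priors=priors, sampler=sampler, **payload)

    def with_overrides(self, **overrides) -> "RunConfig":
        """Apply non-None CLI overrides; seed propagates into generator and sampler."""
        overrides = {k: v for k, v in overrides.items() if v is not None}
        sampler_keys = {k: overrides.pop(k) for k in ("n_chains", "n_iterations", "n_warmup")
                        if k in overrides}
        cfg = replace(self, **overrides) if overrides else self
        sampler = replace(cfg.sampler, **sampler_keys) if sampler_keys else cfg.sampler
        return replace(cfg,
                       sampler=replace(sampler, seed=cfg.seed),
                       generator=replace(cfg.generator, seed=cfg.seed))

    def resolved_dict(self) -> dict:
        """JSON-serializable view of every setting (for run logs)."""
        out = dataclasses.asdict(self)
        out["generator"]["true_beta"] = [float(b) for b in self.generator.true_beta]
        out["generator"]["covariates"] = [
            getattr(c, "name") for c in self.generator.covariates]
        return out
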