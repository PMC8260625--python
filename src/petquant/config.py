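"""YAML/JSON run configuration.

A config file mirrors the generator specs plus statistical options::

    seed: 7
    phantom:
      psf_fwhm_mm: 7.0
      noise_sd_fraction: 0.02
    cohort:
      n_patients: 98
    variants:
      - {name: A, supports_lbm: false, threshold_step_percent: 2}
      - {name: B, calibration_scale: 0.97}
      - {name: C, pre_max_smoothing_fwhm_mm: 4.0, calibration_scale: 1.03}
    stats:
      alpha: 0.05
      holm: false
      population_sd: false

Unknown keys raise a :class:`ConfigurationError` rather than being ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .phantom import CohortSpec, PhantomSpec
from .variants import DEFAULT_VARIANTS, VariantConvention

__all__ = ["StatsOptions", "RunConfig", "load_config"]


def _build(cls, block: dict, what: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown {what} keys: {sorted(unknown)}")
    # YAML lists become tuples where the spec expects them
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in block.items()}
    try:
        return cls(**coerced)
    except Exception as e:
        raise ConfigurationError(f"invalid {what} block: {e}") from e


@dataclass(frozen=True)
class StatsOptions:
    alpha: float = 0.05
    holm: bool = False
    population_sd: bool = False


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    variants: tuple[VariantConvention, ...] = DEFAULT_VARIANTS
    stats: StatsOptions = field(default_factory=StatsOptions)
    seed: int = 0

    def with_seed(self, seed: int) -> "RunConfig":
        """Copy of the config with all stochastic stages reseeded."""
        phantom = dataclasses.replace(self.phantom, seed=seed)
        cohort = dataclasses.replace(self.cohort, seed=seed + 1,
                                     variants=self.variants)
        return RunConfig(phantom=phantom, cohort=cohort, variants=self.variants,
                         stats=self.stats, seed=seed)

    def content_hash(self) -> str:
        """Stable hash of the configuration for run logs."""
        blob = json.dumps({
            "phantom": dataclasses.asdict(self.phantom),
            "cohort": {k: v for k, v in dataclasses.asdict(self.cohort).items()},
            "variants": [dataclasses.asdict(v) for v in self.variants],
            "stats": dataclasses.asdict(self.stats),
            "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML (or JSON) run configuration; None gives all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - {"phantom", "cohort", "variants", "stats", "seed"}
    if unknown:
        raise ConfigurationError(f"unknown top-level keys: {sorted(unknown)}")
    variants = tuple(
        _build(VariantConvention, v, "variant") for v in raw.get("variants", [])
    ) or DEFAULT_VARIANTS
    cohort_block = dict(raw.get("cohort", {}))
    cfg = RunConfig(
        phantom=_build(PhantomSpec, raw.get("phantom", {}), "phantom"),
        cohort=_build(CohortSpec, cohort_block, "cohort"),
        variants=variants,
        stats=_build(StatsOptions, raw.get("stats", {}), "stats"),
        seed=int(raw.get("seed", 0)),
    )
    if "variants" not in cohort_block:
        cfg.cohort = dataclasses.replace(cfg.cohort, variants=variants)
    return cfg
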