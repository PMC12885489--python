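"""YAML pipeline configuration and the two study presets."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import (
    DEFAULT_GROUP_PARAMS,
    DEVELOPMENT_GROUP_SIZES,
    VALIDATION_GROUP_SIZES,
    CohortSpec,
    GroupParams,
)
from .processing import ProcessingConfig


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything the four-stage pipeline needs, from one seed."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    scales: list[int] = field(default_factory=lambda: [14])
    scheme: str = "mid_insp"
    eval_scale: int = 14
    k_folds: int = 5
    n_boot: int = 2000
    min_breaths: int = 3
    min_fraction: float = 0.70
    min_points_fraction: float = 10.0 / 14.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["group_params"] = {
            g: asdict(p) for g, p in self.cohort.group_params.items()
        }
        return d

    def content_hash(self) -> str:
        """Stable hash of the full configuration (recorded in every output)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def preset(name: str, seed: int = 0) -> PipelineConfig:
    """Study presets: ``development`` (10/10/10 x 20 d) or ``validation``
    (45/33/20 x 14 d)."""
    if name == "development":
        cohort = CohortSpec(
            group_sizes=dict(DEVELOPMENT_GROUP_SIZES), n_days=20, rng_seed=seed
        )
        return PipelineConfig(
            cohort=cohort,
            scales=list(range(2, 21)),
            eval_scale=20,
            seed=seed,
        )
    if name == "validation":
        cohort = CohortSpec(
            group_sizes=dict(VALIDATION_GROUP_SIZES), n_days=14, rng_seed=seed
        )
        return PipelineConfig(cohort=cohort, scales=[14], eval_scale=14, seed=seed)
    raise ConfigError(f"unknown preset '{name}'")


def _group_params_from_dict(d: dict) -> dict[str, GroupParams]:
    out = {}
    for g, p in d.items():
        base = DEFAULT_GROUP_PARAMS.get(g)
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in p.items()}
        out[g] = replace(base, **kwargs) if base else GroupParams(**kwargs)
    return out


def load_config(path: str | Path, seed: int | None = None) -> PipelineConfig:
    """Load a pipeline configuration from YAML.

    The file may start from a ``preset:`` and override any subset of fields;
    an explicit ``seed`` argument wins over the file.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = preset(raw.pop("preset", "validation"), seed=raw.get("seed", 0))

    if "cohort" in raw:
        c = dict(raw.pop("cohort"))
        if "group_params" in c:
            c["group_params"] = _group_params_from_dict(c.pop("group_params"))
        if "band_hz" in c:
            c["band_hz"] = tuple(c["band_hz"])
        cfg.cohort = replace(cfg.cohort, **c)
    if "processing" in raw:
        p = dict(raw.pop("processing"))
        for key in ("band_hz", "breath_duration_s", "insp_fraction_bounds",
                    "mid_insp_window"):
            if key in p:
                p[key] = tuple(p[key])
        cfg.processing = replace(cfg.processing, **p)
    for key, val in raw.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown configuration key '{key}'")
        setattr(cfg, key, val)
    if seed is not None:
        cfg.seed = seed
    cfg.cohort = replace(cfg.cohort, rng_seed=cfg.seed)
    return cfg
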