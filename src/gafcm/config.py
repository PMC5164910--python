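"""Flat key/value (YAML) configuration mapped onto :class:`PipelineConfig`.

An empty file yields the full defaults (population 100, chromosome length
6, 40 generations, 60%/30%/10% crossover/mutation/elitism, genes uniform
on (0, 255)).  Unknown keys are rejected with a field-level message, as
are out-of-range values and operator fractions that do not sum to 1.
``clusters`` sets both the FCM cluster count and the GA chromosome length,
since one gene encodes one class center.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .fcm import FCMParams
from .ga import GAParams
from .pipeline import PipelineConfig

__all__ = ["load_config", "default_config", "config_to_dict"]

_FCM_KEYS = {
    "clusters": "n_clusters",
    "fuzzifier": "m",
    "max_iter": "max_iter",
    "tol": "tol",
    "spatial_enabled": "spatial_enabled",
    "spatial_p": "p",
    "spatial_q": "q",
    "spatial_window": "window",
}
_GA_KEYS = {
    "pop_size": "pop_size",
    "generations": "generations",
    "crossover_frac": "crossover_frac",
    "mutation_frac": "mutation_frac",
    "elite_frac": "elite_frac",
    "mutation_scale": "mutation_scale",
    "mutation_decay": "mutation_decay",
    "inner_iterations": "inner_iterations",
}
_PIPELINE_KEYS = {
    "gaussian_sigma": "gaussian_sigma",
    "gaussian_kernel": "gaussian_kernel",
    "vessel_rule": "vessel_rule",
    "k_brightest": "k_brightest",
    "vessel_clusters": "vessel_clusters",
}
_ALL_KEYS = set(_FCM_KEYS) | set(_GA_KEYS) | set(_PIPELINE_KEYS)


def default_config() -> PipelineConfig:
    return PipelineConfig()


def _build(mapping: dict) -> PipelineConfig:
    unknown = sorted(set(mapping) - _ALL_KEYS)
    if unknown:
        raise ValueError(
            f"unknown configuration key(s): {', '.join(unknown)}; "
            f"valid keys are: {', '.join(sorted(_ALL_KEYS))}"
        )
    fcm_kwargs = {_FCM_KEYS[k]: v for k, v in mapping.items() if k in _FCM_KEYS}
    ga_kwargs = {_GA_KEYS[k]: v for k, v in mapping.items() if k in _GA_KEYS}
    pipe_kwargs = {_PIPELINE_KEYS[k]: v for k, v in mapping.items() if k in _PIPELINE_KEYS}
    if "vessel_clusters" in pipe_kwargs:
        pipe_kwargs["vessel_clusters"] = tuple(pipe_kwargs["vessel_clusters"])
    if "clusters" in mapping:
        ga_kwargs["chrom_len"] = int(mapping["clusters"])

    try:
        fcm = FCMParams(**fcm_kwargs)
        ga = GAParams(**ga_kwargs)
        return PipelineConfig(fcm=fcm, ga=ga, **pipe_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc


def load_config(path) -> PipelineConfig:
    """Parse and validate a flat YAML key/value configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a flat key/value mapping")
    return _build(data)


def config_to_dict(config: PipelineConfig) -> dict:
    """Serialise a config back to the flat key/value form (round-trips)."""
    out = {
        "clusters": config.fcm.n_clusters,
        "fuzzifier": config.fcm.m,
        "max_iter": config.fcm.max_iter,
        "tol": config.fcm.tol,
        "spatial_enabled": config.fcm.spatial_enabled,
        "spatial_p": config.fcm.p,
        "spatial_q": config.fcm.q,
        "spatial_window": config.fcm.window,
        "pop_size": config.ga.pop_size,
        "generations": config.ga.generations,
        "crossover_frac": config.ga.crossover_frac,
        "mutation_frac": config.ga.mutation_frac,
        "elite_frac": config.ga.elite_frac,
        "mutation_scale": config.ga.mutation_scale,
        "mutation_decay": config.ga.mutation_decay,
        "inner_iterations": config.ga.inner_iterations,
        "gaussian_sigma": config.gaussian_sigma,
        "gaussian_kernel": config.gaussian_kernel,
        "vessel_rule": config.vessel_rule,
        "k_brightest": config.k_brightest,
    }
    if config.vessel_rule == "explicit":
        out["vessel_clusters"] = list(config.vessel_clusters)
    return out
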