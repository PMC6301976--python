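"""Packaged scenario/site presets and the builder that assembles them.

The YAML shipped with the package pins the published parameter sets: site
entries carry (K, Beta r-summary, p0); scenario entries carry the SST
coefficient set plus (gamma, eps, interval bounds).  ``make_scenario``
combines one of each into a runnable :class:`~reefcast.ensemble.ScenarioConfig`.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import yaml

from .ensemble import ScenarioConfig
from .errors import ConfigurationError
from .events import ScheduleConfig
from .dynamics import ModelParams
from .inference import BetaFit
from .temperature import scenario_model

__all__ = ["available_sites", "available_scenarios", "make_scenario", "load_presets"]


@lru_cache(maxsize=1)
def load_presets() -> dict:
    """Parse the packaged scenarios.yaml (cached)."""
    text = resources.files("reefcast.data").joinpath("scenarios.yaml").read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "sites" not in data or "scenarios" not in data:
        raise ConfigurationError("packaged scenarios.yaml is malformed")
    return data


def available_sites() -> list[str]:
    return sorted(load_presets()["sites"])


def available_scenarios() -> list[str]:
    return sorted(load_presets()["scenarios"])


def make_scenario(
    scenario: str = "rcp45",
    site: str = "japan",
    n_runs: int = 1000,
    seed: int = 0,
    **overrides,
) -> ScenarioConfig:
    """Build a ScenarioConfig from packaged presets.

    ``overrides`` may adjust any ScenarioConfig field (e.g. ``horizon``) or
    the shortcut keys ``eps``, ``gamma``, ``p0``, ``p_floor``, ``interval``,
    ``mean_interval``.
    """
    presets = load_presets()
    try:
        site_cfg = presets["sites"][site]
    except KeyError:
        raise ConfigurationError(f"unknown site {site!r}; choose from {available_sites()}")
    try:
        scen_cfg = presets["scenarios"][scenario]
    except KeyError:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; choose from {available_scenarios()}"
        )

    gamma = float(overrides.pop("gamma", scen_cfg["gamma"]))
    eps = float(overrides.pop("eps", scen_cfg["eps"]))
    p0 = float(overrides.pop("p0", site_cfg["p0"]))
    p_floor = float(overrides.pop("p_floor", 0.1))
    lo, hi = overrides.pop("interval", scen_cfg["interval"])
    mean_interval = float(overrides.pop("mean_interval", scen_cfg["mean_interval"]))

    params = ModelParams(
        r=float(site_cfg["r_mean"]), K=float(site_cfg["K"]), gamma=gamma, p0=p0, p_floor=p_floor
    )
    schedule = ScheduleConfig(
        interval_min=int(lo), interval_max=int(hi), mean_interval=mean_interval, eps=eps
    )
    beta = site_cfg["beta"]
    cfg = ScenarioConfig(
        label=f"{scenario}:{site}",
        temperature=scenario_model(scen_cfg["temperature"]),
        params=params,
        schedule=schedule,
        r_beta=BetaFit(alpha=float(beta["alpha"]), beta=float(beta["beta"])),
        n_runs=n_runs,
        seed=seed,
    )
    if overrides:
        cfg = cfg.replace(**overrides)
    return cfg
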