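"""JSON configuration for simulations and analyses.

A config file is a JSON object with optional keys ``regime``, ``harvest``,
``simulator`` and ``design``; anything omitted falls back to the experiment's
defaults. Example::

    {
      "design": {"n_replicates": 6, "n_weeks": 102, "master_seed": 1},
      "regime": {"random": {"mean": 2.0, "dispersion": 0.5, "daily_cap": 13,
                             "block_length": 56, "constrain_block_totals": true}},
      "harvest": {"proportional": {"rate": 0.4}, "threshold": {"limit": 173},
                   "active_weeks": [13, 83]},
      "simulator": {"env_noise_sd": 0.35}
    }
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .regimes import DEFAULT_HARVEST_WEEKS, HarvestRule, RandomRegimeSpec
from .simulate import ExperimentDesign, VitalRates


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(f"unknown {section} config keys: {sorted(unknown)}")


def load_config(path) -> dict:
    """Parse and validate a JSON config into domain objects.

    Returns a dict with ``design`` (ExperimentDesign), ``rates`` (VitalRates),
    ``random_spec`` (RandomRegimeSpec | None) and ``harvest_rules``
    (kind -> HarvestRule).
    """
    raw = json.loads(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a JSON object")
    _check_keys("top-level", raw, {"regime", "harvest", "simulator", "design"})

    design_kwargs = dict(raw.get("design", {}))
    _check_keys("design", design_kwargs,
                {f.name for f in dataclasses.fields(ExperimentDesign)})
    if "treatments" in design_kwargs:
        design_kwargs["treatments"] = tuple(tuple(t) for t in design_kwargs["treatments"])
    design = ExperimentDesign(**design_kwargs)

    sim_kwargs = dict(raw.get("simulator", {}))
    _check_keys("simulator", sim_kwargs, {f.name for f in dataclasses.fields(VitalRates)})
    rates = VitalRates(**sim_kwargs)

    regime = dict(raw.get("regime", {}))
    _check_keys("regime", regime, {"random"})
    random_spec = None
    if "random" in regime:
        rk = dict(regime["random"])
        _check_keys("regime.random", rk, {f.name for f in dataclasses.fields(RandomRegimeSpec)})
        rk.setdefault("seed", design.master_seed)
        random_spec = RandomRegimeSpec(**rk)

    harvest = dict(raw.get("harvest", {}))
    _check_keys("harvest", harvest, {"proportional", "threshold", "active_weeks"})
    weeks = tuple(harvest.get("active_weeks", DEFAULT_HARVEST_WEEKS))
    rules = {
        "none": HarvestRule(kind="none", active_weeks=weeks),
        "proportional": HarvestRule(kind="proportional",
                                    rate=harvest.get("proportional", {}).get("rate", 0.40),
                                    active_weeks=weeks),
        "threshold": HarvestRule(kind="threshold",
                                 limit=harvest.get("threshold", {}).get("limit", 173),
                                 active_weeks=weeks),
    }
    return {"design": design, "rates": rates, "random_spec": random_spec,
            "harvest_rules": rules}
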