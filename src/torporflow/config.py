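"""YAML configuration loading for cohort simulations and pipeline runs.

A config file may carry four optional sections::

    seed: 7
    population:        # CohortPopulation fields
      mass_mean: 7.82
    analyzer:          # AnalyzerModel fields; drift given as knot lists
      noise_sd_o2: 2.0e-5
      drift_o2: {times: [0, 1050], offsets: [0.0, -3.0e-4]}
    protocol:          # make_default_protocol keyword arguments
      start_clock: "01:30"
      torpor_flow: 150
    processing:        # ProcessingConfig fields
      settle_min: 10
"""

from __future__ import annotations

import yaml

from .pipeline import ProcessingConfig
from .simulate import AnalyzerModel, CohortPopulation, piecewise_linear_drift

__all__ = ["load_config", "cohort_inputs_from_config"]


def load_config(path) -> dict:
    """Read a YAML config file into a plain dict (empty file -> empty dict)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _analyzer_from(section: dict) -> AnalyzerModel:
    kwargs = dict(section)
    for key in ("drift_o2", "drift_co2"):
        spec = kwargs.get(key)
        if isinstance(spec, dict):
            kwargs[key] = piecewise_linear_drift(spec["times"], spec["offsets"])
    return AnalyzerModel(**kwargs)


def cohort_inputs_from_config(cfg: dict):
    """Build (population, analyzer, protocol_kwargs, processing, seed) from a
    parsed config dict, falling back to package defaults for absent sections."""
    population = CohortPopulation(**cfg.get("population", {}))
    analyzer = (
        _analyzer_from(cfg["analyzer"]) if "analyzer" in cfg
        else AnalyzerModel(noise_sd_o2=2e-5, noise_sd_co2=2e-5)
    )
    protocol_kwargs = dict(cfg.get("protocol", {}))
    processing = ProcessingConfig(**cfg.get("processing", {}))
    seed = int(cfg.get("seed", 0))
    return population, analyzer, protocol_kwargs, processing, seed
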