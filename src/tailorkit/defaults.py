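"""Loaders for the packaged default configuration documents."""

from __future__ import annotations

import json
from importlib import resources

import yaml

from .messages import MessageLibrary, load_library
from .pipeline import WaveSchedule
from .simulate import CohortConfig, RatingsConfig, ReturnModel
from .variables import VariableCatalog, load_catalog


def _read(name: str):
    text = resources.files("tailorkit.data").joinpath(name).read_text()
    if name.endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def default_catalog() -> VariableCatalog:
    """The demonstration variable catalog (activity items, guideline
    classifier, 13-code behaviour-feedback chain, persuasive chain)."""
    return load_catalog(_read("catalog_default.json"))


def default_library() -> MessageLibrary:
    """The demonstration message library covering every catalog code."""
    return load_library(_read("library_default.json"))


def default_schedule() -> WaveSchedule:
    return WaveSchedule.model_validate(_read("schedule_default.yaml"))


def default_cohort_config() -> CohortConfig:
    """Baseline generator calibrated to the published cohort profile."""
    return CohortConfig.model_validate(_read("table8_default.yaml"))


def default_return_model() -> ReturnModel:
    return ReturnModel.model_validate(_read("returns_default.yaml"))


def default_ratings_config() -> RatingsConfig:
    return RatingsConfig.model_validate(_read("ratings_default.yaml"))
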