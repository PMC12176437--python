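"""Machine-readable reference values from the source publication.

Single source of truth for the headline estimates the pipeline is designed
to reproduce on the real PeNSE 2019 microdata; nothing else in the package
hard-codes them.
"""
from __future__ import annotations

from importlib import resources

import yaml

#: Mapping of (variable, category) in the final adjusted model to the key
#: used in the reference-values file.
PR_KEYS: dict[tuple[str, str], str] = {
    ("area", "rural"): "pr_rural",
    ("region", "Southeast"): "pr_region_southeast",
    ("region", "North"): "pr_region_north",
    ("region", "Midwest"): "pr_region_midwest",
    ("region", "Northeast"): "pr_region_northeast",
    ("territory", "out_of_capital"): "pr_out_of_capital",
    ("body_satisfaction", "unhappy"): "pr_body_unhappy",
    ("body_satisfaction", "indifferent"): "pr_body_indifferent",
    ("body_satisfaction", "happy"): "pr_body_happy",
    ("body_satisfaction", "very_happy"): "pr_body_very_happy",
    ("self_rated_health", "bad"): "pr_health_bad",
    ("self_rated_health", "regular"): "pr_health_regular",
    ("self_rated_health", "good"): "pr_health_good",
    ("self_rated_health", "very_good"): "pr_health_very_good",
}


def load_reference_values() -> dict[str, dict]:
    text = (
        resources.files("guia_adherence")
        .joinpath("data/published_values.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def reference_value(key: str) -> float:
    return float(load_reference_values()[key]["value"])
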