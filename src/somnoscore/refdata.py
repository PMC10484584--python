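"""Bundled reference data: printed confusion tables from a published HSAT
validation study, used to exercise the evaluation statistics end-to-end
without any recordings."""

from __future__ import annotations

import json
from importlib import resources

from .stats import ConfusionMatrix4


def load_reference_tables() -> dict:
    """Raw reference-table document (confusion counts + p-value families)."""
    with resources.files("somnoscore.data").joinpath("reference_tables.json").open() as fh:
        return json.load(fh)


def reference_confusions() -> dict[str, ConfusionMatrix4]:
    doc = load_reference_tables()
    return {name: ConfusionMatrix4(counts) for name, counts in doc["confusion"].items()}


def reference_pvalues(censored_value: float = 0.0005) -> dict[str, list[float]]:
    """P-value families with censored entries ('<0.001') mapped to a number."""
    doc = load_reference_tables()
    out = {}
    for fam, values in doc["pvalue_families"].items():
        out[fam] = [censored_value if v.startswith("<") else float(v) for v in values]
    return out
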