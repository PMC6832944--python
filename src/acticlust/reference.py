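"""Bundled reference tables from the original wrist-accelerometer study.

Four published purity matrices (a two-study adult development sample, an
independent child laboratory sample, an independent adult laboratory sample
and a free-living sample criterion-labelled by a thigh-worn posture monitor)
plus the free-living daily-minutes agreement summary.  They serve as fixed
inputs for the evaluation arithmetic — category capture, purity statistics
and Bland-Altman bias — and as layout references for report output.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .evaluation import CategoryMap, PurityMatrix

__all__ = [
    "REFERENCE_SAMPLES",
    "load_reference_purity",
    "load_reference_daily_minutes",
    "DEFAULT_CATEGORY_MAP",
]

REFERENCE_SAMPLES = ("development", "child_lab", "adult_lab", "freeliving")

#: The behaviour-category partition of the ten intensity-ordered clusters:
#: sedentary A-E, standing/mixed/slow-ambulatory F-H, brisk ambulatory I,
#: running J.
DEFAULT_CATEGORY_MAP = CategoryMap({
    "sedentary": ("A", "B", "C", "D", "E"),
    "standing_mixed_slow": ("F", "G", "H"),
    "brisk_ambulatory": ("I",),
    "running": ("J",),
})


def _data_path(name: str):
    return resources.files("acticlust.data").joinpath(name)


def load_reference_purity(sample: str) -> PurityMatrix:
    """Load one bundled purity matrix (rows: classes; columns: clusters A-J)."""
    if sample not in REFERENCE_SAMPLES:
        raise ValueError(f"unknown sample {sample!r}; choose from {REFERENCE_SAMPLES}")
    with _data_path(f"purity_{sample}.csv").open() as fh:
        df = pd.read_csv(fh, index_col="class")
    share = df.loc["% of total time"]
    values = df.drop(index="% of total time")
    return PurityMatrix(values=values, cluster_share=share)


def load_reference_daily_minutes() -> dict:
    """Free-living daily-minutes summary: per category, the mean/SD daily
    minutes of the model's cluster groups and of the criterion monitor."""
    with _data_path("daily_minutes_agreement.json").open() as fh:
        return json.load(fh)["categories"]
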