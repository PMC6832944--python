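"""End-to-end convenience wrappers over the stage modules.

These glue functions run the standard flow — trim transitions, window,
extract features, normalize, fit or reapply the portable model, letter the
clusters by intensity — without adding behaviour of their own.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import cluster as _cluster
from .features import (CANONICAL_FEATURES, MinMaxNormalizer, extract_features,
                       minmax_fit)
from .signal_io import LabelBout, RawRecording, make_windows, trim_transitions

__all__ = ["extract", "fit_portable_model", "apply_letters", "Lettering"]


def extract(rec: RawRecording, bouts: Sequence[LabelBout] | None = None,
            window_seconds: float = 10.0, trim_seconds: float = 30.0,
            labelled_only: bool = False) -> pd.DataFrame:
    """Trim, window and extract the full candidate feature matrix."""
    trimmed = trim_transitions(bouts, trim_seconds) if bouts is not None else None
    slices = make_windows(rec, trimmed, width=window_seconds)
    fm = extract_features(rec, slices)
    if labelled_only:
        fm = fm[fm["label"].notna()].reset_index(drop=True)
    return fm


def fit_portable_model(fm: pd.DataFrame,
                       feature_names: Sequence[str] | None = None,
                       k: int = 10, seed: int | None = None,
                       n_restarts: int = 10,
                       window_seconds: float = 10.0,
                       trim_seconds: float = 30.0):
    """Normalize, fit k-means and package the portable model.

    Returns ``(model, assignments)`` where assignments index the model's raw
    clusters on the training windows.
    """
    names = list(feature_names) if feature_names is not None else list(CANONICAL_FEATURES)
    norm = minmax_fit(fm, columns=names)
    fm_norm = norm.transform(fm)
    model = _cluster.kmeans_fit(fm_norm, k=k, seed=seed, n_restarts=n_restarts,
                                norm=norm, window_seconds=window_seconds,
                                trim_seconds=trim_seconds)
    return model, _cluster.assign(fm_norm, model)


class Lettering(dict):
    """Mapping raw cluster index -> intensity-ordered letter."""

    def letters(self, assignments: Sequence[int]) -> list[str]:
        return [self[int(a)] for a in assignments]


def apply_letters(model, fm: pd.DataFrame,
                  assignments: Sequence[int] | None = None) -> tuple[list[str], Lettering]:
    """Assign windows (if needed) and name their clusters A, B, ... by intensity.

    The intensity ordering is computed on ``fm``'s raw ``enmo_mean`` column.
    Returns the per-window letters and the index->letter mapping.
    """
    if assignments is None:
        assignments = _cluster.apply_model(fm, model)
    mapping = Lettering(_cluster.order_clusters(model, fm, assignments))
    return mapping.letters(np.asarray(assignments)), mapping
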