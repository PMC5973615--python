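"""Normalization and the two-rule quality-control transcript filter.

The QC filter keeps a transcript when (a) it is detected ("present") in at
least a given fraction of samples and (b) its expression in at least one
sample departs from its cross-sample median intensity by at least a given
linear fold.  Plain intensity matrices carry no detection p-values, so
"present" is operationalized as intensity above a detection floor — either a
fixed linear intensity or, by default, 3x the 5th percentile of each sample's
own intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import ExpressionMatrix

__all__ = ["QcFilterParams", "normalize_median_scale", "qc_filter_transcripts"]


@dataclass(frozen=True)
class QcFilterParams:
    """Parameters of the presence + fold-change transcript filter.

    presence_fraction
        Minimum fraction of samples in which a transcript must be detected
        (default 0.10).
    fold_threshold
        Minimum linear fold departure from the median intensity (default 2.0).
    detection
        ``"relative_floor"`` — detected when the linear intensity exceeds
        ``floor_multiplier`` x the sample's 5th-percentile intensity;
        ``"absolute_floor"`` — detected when it exceeds ``floor`` (linear).
    median_scope
        ``"per_transcript"`` compares each transcript with its own
        cross-sample median; ``"global"`` with the single grand median.
    """

    presence_fraction: float = 0.10
    fold_threshold: float = 2.0
    detection: Literal["relative_floor", "absolute_floor"] = "relative_floor"
    floor: float | None = None
    floor_multiplier: float = 3.0
    median_scope: Literal["per_transcript", "global"] = "per_transcript"

    def __post_init__(self) -> None:
        if not (0.0 < self.presence_fraction <= 1.0):
            raise ValueError("presence_fraction must be in (0, 1]")
        if self.fold_threshold < 1.0:
            raise ValueError("fold_threshold must be >= 1")
        if self.detection == "absolute_floor" and (self.floor is None or self.floor <= 0):
            raise ValueError("absolute_floor detection requires a positive floor")


def normalize_median_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Equalize per-sample medians (log2) to the global median.

    Each sample is shifted additively in log2 space — a pure rescaling in
    linear space — so within-sample rank order is preserved.  A degenerate
    constant-valued sample cannot be meaningfully rescaled; it is passed
    through with a warning.
    """
    m = m.to_log2()
    x = m.values.copy()
    if x.size == 0:
        return m
    sample_medians = np.median(x, axis=1)
    target = float(np.median(sample_medians))
    constant = x.std(axis=1) == 0.0
    if constant.any():
        bad = [m.sample_ids[i] for i in np.flatnonzero(constant)]
        warnings.warn(f"constant-valued samples left unscaled: {bad}")
    shift = np.where(constant, 0.0, target - sample_medians)
    x = x + shift[:, None]
    df = m.data.copy()
    df.loc[:, :] = x
    return ExpressionMatrix(df, scale="log2")


def qc_filter_transcripts(m: ExpressionMatrix, params: QcFilterParams | None = None) -> list[str]:
    """Apply the presence and fold-change rules; return kept transcript IDs
    in input order."""
    if params is None:
        params = QcFilterParams()
    m = m.to_log2()
    x = m.values  # samples x transcripts, log2
    if x.size == 0:
        return []

    # presence rule (floors are defined on the linear scale; percentiles and
    # thresholds commute with log2, so everything is evaluated in log2)
    if params.detection == "absolute_floor":
        floor = np.full(x.shape[0], np.log2(params.floor))
    else:
        floor = np.percentile(x, 5.0, axis=1) + np.log2(params.floor_multiplier)
    present = x > floor[:, None]
    presence_ok = present.mean(axis=0) >= params.presence_fraction

    # fold-change rule vs the median intensity
    if params.median_scope == "per_transcript":
        med = np.median(x, axis=0)
    else:
        med = np.full(x.shape[1], np.median(x))
    fold_ok = np.abs(x - med).max(axis=0) >= np.log2(params.fold_threshold)

    keep = presence_ok & fold_ok
    return [t for t, k in zip(m.transcript_ids, keep) if k]
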