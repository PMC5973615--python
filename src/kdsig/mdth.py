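"""Molecular distance to health (MDTH).

The MDTH score condenses a sample's global transcriptional perturbation into
one number: over a chosen transcript universe, every transcript whose log2
expression lies more than two standard deviations from the healthy-control
mean contributes its absolute deviation in SD units, and the score is the
sum of those contributions.  A healthy-looking sample scores near zero; an
acutely perturbed sample over a ~10^4-transcript universe scores in the
thousands.

The healthy baseline is a per-transcript mean and sample SD computed from an
explicit control set; zero-variance transcripts cannot be scored and are
dropped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ExpressionMatrix

__all__ = [
    "ControlReference",
    "MdthResult",
    "build_control_reference",
    "mdth_score",
    "mdth_score_matrix",
    "mdth_delta",
]


@dataclass(frozen=True)
class ControlReference:
    """Per-transcript healthy-control mean and SD (log2 units)."""

    transcript_ids: tuple[str, ...]
    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("reference requires at least 2 controls")
        if np.any(self.sigma <= 0):
            raise ValueError("reference SDs must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"transcript_id": self.transcript_ids, "mu": self.mu, "sigma": self.sigma}
        )


@dataclass(frozen=True)
class MdthEntry:
    score: float
    n_perturbed: int


@dataclass(frozen=True)
class MdthResult:
    per_sample: Mapping[str, MdthEntry]

    def scores(self) -> dict[str, float]:
        return {s: e.score for s, e in self.per_sample.items()}


def build_control_reference(
    m: ExpressionMatrix,
    controls: Sequence[str],
    universe: Sequence[str] | None = None,
) -> ControlReference:
    """Mean and sample SD (n-1 denominator) per transcript over the controls."""
    if len(controls) < 2:
        raise ValueError("need at least 2 control samples")
    m = m.to_log2()
    sub = m.subset(samples=list(controls),
                   transcripts=list(universe) if universe is not None else None)
    x = sub.values
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    keep = sigma > 0
    if not keep.all():
        dropped = [t for t, k in zip(sub.transcript_ids, keep) if not k]
        warnings.warn(
            f"{len(dropped)} zero-variance transcripts dropped from reference"
        )
    tids = tuple(t for t, k in zip(sub.transcript_ids, keep) if k)
    return ControlReference(
        transcript_ids=tids, mu=mu[keep], sigma=sigma[keep], n_controls=len(controls)
    )


def mdth_score(
    sample: Mapping[str, float] | pd.Series,
    ref: ControlReference,
    excess_only: bool = False,
) -> MdthEntry:
    """Score one expression vector against the healthy baseline.

    score = sum over the universe of (|x - mu| / sigma) for transcripts with
    |x - mu| > 2 sigma.  With ``excess_only`` the contribution is instead the
    part exceeding the 2-SD band, (|x - mu| / sigma) - 2.
    """
    missing = [t for t in ref.transcript_ids if t not in sample]
    if missing:
        raise ValueError(f"sample missing reference transcripts: {missing[:5]}")
    x = np.array([float(sample[t]) for t in ref.transcript_ids])
    dev = np.abs(x - ref.mu) / ref.sigma
    hit = dev > 2.0
    contrib = (dev - 2.0) if excess_only else dev
    return MdthEntry(score=float(contrib[hit].sum()), n_perturbed=int(hit.sum()))


def mdth_score_matrix(
    m: ExpressionMatrix, ref: ControlReference, excess_only: bool = False
) -> MdthResult:
    """Vectorized MDTH for every sample in the matrix."""
    sub = m.to_log2().subset(transcripts=list(ref.transcript_ids))
    x = sub.values
    dev = np.abs(x - ref.mu) / ref.sigma
    hit = dev > 2.0
    contrib = np.where(hit, dev - 2.0 if excess_only else dev, 0.0)
    scores = contrib.sum(axis=1)
    n_hits = hit.sum(axis=1)
    return MdthResult(
        per_sample={
            s: MdthEntry(float(scores[i]), int(n_hits[i]))
            for i, s in enumerate(sub.sample_ids)
        }
    )


def mdth_delta(
    series: Mapping[str, Mapping[str, float]],
    timepoints: Sequence[str] = ("pre", "post24h", "convalescent"),
) -> dict[str, tuple[float, ...]]:
    """Ordered per-patient MDTH changes across timepoints.

    ``series`` maps patient -> {timepoint: score}.  Returns patient ->
    successive differences (post24h - pre, convalescent - post24h, ...).
    Patients missing any timepoint are skipped with a warning.
    """
    out: dict[str, tuple[float, ...]] = {}
    skipped = []
    for patient, scores in series.items():
        if any(tp not in scores for tp in timepoints):
            skipped.append(patient)
            continue
        vals = [scores[tp] for tp in timepoints]
        out[patient] = tuple(vals[i + 1] - vals[i] for i in range(len(vals) - 1))
    if skipped:
        warnings.warn(f"patients missing timepoints skipped: {skipped[:5]}")
    return out
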