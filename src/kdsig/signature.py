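"""Differential-expression signature derivation and clustering validation.

Supervised stage: per-transcript Mann-Whitney U test of patients vs matched
controls, Benjamini-Hochberg correction across the tested universe, and a
linear fold-change filter on group medians (patient / control).  Selection
uses adjusted p < alpha together with fold change >= fc (over-expressed) or
<= 1/fc (under-expressed); the fold threshold is non-strict.

Unsupervised stage: agglomerative clustering of samples over the signature
transcripts (default 1 - Pearson correlation distance, average linkage) with
a two-cluster cut and a purity summary against the annotated groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix

__all__ = [
    "TranscriptStat",
    "SignatureResult",
    "DendrogramResult",
    "mann_whitney_u",
    "bh_adjust",
    "derive_signature",
    "hierarchical_cluster",
]


@dataclass(frozen=True)
class TranscriptStat:
    transcript_id: str
    p_raw: float
    p_bh: float
    fold_change: float  # linear ratio, patient median / control median
    direction: Literal["over", "under"]


@dataclass(frozen=True)
class SignatureResult:
    stats: tuple[TranscriptStat, ...]
    selected: tuple[str, ...]
    n_over: int
    n_under: int
    alpha: float
    fc: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([s.__dict__ for s in self.stats])
        if len(df):
            df["selected"] = df["transcript_id"].isin(set(self.selected))
        return df


@dataclass(frozen=True)
class DendrogramResult:
    sample_ids: tuple[str, ...]
    linkage_matrix: np.ndarray
    labels: np.ndarray  # flat 2-cluster labels, values {1, 2}
    purity: float


def mann_whitney_u(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is <= 12
    and the data are tie-free; otherwise the normal approximation with
    midranks and tie-corrected variance.  Returns (U for group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0.0:  # all values identical: no evidence either way
        return a.size * b.size / 2.0, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = a.size + b.size <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_stats(
    m: ExpressionMatrix, patients: Sequence[str], controls: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-transcript Mann-Whitney p and linear fold change."""
    xp = m.subset(samples=list(patients)).values
    xc = m.subset(samples=list(controls)).values
    n = xp.shape[1]
    small = xp.shape[0] + xc.shape[0] <= 12
    if small:
        p = np.empty(n)
        u = np.empty(n)
        for j in range(n):
            u[j], p[j] = mann_whitney_u(xp[:, j], xc[:, j])
    else:
        res = stats.mannwhitneyu(xp, xc, alternative="two-sided",
                                 method="asymptotic", axis=0)
        u = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance transcripts (all values tied) carry no evidence
        flat = np.ptp(np.vstack([xp, xc]), axis=0) == 0.0
        p = np.where(flat, 1.0, np.minimum(np.nan_to_num(p, nan=1.0), 1.0))
    # medians commute with the monotone log2 transform, so the linear ratio
    # of medians is 2**(difference of log2 medians)
    fc = 2.0 ** (np.median(xp, axis=0) - np.median(xc, axis=0))
    return u, p, fc


def derive_signature(
    m: ExpressionMatrix,
    patients: Sequence[str],
    controls: Sequence[str],
    alpha: float = 0.01,
    fc: float = 1.25,
) -> SignatureResult:
    """Derive the differentially-expressed transcript signature.

    The matrix should already be restricted to the QC-filtered universe: the
    BH correction runs across exactly the transcripts present.
    """
    pset, cset = set(patients), set(controls)
    if not pset or not cset:
        raise ValueError("patient and control sets must be non-empty")
    if pset & cset:
        raise ValueError(f"patient/control overlap: {sorted(pset & cset)[:5]}")
    _, p_raw, fold = _group_stats(m, list(patients), list(controls))
    p_bh = bh_adjust(p_raw)
    tids = m.transcript_ids
    stats_out = []
    selected = []
    n_over = n_under = 0
    for j, tid in enumerate(tids):
        direction = "over" if fold[j] > 1.0 else "under"
        stats_out.append(
            TranscriptStat(tid, float(p_raw[j]), float(p_bh[j]), float(fold[j]), direction)
        )
        if p_bh[j] < alpha and (fold[j] >= fc or fold[j] <= 1.0 / fc):
            selected.append(tid)
            if fold[j] >= fc:
                n_over += 1
            else:
                n_under += 1
    return SignatureResult(
        stats=tuple(stats_out),
        selected=tuple(selected),
        n_over=n_over,
        n_under=n_under,
        alpha=alpha,
        fc=fc,
    )


def hierarchical_cluster(
    m: ExpressionMatrix,
    signature: Sequence[str],
    target_samples: Sequence[str],
    distance: Literal["correlation", "euclidean"] = "correlation",
    method: Literal["average", "complete"] = "average",
) -> DendrogramResult:
    """Cluster samples over the signature transcripts and cut into 2 groups.

    ``purity`` is the fraction of ``target_samples`` (typically the disease
    group) falling in their majority cluster — 1.0 when the cut isolates the
    group perfectly.
    """
    if len(m.sample_ids) < 2:
        raise ValueError("clustering requires at least 2 samples")
    if not signature:
        raise ValueError("signature must be non-empty")
    sub = m.subset(transcripts=list(signature))
    x = sub.values
    metric = "correlation" if distance == "correlation" else "euclidean"
    d = pdist(x, metric=metric)
    z = linkage(d, method=method)
    labels = fcluster(z, t=2, criterion="maxclust")
    ids = sub.sample_ids
    target = set(target_samples)
    in_target = np.array([s in target for s in ids])
    if not in_target.any():
        raise ValueError("no target samples present in the matrix")
    counts = [np.sum(labels[in_target] == c) for c in (1, 2)]
    purity = float(max(counts) / in_target.sum())
    return DendrogramResult(
        sample_ids=tuple(ids), linkage_matrix=z, labels=labels, purity=purity
    )
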