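"""Modular transcriptional fingerprints.

A fingerprint summarizes patient-vs-control differential expression at the
level of predefined transcriptional modules: for each module, the percentage
of member transcripts significantly over-expressed and the percentage
significantly under-expressed.  Module percentages are themselves the
aggregation device, so per-transcript significance uses the raw Mann-Whitney
p-value by default (a within-module BH correction is available).

Two fingerprints (e.g. training vs test cohort) are compared by Spearman
correlation of the per-module net score, pct_over - pct_under.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, ModuleCatalog
from .signature import _group_stats, bh_adjust

__all__ = ["ModuleScore", "ModuleFingerprint", "fingerprint", "compare_fingerprints"]


@dataclass(frozen=True)
class ModuleScore:
    module_id: str
    annotation: str
    pct_over: float
    pct_under: float
    n_transcripts: int
    significant: bool  # False = "blank" module (no significant transcripts)

    @property
    def net(self) -> float:
        return self.pct_over - self.pct_under


@dataclass(frozen=True)
class ModuleFingerprint:
    scores: tuple[ModuleScore, ...]

    def __iter__(self):
        return iter(self.scores)

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def module_ids(self) -> list[str]:
        return [s.module_id for s in self.scores]

    def net_scores(self) -> dict[str, float]:
        return {s.module_id: s.net for s in self.scores}


def fingerprint(
    m: ExpressionMatrix,
    patients: Sequence[str],
    controls: Sequence[str],
    catalog: ModuleCatalog,
    alpha: float = 0.01,
    within_module_bh: bool = False,
) -> ModuleFingerprint:
    """Percentage of significantly over/under-expressed transcripts per module.

    Catalog transcripts absent from the matrix are dropped with a warning;
    a module left empty after intersection is reported blank.
    """
    present = set(m.transcript_ids)
    missing = catalog.all_transcripts() - present
    if missing:
        warnings.warn(
            f"{len(missing)} catalog transcripts absent from matrix; dropped"
        )
    universe = sorted(catalog.all_transcripts() & present)
    scores: list[ModuleScore] = []
    if universe:
        sub = m.subset(transcripts=universe)
        _, p_raw, fold = _group_stats(sub, list(patients), list(controls))
        p_of = dict(zip(universe, p_raw))
        fc_of = dict(zip(universe, fold))
    for entry in catalog:
        members = sorted(entry.transcript_ids & present)
        if not members:
            warnings.warn(f"module {entry.module_id} empty after intersection; blank")
            scores.append(
                ModuleScore(entry.module_id, entry.annotation, 0.0, 0.0, 0, False)
            )
            continue
        p = np.array([p_of[t] for t in members])
        if within_module_bh:
            p = bh_adjust(p)
        fc = np.array([fc_of[t] for t in members])
        sig = p < alpha
        n = len(members)
        n_over = int(np.sum(sig & (fc > 1.0)))
        n_under = int(np.sum(sig & (fc < 1.0)))
        scores.append(
            ModuleScore(
                module_id=entry.module_id,
                annotation=entry.annotation,
                pct_over=100.0 * n_over / n,
                pct_under=100.0 * n_under / n,
                n_transcripts=n,
                significant=(n_over + n_under) > 0,
            )
        )
    return ModuleFingerprint(scores=tuple(scores))


def compare_fingerprints(
    f1: ModuleFingerprint, f2: ModuleFingerprint
) -> tuple[float, float]:
    """Spearman correlation of per-module net scores between two fingerprints."""
    n1, n2 = f1.net_scores(), f2.net_scores()
    shared = [mid for mid in f1.module_ids if mid in n2]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared modules to correlate")
    x = np.array([n1[mid] for mid in shared])
    y = np.array([n2[mid] for mid in shared])
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
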