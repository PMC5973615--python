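"""Synthetic whole-blood cohort generator.

Emulates the statistical structure of a pediatric febrile-illness microarray
study: a shared healthy baseline per transcript, disease groups (complete and
incomplete Kawasaki disease, adenovirus, group A streptococcus) whose
perturbation is organised in transcriptional modules, a per-patient global
perturbation magnitude that drives both the molecular-distance-to-health
score and the probability of IVIG non-response, and longitudinal samples with
decaying perturbation after treatment.

The generating model, per transcript g and sample i (all on log2 scale):

    healthy:  x_ig = mu_g + eps_ig,                    eps_ig ~ N(0, sd_g)
    disease:  x_ig = mu_g + s_i * e_g + eps_ig + eta_ig,
              eta_ig ~ N(0, within_group_sd)

where e_g is the module-level effect for the sample's disease group, and
s_i = exp(N(0, scale_sigma)) * inflation^NR_i is the patient's global
perturbation scale.  Non-response NR_i ~ Bernoulli(nonresponder_fraction) is
drawn first and inflates the scale multiplicatively; because the two
conditional scale distributions are lognormal with a shared variance, the
induced P(NR | s) is exactly logistic in log(s), and the generating logistic
coefficients are recorded in :class:`SimulatedTruth` for recovery tests.

All randomness flows from a single master seed through named child streams,
so identical configurations give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    ModuleCatalog,
    ModuleEntry,
    SampleAnnotation,
)

__all__ = [
    "CohortConfig",
    "SimulatedTruth",
    "Cohort",
    "generate_module_catalog",
    "generate_cohort",
    "generate_longitudinal_series",
    "kd_effect_profile",
    "adv_effect_profile",
    "gas_effect_profile",
]


class ConfigError(ValueError):
    pass


# Annotation pool: the functional themes of the 62-module whole-blood
# framework, cycled over generated modules so every theme is represented.
_ANNOTATION_POOL = (
    "inflammation",
    "interferon",
    "platelets",
    "neutrophils",
    "apoptosis",
    "T cells",
    "B cells",
    "cytotoxic/NK cells",
    "lymphoid lineage",
    "monocytes",
    "plasma cells",
    "erythrocytes",
    "protein synthesis",
    "undetermined",
)

# Default group sizes mirror a three-cohort KD study design: a complete-KD
# training set, a complete-KD test set, an incomplete-KD validation set, the
# two febrile comparator groups, and matched healthy controls for each
# comparison.
_DEFAULT_GROUP_SIZES: dict[str, int] = {
    "cKD_training": 39,
    "HC_training": 16,
    "cKD_test": 37,
    "HC_test": 20,
    "inKD_validation": 13,
    "HC_validation": 8,
    "AdV": 19,
    "GAS": 17,
    "HC_febrile": 10,
}

_GROUP_OF = {
    "cKD_training": ("cKD", "training"),
    "HC_training": ("HC", "training"),
    "cKD_test": ("cKD", "test"),
    "HC_test": ("HC", "test"),
    "inKD_validation": ("inKD", "validation"),
    "HC_validation": ("HC", "validation"),
    "AdV": ("AdV", "none"),
    "GAS": ("GAS", "none"),
    "HC_febrile": ("HC", "none"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; defaults emulate the study design.

    ``effect_profile`` maps disease group -> {module_id: mean log2 shift};
    when ``None`` a Kawasaki-like profile (inflammation/platelets/neutrophils
    up, T/B/NK cells down) is derived from the generated catalog.
    """

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_GROUP_SIZES)
    )
    n_transcripts: int = 10_000
    n_modules: int = 62
    module_size_range: tuple[int, int] = (20, 100)
    effect_profile: Mapping[str, Mapping[str, float]] | None = None
    within_group_sd: float = 0.35
    baseline_mean_range: tuple[float, float] = (6.0, 14.0)
    baseline_sd_range: tuple[float, float] = (0.2, 0.6)
    nonresponder_fraction: float = 0.13
    nonresponder_inflation: float = 2.0
    scale_sigma: float = 0.4
    longitudinal_decay: tuple[float, float, float] = (1.0, 0.5, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        for k, v in self.n_per_group.items():
            if k not in _GROUP_OF:
                raise ConfigError(f"unknown group key {k!r}")
            if v < 0:
                raise ConfigError(f"negative count for {k!r}")
        if self.n_modules < 0 or self.n_transcripts < 0:
            raise ConfigError("counts must be >= 0")
        lo, hi = self.module_size_range
        if not (1 <= lo <= hi):
            raise ConfigError("invalid module_size_range")
        if self.within_group_sd <= 0 or self.scale_sigma <= 0:
            raise ConfigError("SDs must be > 0")
        if not (0.0 <= self.nonresponder_fraction <= 1.0):
            raise ConfigError("nonresponder_fraction must be in [0,1]")
        if self.nonresponder_inflation <= 0:
            raise ConfigError("nonresponder_inflation must be > 0")
        if any(d < 0 for d in self.longitudinal_decay):
            raise ConfigError("decay multipliers must be >= 0")
        if self.baseline_sd_range[0] <= 0:
            raise ConfigError("baseline SDs must be > 0")


@dataclass
class SimulatedTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests."""

    planted_de_transcripts: dict[str, float]  # transcript -> signed log2 effect (cKD)
    planted_module_directions: dict[str, str]  # module -> {"up","down","null"}
    per_patient_perturbation: dict[str, float]  # sample -> scale s_i (0 for HC)
    outcome_model: dict[str, float]  # logistic P(NR | log s) coefficients
    # internals reused by the longitudinal generator
    baseline_mean: np.ndarray = field(repr=False, default=None)
    baseline_sd: np.ndarray = field(repr=False, default=None)
    group_effects: dict[str, np.ndarray] = field(repr=False, default_factory=dict)


@dataclass
class Cohort:
    matrix: ExpressionMatrix
    annotations: list[SampleAnnotation]
    catalog: ModuleCatalog
    truth: SimulatedTruth


def _child_rng(seed: int, label: str) -> np.random.Generator:
    # stable named substreams off one master seed
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(abs(hash_label(label)),))
    )


def hash_label(label: str) -> int:
    # deterministic across processes (builtin hash is salted)
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % (2**31)
    return h


def _module_id(k: int) -> str:
    return f"M{1 + k // 10}.{1 + k % 10}"


def generate_module_catalog(
    config: CohortConfig, seed: int | None = None
) -> ModuleCatalog:
    """Partition the transcript universe into disjoint annotated modules."""
    if config.n_modules * config.module_size_range[1] > config.n_transcripts:
        raise ConfigError(
            "n_modules x max module size exceeds the transcript universe"
        )
    rng = _child_rng(config.seed if seed is None else seed, "catalog")
    n = config.n_transcripts
    transcript_ids = np.array([f"T{i:06d}" for i in range(n)])
    order = rng.permutation(n)
    lo, hi = config.module_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_modules)
    entries = []
    cursor = 0
    for k in range(config.n_modules):
        size = int(sizes[k])
        members = transcript_ids[order[cursor : cursor + size]]
        cursor += size
        entries.append(
            ModuleEntry(
                module_id=_module_id(k),
                annotation=_ANNOTATION_POOL[k % len(_ANNOTATION_POOL)],
                transcript_ids=frozenset(members.tolist()),
            )
        )
    return ModuleCatalog(entries=tuple(entries))


# ---------------------------------------------------------------------------
# Effect profiles


def _profile_by_annotation(
    catalog: ModuleCatalog, shifts: Mapping[str, float]
) -> dict[str, float]:
    return {
        e.module_id: shifts[e.annotation]
        for e in catalog
        if e.annotation in shifts and shifts[e.annotation] != 0.0
    }


def kd_effect_profile(catalog: ModuleCatalog) -> dict[str, float]:
    """Kawasaki-like fingerprint: innate/inflammatory modules over-expressed,
    adaptive and cytotoxic modules under-expressed."""
    return _profile_by_annotation(
        catalog,
        {
            "inflammation": 1.0,
            "platelets": 0.8,
            "neutrophils": 0.8,
            "apoptosis": 0.6,
            "T cells": -0.8,
            "B cells": -0.6,
            "cytotoxic/NK cells": -0.8,
            "lymphoid lineage": -0.6,
        },
    )


def adv_effect_profile(catalog: ModuleCatalog) -> dict[str, float]:
    """Adenovirus-like fingerprint: strong interferon and plasma-cell
    over-expression, milder inflammation."""
    return _profile_by_annotation(
        catalog,
        {
            "interferon": 1.2,
            "plasma cells": 0.8,
            "inflammation": 0.5,
            "neutrophils": 0.4,
            "T cells": -0.3,
            "cytotoxic/NK cells": -0.3,
        },
    )


def gas_effect_profile(catalog: ModuleCatalog) -> dict[str, float]:
    """Streptococcal fingerprint: moderate inflammation/neutrophils, shares
    direction with Kawasaki disease at lower magnitude."""
    return _profile_by_annotation(
        catalog,
        {
            "inflammation": 0.6,
            "neutrophils": 0.5,
            "T cells": -0.4,
            "cytotoxic/NK cells": -0.3,
        },
    )


def _default_profiles(catalog: ModuleCatalog) -> dict[str, dict[str, float]]:
    kd = kd_effect_profile(catalog)
    return {
        "cKD": kd,
        "inKD": dict(kd),
        "AdV": adv_effect_profile(catalog),
        "GAS": gas_effect_profile(catalog),
    }


# ---------------------------------------------------------------------------
# Cohort generation


def _effect_vector(
    profile: Mapping[str, float], catalog: ModuleCatalog, transcript_ids: Sequence[str]
) -> np.ndarray:
    idx = {t: i for i, t in enumerate(transcript_ids)}
    e = np.zeros(len(transcript_ids))
    for mid, shift in profile.items():
        for t in catalog.transcripts(mid):
            if t in idx:
                e[idx[t]] = shift
    return e


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cross-sectional cohort (all samples at the pre-treatment
    timepoint) with its module catalog and ground truth."""
    catalog = generate_module_catalog(config)
    n_t = config.n_transcripts
    transcript_ids = [f"T{i:06d}" for i in range(n_t)]

    rng_base = _child_rng(config.seed, "baseline")
    mu = rng_base.uniform(*config.baseline_mean_range, size=n_t)
    sd = rng_base.uniform(*config.baseline_sd_range, size=n_t)

    profiles = (
        _default_profiles(catalog)
        if config.effect_profile is None
        else {g: dict(p) for g, p in config.effect_profile.items()}
    )
    for g, prof in profiles.items():
        unknown = set(prof) - set(catalog.module_ids)
        if unknown:
            raise ConfigError(f"effect profile for {g!r} names unknown modules: {sorted(unknown)[:5]}")
    effects = {
        g: _effect_vector(prof, catalog, transcript_ids) for g, prof in profiles.items()
    }

    rng_scale = _child_rng(config.seed, "scales")
    rng_noise = _child_rng(config.seed, "noise")
    rng_clin = _child_rng(config.seed, "clinical")

    f = config.nonresponder_inflation
    sig = config.scale_sigma
    pi = config.nonresponder_fraction
    # P(NR | s) is logistic in log s (mixture of two lognormals, equal variance)
    if 0.0 < pi < 1.0 and f != 1.0:
        beta1 = math.log(f) / sig**2
        beta0 = math.log(pi / (1 - pi)) - beta1 * (math.log(f) / 2.0)
    else:
        beta1 = 0.0
        beta0 = math.log(pi / (1 - pi)) if 0.0 < pi < 1.0 else (-math.inf if pi == 0 else math.inf)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    annotations: list[SampleAnnotation] = []
    perturbation: dict[str, float] = {}

    for key in sorted(config.n_per_group):
        n = config.n_per_group[key]
        group, cohort = _GROUP_OF[key]
        for j in range(n):
            sid = f"{key}_{j + 1:03d}"
            is_hc = group == "HC"
            if is_hc:
                s_i = 0.0
                nr: bool | None = None
            else:
                nr_draw = bool(rng_scale.random() < pi)
                s_i = float(np.exp(rng_scale.normal(0.0, sig)))
                if nr_draw:
                    s_i *= f
                # IVIG outcomes only meaningful for Kawasaki groups
                nr = nr_draw if group in ("cKD", "inKD") else None
            e = effects.get(group, np.zeros(n_t)) if not is_hc else None
            x = mu + rng_noise.normal(0.0, 1.0, size=n_t) * sd
            if not is_hc:
                x = x + s_i * e + rng_noise.normal(0.0, config.within_group_sd, size=n_t)
            rows.append(x)
            sample_ids.append(sid)
            perturbation[sid] = s_i

            age = float(np.exp(rng_clin.normal(math.log(46.0), 0.5)))
            sex = "M" if rng_clin.random() < 0.57 else "F"
            if is_hc:
                ann = SampleAnnotation(
                    sample_id=sid, group=group, cohort=cohort, timepoint="pre",
                    age_months=round(age, 1), sex=sex,
                )
            else:
                z_s = math.log(s_i) / sig
                # CRP weakly coupled to perturbation; days of fever weakly inverse
                crp = max(0.1, 11.0 + 5.0 * (0.3 * z_s + math.sqrt(1 - 0.09) * rng_clin.normal()))
                fever = min(10.0, max(3.0, round(6.0 - 0.5 * z_s + 1.5 * rng_clin.normal())))
                alb = max(1.5, rng_clin.normal(3.3, 0.4))
                caa = bool(rng_clin.random() < 0.15) if group in ("cKD", "inKD") else None
                ann = SampleAnnotation(
                    sample_id=sid, group=group, cohort=cohort, timepoint="pre",
                    age_months=round(age, 1), sex=sex, days_fever=fever,
                    crp_mg_dl=round(crp, 1), albumin_g_dl=round(alb, 2),
                    ivig_nonresponse=nr, caa=caa,
                )
            annotations.append(ann)

    data = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, n_t)),
                        index=sample_ids, columns=transcript_ids)
    matrix = ExpressionMatrix(data, scale="log2")

    kd_effect = effects.get("cKD", np.zeros(n_t))
    planted = {
        t: float(kd_effect[i]) for i, t in enumerate(transcript_ids) if kd_effect[i] != 0.0
    }
    directions = {}
    kd_profile = profiles.get("cKD", {})
    for e in catalog:
        shift = kd_profile.get(e.module_id, 0.0)
        directions[e.module_id] = "up" if shift > 0 else ("down" if shift < 0 else "null")

    truth = SimulatedTruth(
        planted_de_transcripts=planted,
        planted_module_directions=directions,
        per_patient_perturbation=perturbation,
        outcome_model={"intercept": beta0, "log_scale": beta1},
        baseline_mean=mu,
        baseline_sd=sd,
        group_effects=effects,
    )
    return Cohort(matrix=matrix, annotations=annotations, catalog=catalog, truth=truth)


def generate_longitudinal_series(
    config: CohortConfig,
    cohort: Cohort,
    per_patient_decay: Mapping[str, Sequence[float]] | None = None,
) -> tuple[ExpressionMatrix, list[SampleAnnotation]]:
    """Draw 24h-post-IVIG and convalescent samples for the Kawasaki patients.

    Each later timepoint multiplies the patient's perturbation scale by the
    corresponding ``longitudinal_decay`` entry (the first entry is the
    pre-treatment multiplier and is not re-drawn).  ``per_patient_decay``
    overrides the decay schedule for named samples — e.g. a treatment
    non-responder whose perturbation grows at 24 h.
    """
    kd = [a for a in cohort.annotations if a.group in ("cKD", "inKD")]
    if not kd:
        raise ConfigError("base cohort contains no Kawasaki samples")
    truth = cohort.truth
    n_t = len(truth.baseline_mean)
    rng = _child_rng(config.seed, "longitudinal")
    suffix = {"post24h": "_24h", "convalescent": "_conv"}
    rows, ids, anns = [], [], []
    timepoints = ("post24h", "convalescent")
    for a in kd:
        e = truth.group_effects.get(a.group)
        s_i = truth.per_patient_perturbation[a.sample_id]
        decays = (
            per_patient_decay[a.sample_id]
            if per_patient_decay and a.sample_id in per_patient_decay
            else config.longitudinal_decay
        )
        for t_idx, tp in enumerate(timepoints, start=1):
            d = decays[t_idx]
            x = (
                truth.baseline_mean
                + rng.normal(0.0, 1.0, size=n_t) * truth.baseline_sd
                + (s_i * d) * e
                + rng.normal(0.0, config.within_group_sd, size=n_t)
            )
            sid = a.sample_id + suffix[tp]
            rows.append(x)
            ids.append(sid)
            anns.append(
                replace(a, sample_id=sid, timepoint=tp, patient_id=a.patient_id)
            )
    data = pd.DataFrame(
        np.vstack(rows), index=ids, columns=cohort.matrix.transcript_ids
    )
    return ExpressionMatrix(data, scale="log2"), anns
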