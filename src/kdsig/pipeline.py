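"""End-to-end pipeline orchestration.

Runs the study workflow — synthesize (or load) a cohort, normalize + QC
filter, derive the DE signature, module fingerprints, KNN classification,
MDTH scoring, and outcome analysis — writing each stage's artifacts plus a
manifest (parameters, seed, SHA-256 checksums) so a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import mdth as mdth_mod
from . import outcomes as out_mod
from .core import (
    ExpressionMatrix,
    annotation_frame,
    write_expression_matrix,
    write_module_catalog,
    write_sample_annotation,
)
from .fingerprint import compare_fingerprints, fingerprint
from .preprocess import QcFilterParams, normalize_median_scale, qc_filter_transcripts
from .signature import derive_signature, hierarchical_cluster
from .synth import Cohort, CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "STAGES", "STAGE_DEPS"]

STAGES = ("synth", "preprocess", "signature", "fingerprint", "classify", "mdth", "outcomes")

STAGE_DEPS: dict[str, tuple[str, ...]] = {
    "synth": (),
    "preprocess": ("synth",),
    "signature": ("preprocess",),
    "fingerprint": ("signature",),
    "classify": ("preprocess",),
    "mdth": ("preprocess",),
    "outcomes": ("mdth",),
}


class DependencyError(RuntimeError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig | None = None
    qc: QcFilterParams = field(default_factory=QcFilterParams)
    alpha: float = 0.01
    fc: float = 1.25
    knn: cls.KnnConfig = field(default_factory=cls.KnnConfig)
    max_classifier_genes: int = 20
    mdth_universe: str = "qc"  # "qc" | "signature" | "all"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        enabled = set(self.stages)
        for s in self.stages:
            missing = set(STAGE_DEPS[s]) - enabled
            if missing:
                raise DependencyError(
                    f"stage {s!r} requires disabled prerequisite(s): {sorted(missing)}"
                )
        if self.cohort is None:
            self.cohort = CohortConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict[str, Any] = {}
        for key in ("outdir", "seed", "alpha", "fc", "max_classifier_genes", "mdth_universe"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        if "cohort" in raw:
            c = dict(raw["cohort"])
            for tup in ("module_size_range", "baseline_mean_range",
                        "baseline_sd_range", "longitudinal_decay"):
                if tup in c:
                    c[tup] = tuple(c[tup])
            kwargs["cohort"] = CohortConfig(**c)
        if "qc" in raw:
            kwargs["qc"] = QcFilterParams(**raw["qc"])
        if "knn" in raw:
            kwargs["knn"] = cls.KnnConfig(**raw["knn"])
        return cls_(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _params_dict(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _params_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_params_dict(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _ids(annotations, group: str | None = None, cohort: str | None = None,
         timepoint: str = "pre") -> list[str]:
    return [
        a.sample_id
        for a in annotations
        if (group is None or a.group == group)
        and (cohort is None or a.cohort == cohort)
        and a.timepoint == timepoint
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"seed": config.seed, "stages": {}}
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    state: dict[str, Any] = {}

    for stage in config.stages:
        runner = _RUNNERS[stage]
        artifacts: dict[str, str] = {}
        try:
            counts = runner(config, state, outdir, artifacts)
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
        params = _stage_params(config, stage)
        report["stages"][stage] = {"status": "completed", "counts": counts}
        manifest["stages"][stage] = {
            "status": "completed",
            "params": _params_dict(params),
            "counts": counts,
            "artifacts": artifacts,
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report["manifest"] = str(outdir / "manifest.json")
    return report


def _stage_params(config: PipelineConfig, stage: str) -> Any:
    return {
        "synth": config.cohort,
        "preprocess": config.qc,
        "signature": {"alpha": config.alpha, "fc": config.fc},
        "fingerprint": {"alpha": config.alpha},
        "classify": {"knn": config.knn, "max_genes": config.max_classifier_genes},
        "mdth": {"universe": config.mdth_universe},
        "outcomes": {},
    }[stage]


def _write(df: pd.DataFrame, path: Path, artifacts: dict[str, str], **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), float_format="%.6g")
    artifacts[path.name] = _sha256(path)


def _run_synth(config, state, outdir, artifacts):
    cohort: Cohort = generate_cohort(config.cohort)
    state["cohort"] = cohort
    mpath = outdir / "expression.tsv"
    write_expression_matrix(cohort.matrix, mpath)
    artifacts[mpath.name] = _sha256(mpath)
    apath = outdir / "annotations.csv"
    write_sample_annotation(cohort.annotations, apath)
    artifacts[apath.name] = _sha256(apath)
    cpath = outdir / "modules.csv"
    write_module_catalog(cohort.catalog, cpath)
    artifacts[cpath.name] = _sha256(cpath)
    return {
        "n_samples": len(cohort.matrix.sample_ids),
        "n_transcripts": len(cohort.matrix.transcript_ids),
        "n_modules": len(cohort.catalog),
    }


def _run_preprocess(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    norm = normalize_median_scale(cohort.matrix)
    kept = qc_filter_transcripts(norm, config.qc)
    state["normalized"] = norm
    state["qc_transcripts"] = kept
    path = outdir / "qc_transcripts.txt"
    path.write_text("\n".join(kept) + ("\n" if kept else ""))
    artifacts[path.name] = _sha256(path)
    return {"n_kept": len(kept), "n_input": len(norm.transcript_ids)}


def _run_signature(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    ann = cohort.annotations
    m = state["normalized"].subset(transcripts=state["qc_transcripts"])
    patients = _ids(ann, "cKD", "training")
    controls = _ids(ann, "HC", "training")
    sig = derive_signature(m, patients, controls, config.alpha, config.fc)
    state["signature"] = sig
    _write(sig.to_frame(), outdir / "signature_stats.tsv", artifacts)
    counts = {"n_selected": len(sig.selected), "n_over": sig.n_over, "n_under": sig.n_under}
    test_ids = _ids(ann, "cKD", "test") + _ids(ann, "HC", "test")
    if sig.selected and len(test_ids) >= 2:
        dend = hierarchical_cluster(
            m.subset(samples=test_ids), sig.selected, _ids(ann, "cKD", "test")
        )
        counts["test_set_purity"] = dend.purity
    return counts


def _run_fingerprint(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    ann = cohort.annotations
    m = state["normalized"]
    fps = {}
    for name, (grp, coh, ctl_grp, ctl_coh) in {
        "training": ("cKD", "training", "HC", "training"),
        "test": ("cKD", "test", "HC", "test"),
        "inKD": ("inKD", "validation", "HC", "validation"),
    }.items():
        patients = _ids(ann, grp, coh)
        controls = _ids(ann, ctl_grp, ctl_coh)
        if patients and controls:
            fps[name] = fingerprint(m, patients, controls, cohort.catalog, config.alpha)
    state["fingerprints"] = fps
    rows = []
    for name, fp in fps.items():
        for s in fp:
            rows.append({"cohort": name, "module_id": s.module_id,
                         "annotation": s.annotation, "pct_over": s.pct_over,
                         "pct_under": s.pct_under, "n": s.n_transcripts})
    _write(pd.DataFrame(rows), outdir / "fingerprints.tsv", artifacts)
    counts = {name: sum(1 for s in fp if s.significant) for name, fp in fps.items()}
    if "training" in fps and "test" in fps:
        rho, _ = compare_fingerprints(fps["training"], fps["test"])
        counts["rho_training_test"] = rho
    if "training" in fps and "inKD" in fps:
        rho, _ = compare_fingerprints(fps["training"], fps["inKD"])
        counts["rho_training_inKD"] = rho
    return counts


def _run_classify(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    ann = cohort.annotations
    m = state["normalized"].subset(transcripts=state["qc_transcripts"])
    kd = _ids(ann, "cKD", "training")
    adv = _ids(ann, "AdV")
    labels = {s: "cKD" for s in kd} | {s: "AdV" for s in adv}
    model = cls.select_classifier_genes(
        m.subset(samples=sorted(labels)), labels, config.knn, config.max_classifier_genes
    )
    confusion = cls.loocv_confusion(
        m.subset(samples=sorted(labels)), labels, model.classifier_genes, config.knn
    )
    perf = cls.performance_metrics(confusion, positive_class="cKD")
    state["classifier"] = model
    (outdir / "classifier_model.json").write_text(
        json.dumps(model.to_json_dict(), indent=2, sort_keys=True)
    )
    artifacts["classifier_model.json"] = _sha256(outdir / "classifier_model.json")
    return {
        "n_classifier_genes": len(model.classifier_genes),
        "loocv_sensitivity": perf.sensitivity,
        "loocv_specificity": perf.specificity,
        "loocv_accuracy": perf.accuracy,
    }


def _run_mdth(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    ann = cohort.annotations
    m = state["normalized"]
    if config.mdth_universe == "qc":
        universe = state["qc_transcripts"]
    elif config.mdth_universe == "signature":
        universe = list(state["signature"].selected)
    else:
        universe = m.transcript_ids
    controls = _ids(ann, "HC", "training") + _ids(ann, "HC", "test")
    ref = mdth_mod.build_control_reference(m, controls, universe)
    kd_pre = [a.sample_id for a in ann if a.group in ("cKD", "inKD") and a.timepoint == "pre"]
    result = mdth_mod.mdth_score_matrix(m.subset(samples=kd_pre), ref)
    state["mdth"] = result
    state["mdth_ref"] = ref
    df = pd.DataFrame(
        [
            {"sample_id": s, "mdth": e.score, "n_perturbed": e.n_perturbed}
            for s, e in result.per_sample.items()
        ]
    )
    _write(df, outdir / "mdth_scores.tsv", artifacts)
    return {
        "n_scored": len(result.per_sample),
        "median_mdth": float(np.median([e.score for e in result.per_sample.values()])),
        "universe_size": len(ref.transcript_ids),
    }


def _run_outcomes(config, state, outdir, artifacts):
    cohort: Cohort = state["cohort"]
    ann_by_id = {a.sample_id: a for a in cohort.annotations}
    scores = state["mdth"].scores()
    rows = []
    for sid, score in scores.items():
        a = ann_by_id[sid]
        if a.ivig_nonresponse is None:
            continue
        rows.append(
            {"sample_id": sid, "mdth": score, "nr": int(a.ivig_nonresponse),
             "age_months": a.age_months, "crp": a.crp_mg_dl,
             "days_fever": a.days_fever}
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    counts: dict[str, Any] = {"n": len(df)}
    if df["nr"].nunique() == 2:
        roc = out_mod.roc_auc(df["mdth"].to_numpy(), df["nr"].to_numpy())
        thr, sens, spec = out_mod.youden_threshold(roc)
        counts |= {"auc": roc.auc, "youden_threshold": thr, "J": roc.J}
        try:
            fit = out_mod.logistic_regression(
                df["nr"], df[["mdth", "age_months"]], scaling={"mdth": 1000.0},
                outcome_name="ivig_nonresponse",
            )
            counts["or_mdth_per_1000"] = fit.effect("mdth").odds_ratio
        except out_mod.SeparationError:
            counts["or_mdth_per_1000"] = None
        rho, p = out_mod.spearman_corr(df["mdth"], df["crp"])
        counts["rho_mdth_crp"] = rho
    _write(df.reset_index(), outdir / "outcomes_input.tsv", artifacts)
    (outdir / "outcomes.json").write_text(json.dumps(counts, indent=2, sort_keys=True))
    artifacts["outcomes.json"] = _sha256(outdir / "outcomes.json")
    return counts


_RUNNERS = {
    "synth": _run_synth,
    "preprocess": _run_preprocess,
    "signature": _run_signature,
    "fingerprint": _run_fingerprint,
    "classify": _run_classify,
    "mdth": _run_mdth,
    "outcomes": _run_outcomes,
}
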