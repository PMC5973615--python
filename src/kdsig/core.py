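"""Core data containers and plain-text I/O.

The pipeline's central object is an :class:`ExpressionMatrix` — a samples ×
transcripts grid of microarray intensities.  The canonical in-memory scale is
log2: linear input (the usual scanner-software export) is transformed at load
so that fold changes and control-baseline standard deviations are computed
consistently downstream.

On disk the matrix follows the GEO convention (transcripts as rows, samples
as columns, tab-delimited); in memory it is samples-major (a pandas DataFrame
indexed by sample).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "ModuleCatalog",
    "ModuleEntry",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_module_catalog",
    "write_module_catalog",
    "read_sample_annotation",
    "write_sample_annotation",
    "annotation_frame",
]

Scale = Literal["linear", "log2"]

GROUPS = ("cKD", "inKD", "AdV", "GAS", "HC")
COHORTS = ("training", "test", "validation", "none")
TIMEPOINTS = ("pre", "post24h", "convalescent")


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Samples × transcripts intensity grid.

    Parameters
    ----------
    data
        DataFrame indexed by sample ID with transcript IDs as columns.
    scale
        ``"log2"`` (canonical) or ``"linear"``.  Linear values must be
        strictly positive.
    """

    data: pd.DataFrame
    scale: Scale = "log2"

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample ID: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate transcript ID: {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if values.size and not np.isfinite(values).all():
            raise ValidationError("expression values must be finite (no NaN/Inf)")
        if self.scale == "linear" and values.size and (values <= 0).any():
            raise ValidationError("linear-scale intensities must be > 0")
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def to_log2(self) -> "ExpressionMatrix":
        if self.scale == "log2":
            return self
        return ExpressionMatrix(np.log2(self.data), scale="log2")

    def subset(
        self,
        samples: Sequence[str] | None = None,
        transcripts: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        df = self.data
        if samples is not None:
            missing = set(samples) - set(df.index)
            if missing:
                raise KeyError(f"unknown sample IDs: {sorted(missing)[:5]}")
            df = df.loc[list(samples)]
        if transcripts is not None:
            missing = set(transcripts) - set(df.columns)
            if missing:
                raise KeyError(f"unknown transcript IDs: {sorted(missing)[:5]}")
            df = df[list(transcripts)]
        return ExpressionMatrix(df, scale=self.scale)

    def __eq__(self, other: object) -> bool:  # value equality, used in tests
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return (
            self.scale == other.scale
            and self.data.index.equals(other.data.index)
            and self.data.columns.equals(other.data.columns)
            and np.allclose(self.values, other.values, rtol=1e-6, atol=0)
        )


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


@dataclass
class SampleAnnotation:
    """Per-sample clinical and design metadata.

    Clinical covariates are ``None`` when missing; they are never imputed.
    Healthy controls carry no treatment-outcome fields.
    """

    sample_id: str
    group: str
    cohort: str = "none"
    timepoint: str = "pre"
    age_months: float | None = None
    sex: str | None = None
    days_fever: float | None = None
    crp_mg_dl: float | None = None
    albumin_g_dl: float | None = None
    ivig_nonresponse: bool | None = None
    caa: bool | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.group == "HC" and not (
            _missing(self.ivig_nonresponse) and _missing(self.caa)
        ):
            raise ValidationError(
                f"healthy control {self.sample_id!r} cannot carry IVIG/CAA outcomes"
            )
        if self.patient_id is None:
            self.patient_id = self.sample_id


def annotation_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    """Tabulate annotations as a DataFrame indexed by sample_id."""
    rows = [
        {f.name: getattr(a, f.name) for f in fields(SampleAnnotation)}
        for a in annotations
    ]
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("sample_id", drop=False)
    return df


def validate_annotations(
    matrix: ExpressionMatrix, annotations: Sequence[SampleAnnotation]
) -> None:
    """Every sample in the matrix must be annotated exactly once."""
    ids = [a.sample_id for a in annotations]
    if len(ids) != len(set(ids)):
        raise ValidationError("duplicate sample_id in annotations")
    missing = set(matrix.sample_ids) - set(ids)
    if missing:
        raise ValidationError(f"unannotated samples: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class ModuleEntry:
    module_id: str
    annotation: str
    transcript_ids: frozenset[str]


@dataclass(frozen=True)
class ModuleCatalog:
    """Mapping of transcriptional-module IDs (e.g. ``"M3.2"``) to transcript sets.

    By default a transcript may belong to at most one module (the modular
    framework treats modules as a partition of co-expressed transcripts);
    readers expose a policy switch for catalogs that violate this.
    """

    entries: tuple[ModuleEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.module_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate module IDs in catalog")
        for e in self.entries:
            if not e.transcript_ids:
                raise ValidationError(f"module {e.module_id!r} has no transcripts")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def module_ids(self) -> list[str]:
        return [e.module_id for e in self.entries]

    def transcripts(self, module_id: str) -> frozenset[str]:
        for e in self.entries:
            if e.module_id == module_id:
                return e.transcript_ids
        raise KeyError(module_id)

    def annotation(self, module_id: str) -> str:
        for e in self.entries:
            if e.module_id == module_id:
                return e.annotation
        raise KeyError(module_id)

    def all_transcripts(self) -> set[str]:
        out: set[str] = set()
        for e in self.entries:
            out |= e.transcript_ids
        return out


# ---------------------------------------------------------------------------
# Expression-matrix I/O


def read_expression_matrix(
    path: str | Path,
    dialect: Literal["tsv", "geo_series_matrix"] = "tsv",
    scale: Scale = "log2",
) -> ExpressionMatrix:
    """Read a transcripts-rows × samples-columns matrix.

    ``tsv``: header row of sample IDs, first column of transcript IDs.
    ``geo_series_matrix``: the GEO series-matrix text dialect — ``!``-prefixed
    metadata lines are skipped and the ``ID_REF`` column supplies the
    transcript axis.

    ``scale`` declares the on-disk scale; linear input is log2-transformed so
    the returned matrix is always on the canonical log2 scale.
    """
    path = Path(path)
    if dialect == "tsv":
        text = path.read_text()
    elif dialect == "geo_series_matrix":
        kept = [
            line
            for line in path.read_text().splitlines()
            if line.strip() and not line.startswith("!")
        ]
        text = "\n".join(kept)
        if not kept:
            raise ValidationError(f"{path}: no data lines in series matrix")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0)
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"{path}: malformed matrix file: {exc}") from exc
    if df.index.name is not None and df.index.name.strip('"') == "ID_REF":
        df.index.name = "ID_REF"
    # strip quoting that GEO series matrices apply to identifiers
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
    if len(bad):
        # locate the first offending line for the error message
        for lineno, line in enumerate(text.splitlines()[1:], start=2):
            cells = line.split("\t")
            for cell in cells[1:]:
                try:
                    float(cell.strip('"'))
                except ValueError:
                    raise ValidationError(
                        f"{path}: non-numeric value {cell!r} at line {lineno}"
                    ) from None
        raise ValidationError(f"{path}: non-numeric column {bad[0]!r}")
    if df.isna().to_numpy().any():
        raise ValidationError(f"{path}: matrix contains missing values")
    m = ExpressionMatrix(df.T, scale=scale)
    return m.to_log2()


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write transcripts-rows TSV; 9 significant digits keep the round trip
    well inside 1e-6 relative tolerance."""
    path = Path(path)
    df = m.to_log2().data.T
    df.index.name = "transcript_id"
    df.to_csv(path, sep="\t", float_format="%.9g")


# ---------------------------------------------------------------------------
# Annotation I/O

_BOOL = {"True": True, "False": False, "true": True, "false": False, "1": True, "0": False}


def write_sample_annotation(
    annotations: Sequence[SampleAnnotation], path: str | Path
) -> None:
    annotation_frame(annotations).to_csv(path, index=False)


def read_sample_annotation(path: str | Path) -> list[SampleAnnotation]:
    out: list[SampleAnnotation] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            kwargs: dict = {}
            for f in fields(SampleAnnotation):
                raw = row.get(f.name, "")
                if raw is None or raw == "":
                    continue
                if f.name in ("ivig_nonresponse", "caa"):
                    kwargs[f.name] = _BOOL[raw]
                elif f.name in (
                    "age_months",
                    "days_fever",
                    "crp_mg_dl",
                    "albumin_g_dl",
                ):
                    kwargs[f.name] = float(raw)
                else:
                    kwargs[f.name] = raw
            out.append(SampleAnnotation(**kwargs))
    return out


# ---------------------------------------------------------------------------
# Module-catalog I/O


def read_module_catalog(
    path: str | Path,
    duplicate_policy: Literal["error", "first"] = "error",
) -> ModuleCatalog:
    """Read a module catalog.

    Two layouts are accepted, distinguished by the header:

    * long — columns ``module_id, transcript_id[, annotation]``, one row per
      (module, transcript) pair;
    * grouped — columns ``module_id, annotation, transcript_ids`` with the
      transcript set ``;``-separated.

    Repeats of the same (module, transcript) row are deduplicated.  A
    transcript assigned to two different modules is rejected under the default
    policy; ``duplicate_policy="first"`` keeps the first assignment.
    """
    path = Path(path)
    modules: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    seen: dict[str, str] = {}  # transcript -> module
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return ModuleCatalog(entries=())
        grouped = "transcript_ids" in reader.fieldnames
        for lineno, row in enumerate(reader, start=2):
            mid = row["module_id"].strip()
            label = (row.get("annotation") or "").strip()
            if grouped:
                tids = [t.strip() for t in row["transcript_ids"].split(";") if t.strip()]
            else:
                tids = [row["transcript_id"].strip()]
            modules.setdefault(mid, set())
            if label:
                labels[mid] = label
            for tid in tids:
                owner = seen.get(tid)
                if owner is not None and owner != mid:
                    if duplicate_policy == "error":
                        raise ValidationError(
                            f"{path}:{lineno}: transcript {tid!r} assigned to both "
                            f"{owner!r} and {mid!r}"
                        )
                    continue  # keep first assignment
                seen[tid] = mid
                modules[mid].add(tid)
    entries = tuple(
        ModuleEntry(mid, labels.get(mid, ""), frozenset(tids))
        for mid, tids in modules.items()
        if tids
    )
    dropped = set(modules) - {e.module_id for e in entries}
    if dropped:
        warnings.warn(f"modules with no transcripts dropped: {sorted(dropped)}")
    return ModuleCatalog(entries=entries)


def write_module_catalog(catalog: ModuleCatalog, path: str | Path) -> None:
    """Write the long (one row per module–transcript pair) layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["module_id", "transcript_id", "annotation"])
        for e in catalog:
            for tid in sorted(e.transcript_ids):
                writer.writerow([e.module_id, tid, e.annotation])
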