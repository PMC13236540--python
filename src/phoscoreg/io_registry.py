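"""Data model, dataset registry, and tabular readers/writers.

A corpus is a collection of *datasets*, each belonging to one study and one
experimental condition.  Datasets are either *differential* (test-vs-control
fold changes per phosphosite) or *profiling* (qualitative catalogues of
detected phosphosites).  Everything downstream — regulation calling,
frequency ranking, co-occurrence and co-regulation statistics — consumes the
:class:`Registry` built here.

Canonical tab-separated schemas (header mandatory, UTF-8, ``.`` or empty
cell = missing):

differential
    dataset_id, study_id, condition_id, gene_symbol, uniprot_acc, residue,
    position, fold_change, p_value, localization_probability, a_score,
    cell_context, disease_label

profiling
    as above minus fold_change / p_value

Foreign tables are adapted with a *dialect*: a ``{foreign_name:
canonical_name}`` rename map applied before validation.  Gene symbols are
uppercased on ingest; positions are 1-based coordinates on whatever
reference sequence the user's tables declare — no isoform remapping is
attempted.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_RESIDUES = frozenset({"S", "T", "Y"})

#: Mandatory columns for a differential table (before considering dialect).
DIFFERENTIAL_REQUIRED = (
    "dataset_id",
    "study_id",
    "condition_id",
    "gene_symbol",
    "residue",
    "position",
    "fold_change",
)
#: Mandatory columns for a profiling table.
PROFILING_REQUIRED = (
    "dataset_id",
    "study_id",
    "condition_id",
    "gene_symbol",
    "residue",
    "position",
)
DIFFERENTIAL_OPTIONAL = (
    "uniprot_acc",
    "p_value",
    "localization_probability",
    "a_score",
    "cell_context",
    "disease_label",
)
PROFILING_OPTIONAL = (
    "uniprot_acc",
    "localization_probability",
    "a_score",
    "cell_context",
    "disease_label",
)

MEASUREMENT_COLUMNS = [
    "dataset_id",
    "gene_symbol",
    "uniprot_acc",
    "residue",
    "position",
    "fold_change",
    "p_value",
    "localization_probability",
    "a_score",
]
DETECTION_COLUMNS = [
    "dataset_id",
    "gene_symbol",
    "uniprot_acc",
    "residue",
    "position",
    "localization_probability",
    "a_score",
]


class FormatError(ValueError):
    """A table does not conform to the canonical schema (e.g. missing column)."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


class RegistryMergeError(ValueError):
    """Two registry fragments disagree about the same dataset_id."""


class UsageError(ValueError):
    """An operation was invoked with inconsistent arguments."""


@dataclass(frozen=True)
class SiteKey:
    """Identity of one phosphosite.

    Equality and hashing use (gene_symbol, residue, position) only; the
    UniProt accession is annotation, not identity.
    """

    gene_symbol: str
    residue: str
    position: int
    uniprot_acc: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.residue not in VALID_RESIDUES:
            raise ValidationError(
                f"residue must be one of S/T/Y, got {self.residue!r}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.gene_symbol}:{self.residue}{self.position}"

    @classmethod
    def parse(cls, text: str) -> "SiteKey":
        """Parse ``GENE:S123`` (or ``GENE:S123@P10636``) back into a SiteKey."""
        acc = None
        if "@" in text:
            text, acc = text.rsplit("@", 1)
        gene, _, sitepart = text.rpartition(":")
        if not gene or len(sitepart) < 2:
            raise ValidationError(f"cannot parse site string {text!r}")
        return cls(
            gene_symbol=gene.upper(),
            residue=sitepart[0].upper(),
            position=int(sitepart[1:]),
            uniprot_acc=acc,
        )


@dataclass(frozen=True)
class DatasetMeta:
    dataset_id: str
    study_id: str
    condition_id: str
    dataset_kind: str  # "profiling" | "differential"
    cell_context: str | None = None
    disease_label: str | None = None

    def __post_init__(self) -> None:
        if self.dataset_kind not in ("profiling", "differential"):
            raise ValidationError(
                f"dataset_kind must be profiling/differential, got {self.dataset_kind!r}"
            )


@dataclass(frozen=True)
class ParseIssue:
    """One rejected or suspicious input row; rows are reported, never silently dropped."""

    path: str
    row: int  # 1-based data-row index (header excluded)
    message: str


@dataclass
class Registry:
    """A consistent corpus: dataset metadata plus measurement/detection tables.

    ``measurements`` and ``detections`` are pandas DataFrames with the
    MEASUREMENT_COLUMNS / DETECTION_COLUMNS schemas; every dataset_id they
    mention exists in ``datasets`` with the matching kind.
    """

    datasets: dict[str, DatasetMeta] = field(default_factory=dict)
    measurements: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=MEASUREMENT_COLUMNS)
    )
    detections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=DETECTION_COLUMNS)
    )
    issues: list[ParseIssue] = field(default_factory=list)

    def differential_ids(self) -> list[str]:
        return sorted(
            d for d, m in self.datasets.items() if m.dataset_kind == "differential"
        )

    def profiling_ids(self) -> list[str]:
        return sorted(
            d for d, m in self.datasets.items() if m.dataset_kind == "profiling"
        )

    def validate(self) -> None:
        """Raise ValidationError if any cross-table invariant is broken."""
        for frame, kind in ((self.measurements, "differential"), (self.detections, "profiling")):
            for ds in frame["dataset_id"].unique():
                meta = self.datasets.get(ds)
                if meta is None:
                    raise ValidationError(f"dataset_id {ds!r} not registered")
                if meta.dataset_kind != kind:
                    raise ValidationError(
                        f"dataset {ds!r} is {meta.dataset_kind}, expected {kind}"
                    )
        if len(self.measurements) and (self.measurements["fold_change"] <= 0).any():
            raise ValidationError("non-positive fold_change in measurements")


# ---------------------------------------------------------------------------
# readers


_MISSING = {"", ".", "na", "nan", "NA", "NaN", "None"}


def _clean(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    text = str(value).strip()
    return None if text in _MISSING else text


def _coerce_float(text: str | None, name: str, lo=None, hi=None):
    if text is None:
        return None
    try:
        value = float(text)
    except ValueError as exc:
        raise ValidationError(f"{name} {text!r} is not a number") from exc
    if lo is not None and value < lo:
        raise ValidationError(f"{name} {value} < {lo}")
    if hi is not None and value > hi:
        raise ValidationError(f"{name} {value} > {hi}")
    return value


def _read_raw(path, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect:
        raw = raw.rename(columns=dict(dialect))
    return raw


def _ingest(
    path,
    dialect: Mapping[str, str] | None,
    required: Sequence[str],
    kind: str,
) -> Registry:
    raw = _read_raw(path, dialect)
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    differential = kind == "differential"
    rows: list[dict] = []
    issues: list[ParseIssue] = []
    metas: dict[str, DatasetMeta] = {}
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        get = lambda col: _clean(rec.get(col))  # noqa: E731
        try:
            dataset_id = get("dataset_id")
            study_id = get("study_id")
            condition_id = get("condition_id")
            gene = get("gene_symbol")
            residue = get("residue")
            pos_text = get("position")
            if not all((dataset_id, study_id, condition_id, gene, residue, pos_text)):
                raise ValidationError("missing identity field")
            gene = gene.upper()
            residue = residue.upper()
            if residue not in VALID_RESIDUES:
                raise ValidationError(f"residue {residue!r} not in S/T/Y")
            try:
                position = int(pos_text)
            except ValueError as exc:
                raise ValidationError(f"position {pos_text!r} is not an integer") from exc
            if position < 1:
                raise ValidationError(f"position {position} < 1")
            meta = DatasetMeta(
                dataset_id=dataset_id,
                study_id=study_id,
                condition_id=condition_id,
                dataset_kind=kind,
                cell_context=get("cell_context"),
                disease_label=get("disease_label"),
            )
            prior = metas.get(dataset_id)
            if prior is not None and prior != meta:
                raise ValidationError(
                    f"conflicting metadata for dataset {dataset_id!r}"
                )
            row = {
                "dataset_id": dataset_id,
                "gene_symbol": gene,
                "uniprot_acc": get("uniprot_acc"),
                "residue": residue,
                "position": position,
                "localization_probability": _coerce_float(
                    get("localization_probability"), "localization_probability", 0.0, 1.0
                ),
                "a_score": _coerce_float(get("a_score"), "a_score", 0.0),
            }
            if differential:
                fc = _coerce_float(get("fold_change"), "fold_change")
                if fc is None:
                    raise ValidationError("fold_change missing")
                if fc <= 0:
                    raise ValidationError(f"fold_change {fc} is not positive")
                row["fold_change"] = fc
                row["p_value"] = _coerce_float(get("p_value"), "p_value", 0.0, 1.0)
        except ValidationError as exc:
            issues.append(ParseIssue(path=str(path), row=i, message=str(exc)))
            continue
        metas.setdefault(dataset_id, meta)
        rows.append(row)

    columns = MEASUREMENT_COLUMNS if differential else DETECTION_COLUMNS
    frame = pd.DataFrame(rows, columns=columns)
    if not differential and len(frame):
        before = len(frame)
        frame = frame.drop_duplicates(
            subset=["dataset_id", "gene_symbol", "residue", "position"]
        ).reset_index(drop=True)
        dropped = before - len(frame)
        if dropped:
            issues.append(
                ParseIssue(
                    path=str(path),
                    row=0,
                    message=f"{dropped} duplicate detection row(s) collapsed",
                )
            )
    reg = Registry(datasets=metas, issues=issues)
    if differential:
        reg.measurements = frame
    else:
        reg.detections = frame
    return reg


def read_differential_table(path, dialect: Mapping[str, str] | None = None) -> Registry:
    """Read a differential (fold-change) site table into a registry fragment.

    Rows that fail type coercion or violate invariants (e.g. fold_change <= 0)
    are recorded in ``Registry.issues`` and excluded; valid rows are kept.
    A missing mandatory column raises :class:`FormatError`.
    """
    return _ingest(path, dialect, DIFFERENTIAL_REQUIRED, "differential")


def read_profiling_table(path, dialect: Mapping[str, str] | None = None) -> Registry:
    """Read a profiling (qualitative detection) table into a registry fragment.

    Duplicate (dataset, site) rows collapse to one detection with a logged
    issue — detections are set-valued evidence.
    """
    return _ingest(path, dialect, PROFILING_REQUIRED, "profiling")


def merge_registries(parts: Iterable[Registry]) -> Registry:
    """Union registry fragments into one consistent Registry.

    dataset_id collisions are allowed only when the DatasetMeta agree;
    otherwise :class:`RegistryMergeError`.  Merging is associative and
    idempotent: byte-identical measurement rows deduplicate.
    """
    datasets: dict[str, DatasetMeta] = {}
    meas: list[pd.DataFrame] = []
    dets: list[pd.DataFrame] = []
    issues: list[ParseIssue] = []
    for part in parts:
        for ds, meta in part.datasets.items():
            prior = datasets.get(ds)
            if prior is not None and prior != meta:
                raise RegistryMergeError(
                    f"conflicting DatasetMeta for dataset_id {ds!r}: {prior} vs {meta}"
                )
            datasets[ds] = meta
        if len(part.measurements):
            meas.append(part.measurements)
        if len(part.detections):
            dets.append(part.detections)
        issues.extend(part.issues)
    reg = Registry(datasets=datasets, issues=issues)
    if meas:
        reg.measurements = (
            pd.concat(meas, ignore_index=True).drop_duplicates().reset_index(drop=True)
        )
    if dets:
        reg.detections = (
            pd.concat(dets, ignore_index=True)
            .drop_duplicates(subset=["dataset_id", "gene_symbol", "residue", "position"])
            .reset_index(drop=True)
        )
    reg.validate()
    return reg


# ---------------------------------------------------------------------------
# writers


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(records)


def write_table(records, path, format: str = "tsv") -> None:
    """Serialise a result collection to TSV or JSON records.

    Floats are written with full round-trip precision; re-reading with
    :func:`read_table` reproduces every field.
    """
    frame = _as_frame(records)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, na_rep="")
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                json.loads(frame.to_json(orient="records", double_precision=15)),
                fh,
                indent=1,
            )
            fh.write("\n")
    else:
        raise UsageError(f"unknown format {format!r}; use 'tsv' or 'json'")


def read_table(path, format: str = "tsv") -> pd.DataFrame:
    """Inverse of :func:`write_table`."""
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            return pd.DataFrame(json.load(fh))
    raise UsageError(f"unknown format {format!r}; use 'tsv' or 'json'")
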