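"""Class-1 filtering and U/D/NR regulation calling.

A site measurement becomes a directional call per dataset:

* Class-1 eligibility: localisation probability >= 0.75 OR A-score >= 13
  (phosphosite position confidently localised on the peptide).
* U (upregulated): fold change >= 1.3 and p < 0.05.
* D (downregulated): fold change <= 0.76 and p < 0.05.
* NR (not regulated): everything else.

Boundary semantics are deliberate: the fold-change gates are inclusive
(">= 1.3", "<= 0.76"), the significance gate is exclusive (p strictly below
alpha), and both Class-1 gates are inclusive.  Multi-peptide evidence for the
same (dataset, site) collapses to one call; a U/D conflict collapses to NR
with a ``conflict`` flag rather than a majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_registry import Registry, SiteKey, UsageError

U, D, NR = "U", "D", "NR"

CALL_COLUMNS = [
    "dataset_id",
    "gene_symbol",
    "residue",
    "position",
    "direction",
    "flag",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Every tunable gate of the pipeline, with the defaults used throughout.

    fc_up / fc_down are raw test/control ratios (not log), alpha is the
    p-value gate, min_loc_prob / min_a_score define Class-1, and the last
    three parametrise the high-confidence co-regulation filter (minimum
    support as a fraction of the anchor's regulated datasets, and minimum
    numbers of distinct experimental conditions and studies).
    """

    fc_up: float = 1.3
    fc_down: float = 0.76
    alpha: float = 0.05
    min_loc_prob: float = 0.75
    min_a_score: float = 13.0
    min_support_fraction: float = 0.10
    min_conditions: int = 3
    min_studies: int = 3
    allow_missing_p: bool = False

    def __post_init__(self) -> None:
        if not (self.fc_down < 1.0 < self.fc_up):
            raise ValueError("require fc_down < 1 < fc_up")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.0 <= self.min_support_fraction <= 1.0):
            raise ValueError("min_support_fraction must be in [0, 1]")
        if self.min_conditions < 1 or self.min_studies < 1:
            raise ValueError("min_conditions and min_studies must be >= 1")


@dataclass(frozen=True)
class RegulationCall:
    dataset_id: str
    site: SiteKey
    direction: str  # U | D | NR
    flag: str | None = None  # None | "missing-p" | "conflict"


@dataclass
class CallReport:
    """Accounting for one corpus-wide calling pass."""

    n_measurements: int = 0
    n_not_class1: int = 0
    n_missing_p: int = 0
    n_conflict: int = 0
    n_calls: int = 0
    direction_totals: dict = field(default_factory=dict)


def is_class1(record, t: ThresholdConfig | None = None) -> bool:
    """True iff the site's localisation is confident enough for Class-1.

    ``record`` is anything with localization_probability / a_score attributes
    or keys (measurement row, detection row, dataclass).  Both criteria
    absent -> False (eligibility undecidable means excluded).
    """
    t = t or ThresholdConfig()
    lp = _get(record, "localization_probability")
    asc = _get(record, "a_score")
    if lp is not None and not pd.isna(lp) and lp >= t.min_loc_prob:
        return True
    if asc is not None and not pd.isna(asc) and asc >= t.min_a_score:
        return True
    return False


def classify_regulation(m, t: ThresholdConfig | None = None) -> str:
    """Direction for one measurement: U, D or NR (boundary rules above)."""
    t = t or ThresholdConfig()
    fc = _get(m, "fold_change")
    p = _get(m, "p_value")
    if fc is None or pd.isna(fc):
        return NR
    if p is None or pd.isna(p):
        if not t.allow_missing_p:
            return NR
        significant = True
    else:
        significant = p < t.alpha
    if significant and fc >= t.fc_up:
        return U
    if significant and fc <= t.fc_down:
        return D
    return NR


def collapse_site_calls(calls: Sequence[RegulationCall]) -> RegulationCall:
    """Collapse multi-peptide evidence for one (dataset, site) into one call."""
    if not calls:
        raise UsageError("collapse_site_calls requires at least one call")
    keys = {(c.dataset_id, c.site) for c in calls}
    if len(keys) > 1:
        raise UsageError(f"calls span multiple (dataset, site) keys: {keys}")
    directions = {c.direction for c in calls if c.direction != NR}
    if directions == {U}:
        return replace(calls[0], direction=U, flag=None)
    if directions == {D}:
        return replace(calls[0], direction=D, flag=None)
    if directions == {U, D}:
        return replace(calls[0], direction=NR, flag="conflict")
    flags = {c.flag for c in calls if c.flag}
    return replace(calls[0], direction=NR, flag=next(iter(flags), None))


def call_registry(
    reg: Registry, t: ThresholdConfig | None = None
) -> tuple[pd.DataFrame, CallReport]:
    """Corpus-wide regulation calling.

    Returns a call table with exactly one row per (differential dataset,
    Class-1 site measured in it) and a :class:`CallReport` counting the
    measurements excluded by the Class-1 filter and the collapse outcomes.
    """
    t = t or ThresholdConfig()
    report = CallReport()
    m = reg.measurements
    report.n_measurements = len(m)
    if not len(m):
        empty = pd.DataFrame(columns=CALL_COLUMNS)
        report.direction_totals = {U: 0, D: 0, NR: 0}
        return empty, report

    lp = pd.to_numeric(m["localization_probability"], errors="coerce")
    asc = pd.to_numeric(m["a_score"], errors="coerce")
    class1 = (lp >= t.min_loc_prob).fillna(False) | (asc >= t.min_a_score).fillna(False)
    report.n_not_class1 = int((~class1).sum())
    m = m[class1]

    fc = pd.to_numeric(m["fold_change"], errors="coerce")
    p = pd.to_numeric(m["p_value"], errors="coerce")
    missing_p = p.isna()
    report.n_missing_p = int(missing_p.sum())
    significant = (p < t.alpha) if not t.allow_missing_p else ((p < t.alpha) | missing_p)
    significant = significant.fillna(False)
    direction = np.where(
        significant & (fc >= t.fc_up), U, np.where(significant & (fc <= t.fc_down), D, NR)
    )
    calls = pd.DataFrame(
        {
            "dataset_id": m["dataset_id"].to_numpy(),
            "gene_symbol": m["gene_symbol"].to_numpy(),
            "residue": m["residue"].to_numpy(),
            "position": m["position"].to_numpy(),
            "direction": direction,
            "flag": np.where(missing_p & ~t.allow_missing_p, "missing-p", None),
        }
    )

    # collapse duplicate (dataset, site) evidence: agreement keeps the
    # direction, U+D conflict -> NR(conflict)
    key = ["dataset_id", "gene_symbol", "residue", "position"]
    grouped = calls.groupby(key, sort=True)
    agg = grouped["direction"].agg(
        has_u=lambda s: (s == U).any(), has_d=lambda s: (s == D).any()
    )
    flag_any = grouped["flag"].first()
    out = agg.reset_index()
    out["direction"] = np.where(
        out["has_u"] & out["has_d"], NR, np.where(out["has_u"], U, np.where(out["has_d"], D, NR))
    )
    out["flag"] = np.where(
        out["has_u"] & out["has_d"], "conflict", flag_any.reset_index(drop=True)
    )
    out = out[CALL_COLUMNS]
    report.n_conflict = int((out["flag"] == "conflict").sum())
    report.n_calls = len(out)
    report.direction_totals = out["direction"].value_counts().reindex([U, D, NR], fill_value=0).to_dict()
    return out.reset_index(drop=True), report


def calls_to_records(calls: pd.DataFrame) -> list[RegulationCall]:
    """Materialise a call table into RegulationCall dataclasses (small inputs)."""
    return [
        RegulationCall(
            dataset_id=r.dataset_id,
            site=SiteKey(r.gene_symbol, r.residue, int(r.position)),
            direction=r.direction,
            flag=None if pd.isna(r.flag) else r.flag,
        )
        for r in calls.itertuples()
    ]


def _get(record, name):
    if isinstance(record, dict):
        return record.get(name)
    if isinstance(record, pd.Series):
        return record.get(name)
    return getattr(record, name, None)
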