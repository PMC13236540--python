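"""Detection-frequency ranking of an anchor protein's phosphosites.

For each distinct site of the protein observed anywhere in the corpus we
count (i) profiling datasets with a Class-1 detection and (ii) differential
datasets in which the site was called regulated (U or D).  Sites are ranked
by differential frequency (profiling frequency, then position, break ties)
and the top of the ranking is flagged *predominant* — either the top_k
sites or every site reaching a minimum frequency, since no universal numeric
cutoff exists for "appears most often".

``freq_mode="detected"`` switches the differential count from regulated
datasets to any measured dataset, for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io_registry import Registry, SiteKey, UsageError, ValidationError
from .regulation import ThresholdConfig, is_class1

REPORT_COLUMNS = [
    "gene_symbol",
    "residue",
    "position",
    "profiling_frequency",
    "differential_frequency",
    "rank",
    "predominant",
]


@dataclass(frozen=True)
class PredominantSiteReport:
    site: SiteKey
    profiling_frequency: int
    differential_frequency: int
    rank: int | None = None
    predominant: bool = False


def site_frequencies(
    protein: str,
    reg: Registry,
    calls: pd.DataFrame,
    t: ThresholdConfig | None = None,
    freq_mode: str = "regulated",
) -> pd.DataFrame:
    """Unranked per-site frequency table for one protein (may be empty)."""
    if freq_mode not in ("regulated", "detected"):
        raise UsageError(f"freq_mode must be 'regulated' or 'detected', got {freq_mode!r}")
    t = t or ThresholdConfig()
    protein = protein.upper()

    det = reg.detections
    det = det[det["gene_symbol"] == protein]
    if len(det):
        class1 = det.apply(lambda r: is_class1(r, t), axis=1)
        det = det[class1]
    prof = (
        det.groupby(["residue", "position"])["dataset_id"].nunique()
        if len(det)
        else pd.Series(dtype=int)
    )

    sub = calls[calls["gene_symbol"] == protein]
    if freq_mode == "regulated":
        sub = sub[sub["direction"].isin(["U", "D"])]
    diff = (
        sub.groupby(["residue", "position"])["dataset_id"].nunique()
        if len(sub)
        else pd.Series(dtype=int)
    )

    # any site of the protein seen anywhere in the registry gets a row
    seen = set(prof.index) | set(diff.index)
    for frame in (reg.detections, reg.measurements):
        mine = frame[frame["gene_symbol"] == protein]
        seen |= {(r, int(p)) for r, p in zip(mine["residue"], mine["position"])}
    rows = [
        {
            "gene_symbol": protein,
            "residue": res,
            "position": int(pos),
            "profiling_frequency": int(prof.get((res, pos), 0)),
            "differential_frequency": int(diff.get((res, pos), 0)),
        }
        for res, pos in sorted(seen, key=lambda k: (k[1], k[0]))
    ]
    out = pd.DataFrame(rows, columns=REPORT_COLUMNS[:5])
    return out


def rank_predominant(
    reports: pd.DataFrame,
    top_k: int | None = None,
    min_frequency: int | None = None,
) -> pd.DataFrame:
    """Sort by differential frequency and flag predominant sites.

    Exactly one of top_k / min_frequency selects the predominant set;
    passing both is a usage error, passing neither defaults to top_k=4.
    Ordering is total: differential desc, profiling desc, position asc.
    """
    if top_k is not None and min_frequency is not None:
        raise UsageError("give top_k or min_frequency, not both")
    if top_k is None and min_frequency is None:
        top_k = 4
    if not len(reports):
        raise UsageError("rank_predominant requires a non-empty report table")
    out = reports.sort_values(
        ["differential_frequency", "profiling_frequency", "position"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    if top_k is not None:
        out["predominant"] = out["rank"] <= top_k
    else:
        out["predominant"] = out["differential_frequency"] >= min_frequency
    return out


def lollipop_export(reports: pd.DataFrame, sequence_length: int) -> pd.DataFrame:
    """Plot-ready (position, residue, frequencies) track table."""
    cols = ["position", "residue", "profiling_frequency", "differential_frequency"]
    if not len(reports):
        return pd.DataFrame(columns=cols)
    worst = int(reports["position"].max())
    if worst > sequence_length:
        raise ValidationError(
            f"site position {worst} exceeds sequence length {sequence_length}"
        )
    return reports.sort_values("position")[cols].reset_index(drop=True)
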