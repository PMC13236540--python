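"""Annotation joins and network edge-list export.

User-supplied static annotation tables (binary interactors, complex
interactors, upstream kinases) are joined onto high-confidence co-regulation
results: gene-level joins for interactor roles, site-level joins for
kinase -> substrate records.  The result is exported as a typed edge list
(TSV or a simple nodes+edges JSON graph) loadable by common viewers.

Annotation TSV columns: subject_gene, subject_site (optional), role,
target_gene, target_site (optional), evidence, source.  ``role`` is one of
binary_interactor / complex_interactor / kinase; kinase rows must carry a
target_site.  No live database retrieval is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io_registry import ParseIssue, SiteKey, UsageError, ValidationError

ROLES = ("binary_interactor", "complex_interactor", "kinase")
EVIDENCE = ("experimental", "predicted")

EDGE_COLUMNS = ["source_node", "target_node", "edge_type", "weight", "attributes"]


@dataclass(frozen=True)
class AnnotationRecord:
    subject: str  # gene symbol (kinases: the kinase gene)
    role: str
    evidence: str
    source: str
    subject_site: SiteKey | None = None
    target_site: SiteKey | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.evidence not in EVIDENCE:
            raise ValidationError(
                f"evidence must be one of {EVIDENCE}, got {self.evidence!r}"
            )
        if self.role == "kinase" and self.target_site is None:
            raise ValidationError("kinase records must carry a target_site")


def read_annotation_table(path) -> tuple[list[AnnotationRecord], list[ParseIssue]]:
    """Parse an annotation TSV; malformed rows are reported, not fatal."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[AnnotationRecord] = []
    issues: list[ParseIssue] = []
    for i, rec in enumerate(raw.to_dict("records"), start=1):
        try:
            subject = (rec.get("subject_gene") or "").strip().upper()
            if not subject:
                raise ValidationError("subject_gene missing")
            site = None
            tgt = None
            if (rec.get("subject_site") or "").strip():
                site = SiteKey.parse(f"{subject}:{rec['subject_site'].strip()}")
            tg = (rec.get("target_gene") or "").strip().upper()
            if (rec.get("target_site") or "").strip():
                if not tg:
                    raise ValidationError("target_site without target_gene")
                tgt = SiteKey.parse(f"{tg}:{rec['target_site'].strip()}")
            records.append(
                AnnotationRecord(
                    subject=subject,
                    subject_site=site,
                    role=(rec.get("role") or "").strip(),
                    target_site=tgt,
                    evidence=(rec.get("evidence") or "").strip(),
                    source=(rec.get("source") or "").strip(),
                )
            )
        except (ValidationError, ValueError) as exc:
            issues.append(ParseIssue(path=str(path), row=i, message=str(exc)))
    return records, issues


def annotate_results(
    stats: pd.DataFrame, annotations: list[AnnotationRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag high-confidence PsOPs with annotation roles.

    Gene-symbol join for interactor roles; site-level join for kinase
    records (the kinase's target_site must equal the PsOP site).  Returns
    (stats with a ``roles`` column, per-(anchor, role, polarity) count
    table).  Untagged PsOPs are retained with an empty role string.
    """
    stats = stats.copy()
    by_gene: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        if rec.role == "kinase":
            by_gene.setdefault(str(rec.target_site), []).append(rec)
        else:
            by_gene.setdefault(rec.subject, []).append(rec)

    roles = []
    for row in stats.itertuples():
        tags = []
        for rec in by_gene.get(row.psop_gene, []):
            if rec.role != "kinase":
                tags.append(f"{rec.role}:{rec.source}")
        site_str = f"{row.psop_gene}:{row.psop_site}"
        for rec in by_gene.get(site_str, []):
            tags.append(f"kinase={rec.subject}:{rec.source}")
        roles.append("|".join(sorted(set(tags))))
    stats["roles"] = roles

    tagged = stats[(stats["high_confidence"]) & (stats["roles"] != "")]
    counts = []
    for row in tagged.itertuples():
        for tag in row.roles.split("|"):
            counts.append(
                {
                    "anchor": row.anchor,
                    "role": tag.split(":")[0].split("=")[0],
                    "polarity": row.classification,
                }
            )
    count_table = (
        pd.DataFrame(counts)
        .groupby(["anchor", "role", "polarity"])
        .size()
        .rename("n")
        .reset_index()
        if counts
        else pd.DataFrame(columns=["anchor", "role", "polarity", "n"])
    )
    return stats, count_table


def build_edge_list(
    annotated: pd.DataFrame, annotations: list[AnnotationRecord] | None = None
) -> pd.DataFrame:
    """Typed edge list: one co-regulation edge per high-confidence pair plus
    one role edge per matched annotation record.

    Co-regulation edge weight = winning-polarity support count
    (support_fraction x anchor detections is already folded into the scan
    table, so the d or c cell is used directly); duplicate (source, target,
    type) edges collapse.
    """
    edges = []
    hc = annotated[annotated["high_confidence"]] if len(annotated) else annotated
    for row in hc.itertuples():
        psop_node = f"{row.psop_gene}:{row.psop_site}"
        weight = row.d if row.classification == "positive" else row.c
        edges.append(
            {
                "source_node": row.anchor,
                "target_node": psop_node,
                "edge_type": f"coregulation_{row.classification}",
                "weight": float(weight),
                "attributes": json.dumps(
                    {
                        "fet_p": row.fet_p_neg
                        if row.classification == "negative"
                        else row.fet_p_pos,
                        "n_studies": int(row.n_studies),
                    },
                    sort_keys=True,
                ),
            }
        )
    role_to_type = {
        "binary_interactor": "binary_interaction",
        "complex_interactor": "complex_interaction",
    }
    if annotations:
        hc_genes = set(hc["psop_gene"]) if len(hc) else set()
        anchor_sites = set(hc["anchor"]) if len(hc) else set()
        anchor_genes = sorted({a.split(":")[0] for a in anchor_sites})
        for rec in annotations:
            if rec.role == "kinase":
                target = str(rec.target_site)
                if target in anchor_sites:
                    edges.append(
                        {
                            "source_node": rec.subject,
                            "target_node": target,
                            "edge_type": "kinase_substrate",
                            "weight": 1.0,
                            "attributes": json.dumps(
                                {"evidence": rec.evidence, "source": rec.source},
                                sort_keys=True,
                            ),
                        }
                    )
            elif rec.subject in hc_genes:
                for anchor_gene in anchor_genes:
                    edges.append(
                        {
                            "source_node": rec.subject,
                            "target_node": anchor_gene,
                            "edge_type": role_to_type[rec.role],
                            "weight": 1.0,
                            "attributes": json.dumps(
                                {"evidence": rec.evidence, "source": rec.source},
                                sort_keys=True,
                            ),
                        }
                    )
    frame = pd.DataFrame(edges, columns=EDGE_COLUMNS)
    if len(frame):
        frame = frame.drop_duplicates(
            subset=["source_node", "target_node", "edge_type"]
        ).reset_index(drop=True)
    return frame


def export_json_graph(edges: pd.DataFrame, path) -> None:
    """nodes + edges arrays, loadable by common graph viewers."""
    nodes = sorted(set(edges["source_node"]) | set(edges["target_node"]))
    graph = {
        "nodes": [{"id": n} for n in nodes],
        "edges": [
            {
                "source": r.source_node,
                "target": r.target_node,
                "type": r.edge_type,
                "weight": r.weight,
                "attributes": json.loads(r.attributes) if r.attributes else {},
            }
            for r in edges.itertuples()
        ],
    }
    Path(path).write_text(json.dumps(graph, indent=1) + "\n", encoding="utf-8")
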