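"""End-to-end pipeline: ingest -> call -> rank -> co-occur -> co-regulate ->
filter -> annotate -> export, with a run report accounting for every filter
layer.

Driven by a single YAML/JSON config (see :func:`run_pipeline`); every stage
is also usable standalone through the library or the CLI subcommands.
Outputs are plain TSV/JSON with deterministic ordering, so a rerun with the
same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotation_network, cooccurrence, coregulation, site_frequency
from .io_registry import (
    Registry,
    SiteKey,
    UsageError,
    merge_registries,
    read_differential_table,
    read_profiling_table,
    write_table,
)
from .regulation import ThresholdConfig, call_registry
from .synthetic_data import (
    PlantedPair,
    SyntheticCorpusConfig,
    generate_corpus,
    write_corpus,
)

log = logging.getLogger("phoscoreg")


@dataclass
class RunReport:
    """Counts at every stage; exclusions + retained always add back up."""

    n_datasets: int = 0
    n_studies: int = 0
    n_conditions: int = 0
    n_differential_datasets: int = 0
    n_profiling_datasets: int = 0
    n_measurements: int = 0
    n_not_class1: int = 0
    n_calls: int = 0
    direction_totals: dict = field(default_factory=dict)
    predominant_sites: list = field(default_factory=list)
    pairs_tested: int = 0
    pairs_significant: int = 0
    pairs_high_confidence: int = 0
    warnings: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"


def load_config(path) -> dict:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def thresholds_from_config(cfg: dict) -> ThresholdConfig:
    return ThresholdConfig(**cfg.get("thresholds", {}))


def corpus_config_from_dict(sim: dict) -> SyntheticCorpusConfig:
    sim = dict(sim)
    if "anchor_sites" in sim:
        sim["anchor_sites"] = tuple(SiteKey.parse(s) for s in sim["anchor_sites"])
    if "planted_pairs" in sim:
        sim["planted_pairs"] = tuple(
            PlantedPair(
                anchor_site=SiteKey.parse(p["anchor"]),
                partner_site=SiteKey.parse(p["partner"]),
                polarity=p["polarity"],
                concordance=p.get("concordance", 0.95),
                co_measurement_rate=p.get("co_measurement_rate", 0.8),
            )
            for p in sim["planted_pairs"]
        )
    return SyntheticCorpusConfig(**sim)


def _load_registry(cfg: dict, report: RunReport) -> Registry:
    inputs = cfg.get("inputs")
    sim = cfg.get("simulate")
    if bool(inputs) == bool(sim):
        raise UsageError("config must provide exactly one of 'inputs' or 'simulate'")
    if sim:
        registry, _truth = generate_corpus(corpus_config_from_dict(sim))
        return registry
    parts = []
    for path in inputs.get("differential", []):
        parts.append(read_differential_table(path, inputs.get("dialect")))
    for path in inputs.get("profiling", []):
        parts.append(read_profiling_table(path, inputs.get("dialect")))
    if not parts:
        raise UsageError("config 'inputs' lists no tables")
    registry = merge_registries(parts)
    for issue in registry.issues:
        report.warnings.append(f"{issue.path} row {issue.row}: {issue.message}")
    return registry


def run_pipeline(config, out_dir=None) -> RunReport:
    """Execute the full pipeline from a config path or dict.

    Writes calls.tsv, site_frequencies.tsv, cooccurrence.tsv, one
    coreg_<anchor>.tsv per predominant site, shared_psops.tsv, edges.tsv,
    graph.json and report.json into ``out_dir``.  Raises stage-named errors
    on validation failure.
    """
    cfg = load_config(config) if not isinstance(config, dict) else config
    out = Path(out_dir or cfg.get("out_dir", "phoscoreg_out"))
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    t = thresholds_from_config(cfg)
    anchor_protein = str(cfg.get("anchor_protein", "MAPT")).upper()

    log.info("stage=ingest")
    registry = _load_registry(cfg, report)
    report.n_datasets = len(registry.datasets)
    report.n_studies = len({m.study_id for m in registry.datasets.values()})
    report.n_conditions = len({m.condition_id for m in registry.datasets.values()})
    report.n_differential_datasets = len(registry.differential_ids())
    report.n_profiling_datasets = len(registry.profiling_ids())

    log.info("stage=classify thresholds=%s", t)
    calls, call_report = call_registry(registry, t)
    report.n_measurements = call_report.n_measurements
    report.n_not_class1 = call_report.n_not_class1
    report.n_calls = call_report.n_calls
    report.direction_totals = call_report.direction_totals
    write_table(calls.sort_values(list(calls.columns)).reset_index(drop=True),
                out / "calls.tsv")

    log.info("stage=predominant protein=%s", anchor_protein)
    freqs = site_frequency.site_frequencies(
        anchor_protein, registry, calls, t, cfg.get("freq_mode", "regulated")
    )
    anchors: list[SiteKey] = []
    if len(freqs):
        ranked = site_frequency.rank_predominant(
            freqs,
            top_k=cfg.get("top_k") if "min_frequency" not in cfg else None,
            min_frequency=cfg.get("min_frequency"),
        )
        write_table(ranked, out / "site_frequencies.tsv")
        chosen = ranked[ranked["predominant"]]
        anchors = [
            SiteKey(anchor_protein, r.residue, int(r.position))
            for r in chosen.itertuples()
        ]
        report.predominant_sites = [str(a) for a in anchors]
        if "seq_length" in cfg:
            write_table(
                site_frequency.lollipop_export(ranked, int(cfg["seq_length"])),
                out / "lollipop.tsv",
            )
    else:
        report.warnings.append(f"predominant: no sites for {anchor_protein}")
        write_table(freqs, out / "site_frequencies.tsv")

    log.info("stage=cooccur")
    matrix = cooccurrence.cooccurrence_matrix(
        anchor_protein, calls, registry, cfg.get("pseudocount", 0.0)
    )
    if not len(matrix):
        report.warnings.append("cooccur: fewer than two regulated sites")
    write_table(matrix, out / "cooccurrence.tsv")

    log.info("stage=coreg anchors=%s", [str(a) for a in anchors])
    all_stats = []
    for anchor in anchors:
        stats = coregulation.coregulation_scan(
            anchor,
            calls,
            registry,
            t,
            universe=cfg.get("universe", "anchor-measured"),
            cell_mode=cfg.get("cell_mode", "regulated"),
            fdr=bool(cfg.get("fdr", False)),
        )
        if not len(stats):
            report.warnings.append(f"coreg: anchor {anchor} unregulated everywhere")
        stats = stats.sort_values(["psop_gene", "psop_site"]).reset_index(drop=True)
        write_table(stats, out / f"coreg_{anchor.residue}{anchor.position}.tsv")
        all_stats.append(stats)
    stats = (
        pd.concat(all_stats, ignore_index=True)
        if all_stats
        else pd.DataFrame(columns=coregulation.SCAN_COLUMNS)
    )
    report.pairs_tested = len(stats)
    report.pairs_significant = int(
        (stats["classification"] != "none").sum()) if len(stats) else 0
    report.pairs_high_confidence = int(stats["high_confidence"].sum()) if len(stats) else 0

    if len(anchors) >= 2 and len(stats):
        for polarity in ("positive", "negative"):
            sets = {
                str(a): {
                    f"{r.psop_gene}:{r.psop_site}"
                    for r in stats[
                        (stats["anchor"] == str(a))
                        & stats["high_confidence"]
                        & (stats["classification"] == polarity)
                    ].itertuples()
                }
                for a in anchors
            }
            overlap, _excl = coregulation.shared_psops(sets, polarity)
            mode = "w" if polarity == "positive" else "a"
            overlap.to_csv(
                out / "shared_psops.tsv", sep="\t", index=False, mode=mode,
                header=(polarity == "positive"),
            )

    log.info("stage=annotate")
    annotations = []
    if cfg.get("annotations"):
        annotations, issues = annotation_network.read_annotation_table(cfg["annotations"])
        for issue in issues:
            report.warnings.append(f"annotations row {issue.row}: {issue.message}")
    annotated, role_counts = annotation_network.annotate_results(stats, annotations)
    edges = annotation_network.build_edge_list(annotated, annotations)
    write_table(edges, out / "edges.tsv")
    annotation_network.export_json_graph(edges, out / "graph.json")
    if len(role_counts):
        write_table(role_counts, out / "role_counts.tsv")

    (out / "report.json").write_text(report.to_json(), encoding="utf-8")
    log.info(
        "done: %d pairs tested, %d significant, %d high-confidence",
        report.pairs_tested, report.pairs_significant, report.pairs_high_confidence,
    )
    return report


def simulate_to_dir(sim_cfg: dict, out_dir, seed: int | None = None) -> dict:
    """Generate a corpus from a config dict and write it to ``out_dir``."""
    if seed is not None:
        sim_cfg = {**sim_cfg, "seed": seed}
    cfg = corpus_config_from_dict(sim_cfg)
    registry, truth = generate_corpus(cfg)
    paths = write_corpus(registry, truth, out_dir)
    return {k: str(v) for k, v in paths.items()}
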