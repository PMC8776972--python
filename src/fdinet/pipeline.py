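"""End-to-end orchestration: sources -> graph -> predictions -> evaluation.

A run is fully described by a :class:`RunConfig`; the resolved config is
written beside the outputs, and two runs with the same config produce
byte-identical summaries.  One top-level seed fans out to per-stage
sub-seeds through a fixed derivation rule (``numpy.random.SeedSequence([
seed, stage_index])``), so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from fdinet import evaluate, fixtures, graph_build, ingest, link_prediction, similarity

logger = logging.getLogger(__name__)

#: Fixed stage order for sub-seed derivation.
STAGES = ("fixtures", "ingest", "ssp", "graph", "predict", "evaluate")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage sub-seed (< 2**31) from the run seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    out_dir: str = "run"
    # inputs: either existing files, or fixtures generated into the run dir
    drugbank_xml: str | None = None
    foodb_dir: str | None = None
    n_drugs: int = 30
    n_foods: int = 10
    # graph construction
    tanimoto_threshold: float = graph_build.DEFAULT_TANIMOTO_THRESHOLD
    contribution_threshold: float = graph_build.DEFAULT_CONTRIBUTION_THRESHOLD
    bridge_weight: float = graph_build.DEFAULT_BRIDGE_WEIGHT
    graph_variant: str = "disjoint"
    content_range_mode: str = "max"
    health_effect_filter: bool = True
    # prediction and evaluation
    methods: tuple[str, ...] = ("sp2", "ra")
    evaluation: int | None = 1
    fraction_removed: float = 0.3
    repeats: int = 3
    split_scope: str = evaluate.DD_ONLY
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tanimoto_threshold", "contribution_threshold"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.graph_variant not in ("disjoint", "joint"):
            raise ValueError("graph_variant must be 'disjoint' or 'joint'")
        for m in self.methods:
            if m not in link_prediction.METHODS:
                raise ValueError(f"unknown method {m!r}")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["methods"] = list(self.methods)
        return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the machine-readable run summary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    summary: dict = {"config": config.to_dict(), "stages": {}}

    # --- sources ----------------------------------------------------------
    if config.drugbank_xml is None or config.foodb_dir is None:
        spec = fixtures.FixtureSpec(
            n_drugs=config.n_drugs,
            n_foods=config.n_foods,
            seed=stage_seed(config.seed, "fixtures"),
        )
        fixture_dir = out_dir / "fixtures"
        drugbank_xml = fixtures.generate_drugbank_fixture(spec, fixture_dir)
        foodb_dir = fixtures.generate_foodb_fixture(spec, fixture_dir)
        summary["stages"]["fixtures"] = {"dir": str(fixture_dir)}
    else:
        drugbank_xml, foodb_dir = Path(config.drugbank_xml), Path(config.foodb_dir)

    # --- ingest -----------------------------------------------------------
    drugs = ingest.parse_drugbank(drugbank_xml)
    food_nodes, entries = ingest.parse_foodb(
        foodb_dir,
        health_effect_filter=config.health_effect_filter,
        content_range_mode=config.content_range_mode,
    )
    nodes = drugs + food_nodes
    ingest.write_nodes_tsv(nodes, out_dir / "nodes.tsv")
    ingest.write_contributions_tsv(entries, out_dir / "contributions.tsv")
    summary["stages"]["ingest"] = {
        "n_drugs": len(drugs),
        "n_food_compounds": len(food_nodes),
        "n_contribution_entries": len(entries),
    }
    logger.info("ingest: %d drugs, %d food compounds", len(drugs), len(food_nodes))

    # --- similarity profile ----------------------------------------------
    ssp = similarity.build_ssp(nodes)
    similarity.write_edges_tsv(ssp, out_dir / "ssp.tsv")
    summary["stages"]["ssp"] = {"n_pairs": len(ssp)}

    # --- graph ------------------------------------------------------------
    kept = graph_build.apply_threshold(ssp, config.tanimoto_threshold)
    updated = graph_build.update_scores(kept, nodes, ingest.contribution_map(entries))
    final_edges = graph_build.apply_contribution_threshold(
        updated, config.contribution_threshold
    )
    graph = graph_build.build_graph(final_edges, nodes)
    if config.graph_variant == "joint":
        graph = graph_build.joinify(
            graph, config.bridge_weight, seed=stage_seed(config.seed, "graph")
        )
    graph_build.write_graph_tsv(graph, out_dir / "graph.tsv")
    graph_build.write_summary_json(graph, out_dir / "graph_summary.json")
    summary["stages"]["graph"] = graph.summary() | {
        "edges_after_tanimoto_threshold": len(kept),
        "edges_after_contribution_threshold": len(final_edges),
    }
    logger.info(
        "graph: %d kept at tc>=%g, %d after contribution threshold, %d components",
        len(kept), config.tanimoto_threshold, len(final_edges), graph.n_components,
    )

    # --- predictions ------------------------------------------------------
    summary["stages"]["predict"] = {}
    for method in config.methods:
        ranked = link_prediction.predict(graph, method)
        link_prediction.write_predictions_tsv(ranked, out_dir / f"predictions_{method}.tsv")
        summary["stages"]["predict"][method] = {"n_predictions": len(ranked)}

    # --- evaluation -------------------------------------------------------
    if config.evaluation is not None:
        split = evaluate.SplitSpec(
            fraction_removed=config.fraction_removed,
            scope=config.split_scope,
            repeats=config.repeats,
            seed=stage_seed(config.seed, "evaluate"),
        )
        reports = evaluate.run_evaluation(
            graph, config.evaluation, config.methods, split=split
        )
        evaluate.write_report_tsv(reports, out_dir / "evaluation.tsv")
        summary["stages"]["evaluate"] = {r.method: r.summary() for r in reports}

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
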