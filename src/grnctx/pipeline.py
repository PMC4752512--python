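"""End-to-end pipeline: scan → merge → booleanize → contextualize → rank."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from grnctx import expression as expr_mod
from grnctx.contextualize import ContextualizationResults, NetworkContextualizer, attach_stimulus_edges
from grnctx.network import GRN, merge
from grnctx.paths import PathSet, enumerate_simple_paths, rank_regulators
from grnctx.scan import ScanConfig, build_upstream_network, scan_library
from grnctx.simulate import ScenarioData


@dataclass
class PipelineResult:
    upstream: GRN
    merged: GRN
    degs: pd.DataFrame
    contextualization: ContextualizationResults
    final_network: GRN
    pathset: PathSet
    ranking: pd.DataFrame


def run_scenario(
    scenario: ScenarioData,
    scan_cfg: ScanConfig = ScanConfig(),
    lfc_min: float = 1.0,
    p_max: float = 0.01,
    penalty: float = 0.01,
    ga: dict | None = None,
    max_path_len: int | None = None,
) -> PipelineResult:
    """Run the full inference chain on a (synthetic or loaded) scenario."""
    stimulus = scenario.config.stimulus
    target = scenario.config.target

    hits = scan_library(scenario.pwms, scenario.promoters, scan_cfg)
    upstream = build_upstream_network(hits)
    merged = merge(upstream, scenario.literature)

    logfc = expr_mod.log_fold_change(scenario.expression, scenario.conditions)
    p = expr_mod.deg_test(scenario.expression, scenario.conditions)
    degs = expr_mod.call_degs(logfc, p, lfc_min=lfc_min, p_max=p_max)
    phenotypes = expr_mod.booleanize(degs, merged.nodes, stimulus)

    model = NetworkContextualizer(merged, phenotypes, stimulus, target, penalty=penalty)
    ctx = model.fit(**(ga or {}))
    final = attach_stimulus_edges(ctx.network, scenario.literature, stimulus)

    pathset = enumerate_simple_paths(final, stimulus, target, max_len=max_path_len)
    ranking = rank_regulators(pathset)
    return PipelineResult(
        upstream=upstream,
        merged=merged,
        degs=degs,
        contextualization=ctx,
        final_network=final,
        pathset=pathset,
        ranking=ranking,
    )
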