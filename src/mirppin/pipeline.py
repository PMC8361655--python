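"""End-to-end orchestration: DE -> network -> topology -> screen -> ROC ->
MCODE -> enrichment, with a JSON run report of per-stage counts.

Every stage is a pure function of its inputs and the configuration, so a
rerun with identical inputs produces identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import evaluation, expression, modules, topology
from .screen import screen as run_screen, records_to_frame as screen_records_to_frame
from .screen import ScreenRecord
from .expression import ExpressionMatrix
from .io import read_gmt, read_probe_map
from .network import InteractionCatalog, MiRPPIN, PPICatalog, build_bipartite, build_ppin, filter_ppi, merge

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_all", "run_objects"]

TOOL_VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    mirna_expr: str = ""
    mirna_groups: str = ""
    mrna_expr: str = ""
    mrna_groups: str = ""
    targets: str = ""
    ppi: str = ""
    gmt: str = ""
    probe_map: str = ""
    case_label: str = "KTR"
    control_label: str = "Normal"
    de_alpha: float = 0.05
    ppi_min_score: float = 0.7
    screen_alpha: float = 0.05
    mcode: modules.MCODEParams = dataclasses.field(default_factory=modules.MCODEParams)
    out_dir: str = "mirppin_out"

    def __post_init__(self) -> None:
        if not 0 < self.de_alpha <= 1 or not 0 < self.screen_alpha <= 1:
            raise ValueError("alpha thresholds must be in (0, 1]")
        if not 0 <= self.ppi_min_score <= 1:
            raise ValueError("ppi_min_score must be in [0, 1]")
        if isinstance(self.mcode, dict):
            self.mcode = modules.MCODEParams(**self.mcode)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class PipelineResult:
    de_mirnas: list[expression.DERecord]
    de_genes: list[expression.DERecord]
    network: MiRPPIN
    centralities: list[topology.CentralityRecord]
    core: set[str]
    screen_records: list[ScreenRecord]
    candidates: list[str]
    roc_results: list
    clusters: list[modules.ModuleCluster]
    enrichment: list[modules.EnrichmentRow]
    report: dict


def run_objects(
    mirna_matrix: ExpressionMatrix,
    mrna_matrix: ExpressionMatrix,
    catalog: InteractionCatalog,
    ppi_catalog: PPICatalog,
    config: PipelineConfig,
    gene_sets: dict[str, set[str]] | None = None,
    probe_map: dict[str, str] | None = None,
    run_mcode: bool = True,
) -> PipelineResult:
    """Run the full pipeline on in-memory inputs."""
    # differential expression
    de_mir_all = expression.moderated_t_test(
        mirna_matrix, config.case_label, config.control_label
    )
    de_rna_all = expression.moderated_t_test(
        mrna_matrix, config.case_label, config.control_label
    )
    if probe_map:
        de_rna_all = expression.collapse_probes(de_rna_all, probe_map)
    de_mirnas = expression.select_de(de_mir_all, config.de_alpha)
    de_genes = expression.select_de(de_rna_all, config.de_alpha)

    # network construction
    reg = build_bipartite([r.feature_id for r in de_mirnas],
                          [r.feature_id for r in de_genes], catalog)
    ppin = build_ppin([r.feature_id for r in de_genes],
                      filter_ppi(ppi_catalog, config.ppi_min_score))
    net = merge(reg, ppin)

    # topology and CORE classification
    cents = topology.compute_centralities(net)
    core = {c.gene_id for c in cents if c.is_core}
    ppi_dist = topology.degree_distribution(net, "PPI")

    # two-step biomarker screen
    recs = run_screen(net, core, alpha=config.screen_alpha)
    candidates = [r.mirna_id for r in recs if r.passes_step2]

    # ROC evaluation of the candidate panel on the miRNA expression matrix
    roc_results = []
    if candidates:
        panel_rows = [mirna_matrix.feature_ids.index(m) for m in candidates
                      if m in mirna_matrix.feature_ids]
        present = [mirna_matrix.feature_ids[i] for i in panel_rows]
        if present:
            expr_df = pd.DataFrame(
                mirna_matrix.values[panel_rows, :].T,
                index=mirna_matrix.sample_ids, columns=present,
            )
            labels = [1 if mirna_matrix.group_of[s] == config.case_label else 0
                      for s in mirna_matrix.sample_ids]
            roc_results, _ = evaluation.evaluate_panel(expr_df, labels, present)

    clusters = modules.mcode(net, config.mcode) if run_mcode else []

    enrichment: list[modules.EnrichmentRow] = []
    if gene_sets and net.gene_nodes:
        query = set().union(*(net.targets(m) for m in candidates)) if candidates else set()
        if query:
            enrichment = modules.fisher_enrichment(query, gene_sets, net.gene_nodes)

    report = {
        "tool_version": TOOL_VERSION,
        # hash of the analysis configuration (where outputs land is excluded)
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in dataclasses.asdict(config).items() if k != "out_dir"},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
        "n_de_mirnas": len(de_mirnas),
        "n_de_genes": len(de_genes),
        **net.summary(),
        "n_core": len(core),
        "ppi_degree_slope": ppi_dist.slope,
        "candidates": candidates,
        "n_candidates": len(candidates),
        "auc": {r.name: r.auc for r in roc_results},
        "n_clusters": len(clusters),
        "n_enriched_terms": sum(1 for e in enrichment if e.p_value < 0.05),
    }
    return PipelineResult(
        de_mirnas=de_mirnas,
        de_genes=de_genes,
        network=net,
        centralities=cents,
        core=core,
        screen_records=recs,
        candidates=candidates,
        roc_results=roc_results,
        clusters=clusters,
        enrichment=enrichment,
        report=report,
    )


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the pipeline from the files named in ``config`` and write every
    intermediate table plus a JSON report under ``config.out_dir``."""
    for name in ("mirna_expr", "mirna_groups", "mrna_expr", "mrna_groups", "targets", "ppi"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input '{name}' missing: {path!r}")

    mirna_matrix = ExpressionMatrix.from_tsv(config.mirna_expr, config.mirna_groups)
    mrna_matrix = ExpressionMatrix.from_tsv(config.mrna_expr, config.mrna_groups)
    catalog = InteractionCatalog.from_tsv(config.targets)
    ppi_catalog = PPICatalog.from_tsv(config.ppi)
    gene_sets = read_gmt(config.gmt) if config.gmt else None
    probe_map = read_probe_map(config.probe_map) if config.probe_map else None

    result = run_objects(
        mirna_matrix, mrna_matrix, catalog, ppi_catalog, config,
        gene_sets=gene_sets, probe_map=probe_map,
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expression.records_to_frame(result.de_mirnas).to_csv(out / "de_mirna.tsv", sep="\t", index=False)
    expression.records_to_frame(result.de_genes).to_csv(out / "de_mrna.tsv", sep="\t", index=False)
    result.network.to_tsv(out / "network.tsv")
    topology.records_to_frame(result.centralities).to_csv(out / "centrality.tsv", sep="\t", index=False)
    screen_records_to_frame(result.screen_records).to_csv(out / "screen.tsv", sep="\t", index=False)
    if result.roc_results:
        evaluation.results_to_frame(result.roc_results).to_csv(out / "roc.tsv", sep="\t", index=False)
    modules.clusters_to_frame(result.clusters).to_csv(out / "clusters.tsv", sep="\t", index=False)
    if result.enrichment:
        modules.enrichment_to_frame(result.enrichment).to_csv(out / "enrichment.tsv", sep="\t", index=False)
    (out / "report.json").write_text(json.dumps(result.report, indent=1, sort_keys=True))
    logger.info("pipeline report: %s", result.report)
    return result
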