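"""End-to-end orchestration: screening → network → hub screen → MCODE →
over-representation → expression, from one validated configuration.

The pipeline runs either from user-supplied input files or in synthetic mode,
where the fixture generators produce every input from a single seed first.
Every stage writes its artifact into the output directory and contributes its
counts to a machine-readable run report; an empty result at any stage halts
the run with the stage named in the report rather than raising through.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Optional

from pydantic import BaseModel, ConfigDict, ValidationError

from . import __version__, enrichment, expression, hubs, ppi, screening, synthetic
from .errors import ConfigurationError, EmptyNetworkError, NoModuleError


class InputPaths(BaseModel):
    """File-mode input locations (all produced/readable by the format layer)."""

    model_config = ConfigDict(extra="forbid")

    compounds: str
    predictions: str
    disease_lists: dict[str, str]
    edges: str
    gene_sets: str
    expression_values: str
    expression_labels: str


class PipelineConfig(BaseModel):
    """Aggregated configuration for a full run.

    ``seed`` overrides the fixture seed so one flag controls all randomness;
    ``background`` for the over-representation test defaults to the number of
    distinct genes appearing in the PPI edge input.
    """

    model_config = ConfigDict(extra="forbid")

    fixture: synthetic.FixtureConfig = synthetic.FixtureConfig()
    screen: screening.ScreenConfig = screening.ScreenConfig()
    min_score: float = 0.7
    thresholds: hubs.ScreenThresholds = hubs.ScreenThresholds()
    mcode: hubs.MCODEParams = hubs.MCODEParams()
    p_max: float = 0.05
    background: Optional[int] = None
    ease: bool = False
    seed: Optional[int] = None
    inputs: Optional[InputPaths] = None


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a JSON config; empty file means all defaults."""
    text = Path(path).read_text(encoding="utf-8").strip()
    data = json.loads(text) if text else {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as err:
        first = err.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigurationError(f"config key '{loc}': {first['msg']}") from err


@dataclass
class RunReport:
    """Counts, thresholds and decisions of one run, serializable to JSON.

    ``timestamps`` is kept apart so deterministic comparisons can exclude it.
    """

    seed: int
    version: str = __version__
    mode: str = "synthetic"
    counts: dict[str, Any] = dc_field(default_factory=dict)
    thresholds: dict[str, Any] = dc_field(default_factory=dict)
    key_module_genes: list[str] = dc_field(default_factory=list)
    halted_at: Optional[str] = None
    halt_reason: Optional[str] = None
    timestamps: dict[str, float] = dc_field(default_factory=dict)

    def payload(self, include_timestamps: bool = True) -> dict[str, Any]:
        out = {
            "version": self.version,
            "seed": self.seed,
            "mode": self.mode,
            "counts": self.counts,
            "thresholds": self.thresholds,
            "key_module_genes": self.key_module_genes,
            "halted_at": self.halted_at,
            "halt_reason": self.halt_reason,
        }
        if include_timestamps:
            out["timestamps"] = self.timestamps
        return out

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.payload(), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _generate_inputs(cfg: PipelineConfig, indir: Path) -> dict[str, Any]:
    fx = cfg.fixture
    compounds = synthetic.gen_compound_table(fx)
    synthetic.write_compounds(compounds, indir / "compounds.tsv")
    predictions = synthetic.gen_target_predictions(compounds, fx)
    synthetic.write_predictions(predictions, indir / "predictions.tsv")
    disease = synthetic.gen_disease_targets(fx)
    for src, genes in disease.items():
        synthetic.write_gene_list(genes, indir / f"disease_{src}.txt")
    # round-trip through the format layer so file and synthetic modes share a path
    compounds = synthetic.read_compounds(indir / "compounds.tsv")
    predictions = synthetic.read_predictions(indir / "predictions.tsv")
    disease = {
        src: set(synthetic.read_gene_list(indir / f"disease_{src}.txt")) for src in disease
    }
    return {"compounds": compounds, "predictions": predictions, "disease": disease}


def _load_inputs(paths: InputPaths) -> dict[str, Any]:
    return {
        "compounds": synthetic.read_compounds(paths.compounds),
        "predictions": synthetic.read_predictions(paths.predictions),
        "disease": {
            src: set(synthetic.read_gene_list(p)) for src, p in paths.disease_lists.items()
        },
    }


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, synthetic_mode: bool = True
) -> RunReport:
    """Execute every stage in order, writing artifacts and the run report.

    In synthetic mode all inputs are generated from the configured seed; in
    file mode they are read from ``config.inputs``. An empty result at any
    stage (no OGEs, no surviving network, empty hub, no MCODE complex) stops
    the run; the report names the stage and partial artifacts are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    indir = outdir / "inputs"
    indir.mkdir(exist_ok=True)

    cfg = config.model_copy(deep=True)
    if cfg.seed is not None:
        cfg.fixture = cfg.fixture.model_copy(update={"seed": cfg.seed})
    fx = cfg.fixture

    report = RunReport(seed=fx.seed, mode="synthetic" if synthetic_mode else "files")
    report.timestamps["start"] = time.time()
    report.thresholds.update(
        {
            "ob_min": cfg.screen.ob_min,
            "dl_min": cfg.screen.dl_min,
            "source_min_score": dict(cfg.screen.source_min_score),
            "min_edge_score": cfg.min_score,
            "degree_multiplier": cfg.thresholds.degree_multiplier,
            "strict": cfg.thresholds.strict,
            "p_max": cfg.p_max,
        }
    )

    def finish(stage: str | None = None, reason: str | None = None) -> RunReport:
        report.halted_at = stage
        report.halt_reason = reason
        report.timestamps["end"] = time.time()
        report.write(outdir / "run_report.json")
        return report

    # ---- inputs -----------------------------------------------------------
    if synthetic_mode:
        inputs = _generate_inputs(cfg, indir)
    else:
        if cfg.inputs is None:
            raise ConfigurationError("file mode requires 'inputs' paths in the config")
        inputs = _load_inputs(cfg.inputs)

    # ---- screening --------------------------------------------------------
    compounds = inputs["compounds"]
    report.counts["compounds_total"] = int(len(compounds))
    passed = screening.filter_compounds(compounds, cfg.screen)
    report.counts["compounds_pass_adme"] = int(len(passed))
    deduped = screening.dedupe_compounds(passed)
    report.counts["compounds_distinct"] = int(len(deduped))
    synthetic.write_compounds(deduped, outdir / "compounds_filtered.tsv")

    kept_ids = set(deduped["compound_id"])
    predictions = inputs["predictions"]
    predictions = predictions[predictions["compound_id"].isin(kept_ids)]
    compound_targets = screening.assemble_compound_targets(predictions, cfg.screen)
    report.counts["compound_targets"] = len(compound_targets)
    report.counts["compounds_without_targets"] = len(
        screening.compounds_without_targets(deduped, predictions, cfg.screen)
    )
    synthetic.write_gene_list(compound_targets, outdir / "compound_targets.txt")

    disease = inputs["disease"]
    report.counts["disease_targets_per_source"] = {
        src: len(genes) for src, genes in sorted(disease.items())
    }
    disease_union = screening.union_disease_targets(disease)
    report.counts["disease_targets_union"] = len(disease_union)
    synthetic.write_gene_list(disease_union, outdir / "disease_targets.txt")

    oges = screening.overlap_genes(compound_targets, disease_union)
    report.counts["oges"] = len(oges)
    synthetic.write_gene_list(oges, outdir / "oges.txt")
    if not oges:
        return finish("overlap", "compound and disease target sets are disjoint")

    # ---- PPI network ------------------------------------------------------
    if synthetic_mode:
        max_module = sum(size for size, _ in fx.planted_modules)
        planted: list[list[str]] = []
        if max_module <= len(oges):
            edges, planted = synthetic.gen_ppi_edges(oges, fx)
        else:  # too few OGEs to host the modules: background-only fixture
            bg_only = fx.model_copy(update={"planted_modules": []})
            edges, planted = synthetic.gen_ppi_edges(oges, bg_only)
        synthetic.write_edges(edges, indir / "ppi_edges.tsv")
        report.counts["planted_modules"] = [len(m) for m in planted]
        edges = ppi.read_string_edges(indir / "ppi_edges.tsv")
    else:
        edges = ppi.read_string_edges(cfg.inputs.edges)

    background_universe = len(set(edges["protein1"]) | set(edges["protein2"]))
    try:
        build = ppi.build_network(edges, min_score=cfg.min_score, whitelist=oges)
    except EmptyNetworkError as err:
        return finish("network", str(err))
    net = build.graph
    report.counts["network_nodes"] = net.number_of_nodes()
    report.counts["network_edges"] = net.number_of_edges()
    report.counts["unmapped_genes"] = len(build.unmapped)
    report.counts["isolated_genes_removed"] = len(build.dropped)
    ppi.write_graphml(net, outdir / "network.graphml")
    ppi.write_edge_tsv(net, outdir / "network_edges.tsv")
    table = ppi.centrality_table(net)
    ppi.write_centrality_tsv(table, outdir / "centrality.tsv")

    # ---- hub screen + MCODE ----------------------------------------------
    try:
        result = hubs.screen_hubs(net, cfg.thresholds)
    except EmptyNetworkError as err:
        return finish("hub_screen", str(err))
    report.counts["preliminary_hub_nodes"] = result.preliminary_hub.number_of_nodes()
    report.counts["hub_nodes"] = result.hub.number_of_nodes()
    report.thresholds["degree_median"] = result.degree_median
    report.thresholds["per_metric_medians"] = result.per_metric_medians
    ppi.write_graphml(result.preliminary_hub, outdir / "preliminary_hub.graphml")
    ppi.write_edge_tsv(result.preliminary_hub, outdir / "preliminary_hub_edges.tsv")
    ppi.write_graphml(result.hub, outdir / "hub.graphml")
    ppi.write_edge_tsv(result.hub, outdir / "hub_edges.tsv")

    clusters = hubs.mcode_find_complexes(result.hub, cfg.mcode)
    hubs.write_clusters_tsv(clusters, outdir / "mcode_clusters.tsv")
    try:
        key_genes = hubs.key_module(clusters)
    except NoModuleError as err:
        return finish("mcode", str(err))
    result.key_module = clusters[0]
    report.key_module_genes = key_genes
    report.counts["key_module_size"] = len(key_genes)
    synthetic.write_gene_list(key_genes, outdir / "key_targets.txt")

    # nesting invariant of the screen, asserted on every run
    assert set(key_genes) <= set(result.hub.nodes) <= set(
        result.preliminary_hub.nodes
    ) <= set(net.nodes)

    # ---- over-representation ---------------------------------------------
    if synthetic_mode:
        collection = synthetic.gen_gene_sets(fx, focus_genes=key_genes)
        enrichment.write_gmt(collection, indir / "gene_sets.gmt")
        collection = enrichment.read_gmt(indir / "gene_sets.gmt")
    else:
        collection = enrichment.read_gmt(cfg.inputs.gene_sets)
    background = cfg.background or background_universe
    enriched = enrichment.enrich(
        key_genes, collection, background=background, p_max=cfg.p_max, ease=cfg.ease
    )
    report.counts["enriched_terms_per_category"] = {
        cat: int(n) for cat, n in enriched.groupby("category").size().items()
    }
    report.counts["enriched_terms_total"] = int(len(enriched))
    report.thresholds["enrichment_background"] = background
    enrichment.write_enrichment_tsv(enriched, outdir)

    # ---- expression -------------------------------------------------------
    if synthetic_mode:
        fx_expr = fx
        if not fx.de_genes:
            # designate the key targets as the true DE genes, alternating sign
            de = [(g, 2.0 if i % 2 == 0 else -2.0) for i, g in enumerate(key_genes)]
            fx_expr = fx.model_copy(update={"de_genes": de})
        matrix = synthetic.gen_expression_matrix(fx_expr)
        expression.write_expression(
            matrix, indir / "expression.tsv", indir / "expression_labels.tsv"
        )
        matrix = expression.read_expression(
            indir / "expression.tsv", indir / "expression_labels.tsv"
        )
    else:
        matrix = expression.read_expression(
            cfg.inputs.expression_values, cfg.inputs.expression_labels
        )
    testable = [g for g in key_genes if g in matrix.values.index]
    report.counts["key_genes_in_expression"] = len(testable)
    if testable:
        results = expression.two_group_test(matrix, testable)
        expression.write_results(results, outdir / "expression_results.tsv")
        report.counts["key_genes_significant"] = int((results["p"] < 0.05).sum())
    else:
        report.counts["key_genes_significant"] = 0

    return finish(None, None)
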