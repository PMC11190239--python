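"""End-to-end orchestration: simulate/load -> preprocess -> periods ->
landscape -> phenotypes -> dynamics -> health, with per-stage manifests.

Every run writes its resolved configuration next to the outputs and a
manifest recording unit counts in and out of each stage (nights filtered,
blocks dropped per exclusion reason, ...), so the accounting mirrors the
filtering story of the analysis it implements.  All randomness flows from
one master seed, split per stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from ._errors import ConfigError
from .dynamics import build_ctp, extract_transition_pairs, transition_summaries
from .health import CohortDesign, static_vs_dynamic
from .landscape import (
    DbscanParams,
    UmapParams,
    characterize_clusters,
    fit_landscape,
    rule_based_cluster,
    silhouette_by_cluster,
)
from .periods import build_candidate_periods, build_periods
from .phenotypes import assign_phenotypes, phenotype_report
from .preprocess import filter_nights, nights_to_frame
from .simulate import GeneratorConfig, generate_population

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved parameters for a full run.

    ``generator`` is used when ``hypnogram_path`` is None; otherwise nights
    are read from ``hypnogram_path``/``nights_path``.  ``labelling`` selects
    the phenotype route: "embedding" (UMAP + DBSCAN + geometry) or "rules"
    (deterministic composition rules; Cluster 0 stays unsplit).
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    hypnogram_path: str | None = None
    nights_path: str | None = None
    survey_path: str | None = None
    symptoms_path: str | None = None
    labelling: str = "embedding"
    umap_params: UmapParams = field(default_factory=UmapParams)
    dbscan_params: DbscanParams = field(default_factory=DbscanParams)
    min_periods: int = 500
    periphery_fraction: float = 0.084
    block_days: int = 6
    max_section_nonwear_h: float = 5.0
    health_conditions: tuple[CohortDesign, ...] = ()
    # added to every contingency cell when > 0; keeps sparse dynamic
    # categories from aborting the chi-square stage on small populations
    chi2_pseudocount: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.labelling not in ("embedding", "rules"):
            raise ConfigError("labelling must be 'embedding' or 'rules'")

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        gen = d["generator"]
        gen["truth_transition_matrix"] = np.asarray(
            self.generator.truth_transition_matrix
        ).tolist()
        gen["initial_distribution"] = np.asarray(
            self.generator.initial_distribution
        ).tolist()
        gen["start_date"] = self.generator.start_date.isoformat()
        return d


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, write artifacts under ``outdir``, return results.

    Returns a dict with the in-memory tables (nights, periods, labelled
    periods, transition graph, summaries, health reports) and the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_json(config.to_jsonable(), outdir / "config.json")
    manifest: dict = {"stages": {}}

    # --- inputs -----------------------------------------------------------
    survey = symptoms = None
    truth = None
    if config.hypnogram_path is not None:
        for p in (config.hypnogram_path, config.nights_path):
            if p is None or not Path(p).exists():
                raise ConfigError(f"input path missing: {p}")
        nights_raw = io.read_hypnograms(config.hypnogram_path, config.nights_path)
        if config.survey_path:
            survey = io.read_table(config.survey_path)
        if config.symptoms_path:
            symptoms = io.read_table(config.symptoms_path, date_cols=["report_date"])
        logger.info("loaded %d nights", len(nights_raw))
    else:
        gen_config = dataclasses.replace(config.generator, seed=config.seed)
        nights_raw, survey, symptoms, truth = generate_population(gen_config)
        io.write_truth(truth, outdir / "truth.jsonl")
        logger.info("simulated %d nights", len(nights_raw))
    manifest["stages"]["input"] = {"nights": len(nights_raw)}

    # --- preprocessing ----------------------------------------------------
    nights = filter_nights(nights_raw)
    night_features = nights_to_frame(nights)
    manifest["stages"]["preprocess"] = {
        "nights_in": len(nights_raw),
        "nights_kept": len(nights),
    }

    # --- periods ----------------------------------------------------------
    periods, dropped = build_periods(
        night_features,
        block_days=config.block_days,
        max_section_nonwear_h=config.max_section_nonwear_h,
    )
    if periods.empty:
        raise ConfigError("no sleep periods survive the exclusion criteria")
    night_features = build_candidate_periods(night_features, block_days=config.block_days)
    audit = night_features.drop(columns=["windows"])
    io.write_table(audit, outdir / "night_features.csv")
    io.write_periods(periods, outdir / "periods.csv")
    manifest["stages"]["periods"] = {
        "candidates": len(periods) + len(dropped),
        "kept": len(periods),
        "dropped_by_reason": dropped["reason"].value_counts().to_dict()
        if len(dropped)
        else {},
    }

    # --- landscape + phenotypes -------------------------------------------
    model = None
    if config.labelling == "embedding":
        model = fit_landscape(
            periods,
            umap_params=config.umap_params,
            dbscan_params=config.dbscan_params,
            seed=config.seed,
            min_periods=min(config.min_periods, len(periods)),
        )
        summary, semantic_map = characterize_clusters(model.cluster_id, periods)
        model.semantic_map = semantic_map
        semantic = model.semantic_labels()
        embedding = model.embedding
        io.write_table(summary, outdir / "cluster_summary.csv")
        if model.n_clusters > 1:
            sil = silhouette_by_cluster(model.embedding, model.cluster_id)
            sil.to_csv(outdir / "silhouette.csv", index_label="cluster_id")
        emb = periods[["individual_id", "period_index"]].copy()
        emb[["x", "y"]] = embedding
        emb["cluster_id"] = model.cluster_id
        emb["semantic_cluster"] = semantic
        io.write_table(emb, outdir / "embedding.csv")
    else:
        semantic = rule_based_cluster(periods)
        embedding = None
    labelled = assign_phenotypes(
        periods,
        semantic,
        embedding,
        periphery_fraction=config.periphery_fraction,
    )
    io.write_periods(labelled, outdir / "phenotype_labels.csv")
    pheno_summary = phenotype_report(labelled, night_features)
    io.write_table(pheno_summary, outdir / "phenotype_report.csv")
    manifest["stages"]["phenotypes"] = {
        "n_subclusters": int(labelled["subcluster"].nunique())
    }

    # --- dynamics ---------------------------------------------------------
    pairs = extract_transition_pairs(labelled)
    graph = build_ctp(pairs)
    io.write_matrix(graph.count_matrix, graph.nodes, outdir / "transition_counts.csv")
    io.write_matrix(graph.ctp_matrix, graph.nodes, outdir / "transition_ctp.csv")
    io.write_table(graph.to_edge_list(), outdir / "transition_edges.csv")
    summaries = transition_summaries(graph)
    io.write_table(summaries, outdir / "transition_summaries.csv")
    manifest["stages"]["dynamics"] = {"pairs": len(pairs)}

    # --- health -----------------------------------------------------------
    health_reports = []
    for design in config.health_conditions:
        rep = static_vs_dynamic(
            labelled,
            pairs,
            design,
            survey=survey,
            symptoms=symptoms,
            pseudocount=config.chi2_pseudocount,
        )
        health_reports.append(rep)
    if health_reports:
        io.write_json(health_reports, outdir / "health_reports.json")
        io.write_table(pd.DataFrame(health_reports), outdir / "health_reports.csv")
    manifest["stages"]["health"] = {"conditions": len(health_reports)}

    io.write_json(manifest, outdir / "manifest.json")
    return {
        "nights": night_features,
        "periods": periods,
        "labelled": labelled,
        "pairs": pairs,
        "graph": graph,
        "summaries": summaries,
        "health": health_reports,
        "truth": truth,
        "model": model,
        "manifest": manifest,
    }
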