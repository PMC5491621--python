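"""One-command orchestration of the full analysis.

Stage order mirrors the analysis flow: quantify (NSAF, metabolite
normalization) -> presence filter -> stage averaging / integration ->
ANOVA + Duncan -> PCA -> hierarchical bi-clustering + Venn ->
restart-selected k-means -> Granger causality (features and clusters) ->
network assembly -> exports. A run manifest records the config hash,
seed, package versions and per-stage record counts; given the same
config and seed the output directory is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .granger import build_network, granger_all_pairs, granger_clusters, node_table
from .io_formats import (
    AbundanceMatrix,
    SampleDesign,
    read_abundance,
    read_spectral_counts,
    write_abundance,
    write_design,
    write_edge_table,
    write_ground_truth,
    write_network_graphml,
    write_network_sif,
    write_spectral_counts,
)
from .multivariate import (
    anova_table,
    group_specific_features,
    hierarchical_bicluster,
    kmeans_restarts,
    pca,
)
from .quantify import (
    compute_nsaf,
    integrate,
    normalize_metabolites,
    presence_filter,
    stage_average,
)
from .synthetic import CausalLink, SyntheticSpec, generate_dataset

logger = logging.getLogger(__name__)

try:  # stdlib on 3.11+
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run.

    Defaults are the canonical analysis settings: k = 12 clusters,
    100 k-means restarts, Granger lags {1, 2, 3}, alpha = 0.05, no
    multiple-testing correction.
    """

    out_dir: str = "run"
    # either file inputs ...
    counts_path: str | None = None
    metabolites_path: str | None = None
    design_path: str | None = None
    # ... or a synthetic dataset
    synthetic: SyntheticSpec | None = None
    # analysis settings
    gc_mode: str = "internal_standard"
    lc_mode: str = "total_ion"
    zscore: bool = True
    k: int = 12
    restarts: int = 100
    k_groups: int = 3
    lags: tuple[int, ...] = (1, 2, 3)
    alpha: float = 0.05
    fdr: str = "off"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.synthetic is None and not (
            self.counts_path and self.metabolites_path and self.design_path
        ):
            raise ValueError("config needs either a synthetic spec or all three input paths")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.fdr not in ("off", "bh"):
            raise ValueError("fdr must be 'off' or 'bh'")
        if self.k < 1 or self.restarts < 1 or self.k_groups < 1:
            raise ValueError("k, restarts and k_groups must be >= 1")
        if any(l < 1 for l in self.lags):
            raise ValueError("lags must be >= 1")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        syn = raw.pop("synthetic", None)
        if syn is not None:
            links = [CausalLink(**l) for l in syn.pop("causal_links", [])]
            syn = SyntheticSpec(causal_links=links, **syn)
        if "lags" in raw:
            raw["lags"] = tuple(raw["lags"])
        return cls(synthetic=syn, **raw)

    def content_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded,
        so re-running the same analysis elsewhere is recognizably the same)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to everything the run wrote to disk."""

    out_dir: Path
    design: SampleDesign
    nsaf: AbundanceMatrix
    metabolites: AbundanceMatrix
    integrated: "StageSeries"
    anova: pd.DataFrame
    pca: "PcaResult"
    grouping: "SampleGrouping"
    venn: "VennCounts"
    clusters: "ClusterModel"
    feature_edges: list
    cluster_edges: list
    network: "GrangerNetwork"
    manifest: dict = field(default_factory=dict)


def _kmeans_seed(seed: int) -> int:
    """Derive an independent k-means restart stream from the run seed."""
    return int(np.random.SeedSequence([seed, 0x6B6D]).generate_state(1)[0] % (2**31))


def _log_stage(name: str, t0: float, **counts) -> None:
    parts = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, parts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        counts, met_raw, design, truth = generate_dataset(spec)
        write_spectral_counts(counts, out / "input_spectral_counts.tsv")
        write_abundance(met_raw, out / "input_metabolites_raw.tsv")
        write_design(design, out / "input_design.tsv")
        write_ground_truth(truth, out)
    else:
        counts, design = read_spectral_counts(config.counts_path, config.design_path)
        met_raw, _ = read_abundance(config.metabolites_path, config.design_path)
    stage_counts["input_proteins"] = counts.counts.shape[0]
    stage_counts["input_metabolites"] = met_raw.values.shape[0]
    _log_stage("input", t0, **stage_counts)

    # --- quantify ---------------------------------------------------------
    t0 = time.perf_counter()
    nsaf = compute_nsaf(counts)
    gc = met_raw.of_kind("metabolite_gc")
    lc = met_raw.of_kind("metabolite_lc")
    parts = []
    if gc.values.shape[0]:
        parts.append(normalize_metabolites(gc, design, config.gc_mode))
    if lc.values.shape[0]:
        parts.append(normalize_metabolites(lc, design, config.lc_mode))
    met_norm = AbundanceMatrix(
        pd.concat([p.values for p in parts]).loc[met_raw.features],
        pd.concat([p.kinds for p in parts]).loc[met_raw.features],
    )
    _log_stage("quantify", t0)

    # --- presence filter --------------------------------------------------
    t0 = time.perf_counter()
    nsaf_f = presence_filter(nsaf, design)
    met_f = presence_filter(met_norm, design)
    stage_counts["filtered_proteins"] = nsaf_f.values.shape[0]
    stage_counts["filtered_metabolites"] = met_f.values.shape[0]
    write_abundance(nsaf_f, out / "proteins_nsaf_filtered.tsv")
    write_abundance(met_f, out / "metabolites_normalized_filtered.tsv")
    _log_stage("presence_filter", t0, proteins=stage_counts["filtered_proteins"],
               metabolites=stage_counts["filtered_metabolites"])

    # --- stage averaging / integration ------------------------------------
    t0 = time.perf_counter()
    met_series = stage_average(met_f, design, zscore=False)
    prot_series = stage_average(nsaf_f, design, zscore=False)
    integrated = integrate(met_series, prot_series)
    if not config.zscore:
        combined = pd.concat(
            [
                met_series.values.rename(index=lambda f: f"met:{f}"),
                prot_series.values.rename(index=lambda f: f"prot:{f}"),
            ]
        )
        from .quantify import StageSeries

        integrated = StageSeries(combined, zscored=False)
    stage_counts["integrated_features"] = integrated.values.shape[0]
    integrated.values.rename_axis("feature_id").to_csv(
        out / "integrated_stage_series.tsv", sep="\t", float_format="%.10g"
    )
    _log_stage("integrate", t0, features=stage_counts["integrated_features"])

    # --- ANOVA + Duncan ----------------------------------------------------
    t0 = time.perf_counter()
    anova_prot = anova_table(nsaf_f, design, alpha=config.alpha)
    anova_met = anova_table(met_f, design, alpha=config.alpha)
    anova_all = pd.concat(
        [
            anova_met.rename(index=lambda f: f"met:{f}"),
            anova_prot.rename(index=lambda f: f"prot:{f}"),
        ]
    )
    anova_all.to_csv(out / "anova_duncan.tsv", sep="\t", float_format="%.10g")
    stage_counts["anova_features"] = anova_all.shape[0]
    _log_stage("anova", t0, features=anova_all.shape[0])

    # --- PCA ---------------------------------------------------------------
    t0 = time.perf_counter()
    pca_res = pca(integrated)
    pca_res.scores.rename_axis("sample").to_csv(out / "pca_scores.tsv", sep="\t", float_format="%.10g")
    pca_res.loadings.rename_axis("feature_id").to_csv(
        out / "pca_loadings.tsv", sep="\t", float_format="%.10g"
    )
    pd.Series(
        pca_res.variance_explained,
        index=[f"PC{i + 1}" for i in range(len(pca_res.variance_explained))],
        name="variance_explained_pct",
    ).rename_axis("component").to_csv(out / "pca_variance.tsv", sep="\t", float_format="%.10g")
    _log_stage("pca", t0)

    # --- hierarchical bi-clustering + Venn ---------------------------------
    t0 = time.perf_counter()
    bic = hierarchical_bicluster(integrated.values, k_groups=config.k_groups)
    bic.grouping.membership.rename("group").rename_axis("stage").to_csv(
        out / "sample_groups.tsv", sep="\t"
    )
    venn = group_specific_features(nsaf_f, design, bic.grouping)
    venn_rows = [
        {"region": "+".join(str(g) for g in key), "count": venn.counts[key]}
        for key in sorted(venn.counts)
    ]
    pd.DataFrame(venn_rows).to_csv(out / "venn_protein_groups.tsv", sep="\t", index=False)
    _log_stage("bicluster", t0, groups=config.k_groups)

    # --- k-means -----------------------------------------------------------
    t0 = time.perf_counter()
    model = kmeans_restarts(integrated, k=config.k, restarts=config.restarts,
                            seed=_kmeans_seed(config.seed))
    model.assignments.rename("cluster").rename_axis("feature_id").to_csv(
        out / "kmeans_assignments.tsv", sep="\t"
    )
    model.centroids.rename_axis("cluster").to_csv(
        out / "kmeans_centroids.tsv", sep="\t", float_format="%.10g"
    )
    stage_counts["kmeans_clusters"] = model.k
    _log_stage("kmeans", t0, total_distance=round(model.total_distance, 4))

    # --- Granger causality --------------------------------------------------
    t0 = time.perf_counter()
    feature_edges = granger_all_pairs(integrated, lags=config.lags, alpha=config.alpha,
                                      fdr=config.fdr)
    cluster_edges = granger_clusters(model, lags=config.lags, alpha=config.alpha,
                                     fdr=config.fdr)
    write_edge_table(feature_edges, out / "granger_edges_features.tsv")
    write_edge_table(cluster_edges, out / "granger_edges_clusters.tsv")
    stage_counts["granger_feature_edges"] = len(feature_edges)
    stage_counts["granger_cluster_edges"] = len(cluster_edges)
    _log_stage("granger", t0, feature_edges=len(feature_edges),
               cluster_edges=len(cluster_edges))

    # --- network -----------------------------------------------------------
    t0 = time.perf_counter()
    network = build_network(feature_edges)
    write_network_sif(network, out / "granger_network.sif")
    write_network_graphml(network, out / "granger_network.graphml")
    node_table(network).to_csv(out / "granger_nodes.tsv", sep="\t")
    cluster_net = build_network(cluster_edges)
    write_network_sif(cluster_net, out / "granger_cluster_network.sif")
    stage_counts["network_nodes"] = len(network.nodes)
    _log_stage("network", t0, nodes=len(network.nodes),
               mean_neighbors=round(network.mean_neighbors, 3))

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "berrychron": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": stage_counts,
        "mean_neighbors": network.mean_neighbors,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return PipelineResult(
        out_dir=out,
        design=design,
        nsaf=nsaf_f,
        metabolites=met_f,
        integrated=integrated,
        anova=anova_all,
        pca=pca_res,
        grouping=bic.grouping,
        venn=venn,
        clusters=model,
        feature_edges=feature_edges,
        cluster_edges=cluster_edges,
        network=network,
        manifest=manifest,
    )


def configure_logging(verbose: bool = True, logfile=None) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(message)s",
        handlers=handlers,
        force=True,
    )
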