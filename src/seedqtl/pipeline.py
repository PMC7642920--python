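"""End-to-end orchestration: per-stage mapping, hotspots, networks, overview.

Every run is reproducible from a master seed; child seeds are derived as
``SeedSequence([master, stage_index])`` for mapping and
``SeedSequence([master, 100 + hotspot_index])`` for network inference.
Each output file carries a ``#`` header naming the package version and a
hash of the run configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataio import (
    read_expression,
    read_gene_annotation,
    read_genotypes,
    read_marker_map,
    write_table,
)
from .eqtl import EqtlMapper, shared_eqtl_counts
from .grn import NetworkEnsemble, assemble_candidate_set
from .hotspot import HotspotDetector
from .overview import (
    STAGE_ORDER,
    abs_pearson_distance,
    consecutive_fold_change_filter,
    pca_variance,
    ward_cluster,
)

log = logging.getLogger("seedqtl")

__all__ = ["RunConfig", "load_inputs", "run_stage", "run_full"]


@dataclass
class RunConfig:
    markers_path: str = ""
    genotypes_path: str = ""
    expression_path: str = ""
    genes_path: str = ""
    design_path: str = ""
    output_dir: str = "seedqtl_out"
    q: float = 0.05
    n_permutations: int = 100
    bin_width: int = 2_000_000
    hotspot_alpha: float = 1e-4
    ci_drop: float = 1.5
    local_window_bp: int = 1_000_000
    threshold_log_base: str = "e"
    grn_methods: tuple = ("spearman", "clr", "aracne", "genie3", "tigress")
    grn_mi_bins: int = 10
    genie3_trees: int = 1000
    tigress_resamples: int = 500
    tigress_alpha: float = 0.2
    tigress_steps: int = 5
    network_hotspots: tuple = ()  # hotspot ids; empty = all detected
    min_fold_change: float = 2.0
    n_clusters: int = 8
    chrom_lengths: dict = field(default_factory=dict)  # inferred if empty
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.q < 1):
            raise ValueError("q must lie in (0, 1)")
        for name in ("n_permutations", "bin_width", "ci_drop", "local_window_bp",
                     "hotspot_alpha", "min_fold_change", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        from .grn import METHODS
        if set(self.grn_methods) - set(METHODS):
            raise ValueError(f"grn_methods must be a subset of {METHODS}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header(self) -> str:
        return f"seedqtl v{__version__} config={self.config_hash()}"


def _child_seed(master: int, *path: int) -> int:
    return int(np.random.SeedSequence([int(master), *path]).generate_state(1)[0] % (2 ** 31))


def load_inputs(cfg: RunConfig) -> dict:
    mmap = read_marker_map(cfg.markers_path)
    geno = read_genotypes(cfg.genotypes_path, mmap)
    expr = read_expression(cfg.expression_path)
    genes = read_gene_annotation(cfg.genes_path)
    design = pd.read_csv(cfg.design_path, sep="\t", comment="#", index_col=0)["stage"]
    return {"marker_map": mmap, "genotypes": geno, "expression": expr,
            "genes": genes, "design": design}


def _chrom_lengths(cfg: RunConfig, mmap: pd.DataFrame, genes: pd.DataFrame) -> dict:
    if cfg.chrom_lengths:
        return {str(k): int(v) for k, v in cfg.chrom_lengths.items()}
    lengths = {}
    for chrom, sub in mmap.groupby("chromosome"):
        lengths[str(chrom)] = int(sub["position_bp"].max()) + 1
    for chrom, sub in genes.groupby("chromosome"):
        lengths[str(chrom)] = max(lengths.get(str(chrom), 0), int(sub["end_bp"].max()) + 1)
    return lengths


def run_stage(cfg: RunConfig, data: dict, stage: str, outdir: Path | None = None):
    """Map eQTLs for one stage subpopulation; returns (records, threshold)."""
    design = data["design"]
    samples = design.index[design == stage]
    if len(samples) == 0:
        raise ValueError(f"stage {stage!r} absent from the design")
    stage_index = list(dict.fromkeys(design)).index(stage)
    mapper = EqtlMapper(
        q=cfg.q, n_permutations=cfg.n_permutations, ci_drop=cfg.ci_drop,
        local_window_bp=cfg.local_window_bp,
        threshold_log_base=cfg.threshold_log_base,
        random_state=_child_seed(cfg.seed, stage_index),
    )
    mapper.fit(data["expression"][samples], data["genotypes"].loc[samples],
               data["marker_map"], data["genes"], stage=stage)
    rec = mapper.records_
    n_local = int((rec["type"] == "local").sum())
    n_distant = int((rec["type"] == "distant").sum())
    log.info("stage %s: threshold %.1f, %d eQTLs (%d genes), %d local (%.2f), %d distant",
             stage, mapper.threshold_.threshold, len(rec), rec["gene"].nunique(),
             n_local, n_local / max(len(rec), 1), n_distant)
    if outdir is not None:
        write_table(rec.set_index("gene"), outdir / f"eqtl_{stage}.tsv", cfg.header())
    return rec, mapper.threshold_


def run_full(cfg: RunConfig, data: dict | None = None) -> dict:
    """Run the whole pipeline and write all artifacts under ``cfg.output_dir``.

    Returns a dict with the per-stage records, thresholds, hotspot table,
    per-hotspot networks/priorities, overview outputs and the summary.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    if data is None:
        data = load_inputs(cfg)
    stages = [s for s in STAGE_ORDER if s in set(data["design"])]
    stages += [s for s in dict.fromkeys(data["design"]) if s not in stages]
    chrom_lengths = _chrom_lengths(cfg, data["marker_map"], data["genes"])

    records_by_stage, thresholds = {}, {}
    for stage in stages:
        rec, thr = run_stage(cfg, data, stage, outdir)
        records_by_stage[stage] = rec
        thresholds[stage] = thr.threshold

    # hotspots per stage
    hotspot_tables = []
    for stage in stages:
        det = HotspotDetector(bin_width=cfg.bin_width, alpha=cfg.hotspot_alpha)
        det.fit(records_by_stage[stage], chrom_lengths, stage_prefix=stage)
        tab = det.hotspots_.copy()
        tab.insert(0, "stage", stage)
        hotspot_tables.append(tab)
    hotspots = (pd.concat(hotspot_tables, ignore_index=True)
                if hotspot_tables else pd.DataFrame())
    if len(hotspots):
        cols = ["hotspot_id", "stage", "chromosome", "start_bp", "end_bp",
                "observed", "expected", "p_value"]
        write_table(hotspots[cols].set_index("hotspot_id"),
                    outdir / "hotspots.tsv", cfg.header())
    log.info("detected %d hotspots", len(hotspots))

    # networks per hotspot
    networks = {}
    wanted = set(cfg.network_hotspots) or set(hotspots.get("hotspot_id", []))
    for h_idx, row in enumerate(hotspots.itertuples(index=False)):
        if row.hotspot_id not in wanted:
            continue
        stage = row.stage
        samples = data["design"].index[data["design"] == stage]
        try:
            cs = assemble_candidate_set(
                records_by_stage[stage],
                pd.DataFrame([{"chromosome": row.chromosome,
                               "start_bp": row.start_bp, "end_bp": row.end_bp}]),
                data["expression"][samples])
        except ValueError as exc:
            log.warning("hotspot %s skipped: %s", row.hotspot_id, exc)
            continue
        ens = NetworkEnsemble(
            methods=tuple(cfg.grn_methods), n_bins=cfg.grn_mi_bins,
            genie3_trees=cfg.genie3_trees,
            tigress_resamples=cfg.tigress_resamples,
            tigress_alpha=cfg.tigress_alpha, tigress_steps=cfg.tigress_steps,
            random_state=_child_seed(cfg.seed, 100 + h_idx),
        )
        ens.fit(cs["expression"], cs["candidates"], cs["targets"])
        networks[row.hotspot_id] = ens
        write_table(ens.network_.set_index("source"),
                    outdir / f"network_edges_{row.hotspot_id}.tsv", cfg.header())
        with open(outdir / f"network_{row.hotspot_id}.sif", "w", encoding="utf-8") as fh:
            for e in ens.network_.itertuples(index=False):
                fh.write(f"{e.source}\tregulates\t{e.target}\n")
        write_table(ens.centralities_.join(
                        ens.priorities_[["priority_rank"]], how="left"),
                    outdir / f"candidates_{row.hotspot_id}.tsv", cfg.header())
        log.info("hotspot %s: %d nodes, %d edges, top candidate %s",
                 row.hotspot_id, len(ens.centralities_), len(ens.network_),
                 ens.priorities_.index[0])

    # overview
    scores, fractions = pca_variance(data["expression"])
    pca = scores.copy()
    pca.insert(0, "stage", data["design"].reindex(pca.index))
    write_table(pca, outdir / "pca.tsv", cfg.header())
    write_table(fractions.rename("variance_fraction").to_frame(),
                outdir / "pca_variance.tsv", cfg.header())
    filtered = consecutive_fold_change_filter(
        data["expression"], data["design"], cfg.min_fold_change)
    clusters = pd.Series(dtype=int)
    if len(filtered) >= cfg.n_clusters:
        dist = abs_pearson_distance(data["expression"].loc[filtered])
        clusters = ward_cluster(dist, cfg.n_clusters)
        write_table(clusters.to_frame(), outdir / "clusters.tsv", cfg.header())

    shared = (shared_eqtl_counts(records_by_stage)
              if len(records_by_stage) >= 2 else pd.DataFrame())
    if len(shared):
        write_table(shared.set_index("type"), outdir / "shared_eqtl.tsv", cfg.header())

    summary = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "stages": stages,
        "thresholds": thresholds,
        "n_eqtl": {s: int(len(r)) for s, r in records_by_stage.items()},
        "n_genes_with_eqtl": {s: int(r["gene"].nunique())
                              for s, r in records_by_stage.items()},
        "n_local": {s: int((r["type"] == "local").sum())
                    for s, r in records_by_stage.items()},
        "n_distant": {s: int((r["type"] == "distant").sum())
                      for s, r in records_by_stage.items()},
        "n_hotspots": int(len(hotspots)),
        "hotspot_ids": list(hotspots.get("hotspot_id", [])),
        "top_candidates": {h: list(net.priorities_.index[:3])
                           for h, net in networks.items()},
        "n_filtered_genes": int(len(filtered)),
        "pc1_variance_fraction": float(fractions.iloc[0]),
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return {"records": records_by_stage, "thresholds": thresholds,
            "hotspots": hotspots, "networks": networks,
            "pca_fractions": fractions, "filtered_genes": filtered,
            "clusters": clusters, "shared": shared, "summary": summary}
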