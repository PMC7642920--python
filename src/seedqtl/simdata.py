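"""Synthetic RIL genotypes and expression with planted eQTL ground truth.

The generator emulates a staged genetical-genomics design: a biparental
recombinant-inbred population split into one subpopulation per germination
stage, genotyped at ~1,000 biallelic markers on five chromosomes, with
gene-level log2 expression driven by an additive model

    y = mu + sum_k beta_k * g_k + effects(hotspots) + eps,   eps ~ N(0, noise_sd^2)

with genotypes coded -1 (allele A) / +1 (allele B).  Recombination along a
chromosome follows the Haldane map function r = (1 - exp(-2d))/2 on the
inter-marker distance d in Morgans, expanded for a selfed RIL to
R = 2r / (1 + 2r); chromosomes segregate independently.

Planted structure (local eQTLs, hotspot master regulators with their distant
targets) is returned as a truth table so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import write_table

STAGES = ("PD", "AR", "IM", "RP")

#: Approximate Arabidopsis thaliana chromosome lengths (bp).
DEFAULT_CHROM_LENGTHS = (30_400_000, 19_700_000, 23_500_000, 18_600_000, 26_900_000)

__all__ = [
    "STAGES",
    "DEFAULT_CHROM_LENGTHS",
    "HotspotSpec",
    "SimConfig",
    "simulate_marker_map",
    "simulate_ril_genotypes",
    "simulate_expression",
    "simulate_study",
    "simulate_network_scenario",
    "write_fixture_set",
]


@dataclass(frozen=True)
class HotspotSpec:
    """A planted master regulator driving many distant targets.

    The regulator is a gene with a strong local eQTL at (chromosome,
    position_bp).  Targets receive ``target_effect`` times either the
    regulator's standardized expression (``expression_mediated``) or the
    genotype at the regulator's marker (``genotype_direct``).
    """

    chromosome: str
    position_bp: int
    n_targets: int
    target_effect: float = 1.2
    mediation: str = "expression_mediated"
    regulator_r2: float = 0.6

    def __post_init__(self):
        if self.mediation not in ("expression_mediated", "genotype_direct"):
            raise ValueError(f"unknown mediation mode: {self.mediation}")
        if self.n_targets < 0:
            raise ValueError("n_targets must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_lines: int = 40
    n_stages: int = 4
    chrom_lengths_bp: tuple[int, ...] = DEFAULT_CHROM_LENGTHS
    n_markers: int = 1059
    cm_per_mb: float = 4.0
    n_genes: int = 1000
    local_fraction: float = 0.3
    local_r2: float = 0.3
    noise_sd: float = 1.0
    stage_fraction: float = 0.05
    stage_effect_sd: float = 2.0
    hotspot_spec: tuple[HotspotSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_lines, self.n_stages, self.n_markers) <= 0 or self.n_genes < 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.local_fraction <= 1 and 0 <= self.local_r2 < 1
                and 0 <= self.stage_fraction <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if any(l <= 0 for l in self.chrom_lengths_bp):
            raise ValueError("chromosome lengths must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def _chrom_names(cfg: SimConfig) -> list[str]:
    return [str(i + 1) for i in range(len(cfg.chrom_lengths_bp))]


def simulate_marker_map(cfg: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Place ``n_markers`` uniformly over the genome, proportional to length."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lengths = np.asarray(cfg.chrom_lengths_bp, dtype=float)
    total = lengths.sum()
    # proportional allocation, remainders to the longest chromosomes
    raw = cfg.n_markers * lengths / total
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts))[: cfg.n_markers - counts.sum()]:
        counts[i] += 1
    rows = []
    k = 0
    for name, length, c in zip(_chrom_names(cfg), lengths, counts):
        pos = np.sort(rng.integers(0, int(length), size=c))
        for p in pos:
            rows.append((f"M{k:05d}", name, int(p)))
            k += 1
    mmap = pd.DataFrame(rows, columns=["marker", "chromosome", "position_bp"]).set_index("marker")
    return mmap


def _switch_probabilities(positions_bp: np.ndarray, cm_per_mb: float) -> np.ndarray:
    """Adjacent-marker switch probability on a selfed-RIL genome.

    Haldane: r = (1 - exp(-2d))/2 with d in Morgans; RIL map expansion
    R = 2r / (1 + 2r).
    """
    d_morgan = np.diff(positions_bp) / 1e6 * cm_per_mb / 100.0
    r = (1.0 - np.exp(-2.0 * d_morgan)) / 2.0
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril_genotypes(
    marker_map: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator | None = None,
    line_prefix: str = "L",
) -> pd.DataFrame:
    """Draw homozygous RIL genotypes as a Markov chain along each chromosome."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_lines
    columns = {}
    for chrom, sub in marker_map.groupby("chromosome", sort=False):
        pos = sub["position_bp"].to_numpy()
        R = _switch_probabilities(pos, cfg.cm_per_mb)
        state = rng.random(n) < 0.5  # True = B allele
        states = [state]
        for j in range(len(pos) - 1):
            flip = rng.random(n) < R[j]
            state = state ^ flip
            states.append(state)
        for marker, s in zip(sub.index, states):
            columns[marker] = np.where(s, "B", "A")
    lines = [f"{line_prefix}{i:03d}" for i in range(n)]
    geno = pd.DataFrame(columns, index=pd.Index(lines, name="line"))
    return geno.loc[:, marker_map.index]


def _local_beta(local_r2: float, noise_sd: float) -> float:
    # beta^2 Var(g) / (beta^2 Var(g) + noise^2) = r2 with Var(g) = 1
    return noise_sd * np.sqrt(local_r2 / (1.0 - local_r2))


def _nearest_marker(mmap: pd.DataFrame, chrom: str, bp: int) -> str:
    sub = mmap[mmap["chromosome"] == chrom]
    if sub.empty:
        raise ValueError(f"hotspot regulator locus on unknown chromosome {chrom!r}")
    return sub.index[np.argmin(np.abs(sub["position_bp"].to_numpy() - bp))]


def simulate_expression(
    geno: pd.DataFrame,
    marker_map: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    baseline: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate gene-level log2 expression with planted eQTL structure.

    Returns ``(expression, gene_annotation, truth)``.  The truth table has one
    row per planted effect: ``gene, causal_marker, beta, type, regulator``
    (``regulator`` is the regulator gene id for hotspot targets, else "").
    Gene starts for local-eQTL genes are placed within 1 Mb of their causal
    marker; hotspot targets are placed away from their causal locus so their
    eQTL is distant by construction.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lengths = dict(zip(_chrom_names(cfg), cfg.chrom_lengths_bp))
    g = pd.DataFrame(np.where(geno.to_numpy() == "B", 1.0, -1.0),
                     index=geno.index, columns=geno.columns)
    n_samples = len(geno)

    n_hot_genes = sum(1 + h.n_targets for h in cfg.hotspot_spec)
    if cfg.n_genes < n_hot_genes:
        raise ValueError("n_genes too small for the requested hotspot_spec")

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    ann_rows: dict[str, tuple[str, int, int]] = {}
    truth_rows: list[tuple[str, str, float, str, str]] = []
    expr = pd.DataFrame(
        rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples)),
        index=pd.Index(gene_ids, name="gene"), columns=geno.index,
    )
    if baseline is None:
        baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)  # per-gene mean log2 level
    expr = expr.add(baseline, axis=0)

    def place_random_gene(gid: str, avoid: tuple[str, int] | None = None, min_dist: int = 3_000_000):
        while True:
            chrom = rng.choice(list(lengths))
            start = int(rng.integers(0, lengths[chrom] - 1000))
            if avoid is None or chrom != avoid[0] or abs(start - avoid[1]) > min_dist:
                ann_rows[gid] = (chrom, start, start + 1000)
                return

    pool = iter(gene_ids)

    # hotspot regulators and their targets first
    for h_idx, h in enumerate(cfg.hotspot_spec):
        reg_marker = _nearest_marker(marker_map, str(h.chromosome), h.position_bp)
        reg_pos = int(marker_map.loc[reg_marker, "position_bp"])
        reg_gene = next(pool)
        start = max(0, min(reg_pos, lengths[str(h.chromosome)] - 1000))
        ann_rows[reg_gene] = (str(h.chromosome), start, start + 1000)
        beta_reg = _local_beta(h.regulator_r2, cfg.noise_sd)
        expr.loc[reg_gene] += beta_reg * g[reg_marker]
        truth_rows.append((reg_gene, reg_marker, beta_reg, "local", ""))

        reg_std = (expr.loc[reg_gene] - expr.loc[reg_gene].mean()) / expr.loc[reg_gene].std(ddof=0)
        for _ in range(h.n_targets):
            gid = next(pool)
            place_random_gene(gid, avoid=(str(h.chromosome), reg_pos))
            driver = reg_std if h.mediation == "expression_mediated" else g[reg_marker]
            expr.loc[gid] += h.target_effect * driver
            truth_rows.append((gid, reg_marker, h.target_effect, "distant", reg_gene))

    # remaining genes: a local_fraction subset gets a local eQTL
    rest = list(pool)
    n_local = int(round(cfg.local_fraction * len(rest)))
    local_set = set(rng.choice(len(rest), size=n_local, replace=False)) if n_local else set()
    beta = _local_beta(cfg.local_r2, cfg.noise_sd) if cfg.local_r2 > 0 else 0.0
    marker_chrom = marker_map["chromosome"].to_numpy()
    marker_pos = marker_map["position_bp"].to_numpy()
    for i, gid in enumerate(rest):
        if i in local_set and beta > 0:
            m_idx = int(rng.integers(0, len(marker_map)))
            marker = marker_map.index[m_idx]
            chrom = marker_chrom[m_idx]
            # gene start within 1 Mb of its causal marker
            lo = max(0, marker_pos[m_idx] - 1_000_000)
            hi = min(lengths[chrom] - 1000, marker_pos[m_idx] + 1_000_000)
            start = int(rng.integers(lo, hi + 1))
            ann_rows[gid] = (chrom, start, start + 1000)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            expr.loc[gid] += sign * beta * g[marker]
            truth_rows.append((gid, marker, sign * beta, "local", ""))
        else:
            place_random_gene(gid)

    annotation = pd.DataFrame.from_dict(ann_rows, orient="index",
                                        columns=["chromosome", "start_bp", "end_bp"])
    annotation.index.name = "gene"
    annotation = annotation.loc[gene_ids]
    truth = pd.DataFrame(truth_rows, columns=["gene", "causal_marker", "beta", "type", "regulator"])
    return expr, annotation, truth


def simulate_study(cfg: SimConfig) -> dict:
    """Simulate the full staged design: one RIL subpopulation per stage.

    Stages share the marker map, gene annotation and planted truth (the same
    genes carry the same effects at every stage) but each stage is an
    independent draw of ``n_lines`` RIL genomes, mirroring disjoint
    subpopulations assayed at different germination stages.

    Returns a dict with keys ``marker_map``, ``genes``, ``truth``,
    ``genotypes`` (samples x markers over all stages), ``expression``
    (genes x samples), ``design`` (Series sample -> stage label).
    """
    root = np.random.default_rng(cfg.seed)
    mmap = simulate_marker_map(cfg, root)
    genos, exprs, design = [], [], {}
    genes = truth = None
    # study-level per-gene structure, identical across stages
    base_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 555]))
    baseline = base_rng.normal(8.0, 1.0, size=cfg.n_genes)
    n_stage_genes = int(round(cfg.stage_fraction * cfg.n_genes))
    stage_gene_idx = base_rng.choice(cfg.n_genes, size=n_stage_genes, replace=False)
    stage_offsets = base_rng.normal(0.0, cfg.stage_effect_sd,
                                    size=(n_stage_genes, cfg.n_stages))
    stage_names = [STAGES[i] if i < len(STAGES) else f"S{i}" for i in range(cfg.n_stages)]
    for s_idx, stage in enumerate(stage_names):
        stage_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, s_idx]))
        geno = simulate_ril_genotypes(mmap, cfg, stage_rng, line_prefix=f"{stage}_")
        # the same planted effects at every stage: reuse one effect-layout rng
        effect_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1000 + s_idx]))
        expr, g_ann, t = _expression_with_shared_truth(
            geno, mmap, cfg, effect_rng, genes, truth, baseline)
        if genes is None:
            genes, truth = g_ann, t
        expr.iloc[stage_gene_idx] += stage_offsets[:, s_idx][:, None]
        genos.append(geno)
        exprs.append(expr)
        design.update({s: stage for s in geno.index})
    genotypes = pd.concat(genos)
    expression = pd.concat(exprs, axis=1)
    return {
        "marker_map": mmap,
        "genes": genes,
        "truth": truth,
        "genotypes": genotypes,
        "expression": expression,
        "design": pd.Series(design, name="stage"),
    }


def _expression_with_shared_truth(geno, mmap, cfg, rng, genes, truth, baseline=None):
    """First call derives annotation+truth; later calls re-apply the same effects."""
    if genes is None:
        layout_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 999]))
        expr, genes, truth = simulate_expression(geno, mmap, cfg, layout_rng, baseline)
        return expr, genes, truth
    g = np.where(geno.to_numpy() == "B", 1.0, -1.0)
    g = pd.DataFrame(g, index=geno.index, columns=geno.columns)
    expr = pd.DataFrame(
        rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(geno))),
        index=genes.index, columns=geno.index,
    )
    if baseline is None:
        baseline = rng.normal(8.0, 1.0, size=cfg.n_genes)
    expr = expr.add(baseline, axis=0)
    reg_expr: dict[str, pd.Series] = {}
    for row in truth.itertuples(index=False):
        if row.type == "local":
            expr.loc[row.gene] += row.beta * g[row.causal_marker]
            std = expr.loc[row.gene].std(ddof=0)
            reg_expr[row.gene] = (expr.loc[row.gene] - expr.loc[row.gene].mean()) / std
    for row in truth.itertuples(index=False):
        if row.type == "distant":
            spec = _spec_for_regulator(cfg, row.regulator, truth)
            if spec is not None and spec.mediation == "genotype_direct":
                expr.loc[row.gene] += row.beta * g[row.causal_marker]
            else:
                expr.loc[row.gene] += row.beta * reg_expr[row.regulator]
    return expr, genes, truth


def _spec_for_regulator(cfg, regulator, truth):
    # regulators are emitted first, one local truth row per hotspot, in spec order
    reg_genes = truth[truth["type"] == "local"]["gene"].tolist()[: len(cfg.hotspot_spec)]
    if regulator not in reg_genes:
        return None
    return cfg.hotspot_spec[reg_genes.index(regulator)]


def simulate_network_scenario(
    n_candidates: int, n_targets: int, n_samples: int, hub_effect: float, seed: int,
) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    """Star-topology fixture for network inference: one true hub, decoy candidates.

    The first candidate (``hub``) linearly drives every target with slope
    ``hub_effect``; remaining candidates and residuals are independent unit
    Gaussians.  Returns ``(expression, candidate_set, truth)`` where
    ``candidate_set`` maps ``candidates``/``targets`` to gene-id lists.
    """
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    rng = np.random.default_rng(seed)
    cand_ids = [f"C{i:03d}" for i in range(n_candidates)]
    target_ids = [f"T{i:03d}" for i in range(n_targets)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    cand = rng.normal(size=(n_candidates, n_samples))
    hub = cand[0]
    targets = hub_effect * hub + rng.normal(size=(n_targets, n_samples))
    expr = pd.DataFrame(np.vstack([cand, targets]),
                        index=pd.Index(cand_ids + target_ids, name="gene"), columns=samples)
    truth = pd.DataFrame({"gene": target_ids, "causal_marker": "",
                          "beta": hub_effect, "type": "distant", "regulator": cand_ids[0]})
    return expr, {"candidates": cand_ids, "targets": target_ids, "hub": cand_ids[0]}, truth


def write_fixture_set(outdir, cfg: SimConfig) -> dict[str, Path]:
    """Simulate a full study and write the TSV fixture files.

    Emits ``markers.tsv``, ``genotypes.tsv``, ``expression.tsv``,
    ``genes.tsv``, ``truth.tsv`` and ``design.tsv`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg)
    paths = {}
    for name, obj in [
        ("markers", study["marker_map"]),
        ("genotypes", study["genotypes"]),
        ("expression", study["expression"]),
        ("genes", study["genes"]),
        ("truth", study["truth"].set_index("gene")),
        ("design", study["design"].rename_axis("sample").to_frame()),
    ]:
        path = outdir / f"{name}.tsv"
        write_table(obj, path)
        paths[name] = path
    return paths
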