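"""Single-marker eQTL mapping with permutation-derived genome-wide thresholds.

For every (gene, marker) pair the log2 expression y of the gene across the
lines of one subpopulation is fitted to the simple linear model

    y_j ~ x_j + e_j

with the homozygous genotype x coded -1/+1, which is equivalent to a pooled
two-sample t-test between the allele groups.  The score reported per cell is
-log10 of the two-sided p-value of the genotype term.

Genome-wide significance is controlled by a per-gene permutation scheme: the
expression values of each gene are shuffled over the genotypes, the scan is
repeated, and per-gene genome-wide maximum scores are collected over rounds.
A threshold T is accepted when

    FDS(T) / RDS(T) <= (m0 / m) * q * log(m),        m0 = m - RDS(T)

where RDS counts genes whose real maximum score reaches T and FDS is the mean
such count over permutation rounds; the smallest qualifying T on a fixed grid
is returned.  Peaks (at most one per chromosome), 1.5-drop confidence
intervals, the 1 Mb local/distant rule and per-eQTL variance explained follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .dataio import encode_genotypes

LOG10E = np.log10(np.e)

__all__ = [
    "ScanResult",
    "SignificanceThreshold",
    "NoThresholdError",
    "marker_regression_scan",
    "variance_explained",
    "permute_gene",
    "fdr_threshold",
    "call_peaks",
    "confidence_interval",
    "classify_local_distant",
    "map_stage",
    "shared_eqtl_counts",
    "EqtlMapper",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = [
    "gene", "stage", "peak_marker", "peak_chr", "peak_bp", "score",
    "threshold", "ci_start", "ci_end", "type", "r2", "effect_sign",
]


class NoThresholdError(RuntimeError):
    """No candidate threshold satisfies the FDS/RDS criterion."""

    def __init__(self, message: str, table: pd.DataFrame | None = None):
        super().__init__(message)
        self.table = table


@dataclass
class ScanResult:
    """Dense scan output: genes x markers scores plus effect diagnostics.

    ``scores`` holds -log10(p); ``r`` the signed Pearson correlation between
    expression and the -1/+1 genotype coding (its sign is the allelic effect
    direction, mean_B - mean_A); ``r2`` the variance explained per cell.
    """

    scores: pd.DataFrame
    r: pd.DataFrame

    @property
    def r2(self) -> pd.DataFrame:
        return self.r ** 2

    @property
    def effect_sign(self) -> pd.DataFrame:
        return np.sign(self.r)

    def max_per_gene(self) -> pd.Series:
        return self.scores.max(axis=1)


@dataclass
class SignificanceThreshold:
    threshold: float
    q: float
    m: int
    n_permutations: int
    table: pd.DataFrame  # columns: threshold, RDS, FDS, bound

    def __float__(self) -> float:
        return float(self.threshold)


def _scores_from_r(r: np.ndarray, df: int, cap: float) -> np.ndarray:
    """Convert correlations to -log10 two-sided t-test p-values (capped)."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(df / np.maximum(1.0 - r * r, 1e-300))
    # logsf keeps precision far in the tail where sf underflows
    log10p = (np.log(2.0) + stats.t.logsf(t, df)) * LOG10E
    return np.minimum(-log10p, cap)


def marker_regression_scan(
    expr: pd.DataFrame, geno: pd.DataFrame, score_cap: float = 300.0,
) -> ScanResult:
    """Scan all genes against all markers.

    Parameters
    ----------
    expr : genes x samples log2 expression.
    geno : lines x markers A/B(/NA) genotypes; rows must match ``expr``
        columns 1:1 (same ids, any order).
    score_cap : upper bound on -log10(p) for numerically exact fits.
    """
    if set(expr.columns) != set(geno.index):
        raise ValueError("expression samples and genotype lines do not match")
    geno = geno.loc[list(expr.columns)]
    G = encode_genotypes(geno)  # n x p, -1/+1/NaN
    Y = expr.to_numpy(dtype=float)  # g x n
    n = Y.shape[1]
    scores = np.zeros((Y.shape[0], G.shape[1]))
    rmat = np.zeros_like(scores)

    missing_cols = np.isnan(G).any(axis=0)
    # fast path: complete markers, one matmul over all genes
    if (~missing_cols).any():
        Gc = G[:, ~missing_cols]
        r, ok = _corr_genes_markers(Y, Gc)
        df = n - 2
        s = np.where(ok, _scores_from_r(r, df, score_cap), 0.0)
        scores[:, ~missing_cols] = s
        rmat[:, ~missing_cols] = np.where(ok, r, 0.0)
    # markers with missing calls: pairwise exclusion, per marker
    for j in np.where(missing_cols)[0]:
        mask = ~np.isnan(G[:, j])
        if mask.sum() < 3:
            continue
        r, ok = _corr_genes_markers(Y[:, mask], G[mask, j][:, None])
        df = int(mask.sum()) - 2
        scores[:, j] = np.where(ok[:, 0], _scores_from_r(r[:, 0], df, score_cap), 0.0)
        rmat[:, j] = np.where(ok[:, 0], r[:, 0], 0.0)

    idx, cols = expr.index, geno.columns
    return ScanResult(
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        r=pd.DataFrame(rmat, index=idx, columns=cols),
    )


def _corr_genes_markers(Y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson correlation between every row of Y and every column of G.

    Returns (r, ok) where ok flags cells with non-degenerate variance on both
    sides (monomorphic markers / constant genes get ok = False).
    """
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Gc = G - G.mean(axis=0, keepdims=True)
    ys = np.sqrt((Yc * Yc).sum(axis=1))
    gs = np.sqrt((Gc * Gc).sum(axis=0))
    ok = (ys[:, None] > 0) & (gs[None, :] > 0)
    denom = np.where(ok, ys[:, None] * gs[None, :], 1.0)
    r = (Yc @ Gc) / denom
    return np.where(ok, r, 0.0), ok


def variance_explained(y: np.ndarray, g: np.ndarray) -> float:
    """Fraction of expression variance explained by the genotype (squared r)."""
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    if y.std() == 0 or g.std() == 0:
        return 0.0
    return float(np.corrcoef(y, g)[0, 1] ** 2)


def permute_gene(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Shuffle one gene's expression values over the genotypes."""
    return rng.permutation(np.asarray(y))


def permuted_max_scores(
    expr: pd.DataFrame, geno: pd.DataFrame, n_permutations: int,
    rng: np.random.Generator, score_cap: float = 300.0,
) -> np.ndarray:
    """Per-gene genome-wide maximum score for each permutation round.

    Every gene is permuted independently within every round.  Returns an
    array of shape (n_genes, n_permutations).

    When no genotypes are missing the residual df is constant across markers,
    so the maximum score equals the score of the maximum |r|; only that value
    is converted per gene, which keeps 100-round permutation scans cheap.
    """
    geno = geno.loc[list(expr.columns)]
    G = encode_genotypes(geno)
    Y = expr.to_numpy(dtype=float)
    n = Y.shape[1]
    out = np.empty((Y.shape[0], n_permutations))
    complete = not np.isnan(G).any()
    for b in range(n_permutations):
        Yp = np.take_along_axis(Y, np.argsort(rng.random(Y.shape), axis=1), axis=1)
        if complete:
            r, ok = _corr_genes_markers(Yp, G)
            rmax = np.abs(np.where(ok, r, 0.0)).max(axis=1)
            out[:, b] = _scores_from_r(rmax, n - 2, score_cap)
        else:
            perm_expr = pd.DataFrame(Yp, index=expr.index, columns=expr.columns)
            out[:, b] = marker_regression_scan(perm_expr, geno, score_cap).max_per_gene().to_numpy()
    return out


def fdr_threshold(
    real_max_scores: np.ndarray,
    permuted_max_scores: np.ndarray,
    q: float = 0.05,
    grid_step: float = 0.1,
    grid_max: float = 20.0,
    log_base: str = "e",
) -> SignificanceThreshold:
    """Pick the genome-wide score threshold from the FDS/RDS criterion.

    Parameters
    ----------
    real_max_scores : per-gene genome-wide maximum score, shape (m,).
    permuted_max_scores : shape (m, n_rounds); per-gene maxima per round.
    q : FDR level.
    log_base : "e" (default) or "10" for the log(m) factor.
    """
    real = np.asarray(real_max_scores, dtype=float)
    perm = np.asarray(permuted_max_scores, dtype=float)
    if perm.ndim != 2 or perm.shape[1] < 2:
        raise ValueError("need permuted maxima from >= 2 rounds")
    m = real.shape[0]
    logm = np.log(m) if log_base == "e" else np.log10(m)
    grid = np.round(np.arange(0.0, grid_max + grid_step / 2, grid_step), 10)
    # survival counts over the grid
    rds = (real[None, :] >= grid[:, None]).sum(axis=1).astype(float)
    fds = (perm[None, :, :] >= grid[:, None, None]).sum(axis=(1, 2)) / perm.shape[1]
    m0 = m - rds
    bound = (m0 / m) * q * logm
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rds > 0, fds / np.maximum(rds, 1e-300), np.inf)
    table = pd.DataFrame({"threshold": grid, "RDS": rds, "FDS": fds, "bound": bound})
    ok = (rds > 0) & (ratio <= bound)
    if not ok.any():
        raise NoThresholdError(
            f"no threshold on [0, {grid_max}] satisfies FDS/RDS <= (m0/m)*q*log(m)", table
        )
    t = float(grid[np.argmax(ok)])
    return SignificanceThreshold(threshold=t, q=q, m=m,
                                 n_permutations=perm.shape[1], table=table)


def call_peaks(scan_row: pd.Series, marker_map: pd.DataFrame, threshold: float) -> list[str]:
    """At most one peak marker per chromosome: the (leftmost) maximum >= threshold."""
    peaks = []
    for _, sub in marker_map.groupby("chromosome", sort=False):
        s = scan_row.loc[sub.index]
        best = float(s.max())
        if best >= threshold and best > 0:
            peaks.append(s.index[int(np.argmax(s.to_numpy()))])  # argmax -> leftmost tie
    return peaks


def confidence_interval(
    scan_row: pd.Series, marker_map: pd.DataFrame, peak_marker: str, drop: float = 1.5,
) -> tuple[int, int]:
    """1.5-drop support interval around a peak, on the peak's chromosome.

    Extends outward over the contiguous run of markers whose score stays
    within ``drop`` of the peak score, stopping at the first marker below the
    cutoff on each side.
    """
    chrom = marker_map.loc[peak_marker, "chromosome"]
    sub = marker_map[marker_map["chromosome"] == chrom]
    scores = scan_row.loc[sub.index].to_numpy()
    pos = sub["position_bp"].to_numpy()
    p = sub.index.get_loc(peak_marker)
    cutoff = scores[p] - drop
    left = p
    while left > 0 and scores[left - 1] >= cutoff:
        left -= 1
    right = p
    while right < len(scores) - 1 and scores[right + 1] >= cutoff:
        right += 1
    return int(pos[left]), int(pos[right])


def classify_local_distant(
    peak_chr: str, peak_bp: int, ci_start: int, ci_end: int,
    gene_chr: str | None, gene_start: int | None, local_window_bp: int = 1_000_000,
) -> str:
    """Local iff the gene start lies within 1 Mb (inclusive) of the peak/CI span."""
    if gene_chr is None or gene_start is None:
        return "unknown"
    if str(gene_chr) != str(peak_chr):
        return "distant"
    lo = min(ci_start, peak_bp)
    hi = max(ci_end, peak_bp)
    dist = 0 if lo <= gene_start <= hi else min(abs(gene_start - lo), abs(gene_start - hi))
    return "local" if dist <= local_window_bp else "distant"


class EqtlMapper(BaseEstimator):
    """Single-marker eQTL mapper for one subpopulation (sklearn-style).

    Parameters
    ----------
    q : FDR level for the permutation threshold.
    n_permutations : permutation rounds (expression shuffled per gene).
    ci_drop : -log10(p) drop defining the confidence interval.
    local_window_bp : maximum gene-to-eQTL distance still called local.
    score_cap : cap on -log10(p) for exact fits.
    grid_step, grid_max : candidate-threshold grid.
    threshold_log_base : "e" or "10" for log(m) in the FDS/RDS bound.
    classify : set False for non-expression trait matrices (no gene positions).
    random_state : permutation seed.

    Attributes (after :meth:`fit`)
    ------------------------------
    scan_ : :class:`ScanResult`
    threshold_ : :class:`SignificanceThreshold`
    records_ : DataFrame with one row per eQTL (columns ``RECORD_COLUMNS``).
    """

    def __init__(self, q=0.05, n_permutations=100, ci_drop=1.5,
                 local_window_bp=1_000_000, score_cap=300.0, grid_step=0.1,
                 grid_max=20.0, threshold_log_base="e", classify=True,
                 random_state=None):
        self.q = q
        self.n_permutations = n_permutations
        self.ci_drop = ci_drop
        self.local_window_bp = local_window_bp
        self.score_cap = score_cap
        self.grid_step = grid_step
        self.grid_max = grid_max
        self.threshold_log_base = threshold_log_base
        self.classify = classify
        self.random_state = random_state

    def fit(self, expr, geno, marker_map, gene_annotation=None, stage=""):
        rng = np.random.default_rng(self.random_state)
        self.scan_ = marker_regression_scan(expr, geno, self.score_cap)
        perm = permuted_max_scores(expr, geno, self.n_permutations, rng, self.score_cap)
        self.threshold_ = fdr_threshold(
            self.scan_.max_per_gene().to_numpy(), perm, q=self.q,
            grid_step=self.grid_step, grid_max=self.grid_max,
            log_base=self.threshold_log_base,
        )
        self.records_ = self._call_records(marker_map, gene_annotation, stage)
        return self

    def _call_records(self, marker_map, gene_annotation, stage):
        t = self.threshold_.threshold
        rows = []
        scores, r = self.scan_.scores, self.scan_.r
        gene_max = scores.to_numpy().max(axis=1)
        for gi in np.where(gene_max >= t)[0]:
            gene = scores.index[gi]
            row = scores.iloc[gi]
            for peak in call_peaks(row, marker_map, t):
                ci_start, ci_end = confidence_interval(row, marker_map, peak, self.ci_drop)
                peak_chr = str(marker_map.loc[peak, "chromosome"])
                peak_bp = int(marker_map.loc[peak, "position_bp"])
                if self.classify and gene_annotation is not None and gene in gene_annotation.index:
                    etype = classify_local_distant(
                        peak_chr, peak_bp, ci_start, ci_end,
                        str(gene_annotation.loc[gene, "chromosome"]),
                        int(gene_annotation.loc[gene, "start_bp"]),
                        self.local_window_bp,
                    )
                elif self.classify:
                    etype = "unknown"
                else:
                    etype = "na"
                rr = float(r.loc[gene, peak])
                rows.append((gene, stage, peak, peak_chr, peak_bp,
                             float(row.loc[peak]), t, ci_start, ci_end, etype,
                             rr ** 2, int(np.sign(rr))))
        return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def map_stage(expr, geno, marker_map, gene_annotation=None, stage="",
              q=0.05, n_permutations=100, seed=None, **kwargs):
    """Functional wrapper: scan -> permutation threshold -> peaks -> CI -> labels."""
    mapper = EqtlMapper(q=q, n_permutations=n_permutations, random_state=seed, **kwargs)
    mapper.fit(expr, geno, marker_map, gene_annotation, stage)
    return mapper.records_, mapper.threshold_


def shared_eqtl_counts(records_by_stage: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Count genes with an eQTL of each type in exactly each stage subset.

    Returns a table with columns ``type``, ``stages`` ("+"-joined subset) and
    ``n_genes``; the counts over all subsets partition the (gene, type) pairs
    that have at least one eQTL anywhere.
    """
    if len(records_by_stage) < 2:
        raise ValueError("need records from >= 2 stages")
    membership: dict[tuple[str, str], list[str]] = {}
    for stage in records_by_stage:
        rec = records_by_stage[stage]
        for etype in ("local", "distant"):
            for gene in rec.loc[rec["type"] == etype, "gene"].unique():
                membership.setdefault((gene, etype), []).append(stage)
    stage_order = {s: i for i, s in enumerate(records_by_stage)}
    counts: dict[tuple[str, str], int] = {}
    for (gene, etype), stages in membership.items():
        key = (etype, "+".join(sorted(stages, key=stage_order.get)))
        counts[key] = counts.get(key, 0) + 1
    rows = [(etype, stages, n) for (etype, stages), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["type", "stages", "n_genes"])
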