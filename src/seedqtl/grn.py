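"""Ensemble gene-regulatory-network inference and candidate prioritization.

Genes with a local eQTL at a hotspot are *candidate regulators*; genes with a
distant eQTL there are *targets*.  The expression submatrix of both groups is
scored by five inference methods — absolute Spearman correlation, CLR and
ARACNE (both on a plug-in mutual-information matrix over equal-frequency
bins), GENIE3 (per-target randomized tree ensembles) and TIGRESS (stability
selection with LARS).  GENIE3's directed importances fix the orientation of
every gene pair (the weaker direction is dropped); the methods are then
integrated by averaging per-method ranks over the kept directions, and the
network is the shortest prefix of the ascending average-rank edge list that
covers every node.  Candidates are prioritized by outdegree, then closeness
centrality.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lars_path

METHODS = ("spearman", "clr", "aracne", "genie3", "tigress")
SYMMETRIC_METHODS = frozenset({"spearman", "clr", "aracne"})

__all__ = [
    "METHODS",
    "assemble_candidate_set",
    "spearman_scores",
    "mutual_information_matrix",
    "clr_scores",
    "aracne_prune",
    "genie3_scores",
    "tigress_scores",
    "orient_by_genie3",
    "average_rank_aggregate",
    "coverage_threshold",
    "node_centralities",
    "prioritize_candidates",
    "NetworkEnsemble",
]


def assemble_candidate_set(
    records: pd.DataFrame, hotspot_bins: pd.DataFrame, expr: pd.DataFrame,
) -> dict:
    """Split the genes whose eQTL peaks fall in a hotspot's bin(s).

    ``hotspot_bins`` holds the bin row(s) of one hotspot (chromosome,
    start_bp, end_bp).  Genes with a local peak there become candidates,
    genes with a distant peak targets; a gene qualifying as both is kept as
    candidate (regulator status dominates).  Returns a dict with
    ``candidates``, ``targets`` and the ``expression`` submatrix.
    """
    in_bin = np.zeros(len(records), dtype=bool)
    for row in hotspot_bins.itertuples(index=False):
        in_bin |= (
            (records["peak_chr"].astype(str) == str(row.chromosome))
            & (records["peak_bp"] >= row.start_bp)
            & (records["peak_bp"] < row.end_bp)
        ).to_numpy()
    sub = records[in_bin]
    candidates = sorted(sub.loc[sub["type"] == "local", "gene"].unique())
    targets = sorted(set(sub.loc[sub["type"] == "distant", "gene"]) - set(candidates))
    if not candidates or not targets:
        raise ValueError("hotspot yields an empty candidate or target set")
    genes = candidates + targets
    missing = [x for x in genes if x not in expr.index]
    if missing:
        raise ValueError(f"genes absent from expression matrix: {missing[:5]}")
    return {"candidates": candidates, "targets": targets,
            "expression": expr.loc[genes]}


# ---------------------------------------------------------------- scoring

def _zero_diag(m: np.ndarray) -> np.ndarray:
    np.fill_diagonal(m, 0.0)
    return m


def spearman_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Absolute Spearman correlation; symmetric, constant genes score 0."""
    if expr.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    import warnings

    from scipy.stats import ConstantInputWarning
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantInputWarning)  # NaN -> 0 below
        rho = spearmanr(expr.to_numpy().T).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-gene case to a scalar
        rho = np.array([[1.0, rho], [rho, 1.0]])
    rho = np.nan_to_num(np.asarray(rho, dtype=float), nan=0.0)
    return pd.DataFrame(_zero_diag(np.abs(rho)), index=expr.index, columns=expr.index)


def _discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Rank-based equal-frequency binning of one profile into 0..n_bins-1."""
    n = x.size
    order = rankdata(x, method="ordinal") - 1
    return (order * n_bins // n).astype(np.int64)


def mutual_information_matrix(expr: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Plug-in mutual information (nats) on equal-frequency-discretized profiles."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples")
    X = expr.to_numpy(dtype=float)
    p, n = X.shape
    D = np.vstack([_discretize_equal_frequency(X[i], n_bins) for i in range(p)])
    mi = np.zeros((p, p))
    logn = np.log(n)
    for i in range(p):
        di = D[i]
        for j in range(i + 1, p):
            joint = np.bincount(di * n_bins + D[j], minlength=n_bins * n_bins) / n
            pi = joint.reshape(n_bins, n_bins).sum(axis=1)
            pj = joint.reshape(n_bins, n_bins).sum(axis=0)
            nz = joint > 0
            outer = np.outer(pi, pj).ravel()
            val = float((joint[nz] * (np.log(joint[nz]) - np.log(outer[nz]))).sum())
            mi[i, j] = mi[j, i] = max(val, 0.0)
    return pd.DataFrame(mi, index=expr.index, columns=expr.index)


def clr_scores(mi: pd.DataFrame) -> pd.DataFrame:
    """Context likelihood of relatedness: z-score MI against each gene's background.

    z_i(j) is MI_ij standardized over gene i's off-diagonal MI row (negative
    z clipped at 0); the edge score is sqrt(z_i(j)^2 + z_j(i)^2).
    """
    M = mi.to_numpy(dtype=float).copy()
    p = M.shape[0]
    off = ~np.eye(p, dtype=bool)
    means = np.array([M[i, off[i]].mean() for i in range(p)]) if p > 1 else np.zeros(p)
    sds = np.array([M[i, off[i]].std(ddof=0) for i in range(p)]) if p > 1 else np.zeros(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (M - means[:, None]) / np.where(sds[:, None] > 0, sds[:, None], np.inf)
    z = np.maximum(z, 0.0)
    score = np.sqrt(z ** 2 + z.T ** 2)
    return pd.DataFrame(_zero_diag(score), index=mi.index, columns=mi.columns)


def aracne_prune(mi: pd.DataFrame, dpi_tolerance: float = 0.0) -> pd.DataFrame:
    """ARACNE data-processing-inequality pruning of an MI matrix.

    For every gene triangle the weakest edge is removed when its MI is below
    ``(1 - tolerance)`` times the smaller of the other two; surviving edges
    keep their MI as score, removed edges score 0.
    """
    M = mi.to_numpy(dtype=float).copy()
    p = M.shape[0]
    keep = np.ones((p, p), dtype=bool)
    for i, j, k in itertools.combinations(range(p), 3):
        e = [(M[i, j], (i, j)), (M[i, k], (i, k)), (M[j, k], (j, k))]
        e.sort(key=lambda t: t[0])
        weakest, others = e[0], (e[1][0], e[2][0])
        if weakest[0] < (1.0 - dpi_tolerance) * min(others):
            a, b = weakest[1]
            keep[a, b] = keep[b, a] = False
    out = np.where(keep, M, 0.0)
    return pd.DataFrame(_zero_diag(out), index=mi.index, columns=mi.columns)


def genie3_scores(
    expr: pd.DataFrame, n_trees: int = 1000, k_features="sqrt", seed=None,
) -> pd.DataFrame:
    """GENIE3: per-target random-forest importances as directed edge scores.

    For each target gene j a randomized tree ensemble regresses y_j on all
    other genes' standardized profiles; score(i -> j) is gene i's total
    variance-reduction importance, normalized to sum 1 over predictors.
    Entry [i, j] of the returned frame is score(i -> j).
    """
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    p = X.shape[0]
    scores = np.zeros((p, p))
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(p)
    for j in range(p):
        predictors = np.delete(np.arange(p), j)
        model = RandomForestRegressor(
            n_estimators=n_trees, max_features=k_features,
            random_state=int(child_seeds[j] % (2 ** 31)), n_jobs=1,
        )
        model.fit(Xs[predictors].T, Xs[j])
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        scores[predictors, j] = imp
    return pd.DataFrame(scores, index=expr.index, columns=expr.index)


def tigress_scores(
    expr: pd.DataFrame, n_resamples: int = 500, alpha: float = 0.2,
    n_steps: int = 5, seed=None,
) -> pd.DataFrame:
    """TIGRESS: LARS stability-selection frequencies as directed edge scores.

    For each target, ``n_resamples`` rounds subsample half the samples,
    jitter each predictor by an independent Uniform(alpha, 1) weight and run
    LARS for ``n_steps`` steps; score(i -> j) is the fraction of rounds in
    which predictor i entered the path.  ``alpha = 1`` disables reweighting.
    """
    if expr.shape[1] < 8:
        raise ValueError("need >= 8 samples")
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Xs = (X - X.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    p, n = Xs.shape
    half = max(n // 2, 4)
    rng = np.random.default_rng(seed)
    freq = np.zeros((p, p))
    for j in range(p):
        predictors = np.delete(np.arange(p), j)
        Xp = Xs[predictors].T  # n x (p-1)
        y = Xs[j]
        for _ in range(n_resamples):
            rows = rng.choice(n, size=half, replace=False)
            w = rng.uniform(alpha, 1.0, size=p - 1)
            Xw = Xp[rows] * w
            yb = y[rows]
            try:
                _, active, _ = lars_path(Xw, yb, method="lar", max_iter=n_steps)
            except Exception:  # degenerate subsample
                continue
            freq[predictors[list(active[:n_steps])], j] += 1.0
    return pd.DataFrame(freq / n_resamples, index=expr.index, columns=expr.index)


# ---------------------------------------------------------- integration

def orient_by_genie3(genie3: pd.DataFrame, candidates: set | None = None) -> pd.DataFrame:
    """Keep one direction per gene pair: the larger GENIE3 importance wins.

    Ties keep the candidate -> non-candidate orientation when exactly one
    endpoint is a candidate, else the lexicographically smaller source.
    Returns a boolean frame; entry [i, j] True means i -> j is kept.
    """
    genes = list(genie3.index)
    candidates = set() if candidates is None else set(candidates)
    G = genie3.to_numpy(dtype=float)
    keep = np.zeros_like(G, dtype=bool)
    for a, b in itertools.combinations(range(len(genes)), 2):
        fwd, rev = G[a, b], G[b, a]
        if fwd > rev:
            keep[a, b] = True
        elif rev > fwd:
            keep[b, a] = True
        else:
            ga, gb = genes[a], genes[b]
            if (ga in candidates) != (gb in candidates):
                src = a if ga in candidates else b
            else:
                src = a if ga <= gb else b
            keep[src, src ^ a ^ b] = True
    return pd.DataFrame(keep, index=genie3.index, columns=genie3.columns)


def average_rank_aggregate(
    method_scores: dict[str, pd.DataFrame], kept: pd.DataFrame,
) -> pd.DataFrame:
    """Integrate methods by the mean of their per-edge ranks over kept directions.

    Within each method the kept directed edges are ranked descending by score
    (rank 1 = strongest, midrank on ties); symmetric methods contribute their
    undirected score to whichever direction was kept.  Returns an edge table
    (source, target, average_rank, rank_<method>..., score_<method>...)
    sorted ascending by average rank (best first).
    """
    if len(method_scores) < 2:
        raise ValueError("need >= 2 methods to aggregate")
    genes = list(kept.index)
    mask = kept.to_numpy(dtype=bool)
    src_idx, tgt_idx = np.where(mask)
    edges = pd.DataFrame({
        "source": [genes[i] for i in src_idx],
        "target": [genes[j] for j in tgt_idx],
    })
    ranks = []
    for name, frame in method_scores.items():
        vals = frame.to_numpy(dtype=float)[src_idx, tgt_idx]
        r = rankdata(-vals, method="average")
        edges[f"score_{name}"] = vals
        edges[f"rank_{name}"] = r
        ranks.append(r)
    edges["average_rank"] = np.mean(ranks, axis=0)
    edges = edges.sort_values(
        ["average_rank", "source", "target"], kind="stable"
    ).reset_index(drop=True)
    cols = ["source", "target", "average_rank"] + [c for c in edges.columns
                                                   if c not in ("source", "target", "average_rank")]
    return edges[cols]


def coverage_threshold(ranked_edges: pd.DataFrame, nodes: list[str]) -> tuple[pd.DataFrame, float]:
    """Shortest prefix of the rank-sorted edge list touching every node.

    Returns (network edge table, threshold = average_rank of the last admitted
    edge).  Raises if some node appears in no edge at all.
    """
    nodes = list(nodes)
    touched = set(ranked_edges["source"]) | set(ranked_edges["target"])
    missing = [n for n in nodes if n not in touched]
    if missing:
        raise ValueError(f"nodes never appear in any edge: {missing[:5]}")
    needed = set(nodes)
    covered: set[str] = set()
    for i, row in enumerate(ranked_edges.itertuples(index=False)):
        covered.add(row.source)
        covered.add(row.target)
        if needed <= covered:
            net = ranked_edges.iloc[: i + 1].reset_index(drop=True)
            return net, float(net["average_rank"].iloc[-1])
    raise AssertionError("unreachable: all nodes touched but prefix never covers them")


def node_centralities(edges: pd.DataFrame, nodes: list[str]) -> pd.DataFrame:
    """Outdegree and directed closeness per node.

    Closeness(n) = (#nodes reachable from n) / (sum of shortest-path lengths
    from n to those nodes); 0 when nothing is reachable (reciprocal
    mean-distance convention restricted to reachable nodes).
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(zip(edges["source"], edges["target"]))
    rows = []
    for n in nodes:
        lengths = nx.single_source_shortest_path_length(g, n)
        lengths.pop(n, None)
        total = sum(lengths.values())
        closeness = len(lengths) / total if total > 0 else 0.0
        rows.append((n, g.out_degree(n), g.degree(n), closeness))
    return pd.DataFrame(rows, columns=["gene", "outdegree", "degree", "closeness"]).set_index("gene")


def prioritize_candidates(
    centralities: pd.DataFrame, network: pd.DataFrame, candidates: list[str],
) -> pd.DataFrame:
    """Rank candidates by outdegree (desc), then closeness (desc), then gene id.

    The table also reports each candidate's mean average-rank over its
    out-edges in the final network (NaN for candidates with no out-edge).
    """
    sub = centralities.loc[candidates].copy()
    mean_rank = network.groupby("source")["average_rank"].mean()
    sub["mean_outedge_rank"] = mean_rank.reindex(sub.index)
    sub = sub.reset_index()
    sub = sub.sort_values(["outdegree", "closeness", "gene"],
                          ascending=[False, False, True], kind="stable")
    sub = sub.set_index("gene")
    sub["priority_rank"] = np.arange(1, len(sub) + 1)
    return sub


class NetworkEnsemble(BaseEstimator):
    """Five-method ensemble GRN with rank integration (sklearn-style).

    Parameters mirror the individual methods; ``methods`` selects a subset
    (GENIE3 always runs, as it fixes edge directions).

    Attributes after :meth:`fit`:

    ``method_scores_`` : dict of per-method score frames
    ``kept_directions_`` : boolean frame of surviving orientations
    ``edges_`` : full rank-aggregated edge list
    ``network_`` : the coverage-threshold prefix (the reported network)
    ``threshold_rank_`` : average rank of the last admitted edge
    ``centralities_`` : per-node outdegree/degree/closeness
    ``priorities_`` : ranked candidate table
    """

    def __init__(self, methods=METHODS, n_bins=10, genie3_trees=1000,
                 genie3_k="sqrt", tigress_resamples=500, tigress_alpha=0.2,
                 tigress_steps=5, aracne_tolerance=0.0, random_state=None):
        self.methods = methods
        self.n_bins = n_bins
        self.genie3_trees = genie3_trees
        self.genie3_k = genie3_k
        self.tigress_resamples = tigress_resamples
        self.tigress_alpha = tigress_alpha
        self.tigress_steps = tigress_steps
        self.aracne_tolerance = aracne_tolerance
        self.random_state = random_state

    def fit(self, expr, candidates, targets):
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        genes = list(candidates) + list(targets)
        expr = expr.loc[genes]
        ss = np.random.SeedSequence(self.random_state)
        g3_seed, tg_seed = (int(s % (2 ** 31)) for s in ss.generate_state(2))

        scores: dict[str, pd.DataFrame] = {}
        genie3 = genie3_scores(expr, self.genie3_trees, self.genie3_k, g3_seed)
        if "genie3" in self.methods:
            scores["genie3"] = genie3
        mi = None
        if {"clr", "aracne"} & set(self.methods):
            mi = mutual_information_matrix(expr, self.n_bins)
        if "spearman" in self.methods:
            scores["spearman"] = spearman_scores(expr)
        if "clr" in self.methods:
            scores["clr"] = clr_scores(mi)
        if "aracne" in self.methods:
            scores["aracne"] = aracne_prune(mi, self.aracne_tolerance)
        if "tigress" in self.methods:
            scores["tigress"] = tigress_scores(
                expr, self.tigress_resamples, self.tigress_alpha,
                self.tigress_steps, tg_seed)

        self.method_scores_ = scores
        self.kept_directions_ = orient_by_genie3(genie3, set(candidates))
        self.edges_ = average_rank_aggregate(scores, self.kept_directions_)
        self.network_, self.threshold_rank_ = coverage_threshold(self.edges_, genes)
        self.centralities_ = node_centralities(self.network_, genes)
        self.centralities_["label"] = [
            "candidate" if n in set(candidates) else "target"
            for n in self.centralities_.index
        ]
        self.priorities_ = prioritize_candidates(
            self.centralities_, self.network_, list(candidates))
        return self
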