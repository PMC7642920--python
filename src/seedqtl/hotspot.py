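"""Distant-eQTL hotspot detection on fixed genomic bins.

The genome is tiled with half-open 2 Mb bins anchored at position 0 of each
chromosome.  Under the null, distant eQTLs fall uniformly over bins, so each
bin count is compared against Poisson(lambda) with

    lambda = (total distant eQTLs) / (total bins)

and a bin is flagged as a hotspot when the upper-tail probability
P(X >= observed) falls below alpha (default 1e-4).  A trait-QTL overlay
reuses the same scan machinery on phenotype/metabolite matrices to count
significant trait QTL per bin for collocation summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .eqtl import EqtlMapper

__all__ = [
    "bin_genome",
    "count_distant_per_bin",
    "poisson_hotspot_test",
    "call_hotspots",
    "trait_qtl_overlay",
    "HotspotDetector",
]


def bin_genome(chrom_lengths: dict[str, int] | list[int], width: int = 2_000_000) -> pd.DataFrame:
    """Tile each chromosome with half-open [start, end) bins from position 0.

    The last bin of a chromosome may be partial.  Returns a DataFrame with
    columns ``chromosome``, ``start_bp``, ``end_bp``.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    if not isinstance(chrom_lengths, dict):
        chrom_lengths = {str(i + 1): int(l) for i, l in enumerate(chrom_lengths)}
    rows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError("chromosome lengths must be positive")
        start = 0
        while start < length:
            rows.append((str(chrom), start, min(start + width, length)))
            start += width
    return pd.DataFrame(rows, columns=["chromosome", "start_bp", "end_bp"])


def _assign_bins(records: pd.DataFrame, bins: pd.DataFrame,
                 chrom_col="peak_chr", pos_col="peak_bp") -> np.ndarray:
    """Bin index for each record's peak; -1 if outside all bins."""
    idx = np.full(len(records), -1)
    for chrom, sub in bins.groupby("chromosome", sort=False):
        mask = records[chrom_col].astype(str).to_numpy() == str(chrom)
        if not mask.any():
            continue
        pos = records.loc[mask, pos_col].to_numpy()
        starts = sub["start_bp"].to_numpy()
        ends = sub["end_bp"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        inside = (j >= 0) & (pos < ends[np.clip(j, 0, len(ends) - 1)])
        out = np.where(inside, sub.index.to_numpy()[np.clip(j, 0, len(sub) - 1)], -1)
        idx[np.where(mask)[0]] = out
    return idx


def count_distant_per_bin(records: pd.DataFrame, bins: pd.DataFrame) -> np.ndarray:
    """Count distant eQTL peaks per bin; local/unknown records are ignored."""
    distant = records[records["type"] == "distant"]
    counts = np.zeros(len(bins), dtype=int)
    if distant.empty:
        return counts
    idx = _assign_bins(distant, bins)
    if (idx < 0).any():
        bad = distant.iloc[np.where(idx < 0)[0][:3]]
        raise ValueError(f"peak position outside all bins for: {bad['gene'].tolist()}")
    np.add.at(counts, idx, 1)
    return counts


def poisson_hotspot_test(k: int, lam: float) -> float:
    """Upper-tail Poisson probability P(X >= k) for an observed bin count."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k <= 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def call_hotspots(
    records: pd.DataFrame, bins: pd.DataFrame, alpha: float = 1e-4,
    stage_prefix: str = "H", merge_adjacent: bool = False,
) -> pd.DataFrame:
    """Per-bin Poisson test of distant-eQTL enrichment.

    Returns the full bin table (observed, expected, p_value, is_hotspot) with
    hotspot ids ``<stage_prefix><ordinal>`` assigned in genome order.  With
    ``merge_adjacent`` consecutive significant bins on one chromosome share
    a single id and are reported as one widened window.
    """
    counts = count_distant_per_bin(records, bins)
    total = int(counts.sum())
    out = bins.copy()
    out["observed"] = counts
    if total == 0:
        out["expected"] = 0.0
        out["p_value"] = 1.0
        out["is_hotspot"] = False
        out["hotspot_id"] = ""
        return out
    lam = total / len(bins)
    out["expected"] = lam
    out["p_value"] = [poisson_hotspot_test(int(k), lam) for k in counts]
    out["is_hotspot"] = out["p_value"] < alpha
    ids = [""] * len(out)
    ordinal = 0
    prev_sig_key = None
    for i in out.index[out["is_hotspot"]]:
        key = (out.at[i, "chromosome"], out.at[i, "start_bp"])
        adjacent = (prev_sig_key is not None and prev_sig_key[0] == key[0]
                    and prev_sig_key[1] == key[1] - (out.at[i, "end_bp"] - out.at[i, "start_bp"]))
        if not (merge_adjacent and adjacent):
            ordinal += 1
        ids[i] = f"{stage_prefix}{ordinal}"
        prev_sig_key = (out.at[i, "chromosome"], out.at[i, "start_bp"])
    out["hotspot_id"] = ids
    return out


class HotspotDetector(BaseEstimator):
    """Poisson hotspot caller over fixed genomic bins (sklearn-style).

    Attributes after :meth:`fit`: ``bins_`` (full per-bin table) and
    ``hotspots_`` (significant bins only).
    """

    def __init__(self, bin_width=2_000_000, alpha=1e-4, merge_adjacent=False):
        self.bin_width = bin_width
        self.alpha = alpha
        self.merge_adjacent = merge_adjacent

    def fit(self, records, chrom_lengths, stage_prefix="H"):
        bins = bin_genome(chrom_lengths, self.bin_width)
        self.bins_ = call_hotspots(records, bins, self.alpha, stage_prefix,
                                   self.merge_adjacent)
        self.hotspots_ = self.bins_[self.bins_["is_hotspot"]].reset_index(drop=True)
        return self


def trait_qtl_overlay(
    trait_matrix: pd.DataFrame, geno: pd.DataFrame, marker_map: pd.DataFrame,
    bins: pd.DataFrame, q: float = 0.05, n_permutations: int = 100,
    seed=None, **mapper_kwargs,
) -> pd.DataFrame:
    """Count significant trait QTL (phenotypes, metabolites) per genomic bin.

    Runs the same single-marker scan + permutation threshold on an arbitrary
    traits x samples matrix; no local/distant classification applies.
    Returns the bin table with a ``qtl_count`` column (all zeros for an
    empty trait matrix).
    """
    out = bins.copy()
    if trait_matrix.shape[0] == 0:
        out["qtl_count"] = 0
        return out
    mapper = EqtlMapper(q=q, n_permutations=n_permutations, classify=False,
                        random_state=seed, **mapper_kwargs)
    mapper.fit(trait_matrix, geno, marker_map)
    rec = mapper.records_
    counts = np.zeros(len(bins), dtype=int)
    if len(rec):
        idx = _assign_bins(rec, bins)
        np.add.at(counts, idx[idx >= 0], 1)
    out["qtl_count"] = counts
    return out
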