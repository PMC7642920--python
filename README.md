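# seedqtl

Genetical-genomics analysis for staged recombinant-inbred-line (RIL)
expression data: single-marker eQTL mapping with permutation-derived
genome-wide thresholds, local/distant classification, Poisson detection of
distant-eQTL hotspots, and ensemble gene-regulatory-network inference to
prioritize the candidate master-regulator genes under each hotspot.  It is
aimed at plant and quantitative geneticists who profile expression in a
biparental RIL population — for example the four seed germination stages
(primary dormant, after-ripened, imbibed, radicle protrusion) of an
Arabidopsis Bay×Sha population — and want to go from expression matrices to
a ranked list of candidate *trans* regulators.

A synthetic-data module generates RIL genotypes (Haldane recombination with
selfed-RIL map expansion) and expression matrices with planted local eQTLs,
hotspot regulators and known ground truth, so the whole pipeline can be
exercised and validated without any data download.

## The statistics

* **Scan** — per gene *i* and marker *x*, the linear model `y_ij ~ x_j +
  e_j` with genotypes coded −1/+1; the score is −log10 of the two-sided
  p-value of the slope (equivalently a pooled two-sample t-test).
* **Threshold** — expression values are permuted per gene over the lines
  (100 rounds); the genome-wide threshold is the smallest score T with
  `FDS(T)/RDS(T) ≤ (m0/m)·q·log(m)`, where RDS counts genes whose real
  maximum score reaches T, FDS the mean such count in permuted data,
  m0 = m − RDS, and q = 0.05.
* **eQTL calls** — at most one peak per chromosome, a 1.5-drop
  −log10(p) confidence interval, and the 1 Mb rule: local if the gene start
  lies within 1 Mb (inclusive) of the peak/CI span on the same chromosome,
  else distant.
* **Hotspots** — 2 Mb genomic bins; a bin with k distant eQTLs is a hotspot
  when P(X ≥ k) < 1e-4 for X ~ Poisson(λ), λ = total distant eQTLs / total
  bins.
* **Networks** — genes with a local eQTL at a hotspot are candidate
  regulators, genes with a distant eQTL its targets; |Spearman|, CLR,
  ARACNE, GENIE3 and TIGRESS score all pairs, GENIE3 fixes each pair's
  direction, predictions are integrated by average rank, the network is cut
  at the minimum average rank covering every node, and candidates are
  ranked by outdegree, then closeness centrality.

See `docs/methods.md` for the full model description, parameter defaults,
numerical choices and limitations.

## Worked example

The library surface is sklearn-style: `EqtlMapper`, `HotspotDetector` and
`NetworkEnsemble` are estimators with `fit` and fitted attributes
(`records_`, `hotspots_`, `priorities_`, …); `seedqtl.pipeline.run_full`
composes them.  A CLI (`seedqtl simulate|map|hotspots|network|overview|run`)
wraps the same functions.

```python
from seedqtl.pipeline import RunConfig, run_full
from seedqtl.simdata import HotspotSpec, SimConfig, write_fixture_set

cfg = SimConfig(
    n_lines=40, n_stages=4, n_genes=250, n_markers=150,
    local_fraction=0.2, local_r2=0.35, seed=11,
    hotspot_spec=(HotspotSpec("5", 24_500_000, n_targets=35, target_effect=1.3),),
)
paths = write_fixture_set("example_data", cfg)

rc = RunConfig(
    markers_path=str(paths["markers"]), genotypes_path=str(paths["genotypes"]),
    expression_path=str(paths["expression"]), genes_path=str(paths["genes"]),
    design_path=str(paths["design"]), output_dir="example_out",
    n_permutations=50, genie3_trees=100, tigress_resamples=50, seed=5,
)
result = run_full(rc)

s = result["summary"]
print("thresholds:", s["thresholds"])
print("eQTLs per stage:", s["n_eqtl"])
print("local / distant (RP):", s["n_local"]["RP"], "/", s["n_distant"]["RP"])
print("hotspots:", s["hotspot_ids"])
print("top candidates:", {h: t[0] for h, t in s["top_candidates"].items()})
```

prints

```
thresholds: {'PD': 3.1, 'AR': 3.1, 'IM': 3.1, 'RP': 3.2}
eQTLs per stage: {'PD': 74, 'AR': 78, 'IM': 92, 'RP': 82}
local / distant (RP): 34 / 48
hotspots: ['PD1', 'AR1', 'IM1', 'RP1']
top candidates: {'PD1': 'G00000', 'AR1': 'G00000', 'IM1': 'G00000', 'RP1': 'G00000'}
```

The planted regulator `G00000` (a gene with a strong local eQTL on
chromosome 5 driving 35 distant targets) produces one detected hotspot per
stage and is ranked the top candidate regulator in every stage's network.
Per-stage eQTL tables, the hotspot table, network edge lists (`.tsv` and
Cytoscape `.sif`), candidate rankings, PCA/cluster outputs and a
machine-readable `summary.json` land in `example_out/`.

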