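# triomics

Integrative analysis of DNA copy number, DNA methylation and mRNA
expression for small cancer cell-line panels (the motivating system is a
panel of ~19 osteosarcoma cell lines profiled on three microarray
platforms against two normal osteoblast controls).

The package turns three heterogeneous data types into per-gene,
per-sample binary aberration calls and then asks three questions:

1. **Which genes are recurrently altered through more than one
   mechanism?** Each platform contributes two aberration channels
   (gain/loss, hyper-/hypo-methylation, over-/under-expression), giving
   12 cross-platform two-way and 8 three-way combinations. A gene is
   selected when an expression-consistent pair (gain+over, hypo+over,
   loss+under, hyper+under) recurs in ≥ k of n samples (default 6 of 19,
   i.e. > 30%), or when over-expression co-occurs with *either* gain or
   hypo-methylation (and under-expression with either loss or
   hyper-methylation) in a total of ≥ k samples — the union rule.
2. **How do the mechanisms depend on each other within a sample?** For
   every sample and channel pair, a 2×2 contingency table over the gene
   universe yields an odds ratio OR = (a·d)/(b·c) (OR > 1: positive
   association) and a Pearson χ² p-value, corrected per sample
   (Benjamini–Hochberg by default, Bonferroni available). A three-state
   analysis conditions hyper-methylation × expression tables on the
   copy-number state (gain / normal / loss).
3. **Is copy-number gain biased toward gene-dense regions?** The cohort
   gain (or loss) frequency is laid out as a segment track; the test
   statistic is the base-pair-weighted mean track value inside
   gene-covered regions, and the null distribution shuffles segment
   values among fixed segment positions (Monte Carlo, default 1,000
   permutations, add-one p-value estimator), genome-wide and per
   chromosome arm.

Calling thresholds follow the platform conventions: segment mean
log-ratio ≥ 0.2 → gain / ≤ −0.2 → loss (high-level gain 0.6 and
homozygous loss −1.0 merged in), deltaBeta (case beta minus mean control
beta) > 0.4 / < −0.4 → hyper-/hypo-methylation, vst-scale ratio > 1 /
< −1 → over-/under-expression. Probes collapse to genes by inclusion: a
gene joins every list any of its probes reaches. Differential testing
versus controls uses M-values (M = log2(β/(1−β))), two-sample t-tests,
BH correction and fold-change cuts (|ΔM| > 6, |Δvst| > 0.5).
Hierarchical clustering uses 1 − Spearman ρ (or Euclidean) distance with
complete linkage.

A synthetic-data generator (`triomics.simulate`) emulates the full
three-platform design — segmented copy-number profiles, logistic-latent
beta values, additively coupled expression, planted recurrent
aberrations with exact ground truth, and density-biased gain placement —
so every stage is testable without array downloads.

## Worked example

```python
import triomics as t
from triomics.simulate import simulate_genome, simulate_dataset

cfg = t.SimulationConfig(
    seed=1,
    planted=(t.PlantedSet("gain+over", 10, 8),
             t.PlantedSet("hyper+under", 10, 8)),
)
genome = simulate_genome(cfg)
data = simulate_dataset(cfg, genome)
calls = t.build_call_matrix(
    data.segments, data.beta, data.expression, genome.annotation,
    data.meth_probe_map, data.expr_probe_map,
)
result = t.integrate(calls, k=6)
print(f"universe: {calls.n_genes} genes x {calls.n_samples} samples")
print(f"selected: {result['n_selected']} genes "
      f"(+{result['n_additional']} via the union rule)")

dep = t.pairwise_dependency(calls)
go = dep[dep["combo"] == "gain+over"]
print(f"gain+over odds ratio, median across samples: {go['odds_ratio'].median():.1f}")
print(f"samples with BH-adjusted p < 0.05: {(go['p_adj'] < 0.05).sum()}/{len(go)}")
```

prints

```
universe: 2200 genes x 19 samples
selected: 21 genes (+0 via the union rule)
gain+over odds ratio, median across samples: 36.0
samples with BH-adjusted p < 0.05: 19/19
```

Twenty genes were planted with recurrent two-channel aberrations in 8 of
19 samples; the recurrence selection at k = 6 recovers them (21 selected
= 20 planted + 1 background co-occurrence), and the planted
copy-number→expression coupling shows up as a strong positive gain+over
association in every sample.

The same analysis is available from the shell:

```sh
triomics run-all --seed 1 --out run1/
triomics density-test --track run1/frequency_gain.tsv \
    --annotation run1/annotation.tsv --per-arm --seed 1 --out density.tsv
```

`run-all` executes simulate → call → integrate → depend → density-test →
diff → cluster and writes a `manifest.json` with seeds and output hashes;
reruns with the same configuration are byte-identical.

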