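# foragenet

Coexpression-module analysis of root transcriptomes along soil-nutrient
gradients.

Plants juggle several nutrient-foraging strategies at once — arbuscular
mycorrhiza (AM) formation, the phosphate-starvation response (PSR), and
root-system development — and field transcriptomes of roots sampled across
wide nitrate/phosphate gradients let one ask which genetic module drives
which strategy. `foragenet` implements the full desk-scale analysis chain
for that question, for researchers working with bulk root RNA-seq plus
soil/plant chemistry tables:

* **Expression preprocessing** — TPM normalization
  (TPM_gs = 10⁶·(c_gs/ℓ_g)/Σ_g(c_gs/ℓ_g)), a mean-TPM ≥ 5 gene filter,
  and log₂(TPM+1) transformation.
* **Weighted coexpression network** — unsigned adjacency a_ij = |cor(x_i,x_j)|^β
  with β chosen by the scale-free topology fit, the topological overlap
  matrix TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
  average-linkage clustering of 1−TOM, a static height cut with a minimum
  module size, eigengene merging, and module eigengenes **E** (PC1 sample
  scores of the standardized member genes) with kME connectivity
  kME_g = cor(x_g, **E**).
* **Module structure** — k-means submodules under correlation distance,
  member-gene PCA, and one-sided Fisher's exact GO enrichment with
  Benjamini–Hochberg control.
* **Seeded modules** — grow a module from curated marker genes: seeds are
  candidates significantly correlated with a factor, samples are scored by
  the seeds' PC1, and every gene with |r| > 0.5 against those scores joins;
  overlap and eigengene correlation against the unsupervised modules say
  whether the seeded module is genuinely new.
* **Module–environment statistics** — pairwise eigengene–factor correlations,
  |r| ≥ 0.9 collinearity pruning, min–max standardization to [−50, +50],
  multiple linear regression of eigengenes on factors, a PCA biplot of the
  correlation-coefficient matrix, and gene–eigengene cross-correlation
  distributions.
* **Dual-RNA fungal quantification** — rRNA reads carried over in mRNA-seq
  libraries are assigned to a plant LSU rRNA reference and AM fungal OTU
  references (consensus-trimmed; ≥ 95 % identity over ≥ 75 bp), counts are
  normalized per nt of reference, and total fungal reads per 10⁵ plant reads
  (log₁₀) give a relative fungal-biomass index; Bray–Curtis + NMDS compare
  community compositions between protocols.
* **Synthetic data** — a generator that plants modules whose eigengenes are
  linear responses to latent soil factors, plus mixed plant/fungal rRNA read
  sets, with full ground truth for benchmarking every stage.

## Worked example

Detect modules in a synthetic dataset with five planted modules (100 genes
each, kME ∈ [0.6, 0.95]) over 500 background genes and 100 samples:

```python
import numpy as np
from foragenet import expression as ex, network, simulate
from sklearn.metrics import adjusted_rand_score

config = simulate.SimulationConfig(seed=1)
factors = simulate.generate_factor_table(config)
counts, truth = simulate.generate_expression(config, factors)
logexpr = ex.log_transform(ex.filter_by_mean_tpm(ex.counts_to_tpm(counts)))
modules, scan = network.detect_modules(logexpr)
print("chosen soft power:", scan.chosen_power)
print("module sizes:", dict(modules.sizes))
print("ARI vs planted labels:", round(adjusted_rand_score(
    truth.planted_labels.reindex(logexpr.gene_ids),
    modules.labels.reindex(logexpr.gene_ids)), 3))
```

prints

```
chosen soft power: 12.0
module sizes: {'turquoise': 100, 'yellow': 100, 'blue': 100, 'brown': 98, 'green': 98}
ARI vs planted labels: 0.989
```

i.e. the scan settles on soft power 12, the five planted modules are
recovered essentially intact (named by size rank with the conventional
colour codes), and the partition agrees with the planted labels at an
adjusted Rand index of 0.989. The hub gene of the largest module
(`planted1_g095`, kME = 0.95) is the planted gene with the strongest
eigengene loading, which is how hub genes such as lipid-exporter orthologs
surface in real root data.

The same chain is available from the shell:

```
foragenet simulate --seed 1 --out data/
foragenet run-all --data-dir data/ --out results/ --seed 1
```

which writes per-stage artifacts (log₂ TPM matrix, module labels,
eigengenes, kME, submodules, GO enrichment, regression tables, fungal
abundance index) plus a JSON run manifest sufficient to reproduce the run
bit-for-bit.

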