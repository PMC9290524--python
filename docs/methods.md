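# Methods

This note records the models implemented in `foragenet`, the parameter
choices that matter, and what the synthetic benchmarks do and do not show.

## Expression preprocessing

Counts are converted to TPM using the transcript lengths supplied with the
count matrix; each sample column then sums to 10⁶ exactly. Genes are kept
when their arithmetic mean TPM across all samples is ≥ 5 (inclusive
boundary), and values are transformed to log₂(TPM + 1). The pseudo-count of
1 is the dominant convention for keeping zeros finite; it is exposed as
`log_pseudo` because analyses differ on this point. A sample whose counts
are all zero has no defined TPM normalization: the column is emitted as
zeros and the sample id is recorded on the matrix (`flagged_samples`) with
a warning, rather than aborting a 250-sample run for one failed library.

## Network construction

The network is the canonical unsigned weighted one: adjacency
a_ij = |pearson(x_i, x_j)|^β. The soft power β is scanned over 1–20; for
each power the connectivity k_i = Σ_j a_ij is binned into 10 equal-width
bins and log₁₀(bin frequency) is regressed on log₁₀(mean bin
connectivity); the fit index is −sign(slope)·R², and the chosen power is
the smallest one reaching 0.9 (falling back to the argmax when none does).
Degenerate scans (constant connectivity, fewer than three usable bins)
score 0 instead of crashing. Signedness and correlation type are the
defaults of the one-step procedure this mirrors; signed variants were
deliberately left out of scope for the first release.

Topological overlap is the standard unsigned TOM,
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij), TOM_ii = 1,
with zero-denominator cells defined as 0. The implementation is a single
matrix product; the test-suite checks it against a literal triple-loop
evaluation to 10⁻¹².

Genes are clustered by average linkage on 1 − TOM. Instead of the dynamic
hybrid tree cut, modules come from a **static height cut** (default 0.995)
with a minimum module size of 30: branches below the cut with enough leaves
become modules, the rest start as "unassigned". The static cut is
deterministic and fully auditable; its known weakness — genes on long thin
branches stranded outside every module — is compensated by a **kME rescue
pass** run after merging: every gene is (re)assigned to the module of its
strongest kME when |kME| ≥ 0.5, and genes below that stay unassigned
(modules shrinking under the minimum size are dissolved). This plays the
role the partitioning-around-medoids stage plays in the reference tooling.
Both the cut height and the rescue threshold are configuration knobs.

Module eigengenes are PC1 sample scores: member genes are z-scored across
samples, the first right-singular vector of the member matrix is rescaled
to unit variance (population convention, ddof = 0), and the sign is
oriented so the mean correlation with member genes is positive. Because
rows are centered, eigengenes are exactly zero-mean. Merging is greedy:
while any two module eigengenes have dissimilarity 1 − cor below the merge
height, the closest pair merges (the larger keeps its name) and the merged
eigengene is recomputed. The pipeline applies the construction-time height
0.2 and then a coarser 0.3, as two explicit calls.

Modules are named by size rank from the conventional colour list
(turquoise, blue, brown, ...), echoing — not reproducing — the colour codes
used in field studies. kME percentile genes use rank = ceil(p/100 · size)
with kME ties broken by gene id.

## Module structure

Submodules come from k-means (k = 5 by default, best of 20 restarts,
seeded) on row-z-scored profiles; on that scale squared Euclidean distance
is 2n(1 − r), i.e. centered correlation distance. Module PCA treats genes
as observations over centered sample dimensions; an all-identical module is
a single point in that space and returns zero scores and zero variance
fractions (with a warning) rather than an error, so plotting code can
degrade gracefully.

GO enrichment is a one-sided (over-representation) Fisher's exact test per
term on the in-set/out-set 2×2 table, with Benjamini–Hochberg control
across terms; the pipeline uses FDR < 0.01 for modules and < 0.05 for
submodules. Annotations are used exactly as given — no propagation up the
GO graph — so enrichment results are only as complete as the annotation
table.

## Seeded modules

Seed selection computes Pearson r of each candidate gene (log₂ scale, as
everywhere downstream of preprocessing) against a factor, with two-sided
p-values from the t distribution (n − 2 df), keeping genes with p < 0.05
and the requested sign. Sample scores are the seeds' PC1 under exactly the
eigengene contract. Extraction keeps every filtered gene with |r| strictly
greater than 0.5 against those scores; the correlation criterion is primary
and p-values are reported but not enforced, because the p-value that
accompanies |r| = 0.5 depends on the sample count and would be unattainable
at small synthetic n. Overlap counts and eigengene correlations against an
existing module set quantify redundancy.

## Module–environment statistics

Eigengene–factor correlations are pairwise-complete Pearson with per-cell
n recorded; regression is complete-case. Before regression, factor pairs
with |r| ≥ 0.9 are pruned keeping the earlier-listed factor (the rule is
order-based so it is deterministic and auditable), and both response and
factors are linearly rescaled to [−50, +50] (min → −50, max → +50). The
regression is ordinary least squares with an intercept; rank-deficient
designs raise a named error pointing at the pruning step. Significance
stars follow the usual 0.05/0.01/0.001 coding. The biplot is a PCA of the
module × factor correlation matrix with columns centered but not rescaled
— the cells already share the r scale.

## Dual-RNA quantification

Fungal OTU references carry conserved termini
(`GTGAAATTGTTGAAAGGGAAACG` 5′, `GACGTAATGGCTTTAAACGAC` 3′) that are removed
by exact terminal match before read assignment; references lacking them are
left unchanged with a warning, and trimming is idempotent. Post-trim
lengths are used for normalization.

The bundled read matcher seeds on exact 15-mers over both strands, fixes a
diagonal per seed, and scores the full ungapped read/reference overlap;
the best hit maximizes matching bases with ties broken by longer alignment
then lexicographically smaller reference id, and a full-length perfect
match short-circuits the search. A read is assigned when its best hit has
≥ 95 % identity over ≥ 75 bp. The E-value criterion of the original BLAST
protocol is not reimplemented — at 75 bp read length the identity and
length thresholds dominate acceptance — and the matcher interface is
pluggable (`matcher=`) so an external aligner can substitute.

Assigned counts are divided by reference length (nt); the abundance index
is 10⁵ · Σ(normalized OTU counts)/normalized plant count, reported on a
log₁₀ scale. Samples with zero plant or zero fungal counts are flagged
missing rather than pseudo-counted: an index built on a zero denominator or
a zero numerator would be a statement the data cannot support. Protocol
agreement is the Pearson correlation of log indices over shared defined
samples.

Bray–Curtis is Σ|u−v|/Σ(u+v) with all-zero samples flagged NaN. NMDS
minimizes Kruskal stress-1 by alternating pool-adjacent-violators isotonic
regression of configuration distances on the dissimilarity order with a
Guttman majorization update; an update that would increase stress-1
terminates that start, which makes the recorded stress trace monotone
non-increasing by construction (plain SMACOF guarantees monotone raw
stress, not stress-1). The first start is classical-scaling (principal
coordinates) initialization, so exactly-Euclidean inputs converge to ~0
stress immediately; remaining starts are random and seeded.

## Synthetic data generator

The generator emulates the targeted study design, not its biology. Factor
tables draw five soil/plant gradients per sample: NO₃-N 10.5–212 mg kg⁻¹
and Bray II-P 5.3–494 mg kg⁻¹ (log-uniform, as field nutrient gradients
are closer to log-uniform), organic matter 1–12 %, leaf P 0.5–6 mg g⁻¹ and
pH 4.5–8 (uniform). Each planted module's eigengene is the standardized
sum of weighted standardized factors plus N(0, noise_sd²) noise
(noise_sd = 0.3 by default); the default weight matrix gives each module
one dominant factor with mild cross-loadings. The weight vectors are kept
far from parallel *and* anti-parallel deliberately: an unsigned network
cannot distinguish two anti-correlated eigengenes, so planted modules with
(anti-)parallel responses would make the ground truth ill-posed.

A member gene's latent profile is kME·eigengene + √(1−kME²)·N(0,1) with
kME drawn uniformly from [0.6, 0.95]; background genes are i.i.d. N(0,1).
Latents map through exp() rescaled to a mean TPM of 50 — safely above the
filter threshold — and counts are Poisson at a 2·10⁶ library size with
per-gene lengths uniform in 500–5000 bp (negative-binomial overdispersion
is available as an option). Note that per-sample TPM renormalization
removes any signal shared by *all* genes; the planted design avoids
global signals, and the truth object records the pre-link latents for
exact identity checks.

rRNA read sets mirror single-end 75-base sequencing: 20 fungal OTUs
(600–750 nt cores plus the consensus termini) and a 3000 nt plant
reference; per sample the fungal:plant abundance ratio is log-uniform in
[3·10⁻³, 3·10⁻¹] with the fungal share split by a Dirichlet draw, read
sources are drawn proportional to abundance × reference length, and
substitutions are applied at 1 %. The default depth of 20 000–40 000 rRNA
reads per sample is a ~500× scale-down of the deep sequencing the design
assumes; it is the depth at which the binomial counting noise of the
lowest-abundance samples stays small against the two-decade abundance
gradient, so that protocol replicates of identical abundances agree to
r ≥ 0.99 — at a few thousand reads per sample that agreement is
information-theoretically out of reach regardless of implementation.

What passing the synthetic benchmarks shows: the network/TOM/eigengene
machinery, the seeded-module procedure, the regression pipeline and the
read-assignment/abundance chain are numerically correct and recover
planted structure under linear-response, Poisson-count,
substitution-error-only conditions. What it does not show: robustness to
batch effects, compositional distortions, overdispersion beyond Poisson,
chimeric or gapped-alignment reads, GO annotation bias, or non-linear
gene–environment responses — none of which the generator emulates.

## Numerical conventions

Population (ddof = 0) standard deviations throughout; eigengene sign by
positive mean member correlation; kME ties by gene id; submodule numbering
by first-member position; module naming by size rank; correlation values
clipped to [−1, 1] before p-values; p-values from the t distribution with
n − 2 df everywhere a correlation is tested. All randomness flows from
explicit seeds (the pipeline derives stage seeds from one config seed), and
every writer uses fixed float formatting so reruns are byte-identical.

## Problem sizes

The shipped benchmarks run at 5 modules × 100 genes + 500 background genes
× 100 samples (module recovery, 20 seeds), n = 200 samples for the seeded
and regression checks, 50 samples × ~30 000 reads for the dual-RNA chain,
and 10–14-point configurations for the ordination oracles. These sizes
were chosen so the full suite completes on a laptop-class single CPU in
about a minute while keeping every statistical margin wide.
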