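# Methods

## Model and scope

The unit of analysis is the transcript isoform. For a gene with *n* ≥ 2
isoforms and non-negative expression vector *x* in one sample, the isoform
proportion vector is *p = x / Σx*. Each diversity metric is a scalar
functional of *p* (the Laplace entropy, of *x* directly):

| metric | formula | range | direction |
|---|---|---|---|
| naive entropy | −Σ pᵢ log₂ pᵢ | [0, log₂ n] | up = more diverse |
| normalized naive | above / log₂ n | [0, 1] | up |
| Laplace entropy | entropy of qᵢ = (xᵢ+1)/(Σx+n) | (0, log₂ n] | up |
| Gini index | Σᵢⱼ\|pᵢ−pⱼ\| / (2n²·(1/n)) · n/(n−1) | [0, 1] | **down** |
| Gini–Simpson | 1 − Σ pᵢ² | [0, 1 − 1/n] | up |
| inverse Simpson | 1 / Σ pᵢ² | [1, n] | up |

Single-isoform genes are removed before any computation — every metric is
degenerate at n = 1. A gene with Σx = 0 in a sample has no proportion
vector; all metrics return NA there except the Laplace entropy, whose
pseudocount yields the uniform q and hence the maximal value. This is a
known artifact of the pseudocount (silent genes look maximally diverse)
and the reason the Laplace entropy is the most sensitive metric to
low-expression filtering.

Numerical conventions: base-2 logarithms throughout; 0·log₂0 := 0. The
Gini estimator carries the n/(n−1) small-sample correction so that the
one-hot vector scores exactly 1 for every n; the uncorrected estimator
caps at (n−1)/n, which contradicts the intended [0, 1] interpretation.
The Laplace pseudocount is applied in count space (+1 per isoform before
forming proportions), the only reading under which an all-zero gene
attains exactly 1; the alternative proportion-space reading was noted and
not implemented.

TPM (or another length-normalized unit) is the recommended input: raw
counts inflate the apparent share of long isoforms (see the worked example
in the README), and all proportion-based metrics inherit that bias.

## Filtering and uncertainty

`filter_low_abundance(expr, map, threshold_pct)` keeps a transcript iff
its share of the gene total is ≥ threshold in *every* sample where the
gene is expressed. Samples where the gene total is zero are
non-disqualifying — 0/0 carries no evidence against a transcript.
Threshold 0 is the identity; thresholds in the 1–20 % range are the
practically useful grid.

`bootstrap_diversity_mad` ingests plain-text bootstrap replicates of the
expression estimates (Kallisto plaintext one-file-per-replicate, or the
one-row-per-replicate TSV export of Salmon bootstraps; Salmon bootstrap
*counts* should be converted with `bootstrap_counts_to_tpm` using the
stored transcript lengths). Per gene, the metric is computed on each
replicate and summarized by the unscaled median absolute deviation
(MAD = median |v − median v|); gene-level summed expression is summarized
the same way. Replicates where the metric is undefined are dropped; fewer
than two defined values yields NA.

## Differential analysis

Group 1 is the reference condition (lexicographically smallest label
unless the user names one); the reported effect is central₂ − central₁.
NA diversity values are dropped per group, never imputed. Genes with fewer
than `min_samples_per_group` (default 3 — the smallest group size with a
non-degenerate rank test) non-NA values in either group are excluded from
testing with a machine-readable reason.

Wilcoxon variant: exact null distribution when the pooled values are
tie-free and n₁+n₂ ≤ 25, otherwise the normal approximation with tie and
continuity corrections (scipy's `mannwhitneyu`). Two groups with all
values identical return P = 1. The label-shuffling alternative permutes
condition labels over the non-NA samples and uses |difference of centrals|
as the statistic — whichever central measure (mean/median) the user
configured; Monte-Carlo mode uses the add-one estimator
p = (1 + #{perm ≥ obs})/(1 + B) for finite-sample validity, and designs
with fewer than 20 distinct label assignments are enumerated exhaustively
(p = #{perm ≥ obs}/#assignments) with a logged notice.

BH adjustment is delegated to `statsmodels.stats.multitest.multipletests`
(`fdr_bh`); NA p-values stay NA and do not count toward m. The default
significance rule is |difference| > 0.1 AND adjusted P < 0.05. For metrics
bounded in [0, 1] the difference of centrals is the advised effect size
(log ratios over-emphasize small changes near 0); for unbounded metrics
the log₂ fold change — logged as an advisory, never enforced.

## Synthetic fixture generator

The generator emulates the *shape* of quantifier output for a two-group
bulk RNA-seq design; it does not simulate reads, positional bias or
quantifier error. Per gene: an isoform count from {1…10} (weight 0.2 on
single-isoform genes, which act as diversity-undefined decoys), a latent
proportion vector, and a lognormal total expression (meanlog 3 ≈ 20 TPM,
sdlog 1). A sample observes gene_total · p with i.i.d. multiplicative
lognormal noise per transcript (default sd 0.25, a mid-range choice for
combined technical and biological variability).

Proportion vectors are drawn from a symmetric Dirichlet whose
concentration α is solved from the target expected normalized entropy via
the closed form E[H] = ψ(nα+1) − ψ(α+1) (nats), then exponent-tilted
(pᵢ → pᵢᵗ/Σpⱼᵗ, t solved by bisection) so the realized entropy equals the
target exactly. The Dirichlet draw decides *which* isoforms dominate; the
tilt pins *how much*. Consequence: ground-truth labels are exact by
construction — a "shifted" gene's group-2 entropy is its group-1 entropy
plus exactly the requested effect (a fresh Dirichlet draw at the shifted
target, so the dominant isoforms may also change), and null genes share
one latent vector across groups. A target entropy outside (0, 1) is a
hard error. Base entropies are drawn uniformly from (0.15, 0.65) so the
default +0.3 shift always stays feasible.

Because between-sample variation comes only from the multiplicative
noise, group separation in the fixture is cleaner than in real cohorts
with biological heterogeneity; recovery results on the fixture bound what
the pipeline can do under its own stated noise model, not on real data.
Generators are pure functions of (spec, seed); identical seeds give
byte-identical tables.

## Problem sizes used in the checks

The simulation-based checks run at 2000 genes with 8 samples per group —
large enough for stable empirical type-I/recovery rates (binomial SE ≈
0.5 % at 2000 genes) while keeping the whole suite around ten seconds.
Property checks over random proportion vectors use 10⁴ vectors per isoform
count 2–20 through the vectorized path; exhaustive-enumeration oracles are
run for pooled sample sizes ≤ 10 and tenth-granularity proportion grids
with ≤ 4 isoforms.

## Known limitations

- Two unpaired conditions only; no covariates, paired designs or >2-group
  contrasts.
- Event-level (exon/junction) diversity is out of scope; the isoform is
  the unit.
- Kallisto HDF5 bootstraps are not parsed — plain-text exports only.
- Duplicate transcript rows in quantifier output are an error, not summed.
- The Laplace entropy's pseudocount makes silent, low-coverage genes look
  maximally diverse; interpret it jointly with expression level.
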