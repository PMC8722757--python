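# splicediversity

Splicing isoform diversity analysis for bulk and single-cell transcriptome
data.

Most differential-splicing tools look for coordinated shifts in the usage
of specific isoforms. `splicediversity` asks a different question: how
*evenly* is a gene's expression spread across its transcript isoforms, and
does that evenness change between conditions? A sample can be dominated by
a single isoform while another expresses several isoforms at similar
levels — a change in isoform *diversity* that conventional isoform-ratio
tests can miss, and that can arise from splicing-factor mutations, drug
treatments or tissue context.

The analysis is a two-step workflow on transcript-level expression
estimates (e.g. Salmon or Kallisto TPM):

1. **Diversity** — for every gene *g* with *n* ≥ 2 isoforms and isoform
   proportions *p₁…pₙ* in a sample, compute one of:
   - Shannon ("naive") entropy  H = −Σ pᵢ log₂ pᵢ ∈ [0, log₂ n], optionally
     normalized by log₂ n onto [0, 1];
   - Laplace entropy — the same after a +1 pseudocount on each isoform's
     expression, qᵢ = (xᵢ+1)/(Σx+n), defined even for silent genes;
   - Gini index (with the n/(n−1) small-sample correction) ∈ [0, 1],
     where 1 means all expression in one isoform — note it runs *opposite*
     to the entropies;
   - Gini–Simpson index 1 − Σ pᵢ² and inverse Simpson 1/Σ pᵢ² (the
     effective number of expressed isoforms, 1…n).
2. **Difference** — per gene, compare diversity between two sample groups
   by the difference of means/medians and log₂ fold change, with a
   two-sided Wilcoxon rank-sum test (exact when tie-free and pooled n ≤ 25)
   or a seeded label-shuffling permutation test, and Benjamini–Hochberg FDR
   correction. A gene is called significant when |mean difference| > 0.1
   and adjusted P < 0.05.

Supporting machinery: Salmon `quant.sf` / Kallisto `abundance.tsv` readers,
counts→TPM conversion, plain-text bootstrap-replicate ingestion with
per-gene diversity MAD (uncertainty), relative-abundance transcript
filtering, and a seeded synthetic-fixture generator with exact ground-truth
entropy shifts.

## Worked example

Why TPM rather than raw counts: a gene has three isoforms with lengths
100, 100 and 1000 nt and read counts 20, 20 and 200.

```python
>>> import splicediversity as sd
>>> counts, lengths = sd.worked_example_fixture()
>>> sd.proportions(counts).p.round(3)          # raw counts mislead
array([0.083, 0.083, 0.833])
>>> tpm = sd.counts_to_tpm(counts, lengths)
>>> sd.proportions(tpm).p.round(3)             # length-normalized truth
array([0.333, 0.333, 0.333])
>>> sd.entropy_naive(sd.proportions(counts), normalized=True)
0.5152734452350943
>>> sd.entropy_naive(sd.proportions(tpm), normalized=True)
1.0
```

On raw counts the long isoform looks dominant (proportions 0.083 / 0.083 /
0.833, normalized entropy 0.52); after length normalization all three
isoforms are equally used (each 0.333) and the entropy is maximal (1.0) —
the same reads, a very different biological conclusion.

A full two-group run from the shell:

```sh
splicediversity fixture --n-genes 500 --group-effect 0.3 --seed 7 --out-dir data/
splicediversity diversity --expression data/expression.tsv \
    --tx2gene data/tx2gene.tsv --metric naive --normalized --out-dir run/
splicediversity difference --diversity run/diversity.tsv \
    --groups data/groups.tsv --out-dir run/
```

`run/difference.tsv` holds one row per gene: group central values, their
difference, log₂ fold change, raw and BH-adjusted P-values, per-group
sample counts, the significance call and any exclusion reason. Every run
echoes its resolved configuration to `config.yaml` in the output directory
so results can be reproduced from that file alone.

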