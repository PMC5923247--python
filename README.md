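# biisq

Bayesian nonparametric discovery and per-sample quantification of mRNA
isoforms from short-read RNA-seq, across many samples at once.

Most genes produce several mRNA isoforms that differ in which exons they
include. Short reads rarely identify an isoform on their own — they share
subsequences across isoforms — and isoform abundances vary strongly between
samples. `biisq` addresses this by modelling all samples of an experiment
jointly: samples share one global catalog of isoforms and differ only in
their mixing proportions, so evidence for a rare isoform accumulates across
the cohort. No isoform reference is required, only a gene annotation (the
ordered exons of one representative transcript per gene) and coordinate-
sorted alignments.

## Model

For one gene with exons `ι = 1..E` (transcription order), each mapped read
is summarised as a *read term* `(start, end, exon set)` — its terminal base
pairs and the exons it covers, with half-open coordinates. Observations are
the counts `x_vj` of term `v` in sample `j`, forming the `V × m` matrix `X`.

An isoform is a binary exon-composition vector, encoded as an integer by
reading it 5′→3′ as a binary numeral (so `(1,0,1) ↔ 5` for a 3-exon gene).
The hierarchy is a two-level Dirichlet process:

    G_0 | ω, H ~ DP(ω, H),   H uniform over isoform codes
    G_j | α, G_0 ~ DP(α, G_0)          (sample-specific isoform weights)
    β_k ~ Dir(b_k1 η_1, …, b_kV η_V)   (per-isoform term emissions)
    b_kv ~ Bernoulli(π_ι),  π_ι ~ Beta(r, s),  ι = exon where term v starts
    reads: z_ji ~ Mult(ψ_j),  w_ji ~ Mult(β_{c_{j,z_ji}})

A small noise floor ε keeps every emission Dirichlet well defined. The
usage vector `b_k` is constrained to *junction-consistent* terms: a term is
compatible with an isoform iff all of its covered exons are included and
every exon its junctions skip is excluded.

Inference is stochastic variational: minibatch local updates, Robbins–Monro
natural-gradient global updates, and every 30 iterations a
merge–propose–reduce round that fuses redundant isoforms, builds candidate
isoforms from the exon unions of poorly mapped reads (mapping
responsibility < 0.5), and deletes isoforms no read maps to with
probability > 0.01. The best maximum-a-posteriori solution over several
random restarts is returned.

Per sample, transcript read counts are allocated as
`X_t = (gene reads) × ψ_t`, expressed as
`RPKM_t = 10⁹ · X_t / (L_t · N)` and as transcript ratios
`X_t / Σ_t X_t`. Inferred catalogs are scored against a truth set by
maximum-cardinality minimum-weight Hamming matching, with `p`-partial
true positives at distance ≤ `p·E`, plus base-coverage of matched pairs.
A `splice_stats` module tests group-specific transcript ratios with a
Dirichlet likelihood-ratio test (`2·(Σ_g ℓ̂_g − ℓ̂_pooled) ~ χ²_{(G−1)T}`)
and population-specific allele over-representation with a hypergeometric
test.

## Worked example

```python
import numpy as np
from biisq import (GeneModel, Hyperparameters, Isoform, FitConfig,
                   read_to_term, encode_isoform, sample_dataset, fit)

# Read terms: a 100 bp read starting 40 bp into a gene whose first two
# exons are [1,67) and [2617,2865) crosses the first junction:
gene = GeneModel("BRCA2", ((1, 67), (2617, 2865)))
print(read_to_term(40, 100, gene))
# ReadTerm(start=40, end=2690, exon_set=(1, 2), gene_id='BRCA2')

print(encode_isoform((1, 0, 1)))   # -> 5

# Recover two isoforms from model-simulated data: 50 samples, ~20 reads each
g4 = GeneModel("G4", ((0, 150), (250, 400), (500, 650), (750, 900)))
true = [Isoform((1, 1, 0, 0)), Isoform((0, 0, 1, 1))]
hyp = Hyperparameters()
X, truth = sample_dataset(g4, true, hyp, m=50, reads_per_sample=20, seed=0)
state = fit(X, g4, hyp, FitConfig(restarts=5, seed=0))
print(state.compositions())
# [(0, 0, 1, 1), (1, 1, 0, 0)]
emp = truth["z_counts"] / truth["z_counts"].sum(1, keepdims=True)
idx = {c: i for i, c in enumerate(state.compositions())}
perm = [idx[i.composition] for i in true]
print(round(float(np.abs(state.p[:, perm] - emp).mean()), 4))
# 0.0002
```

The fitted state holds the recovered exon compositions (here exactly the
two simulated isoforms) and per-sample proportions `state.p`; the final
number is the mean absolute error of those proportions against the realised
per-sample read allocation — about 2 parts in 10⁴ here.

The same pipeline is available from a shell:

```bash
biisq simulate gene --gff gene.gtf --gene GENE1 --isoforms 2 --samples 20 \
      --coverage 15 --seed 1 --out sim
biisq extract  --gff gene.gtf --bam sim.sam --gene GENE1 --out terms
biisq fit      --terms terms.terms.tsv --gff gene.gtf --gene GENE1 \
      --restarts 5 --seed 0 --out fitted
biisq evaluate --truth sim.truth.gtf --pred fitted.catalog.gtf \
      --gff gene.gtf --gene GENE1 --threshold 0.1 --out scores.tsv
```

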