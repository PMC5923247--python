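# Methods

## The generative model

Each gene is analysed independently. Its transcription model is an ordered
list of non-overlapping exonic intervals in 5′→3′ order; minus-strand genes
are converted to transcription order when the model is built, so exon 1 is
always 5′-most. Coordinates are half-open throughout: the worked example of
a 100 bp read at coordinate 40 of a gene with exons [1,67) and [2617,2865)
is arithmetically consistent (27 + 73 = 100 bp) only with exclusive ends,
which fixes the convention.

A mapped read is summarised as a read term `(start, end, exon_set)`. Terms
are the observation unit: the `V × m` matrix `X` counts each term per
sample. An isoform is a binary exon-composition vector; its integer code
reads the composition 5′→3′ as an MSB-first binary numeral. The palindrome
`(1,0,1) ↔ 5` does not pin the bit order down, so MSB-first is fixed here
and used consistently.

Compatibility between a term and an isoform is *junction consistency*:
every covered exon included, every exon strictly between consecutive
covered exons excluded. Equivalently, the term's exon set must be an infix
of the isoform's exon chain (the exhaustive oracle used in the tests).

The hierarchy couples samples through two Dirichlet-process levels (global
concentration ω, per-sample concentration α) over a countable isoform
catalog with a uniform base measure on codes. Isoform `k` emits terms from
`β_k ~ Dir(η_v (b_kv + ε))`, where `b_kv` is the compatibility indicator
and ε is a small noise floor that keeps the Dirichlet well defined even
for terms the isoform cannot emit. In deterministic contexts (the exact
log joint, move decisions, data simulation) the emission simplex is the
Dirichlet mean: uniform over compatible terms with an additive `ε/V` floor
renormalised over all `V` terms.

### Hyperparameters

| name | meaning | default |
|------|---------|---------|
| ω | global DP concentration | 1 |
| α | per-sample DP concentration | 1 |
| r, s | beta prior on per-exon inclusion π_ι | 1, 1 |
| η | emission Dirichlet base weight (per term) | 1 |
| ε | emission noise floor | 10⁻³ |
| K_max, L_max | global / per-sample truncation | 20, 10 |

All symmetric and configurable (flat `key=value` config files are
accepted); `r < s` would bias toward fewer included exons. ε enters both
the emission prior (`η(b+ε)`) and the deterministic emission floor.

## Posterior inference

Stochastic variational inference over a truncated family: Dirichlet
factors for emissions, beta factors for global and per-sample sticks,
categorical responsibilities for slot-to-isoform maps (`c`) and
read-to-slot assignments (`z`). Each iteration draws a minibatch of
`min(m, 16)` samples, runs a fixed number of local coordinate-ascent
sweeps, and blends the implied sufficient statistics into the global
factors with step size `ρ_t = (t + delay)^(−forgetting)` (delay 1,
forgetting 0.6). Read mass is accumulated only on compatible `(k, v)`
pairs, keeping incompatible emissions at the ε floor — without this mask a
broad composition's fitted emissions drift toward the pooled term
distribution and the catalog becomes unidentifiable.

The per-iteration trace records a minibatch-scaled likelihood estimate and
the current `K`; a full-data likelihood is evaluated every few iterations
and convergence is declared when its relative change stays below 10⁻⁵
(default; maximum 1000 iterations, non-convergence is flagged, not
raised). Five restarts are run by default and the winner maximises the
plug-in MAP score: data log likelihood plus the uniform base-measure
catalog prior `−K·E·log 2`.

The truncated local family deliberately runs with symmetric slot
initialisation, which collapses each sample's slots during the stochastic
updates; the final reported proportions and responsibilities are instead
computed by exact per-sample mixture-weight EM under the model emissions
(the read-allocation E-step), which is sharper than the truncated
representation and is what quantification consumes.

### Merge-propose-reduce

Catalog moves run every 30 iterations, in the order merge, propose,
reduce. All move decisions score compositions with the *model* emission
simplexes rather than the fitted ones: the composition is the hypothesis
being tested, and fitted emissions would let a superset composition mimic
any sub-isoform at no cost.

*Merge.* For every ordered pair, the loser's per-sample mass is pooled
onto the winner, mixture weights are re-optimised by a short EM, and the
resulting data likelihood is compared with the pre-merge value (itself the
better of EM runs from the variational and from uniform weights — mixture
optima are flat across redundant compositions and a single start can park
mass on the wrong one). Acceptance allows a BIC-style complexity credit of
`½·m·log(n̄)` (m samples, n̄ mean reads per sample) for the per-sample
weight dimension a merge removes. This allowance is essential: an extra
mixture component always gains roughly half a nat per sample by fitting
sampling noise, and a nested pair of compositions is exactly
likelihood-neutral, so a strict "never lower the likelihood" rule would
never accept any non-trivial merge. Candidate pairs are evaluated
best-first so that removing a redundant isoform (often free) is always
preferred over eroding a supported one; ties therefore collapse duplicate
slots, preferring fewer isoforms.

*Propose.* Read occurrences whose best junction-consistent mapping
responsibility falls below 0.5 are pooled; random subsets are drawn
(count-weighted) and each subset proposes the isoform whose composition is
the union of its exons, with exons skipped by every sampled junction
excluded. Novel compositions enlarge the catalog (up to K_max) and all
variational parameters are reinitialised with the catalog kept.

*Reduce.* An isoform is dropped when no read maps to it with probability
above 0.01. The responsibilities for this decision come from a short
uniform-weight EM, asking whether any read *could* plausibly map there
rather than whether the current optimum happens to use it; the final
remaining isoform is never removed.

*Initialisation.* The catalog is seeded with one junction-consistent
isoform per observed exon-set span (ones on `[min,max]` of the set minus
explicitly skipped exons, zeros outside; most-supported spans first), the
union-of-observed-exons composition, and the full-length isoform last —
last, because stick-breaking order favours early atoms and the full-length
isoform is the one composition able to absorb everything.

## Quantification and evaluation

Reads are allocated as `X_t = (gene total) × ψ_t` (exactly conservative),
`RPKM_t = 10⁹·X_t/(L_t·N)` with `L_t` the summed half-open lengths of
included exons and `N` the per-sample total of retained mapped reads, and
ratios `X_t/ΣX_t` (all-zero genes flagged missing).

Catalog accuracy uses maximum-cardinality minimum-weight matching under
Hamming distance, solved as a rectangular assignment problem (`O(I³)`).
The square formulation forces a perfect bijection, impossible for unequal
sets; matching all of the smaller side restores maximum-cardinality
semantics, and the excess side is left unmatched (unmatched inferred =
false positives at every threshold). Ties are broken deterministically by
sorting both sets lexicographically. A matched pair at distance ≤ `p·E` is
a `p`-partial true positive; `p = 0` is exact matching. Base coverage is
the length-weighted fraction of true exonic bases present in the matched
partner (a superset scores 1). When importing third-party GTFs, an
annotated exon overlapping any part of a reference exon snaps to that exon
index.

## Synthetic data

`simulate_gene_reads` emulates multi-sample short-read simulation:
per-sample proportions from a symmetric Dirichlet (concentration 1),
per-read isoform choice from those proportions, and start positions from a
5′-biased distribution over the isoform's exonic coordinates. The bias
weights positions by a Gamma density with shape `1/(1+bias)` evaluated at
the transcript-relative position — small shapes pile density at the 5′
end — with an exact uniform fallback at bias 0. Realisations violating the
coverage target or leaving a used exon uncovered are resampled and logged.
The historical simulation grid (novel transcripts {2,4,6,12,16},
coverages {1,5,15,50,100}) is exposed as presets.

`fragment_long_reads` emulates fragmentation of long (Iso-Seq-style)
alignments: short reads are emitted along each long read separated by
inserts drawn from Normal(10, 40²) bp truncated at zero (negative draws
abut reads; the pre-truncation draws are returned so their sample moments
retain the nominal mean and standard deviation), with passes restarting at
jittered offsets
until the covered fraction reaches the span target. Positions are copied
from the source so mapping biases persist.

What the generators do *not* emulate: sequencing errors, quality scores,
mapping ambiguity, paired-end fragment-length information, or real exon
length/usage distributions. Passing recovery tests on these data shows the
inference machinery is correct under the model's own assumptions, not that
real-data performance matches.

## Statistics on transcript ratios

Per gene, transcripts with ratios constant at 0 or 1 across samples or
expressed in fewer than 10% of samples are discarded; genes left with one
transcript or fewer than three exons are dropped. The group-specificity
test fits Dirichlet distributions by maximum likelihood (Minka fixed point
warm-started from method of moments, then Newton with the closed-form
Hessian inverse to gradient norm < 10⁻⁸; exact zeros clamped to 10⁻⁶) and
compares `2(Σ_g ℓ̂_g − ℓ̂_pooled)` against `χ²` with `(G−1)·T` degrees of
freedom — the standard nested-model parameter count for G group-specific
T-dimensional Dirichlet fits against one pooled fit, configurable if a
different reference is wanted. Groups with fewer than two samples are
excluded with
a warning. A variant is population-specific when some allele's count in
some population exceeds fraction `t` of that allele's total (strict
inequality); over-representation of such alleles (at a minimum MAF) in a
selected gene set versus a disjoint background set is scored by the
hypergeometric upper tail. LD pruning is the caller's responsibility.

## Problem sizes and numerical choices

The recovery experiments run at desk scale by design: genes of 4–6 exons
of 150 bp, catalogs of ~60–200 read terms, 20–50 samples, ~20 reads per
sample, 5 restarts — sizes at which the full pipeline (simulation, fit,
evaluation) completes in about a second per fit while exercising every
code path. Proportions are compared against the realised per-sample read
allocation recorded in the truth record; with ~20 reads per sample the
posterior cannot beat multinomial noise against the latent Dirichlet draw
itself (the Bayes-optimal error is ≈ 0.07), so the realised allocation is
the meaningful reference.

Tolerances: simplex checks at 10⁻⁶; likelihood-oracle agreement at 10⁻⁸;
probability floors at 10⁻¹² (weights) and 10⁻³⁰⁰ (log arguments). Ties in
matching are broken lexicographically; ties in merging prefer fewer
isoforms; reduce never removes the final isoform.

## Known limitations

- **Overlapping isoform families.** Isoform sets whose members share most
  exons (e.g. full-length plus exon-skipping variants with long shared
  flanks) are not reliably recovered exactly: fragment mixtures or a
  superset composition can be likelihood-equivalent to the truth under
  single-end terms, and the moves then choose among near-ties. Recovery is
  reliable for well-separated families (pairwise Hamming ≥ 2 with
  junction-distinguishable compositions, e.g. disjoint exon sets). This
  mirrors the moderate precision/recall any short-read method attains on
  complex genes.
- Paired-end mates are treated as independent segments; fragment-length
  information is not modelled.
- The merge acceptance uses a plug-in likelihood with a BIC-style
  allowance rather than the variational bound; the ELBO-based alternative
  would integrate the emission uncertainty but is substantially more
  expensive per pair.
- Multi-gene reads and whole-transcriptome orchestration are out of scope;
  genes are independent.
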