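# Methods

`m16s` implements a complete, self-contained pipeline for taxonomic
classification of bacterial 16S rRNA short reads: read simulation from
labelled reference sequences, k-mer vectorization, and per-rank
classification with three classifiers (a 1-D convolutional network, a
deep belief network, and an RDP-style naive Bayes baseline), evaluated
by stratified cross-validation. This note records the models, their
assumptions, and the design choices made where the design was open.

## Read simulation

Reads are drawn per reference with count `round_half_up(coverage * L /
mean_read_len)`, so a 1400 bp reference at 5.0x coverage with 250 bp
reads yields 28 reads. Read length is uniform over `center ± halfwidth`
(default 250 ± 10 bp), the start position uniform over valid offsets.
Shotgun reads sample both strands uniformly (minus-strand reads are
reverse-complemented); amplicon reads are forward-orientation only,
since amplicon sequencing is primer-anchored.

### Error model

The per-position error is an Illumina-style polynomial in the
sequencing cycle i (1-based along the read, not the reference, because
position-dependent error is a cycle effect):

    error%(i) = base_rate + quartic_coeff * i^4      (a percentage)

with defaults `3e-3 + 3.3e-8 * i^4`, divided by 100 and capped at 1.
Note the cap binds: at the default coefficients the polynomial crosses
100% near cycle 236, so the last ~15 bp of a 250 bp read are always
mutated and a typical read carries on the order of 60 mutations. This
is a property of the published parameterization, kept as-is; callers
that need clean or mildly noisy reads set the coefficients accordingly
(`ZERO_MUTATION` is provided).

A mutation is a substitution (to a uniformly chosen different base)
with probability `substitution_fraction` (default 0.8, i.e. an 80/20
substitution/indel split), otherwise an insertion or a deletion with
equal probability. Insertions add a uniform base after the position;
deletions remove it; read length is not re-padded after indels.

### Amplicon mode

The amplicon is located by the first IUPAC-compatible match of the
forward primer on the forward strand and, downstream, the first match
of the reverse complement of the reverse primer (defaults are the V3-V4
pair CCTACGGGAGGCAGCAG / CCGTCAATTCMTTTRAGT). References without a
match are reported as lost rather than erroring, mirroring how real
amplicon protocols silently drop non-matching templates. Primer
trimming is exact-prefix/suffix IUPAC matching with no mismatch
tolerance, so primer bases hit by the error model can survive trimming
— real trimmers behave the same way. If the amplicon is shorter than
the drawn read length, the read is truncated to the amplicon.

## k-mer representation

A read maps to a dense vector of length 4^k counting all k-length
windows (stride 1), indexed by lexicographic rank with A<C<G<T. Windows
containing a non-ACGT character are skipped rather than expanded over
IUPAC possibilities (cheap, deterministic, and simulated reads contain
none). Vectors are min-max scaled **per read** to [0,1]; a constant
vector maps to zeros. Per-read scaling needs no statistics fitted on
training data, so cross-validation folds cannot leak through the
normalization; a per-feature alternative can be fitted inside a fold by
the estimator (the CV driver trains a fresh estimator per fold on the
training portion only).

At k=5, 250 bp reads give sparse vectors: pooling runs across reads,
non-zero entries are mostly isolated (mean non-zero run ~1.3) and
separated by zero gaps of a few entries (mean ~4-5 on synthetic pools).
This sparsity is the motivation for small convolution kernels. Run
statistics pool all runs across reads; averaging per read first and
then across reads is the documented alternative and differs only at the
second decimal on these pools.

## Classifiers

One independent flat classifier is trained per taxonomic rank; no
hierarchical consistency is enforced between ranks.

### Naive Bayes baseline

Words are the distinct 8-mers of a sequence (presence, not counts). A
query s is assigned to the class g maximising

    P(s|g) = prod over the query's words r of (m(r) + P_r) / (M_g + 1),
    P_r = (n(r) + 0.5) / (N - 1)

where N is the corpus size, n(r) the number of training sequences
containing r, M_g the class's size and m(r) of those containing r.
Scores accumulate in log space (hundreds of factors underflow a
float64 product). Two formulation details are configurable: the prior
denominator (N−1 by default; N+1 under the original RDP convention) and
nothing else — the product ranges over the *query's* words, because a
product over the training set's word inventory would not depend on the
query. Ties in the argmax break to the first label in sorted order.
The prior can exceed 1 for near-ubiquitous words; the formula is
applied as defined.

### CNN

LeNet-lineage topology on the 4^k vector treated as a 1-channel signal:
conv(5 kernels, size 5) → maxpool(2) → conv(10 kernels, size 5) →
maxpool(2) → ReLU → dense(500, ReLU) → softmax. Convolutions are
"valid" (no padding), stride 1; pooling is non-overlapping. These layer
sizes are the defaults; all are configurable through `CNNSpec`.

### DBN

Two stacked RBMs (real-valued visible units in [0,1] read as activation
probabilities — the standard treatment for normalized count data —
binary stochastic hidden units) pre-trained greedily with contrastive
divergence (CD-1 by default; the second RBM trains on the first's
hidden probabilities), then unrolled into a sigmoid MLP with a softmax
output layer and fine-tuned end to end by backpropagation (all weights
update, not only the head). Default widths tie both hidden layers to
the k-mer order: k=3 → 32, k=4 → 128, k≥5 → 256; a `formula` scheme
(4^(k−1) capped at 256) is available — the two disagree at k=3,4 and
the table values are the default.

### Optimization

No optimizer settings are inherited from anywhere; they are this
package's choices. Both networks train with mini-batch SGD with
classical momentum 0.9, batch 64, cross-entropy loss, float32
arithmetic. CNN default: lr 0.01, 30 epochs. DBN default: 10 pretrain
epochs at lr 0.05, then 50 fine-tune epochs at lr 0.1 — sigmoid stacks
need a larger step and more epochs than ReLU networks; at lr 0.01 and
20 epochs the DBN stays near chance on tasks where logistic regression
is nearly perfect, which is an optimization failure, not a model
property. All randomness (init, shuffling, CD sampling) flows from
explicit seeds; a fixed seed reproduces fitted weights bit-for-bit on
one platform (cross-platform BLAS differences may perturb the last few
ulps).

## Evaluation

Stratified k-fold (default 10) with seeded shuffling; fold sizes and
per-class counts differ by at most one. Reads are assigned to folds
independently, so reads from one reference can land in train and test;
this matches the per-read experimental unit, and grouping by reference
is the leakage-safe alternative for callers that need it. Metrics are
accuracy plus macro-averaged precision/recall/F1 over the classes
present in the truth (macro ≈ weighted on balanced designs, and macro
is the stricter convention; weighted is a parameter). A class never
predicted contributes precision 0. Across-fold dispersion is the sample
standard deviation (n−1). A cross-technology mode trains on one
technology's reads and tests on the other's without folding.

## Synthetic reference pools

The fixture generator emulates the 16S gene's layout: nine variable
blocks (80 bp) separated by conserved blocks inside a 1500 bp gene,
with the primer pair planted verbatim (degenerate positions resolved
once) in the conserved blocks flanking variable blocks 2-3, so the
amplicon spans two variable regions (~273 bp) and primer location
succeeds on 100% of references by construction. Taxonomy is nested by
integer division of the genus index, giving exact genus→family→order→
class functional dependencies. Genus ancestors diverge from the root by
i.i.d. substitutions in variable blocks only (default 12% of variable
sites, i.e. ~94% overall identity between genera — realistic 16S
scale); species diverge from their ancestor at 2%. Substitution-only
divergence keeps coordinates fixed so amplicon truth stays exact.

What the fixtures do **not** emulate: real 16S base composition and
covariation, secondary structure, indel divergence between taxa,
chimeras, copy-number variation, or real taxonomies. Passing the
learning tests therefore demonstrates that the implementations learn
and generalise on well-posed read-classification tasks at desk scale —
not that the published accuracy on RDP-derived corpora is reproduced.

## Problem sizes in the shipped checks

The test suite and the acceptance script run everything at desk scale,
chosen once as the package's own evaluation design: learning checks use
10 genera × 10 species pools (~2000 reads at 3.3x coverage, 80/20
split, three seeds) with the error model disabled — the error model's
statistics are validated separately by Monte-Carlo checks, while
learning sanity isolates the classifiers; with the full published error
model (which saturates late in the read) even a logistic-regression
ceiling on 5-mers is ~0.74 at this scale, so noisy-read accuracy
reflects the noise, not the learner. The k-trend check (accuracy
non-decreasing over k ∈ {3,4,5}) uses the same clean pools, where the
trend has dynamic range for both networks. Monte-Carlo error-model
checks use ~10^6 positions and 3-sigma binomial bands.

## Known limitations

- Training is pure numpy on one CPU; k=6,7 runs are configurationally
  supported but slow, and k=8,9 vectors (65536/262144-dim) are
  supported by the representation but impractical to train here.
- The DBN's RBM pre-training uses CD-1 with a fixed learning rate; no
  persistent chains, weight decay or sparsity targets.
- No quality scores (FASTA only), no chimera or PCR-bias model, no
  paired ends.
- `reads_per_reference` applies the same coverage arithmetic to
  amplicon runs (full reference length), making coverage the free
  parameter that sets read counts; amplicon-relative accounting would
  need a different convention.
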