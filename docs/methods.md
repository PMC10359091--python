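# Methods

## Model

`promethyl` predicts, for every promoter of a single cell, the
methylation level of each base pair in a 1-kb window around the TSS,
from two inputs: the reference DNA sequence (identical across cells) and
the cell's Hi-C contacts (the only cell-specific signal). The levels of
interest are the CpG cytosines on both strands; the G of a CpG stands
for the cytosine on the negative strand, so predictions and truths are
defined on the C *and* G positions of reference CpG dinucleotides.

### Coordinates and windows

All internal coordinates are 0-based, half-open. Input conventions are
declared per format: GTF is 1-based, BED 0-based, contact-pair and
coverage files default to 1-based. Each promoter has two windows anchored
on its strand-aware TSS: a contact window `[tss - 5000, tss + 5001)`
(5 kb on each side plus the TSS base, 10,001 bp) used for assigning Hi-C
contacts, and a 1,000-bp sequence/target window used for prediction. The
sequence window is centered on the TSS (`[tss - 500, tss + 500)`); since
nothing anchors it uniquely, the length and centering are configurable.
Windows that would cross a chromosome boundary are clipped, not dropped,
and flagged; positions outside the clipped window are invalid in targets.

### Meta-cells

Single-cell Hi-C and methylation data are far too sparse per cell, so
both are pooled over a meta-cell: the target cell plus its k = 20 most
similar cells. k = 20 is the default because the edge feature's length is
tied to the member count (21 counts at k = 20); k is configurable and
the edge-feature length tracks k + 3. Similarity metrics are pluggable;
the defaults are

- Hi-C: cosine similarity between genome-wide binned contact-count
  vectors (bin pairs at 1 Mb by default; the synthetic benchmark uses
  20 kb because its toy chromosomes are only 200 kb long);
- methylation: cosine similarity between methylation-level vectors on
  the sites both cells cover (0 when no site is shared).

Ties in similarity break lexicographically by cell id, making selection
deterministic. Hi-C aggregation is an elementwise sum of the members'
promoter-promoter contact-count matrices (conserving total counts);
methylation pooling sums read counts per strand-resolved site, so the
pooled level is a ratio of sums and sites with more reads weigh more.
For cells whose type label is usable (training and validation), the
neighbor pool is restricted to the same type; held-out cells select from
the full pool — the blind setting in which labels are unknown.

### Graphs

Per (cell, chromosome): nodes are promoters in TSS order; an undirected
edge joins promoters i and j iff the aggregated contact count is >= 1. A
contact whose ends fall inside the (possibly overlapping) contact windows
of several promoters increments every qualifying unordered pair once.
Node features come from a pluggable sequence encoder of fixed output
dimension; the default encodes the window as L1-normalized overlapping
k-mer frequencies (k = 6 by default, 4,096 values; k is a config knob and
the benchmark uses k = 4 to keep the input dimension small). For
minus-strand promoters the base-wise complement of the stored
positive-strand window is encoded, in positive-strand 5'→3' order,
without reversal. k-mers containing N are skipped; CpG detection demands
a literal `CG` in the reference.

Edge features hold k + 3 = 23 values: the per-member contact counts for
the pair (target first, then neighbors in selection order), one
occurrence value, and the genomic TSS distance in bp. The occurrence
value is defined here as the number of members (of 21) with a nonzero
count for the pair — an integer in [1, 21]; a config switch yields the
alternative normalized reading (that count divided by the member count).
Targets are 1000-vectors with a boolean mask; the mask is true only where
the position is the C or G of a reference CpG *and* the pooled meta-cell
has coverage there (the C position reads the plus-strand call at its own
coordinate, the G position the minus-strand call at its own coordinate).

### Graph transformer

Per block `o` and head `h`, with node states `p_i` and edge states
`e_ij`:

    q_i = W_q p_i + b_q,  k_j = W_k p_j + b_k,  v_j = W_v p_j + b_v,
    e'_ij = W_e e_ij + b_e
    alpha_ij = exp(q_i^T (k_j + e'_ij) / sqrt(d)) /
               sum_{u in N(i)} exp(q_i^T (k_u + e'_iu) / sqrt(d))
    p^_i  = ||_h sum_j alpha_ij (v_j + e'_ij)        (concatenate heads)
    p_i   <- ReLU(LayerNorm(p^_i))
    e^_ij = ||_h (alpha_ij, e_ij)
    e_ij  <- ReLU(LayerNorm(e^_ij))

In the final block the concatenation over heads is replaced by their
mean. The displayed final-block equation admits two readings (with or
without the LayerNorm + ReLU that the other blocks apply); this
implementation applies them uniformly in every block, which with the
default single head makes the final block identical to the others except
for the head reduction. The softmax is stabilized by row-max subtraction,
which is value-identical in exact arithmetic. Isolated nodes receive a
zero aggregation term before LayerNorm + ReLU, so they still obtain
predictions through the output head's bias path — all promoters are
evaluated, including degree-0 ones.

Defaults: 5 blocks, 1 head, head dimension d = 64 (the benchmark uses
16). Edge states are carried forward between blocks (the updated state
`e^{(o+1)}` feeds block o + 1); a config switch re-projects the raw
23-vector in every block instead. Dimension changes between blocks (node
dim becomes H·d, edge dim grows to H·(1 + F)) are absorbed by the
per-block projection matrices themselves. Because raw edge features mix
counts (order 1-10) with bp distances (order 1e4-1e8), the model applies
log1p to raw edge features before the first projection (`edge_transform`,
default `log1p`; `none` disables it).

The output head is affine + sigmoid from the final node state to 1000
values. Training minimizes mean squared error over mask-true positions
(the levels are real-valued, not binary labels), with Adam (lr 1e-3
default, 3e-3 in the benchmark), one graph per update step, global
gradient-norm clipping at 5, early stopping on validation loss with
patience 10 (benchmark: 6), and the best-validation parameters returned.
All randomness (init, shuffling) flows from a single seed; runs are
bit-reproducible. On NaN loss the last good checkpoint is returned with
a divergence flag. No deep-learning framework is used: the model runs on
a small reverse-mode autodiff engine over numpy arrays
(`promethyl.autodiff`), grad-checked against numerical differentiation,
with the full forward pass additionally verified against an independent
straight-line scalar implementation of the equations above.

### Evaluation

Metrics are computed only on positions with truth available. PCC and MAE
use the continuous levels. MCC, AP and AUC binarize the truth at 0.5
(predictions stay continuous scores; MCC also thresholds them at 0.5).
The threshold is configurable; since true levels are strongly bimodal at
0/1, sensitivity to it is low. Single-class truths yield NaN for the
three classification metrics with an explicit flag. Error profiles are
stratified by true-level bins (exact 0 and exact 1 are their own bins)
and by node degree (per-degree pooling of positions, degree-0 excluded).

Two naive baselines predict directly from the true methylation of
spatial neighbors: variant 1 copies the bp-wise levels of the single
most-connected neighbor (highest aggregated count, ties to the lowest
index); variant 2 takes the contact-count-weighted mean of all neighbors'
levels at alignable window offsets. Both leave isolated nodes (and
uncovered offsets) unpredicted; evaluation intersects their coverage
with the truth mask. These definitions are this package's documented
substitutes, not reconstructions of any external tool's baselines.

Cell-type clustering builds a cells x CpG-position matrix of predicted
levels (columns are reference CpG C/G coordinates, shared across cells;
when mixing predictions with missing truths, -1 marks unavailable
entries), runs K-means (k = 4, 10 restarts, fixed seed) for ARI-all-data
and K-means on the top-2 t-SNE components (perplexity 30, capped below
the cell count; fixed seed) for ARI-two-components, both scored against
the true types with the adjusted Rand index. Promoters can be ranked by
single-promoter ARI with a cumulative top-k curve.

## Synthetic data

The generator emulates exactly the coupling the predictor assumes: cell
types differ only through Hi-C structure, and methylation depends on
that structure plus shared sequence. Per type, a clique of 5 promoters
has its within-clique pair weight multiplied by (1 + boost); contacts
per cell are Poisson with uniform positions inside the two windows.
Per-CpG methylation probability is

    p = sigmoid(baseline + beta_seq * motif + beta_topo * in_clique + eps)

with `motif` a fixed pseudo-random score of the 6-mer starting at the C
(a deterministic property of the sequence), and `eps` per-CpG Gaussian
noise. Reads per strand-site are Poisson; methylated reads Binomial(reads,
p); zero-read sites are absent, reproducing coverage sparsity. Promoter
windows are CpG-enriched by planting CG dinucleotides on top of the
random background.

The documented strong-signal conditions — the defaults — are 2
chromosomes of 200 kb, 20 promoters each (40 total), 4 types x 40 cells,
Poisson(60) contacts per cell, boost 8, Poisson(0.5) reads per
strand-site, baseline -1.5, beta_seq 1.0, beta_topo 3.0, noise sd 0.5.
With |baseline + effects| large, true levels are strongly bimodal near
0/1, as sparse-read single-cell data are. These sizes were chosen as the
smallest at which every pipeline stage (meta-cell selection among 160
cells, graphs with hundreds of edges, four-way clustering) is exercised
meaningfully. What the generator does *not* emulate: polymer physics of
chromatin, distance-decay contact profiles, read-level bisulfite noise,
copy-number or allelic effects, and realistic genome scale. Passing the
synthetic benchmark therefore shows that the implementation learns and
propagates a planted topology-methylation coupling — not that the model
attains any particular accuracy on real methyl-3C data.

## Benchmark protocol

Cells are split within each type (60/20/20 per type), so held-out cells
span all four types and can be clustered four-ways; type-disjoint splits
(the blind-test semantics, supported and default in the CLI) are
incompatible with four-way clustering when only four types exist.
Training/validation cells pick meta-cell neighbors among
training+validation cells of their own type; held-out cells pick from the
full pool, unrestricted. The benchmark model is a scaled-down instance of
the default architecture (5 blocks, 1 head, d = 16, 4-mer node encoder,
<= 30 epochs), sized so the whole benchmark — data generation, graph
building, training, evaluation, clustering, plus the zero-signal control
— completes in a few minutes on one CPU. The zero-signal control sets
beta_topo = 0 and boost = 0: graphs then carry no type information, and
clustering of held-out predictions should score ARI ~ 0, confirming that
type recovery in the strong run comes from the Hi-C signal rather than
from the shared sequence (identical inputs would force identical
predictions).

## Numerical choices and degenerate inputs

- LayerNorm epsilon 1e-5; softmax row-max subtraction; sigmoid input
  clipped at +-500 to avoid overflow in exp.
- Attention for isolated nodes is undefined; their aggregation is the
  zero vector (see above).
- Zero-coverage methylation records are skipped with a warning;
  n_methylated > n_total is an error.
- A contact with both ends in one promoter's window contributes nothing
  (zero diagonal); matrices are symmetric by construction.
- Empty target masks: graphs without any covered CpG are excluded from
  training; a fully empty batch is an error.
- All-N sequences encode to the zero vector.
- Duplicate methylation calls at one site sum their reads.

## Known limitations

- The node sequence encoder is a bag-of-k-mers; it carries composition,
  not position, so within-window positional signal reaches predictions
  only through the output head's per-position biases.
- The per-member edge counts assume a fixed meta-cell size; cells whose
  eligible pool is smaller than k are an error rather than a shorter
  feature.
- Graphs are per-chromosome; inter-chromosomal contacts contribute to
  cell similarity but not to edges.
- The meta-cell similarity metrics and the naive-baseline definitions
  are this package's own documented choices among reasonable options.
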