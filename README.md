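# promethyl

Base-pair-specific prediction of single-cell DNA methylation levels in
promoter regions from single-cell Hi-C data and DNA sequence, using an
edge-aware graph transformer.

## The problem

Assays that capture chromosome conformation and DNA methylation in the
*same* single cell (methyl-3C / Methyl-HiC) are rare, while plain
single-cell Hi-C data are comparatively abundant. If 3D genome structure
and methylation are coupled, the methylation state of promoter CpGs
should be predictable from a cell's Hi-C contacts plus the reference
sequence — and, because the sequence is shared by all cells, any
cell-to-cell variation in the predictions must come from the Hi-C signal
alone. `promethyl` implements that idea end to end for computational
biologists working with sparse single-cell 3C-type data:

1. **Meta-cells** — each target cell is pooled with its *k* = 20 most
   similar cells (cosine similarity over binned contacts for Hi-C, over
   shared-site levels for methylation) to densify both signals.
2. **Promoter-promoter spatial interaction graphs** — per cell and
   chromosome, promoters (10,001-bp windows centered on the TSS) are
   nodes; an edge exists wherever at least one aggregated Hi-C contact
   links two windows. Each edge carries 23 values: the 21 per-member
   contact counts, the number of members with a nonzero count, and the
   TSS distance. Each node carries a sequence encoding of its 1-kb
   promoter window (pluggable encoder; default: L1-normalized 6-mer
   frequencies).
3. **Graph transformer** — per block *o* and head *h*, attention over
   neighbors *j* of node *i* with edge encodings added to the keys:

       alpha_ij = <q_i, k_j + e_ij> / sum_u <q_i, k_u + e_iu>,
       <q, k+e>  = exp(q^T (k + e) / sqrt(d)),

   messages `alpha_ij (v_j + e_ij)` summed over neighbors, heads
   concatenated (averaged in the final block), then LayerNorm + ReLU;
   edge states updated as `LayerNorm(concat_h(alpha_ij, e_ij))` + ReLU.
   Five blocks, one head by default. A sigmoid output head yields 1000
   per-bp methylation levels per promoter; training minimizes MSE over
   positions whose true (meta-cell pooled) level is known.
4. **Evaluation & clustering** — PCC, MCC, average precision, ROC AUC
   and mean absolute error on positions with truth available (the C *and*
   G of each CpG; the G reports the minus-strand cytosine); error
   stratified by true level and node degree; naive neighbor-copying
   baselines; K-means / t-SNE cell-type clustering scored with the
   adjusted Rand index (ARI-all-data and ARI-two-components).
5. **Synthetic data** — a generator that plants cell-type-specific
   contact cliques and couples methylation to sequence and clique
   membership, so the whole pipeline is testable without downloads.

## Worked example

```bash
python examples/02_metacells_and_graphs.py
```

prints, for one fixture cell:

```
meta-cell for cell00: 21 members
aggregated contacts on chr1: 2814
graph: 12 promoters, 66 edges
edge (0, 1) feature (23 values):
  per-member counts (21): [4 5 3 1 7 3 5 3 2 7 2 2 5 5 7 7 4 3 1 2 6]
  nonzero occurrence:     21
  TSS distance (bp):      8333
targets: 872 CpG C/G positions with pooled truth (7.3% of window positions)
```

The 21 counts are the contacts between the two promoter windows in the
target cell and each of its 20 neighbors; all 21 members touch this pair,
so the occurrence value is 21; the promoters' TSSs are 8,333 bp apart.
`examples/03_train_and_evaluate.py` then trains a small model and prints
the five metrics on held-out cells, and `examples/04_cluster_cell_types.py`
clusters held-out cells by their predicted methylation profiles.

A thin CLI wraps the same functions for shell use
(`promethyl simulate|build-graphs|train|predict|evaluate|cluster --config run.cfg`).

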