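"""Promoter-promoter spatial-interaction graphs with node, edge and target data.

Per (cell, chromosome): nodes are promoters in TSS order, an undirected
edge links two promoters whenever at least one aggregated meta-cell Hi-C
contact exists between their contact windows, each edge carries a
(k + 3)-value feature (23 at the default meta-cell size k = 20), and each
node carries a 1000-length bp-specific methylation target with a validity
mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np

from .core import Cell, TargetRegion, ValidationError
from .metacell import HiCMetaCell, MethMetaCell

__all__ = [
    "SequenceEncoder",
    "KmerFrequencyEncoder",
    "encode_node_sequence",
    "compute_edge_feature",
    "build_targets",
    "assemble_graph",
    "PromoterGraph",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceEncoder(Protocol):
    """Any callable mapping a window sequence + strand to a fixed-length vector."""

    dim: int

    def __call__(self, seq: str, strand: str) -> np.ndarray: ...


def _kmer_index(kmer: str) -> int:
    idx = 0
    for base in kmer:
        code = "ACGT".find(base)
        if code < 0:
            return -1
        idx = idx * 4 + code
    return idx


def encode_node_sequence(
    seq: str, strand: str, k: int = 6, expected_length: Optional[int] = 1000
) -> np.ndarray:
    """Encode a promoter window as an L1-normalized k-mer frequency vector.

    For '-'-strand promoters the base-wise complement of the stored
    positive-strand window is encoded, keeping positive-strand 5'->3'
    order (no reversal). k-mers containing 'N' are skipped. Returns the
    zero vector when no valid k-mer exists.
    """
    if expected_length is not None and len(seq) != expected_length:
        raise ValidationError(
            f"sequence length {len(seq)} != {expected_length} (pass expected_length=None "
            "for clipped windows)"
        )
    seq = seq.upper()
    if strand == "-":
        seq = seq.translate(_COMPLEMENT)
    counts = np.zeros(4**k)
    for i in range(len(seq) - k + 1):
        idx = _kmer_index(seq[i : i + k])
        if idx >= 0:
            counts[idx] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts


@dataclass
class KmerFrequencyEncoder:
    """Default node-sequence encoder: overlapping k-mer frequencies (k = 6)."""

    k: int = 6
    expected_length: Optional[int] = 1000

    @property
    def dim(self) -> int:
        return 4**self.k

    def __call__(self, seq: str, strand: str) -> np.ndarray:
        return encode_node_sequence(seq, strand, k=self.k, expected_length=self.expected_length)


def compute_edge_feature(
    i: int,
    j: int,
    meta: HiCMetaCell,
    regions: Sequence[TargetRegion],
    occurrence_as_fraction: bool = False,
) -> np.ndarray:
    """The (k + 3)-value edge feature for promoter pair (i, j).

    Layout: per-member contact counts (target cell first, then neighbors
    in selection order; 21 values at k = 20), the occurrence value (the
    number of members with a nonzero count, or that count divided by the
    member count when ``occurrence_as_fraction``), and the genomic
    distance |TSS_i - TSS_j| in bp.
    """
    chrom = regions[i].chrom
    members = meta.member_matrices[chrom]
    per_cell = np.array([m.counts[i, j] for m in members], dtype=float)
    if per_cell.sum() < 1:
        raise ValidationError(
            f"({i}, {j}) is not an edge: no aggregated contact between the promoters"
        )
    occurrence = float(np.count_nonzero(per_cell))
    if occurrence_as_fraction:
        occurrence /= len(members)
    distance = float(abs(regions[i].tss.pos - regions[j].tss.pos))
    return np.concatenate([per_cell, [occurrence, distance]])


def build_targets(
    meth: MethMetaCell, region: TargetRegion, genome: dict[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bp methylation targets and validity mask for one promoter window.

    The mask is true only at positions that are the C or G of a reference
    CpG inside seq_window AND have pooled coverage in the meta-cell. The
    C position reads the '+'-strand call at that coordinate; the G
    position reads the '-'-strand call at its own coordinate (the
    negative-strand cytosine of the CpG).
    """
    start, end = region.seq_window
    length = end - start
    seq = genome[region.chrom][start:end]
    values = np.zeros(length)
    mask = np.zeros(length, dtype=bool)
    idx = seq.find("CG")
    while idx != -1:
        for offset, strand in ((idx, "+"), (idx + 1, "-")):
            level = meth.level((region.chrom, start + offset, strand))
            if level is not None:
                values[offset] = level
                mask[offset] = True
        idx = seq.find("CG", idx + 1)
    return values, mask


@dataclass
class PromoterGraph:
    """Per-(cell, chromosome) graph ready for the graph transformer.

    Nodes follow TSS order of ``regions``. ``edges`` lists undirected
    (i, j, feature) triples with i < j; dense tensors for the model are
    produced by :meth:`to_dense`.
    """

    cell_id: str
    chrom: str
    regions: list[TargetRegion]
    node_features: np.ndarray        # (n, D)
    edges: list[tuple[int, int, np.ndarray]]
    targets: np.ndarray              # (n, window)
    target_mask: np.ndarray          # (n, window) bool
    cell_type: Optional[str] = None
    aggregated_counts: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def edge_dim(self) -> int:
        return len(self.edges[0][2]) if self.edges else 0

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for i, j, _ in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency(self) -> np.ndarray:
        adj = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j, _ in self.edges:
            adj[i, j] = adj[j, i] = True
        return adj

    def to_dense(self, edge_dim: Optional[int] = None):
        """Dense (X, E, A, Y, M) arrays; E presents each feature in both directions."""
        n = self.n_nodes
        f = edge_dim if edge_dim is not None else self.edge_dim
        E = np.zeros((n, n, f))
        for i, j, feat in self.edges:
            E[i, j] = feat
            E[j, i] = feat
        return self.node_features, E, self.adjacency(), self.targets, self.target_mask


def assemble_graph(
    cell: Cell,
    chrom: str,
    regions: Sequence[TargetRegion],
    hic_meta: HiCMetaCell,
    meth_meta: MethMetaCell,
    encoder: SequenceEncoder,
    genome: dict[str, str],
    occurrence_as_fraction: bool = False,
    node_feature_cache: Optional[dict[str, np.ndarray]] = None,
) -> PromoterGraph:
    """Assemble the full promoter graph for one (cell, chromosome).

    Edge set is exactly {(i, j): aggregated(i, j) >= 1, i < j}. Node
    features come from ``encoder`` over each region's seq_window (cacheable
    across cells because the reference sequence is shared).
    """
    regions = sorted(regions, key=lambda r: r.tss.pos)
    n = len(regions)
    feats = []
    for r in regions:
        cached = None if node_feature_cache is None else node_feature_cache.get(r.gene_id)
        if cached is None:
            seq = genome[r.chrom][r.seq_window[0] : r.seq_window[1]]
            cached = encoder(seq, r.strand)
            if node_feature_cache is not None:
                node_feature_cache[r.gene_id] = cached
        feats.append(cached)
    dims = {len(f) for f in feats}
    if len(dims) > 1:
        raise ValidationError(f"encoder produced inconsistent dimensions: {sorted(dims)}")
    node_features = np.array(feats) if feats else np.zeros((0, encoder.dim))

    agg = hic_meta.aggregated[chrom]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if agg[i, j] >= 1:
                edges.append(
                    (i, j, compute_edge_feature(i, j, hic_meta, regions, occurrence_as_fraction))
                )

    window = regions[0].seq_window[1] - regions[0].seq_window[0] if regions else 0
    targets = np.zeros((n, window))
    mask = np.zeros((n, window), dtype=bool)
    for idx, r in enumerate(regions):
        values, m = build_targets(meth_meta, r, genome)
        targets[idx, : len(values)] = values
        mask[idx, : len(m)] = m

    return PromoterGraph(
        cell_id=cell.cell_id,
        chrom=chrom,
        regions=list(regions),
        node_features=node_features,
        edges=edges,
        targets=targets,
        target_mask=mask,
        cell_type=cell.cell_type,
        aggregated_counts=agg,
    )
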