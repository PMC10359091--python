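"""Meta-cell construction for sparse single-cell Hi-C and methylation data.

A meta-cell pools a target cell with its k most similar cells (k = 20 by
default) so that the aggregated contact matrix and the pooled read counts
are dense enough to define graphs and per-bp targets. Neighbor similarity
is cosine: over 1-Mb-binned genome-wide contact counts for Hi-C, and over
shared-site methylation levels for methylation. Both metrics are pluggable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .core import Cell, TargetRegion, ValidationError

__all__ = [
    "PromoterContactMatrix",
    "HiCMetaCell",
    "MethMetaCell",
    "build_promoter_contact_matrix",
    "hic_cell_similarity",
    "methylation_cell_similarity",
    "select_hic_neighbors",
    "aggregate_methylation",
    "binned_contact_vector",
]

DEFAULT_K = 20
DEFAULT_BIN_SIZE = 1_000_000


@dataclass
class PromoterContactMatrix:
    """Promoter-promoter contact counts for one cell on one chromosome."""

    cell_id: str
    chrom: str
    counts: np.ndarray  # (n, n) symmetric, zero diagonal

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class HiCMetaCell:
    """A target cell plus its selected Hi-C neighbors with aggregated contacts."""

    target_cell_id: str
    neighbor_ids: list[str]
    # chrom -> list of member matrices, target first then neighbors in
    # selection order; aggregated[chrom] is their elementwise sum.
    member_matrices: dict[str, list[PromoterContactMatrix]] = field(default_factory=dict)
    aggregated: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return 1 + len(self.neighbor_ids)


@dataclass
class MethMetaCell:
    """Pooled methylation read counts over a target cell and its neighbors."""

    target_cell_id: str
    neighbor_ids: list[str]
    # (chrom, pos, strand) -> (sum n_methylated, sum n_total)
    pooled_calls: dict[tuple[str, int, str], tuple[int, int]] = field(default_factory=dict)

    def level(self, site: tuple[str, int, str]) -> Optional[float]:
        counts = self.pooled_calls.get(site)
        if counts is None:
            return None
        return counts[0] / counts[1]


def _window_membership(
    positions: np.ndarray, regions: Sequence[TargetRegion]
) -> list[np.ndarray]:
    """For each position, the indices of regions whose contact_window contains it."""
    starts = np.array([r.contact_window[0] for r in regions])
    ends = np.array([r.contact_window[1] for r in regions])
    return [
        np.flatnonzero((starts <= p) & (p < ends)) for p in positions
    ]


def build_promoter_contact_matrix(
    cell: Cell, regions: Sequence[TargetRegion]
) -> PromoterContactMatrix:
    """Count contacts between promoter contact windows on one chromosome.

    counts[i, j] is the number of contact records with one end inside
    regions[i]'s contact_window and the other inside regions[j]'s, i != j.
    A contact whose ends fall in overlapping windows increments every
    qualifying unordered pair once; the diagonal is forced to zero.
    """
    chroms = {r.chrom for r in regions}
    if len(chroms) > 1:
        raise ValidationError(f"regions span multiple chromosomes: {sorted(chroms)}")
    (chrom,) = chroms or {None}
    n = len(regions)
    counts = np.zeros((n, n), dtype=np.int64)
    relevant = [
        c for c in cell.contacts
        if c.end_a.chrom == chrom and c.end_b.chrom == chrom
    ]
    if relevant:
        pos_a = np.array([c.end_a.pos for c in relevant])
        pos_b = np.array([c.end_b.pos for c in relevant])
        members_a = _window_membership(pos_a, regions)
        members_b = _window_membership(pos_b, regions)
        for sa, sb in zip(members_a, members_b):
            pairs = {(min(i, j), max(i, j)) for i in sa for j in sb if i != j}
            for i, j in pairs:
                counts[i, j] += 1
                counts[j, i] += 1
    return PromoterContactMatrix(cell_id=cell.cell_id, chrom=chrom, counts=counts)


def binned_contact_vector(
    cell: Cell, bin_size: int = DEFAULT_BIN_SIZE
) -> dict[tuple[str, int, str, int], int]:
    """Genome-wide binned contact counts keyed by canonical bin pairs."""
    vec: dict[tuple[str, int, str, int], int] = {}
    for c in cell.contacts:
        key = (c.end_a.chrom, c.end_a.pos // bin_size, c.end_b.chrom, c.end_b.pos // bin_size)
        vec[key] = vec.get(key, 0) + 1
    return vec


def _sparse_cosine(a: dict, b: dict) -> float:
    if not a or not b:
        return 0.0
    dot = sum(v * b[k] for k, v in a.items() if k in b)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 0.0
    return float(dot / (na * nb))


def hic_cell_similarity(a: Cell, b: Cell, bin_size: int = DEFAULT_BIN_SIZE) -> float:
    """Cosine similarity between genome-wide binned contact-count vectors."""
    if not a.contacts or not b.contacts:
        raise ValidationError("cannot compute Hi-C similarity for a cell with no contacts")
    return _sparse_cosine(
        binned_contact_vector(a, bin_size), binned_contact_vector(b, bin_size)
    )


def methylation_cell_similarity(a: Cell, b: Cell) -> float:
    """Cosine similarity over methylation levels at shared covered sites.

    Returns 0 when the cells share no covered site.
    """
    la = {k: m / t for k, (m, t) in a.methylation_by_site().items()}
    lb = {k: m / t for k, (m, t) in b.methylation_by_site().items()}
    shared = [k for k in la if k in lb]
    if not shared:
        return 0.0
    va = np.array([la[k] for k in shared])
    vb = np.array([lb[k] for k in shared])
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        return 0.0
    return float(va @ vb / (na * nb))


def _top_k(
    target: Cell,
    pool: Sequence[Cell],
    k: int,
    similarity: Callable[[Cell, Cell], float],
    restrict_to_type: bool,
) -> list[Cell]:
    eligible = [c for c in pool if c.cell_id != target.cell_id]
    if restrict_to_type:
        eligible = [c for c in eligible if c.cell_type == target.cell_type]
    if len(eligible) < k:
        raise ValidationError(
            f"need {k} eligible neighbor cells for {target.cell_id}, have {len(eligible)}"
        )
    scored = sorted(
        eligible, key=lambda c: (-similarity(target, c), c.cell_id)
    )
    return scored[:k]


def select_hic_neighbors(
    target: Cell,
    pool: Sequence[Cell],
    regions_by_chrom: dict[str, Sequence[TargetRegion]],
    k: int = DEFAULT_K,
    restrict_to_type: bool = False,
    bin_size: int = DEFAULT_BIN_SIZE,
    similarity: Optional[Callable[[Cell, Cell], float]] = None,
    matrix_cache: Optional[dict[tuple[str, str], PromoterContactMatrix]] = None,
) -> HiCMetaCell:
    """Build a Hi-C meta-cell: the target plus its top-k most similar cells.

    Ties in similarity are broken by lexicographic cell_id. With
    ``restrict_to_type`` (training/validation cells) the pool is first
    filtered to the target's labeled type. ``matrix_cache`` maps
    (cell_id, chrom) to a precomputed PromoterContactMatrix to avoid
    recounting when many meta-cells share members.
    """
    sim = similarity or (lambda a, b: hic_cell_similarity(a, b, bin_size))
    neighbors = _top_k(target, pool, k, sim, restrict_to_type)
    meta = HiCMetaCell(
        target_cell_id=target.cell_id,
        neighbor_ids=[c.cell_id for c in neighbors],
    )
    members = [target] + neighbors
    for chrom, regions in regions_by_chrom.items():
        mats = []
        for cell in members:
            cached = None if matrix_cache is None else matrix_cache.get((cell.cell_id, chrom))
            if cached is None:
                cached = build_promoter_contact_matrix(cell, regions)
                if matrix_cache is not None:
                    matrix_cache[(cell.cell_id, chrom)] = cached
            mats.append(cached)
        meta.member_matrices[chrom] = mats
        meta.aggregated[chrom] = np.sum([m.counts for m in mats], axis=0)
    return meta


def aggregate_methylation(
    target: Cell,
    pool: Sequence[Cell],
    k: int = DEFAULT_K,
    restrict_to_type: bool = False,
    similarity: Optional[Callable[[Cell, Cell], float]] = None,
) -> MethMetaCell:
    """Pool methylation read counts over the target and its top-k neighbors.

    Pooling sums reads (ratio-of-sums, not mean-of-ratios), so sites with
    more reads weigh more; sites covered by no member are absent.
    """
    sim = similarity or methylation_cell_similarity
    neighbors = _top_k(target, pool, k, sim, restrict_to_type)
    pooled: dict[tuple[str, int, str], tuple[int, int]] = {}
    for cell in [target] + neighbors:
        for site, (n_meth, n_total) in cell.methylation_by_site().items():
            prev = pooled.get(site, (0, 0))
            pooled[site] = (prev[0] + n_meth, prev[1] + n_total)
    return MethMetaCell(
        target_cell_id=target.cell_id,
        neighbor_ids=[c.cell_id for c in neighbors],
        pooled_calls=pooled,
    )
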