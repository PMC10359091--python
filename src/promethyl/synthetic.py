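"""Synthetic paired single-cell Hi-C + bp-resolution methylation data.

The generator plants the statistical structure the predictor assumes:
cell types differ only in their Hi-C contact pattern (each type has a
clique of promoters with boosted contact probability), and per-CpG
methylation probability depends on local sequence and on membership of
the cell type's clique:

    p(CpG) = sigmoid(baseline + beta_seq * motif + beta_topo * in_clique + noise)

so the Hi-C graph carries the cell-type signal while sequence contributes
a type-independent component (all cells share the reference genome). At
the default strong-signal parameters the true levels are strongly bimodal
near 0 and 1.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Cell, ContactRecord, GenomicPosition, MethylationCall, TargetRegion
from . import io as pio

__all__ = ["SimConfig", "SimDataset", "simulate_genome", "simulate_cells",
           "simulate_dataset", "write_dataset", "fixture_small", "motif_score"]

# fixed motif lookup: a property of the sequence, independent of dataset seed
_MOTIF_TABLE = np.random.default_rng(991_823).uniform(-1.0, 1.0, size=4096)
_BASES = np.array(list("ACGT"))


def motif_score(context: str) -> float:
    """Score in [-1, 1] for the 6-mer context starting at a CpG's C; 0 if invalid."""
    if len(context) != 6:
        return 0.0
    idx = 0
    for base in context:
        code = "ACGT".find(base)
        if code < 0:
            return 0.0
        idx = idx * 4 + code
    return float(_MOTIF_TABLE[idx])


@dataclass
class SimConfig:
    """Study conditions for the synthetic benchmark.

    The defaults are the documented strong-signal conditions: 2
    chromosomes, 20 promoters each (40 total), 4 cell types x 40 cells,
    with a clique of 5 promoters per type whose within-clique contact
    weight is multiplied by (1 + contact_boost) and whose CpGs gain
    beta_topo on the logit scale for cells of that type.
    """

    n_chroms: int = 2
    chrom_length: int = 200_000
    n_promoters: int = 20
    cell_types: tuple[str, ...] = ("A", "B", "C", "D")
    cells_per_type: int = 40
    clique_size: int = 5
    type_block_map: Optional[dict[str, tuple[int, ...]]] = None
    contacts_per_cell: float = 60.0
    contact_boost: float = 8.0
    reads_per_cpg: float = 0.5
    planted_cpgs_per_window: int = 15
    gc_content: float = 0.30
    baseline_logit: float = -1.5
    beta_seq: float = 1.0
    beta_topo: float = 3.0
    noise_sd: float = 0.5
    tss_margin: int = 10_000
    seed: int = 0

    def cliques(self) -> dict[str, tuple[int, ...]]:
        if self.type_block_map is not None:
            return self.type_block_map
        if self.n_promoters == 0:
            return {t: () for t in self.cell_types}
        out = {}
        for i, t in enumerate(self.cell_types):
            start = i * self.clique_size
            idx = []
            for j in range(min(self.clique_size, self.n_promoters)):
                p = (start + j) % self.n_promoters
                if p not in idx:
                    idx.append(p)
            out[t] = tuple(idx)
        return out


@dataclass
class SimDataset:
    config: SimConfig
    genome: dict[str, str]
    regions_by_chrom: dict[str, list[TargetRegion]]
    cells: list[Cell]
    truth: pd.DataFrame                 # cell_id, cell_type
    cpg_probs: pd.DataFrame             # cell_type, chrom, pos, promoter, probability

    @property
    def cell_types(self) -> dict[str, str]:
        return dict(zip(self.truth["cell_id"], self.truth["cell_type"]))


def _tss_positions(config: SimConfig) -> list[int]:
    usable = config.chrom_length - 2 * config.tss_margin
    if config.n_promoters > 0 and usable < (config.n_promoters - 1):
        raise ValueError("chromosome too short for the requested promoter count")
    if config.n_promoters == 0:
        return []
    spacing = usable // max(config.n_promoters, 1)
    return [config.tss_margin + i * spacing for i in range(config.n_promoters)]


def simulate_genome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], dict[str, list[TargetRegion]]]:
    """Random genome with CpG-enriched promoter windows plus TSS regions.

    Background composition uses ``gc_content``; each 1-kb promoter window
    additionally gets ``planted_cpgs_per_window`` CG dinucleotides at even
    offsets, so windows carry CpGs with near certainty.
    """
    rng = rng or np.random.default_rng(config.seed)
    gc = config.gc_content / 2
    probs = np.array([0.5 - gc, gc, gc, 0.5 - gc])  # A, C, G, T
    genome: dict[str, str] = {}
    regions_by_chrom: dict[str, list[TargetRegion]] = {}
    tss_list = _tss_positions(config)
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=config.chrom_length, p=probs)
        regions = []
        for pi, tss in enumerate(tss_list):
            strand = "+" if pi % 2 == 0 else "-"
            region = TargetRegion.from_tss(
                f"P{chrom}_{pi}", chrom, tss, strand, chrom_length=config.chrom_length
            )
            if region.clipped:
                raise ValueError(f"promoter window of {region.gene_id} exceeds chromosome")
            start, end = region.seq_window
            offsets = rng.choice(
                np.arange(start, end - 1, 2), size=config.planted_cpgs_per_window,
                replace=False,
            )
            for off in offsets:
                seq[off] = "C"
                seq[off + 1] = "G"
            regions.append(region)
        genome[chrom] = "".join(seq)
        regions_by_chrom[chrom] = regions
    return genome, regions_by_chrom


def _cpg_sites(genome: dict[str, str], regions: list[TargetRegion]) -> tuple[np.ndarray, np.ndarray]:
    """(absolute C positions, promoter index) of CpGs in each seq window."""
    positions, owners = [], []
    for idx, region in enumerate(regions):
        start, end = region.seq_window
        seq = genome[region.chrom][start:end]
        at = seq.find("CG")
        while at != -1:
            positions.append(start + at)
            owners.append(idx)
            at = seq.find("CG", at + 1)
    return np.array(positions, dtype=int), np.array(owners, dtype=int)


def simulate_cells(
    config: SimConfig,
    genome: dict[str, str],
    regions_by_chrom: dict[str, list[TargetRegion]],
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[Cell], pd.DataFrame, pd.DataFrame]:
    """Draw cells: type-structured contacts and sequence+topology methylation.

    Contacts: each cell draws max(1, Poisson(contacts_per_cell)) contacts;
    a contact picks a chromosome uniformly, then a promoter pair with
    probability proportional to 1 + contact_boost x (both in the cell
    type's clique), then uniform positions inside the two contact windows.
    Methylation: per strand-resolved CpG cytosine, reads ~
    Poisson(reads_per_cpg), methylated reads ~ Binomial(reads, p) with p
    from the planted logit model; zero-read sites are absent. A cell with
    no covered site gets one forced single-read call so every emitted cell
    parses and pools.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    cliques = config.cliques()
    chroms = sorted(regions_by_chrom)
    n_prom = config.n_promoters

    # per chrom: CpG sites, owners, motif scores, per-CpG noise
    site_info = {}
    for chrom in chroms:
        pos, owners = _cpg_sites(genome, regions_by_chrom[chrom])
        motifs = np.array(
            [motif_score(genome[chrom][p : p + 6]) for p in pos]
        )
        noise = rng.normal(0.0, config.noise_sd, size=len(pos))
        site_info[chrom] = (pos, owners, motifs, noise)

    # per (type, chrom): per-CpG methylation probability
    prob_rows = []
    probs: dict[tuple[str, str], np.ndarray] = {}
    for t in config.cell_types:
        clique = set(cliques.get(t, ()))
        for chrom in chroms:
            pos, owners, motifs, noise = site_info[chrom]
            topo = np.isin(owners, list(clique)).astype(float)
            logit = (
                config.baseline_logit
                + config.beta_seq * motifs
                + config.beta_topo * topo
                + noise
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            probs[(t, chrom)] = p
            for j in range(len(pos)):
                prob_rows.append(
                    {"cell_type": t, "chrom": chrom, "pos": int(pos[j]),
                     "promoter": int(owners[j]), "probability": float(p[j])}
                )
    cpg_probs = pd.DataFrame(prob_rows)

    # per (type, chrom): promoter-pair sampling weights
    iu = np.triu_indices(n_prom, k=1)
    pair_weights: dict[tuple[str, str], np.ndarray] = {}
    for t in config.cell_types:
        clique = np.zeros(n_prom, dtype=bool)
        clique[list(cliques.get(t, ()))] = True
        w = 1.0 + config.contact_boost * (clique[iu[0]] & clique[iu[1]])
        pair_weights[t] = w / w.sum()

    cells: list[Cell] = []
    truth_rows = []
    width = len(str(len(config.cell_types) * config.cells_per_type))
    counter = 0
    for t in config.cell_types:
        for _ in range(config.cells_per_type):
            cell_id = f"cell{counter:0{width}d}"
            counter += 1
            truth_rows.append({"cell_id": cell_id, "cell_type": t})
            # ---- contacts
            n_contacts = max(1, int(rng.poisson(config.contacts_per_cell)))
            contact_chroms = rng.integers(0, len(chroms), size=n_contacts)
            contacts = []
            for ci in range(len(chroms)):
                chrom = chroms[ci]
                count = int((contact_chroms == ci).sum())
                if count == 0:
                    continue
                pairs = rng.choice(len(iu[0]), size=count, p=pair_weights[t])
                regions = regions_by_chrom[chrom]
                for pair_idx in pairs:
                    i, j = int(iu[0][pair_idx]), int(iu[1][pair_idx])
                    wa, wb = regions[i].contact_window, regions[j].contact_window
                    pa = int(rng.integers(wa[0], wa[1]))
                    pb = int(rng.integers(wb[0], wb[1]))
                    contacts.append(
                        ContactRecord.make(
                            GenomicPosition(chrom, pa), GenomicPosition(chrom, pb)
                        )
                    )
            # ---- methylation
            calls: list[MethylationCall] = []
            for chrom in chroms:
                pos, owners, motifs, noise = site_info[chrom]
                p = probs[(t, chrom)]
                for strand, offset in (("+", 0), ("-", 1)):
                    reads = rng.poisson(config.reads_per_cpg, size=len(pos))
                    covered = np.flatnonzero(reads)
                    meth = rng.binomial(reads[covered], p[covered])
                    for idx, n_meth in zip(covered, meth):
                        calls.append(
                            MethylationCall(
                                GenomicPosition(chrom, int(pos[idx]) + offset, strand),
                                int(n_meth),
                                int(reads[idx]),
                            )
                        )
            if not calls:
                chrom = chroms[0]
                pos, _, _, _ = site_info[chrom]
                j = int(rng.integers(len(pos)))
                covered_p = probs[(t, chrom)][j]
                calls.append(
                    MethylationCall(
                        GenomicPosition(chrom, int(pos[j]), "+"),
                        int(rng.random() < covered_p),
                        1,
                    )
                )
            cells.append(Cell(cell_id=cell_id, cell_type=t, contacts=contacts, methylation=calls))
    return cells, pd.DataFrame(truth_rows), cpg_probs


def simulate_dataset(config: SimConfig) -> SimDataset:
    """End-to-end deterministic dataset generation from config.seed."""
    rng = np.random.default_rng(config.seed)
    genome, regions_by_chrom = simulate_genome(config, rng)
    cells, truth, cpg_probs = simulate_cells(config, genome, regions_by_chrom, rng)
    return SimDataset(
        config=config, genome=genome, regions_by_chrom=regions_by_chrom,
        cells=cells, truth=truth, cpg_probs=cpg_probs,
    )


def write_dataset(ds: SimDataset, outdir) -> str:
    """Write the dataset in the pipeline's standard file formats.

    genome.fa, promoters.bed (BED6, one line per TSS), cells/<id>.contacts.tsv,
    cells/<id>.meth.tsv, manifest.tsv, truth.tsv, cpg_probs.tsv. Returns the
    manifest path.
    """
    outdir = str(outdir)
    os.makedirs(os.path.join(outdir, "cells"), exist_ok=True)
    with open(os.path.join(outdir, "genome.fa"), "w") as fh:
        for chrom in sorted(ds.genome):
            fh.write(f">{chrom}\n")
            seq = ds.genome[chrom]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(os.path.join(outdir, "promoters.bed"), "w") as fh:
        for chrom in sorted(ds.regions_by_chrom):
            for region in ds.regions_by_chrom[chrom]:
                tss = region.tss.pos
                fh.write(
                    f"{chrom}\t{tss}\t{tss + 1}\t{region.gene_id}\t0\t{region.strand}\n"
                )
    manifest_rows = []
    for cell in ds.cells:
        cpath = os.path.join("cells", f"{cell.cell_id}.contacts.tsv")
        mpath = os.path.join("cells", f"{cell.cell_id}.meth.tsv")
        pio.write_contact_pairs(os.path.join(outdir, cpath), cell.contacts)
        pio.write_methylation_calls(os.path.join(outdir, mpath), cell.methylation)
        manifest_rows.append((cell.cell_id, cell.cell_type or "", cpath, mpath))
    manifest_path = os.path.join(outdir, "manifest.tsv")
    pio.write_manifest(manifest_path, manifest_rows)
    ds.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    ds.cpg_probs.to_csv(os.path.join(outdir, "cpg_probs.tsv"), sep="\t", index=False)
    return manifest_path


def fixture_small() -> SimDataset:
    """Deterministic tiny dataset: 2 types x 25 cells, 1 chromosome, 12 promoters."""
    config = SimConfig(
        n_chroms=1,
        chrom_length=120_000,
        n_promoters=12,
        cell_types=("A", "B"),
        cells_per_type=25,
        clique_size=4,
        contacts_per_cell=40.0,
        seed=20_230_610,
    )
    return simulate_dataset(config)
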