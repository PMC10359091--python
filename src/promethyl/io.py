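"""Readers and writers for the file formats the pipeline touches.

Formats
-------
- contact pairs: tab-separated ``chrom1 pos1 chrom2 pos2`` (1-based by default)
- methylation calls: coverage-style ``chrom pos strand n_methylated n_total``
- TSS annotation: BED6 or GTF gene records
- genome: FASTA (via Biopython)
- predictions: bedGraph-style ``chrom start end value``
- cell manifest: tab-separated ``cell_id cell_type contacts_path methylation_path``
"""

from __future__ import annotations

import os
import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    Cell,
    ContactRecord,
    GenomicPosition,
    MethylationCall,
    ParseError,
    TargetRegion,
    ValidationError,
)

__all__ = [
    "read_contact_pairs",
    "read_methylation_calls",
    "read_tss_annotation",
    "read_genome",
    "write_predictions",
    "read_predictions",
    "read_manifest",
    "write_manifest",
    "load_cell",
    "write_contact_pairs",
    "write_methylation_calls",
]


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_contact_pairs(path, one_based: bool = True) -> list[ContactRecord]:
    """Read a tab-separated contact-pair file into canonicalized records.

    Each data line needs at least four fields: chrom1, pos1, chrom2, pos2.
    Positions are converted to the internal 0-based convention (input is
    declared 1-based by default).
    """
    shift = 1 if one_based else 0
    records: list[ContactRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected >=4 fields, got {len(fields)}")
        try:
            c1, p1, c2, p2 = fields[0], int(fields[1]), fields[2], int(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if p1 - shift < 0 or p2 - shift < 0:
            raise ValidationError(f"{path}:{lineno}: negative position after conversion")
        records.append(
            ContactRecord.make(
                GenomicPosition(c1, p1 - shift), GenomicPosition(c2, p2 - shift)
            )
        )
    return records


def read_methylation_calls(path, one_based: bool = True) -> list[MethylationCall]:
    """Read coverage-style methylation calls.

    Records with n_total == 0 are skipped with a warning; n_methylated >
    n_total is a validation error. '-'-strand records represent cytosines
    on the negative strand and are retained as-is.
    """
    shift = 1 if one_based else 0
    calls: list[MethylationCall] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 5:
            raise ParseError(f"{path}:{lineno}: expected >=5 fields, got {len(fields)}")
        chrom, strand = fields[0], fields[2]
        try:
            pos, n_meth, n_total = int(fields[1]), int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if n_total == 0:
            warnings.warn(f"{path}:{lineno}: zero-coverage record skipped")
            continue
        if n_meth > n_total:
            raise ValidationError(
                f"{path}:{lineno}: n_methylated {n_meth} > n_total {n_total}"
            )
        calls.append(
            MethylationCall(GenomicPosition(chrom, pos - shift, strand), n_meth, n_total)
        )
    return calls


def _region_from_fields(gene_id, chrom, tss, strand, chrom_sizes, seq_window_length):
    length = None if chrom_sizes is None else chrom_sizes.get(chrom)
    return TargetRegion.from_tss(
        gene_id, chrom, tss, strand, chrom_length=length,
        seq_window_length=seq_window_length,
    )


def read_tss_annotation(
    path,
    fmt: Optional[str] = None,
    chrom_sizes: Optional[dict[str, int]] = None,
    seq_window_length: int = 1000,
) -> list[TargetRegion]:
    """Read a gene annotation (BED6 or GTF) into one TargetRegion per gene.

    The TSS is the 5' end of the gene respecting strand. Duplicate gene ids
    keep the first occurrence with a warning; a missing strand is an error.
    """
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = "gtf" if ext in (".gtf", ".gff") else "bed"
    regions: list[TargetRegion] = []
    seen: set[str] = set()

    def add(gene_id, chrom, tss, strand, lineno):
        if strand not in ("+", "-"):
            raise ValidationError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
        if gene_id in seen:
            warnings.warn(f"{path}:{lineno}: duplicate gene_id {gene_id}, keeping first")
            return
        seen.add(gene_id)
        regions.append(
            _region_from_fields(gene_id, chrom, tss, strand, chrom_sizes, seq_window_length)
        )

    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fmt == "bed":
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 needs 6 fields")
            chrom, start, end, name, strand = (
                fields[0], int(fields[1]), int(fields[2]), fields[3], fields[5],
            )
            tss = start if strand == "+" else end - 1
            add(name, chrom, tss, strand, lineno)
        else:  # GTF: 1-based inclusive intervals, gene features only
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 fields")
            if fields[2] != "gene":
                continue
            chrom, start, end, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
            attrs = dict(
                kv.strip().split(" ", 1)
                for kv in fields[8].rstrip(";").split(";")
                if kv.strip()
            )
            gene_id = attrs.get("gene_id", f"line{lineno}").strip('"')
            tss = start - 1 if strand == "+" else end - 1
            add(gene_id, chrom, tss, strand, lineno)
    return regions


def read_genome(path) -> dict[str, str]:
    """Read a FASTA into an upper-cased chrom -> sequence mapping."""
    genome: dict[str, str] = {}
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise ValidationError(f"duplicate contig {rec.id} in {path}")
            genome[rec.id] = str(rec.seq).upper()
    return genome


def cpg_mask_for_region(genome: dict[str, str], region: TargetRegion) -> np.ndarray:
    """Boolean mask over the seq_window marking the C and G of reference CpGs."""
    start, end = region.seq_window
    seq = genome[region.chrom][start:end]
    mask = np.zeros(end - start, dtype=bool)
    idx = seq.find("CG")
    while idx != -1:
        mask[idx] = True
        mask[idx + 1] = True
        idx = seq.find("CG", idx + 1)
    return mask


def write_predictions(
    path,
    regions: Sequence[TargetRegion],
    predictions: Sequence[np.ndarray],
    genome: dict[str, str],
) -> None:
    """Write per-bp predictions as a bedGraph-style file.

    One line per C or G of a reference CpG inside each region's seq_window:
    chrom, start, end (0-based half-open single base), value in [0, 1].
    """
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tvalue\n")
        for region, pred in zip(regions, predictions):
            start, end = region.seq_window
            if len(pred) != end - start:
                raise ValidationError(
                    f"{region.gene_id}: prediction length {len(pred)} != window {end - start}"
                )
            mask = cpg_mask_for_region(genome, region)
            for offset in np.flatnonzero(mask):
                value = float(pred[offset])
                if not 0.0 <= value <= 1.0:
                    raise ValidationError(
                        f"{region.gene_id}: prediction {value} outside [0, 1]"
                    )
                pos = start + int(offset)
                fh.write(f"{region.chrom}\t{pos}\t{pos + 1}\t{value:.6f}\n")


def read_predictions(path) -> pd.DataFrame:
    """Read a predictions file back into a (chrom, start, end, value) frame."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )


def write_contact_pairs(path, contacts: Iterable[ContactRecord], one_based=True):
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("#chrom1\tpos1\tchrom2\tpos2\n")
        for rec in contacts:
            fh.write(
                f"{rec.end_a.chrom}\t{rec.end_a.pos + shift}\t"
                f"{rec.end_b.chrom}\t{rec.end_b.pos + shift}\n"
            )


def write_methylation_calls(path, calls: Iterable[MethylationCall], one_based=True):
    shift = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\tstrand\tn_methylated\tn_total\n")
        for call in calls:
            fh.write(
                f"{call.site.chrom}\t{call.site.pos + shift}\t{call.site.strand}\t"
                f"{call.n_methylated}\t{call.n_total}\n"
            )


def write_manifest(path, rows: Iterable[tuple[str, str, str, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("#cell_id\tcell_type\tcontacts\tmethylation\n")
        for cell_id, cell_type, cpath, mpath in rows:
            fh.write(f"{cell_id}\t{cell_type}\t{cpath}\t{mpath}\n")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["cell_id", "cell_type", "contacts", "methylation"], dtype=str,
    )
    if df["cell_id"].duplicated().any():
        dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
        raise ValidationError(f"duplicate cell ids in manifest: {dupes}")
    return df


def load_cell(manifest_row, base_dir=".", one_based: bool = True) -> Cell:
    """Load one cell's contact and methylation files named by a manifest row."""
    cdir = os.path.join(base_dir, manifest_row["contacts"])
    mdir = os.path.join(base_dir, manifest_row["methylation"])
    return Cell(
        cell_id=manifest_row["cell_id"],
        cell_type=manifest_row["cell_type"],
        contacts=read_contact_pairs(cdir, one_based=one_based),
        methylation=read_methylation_calls(mdir, one_based=one_based),
    )
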