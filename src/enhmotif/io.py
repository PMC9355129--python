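"""Readers and writers for the formats the pipeline touches.

FASTA (soft-masked, case preserved), BED intervals carrying the Q/A/PAN
group label, JASPAR-style position count matrices, and TSV gene tables.
All readers transparently accept gzip-compressed files (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io as _io
import logging
import re
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._types import BASES, EnhancerSequence, GeneRecord, GenomicInterval, PositionCountMatrix

log = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "read_jaspar_counts",
    "write_jaspar_counts",
    "read_gene_table",
    "write_gene_table",
    "attach_sequences",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]``, order and case kept.

    Raises ``ValueError`` on duplicate ids or an empty record.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r}")
            seen.add(rec.id)
            records.append((rec.id, seq))
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with _open_text(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# BED

def read_bed(path, group_column: int = 4) -> list[GenomicInterval]:
    """Read enhancer intervals from BED (0-based half-open, >=5 columns).

    Column 4 (0-based index 3) holds the interval name; ``group_column``
    (default the 5th column) holds the Q/A/PAN label. Errors name the
    offending line.
    """
    intervals: list[GenomicInterval] = []
    seen: set[str] = set()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) <= max(3, group_column):
                raise ValueError(f"line {lineno}: expected > {group_column} columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3]
            if name in seen:
                raise ValueError(f"line {lineno}: duplicate interval id {name!r}")
            seen.add(name)
            try:
                iv = GenomicInterval(fields[0], start, end, name, fields[group_column])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    with _open_text(path, "wt") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.group}\n")


# ---------------------------------------------------------------------------
# JASPAR position count matrices
#
# Format (2016+ text flavour):
#   >MA0768.1 LEF1
#   A  [  10  20 ... ]
#   C  [   0   5 ... ]
#   G  [ ... ]
#   T  [ ... ]
# Parsed strictly: four rows in A,C,G,T order, equal widths, no negatives.

_JASPAR_ROW = re.compile(r"^([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def read_jaspar_counts(path) -> list[PositionCountMatrix]:
    """Parse JASPAR-format count matrices into PositionCountMatrix objects."""
    matrices: list[PositionCountMatrix] = []
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.startswith(">"):
            raise ValueError(f"expected header line, got {line!r}")
        header = line[1:].split(None, 1)
        motif_id = header[0]
        name = header[1] if len(header) > 1 else ""
        rows: dict[str, list[float]] = {}
        for j in range(4):
            if i + 1 + j >= len(lines):
                raise ValueError(f"{motif_id}: truncated matrix")
            m = _JASPAR_ROW.match(lines[i + 1 + j].strip())
            if m is None:
                raise ValueError(
                    f"{motif_id}: malformed row {lines[i + 1 + j]!r}"
                )
            base, values = m.group(1), m.group(2).split()
            rows[base] = [float(v) for v in values]
        if set(rows) != set(BASES):
            raise ValueError(f"{motif_id}: rows must cover A, C, G, T")
        widths = {len(rows[b]) for b in BASES}
        if len(widths) != 1:
            raise ValueError(f"{motif_id}: row width mismatch {sorted(widths)}")
        counts = np.array([rows[b] for b in BASES], dtype=float)
        if (counts < 0).any():
            raise ValueError(f"{motif_id}: negative count")
        matrices.append(PositionCountMatrix(motif_id, counts, name))
        i += 5
    return matrices


def write_jaspar_counts(path, matrices: Iterable[PositionCountMatrix]) -> None:
    with _open_text(path, "wt") as fh:
        for pcm in matrices:
            header = f">{pcm.motif_id}"
            if pcm.name:
                header += f" {pcm.name}"
            fh.write(header + "\n")
            for b, row in zip(BASES, pcm.counts):
                vals = " ".join(repr(float(v)) for v in row)
                fh.write(f"{b} [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Gene tables

GENE_TABLE_COLUMNS = ("gene_id", "direction", "p_value", "enhancer_ids")


def read_gene_table(path, de_p_threshold: float = 0.01) -> list[GeneRecord]:
    """Read a TSV of genes and call DE classes at ``de_p_threshold``.

    Columns: gene id, direction sign (+/-), p-value, semicolon-joined
    enhancer ids. A gene is up- (or down-) regulated when its p-value falls
    below the threshold with the stated sign; otherwise it is ``ns``.
    """
    genes: list[GeneRecord] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_enh = len(header) >= 4
        if not has_enh:
            log.warning("gene table %s lacks an enhancer column; "
                        "all association lists will be empty", path)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            gene_id, sign, p_str = fields[0], fields[1], fields[2]
            p = float(p_str)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"line {lineno}: p-value {p} outside [0, 1]")
            if p < de_p_threshold:
                de_class = "up" if sign == "+" else "down"
            else:
                de_class = "ns"
            enh_ids: tuple[str, ...] = ()
            if has_enh and len(fields) >= 4 and fields[3]:
                enh_ids = tuple(fields[3].split(";"))
            genes.append(GeneRecord(gene_id, de_class, p, enh_ids))
    return genes


def write_gene_table(path, rows: Iterable[tuple[str, str, float, Iterable[str]]]) -> None:
    """Write (gene_id, sign, p_value, enhancer_ids) rows as TSV."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(GENE_TABLE_COLUMNS) + "\n")
        for gene_id, sign, p, enh_ids in rows:
            fh.write(f"{gene_id}\t{sign}\t{p:.6g}\t{';'.join(enh_ids)}\n")


# ---------------------------------------------------------------------------
# Sequence attachment

def attach_sequences(
    intervals: list[GenomicInterval], contigs: dict[str, str]
) -> list[EnhancerSequence]:
    """Extract each interval's sequence from ``contigs`` (chrom -> sequence).

    Case (soft-masking) is preserved; an interval running past its contig
    end is an error.
    """
    out: list[EnhancerSequence] = []
    for iv in intervals:
        if iv.chrom not in contigs:
            raise KeyError(f"{iv.name}: no sequence for chromosome {iv.chrom}")
        contig = contigs[iv.chrom]
        if iv.end > len(contig):
            raise ValueError(
                f"{iv.name}: interval end {iv.end} beyond contig length {len(contig)}"
            )
        out.append(EnhancerSequence(iv, contig[iv.start:iv.end]))
    return out
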