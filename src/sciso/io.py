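"""Readers and writers for the file formats the pipeline exchanges.

FASTA goes through Biopython. GTF is written 1-based inclusive with
``gene_id``/``transcript_id``/``gene_biotype``/``transcript_biotype``
attributes; BED files are 0-based half-open. Spliced alignments use a
documented TSV dialect (see :func:`write_alignments`) so the pipeline is
testable without a genome aligner; chimeric molecules occupy several
rows sharing a ``read_id``.
"""

from __future__ import annotations

import csv
import re
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import AlignmentRecord, TranscriptModel

# ---------------------------------------------------------------------------
# FASTA

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(transcripts: list[TranscriptModel], path: str | Path) -> None:
    """Write transcript/exon (and 3'UTR) features, 1-based inclusive."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{tx.gene_biotype}"; transcript_biotype "{tx.biotype}";'
            )
            if tx.gene_name:
                attrs += f' gene_name "{tx.gene_name}";'
            rows = [("transcript", tx.start, tx.end)]
            rows += [("exon", s, e) for s, e in tx.blocks]
            if tx.utr3 is not None:
                rows.append(("three_prime_utr", tx.utr3[0], tx.utr3[1]))
            for feature, s, e in rows:
                fh.write(
                    f"{tx.chrom}\tsciso\t{feature}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse the GTF dialect written by :func:`write_gtf` back into models."""
    exons: dict[str, list[tuple[int, int]]] = {}
    utrs: dict[str, tuple[int, int]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attr_str = line.rstrip("\n").split("\t")
            attrs = dict(_ATTR_RE.findall(attr_str))
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            s, e = int(start) - 1, int(end)
            if feature == "exon":
                exons.setdefault(tid, []).append((s, e))
            elif feature == "three_prime_utr":
                utrs[tid] = (s, e)
            meta.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", ""),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": attrs.get("transcript_biotype", "protein_coding"),
                    "gene_biotype": attrs.get("gene_biotype", "protein_coding"),
                    "gene_name": attrs.get("gene_name") or None,
                },
            )
    out = []
    for tid, blocks in exons.items():
        m = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                blocks=blocks,
                biotype=m["biotype"],
                gene_biotype=m["gene_biotype"],
                gene_name=m["gene_name"],
                utr3=utrs.get(tid),
            )
        )
    out.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return out


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals: list[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (chrom, start, end, name) intervals, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            name = fields[3] if len(fields) > 3 else "."
            out.append((fields[0], int(fields[1]), int(fields[2]), name))
    return out


# ---------------------------------------------------------------------------
# Alignment TSV dialect

_ALN_COLUMNS = [
    "read_id",
    "cell_barcode",
    "umi",
    "chrom",
    "strand",
    "block_starts",
    "block_ends",
    "locus_index",
    "subs",
]


def write_alignments(records: list[AlignmentRecord], path: str | Path) -> None:
    """Serialize spliced alignments to TSV.

    Columns: read_id, cell_barcode, umi, chrom, strand, comma-separated
    block starts and ends (0-based half-open), locus_index (0 for simple
    molecules; 0,1,... for the ordered loci of a chimeric read) and
    ``subs`` — semicolon-separated ``pos:base`` substitutions carried by
    the molecule (``.`` when none).
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ALN_COLUMNS)
        for rec in records:
            subs = ";".join(f"{p}:{b}" for p, b in sorted(rec.subs.items())) or "."
            writer.writerow(
                [
                    rec.read_id,
                    rec.cell_barcode,
                    rec.umi,
                    rec.chrom,
                    rec.strand,
                    ",".join(str(s) for s, _ in rec.blocks),
                    ",".join(str(e) for _, e in rec.blocks),
                    rec.locus_index,
                    subs,
                ]
            )


def read_alignments(path: str | Path) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            starts = [int(x) for x in row["block_starts"].split(",")]
            ends = [int(x) for x in row["block_ends"].split(",")]
            subs = {}
            if row.get("subs", ".") not in (".", ""):
                for item in row["subs"].split(";"):
                    pos, base = item.split(":")
                    subs[int(pos)] = base
            out.append(
                AlignmentRecord(
                    read_id=row["read_id"],
                    cell_barcode=row["cell_barcode"],
                    umi=row["umi"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    blocks=list(zip(starts, ends)),
                    locus_index=int(row.get("locus_index", 0) or 0),
                    subs=subs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Simple tables

def write_lines(lines: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{x}\n" for x in lines))


def read_lines(path: str | Path) -> list[str]:
    return [x.strip() for x in Path(path).read_text().splitlines() if x.strip()]


def read_group_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (cell barcode -> group label), headerless or headered."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip():
                continue
            a, b = line.rstrip("\n").split("\t")[:2]
            if i == 0 and a.lower() in ("cell_barcode", "barcode", "cell"):
                continue
            out[a] = b
    return out


def write_group_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_barcode\tgroup\n")
        for k in sorted(mapping):
            fh.write(f"{k}\t{mapping[k]}\n")
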