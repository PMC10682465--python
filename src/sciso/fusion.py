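"""Gene-fusion detection from chimeric split alignments.

A fusion candidate is a (UMI-deduplicated) molecule whose alignment
splits across two genes, either on different chromosomes or far apart
on the same chromosome, with substantial alignment on each side.
Candidates are aggregated into events by gene pair and breakpoint
(clustered with a small tolerance for alignment end wobble), and events
below a minimum UMI support are dropped.

For targeted follow-up, reads can be assigned to a small custom
reference (wild-type junction and fusion breakpoint spans) by best
edit-distance alignment, and per-group assignment counts tested for
group specificity with Fisher's exact test.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd
from scipy.stats import fisher_exact

from .models import AlignmentRecord, TranscriptModel

DEFAULT_MIN_DISTANCE = 100_000
DEFAULT_MIN_LOCUS_BP = 200
DEFAULT_MIN_UMIS = 10
BREAKPOINT_TOLERANCE = 10  # bp, clustering of event breakpoints
ASSIGN_MARGIN = 2  # edits between best and runner-up reference
ASSIGN_MIN_IDENTITY = 0.8


@dataclass
class SplitAlignment:
    read_id: str
    cell_barcode: str
    loci: list[tuple[str, str, str, tuple[int, int], int]]
    # (gene_id, chrom, strand, genomic span, aligned bases), read order


@dataclass
class FusionEvent:
    gene5: str
    gene3: str
    breakpoint5: tuple[str, int]  # (chrom, position)
    breakpoint3: tuple[str, int]
    umi_count: int
    per_cell_type: dict[str, int]
    n_cells: int
    read_ids: list[str] = field(default_factory=list)


def _gene_spans(
    annotation: list[TranscriptModel],
) -> dict[str, list[tuple[int, int, str]]]:
    spans: dict[str, dict[str, tuple[int, int]]] = defaultdict(dict)
    for tx in annotation:
        lo, hi = spans[tx.chrom].get(tx.gene_id, (tx.start, tx.end))
        spans[tx.chrom][tx.gene_id] = (min(lo, tx.start), max(hi, tx.end))
    return {
        chrom: sorted((lo, hi, g) for g, (lo, hi) in genes.items())
        for chrom, genes in spans.items()
    }


def _assign_gene(
    spans: dict[str, list[tuple[int, int, str]]], chrom: str, start: int, end: int
) -> str | None:
    best, best_ov = None, 0
    for lo, hi, gene in spans.get(chrom, []):
        ov = min(end, hi) - max(start, lo)
        if ov > best_ov:
            best, best_ov = gene, ov
    return best


def find_fusion_reads(
    alignments: list[AlignmentRecord],
    annotation: list[TranscriptModel],
    min_distance: int = DEFAULT_MIN_DISTANCE,
    min_locus_bp: int = DEFAULT_MIN_LOCUS_BP,
) -> list[SplitAlignment]:
    """Reads whose loci hit two distinct genes far apart or on different chromosomes.

    Each retained locus must align at least ``min_locus_bp`` bases;
    same-chromosome locus pairs must be separated by more than
    ``min_distance`` bp.
    """
    spans = _gene_spans(annotation)
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)
    out = []
    for read_id in sorted(by_read):
        records = sorted(by_read[read_id], key=lambda a: a.locus_index)
        if len(records) < 2:
            continue
        loci = []
        for rec in records:
            if rec.aligned_bases < min_locus_bp:
                continue
            gene = _assign_gene(spans, rec.chrom, rec.start, rec.end)
            if gene is None:
                continue
            loci.append((gene, rec.chrom, rec.strand, (rec.start, rec.end), rec.aligned_bases))
        genes = {g for g, *_ in loci}
        if len(genes) < 2:
            continue
        # every cross-gene pair must be distant or trans-chromosomal
        ok = True
        for i in range(len(loci)):
            for j in range(i + 1, len(loci)):
                gi, ci, _, (si, ei), _ = loci[i]
                gj, cj, _, (sj, ej), _ = loci[j]
                if gi == gj:
                    continue
                if ci == cj and max(si, sj) - min(ei, ej) <= min_distance:
                    ok = False
        if ok:
            out.append(
                SplitAlignment(
                    read_id=read_id,
                    cell_barcode=records[0].cell_barcode,
                    loci=loci,
                )
            )
    return out


def aggregate_events(
    fusion_reads: list[SplitAlignment],
    cell_types: dict[str, str] | None = None,
    min_umis: int = DEFAULT_MIN_UMIS,
    tolerance: int = BREAKPOINT_TOLERANCE,
) -> list[FusionEvent]:
    """Group fusion reads by gene pair and clustered breakpoints.

    The 5' breakpoint is the read-orientation end of the first locus and
    the 3' breakpoint the start of the second; breakpoints within
    ``tolerance`` bp join the same event. Events supported by fewer than
    ``min_umis`` deduplicated molecules are dropped.
    """
    def breakpoints(read: SplitAlignment):
        (g5, c5, s5, (lo5, hi5), _), (g3, c3, s3, (lo3, hi3), _) = read.loci[0], read.loci[1]
        bp5 = hi5 - 1 if s5 == "+" else lo5  # 3' end of the 5' locus
        bp3 = lo3 if s3 == "+" else hi3 - 1  # 5' start of the 3' locus
        return (g5, g3, (c5, bp5), (c3, bp3))

    clusters: dict[tuple[str, str], list[dict]] = defaultdict(list)
    for read in fusion_reads:
        g5, g3, bp5, bp3 = breakpoints(read)
        placed = None
        for cluster in clusters[(g5, g3)]:
            if (
                cluster["bp5"][0] == bp5[0]
                and cluster["bp3"][0] == bp3[0]
                and abs(cluster["bp5"][1] - bp5[1]) <= tolerance
                and abs(cluster["bp3"][1] - bp3[1]) <= tolerance
            ):
                placed = cluster
                break
        if placed is None:
            clusters[(g5, g3)].append(
                {"bp5": bp5, "bp3": bp3, "reads": [read]}
            )
        else:
            placed["reads"].append(read)

    events = []
    for (g5, g3) in sorted(clusters):
        for cluster in clusters[(g5, g3)]:
            reads = cluster["reads"]
            if len(reads) < min_umis:
                continue
            per_type: dict[str, int] = defaultdict(int)
            cells = set()
            for read in reads:
                cells.add(read.cell_barcode)
                label = (cell_types or {}).get(read.cell_barcode, "unknown")
                per_type[label] += 1
            events.append(
                FusionEvent(
                    gene5=g5,
                    gene3=g3,
                    breakpoint5=cluster["bp5"],
                    breakpoint3=cluster["bp3"],
                    umi_count=len(reads),
                    per_cell_type=dict(per_type),
                    n_cells=len(cells),
                    read_ids=[r.read_id for r in reads],
                )
            )
    return events


# ---------------------------------------------------------------------------
# Custom-reference assignment


def assign_reads_to_references(
    reads: dict[str, str],
    reference: dict[str, str],
    margin: int = ASSIGN_MARGIN,
    min_identity: float = ASSIGN_MIN_IDENTITY,
) -> pd.DataFrame:
    """Assign each read to the uniquely best-matching reference sequence.

    Each read is scored against every reference sequence (and its
    reverse complement) by best infix edit alignment. A read is assigned
    when exactly one sequence attains the best score with a margin of at
    least ``margin`` edits over the runner-up and at least
    ``min_identity`` identity over the aligned span; otherwise it is
    unassigned (reason ``ambiguous`` or ``poor_match``).
    """
    from .models import revcomp

    if not reference:
        raise ValueError("empty custom reference")
    rows = []
    names = sorted(reference)
    for read_id in sorted(reads):
        seq = reads[read_id]
        scores = {}
        for name in names:
            ref = reference[name]
            # query the shorter sequence as infix of the longer
            best = None
            for r in (ref, revcomp(ref)):
                query, target = (r, seq) if len(r) <= len(seq) else (seq, r)
                d = edlib.align(query, target, mode="HW", task="distance")["editDistance"]
                if best is None or d < best:
                    best = d
            scores[name] = best
        ordered = sorted(names, key=lambda n: (scores[n], n))
        best_name, best_score = ordered[0], scores[ordered[0]]
        runner_up = scores[ordered[1]] if len(ordered) > 1 else best_score + margin
        span = min(len(reference[best_name]), len(seq))
        identity = 1.0 - best_score / span if span else 0.0
        if identity < min_identity:
            assigned, reason = None, "poor_match"
        elif runner_up - best_score < margin:
            assigned, reason = None, "ambiguous"
        else:
            assigned, reason = best_name, ""
        rows.append(
            {
                "read_id": read_id,
                "assigned": assigned,
                "reason": reason,
                "edit_distance": best_score,
                "identity": identity,
            }
        )
    return pd.DataFrame(rows)


def contingency_test(
    assignments: pd.DataFrame, group_labels: dict[str, str]
) -> pd.DataFrame:
    """Per-reference two-sided Fisher test of group specificity.

    For each reference sequence, the 2x2 table is [[group1 hits, group1
    assigned elsewhere], [group2 hits, group2 assigned elsewhere]] over
    assigned reads only. Degenerate tables (an empty group) are valid
    and give p = 1.
    """
    assigned = assignments[assignments["assigned"].notna()].copy()
    assigned["group"] = assigned["read_id"].map(group_labels)
    groups = sorted(assigned["group"].dropna().unique())
    if len(groups) > 2:
        raise ValueError("contingency_test expects at most two groups")
    rows = []
    for ref_name in sorted(assigned["assigned"].unique()):
        table = []
        for g in groups:
            sub = assigned[assigned["group"] == g]
            hits = int((sub["assigned"] == ref_name).sum())
            table.append([hits, len(sub) - hits])
        while len(table) < 2:
            table.append([0, 0])
        _, p = fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "reference": ref_name,
                "table": table,
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows, columns=["reference", "table", "p_value"])


def events_table(events: list[FusionEvent]) -> pd.DataFrame:
    rows = [
        {
            "gene5": e.gene5,
            "gene3": e.gene3,
            "chrom5": e.breakpoint5[0],
            "breakpoint5": e.breakpoint5[1],
            "chrom3": e.breakpoint3[0],
            "breakpoint3": e.breakpoint3[1],
            "umi_count": e.umi_count,
            "n_cells": e.n_cells,
            "per_cell_type": ";".join(f"{k}={v}" for k, v in sorted(e.per_cell_type.items())),
        }
        for e in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "gene5", "gene3", "chrom5", "breakpoint5", "chrom3", "breakpoint3",
            "umi_count", "n_cells", "per_cell_type",
        ],
    )
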