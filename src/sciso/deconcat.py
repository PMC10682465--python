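"""Deconcatenation of concatenated full-length cDNA reads.

A raw read is a concatenation of segments, each laid out as
``5'primer + barcode(16) + UMI(12) + polyT + revcomp(cDNA) + 3'primer``
in either strand orientation. The module locates approximate primer
occurrences, cuts the read at them, validates segment orientation,
extracts cell barcode / UMI / polyA status, and deduplicates UMIs per
cell. Only segments with a correctly oriented primer pair, a
whitelisted barcode, a UMI and a polyA tail survive — every rejection
carries exactly one primary reason.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .models import revcomp

DEFAULT_MAX_EDIT = 3
DEFAULT_POLYA_MIN_RUN = 20
POLYA_MISMATCH_TOLERANCE = 0.10
_TAG_LEN = 28  # barcode(16) + UMI(12)


@dataclass(frozen=True)
class PrimerHit:
    read_id: str
    primer_kind: str  # "forward" | "reverse"
    strand: str  # "+" | "-"
    start: int
    end: int  # half-open offsets within the read
    edit_distance: int


@dataclass
class Segment:
    """A candidate segment between two successive primer hits."""

    read_id: str
    index: int
    start: int
    end: int
    sequence: str
    left: PrimerHit
    right: PrimerHit
    valid: bool
    strand: str | None  # orientation of the segment when valid


@dataclass
class TaggedMolecule:
    molecule_id: str
    cell_barcode: str
    umi: str
    has_polya: bool
    cdna_sequence: str  # sense orientation, polyA removed
    source_read_id: str
    segment_index: int
    read_count: int = 1
    merged_members: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class Rejection:
    source_read_id: str
    segment_index: int
    reason: str  # invalid_pair | too_short | no_barcode_match | no_polya


def _matches_of(pattern: str, read: str, max_edit: int) -> list[tuple[int, int, int]]:
    """All non-overlapping approximate occurrences of ``pattern`` in ``read``.

    Best (lowest edit distance) occurrences are located first and masked
    out, so overlapping candidates resolve lowest-distance-first.
    """
    text = bytearray(read, "ascii")
    found: list[tuple[int, int, int]] = []
    while True:
        res = edlib.align(pattern, text.decode(), mode="HW", task="locations", k=max_edit)
        if res["editDistance"] == -1:
            break
        new = []
        for s, e in res["locations"]:
            s = s or 0
            e = e + 1
            if any(not (e <= fs or s >= fe) for fs, fe, _ in new):
                continue
            new.append((s, e, res["editDistance"]))
        if not new:
            break
        for s, e, d in new:
            found.append((s, e, d))
            text[s:e] = b"#" * (e - s)
    return found


def find_primer_hits(
    read: str,
    forward_primer: str,
    reverse_primer: str,
    max_edit: int = DEFAULT_MAX_EDIT,
    read_id: str = "",
) -> list[PrimerHit]:
    """Locate all approximate primer occurrences on either strand.

    Overlapping candidates across the four patterns (each primer and its
    reverse complement) are resolved lowest-edit-distance first, then
    leftmost; the result is sorted by start offset.
    """
    if not read:
        return []
    patterns = [
        (forward_primer, "forward", "+"),
        (revcomp(forward_primer), "forward", "-"),
        (reverse_primer, "reverse", "+"),
        (revcomp(reverse_primer), "reverse", "-"),
    ]
    candidates: list[PrimerHit] = []
    for pattern, kind, strand in patterns:
        for s, e, d in _matches_of(pattern, read, max_edit):
            candidates.append(PrimerHit(read_id, kind, strand, s, e, d))
    candidates.sort(key=lambda h: (h.edit_distance, h.start, h.primer_kind, h.strand))
    kept: list[PrimerHit] = []
    for hit in candidates:
        if all(hit.end <= k.start or hit.start >= k.end for k in kept):
            kept.append(hit)
    kept.sort(key=lambda h: h.start)
    return kept


def split_segments(read: str, hits: list[PrimerHit], read_id: str = "") -> list[Segment]:
    """One candidate segment per gap between successive primer hits.

    A segment is valid when bounded by a correctly oriented primer pair:
    forward(+) then reverse(+), or reverse(-) then forward(-) (the
    reverse-complemented layout). Flanks outside the outermost hits are
    discarded.
    """
    segments = []
    for i in range(len(hits) - 1):
        left, right = hits[i], hits[i + 1]
        if (
            left.primer_kind == "forward"
            and left.strand == "+"
            and right.primer_kind == "reverse"
            and right.strand == "+"
        ):
            valid, strand = True, "+"
        elif (
            left.primer_kind == "reverse"
            and left.strand == "-"
            and right.primer_kind == "forward"
            and right.strand == "-"
        ):
            valid, strand = True, "-"
        else:
            valid, strand = False, None
        segments.append(
            Segment(
                read_id=read_id or left.read_id,
                index=i,
                start=left.end,
                end=right.start,
                sequence=read[left.end : right.start],
                left=left,
                right=right,
                valid=valid,
                strand=strand,
            )
        )
    return segments


def _polya_run(seq: str) -> int:
    """Longest 3'-terminal polyA run allowing <=10% non-A, ending on an A."""
    best = 0
    mismatches = 0
    for length in range(1, len(seq) + 1):
        if seq[-length] != "A":
            mismatches += 1
            if mismatches > POLYA_MISMATCH_TOLERANCE * length:
                break
        else:
            if mismatches <= POLYA_MISMATCH_TOLERANCE * length:
                best = length
    return best


def match_barcode(barcode: str, whitelist: set[str]) -> str | None:
    """Exact whitelist match, else unique Hamming-1 rescue; ambiguous -> None."""
    if barcode in whitelist:
        return barcode
    hits = set()
    for i, orig in enumerate(barcode):
        for b in "ACGT":
            if b == orig:
                continue
            cand = barcode[:i] + b + barcode[i + 1 :]
            if cand in whitelist:
                hits.add(cand)
                if len(hits) > 1:
                    return None
    return hits.pop() if len(hits) == 1 else None


def extract_tags(
    segment: Segment,
    whitelist: set[str],
    polya_min_run: int = DEFAULT_POLYA_MIN_RUN,
) -> TaggedMolecule | Rejection:
    """Extract barcode, UMI and polyA-trimmed sense cDNA from a valid segment."""
    seq = segment.sequence if segment.strand == "+" else revcomp(segment.sequence)
    if len(seq) < _TAG_LEN + polya_min_run:
        return Rejection(segment.read_id, segment.index, "too_short")
    barcode = match_barcode(seq[:16], whitelist)
    if barcode is None:
        return Rejection(segment.read_id, segment.index, "no_barcode_match")
    umi = seq[16:_TAG_LEN]
    cdna_with_tail = revcomp(seq[_TAG_LEN:])  # sense orientation, polyA at 3' end
    run = _polya_run(cdna_with_tail)
    if run < polya_min_run:
        return Rejection(segment.read_id, segment.index, "no_polya")
    cdna = cdna_with_tail[:-run]
    if not cdna:
        return Rejection(segment.read_id, segment.index, "too_short")
    return TaggedMolecule(
        molecule_id=f"{segment.read_id}/{segment.index}",
        cell_barcode=barcode,
        umi=umi,
        has_polya=True,
        cdna_sequence=cdna,
        source_read_id=segment.read_id,
        segment_index=segment.index,
    )


def deconcatenate_read(
    read_id: str,
    read: str,
    forward_primer: str,
    reverse_primer: str,
    whitelist: set[str],
    max_edit: int = DEFAULT_MAX_EDIT,
    polya_min_run: int = DEFAULT_POLYA_MIN_RUN,
) -> tuple[list[TaggedMolecule], list[Rejection]]:
    hits = find_primer_hits(read, forward_primer, reverse_primer, max_edit, read_id)
    accepted, rejected = [], []
    for segment in split_segments(read, hits, read_id):
        if not segment.valid:
            rejected.append(Rejection(read_id, segment.index, "invalid_pair"))
            continue
        result = extract_tags(segment, whitelist, polya_min_run)
        if isinstance(result, Rejection):
            rejected.append(result)
        else:
            accepted.append(result)
    return accepted, rejected


def deconcatenate(
    reads: dict[str, str],
    forward_primer: str,
    reverse_primer: str,
    whitelist: set[str],
    max_edit: int = DEFAULT_MAX_EDIT,
    polya_min_run: int = DEFAULT_POLYA_MIN_RUN,
) -> tuple[list[TaggedMolecule], list[Rejection]]:
    """Deconcatenate a read set; returns accepted molecules and rejections."""
    accepted: list[TaggedMolecule] = []
    rejected: list[Rejection] = []
    for read_id, seq in reads.items():
        a, r = deconcatenate_read(
            read_id, seq, forward_primer, reverse_primer, whitelist, max_edit, polya_min_run
        )
        accepted.extend(a)
        rejected.extend(r)
    return accepted, rejected


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    diff = 0
    for x, y in zip(a, b):
        if x != y:
            diff += 1
            if diff > 1:
                return False
    return diff == 1


def dedup_umis(molecules: list[TaggedMolecule]) -> list[TaggedMolecule]:
    """Directional UMI deduplication within each cell.

    UMIs identical or within Hamming distance 1 merge, lower-count into
    higher-count; the representative molecule is the longest cDNA in the
    cluster and the output ``read_count`` is the number of merged reads.
    """
    by_cell: dict[str, list[TaggedMolecule]] = defaultdict(list)
    for mol in molecules:
        by_cell[mol.cell_barcode].append(mol)
    out: list[TaggedMolecule] = []
    for barcode in sorted(by_cell):
        group = by_cell[barcode]
        counts: dict[str, list[TaggedMolecule]] = defaultdict(list)
        for mol in group:
            counts[mol.umi].append(mol)
        ordered = sorted(counts, key=lambda u: (-len(counts[u]), u))
        cluster_of: dict[str, str] = {}
        members: dict[str, list[str]] = {}
        for umi in ordered:
            target = None
            for rep in members:  # insertion order = descending count
                if _hamming1(umi, rep) and len(counts[rep]) >= len(counts[umi]):
                    target = rep
                    break
            if target is None:
                members[umi] = [umi]
                cluster_of[umi] = umi
            else:
                members[target].append(umi)
                cluster_of[umi] = target
        for rep, umis in members.items():
            mols = [m for u in umis for m in counts[u]]
            best = max(mols, key=lambda m: (len(m.cdna_sequence), m.molecule_id))
            out.append(
                TaggedMolecule(
                    molecule_id=best.molecule_id,
                    cell_barcode=barcode,
                    umi=rep,
                    has_polya=best.has_polya,
                    cdna_sequence=best.cdna_sequence,
                    source_read_id=best.source_read_id,
                    segment_index=best.segment_index,
                    read_count=len(mols),
                    merged_members=[m.molecule_id for m in mols],
                )
            )
    return out
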