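"""Isoform catalog construction, structural classification and filtering.

Molecules sharing an identical splice-junction chain collapse into one
isoform; each isoform is then assigned a SQANTI-style structural
category against the reference annotation:

* **FSM** — the junction chain equals a reference transcript's chain;
* **ISM** — a contiguous sub-chain of a reference chain (a shortened
  version of a known isoform);
* **NIC** — every splice donor and acceptor is known at the locus but
  the combination (or the donor/acceptor pairing) is new;
* **NNC** — at least one donor or acceptor is novel (a neojunction);
* **other** — mono-exon or intergenic isoforms.

Library-preparation artifacts are then flagged and removed: genomic
A-stretch intrapriming at the 3' end, noncanonical novel junction
motifs, reverse-transcriptase template switching at direct repeats, and
low UMI support. End validation retains non-FSM isoforms only when
their TSS lies near a CAGE peak and their TES near a known polyA site.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .models import AlignmentRecord, SpliceJunction, TranscriptModel, revcomp

CATEGORIES = ("FSM", "ISM", "NIC", "NNC", "other")
CANONICAL_MOTIFS = frozenset({"GT-AG", "GC-AG", "AT-AC"})
DEFAULT_MIN_UMIS = 3
DEFAULT_END_WINDOW = 50
DEFAULT_INTRAPRIMING_WINDOW = 20
DEFAULT_INTRAPRIMING_A_FRACTION = 0.6
DEFAULT_RT_REPEAT_LEN = 8


@dataclass
class IsoformRecord:
    isoform_id: str
    chrom: str
    strand: str
    blocks: list[tuple[int, int]]
    junctions: tuple[SpliceJunction, ...]
    tss: int
    tes: int
    counts: dict[str, int]  # cell barcode -> UMIs
    category: str = "other"
    gene_id: str | None = None
    matched_transcript_id: str | None = None
    biotype: str | None = None
    flags: set[str] = field(default_factory=set)
    specificity: str = "not_assessed"

    @property
    def total_umis(self) -> int:
        return sum(self.counts.values())

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


# ---------------------------------------------------------------------------
# Collapse


def _strand_ends(strand: str, start: int, end: int) -> tuple[int, int]:
    """(tss, tes) genomic coordinates for a span in transcript orientation."""
    return (start, end - 1) if strand == "+" else (end - 1, start)


def collapse_molecules(alignments: list[AlignmentRecord]) -> list[IsoformRecord]:
    """Merge molecules into isoforms by exact junction-chain identity.

    Multi-exon molecules with an identical chain merge into one isoform
    whose TSS is the 5'-most observed start and whose TES is the modal
    observed end (ties resolved 3'-most). Mono-exon molecules merge when
    their intervals overlap reciprocally by at least 95%. Chimeric
    records (locus_index > 0 present) are left out — they are the fusion
    caller's input, not isoforms.
    """
    chimeric = {a.read_id for a in alignments if a.locus_index > 0}
    simple = [a for a in alignments if a.read_id not in chimeric]
    multi: dict[tuple, list[AlignmentRecord]] = defaultdict(list)
    mono: dict[tuple[str, str], list[AlignmentRecord]] = defaultdict(list)
    for aln in simple:
        if len(aln.blocks) > 1:
            key = (aln.chrom, aln.strand, tuple((j.donor, j.acceptor) for j in aln.junctions))
            multi[key].append(aln)
        else:
            mono[(aln.chrom, aln.strand)].append(aln)

    isoforms: list[IsoformRecord] = []

    def build(members: list[AlignmentRecord], idx: int) -> IsoformRecord:
        chrom, strand = members[0].chrom, members[0].strand
        counts: dict[str, int] = defaultdict(int)
        for m in members:
            counts[m.cell_barcode] += 1
        if strand == "+":
            start = min(m.start for m in members)  # 5'-most observed start
            end = _modal_end([m.end for m in members], prefer_high=True)
            tss, tes = start, end - 1
        else:
            end = max(m.end for m in members)  # 5'-most observed start (minus strand)
            start = _modal_end([m.start for m in members], prefer_high=False)
            tss, tes = end - 1, start
        rep = members[0]
        blocks = [list(b) for b in rep.blocks]
        blocks[0][0] = start
        blocks[-1][1] = end
        blocks = [tuple(b) for b in blocks]
        return IsoformRecord(
            isoform_id=f"iso{idx:06d}",
            chrom=chrom,
            strand=strand,
            blocks=blocks,
            junctions=tuple(
                SpliceJunction(chrom, d, a, strand)
                for d, a in ((j.donor, j.acceptor) for j in rep.junctions)
            ),
            tss=tss,
            tes=tes,
            counts=dict(counts),
        )

    idx = 0
    for key in sorted(multi, key=lambda k: (k[0], k[1], k[2])):
        idx += 1
        isoforms.append(build(multi[key], idx))
    for (chrom, strand) in sorted(mono):
        for members in _cluster_mono(mono[(chrom, strand)]):
            idx += 1
            isoforms.append(build(members, idx))
    return isoforms


def _modal_end(votes: list[int], prefer_high: bool) -> int:
    counts: dict[int, int] = defaultdict(int)
    for v in votes:
        counts[v] += 1
    best = max(counts.items(), key=lambda kv: (kv[1], kv[0] if prefer_high else -kv[0]))
    return best[0]


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return 0.0
    return min(ov / (a[1] - a[0]), ov / (b[1] - b[0]))


def _cluster_mono(
    records: list[AlignmentRecord], min_overlap: float = 0.95
) -> list[list[AlignmentRecord]]:
    """Single-linkage clustering of mono-exon intervals at >=95% reciprocal overlap."""
    records = sorted(records, key=lambda r: (r.start, r.end, r.read_id))
    clusters: list[list[AlignmentRecord]] = []
    for rec in records:
        placed = False
        for cluster in clusters:
            if any(
                _reciprocal_overlap((rec.start, rec.end), (m.start, m.end)) >= min_overlap
                for m in cluster
            ):
                cluster.append(rec)
                placed = True
                break
        if not placed:
            clusters.append([rec])
    return clusters


# ---------------------------------------------------------------------------
# Classification


class ReferenceIndex:
    """Per-locus junction-chain and splice-site index over the annotation."""

    def __init__(self, transcripts: list[TranscriptModel]):
        self.transcripts = transcripts
        self.by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
        self.gene_span: dict[str, tuple[str, str, int, int]] = {}
        self.chains: dict[str, set[tuple]] = defaultdict(set)
        self.chain_to_tx: dict[tuple, str] = {}
        self.donors: dict[str, set[int]] = defaultdict(set)
        self.acceptors: dict[str, set[int]] = defaultdict(set)
        self.known_junctions: dict[str, set[tuple[int, int]]] = defaultdict(set)
        for tx in transcripts:
            g = tx.gene_id
            self.by_gene[g].append(tx)
            chrom, strand, lo, hi = self.gene_span.get(g, (tx.chrom, tx.strand, tx.start, tx.end))
            self.gene_span[g] = (chrom, strand, min(lo, tx.start), max(hi, tx.end))
            chain = tuple((j.donor, j.acceptor) for j in tx.junctions)
            self.chains[g].add(chain)
            self.chain_to_tx.setdefault((tx.chrom, tx.strand, chain), tx.transcript_id)
            for d, a in chain:
                self.donors[g].add(d)
                self.acceptors[g].add(a)
                self.known_junctions[g].add((d, a))

    def assign_gene(self, chrom: str, strand: str, start: int, end: int) -> str | None:
        """Locus with maximal span overlap on the same chrom and strand."""
        best, best_ov = None, 0
        for g, (gchrom, gstrand, lo, hi) in sorted(self.gene_span.items()):
            if gchrom != chrom or gstrand != strand:
                continue
            ov = min(end, hi) - max(start, lo)
            if ov > best_ov:
                best, best_ov = g, ov
        return best


def _is_subchain(query: tuple, chain: tuple) -> bool:
    """True when ``query`` is a contiguous sub-chain of ``chain``."""
    n, m = len(query), len(chain)
    if n > m:
        return False
    return any(chain[i : i + n] == query for i in range(m - n + 1))


def classify_isoform(
    isoform: IsoformRecord, index: ReferenceIndex
) -> tuple[str, str | None, str | None]:
    """Structural category, assigned gene and matched transcript (FSM/ISM)."""
    if len(isoform.blocks) < 2:
        gene = index.assign_gene(isoform.chrom, isoform.strand, isoform.start, isoform.end)
        return "other", gene, None
    gene = index.assign_gene(isoform.chrom, isoform.strand, isoform.start, isoform.end)
    if gene is None:
        return "other", None, None
    query = tuple((j.donor, j.acceptor) for j in isoform.junctions)
    if query in index.chains[gene]:
        return "FSM", gene, index.chain_to_tx[(isoform.chrom, isoform.strand, query)]
    for chain in sorted(index.chains[gene]):
        if _is_subchain(query, chain):
            return "ISM", gene, index.chain_to_tx[(isoform.chrom, isoform.strand, chain)]
    donors, acceptors = index.donors[gene], index.acceptors[gene]
    if all(d in donors for d, _ in query) and all(a in acceptors for _, a in query):
        return "NIC", gene, None
    return "NNC", gene, None


def classify_catalog(
    isoforms: list[IsoformRecord], reference: list[TranscriptModel]
) -> list[IsoformRecord]:
    index = ReferenceIndex(reference)
    biotype_of = {tx.transcript_id: tx.biotype for tx in reference}
    for iso in isoforms:
        category, gene, matched = classify_isoform(iso, index)
        iso.category = category
        iso.gene_id = gene
        iso.matched_transcript_id = matched
        iso.biotype = biotype_of.get(matched) if matched else "novel"
    return isoforms


# ---------------------------------------------------------------------------
# Artifact detection


def detect_intrapriming(
    isoform: IsoformRecord,
    genome: dict[str, str],
    window: int = DEFAULT_INTRAPRIMING_WINDOW,
    a_fraction: float = DEFAULT_INTRAPRIMING_A_FRACTION,
) -> bool:
    """A-rich genomic window immediately downstream of the TES.

    On the minus strand the window is taken genomically upstream and
    complemented, so the same decision applies to mirrored loci.
    """
    seq = genome[isoform.chrom]
    if isoform.strand == "+":
        downstream = seq[isoform.tes + 1 : isoform.tes + 1 + window]
        target = "A"
    else:
        downstream = seq[max(0, isoform.tes - window) : isoform.tes]
        target = "T"  # complement of A on the plus strand
    if not downstream:
        return False
    frac = downstream.count(target) / len(downstream)
    return frac >= a_fraction


def _junction_is_novel(isoform: IsoformRecord, index: ReferenceIndex, j: SpliceJunction) -> bool:
    if isoform.gene_id is None:
        return True
    return (j.donor, j.acceptor) not in index.known_junctions[isoform.gene_id]


def detect_rt_switch(
    isoform: IsoformRecord,
    genome: dict[str, str],
    index: ReferenceIndex,
    repeat_len: int = DEFAULT_RT_REPEAT_LEN,
) -> bool:
    """Direct-repeat signature of reverse-transcriptase template switching.

    A novel junction is flagged when an exact repeat of ``repeat_len``
    spans both the donor exon/intron boundary and the intron/acceptor
    boundary. Reference-supported junctions are never flagged.
    """
    seq = genome[isoform.chrom]
    for j in isoform.junctions:
        if not _junction_is_novel(isoform, index, j):
            continue
        for s1 in range(j.donor - repeat_len + 1, j.donor + 1):
            if s1 < 0:
                continue
            w1 = seq[s1 : s1 + repeat_len]
            for s2 in range(j.acceptor - repeat_len + 1, j.acceptor + 1):
                if s2 < 0:
                    continue
                if w1 == seq[s2 : s2 + repeat_len]:
                    return True
    return False


# ---------------------------------------------------------------------------
# Filtering


def filter_catalog(
    isoforms: list[IsoformRecord],
    genome: dict[str, str],
    reference: list[TranscriptModel],
    min_umis: int = DEFAULT_MIN_UMIS,
    intrapriming_window: int = DEFAULT_INTRAPRIMING_WINDOW,
    intrapriming_a_fraction: float = DEFAULT_INTRAPRIMING_A_FRACTION,
    rt_repeat_len: int = DEFAULT_RT_REPEAT_LEN,
) -> tuple[list[IsoformRecord], dict[str, int]]:
    """Remove artifact and low-support isoforms.

    Removal reasons, checked in fixed order for deterministic reporting:
    ``intrapriming``, ``noncanonical`` (a novel junction with a motif
    outside GT-AG/GC-AG/AT-AC), ``rt_switch``, ``min_umis``. Junctions
    present in the reference are exempt from the motif rule.
    """
    index = ReferenceIndex(reference)
    retained = []
    removals: dict[str, int] = {
        "intrapriming": 0,
        "noncanonical": 0,
        "rt_switch": 0,
        "min_umis": 0,
    }
    for iso in isoforms:
        if detect_intrapriming(iso, genome, intrapriming_window, intrapriming_a_fraction):
            iso.flags.add("intrapriming")
            removals["intrapriming"] += 1
            continue
        novel_noncanonical = any(
            _junction_is_novel(iso, index, j)
            and j.motif(genome) not in CANONICAL_MOTIFS
            for j in iso.junctions
        )
        if novel_noncanonical:
            iso.flags.add("noncanonical")
            removals["noncanonical"] += 1
            continue
        if detect_rt_switch(iso, genome, index, rt_repeat_len):
            iso.flags.add("rt_switch")
            removals["rt_switch"] += 1
            continue
        if iso.total_umis < min_umis:
            removals["min_umis"] += 1
            continue
        retained.append(iso)
    return retained, removals


def validate_ends(
    isoforms: list[IsoformRecord],
    cage: list[tuple[str, int, int, str]],
    polya_sites: list[tuple[str, int, int, str]],
    window: int = DEFAULT_END_WINDOW,
) -> tuple[list[IsoformRecord], int]:
    """Retain isoforms with CAGE-supported TSS and polyA-supported TES.

    An isoform is validated when its TSS lies within ``window`` bp of a
    CAGE interval and its TES within ``window`` bp of a polyA site.
    Unvalidated ISM/NIC/NNC/other isoforms are removed; FSM isoforms are
    always retained (the flag is still recorded). Returns the retained
    catalog and the number removed.
    """
    import warnings

    if not cage or not polya_sites:
        warnings.warn("empty CAGE or polyA reference: all non-FSM isoforms removed")
    cage_by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for chrom, s, e, _ in cage:
        cage_by_chrom[chrom].append((s, e))
    pas_by_chrom: dict[str, list[int]] = defaultdict(list)
    for chrom, s, e, _ in polya_sites:
        pas_by_chrom[chrom].extend(range(s, e))

    def near_interval(chrom: str, pos: int) -> bool:
        return any(
            s - window <= pos < e + window for s, e in cage_by_chrom.get(chrom, [])
        )

    def near_site(chrom: str, pos: int) -> bool:
        return any(abs(pos - p) <= window for p in pas_by_chrom.get(chrom, []))

    retained = []
    n_removed = 0
    for iso in isoforms:
        validated = near_interval(iso.chrom, iso.tss) and near_site(iso.chrom, iso.tes)
        if not validated:
            iso.flags.add("end_unvalidated")
        if validated or iso.category == "FSM":
            retained.append(iso)
        else:
            n_removed += 1
    return retained, n_removed


# ---------------------------------------------------------------------------
# Cell-type specificity


def specificity_class(
    isoforms: list[IsoformRecord],
    cell_type_labels: dict[str, str],
    min_reads: int = 3,
) -> list[IsoformRecord]:
    """Label FSM/NIC/NNC isoforms with >= ``min_reads`` UMIs by specificity.

    ``cell_specific``: present in exactly one cell. ``cell_type_specific``:
    present in at least three cells, all of a single cell type. Otherwise
    ``shared``. Isoforms outside the eligible categories or below the
    read threshold keep the ``not_assessed`` label; cells without a type
    label are excluded with a warning.
    """
    import warnings

    unlabeled = {
        bc for iso in isoforms for bc in iso.counts if bc not in cell_type_labels
    }
    if unlabeled:
        warnings.warn(f"{len(unlabeled)} cells lack a cell-type label; excluded")
    for iso in isoforms:
        if iso.category not in ("FSM", "NIC", "NNC") or iso.total_umis < min_reads:
            iso.specificity = "not_assessed"
            continue
        cells = [bc for bc, n in iso.counts.items() if n > 0 and bc in cell_type_labels]
        types = {cell_type_labels[bc] for bc in cells}
        if len(cells) == 1:
            iso.specificity = "cell_specific"
        elif len(cells) >= 3 and len(types) == 1:
            iso.specificity = "cell_type_specific"
        else:
            iso.specificity = "shared"
    return isoforms


# ---------------------------------------------------------------------------
# Whole-stage convenience


def build_catalog(
    alignments: list[AlignmentRecord],
    reference: list[TranscriptModel],
    genome: dict[str, str],
    cage: list[tuple[str, int, int, str]],
    polya_sites: list[tuple[str, int, int, str]],
    cell_type_labels: dict[str, str] | None = None,
    min_umis: int = DEFAULT_MIN_UMIS,
    end_window: int = DEFAULT_END_WINDOW,
) -> tuple[list[IsoformRecord], dict[str, int]]:
    """Collapse, classify, filter and validate in one pass."""
    isoforms = collapse_molecules(alignments)
    classify_catalog(isoforms, reference)
    retained, removals = filter_catalog(isoforms, genome, reference, min_umis=min_umis)
    retained, n_unvalidated = validate_ends(retained, cage, polya_sites, window=end_window)
    removals["end_unvalidated"] = n_unvalidated
    if cell_type_labels:
        specificity_class(retained, cell_type_labels)
    return retained, removals
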