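"""Isoform collapse, structural classification, artifact filters, specificity."""

from __future__ import annotations

import pytest

from sciso.catalog import (
    IsoformRecord,
    ReferenceIndex,
    classify_catalog,
    classify_isoform,
    collapse_molecules,
    detect_intrapriming,
    detect_rt_switch,
    filter_catalog,
    specificity_class,
    validate_ends,
)
from sciso.models import AlignmentRecord, SpliceJunction, TranscriptModel, revcomp

# ---------------------------------------------------------------------------
# Brute-force classification oracle (independent of the implementation)


def oracle_category(chain: tuple, ref_chains: list[tuple]) -> str:
    if chain in ref_chains:
        return "FSM"
    for rc in ref_chains:
        for i in range(len(rc)):
            for j in range(i + 1, len(rc) + 1):
                if rc[i:j] == chain:
                    return "ISM"
    donors = {d for rc in ref_chains for d, _ in rc}
    acceptors = {a for rc in ref_chains for _, a in rc}
    if all(d in donors for d, _ in chain) and all(a in acceptors for _, a in chain):
        return "NIC"
    return "NNC"


def _aln(chrom, strand, blocks, cell="c1", read="r1", umi="U"):
    return AlignmentRecord(read, cell, umi, chrom, strand, [tuple(b) for b in blocks])


def _chain_to_blocks(chain: tuple, lo: int, hi: int) -> list[tuple[int, int]]:
    """Exon blocks spanning [lo, hi) with introns at the chain positions."""
    blocks = []
    start = lo
    for d, a in chain:
        blocks.append((start, d))
        start = a
    blocks.append((start, hi))
    return blocks


def make_reference(chains, chrom="chr1", strand="+", gene="gA", lo=100, hi=5000):
    return [
        TranscriptModel(f"{gene}.T{i + 1}", gene, chrom, strand, _chain_to_blocks(c, lo, hi))
        for i, c in enumerate(chains)
    ]


# ---------------------------------------------------------------------------
# Collapse


def test_collapse_identical_chains_different_tss():
    a1 = _aln("chr1", "+", [(100, 200), (300, 400), (500, 650)], read="r1")
    a2 = _aln("chr1", "+", [(120, 200), (300, 400), (500, 650)], read="r2")
    isoforms = collapse_molecules([a1, a2])
    assert len(isoforms) == 1
    iso = isoforms[0]
    assert iso.total_umis == 2
    assert iso.tss == 100  # 5'-most observed start
    assert iso.tes == 649


def test_collapse_accumulates_per_cell_counts():
    a1 = _aln("chr1", "+", [(100, 200), (300, 400)], cell="cellA", read="r1")
    a2 = _aln("chr1", "+", [(100, 200), (300, 400)], cell="cellB", read="r2")
    isoforms = collapse_molecules([a1, a2])
    assert len(isoforms) == 1
    assert isoforms[0].counts == {"cellA": 1, "cellB": 1}


def test_collapse_distinguishes_acceptor_shift():
    a1 = _aln("chr1", "+", [(100, 200), (300, 400)], read="r1")
    a2 = _aln("chr1", "+", [(100, 200), (306, 400)], read="r2")
    assert len(collapse_molecules([a1, a2])) == 2


def test_collapse_modal_tes_tie_breaks_3prime():
    ends = [650, 650, 700, 700]  # tie -> 3'-most (700 on plus strand)
    alns = [
        _aln("chr1", "+", [(100, 200), (300, e)], read=f"r{i}") for i, e in enumerate(ends)
    ]
    assert collapse_molecules(alns)[0].tes == 699


def test_collapse_mono_exon_reciprocal_overlap():
    a1 = _aln("chr1", "+", [(100, 600)], read="r1")
    a2 = _aln("chr1", "+", [(105, 605)], read="r2")  # ~98% reciprocal overlap
    a3 = _aln("chr1", "+", [(400, 900)], read="r3")  # 40% overlap
    isoforms = collapse_molecules([a1, a2, a3])
    assert sorted(i.total_umis for i in isoforms) == [1, 2]


def test_collapse_empty_input():
    assert collapse_molecules([]) == []


# ---------------------------------------------------------------------------
# Classification


REF_CHAINS = [
    ((200, 300), (400, 500), (600, 700), (800, 900)),
    ((200, 300), (600, 700), (800, 900)),  # annotated exon skip
]


def _record_from_chain(chain, chrom="chr1", strand="+", lo=110, hi=4900):
    blocks = _chain_to_blocks(chain, lo, hi)
    return IsoformRecord(
        isoform_id="q",
        chrom=chrom,
        strand=strand,
        blocks=blocks,
        junctions=tuple(SpliceJunction(chrom, d, a, strand) for d, a in chain),
        tss=blocks[0][0] if strand == "+" else blocks[-1][1] - 1,
        tes=blocks[-1][1] - 1 if strand == "+" else blocks[0][0],
        counts={"c": 1},
    )


@pytest.fixture(scope="module")
def ref_index():
    return ReferenceIndex(make_reference(REF_CHAINS))


@pytest.mark.parametrize(
    "chain, expected",
    [
        (REF_CHAINS[0], "FSM"),
        (REF_CHAINS[1], "FSM"),
        (REF_CHAINS[0][-2:], "ISM"),  # last two junctions of the full chain
        (REF_CHAINS[0][:2], "ISM"),
        (((200, 300), (400, 500), (800, 900)), "NIC"),  # known sites, new combination
        (((200, 500), (600, 700), (800, 900)), "NIC"),  # known donor + known acceptor, new pairing
        (((200, 300), (400, 506), (600, 700), (800, 900)), "NNC"),  # +6 acceptor shift
        (((200, 300), (410, 500)), "NNC"),  # novel donor
    ],
)
def test_structural_categories(ref_index, chain, expected):
    record = _record_from_chain(chain)
    category, gene, matched = classify_isoform(record, ref_index)
    assert category == expected == oracle_category(chain, REF_CHAINS)
    assert gene == "gA"
    if expected == "FSM":
        assert matched is not None


def test_mono_exon_and_intergenic_are_other(ref_index):
    mono = IsoformRecord(
        "m", "chr1", "+", [(110, 4900)], (), 110, 4899, {"c": 1}
    )
    assert classify_isoform(mono, ref_index)[0] == "other"
    far = _record_from_chain(((200, 300),), chrom="chr9")
    assert classify_isoform(far, ref_index)[0] == "other"


def test_category_partition_is_exclusive(ref_index):
    """Every multi-exon chain maps to exactly one category; FSM and ISM never co-occur."""
    chains = [REF_CHAINS[0], REF_CHAINS[0][1:3], ((200, 300), (400, 500), (600, 900))]
    for chain in chains:
        cat, _, _ = classify_isoform(_record_from_chain(chain), ref_index)
        assert cat in ("FSM", "ISM", "NIC", "NNC")
        if cat == "FSM":
            assert chain in REF_CHAINS


# ---------------------------------------------------------------------------
# Intrapriming / RT switch


def _genome_with(window: str, tes: int = 499, size: int = 1200) -> dict[str, str]:
    base = ("GCTC" * (size // 4))[:size]
    return {"chr1": base[: tes + 1] + window + base[tes + 1 + len(window) :]}


def _simple_iso(strand="+", tes=499, blocks=((100, 200), (300, 500))):
    blocks = [tuple(b) for b in blocks]
    return IsoformRecord(
        "i", "chr1", strand, blocks,
        (SpliceJunction("chr1", blocks[0][1], blocks[1][0], strand),),
        blocks[0][0] if strand == "+" else blocks[-1][1] - 1,
        tes,
        {"c": 5},
    )


def test_intrapriming_pure_a_window_flagged():
    genome = _genome_with("A" * 20)
    assert detect_intrapriming(_simple_iso(), genome) is True


def test_intrapriming_half_a_window_not_flagged():
    genome = _genome_with("AG" * 10)  # 50% A < 0.6
    assert detect_intrapriming(_simple_iso(), genome) is False


def test_intrapriming_strand_symmetry():
    """A minus-strand isoform over the mirrored genome gets the same decision."""
    window = "AAAAAGAAAAAGAAAAAGAA"  # 85% A
    genome_plus = _genome_with(window)
    plus = _simple_iso(strand="+", tes=499)
    # mirrored: reverse-complement the chromosome; coordinates flip
    seq = genome_plus["chr1"]
    genome_minus = {"chr1": revcomp(seq)}
    L = len(seq)
    flip = lambda s, e: (L - e, L - s)
    minus_blocks = sorted([flip(100, 200), flip(300, 500)])
    minus = IsoformRecord(
        "i", "chr1", "-", minus_blocks,
        (SpliceJunction("chr1", minus_blocks[0][1], minus_blocks[1][0], "-"),),
        minus_blocks[-1][1] - 1,
        L - 1 - 499,
        {"c": 5},
    )
    assert detect_intrapriming(plus, genome_plus) == detect_intrapriming(minus, genome_minus) is True


def test_rt_switch_planted_repeat_flagged():
    repeat = "ACGTACGT"  # 8 nt
    # distinct backgrounds around the two boundaries so only the planted
    # 8-mer (not any 9-mer extension) repeats across them
    seq = ["G"] * 700 + ["C"] * 1300
    donor, acceptor = 500, 900
    # copy 1 spans the donor boundary, copy 2 spans the intron end at the acceptor
    for i, ch in enumerate(repeat):
        seq[donor - 4 + i] = ch
        seq[acceptor - 4 + i] = ch
    genome = {"chr1": "".join(seq)}
    iso = IsoformRecord(
        "i", "chr1", "+", [(100, donor), (acceptor, 1200)],
        (SpliceJunction("chr1", donor, acceptor, "+"),),
        100, 1199, {"c": 5},
    )
    index = ReferenceIndex(make_reference([((1300, 1400),)], lo=1250, hi=1500))  # junction is novel
    assert detect_rt_switch(iso, genome, index, repeat_len=8) is True
    assert detect_rt_switch(iso, genome, index, repeat_len=9) is False


def test_rt_switch_reference_junction_never_flagged():
    repeat = "ACGTACGT"
    seq = ["C"] * 2000
    donor, acceptor = 500, 900
    for i, ch in enumerate(repeat):
        seq[donor - 4 + i] = ch
        seq[acceptor - 4 + i] = ch
    genome = {"chr1": "".join(seq)}
    reference = make_reference([((donor, acceptor),)], lo=100, hi=1200)
    iso = IsoformRecord(
        "i", "chr1", "+", [(100, donor), (acceptor, 1200)],
        (SpliceJunction("chr1", donor, acceptor, "+"),),
        100, 1199, {"c": 5},
    )
    iso.gene_id = "gA"
    assert detect_rt_switch(iso, genome, ReferenceIndex(reference), repeat_len=8) is False


# ---------------------------------------------------------------------------
# Filtering and end validation


def _filterable_catalog(plain_dataset):
    isoforms = collapse_molecules(plain_dataset.alignments)
    classify_catalog(isoforms, plain_dataset.reference.transcripts)
    return isoforms


def test_min_umi_filter(plain_dataset):
    ref = plain_dataset.reference
    isoforms = _filterable_catalog(plain_dataset)
    low = isoforms[0]
    low.counts = {"c": 2}
    retained, removals = filter_catalog(isoforms, ref.genome, ref.transcripts, min_umis=3)
    assert removals["min_umis"] == 1
    assert low not in retained


def test_fsm_with_noncanonical_motif_retained():
    """Reference-supported junctions are exempt from the motif rule."""
    genome = {"chr1": "GCTC" * 500}  # junction motifs are not GT-AG
    reference = make_reference([((200, 300), (400, 500))], lo=100, hi=900)
    iso = _record_from_chain(((200, 300), (400, 500)), lo=100, hi=900)
    iso.counts = {"c": 5}
    classify_catalog([iso], reference)
    assert iso.category == "FSM"
    retained, removals = filter_catalog([iso], genome, reference)
    assert retained == [iso] and removals["noncanonical"] == 0


def test_novel_noncanonical_junction_removed():
    genome = {"chr1": "GCTC" * 500}
    reference = make_reference([((200, 300), (400, 500))], lo=100, hi=900)
    iso = _record_from_chain(((200, 300), (410, 500)), lo=100, hi=900)  # novel donor
    iso.counts = {"c": 5}
    classify_catalog([iso], reference)
    assert iso.category == "NNC"
    retained, removals = filter_catalog([iso], genome, reference)
    assert retained == [] and removals["noncanonical"] == 1


def test_filter_reports_planted_intrapriming(plain_dataset):
    """Isoforms with planted A-rich 3' flanks are removed for exactly that reason."""
    ref = plain_dataset.reference
    isoforms = _filterable_catalog(plain_dataset)
    genome = dict(ref.genome)
    planted = 0
    for iso in isoforms[:10]:
        seq = genome[iso.chrom]
        if iso.strand == "+":
            genome[iso.chrom] = seq[: iso.tes + 1] + "A" * 20 + seq[iso.tes + 21 :]
        else:
            genome[iso.chrom] = seq[: iso.tes - 20] + "T" * 20 + seq[iso.tes :]
        planted += 1
    retained, removals = filter_catalog(isoforms, genome, ref.transcripts)
    assert removals["intrapriming"] == planted


def test_validate_ends_window_boundaries():
    cage = [("chr1", 95, 106, "peak")]
    pas = [("chr1", 900, 901, "pas")]
    near = _record_from_chain(REF_CHAINS[0], lo=110, hi=900)  # TSS 110, TES 899
    near.category = "NNC"
    retained, removed = validate_ends([near], cage, pas, window=50)
    assert retained == [near] and removed == 0
    far = _record_from_chain(REF_CHAINS[0], lo=110, hi=952)  # TES 951, 51 bp from pas
    far.category = "NNC"
    retained, removed = validate_ends([far], cage, pas, window=50)
    assert retained == [] and removed == 1


def test_validate_ends_fsm_always_retained():
    iso = _record_from_chain(REF_CHAINS[0])
    iso.category = "FSM"
    retained, removed = validate_ends([iso], [("chr9", 0, 1, "x")], [("chr9", 0, 1, "y")])
    assert retained == [iso] and removed == 0
    assert "end_unvalidated" in iso.flags


# ---------------------------------------------------------------------------
# Specificity


def _iso_with_cells(counts: dict[str, int], category="FSM"):
    iso = IsoformRecord(
        "i", "chr1", "+", [(0, 10), (20, 30)],
        (SpliceJunction("chr1", 10, 20, "+"),), 0, 29, counts,
    )
    iso.category = category
    return iso


LABELS = {f"t{i}": "tumor" for i in range(5)} | {f"d{i}": "distal" for i in range(5)}


@pytest.mark.parametrize(
    "counts, expected",
    [
        ({"t0": 3}, "cell_specific"),  # one cell only
        ({"t0": 1, "t1": 1, "t2": 1}, "cell_type_specific"),  # >=3 cells, one type
        ({"t0": 2, "t1": 1}, "shared"),  # two cells: neither rule applies
        ({"t0": 1, "t1": 1, "d0": 1}, "shared"),  # mixed types
    ],
)
def test_specificity_rules(counts, expected):
    iso = _iso_with_cells(counts)
    specificity_class([iso], LABELS)
    assert iso.specificity == expected


def test_specificity_requires_min_reads_and_category():
    low = _iso_with_cells({"t0": 1, "t1": 1})  # 2 reads < 3
    ism = _iso_with_cells({"t0": 5}, category="ISM")
    specificity_class([low, ism], LABELS)
    assert low.specificity == "not_assessed"
    assert ism.specificity == "not_assessed"


# ---------------------------------------------------------------------------
# Round trip on synthetic data


def test_full_length_synthetic_catalog_all_fsm_and_conserved(plain_dataset):
    """Error-free full-length molecules: every isoform FSM, validated, counts conserved."""
    ref = plain_dataset.reference
    isoforms = collapse_molecules(plain_dataset.alignments)
    classify_catalog(isoforms, ref.transcripts)
    assert all(iso.category == "FSM" for iso in isoforms)
    retained, removals = filter_catalog(isoforms, ref.genome, ref.transcripts)
    retained, n_removed = validate_ends(retained, ref.cage, ref.polya)
    assert n_removed == 0
    assert sum(v for v in removals.values()) == 0
    total = sum(iso.total_umis for iso in retained)
    assert total == len(plain_dataset.molecules)
    n_truth = plain_dataset.truth.pi.groupby(["gene_id", "transcript_id"]).ngroups
    assert len(retained) == n_truth
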