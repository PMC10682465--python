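# Methods

This note documents the models, parameter choices and numerical decisions
behind each pipeline stage, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Synthetic data generator

The generator is the inverse of the analysis: it draws molecules from the
generative models the downstream statistics assume, so that every estimate
has a known target.

**Reference.** Genes are laid out round-robin over ≥ 2 chromosomes
(consecutive genes therefore always sit on different chromosomes, which is
what the fusion simulator relies on). Each gene has 4–5 exons (internal
exons 120–200 nt, introns 200–400 nt) and a terminal exon carrying a 60-nt
coding tail plus the 3'UTR (default 300 nt). Isoforms are the full exon
chain plus exon-skipping variants sharing the terminal exon; at least half
the genes are multi-isoform. All introns are written GT-AG on the
transcript strand. Every transcript gets a CAGE interval (TSS ± 5) and
every gene polyA sites at both its distal end and the proximal site. The
20 nt downstream of each polyA site are set to a fixed balanced 20-mer so
that no synthetic gene accidentally mimics an intrapriming A-stretch
(random sequence would do so for ~0.1 % of sites, which would contaminate
truth-tagged filter tests).

**Molecules.** Per gene and cell type, isoform identities are multinomial
draws from the configured usage vector and each molecule terminates at the
distal UTR end with the configured probability, else at the fixed proximal
site (default `utr_length // 2`, constrained to `(50, L − 50]` so that both
averaging windows of the two-site model fit). Barcodes (16 nt) are unique
across cells and UMIs (12 nt) unique within a cell — real data has UMI
collisions; here uniqueness makes count round trips exact, and the
deduplicator's tolerance of Hamming-1 collisions is tested separately.
Variants are implanted as substitutions at a stated allele fraction in
carrier cell types; fusion molecules concatenate the 5' exons of one gene
with the 3' exons of a gene on another chromosome.

**Reads.** Segment counts per read follow a zero-truncated Poisson with
the configured mean (default 4 molecules per read; the rate is solved from
`λ/(1−e^{−λ}) = mean`). The polyT tract is fixed at 30 nt — only its
presence matters downstream. Errors are uniform substitutions (default
rate 0.001, the scale of HiFi consensus error); indels are not simulated,
so the deconcatenator's edit-distance budget is exercised by substitutions
only. A configurable fraction of segments (default 5 %) is rendered as an
artifact: the polyT omitted, or the 3' primer dropped. Artifact
proportions are free parameters of the simulation, not calibrated claims
about any real library.

**Determinism.** One top-level seed; each stage (reference, molecules,
reads, usage resolution, APA fractions) derives its own stream from the
seed plus a fixed offset, so outputs are byte-identical across runs and
insensitive to the order in which stages are invoked.

What passing tests on this generator show: that the analysis recovers the
parameters of its own generative model. What they do not show: robustness
to alignment error, indels, degraded RNA, barcode swapping, or annotation
incompleteness — none of which the generator emulates.

## Deconcatenation

Primer occurrences are found per pattern (each primer and its reverse
complement) by repeated best-first infix edit-distance search (edlib) with
masking, which resolves overlapping candidates lowest-distance-first, then
leftmost. The default budget is 3 edits for ~22-nt primers (~14 %
divergence). Segments are the gaps between successive hits; a segment is
valid only when bounded by forward→reverse (or the reverse-complemented
mirror) — the gap between two adjacent segments is intrinsically invalid
(reverse→forward), so rejection reports always contain those gaps; they
are not errors.

Tag extraction takes the 16-nt barcode adjacent to the 5' primer, then the
12-nt UMI. Barcode rescue: exact whitelist match, else unique Hamming-1
neighbor, ambiguous rejected. The polyA tail is the longest 3'-terminal
run with ≤ 10 % non-A ending on an A, required ≥ 20 nt. Because the tail
is appended to genomic sequence, trimming can consume genuine 3'-terminal
A's (and, with the mismatch tolerance, a few adjacent bases); tags are
unaffected and the recovered cDNA is always a prefix of the true molecule.
Rejection precedence is fixed: invalid_pair → too_short →
no_barcode_match → no_polya, one primary reason per segment.

UMI deduplication is directional: per cell, UMIs sorted by read count
merge into an already-kept UMI at Hamming distance 1 with at least equal
count; the cluster representative is the longest cDNA.

## Isoform catalog

Collapse identity is exact junction-chain equality (TSS = 5'-most observed
start, TES = modal end with ties broken 3'-most); mono-exon molecules
cluster at ≥ 95 % reciprocal overlap by single linkage. Exact chain
equality replaces alignment-level coverage/identity thresholds, which have
no meaning on exact synthetic alignments. Classification is per locus
(gene assigned by maximal span overlap on the same chromosome and strand):
FSM = chain equality, ISM = contiguous sub-chain, NIC = all donors and
acceptors known at the locus (including novel pairings of known sites),
NNC = any novel site, other = mono-exon or intergenic.

Filters, in fixed order for deterministic reason reporting: intrapriming
(A-fraction ≥ 0.6 in the 20 nt downstream of the TES in transcript
orientation), noncanonical motif on a novel junction (outside GT-AG,
GC-AG, AT-AC; reference-supported junctions exempt), RT-switch (an exact
direct repeat of ≥ 8 nt spanning both the donor exon/intron boundary and
the intron end before the acceptor, novel junctions only), and < 3 total
UMIs. The intrapriming window/threshold and repeat length follow common
SQANTI practice. The UMI filter runs with the artifact filters, before
end validation; end validation then removes non-FSM isoforms whose TSS is
not within 50 bp of a CAGE interval or whose TES is not within 50 bp of a
polyA site (FSM isoforms are kept but flagged). Specificity labels apply
to FSM/NIC/NNC isoforms with ≥ 3 UMIs: present in one cell →
cell-specific; in ≥ 3 cells of a single type → cell-type-specific; else
shared.

## APA

The two-site model reads coverage in transcript orientation (index 1 = UTR
5' end; minus-strand arrays are reversed at extraction). The distal site
is the most 3' position with coverage strictly above 10 in any condition;
the proximal site maximizes the squared difference between the mean
coverage of the 50 positions after and the 50 before a candidate P, with P
searched over [51, L* − 50] so both windows fit, position P itself in
neither window, and ties broken toward the smallest P, then the smallest
condition index. Flat profiles (objective identically zero) are flagged
degenerate and excluded — a zero gap carries no site information.

`W_d` and `W_p` average the 50 positions upstream of L* and P*;
`F = W_d/(W_d + W_p)`. Since reads using the distal site also cover the
proximal window, `W_p` counts reads using either site: under the two-site
generative model with true distal fraction f, `F = f/(1+f)` — an
invertible, strictly increasing mapping. The definition is implemented
exactly as stated, and recovery tests check against `f/(1+f)`.

Fisher's exact test needs integers; `W_d`/`W_p` are means of integer
counts and are rounded half-away-from-zero (deterministic, unbiased).
Multiplying all coverage by a constant leaves F unchanged but changes the
Fisher p through the counts — the test is deliberately sensitive to
absolute depth. Site detection pools all conditions; testing is pairwise.
Genes whose overlapping 3'UTR exons have different 5' starts are excluded
up front (they would create false positive APA calls); at most two polyA
sites per UTR are modeled.

## Differential isoform usage

Pearson's χ² without continuity correction on the isoform × condition
table; isoforms with zero counts in both conditions are dropped from the
table (zero expected counts), their ΔΠ is 0 by definition. Genes with
small expected counts are flagged (`low_expected`), not excluded. ΔΠ is
expressed in percentage points so the 20-point calling threshold applies
directly; the effect summary is the larger of (sum of the two largest
positive ΔΠ) and (magnitude of the sum of the two most negative), a single
moving isoform summing alone. Calling: BH-adjusted p ≤ 0.05 (inclusive)
and top-2 sum > 20 (strict). Depth filtering requires ≥ 25 UMIs per
condition (inclusive — "did not reach 25" excludes), ≥ 2 isoforms, and a
gene name not matching the mitochondrial/ribosomal prefix pattern
(`^(MT-|RPS|RPL|MRPS|MRPL)`, configurable). Ranking uses ordinal ranks
(ties broken by gene id) of effect size (descending) and adjusted p
(ascending), combined as the geometric mean, smallest first.

Biotype accounting compares the biotype of each condition's most expressed
isoform (ties: larger count in the other condition, then lexicographic);
a change is a biotype difference, not an isoform-identity difference. The
noncoding fraction is reported per protein-coding gene and condition with
≥ 20 UMIs, as noncoding-isoform UMIs over total.

## Fusions

Split reads qualify when ≥ 2 loci hit distinct genes, each with ≥ 200
aligned bases, on different chromosomes or separated by > 100,000 bp
(default; configurable). Events group reads by gene pair and breakpoint
with ± 10 bp clustering tolerance (long-read end wobble) and require ≥ 10
supporting UMIs. Custom-reference assignment scores each read against
every reference sequence (both orientations) by best infix edit alignment
and assigns only a unique best hit with ≥ 2 edits margin over the
runner-up and ≥ 80 % identity; group specificity per reference sequence is
a two-sided Fisher test of hits vs other assignments between two groups.
An optional deny-list filter for recurrent artifact gene pairs (e.g.
mitochondrial rRNA partners) is available but off by default.

## Mutations

At each panel position (1-based input, SNVs only), reads covering the
position in a cell count as alt or ref by their carried base; a cell is
mutated at ≥ 1 alt read (configurable), with no base-quality filtering
(HiFi input assumed). Cells without coverage receive no call — absence of
coverage is never wild-type evidence. A variant mutated in at least one
distal-biopsy cell is germline; mutated only in tumor-site cells, somatic;
never mutated, unclassified. A panel ref allele disagreeing with the
genome triggers a warning rather than an error, since panels and genome
builds can legitimately disagree.

## Problem sizes and test calibration

The test suite and the acceptance script size their simulations to the
statistics they check: 100 genes at 400 molecules per gene and condition
for APA recovery (the ± 0.05 band on F must hold for the maximum over 200
per-condition estimates, which needs a per-gene standard error ≈ 0.014);
200 null + 4 signal genes × 50 replicates at depth 100 per condition for
differential-usage error control; ~10,000 reads (40,000 molecules, 10 %
artifacts) for the deconcatenation round trip; exhaustive Fisher
verification over every 2×2 table with total ≤ 30. The χ²-vs-Monte-Carlo
calibration runs at depth 200 per condition with an explicit 0.0075
allowance for the discreteness of the lattice statistic — the exact null
tail of a discrete statistic cannot coincide with the continuous χ² tail,
and the gap (~0.011 at depth 50, ~0.005 at depth 200) dominates
Monte-Carlo error at 10⁵ draws.

## Known limitations

- The generator produces exact spliced alignments; no aligner is run, so
  alignment-induced errors (soft-clipping, wrong junction placement) are
  outside the tested space.
- Substitution-only errors; primer/tag indels are handled by the
  edit-distance search but never generated.
- Two polyA sites per UTR; more complex APA architectures are out of scope.
- Two-condition differential testing only.
- PolyA trimming can shorten the recovered cDNA by genuine 3' A's — an
  inherent ambiguity of tail trimming, bounded and documented in tests.
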