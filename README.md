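# sciso

Long-read single-cell isoform analysis: deconcatenation of concatenated
full-length cDNA reads, SQANTI-style isoform structural classification,
alternative-polyadenylation (APA) detection, differential isoform usage,
split-read gene-fusion calling and panel-guided per-cell mutation calling —
with a first-class synthetic-data generator that produces every pipeline
input together with its ground truth.

## Who this is for

Concatenating several cDNA molecules per HiFi read multiplies the effective
throughput of long-read single-cell RNA-seq, at the cost of a bespoke
computational path: reads must be cut back into tagged molecules before any
isoform-level analysis can start. This package implements that path as a
tested, reusable library for people developing or validating such pipelines
— every stage can be exercised on simulated data where the right answer is
known, without an aligner and without access-controlled patient data.

## The methods at the core

**Deconcatenation.** Each read is a concatenation of segments laid out as
`5'primer + barcode(16) + UMI(12) + polyT + revcomp(cDNA) + 3'primer` in
either orientation. Primers are located by bounded edit-distance search;
segments bounded by a correctly oriented primer pair are retained when the
barcode is whitelisted (exact or unique Hamming-1 match), a UMI is present
and a polyA tail (run of ≥ 20 A, ≤ 10 % mismatch) is found. UMIs within
Hamming distance 1 are merged directionally per cell.

**Isoform classification.** Molecules sharing a splice-junction chain
collapse into one isoform, categorized against the annotation as FSM
(chain matches a reference transcript), ISM (contiguous sub-chain), NIC
(all donors/acceptors known, combination new) or NNC (≥ 1 novel splice
site). Artifact filters remove intrapriming (A-rich genomic window past
the TES), noncanonical novel junctions (motif outside GT-AG/GC-AG/AT-AC),
RT template switching (direct repeat spanning both junction boundaries)
and isoforms with fewer than 3 UMIs; non-FSM isoforms must also end within
50 bp of a CAGE TSS peak and a known polyA site.

**APA, two-site model.** For each 3'UTR, per-condition coverage
`w_k^c` (k = 1..L, 5'→3') defines the distal site
`L* = max{k : w_k^c > 10 for some c}` and the proximal site

```
(C*, P*) = argmax_{c, P} ( mean_{i=1..50} w_{P+i}^c − mean_{i=1..50} w_{P−i}^c )²
```

Per condition, `W_d` and `W_p` are the mean coverages over the 50 positions
upstream of `L*` and `P*`, the distal-usage fraction is
`F = W_d / (W_d + W_p)`, and two conditions are compared by
`Fraction Change = F_C1 − F_C2` (positive = 3'UTR lengthening) with a
two-sided Fisher's exact test on the rounded coverages, BH-corrected
across genes.

**Differential isoform usage.** Per gene, isoform × condition UMI counts
are tested with Pearson's χ²; isoform shares Π (percent) give per-isoform
ΔΠ, summarized by the largest common-sign sum over the top two isoforms.
A gene is called when adjusted p ≤ 0.05 and that sum exceeds 20 points;
called genes rank by √(rank_ΔΠ · rank_p). Biotype switches of the top
isoform and the noncoding share of protein-coding gene expression are
reported alongside.

**Fusions and mutations.** Reads splitting across two genes (different
chromosomes or > 100 kb apart, ≥ 200 aligned bp per locus) aggregate into
events by gene pair and breakpoint (± 10 bp), kept at ≥ 10 UMIs; reads can
also be assigned to small custom breakpoint references by best edit
alignment and tested for group specificity with Fisher's exact test. At
panel SNV positions, a cell is mutated as soon as one alt read is seen;
a variant mutated in any distal-biopsy cell is germline, otherwise somatic.

## Worked example

```python
from sciso.simulate import SimConfig, simulate_dataset
from sciso import apa, catalog, deconcat, diffusage

genes = [f"G{i+1:04d}" for i in range(4)]
usage = {g: {"tumor": (0.9, 0.1), "distal": (0.4, 0.6)} if g == "G0001"
         else {ct: (0.5, 0.5) for ct in ("tumor", "distal")} for g in genes}
distal = {g: {"tumor": 0.8, "distal": 0.3} if g == "G0002"
          else {"tumor": 0.5, "distal": 0.5} for g in genes}
config = SimConfig(seed=11, n_genes=4, cells_per_type=50, molecules_per_gene=300,
                   isoform_usage=usage, apa_distal_fraction=distal,
                   error_rate=0.0, artifact_fraction=0.0)
ds = simulate_dataset(config)

accepted, _ = deconcat.deconcatenate(
    ds.reads, config.fwd_primer, config.rev_primer, set(ds.truth.cells))
molecules = deconcat.dedup_umis(accepted)
print(f"{len(ds.reads)} reads -> {len(molecules)} deduplicated molecules")

table, _ = apa.run_apa(ds.reference.transcripts, ds.alignments,
                       ds.truth.cells, "tumor", "distal")
row = table.set_index("gene_id").loc["G0002"]
print(f"G0002: L*={row.L_star} P*={row.P_star} "
      f"F_tumor={row.F_c1:.3f} F_distal={row.F_c2:.3f} "
      f"FractionChange={row.fraction_change:+.3f} "
      f"p_adj={row.p_adjusted:.2e} -> {row.direction}")
```

prints

```
594 reads -> 2400 deduplicated molecules
G0002: L*=300 P*=150 F_tumor=0.453 F_distal=0.231 FractionChange=+0.222 p_adj=9.36e-12 -> lengthened
```

The 2,400 molecules are exactly the 4 genes × 2 cell types × 300 simulated
molecules, recovered losslessly from ~600 four-segment concatenated reads.
For gene `G0002`, simulated with true distal fractions 0.8 (tumor) and 0.3
(distal), the detector finds the distal site at the UTR end (L\* = 300),
the proximal site at the implanted position 150, and usage fractions near
the two-site-model expectation F = f/(1+f) (0.444 and 0.231); the positive
Fraction Change calls the 3'UTR lengthened in tumor. Feeding the same
dataset through `catalog.build_catalog` and `diffusage.run_differential_usage`
calls the implanted isoform switch in `G0001` (ΔΠ top-2 sum ≈ 52 points,
p_adj ≈ 4e-40) and nothing else.

The same stages are available as a CLI:
`sciso simulate|deconcat|catalog|apa|diu|fusion|variants` (see `--help`).

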