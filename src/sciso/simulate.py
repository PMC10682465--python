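"""Synthetic long-read single-cell RNA-seq data with recorded ground truth.

The generator produces every input the analysis modules consume: a toy
genome and transcript annotation (multi-isoform genes with canonical
GT-AG introns and an annotated 3'UTR on the shared terminal exon), CAGE
TSS intervals and polyA sites, concatenated raw reads with the
primer + barcode(16) + UMI(12) + polyT + cDNA segment architecture, exact
spliced alignments, and truth tables tying every emitted molecule back
to its transcript, cell and tags.

The statistical structure mirrors what the downstream analysis assumes:

* per gene and cell type, molecule isoform identities are multinomial
  draws from a configured usage vector (the generative counterpart of
  the isoform proportions tested for differential usage);
* each molecule terminates at the gene's distal 3'UTR end with a
  configured per-cell-type probability, otherwise at a fixed proximal
  site — the two-polyA-site model of APA regulation;
* reads concatenate a truncated-Poisson number of cDNA segments
  (mean configurable, default 4 molecules per read);
* optional fusion molecules join the 5' exons of one gene to the 3'
  exons of a gene on another chromosome, and optional SNVs are
  implanted at a stated allele fraction in carrier cell types.

A single top-level seed determines every output byte; sub-streams are
derived with fixed per-stage offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import io
from .models import AlignmentRecord, TranscriptModel, revcomp

DEFAULT_FWD_PRIMER = "CTACACGACGCTCTTCCGATCT"  # Read-1 / 5' amplification primer
DEFAULT_REV_PRIMER = "AAGCAGTGGTATCAACGCAGAGT"  # template-switch side primer
POLYT_LEN = 30  # fixed tract length; only presence/absence matters downstream
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# balanced 20-mer written downstream of polyA sites so that synthetic UTR/
# flank sequence never mimics an intrapriming A-stretch
_BALANCED_FLANK = "GCTCGTACGATCGTCAGCTG"


class ConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass
class FusionSpec:
    """An implanted fusion: 5' exons of ``gene5`` joined to the tail of ``gene3``.

    Breakpoints may be given as genomic coordinates; when left ``None``
    they are resolved to exon boundaries (after ``n_exons5`` exons of
    ``gene5``, resuming at the last ``n_exons3`` exons of ``gene3``).
    """

    gene5: str
    gene3: str
    n_umis: int
    cell_type: str
    n_exons5: int = 2
    n_exons3: int = 2
    breakpoint5: int | None = None
    breakpoint3: int | None = None


@dataclass
class VariantSpec:
    """An implanted SNV carried by ``carrier_cell_types`` at ``allele_fraction``.

    When ``position`` is ``None`` the variant is placed inside ``gene``'s
    3'UTR upstream of the proximal polyA site, where every molecule of
    the gene provides coverage.
    """

    carrier_cell_types: tuple[str, ...]
    allele_fraction: float = 0.5
    gene: str | None = None
    chrom: str | None = None
    position: int | None = None  # 0-based genomic
    ref: str | None = None
    alt: str | None = None
    name: str | None = None


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 20
    n_cell_types: int = 2
    cells_per_type: int = 100
    cell_type_names: tuple[str, ...] | None = None
    molecules_per_gene: int = 200  # per gene per cell type
    isoform_usage: dict[str, dict[str, tuple[float, ...]]] | None = None
    apa_distal_fraction: dict[str, dict[str, float]] | None = None
    utr_length: int = 300
    proximal_site: int | None = None  # transcript-orientation UTR position
    mean_segments_per_read: float = 4.0
    error_rate: float = 0.001
    artifact_fraction: float = 0.05
    fusion_spec: FusionSpec | None = None
    variant_spec: list[VariantSpec] = field(default_factory=list)
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.cell_type_names is None:
            if self.n_cell_types == 2:
                self.cell_type_names = ("tumor", "distal")
            else:
                self.cell_type_names = tuple(
                    f"type{i + 1}" for i in range(self.n_cell_types)
                )
        if len(self.cell_type_names) != self.n_cell_types:
            raise ConfigError("cell_type_names length must equal n_cell_types")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigError("error_rate must be in [0, 1]")
        if self.proximal_site is None:
            self.proximal_site = self.utr_length // 2
        if self.utr_length > 101 and not (
            50 < self.proximal_site <= self.utr_length - 50
        ):
            raise ConfigError("proximal_site must lie in (50, utr_length - 50]")
        if self.isoform_usage is not None:
            for gene, per_ct in self.isoform_usage.items():
                for ct, vec in per_ct.items():
                    if abs(sum(vec) - 1.0) > 1e-9:
                        raise ConfigError(
                            f"isoform_usage for {gene}/{ct} does not sum to 1"
                        )
        if self.apa_distal_fraction is not None:
            for gene, per_ct in self.apa_distal_fraction.items():
                for ct, f in per_ct.items():
                    if not 0.0 <= f <= 1.0:
                        raise ConfigError(f"apa_distal_fraction for {gene}/{ct} not in [0,1]")

    def site_of(self, cell_type: str) -> str:
        """Biopsy site of a cell type: 'tumor' for the tumor type, else 'distal'."""
        return "tumor" if cell_type == "tumor" else "distal"


@dataclass
class GeneInfo:
    gene_id: str
    chrom: str
    strand: str
    utr: tuple[int, int]  # genomic interval of the shared 3'UTR
    proximal_site: int  # transcript-orientation UTR position (1-based)
    transcripts: list[TranscriptModel]

    @property
    def utr_length(self) -> int:
        return self.utr[1] - self.utr[0]

    def utr_transcript_to_genomic(self, k: int) -> int:
        """Genomic coordinate of 1-based UTR position ``k`` (5'->3')."""
        us, ue = self.utr
        return us + k - 1 if self.strand == "+" else ue - k

    def truncated_blocks(self, blocks: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
        """Exon blocks of a molecule terminating at UTR position ``k``."""
        us, ue = self.utr
        out = [tuple(b) for b in blocks]
        if self.strand == "+":
            s, e = out[-1]
            out[-1] = (s, us + k)
        else:
            s, e = out[0]
            out[0] = (ue - k, e)
        return out


@dataclass
class Reference:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    cage: list[tuple[str, int, int, str]]
    polya: list[tuple[str, int, int, str]]
    genes: dict[str, GeneInfo]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        io.write_fasta(self.genome, outdir / "genome.fa")
        io.write_gtf(self.transcripts, outdir / "annotation.gtf")
        io.write_bed(self.cage, outdir / "cage.bed")
        io.write_bed(self.polya, outdir / "polya.bed")


@dataclass
class Molecule:
    """A single cDNA molecule before read rendering (one UMI)."""

    molecule_id: str
    gene_id: str
    transcript_id: str
    cell_barcode: str
    cell_type: str
    umi: str
    loci: list[tuple[str, str, list[tuple[int, int]]]]  # (chrom, strand, blocks) 5'->3'
    cdna: str  # sense orientation, no polyA
    uses_distal: bool | None
    is_fusion: bool = False
    subs: dict[str, dict[int, str]] = field(default_factory=dict)  # chrom -> pos -> alt
    variant_names: list[str] = field(default_factory=list)


@dataclass
class ResolvedVariant:
    name: str
    chrom: str
    position: int  # 0-based
    ref: str
    alt: str
    carrier_cell_types: tuple[str, ...]
    allele_fraction: float
    truth_class: str  # germline | somatic, by the distal-presence rule


@dataclass
class GroundTruth:
    molecules: pd.DataFrame
    gene_condition: pd.DataFrame  # gene_id, cell_type, distal_fraction
    pi: pd.DataFrame  # gene_id, transcript_id, cell_type, pi (fraction)
    cells: dict[str, str]  # barcode -> cell type
    variants: list[ResolvedVariant]
    fusion: dict | None
    segments: pd.DataFrame | None = None  # filled by render_reads


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stage)])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


# ---------------------------------------------------------------------------
# Reference


def _isoform_count(i: int, config: SimConfig) -> int:
    if config.isoform_usage is not None:
        return len(next(iter(config.isoform_usage[f"G{i + 1:04d}"].values())))
    # ensure multi-isoform genes for at least half the loci
    return 1 if i % 4 == 3 else 2 + (i % 2)


_ISOFORM_BIOTYPES = ("protein_coding", "retained_intron", "NMD", "lncRNA")


def simulate_reference(config: SimConfig) -> Reference:
    """Build genome, annotation, CAGE intervals and polyA sites.

    Genes are laid out round-robin over at least two chromosomes, so a
    fusion between consecutive genes always spans chromosomes. Each
    multi-isoform gene exposes one full-exon isoform plus exon-skipping
    variants; all isoforms share the terminal exon carrying the 3'UTR.
    """
    rng = _rng(config.seed, 0)
    n_chroms = max(2, math.ceil(config.n_genes / 10))
    cursors = {f"chr{i + 1}": 300 for i in range(n_chroms)}
    plans: list[dict] = []
    for i in range(config.n_genes):
        gene_id = f"G{i + 1:04d}"
        chrom = f"chr{(i % n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(4, 6))
        exon_lens = [int(rng.integers(120, 201)) for _ in range(n_exons - 1)]
        exon_lens.append(60 + config.utr_length)  # terminal exon: CDS tail + UTR
        intron_lens = [int(rng.integers(200, 401)) for _ in range(n_exons - 1)]
        if strand == "-":
            exon_lens.reverse()
        start = cursors[chrom]
        blocks = []
        pos = start
        for j, el in enumerate(exon_lens):
            blocks.append((pos, pos + el))
            pos += el + (intron_lens[j] if j < n_exons - 1 else 0)
        cursors[chrom] = pos + 500
        plans.append(
            {
                "gene_id": gene_id,
                "chrom": chrom,
                "strand": strand,
                "blocks": blocks,
                "n_isoforms": _isoform_count(i, config),
            }
        )

    genome = {
        chrom: _random_seq(rng, end + 500) for chrom, end in sorted(cursors.items())
    }
    genome_arrays = {c: bytearray(s, "ascii") for c, s in genome.items()}

    transcripts: list[TranscriptModel] = []
    cage: list[tuple[str, int, int, str]] = []
    polya: list[tuple[str, int, int, str]] = []
    genes: dict[str, GeneInfo] = {}
    for plan in plans:
        gene_id, chrom, strand = plan["gene_id"], plan["chrom"], plan["strand"]
        blocks = plan["blocks"]
        arr = genome_arrays[chrom]
        # canonical GT-AG introns on the transcript strand
        for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
            if strand == "+":
                arr[e1 : e1 + 2] = b"GT"
                arr[s2 - 2 : s2] = b"AG"
            else:
                arr[e1 : e1 + 2] = b"CT"
                arr[s2 - 2 : s2] = b"AC"
        if strand == "+":
            utr = (blocks[-1][1] - config.utr_length, blocks[-1][1])
        else:
            utr = (blocks[0][0], blocks[0][0] + config.utr_length)
        prox = config.proximal_site if config.utr_length > 101 else None
        gene_txs: list[TranscriptModel] = []
        terminal_idx = len(blocks) - 1 if strand == "+" else 0
        skippable = [j for j in range(len(blocks)) if j not in (0, len(blocks) - 1)]
        if strand == "-":
            skippable.reverse()  # skip in transcript order for stable naming
        for k in range(plan["n_isoforms"]):
            if k == 0:
                iso_blocks = list(blocks)
            else:
                drop = skippable[(k - 1) % len(skippable)]
                iso_blocks = [b for j, b in enumerate(blocks) if j != drop]
            tx = TranscriptModel(
                transcript_id=f"{gene_id}.T{k + 1}",
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                blocks=iso_blocks,
                biotype=_ISOFORM_BIOTYPES[k % len(_ISOFORM_BIOTYPES)],
                gene_biotype="protein_coding",
                gene_name=gene_id,
                utr3=utr,
            )
            gene_txs.append(tx)
            transcripts.append(tx)
            cage.append((chrom, tx.tss - 5, tx.tss + 6, f"{tx.transcript_id}.cage"))
        info = GeneInfo(
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            utr=utr,
            proximal_site=prox if prox is not None else 0,
            transcripts=gene_txs,
        )
        genes[gene_id] = info
        tes = gene_txs[0].tes
        polya.append((chrom, tes, tes + 1, f"{gene_id}.pas_distal"))
        # keep the 20 nt downstream (transcript orientation) of each polyA
        # site free of A-stretches so no synthetic gene mimics intrapriming
        if strand == "+":
            arr[tes + 1 : tes + 21] = _BALANCED_FLANK.encode()
        else:
            arr[tes - 20 : tes] = revcomp(_BALANCED_FLANK).encode()
        if prox is not None:
            ppos = info.utr_transcript_to_genomic(prox)
            polya.append((chrom, ppos, ppos + 1, f"{gene_id}.pas_proximal"))
            if strand == "+":
                arr[ppos + 1 : ppos + 21] = _BALANCED_FLANK.encode()
            else:
                arr[ppos - 20 : ppos] = revcomp(_BALANCED_FLANK).encode()

    genome = {c: a.decode() for c, a in genome_arrays.items()}
    return Reference(
        genome=genome, transcripts=transcripts, cage=cage, polya=polya, genes=genes
    )


# ---------------------------------------------------------------------------
# Molecules


def _resolve_usage(
    config: SimConfig, reference: Reference, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    usage: dict[str, dict[str, np.ndarray]] = {}
    for gene_id, info in reference.genes.items():
        n_iso = len(info.transcripts)
        per_ct = {}
        for ct in config.cell_type_names:
            if config.isoform_usage is not None:
                vec = np.asarray(config.isoform_usage[gene_id][ct], dtype=float)
                if len(vec) != n_iso:
                    raise ConfigError(
                        f"usage vector length {len(vec)} != {n_iso} isoforms for {gene_id}"
                    )
            else:
                vec = rng.dirichlet(np.full(n_iso, 1.5))
            per_ct[ct] = vec
        usage[gene_id] = per_ct
    return usage


def _resolve_distal(
    config: SimConfig, reference: Reference, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    out: dict[str, dict[str, float]] = {}
    for gene_id in reference.genes:
        per_ct = {}
        for ct in config.cell_type_names:
            if config.apa_distal_fraction is not None:
                per_ct[ct] = float(config.apa_distal_fraction[gene_id][ct])
            else:
                per_ct[ct] = float(rng.uniform(0.2, 0.8))
        out[gene_id] = per_ct
    return out


def _genomic_to_transcript_offset(
    loci: list[tuple[str, str, list[tuple[int, int]]]], chrom: str, pos: int
) -> int | None:
    """Offset of genomic ``pos`` within the molecule's spliced sequence."""
    offset = 0
    for lchrom, strand, blocks in loci:
        length = sum(e - s for s, e in blocks)
        if lchrom == chrom:
            local = 0
            iterate = blocks if strand == "+" else reversed(blocks)
            for s, e in iterate:
                if s <= pos < e:
                    within = pos - s if strand == "+" else e - 1 - pos
                    return offset + local + within
                local += e - s
        offset += length
    return None


def _resolve_variants(config: SimConfig, reference: Reference) -> list[ResolvedVariant]:
    out = []
    for i, spec in enumerate(config.variant_spec):
        if spec.position is not None:
            chrom, pos = spec.chrom, spec.position
            if chrom is None:
                raise ConfigError("variant with explicit position needs a chrom")
        else:
            if spec.gene is None:
                raise ConfigError("variant needs a gene or an explicit position")
            info = reference.genes[spec.gene]
            # mid-way between UTR start and proximal site: covered by every molecule
            k = max(1, info.proximal_site // 2) if info.proximal_site else 1
            chrom, pos = info.chrom, info.utr_transcript_to_genomic(k)
        ref_base = spec.ref or reference.genome[chrom][pos]
        if spec.alt is not None:
            alt = spec.alt
        else:
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
        if ref_base == alt:
            raise ConfigError("variant ref and alt must differ")
        sites = {config.site_of(ct) for ct in spec.carrier_cell_types}
        out.append(
            ResolvedVariant(
                name=spec.name or f"var{i + 1}",
                chrom=chrom,
                position=pos,
                ref=ref_base,
                alt=alt,
                carrier_cell_types=tuple(spec.carrier_cell_types),
                allele_fraction=spec.allele_fraction,
                truth_class="germline" if "distal" in sites else "somatic",
            )
        )
    return out


def _apply_sub(cdna: str, offset: int, strand: str, alt: str) -> str:
    base = alt if strand == "+" else revcomp(alt)
    return cdna[:offset] + base + cdna[offset + 1 :]


def simulate_molecules(
    config: SimConfig, reference: Reference
) -> tuple[list[Molecule], GroundTruth]:
    """Draw cDNA molecules per gene and cell type from the configured mixtures."""
    rng = _rng(config.seed, 1)
    usage = _resolve_usage(config, reference, _rng(config.seed, 3))
    distal = _resolve_distal(config, reference, _rng(config.seed, 4))
    variants = _resolve_variants(config, reference)

    # cells: unique 16-nt barcodes per cell type
    cells: dict[str, str] = {}
    barcodes_by_type: dict[str, list[str]] = {ct: [] for ct in config.cell_type_names}
    seen: set[str] = set()
    for ct in config.cell_type_names:
        while len(barcodes_by_type[ct]) < config.cells_per_type:
            bc = _random_seq(rng, 16)
            if bc in seen:
                continue
            seen.add(bc)
            barcodes_by_type[ct].append(bc)
            cells[bc] = ct

    umis_per_cell: dict[str, set[str]] = {bc: set() for bc in cells}

    def new_umi(bc: str) -> str:
        while True:
            u = _random_seq(rng, 12)
            if u not in umis_per_cell[bc]:
                umis_per_cell[bc].add(u)
                return u

    molecules: list[Molecule] = []
    counter = 0

    def make_molecule(
        gene_id: str,
        transcript: TranscriptModel,
        ct: str,
        loci,
        cdna: str,
        uses_distal,
        is_fusion=False,
    ) -> Molecule:
        nonlocal counter
        counter += 1
        bc = barcodes_by_type[ct][int(rng.integers(len(barcodes_by_type[ct])))]
        mol = Molecule(
            molecule_id=f"m{counter:07d}",
            gene_id=gene_id,
            transcript_id=transcript.transcript_id,
            cell_barcode=bc,
            cell_type=ct,
            umi=new_umi(bc),
            loci=loci,
            cdna=cdna,
            uses_distal=uses_distal,
            is_fusion=is_fusion,
        )
        # implant SNVs carried by this cell type
        for var in variants:
            if ct not in var.carrier_cell_types:
                continue
            off = _genomic_to_transcript_offset(mol.loci, var.chrom, var.position)
            if off is None:
                continue
            if rng.random() < var.allele_fraction:
                strand = next(s for c, s, b in mol.loci if c == var.chrom)
                mol.cdna = _apply_sub(mol.cdna, off, strand, var.alt)
                mol.subs.setdefault(var.chrom, {})[var.position] = var.alt
                mol.variant_names.append(var.name)
        molecules.append(mol)
        return mol

    for gene_id, info in reference.genes.items():
        apa_capable = info.utr_length > 101 and info.proximal_site > 0
        for ct in config.cell_type_names:
            vec = usage[gene_id][ct]
            f_distal = distal[gene_id][ct]
            choices = rng.choice(len(vec), size=config.molecules_per_gene, p=vec)
            distal_draws = rng.random(config.molecules_per_gene) < f_distal
            for j in range(config.molecules_per_gene):
                tx = info.transcripts[int(choices[j])]
                uses_distal = bool(distal_draws[j]) if apa_capable else None
                if uses_distal is False:
                    blocks = info.truncated_blocks(tx.blocks, info.proximal_site)
                else:
                    blocks = [tuple(b) for b in tx.blocks]
                model = TranscriptModel(
                    transcript_id="tmp",
                    gene_id=gene_id,
                    chrom=info.chrom,
                    strand=info.strand,
                    blocks=blocks,
                )
                cdna = model.spliced_sequence(reference.genome)
                make_molecule(
                    gene_id,
                    tx,
                    ct,
                    [(info.chrom, info.strand, blocks)],
                    cdna,
                    uses_distal,
                )

    fusion_truth = None
    if config.fusion_spec is not None:
        fusion_truth = _make_fusion_molecules(
            config, reference, rng, make_molecule
        )

    mol_rows = [
        {
            "molecule_id": m.molecule_id,
            "gene_id": m.gene_id,
            "transcript_id": m.transcript_id,
            "cell_barcode": m.cell_barcode,
            "cell_type": m.cell_type,
            "umi": m.umi,
            "uses_distal": m.uses_distal,
            "is_fusion": m.is_fusion,
            "variants": ";".join(m.variant_names),
        }
        for m in molecules
    ]
    gc_rows = [
        {"gene_id": g, "cell_type": ct, "distal_fraction": f}
        for g, per_ct in distal.items()
        for ct, f in per_ct.items()
    ]
    pi_rows = [
        {
            "gene_id": g,
            "transcript_id": reference.genes[g].transcripts[k].transcript_id,
            "cell_type": ct,
            "pi": float(vec[k]),
        }
        for g, per_ct in usage.items()
        for ct, vec in per_ct.items()
        for k in range(len(vec))
    ]
    truth = GroundTruth(
        molecules=pd.DataFrame(mol_rows),
        gene_condition=pd.DataFrame(gc_rows),
        pi=pd.DataFrame(pi_rows),
        cells=cells,
        variants=variants,
        fusion=fusion_truth,
    )
    return molecules, truth


def _make_fusion_molecules(config, reference, rng, make_molecule) -> dict:
    spec = config.fusion_spec
    g5, g3 = reference.genes[spec.gene5], reference.genes[spec.gene3]
    tx5, tx3 = g5.transcripts[0], g3.transcripts[0]
    # exon blocks in transcript order
    b5 = tx5.blocks if g5.strand == "+" else list(reversed(tx5.blocks))
    b3 = tx3.blocks if g3.strand == "+" else list(reversed(tx3.blocks))
    part5 = sorted(b5[: spec.n_exons5])
    part3 = sorted(b3[-spec.n_exons3 :])
    # breakpoint: 3' end of the 5' part / 5' start of the 3' part
    bp5 = part5[-1][1] - 1 if g5.strand == "+" else part5[0][0]
    bp3 = part3[0][0] if g3.strand == "+" else part3[-1][1] - 1
    if spec.breakpoint5 is not None:
        bp5 = spec.breakpoint5
    if spec.breakpoint3 is not None:
        bp3 = spec.breakpoint3
    seq5 = TranscriptModel("tmp5", spec.gene5, g5.chrom, g5.strand, part5).spliced_sequence(
        reference.genome
    )
    seq3 = TranscriptModel("tmp3", spec.gene3, g3.chrom, g3.strand, part3).spliced_sequence(
        reference.genome
    )
    for _ in range(spec.n_umis):
        make_molecule(
            spec.gene5,
            tx5,
            spec.cell_type,
            [(g5.chrom, g5.strand, part5), (g3.chrom, g3.strand, part3)],
            seq5 + seq3,
            None,
            is_fusion=True,
        )
    return {
        "gene5": spec.gene5,
        "gene3": spec.gene3,
        "breakpoint5": bp5,
        "breakpoint3": bp3,
        "n_umis": spec.n_umis,
        "cell_type": spec.cell_type,
    }


# ---------------------------------------------------------------------------
# Reads


def truncated_poisson_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (mean > 1)."""
    if mean <= 1.0:
        raise ValueError("truncated Poisson mean must exceed 1")
    return float(
        brentq(lambda lam: lam / (1.0 - math.exp(-lam)) - mean, 1e-9, 10 * mean)
    )


def _sample_segment_counts(
    rng: np.random.Generator, n_molecules: int, mean: float
) -> list[int]:
    if mean <= 1.0 + 1e-9:
        return [1] * n_molecules
    lam = truncated_poisson_lambda(mean)
    counts: list[int] = []
    total = 0
    while total < n_molecules:
        k = 0
        while k == 0:
            k = int(rng.poisson(lam))
        counts.append(k)
        total += k
    counts[-1] -= total - n_molecules
    if counts[-1] == 0:
        counts.pop()
    return counts


def render_reads(
    molecules: list[Molecule], config: SimConfig
) -> tuple[dict[str, str], pd.DataFrame]:
    """Concatenate molecules into raw reads; returns sequences and segment truth.

    Each segment is fwd-primer + barcode(16) + UMI(12) + polyT(30) +
    reverse-complemented cDNA + rev-primer, emitted in a random strand
    orientation. A configurable fraction of segments is rendered as an
    artifact: the polyT tract omitted (``no_polya``) or the reverse
    primer dropped (``missing_primer``). Substitution errors are applied
    uniformly at ``error_rate``.
    """
    rng = _rng(config.seed, 2)
    order = rng.permutation(len(molecules))
    counts = _sample_segment_counts(rng, len(molecules), config.mean_segments_per_read)
    reads: dict[str, str] = {}
    rows = []
    idx = 0
    for r, k in enumerate(counts):
        read_id = f"read{r + 1:06d}"
        parts = []
        for seg_idx in range(k):
            mol = molecules[order[idx]]
            idx += 1
            artifact = ""
            if rng.random() < config.artifact_fraction:
                artifact = "no_polya" if rng.random() < 0.5 else "missing_primer"
            polyt = "" if artifact == "no_polya" else "T" * POLYT_LEN
            seg = (
                config.fwd_primer
                + mol.cell_barcode
                + mol.umi
                + polyt
                + revcomp(mol.cdna)
            )
            if artifact != "missing_primer":
                seg += config.rev_primer
            orientation = "+"
            if rng.random() < 0.5:
                orientation = "-"
                seg = revcomp(seg)
            parts.append(seg)
            rows.append(
                {
                    "read_id": read_id,
                    "segment_index": seg_idx,
                    "molecule_id": mol.molecule_id,
                    "cell_barcode": mol.cell_barcode,
                    "umi": mol.umi,
                    "artifact": artifact,
                    "orientation": orientation,
                }
            )
        seq = "".join(parts)
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < config.error_rate
            n_hit = int(hit.sum())
            if n_hit:
                shifts = rng.integers(1, 4, size=n_hit)
                base_idx = np.searchsorted(_BASES, arr[hit])
                arr[hit] = _BASES[(base_idx + shifts) % 4]
            seq = arr.tobytes().decode()
        reads[read_id] = seq
    return reads, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Alignments


def emit_alignments(
    molecules: list[Molecule], reference: Reference
) -> list[AlignmentRecord]:
    """Exact spliced-alignment records, one per deduplicated molecule.

    Chimeric (fusion) molecules contribute one record per locus sharing
    the molecule id, with ``locus_index`` preserving 5'->3' order.
    """
    records = []
    for mol in molecules:
        for i, (chrom, strand, blocks) in enumerate(mol.loci):
            records.append(
                AlignmentRecord(
                    read_id=mol.molecule_id,
                    cell_barcode=mol.cell_barcode,
                    umi=mol.umi,
                    chrom=chrom,
                    strand=strand,
                    blocks=[tuple(b) for b in blocks],
                    locus_index=i,
                    subs=dict(mol.subs.get(chrom, {})),
                )
            )
    return records


# ---------------------------------------------------------------------------
# Count-level simulation (for statistical calibration experiments)


def simulate_isoform_counts(
    usage_c1: np.ndarray,
    usage_c2: np.ndarray,
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial isoform x 2-condition count table at a given depth."""
    c1 = rng.multinomial(depth, np.asarray(usage_c1, dtype=float))
    c2 = rng.multinomial(depth, np.asarray(usage_c2, dtype=float))
    return np.stack([c1, c2], axis=1)


# ---------------------------------------------------------------------------
# Whole-dataset convenience


@dataclass
class SimulatedDataset:
    config: SimConfig
    reference: Reference
    molecules: list[Molecule]
    truth: GroundTruth
    reads: dict[str, str]
    alignments: list[AlignmentRecord]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.reference.write(outdir)
        io.write_fasta(self.reads, outdir / "reads.fa")
        io.write_alignments(self.alignments, outdir / "alignments.tsv")
        io.write_lines(sorted(self.truth.cells), outdir / "whitelist.txt")
        io.write_group_map(self.truth.cells, outdir / "cell_types.tsv")
        self.truth.molecules.to_csv(outdir / "truth_molecules.tsv", sep="\t", index=False)
        self.truth.gene_condition.to_csv(
            outdir / "truth_gene_condition.tsv", sep="\t", index=False
        )
        self.truth.pi.to_csv(outdir / "truth_pi.tsv", sep="\t", index=False)
        if self.truth.segments is not None:
            self.truth.segments.to_csv(outdir / "truth_segments.tsv", sep="\t", index=False)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run every generator stage under the config's seed."""
    reference = simulate_reference(config)
    molecules, truth = simulate_molecules(config, reference)
    reads, segments = render_reads(molecules, config)
    truth.segments = segments
    alignments = emit_alignments(molecules, reference)
    return SimulatedDataset(
        config=config,
        reference=reference,
        molecules=molecules,
        truth=truth,
        reads=reads,
        alignments=alignments,
    )
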