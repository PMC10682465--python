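"""Panel-guided per-cell mutation calling and germline/somatic classification.

At each panel position, reads covering the position in a cell are
counted as alt or ref; a cell is considered mutated at a variant as
soon as one alt read is observed (high-fidelity long reads need no
base-quality filtering). A variant is classified germline when at
least one mutated cell comes from a distal (tumor-free) biopsy sample,
somatic otherwise; a position never covered in a cell yields no call
for that cell (absence of coverage is not wild-type evidence).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .models import AlignmentRecord


@dataclass(frozen=True)
class PanelVariant:
    chrom: str
    position: int  # 1-based, as distributed in panel tables
    ref: str
    alt: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("panel variant ref and alt must differ")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide substitutions are supported")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.position}{self.ref}>{self.alt}"


@dataclass
class CellMutationCall:
    cell_barcode: str
    variant: PanelVariant
    n_alt: int
    n_ref: int
    min_alt_reads: int = 1

    @property
    def mutated(self) -> bool:
        return self.n_alt >= self.min_alt_reads


def read_panel(path: str | Path) -> list[PanelVariant]:
    """Panel TSV with columns chrom, position (1-based), ref, alt[, gene]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    return [
        PanelVariant(
            chrom=row["chrom"],
            position=int(row["position"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=str(row.get("gene", "")),
        )
        for _, row in df.iterrows()
    ]


def call_mutations(
    alignments: list[AlignmentRecord],
    panel: list[PanelVariant],
    genome: dict[str, str],
    min_alt_reads: int = 1,
) -> list[CellMutationCall]:
    """Count alt/ref reads per cell at each panel position.

    Only cells with at least one read covering a position receive a call
    for it. ``min_alt_reads`` alt reads (default one, matching the
    single-mutated-read rule) make a cell mutated.
    """
    import warnings

    by_variant_cell: dict[tuple[str, str], list[int]] = defaultdict(lambda: [0, 0])
    for variant in panel:
        pos0 = variant.position - 1
        genome_base = genome.get(variant.chrom, "")[pos0 : pos0 + 1]
        if genome_base and genome_base != variant.ref:
            warnings.warn(
                f"panel ref {variant.ref} at {variant.chrom}:{variant.position} "
                f"disagrees with the genome base {genome_base}; calls at this "
                "site count alleles against the panel as given"
            )
        for aln in alignments:
            if aln.chrom != variant.chrom:
                continue
            base = aln.base_at(pos0, genome)
            if base is None:
                continue
            counts = by_variant_cell[(variant.key, aln.cell_barcode)]
            if base == variant.alt:
                counts[0] += 1
            elif base == variant.ref:
                counts[1] += 1
    key_to_variant = {v.key: v for v in panel}
    calls = []
    for (vkey, barcode) in sorted(by_variant_cell):
        n_alt, n_ref = by_variant_cell[(vkey, barcode)]
        calls.append(
            CellMutationCall(
                cell_barcode=barcode,
                variant=key_to_variant[vkey],
                n_alt=n_alt,
                n_ref=n_ref,
                min_alt_reads=min_alt_reads,
            )
        )
    return calls


def classify_variants(
    calls: list[CellMutationCall], cell_sites: dict[str, str]
) -> pd.DataFrame:
    """Germline/somatic classification by the distal-tissue rule.

    ``cell_sites`` maps cell barcode to biopsy site ("tumor" or
    "distal"). A variant mutated in at least one distal-site cell is
    germline; mutated only in tumor-site cells, somatic; never mutated,
    unclassified.
    """
    per_variant: dict[str, dict] = {}
    for call in calls:
        entry = per_variant.setdefault(
            call.variant.key,
            {"variant": call.variant, "mutated_cells": [], "sites": set()},
        )
        if call.mutated:
            entry["mutated_cells"].append(call.cell_barcode)
            entry["sites"].add(cell_sites.get(call.cell_barcode, "unknown"))
    rows = []
    for vkey in sorted(per_variant):
        entry = per_variant[vkey]
        if not entry["mutated_cells"]:
            classification = "unclassified"
        elif "distal" in entry["sites"]:
            classification = "germline"
        else:
            classification = "somatic"
        rows.append(
            {
                "variant": vkey,
                "gene": entry["variant"].gene,
                "n_mutated_cells": len(entry["mutated_cells"]),
                "classification": classification,
            }
        )
    return pd.DataFrame(
        rows, columns=["variant", "gene", "n_mutated_cells", "classification"]
    )


def calls_table(calls: list[CellMutationCall]) -> pd.DataFrame:
    rows = [
        {
            "cell_barcode": c.cell_barcode,
            "variant": c.variant.key,
            "gene": c.variant.gene,
            "n_alt": c.n_alt,
            "n_ref": c.n_ref,
            "mutated": c.mutated,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["cell_barcode", "variant", "gene", "n_alt", "n_ref", "mutated"]
    )
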