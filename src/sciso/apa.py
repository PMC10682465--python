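"""Long-read alternative-polyadenylation (APA) detection.

Implements the two-polyA-site coverage-gap model. For each annotated
3'UTR region, per-condition coverage arrays ``w[c][k]`` are computed in
transcript (5'->3') orientation over UTR positions ``k = 1..L``. The
distal site is the most 3' position whose coverage exceeds a threshold
in any condition,

    L* = max{ k : w_k^c > threshold for some c },

and the proximal site maximizes the squared coverage gap between the 50
positions after and before a candidate position P:

    (C*, P*) = argmax_{c, P} ( mean_{i=1..50} w_{P+i}^c
                             - mean_{i=1..50} w_{P-i}^c )^2 .

Per condition, the mean coverages just upstream of the two sites give
``W_d`` and ``W_p`` and the distal-usage fraction ``F = W_d/(W_d+W_p)``;
conditions are compared by ``Fraction Change = F_C1 - F_C2`` (positive =
3'UTR lengthening) with a two-sided Fisher's exact test on the rounded
coverages, BH-corrected across genes.

Note on scale: because reads using the distal site also cover the
proximal window, ``W_p`` counts reads using *either* site, so under a
two-site generative model with true distal fraction ``f`` the statistic
satisfies ``F = f/(1+f)`` (an invertible, strictly increasing mapping).
The definition is kept exactly as stated above.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .models import AlignmentRecord, TranscriptModel

DEFAULT_COVERAGE_THRESHOLD = 10
WINDOW = 50  # averaging window of the two-site model


@dataclass
class UTRRegion:
    gene_id: str
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class UTRCoverage:
    region: UTRRegion
    conditions: list[str]
    w: np.ndarray  # shape (m, L); w[c][k-1] = coverage at UTR position k (5'->3')


@dataclass
class APASiteCall:
    L_star: int  # 1-based distal site position
    P_star: int  # 1-based proximal site position
    C_star: str  # condition attaining the argmax
    degenerate: bool = False  # flat objective (no coverage gap anywhere)


@dataclass
class APAUsage:
    condition: str
    W_d: float
    W_p: float
    F: float | None  # None when W_d + W_p == 0


@dataclass
class APAComparison:
    gene_id: str
    condition_pair: tuple[str, str]
    fraction_change: float
    p_value: float
    F_c1: float
    F_c2: float
    L_star: int
    P_star: int
    C_star: str
    p_adjusted: float | None = None
    direction: str = "none"


class UntestableGene(Exception):
    """Raised when a gene cannot be tested for APA; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


# ---------------------------------------------------------------------------
# UTR regions


def build_utr_regions(annotation: list[TranscriptModel]) -> list[UTRRegion]:
    """One region per retained terminal 3'UTR exon.

    Overlapping 3'UTR exons sharing the same 5' start merge to their
    union; overlap groups with differing 5' starts are discarded (they
    would create false-positive APA calls). Non-overlapping alternative
    last exons are retained as separate regions. Transcripts without an
    annotated 3'UTR are skipped.
    """
    by_gene: dict[str, list[TranscriptModel]] = defaultdict(list)
    for tx in annotation:
        if tx.utr3 is not None:
            by_gene[tx.gene_id].append(tx)
    regions: list[UTRRegion] = []
    for gene_id in sorted(by_gene):
        txs = by_gene[gene_id]
        chrom, strand = txs[0].chrom, txs[0].strand
        intervals = sorted({tx.utr3 for tx in txs})
        # connected components of overlapping intervals
        groups: list[list[tuple[int, int]]] = []
        for iv in intervals:
            if groups and iv[0] < max(e for _, e in groups[-1]):
                groups[-1].append(iv)
            else:
                groups.append([iv])
        for group in groups:
            starts5 = {s if strand == "+" else e for s, e in group}
            if len(starts5) > 1:
                continue  # ambiguous 5' start: drop the whole overlap group
            s = min(s for s, _ in group)
            e = max(e for _, e in group)
            regions.append(UTRRegion(gene_id, chrom, strand, s, e))
    return regions


# ---------------------------------------------------------------------------
# Coverage


def utr_coverage(
    region: UTRRegion,
    alignments: list[AlignmentRecord],
    cell_to_condition: dict[str, str],
    conditions: list[str] | None = None,
) -> UTRCoverage:
    """Per-condition per-base read coverage over the UTR, 5'->3' oriented.

    Coverage at position k is the number of molecules of that condition
    whose aligned blocks overlap the corresponding genomic base; index 1
    is the UTR 5' end regardless of genomic strand.
    """
    if conditions is None:
        conditions = sorted(set(cell_to_condition.values()))
    cond_idx = {c: i for i, c in enumerate(conditions)}
    L = region.length
    w = np.zeros((len(conditions), L), dtype=float)
    for aln in alignments:
        if aln.chrom != region.chrom:
            continue
        c = cond_idx.get(cell_to_condition.get(aln.cell_barcode, ""))
        if c is None:
            continue
        for s, e in aln.blocks:
            lo, hi = max(s, region.start) - region.start, min(e, region.end) - region.start
            if lo < hi:
                w[c, lo:hi] += 1
    if region.strand == "-":
        w = w[:, ::-1].copy()
    return UTRCoverage(region=region, conditions=conditions, w=w)


# ---------------------------------------------------------------------------
# Site detection


def find_distal_site(
    cov: UTRCoverage, threshold: int = DEFAULT_COVERAGE_THRESHOLD
) -> int:
    """Most 3' UTR position with coverage strictly above ``threshold`` in any condition."""
    above = (cov.w > threshold).any(axis=0)
    if not above.any():
        raise UntestableGene("no position exceeds the coverage threshold")
    return int(np.nonzero(above)[0].max()) + 1  # 1-based


def find_proximal_site(cov: UTRCoverage, L_star: int) -> APASiteCall:
    """Maximize the squared gap between the 50-position windows around P.

    The search range is P in [51, L*-50] so both windows fit; ties break
    toward the smallest P, then the smallest condition index. A flat
    profile (objective identically zero) is reported as degenerate.
    """
    if L_star < 2 * WINDOW + 2:
        raise UntestableGene("UTR too short for the two-site model")
    w = cov.w
    csum = np.concatenate([np.zeros((w.shape[0], 1)), np.cumsum(w, axis=1)], axis=1)
    best = (-1.0, None, None)  # (objective, P, c)
    for c in range(w.shape[0]):
        for P in range(WINDOW + 1, L_star - WINDOW + 1):
            after = (csum[c, P + WINDOW] - csum[c, P]) / WINDOW  # w_{P+1..P+50}
            before = (csum[c, P - 1] - csum[c, P - 1 - WINDOW]) / WINDOW  # w_{P-50..P-1}
            obj = (after - before) ** 2
            if obj > best[0]:
                best = (obj, P, c)
    obj, P, c = best
    return APASiteCall(
        L_star=L_star,
        P_star=int(P),
        C_star=cov.conditions[c],
        degenerate=obj == 0.0,
    )


# ---------------------------------------------------------------------------
# Usage and comparison


def compute_usage(cov: UTRCoverage, site: APASiteCall, condition: str) -> APAUsage:
    """Mean coverages upstream of the distal and proximal sites, and F."""
    c = cov.conditions.index(condition)
    w = cov.w[c]
    # 1-based positions L*-1 .. L*-50 -> 0-based indices L*-2 .. L*-51
    W_d = float(w[site.L_star - WINDOW - 1 : site.L_star - 1].mean())
    W_p = float(w[site.P_star - WINDOW - 1 : site.P_star - 1].mean())
    F = W_d / (W_d + W_p) if (W_d + W_p) > 0 else None
    return APAUsage(condition=condition, W_d=W_d, W_p=W_p, F=F)


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def compare_conditions(
    gene_id: str, site: APASiteCall, usage_c1: APAUsage, usage_c2: APAUsage
) -> APAComparison:
    """Fraction Change and two-sided Fisher's exact p for a condition pair."""
    if usage_c1.F is None or usage_c2.F is None:
        raise UntestableGene("zero_coverage")
    table = [
        [_round_half_away(usage_c1.W_d), _round_half_away(usage_c1.W_p)],
        [_round_half_away(usage_c2.W_d), _round_half_away(usage_c2.W_p)],
    ]
    _, p = fisher_exact(table, alternative="two-sided")
    return APAComparison(
        gene_id=gene_id,
        condition_pair=(usage_c1.condition, usage_c2.condition),
        fraction_change=usage_c1.F - usage_c2.F,
        p_value=float(p),
        F_c1=usage_c1.F,
        F_c2=usage_c2.F,
        L_star=site.L_star,
        P_star=site.P_star,
        C_star=site.C_star,
    )


def apa_table(comparisons: list[APAComparison], alpha: float = 0.05) -> pd.DataFrame:
    """BH adjustment across genes and lengthened/shortened direction calls."""
    if not comparisons:
        return pd.DataFrame(
            columns=[
                "gene_id", "condition_1", "condition_2", "L_star", "P_star", "C_star",
                "F_c1", "F_c2", "fraction_change", "p_value", "p_adjusted", "direction",
            ]
        )
    pvals = np.array([c.p_value for c in comparisons])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for comp, pa in zip(comparisons, p_adj):
        comp.p_adjusted = float(pa)
        if pa < alpha and comp.fraction_change > 0:
            comp.direction = "lengthened"
        elif pa < alpha and comp.fraction_change < 0:
            comp.direction = "shortened"
        else:
            comp.direction = "none"
    rows = [
        {
            "gene_id": c.gene_id,
            "condition_1": c.condition_pair[0],
            "condition_2": c.condition_pair[1],
            "L_star": c.L_star,
            "P_star": c.P_star,
            "C_star": c.C_star,
            "F_c1": c.F_c1,
            "F_c2": c.F_c2,
            "fraction_change": c.fraction_change,
            "p_value": c.p_value,
            "p_adjusted": c.p_adjusted,
            "direction": c.direction,
        }
        for c in comparisons
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["p_adjusted", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Whole-stage convenience


def run_apa(
    annotation: list[TranscriptModel],
    alignments: list[AlignmentRecord],
    cell_to_condition: dict[str, str],
    condition_1: str,
    condition_2: str,
    threshold: int = DEFAULT_COVERAGE_THRESHOLD,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """APA comparison of two conditions over every testable UTR region.

    Site detection uses all conditions jointly; the hypothesis test is
    pairwise between the two named conditions. Returns the result table
    and a per-gene exclusion report (reason per untestable region).
    """
    regions = build_utr_regions(annotation)
    by_chrom: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for aln in alignments:
        by_chrom[aln.chrom].append(aln)
    comparisons = []
    excluded = []
    for region in regions:
        cov = utr_coverage(region, by_chrom.get(region.chrom, []), cell_to_condition)
        try:
            L_star = find_distal_site(cov, threshold)
            site = find_proximal_site(cov, L_star)
            if site.degenerate:
                raise UntestableGene("flat coverage profile")
            u1 = compute_usage(cov, site, condition_1)
            u2 = compute_usage(cov, site, condition_2)
            comparisons.append(compare_conditions(region.gene_id, site, u1, u2))
        except UntestableGene as exc:
            excluded.append({"gene_id": region.gene_id, "reason": exc.reason})
        except ValueError as exc:  # condition absent from the coverage matrix
            excluded.append({"gene_id": region.gene_id, "reason": str(exc)})
    table = apa_table(comparisons, alpha=alpha)
    report = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return table, report
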