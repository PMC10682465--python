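"""Differential isoform usage between two conditions.

Per gene, isoform UMI counts are cross-tabulated against condition and
tested with Pearson's chi-squared test (no continuity correction). Each
condition's counts are normalized to isoform percentages Pi; the
per-isoform difference DeltaPi = Pi(C1) - Pi(C2) is summarized by the
largest summed shift of common sign over at most two isoforms
(``top2_sum``). A gene is called differentially spliced when the
BH-adjusted p-value is <= 0.05 and ``top2_sum`` exceeds 20 percentage
points. Called genes are ranked by the geometric mean of their
effect-size and significance ranks.

The module also accounts for biotype switches of the most expressed
isoform between conditions and for the noncoding fraction of
protein-coding gene expression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_DEPTH = 25
DEFAULT_ALPHA = 0.05
DEFAULT_DELTA_THRESHOLD = 20.0  # percentage points
DEFAULT_EXCLUDE_PATTERN = r"^(MT-|RPS|RPL|MRPS|MRPL)"
NONCODING_MIN_UMIS = 20
CODING_BIOTYPES = frozenset({"protein_coding"})


@dataclass
class IsoformCountTable:
    gene_id: str
    isoform_ids: list[str]
    counts: np.ndarray  # isoform x condition
    conditions: tuple[str, str]
    gene_name: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class UsageResult:
    gene_id: str
    p_value: float
    pi: np.ndarray  # isoform x condition, percent (columns sum to 100)
    delta_pi: np.ndarray  # percentage points, Pi(C1) - Pi(C2)
    top2_sum: float
    isoform_ids: list[str]
    low_expected: bool = False  # any expected cell < 5 (flagged, still tested)
    p_adjusted: float | None = None
    called: bool = False
    rank_score: float | None = None


@dataclass
class BiotypeChange:
    gene_id: str
    top_isoform: dict[str, str]  # condition -> isoform id
    top_biotype: dict[str, str]  # condition -> biotype
    changed: bool
    transition: str  # e.g. "protein_coding->non_coding" or "none"


# ---------------------------------------------------------------------------
# Filtering


def filter_testable(
    tables: list[IsoformCountTable],
    min_depth: int = DEFAULT_MIN_DEPTH,
    exclude_pattern: str = DEFAULT_EXCLUDE_PATTERN,
) -> tuple[list[IsoformCountTable], pd.DataFrame]:
    """Drop mitochondrial/ribosomal genes, shallow genes and single-isoform genes.

    A gene is testable when its name matches no exclusion pattern, every
    condition column reaches ``min_depth`` UMIs (inclusive), and it has
    at least two isoforms.
    """
    pattern = re.compile(exclude_pattern)
    testable, report = [], []
    for table in tables:
        name = table.gene_name or table.gene_id
        if pattern.match(name):
            report.append({"gene_id": table.gene_id, "reason": "mito_ribo"})
        elif table.counts.shape[0] < 2:
            report.append({"gene_id": table.gene_id, "reason": "single_isoform"})
        elif (table.counts.sum(axis=0) < min_depth).any():
            report.append({"gene_id": table.gene_id, "reason": "depth"})
        else:
            testable.append(table)
    return testable, pd.DataFrame(report, columns=["gene_id", "reason"])


# ---------------------------------------------------------------------------
# Testing


def top2_signed_sum(delta_pi: np.ndarray) -> float:
    """Largest summed shift of common sign over at most two isoforms.

    The positive direction sums the two largest positive DeltaPi values
    (a single positive entry sums alone); the negative direction mirrors
    it. Returns the larger magnitude of the two directions.
    """
    pos = np.sort(delta_pi[delta_pi > 0])[::-1]
    neg = np.sort(-delta_pi[delta_pi < 0])[::-1]
    return float(max(pos[:2].sum() if pos.size else 0.0, neg[:2].sum() if neg.size else 0.0))


def test_gene(table: IsoformCountTable) -> UsageResult:
    """Pearson chi-squared test for differential isoform usage of one gene.

    Isoforms unobserved in both conditions carry no usage information and
    are dropped from the contingency table (they would give zero expected
    counts); their DeltaPi is reported as 0.
    """
    counts = table.counts
    col_sums = counts.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError(f"{table.gene_id}: zero-depth condition column")
    observed_rows = counts.sum(axis=1) > 0
    if observed_rows.sum() < 2:  # a single expressed isoform: nothing to test
        p, expected = 1.0, counts[observed_rows]
    else:
        chi2, p, _, expected = chi2_contingency(counts[observed_rows], correction=False)
    pi = 100.0 * counts / col_sums
    delta = pi[:, 0] - pi[:, 1]
    return UsageResult(
        gene_id=table.gene_id,
        p_value=float(p),
        pi=pi,
        delta_pi=delta,
        top2_sum=top2_signed_sum(delta),
        isoform_ids=list(table.isoform_ids),
        low_expected=bool((expected < 5).any()),
    )


def call_differential(
    results: list[UsageResult],
    alpha: float = DEFAULT_ALPHA,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> list[UsageResult]:
    """BH-adjust across all tested genes and apply the calling rule.

    Called iff adjusted p <= alpha (inclusive) and top2_sum strictly
    exceeds ``delta_threshold`` percentage points.
    """
    if not results:
        return results
    pvals = np.array([r.p_value for r in results])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    for r, pa in zip(results, p_adj):
        r.p_adjusted = float(pa)
        r.called = bool(pa <= alpha) and (r.top2_sum > delta_threshold)
    return results


def rank_genes(results: list[UsageResult]) -> list[UsageResult]:
    """Rank called genes by sqrt(rank_by_effect * rank_by_p).

    Effect rank orders top2_sum descending (1 = largest shift);
    significance rank orders adjusted p ascending (1 = most significant).
    Output is sorted ascending by the combined score, ties broken by
    gene id.
    """
    called = [r for r in results if r.called]
    by_delta = sorted(called, key=lambda r: (-r.top2_sum, r.gene_id))
    by_p = sorted(called, key=lambda r: (r.p_adjusted, r.gene_id))
    rank_delta = {r.gene_id: i + 1 for i, r in enumerate(by_delta)}
    rank_p = {r.gene_id: i + 1 for i, r in enumerate(by_p)}
    for r in called:
        r.rank_score = float(np.sqrt(rank_delta[r.gene_id] * rank_p[r.gene_id]))
    return sorted(called, key=lambda r: (r.rank_score, r.gene_id))


# ---------------------------------------------------------------------------
# Biotype accounting


def _coding_label(biotype: str) -> str:
    return "protein_coding" if biotype in CODING_BIOTYPES else "non_coding"


def biotype_change(
    table: IsoformCountTable, biotypes: dict[str, str]
) -> BiotypeChange:
    """Compare the biotype of each condition's most expressed isoform.

    The top isoform per condition is the one with the highest UMI count,
    ties resolved toward the isoform with the larger count in the other
    condition, then lexicographically. The gene's biotype changed when
    the two top isoforms' biotypes differ (biotype equality, not isoform
    identity).
    """
    counts = table.counts
    tops: dict[str, str] = {}
    for c, cond in enumerate(table.conditions):
        other = 1 - c
        order = sorted(
            range(len(table.isoform_ids)),
            key=lambda i: (-counts[i, c], -counts[i, other], table.isoform_ids[i]),
        )
        tops[cond] = table.isoform_ids[order[0]]
    b1 = biotypes.get(tops[table.conditions[0]], "unknown")
    b2 = biotypes.get(tops[table.conditions[1]], "unknown")
    changed = b1 != b2
    transition = f"{_coding_label(b1)}->{_coding_label(b2)}" if changed else "none"
    return BiotypeChange(
        gene_id=table.gene_id,
        top_isoform=tops,
        top_biotype={table.conditions[0]: b1, table.conditions[1]: b2},
        changed=changed,
        transition=transition,
    )


def noncoding_fraction(
    tables: list[IsoformCountTable],
    biotypes: dict[str, str],
    gene_biotypes: dict[str, str],
    min_umis: int = NONCODING_MIN_UMIS,
) -> pd.DataFrame:
    """Noncoding share of expression per protein-coding gene and condition.

    Only genes annotated protein-coding are considered, and only
    gene-conditions reaching ``min_umis`` total UMIs are reported. The
    fraction is noncoding-isoform UMIs over total UMIs.
    """
    rows = []
    for table in tables:
        if gene_biotypes.get(table.gene_id) != "protein_coding":
            continue
        noncoding_mask = np.array(
            [_coding_label(biotypes.get(i, "unknown")) == "non_coding" for i in table.isoform_ids]
        )
        for c, cond in enumerate(table.conditions):
            total = float(table.counts[:, c].sum())
            if total < min_umis:
                continue
            nc = float(table.counts[noncoding_mask, c].sum()) if noncoding_mask.any() else 0.0
            rows.append(
                {
                    "gene_id": table.gene_id,
                    "condition": cond,
                    "total_umis": total,
                    "noncoding_umis": nc,
                    "fraction": nc / total,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "total_umis", "noncoding_umis", "fraction"]
    )


# ---------------------------------------------------------------------------
# Table construction and whole-stage convenience


def tables_from_catalog(
    isoforms,
    cell_to_condition: dict[str, str],
    condition_1: str,
    condition_2: str,
) -> list[IsoformCountTable]:
    """Build per-gene isoform x condition count tables from a catalog."""
    by_gene: dict[str, list] = {}
    for iso in isoforms:
        if iso.gene_id is None:
            continue
        by_gene.setdefault(iso.gene_id, []).append(iso)
    tables = []
    for gene_id in sorted(by_gene):
        isos = sorted(by_gene[gene_id], key=lambda i: i.isoform_id)
        counts = np.zeros((len(isos), 2))
        for i, iso in enumerate(isos):
            for bc, n in iso.counts.items():
                cond = cell_to_condition.get(bc)
                if cond == condition_1:
                    counts[i, 0] += n
                elif cond == condition_2:
                    counts[i, 1] += n
        tables.append(
            IsoformCountTable(
                gene_id=gene_id,
                isoform_ids=[i.isoform_id for i in isos],
                counts=counts,
                conditions=(condition_1, condition_2),
                gene_name=gene_id,
            )
        )
    return tables


def run_differential_usage(
    tables: list[IsoformCountTable],
    min_depth: int = DEFAULT_MIN_DEPTH,
    alpha: float = DEFAULT_ALPHA,
    delta_threshold: float = DEFAULT_DELTA_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, test, adjust, call and rank; returns results and exclusions."""
    testable, report = filter_testable(tables, min_depth=min_depth)
    results = [test_gene(t) for t in testable]
    call_differential(results, alpha=alpha, delta_threshold=delta_threshold)
    rank_genes(results)
    rows = [
        {
            "gene_id": r.gene_id,
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
            "top2_sum": r.top2_sum,
            "called": r.called,
            "rank_score": r.rank_score,
            "low_expected": r.low_expected,
        }
        for r in results
    ]
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "p_value", "p_adjusted", "top2_sum", "called",
            "rank_score", "low_expected",
        ],
    )
    if len(out):
        out = out.sort_values(
            ["rank_score", "p_adjusted", "gene_id"], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
    return out, report
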