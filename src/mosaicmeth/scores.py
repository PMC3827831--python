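"""Per-gene methylation degree, bimodal classification, and gene-level structure.

A gene's methylation degree is the fraction of its transcription unit that is
methylated, measured in one of two modes:

``domain_overlap``
    base pairs of the span covered by CAP-seq-derived methylated domains,
    divided by span length.  A gene is eligible only if its whole span lies
    inside input-covered regions, so that an absence of affinity coverage is
    informative.
``cpg_fraction``
    methylated-called CpG sites divided by assessed CpG sites (coverage >= 2)
    within the span.  A gene is eligible only if strictly more than 60% of
    its CpG sites are assessed and it contains at least one CpG.

Degrees are classified bimodally: > 0.9 methylated, < 0.1 unmethylated,
otherwise intermediate; both cutoffs are configurable (0.05/0.95 and 0.2/0.8
are the standard sensitivity settings).

The module also computes metagene domain-occupancy profiles around four
anchors (5' end, 3' end, start codon, stop codon) and detects convergent
tail-to-tail gene pairs that share one uninterrupted methylated domain across
an intergenic gap of more than ``convergent_min_gap`` (500 bp) between their
poly(A) sites.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, IntervalSet, overlap_fraction
from .methylation import CALL_METHYLATED, CALL_UNASSESSED

__all__ = [
    "ScoreConfig",
    "GeneMethylationRecord",
    "METH_CLASSES",
    "classify_degree",
    "sperm_gene_eligibility",
    "degree_by_domain_overlap",
    "degree_by_cpg_fraction",
    "score_genes_domain_overlap",
    "score_genes_cpg_fraction",
    "records_to_frame",
    "degree_histogram",
    "metagene_domain_profile",
    "detect_convergent_shared_domain_pairs",
    "write_gene_records",
    "read_gene_records",
]

METH_CLASSES = ("methylated", "unmethylated", "intermediate", "ineligible")
ANCHORS = ("five_prime", "three_prime", "start_codon", "stop_codon")


@dataclass(frozen=True)
class ScoreConfig:
    lo: float = 0.1
    hi: float = 0.9
    min_site_coverage: int = 2
    min_assessed_cpg_fraction: float = 0.6
    metagene_overlap_threshold: float = 0.8
    convergent_min_gap: int = 500
    flank: int = 1000
    # "assessed" follows the statistical intent (degree over sites that could
    # be called); "all" restores the literal all-CpG denominator.
    cpg_denominator: str = "assessed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.lo < self.hi <= 1.0:
            raise ValueError(f"need 0 <= lo < hi <= 1, got lo={self.lo}, hi={self.hi}")
        if self.cpg_denominator not in ("assessed", "all"):
            raise ValueError(f"unknown cpg_denominator {self.cpg_denominator!r}")
        if self.min_site_coverage < 1:
            raise ValueError("min_site_coverage must be >= 1")

    def with_thresholds(self, lo: float, hi: float) -> "ScoreConfig":
        return replace(self, lo=lo, hi=hi)


@dataclass(frozen=True)
class GeneMethylationRecord:
    gene_id: str
    mode: str  # domain_overlap | cpg_fraction
    degree: float | None
    eligible: bool
    meth_class: str


def classify_degree(degree: float, config: ScoreConfig) -> str:
    if degree > config.hi:
        return "methylated"
    if degree < config.lo:
        return "unmethylated"
    return "intermediate"


# ---------------------------------------------------------------------------
# domain-overlap mode (CAP-seq)
# ---------------------------------------------------------------------------


def sperm_gene_eligibility(gene: GeneModel, input_covered: IntervalSet) -> bool:
    """True iff the whole gene span is contained in input-covered regions."""
    covered = input_covered.overlap_bp(gene.contig, gene.span_start, gene.span_end)
    return covered == gene.length


def degree_by_domain_overlap(
    gene: GeneModel,
    methylated_domains: IntervalSet,
    config: ScoreConfig = ScoreConfig(),
    eligible: bool = True,
) -> GeneMethylationRecord:
    """Degree = fraction of the span overlapped by methylated domains."""
    if not eligible:
        return GeneMethylationRecord(gene.gene_id, "domain_overlap", None, False, "ineligible")
    degree = overlap_fraction(gene.span, methylated_domains)
    return GeneMethylationRecord(
        gene.gene_id, "domain_overlap", degree, True, classify_degree(degree, config)
    )


def score_genes_domain_overlap(
    genes: Sequence[GeneModel],
    methylated_domains: IntervalSet,
    input_covered: IntervalSet | None = None,
    config: ScoreConfig = ScoreConfig(),
) -> list[GeneMethylationRecord]:
    """Score every gene; with ``input_covered`` given, apply the eligibility filter."""
    out = []
    for g in genes:
        eligible = True if input_covered is None else sperm_gene_eligibility(g, input_covered)
        out.append(degree_by_domain_overlap(g, methylated_domains, config, eligible=eligible))
    return out


# ---------------------------------------------------------------------------
# CpG-fraction mode (BS-seq)
# ---------------------------------------------------------------------------


def _cpg_counts_in_span(
    gene: GeneModel, positions: np.ndarray, calls: np.ndarray, min_coverage_mask: np.ndarray
) -> tuple[int, int, int]:
    lo = np.searchsorted(positions, gene.span_start, side="left")
    hi = np.searchsorted(positions, gene.span_end, side="left")
    n_all = hi - lo
    assessed = min_coverage_mask[lo:hi]
    n_assessed = int(assessed.sum())
    n_meth = int((calls[lo:hi][assessed] == CALL_METHYLATED).sum())
    return int(n_all), n_assessed, n_meth


def degree_by_cpg_fraction(
    gene: GeneModel,
    called_sites: pd.DataFrame,
    config: ScoreConfig = ScoreConfig(),
) -> GeneMethylationRecord:
    """Degree from called CpG sites inside the gene span.

    ``called_sites`` is a call table (columns contig, pos, context, X, call);
    non-CpG contexts and other contigs are filtered out here.
    """
    sub = called_sites[
        (called_sites["contig"] == gene.contig) & (called_sites["context"] == "CpG")
    ].sort_values("pos", kind="stable")
    pos = sub["pos"].to_numpy(dtype=np.int64)
    calls = sub["call"].to_numpy()
    assessed_mask = sub["X"].to_numpy() >= config.min_site_coverage
    return _cpg_record(gene, *_cpg_counts_in_span(gene, pos, calls, assessed_mask), config)


def _cpg_record(
    gene: GeneModel, n_all: int, n_assessed: int, n_meth: int, config: ScoreConfig
) -> GeneMethylationRecord:
    eligible = n_all >= 1 and (n_assessed / n_all) > config.min_assessed_cpg_fraction
    if not eligible:
        return GeneMethylationRecord(gene.gene_id, "cpg_fraction", None, False, "ineligible")
    denom = n_assessed if config.cpg_denominator == "assessed" else n_all
    if denom == 0:
        return GeneMethylationRecord(gene.gene_id, "cpg_fraction", None, False, "ineligible")
    degree = n_meth / denom
    return GeneMethylationRecord(
        gene.gene_id, "cpg_fraction", degree, True, classify_degree(degree, config)
    )


def score_genes_cpg_fraction(
    genes: Sequence[GeneModel],
    called_sites: pd.DataFrame,
    config: ScoreConfig = ScoreConfig(),
) -> list[GeneMethylationRecord]:
    """Vectorized scoring of many genes against one call table."""
    cpg = called_sites[called_sites["context"] == "CpG"]
    by_contig: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig, sub in cpg.groupby("contig", sort=False):
        sub = sub.sort_values("pos", kind="stable")
        by_contig[contig] = (
            sub["pos"].to_numpy(dtype=np.int64),
            sub["call"].to_numpy(),
            sub["X"].to_numpy() >= config.min_site_coverage,
        )
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=object), np.empty(0, dtype=bool))
    out = []
    for g in genes:
        pos, calls, mask = by_contig.get(g.contig, empty)
        out.append(_cpg_record(g, *_cpg_counts_in_span(g, pos, calls, mask), config))
    return out


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[GeneMethylationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": r.gene_id,
                "mode": r.mode,
                "degree": np.nan if r.degree is None else r.degree,
                "eligible": r.eligible,
                "meth_class": r.meth_class,
            }
            for r in records
        ]
    )


def degree_histogram(records: Iterable[GeneMethylationRecord], n_bins: int = 10) -> np.ndarray:
    """Counts of eligible genes in equal-width degree bins on [0, 1]."""
    degrees = np.array([r.degree for r in records if r.eligible], dtype=float)
    if degrees.size == 0:
        return np.zeros(n_bins, dtype=np.int64)
    idx = np.minimum((degrees * n_bins).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def metagene_domain_profile(
    genes: Sequence[GeneModel],
    methylated_domains: IntervalSet,
    align_at: str = "five_prime",
    flank: int = 1000,
    config: ScoreConfig = ScoreConfig(),
) -> pd.DataFrame:
    """Domain-occupancy counts around a common anchor, strand-aware.

    Genes with domain overlap above ``config.metagene_overlap_threshold`` are
    aligned at the chosen anchor; for each relative position in
    [-flank, +flank] the returned frame counts the genes whose aligned base
    lies inside a methylated domain.  Minus-strand genes are flipped so that
    positive offsets always point into the gene body / downstream.
    """
    if align_at not in ANCHORS:
        raise ValueError(f"unknown anchor {align_at!r}; expected one of {ANCHORS}")
    rel = np.arange(-flank, flank + 1, dtype=np.int64)
    counts = np.zeros(rel.size, dtype=np.int64)
    for g in genes:
        if overlap_fraction(g.span, methylated_domains) <= config.metagene_overlap_threshold:
            continue
        if align_at == "five_prime":
            anchor = g.tss
        elif align_at == "three_prime":
            anchor = g.polya_site
        elif align_at == "start_codon":
            anchor = g.cds_start if g.strand == "+" else g.cds_end - 1
        else:  # stop_codon
            anchor = g.cds_end - 1 if g.strand == "+" else g.cds_start
        pos = anchor + rel if g.strand == "+" else anchor - rel
        counts += methylated_domains.contains(g.contig, pos).astype(np.int64)
    return pd.DataFrame({"rel_pos": rel, "count": counts})


def detect_convergent_shared_domain_pairs(
    genes: Sequence[GeneModel],
    methylated_domains: IntervalSet,
    config: ScoreConfig = ScoreConfig(),
) -> list[tuple[str, str]]:
    """Tail-to-tail adjacent gene pairs sharing one uninterrupted domain.

    A pair qualifies when the + gene immediately precedes the - gene on the
    contig, their spans do not overlap, the gap between their poly(A) sites
    exceeds ``convergent_min_gap``, and a single domain interval covers the
    entire gap plus at least one base of each gene body.
    """
    pairs: list[tuple[str, str]] = []
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=lambda g: (g.span_start, g.span_end))
        for g1, g2 in zip(ordered, ordered[1:]):
            if g1.strand != "+" or g2.strand != "-":
                continue
            gap = g2.span_start - g1.span_end
            if gap <= config.convergent_min_gap:
                continue
            dom = methylated_domains.enclosing_interval(contig, g1.span_end)
            if dom is None:
                continue
            ds, de = dom
            if ds < g1.span_end and de > g2.span_start:
                pairs.append((g1.gene_id, g2.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_RECORD_COLUMNS = ["gene_id", "mode", "degree", "eligible", "meth_class"]


def write_gene_records(records, path, header: str | None = None) -> None:
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# " + "\t".join(_RECORD_COLUMNS) + "\n")
        frame[_RECORD_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_gene_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_RECORD_COLUMNS)
    df["eligible"] = df["eligible"].astype(bool)
    return df
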