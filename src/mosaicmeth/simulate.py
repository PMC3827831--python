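"""Synthetic mosaic-methylome generator.

The generator emulates the statistical structure of a compact invertebrate
genome with comprehensive gene body methylation: methylated domains coincide
with a fixed fraction (~60%) of gene bodies, promoters and intergenic space
are unmethylated, within-domain CpG methylation sits near 0.979 in a
sperm-like tissue and 0.705 in a muscle-like tissue, and a small number of
convergent (tail-to-tail) gene pairs share one uninterrupted domain across
their intergenic gap.  On top of the true methylome it simulates

* CAP-seq observations: an input library with uniform read starts, and a
  CXXC affinity library whose reads start inside unmethylated regions except
  for a small uniform contamination fraction;
* BS-seq observations: per-cytosine coverage X ~ Poisson(depth) and
  methylated-evidence counts m ~ Binomial(X, p_site), where p_site is the
  tissue's within-domain level for CpG-context sites inside domains and the
  bisulfite error rate (0.00091 by default) everywhere else, including the
  whole unmethylated control contig;
* a per-gene expression-class table in which methylated genes have elevated
  odds of the maternal and stable classes.

Counts that a test can pin down exactly — the number of methylated genes and
the number of shared-domain convergent pairs — are deterministic given the
configuration; only their identities and positions are random.  All outputs
are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import GenomeLayout, GeneModel, IntervalSet, merge_intervals
from .methylation import extract_cytosine_sites

__all__ = [
    "SimulationConfig",
    "TrueMethylome",
    "SyntheticGenome",
    "TISSUES",
    "build_synthetic_genome",
    "simulate_capseq",
    "simulate_bsseq",
    "simulate_expression_classes",
]

TISSUES = ("sperm_like", "muscle_like")

# rng substream indices, one per stochastic stage
_STREAM_GENOME = 0
_STREAM_CAPSEQ = 1
_STREAM_BSSEQ = {"sperm_like": 2, "muscle_like": 3}
_STREAM_CLASSES = 4


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_contigs: int = 5
    contig_length: int = 1_000_000
    n_genes: int = 2000
    fraction_methylated: float = 0.6
    gene_length_min: int = 1200
    gene_length_max: int = 2200
    min_intergenic_gap: int = 600
    promoter_unmethylated_window: int = 30
    domain_inner_offset_frac: float = 0.01
    n_convergent_shared_pairs: int = 5
    cpg_density: float = 0.02
    gc_content: float = 0.36
    within_domain_level_sperm: float = 0.979
    within_domain_level_muscle: float = 0.705
    error_rate: float = 0.00091
    capseq_depth_mean: float = 20.0
    bsseq_depth_mean: float = 10.0
    capseq_read_length: int = 36
    cxxc_contamination: float = 0.01
    control_contig_length: int = 60_000
    expression_class_proportions: tuple[float, float, float, float, float] = (
        0.15,
        0.25,
        0.25,
        0.20,
        0.15,
    )
    methylation_class_odds: float = 5.0

    def validate(self) -> list[str]:
        """Human-readable configuration problems (empty list when valid)."""
        issues: list[str] = []
        if self.n_contigs < 1 or self.contig_length < 1:
            issues.append("need at least one contig of positive length")
        if self.n_genes < 0:
            issues.append("n_genes must be non-negative")
        for name in (
            "fraction_methylated",
            "cpg_density",
            "gc_content",
            "within_domain_level_sperm",
            "within_domain_level_muscle",
            "error_rate",
            "cxxc_contamination",
            "domain_inner_offset_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                issues.append(f"{name}={v} outside [0, 1]")
        if not 0 < self.gene_length_min <= self.gene_length_max:
            issues.append("need 0 < gene_length_min <= gene_length_max")
        if self.min_intergenic_gap < 1:
            issues.append("min_intergenic_gap must be >= 1")
        if self.n_convergent_shared_pairs > 0 and self.min_intergenic_gap <= 500:
            issues.append(
                "convergent shared-domain pairs need min_intergenic_gap > 500 bp "
                f"(got {self.min_intergenic_gap})"
            )
        if self.capseq_read_length < 1:
            issues.append("capseq_read_length must be >= 1")
        if self.capseq_depth_mean <= 0 or self.bsseq_depth_mean <= 0:
            issues.append("sequencing depth means must be positive")
        if self.control_contig_length < 1:
            issues.append("control_contig_length must be >= 1")
        props = self.expression_class_proportions
        if len(props) != 5 or any(p < 0 for p in props):
            issues.append("expression_class_proportions must be 5 non-negative values")
        elif abs(sum(props) - 1.0) > 1e-9:
            issues.append(f"expression_class_proportions sum to {sum(props):.6g}, expected 1")
        if self.methylation_class_odds < 0:
            issues.append("methylation_class_odds must be >= 0")
        n_meth = int(round(self.fraction_methylated * self.n_genes))
        if 2 * self.n_convergent_shared_pairs > n_meth:
            issues.append(
                f"{self.n_convergent_shared_pairs} convergent pairs need "
                f"{2 * self.n_convergent_shared_pairs} methylated genes but only "
                f"{n_meth} are configured"
            )
        # domain insets must leave every methylated gene > 90% covered
        if self.gene_length_min > 0:
            worst = (
                self.promoter_unmethylated_window / self.gene_length_min
                + 2 * self.domain_inner_offset_frac
            )
            if worst >= 0.1:
                issues.append(
                    "promoter window plus domain inner offsets can cover "
                    f">= 10% of the shortest gene ({worst:.3f}); methylated genes "
                    "would not be > 90% domain-covered"
                )
        return issues

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expression_class_proportions"] = list(self.expression_class_proportions)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        if "expression_class_proportions" in kwargs:
            kwargs["expression_class_proportions"] = tuple(
                kwargs["expression_class_proportions"]
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass(frozen=True)
class TrueMethylome:
    """Ground truth: per-gene status, true domains, per-cytosine probabilities."""

    gene_status: dict[str, str]  # gene_id -> methylated | unmethylated
    domains: IntervalSet
    convergent_pairs: tuple[tuple[str, str], ...]

    @property
    def methylated_genes(self) -> frozenset:
        return frozenset(g for g, s in self.gene_status.items() if s == "methylated")

    def site_probabilities(
        self, sites: pd.DataFrame, level: float, error_rate: float
    ) -> np.ndarray:
        """True methylation probability per cytosine site.

        CpG-context sites inside domains carry the tissue level; all other
        sites (non-CpG context, outside domains, control contig) carry the
        error rate.
        """
        p = np.full(len(sites), error_rate)
        is_cpg = (sites["context"] == "CpG").to_numpy()
        pos = sites["pos"].to_numpy()
        for contig, idx in sites.groupby("contig", sort=False).indices.items():
            inside = self.domains.contains(contig, pos[idx])
            sel = idx[inside & is_cpg[idx]]
            p[sel] = level
        return p


@dataclass(frozen=True)
class SyntheticGenome:
    layout: GenomeLayout
    sequences: dict[str, str]
    genes: list[GeneModel]
    truth: TrueMethylome

    def genes_by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, int(config.seed)])


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float, cpg_density: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=length, p=p)].copy()
    if length >= 2 and cpg_density > 0:
        candidates = np.flatnonzero(rng.random(length - 1) < cpg_density)
        last = -2
        for c in candidates:  # greedy non-overlapping planting
            if c > last + 1:
                seq[c] = ord("C")
                seq[c + 1] = ord("G")
                last = c
    return seq.tobytes().decode("ascii")


def build_synthetic_genome(config: SimulationConfig) -> SyntheticGenome:
    """Lay out genes, pick methylated targets, construct true domains and sequence.

    Exactly ``round(fraction_methylated * n_genes)`` genes are methylated and
    exactly ``n_convergent_shared_pairs`` adjacent (+,-) gene pairs share one
    uninterrupted domain spanning both bodies and the intergenic gap.
    """
    issues = config.validate()
    if issues:
        raise ValueError("invalid simulation config: " + "; ".join(issues))
    rng = _rng(config, _STREAM_GENOME)

    contig_names = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    layout = GenomeLayout(
        contigs=tuple(
            [(n, config.contig_length) for n in contig_names]
            + [("mito", config.control_contig_length)]
        ),
        control_contig="mito",
    )

    # distribute genes over contigs, then pack each contig left to right
    base, rem = divmod(config.n_genes, config.n_contigs)
    counts = [base + (1 if i < rem else 0) for i in range(config.n_contigs)]
    gap_floor = config.min_intergenic_gap

    spans: list[tuple[str, int, int]] = []  # (contig, start, end) in gene order
    for contig, k in zip(contig_names, counts):
        if k == 0:
            continue
        lengths = rng.integers(config.gene_length_min, config.gene_length_max + 1, size=k)
        required = int(lengths.sum()) + (k + 1) * gap_floor
        if required > config.contig_length:
            raise ValueError(
                f"infeasible packing on {contig}: {k} genes plus minimum gaps need "
                f"{required} bp but the contig has {config.contig_length} bp"
            )
        extra = config.contig_length - required
        weights = rng.dirichlet(np.ones(k + 1))
        gap_extra = np.floor(weights * extra).astype(np.int64)
        cursor = 0
        for j in range(k):
            cursor += gap_floor + int(gap_extra[j])
            spans.append((contig, cursor, cursor + int(lengths[j])))
            cursor += int(lengths[j])

    n = len(spans)
    strands = np.array(rng.choice(["+", "-"], size=n))

    # designate convergent shared-domain pairs among adjacent same-contig slots
    slot_ok = np.array(
        [i < n - 1 and spans[i][0] == spans[i + 1][0] for i in range(n)], dtype=bool
    )
    candidates = rng.permutation(np.flatnonzero(slot_ok))
    pair_slots: list[int] = []
    used: set[int] = set()
    for c in candidates:
        if len(pair_slots) == config.n_convergent_shared_pairs:
            break
        if c in used or c + 1 in used:
            continue
        pair_slots.append(int(c))
        used.update((c, c + 1))
    if len(pair_slots) != config.n_convergent_shared_pairs:
        raise ValueError(
            f"cannot place {config.n_convergent_shared_pairs} convergent pairs: "
            f"only {len(pair_slots)} disjoint adjacent slots available"
        )
    for c in pair_slots:
        strands[c], strands[c + 1] = "+", "-"

    # deterministic methylated count; pair genes are methylated by construction
    n_meth = int(round(config.fraction_methylated * config.n_genes))
    forced = sorted(used)
    free = np.setdiff1d(np.arange(n), np.array(forced, dtype=int))
    extra_meth = rng.choice(free, size=n_meth - len(forced), replace=False)
    methylated_idx = np.zeros(n, dtype=bool)
    methylated_idx[forced] = True
    methylated_idx[extra_meth] = True

    # gene models with CDS insets (UTR margins of 100-300 bp each side)
    genes: list[GeneModel] = []
    digits = max(4, len(str(max(n - 1, 1))))
    for i, (contig, s, e) in enumerate(spans):
        m5 = int(rng.integers(100, 301))
        m3 = int(rng.integers(100, 301))
        genes.append(
            GeneModel(
                gene_id=f"g{i:0{digits}d}",
                contig=contig,
                strand=str(strands[i]),
                span_start=s,
                span_end=e,
                cds_start=s + m5,
                cds_end=e - m3,
            )
        )

    # true domains: inset within each methylated gene body; the TSS side gets
    # the promoter window on top of its random inset.  Pair domains run from
    # the + gene's 5' inset to the - gene's 5' inset, across the gap.
    W = config.promoter_unmethylated_window
    frac = config.domain_inner_offset_frac

    def _insets(g: GeneModel) -> tuple[int, int]:
        emax = int(frac * g.length)
        tss_side = W + int(rng.integers(0, emax + 1))
        other = int(rng.integers(0, emax + 1))
        return (tss_side, other) if g.strand == "+" else (other, tss_side)

    pair_members = set(used)
    raw_domains: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    for i, g in enumerate(genes):
        if not methylated_idx[i] or i in pair_members:
            continue
        left, right = _insets(g)
        raw_domains[g.contig].append((g.span_start + left, g.span_end - right))
    pairs: list[tuple[str, str]] = []
    for c in sorted(pair_slots):
        g1, g2 = genes[c], genes[c + 1]
        left, _ = _insets(g1)
        _, right = _insets(g2)
        raw_domains[g1.contig].append((g1.span_start + left, g2.span_end - right))
        pairs.append((g1.gene_id, g2.gene_id))
    domains = merge_intervals(raw_domains, layout=layout)

    sequences = {
        name: _random_sequence(rng, length, config.gc_content, config.cpg_density)
        for name, length in layout.contigs
    }

    truth = TrueMethylome(
        gene_status={
            g.gene_id: ("methylated" if methylated_idx[i] else "unmethylated")
            for i, g in enumerate(genes)
        },
        domains=domains,
        convergent_pairs=tuple(pairs),
    )
    return SyntheticGenome(layout=layout, sequences=sequences, genes=genes, truth=truth)


# ---------------------------------------------------------------------------
# CAP-seq simulation
# ---------------------------------------------------------------------------


def _starts_to_reads(contig_starts: dict[str, list[np.ndarray]], read_length: int):
    out = {}
    for contig, chunks in contig_starts.items():
        if not chunks:
            continue
        starts = np.sort(np.concatenate(chunks))
        out[contig] = np.column_stack([starts, starts + read_length])
    return out


def simulate_capseq(
    genome: SyntheticGenome, truth: TrueMethylome, config: SimulationConfig
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Simulate (input_reads, cxxc_reads) as per-contig interval arrays.

    Input read starts are uniform per contig at the configured mean depth.
    CXXC reads start uniformly inside unmethylated (non-domain) regions,
    except for a ``cxxc_contamination`` fraction placed uniformly genome-wide.
    """
    rng = _rng(config, _STREAM_CAPSEQ)
    rl = config.capseq_read_length
    layout = genome.layout

    input_reads: dict[str, list[np.ndarray]] = {n: [] for n in layout.names}
    for name, length in layout.contigs:
        n_reads = int(round(config.capseq_depth_mean * length / rl))
        hi = max(length - rl, 0) + 1
        input_reads[name].append(rng.integers(0, hi, size=n_reads))

    n_cxxc = int(round(config.capseq_depth_mean * layout.total_bp / rl))
    n_contam = int(round(config.cxxc_contamination * n_cxxc))
    n_clean = n_cxxc - n_contam
    cxxc: dict[str, list[np.ndarray]] = {n: [] for n in layout.names}

    # clean reads: uniform over the complement of the true domains
    unmeth = truth.domains.complement(layout)
    seg_contig: list[str] = []
    seg_start: list[int] = []
    seg_len: list[int] = []
    for contig, arr in unmeth.items():
        for s, e in arr:
            seg_contig.append(contig)
            seg_start.append(int(s))
            seg_len.append(int(e - s))
    seg_len_arr = np.array(seg_len, dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(seg_len_arr)])
    total_unmeth = int(cum[-1])
    if n_clean > 0 and total_unmeth > 0:
        u = rng.integers(0, total_unmeth, size=n_clean)
        seg_idx = np.searchsorted(cum, u, side="right") - 1
        pos = u - cum[seg_idx] + np.array(seg_start)[seg_idx]
        contigs_arr = np.array(seg_contig)[seg_idx]
        for contig in np.unique(contigs_arr):
            sel = pos[contigs_arr == contig]
            limit = max(layout.length_of(str(contig)) - rl, 0)
            cxxc[str(contig)].append(np.minimum(sel, limit))

    # contamination: uniform genome-wide
    if n_contam > 0:
        lengths = np.array([l for _, l in layout.contigs], dtype=np.int64)
        cum_g = np.concatenate([[0], np.cumsum(lengths)])
        u = rng.integers(0, int(cum_g[-1]), size=n_contam)
        idx = np.searchsorted(cum_g, u, side="right") - 1
        pos = u - cum_g[idx]
        names = np.array(layout.names)
        for ci in np.unique(idx):
            name = str(names[ci])
            sel = pos[idx == ci]
            limit = max(layout.length_of(name) - rl, 0)
            cxxc[name].append(np.minimum(sel, limit))

    return (
        _starts_to_reads(input_reads, rl),
        _starts_to_reads(cxxc, rl),
    )


# ---------------------------------------------------------------------------
# BS-seq simulation
# ---------------------------------------------------------------------------


def simulate_bsseq(
    genome: SyntheticGenome,
    truth: TrueMethylome,
    config: SimulationConfig,
    tissue: str,
) -> pd.DataFrame:
    """Per-cytosine (contig, pos, strand, context, X, m) counts for one tissue."""
    if tissue not in TISSUES:
        raise ValueError(f"unknown tissue {tissue!r}; expected one of {TISSUES}")
    level = (
        config.within_domain_level_sperm
        if tissue == "sperm_like"
        else config.within_domain_level_muscle
    )
    rng = _rng(config, _STREAM_BSSEQ[tissue])
    sites = extract_cytosine_sites(genome.sequences)
    p = truth.site_probabilities(sites, level=level, error_rate=config.error_rate)
    X = rng.poisson(config.bsseq_depth_mean, size=len(sites))
    m = rng.binomial(X, p)
    out = sites.copy()
    out["X"] = X.astype(np.int64)
    out["m"] = m.astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# expression classes
# ---------------------------------------------------------------------------


def simulate_expression_classes(
    genes: list[GeneModel], truth: TrueMethylome, config: SimulationConfig
) -> pd.DataFrame:
    """Sample a gene -> expression-class table.

    Methylated genes have the odds of the maternal and stable classes
    multiplied by ``methylation_class_odds`` (then renormalized).
    """
    from .core import EXPRESSION_CLASSES

    rng = _rng(config, _STREAM_CLASSES)
    base = np.asarray(config.expression_class_proportions, dtype=float)
    base = base / base.sum()
    boosted = base * np.array([config.methylation_class_odds] * 2 + [1.0] * 3)
    total = boosted.sum()
    if total == 0:
        raise ValueError("methylation_class_odds=0 with all mass on maternal/stable")
    boosted = boosted / total

    is_meth = np.array([truth.gene_status[g.gene_id] == "methylated" for g in genes])
    draws = np.empty(len(genes), dtype=int)
    draws[is_meth] = rng.choice(5, size=int(is_meth.sum()), p=boosted)
    draws[~is_meth] = rng.choice(5, size=int((~is_meth).sum()), p=base)
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "expression_class": [EXPRESSION_CLASSES[d] for d in draws],
        }
    )
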