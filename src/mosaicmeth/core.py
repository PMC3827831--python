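"""Genome data model, interval algebra, and readers/writers.

All coordinates are 0-based half-open in memory. BED and BedGraph are native
in that convention; GFF3 (1-based, closed) is converted on read and write.

The central containers are

``GenomeLayout``
    named contigs with lengths, optionally flagging one contig as the
    unmethylated control (a mitochondrial-like sequence used to estimate the
    bisulfite non-conversion error rate).
``IntervalSet``
    per-contig sorted, disjoint, non-adjacent half-open intervals — the
    representation for covered regions and methylated domains.  Adjacent
    intervals are merged so every per-base membership pattern has exactly one
    canonical form.
``CoverageTrack``
    run-length encoded read depth per contig.
``GeneModel``
    a transcript span (TSS to poly(A) site) with CDS bounds, strand, and an
    optional expression class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("mosaicmeth")

EXPRESSION_CLASSES = ("maternal", "stable", "embryonic", "embryo_adult", "adult")

__all__ = [
    "EXPRESSION_CLASSES",
    "GenomeLayout",
    "IntervalSet",
    "CoverageTrack",
    "GeneModel",
    "merge_intervals",
    "subtract_intervals",
    "intersect_intervals",
    "overlap_fraction",
    "pileup_coverage",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_gff3",
    "read_expression_classes",
    "write_expression_classes",
]


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered contigs with lengths; optionally one unmethylated control contig."""

    contigs: tuple[tuple[str, int], ...]
    control_contig: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "contigs", tuple((str(n), int(l)) for n, l in self.contigs))
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        if self.control_contig is not None and self.control_contig not in names:
            raise ValueError(f"control_contig {self.control_contig!r} is not a contig")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.contigs)

    def length_of(self, name: str) -> int:
        for n, l in self.contigs:
            if n == name:
                return l
        raise KeyError(name)

    @property
    def total_bp(self) -> int:
        return sum(l for _, l in self.contigs)

    def lengths(self) -> dict[str, int]:
        return dict(self.contigs)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def _as_interval_array(raw: Iterable[Sequence[int]]) -> np.ndarray:
    arr = np.asarray(list(raw), dtype=np.int64)
    if arr.size == 0:
        return arr.reshape(0, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("intervals must be (start, end) pairs")
    return arr


def _canonicalize(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or adjacent half-open intervals."""
    if arr.shape[0] == 0:
        return arr
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    arr = arr[order]
    out_start = [arr[0, 0]]
    out_end = [arr[0, 1]]
    for s, e in arr[1:]:
        if s <= out_end[-1]:  # overlap or exact adjacency -> merge
            if e > out_end[-1]:
                out_end[-1] = e
        else:
            out_start.append(s)
            out_end.append(e)
    return np.column_stack([out_start, out_end]).astype(np.int64)


class IntervalSet:
    """Per-contig sorted disjoint non-adjacent half-open intervals.

    Construct through :func:`merge_intervals` (validating, canonicalizing) or
    :meth:`from_dict` when data is already canonical.
    """

    __slots__ = ("_data",)

    def __init__(self, data: Mapping[str, np.ndarray] | None = None):
        self._data: dict[str, np.ndarray] = {}
        if data:
            for contig, arr in data.items():
                self._data[str(contig)] = _canonicalize(_as_interval_array(arr))

    @classmethod
    def from_dict(cls, data: Mapping[str, np.ndarray]) -> "IntervalSet":
        return cls(data)

    # -- accessors ---------------------------------------------------------

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(sorted(self._data))

    def get(self, contig: str) -> np.ndarray:
        return self._data.get(contig, np.empty((0, 2), dtype=np.int64))

    def items(self):
        for contig in self.contigs:
            yield contig, self._data[contig]

    @property
    def total_bp(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._data.values()))

    def n_intervals(self) -> int:
        return int(sum(a.shape[0] for a in self._data.values()))

    def is_empty(self) -> bool:
        return self.total_bp == 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        keys = set(self._data) | set(other._data)
        return all(np.array_equal(self.get(k), other.get(k)) for k in keys)

    def __repr__(self) -> str:
        return f"IntervalSet({self.n_intervals()} intervals, {self.total_bp} bp, {len(self._data)} contigs)"

    # -- point / range queries --------------------------------------------

    def contains(self, contig: str, positions) -> np.ndarray:
        """Boolean membership for an array of positions on one contig."""
        pos = np.asarray(positions, dtype=np.int64)
        arr = self.get(contig)
        if arr.shape[0] == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(arr[:, 0], pos, side="right") - 1
        ok = idx >= 0
        safe = np.clip(idx, 0, arr.shape[0] - 1)
        return ok & (pos < arr[safe, 1])

    def overlap_bp(self, contig: str, start: int, end: int) -> int:
        arr = self.get(contig)
        if arr.shape[0] == 0:
            return 0
        lo = np.maximum(arr[:, 0], start)
        hi = np.minimum(arr[:, 1], end)
        return int(np.clip(hi - lo, 0, None).sum())

    def enclosing_interval(self, contig: str, pos: int) -> tuple[int, int] | None:
        """The single interval containing ``pos``, or None."""
        arr = self.get(contig)
        if arr.shape[0] == 0:
            return None
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        if i >= 0 and pos < arr[i, 1]:
            return int(arr[i, 0]), int(arr[i, 1])
        return None

    # -- set algebra -------------------------------------------------------

    def _combine(self, other: "IntervalSet", keep) -> "IntervalSet":
        out: dict[str, np.ndarray] = {}
        for contig in set(self._data) | set(other._data):
            a, b = self.get(contig), other.get(contig)
            bounds = np.unique(np.concatenate([a.ravel(), b.ravel()]))
            if bounds.size < 2:
                segs = np.empty((0, 2), dtype=np.int64)
            else:
                starts = bounds[:-1]
                in_a = self.contains(contig, starts)
                in_b = other.contains(contig, starts)
                mask = keep(in_a, in_b)
                segs = np.column_stack([bounds[:-1][mask], bounds[1:][mask]])
            out[contig] = segs
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return self._combine(other, lambda a, b: a | b)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        return self._combine(other, lambda a, b: a & b)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        return self._combine(other, lambda a, b: a & ~b)

    def complement(self, layout: GenomeLayout) -> "IntervalSet":
        """Per-contig complement with respect to a layout (covers every contig)."""
        out: dict[str, np.ndarray] = {}
        for name, length in layout.contigs:
            arr = self.get(name)
            edges = np.concatenate([[0], arr.ravel(), [length]])
            starts, ends = edges[::2], edges[1::2]
            mask = ends > starts
            out[name] = np.column_stack([starts[mask], ends[mask]])
        return IntervalSet(out)

    def clip(self, contig: str, start: int, end: int) -> "IntervalSet":
        """Restrict to a single window."""
        arr = self.get(contig)
        lo = np.maximum(arr[:, 0], start)
        hi = np.minimum(arr[:, 1], end)
        keep = hi > lo
        return IntervalSet({contig: np.column_stack([lo[keep], hi[keep]])})


def merge_intervals(
    raw: Mapping[str, Iterable[Sequence[int]]],
    layout: GenomeLayout | None = None,
) -> IntervalSet:
    """Build a canonical :class:`IntervalSet` from raw per-contig intervals.

    Raises ``ValueError`` naming the first offending record if an interval has
    ``start >= end`` or falls outside its contig (when a layout is given).
    """
    data: dict[str, np.ndarray] = {}
    for contig, ivs in raw.items():
        arr = _as_interval_array(ivs)
        bad = arr[:, 0] >= arr[:, 1]
        if bad.any():
            s, e = arr[bad][0]
            raise ValueError(f"invalid interval on {contig}: [{s}, {e}) has start >= end")
        if layout is not None:
            if contig not in layout.names:
                raise ValueError(f"interval on unknown contig {contig!r}")
            length = layout.length_of(contig)
            oob = (arr[:, 0] < 0) | (arr[:, 1] > length)
            if oob.any():
                s, e = arr[oob][0]
                raise ValueError(
                    f"interval [{s}, {e}) on {contig} outside contig bounds [0, {length})"
                )
        elif (arr[:, 0] < 0).any():
            s, e = arr[arr[:, 0] < 0][0]
            raise ValueError(f"invalid interval on {contig}: [{s}, {e}) has negative start")
        data[contig] = arr
    return IntervalSet(data)


def _require_matching_contigs(a: IntervalSet, b: IntervalSet) -> None:
    extra = [c for c in b.contigs if b.get(c).size and c not in a.contigs]
    if extra:
        raise ValueError(f"contigs present in subtrahend but missing from minuend: {extra}")


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Per-base set difference ``a \\ b``; contigs of ``b`` must exist in ``a``."""
    _require_matching_contigs(a, b)
    return a.subtract(b)


def intersect_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def overlap_fraction(span: tuple[str, int, int], domains: IntervalSet) -> float:
    """Fraction of a half-open span covered by ``domains``."""
    contig, start, end = span
    if end <= start:
        raise ValueError(f"zero-length span [{start}, {end}) on {contig}")
    return domains.overlap_bp(contig, start, end) / (end - start)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------


class CoverageTrack:
    """Run-length encoded read depth: per contig (starts, ends, depths).

    Canonical form stores only depth > 0 runs, sorted, non-overlapping, with
    equal-depth adjacent runs merged.
    """

    __slots__ = ("_data", "layout")

    def __init__(
        self,
        data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]] | None = None,
        layout: GenomeLayout | None = None,
    ):
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.layout = layout
        if data:
            for contig, (s, e, d) in data.items():
                self._data[str(contig)] = _canonical_runs(
                    np.asarray(s, dtype=np.int64),
                    np.asarray(e, dtype=np.int64),
                    np.asarray(d, dtype=np.int64),
                )

    @classmethod
    def from_runs(
        cls,
        runs: Mapping[str, Iterable[Sequence[int]]],
        layout: GenomeLayout | None = None,
    ) -> "CoverageTrack":
        """Build from per-contig (start, end, depth) triples."""
        data = {}
        for contig, triples in runs.items():
            arr = np.asarray(list(triples), dtype=np.int64).reshape(-1, 3)
            data[contig] = (arr[:, 0], arr[:, 1], arr[:, 2])
        return cls(data, layout=layout)

    @property
    def contigs(self) -> tuple[str, ...]:
        return tuple(sorted(self._data))

    def get(self, contig: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        empty = np.empty(0, dtype=np.int64)
        return self._data.get(contig, (empty, empty, empty))

    def depth_at(self, contig: str, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        s, e, d = self.get(contig)
        if s.size == 0:
            return np.zeros(pos.shape, dtype=np.int64)
        idx = np.searchsorted(s, pos, side="right") - 1
        safe = np.clip(idx, 0, s.size - 1)
        hit = (idx >= 0) & (pos < e[safe])
        return np.where(hit, d[safe], 0)

    def total_depth_bp(self) -> int:
        """Sum over bases of depth == sum of read lengths that built the track."""
        return int(sum(((e - s) * d).sum() for s, e, d in self._data.values()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        keys = set(self._data) | set(other._data)
        for k in keys:
            for x, y in zip(self.get(k), other.get(k)):
                if not np.array_equal(x, y):
                    return False
        return True


def _canonical_runs(
    starts: np.ndarray, ends: np.ndarray, depths: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if (depths < 0).any():
        raise ValueError("negative depth in coverage run")
    keep = (depths > 0) & (ends > starts)
    starts, ends, depths = starts[keep], ends[keep], depths[keep]
    order = np.argsort(starts, kind="stable")
    starts, ends, depths = starts[order], ends[order], depths[order]
    if starts.size and (starts[1:] < ends[:-1]).any():
        raise ValueError("overlapping coverage runs")
    if starts.size == 0:
        return starts, ends, depths
    # merge equal-depth adjacent runs
    brk = np.flatnonzero((starts[1:] != ends[:-1]) | (depths[1:] != depths[:-1]))
    seg_start = np.concatenate([[0], brk + 1])
    seg_end = np.concatenate([brk, [starts.size - 1]])
    return starts[seg_start], ends[seg_end], depths[seg_start]


def pileup_coverage(
    reads: Mapping[str, Iterable[Sequence[int]]],
    layout: GenomeLayout,
) -> CoverageTrack:
    """Per-base read depth from mapped-read intervals.

    Reads falling outside their contig (or on unknown contigs) are dropped and
    counted in a single WARNING log line.
    """
    dropped = 0
    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    lengths = layout.lengths()
    for contig, ivs in reads.items():
        arr = _as_interval_array(ivs)
        if contig not in lengths:
            dropped += arr.shape[0]
            continue
        length = lengths[contig]
        ok = (arr[:, 0] >= 0) & (arr[:, 1] <= length) & (arr[:, 0] < arr[:, 1])
        dropped += int((~ok).sum())
        arr = arr[ok]
        if arr.shape[0] == 0:
            continue
        starts = np.sort(arr[:, 0])
        ends = np.sort(arr[:, 1])
        bounds = np.unique(np.concatenate([starts, ends]))
        depth = np.searchsorted(starts, bounds[:-1], side="right") - np.searchsorted(
            ends, bounds[:-1], side="right"
        )
        data[contig] = (bounds[:-1], bounds[1:], depth.astype(np.int64))
    if dropped:
        logger.warning("pileup_coverage: dropped %d read(s) outside contig bounds", dropped)
    for name in lengths:
        data.setdefault(name, (np.empty(0, np.int64),) * 3)
    return CoverageTrack(data, layout=layout)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A transcript unit (TSS to poly(A) site) with CDS bounds.

    ``span_start``/``span_end`` delimit the transcribed region; ``cds_start``/
    ``cds_end`` the first methionine to the termination codon.  The TSS is the
    strand-aware 5' end of the span.
    """

    gene_id: str
    contig: str
    strand: str
    span_start: int
    span_end: int
    cds_start: int
    cds_end: int
    isoform_count: int = 1
    expression_class: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.span_start < self.span_end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        if not (self.span_start <= self.cds_start < self.cds_end <= self.span_end):
            raise ValueError(f"gene {self.gene_id}: CDS not contained in span")
        if self.isoform_count < 1:
            raise ValueError(f"gene {self.gene_id}: isoform_count must be positive")
        if self.expression_class is not None and self.expression_class not in EXPRESSION_CLASSES:
            raise ValueError(
                f"gene {self.gene_id}: unknown expression class {self.expression_class!r}"
            )

    @property
    def tss(self) -> int:
        return self.span_start if self.strand == "+" else self.span_end - 1

    @property
    def polya_site(self) -> int:
        return self.span_end - 1 if self.strand == "+" else self.span_start

    @property
    def span(self) -> tuple[str, int, int]:
        return (self.contig, self.span_start, self.span_end)

    @property
    def length(self) -> int:
        return self.span_end - self.span_start


# ---------------------------------------------------------------------------
# I/O — BED / BedGraph / FASTA / GFF3 / class tables
# ---------------------------------------------------------------------------

_HEADER_PREFIXES = ("#", "track", "browser")


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _HEADER_PREFIXES):
                continue
            yield lineno, line


def read_bed(path) -> IntervalSet:
    """BED3+ file -> IntervalSet (later columns ignored)."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: malformed BED line: {line!r}")
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates: {line!r}") from exc
        raw.setdefault(parts[0], []).append((start, end))
    return merge_intervals(raw)


def write_bed(intervals: IntervalSet, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for contig, arr in intervals.items():
            for s, e in arr:
                fh.write(f"{contig}\t{s}\t{e}\n")


def read_bedgraph(path, layout: GenomeLayout | None = None) -> CoverageTrack:
    runs: dict[str, list[tuple[int, int, int]]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: malformed BedGraph line: {line!r}")
        try:
            runs.setdefault(parts[0], []).append(
                (int(parts[1]), int(parts[2]), int(float(parts[3])))
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed BedGraph line: {line!r}") from exc
    return CoverageTrack.from_runs(runs, layout=layout)


def write_bedgraph(track: CoverageTrack, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for contig in track.contigs:
            s, e, d = track.get(contig)
            for i in range(s.size):
                fh.write(f"{contig}\t{s[i]}\t{e[i]}\t{d[i]}\n")


def read_bed_records(path) -> dict[str, np.ndarray]:
    """BED3 file -> per-contig (n, 2) interval arrays, duplicates preserved.

    Used for mapped-read intervals, where each line is one read and merging
    would destroy the depth signal.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["contig", "start", "end"],
        dtype={"contig": str, "start": np.int64, "end": np.int64},
    )
    return {
        contig: sub[["start", "end"]].to_numpy(dtype=np.int64)
        for contig, sub in df.groupby("contig", sort=True)
    }


def write_bed_records(records: Mapping[str, np.ndarray], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        for contig in sorted(records):
            arr = np.asarray(records[contig], dtype=np.int64)
            arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
            pd.DataFrame({"c": contig, "s": arr[:, 0], "e": arr[:, 1]}).to_csv(
                fh, sep="\t", header=False, index=False
            )


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genes: Sequence[GeneModel], path, header_extra: str | None = None) -> None:
    """Emit gene/mRNA/CDS features, converting to 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if header_extra:
            fh.write(f"# {header_extra}\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.span_start, g.gene_id)):
            attrs = f"ID={g.gene_id};isoforms={g.isoform_count}"
            if g.expression_class:
                attrs += f";expression_class={g.expression_class}"
            fh.write(
                f"{g.contig}\tmosaicmeth\tgene\t{g.span_start + 1}\t{g.span_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.contig}\tmosaicmeth\tmRNA\t{g.span_start + 1}\t{g.span_end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.contig}\tmosaicmeth\tCDS\t{g.cds_start + 1}\t{g.cds_end}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
            )


def _read_gff3_genes(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {feat.id}: unknown strand {feat.strand!r}")
        cds = list(db.children(feat, featuretype="CDS"))
        span_start, span_end = feat.start - 1, feat.end
        if cds:
            cds_start = min(c.start for c in cds) - 1
            cds_end = max(c.end for c in cds)
        else:
            cds_start, cds_end = span_start, span_end
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                strand=feat.strand,
                span_start=span_start,
                span_end=span_end,
                cds_start=cds_start,
                cds_end=cds_end,
                isoform_count=int(feat.attributes.get("isoforms", ["1"])[0]),
                expression_class=(feat.attributes.get("expression_class", [None]) or [None])[0],
            )
        )
    genes.sort(key=lambda g: (g.contig, g.span_start, g.gene_id))
    return genes


def _read_bed12_genes(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 8:
            raise ValueError(f"{path}:{lineno}: BED12 gene line needs >= 8 fields: {line!r}")
        strand = parts[5]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand {strand!r}")
        genes.append(
            GeneModel(
                gene_id=parts[3],
                contig=parts[0],
                strand=strand,
                span_start=int(parts[1]),
                span_end=int(parts[2]),
                cds_start=int(parts[6]),
                cds_end=int(parts[7]),
            )
        )
    genes.sort(key=lambda g: (g.contig, g.span_start, g.gene_id))
    return genes


def read_gene_models(path, format: str = "gff3") -> list[GeneModel]:
    """Read gene models from GFF3 (gene + CDS features) or BED12 (thick = CDS)."""
    if format == "gff3":
        return _read_gff3_genes(path)
    if format == "bed12":
        return _read_bed12_genes(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def read_expression_classes(path) -> dict[str, str]:
    """Two-column TSV gene_id -> expression class (one of the five classes)."""
    out: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: malformed class line: {line!r}")
        gene, cls = parts[0], parts[1]
        if cls not in EXPRESSION_CLASSES:
            raise ValueError(f"{path}:{lineno}: unknown expression class {cls!r}")
        out[gene] = cls
    return out


def write_expression_classes(classes: Mapping[str, str], path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# gene_id\texpression_class\n")
        for gene in sorted(classes):
            fh.write(f"{gene}\t{classes[gene]}\n")
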