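"""CAP-seq covered-region and methylated-domain calling.

CAP-seq enriches unmethylated DNA through the CXXC domain's affinity for
unmethylated CpG, so read coverage in the affinity-purified library marks
unmethylated regions, while the unfractionated input library covers (nearly)
the whole mappable genome.  Covered regions are identified from a depth track
with three parameters:

    H   minimum read depth (height),
    G   maximum gap bridged between qualifying runs,
    L   minimum total span of a merged region, gaps included.

The order of operations is threshold -> gap-merge -> length-filter; bridged
gaps count toward L.  That is the only reading under which the default
parameters H=4, L=90, G=700 are coherent (a 700 bp tolerated gap inside a
region with a 90 bp minimum length).  Methylated domains are the input-covered
regions minus the affinity-covered regions; no further length filter is
applied to the difference.  Both libraries are processed independently with
the same parameters and raw (unnormalized) read depth.

``calibrate_params`` recovers the H/L/G triple that best reproduces a set of
reference unmethylated regions (e.g. bisulfite-validated) inside a
calibration window, scored by the base-pair Jaccard index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import CoverageTrack, IntervalSet, subtract_intervals

__all__ = [
    "DomainCallParams",
    "call_covered_regions",
    "call_methylated_domains",
    "calibrate_params",
    "jaccard_index",
]


@dataclass(frozen=True)
class DomainCallParams:
    """The H/L/G triple of the coverage caller."""

    height: int = 4
    min_length: int = 90
    max_gap: int = 700

    def __post_init__(self) -> None:
        if self.height < 1:
            raise ValueError(f"height (H) must be >= 1, got {self.height}")
        if self.min_length < 1:
            raise ValueError(f"min_length (L) must be >= 1, got {self.min_length}")
        if self.max_gap < 0:
            raise ValueError(f"max_gap (G) must be >= 0, got {self.max_gap}")

    def to_dict(self) -> dict[str, int]:
        return {"height": self.height, "min_length": self.min_length, "max_gap": self.max_gap}

    @classmethod
    def from_dict(cls, d) -> "DomainCallParams":
        return cls(
            height=int(d.get("height", 4)),
            min_length=int(d.get("min_length", 90)),
            max_gap=int(d.get("max_gap", 700)),
        )


def call_covered_regions(track: CoverageTrack, params: DomainCallParams) -> IntervalSet:
    """Maximal depth >= H runs, gap-merged up to G bp, kept if span >= L bp."""
    if not isinstance(params, DomainCallParams):
        params = DomainCallParams.from_dict(params)
    out: dict[str, np.ndarray] = {}
    for contig in track.contigs:
        starts, ends, depths = track.get(contig)
        keep = depths >= params.height
        s, e = starts[keep], ends[keep]
        if s.size == 0:
            out[contig] = np.empty((0, 2), dtype=np.int64)
            continue
        # adjacent qualifying runs are contiguous; bridge gaps <= G
        brk = np.flatnonzero(s[1:] - e[:-1] > params.max_gap)
        seg_first = np.concatenate([[0], brk + 1])
        seg_last = np.concatenate([brk, [s.size - 1]])
        ms, me = s[seg_first], e[seg_last]
        long_enough = (me - ms) >= params.min_length
        out[contig] = np.column_stack([ms[long_enough], me[long_enough]])
    return IntervalSet(out)


def call_methylated_domains(input_covered: IntervalSet, cxxc_covered: IntervalSet) -> IntervalSet:
    """Methylated domains = input-covered regions deprived of affinity coverage."""
    return subtract_intervals(input_covered, cxxc_covered)


def jaccard_index(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard index |a & b| / |a | b| (0 when both are empty)."""
    union = a.union(b).total_bp
    if union == 0:
        return 0.0
    return a.intersect(b).total_bp / union


def calibrate_params(
    cxxc_track: CoverageTrack,
    reference_unmethylated: IntervalSet,
    calibration_window: tuple[str, int, int],
    heights: Sequence[int],
    lengths: Sequence[int],
    gaps: Sequence[int],
) -> tuple[DomainCallParams, float]:
    """Grid-search H/L/G maximizing Jaccard against reference regions in a window.

    Ties are broken toward smaller H, then smaller G, then larger L.  Returns
    (best parameters, best Jaccard).  Raises on an empty grid or a reference
    that is empty within the window.
    """
    if not (len(heights) and len(lengths) and len(gaps)):
        raise ValueError("calibration grid is empty")
    contig, win_start, win_end = calibration_window
    reference = reference_unmethylated.clip(contig, win_start, win_end)
    if reference.is_empty():
        raise ValueError(
            f"reference unmethylated regions are empty within window "
            f"{contig}:{win_start}-{win_end}"
        )
    best: tuple[DomainCallParams, float] | None = None
    # iteration order implements the tie-break: smaller H, then smaller G, then larger L
    for h, g, l in itertools.product(
        sorted(set(heights)), sorted(set(gaps)), sorted(set(lengths), reverse=True)
    ):
        params = DomainCallParams(height=h, min_length=l, max_gap=g)
        called = call_covered_regions(cxxc_track, params).clip(contig, win_start, win_end)
        score = jaccard_index(called, reference)
        if best is None or score > best[1]:
            best = (params, score)
    assert best is not None
    return best
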