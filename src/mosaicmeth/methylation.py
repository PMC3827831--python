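"""Per-cytosine methylation calls from bisulfite-sequencing counts.

Bisulfite treatment converts unmethylated cytosines to uracil (read as T)
while methylated cytosines stay C.  After alignment, each cytosine site i has
a coverage ``X_i`` (reads overlapping the site) and a methylated-evidence
count ``m_i`` (reads in which the base stayed C).  Even a fully unmethylated
site shows occasional C reads because of incomplete conversion, sequencing
error and mismapping; that combined error rate ``e`` is estimated by pooling
counts over an unmethylated control contig (a mitochondrial-like sequence):

    e = sum(m_i) / sum(X_i)   over control sites.

A site is then tested against the null that its methylated reads arise from
error alone: the p-value is the exact upper binomial tail

    P(M >= m | X, e),  M ~ Binomial(X, e)

and sites with p < alpha (default 0.01) are called methylated.  Sites with
X < 2 are left unassessed.  No multiple-testing correction is applied; the
fixed per-site alpha is part of the procedure.

Sequence context is read from the two bases downstream of the cytosine on its
own strand: CG -> CpG, C-H-G -> CHG, C-H-H -> CHH (H = A, C or T).  Strands
are not merged per CpG dyad; every cytosine is its own site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CONTEXTS",
    "CALL_METHYLATED",
    "CALL_UNMETHYLATED",
    "CALL_UNASSESSED",
    "ErrorModel",
    "extract_cytosine_sites",
    "estimate_error_rate",
    "call_site",
    "call_sites",
    "genome_context_summary",
    "read_cytosine_report",
    "write_cytosine_report",
    "write_called_sites",
    "read_called_sites",
]

CONTEXTS = ("CpG", "CHG", "CHH")
CALL_METHYLATED = "methylated"
CALL_UNMETHYLATED = "unmethylated"
CALL_UNASSESSED = "unassessed"

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")


@dataclass(frozen=True)
class ErrorModel:
    """Pooled bisulfite error rate from an unmethylated control contig."""

    error_rate: float
    n_control_sites: int
    n_control_observations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError(
                f"error rate {self.error_rate:.4g} outside [0, 0.5): the control "
                "contig looks methylated, not like an unmethylated control"
            )


# ---------------------------------------------------------------------------
# site extraction
# ---------------------------------------------------------------------------


def extract_cytosine_sites(sequences: Mapping[str, str]) -> pd.DataFrame:
    """All cytosine sites on both strands with their sequence context.

    Every C on the + strand and every G on the + strand (i.e. a C on the
    - strand) is a site.  Context comes from the two downstream bases on the
    site's own strand; sites whose context window leaves the contig or
    contains N are skipped.

    Returns a DataFrame with columns contig, pos (0-based position of the
    C/G on the + strand), strand, context — sorted by contig then pos.
    """
    frames = []
    for contig in sorted(sequences):
        seq = np.frombuffer(sequences[contig].upper().encode("ascii"), dtype=np.uint8)
        n = seq.size
        if n < 2:
            continue
        # pad with N so edge sites fall through the same masks; a CpG needs
        # only its first downstream base, CHG/CHH need both
        padded = np.concatenate([np.full(2, _N, np.uint8), seq, np.full(2, _N, np.uint8)])

        # + strand: C at i, downstream bases seq[i+1], seq[i+2]
        pos = np.flatnonzero(seq == _C)
        b1, b2 = padded[pos + 3], padded[pos + 4]
        h1 = (b1 == _A) | (b1 == _C) | (b1 == _T)
        is_cpg = b1 == _G
        is_chg = h1 & (b2 == _G)
        is_chh = h1 & ((b2 == _A) | (b2 == _C) | (b2 == _T))
        keep = is_cpg | is_chg | is_chh
        ctx = np.where(is_cpg, "CpG", np.where(is_chg, "CHG", "CHH"))[keep]
        frames.append(
            pd.DataFrame({"contig": contig, "pos": pos[keep], "strand": "+", "context": ctx})
        )

        # - strand: G at i; downstream on that strand = complements of seq[i-1], seq[i-2]
        pos = np.flatnonzero(seq == _G)
        b1, b2 = padded[pos + 1], padded[pos]
        h1 = (b1 == _A) | (b1 == _G) | (b1 == _T)  # complement in {T, C, A} = H
        is_cpg = b1 == _C
        is_chg = h1 & (b2 == _C)
        is_chh = h1 & ((b2 == _A) | (b2 == _G) | (b2 == _T))
        keep = is_cpg | is_chg | is_chh
        ctx = np.where(is_cpg, "CpG", np.where(is_chg, "CHG", "CHH"))[keep]
        frames.append(
            pd.DataFrame({"contig": contig, "pos": pos[keep], "strand": "-", "context": ctx})
        )

    if not frames:
        return pd.DataFrame(columns=["contig", "pos", "strand", "context"])
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# error model and binomial test
# ---------------------------------------------------------------------------


def estimate_error_rate(control_sites) -> ErrorModel:
    """Pool (X, m) over control-contig cytosines into a single error rate.

    ``control_sites`` is a DataFrame with columns X and m, or an iterable of
    (X, m) pairs.  Raises on zero total coverage or a pooled rate >= 0.5.
    """
    if isinstance(control_sites, pd.DataFrame):
        X = control_sites["X"].to_numpy(dtype=np.int64)
        m = control_sites["m"].to_numpy(dtype=np.int64)
    else:
        arr = np.asarray(list(control_sites), dtype=np.int64).reshape(-1, 2)
        X, m = arr[:, 0], arr[:, 1]
    if (m > X).any() or (m < 0).any() or (X < 0).any():
        raise ValueError("control sites must satisfy 0 <= m <= X")
    total = int(X.sum())
    if total == 0:
        raise ValueError("control contig has zero total coverage; cannot estimate error rate")
    return ErrorModel(
        error_rate=float(m.sum()) / total,
        n_control_sites=int(X.size),
        n_control_observations=total,
    )


def _binom_upper_tail(m: np.ndarray, X: np.ndarray, p: float) -> np.ndarray:
    """Exact P(M >= m | X, p); 1.0 whenever m == 0."""
    # survival function is P(M > m-1) = P(M >= m)
    return np.where(m <= 0, 1.0, sps.binom.sf(m - 1, X, p))


def call_site(
    X: int, m: int, error_rate: float, alpha: float = 0.01, min_coverage: int = 2
) -> tuple[float | None, str]:
    """Test one cytosine; returns (p_value, call).

    Sites with ``X < min_coverage`` are unassessed and get no p-value.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate {error_rate} outside [0, 1)")
    if not 0 <= m <= X:
        raise ValueError(f"need 0 <= m <= X, got X={X}, m={m}")
    if X < min_coverage:
        return None, CALL_UNASSESSED
    p = float(_binom_upper_tail(np.asarray([m]), np.asarray([X]), error_rate)[0])
    return p, (CALL_METHYLATED if p < alpha else CALL_UNMETHYLATED)


def call_sites(
    sites: pd.DataFrame,
    error_rate: float,
    alpha: float = 0.01,
    min_coverage: int = 2,
) -> pd.DataFrame:
    """Vectorized :func:`call_site` over a (contig, pos, strand, context, X, m) table.

    Adds ``p_value`` (NaN where unassessed) and ``call`` columns.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate {error_rate} outside [0, 1)")
    X = sites["X"].to_numpy(dtype=np.int64)
    m = sites["m"].to_numpy(dtype=np.int64)
    if (m > X).any() or (m < 0).any():
        raise ValueError("sites must satisfy 0 <= m <= X")
    assessed = X >= min_coverage
    p = np.full(X.size, np.nan)
    p[assessed] = _binom_upper_tail(m[assessed], X[assessed], error_rate)
    call = np.full(X.size, CALL_UNASSESSED, dtype=object)
    call[assessed & (p < alpha)] = CALL_METHYLATED
    call[assessed & ~(p < alpha)] = CALL_UNMETHYLATED
    out = sites.copy()
    out["p_value"] = p
    out["call"] = call
    return out


def genome_context_summary(called: pd.DataFrame) -> pd.DataFrame:
    """Per-context assessed count, methylated count, and methylated fraction.

    The fraction is methylated-called / assessed; contexts with zero assessed
    sites report NaN.
    """
    rows = []
    for ctx in CONTEXTS:
        sub = called[called["context"] == ctx]
        assessed = int((sub["call"] != CALL_UNASSESSED).sum())
        meth = int((sub["call"] == CALL_METHYLATED).sum())
        rows.append(
            {
                "context": ctx,
                "assessed": assessed,
                "methylated": meth,
                "fraction": (meth / assessed) if assessed else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ["contig", "pos", "strand", "count_methylated", "count_unmethylated", "context"]


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style genome-wide cytosine report.

    Expected columns: contig, 1-based position, strand, count methylated,
    count unmethylated, context (CG/CpG/CHG/CHH); a seventh trinucleotide
    column, if present, is ignored.  Positions are converted to 0-based and
    counts to the (X, m) parameterization.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str, 2: str, 5: str})
    if df.shape[1] < 6:
        raise ValueError(f"cytosine report {path} needs >= 6 columns, found {df.shape[1]}")
    df = df.iloc[:, :6]
    df.columns = _REPORT_COLUMNS
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"unknown strand {df['strand'][bad].iloc[0]!r} in {path}")
    out = pd.DataFrame(
        {
            "contig": df["contig"],
            "pos": df["pos"].astype(np.int64) - 1,
            "strand": df["strand"],
            "context": df["context"].replace({"CG": "CpG"}),
            "X": (df["count_methylated"] + df["count_unmethylated"]).astype(np.int64),
            "m": df["count_methylated"].astype(np.int64),
        }
    )
    unknown = ~out["context"].isin(CONTEXTS)
    if unknown.any():
        raise ValueError(f"unknown context {out['context'][unknown].iloc[0]!r} in {path}")
    return out.sort_values(["contig", "pos", "strand"], kind="stable").reset_index(drop=True)


def write_cytosine_report(sites: pd.DataFrame, path, header: str | None = None) -> None:
    """Write (contig, pos, strand, context, X, m) as a Bismark-style report (1-based)."""
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        pd.DataFrame(
            {
                "contig": sites["contig"],
                "pos": sites["pos"].astype(np.int64) + 1,
                "strand": sites["strand"],
                "count_methylated": sites["m"].astype(np.int64),
                "count_unmethylated": (sites["X"] - sites["m"]).astype(np.int64),
                "context": sites["context"],
            }
        ).to_csv(fh, sep="\t", header=False, index=False)


_CALLED_COLUMNS = ["contig", "pos", "strand", "context", "X", "m", "p_value", "call"]


def write_called_sites(called: pd.DataFrame, path, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("# " + "\t".join(_CALLED_COLUMNS) + "\n")
        called[_CALLED_COLUMNS].to_csv(fh, sep="\t", header=False, index=False)


def read_called_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=_CALLED_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    return df
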