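"""Cross-tissue concordance and categorical enrichment statistics.

Given per-gene methylation degrees or bimodal classes from two tissues, this
module quantifies agreement three ways:

* the joint binned distribution of degrees over matched genes;
* the Pearson correlation of degrees with an empirical permutation p-value
  (one-sided, gene labels of one tissue permuted, add-one rule
  ``p = (1 + #{r_perm >= r_obs}) / (n_perm + 1)``);
* a 2x2 contingency table of methylated/unmethylated calls with marginals.

Enrichment of expression classes among methylated genes is scored per class
with a two-sided Fisher's exact test on the in-class vs out-of-class by
methylated vs unmethylated table, fold enrichment relative to the overall
methylated fraction, and Bonferroni correction over the classes tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("mosaicmeth")

__all__ = [
    "ContingencyTable2x2",
    "EnrichmentResult",
    "joint_degree_distribution",
    "pearson_r",
    "spearman_r",
    "permutation_test_r",
    "build_contingency",
    "fisher_2x2",
    "class_enrichment",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Gene counts: a = methylated in both tissues, b = A-methylated only,
    c = B-methylated only, d = unmethylated in both."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def methylated_a(self) -> int:  # marginal: methylated in tissue A
        return self.a + self.b

    @property
    def unmethylated_a(self) -> int:
        return self.c + self.d

    @property
    def methylated_b(self) -> int:  # marginal: methylated in tissue B
        return self.a + self.c

    @property
    def unmethylated_b(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def discordant(self) -> int:
        return self.b + self.c

    @property
    def discordant_fraction(self) -> float:
        return self.discordant / self.total if self.total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B_methylated": [self.a, self.c, self.methylated_b],
                "B_unmethylated": [self.b, self.d, self.unmethylated_b],
                "total": [self.methylated_a, self.unmethylated_a, self.total],
            },
            index=["A_methylated", "A_unmethylated", "total"],
        )


@dataclass(frozen=True)
class EnrichmentResult:
    expression_class: str
    n_genes: int
    fold_enrichment: float
    p_raw: float
    p_bonferroni: float


def _matched(degrees_a: Mapping[str, float], degrees_b: Mapping[str, float]):
    genes = sorted(set(degrees_a) & set(degrees_b))
    if not genes:
        raise ValueError("no genes shared between the two degree tables")
    x = np.array([degrees_a[g] for g in genes], dtype=float)
    y = np.array([degrees_b[g] for g in genes], dtype=float)
    return genes, x, y


def joint_degree_distribution(
    degrees_a: Mapping[str, float],
    degrees_b: Mapping[str, float],
    n_bins: int = 10,
) -> np.ndarray:
    """2-D histogram of matched degrees on an ``n_bins`` x ``n_bins`` grid on [0,1]^2."""
    _, x, y = _matched(degrees_a, degrees_b)
    ix = np.minimum((x * n_bins).astype(int), n_bins - 1)
    iy = np.minimum((y * n_bins).astype(int), n_bins - 1)
    grid = np.zeros((n_bins, n_bins), dtype=np.int64)
    np.add.at(grid, (ix, iy), 1)
    return grid


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson_r needs >= 3 matched pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson_r undefined for zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Rank-correlation alternative for non-linear monotone association."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman_r needs >= 3 matched pairs")
    rho = sps.spearmanr(x, y).statistic
    if np.isnan(rho):
        raise ValueError("spearman_r undefined for zero-variance input")
    return float(rho)


def permutation_test_r(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 100_000,
    seed: int | None = None,
    batch: int = 1000,
) -> tuple[float, float]:
    """One-sided permutation test of the Pearson correlation.

    The pairing of ``y`` against ``x`` is permuted ``n_perm`` times; the
    p-value uses the add-one rule, so its floor is ``1 / (n_perm + 1)``.
    Returns (observed r, empirical p).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r_obs = pearson_r(x, y)
    n = x.size
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        k = min(batch, n_perm - done)
        perms = rng.permuted(np.broadcast_to(zy, (k, n)).copy(), axis=1)
        r_perm = perms @ zx / n
        exceed += int((r_perm >= r_obs).sum())
        done += k
    return r_obs, (1 + exceed) / (n_perm + 1)


def build_contingency(
    classes_a: Mapping[str, str], classes_b: Mapping[str, str]
) -> ContingencyTable2x2:
    """Tabulate genes classified methylated/unmethylated in BOTH tissues.

    Intermediate and ineligible genes are excluded before matching.
    """
    keep = {"methylated", "unmethylated"}
    genes = [
        g
        for g in set(classes_a) & set(classes_b)
        if classes_a[g] in keep and classes_b[g] in keep
    ]
    if not genes:
        raise ValueError("no genes classified methylated/unmethylated in both tissues")
    a = b = c = d = 0
    for g in genes:
        ma, mb = classes_a[g] == "methylated", classes_b[g] == "methylated"
        if ma and mb:
            a += 1
        elif ma:
            b += 1
        elif mb:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def fisher_2x2(a: int, b: int, c: int, d: int, sided: str = "two") -> float:
    """Exact hypergeometric test on [[a, b], [c, d]].

    Two-sided p sums the probabilities of all tables (at fixed margins) no
    more probable than the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    alternative = {"two": "two-sided", "greater": "greater", "less": "less"}.get(sided)
    if alternative is None:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def class_enrichment(
    meth_classes: Mapping[str, str],
    expression_classes: Mapping[str, str],
) -> list[EnrichmentResult]:
    """Per-expression-class enrichment among methylated genes.

    Uses genes that are both bimodally classified (methylated/unmethylated)
    and class-annotated.  Fold enrichment is the in-class methylated fraction
    over the overall methylated fraction; p-values are two-sided Fisher with
    Bonferroni correction over the number of classes tested.
    """
    keep = {"methylated", "unmethylated"}
    genes = [
        g
        for g in set(meth_classes) & set(expression_classes)
        if meth_classes[g] in keep
    ]
    if not genes:
        raise ValueError("no genes with both a bimodal methylation class and an expression class")
    total_meth = sum(meth_classes[g] == "methylated" for g in genes)
    total = len(genes)
    classes = sorted({expression_classes[g] for g in genes})
    results: list[EnrichmentResult] = []
    tested = []
    for cls in classes:
        in_cls = [g for g in genes if expression_classes[g] == cls]
        if not in_cls:
            logger.warning("class_enrichment: class %r has no genes; skipped", cls)
            continue
        a = sum(meth_classes[g] == "methylated" for g in in_cls)
        b = len(in_cls) - a
        c = total_meth - a
        d = (total - len(in_cls)) - c
        baseline = total_meth / total
        fold = (a / len(in_cls)) / baseline if baseline > 0 else float("nan")
        tested.append((cls, len(in_cls), fold, fisher_2x2(a, b, c, d)))
    n_tests = len(tested)
    for cls, n_genes, fold, p_raw in tested:
        results.append(
            EnrichmentResult(
                expression_class=cls,
                n_genes=n_genes,
                fold_enrichment=fold,
                p_raw=p_raw,
                p_bonferroni=min(1.0, p_raw * n_tests),
            )
        )
    return results
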