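"""Gene-set overrepresentation statistics with a configurable background.

For each term the 2x2 contingency is: k term members in the mappable gene
list of size n, against K term members in a background universe of size N.
The raw statistic is the hypergeometric right tail (one-sided Fisher exact
test); the default scoring is the conservative EASE variant, which removes
one list hit before testing (tail at k-1 with list size n-1), so singleton
hits carry no evidence.  Multiplicity control is Benjamini-Hochberg by
default.

The default background is the annotation universe — the union of all genes
covered by the supplied term sets — since enrichment against genes that can
never be hit is meaningless.  Fold enrichment is (k/n)/(K/N).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .cohort import TermSet
from .util import pct_half_up

__all__ = [
    "EnrichmentInput",
    "EnrichmentResult",
    "map_to_universe",
    "hypergeom_right_tail",
    "ease_score",
    "bh_adjust",
    "enrich",
]


@dataclass
class EnrichmentInput:
    """A gene list, the term sets to score it against, and options."""

    gene_list: frozenset[str]
    term_sets: Sequence[TermSet]
    background: frozenset[str] | None = None
    ease: bool = True
    min_count: int = 2
    adjust: str = "BH"  # {"BH", "bonferroni", "none"}

    def __post_init__(self) -> None:
        self.gene_list = frozenset(g.upper() for g in self.gene_list)
        if self.background is not None:
            self.background = frozenset(g.upper() for g in self.background)
        if self.adjust not in ("BH", "bonferroni", "none"):
            raise ValueError(f"unknown adjustment {self.adjust!r}")

    def resolved_background(self) -> frozenset[str]:
        if self.background is not None:
            return self.background
        universe: set[str] = set()
        for t in self.term_sets:
            universe.update(t.genes)
        return frozenset(universe)


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # list hits
    n: int  # mappable list size
    K: int  # background hits
    N: int  # background size
    pct: float  # 100*k/n, half-up to two decimals
    fold: float  # (k/n) / (K/N)
    p_raw: float
    p_adjusted: float
    genes: tuple[str, ...] = field(default_factory=tuple)


def map_to_universe(
    gene_list: Iterable[str], background: Iterable[str]
) -> tuple[frozenset[str], frozenset[str]]:
    """Intersect the gene list with the background universe.

    Returns (mappable, unmapped).  Raises if nothing maps, since no
    statistic is then computable.
    """
    genes = frozenset(g.upper() for g in gene_list)
    bg = frozenset(g.upper() for g in background)
    if not bg:
        raise ValueError("background universe is empty")
    mappable = genes & bg
    if not mappable:
        raise ValueError("no input gene maps to the background universe")
    return mappable, genes - bg


def hypergeom_right_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), computed in log space.

    X counts term members among n draws without replacement from a universe
    of N genes of which K belong to the term.  The tail is summed with
    log-gamma binomial terms and logsumexp for numerical stability at large
    N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid configuration n={n}, K={K}, N={N}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k > n or k > K:
        raise ValueError(
            f"impossible configuration: k={k} exceeds n={n} or K={K}"
        )
    if k == 0:
        return 1.0
    i = np.arange(k, min(n, K) + 1)
    log_pmf = (
        gammaln(K + 1)
        - gammaln(i + 1)
        - gammaln(K - i + 1)
        + gammaln(N - K + 1)
        - gammaln(n - i + 1)
        - gammaln(N - K - n + i + 1)
        + gammaln(n + 1)
        + gammaln(N - n + 1)
        - gammaln(N + 1)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """Conservative one-sided Fisher variant: remove one list hit first.

    The removed gene leaves the list (k-1 hits among n-1 genes) while the
    background is unchanged, so a term hit by a single list gene scores 1.0.
    Always >= the plain hypergeometric right tail.
    """
    if k <= 0:
        return 1.0
    return hypergeom_right_tail(k - 1, n - 1, K, N)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m, dtype=float)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def enrich(inp: EnrichmentInput) -> list[EnrichmentResult]:
    """Score every term against the gene list.

    Terms with fewer than ``min_count`` list hits are suppressed (weakly
    supported categories), as are terms with no background members.
    Results are sorted ascending by raw p-value (ties broken by term id).
    """
    background = inp.resolved_background()
    mappable, _unmapped = map_to_universe(inp.gene_list, background)
    n = len(mappable)
    N = len(background)
    results: list[EnrichmentResult] = []
    for term in inp.term_sets:
        term_bg = term.genes & background
        K = len(term_bg)
        hits = term.genes & mappable
        k = len(hits)
        if K == 0 or k < inp.min_count:
            continue
        score = ease_score if inp.ease else hypergeom_right_tail
        p = score(k, n, K, N)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                k=k,
                n=n,
                K=K,
                N=N,
                pct=pct_half_up(k, n, 2),
                fold=(k / n) / (K / N),
                p_raw=p,
                p_adjusted=p,
                genes=tuple(sorted(hits)),
            )
        )
    if results:
        raw = [r.p_raw for r in results]
        if inp.adjust == "BH":
            adjusted = bh_adjust(raw)
        elif inp.adjust == "bonferroni":
            adjusted = np.minimum(np.asarray(raw) * len(raw), 1.0)
        else:
            adjusted = np.asarray(raw)
        for r, p_adj in zip(results, adjusted):
            r.p_adjusted = float(p_adj)
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results
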