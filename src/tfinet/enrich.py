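"""Hypergeometric over-representation of gene sets.

Conventions: the universe N is passed explicitly (never inferred from the
inputs), the test is upper-tail only P(X >= k), and fold enrichment is
observed over expected, k / (n*K/N). Term enrichment applies the three
reporting gates common in GO-style analyses: minimum term size, FDR cap and
minimum fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .stats import bh_fdr


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    N: int  # universe size
    K: int  # term size within the universe
    n: int  # query size within the universe
    k: int  # overlap
    fold: float
    p: float
    padj: float = float("nan")

    def rounded_fold(self) -> str:
        """Fold as reported in summaries, to one decimal."""
        return f"{self.fold:.1f}"


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if not all(int(x) == x and x >= 0 for x in (N, K, n, k)):
        raise ValueError("N, K, n, k must be non-negative integers")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"inconsistent counts N={N} K={K} n={n} k={k}")


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), in log space.

    X counts the overlap when drawing n items without replacement from a
    universe of N containing K marked items.
    """
    _check_bounds(N, K, n, k)
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if support.size == 0:
        return 0.0 if k > 0 else 1.0
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def fold_enrichment(N: int, K: int, n: int, k: int) -> float:
    """Observed/expected overlap: k * N / (n * K)."""
    _check_bounds(N, K, n, k)
    if n == 0 or K == 0:
        return float("nan")
    return k * N / (n * K)


def set_overrepresentation(universe, term_set, query_set,
                           term_id: str = "term") -> EnrichmentResult:
    """Over-representation of ``term_set`` within ``query_set``.

    Both sets are first restricted to the universe; the result depends only
    on the four counts (N, K, n, k).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    term = set(term_set) & universe
    query = set(query_set) & universe
    N, K, n = len(universe), len(term), len(query)
    k = len(term & query)
    fold = fold_enrichment(N, K, n, k) if K and n else float("nan")
    p = hypergeom_tail(N, K, n, k)
    return EnrichmentResult(term_id, N, K, n, k, fold, p)


def localized_sets(expr_table, lfc: float = 1.5) -> dict[str, set[str]]:
    """Spatially localized transcript sets from a four-region expression table.

    ``expr_table`` must carry log2 expression columns ``animal``,
    ``vegetal``, ``dorsal``, ``ventral``. A transcript is e.g. animal when
    log2(animal) - log2(vegetal) > lfc (strictly). Returns the four sets.
    """
    if lfc <= 0:
        raise ValueError("lfc must be positive")
    for col in ("animal", "vegetal", "dorsal", "ventral"):
        if col not in expr_table.columns:
            raise ValueError(f"missing expression column {col!r}")
    av = expr_table["animal"] - expr_table["vegetal"]
    dv = expr_table["dorsal"] - expr_table["ventral"]
    return {
        "animal": set(expr_table.index[av > lfc]),
        "vegetal": set(expr_table.index[-av > lfc]),
        "dorsal": set(expr_table.index[dv > lfc]),
        "ventral": set(expr_table.index[-dv > lfc]),
    }


def term_enrichment(terms: dict[str, tuple[str, frozenset[str]]],
                    query, universe, min_term: int = 10,
                    max_fdr: float = 0.05, min_fold: float = 4.0
                    ) -> list[EnrichmentResult]:
    """GO-style term over-representation with reporting gates.

    Every term is intersected with the universe before sizing and tested;
    BH FDR is computed across all tested terms. Only terms with
    K >= min_term, padj <= max_fdr and fold >= min_fold are returned,
    sorted by p.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    tested = []
    for term_id, (_desc, members) in terms.items():
        res = set_overrepresentation(universe, members, query, term_id=term_id)
        if res.K > 0:
            tested.append(res)
    padj = bh_fdr([r.p for r in tested])
    adjusted = [EnrichmentResult(r.term_id, r.N, r.K, r.n, r.k, r.fold, r.p,
                                 float(q)) for r, q in zip(tested, padj)]
    kept = [r for r in adjusted
            if r.K >= min_term and r.padj <= max_fdr and r.fold >= min_fold]
    return sorted(kept, key=lambda r: (r.p, r.term_id))
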