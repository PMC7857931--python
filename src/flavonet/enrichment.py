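"""Over-representation analysis of a gene set against GO/pathway annotations.

The statistic is the one-sided upper-tail hypergeometric probability of
observing at least ``k`` study genes inside a term of size ``K``, drawing
``n`` genes from a background universe of size ``N``:

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

An optional EASE-style penalty (the conservative variant popularised by the
DAVID service) removes one success before computing the tail, so singleton
overlaps can never reach significance.  The significance flag defaults to the
raw p < alpha criterion; Benjamini-Hochberg adjusted p-values are always
computed and reported alongside, never silently substituted.

The background universe is explicit: it comes from the annotation database,
and study genes missing from it are dropped (and counted), not silently kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from scipy.stats import hypergeom

__all__ = [
    "AnnotationDatabase",
    "EnrichmentResult",
    "hypergeometric_p",
    "benjamini_hochberg",
    "enrich",
    "coverage_ratio",
    "read_gmt_tsv",
    "results_to_tsv",
]

CATEGORIES = ("BP", "CC", "MF", "PATHWAY")


@dataclass(frozen=True)
class AnnotationDatabase:
    """term_id -> (category, name, gene set), plus the background universe."""

    terms: dict[str, tuple[str, str, frozenset[str]]]
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (category, _, genes) in self.terms.items():
            if category not in CATEGORIES:
                raise ValueError(f"unknown category {category!r} for {term_id}")
            if not genes:
                raise ValueError(f"term {term_id} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(f"term {term_id} has genes outside the background")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    category: str
    name: str
    k: int  # study genes in the term
    K: int  # term size
    n: int  # study size (after background filtering)
    N: int  # background size
    p_value: float
    adjusted_p: float = field(default=1.0)
    significant: bool = False

    @property
    def study_ratio(self) -> str:
        return f"{self.k}/{self.n}"


def hypergeometric_p(k: int, K: int, n: int, N: int, ease: bool = False) -> float:
    """Upper-tail P(X >= k); with ``ease=True`` computed at k-1 (floored at 0)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    kk = max(k - 1, 0) if ease else k
    # sf(kk-1) = P(X >= kk)
    return float(min(1.0, hypergeom.sf(kk - 1, N, K, n)))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values (monotone non-decreasing in rank order)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def enrich(
    study_genes: Iterable[str],
    database: AnnotationDatabase,
    alpha: float = 0.05,
    ease: bool = False,
    flag_on: str = "raw",
) -> tuple[list[EnrichmentResult], int]:
    """Per-term enrichment, sorted by (category, p ascending, term_id).

    Returns the results plus the count of study genes dropped for being
    absent from the background.  ``flag_on`` selects whether the
    ``significant`` flag tests the raw p-value (default) or the BH-adjusted
    one (``"adjusted"``).
    """
    if flag_on not in ("raw", "adjusted"):
        raise ValueError("flag_on must be 'raw' or 'adjusted'")
    study = {g.upper() for g in study_genes}
    dropped = len(study - set(database.background))
    study &= set(database.background)
    if not study:
        return [], dropped
    N = len(database.background)
    n = len(study)
    raw: list[EnrichmentResult] = []
    for term_id, (category, name, genes) in sorted(database.terms.items()):
        k = len(study & genes)
        p = hypergeometric_p(k, len(genes), n, N, ease=ease)
        raw.append(EnrichmentResult(term_id, category, name, k, len(genes), n, N, p))
    adjusted = {}
    for category in CATEGORIES:
        cat_results = [r for r in raw if r.category == category]
        for r, adj in zip(cat_results, benjamini_hochberg([r.p_value for r in cat_results])):
            adjusted[r.term_id] = adj
    results = [
        EnrichmentResult(
            r.term_id, r.category, r.name, r.k, r.K, r.n, r.N, r.p_value,
            adjusted[r.term_id],
            (r.p_value if flag_on == "raw" else adjusted[r.term_id]) < alpha,
        )
        for r in raw
    ]
    results.sort(key=lambda r: (r.category, r.p_value, r.term_id))
    return results, dropped


def coverage_ratio(result: EnrichmentResult) -> tuple[str, float]:
    """The "k/n" ratio and its percentage (1 d.p. is the usual print format)."""
    if result.n == 0:
        raise ValueError("study size is zero")
    return f"{result.k}/{result.n}", 100.0 * result.k / result.n


def read_gmt_tsv(path: str | Path) -> AnnotationDatabase:
    """Read a GMT-like TSV: term_id, category, name, gene, gene, ...

    The background is the union of all term genes unless a special row with
    term_id ``BACKGROUND`` enumerates the universe explicitly.
    """
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    explicit: set[str] = set()
    union: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0] == "BACKGROUND":
            explicit.update(g.upper() for g in parts[2:] if g and g != "-")
            continue
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: expected term_id, category, name, genes...")
        genes = frozenset(g.upper() for g in parts[3:] if g)
        terms[parts[0]] = (parts[1], parts[2], genes)
        union.update(genes)
    return AnnotationDatabase(terms, frozenset(explicit or union))


def results_to_tsv(
    results: Sequence[EnrichmentResult],
    path: str | Path,
    header_comment: str | None = None,
) -> None:
    lines = []
    if header_comment:
        lines.append(f"# {header_comment}")
    lines.append("term_id\tcategory\tname\tk\tK\tn\tN\tratio\tp_value\tadjusted_p\tsignificant")
    for r in results:
        lines.append(
            f"{r.term_id}\t{r.category}\t{r.name}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t"
            f"{r.study_ratio}\t{r.p_value:.6g}\t{r.adjusted_p:.6g}\t{int(r.significant)}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
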