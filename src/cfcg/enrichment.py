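"""Hypergeometric over-representation analysis and coverage reporting.

Given a query gene set (e.g. the CFCG's targets) and a GMT annotation,
each term is tested for over-representation with the upper-tail
hypergeometric probability P(X ≥ k) of drawing k annotated genes in a
query of size q from a universe of size U containing m annotated genes.
P-values are Benjamini–Hochberg adjusted by default.  Coverage metrics
compare two enriched-term (or gene) sets by overlap fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import AnnotationTerm

__all__ = [
    "EnrichmentResult",
    "CoverageReport",
    "ora_pvalue",
    "bh_adjust",
    "enrich",
    "coverage_between",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # overlap
    q: int  # query size
    m: int  # term size (within universe)
    universe: int
    pvalue: float
    adj_pvalue: float
    significant: bool
    overlap_genes: tuple[str, ...]


@dataclass(frozen=True)
class CoverageReport:
    n_a: int
    n_b: int
    n_shared: int
    frac_of_a: float  # |A∩B| / |A|
    frac_of_b: float  # |A∩B| / |B|
    a_empty: bool = False
    b_empty: bool = False


def ora_pvalue(k: int, q: int, m: int, universe: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k).

    X counts marked genes in a draw of q from a universe of ``universe``
    genes of which m are marked.  Symmetric in (q, m).
    """
    if not (0 <= k <= min(q, m) and q <= universe and m <= universe):
        raise ValueError(f"inconsistent counts k={k}, q={q}, m={m}, U={universe}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, universe, m, q))


def bh_adjust(pvalues: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjustment, capped at 1."""
    if not pvalues:
        return []
    if any(not (0 <= p <= 1) for p in pvalues):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(pvalues, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    annotation: list[AnnotationTerm],
    universe: Iterable[str] | None = None,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[EnrichmentResult]:
    """ORA of ``query`` against every annotation term.

    The universe defaults to the union of all annotation genes.  Query
    genes outside the universe are dropped (count logged).  Terms with no
    overlap are omitted; results sort by adjusted p, then term id.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    uni = set(universe) if universe is not None else set().union(*(t.genes for t in annotation))
    if not uni:
        raise ValueError("universe is empty")
    qset = set(query)
    dropped = len(qset - uni)
    if dropped:
        log.info("enrich: dropped %d query gene(s) outside the universe", dropped)
    qset &= uni

    hits: list[tuple[AnnotationTerm, set[str], int, float]] = []
    for term in annotation:
        tg = term.genes & uni
        overlap = qset & tg
        if not overlap:
            continue
        p = ora_pvalue(len(overlap), len(qset), len(tg), len(uni))
        hits.append((term, overlap, len(tg), p))
    if not hits:
        return []
    if correction == "bh":
        adj = bh_adjust([h[3] for h in hits])
    elif correction == "bonferroni":
        adj = [min(1.0, h[3] * len(hits)) for h in hits]
    else:
        raise ValueError(f"unknown correction {correction!r}")

    results = [
        EnrichmentResult(
            term_id=term.term_id, term_name=term.term_name,
            k=len(overlap), q=len(qset), m=m, universe=len(uni),
            pvalue=p, adj_pvalue=a, significant=bool(a <= alpha),
            overlap_genes=tuple(sorted(overlap)),
        )
        for (term, overlap, m, p), a in zip(hits, adj)
    ]
    results.sort(key=lambda r: (r.adj_pvalue, r.term_id))
    return results


def coverage_between(set_a: Iterable[str], set_b: Iterable[str]) -> CoverageReport:
    """Overlap fractions between two id sets (terms or genes).

    An empty side yields fraction 0 with its ``*_empty`` flag raised
    rather than a division error.
    """
    a, b = set(set_a), set(set_b)
    shared = a & b
    return CoverageReport(
        n_a=len(a), n_b=len(b), n_shared=len(shared),
        frac_of_a=(len(shared) / len(a)) if a else 0.0,
        frac_of_b=(len(shared) / len(b)) if b else 0.0,
        a_empty=not a, b_empty=not b,
    )
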