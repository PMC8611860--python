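"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list of size n drawn from a background of N genes, a term
annotating M background genes and hit by m query genes gets the upper-tail
probability

    P(X >= m) = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M,n-i) / C(N,n),

computed in log space for numerical stability.  Terms are BH-adjusted
within each category, ranked by fold enrichment (m/n)/(M/N), and the top-k
selector returns the leading terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)

CATEGORIES = ("BP", "CC", "MF", "KEGG", "custom")


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]
    category: str = "custom"

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.term_id!r} has no members")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def read_gmt(path: str | Path, category: str = "custom") -> list[GeneSet]:
    """Parse a GMT file: term <tab> description <tab> member ids.

    Duplicate member ids within a line are de-duplicated; a line with
    fewer than three fields is an error reported with its line number.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            term, desc, *members = fields
            if term in seen:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term!r}")
            seen.add(term)
            sets.append(
                GeneSet(term_id=term, term_name=desc, members=frozenset(members), category=category)
            )
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.term_id, gs.term_name, *sorted(gs.members)]) + "\n")


def _log_hypergeom_pmf(N: int, M: int, n: int, i) -> np.ndarray:
    i = np.asarray(i, dtype=float)
    return (
        gammaln(M + 1) - gammaln(i + 1) - gammaln(M - i + 1)
        + gammaln(N - M + 1) - gammaln(n - i + 1) - gammaln(N - M - (n - i) + 1)
        + gammaln(n + 1) + gammaln(N - n + 1) - gammaln(N + 1)
    )


def hypergeom_p(N: int, M: int, n: int, m: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= m).

    N: background size; M: background genes annotated to the term;
    n: query size; m: query genes annotated to the term.  Computed by
    log-space summation of the pmf over the upper tail, so it stays
    accurate for backgrounds up to ~1e5 genes.
    """
    if not (0 <= m <= n <= N and 0 <= M <= N):
        raise ValueError(f"invalid hypergeometric arguments N={N} M={M} n={n} m={m}")
    if m > M:
        return 0.0
    lo = max(m, n - (N - M))  # support lower bound of the tail
    hi = min(M, n)
    if m <= max(0, n - (N - M)):
        return 1.0  # tail covers the whole support
    i = np.arange(lo, hi + 1)
    return float(min(1.0, np.exp(logsumexp(_log_hypergeom_pmf(N, M, n, i)))))


@dataclass
class EnrichmentResult:
    """Per-term over-representation outcome."""

    term_id: str
    category: str
    N: int
    M: int
    n: int
    m: int
    p_value: float
    enrichment_factor: float
    member_hits: tuple[str, ...]
    q_value: float = field(default=np.nan)


def enrich(
    query,
    gene_sets: list[GeneSet],
    background,
    min_hits: int = 2,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, within ``background``.

    Query ids outside the background are dropped (logged); gene-set members
    are restricted to the background.  Terms with fewer than ``min_hits``
    query hits are excluded.  BH adjustment runs within each category.
    Result rows are sorted by enrichment factor descending, ties by
    ascending p, then term id.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background")
    query = set(query)
    dropped = query - background
    if dropped:
        log.warning("dropping %d query ids outside the background", len(dropped))
    query &= background
    N = len(background)
    n = len(query)
    if n == 0:
        log.warning("query empty after background restriction")
        return _result_frame([])
    results: list[EnrichmentResult] = []
    for gs in gene_sets:
        members = gs.members & background
        M = len(members)
        if M == 0:
            continue
        hits = sorted(query & members)
        m = len(hits)
        if m < min_hits:
            continue
        p = hypergeom_p(N, M, n, m)
        ef = (m / n) / (M / N)
        results.append(
            EnrichmentResult(
                term_id=gs.term_id,
                category=gs.category,
                N=N, M=M, n=n, m=m,
                p_value=p,
                enrichment_factor=ef,
                member_hits=tuple(hits),
            )
        )
    for cat in {r.category for r in results}:
        in_cat = [r for r in results if r.category == cat]
        qs = bh_adjust([r.p_value for r in in_cat])
        for r, q in zip(in_cat, qs):
            r.q_value = float(q)
    results.sort(key=lambda r: (-r.enrichment_factor, r.p_value, r.term_id))
    return _result_frame(results)


def _result_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "category", "N", "M", "n", "m", "p_value", "q_value",
            "enrichment_factor", "member_hits"]
    if not results:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame([{
        "term_id": r.term_id, "category": r.category, "N": r.N, "M": r.M,
        "n": r.n, "m": r.m, "p_value": r.p_value, "q_value": r.q_value,
        "enrichment_factor": r.enrichment_factor,
        "member_hits": ",".join(r.member_hits),
    } for r in results])
    return df[cols]


def top_terms(results: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Leading ``k`` terms by the enrichment-factor ranking."""
    return results.head(k)
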