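"""Set overlap statistics: Venn partitioning, hypergeometric overlap
significance, and generic term over-representation analysis.

The overlap p-value is the cumulative (upper-tail, inclusive) hypergeometric
probability P(X >= k) of seeing at least the observed intersection when two
sets of the given sizes are drawn from a finite universe; the same tail
probability drives term enrichment, with Benjamini-Hochberg adjustment
across the tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneSet

__all__ = [
    "OverlapResult",
    "hypergeometric_overlap",
    "venn_partition",
    "enrich_terms",
]


@dataclass
class OverlapResult:
    set_a_size: int
    set_b_size: int
    overlap_k: int
    universe_n: int
    p_value: float

    def __post_init__(self) -> None:
        if self.overlap_k > min(self.set_a_size, self.set_b_size):
            raise ValueError("overlap larger than the smaller set")
        if max(self.set_a_size, self.set_b_size) > self.universe_n:
            raise ValueError("set larger than the universe")


def _ids(s) -> frozenset:
    if isinstance(s, GeneSet):
        return s.ids
    return frozenset(s)


def hypergeometric_upper_tail(k: int, universe_n: int, size_a: int, size_b: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(universe_n, size_a, size_b), inclusive."""
    return float(stats.hypergeom.sf(k - 1, universe_n, size_a, size_b))


def hypergeometric_overlap(a, b, universe_n: int) -> OverlapResult:
    """Significance of the overlap between two sets from one universe.

    ``a`` and ``b`` may be :class:`GeneSet` or plain id collections. The
    p-value is the inclusive upper tail P(X >= |a ∩ b|).
    """
    ids_a, ids_b = _ids(a), _ids(b)
    if universe_n < max(len(ids_a), len(ids_b)):
        raise ValueError("universe smaller than a set")
    k = len(ids_a & ids_b)
    return OverlapResult(
        set_a_size=len(ids_a),
        set_b_size=len(ids_b),
        overlap_k=k,
        universe_n=universe_n,
        p_value=hypergeometric_upper_tail(k, universe_n, len(ids_a), len(ids_b)),
    )


def venn_partition(sets: dict[str, object] | list) -> dict[tuple[str, ...], int]:
    """Exhaustive disjoint region counts for 2 or 3 sets.

    Returns a mapping from the tuple of set names whose exclusive region a
    count belongs to (e.g. ("A",), ("A", "B")) to the number of elements in
    that region. Region counts are disjoint and sum to the union size.
    """
    if isinstance(sets, dict):
        named = {name: _ids(s) for name, s in sets.items()}
    else:
        named = {}
        for i, s in enumerate(sets):
            name = s.name if isinstance(s, GeneSet) else f"set_{i}"
            named[name] = _ids(s)
    if not (2 <= len(named) <= 3):
        raise ValueError("venn_partition supports 2 or 3 sets")
    names = list(named)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(set(named[n]) for n in inside))
            for n in names:
                if n not in inside:
                    region -= named[n]
            regions[inside] = len(region)
    return regions


def enrich_terms(
    query,
    annotation: dict[str, object],
    universe_n: int,
    bh: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a query set.

    ``annotation`` maps term_id -> member ids (all within the universe).
    Returns one row per term (term_id, term_size, hits_k, p_value and, when
    ``bh`` is set, q_value) sorted by ascending p then term_id.
    """
    if not annotation:
        raise ValueError("annotation is empty")
    q_ids = _ids(query)
    if universe_n < len(q_ids):
        raise ValueError("universe smaller than the query")
    rows = []
    for term_id in sorted(annotation):
        members = _ids(annotation[term_id])
        if len(members) > universe_n:
            raise ValueError(f"term {term_id!r} larger than the universe")
        k = len(members & q_ids)
        rows.append(
            {
                "term_id": term_id,
                "term_size": len(members),
                "hits_k": k,
                "p_value": hypergeometric_upper_tail(
                    k, universe_n, len(members), len(q_ids)
                ),
            }
        )
    out = pd.DataFrame(rows)
    if bh:
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values(["p_value", "term_id"]).reset_index(drop=True)
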