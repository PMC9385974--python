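"""Hypergeometric over-representation analysis against GMT collections.

This is a transparent local stand-in for web enrichment services: a one-sided
hypergeometric tail per term, Benjamini-Hochberg adjustment across tested
terms, and a TSV report. The background universe defaults to the union of all
term members and can be overridden with the measured-gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .gene_sets import GeneSet, normalize_symbol, read_gmt_rows


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    members: frozenset


@dataclass
class AnnotationCollection:
    """A list of annotation terms plus a background universe."""

    terms: list
    universe: frozenset

    def __post_init__(self):
        if not self.universe:
            raise DataError("annotation universe is empty")
        for t in self.terms:
            if not (t.members & self.universe):
                raise DataError(f"term {t.term_id} has no member in the universe")

    @classmethod
    def from_gmt(cls, path, universe: Iterable[str] | None = None
                 ) -> "AnnotationCollection":
        terms = []
        for name, desc, members in read_gmt_rows(path):
            norm = frozenset(normalize_symbol(m) for m in members)
            terms.append(Term(term_id=name, name=desc or name, members=norm))
        if universe is None:
            uni = frozenset().union(*(t.members for t in terms)) if terms else frozenset()
        else:
            uni = frozenset(normalize_symbol(g) for g in universe)
        return cls(terms=terms, universe=uni)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when drawing ``n`` items from an urn of ``N`` with
    ``K`` marked. Validates 0 <= k <= min(K, n), K <= N, n <= N.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise DataError(f"k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    # survival function at k-1 gives P(X >= k); scipy evaluates in log-space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def run_ora(query: GeneSet, collection: AnnotationCollection,
            min_overlap: int = 2) -> pd.DataFrame:
    """Over-representation analysis of a query gene set.

    Tests each term with overlap >= ``min_overlap`` against the collection's
    universe; BH adjustment is across the tested terms. Rows are sorted by
    p-value ascending, ties broken by term id.
    """
    effective = set(query.symbols) & collection.universe
    if not effective:
        warnings.warn("query has no genes in the annotation universe; "
                      "empty enrichment result", stacklevel=2)
        return _empty_frame()
    n = len(effective)
    N = len(collection.universe)
    records = []
    for term in collection.terms:
        members = term.members & collection.universe
        overlap = sorted(effective & members)
        k = len(overlap)
        if k < min_overlap:
            continue
        p = hypergeometric_tail(k, len(members), n, N)
        records.append({
            "term_id": term.term_id,
            "term_name": term.name,
            "k": k,
            "K": len(members),
            "n": n,
            "N": N,
            "p_value": p,
            "genes": ",".join(overlap),
        })
    if not records:
        return _empty_frame()
    df = pd.DataFrame.from_records(records)
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    df = df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return df[["term_id", "term_name", "k", "K", "n", "N",
               "p_value", "fdr", "genes"]]


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["term_id", "term_name", "k", "K", "n", "N",
                                 "p_value", "fdr", "genes"])


def write_ora_tsv(result: pd.DataFrame, path) -> None:
    result.to_csv(Path(path), sep="\t", index=False)
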