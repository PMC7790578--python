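"""Hypergeometric over-representation analysis (ORA) with BH correction.

Given a query gene list and a collection of annotation terms (GO-like or
pathway-like, read from GMT), each term is scored by the upper-tail
hypergeometric probability of drawing at least the observed number of
term genes when sampling the query from the universe, then adjusted for
multiple testing with the Benjamini-Hochberg step-up rule.

The universe defaults to the union of all term genes — a common tool
default — but since the background changes every p-value it can (and for
real analyses should) be supplied explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ParseError
from .targets import GeneSet, normalize_symbol

__all__ = [
    "AnnotationCollection",
    "read_gmt",
    "hypergeom_tail",
    "bh_adjust",
    "ora",
]


@dataclass(frozen=True)
class AnnotationCollection:
    """Annotation terms plus the background universe.

    ``terms`` maps term_id -> (description, gene frozenset); every term's
    genes are a subset of ``universe``.
    """

    terms: Mapping[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"term {term_id!r} has genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(
    path: str | Path, universe: GeneSet | None = None
) -> AnnotationCollection:
    """Read a GMT file (``term_id <tab> description <tab> gene1 ...``).

    The universe defaults to the union of all term genes unless an
    explicit gene set is supplied. Duplicate term ids and lines with
    fewer than three fields are rejected with the line number.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}: line {line_no}: GMT lines need term, "
                    "description and at least one gene"
                )
            term_id = parts[0].strip()
            if term_id in terms:
                raise ParseError(
                    f"{path}: line {line_no}: duplicate term id {term_id!r}"
                )
            genes = frozenset(
                normalize_symbol(g) for g in parts[2:] if g.strip()
            )
            terms[term_id] = (parts[1].strip(), genes)
    if universe is not None:
        uni = frozenset(universe.genes)
    else:
        uni = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    return AnnotationCollection(terms=terms, universe=uni)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the term size, ``n`` the query size
    and ``k`` the observed overlap. Computed through the survival
    function, which is numerically stable for extreme tails.
    """
    for name, val in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(val) != val or val < 0:
            raise DomainError(f"{name} must be a non-negative integer, got {val}")
    if K > N or n > N:
        raise DomainError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise DomainError(f"k={k} exceeds min(K={K}, n={n})")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    ``q_(i) = min over j >= i of m * p_(j) / j`` on the sorted p-values,
    clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def ora(
    query: GeneSet,
    collection: AnnotationCollection,
    p_cut: float = 0.05,
    q_cut: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of a query gene set against every term.

    The query is first restricted to the universe. One row is produced
    per term with at least one query hit, sorted by p ascending with ties
    by term_id; terms with ``p <= p_cut`` and ``q <= q_cut`` are flagged
    significant. BH adjustment uses all tested terms (every term with a
    hit) as the family.

    Raises
    ------
    DomainError
        If the query shares no genes with the universe — an empty
        effective query is an error, not an empty result.
    """
    eff = query.genes & collection.universe
    if not eff:
        raise DomainError("query has no genes in the annotation universe")
    N = len(collection.universe)
    n = len(eff)
    rows = []
    for term_id, (desc, genes) in collection.terms.items():
        k = len(eff & genes)
        if k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "description": desc,
                "k": k,
                "K": len(genes),
                "n": n,
                "N": N,
                "p": hypergeom_tail(k, len(genes), n, N),
            }
        )
    df = pd.DataFrame(
        rows, columns=["term_id", "description", "k", "K", "n", "N", "p"]
    )
    if not df.empty:
        df = df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
        df["q"] = bh_adjust(df["p"].tolist())
        df["significant"] = (df["p"] <= p_cut) & (df["q"] <= q_cut)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
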