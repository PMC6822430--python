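"""Annotation-set overrepresentation for the top-scoring kinases.

Given the selected top-K kinase set and user-supplied annotation collections
(KEGG-like pathways, Reactome-like pathways, keyword sets in GMT format),
each term is tested for overrepresentation with the one-sided hypergeometric
upper tail against a fixed kinase universe, and reported as -log10(p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnnotationCollection", "read_gmt", "overrepresentation"]


@dataclass(frozen=True)
class AnnotationCollection:
    """Term -> kinase-set annotations over a fixed kinase universe."""

    terms: Mapping[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = {t: frozenset(s) for t, s in dict(self.terms).items()}
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "universe", frozenset(self.universe))
        if not self.universe:
            raise ValueError("empty universe")
        for t, s in terms.items():
            if not s:
                raise ValueError(f"term {t!r} is empty")
            stray = s - self.universe
            if stray:
                raise ValueError(
                    f"term {t!r} annotates kinases outside the universe: {sorted(stray)[:5]}"
                )


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> AnnotationCollection:
    """Read GMT lines ``term_id <tab> description <tab> member ...``.

    If ``universe`` is omitted it defaults to the union of all term members;
    passing the kinase-map universe is usually the better background.
    Members outside an explicit universe are dropped from the term.
    """
    terms: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    uni = frozenset(universe) if universe is not None else None
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        term, desc, members = parts[0], parts[1], parts[2:]
        kept = frozenset(m for m in members if m) if uni is None else frozenset(
            m for m in members if m and m in uni
        )
        if kept:
            terms[term] = kept
            descriptions[term] = desc
    if uni is None:
        uni = frozenset().union(*terms.values()) if terms else frozenset()
    return AnnotationCollection(terms=terms, universe=uni, descriptions=descriptions)


def overrepresentation(
    top_set: Iterable[str],
    annotations: AnnotationCollection,
    fdr: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric overrepresentation of each annotation term.

    For a term with ``K`` annotated kinases in a universe of size ``N`` and a
    selected set of size ``n`` overlapping the term in ``k`` kinases, the
    p-value is ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``, and the reported
    score is ``-log10(p)``.  Terms are sorted by descending score (ties by
    term id).  ``fdr=True`` adds a Benjamini-Hochberg column; the default
    reports raw p-values only.
    """
    top = frozenset(top_set)
    stray = top - annotations.universe
    if stray:
        raise ValueError(f"top set not contained in universe: {sorted(stray)[:5]}")
    N = len(annotations.universe)
    n = len(top)
    if n > N:
        raise ValueError("top set larger than universe")
    rows = []
    for term in sorted(annotations.terms):
        members = annotations.terms[term]
        K = len(members)
        k = len(top & members)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append((term, k, K, N, p, -np.log10(p)))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "overlap", "term_size", "universe_size", "p", "neg_log10_p"],
    )
    if fdr:
        out["p_bh"] = stats.false_discovery_control(out["p"], method="bh")
    out = out.sort_values(
        by=["neg_log10_p", "term_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out
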