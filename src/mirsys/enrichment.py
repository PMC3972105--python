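"""Offline over-representation analysis against GMT annotation sets.

For a query gene set of size n drawn from a background universe of size N,
a term with K member genes (after intersection with the background) is
scored by the hypergeometric upper tail p = P(X >= k) where k is the number
of query genes in the term.  Benjamini-Hochberg adjusted values are
computed over all testable terms (K >= 1) and carried alongside, but the
default significance filter uses the unadjusted p < alpha, which is the
common practice of the enrichment web services this module replaces
offline; the adjusted mode sits behind a flag.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Set

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationSets

ENRICHMENT_COLUMNS = ["term", "description", "k", "K", "n", "N",
                      "p_value", "adjusted_p"]


def enrich(query: Iterable[str], sets: AnnotationSets,
           background: Iterable[str]) -> pd.DataFrame:
    """One row per term hit by the query (k >= 1), sorted by p ascending.

    The query must be contained in the background; every term is first
    intersected with the background.  BH adjustment is computed over all
    terms with K >= 1 (including those the query misses) so the family is
    not conditioned on the observed hits.
    """
    query = set(query)
    background = set(background)
    outside = sorted(query - background)
    if outside:
        raise ValueError(f"query genes outside the background: {outside}")
    n = len(query)
    N = len(background)

    rows = []
    for term in sorted(sets):
        gs = sets[term]
        members = gs.genes & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, gs.description, k, K, n, N, min(1.0, p)))
    frame = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(frame):
        frame["adjusted_p"] = multipletests(frame["p_value"],
                                            method="fdr_bh")[1]
    else:
        frame["adjusted_p"] = pd.Series(dtype=float)
    frame = frame[frame["k"] >= 1]
    frame = frame.sort_values(["p_value", "term"]).reset_index(drop=True)
    return frame


def significant_terms(rows: pd.DataFrame, alpha: float = 0.05,
                      use_adjusted: bool = False) -> pd.DataFrame:
    """Rows with (adjusted) p below alpha, order preserved."""
    col = "adjusted_p" if use_adjusted else "p_value"
    return rows[rows[col] < alpha].reset_index(drop=True)


def mirs_for_top_terms(rows: pd.DataFrame, sets: AnnotationSets,
                       mir_to_genes: Dict[str, Set[str]],
                       top_n: int = 20) -> List[str]:
    """miRs whose (filtered) targets hit the union of the top-n terms.

    ``rows`` must already be sorted by p (as :func:`enrich` returns);
    ``mir_to_genes`` maps each candidate miR to its filtered target genes.
    """
    top = rows.head(top_n)
    union: Set[str] = set()
    for term in top["term"]:
        union |= set(sets[term].genes)
    return sorted(m for m, genes in mir_to_genes.items()
                  if set(genes) & union)
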