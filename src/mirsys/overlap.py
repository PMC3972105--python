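"""Overlap of the differentially expressed set with a curated disease list.

The significance of the intersection is a hypergeometric upper tail:
drawing |DE| miRs from a background universe containing |known| curated
names, the p-value is P(X >= observed overlap).  The DE set is then split
into Group 1 (DE and curated — previously disease-linked) and Group 2 (DE
only — candidate novel disease miRs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Set, Tuple

from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    n_de: int
    n_known: int
    n_overlap: int
    background: int
    p_value: float
    group1: List[str]
    group2: List[str]

    def to_dict(self) -> dict:
        return {
            "n_de": self.n_de, "n_known": self.n_known,
            "n_overlap": self.n_overlap, "background": self.background,
            "p_value": self.p_value,
            "group1": list(self.group1), "group2": list(self.group2),
        }


def partition_groups(de: Iterable[str],
                     known: Iterable[str]) -> Tuple[List[str], List[str]]:
    """Split DE names into (group1 = DE ∩ known, group2 = DE \\ known).

    Exact and exhaustive: the two groups are disjoint and cover DE.
    Output order is deterministic (sorted).
    """
    de_set, known_set = set(de), set(known)
    group1 = sorted(de_set & known_set)
    group2 = sorted(de_set - known_set)
    return group1, group2


def overlap_significance(de: Iterable[str], known: Iterable[str],
                         background: int) -> OverlapResult:
    """Hypergeometric upper-tail significance of the DE/known intersection.

    ``background`` is the size of the miR universe (e.g. probes assayed);
    it must cover the union of both sets.  Curated entries absent from the
    assayed universe still count toward n_known (they simply cannot
    contribute overlap); this is logged when detectable.
    """
    de_set, known_set = set(de), set(known)
    union = de_set | known_set
    if background < len(union):
        raise ValueError(
            f"background {background} smaller than |DE ∪ known| = {len(union)}"
        )
    group1, group2 = partition_groups(de_set, known_set)
    n_overlap = len(group1)
    only_known = known_set - de_set
    if only_known:
        logger.info("%d curated names outside the DE set (kept in n_known)",
                    len(only_known))
    # P(X >= n_overlap), X ~ Hypergeom(N=background, K=n_known, n=n_de)
    p = float(hypergeom.sf(n_overlap - 1, background, len(known_set),
                           len(de_set)))
    return OverlapResult(
        n_de=len(de_set), n_known=len(known_set), n_overlap=n_overlap,
        background=background, p_value=min(1.0, max(0.0, p)),
        group1=group1, group2=group2,
    )
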