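"""Consensus and confidence filtering of predicted miR->gene targets.

A (miR, gene) pair is a consensus target when it is predicted by at least
``required_predictors`` distinct prediction servers; the record kept for a
consensus pair carries the score of the designated consensus predictor
(DIANA-style miTG score by default — the other predictors only vote
membership).  High-reliability targets have a consensus score of at least
20 (boundary inclusive), and each miR's network contribution is capped at
its top-k targets by score (ties broken by gene name).
"""

from __future__ import annotations

from typing import Iterable, Set

import pandas as pd

CONSENSUS_PREDICTOR = "diana"
DEFAULT_MIN_SCORE = 20.0
DEFAULT_TOP_K = 10


def consensus_targets(table: pd.DataFrame, required_predictors: int = 3,
                      consensus_predictor: str = CONSENSUS_PREDICTOR) -> pd.DataFrame:
    """Keep (miR, gene) pairs predicted by >= required distinct predictors.

    The retained record is the consensus predictor's record for the pair
    (falling back to the pair's highest-score record when that predictor is
    absent), so each surviving pair appears exactly once.
    """
    n_distinct = table["predictor"].nunique()
    if required_predictors > n_distinct:
        raise ValueError(
            f"required_predictors={required_predictors} exceeds the "
            f"{n_distinct} distinct predictors present"
        )
    votes = table.groupby(["miR", "gene"])["predictor"].nunique()
    keep_pairs = set(votes[votes >= required_predictors].index)
    in_kept = pd.Series([(m, g) in keep_pairs for m, g in
                         zip(table["miR"], table["gene"])],
                        index=table.index, dtype=bool)
    kept = table[in_kept].reset_index(drop=True)
    preferred = kept[kept["predictor"] == consensus_predictor]
    have = set(zip(preferred["miR"], preferred["gene"]))
    mask = pd.Series([(m, g) not in have for m, g in
                      zip(kept["miR"], kept["gene"])],
                     index=kept.index, dtype=bool)
    fallback = kept[mask]
    fallback = (fallback.sort_values(["miR", "gene", "score"],
                                     ascending=[True, True, False])
                .drop_duplicates(["miR", "gene"], keep="first"))
    out = pd.concat([preferred, fallback], ignore_index=True)
    return (out.sort_values(["miR", "gene"]).reset_index(drop=True)
            [["miR", "gene", "predictor", "score"]])


def filter_by_score(table: pd.DataFrame,
                    min_score: float = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Keep records with score >= min_score (inclusive boundary)."""
    return table[table["score"] >= min_score].reset_index(drop=True)


def top_k_targets(table: pd.DataFrame, k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Per miR, the k highest-score records; ties by gene name ascending.

    miRs with fewer than k records keep them all, so per-miR out-degree
    never exceeds k.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    ordered = table.sort_values(["miR", "score", "gene"],
                                ascending=[True, False, True],
                                kind="stable")
    return ordered.groupby("miR", group_keys=False).head(k).reset_index(drop=True)


def unique_target_genes(mirs: Iterable[str], table: pd.DataFrame) -> Set[str]:
    """Union of genes targeted by the given miRs in the (filtered) table."""
    mirs = set(mirs)
    return set(table.loc[table["miR"].isin(mirs), "gene"])
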