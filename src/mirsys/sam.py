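"""Two-class Significance Analysis of Microarrays (SAM).

The per-miR statistic is d = r / (s + s0), where r is the disease-minus-
control mean difference of log2 ratios, s is the pooled standard error of
that difference,

    s = sqrt((1/n1 + 1/n2) * (SS_1 + SS_2) / (n1 + n2 - 2)),

and s0 is an exchangeability constant chosen to minimize the coefficient of
variation of d across the range of s (evaluated over candidate percentiles
of the s distribution, with the median absolute deviation of d inside
s-quantile windows playing the role of the spread estimate).

False discovery rates come from label permutations: for a symmetric
threshold Delta on the gap between each ordered d and the permutation-
averaged order statistic, the estimated FDR is the median permuted
exceedance count over the observed call count, and Delta is tuned to the
largest call set whose estimate stays at or below the target (no pi0
correction is applied, which errs conservative).  When the number of
distinct label assignments is small enough the permutation null is
enumerated exhaustively, removing all randomness.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .io import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_S0_PERCENTILES = tuple(np.round(np.linspace(0.0, 1.0, 21), 3))

MAX_MISSING_FRACTION = 0.2  # probes with more missing data sit out the test


@dataclass
class SamParams:
    """Tuning knobs for the permutation test."""

    n_permutations: int = 1000
    fdr_target: float = 0.003
    seed: int = 0
    s0_percentiles: Sequence[float] = DEFAULT_S0_PERCENTILES

    def validate(self) -> None:
        if not (0.0 < self.fdr_target < 1.0):
            raise ValueError(f"fdr_target must lie in (0, 1), "
                             f"got {self.fdr_target}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be at least 1")


@dataclass
class SamResult:
    """Per-miR statistics plus the fitted s0 and the tuned threshold.

    ``table`` is indexed by probe with columns d, r, s, q, called,
    direction, usable.  ``perm_d`` keeps the permuted statistics (probes x
    permutations) for auditing; ``exhaustive`` records whether the label
    permutations were enumerated rather than sampled.
    """

    table: pd.DataFrame
    s0: float
    delta: float
    cutup: float
    cutlo: float
    fdr_target: float
    n_permutations: int
    exhaustive: bool
    perm_d: Optional[np.ndarray] = None

    @property
    def n_called(self) -> int:
        return int(self.table["called"].sum())


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def _group_stats(values: np.ndarray, masks: np.ndarray, s0: float):
    """d, r, s for every probe under every disease-label mask.

    values: probes x samples (NaN = missing); masks: B x samples boolean
    (True = disease).  Returns three (probes x B) arrays.
    """
    finite = np.isfinite(values)
    xz = np.where(finite, values, 0.0)
    x2 = xz * xz
    m1 = masks.T.astype(float)
    m2 = (~masks).T.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        c1 = finite @ m1
        c2 = finite @ m2
        s1 = xz @ m1
        s2 = xz @ m2
        mean1 = s1 / c1
        mean2 = s2 / c2
        ss1 = np.clip(x2 @ m1 - s1 * s1 / c1, 0.0, None)
        ss2 = np.clip(x2 @ m2 - s2 * s2 / c2, 0.0, None)
        r = mean1 - mean2
        dof = c1 + c2 - 2.0
        s = np.sqrt((1.0 / c1 + 1.0 / c2) * (ss1 + ss2) / dof)
        d = r / (s + s0)
    bad = (c1 < 2) | (c2 < 2)
    for arr in (d, r, s):
        arr[bad] = np.nan
    return d, r, s


def _disease_mask(dataset: ExpressionDataset) -> np.ndarray:
    return (dataset.groups.values == "disease")


def sam_statistic(dataset: ExpressionDataset, s0: float) -> pd.DataFrame:
    """Per-miR (d, r, s) under the true labels.

    Probes with fewer than two usable values in either group are flagged
    ``usable=False`` (their statistics are NaN) and are excluded from
    calling downstream.
    """
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    values = dataset.values.to_numpy(dtype=float)
    mask = _disease_mask(dataset)[None, :]
    d, r, s = _group_stats(values, mask, s0)
    out = pd.DataFrame({
        "d": d[:, 0], "r": r[:, 0], "s": s[:, 0],
    }, index=dataset.values.index)
    out["usable"] = np.isfinite(out["d"])
    return out


# ---------------------------------------------------------------------------
# s0 tuning
# ---------------------------------------------------------------------------

def choose_s0(dataset: ExpressionDataset,
              s0_percentiles: Sequence[float] = DEFAULT_S0_PERCENTILES,
              n_windows: int = 100) -> float:
    """Fit the exchangeability constant by minimizing the CV of d over s.

    Candidates are the given percentiles of the s distribution; for each,
    the spread of d (median absolute deviation) is computed inside
    s-quantile windows and the coefficient of variation of those spreads is
    the objective.  Ties go to the smallest candidate.  With fewer than 20
    usable probes the median of s is returned with a warning.
    """
    stats = sam_statistic(dataset, 0.0)
    usable = stats["usable"]
    s = stats.loc[usable, "s"].to_numpy()
    r = stats.loc[usable, "r"].to_numpy()
    if usable.sum() < 20:
        logger.warning("only %d usable probes; s0 falls back to median(s)",
                       int(usable.sum()))
        return float(np.median(s)) if s.size else 0.0

    candidates = np.quantile(s, np.asarray(sorted(s0_percentiles)))
    if s.max() == s.min():
        windows = [np.arange(s.size)]
    else:
        n_bins = min(n_windows, s.size)
        ranks = pd.qcut(pd.Series(s).rank(method="first"), n_bins,
                        labels=False, duplicates="drop").to_numpy()
        windows = [np.flatnonzero(ranks == b) for b in np.unique(ranks)]

    best_cv = math.inf
    best = float(candidates[0])
    for cand in candidates:
        d = r / (s + cand)
        mads = np.array([
            median_abs_deviation(d[w], scale="normal") for w in windows
        ])
        mean_mad = mads.mean()
        if mean_mad == 0 or len(mads) < 2:
            cv = 0.0
        else:
            cv = mads.std(ddof=1) / mean_mad
        if cv < best_cv:  # strict: ties keep the smaller candidate
            best_cv = cv
            best = float(cand)
    return best


# ---------------------------------------------------------------------------
# permutation FDR
# ---------------------------------------------------------------------------

def _permutation_masks(labels: np.ndarray, params: SamParams):
    """Disease-label masks for the permutation null.

    Exhaustive over all distinct assignments when their number does not
    exceed ``n_permutations`` (result then independent of the seed);
    otherwise a seeded sample of label shuffles.
    """
    n = labels.size
    n1 = int(labels.sum())
    n_distinct = math.comb(n, n1)
    if n_distinct <= params.n_permutations:
        masks = np.zeros((n_distinct, n), dtype=bool)
        for b, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[b, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(params.seed)
    masks = np.zeros((params.n_permutations, n), dtype=bool)
    for b in range(params.n_permutations):
        masks[b, rng.permutation(n)[:n1]] = True
    return masks, False


def _estimate_fdr(d_obs: np.ndarray, perm_d: np.ndarray,
                  cutup: float, cutlo: float) -> Tuple[int, float]:
    """Observed call count and median-permutation FDR for a (cutlo, cutup)."""
    n_called = int(np.sum(d_obs >= cutup) + np.sum(d_obs <= cutlo))
    if n_called == 0:
        return 0, 0.0
    exceed = np.sum(perm_d >= cutup, axis=0) + np.sum(perm_d <= cutlo, axis=0)
    return n_called, float(np.median(exceed)) / n_called


def permutation_fdr(dataset: ExpressionDataset,
                    params: SamParams = SamParams()) -> SamResult:
    """Run the full SAM procedure: s0 fit, permutation null, Delta tuning.

    Probes with more than 20% missing values, or fewer than two usable
    values in a group, are excluded before fitting.  If no Delta achieves
    the target FDR the call set is empty (logged).
    """
    params.validate()
    values_all = dataset.values.to_numpy(dtype=float)
    missing_frac = np.mean(~np.isfinite(values_all), axis=1)
    too_missing = missing_frac > MAX_MISSING_FRACTION
    if too_missing.any():
        logger.warning("%d probes exceed %.0f%% missing values; excluded",
                       int(too_missing.sum()), 100 * MAX_MISSING_FRACTION)

    base = sam_statistic(dataset, 0.0)
    usable = base["usable"].to_numpy() & ~too_missing
    sub = ExpressionDataset(dataset.values.loc[usable], dataset.groups.copy())
    s0 = choose_s0(sub, params.s0_percentiles)

    stats = sam_statistic(dataset, s0)
    stats.loc[~usable, ["d", "r", "s"]] = np.nan
    stats["usable"] = usable
    d_obs = stats.loc[usable, "d"].to_numpy()

    labels = _disease_mask(dataset)
    masks, exhaustive = _permutation_masks(labels, params)
    perm_d, _, _ = _group_stats(values_all[usable], masks, s0)

    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]
    dbar = np.sort(perm_d, axis=0).mean(axis=1)
    gap = d_sorted - dbar

    candidates = np.unique(np.abs(gap))
    best = None  # (n_called, delta, cutup, cutlo, fdr)
    for delta in candidates:
        pos = gap >= delta
        neg = -gap >= delta
        cutup = float(d_sorted[pos].min()) if pos.any() else math.inf
        cutlo = float(d_sorted[neg].max()) if neg.any() else -math.inf
        if cutlo >= cutup:  # degenerate overlap; call everything at Delta=0
            cutlo = -math.inf if cutup < math.inf else cutlo
        n_called, fdr = _estimate_fdr(d_obs, perm_d, cutup, cutlo)
        if fdr <= params.fdr_target and n_called > 0:
            if (best is None or n_called > best[0]
                    or (n_called == best[0] and delta > best[1])):
                best = (n_called, float(delta), cutup, cutlo, fdr)

    if best is None:
        logger.info("no Delta achieves FDR <= %g; empty call set",
                    params.fdr_target)
        delta, cutup, cutlo = math.inf, math.inf, -math.inf
    else:
        _, delta, cutup, cutlo, _ = best

    called = np.zeros(len(stats), dtype=bool)
    dvals = stats["d"].to_numpy()
    with np.errstate(invalid="ignore"):
        called[usable] = (dvals[usable] >= cutup) | (dvals[usable] <= cutlo)
    stats["called"] = called
    stats["direction"] = np.where(np.isfinite(dvals) & (dvals >= 0),
                                  "up", "down")
    stats.loc[~usable, "direction"] = ""

    # per-probe q: smallest estimated FDR over thresholds that call it
    fdr_at = np.full(candidates.size, np.nan)
    for i, delta_i in enumerate(candidates):
        pos = gap >= delta_i
        neg = -gap >= delta_i
        cu = float(d_sorted[pos].min()) if pos.any() else math.inf
        cl = float(d_sorted[neg].max()) if neg.any() else -math.inf
        n_c, f = _estimate_fdr(d_obs, perm_d, cu, cl)
        fdr_at[i] = f if n_c > 0 else 0.0
    prefix_min = np.minimum.accumulate(fdr_at) if candidates.size else fdr_at
    gap_by_probe = np.empty_like(d_obs)
    gap_by_probe[order] = np.abs(gap)
    q = np.full(len(stats), np.nan)
    if candidates.size:
        pos_idx = np.searchsorted(candidates, gap_by_probe, side="right") - 1
        pos_idx = np.clip(pos_idx, 0, candidates.size - 1)
        q[usable] = prefix_min[pos_idx]
    stats["q"] = q

    return SamResult(
        table=stats[["d", "r", "s", "q", "called", "direction", "usable"]],
        s0=float(s0), delta=float(delta), cutup=cutup, cutlo=cutlo,
        fdr_target=params.fdr_target, n_permutations=masks.shape[0],
        exhaustive=exhaustive, perm_d=perm_d,
    )


def select_de(result: SamResult) -> list[str]:
    """Called miRs, sorted by |d| descending (name breaks ties)."""
    tab = result.table
    called = tab.loc[tab["called"]]
    order = sorted(called.index, key=lambda m: (-abs(called.loc[m, "d"]), m))
    return list(order)
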