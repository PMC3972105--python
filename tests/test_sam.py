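"""SAM statistic, s0 tuning and permutation FDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from brute import sam_d
from conftest import make_dataset
from mirsys.sam import (SamParams, choose_s0, permutation_fdr, sam_statistic,
                        select_de)
from mirsys.synth import SimConfig, generate_expression


def test_statistic_matches_hand_computation(tiny_dataset):
    stats = sam_statistic(tiny_dataset, s0=0.0)
    row = stats.loc["hsa-mir-t000"]
    # disease {3,4,5}, control {1,2,3}: r=2, s=sqrt((1/3+1/3)*4/4)=sqrt(2/3)
    assert row["r"] == pytest.approx(2.0)
    assert row["s"] == pytest.approx(math.sqrt(2 / 3))
    assert row["d"] == pytest.approx(2 / math.sqrt(2 / 3))
    d, r, s = sam_d([3, 4, 5], [1, 2, 3], 0.0)
    assert row["d"] == pytest.approx(d)


def test_equal_groups_give_zero_statistic():
    ds = make_dataset([[1, 2, 3, 1, 2, 3]], n_disease=3)
    stats = sam_statistic(ds, s0=0.5)
    assert stats.loc[stats.index[0], "r"] == pytest.approx(0.0)
    assert stats.loc[stats.index[0], "d"] == pytest.approx(0.0)


def test_scale_equivariance():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(30, 10))
    a = sam_statistic(make_dataset(values), s0=0.0)
    b = sam_statistic(make_dataset(values * 10), s0=0.0)
    np.testing.assert_allclose(b["r"], a["r"] * 10)
    np.testing.assert_allclose(b["s"], a["s"] * 10)
    np.testing.assert_allclose(b["d"], a["d"])


def test_random_rows_match_oracle():
    rng = np.random.default_rng(1)
    values = rng.normal(size=(25, 9))
    ds = make_dataset(values, n_disease=5)
    stats = sam_statistic(ds, s0=0.3)
    for i, probe in enumerate(ds.probe_names):
        d, r, s = sam_d(list(values[i, :5]), list(values[i, 5:]), 0.3)
        assert stats.loc[probe, "d"] == pytest.approx(d)


def test_insufficient_group_values_flagged_unusable():
    values = np.ones((1, 6))
    values[0, :2] = [1.0, np.nan]  # one usable disease value only
    ds = make_dataset(values, n_disease=2)
    stats = sam_statistic(ds, s0=0.0)
    assert not stats["usable"].iloc[0]


# --- s0 tuning -------------------------------------------------------------

def test_choose_s0_degenerate_all_equal_rows():
    values = np.tile([1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 5.0], (25, 1))
    ds = make_dataset(values, n_disease=4)
    s0 = choose_s0(ds, s0_percentiles=(0.0, 0.5, 1.0))
    # every candidate gives CV 0; tie goes to the smallest candidate,
    # and all s_i are equal so every quantile is that common value
    stats = sam_statistic(ds, 0.0)
    assert s0 == pytest.approx(stats["s"].iloc[0])


def test_choose_s0_positive_for_heteroskedastic_data():
    rng = np.random.default_rng(2)
    n = 200
    values = np.empty((n, 12))
    for i in range(n):
        sd = 0.01 if i < n // 2 else 1.0
        shift = rng.choice([-0.5, 0.5]) if i < n // 2 else 0.0
        values[i] = rng.normal(scale=sd, size=12)
        values[i, :6] += shift
    ds = make_dataset(values, n_disease=6)
    assert choose_s0(ds) > 0.0


def test_choose_s0_scale_equivariance():
    rng = np.random.default_rng(3)
    values = rng.normal(size=(60, 10)) * np.linspace(0.1, 2, 60)[:, None]
    a = choose_s0(make_dataset(values))
    b = choose_s0(make_dataset(values * 2))
    assert b == pytest.approx(2 * a)


def test_choose_s0_small_data_falls_back_to_median():
    rng = np.random.default_rng(4)
    values = rng.normal(size=(5, 8))
    ds = make_dataset(values)
    stats = sam_statistic(ds, 0.0)
    assert choose_s0(ds) == pytest.approx(float(np.median(stats["s"])))


# --- permutation FDR -------------------------------------------------------

def test_exhaustive_mode_on_2v2_matches_enumeration():
    values = np.array([[5.0, 6.0, 1.0, 2.0],
                       [0.1, -0.2, 0.3, 0.0],
                       [2.0, 1.0, 2.5, 1.5]])
    ds = make_dataset(values, n_disease=2)
    res1 = permutation_fdr(ds, SamParams(n_permutations=100, seed=1,
                                         fdr_target=0.5))
    res2 = permutation_fdr(ds, SamParams(n_permutations=100, seed=99,
                                         fdr_target=0.5))
    assert res1.exhaustive and res2.exhaustive
    assert res1.n_permutations == math.comb(4, 2) == 6
    # exhaustiveness removes all randomness
    pd.testing.assert_frame_equal(res1.table, res2.table)
    # permuted statistics match an independent enumeration of labelings
    expected = set()
    for idx in itertools.combinations(range(4), 2):
        dis = [values[0][j] for j in idx]
        ctl = [values[0][j] for j in range(4) if j not in idx]
        expected.add(round(sam_d(dis, ctl, res1.s0)[0], 9))
    got = {round(x, 9) for x in res1.perm_d[0, :]}
    assert got == expected


def test_lower_fdr_target_never_enlarges_call_set():
    cfg = SimConfig(n_probes=120, n_de=12, seed=11, block_sizes=())
    ds, _ = generate_expression(cfg)
    sizes = []
    for target in (0.2, 0.05, 0.01, 0.003):
        res = permutation_fdr(ds, SamParams(n_permutations=200, seed=0,
                                            fdr_target=target))
        sizes.append(res.n_called)
    assert sizes == sorted(sizes, reverse=True)


def test_planted_upregulation_called_up():
    cfg = SimConfig(n_probes=300, n_de=30, de_effect=2.0, noise_sd=1.0,
                    seed=21, block_sizes=())
    ds, truth = generate_expression(cfg)
    res = permutation_fdr(ds, SamParams(n_permutations=300, seed=0))
    de = select_de(res)
    assert len(de) > 0
    directions = res.table.loc[de, "direction"]
    assert (directions == "up").all()
    # recovery of the planted set is substantial at this effect size
    assert len(set(de) & truth.de_mirs) / 30 >= 0.8


def test_select_de_sorted_by_abs_d():
    cfg = SimConfig(n_probes=150, n_de=15, seed=5, block_sizes=())
    ds, _ = generate_expression(cfg)
    res = permutation_fdr(ds, SamParams(n_permutations=200, seed=0))
    de = select_de(res)
    mags = [abs(res.table.loc[m, "d"]) for m in de]
    assert mags == sorted(mags, reverse=True)
    assert set(de) == set(res.table.index[res.table["called"]])


def test_mostly_missing_probe_excluded():
    rng = np.random.default_rng(6)
    values = rng.normal(size=(30, 10))
    values[0, :4] = np.nan  # 40% missing
    ds = make_dataset(values)
    res = permutation_fdr(ds, SamParams(n_permutations=50, seed=0))
    assert not res.table["usable"].iloc[0]
    assert not res.table["called"].iloc[0]
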