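"""Synthetic-input generator: determinism, planted structure, validation."""

import numpy as np
import pandas as pd
import pytest

from mirsys.synth import (ConfigError, SimConfig, generate_annotations,
                          generate_expression, generate_known_list,
                          generate_regulation_tables, simulate, write_inputs)
from mirsys.targets import consensus_targets, filter_by_score, top_k_targets


def test_same_seed_is_bit_identical():
    cfg = SimConfig(n_probes=50, n_de=5, seed=7, block_sizes=(5,))
    a, _ = generate_expression(cfg)
    b, _ = generate_expression(cfg)
    assert a.values.equals(b.values)
    bundle1 = simulate(cfg)
    bundle2 = simulate(cfg)
    assert bundle1.tf_table.equals(bundle2.tf_table)
    assert bundle1.target_table.equals(bundle2.target_table)
    assert bundle1.known_list == bundle2.known_list
    assert set(bundle1.annotations) == set(bundle2.annotations)
    for term in bundle1.annotations:
        assert bundle1.annotations[term].genes == bundle2.annotations[term].genes


def test_different_seed_differs():
    a, _ = generate_expression(SimConfig(n_probes=50, seed=1))
    b, _ = generate_expression(SimConfig(n_probes=50, seed=2))
    assert not a.values.equals(b.values)


def test_null_model_has_no_planted_signal():
    cfg = SimConfig(n_probes=200, n_de=0, block_sizes=(), seed=3)
    ds, truth = generate_expression(cfg)
    assert truth.de_mirs == frozenset()
    dis = ds.values[ds.samples_in_group("disease")].mean(axis=1)
    ctl = ds.values[ds.samples_in_group("control")].mean(axis=1)
    # group difference is pure noise: mean contrast near 0 at noise scale
    contrast = (dis - ctl).mean()
    se = cfg.noise_sd * np.sqrt(1 / 19 + 1 / 13) / np.sqrt(200)
    assert abs(contrast) < 5 * se


def test_planted_effect_recovered_within_3_se():
    cfg = SimConfig(n_probes=300, n_de=30, de_effect=2.0, noise_sd=1.0,
                    block_sizes=(), seed=1)
    ds, truth = generate_expression(cfg)
    de = sorted(truth.de_mirs)
    dis = ds.values.loc[de, ds.samples_in_group("disease")].mean(axis=1)
    ctl = ds.values.loc[de, ds.samples_in_group("control")].mean(axis=1)
    observed = (dis - ctl).mean()
    # SE of the mean of 30 independent normal contrasts
    se = cfg.noise_sd * np.sqrt(1 / 19 + 1 / 13) / np.sqrt(30)
    assert abs(observed - 2.0) <= 3 * se


def test_block_members_share_latent_factor():
    cfg = SimConfig(n_probes=100, n_de=0, block_sizes=(20,), block_rho=0.95,
                    n_disease=50, n_control=50, seed=5)
    ds, truth = generate_expression(cfg)
    members = [m for m, b in truth.block_assignments.items() if b == 0]
    assert len(members) == 20
    corr = ds.values.loc[members].T.corr().to_numpy()
    off = corr[np.triu_indices(20, 1)]
    # expected pairwise correlation is rho; generous band for n=100 samples
    assert abs(off.mean() - 0.95) < 0.05


def test_regulation_tables_structure():
    cfg = SimConfig(n_probes=20, n_de=5, targets_per_mir=12, seed=2,
                    tf_per_mir_range=(2, 6), block_sizes=())
    _, truth = generate_expression(cfg)
    tf_table, target_table = generate_regulation_tables(cfg, truth)
    per_mir_tfs = tf_table.groupby("miR")["TF"].nunique()
    assert per_mir_tfs.between(2, 6).all()
    # every miR appears under all predictors for its primary targets
    filtered = top_k_targets(filter_by_score(
        consensus_targets(target_table, 3)), 10)
    counts = filtered.groupby("miR").size()
    assert set(counts.index) == set(truth.probe_names)
    assert (counts == 10).all()  # 12 targets, 1 sub-threshold, top-10 kept


def test_tf_range_zero_gives_no_regulators():
    cfg = SimConfig(n_probes=10, n_de=2, tf_per_mir_range=(0, 0), seed=2,
                    block_sizes=())
    _, truth = generate_expression(cfg)
    tf_table, _ = generate_regulation_tables(cfg, truth)
    assert len(tf_table) == 0


def test_decoys_fail_consensus():
    cfg = SimConfig(n_probes=10, n_de=2, decoy_fraction=0.5, seed=4,
                    block_sizes=())
    _, truth = generate_expression(cfg)
    _, target_table = generate_regulation_tables(cfg, truth)
    votes = target_table.groupby(["miR", "gene"])["predictor"].nunique()
    assert (votes < 3).any()  # decoys present
    kept = consensus_targets(target_table, 3)
    kept_votes = kept.merge(votes.rename("votes"), on=["miR", "gene"])
    assert (kept_votes["votes"] >= 3).all()


def test_no_decoys_keeps_everything():
    cfg = SimConfig(n_probes=8, n_de=0, decoy_fraction=0.0, seed=4,
                    block_sizes=())
    _, truth = generate_expression(cfg)
    _, table = generate_regulation_tables(cfg, truth)
    kept = consensus_targets(table, 3)
    assert len(kept) == table[["miR", "gene"]].drop_duplicates().shape[0]


@pytest.mark.parametrize("overlap,expected", [(0.0, 0), (0.5, 15), (1.0, 30)])
def test_known_list_overlap_counts(overlap, expected):
    cfg = SimConfig(n_probes=300, n_de=30, known_list_overlap=overlap,
                    seed=6, block_sizes=())
    _, truth = generate_expression(cfg)
    known = generate_known_list(cfg, truth)
    assert len(known) == len(set(known))
    assert len(set(known) & truth.de_mirs) == expected
    assert len(known) == cfg.known_list_size


def test_annotations_contain_planted_term_and_no_empty_sets():
    cfg = SimConfig(n_probes=30, n_de=10, seed=8, block_sizes=())
    _, truth = generate_expression(cfg)
    _, target_table = generate_regulation_tables(cfg, truth)
    sets = generate_annotations(cfg, truth, target_table)
    assert truth.enriched_terms
    for term in truth.enriched_terms:
        assert term in sets
    assert all(len(gs.genes) > 0 for gs in sets.values())


@pytest.mark.parametrize("field,value", [
    ("n_de", 500), ("block_rho", 1.0), ("block_rho", -0.1),
    ("known_list_overlap", 1.5), ("noise_sd", -1.0),
    ("tf_per_mir_range", (5, 2)), ("n_predictors", 0),
])
def test_invalid_config_names_field(field, value):
    cfg = SimConfig(**{field: value})
    with pytest.raises(ConfigError) as err:
        cfg.validate()
    assert field.split("_")[0] in str(err.value)


def test_write_inputs_round_trip(tmp_path):
    from mirsys.io import (read_expression, read_gmt, read_target_table,
                           read_tf_table)
    cfg = SimConfig(n_probes=20, n_de=5, seed=9, block_sizes=(5,))
    bundle = simulate(cfg)
    paths = write_inputs(bundle, tmp_path)
    ds = read_expression(paths["expression"], paths["metadata"])
    pd.testing.assert_frame_equal(ds.values, bundle.dataset.values,
                                  check_exact=False, atol=1e-9)
    assert read_tf_table(paths["tf_table"]).equals(bundle.tf_table)
    tt = read_target_table(paths["target_table"])
    assert len(tt) == len(bundle.target_table)
    gmt = read_gmt(paths["annotations"])
    assert set(gmt) == set(bundle.annotations)
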