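"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the full input bundle of a two-channel miR microarray
study: a log2(Hy3/Hy5) expression matrix over a disease and a control group
(default 19 vs 13 samples) with a planted set of upregulated miRs and planted
high-correlation miR blocks; a TF->miR regulation table; a miR->gene target
table scored under several predictors (with decoy records that fail the
consensus rule and a few sub-threshold scores so the filters have work to
do); a curated known-disease miR list overlapping the planted set; and GMT
annotation sets with terms enriched for the planted miRs' targets.

Correlated blocks use a single latent factor per block,
``x = sqrt(rho) * f + sqrt(1 - rho) * eps``, so the expected pairwise
correlation within a block is exactly ``rho``.  The disease effect is
additive on the log2-ratio scale and disease-only (all planted miRs
upregulated).  One global seed feeds independent per-generator streams, so
adding a generator never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (AnnotationSets, ExpressionDataset, GeneSet, write_expression,
                 write_gmt, write_target_table, write_tf_table)

PREDICTOR_NAMES = ("diana", "miranda", "targetscan")

_STREAMS = {"expression": 0, "regulation": 1, "known": 2, "annotation": 3}


class ConfigError(ValueError):
    """A SimConfig field violated its constraint; message names the field."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic input bundle.

    Defaults mirror the emulated study: 19 disease vs 13 control samples,
    a planted upregulated subset (log2 shift ``de_effect`` in disease only),
    one correlated block of 20 miRs at rho = 0.95, three target predictors
    and a 73-entry curated known list covering half of the planted miRs.
    """

    n_probes: int = 300
    n_disease: int = 19
    n_control: int = 13
    n_de: int = 30
    de_effect: float = 2.0
    noise_sd: float = 1.0
    block_sizes: Sequence[int] = (20,)
    block_rho: float = 0.95
    n_tfs: int = 40
    tf_per_mir_range: Tuple[int, int] = (0, 14)
    n_genes: int = 600
    targets_per_mir: int = 12
    n_predictors: int = 3
    score_range: Tuple[float, float] = (20.0, 40.0)
    known_list_overlap: float = 0.5
    known_list_size: int = 73
    decoy_fraction: float = 0.3
    low_score_per_mir: int = 1
    n_annotation_terms: int = 40
    n_planted_terms: int = 2
    term_size_range: Tuple[int, int] = (10, 40)
    seed: int = 0

    def validate(self) -> None:
        counts = ("n_probes", "n_disease", "n_control", "n_de", "n_tfs",
                  "n_genes", "targets_per_mir", "n_predictors",
                  "known_list_size", "low_score_per_mir",
                  "n_annotation_terms", "n_planted_terms")
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigError(f"{name} must be a non-negative integer, "
                                  f"got {v!r}")
        if self.n_de > self.n_probes:
            raise ConfigError("n_de exceeds n_probes")
        if sum(self.block_sizes) > self.n_probes:
            raise ConfigError("block_sizes sum exceeds n_probes")
        if any(b < 0 for b in self.block_sizes):
            raise ConfigError("block_sizes entries must be non-negative")
        if not (0.0 <= self.block_rho < 1.0):
            raise ConfigError(f"block_rho must lie in [0, 1), "
                              f"got {self.block_rho}")
        if not (0.0 <= self.known_list_overlap <= 1.0):
            raise ConfigError(f"known_list_overlap must lie in [0, 1], "
                              f"got {self.known_list_overlap}")
        if not (0.0 <= self.decoy_fraction <= 1.0):
            raise ConfigError("decoy_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        lo, hi = self.tf_per_mir_range
        if lo < 0 or hi < lo:
            raise ConfigError("tf_per_mir_range must be 0 <= lo <= hi")
        if hi > self.n_tfs:
            raise ConfigError("tf_per_mir_range upper bound exceeds n_tfs")
        if self.targets_per_mir > self.n_genes:
            raise ConfigError("targets_per_mir exceeds n_genes")
        if self.n_predictors < 1:
            raise ConfigError("n_predictors must be at least 1")
        if self.score_range[1] < self.score_range[0]:
            raise ConfigError("score_range must be (lo, hi) with lo <= hi")
        if self.low_score_per_mir > self.targets_per_mir:
            raise ConfigError("low_score_per_mir exceeds targets_per_mir")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Oracle record of what was planted (for recovery tests)."""

    de_mirs: frozenset
    block_assignments: Dict[str, int]
    probe_names: Tuple[str, ...]
    enriched_terms: Tuple[str, ...] = ()


def _probe_names(n: int) -> List[str]:
    return [f"hsa-mir-sim{i:04d}" for i in range(1, n + 1)]


def generate_expression(config: SimConfig) -> Tuple[ExpressionDataset, GroundTruth]:
    """Simulate the log2-ratio matrix and the planted ground truth.

    Planted DE rows receive an additive ``de_effect`` in disease samples;
    block members share a latent factor giving expected pairwise correlation
    ``block_rho``.  Blocks are drawn from the planted DE rows first so the
    downstream co-expression stage (which runs on the DE set) sees them.
    Bit-identical under a fixed seed.
    """
    config.validate()
    rng = config.rng("expression")
    probes = _probe_names(config.n_probes)
    samples = ([f"PD_{i:02d}" for i in range(1, config.n_disease + 1)]
               + [f"CT_{i:02d}" for i in range(1, config.n_control + 1)])
    n_samples = config.n_disease + config.n_control

    de_idx = np.sort(rng.choice(config.n_probes, size=config.n_de,
                                replace=False))
    # block members: planted DE rows first, then the remaining rows
    pool = list(de_idx) + [i for i in range(config.n_probes)
                           if i not in set(de_idx)]
    block_assignments: Dict[str, int] = {}
    cursor = 0
    block_members: List[List[int]] = []
    for b, size in enumerate(config.block_sizes):
        members = pool[cursor:cursor + size]
        cursor += size
        block_members.append(members)
        for i in members:
            block_assignments[probes[i]] = b

    eps = rng.standard_normal((config.n_probes, n_samples))
    values = config.noise_sd * eps
    rho = config.block_rho
    for members in block_members:
        f = rng.standard_normal(n_samples)
        values[members, :] = config.noise_sd * (
            np.sqrt(rho) * f[None, :]
            + np.sqrt(1.0 - rho) * eps[members, :]
        )
    values[de_idx[:, None], np.arange(config.n_disease)[None, :]] += config.de_effect

    frame = pd.DataFrame(values, index=probes, columns=samples)
    groups = pd.Series(["disease"] * config.n_disease
                       + ["control"] * config.n_control, index=samples)
    truth = GroundTruth(
        de_mirs=frozenset(probes[i] for i in de_idx),
        block_assignments=block_assignments,
        probe_names=tuple(probes),
    )
    return ExpressionDataset(frame, groups), truth


def _predictor_names(n: int) -> List[str]:
    names = list(PREDICTOR_NAMES[:n])
    names += [f"pred{i}" for i in range(len(names) + 1, n + 1)]
    return names


def generate_regulation_tables(config: SimConfig,
                               truth: GroundTruth) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the TF->miR table and the scored miR->gene target table.

    Every miR draws a TF count in ``tf_per_mir_range`` and
    ``targets_per_mir`` genes listed under all predictors;
    ``low_score_per_mir`` of those get a consensus (first-predictor) score
    below 20 so the reliability filter is exercised, and a ``decoy_fraction``
    of extra pairs appear under fewer than ``n_predictors`` predictors so the
    consensus filter is exercised.  Deterministic under the config seed.
    """
    config.validate()
    rng = config.rng("regulation")
    tfs = [f"TF{i:03d}" for i in range(1, config.n_tfs + 1)]
    genes = [f"GENE{i:05d}" for i in range(1, config.n_genes + 1)]
    predictors = _predictor_names(config.n_predictors)
    lo, hi = config.tf_per_mir_range
    slo, shi = config.score_range

    tf_records = []
    target_records = []
    n_decoys = int(round(config.decoy_fraction * config.targets_per_mir))
    for mir in truth.probe_names:
        m = int(rng.integers(lo, hi + 1))
        for tf_i in sorted(rng.choice(config.n_tfs, size=m, replace=False)):
            effect = "Activation" if rng.random() < 0.5 else "Repression"
            tf_records.append((tfs[tf_i], mir, effect))

        gene_idx = rng.choice(config.n_genes, size=config.targets_per_mir,
                              replace=False)
        for j, g_i in enumerate(gene_idx):
            for p, pred in enumerate(predictors):
                if p == 0 and j < config.low_score_per_mir:
                    score = rng.uniform(10.0, 19.5)  # fails the >= 20 screen
                else:
                    score = rng.uniform(slo, shi)
                target_records.append((mir, genes[g_i], pred, round(score, 3)))
        if n_decoys and config.n_predictors > 1:
            decoy_pool = [i for i in range(config.n_genes)
                          if i not in set(gene_idx)]
            decoy_idx = rng.choice(len(decoy_pool), size=n_decoys,
                                   replace=False)
            for d_i in decoy_idx:
                k = int(rng.integers(1, config.n_predictors))
                for pred_i in sorted(rng.choice(config.n_predictors, size=k,
                                                replace=False)):
                    score = rng.uniform(slo, shi)
                    target_records.append((mir, genes[decoy_pool[d_i]],
                                           predictors[pred_i], round(score, 3)))

    tf_table = pd.DataFrame(tf_records, columns=["TF", "miR", "effect"])
    target_table = pd.DataFrame(target_records,
                                columns=["miR", "gene", "predictor", "score"])
    return tf_table, target_table


def generate_known_list(config: SimConfig, truth: GroundTruth) -> List[str]:
    """Simulate the curated known-disease miR list.

    Contains ``round(known_list_overlap * n_de)`` planted DE names plus
    non-DE fillers up to ``known_list_size`` entries; no duplicates.
    """
    config.validate()
    rng = config.rng("known")
    de = sorted(truth.de_mirs)
    n_overlap = int(round(config.known_list_overlap * len(de)))
    chosen = [de[i] for i in sorted(rng.choice(len(de), size=n_overlap,
                                               replace=False))]
    fillers_pool = sorted(set(truth.probe_names) - truth.de_mirs)
    n_fillers = max(0, config.known_list_size - n_overlap)
    n_fillers = min(n_fillers, len(fillers_pool))
    fillers = [fillers_pool[i] for i in
               sorted(rng.choice(len(fillers_pool), size=n_fillers,
                                 replace=False))]
    return sorted(chosen + fillers)


def generate_annotations(config: SimConfig, truth: GroundTruth,
                         target_table: pd.DataFrame) -> AnnotationSets:
    """Simulate GMT annotation sets with planted enriched terms.

    Planted terms draw ~80% of their members from the (consensus- and
    score-filtered) targets of the planted DE miRs, so the enrichment stage
    can recover them; background terms draw uniformly from the gene
    universe.  Empty terms are never emitted.  Records the planted term ids
    in ``truth.enriched_terms``.
    """
    from .targets import consensus_targets, filter_by_score

    config.validate()
    rng = config.rng("annotation")
    universe = sorted(target_table["gene"].unique())
    filtered = filter_by_score(
        consensus_targets(target_table, config.n_predictors))
    de_genes = sorted(filtered.loc[filtered["miR"].isin(truth.de_mirs),
                                   "gene"].unique())

    sets: AnnotationSets = {}
    planted: List[str] = []
    t_lo, t_hi = config.term_size_range
    for i in range(1, config.n_planted_terms + 1):
        if not de_genes:
            break
        size = int(rng.integers(t_lo, t_hi + 1))
        n_sig = min(len(de_genes), max(1, int(round(0.8 * size))))
        members = set(rng.choice(de_genes, size=n_sig, replace=False))
        others = [g for g in universe if g not in members]
        n_bg = min(len(others), size - n_sig)
        if n_bg > 0:
            members |= set(rng.choice(others, size=n_bg, replace=False))
        term = f"SIMSET:P{i:03d}"
        sets[term] = GeneSet(term, "planted disease-target term",
                             frozenset(members))
        planted.append(term)
    for i in range(1, config.n_annotation_terms + 1):
        size = int(rng.integers(t_lo, t_hi + 1))
        size = min(size, len(universe))
        if size == 0:
            continue
        members = frozenset(rng.choice(universe, size=size, replace=False))
        term = f"SIMSET:B{i:03d}"
        sets[term] = GeneSet(term, "background term", members)
    truth.enriched_terms = tuple(planted)
    return sets


@dataclass
class SimulatedInputs:
    """The full bundle: every file the pipeline consumes, plus the truth."""

    dataset: ExpressionDataset
    truth: GroundTruth
    tf_table: pd.DataFrame
    target_table: pd.DataFrame
    known_list: List[str]
    annotations: AnnotationSets


def simulate(config: SimConfig) -> SimulatedInputs:
    """Generate the complete input bundle in memory."""
    dataset, truth = generate_expression(config)
    tf_table, target_table = generate_regulation_tables(config, truth)
    known = generate_known_list(config, truth)
    annotations = generate_annotations(config, truth, target_table)
    return SimulatedInputs(dataset, truth, tf_table, target_table, known,
                           annotations)


def write_inputs(sim: SimulatedInputs, out_dir) -> Dict[str, Path]:
    """Write the bundle as the standard files; returns path per artifact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "samples.tsv",
        "tf_table": out / "tf_mir.tsv",
        "target_table": out / "mir_targets.tsv",
        "known_list": out / "known_mirs.txt",
        "annotations": out / "annotations.gmt",
        "truth": out / "ground_truth.json",
    }
    write_expression(sim.dataset, paths["expression"], paths["metadata"])
    write_tf_table(sim.tf_table, paths["tf_table"])
    write_target_table(sim.target_table, paths["target_table"])
    paths["known_list"].write_text("\n".join(sim.known_list) + "\n")
    write_gmt(sim.annotations, paths["annotations"])
    truth_doc = {
        "de_mirs": sorted(sim.truth.de_mirs),
        "block_assignments": sim.truth.block_assignments,
        "enriched_terms": list(sim.truth.enriched_terms),
    }
    paths["truth"].write_text(json.dumps(truth_doc, indent=1, sort_keys=True))
    return paths
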