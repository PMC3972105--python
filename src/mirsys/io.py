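"""Readers and writers for the tab-separated formats the pipeline exchanges.

Every table is UTF-8, tab-separated, with a header row.  miR names are
canonicalized at each file boundary (lowercase, ``hsa-`` prefix, stripped
whitespace) so that overlap counting and network joins across data sources
use consistent keys; gene and transcription-factor symbols are upper-cased.

Formats covered: expression matrix TSV (+ sample metadata TSV), TF->miR and
miR->gene edge TSVs, GMT annotation sets, and SIF / GraphML network export.
Missing expression values ("NA" or empty cells) are accepted on read and
carried as NaN; downstream stages decide how to treat them (pairwise-complete
correlation, exclusion from the differential test when a probe is mostly
missing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Mapping, Union

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUP_LABELS = ("disease", "control")

_NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null"}


class ParseError(ValueError):
    """A file violated the expected format; message carries coordinates."""


# ---------------------------------------------------------------------------
# name canonicalization (shared rule, applied at every file boundary)
# ---------------------------------------------------------------------------

def canonical_mir(name: str) -> str:
    """Canonical miR key: strip, lowercase, ensure an ``hsa-`` prefix."""
    n = str(name).strip().lower()
    if not n:
        raise ParseError("empty miR name")
    if not n.startswith("hsa-"):
        n = "hsa-" + n
    return n


def canonical_gene(name: str) -> str:
    """Canonical gene/TF symbol: stripped, upper-case."""
    n = str(name).strip().upper()
    if not n:
        raise ParseError("empty gene name")
    return n


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """A probes x samples matrix of log2(Hy3/Hy5) ratios with group labels.

    ``values`` is a float DataFrame (NaN = missing); ``groups`` maps every
    sample name to ``"disease"`` or ``"control"``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        probes = self.values.index
        samples = self.values.columns
        if probes.duplicated().any():
            dups = sorted(probes[probes.duplicated()].unique())
            raise ParseError(f"duplicate probe names: {dups}")
        if samples.duplicated().any():
            dups = sorted(samples[samples.duplicated()].unique())
            raise ParseError(f"duplicate sample names: {dups}")
        missing = [s for s in samples if s not in self.groups.index]
        if missing:
            raise ParseError(f"samples missing from metadata: {missing}")
        bad = sorted(set(self.groups.unique()) - set(GROUP_LABELS))
        if bad:
            raise ParseError(
                f"unknown group labels {bad}; expected one of {GROUP_LABELS}"
            )
        self.groups = self.groups.reindex(samples)
        for label in GROUP_LABELS:
            if not (self.groups == label).any():
                raise ParseError(f"group {label!r} has no samples")

    @property
    def probe_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_names(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, label: str) -> list[str]:
        return list(self.groups.index[self.groups == label])

    def subset_probes(self, names: Iterable[str]) -> "ExpressionDataset":
        names = [n for n in names if n in self.values.index]
        return ExpressionDataset(self.values.loc[names], self.groups.copy())


def read_expression(path, metadata_path) -> ExpressionDataset:
    """Read an expression TSV (first column probe names, header row samples)
    plus a sample metadata TSV with columns ``sample`` and ``group``.

    Non-numeric cells raise a :class:`ParseError` naming the probe and
    sample; NA tokens become NaN.  Column order is preserved.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = [canonical_mir(p) for p in raw.index]
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        for probe, cell in raw[col].items():
            cell = cell.strip()
            if cell in _NA_TOKENS:
                values.loc[probe, col] = np.nan
                continue
            try:
                values.loc[probe, col] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at probe {probe!r}, "
                    f"sample {col!r} in {path}"
                ) from None
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for needed in ("sample", "group"):
        if needed not in meta.columns:
            raise ParseError(f"metadata {metadata_path} lacks column {needed!r}")
    groups = pd.Series(meta["group"].values, index=meta["sample"].values)
    if groups.index.duplicated().any():
        raise ParseError("duplicate sample rows in metadata")
    return ExpressionDataset(values, groups)


def write_expression(dataset: ExpressionDataset, path, metadata_path) -> None:
    dataset.values.to_csv(path, sep="\t", index_label="probe", na_rep="NA")
    meta = pd.DataFrame({"sample": dataset.sample_names,
                         "group": dataset.groups.values})
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT annotation sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    description: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ParseError(f"annotation term {self.term_id!r} is empty")


AnnotationSets = Dict[str, GeneSet]


def read_gmt(path) -> AnnotationSets:
    """Read a GMT file: term, description, then tab-separated member genes."""
    sets: AnnotationSets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected at least 3 (term, description, members...)"
                )
            term, desc, *members = fields
            members = [canonical_gene(m) for m in members if m.strip()]
            if len(members) != len(set(members)):
                logger.warning("GMT term %s line %d has duplicate genes; "
                               "deduplicated", term, lineno)
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = GeneSet(term, desc, frozenset(members))
    return sets


def write_gmt(sets: AnnotationSets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(sets):
            gs = sets[term]
            fh.write("\t".join([gs.term_id, gs.description,
                                *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# edge tables (TF->miR regulation, miR->gene targets)
# ---------------------------------------------------------------------------

TF_COLUMNS = ["TF", "miR", "effect"]
TARGET_COLUMNS = ["miR", "gene", "predictor", "score"]


def read_tf_table(path) -> pd.DataFrame:
    """TF->miR regulation records with columns TF, miR, effect."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, TF_COLUMNS, path)
    df = df[TF_COLUMNS].copy()
    df["TF"] = df["TF"].map(canonical_gene)
    df["miR"] = df["miR"].map(canonical_mir)
    return df


def write_tf_table(df: pd.DataFrame, path) -> None:
    df[TF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_target_table(path) -> pd.DataFrame:
    """miR->gene predicted-target records: miR, gene, predictor, score."""
    df = pd.read_csv(path, sep="\t", dtype={"score": float},
                     converters={})
    _require_columns(df, TARGET_COLUMNS, path)
    df = df[TARGET_COLUMNS].copy()
    df["miR"] = df["miR"].map(canonical_mir)
    df["gene"] = df["gene"].map(canonical_gene)
    df["predictor"] = df["predictor"].astype(str).str.strip().str.lower()
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if not np.isfinite(df["score"]).all():
        bad = df.loc[~np.isfinite(df["score"])]
        raise ParseError(f"non-finite scores in {path}: rows {list(bad.index)}")
    dup = df.duplicated(subset=["miR", "gene", "predictor"])
    if dup.any():
        raise ParseError(
            f"duplicate (miR, gene, predictor) records in {path}: "
            f"rows {list(df.index[dup])}"
        )
    return df


def write_target_table(df: pd.DataFrame, path) -> None:
    df[TARGET_COLUMNS].to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path} lacks required columns {missing}")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

SIF_DIALECT = "SIF"
GRAPHML_DIALECT = "GraphML"


def write_network(graph: Union[nx.Graph, nx.DiGraph], path, dialect) -> None:
    """Export a typed network for external graph tools.

    SIF lines are ``source <tab> interaction <tab> target`` using the edge
    attribute ``interaction`` ("regulates" TF->miR, "targets" miR->gene,
    "coexpressed" miR-miR).  GraphML carries whatever node attributes are
    present (layer, degree, ir, betweenness, eccentricity, clustering).
    """
    if dialect == SIF_DIALECT:
        with open(path, "w", encoding="utf-8") as fh:
            for u, v, attrs in sorted(graph.edges(data=True)):
                fh.write(f"{u}\t{attrs.get('interaction', 'interacts')}\t{v}\n")
    elif dialect == GRAPHML_DIALECT:
        nx.write_graphml(graph, path)
    else:
        raise ValueError(f"unknown network dialect {dialect!r}; "
                         f"use {SIF_DIALECT} or {GRAPHML_DIALECT}")
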