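"""Consensus miRNA-target aggregation and projection onto a disease module.

Per-source target prediction tables (rank 1 = best) are combined by the
geometric mean of the ranks over the sources that contain each
(miRNA, gene) pair; pairs present in fewer than ``min_sources`` sources
(default 2 of 4) are discarded. Consensus targets of a differential-
expression signature are then intersected with the disease module,
flagged by LCC membership, and the target subnetwork within the LCC is
extracted with hub centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .de_analysis import has_arm_suffix, normalize_mirna_name
from .network_module import DiseaseModule, PPINetwork, node_centrality, normalize_symbol

__all__ = [
    "TargetTable",
    "read_rank_tables",
    "aggregate_targets",
    "map_targets_to_module",
    "ModuleTargetReport",
    "target_subnetwork",
    "TargetSubnetwork",
]


@dataclass
class TargetTable:
    """Consensus miRNA->gene assignments.

    ``records`` columns: ``mirna``, ``gene``, one ``rank_<source>`` column
    per source (NaN when the pair is absent from that source),
    ``n_sources_present`` and ``aggregate_score`` (geometric mean of the
    available ranks; smaller is better). Within each miRNA, records are
    ordered ascending by score, ties broken by more sources then gene name.
    """

    records: pd.DataFrame
    sources: list[str]
    min_sources: int = 2

    def targets_of(self, mirna: str) -> pd.DataFrame:
        key = normalize_mirna_name(mirna)
        return self.records[self.records["mirna"] == key]

    @property
    def mirnas(self) -> set[str]:
        return set(self.records["mirna"].unique())

    def to_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def read_rank_tables(path: str | Path) -> list[pd.DataFrame]:
    """Read a combined rank TSV (source, mirna, gene, rank) into per-source tables."""
    df = pd.read_csv(path, sep="\t")
    required = {"source", "mirna", "gene", "rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    return [
        g.drop(columns="source").reset_index(drop=True).rename_axis(None)
        for _, g in df.groupby("source", sort=True)
    ]


def _normalize_table(tab: pd.DataFrame, label: str) -> pd.DataFrame:
    t = tab.copy()
    if "rank" not in t.columns:
        if "score" not in t.columns:
            raise ValueError(f"source {label}: need a 'rank' or 'score' column")
        # scores -> per-miRNA ranks, best score = rank 1, average ties
        t["rank"] = t.groupby("mirna")["score"].transform(
            lambda s: rankdata(-s.to_numpy(), method="average")
        )
    if (t["rank"] < 1).any():
        raise ValueError(f"source {label}: ranks must be >= 1")
    t["mirna"] = t["mirna"].map(normalize_mirna_name)
    t["gene"] = t["gene"].map(normalize_symbol)
    if t.duplicated(["mirna", "gene"]).any():
        raise ValueError(f"source {label}: duplicate (mirna, gene) pairs")
    return t[["mirna", "gene", "rank"]]


def aggregate_targets(
    source_tables: Sequence[pd.DataFrame],
    min_sources: int = 2,
    source_names: Sequence[str] | None = None,
) -> TargetTable:
    """Consensus ranking over prediction sources by geometric-mean rank.

    The union of (miRNA, gene) pairs over all sources is taken; a pair is
    retained only if it appears in at least ``min_sources`` sources, and
    its score is the geometric mean of the ranks from the sources that
    contain it.
    """
    if len(source_tables) < min_sources:
        raise ValueError(
            f"need at least min_sources={min_sources} tables, got {len(source_tables)}"
        )
    if source_names is None:
        source_names = [f"source{i+1}" for i in range(len(source_tables))]
    source_names = list(map(str, source_names))

    frames = []
    for name, tab in zip(source_names, source_tables):
        t = _normalize_table(tab, name)
        t = t.rename(columns={"rank": f"rank_{name}"})
        frames.append(t.set_index(["mirna", "gene"]))
    wide = pd.concat(frames, axis=1, join="outer")
    rank_cols = [f"rank_{n}" for n in source_names]
    n_present = wide[rank_cols].notna().sum(axis=1)
    keep = wide[n_present >= min_sources].copy()
    keep["n_sources_present"] = n_present[n_present >= min_sources]
    keep["aggregate_score"] = np.exp(np.log(keep[rank_cols]).mean(axis=1, skipna=True))
    records = keep.reset_index()
    records = records.sort_values(
        ["mirna", "aggregate_score", "n_sources_present", "gene"],
        ascending=[True, True, False, True],
    ).reset_index(drop=True)
    return TargetTable(records, sources=source_names, min_sources=min_sources)


# ---------------------------------------------------------------------------
# projection onto the disease module
# ---------------------------------------------------------------------------

@dataclass
class ModuleTargetReport:
    """Targets of a DE miRNA signature within the disease module.

    ``per_mirna`` columns: mirna, direction, target, lcc_flag,
    aggregate_score. Totals count target hits with multiplicity (a gene
    targeted by k signature miRNAs contributes k) alongside unique genes.
    """

    per_mirna: pd.DataFrame
    total_hits: int
    unique_genes: int
    lcc_hits: int
    lcc_unique_genes: int
    shared_up_down_genes: list[str]
    missing_mirnas: list[str]

    def counts(self) -> dict:
        return {
            "total_hits": self.total_hits,
            "unique_genes": self.unique_genes,
            "lcc_hits": self.lcc_hits,
            "lcc_unique_genes": self.lcc_unique_genes,
            "n_shared_up_down_genes": len(self.shared_up_down_genes),
            "n_missing_mirnas": len(self.missing_mirnas),
        }

    def to_tsv(self, path: str | Path) -> None:
        self.per_mirna.to_csv(path, sep="\t", index=False)


def _match_signature_mirnas(sig_name: str, table_mirnas: set[str]) -> list[str]:
    key = normalize_mirna_name(sig_name)
    if key in table_mirnas:
        return [key]
    if not has_arm_suffix(key):
        arms = [f"{key}-5p", f"{key}-3p"]
        found = [a for a in arms if a in table_mirnas]
        if found:
            warnings.warn(
                f"signature miRNA {sig_name!r} has no arm suffix; matched {found}",
                stacklevel=3,
            )
        return found
    return []


def map_targets_to_module(
    targets: TargetTable,
    module: DiseaseModule,
    signature: pd.DataFrame,
) -> ModuleTargetReport:
    """Intersect consensus targets of signature miRNAs with the module.

    ``signature`` needs columns ``mirna`` and ``direction``. Signature
    entries absent from the target table are reported in
    ``missing_mirnas``. Genes targeted by both up- and downregulated
    miRNAs are cross-tabulated.
    """
    if not module.mapped_genes:
        raise ValueError("empty disease module")
    module_genes = set(module.mapped_genes)
    lcc = set(module.lcc_members)
    table_mirnas = targets.mirnas

    rows = []
    missing = []
    genes_by_direction: dict[str, set[str]] = {"up": set(), "down": set()}
    for _, sig_row in signature.iterrows():
        name = sig_row["mirna"]
        direction = str(sig_row.get("direction", "none"))
        matched = _match_signature_mirnas(name, table_mirnas)
        if not matched:
            missing.append(name)
            continue
        for key in matched:
            hits = targets.records[
                (targets.records["mirna"] == key)
                & (targets.records["gene"].isin(module_genes))
            ]
            for _, h in hits.iterrows():
                rows.append(
                    (name, direction, h["gene"], h["gene"] in lcc, float(h["aggregate_score"]))
                )
                if direction in genes_by_direction:
                    genes_by_direction[direction].add(h["gene"])
    per = pd.DataFrame(
        rows, columns=["mirna", "direction", "target", "lcc_flag", "aggregate_score"]
    )
    shared = sorted(genes_by_direction["up"] & genes_by_direction["down"])
    return ModuleTargetReport(
        per_mirna=per,
        total_hits=len(per),
        unique_genes=per["target"].nunique(),
        lcc_hits=int(per["lcc_flag"].sum()),
        lcc_unique_genes=per.loc[per["lcc_flag"], "target"].nunique(),
        shared_up_down_genes=shared,
        missing_mirnas=missing,
    )


@dataclass
class TargetSubnetwork:
    """Largest connected component of module targets within the LCC."""

    graph: nx.Graph
    members: list[str]
    centrality: pd.DataFrame
    hubs: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def write_graphml(self, path: str | Path) -> None:
        g = nx.Graph(self.graph)
        cent = self.centrality.set_index("gene")
        for n in g.nodes:
            g.nodes[n]["degree"] = int(cent.loc[n, "degree"])
            g.nodes[n]["betweenness"] = float(cent.loc[n, "betweenness"])
        nx.write_graphml(g, str(path))


def target_subnetwork(
    net: PPINetwork,
    module: DiseaseModule,
    target_genes: Sequence[str],
) -> TargetSubnetwork:
    """Connected subnetwork of target genes within the module's LCC.

    Returns the largest connected component of the induced subgraph of
    ``target_genes`` ∩ LCC, with module-internal degree/betweenness and a
    hub ranking. An empty intersection yields an empty result with a
    warning.
    """
    genes = [normalize_symbol(g) for g in target_genes]
    outside = [g for g in genes if g not in set(module.mapped_genes)]
    if outside:
        raise ValueError(f"target genes outside the module: {outside[:5]}")
    in_lcc = [g for g in genes if g in set(module.lcc_members)]
    if not in_lcc:
        warnings.warn("no target genes fall in the LCC", stacklevel=2)
        empty = pd.DataFrame(columns=["gene", "degree", "betweenness", "hub_rank"])
        return TargetSubnetwork(nx.Graph(), [], empty, [])
    sub = net.graph.subgraph(in_lcc)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), c))
    members = comps[0]
    cent = node_centrality(net, members)
    hubs = list(cent["gene"])
    return TargetSubnetwork(nx.Graph(sub.subgraph(members)), members, cent, hubs)
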