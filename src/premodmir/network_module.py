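"""Disease-module construction and topology statistics on a PPI network.

A gene signature is mapped onto a score-thresholded interactome (STRING
export dialect: ``protein1  protein2  combined_score``). The module's
within-set edge count is compared to uniform random same-size node sets
(PPI enrichment), its mean shortest-path length on the full network is
standardized against the same null (coherence z-score; z < −1.65 marks a
topologically clustered set), and the induced subgraph is split into the
largest connected component (LCC, the observable module) and peripheral
components, with degree/betweenness hub ranking.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_sp

__all__ = [
    "PPINetwork",
    "DiseaseModule",
    "CoherenceResult",
    "EnrichmentStat",
    "read_interactome",
    "read_gene_list",
    "map_gene_set",
    "ppi_enrichment",
    "extract_lcc",
    "module_coherence",
    "node_centrality",
    "Z_SIGNIFICANCE_CUTOFF",
]

STRING_MIN_SCORE_DEFAULT = 0.4
Z_SIGNIFICANCE_CUTOFF = -1.65

# graphs up to this many nodes get a cached all-pairs BFS distance matrix
_FULL_MATRIX_MAX_NODES = 4000


def normalize_symbol(sym: str) -> str:
    """Upper-case gene/protein symbol normalization."""
    return str(sym).strip().upper()


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    """Undirected interactome with combined scores in (threshold, 1]."""

    graph: nx.Graph
    min_score: float = STRING_MIN_SCORE_DEFAULT

    def __post_init__(self) -> None:
        self._node_list: list[str] | None = None
        self._node_pos: dict[str, int] | None = None
        self._dist: np.ndarray | None = None

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def _positions(self) -> dict[str, int]:
        if self._node_pos is None:
            self._node_list = list(self.graph.nodes)
            self._node_pos = {n: i for i, n in enumerate(self._node_list)}
        return self._node_pos

    def _distance_rows(self, nodes: Sequence[str]) -> np.ndarray:
        """Unweighted shortest-path distances from ``nodes`` to all nodes.

        Rows follow the order of ``nodes``; columns the internal node
        order. Infinite where unreachable. For small graphs the full
        all-pairs matrix is computed once and cached.
        """
        pos = self._positions()
        idx = np.array([pos[n] for n in nodes], dtype=int)
        if self.n_nodes <= _FULL_MATRIX_MAX_NODES:
            if self._dist is None:
                adj = nx.to_scipy_sparse_array(self.graph, nodelist=self._node_list, format="csr")
                self._dist = _csgraph_sp(csr_matrix(adj), unweighted=True, directed=False)
            return self._dist[idx]
        adj = nx.to_scipy_sparse_array(self.graph, nodelist=self._node_list, format="csr")
        return _csgraph_sp(csr_matrix(adj), unweighted=True, directed=False, indices=idx)

    def mean_shortest_path(self, nodes: Sequence[str]) -> tuple[float, int]:
        """Mean unweighted shortest-path length over finite unordered pairs
        of ``nodes`` on the full network. Returns (mean, n_finite_pairs)."""
        nodes = list(nodes)
        pos = self._positions()
        idx = np.array([pos[n] for n in nodes], dtype=int)
        rows = self._distance_rows(nodes)
        sub = rows[:, idx]
        iu = np.triu_indices(len(nodes), k=1)
        d = sub[iu]
        finite = np.isfinite(d)
        if not finite.any():
            return float("nan"), 0
        return float(d[finite].mean()), int(finite.sum())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_interactome(
    path: str | Path,
    min_score: float = STRING_MIN_SCORE_DEFAULT,
    score_scale: str = "auto",
) -> PPINetwork:
    """Load a STRING-dialect edge list into a score-thresholded network.

    Expects tab-separated columns ``protein1``, ``protein2``,
    ``combined_score``. Scores on the 0-1000 integer scale are detected
    automatically (any score > 1) and divided by 1000; only edges with
    score strictly above ``min_score`` are kept (0.4 = STRING medium
    confidence). Symmetric duplicates are merged keeping the maximum
    score; self-loops are dropped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"{path}: cannot parse interactome TSV: {exc}") from exc
    if df.shape[1] == 1:  # space-separated STRING export
        df = pd.read_csv(path, sep=r"\s+")
    required = {"protein1", "protein2", "combined_score"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    score = pd.to_numeric(df["combined_score"], errors="coerce")
    bad = df.index[score.isna() | df["protein1"].isna() | df["protein2"].isna()]
    if len(bad):
        # +2: header line and 1-based numbering
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(f"{path}: malformed rows at lines {lines}")

    score = score.astype(float)
    if score_scale == "auto":
        scale = 1000.0 if float(score.max()) > 1.0 else 1.0
    elif score_scale in ("unit", "1"):
        scale = 1.0
    elif score_scale in ("string", "1000"):
        scale = 1000.0
    else:
        raise ValueError(f"unknown score_scale {score_scale!r}")
    score = score / scale

    g = nx.Graph()
    for a, b, s in zip(df["protein1"], df["protein2"], score):
        if s <= min_score:
            continue
        a = normalize_symbol(a)
        b = normalize_symbol(b)
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["score"] = max(g[a][b]["score"], float(s))
        else:
            g.add_edge(a, b, score=float(s))
    if g.number_of_edges() == 0:
        raise ValueError(f"{path}: no edges above score {min_score}")
    return PPINetwork(g, min_score=min_score)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a gene list (one symbol per line; blank lines ignored)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# module mapping and statistics
# ---------------------------------------------------------------------------

@dataclass
class CoherenceResult:
    """Coherence of a node set: mean shortest-path length vs random sets."""

    l_mean: float
    l_rand_mean: float
    l_rand_std: float
    z_score: float | None
    n_random: int
    seed: int
    significant: bool

    def to_dict(self) -> dict:
        return {
            "l_mean": self.l_mean,
            "l_rand_mean": self.l_rand_mean,
            "l_rand_std": self.l_rand_std,
            "z_score": self.z_score,
            "n_random": self.n_random,
            "seed": self.seed,
            "significant": self.significant,
        }


@dataclass
class EnrichmentStat:
    """Within-set edge count vs uniform random same-size node sets."""

    observed_edges: int
    expected_edges: float
    empirical_p: float
    average_node_degree: float
    n_random: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_edges": self.observed_edges,
            "expected_edges": self.expected_edges,
            "empirical_p": self.empirical_p,
            "average_node_degree": self.average_node_degree,
            "n_random": self.n_random,
            "seed": self.seed,
        }


@dataclass
class DiseaseModule:
    """A gene signature mapped onto the interactome."""

    query_genes: list[str]
    mapped_genes: list[str]
    unmapped: list[str]
    lcc_members: list[str] = field(default_factory=list)
    peripheral_components: list[list[str]] = field(default_factory=list)
    centrality: pd.DataFrame | None = None
    coherence: CoherenceResult | None = None
    enrichment: EnrichmentStat | None = None

    @property
    def lcc_fraction(self) -> float:
        return len(self.lcc_members) / len(self.mapped_genes) if self.mapped_genes else float("nan")


def map_gene_set(
    net: PPINetwork,
    genes: Iterable[str],
    alias: dict[str, str] | None = None,
) -> DiseaseModule:
    """Map a gene signature onto the network nodes.

    Symbols are upper-cased; ``alias`` optionally remaps symbols (two-column
    alias table) before matching. Unmapped symbols are reported.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    alias = {normalize_symbol(k): normalize_symbol(v) for k, v in (alias or {}).items()}
    nodes = net.nodes
    mapped, unmapped, seen = [], [], set()
    for g in genes:
        sym = normalize_symbol(g)
        sym = alias.get(sym, sym)
        if sym in seen:
            continue
        seen.add(sym)
        (mapped if sym in nodes else unmapped).append(sym)
    if not mapped:
        raise ValueError("no query genes map to the network")
    return DiseaseModule(query_genes=genes, mapped_genes=mapped, unmapped=unmapped)


def _sample_node_sets(
    net: PPINetwork,
    size: int,
    n_random: int,
    rng: np.random.Generator,
    match_degrees_of: Sequence[str] | None = None,
    n_bins: int = 10,
) -> list[list[str]]:
    """Uniform same-size node sets; optionally degree-binned to match a
    reference set's degree composition (sensitivity-analysis mode)."""
    all_nodes = np.array(list(net.graph.nodes))
    if match_degrees_of is None:
        return [list(rng.choice(all_nodes, size=size, replace=False)) for _ in range(n_random)]
    deg = np.array([net.graph.degree(n) for n in all_nodes], dtype=float)
    edges = np.quantile(deg, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1
    bins = np.searchsorted(edges, deg, side="right") - 1
    ref_deg = np.array([net.graph.degree(n) for n in match_degrees_of], dtype=float)
    ref_bins = np.searchsorted(edges, ref_deg, side="right") - 1
    by_bin = {b: all_nodes[bins == b] for b in np.unique(bins)}
    counts = {b: int((ref_bins == b).sum()) for b in np.unique(ref_bins)}
    out = []
    for _ in range(n_random):
        chosen: list[str] = []
        for b, c in counts.items():
            pool = by_bin.get(b, all_nodes)
            chosen.extend(rng.choice(pool, size=min(c, pool.size), replace=False).tolist())
        while len(chosen) < size:  # top up if a bin ran short
            extra = rng.choice(all_nodes)
            if extra not in chosen:
                chosen.append(str(extra))
        out.append(chosen[:size])
    return out


def ppi_enrichment(
    net: PPINetwork,
    mapped_genes: Sequence[str],
    n_random: int = 1000,
    seed: int = 0,
    degree_matched: bool = False,
) -> EnrichmentStat:
    """PPI enrichment of a node set against uniform same-size random sets.

    empirical_p = (1 + #{null >= observed}) / (n_random + 1); the average
    node degree is within the induced subgraph (2·edges / |set|).
    ``degree_matched=True`` draws null sets matching the set's degree-bin
    composition instead of uniformly (sensitivity analysis).
    """
    mapped = [normalize_symbol(g) for g in mapped_genes]
    if len(mapped) < 2:
        raise ValueError("need at least 2 mapped genes")
    if n_random < 100:
        warnings.warn("n_random < 100: empirical p-values will be coarse", stacklevel=2)
    missing = [g for g in mapped if g not in net.nodes]
    if missing:
        raise ValueError(f"genes not in network: {missing[:5]}")
    rng = np.random.default_rng(seed)
    observed = net.graph.subgraph(mapped).number_of_edges()
    sets = _sample_node_sets(
        net, len(mapped), n_random, rng, match_degrees_of=mapped if degree_matched else None
    )
    null = np.array([net.graph.subgraph(s).number_of_edges() for s in sets], dtype=float)
    p = (1.0 + float(np.sum(null >= observed))) / (n_random + 1.0)
    return EnrichmentStat(
        observed_edges=int(observed),
        expected_edges=float(null.mean()),
        empirical_p=p,
        average_node_degree=2.0 * observed / len(mapped),
        n_random=n_random,
        seed=seed,
    )


def extract_lcc(net: PPINetwork, module: DiseaseModule | Sequence[str]) -> DiseaseModule:
    """Split the induced subgraph into the LCC and peripheral components.

    Components (including isolated mapped nodes) partition the mapped set;
    the largest is the observable module. Size ties resolve to the
    lexicographically smallest member set.
    """
    if isinstance(module, DiseaseModule):
        mod = module
    else:
        mapped = [normalize_symbol(g) for g in module]
        mod = DiseaseModule(query_genes=list(module), mapped_genes=mapped, unmapped=[])
    sub = net.graph.subgraph(mod.mapped_genes)
    comps = [sorted(c) for c in nx.connected_components(sub)]
    comps.sort(key=lambda c: (-len(c), c))
    mod.lcc_members = comps[0] if comps else []
    mod.peripheral_components = comps[1:]
    return mod


def module_coherence(
    net: PPINetwork,
    mapped_genes: Sequence[str],
    n_random: int = 1000,
    seed: int = 0,
    degree_matched: bool = False,
) -> CoherenceResult:
    """Coherence z-score of a node set on the full network.

    ⟨L⟩ is the mean unweighted shortest-path length over finite unordered
    node pairs (disconnected pairs are excluded; the same rule applies to
    the null). The null is ``n_random`` uniform same-size node sets
    (degree-bin matched when ``degree_matched=True``);
    z = (⟨L⟩ − mean_null) / sd_null, significant when z < −1.65.
    """
    mapped = [normalize_symbol(g) for g in mapped_genes]
    missing = [g for g in mapped if g not in net.nodes]
    if missing:
        raise ValueError(f"genes not in network: {missing[:5]}")
    if len(mapped) < 2:
        raise ValueError("need at least 2 genes for coherence")
    l_mean, n_pairs = net.mean_shortest_path(mapped)
    if n_pairs == 0:
        raise ValueError("no finite shortest-path pairs within the gene set")
    rng = np.random.default_rng(seed)
    null = []
    for s in _sample_node_sets(
        net, len(mapped), n_random, rng, match_degrees_of=mapped if degree_matched else None
    ):
        l, k = net.mean_shortest_path(s)
        if k > 0:
            null.append(l)
    if not null:
        raise ValueError("null sets produced no finite pairs")
    null = np.asarray(null)
    mu = float(null.mean())
    sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    if sd > 0:
        z: float | None = (l_mean - mu) / sd
        significant = z < Z_SIGNIFICANCE_CUTOFF
    else:
        z = None
        significant = False
        warnings.warn("null sd is zero; z-score undefined", stacklevel=2)
    return CoherenceResult(
        l_mean=l_mean,
        l_rand_mean=mu,
        l_rand_std=sd,
        z_score=z,
        n_random=n_random,
        seed=seed,
        significant=significant,
    )


def node_centrality(
    net: PPINetwork,
    node_set: Sequence[str],
    scope: str = "module",
) -> pd.DataFrame:
    """Degree and betweenness centrality with hub ranking.

    By default both metrics are computed on the induced subgraph of
    ``node_set`` (module-internal convention); ``scope="network"`` uses
    the full graph instead. Betweenness is normalized by (n−1)(n−2)/2.
    Hubs rank by descending degree, ties broken by betweenness then name.
    """
    nodes = [normalize_symbol(g) for g in node_set]
    missing = [g for g in nodes if g not in net.nodes]
    if missing:
        raise ValueError(f"genes not in network: {missing[:5]}")
    if scope == "module":
        g = net.graph.subgraph(nodes)
        bet = nx.betweenness_centrality(g, normalized=True)
        deg = dict(g.degree())
    elif scope == "network":
        bet_full = nx.betweenness_centrality(net.graph, normalized=True)
        deg_full = dict(net.graph.degree())
        bet = {n: bet_full[n] for n in nodes}
        deg = {n: deg_full[n] for n in nodes}
    else:
        raise ValueError("scope must be 'module' or 'network'")
    df = pd.DataFrame(
        {"gene": nodes, "degree": [deg[n] for n in nodes], "betweenness": [bet[n] for n in nodes]}
    )
    df = df.sort_values(["degree", "betweenness", "gene"], ascending=[False, False, True]).reset_index(drop=True)
    df["hub_rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_module_graphml(net: PPINetwork, module: DiseaseModule, path: str | Path) -> None:
    """Write the induced module subgraph with lcc/degree/betweenness attributes."""
    sub = nx.Graph(net.graph.subgraph(module.mapped_genes))
    lcc = set(module.lcc_members)
    cent = module.centrality
    if cent is None:
        cent = node_centrality(net, module.mapped_genes)
    cent_idx = cent.set_index("gene")
    for n in sub.nodes:
        sub.nodes[n]["lcc_member"] = n in lcc
        sub.nodes[n]["degree"] = int(cent_idx.loc[n, "degree"])
        sub.nodes[n]["betweenness"] = float(cent_idx.loc[n, "betweenness"])
    nx.write_graphml(sub, str(path))


def write_components_tsv(module: DiseaseModule, path: str | Path) -> None:
    rows = [("lcc", g) for g in module.lcc_members]
    for i, comp in enumerate(module.peripheral_components, start=1):
        rows.extend((f"peripheral_{i}", g) for g in comp)
    pd.DataFrame(rows, columns=["component", "gene"]).to_csv(path, sep="\t", index=False)


def write_module_stats_json(module: DiseaseModule, path: str | Path) -> None:
    payload = {
        "n_query": len(module.query_genes),
        "n_mapped": len(module.mapped_genes),
        "n_unmapped": len(module.unmapped),
        "n_lcc": len(module.lcc_members),
        "lcc_fraction": module.lcc_fraction,
        "n_peripheral_components": len(module.peripheral_components),
        "coherence": module.coherence.to_dict() if module.coherence else None,
        "enrichment": module.enrichment.to_dict() if module.enrichment else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))
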