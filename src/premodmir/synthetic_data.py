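"""Synthetic inputs emulating an early-pregnancy qPCR miRNA case-control study.

Generates every input the pipeline consumes, with ground truth for
recovery tests: a Ct matrix with planted differential expression for two
correlated phenotypes (disease status and a vitamin-D dichotomy), hidden
batch-like factors, abundance-dependent nondetects, and haemolysed
samples detectable through the miR-23a/miR-451a ΔCq; an interactome with
a planted dense module; per-source miRNA-target rank tables with planted
consensus pairs; and GMT annotation collections with one designed
enriched set.

Default dimensions mirror a 754-assay panel profiled in 157 samples
(47 cases / 110 controls) with a 31-feature disease signature (10 up,
21 down) of which 16 are shared with the vitamin-D contrast. All
randomness flows through one seeded generator; identical seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network_module import PPINetwork
from .qc_normalize import CtMatrix

import networkx as nx

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_ct_dataset",
    "generate_ppi",
    "generate_target_tables",
    "generate_annotation_sets",
    "write_metadata_tsv",
    "write_string_tsv",
    "write_rank_tables_tsv",
    "write_truth_json",
    "MIR23A_ID",
    "MIR451A_ID",
]

MIR23A_ID = "hsa-miR-23a"
MIR451A_ID = "hsa-miR-451a"


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic Ct dataset.

    Defaults describe the emulated cohort: 754 assays x 157 samples with
    47 cases, a planted disease signature of 10 up + 21 down features on a
    1.0-Cq effect, 16 of them shared with the vitamin-D contrast (9 up)
    plus 10 vitamin-D-only features, two hidden Gaussian factors,
    abundance-dependent nondetects and 3 haemolysed samples.
    """

    n_features: int = 754
    n_samples: int = 157
    n_cases: int = 47
    n_de_up: int = 10
    n_de_down: int = 21
    n_de_vitd_shared: int = 16
    n_de_vitd_only: int = 10
    effect_size_ct: float = 1.0
    n_hidden_factors: int = 2
    factor_sd: float = 0.5
    nondetect_rate: float = 0.25
    hemolysis_samples: int = 3
    baseline_ct_range: tuple[float, float] = (20.0, 34.0)
    noise_sd: float = 0.5
    qc_flag_rate: float = 0.0
    # probability of vitamin-D insufficiency per group; equal by default so
    # the two planted contrasts are label-independent and the shared subset
    # is identifiable by intersection (set 41/47 and 78/110 to emulate the
    # confounded cohort cross-tabulation instead)
    p_insufficient_case: float = 119 / 157
    p_insufficient_control: float = 119 / 157
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.n_cases < self.n_samples:
            raise ValueError("need 0 < n_cases < n_samples")
        if self.n_de_up + self.n_de_down + self.n_de_vitd_only > self.n_features - 2:
            raise ValueError("planted DE features exceed available features (2 reserved for haemolysis proxies)")
        if self.n_de_vitd_shared > self.n_de_up + self.n_de_down:
            raise ValueError("n_de_vitd_shared exceeds the planted disease signature")
        if not 0.0 <= self.nondetect_rate <= 1.0:
            raise ValueError("nondetect_rate must be in [0, 1]")
        if self.hemolysis_samples >= self.n_samples:
            raise ValueError("hemolysis_samples must be < n_samples")
        if self.baseline_ct_range[0] >= self.baseline_ct_range[1]:
            raise ValueError("baseline_ct_range must be (low, high) with low < high")
        if self.n_features < 4:
            raise ValueError("need at least 4 features")
        if min(self.noise_sd, self.factor_sd) < 0 or self.effect_size_ct < 0:
            raise ValueError("scales must be non-negative")
        if not 0.0 <= self.qc_flag_rate <= 1.0:
            raise ValueError("qc_flag_rate must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground-truth labels for recovery tests."""

    de_up_ids: set[str] = field(default_factory=set)
    de_down_ids: set[str] = field(default_factory=set)
    vitd_de_ids: set[str] = field(default_factory=set)
    shared_ids: set[str] = field(default_factory=set)
    hemolysed_ids: set[str] = field(default_factory=set)
    factor_scores: pd.DataFrame | None = None   # samples x factors
    factor_loadings: pd.DataFrame | None = None  # features x factors
    true_values: pd.DataFrame | None = None      # pre-masking Ct matrix
    planted_module_genes: set[str] = field(default_factory=set)
    planted_target_map: dict[str, set[str]] = field(default_factory=dict)
    enriched_set_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "de_up_ids": sorted(self.de_up_ids),
            "de_down_ids": sorted(self.de_down_ids),
            "vitd_de_ids": sorted(self.vitd_de_ids),
            "shared_ids": sorted(self.shared_ids),
            "hemolysed_ids": sorted(self.hemolysed_ids),
            "planted_module_genes": sorted(self.planted_module_genes),
            "planted_target_map": {k: sorted(v) for k, v in self.planted_target_map.items()},
            "enriched_set_id": self.enriched_set_id,
        }


_ND_LOGISTIC_SCALE = 1.5  # Cq units; steepness of the nondetect mechanism


def _calibrate_nondetect_center(ct: np.ndarray, rate: float) -> float:
    """Bisection on the logistic center so the mean nondetect probability
    matches the requested rate."""
    lo, hi = ct.min() - 20.0, ct.max() + 20.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        p = 1.0 / (1.0 + np.exp(-(ct - mid) / _ND_LOGISTIC_SCALE))
        if p.mean() > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_ct_dataset(config: SyntheticConfig) -> tuple[CtMatrix, SyntheticTruth]:
    """Generate a Ct matrix + metadata with planted structure.

    Cell model: Ct = feature baseline + phenotype shifts (cases get
    −effect for up-features, +effect for down-features; likewise for the
    vitamin-D dichotomy on its associated features) + hidden-factor
    contributions (Gaussian per-sample scores x per-feature loadings,
    scaled by ``factor_sd``) + Gaussian noise. Nondetects are drawn with a
    probability that increases logistically with the underlying Ct,
    calibrated to the overall ``nondetect_rate``; haemolysed samples get
    the miR-451a proxy shifted to low Cq so that ΔCq exceeds 5. The two
    haemolysis proxy features are always present and never masked.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.baseline_ct_range

    n_other = config.n_features - 2
    feature_ids = [MIR23A_ID, MIR451A_ID] + [f"hsa-miR-syn-{i:04d}" for i in range(1, n_other + 1)]
    sample_ids = [f"S{i:03d}" for i in range(1, config.n_samples + 1)]

    # phenotype assignment
    case_pos = rng.choice(config.n_samples, size=config.n_cases, replace=False)
    is_case = np.zeros(config.n_samples, dtype=bool)
    is_case[case_pos] = True
    p_insuf = np.where(is_case, config.p_insufficient_case, config.p_insufficient_control)
    is_insufficient = rng.random(config.n_samples) < p_insuf
    arm = rng.choice(["placebo", "treatment"], size=config.n_samples)
    metadata = pd.DataFrame(
        {
            "group": np.where(is_case, "case", "control"),
            "vitd": np.where(is_insufficient, "insufficient", "sufficient"),
            "arm": arm,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # baselines: proxies low-Ct; planted features drawn from the detectable
    # low-Ct stratum so the signature is measurable after QC
    baseline = rng.uniform(lo, hi, size=config.n_features)
    baseline[0] = 24.0  # miR-23a proxy
    baseline[1] = 21.0  # miR-451a proxy
    plantable = np.arange(2, config.n_features)
    planted = rng.choice(
        plantable,
        size=config.n_de_up + config.n_de_down + config.n_de_vitd_only,
        replace=False,
    )
    de_up = planted[: config.n_de_up]
    de_down = planted[config.n_de_up : config.n_de_up + config.n_de_down]
    vitd_only = planted[config.n_de_up + config.n_de_down :]
    low_cap = min(lo + 6.0, 27.0)
    baseline[planted] = rng.uniform(lo, max(low_cap, lo + 1.0), size=planted.size)

    # shared subset of the disease signature also tied to vitamin D:
    # up-features first (9 of 16 by default), remainder from the down set
    n_shared_up = min(config.n_de_up, int(round(config.n_de_vitd_shared * 9 / 16)))
    n_shared_up = min(n_shared_up, config.n_de_vitd_shared)
    n_shared_down = min(config.n_de_down, config.n_de_vitd_shared - n_shared_up)
    shared = np.concatenate([de_up[:n_shared_up], de_down[:n_shared_down]])

    ct = np.tile(baseline[:, None], (1, config.n_samples))
    # disease shifts (lower Ct = higher abundance = "up")
    ct[np.ix_(de_up, case_pos)] -= config.effect_size_ct
    ct[np.ix_(de_down, case_pos)] += config.effect_size_ct
    # vitamin-D shifts on shared + vitd-only features
    insuf_pos = np.flatnonzero(is_insufficient)
    vd_up = np.concatenate([de_up[:n_shared_up], vitd_only[: vitd_only.size // 2]])
    vd_down = np.concatenate([de_down[:n_shared_down], vitd_only[vitd_only.size // 2 :]])
    ct[np.ix_(vd_up, insuf_pos)] -= config.effect_size_ct
    ct[np.ix_(vd_down, insuf_pos)] += config.effect_size_ct

    # hidden factors
    if config.n_hidden_factors > 0:
        scores = rng.standard_normal((config.n_samples, config.n_hidden_factors))
        loadings = rng.standard_normal((config.n_features, config.n_hidden_factors))
        loadings[:2] = 0.0  # haemolysis reference proxies are stable
        ct += config.factor_sd * loadings @ scores.T
        factor_scores = pd.DataFrame(
            scores, index=sample_ids, columns=[f"factor{k+1}" for k in range(config.n_hidden_factors)]
        )
        factor_loadings = pd.DataFrame(
            loadings, index=feature_ids, columns=factor_scores.columns
        )
    else:
        factor_scores = pd.DataFrame(index=pd.Index(sample_ids))
        factor_loadings = pd.DataFrame(index=pd.Index(feature_ids))

    ct += rng.normal(0.0, config.noise_sd, size=ct.shape)

    # haemolysis: shift the miR-451a proxy down in contaminated samples so
    # ΔCq = Cq(23a) − Cq(451a) lands above the 5-cycle alert threshold
    hem_pool = np.flatnonzero(~is_case)
    if hem_pool.size < config.hemolysis_samples:
        hem_pool = np.arange(config.n_samples)
    hem_pos = rng.choice(hem_pool, size=config.hemolysis_samples, replace=False) if config.hemolysis_samples else np.array([], dtype=int)
    ct[1, hem_pos] -= rng.uniform(3.5, 6.0, size=hem_pos.size)

    true_values = pd.DataFrame(ct.copy(), index=feature_ids, columns=sample_ids)

    # abundance-dependent nondetects (proxies exempt: always-detected refs)
    mask = np.zeros_like(ct, dtype=bool)
    if config.nondetect_rate > 0:
        c0 = _calibrate_nondetect_center(ct[2:], config.nondetect_rate)
        p_nd = 1.0 / (1.0 + np.exp(-(ct[2:] - c0) / _ND_LOGISTIC_SCALE))
        mask[2:] = rng.random(p_nd.shape) < p_nd

    qc_fail = np.zeros_like(mask)
    if config.qc_flag_rate > 0:
        qc_fail[2:] = rng.random(ct[2:].shape) < config.qc_flag_rate

    values = pd.DataFrame(np.where(mask, np.nan, ct), index=feature_ids, columns=sample_ids)
    matrix = CtMatrix(
        values,
        nondetect=pd.DataFrame(mask, index=feature_ids, columns=sample_ids),
        qc_fail=pd.DataFrame(qc_fail, index=feature_ids, columns=sample_ids),
        metadata=metadata,
    )
    fid = np.array(feature_ids)
    truth = SyntheticTruth(
        de_up_ids=set(fid[de_up]),
        de_down_ids=set(fid[de_down]),
        vitd_de_ids=set(fid[np.concatenate([shared, vitd_only])]),
        shared_ids=set(fid[shared]),
        hemolysed_ids=set(np.array(sample_ids)[hem_pos]),
        factor_scores=factor_scores,
        factor_loadings=factor_loadings,
        true_values=true_values,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# interactome with a planted dense module
# ---------------------------------------------------------------------------

def generate_ppi(
    n_nodes: int = 500,
    background_p: float = 0.01,
    module_size: int = 50,
    module_p: float = 0.3,
    seed: int = 0,
) -> tuple[PPINetwork, SyntheticTruth]:
    """Erdős–Rényi background with a planted dense, connected subset.

    Edges within the planted module appear with probability ``module_p``
    (plus a random spanning tree guaranteeing connectivity); all node
    pairs also receive background edges with probability ``background_p``.
    Edge scores are uniform on the STRING integer scale (401-1000, i.e.,
    strictly above the 0.4 confidence threshold).
    """
    if module_size < 2:
        raise ValueError("module_size must be >= 2")
    if module_size > n_nodes:
        raise ValueError("module_size must be <= n_nodes")
    if module_p < background_p:
        raise ValueError("module_p must be >= background_p")
    rng = np.random.default_rng(seed)
    names = np.array([f"G{i:04d}" for i in range(1, n_nodes + 1)])
    module_idx = rng.choice(n_nodes, size=module_size, replace=False)
    module_set = set(module_idx.tolist())

    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n_nodes, k=1)
    edge_mask = rng.random(iu.size) < background_p
    in_module = np.isin(iu, module_idx) & np.isin(ju, module_idx)
    edge_mask |= in_module & (rng.random(iu.size) < module_p)
    # random spanning tree over the module for guaranteed connectivity
    perm = rng.permutation(module_idx)
    tree_pairs = {tuple(sorted((int(perm[k - 1]), int(perm[k])))) for k in range(1, module_size)}
    for a, b in zip(iu[edge_mask], ju[edge_mask]):
        tree_pairs.add((int(a), int(b)))
    for a, b in sorted(tree_pairs):
        score = int(rng.integers(401, 1001))
        g.add_edge(names[a], names[b], score=score / 1000.0)

    # isolated background nodes stay as nodes (degree 0)
    net = PPINetwork(g, min_score=0.4)
    truth = SyntheticTruth(planted_module_genes=set(names[sorted(module_set)]))
    return net, truth


# ---------------------------------------------------------------------------
# miRNA-target rank tables
# ---------------------------------------------------------------------------

def generate_target_tables(
    mirna_ids: Sequence[str],
    gene_ids: Sequence[str],
    planted_map: Mapping[str, Sequence[str]],
    n_sources: int = 4,
    rank_noise: float = 1.0,
    seed: int = 0,
    n_decoys_per_mirna: int = 20,
) -> list[pd.DataFrame]:
    """Per-source (mirna, gene, rank) tables with planted consensus pairs.

    Each planted pair is assigned to >= 2 randomly chosen sources, where
    it receives a top rank perturbed by Gaussian noise of scale
    ``rank_noise``; decoy pairs receive deep ranks well below the planted
    block. Rank 1 is best.
    """
    mirna_ids = list(mirna_ids)
    gene_set = set(gene_ids)
    for m, genes in planted_map.items():
        if m not in mirna_ids:
            raise ValueError(f"planted miRNA {m!r} not in mirna_ids")
        bad = set(genes) - gene_set
        if bad:
            raise ValueError(f"planted genes not in gene_ids: {sorted(bad)[:5]}")
    if not planted_map:
        warnings.warn("empty planted_map: generating decoy-only tables", stacklevel=2)
    rng = np.random.default_rng(seed)

    # which sources carry each planted pair
    assignment: dict[tuple[str, str], set[int]] = {}
    for m, genes in planted_map.items():
        for gsym in genes:
            k = int(rng.integers(2, n_sources + 1))
            assignment[(m, gsym)] = set(rng.choice(n_sources, size=k, replace=False).tolist())

    gene_arr = np.array(sorted(gene_set))
    tables = []
    for s in range(n_sources):
        rows = []
        for m in mirna_ids:
            planted_all = sorted(planted_map.get(m, []))
            planted_here = [g for g in planted_all if s in assignment[(m, g)]]
            latent: list[tuple[str, float]] = []
            order = rng.permutation(len(planted_here))
            for pos, g_i in enumerate(order):
                latent.append((planted_here[g_i], pos + 1 + rank_noise * rng.standard_normal()))
            decoy_pool = gene_arr[~np.isin(gene_arr, planted_all)]
            n_dec = min(n_decoys_per_mirna, decoy_pool.size)
            decoys = rng.choice(decoy_pool, size=n_dec, replace=False)
            deep_lo = len(planted_here) + 10.0
            for g_sym in decoys:
                latent.append((str(g_sym), float(rng.uniform(deep_lo, deep_lo + 10 * max(n_dec, 1)))))
            # planted entries occupy the top ranks (noise-perturbed); decoys
            # keep their uniform deep positions
            for g_sym, value in sorted(latent, key=lambda t: (t[1], t[0])):
                rows.append((m, g_sym, max(1, int(round(value)))))
        tables.append(pd.DataFrame(rows, columns=["mirna", "gene", "rank"]))
    return tables


# ---------------------------------------------------------------------------
# annotation sets
# ---------------------------------------------------------------------------

def generate_annotation_sets(
    gene_ids: Sequence[str],
    module_genes: Sequence[str],
    enriched_set_overlap: float = 0.8,
    n_sets: int = 10,
    set_size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
) -> tuple[dict[str, tuple[str, list[str]]], SyntheticTruth]:
    """GMT-style collection with one set overlapping the planted module.

    The designated set draws ``enriched_set_overlap`` of its members from
    ``module_genes`` (at overlap 1.0 it contains the whole module within
    the universe); the remaining sets are uniform draws.
    """
    if not 0.0 <= enriched_set_overlap <= 1.0:
        raise ValueError("enriched_set_overlap must be in [0, 1]")
    universe = sorted({str(g) for g in gene_ids})
    module = [g for g in dict.fromkeys(module_genes) if g in set(universe)]
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes exceed the gene universe")
    if not module:
        raise ValueError("module_genes has no members in the universe")
    rng = np.random.default_rng(seed)

    sets: dict[str, tuple[str, list[str]]] = {}
    if enriched_set_overlap == 1.0:
        members = list(module)
    else:
        size = int(rng.integers(lo, hi + 1))
        n_mod = min(len(module), max(1, int(round(enriched_set_overlap * size))))
        mod_part = list(rng.choice(np.array(module), size=n_mod, replace=False))
        outside = np.array([g for g in universe if g not in set(module)])
        n_out = min(size - n_mod, outside.size)
        members = mod_part + list(rng.choice(outside, size=n_out, replace=False))
    sets["SET_ENRICHED"] = ("designed module-overlapping set", sorted(members))

    uni_arr = np.array(universe)
    for i in range(1, n_sets):
        size = int(rng.integers(lo, hi + 1))
        sets[f"SET_{i:03d}"] = (
            "uniform background set",
            sorted(rng.choice(uni_arr, size=size, replace=False).tolist()),
        )
    truth = SyntheticTruth(planted_module_genes=set(module), enriched_set_id="SET_ENRICHED")
    return sets, truth


# ---------------------------------------------------------------------------
# writers (file dialects consumed by the pipeline readers)
# ---------------------------------------------------------------------------

def write_metadata_tsv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def write_string_tsv(net: PPINetwork, path: str | Path) -> None:
    """Write a STRING-dialect TSV (protein1, protein2, combined_score 0-1000)."""
    rows = [
        (a, b, int(round(d["score"] * 1000)))
        for a, b, d in sorted(net.graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"]).to_csv(
        path, sep="\t", index=False
    )


def write_rank_tables_tsv(tables: Sequence[pd.DataFrame], path: str | Path,
                          source_names: Sequence[str] | None = None) -> None:
    if source_names is None:
        source_names = [f"source{i+1}" for i in range(len(tables))]
    frames = []
    for name, t in zip(source_names, tables):
        t = t.copy()
        t.insert(0, "source", name)
        frames.append(t)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_truth_json(truth: SyntheticTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
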