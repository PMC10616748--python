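"""Over-representation statistics for annotation sets and gene attributes.

Upper-tail hypergeometric tests of a query gene set against GMT-style
annotation collections (with Benjamini–Hochberg adjustment across sets)
and against binary gene attributes such as "expressed in placenta".
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .network_module import normalize_symbol

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_attribute_tsv",
    "hypergeometric_enrichment",
    "attribute_enrichment",
]

MIN_SET_SIZE_DEFAULT = 3
MAX_SET_SIZE_DEFAULT = 2000


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT file: set_id -> (description, member genes)."""
    out: dict[str, tuple[str, list[str]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {i}: GMT rows need id, description, >=1 member")
        out[parts[0]] = (parts[1], parts[2:])
    return out


def write_gmt(sets: Mapping[str, tuple[str, Sequence[str]]], path: str | Path) -> None:
    lines = [
        "\t".join([set_id, desc, *map(str, genes)])
        for set_id, (desc, genes) in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_attribute_tsv(path: str | Path) -> pd.Series:
    """Read a two-column attribute table (gene, 0/1) into a boolean Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "flag"], comment="#")
    # tolerate a header row
    if str(df.iloc[0, 1]).lower() in ("flag", "attribute", "value"):
        df = df.iloc[1:]
    s = pd.Series(
        df["flag"].astype(int).astype(bool).to_numpy(),
        index=df["gene"].map(normalize_symbol),
    )
    return s[~s.index.duplicated()]


def _prepare_query(query_genes: Iterable[str], universe: Iterable[str]) -> tuple[set[str], set[str]]:
    uni = {normalize_symbol(g) for g in universe}
    if not uni:
        raise ValueError("empty universe")
    q_raw = {normalize_symbol(g) for g in query_genes}
    if not q_raw:
        raise ValueError("empty query")
    dropped = q_raw - uni
    if dropped:
        warnings.warn(
            f"{len(dropped)} query genes outside the universe were dropped", stacklevel=3
        )
    query = q_raw & uni
    if not query:
        raise ValueError("no query genes in the universe")
    return query, uni


def hypergeometric_enrichment(
    query_genes: Iterable[str],
    annotation: Mapping[str, tuple[str, Sequence[str]]],
    universe: Iterable[str],
    fdr_cutoff: float = 0.05,
    min_set_size: int = MIN_SET_SIZE_DEFAULT,
    max_set_size: int = MAX_SET_SIZE_DEFAULT,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation across annotation sets.

    For each set with universe-restricted size in
    [``min_set_size``, ``max_set_size``], p = P(X >= overlap) for X
    hypergeometric(universe, set, query); Benjamini–Hochberg adjusts
    across the tested sets. Rows are ordered by p; ``significant`` flags
    fdr < ``fdr_cutoff``.
    """
    query, uni = _prepare_query(query_genes, universe)
    M, n = len(uni), len(query)
    rows = []
    for set_id, (desc, members) in annotation.items():
        members_u = {normalize_symbol(g) for g in members} & uni
        K = len(members_u)
        if not min_set_size <= K <= max_set_size:
            continue
        k = len(members_u & query)
        p = float(hypergeom.sf(k - 1, M, K, n))  # P(X >= k); k=0 -> 1
        rows.append((set_id, desc, K, k, M, n, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(
            columns=["set_id", "description", "set_size", "overlap",
                     "universe_size", "query_size", "p_value", "fdr", "significant"]
        )
    df = pd.DataFrame(
        rows,
        columns=["set_id", "description", "set_size", "overlap", "universe_size", "query_size", "p_value"],
    )
    df["fdr"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["significant"] = df["fdr"] < fdr_cutoff
    return df.sort_values(["p_value", "set_id"]).reset_index(drop=True)


def attribute_enrichment(
    query_genes: Iterable[str],
    attribute: pd.Series | Mapping[str, bool],
    universe: Iterable[str],
) -> tuple[float, float]:
    """Fraction of the query carrying a binary attribute, with one-sided p.

    The null is the attribute's prevalence in the universe: p = P(X >=
    observed) under hypergeometric sampling of the query from the
    universe. Query genes with no attribute value are treated as lacking
    it, with a warning. Returns (fraction, p_value).
    """
    query, uni = _prepare_query(query_genes, universe)
    attr = pd.Series(attribute) if not isinstance(attribute, pd.Series) else attribute
    attr = attr.copy()
    attr.index = attr.index.map(normalize_symbol)
    missing = [g for g in query if g not in attr.index]
    if missing:
        warnings.warn(
            f"{len(missing)} query genes have no attribute value; treated as absent",
            stacklevel=2,
        )
    flagged_universe = {g for g in uni if bool(attr.get(g, False))}
    K = len(flagged_universe)
    k = len(query & flagged_universe)
    M, n = len(uni), len(query)
    fraction = k / n
    p = float(min(hypergeom.sf(k - 1, M, K, n), 1.0))
    return fraction, p
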