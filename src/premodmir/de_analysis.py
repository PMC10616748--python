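"""Differential expression of miRNAs by the rank-product method, with
surrogate-variable adjustment for hidden expression heterogeneity.

The analysis runs on the expression scale (−Ct), so "upregulated" means a
lower Cq in cases; linear fold changes are reconstructed as
``2^(mean Ct_control − mean Ct_case)``. Significance is assessed by the
percentage of false prediction (pfp) from within-comparison permutations,
used as an FDR estimate with Benjamini–Hochberg-style step-up
monotonization. Two phenotype contrasts (e.g., preeclampsia vs normal
pregnancy and vitamin-D sufficient vs insufficient) can be intersected to
obtain a doubly supported signature.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .qc_normalize import CtMatrix

__all__ = [
    "normalize_mirna_name",
    "SurrogateVariableSet",
    "estimate_surrogate_variables",
    "remove_unwanted_variation",
    "DEResult",
    "rank_product_test",
    "fold_change_ct",
    "significant_features",
    "intersect_signatures",
    "write_signature_tsv",
]

_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")


def normalize_mirna_name(name: str, strip_prefix: bool = True) -> str:
    """Normalize a miRNA name for exact matching.

    Case-folds, maps unicode dashes to ``-``, optionally strips the species
    prefix (``hsa-``), and preserves the arm suffix (``-5p``/``-3p``).
    ``"hsa‐miR‐885‐5p"`` and ``"miR-885-5p"`` normalize identically.
    """
    s = str(name).strip().translate(_DASHES).casefold()
    if strip_prefix:
        s = re.sub(r"^hsa-", "", s)
    return s


def has_arm_suffix(name: str) -> bool:
    return bool(re.search(r"-(5p|3p)$", normalize_mirna_name(name)))


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

def _as_values(expr) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Accept a CtMatrix or features x samples DataFrame."""
    if isinstance(expr, CtMatrix):
        if not expr.is_complete():
            raise ValueError("expression matrix must be complete (impute first)")
        df = expr.values
    else:
        df = pd.DataFrame(expr)
        if df.isna().to_numpy().any():
            raise ValueError("expression matrix must be complete (impute first)")
    return df.to_numpy(dtype=float), df.index, df.columns


def _design_matrix(
    samples: pd.Index,
    primary: pd.Series | Sequence | None,
    protect: pd.DataFrame | None,
) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded primary labels + protected covariates."""
    cols = [np.ones(len(samples))]
    names = ["intercept"]
    if primary is not None:
        prim = pd.Series(np.asarray(primary), index=samples) if not isinstance(primary, pd.Series) else primary.loc[samples]
        dummies = pd.get_dummies(prim.astype(str), drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(f"primary[{c}]")
    if protect is not None and len(protect.columns):
        prot = protect.loc[samples]
        for c in prot.columns:
            col = prot[c]
            if col.dtype == object or str(col.dtype) == "category":
                dummies = pd.get_dummies(col.astype(str), drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
                    names.append(f"{c}[{dc}]")
            else:
                cols.append(col.to_numpy(dtype=float))
                names.append(str(c))
    return np.column_stack(cols), names


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y (features x samples) on columns of X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


# ---------------------------------------------------------------------------
# surrogate variable analysis
# ---------------------------------------------------------------------------

@dataclass
class SurrogateVariableSet:
    """Surrogate variables capturing hidden expression heterogeneity."""

    scores: pd.DataFrame  # samples x n_sv, orthonormal columns
    method: str = "two-step"
    protected: list[str] = field(default_factory=list)

    @property
    def n_sv(self) -> int:
        return self.scores.shape[1]


def _num_sv_be(
    R: np.ndarray,
    X: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float = 0.05,
) -> int:
    """Buja–Eyuboglu parallel-analysis estimate of the number of surrogate
    variables from the residual matrix R (features x samples)."""
    n_eig = min(R.shape) - 1
    if n_eig < 1:
        return 0
    s = np.linalg.svd(R, compute_uv=False)[:n_eig]
    dstat = s**2 / (s**2).sum()
    exceed = np.zeros(n_eig)
    for _ in range(n_perm):
        Rp = rng.permuted(R, axis=1)  # permute within each feature row
        Rp = _residualize(Rp, X)
        sp = np.linalg.svd(Rp, compute_uv=False)[:n_eig]
        dstat0 = sp**2 / (sp**2).sum()
        exceed += dstat0 >= dstat
    pvals = (exceed + 1.0) / (n_perm + 1.0)
    pvals = np.maximum.accumulate(pvals)  # eigenvalue k cannot be more real than k-1
    return int(np.sum(pvals <= alpha))


def estimate_surrogate_variables(
    expr,
    primary,
    protect: pd.DataFrame | None = None,
    n_sv: int | str = "auto",
    n_perm: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> SurrogateVariableSet:
    """Estimate surrogate variables from residual expression structure.

    Two-step procedure: (1) residualize features on the primary phenotype
    and protected covariates; (2) when ``n_sv="auto"``, choose the number
    of surrogate variables by Buja–Eyuboglu permutation of the residual
    eigenvalue spectrum at significance ``alpha``; (3) take the leading
    right singular vectors of the residual matrix and refine each against
    the subset of features significantly associated with it.
    """
    Y, features, samples = _as_values(expr)
    rng = np.random.default_rng(seed)
    X, names = _design_matrix(samples, primary, protect)
    if Y.shape[1] <= X.shape[1]:
        raise ValueError(
            f"too few samples ({Y.shape[1]}) for {X.shape[1]} model covariates"
        )
    R = _residualize(Y, X)

    if n_sv == "auto":
        k = _num_sv_be(R, X, n_perm=n_perm, rng=rng, alpha=alpha)
    else:
        k = int(n_sv)
    k = min(k, min(R.shape) - 1)
    if k <= 0:
        empty = pd.DataFrame(index=samples)
        return SurrogateVariableSet(empty, protected=names[1:])

    _, _, Vt = np.linalg.svd(R, full_matrices=False)
    cand = Vt[:k].T  # samples x k

    # refinement: re-estimate each SV from the features it explains
    refined = np.empty_like(cand)
    n = Y.shape[1]
    for j in range(k):
        v = cand[:, j]
        rc = R - R.mean(axis=1, keepdims=True)
        vc = v - v.mean()
        denom = np.sqrt((rc**2).sum(axis=1) * (vc**2).sum())
        r = np.zeros(Y.shape[0])
        ok = denom > 0
        r[ok] = (rc[ok] @ vc) / denom[ok]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / np.maximum(1e-12, 1 - r**2))
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(np.abs(t), df=n - 2)
        sig = np.flatnonzero(_bh(p) < 0.10)
        if sig.size < 3:
            refined[:, j] = v
            continue
        sub = Y[sig] - Y[sig].mean(axis=1, keepdims=True)
        _, _, Vs = np.linalg.svd(sub, full_matrices=False)
        cors = np.abs(Vs @ v)
        best = Vs[int(np.argmax(cors))]
        if best @ v < 0:
            best = -best
        refined[:, j] = best

    # protect the primary contrast and covariates: SVs live in the orthogonal
    # complement of the model design, so removing them cannot alter the
    # primary effect; then enforce orthonormal scores, preserving order
    Xq, _ = np.linalg.qr(X)
    refined = refined - Xq @ (Xq.T @ refined)
    norms = np.linalg.norm(refined, axis=0)
    if np.any(norms < 1e-10):
        refined = cand - Xq @ (Xq.T @ cand)
    Q, _ = np.linalg.qr(refined)
    for j in range(k):
        if Q[:, j] @ refined[:, j] < 0:
            Q[:, j] = -Q[:, j]
    scores = pd.DataFrame(Q[:, :k], index=samples, columns=[f"SV{i+1}" for i in range(k)])
    return SurrogateVariableSet(scores, protected=names[1:])


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.clip(adj, 0, 1)


def remove_unwanted_variation(
    expr,
    svs: SurrogateVariableSet | pd.DataFrame | None,
    protect: pd.DataFrame | None = None,
    primary=None,
) -> pd.DataFrame:
    """Regress surrogate variables and nuisance covariates out of each feature.

    Each feature is fit on [intercept, primary phenotype, protected nuisance
    covariates, SVs]; the returned matrix keeps the intercept, the primary
    effect, and the residual, so the case-control contrast is unchanged in
    expectation while SV/nuisance components are removed.
    """
    Y, features, samples = _as_values(expr)
    sv_df = svs.scores if isinstance(svs, SurrogateVariableSet) else svs
    nuis_cols: list[np.ndarray] = []
    nuis_names: list[str] = []
    if protect is not None and len(protect.columns):
        Xp, np_names = _design_matrix(samples, None, protect)
        nuis_cols.extend(Xp[:, 1:].T)
        nuis_names.extend(np_names[1:])
    if sv_df is not None and sv_df.shape[1]:
        for c in sv_df.columns:
            nuis_cols.append(sv_df.loc[samples, c].to_numpy(dtype=float))
            nuis_names.append(str(c))
    if not nuis_cols:
        return pd.DataFrame(Y, index=features, columns=samples)

    Xk, keep_names = _design_matrix(samples, primary, None)
    X = np.column_stack([Xk] + nuis_cols)
    all_names = keep_names + nuis_names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = _collinear_columns(X, all_names)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    nuis_idx = np.arange(Xk.shape[1], X.shape[1])
    adjusted = Y - (X[:, nuis_idx] @ beta[nuis_idx]).T
    return pd.DataFrame(adjusted, index=features, columns=samples)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    base_rank = 0
    cols: list[np.ndarray] = []
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        r = np.linalg.matrix_rank(trial)
        if r > base_rank:
            cols.append(X[:, j])
            base_rank = r
        else:
            bad.append(names[j])
    return bad


# ---------------------------------------------------------------------------
# rank product
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-feature rank-product statistics for a two-group contrast.

    ``table`` columns: ``rp_up``, ``rp_down`` (geometric-mean ranks, >= 1),
    ``pfp_up``, ``pfp_down`` (percentage of false prediction, clipped to
    [0, 1] after step-up monotonization), ``fold_change`` (linear, case vs
    control; > 1 means up in cases) and ``direction`` at the default 0.05
    cutoff.
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int
    case_label: str
    control_label: str
    n_comparisons: int
    comparisons: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "case_label": self.case_label,
            "control_label": self.control_label,
            "n_comparisons": self.n_comparisons,
            "features": self.table.reset_index().rename(columns={"index": "mirna"}).to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _two_groups(groups, samples: pd.Index, case_label: str | None):
    g = pd.Series(np.asarray(groups), index=samples) if not isinstance(groups, pd.Series) else groups.loc[samples]
    levels = sorted(map(str, g.astype(str).unique()))
    if len(levels) != 2:
        raise ValueError(f"groups must have exactly 2 levels, got {levels}")
    if case_label is None:
        case_label = "case" if "case" in levels else levels[0]
    case_label = str(case_label)
    if case_label not in levels:
        raise ValueError(f"case_label {case_label!r} not among {levels}")
    control_label = next(l for l in levels if l != case_label)
    case_idx = np.flatnonzero((g.astype(str) == case_label).to_numpy())
    ctrl_idx = np.flatnonzero((g.astype(str) == control_label).to_numpy())
    return case_idx, ctrl_idx, case_label, control_label


def _rank_columns(D: np.ndarray) -> np.ndarray:
    """Average-tie ranks of each column; rank 1 = smallest."""
    out = np.empty_like(D)
    for j in range(D.shape[1]):
        out[:, j] = rankdata(D[:, j], method="average")
    return out


def _geomean_ranks(ranks: np.ndarray) -> np.ndarray:
    return np.exp(np.log(ranks).mean(axis=1))


def _pfp(rp: np.ndarray, null_sorted: np.ndarray, n_perm: int) -> np.ndarray:
    """Percentage of false prediction with step-up monotonization.

    For the feature at position r in the ascending rp ordering, the
    expected number of null rp values <= its observed rp (per permutation)
    divided by r; then a step-up pass enforces monotonicity along the
    ranked list, and values are clipped to [0, 1].
    """
    order = np.argsort(rp, kind="stable")
    counts = np.searchsorted(null_sorted, rp[order], side="right")
    expected_fp = counts / n_perm
    pfp_sorted = expected_fp / np.arange(1, rp.size + 1)
    pfp_sorted = np.minimum.accumulate(pfp_sorted[::-1])[::-1]
    out = np.empty_like(pfp_sorted)
    out[order] = np.clip(pfp_sorted, 0.0, 1.0)
    return out


def rank_product_test(
    expr,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
    case_label: str | None = None,
    max_comparisons: int = 50,
    fold_change: pd.Series | None = None,
    scheme: str = "disjoint",
) -> DEResult:
    """Rank-product differential expression between two groups.

    ``expr`` is a complete features x samples matrix on the *expression*
    scale (use −Ct for qPCR data, so that larger values mean higher
    abundance). Each comparison pits one case sample against one control
    sample; features are ranked by their between-sample difference and the
    rank product is the geometric mean of those ranks, computed separately
    for the up and down directions. The null distribution comes from
    ``n_perm`` permutations of feature values within comparisons, yielding
    the pfp.

    ``scheme`` selects the pairing: ``"disjoint"`` (default) pairs each
    case with a distinct control (each sample enters at most one
    comparison, so comparisons are independent and the permutation null is
    exact); ``"all-pairs"`` uses every case-control pairing. Either way,
    at most ``max_comparisons`` comparisons are used, sampled with
    ``seed``.

    ``fold_change`` may supply precomputed linear fold changes; otherwise
    they are derived as ``2^(case mean − control mean)`` of ``expr``
    (exact when ``expr`` is on a log2/−Ct scale).
    """
    Y, features, samples = _as_values(expr)
    case_idx, ctrl_idx, case_label, control_label = _two_groups(groups, samples, case_label)
    if case_idx.size < 2 or ctrl_idx.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if n_perm < 10:
        warnings.warn(f"n_perm={n_perm} is very small; pfp estimates will be unstable", stacklevel=2)

    rng = np.random.default_rng(seed)
    if scheme == "disjoint":
        k = min(case_idx.size, ctrl_idx.size, max_comparisons)
        ci = rng.permutation(case_idx)[:k] if case_idx.size > k else case_idx
        cj = rng.permutation(ctrl_idx)[:k] if ctrl_idx.size > k else ctrl_idx
        pairs = list(zip(ci.tolist(), cj.tolist()))
    elif scheme == "all-pairs":
        pairs = [(i, j) for i in case_idx for j in ctrl_idx]
        if len(pairs) > max_comparisons:
            sel = rng.choice(len(pairs), size=max_comparisons, replace=False)
            pairs = [pairs[int(s)] for s in sorted(sel)]
    else:
        raise ValueError("scheme must be 'disjoint' or 'all-pairs'")
    D = np.column_stack([Y[:, i] - Y[:, j] for i, j in pairs])
    n_feat, n_comp = D.shape

    ranks_up = _rank_columns(-D)   # rank 1 = most up in cases
    ranks_down = _rank_columns(D)  # rank 1 = most down in cases
    rp_up = _geomean_ranks(ranks_up)
    rp_down = _geomean_ranks(ranks_down)

    # null: uniformly random rank columns (== permuting values within comparisons)
    base = np.arange(1.0, n_feat + 1.0)
    null_rp = np.empty((n_perm, n_feat))
    log_acc = np.empty((n_feat, n_comp))
    for p in range(n_perm):
        for c in range(n_comp):
            log_acc[:, c] = np.log(rng.permutation(base))
        null_rp[p] = np.exp(log_acc.mean(axis=1))
    null_sorted = np.sort(null_rp.ravel())

    pfp_up = _pfp(rp_up, null_sorted, n_perm)
    pfp_down = _pfp(rp_down, null_sorted, n_perm)

    if fold_change is None:
        fc = np.power(2.0, Y[:, case_idx].mean(axis=1) - Y[:, ctrl_idx].mean(axis=1))
        fold_change = pd.Series(fc, index=features)
    else:
        fold_change = fold_change.reindex(features)

    table = pd.DataFrame(
        {
            "rp_up": rp_up,
            "rp_down": rp_down,
            "pfp_up": pfp_up,
            "pfp_down": pfp_down,
            "fold_change": fold_change.to_numpy(dtype=float),
        },
        index=features,
    )
    table["direction"] = _call_directions(table, 0.05)
    comparisons = [(str(samples[i]), str(samples[j])) for i, j in pairs]
    return DEResult(table, n_perm, seed, case_label, control_label, n_comp, comparisons)


def _call_directions(table: pd.DataFrame, fdr: float) -> pd.Series:
    up = table["pfp_up"].to_numpy()
    down = table["pfp_down"].to_numpy()
    fc = table["fold_change"].to_numpy()
    best = np.minimum(up, down)
    direction = np.where(
        best < fdr,
        np.where(up < down, "up", np.where(down < up, "down", np.where(fc >= 1.0, "up", "down"))),
        "none",
    )
    return pd.Series(direction, index=table.index)


def fold_change_ct(ct_values: pd.DataFrame, groups, case_label: str | None = None) -> pd.Series:
    """Linear fold change from Ct-scale group means.

    FC = 2^(mean Ct_control − mean Ct_case); FC > 1 means higher abundance
    (lower Cq) in cases.
    """
    df = pd.DataFrame(ct_values)
    case_idx, ctrl_idx, *_ = _two_groups(groups, df.columns, case_label)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValueError("both groups must be non-empty")
    Y = df.to_numpy(dtype=float)
    return pd.Series(
        np.power(2.0, Y[:, ctrl_idx].mean(axis=1) - Y[:, case_idx].mean(axis=1)),
        index=df.index,
        name="fold_change",
    )


def significant_features(de: DEResult, fdr: float = 0.05) -> pd.DataFrame:
    """Call the differential-expression signature at a pfp/FDR cutoff.

    Features with min(pfp_up, pfp_down) < ``fdr``; the winning direction is
    the side with the smaller pfp (pfp ties resolved by the fold-change
    sign, i.e., the larger |log FC| side). Each feature appears at most
    once. Columns: mirna, direction, fold_change, fdr.
    """
    t = de.table
    best = np.minimum(t["pfp_up"], t["pfp_down"])
    keep = best < fdr
    direction = _call_directions(t, fdr)
    sig = pd.DataFrame(
        {
            "mirna": t.index[keep],
            "direction": direction[keep].to_numpy(),
            "fold_change": t.loc[keep, "fold_change"].to_numpy(),
            "fdr": best[keep].to_numpy(),
        }
    )
    sig["_alfc"] = np.abs(np.log2(sig["fold_change"].replace(0, np.nan))).fillna(0.0)
    sig = sig.sort_values(["fdr", "_alfc", "mirna"], ascending=[True, False, True]).drop(columns="_alfc")
    return sig.reset_index(drop=True)


def intersect_signatures(sig_a: pd.DataFrame, sig_b: pd.DataFrame) -> pd.DataFrame:
    """Features called in both signatures, keyed by normalized miRNA name.

    The result carries both directions and both FDRs and is ordered by the
    first signature's pfp.
    """
    a = sig_a.copy()
    b = sig_b.copy()
    a["_key"] = a["mirna"].map(normalize_mirna_name)
    b["_key"] = b["mirna"].map(normalize_mirna_name)
    merged = a.merge(b, on="_key", suffixes=("_a", "_b"))
    merged = merged.sort_values("fdr_a").drop(columns="_key").reset_index(drop=True)
    merged = merged.rename(columns={"mirna_a": "mirna"}).drop(columns=["mirna_b"])
    return merged


def write_signature_tsv(sig: pd.DataFrame, path: str | Path) -> None:
    """Write a signature table (mirna, direction, fold_change, fdr)."""
    cols = [c for c in ("mirna", "direction", "fold_change", "fdr") if c in sig.columns]
    sig.to_csv(path, sep="\t", index=False, columns=cols if cols else None)
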