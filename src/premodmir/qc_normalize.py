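"""Quality control and normalization of qPCR miRNA Ct matrices.

Implements the pre-processing chain used for circulating-miRNA profiling on
OpenArray-style qPCR panels: instrument-flag / detection-cycle masking,
haemolysis assessment from the miR-23a/miR-451a ΔCq, feature-level
missingness filtering, multi-sample quantile normalization of Ct values,
and Bayesian-PCA imputation of nondetects.

Conventions
-----------
* Matrices are features x samples; lower Cq means higher abundance.
* Nondetects are represented as ``NaN`` in ``CtMatrix.values`` and ``True``
  in ``CtMatrix.nondetect``.
* Instrument QC flags (vendor amplification-score / Cq-confidence failures)
  are consumed as a boolean mask; they are never recomputed here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CtMatrix",
    "HemolysisReport",
    "MissingnessReport",
    "read_ct_csv",
    "read_metadata_tsv",
    "apply_detection_filter",
    "hemolysis_assess",
    "filter_by_missingness",
    "quantile_normalize",
    "impute_bpca",
]

DETECTION_CT_DEFAULT = 30.0
MISSINGNESS_MAX_DEFAULT = 0.20
HEMOLYSIS_POSSIBLE_DCQ = 5.0
HEMOLYSIS_HIGH_DCQ = 7.0


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class CtMatrix:
    """A features x samples Cq matrix with nondetect and QC-flag masks.

    Parameters
    ----------
    values
        Cq values; ``NaN`` where the cell is a nondetect.
    nondetect
        Boolean mask, ``True`` where no amplification call was made (or the
        cell has been masked by a filter).
    qc_fail
        Boolean mask of wells failing vendor instrument QC. Supplied as
        input; treated as nondetects by :func:`apply_detection_filter`.
    metadata
        Per-sample table indexed by sample id (columns such as ``group``,
        ``vitd``, ``arm``).
    """

    values: pd.DataFrame
    nondetect: pd.DataFrame | None = None
    qc_fail: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.nondetect is None:
            self.nondetect = self.values.isna()
        if self.qc_fail is None:
            self.qc_fail = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        for name, mask in (("nondetect", self.nondetect), ("qc_fail", self.qc_fail)):
            if mask.shape != self.values.shape:
                raise ValueError(f"{name} mask shape {mask.shape} != values shape {self.values.shape}")
            if not mask.index.equals(self.values.index) or not mask.columns.equals(self.values.columns):
                raise ValueError(f"{name} mask index/columns do not match values")
        self.nondetect = self.nondetect.astype(bool)
        self.qc_fail = self.qc_fail.astype(bool)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        detected = self.values.to_numpy()[~self.nondetect.to_numpy()]
        if detected.size and not np.isfinite(detected).all():
            raise ValueError("non-finite Cq values in detected cells")
        if self.metadata is not None:
            missing = self.values.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing for samples: {sorted(missing)[:5]}")
            self.metadata = self.metadata.loc[self.values.columns]

    # -- basic accessors ----------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "CtMatrix":
        return CtMatrix(
            self.values.copy(),
            self.nondetect.copy(),
            self.qc_fail.copy(),
            None if self.metadata is None else self.metadata.copy(),
        )

    def select_features(self, ids: Sequence[str]) -> "CtMatrix":
        ids = list(ids)
        return CtMatrix(
            self.values.loc[ids],
            self.nondetect.loc[ids],
            self.qc_fail.loc[ids],
            None if self.metadata is None else self.metadata.copy(),
        )

    def select_samples(self, ids: Sequence[str]) -> "CtMatrix":
        ids = list(ids)
        return CtMatrix(
            self.values[ids],
            self.nondetect[ids],
            self.qc_fail[ids],
            None if self.metadata is None else self.metadata.loc[ids],
        )

    def drop_samples(self, ids: Iterable[str]) -> "CtMatrix":
        keep = [s for s in self.sample_ids if s not in set(ids)]
        return self.select_samples(keep)

    def missing_fraction(self) -> pd.Series:
        """Per-feature fraction of nondetect cells."""
        return self.nondetect.mean(axis=1)

    def is_complete(self) -> bool:
        return not bool(self.nondetect.to_numpy().any())

    # -- i/o ----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        """Write as CSV with empty cells for nondetects."""
        out = self.values.where(~self.nondetect)
        out.to_csv(path, index_label="mirna")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        nd = float(self.nondetect.to_numpy().mean()) if self.values.size else 0.0
        return f"CtMatrix({self.n_features} features x {self.n_samples} samples, {nd:.1%} nondetect)"


def read_ct_csv(path: str | Path, metadata: pd.DataFrame | None = None) -> CtMatrix:
    """Read a Ct CSV (rows = miRNA ids, columns = sample ids, empty = nondetect)."""
    values = pd.read_csv(path, index_col=0)
    values.index = values.index.astype(str).rename(None)
    values.columns = values.columns.astype(str)
    return CtMatrix(values, metadata=metadata)


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, group, vitd, arm, ...)."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns:
        raise ValueError(f"{path}: metadata must have a 'sample_id' column")
    return meta.set_index("sample_id")


# ---------------------------------------------------------------------------
# detection / instrument-flag filter
# ---------------------------------------------------------------------------

def apply_detection_filter(ct: CtMatrix, threshold: float = DETECTION_CT_DEFAULT) -> CtMatrix:
    """Mask cells at or above the detection cycle cutoff and QC-flagged wells.

    Cells with Cq >= ``threshold`` (the abundance cutoff; default 30 cycles)
    or with the instrument QC flag set become nondetects. Retained values
    are untouched; the operation is idempotent.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    out = ct.copy()
    above = out.values.ge(threshold) & ~out.nondetect
    mask = out.nondetect | above | out.qc_fail
    out.values = out.values.where(~mask)
    out.nondetect = mask
    return out


# ---------------------------------------------------------------------------
# haemolysis ΔCq
# ---------------------------------------------------------------------------

@dataclass
class HemolysisReport:
    """Per-sample haemolysis assessment from the miR-23a/miR-451a ΔCq.

    ΔCq = mean Cq(miR-23a) − mean Cq(miR-451a). Erythrocyte lysis releases
    miR-451a into plasma, lowering its Cq and inflating ΔCq: values above
    ``possible_threshold`` flag possible haemolysis, above
    ``high_threshold`` a high risk.
    """

    table: pd.DataFrame  # index sample_id; columns delta_cq, status
    mir23a_ids: tuple[str, ...]
    mir451a_ids: tuple[str, ...]
    possible_threshold: float = HEMOLYSIS_POSSIBLE_DCQ
    high_threshold: float = HEMOLYSIS_HIGH_DCQ

    @property
    def excluded_samples(self) -> list[str]:
        """Samples whose status is not ``pass`` (excluded by default)."""
        return list(self.table.index[self.table["status"] != "pass"])

    def to_dict(self) -> dict:
        return {
            "mir23a_ids": list(self.mir23a_ids),
            "mir451a_ids": list(self.mir451a_ids),
            "possible_threshold": self.possible_threshold,
            "high_threshold": self.high_threshold,
            "samples": {
                s: {"delta_cq": None if pd.isna(r.delta_cq) else float(r.delta_cq), "status": r.status}
                for s, r in self.table.iterrows()
            },
        }


def _as_id_tuple(x: str | Sequence[str]) -> tuple[str, ...]:
    return (x,) if isinstance(x, str) else tuple(x)


def hemolysis_assess(
    ct: CtMatrix,
    mir23a_id: str | Sequence[str],
    mir451a_id: str | Sequence[str],
    possible_threshold: float = HEMOLYSIS_POSSIBLE_DCQ,
    high_threshold: float = HEMOLYSIS_HIGH_DCQ,
) -> HemolysisReport:
    """Assess haemolysis per sample from reference-miRNA Cq values.

    ``mir23a_id``/``mir451a_id`` may be single feature ids or lists of
    replicate-well ids; the mean Cq over the given wells is used. A sample
    in which either reference is nondetected is reported ``indeterminate``.
    """
    ids23 = _as_id_tuple(mir23a_id)
    ids451 = _as_id_tuple(mir451a_id)
    for fid in (*ids23, *ids451):
        if fid not in ct.feature_ids:
            raise KeyError(f"reference feature {fid!r} not in matrix")
    detected = ~ct.nondetect
    rows = []
    for s in ct.sample_ids:
        ok23 = bool(detected.loc[list(ids23), s].all())
        ok451 = bool(detected.loc[list(ids451), s].all())
        if not (ok23 and ok451):
            rows.append((s, np.nan, "indeterminate"))
            continue
        dcq = float(ct.values.loc[list(ids23), s].mean() - ct.values.loc[list(ids451), s].mean())
        if dcq > high_threshold:
            status = "high_risk"
        elif dcq > possible_threshold:
            status = "possible"
        else:
            status = "pass"
        rows.append((s, dcq, status))
    table = pd.DataFrame(rows, columns=["sample_id", "delta_cq", "status"]).set_index("sample_id")
    return HemolysisReport(table, ids23, ids451, possible_threshold, high_threshold)


# ---------------------------------------------------------------------------
# missingness filter
# ---------------------------------------------------------------------------

@dataclass
class MissingnessReport:
    """Result of the per-feature missingness filter."""

    matrix: CtMatrix
    dropped_ids: list[str]
    fractions: pd.Series
    max_missing_fraction: float

    def __iter__(self):  # allow tuple unpacking: matrix, dropped
        return iter((self.matrix, self.dropped_ids))


def filter_by_missingness(
    ct: CtMatrix, max_missing_fraction: float = MISSINGNESS_MAX_DEFAULT
) -> MissingnessReport:
    """Drop features whose nondetect fraction strictly exceeds the cutoff.

    The rule is "more than": a feature missing in exactly 20% of samples is
    retained at the default cutoff.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = ct.missing_fraction()
    keep = frac.index[frac <= max_missing_fraction]
    dropped = [f for f in ct.feature_ids if f not in set(keep)]
    if len(keep) == 0:
        raise ValueError("missingness filter dropped every feature")
    return MissingnessReport(ct.select_features(list(keep)), dropped, frac, max_missing_fraction)


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(ct: CtMatrix) -> CtMatrix:
    """Equalize each sample's detected-Cq distribution to a common reference.

    The reference is the mean of the per-sample order statistics (each
    sample's sorted detected values, linearly interpolated onto a common
    grid when samples differ in detected counts). Nondetects are excluded
    from rank computation and remain masked; ties map to the average of the
    tied ranks' reference values.
    """
    if ct.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    n_ref = ct.n_features
    if n_ref < 2:
        raise ValueError("quantile normalization needs at least 2 features")
    grid = np.linspace(0.0, 1.0, n_ref)
    vals = ct.values.to_numpy(copy=True)
    det = ~ct.nondetect.to_numpy()

    profiles = np.empty((ct.n_samples, n_ref))
    for j in range(ct.n_samples):
        v = np.sort(vals[det[:, j], j])
        if v.size < 2:
            raise ValueError(
                f"sample {ct.sample_ids[j]!r} has fewer than 2 detected values"
            )
        profiles[j] = np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    reference = profiles.mean(axis=0)

    out = vals.copy()
    for j in range(ct.n_samples):
        idx = np.flatnonzero(det[:, j])
        v = vals[idx, j]
        r = rankdata(v, method="average")  # 1..m, ties averaged
        pos = (r - 1.0) / (v.size - 1.0)
        out[idx, j] = np.interp(pos, grid, reference)

    res = ct.copy()
    res.values = pd.DataFrame(out, index=ct.feature_ids, columns=ct.sample_ids).where(~ct.nondetect)
    return res


# ---------------------------------------------------------------------------
# Bayesian PCA imputation
# ---------------------------------------------------------------------------

@dataclass
class BpcaFit:
    """Convergence diagnostics of the variational Bayesian-PCA imputer."""

    n_components: int
    n_iter: int
    converged: bool
    tau: float
    delta: float


def impute_bpca(
    ct: CtMatrix,
    n_components: int | None = None,
    tol: float = 1e-4,
    max_iter: int = 1000,
    seed: int | None = None,
) -> CtMatrix:
    """Fill nondetects with the Bayesian-PCA posterior mean.

    Variational EM for probabilistic PCA with an automatic-relevance
    (ARD) prior on the loading columns, estimated on the observed cells
    only; missing cells are replaced by their posterior mean ``W z + mu``.
    Observed cells are returned unchanged. Samples are treated as
    observations and features as variables.

    Parameters
    ----------
    n_components
        Latent dimensionality; defaults to ``min(10, min(shape) - 1)``. The
        ARD prior prunes unneeded components automatically.
    tol
        Convergence threshold on the maximum change of imputed values
        between iterations (Cq units).
    max_iter
        Iteration cap; non-convergence returns the current fit with a
        warning.
    seed
        Accepted for interface uniformity; the algorithm is deterministic
        (SVD initialization).
    """
    if ct.is_complete():
        out = ct.copy()
        out._bpca_fit = BpcaFit(0, 0, True, float("inf"), 0.0)  # type: ignore[attr-defined]
        return out

    # samples x features orientation
    Y = ct.values.to_numpy().T.copy()
    miss = ct.nondetect.to_numpy().T
    n, d = Y.shape
    if n_components is None:
        n_components = max(1, min(10, min(n, d) - 1))
    if not 0 < n_components < min(n, d):
        raise ValueError(f"n_components must be in (0, {min(n, d)}) for a {n}x{d} matrix")
    q = n_components

    col_mean = np.nanmean(Y, axis=0)
    if np.isnan(col_mean).any():
        raise ValueError("a feature has no detected values; filter by missingness first")
    Yf = np.where(miss, col_mean[None, :], Y)
    mu = Yf.mean(axis=0)

    C = Yf - mu
    # SVD init
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    W = Vt[:q].T * (s[:q] / np.sqrt(n))[None, :]
    resid_var = max((C ** 2).sum() / (n * d) - (s[:q] ** 2).sum() / (n * d), 1e-8)
    tau = 1.0 / resid_var
    if not np.isfinite(tau) or tau <= 0:
        raise np.linalg.LinAlgError("degenerate covariance at initialization")
    alpha = np.full(q, 1.0)

    miss_rows = [np.flatnonzero(miss[i]) for i in range(n)]
    obs_rows = [np.flatnonzero(~miss[i]) for i in range(n)]
    for i, o in enumerate(obs_rows):
        if o.size == 0:
            raise ValueError(f"sample {ct.sample_ids[i]!r} has no detected values")

    imputed_prev = Yf[miss]
    n_obs_cells = int((~miss).sum())
    converged = False
    delta = np.inf
    it = 0
    eye_q = np.eye(q)
    for it in range(1, max_iter + 1):
        Sxx = np.zeros((q, q))
        Syx = np.zeros((d, q))
        mu_acc = np.zeros(d)
        sq_err = 0.0
        Ynew = Yf
        X_mean = np.empty((n, q))
        covs = []
        for i in range(n):
            o, m = obs_rows[i], miss_rows[i]
            Wo = W[o]
            M = eye_q + tau * (Wo.T @ Wo)
            Minv = np.linalg.inv(M)
            x = tau * (Minv @ (Wo.T @ (Y[i, o] - mu[o])))
            X_mean[i] = x
            covs.append(Minv)
            Sxx += Minv + np.outer(x, x)
            if m.size:
                Ynew[i, m] = W[m] @ x + mu[m]
        # mu update (from current reconstructions)
        mu_new = Ynew.mean(axis=0)
        # accumulate second-moment stats with the updated mean
        for i in range(n):
            o, m = obs_rows[i], miss_rows[i]
            x = X_mean[i]
            Syx[o] += np.outer(Y[i, o] - mu_new[o], x)
            if m.size:
                Syx[m] += np.outer(Ynew[i, m] - mu_new[m], x) + W[m] @ covs[i]
            r = Y[i, o] - W[o] @ x - mu_new[o]
            sq_err += float(r @ r) + float(np.trace(W[o].T @ W[o] @ covs[i]))
        mu = mu_new
        W = np.linalg.solve((Sxx + np.diag(alpha) / tau).T, Syx.T).T
        tau = min(n_obs_cells / max(sq_err, 1e-12), 1e12)
        alpha = d / (np.einsum("ij,ij->j", W, W) + 1e-12)

        imputed_now = Yf[miss]
        delta = float(np.max(np.abs(imputed_now - imputed_prev))) if imputed_now.size else 0.0
        imputed_prev = imputed_now.copy()
        if delta < tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"BPCA imputation did not converge after {max_iter} iterations (delta={delta:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    filled = Y.copy()
    filled[miss] = Yf[miss]
    out = ct.copy()
    out.values = pd.DataFrame(filled.T, index=ct.feature_ids, columns=ct.sample_ids)
    # masks record provenance of imputed cells; values are now complete
    out.nondetect = pd.DataFrame(False, index=ct.feature_ids, columns=ct.sample_ids)
    out.imputed_mask = ct.nondetect.copy()  # type: ignore[attr-defined]
    out._bpca_fit = BpcaFit(q, it, converged, float(tau), delta)  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

def write_qc_report(
    path: str | Path,
    hemolysis: HemolysisReport | None,
    missingness: MissingnessReport | None,
) -> None:
    """Write the QC report JSON (per-sample ΔCq/status, per-feature missingness)."""
    report: dict = {}
    if hemolysis is not None:
        report["hemolysis"] = hemolysis.to_dict()
    if missingness is not None:
        report["missingness"] = {
            "max_missing_fraction": missingness.max_missing_fraction,
            "dropped_features": list(missingness.dropped_ids),
            "fractions": {k: float(v) for k, v in missingness.fractions.items()},
        }
    Path(path).write_text(json.dumps(report, indent=2))
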