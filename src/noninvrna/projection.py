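"""Reference-space PCA: fit on a reference cohort, project query samples.

The reference (e.g. a deep tissue atlas) defines the space: the top-N
most variable features are selected on the reference alone, centered and
scaled by reference statistics, and decomposed; query samples are then
standardized with the reference means/SDs (or, optionally, their own)
and multiplied by the loadings. Works identically for expression
matrices and splicing inclusion-level (PSI) matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PcaModel",
    "select_hvg",
    "fit_reference_pca",
    "project",
    "filter_splice_events",
]


@dataclass
class PcaModel:
    """Frozen reference PCA: feature statistics plus loadings.

    loadings is features x components with orthonormal columns;
    variance_explained is the per-component fraction, non-increasing.
    """

    feature_ids: pd.Index
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    variance_explained: np.ndarray


def select_hvg(matrix: pd.DataFrame, n: int = 1000) -> pd.Index:
    """Top-n features by cross-sample variance (ties lexicographic).

    ``matrix`` is features x samples, already normalized. Constant
    features are never selected; if fewer than n non-constant features
    exist, all of them are returned with a warning.
    """
    var = matrix.var(axis=1, ddof=1)
    nonconst = var[var > 0]
    if len(nonconst) < n:
        warnings.warn(
            f"only {len(nonconst)} non-constant features available (requested {n})"
        )
        n = len(nonconst)
    order = nonconst.sort_index().sort_values(ascending=False, kind="stable")
    return order.index[:n]


def fit_reference_pca(matrix: pd.DataFrame, n_components: int) -> PcaModel:
    """PCA of the centered-and-scaled reference (features x samples).

    Features with zero SD are dropped with a warning before scaling.
    """
    n_feat, n_samp = matrix.shape
    if n_components > min(n_feat, n_samp - 1):
        raise ValueError("n_components exceeds min(features, samples - 1)")
    x = matrix.to_numpy(dtype=float).T  # samples x features
    sds = x.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s)")
    x = x[:, keep]
    feature_ids = matrix.index[keep]
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    z = (x - means) / sds
    # SVD gives orthonormal loadings and the full variance decomposition
    _, s, vt = np.linalg.svd(z, full_matrices=False)
    ve = s**2 / (z.shape[0] - 1) / z.shape[1]
    return PcaModel(
        feature_ids=feature_ids,
        means=means,
        sds=sds,
        loadings=vt[:n_components].T,
        variance_explained=ve[:n_components],
    )


def project(
    model: PcaModel,
    query: pd.DataFrame,
    scaling: str = "reference",
    max_missing_frac: float = 0.2,
) -> pd.DataFrame:
    """Project query samples (features x samples) into the model space.

    scaling="reference" standardizes the query by the model's means and
    SDs (the default, giving a well-defined shared space);
    scaling="self" standardizes by the query's own statistics. Model
    features absent from the query are imputed at the model mean (zero
    score contribution) up to ``max_missing_frac``, beyond which an
    error is raised instead of silently imputing.
    """
    if scaling not in ("reference", "self"):
        raise ValueError("scaling must be 'reference' or 'self'")
    present = model.feature_ids.isin(query.index)
    n_missing = int((~present).sum())
    if n_missing > max_missing_frac * len(model.feature_ids):
        raise ValueError(
            f"{n_missing}/{len(model.feature_ids)} model features missing from query"
        )
    if n_missing:
        warnings.warn(f"imputing {n_missing} missing feature(s) at the model mean")
    x = np.tile(model.means, (query.shape[1], 1))  # samples x features
    idx = np.flatnonzero(present)
    sub = query.loc[model.feature_ids[present]].to_numpy(dtype=float).T
    x[:, idx] = sub
    if scaling == "reference":
        z = (x - model.means) / model.sds
    else:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        z = (x - mu) / sd
    scores = z @ model.loadings
    cols = [f"PC{i + 1}" for i in range(model.loadings.shape[1])]
    return pd.DataFrame(scores, index=query.columns, columns=cols)


def filter_splice_events(
    psi: pd.DataFrame,
    sig_flag: pd.Series,
    tissues: pd.Series,
    sd_mult: float = 2.0,
    mean_psi: float = 0.3,
) -> pd.DataFrame:
    """Filter an inclusion-level matrix before PCA.

    Drops any event with zero inclusion in any sample of any tissue;
    keeps events flagged significant by the upstream splicing caller
    whose per-tissue median inclusion departs from ``mean_psi`` by more
    than ``sd_mult`` cross-event SDs (SD of per-event overall median
    inclusion, across events) in at least one tissue. Returns the
    surviving rows.
    """
    if not ((psi.to_numpy() >= 0) & (psi.to_numpy() <= 1)).all():
        raise ValueError("PSI values must lie in [0, 1]")
    sig_flag = sig_flag.reindex(psi.index)
    tissues = tissues.reindex(psi.columns)
    if sig_flag.isna().any() or tissues.isna().any():
        raise KeyError("sig_flag must cover events and tissues must cover samples")

    keep = pd.Series(True, index=psi.index)
    tissue_medians = {}
    for t in tissues.unique():
        block = psi.loc[:, tissues[tissues == t].index]
        keep &= (block > 0).all(axis=1)
        tissue_medians[t] = block.median(axis=1)
    sd = float(psi.median(axis=1).std(ddof=1))
    dev = pd.DataFrame(tissue_medians).sub(mean_psi).abs().max(axis=1)
    keep &= sig_flag.astype(bool) & (dev > sd_mult * sd)
    out = psi.loc[keep]
    if out.empty:
        warnings.warn("all splicing events were filtered out")
    return out
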