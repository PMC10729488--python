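"""Expression normalization: TPM, expression filters, TMM factors, INT.

The cis-association pipeline normalizes counts with TMM scaling factors
(trimmed mean of M-values, the edgeR between-sample factor) followed by
a per-gene rank-based inverse normal transform; expression filters keep
genes jointly passing raw-count and TPM thresholds in a minimum fraction
of samples within a tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_tpm",
    "expression_filter",
    "tmm_factors",
    "inverse_normal_transform",
    "median_ratio_log_normalize",
    "EXPRESSION_FILTER_PRESETS",
]

# joint raw-count / TPM thresholds; "study" follows the noninvasive
# cohort's filter, "gtex" the GTEx standard (count floor 6)
EXPRESSION_FILTER_PRESETS = {
    "study": {"min_count": 8, "min_tpm": 0.1, "min_frac": 0.2},
    "gtex": {"min_count": 6, "min_tpm": 0.1, "min_frac": 0.2},
}


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from counts and gene lengths (bp).

    Per sample: rate_g = count_g / length_g, TPM_g = 1e6 rate_g / sum(rate).
    Columns of nonzero-depth samples sum to 1e6. A zero-depth sample
    yields an all-zero column with a warning rather than NaN.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise KeyError("every gene in counts needs a length")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be >= 1 bp")
    rate = counts.div(lengths.astype(float), axis=0)
    tot = rate.sum(axis=0)
    zero = tot == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-depth sample(s) produce all-zero TPM columns",
            stacklevel=2,
        )
        tot = tot.mask(zero, 1.0)
    return rate.div(tot, axis=1) * 1e6


def expression_filter(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    min_count: float = 8,
    min_tpm: float = 0.1,
    min_frac: float = 0.2,
) -> pd.Index:
    """Genes expressed in a tissue: count and TPM floors met jointly.

    A gene is kept iff (count >= min_count AND tpm >= min_tpm) in at
    least ``min_frac`` of the samples. Samples are expected to be
    pre-restricted to one tissue; all bounds are inclusive.
    """
    if counts.shape[1] == 0:
        raise ValueError("expression_filter requires at least one sample")
    if not counts.index.equals(tpm.index) or not counts.columns.equals(tpm.columns):
        raise ValueError("counts and tpm must share gene and sample keys")
    ok = (counts.to_numpy() >= min_count) & (tpm.to_numpy() >= min_tpm)
    frac = ok.mean(axis=1)
    return counts.index[frac >= min_frac]


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, trim_m: float, trim_a: float
) -> float:
    """Log2 TMM factor of one sample against the reference column."""
    n_o, n_r = obs.sum(), ref.sum()
    use = (obs > 0) & (ref > 0)
    if use.sum() < 10:
        warnings.warn("fewer than 10 genes usable against reference; factor set to 1")
        return 0.0
    o, r = obs[use], ref[use]
    # raw-count log-ratios: the factor absorbs the library-size component,
    # so normalized expression is count / factor (factors have geometric
    # mean 1 and are invariant to rescaling all samples by one constant)
    m = np.log2(o / r)
    a = 0.5 * np.log2(o.astype(float) * r)
    # asymptotic (delta-method) inverse variance of M
    w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
    if np.allclose(m, m[0]):
        return float(m[0])
    # double trim: drop trim_m of each M tail and trim_a of each A tail
    n = len(m)
    m_rank = stats.rankdata(m, method="ordinal")
    a_rank = stats.rankdata(a, method="ordinal")
    keep = (
        (m_rank > n * trim_m)
        & (m_rank <= n * (1 - trim_m))
        & (a_rank > n * trim_a)
        & (a_rank <= n * (1 - trim_a))
    )
    if not keep.any():
        return 0.0
    return float(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference column defaults to the sample whose 75th percentile
    of depth-scaled counts is closest to the mean of those percentiles.
    M-values (log-ratios) are trimmed by ``trim_m`` per tail and
    A-values (log-abundance) by ``trim_a`` per tail; the factor is the
    precision-weighted mean of surviving M-values, exponentiated.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("zero-depth sample; remove before TMM")
    if ref_sample is None:
        q75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_j = counts.columns.get_loc(ref_sample)
    log2f = np.array(
        [_tmm_pair(x[:, j], x[:, ref_j], trim_m, trim_a) for j in range(x.shape[1])]
    )
    f = 2.0**log2f
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset.

    value_i -> Phi^{-1}((rank_i - offset) / (n - 2*offset + 1)), with
    average ranks on ties. A constant vector maps to zeros with a
    warning.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("inverse normal transform needs n >= 3")
    if np.all(v == v[0]):
        warnings.warn("constant vector; INT returns zeros")
        return np.zeros(n)
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (n - 2 * offset + 1))


def median_ratio_log_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """log2(count / size-factor + 1) with median-of-ratios size factors.

    A variance-flattening normalization for PCA input: size factors are
    per-sample medians of count ratios to the geometric-mean reference
    gene (computed over genes nonzero in all samples).
    """
    x = counts.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    if pos.sum() < 10:
        raise ValueError("fewer than 10 genes nonzero in all samples")
    log_ref = np.log(x[pos]).mean(axis=1)
    sf = np.exp(np.median(np.log(x[pos]) - log_ref[:, None], axis=0))
    return pd.DataFrame(
        np.log2(x / sf[None, :] + 1.0), index=counts.index, columns=counts.columns
    )
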