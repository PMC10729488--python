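"""eQTL replication via Storey's pi1 with an allele-frequency-matched null.

The replication rate of a discovery cohort's significant gene-variant
pairs in a second cohort is summarized as pi1 = 1 - pi0, where pi0 is
Storey's estimate of the true-null fraction in the replication cohort's
nominal p-values for those pairs. Significance of the observed pi1 is
judged against B re-draws of equally sized, allele-frequency-matched
pair sets from the replication cohort, giving a permutation p-value
(1 + #{null pi1 >= observed}) / (B + 1).

pi0 estimation follows the q-value package: pi0(lambda) =
#{p > lambda} / (m (1 - lambda)) over a lambda grid, smoothed by a
cubic smoothing spline with 3 effective degrees of freedom and
evaluated at the largest lambda. For small sets (m < 100) the spline is
unstable and a fixed lambda = 0.5 point estimate is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import brentq

from .simulate import _rng

__all__ = [
    "DEFAULT_LAMBDAS",
    "estimate_pi0",
    "qvalues",
    "select_discovery_pairs",
    "af_matched_null",
    "replication_test",
    "ReplicationResult",
]

DEFAULT_LAMBDAS = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))

SMOOTHER_MIN_M = 100  # below this, spline pi0 estimation is unstable
FALLBACK_LAMBDA = 0.5


@lru_cache(maxsize=8)
def _smoother_row(lambdas: tuple, df: float = 3.0) -> np.ndarray:
    """Linear weights of the df-3 smoothing spline evaluated at max lambda.

    A smoothing spline fit is linear in the responses, so the fitted
    value at the last grid point is a fixed weight vector over the
    pi0(lambda) sequence; the penalty is chosen so the smoother matrix
    has trace (effective df) equal to ``df``. Cached per grid.
    """
    x = np.asarray(lambdas, dtype=float)
    n = len(x)
    eye = np.eye(n)

    def fit(lam):
        row = np.empty(n)
        tr = 0.0
        for j in range(n):
            sp = make_smoothing_spline(x, eye[j], lam=lam)
            vals = sp(x)
            tr += vals[j]
            row[j] = vals[-1]
        return row, tr

    lo, hi = 1e-9, 1e9
    lam = brentq(lambda l: fit(l)[1] - df, lo, hi, xtol=1e-12, rtol=1e-10)
    return fit(lam)[0]


def _pi0_lambda(p: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    m = len(p)
    tail = np.array([(p > lam).sum() for lam in lambdas], dtype=float)
    return tail / (m * (1.0 - lambdas))


def _pi0_raw(p: np.ndarray, lambdas, method: str) -> float:
    """Unclipped pi0 estimate (may fall outside [0, 1]); the permutation
    test compares these raw statistics so clipping cannot create ties."""
    p = np.asarray(p, dtype=float)
    if len(p) == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    lambdas = np.asarray(lambdas, dtype=float)
    if method == "fixed" or (method == "smoother" and len(p) < SMOOTHER_MIN_M):
        lam = FALLBACK_LAMBDA
        return float((p > lam).sum() / (len(p) * (1.0 - lam)))
    if method != "smoother":
        raise ValueError("method must be 'smoother' or 'fixed'")
    row = _smoother_row(tuple(np.round(lambdas, 6)))
    return float(row @ _pi0_lambda(p, lambdas))


def estimate_pi0(p, lambdas=DEFAULT_LAMBDAS, method: str = "smoother") -> float:
    """Storey pi0: smoothed tail estimate over the lambda grid, in [0, 1].

    ``method="smoother"`` (default) evaluates a df-3 cubic smoothing
    spline of pi0(lambda) at the largest lambda; sets with fewer than
    100 p-values fall back to the fixed lambda = 0.5 point estimate.
    """
    return float(np.clip(_pi0_raw(p, lambdas, method), 0.0, 1.0))


def qvalues(p, pi0: float | None = None) -> np.ndarray:
    """Storey q-values: q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j.

    With pi0 = 1 this reduces to Benjamini-Hochberg adjusted p-values.
    pi0 defaults to the smoothed estimate from the same p-values.
    Output is monotone in p and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p) if len(p) >= SMOOTHER_MIN_M else estimate_pi0(p, method="fixed")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_discovery_pairs(
    pairs: pd.DataFrame,
    min_maf: float = 0.05,
    max_q: float = 0.05,
    min_abs_slope: float = 0.32,
) -> pd.DataFrame:
    """Top pair per gene, then MAF / q-value / effect-size floors.

    Per gene the pair with the smallest nominal p is retained (ties:
    smallest |distance|, then lexicographic variant id); survivors must
    have maf >= min_maf, q <= max_q and |slope| >= min_abs_slope. The
    default slope floor 0.32 is the smallest significant effect
    observed in the weakest-powered reference tissue (kidney cortex).
    """
    need = {"gene", "variant", "p_nominal", "slope", "maf", "q"}
    missing = need - set(pairs.columns)
    if missing:
        raise KeyError(f"pair table lacks columns {sorted(missing)}")
    df = pairs.copy()
    df["_absd"] = df["distance"].abs() if "distance" in df else 0
    df = df.sort_values(
        ["gene", "p_nominal", "_absd", "variant"], kind="stable"
    ).drop_duplicates("gene", keep="first")
    keep = (
        (df["maf"] >= min_maf)
        & (df["q"] <= max_q)
        & (df["slope"].abs() >= min_abs_slope)
    )
    out = df[keep].drop(columns="_absd").reset_index(drop=True)
    if out.empty:
        warnings.warn("no discovery pairs survive selection")
    return out


def _maf_bins(maf: np.ndarray, bin_width: float) -> np.ndarray:
    """Bin MAFs on [0.05, 0.5]; values outside are clipped to end bins."""
    n_bins = max(1, int(np.ceil((0.5 - 0.05) / bin_width)))
    idx = np.floor((maf - 0.05) / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def af_matched_null(
    pool: pd.DataFrame,
    target_mafs,
    bin_width: float = 0.05,
    B: int = 1000,
    seed: int = 0,
    with_replacement: bool = False,
) -> list:
    """B draws of pool rows matching the target's MAF-bin histogram.

    For each draw, every target pair is matched by one pool pair
    sampled uniformly from the same MAF bin, without replacement within
    the draw (so each null set is a set of the target's size with the
    target's exact bin histogram). A bin too small for its demand is
    widened to adjacent bins with a warning; a still-empty bin is an
    error. Returns a list of B integer position arrays into ``pool``.
    """
    target_mafs = np.asarray(target_mafs, dtype=float)
    pool_maf = pool["maf"].to_numpy(dtype=float)
    tb = _maf_bins(target_mafs, bin_width)
    pb = _maf_bins(pool_maf, bin_width)
    n_bins = max(tb.max(), pb.max()) + 1

    bin_pool = {b: np.flatnonzero(pb == b) for b in range(n_bins)}
    demand = {b: int((tb == b).sum()) for b in np.unique(tb)}
    candidates = {}
    for b, k in demand.items():
        cand = bin_pool.get(b, np.array([], dtype=int))
        radius = 0
        while (len(cand) < k if not with_replacement else len(cand) < 1) and radius < n_bins:
            radius += 1
            grab = [bin_pool.get(b - radius), bin_pool.get(b + radius)]
            cand = np.concatenate([cand] + [g for g in grab if g is not None])
        if len(cand) == 0 or (not with_replacement and len(cand) < k):
            raise ValueError(
                f"MAF bin {b} cannot supply {k} pair(s) even after widening"
            )
        if radius:
            warnings.warn(f"MAF bin {b} widened by {radius} bin(s) to meet demand")
        candidates[b] = cand

    rng = _rng(seed, "af_matched_null")
    draws = []
    for _ in range(B):
        take = [
            rng.choice(candidates[b], size=k, replace=with_replacement)
            for b, k in demand.items()
        ]
        draws.append(np.concatenate(take))
    return draws


@dataclass
class ReplicationResult:
    """Observed pi1, its matched-null distribution and permutation p."""

    tissue_pair: tuple
    n_pairs: int
    pi1_observed: float
    null_pi1: np.ndarray
    perm_p: float
    seed: int
    B: int = field(default=0)

    def __post_init__(self):
        self.B = len(self.null_pi1)


def replication_test(
    discovery_pairs: pd.DataFrame,
    replication: pd.DataFrame,
    pool: pd.DataFrame | None = None,
    B: int = 1000,
    seed: int = 0,
    bin_width: float = 0.05,
    tissue_pair: tuple = ("discovery", "replication"),
) -> ReplicationResult:
    """pi1 of discovery pairs in the replication cohort vs a matched null.

    Discovery pairs are intersected with the replication pair table on
    (gene, variant); pi1 is 1 - pi0 of the intersected replication
    p-values. Null pi1 values come from ``B`` allele-frequency-matched
    draws (on the replication cohort's MAFs) from ``pool`` (default:
    the full replication table). The permutation p-value uses the raw
    (unclipped) pi1 statistics so that clipping cannot create ties;
    the reported pi1 values are clipped to [0, 1].
    """
    hit = discovery_pairs.merge(
        replication, on=["gene", "variant"], how="inner", suffixes=("_disc", "")
    )
    if hit.empty:
        raise ValueError("no discovery pairs present in the replication table")
    if len(hit) < 20:
        warnings.warn(f"only {len(hit)} intersected pairs; pi1 will be unstable")
    pool = replication if pool is None else pool
    method = "smoother" if len(hit) >= SMOOTHER_MIN_M else "fixed"

    obs_raw = 1.0 - _pi0_raw(hit["p_nominal"].to_numpy(), DEFAULT_LAMBDAS, method)
    draws = af_matched_null(
        pool, hit["maf"].to_numpy(), bin_width=bin_width, B=B, seed=seed
    )
    pool_p = pool["p_nominal"].to_numpy(dtype=float)
    null_raw = np.array(
        [1.0 - _pi0_raw(pool_p[ix], DEFAULT_LAMBDAS, method) for ix in draws]
    )
    perm_p = (1.0 + np.sum(null_raw >= obs_raw)) / (B + 1.0)
    return ReplicationResult(
        tissue_pair=tuple(tissue_pair),
        n_pairs=int(len(hit)),
        pi1_observed=float(np.clip(obs_raw, 0.0, 1.0)),
        null_pi1=np.clip(null_raw, 0.0, 1.0),
        perm_p=float(perm_p),
        seed=seed,
    )
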