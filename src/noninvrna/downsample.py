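"""Averaged binomial downsampling of count matrices to a common depth.

Each sample's counts are thinned binomially with success probability
p = target_depth / original_depth, independently ``n_reps`` times, and
the replicates are averaged cell-wise. The average is unbiased for
p * count and has 1/n_reps the variance of a single thinning; averaged
matrices are therefore fractional.

One master seed spawns a substream per (sample, replicate) keyed by the
sample label, so subsetting samples never changes other samples' draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import _rng

__all__ = ["DownsampleSpec", "binomial_downsample", "depth_match_cohorts"]


@dataclass(frozen=True)
class DownsampleSpec:
    target_depth: float
    n_reps: int = 5
    seed: int = 0
    depth_metric: str = "coding"

    def __post_init__(self):
        if self.target_depth <= 0:
            raise ValueError("target_depth must be > 0")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.depth_metric not in ("coding", "total"):
            raise ValueError("depth_metric must be 'coding' or 'total'")


def binomial_downsample(
    counts: pd.DataFrame, spec: DownsampleSpec, depths: pd.Series
) -> pd.DataFrame:
    """Thin each sample to the target depth; average over replicates.

    ``depths`` gives each sample's original depth in the spec's metric.
    Samples below the target (p > 1) are an error — they belong on the
    failing side of the depth gate, not here. p = 1 samples pass through
    unchanged.
    """
    depths = depths.reindex(counts.columns)
    if depths.isna().any():
        raise KeyError("every sample in counts needs a depth")
    p = spec.target_depth / depths.to_numpy(dtype=float)
    if np.any(p > 1):
        bad = counts.columns[p > 1]
        raise ValueError(
            f"{len(bad)} sample(s) below target depth (e.g. {bad[0]!r}); "
            "gate on depth before downsampling"
        )
    x = counts.to_numpy()
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    xi = np.asarray(np.rint(x), dtype=np.int64)
    out = np.empty(x.shape, dtype=float)
    for j, sample in enumerate(counts.columns):
        if p[j] == 1.0:
            out[:, j] = x[:, j]
            continue
        acc = np.zeros(x.shape[0], dtype=float)
        for rep in range(spec.n_reps):
            rng = _rng(spec.seed, "downsample", sample, rep)
            acc += rng.binomial(xi[:, j], p[j])
        out[:, j] = acc / spec.n_reps
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def depth_match_cohorts(
    cohort_a: pd.DataFrame,
    depths_a: pd.Series,
    cohort_b: pd.DataFrame,
    depths_b: pd.Series,
    target: float,
    n_reps: int = 5,
    seed: int = 0,
):
    """Downsample two cohorts to one common depth for joint analysis.

    Returns ((matrix_a, matrix_b), manifest); the manifest records the
    thinning probability per sample. Seeds for the two cohorts are
    independent substreams of the one master seed.
    """
    spec_a = DownsampleSpec(target_depth=target, n_reps=n_reps, seed=seed * 2 + 1)
    spec_b = DownsampleSpec(target_depth=target, n_reps=n_reps, seed=seed * 2 + 2)
    a = binomial_downsample(cohort_a, spec_a, depths_a)
    b = binomial_downsample(cohort_b, spec_b, depths_b)
    manifest = pd.concat(
        [
            pd.DataFrame(
                {
                    "cohort": c,
                    "sample": d.index,
                    "p": target / d.to_numpy(dtype=float),
                }
            )
            for c, d in (("a", depths_a), ("b", depths_b))
        ],
        ignore_index=True,
    )
    return (a, b), manifest
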