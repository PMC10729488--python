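"""Allele-specific expression: reference ratios and the NMD contrast.

At heterozygous sites the reference-allele ratio ref/(ref+alt) should
center on 0.5; transcripts carrying a premature stop codon are degraded
by nonsense-mediated decay (NMD), so stop-gain sites show allelic
imbalance. The contrast compares imbalance magnitude |ratio - 0.5|
between stop-gain and synonymous sites with a two-sided Mann-Whitney
test (magnitude, not raw ratio, because NMD depletes whichever allele
carries the stop, so the direction depends on phase).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ref_ratio", "flag_outlier_donors", "nmd_contrast", "NmdContrast"]

MIN_TOTAL_COUNTS = 16


def ref_ratio(sites: pd.DataFrame, min_total: int = MIN_TOTAL_COUNTS) -> pd.DataFrame:
    """Reference-allele ratio per site, dropping shallow sites.

    Sites with fewer than ``min_total`` total counts are filtered (a
    site at exactly the threshold is kept); the ratio
    ref/(ref+alt) in [0, 1] is appended as a column.
    """
    for col in ("ref_count", "alt_count"):
        if col not in sites.columns:
            raise KeyError(f"site table lacks column {col!r}")
        if (sites[col] < 0).any():
            raise ValueError("allele counts must be non-negative")
    total = sites["ref_count"] + sites["alt_count"]
    out = sites[total >= min_total].copy()
    tot = out["ref_count"] + out["alt_count"]
    out["total"] = tot
    out["ratio"] = out["ref_count"] / tot
    return out.reset_index(drop=True)


def flag_outlier_donors(ratios: pd.DataFrame, z_max: float = 3.0) -> list:
    """Donors with extreme mean reference ratios (possible genotyping error).

    Per-donor mean ratios are compared to the cross-donor median; a
    donor beyond ``z_max`` robust SDs (1.4826 * MAD) is flagged. With
    fewer than 3 donors, or zero MAD, nothing is flagged (warning).
    """
    if "ratio" not in ratios.columns:
        raise KeyError("ratio column required (run ref_ratio first)")
    donor_mean = ratios.groupby("donor")["ratio"].mean()
    if len(donor_mean) < 3:
        warnings.warn("fewer than 3 donors; outlier flagging skipped")
        return []
    med = donor_mean.median()
    mad = float(np.median(np.abs(donor_mean - med)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        warnings.warn("zero MAD across donors; outlier flagging skipped")
        return []
    z = (donor_mean - med).abs() / robust_sd
    return sorted(z.index[z > z_max])


@dataclass
class NmdContrast:
    """Imbalance contrast between two consequence classes."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_imbalance_a: float
    median_imbalance_b: float
    median_difference: float
    median_ratio_a: float
    median_ratio_b: float
    p_value: float


def nmd_contrast(
    ratios: pd.DataFrame,
    group_a: str = "stop_gained",
    group_b: str = "synonymous",
    by: list | None = None,
) -> "NmdContrast | pd.DataFrame":
    """Mann-Whitney contrast of allelic-imbalance magnitude between classes.

    Compares |ratio - 0.5| for sites annotated ``group_a`` vs
    ``group_b`` (two-sided; exact method for small groups via scipy's
    automatic choice). With ``by`` (e.g. ["tissue"] or
    ["tissue", "collection"]) a stratified DataFrame of contrasts is
    returned instead.
    """
    if by:
        rows = []
        for key, block in ratios.groupby(by):
            c = nmd_contrast(block, group_a, group_b)
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(by, key)), **c.__dict__})
        return pd.DataFrame(rows)

    a = ratios.loc[ratios["consequence"] == group_a, "ratio"]
    b = ratios.loc[ratios["consequence"] == group_b, "ratio"]
    for name, grp in ((group_a, a), (group_b, b)):
        if grp.empty:
            raise ValueError(f"no sites in group {name!r} after filtering")
    im_a = (a - 0.5).abs()
    im_b = (b - 0.5).abs()
    res = stats.mannwhitneyu(im_a, im_b, alternative="two-sided")
    return NmdContrast(
        group_a=group_a,
        group_b=group_b,
        n_a=len(a),
        n_b=len(b),
        median_imbalance_a=float(im_a.median()),
        median_imbalance_b=float(im_b.median()),
        median_difference=float(im_a.median() - im_b.median()),
        median_ratio_a=float(a.median()),
        median_ratio_b=float(b.median()),
        p_value=float(res.pvalue),
    )
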