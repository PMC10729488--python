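"""Covariate-adjusted nominal cis-association scan.

Genotype hygiene (monomorphic / low-MAF / multiallelic / indel
exclusion), sliding-window LD pruning, genotype and expression principal
components as covariates, cis-window pair enumeration around each TSS,
and a vectorized single-variant OLS scan producing nominal p-values and
slopes — the inputs to the replication (pi1) statistic.

Positions are 1-based (VCF convention); the cis window is inclusive and
the pair distance is signed (variant position minus TSS).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import GenotypeTable

__all__ = [
    "filter_variants",
    "ld_prune",
    "genotype_pcs",
    "expression_pcs",
    "cis_pairs",
    "nominal_scan",
    "residualize",
]


def filter_variants(geno: GenotypeTable, min_maf: float = 0.05) -> GenotypeTable:
    """Drop monomorphic, MAF < min_maf (strict), multiallelic and indel records."""
    v = geno.variants
    for col in ("ref", "alt"):
        if col not in v.columns:
            raise KeyError(f"variant table lacks {col!r}")
        bad = ~v[col].astype(str).str.fullmatch(r"[ACGTacgt,]+")
        if bad.any():
            raise ValueError(f"malformed alleles at {list(v.index[bad][:3])}")
    dosage = geno.dosage.to_numpy(dtype=float)
    freq = dosage.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    monomorphic = (dosage == dosage[:, :1]).all(axis=1)
    multiallelic = v["alt"].astype(str).str.contains(",").to_numpy()
    indel = (v["ref"].astype(str).str.len() != 1).to_numpy() | (
        v["alt"].astype(str).str.len() != 1
    ).to_numpy()
    keep = ~monomorphic & (maf >= min_maf) & ~multiallelic & ~indel
    return geno.subset(v.index[keep])


def ld_prune(
    geno: GenotypeTable, window: int = 50, step: int = 5, r2_max: float = 0.2
) -> list:
    """Greedy sliding-window LD pruning on dosage correlation.

    Within each window of ``window`` variants (advancing by ``step``),
    while any surviving pair has r^2 > r2_max, the lower-MAF member of
    the worst pair is removed (tie: the later position). Variants must
    be position-sorted within each chromosome.
    """
    v = geno.variants
    kept = set(v.index)
    freq = geno.dosage.to_numpy(dtype=float).mean(axis=1) / 2.0
    maf = pd.Series(np.minimum(freq, 1.0 - freq), index=v.index)
    for chrom, block in v.groupby("chrom", sort=False):
        pos = block["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variants on chromosome {chrom!r} are not position-sorted")
        ids = list(block.index)
        dos = geno.dosage.loc[ids].to_numpy(dtype=float)
        start = 0
        while start < len(ids):
            win = [i for i in range(start, min(start + window, len(ids))) if ids[i] in kept]
            while len(win) > 1:
                x = dos[win]
                sd = x.std(axis=1)
                ok = sd > 0
                r = np.zeros((len(win), len(win)))
                if ok.sum() > 1:
                    sub = np.corrcoef(x[ok])
                    r[np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))] = sub
                np.fill_diagonal(r, 0.0)
                r2 = r**2
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                a, b = ids[win[i]], ids[win[j]]
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:  # tie: drop the later position
                    drop = a if v.loc[a, "pos"] >= v.loc[b, "pos"] else b
                kept.discard(drop)
                win = [k for k in win if ids[k] in kept]
            if start + window >= len(ids):
                break
            start += step
    return [vid for vid in v.index if vid in kept]


def genotype_pcs(geno: GenotypeTable, n_pcs: int = 2) -> pd.DataFrame:
    """Donor principal components of standardized dosages.

    Each variant is standardized by its Hardy-Weinberg moments: mean 2f
    and SD sqrt(2 f (1 - f)), the convention of genotype PCA for
    population structure. Zero-variance variants are dropped. PC signs
    are arbitrary.
    """
    dosage = geno.dosage.to_numpy(dtype=float)
    if dosage.shape[1] < 3:
        raise ValueError("genotype PCA needs >= 3 donors")
    freq = dosage.mean(axis=1) / 2.0
    keep = (dosage.std(axis=1) > 0) & (freq > 0) & (freq < 1)
    if not keep.any():
        warnings.warn("no polymorphic variants; genotype PCs are all zero")
        return pd.DataFrame(
            np.zeros((dosage.shape[1], n_pcs)),
            index=geno.dosage.columns,
            columns=[f"gPC{i + 1}" for i in range(n_pcs)],
        )
    z = (dosage[keep] - 2 * freq[keep, None]) / np.sqrt(
        2 * freq[keep, None] * (1 - freq[keep, None])
    )
    zc = z.T - z.T.mean(axis=0)
    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    scores = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(
        scores, index=geno.dosage.columns, columns=[f"gPC{i + 1}" for i in range(n_pcs)]
    )


def expression_pcs(expr: pd.DataFrame, min_ve: float = 0.15) -> pd.DataFrame:
    """Sample PCs of a normalized genes-x-samples matrix above a VE floor.

    Returns every PC whose variance-explained fraction exceeds
    ``min_ve`` (in order); an empty frame if none qualifies.
    """
    if expr.shape[1] < 3:
        raise ValueError("expression PCA needs >= 3 samples")
    x = expr.to_numpy(dtype=float).T
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ve = s**2 / np.sum(s**2)
    n_keep = int(np.sum(ve > min_ve)) if min_ve > 0 else len(s)
    scores = u[:, :n_keep] * s[:n_keep]
    return pd.DataFrame(
        scores, index=expr.columns, columns=[f"ePC{i + 1}" for i in range(n_keep)]
    )


def cis_pairs(
    genes: pd.DataFrame, geno: GenotypeTable, window: float = 1e6
) -> pd.DataFrame:
    """All gene-variant pairs with |pos - tss| <= window on one chromosome.

    Distance is signed (variant - TSS) and the window bound is
    inclusive. Genes lacking a TSS are skipped with a warning.
    """
    has_tss = genes["tss"].notna()
    if not has_tss.all():
        warnings.warn(f"skipping {int((~has_tss).sum())} gene(s) without TSS")
    v = geno.variants
    out = []
    for chrom, vblock in v.groupby("chrom", sort=False):
        gblock = genes[has_tss & (genes["chrom"] == chrom)]
        if gblock.empty:
            continue
        pos = vblock["pos"].to_numpy()
        for gid, tss in zip(gblock.index, gblock["tss"].to_numpy()):
            d = pos - tss
            hit = np.abs(d) <= window
            for vid, dist in zip(vblock.index[hit], d[hit]):
                out.append((gid, vid, int(dist)))
    return pd.DataFrame(out, columns=["gene", "variant", "distance"])


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residuals of y against covariates plus an intercept (least squares)."""
    n = y.shape[-1]
    if covariates is None or covariates.size == 0:
        design = np.ones((n, 1))
    else:
        design = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def nominal_scan(
    expr: pd.DataFrame,
    geno: GenotypeTable,
    covariates: pd.DataFrame | None,
    pairs: pd.DataFrame,
) -> pd.DataFrame:
    """Nominal single-variant association for each candidate pair.

    Expression (genes x donors, inverse-normal transformed upstream)
    and dosages are each residualized against the covariates with an
    intercept; the slope and two-sided t-test p come from the simple
    regression of residualized expression on residualized dosage with
    n - 2 - n_covariates degrees of freedom (the intercept and the
    genotype term each cost one beyond the covariates). Variants
    monomorphic in-sample get p = 1, slope 0 and a flag.
    """
    donors = expr.columns
    if not set(donors).issubset(geno.dosage.columns):
        raise KeyError("expression donors missing from genotype table")
    cov = None
    n_cov = 0
    if covariates is not None and covariates.shape[1] > 0:
        cov = covariates.reindex(donors).to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise KeyError("covariates must cover every donor")
        n_cov = cov.shape[1]
    n = len(donors)
    df = n - 2 - n_cov
    if df < 1:
        raise ValueError(f"too few donors ({n}) for {n_cov} covariates")

    genes = pairs["gene"].unique()
    variants = pairs["variant"].unique()
    y = residualize(expr.loc[genes].to_numpy(dtype=float), cov)
    g = residualize(geno.dosage.loc[variants, donors].to_numpy(dtype=float), cov)

    gi = pd.Index(genes).get_indexer(pairs["gene"])
    vi = pd.Index(variants).get_indexer(pairs["variant"])
    yv = y[gi]
    gv = g[vi]
    gss = (gv**2).sum(axis=1)
    mono = gss == 0
    gss_safe = np.where(mono, 1.0, gss)
    slope = (yv * gv).sum(axis=1) / gss_safe
    rss = (yv**2).sum(axis=1) - slope**2 * gss_safe
    rss = np.maximum(rss, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / gss_safe)
        t = np.where(se > 0, slope / se, np.sign(slope) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    slope = np.where(mono, 0.0, slope)
    p = np.where(mono, 1.0, p)

    dos = geno.dosage.loc[variants, donors].to_numpy(dtype=float)
    freq = dos.mean(axis=1) / 2.0
    maf = np.minimum(freq, 1.0 - freq)[vi]
    out = pairs.copy()
    out["slope"] = slope
    out["p_nominal"] = p
    out["maf"] = maf
    out["monomorphic_in_sample"] = mono
    return out
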