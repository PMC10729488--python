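"""Sample quality-control gates.

Two gates are applied before any analysis: a library-preparation gate on
yield/concentration and fragment size, and a sequencing gate on depth of
reads assigned to protein-coding and lncRNA genes ("coding depth"), the
depth metric used throughout the pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "prep_qc_gate",
    "coding_depth",
    "seq_qc_gate",
    "DEPTH_PRESETS",
    "CODING_BIOTYPES",
]

# named depth thresholds: cross-preparation comparisons, the in-house
# (Loseq) analyses, and comparisons against deeply sequenced references
DEPTH_PRESETS = {"cross-prep": 1e6, "loseq": 2.5e6, "gtex": 5e6}

CODING_BIOTYPES = frozenset({"protein_coding", "lncRNA"})

MIN_CONCENTRATION_NM = 2.0
MAX_LIB_SIZE_BP = 600.0


def prep_qc_gate(
    samples: pd.DataFrame,
    min_concentration: float = MIN_CONCENTRATION_NM,
    max_lib_size: float = MAX_LIB_SIZE_BP,
) -> pd.DataFrame:
    """Pre-sequencing gate: concentration > 2 nM and mean size < 600 bp.

    Returns a table indexed like ``samples`` with boolean ``pass_qc``
    and a comma-joined ``reasons`` column (LOW_YIELD, OVERSIZE, or
    UNEVALUABLE when a required field is missing — a missing field never
    silently passes).
    """
    for col in ("lib_concentration", "lib_size"):
        if col not in samples.columns:
            raise KeyError(f"samples table lacks required column {col!r}")
    conc = pd.to_numeric(samples["lib_concentration"], errors="coerce")
    size = pd.to_numeric(samples["lib_size"], errors="coerce")

    reasons = []
    for c, s in zip(conc, size):
        r = []
        if pd.isna(c) or pd.isna(s):
            r.append("UNEVALUABLE")
        else:
            if not c > min_concentration:
                r.append("LOW_YIELD")
            if not s < max_lib_size:
                r.append("OVERSIZE")
        reasons.append(",".join(r))
    out = pd.DataFrame(index=samples.index)
    out["pass_qc"] = [r == "" for r in reasons]
    out["reasons"] = reasons
    return out


def coding_depth(
    counts: pd.DataFrame, annot: pd.DataFrame, biotypes=CODING_BIOTYPES
) -> pd.Series:
    """Per-sample read depth over protein-coding and lncRNA genes.

    ``annot`` must cover every gene in ``counts`` (indexed by gene id
    with a ``biotype`` column); unannotated genes are an error rather
    than a silent depth undercount. The biotype set is a parameter so a
    strictly protein-coding depth is also available.
    """
    missing = counts.index.difference(annot.index)
    if len(missing):
        raise KeyError(f"unannotated gene ids: {list(missing[:3])}")
    keep = annot.loc[counts.index, "biotype"].isin(set(biotypes)).to_numpy()
    depth = counts.loc[keep].sum(axis=0).astype(float)
    depth.name = "coding_depth"
    return depth


def seq_qc_gate(depths: pd.Series, threshold) -> pd.Series:
    """Depth gate: pass iff depth >= threshold (inclusive boundary).

    ``threshold`` is a number of reads or a preset name from
    ``DEPTH_PRESETS`` ("cross-prep" 1e6, "loseq" 2.5e6, "gtex" 5e6).
    """
    if isinstance(threshold, str):
        try:
            threshold = DEPTH_PRESETS[threshold]
        except KeyError:
            raise KeyError(
                f"unknown preset {threshold!r}; options: {sorted(DEPTH_PRESETS)}"
            ) from None
    threshold = float(threshold)
    if threshold <= 0 or not np.isfinite(threshold):
        raise ValueError("threshold must be a positive finite read count")
    out = depths.astype(float) >= threshold
    out.name = "pass_depth"
    return out
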