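"""Disease-relevance scoring: OMIM gene capture and summed evidence scores.

Two complementary views of whether a tissue's transcriptome covers
disease biology: (i) the fraction of Mendelian (OMIM) disease genes
expressed above a median-TPM floor, and (ii) the summed evidence score
(SES) for a common disease — the evidence mass of disease genes
expressed in the tissue over the evidence mass of disease genes
expressed in any analyzed tissue:

    SES = sum(scores of disease genes in tissue set)
        / sum(scores of disease genes in union set)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

__all__ = [
    "TissueGeneSet",
    "filter_evidence",
    "tissue_gene_sets",
    "ses",
    "omim_capture",
    "capture_upset",
]


@dataclass
class TissueGeneSet:
    """Genes analyzed for one tissue, with the filters that produced them."""

    tissue: str
    genes: frozenset
    provenance: dict = field(default_factory=dict)


def filter_evidence(ev: pd.DataFrame, min_sources: int = 5) -> pd.DataFrame:
    """Keep disease-gene rows supported by >= min_sources evidence sources."""
    for col in ("disease", "gene", "n_sources", "score"):
        if col not in ev.columns:
            raise KeyError(f"evidence table lacks column {col!r}")
    if (ev["n_sources"] < 0).any() or (ev["score"] < 0).any():
        raise ValueError("n_sources and score must be non-negative")
    return ev[ev["n_sources"] >= min_sources].reset_index(drop=True)


def tissue_gene_sets(
    median_tpm: pd.DataFrame, hpa_elevated, top_n: int = 3411
) -> dict:
    """Top-N most-expressed tissue-elevated genes per tissue.

    ``median_tpm`` is genes x tissues (medians over QC-passed,
    depth-matched samples). Per tissue: genes with median TPM > 0,
    intersected with the tissue-elevated list, ranked by median TPM
    descending (ties lexicographic) and truncated to ``top_n`` — the
    default matches the smallest post-filter tissue in the study. A
    tissue with fewer qualifying genes keeps them all, with a warning.
    """
    hpa = set(hpa_elevated)
    out = {}
    for tissue in median_tpm.columns:
        med = median_tpm[tissue]
        qual = med[(med > 0) & med.index.isin(hpa)]
        ranked = qual.sort_index().sort_values(ascending=False, kind="stable")
        if len(ranked) < top_n:
            warnings.warn(
                f"tissue {tissue!r}: only {len(ranked)} qualifying genes (top_n={top_n})"
            )
        chosen = ranked.index[: min(top_n, len(ranked))]
        out[tissue] = TissueGeneSet(
            tissue=tissue,
            genes=frozenset(chosen),
            provenance={
                "median_tpm_gt_zero": int((med > 0).sum()),
                "after_hpa": int(len(qual)),
                "top_n": top_n,
            },
        )
    return out


def ses(tissue_set: TissueGeneSet, ev: pd.DataFrame, union_set) -> float:
    """Summed evidence score of one tissue for one disease.

    ``ev`` must be pre-filtered and restricted to one disease; the
    denominator sums scores of disease genes in ``union_set`` (genes
    expressed in any analyzed tissue), the numerator those also in the
    tissue's set. Returns NaN (reported missing) when the denominator
    is zero rather than dividing by zero.
    """
    if ev["disease"].nunique() > 1:
        raise ValueError("evidence table must be restricted to a single disease")
    union_set = set(union_set)
    if not set(tissue_set.genes) <= union_set:
        raise ValueError("union_set must contain every tissue-set gene")
    in_union = ev[ev["gene"].isin(union_set)]
    denom = float(in_union["score"].sum())
    if denom == 0:
        warnings.warn("no disease evidence among union genes; SES undefined")
        return float("nan")
    num = float(in_union.loc[in_union["gene"].isin(tissue_set.genes), "score"].sum())
    return num / denom


def omim_capture(
    median_tpm: pd.DataFrame, omim_genes, min_tpm: float = 0.1
) -> pd.DataFrame:
    """Per-tissue fraction of OMIM genes with median TPM strictly above floor.

    The denominator is the OMIM genes present in the annotation
    (``median_tpm`` rows); returns a tissue-indexed frame with the
    fraction and the captured gene sets.
    """
    omim = set(omim_genes)
    if not omim:
        raise ValueError("omim_genes is empty")
    annotated = [g for g in median_tpm.index if g in omim]
    if not annotated:
        raise ValueError("no overlap between annotation and the OMIM list")
    rows = []
    for tissue in median_tpm.columns:
        med = median_tpm.loc[annotated, tissue]
        captured = sorted(med.index[med > min_tpm])
        rows.append(
            {
                "tissue": tissue,
                "fraction": len(captured) / len(annotated),
                "n_captured": len(captured),
                "n_omim_annotated": len(annotated),
                "captured": captured,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def capture_upset(sets: dict) -> dict:
    """Exclusive intersection counts over the Venn lattice of gene sets.

    ``sets`` maps label -> gene set. Returns {membership tuple: count}
    where the membership tuple lists, in sorted label order, booleans of
    set membership; every gene in the union is counted in exactly one
    region, so the counts sum to |union|.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    labels = sorted(sets)
    universe = set().union(*sets.values())
    regions = {m: 0 for m in product([False, True], repeat=len(labels)) if any(m)}
    for g in universe:
        m = tuple(g in sets[lbl] for lbl in labels)
        regions[m] += 1
    return {"labels": labels, "regions": regions}
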