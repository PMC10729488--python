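"""Triage of reads that do not map to the host genome.

Reads are partitioned into mapped (host genome), remapped (microbial
species), repeated (highly abundant technical sequences) and unknown,
with precedence mapped > remapped > repeated so the ledger is an exact
partition. Remapped reads yield genome-length-normalized species
abundances (a TPM-like quantity summing to 1 per sample) from which the
top fraction of species is selected, technical-replicate concordance is
scored, and per-tissue dominant species are highlighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReadLedger",
    "classify_reads",
    "species_abundance",
    "top_fraction_species",
    "replicate_concordance",
    "highlight_species",
    "repeated_sequence_sharing",
]


@dataclass
class ReadLedger:
    """Disjoint, exhaustive read-category counts for one sample."""

    sample: str
    n_total: int
    n_mapped: int
    n_remapped: int
    n_repeated: int
    n_unknown: int
    n_precedence_overlaps: int = 0

    def __post_init__(self):
        parts = self.n_mapped + self.n_remapped + self.n_repeated + self.n_unknown
        assert parts == self.n_total, "ledger categories must partition n_total"


def classify_reads(
    sample: str,
    read_ids,
    mapped_ids,
    remapped_ids,
    repeated_ids,
) -> ReadLedger:
    """Partition a sample's reads with precedence mapped > remapped > repeated.

    Ids outside the sample's read set are rejected; a read claimed by
    several categories is counted once under the highest-precedence one
    and tallied in ``n_precedence_overlaps``.
    """
    reads = set(read_ids)
    mapped = set(mapped_ids)
    remapped = set(remapped_ids)
    repeated = set(repeated_ids)
    stray = (mapped | remapped | repeated) - reads
    if stray:
        raise ValueError(f"ids outside the sample's reads: {sorted(stray)[:3]}")
    overlaps = len(mapped & remapped) + len((mapped | remapped) & repeated)
    remapped -= mapped
    repeated -= mapped | remapped
    n_unknown = len(reads) - len(mapped) - len(remapped) - len(repeated)
    return ReadLedger(
        sample=sample,
        n_total=len(reads),
        n_mapped=len(mapped),
        n_remapped=len(remapped),
        n_repeated=len(repeated),
        n_unknown=n_unknown,
        n_precedence_overlaps=overlaps,
    )


def species_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Genome-length-normalized species fractions per sample.

    ``table`` has species rows, a ``genome_length`` column and one
    read-count column per sample. a_s = (reads_s / length_s) /
    sum_s'(reads_s' / length_s'); columns sum to 1. An all-zero sample
    becomes an all-NaN column with a warning.
    """
    if "genome_length" not in table.columns:
        raise KeyError("table needs a genome_length column")
    lengths = table["genome_length"].astype(float)
    if (lengths <= 0).any():
        raise ValueError("genome lengths must be > 0")
    counts = table.drop(columns="genome_length").astype(float)
    if (counts < 0).to_numpy().any():
        raise ValueError("read counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    tot = rate.sum(axis=0)
    empty = tot == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} sample(s) with zero remapped reads")
        tot = tot.mask(empty, np.nan)
    return rate.div(tot, axis=1)


def top_fraction_species(
    abund: pd.DataFrame, frac: float = 0.005, statistic: str = "mean"
) -> list:
    """Top ceil(frac * n_species) species by cross-sample abundance.

    Ranking statistic is the mean abundance over all samples by
    default ("max-median" ranks by the maximum per-sample median is
    not needed here; "max" ranks by the per-species maximum). Ties are
    broken lexicographically.
    """
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    if statistic == "mean":
        score = abund.mean(axis=1)
    elif statistic == "max":
        score = abund.max(axis=1)
    else:
        raise ValueError("statistic must be 'mean' or 'max'")
    n = ceil(frac * abund.shape[0])
    ranked = score.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n])


def replicate_concordance(abund: pd.DataFrame, pairs) -> pd.Series:
    """Per-species Spearman correlation across technical-replicate pairs.

    ``pairs`` lists (sample_1, sample_2) column pairs; the coefficient
    is computed per species over replicate-1 vs replicate-2 abundances
    and reported as NaN where undefined (constant input or < 3 pairs).
    """
    pairs = list(pairs)
    for a, b in pairs:
        if a not in abund.columns or b not in abund.columns:
            raise KeyError(f"replicate pair ({a!r}, {b!r}) not in abundance matrix")
    r1 = abund[[a for a, _ in pairs]].to_numpy()
    r2 = abund[[b for _, b in pairs]].to_numpy()
    out = np.full(abund.shape[0], np.nan)
    if len(pairs) >= 3:
        for i in range(abund.shape[0]):
            x, y = r1[i], r2[i]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() >= 3 and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
                out[i] = stats.spearmanr(x[ok], y[ok]).statistic
    return pd.Series(out, index=abund.index, name="spearman")


def highlight_species(
    abund: pd.DataFrame, tissue_labels: pd.Series, threshold: float = 0.05
) -> dict:
    """Species with per-tissue median abundance strictly above threshold."""
    tissue_labels = tissue_labels.reindex(abund.columns)
    if tissue_labels.isna().any():
        raise KeyError("tissue labels must cover every sample")
    out = {}
    for tissue in tissue_labels.unique():
        block = abund.loc[:, tissue_labels[tissue_labels == tissue].index]
        med = block.median(axis=1)
        out[tissue] = sorted(med.index[med > threshold])
    return out


def repeated_sequence_sharing(presence: pd.DataFrame) -> dict:
    """Sharing breakdown of repeated sequences across tissue/prep groups.

    ``presence`` is sequences x groups, boolean. Returns counts of
    sequences present in all groups, in more than one but not all, and
    in exactly one, plus the exclusive-region counts of the membership
    lattice (as in the gene-capture upset).
    """
    pres = presence.astype(bool)
    n_groups = pres.shape[1]
    per_seq = pres.sum(axis=1)
    counted = pres[per_seq > 0]
    regions: dict = {}
    for m, block in counted.groupby(list(counted.columns)):
        m = m if isinstance(m, tuple) else (m,)
        regions[tuple(bool(x) for x in m)] = len(block)
    return {
        "labels": list(pres.columns),
        "n_sequences": int((per_seq > 0).sum()),
        "in_all_groups": int((per_seq == n_groups).sum()),
        "in_some_groups": int(((per_seq > 1) & (per_seq < n_groups)).sum()),
        "in_one_group": int((per_seq == 1).sum()),
        "regions": regions,
    }
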