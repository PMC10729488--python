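"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline (QC, downsampling, projection,
cis scan, replication, disease scores, ASE contrast, read triage) can be
exercised on data produced here, with the generating parameters emitted
alongside the data so results can be scored against the truth.

The default study design mirrors a longitudinal noninvasive-tissue
cohort: 19 donors, 4 tissues (buccal, hair, saliva, urine), 4 collections
per donor. Counts are negative binomial with log-normal gene means;
donor and tissue effects enter on the log-mean scale, the same scale on
which cis-eQTL effects are planted.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "EqtlTruth",
    "CountSim",
    "GenotypeTable",
    "simulate_counts",
    "simulate_genotypes",
    "plant_eqtls",
    "simulate_pvalues",
    "simulate_ase_sites",
    "simulate_species_reads",
]

DEFAULT_TISSUES = ("buccal", "hair", "saliva", "urine")


def _stable_hash(label: str) -> int:
    """Deterministic 63-bit hash of a label (Python's hash() is salted)."""
    return int.from_bytes(hashlib.blake2b(label.encode(), digest_size=8).digest(), "big") >> 1


def _rng(seed: int, *keys) -> np.random.Generator:
    """Independent substream keyed by (seed, *keys); label keys are hashed."""
    ints = [int(seed)]
    for k in keys:
        ints.append(_stable_hash(k) if isinstance(k, str) else int(k))
    return np.random.default_rng(np.random.SeedSequence(ints))


@dataclass(frozen=True)
class SimConfig:
    """Design and noise parameters for the count generator.

    Parameters
    ----------
    n_genes, n_donors : int
        Matrix dimensions. Donors are labelled D01, D02, ...
    tissues : tuple of str
        Tissue types collected per donor.
    collections_per_donor : int
        Repeated collections per donor and tissue (longitudinal design).
    depth_mean : float
        Expected library size (reads) per sample.
    depth_cv : float
        Coefficient of variation of log-normal library sizes.
    nb_dispersion : float
        Negative-binomial dispersion phi (variance = mu + phi mu^2);
        0 gives Poisson counts.
    donor_sd, tissue_effect_sd : float
        SDs of per-gene log-scale donor and tissue effects. The donor
        effect is shared across collections of the same donor.
    frac_protein_coding : float
        Fraction of genes annotated protein_coding; half the remainder
        is lncRNA, the rest "other".
    """

    n_genes: int = 2000
    n_donors: int = 19
    tissues: tuple = DEFAULT_TISSUES
    collections_per_donor: int = 4
    seed: int = 0
    depth_mean: float = 5e6
    depth_cv: float = 0.3
    nb_dispersion: float = 0.1
    donor_sd: float = 0.3
    tissue_effect_sd: float = 1.0
    frac_protein_coding: float = 0.75

    def __post_init__(self):
        if min(self.n_genes, self.n_donors, self.collections_per_donor) < 1:
            raise ValueError("n_genes, n_donors and collections_per_donor must be >= 1")
        if len(self.tissues) < 1:
            raise ValueError("at least one tissue required")
        if not 0.0 <= self.frac_protein_coding <= 1.0:
            raise ValueError("frac_protein_coding must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.depth_mean <= 0 or self.depth_cv < 0:
            raise ValueError("depth_mean must be > 0 and depth_cv >= 0")


@dataclass(frozen=True)
class EqtlTruth:
    """A planted (or null) gene-variant pair with its additive effect.

    ``effect_beta`` is the log-scale change in the gene's expected count
    per alternate allele; a non-causal pair must carry effect 0.
    """

    gene: str
    variant: str
    effect_beta: float
    maf: float
    is_causal: bool = True

    def __post_init__(self):
        if not 0.0 < self.maf <= 0.5:
            raise ValueError("maf must be in (0, 0.5]")
        if not self.is_causal and self.effect_beta != 0.0:
            raise ValueError("non-causal pairs must have effect_beta = 0")


@dataclass
class CountSim:
    """A simulated count matrix together with its generating state.

    Attributes
    ----------
    counts : DataFrame, genes x samples
    samples : DataFrame with donor, tissue, collection, prep, QC fields
    genes : DataFrame with gene_id, biotype, length, chrom, tss
    mu : ndarray, genes x samples latent expected counts
    config : SimConfig
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame
    mu: np.ndarray
    config: SimConfig


def _draw_counts(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    if phi > 0:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    else:
        lam = mu
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> CountSim:
    """Draw a gene-by-sample count matrix under the configured design.

    Per-gene relative expression is log-normal; per-sample library
    sizes are log-normal with the configured CV; per-gene donor and
    tissue effects shift the log-mean. Expected counts per sample are
    scaled so they sum to that sample's library size, then counts are
    drawn negative-binomially. Deterministic under a fixed seed.
    """
    c = config
    n_tissue = len(c.tissues)
    n_samples = c.n_donors * n_tissue * c.collections_per_donor

    grng = _rng(c.seed, "genes")
    # relative expression weights; heavy-tailed like real bulk RNA-seq
    log_w = grng.normal(0.0, 1.5, size=c.n_genes)
    lengths = np.exp(grng.uniform(np.log(300.0), np.log(30000.0), size=c.n_genes))
    n_pc = int(round(c.frac_protein_coding * c.n_genes))
    n_lnc = int(round(0.5 * (c.n_genes - n_pc)))
    biotype = np.array(
        ["protein_coding"] * n_pc + ["lncRNA"] * n_lnc + ["other"] * (c.n_genes - n_pc - n_lnc)
    )
    grng.shuffle(biotype)
    chrom = np.array([str(1 + i % 22) for i in range(c.n_genes)])
    tss = grng.integers(1, 200_000_000, size=c.n_genes)
    gene_ids = [f"G{i:05d}" for i in range(c.n_genes)]
    genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "biotype": biotype,
            "length": np.round(lengths).astype(int),
            "chrom": chrom,
            "tss": tss,
        }
    ).set_index("gene_id", drop=False)

    donors = [f"D{i + 1:02d}" for i in range(c.n_donors)]
    donor_eff = _rng(c.seed, "donor_effects").normal(0.0, c.donor_sd, size=(c.n_genes, c.n_donors))
    tissue_eff = _rng(c.seed, "tissue_effects").normal(
        0.0, c.tissue_effect_sd, size=(c.n_genes, n_tissue)
    )

    rows = []
    for d_i, donor in enumerate(donors):
        for t_i, tissue in enumerate(c.tissues):
            for col in range(1, c.collections_per_donor + 1):
                rows.append((f"{donor}_{tissue}_C{col}", donor, tissue, col, d_i, t_i))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "donor", "tissue", "collection", "_d", "_t"]
    ).set_index("sample_id", drop=False)

    srng = _rng(c.seed, "samples")
    if c.depth_cv > 0:
        sigma = np.sqrt(np.log1p(c.depth_cv**2))
        lib = c.depth_mean * np.exp(srng.normal(-0.5 * sigma**2, sigma, size=n_samples))
    else:
        lib = np.full(n_samples, c.depth_mean)
    samples["lib_depth"] = lib
    # prep metadata used by the prep-QC gate; all pass by construction
    samples["prep"] = "loseq"
    samples["rna_yield"] = srng.lognormal(np.log(1000.0), 0.8, size=n_samples)
    samples["lib_concentration"] = srng.uniform(2.5, 20.0, size=n_samples)
    samples["lib_size"] = srng.uniform(250.0, 550.0, size=n_samples)

    log_mu = (
        log_w[:, None]
        + donor_eff[:, samples["_d"].to_numpy()]
        + tissue_eff[:, samples["_t"].to_numpy()]
    )
    rel = np.exp(log_mu)
    mu = rel / rel.sum(axis=0, keepdims=True) * lib[None, :]

    counts = _draw_counts(_rng(c.seed, "counts"), mu, c.nb_dispersion)
    counts = pd.DataFrame(counts, index=genes.index, columns=samples.index)
    samples = samples.drop(columns=["_d", "_t"])
    return CountSim(counts=counts, samples=samples, genes=genes, mu=mu, config=c)


@dataclass
class GenotypeTable:
    """Variant-by-donor dosages plus per-variant metadata.

    ``dosage`` holds additive alternate-allele counts in {0, 1, 2};
    ``variants`` carries chrom, pos, ref, alt and the realized MAF.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def subset(self, variant_ids) -> "GenotypeTable":
        variant_ids = list(variant_ids)
        return GenotypeTable(
            dosage=self.dosage.loc[variant_ids], variants=self.variants.loc[variant_ids]
        )


_BASES = np.array(list("ACGT"))


def simulate_genotypes(
    n_donors: int,
    mafs,
    positions=None,
    seed: int = 0,
    chrom: str = "1",
) -> GenotypeTable:
    """Hardy-Weinberg dosages in {0,1,2} at the requested allele frequencies.

    Positions default to an evenly spaced grid; realized MAF is recorded
    per variant alongside the target.
    """
    mafs = np.asarray(mafs, dtype=float)
    if np.any((mafs <= 0) | (mafs > 0.5)):
        raise ValueError("mafs must be in (0, 0.5]")
    if n_donors < 1:
        raise ValueError("n_donors must be >= 1")
    m = len(mafs)
    if positions is None:
        positions = np.arange(1, m + 1) * 10_000
    positions = np.asarray(positions, dtype=int)
    if len(positions) != m:
        raise ValueError("positions and mafs must have equal length")

    rng = _rng(seed, "genotypes")
    dosage = rng.binomial(2, mafs[:, None], size=(m, n_donors))
    ref = rng.choice(_BASES, size=m)
    # alt differs from ref
    alt = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in ref])
    donors = [f"D{i + 1:02d}" for i in range(n_donors)]
    vids = [f"var_{chrom}_{p}" for p in positions]
    freq = dosage.mean(axis=1) / 2.0
    variants = pd.DataFrame(
        {
            "variant": vids,
            "chrom": chrom,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "maf_target": mafs,
            "maf": np.minimum(freq, 1.0 - freq),
        }
    ).set_index("variant", drop=False)
    dosage = pd.DataFrame(dosage, index=variants.index, columns=donors)
    return GenotypeTable(dosage=dosage, variants=variants)


def plant_eqtls(sim: CountSim, geno: GenotypeTable, truth) -> CountSim:
    """Redraw counts for causal genes with dosage-scaled means.

    For each causal pair the gene's latent mean in every sample of donor
    ``d`` is multiplied by exp(effect_beta * dosage[d]) before the
    negative-binomial redraw; non-causal genes are returned untouched.
    """
    truth = list(truth)
    gene_pos = {g: i for i, g in enumerate(sim.counts.index)}
    donors = sim.samples["donor"]
    for t in truth:
        if t.gene not in gene_pos:
            raise KeyError(f"unknown gene id {t.gene!r}")
        if t.variant not in geno.dosage.index:
            raise KeyError(f"unknown variant id {t.variant!r}")
    missing = set(donors) - set(geno.dosage.columns)
    if missing:
        raise KeyError(f"donors missing from genotype table: {sorted(missing)[:3]}")

    mu = sim.mu.copy()
    causal_rows = []
    for t in truth:
        if not t.is_causal or t.effect_beta == 0.0:
            continue
        i = gene_pos[t.gene]
        dos = geno.dosage.loc[t.variant, donors].to_numpy(dtype=float)
        mu[i, :] = mu[i, :] * np.exp(t.effect_beta * dos)
        causal_rows.append(i)

    counts = sim.counts.to_numpy().copy()
    if causal_rows:
        rows = np.array(sorted(set(causal_rows)))
        redraw = _draw_counts(
            _rng(sim.config.seed, "planted_counts"), mu[rows, :], sim.config.nb_dispersion
        )
        counts[rows, :] = redraw
    counts = pd.DataFrame(counts, index=sim.counts.index, columns=sim.counts.columns)
    return replace_counts(sim, counts=counts, mu=mu)


def replace_counts(sim: CountSim, counts: pd.DataFrame, mu: np.ndarray | None = None) -> CountSim:
    return CountSim(
        counts=counts,
        samples=sim.samples,
        genes=sim.genes,
        mu=sim.mu if mu is None else mu,
        config=sim.config,
    )


def simulate_pvalues(m: int, pi1_true: float, alt_shape: float = 0.1, seed: int = 0) -> np.ndarray:
    """Uniform/Beta(a,1) mixture of p-values with known alternative fraction.

    A fraction ``pi1_true`` of the m p-values is Beta(alt_shape, 1)
    (concentrated near 0 for alt_shape < 1); the rest are Uniform(0,1).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= pi1_true <= 1.0:
        raise ValueError("pi1_true must be in [0, 1]")
    if not 0.0 < alt_shape < 1.0:
        raise ValueError("alt_shape must be in (0, 1)")
    rng = _rng(seed, "pvalues")
    n_alt = rng.binomial(m, pi1_true)
    p = np.concatenate(
        [rng.beta(alt_shape, 1.0, size=n_alt), rng.uniform(0.0, 1.0, size=m - n_alt)]
    )
    rng.shuffle(p)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_ase_sites(
    n_sites_per_class: int,
    depth_mean: float = 50.0,
    imbalance: float = 0.8,
    seed: int = 0,
    n_donors: int = 19,
) -> pd.DataFrame:
    """Allele-count table contrasting stop-gain and synonymous sites.

    Synonymous sites draw reference counts Binomial(total, 0.5);
    stop-gain sites Binomial(total, imbalance), emulating
    nonsense-mediated decay of the stop-bearing allele. Totals are
    Poisson(depth_mean); sites are distributed round-robin across
    donors, tissues and collections.
    """
    if not 0.5 <= imbalance < 1.0:
        raise ValueError("imbalance must be in [0.5, 1)")
    if n_sites_per_class < 1:
        raise ValueError("n_sites_per_class must be >= 1")
    rng = _rng(seed, "ase")
    rows = []
    tissues = DEFAULT_TISSUES
    for cls, p_ref in (("stop_gained", imbalance), ("synonymous", 0.5)):
        total = rng.poisson(depth_mean, size=n_sites_per_class)
        ref = rng.binomial(total, p_ref)
        for i in range(n_sites_per_class):
            rows.append(
                {
                    "donor": f"D{1 + i % n_donors:02d}",
                    "tissue": tissues[i % len(tissues)],
                    "collection": 1 + (i // len(tissues)) % 4,
                    "gene": f"G{i:05d}",
                    "variant": f"site_{cls}_{i}",
                    "ref_count": int(ref[i]),
                    "alt_count": int(total[i] - ref[i]),
                    "consequence": cls,
                }
            )
    return pd.DataFrame(rows)


def simulate_species_reads(
    n_species: int,
    tissue_profiles: dict,
    genome_lengths,
    n_replicate_pairs: int = 3,
    depth: int = 100_000,
    jitter_sd: float = 0.0,
    seed: int = 0,
):
    """Multinomial species read counts whose length-normalization inverts.

    Reads per sample are multinomial with probabilities proportional to
    (tissue profile x genome length), so dividing by genome length and
    renormalizing recovers the profile. Both members of a technical
    replicate pair share one profile; with ``jitter_sd`` > 0 each pair's
    profile is perturbed by a shared log-normal factor per species
    (between-pair biological variation, against which replicate
    concordance is meaningful). Returns (table, pairing): ``table`` has
    species rows, a genome_length column and one read-count column per
    sample; ``pairing`` lists (sample_1, sample_2) replicate pairs.
    """
    genome_lengths = np.asarray(genome_lengths, dtype=float)
    if np.any(genome_lengths <= 0):
        raise ValueError("genome lengths must be > 0")
    if len(genome_lengths) != n_species:
        raise ValueError("genome_lengths must have n_species entries")
    rng = _rng(seed, "species")
    species = [f"sp{i:03d}" for i in range(n_species)]
    cols, pairs = {}, []
    for tissue, profile in tissue_profiles.items():
        profile = np.asarray(profile, dtype=float)
        if np.any(profile < 0) or len(profile) != n_species:
            raise ValueError("profiles must be non-negative with n_species entries")
        for i in range(n_replicate_pairs):
            pair_profile = profile
            if jitter_sd > 0:
                pair_profile = profile * np.exp(rng.normal(0.0, jitter_sd, n_species))
            w = pair_profile * genome_lengths
            w = w / w.sum()
            a, b = f"{tissue}_p{i + 1}_r1", f"{tissue}_p{i + 1}_r2"
            cols[a] = rng.multinomial(depth, w)
            cols[b] = rng.multinomial(depth, w)
            pairs.append((a, b))
    table = pd.DataFrame(cols, index=species)
    table.insert(0, "genome_length", genome_lengths.astype(int))
    table.index.name = "species"
    return table, pairs
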