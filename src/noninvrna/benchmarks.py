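"""Simulation experiments that score the pipeline against planted truth.

Each function runs one calibration / recovery / power experiment at the
study's conditions (19 donors where the design matters), seeded from a
single integer, and returns a flat dict of metrics. The acceptance
tests assert on these metrics and ``scripts/acceptance.py`` reports
them; both run the same code path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from . import ase as ase_mod
from . import cis, disease, downsample, normalize, projection, replication, triage
from .simulate import (
    EqtlTruth,
    SimConfig,
    _rng,
    plant_eqtls,
    simulate_ase_sites,
    simulate_counts,
    simulate_genotypes,
    simulate_pvalues,
    simulate_species_reads,
)

__all__ = [
    "pi1_recovery",
    "perm_p_calibration",
    "replication_power",
    "downsample_unbiasedness",
    "normalization_conservation",
    "projection_correctness",
    "null_scan_calibration",
    "ses_checks",
    "ase_contrast_calibration",
    "triage_conservation",
]


def _seed(master: int, k: int) -> int:
    return (int(master) * 10_007 + k) % (2**31 - 1)


# ---------------------------------------------------------------- pi1


def pi1_recovery(
    seed: int = 0,
    pi1_values=(0.0, 0.1, 0.3, 0.5),
    m: int = 5000,
    n_seeds: int = 100,
    alt_shape: float = 0.1,
) -> dict:
    """Recovery of the alternative fraction from uniform/Beta mixtures."""
    out = {}
    all_errs = []
    for pi1 in pi1_values:
        errs = []
        for i in range(n_seeds):
            p = simulate_pvalues(m, pi1, alt_shape, seed=_seed(seed, 1000 + i))
            errs.append((1.0 - replication.estimate_pi0(p)) - pi1)
        errs = np.array(errs)
        all_errs.append(np.abs(errs))
        out[f"pi1_bias_true_{pi1:g}"] = float(errs.mean())
        out[f"pi1_mae_true_{pi1:g}"] = float(np.abs(errs).mean())
    out["pi1_mean_abs_error"] = float(np.concatenate(all_errs).mean())
    return out


def _uniform_pool(n: int, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n)],
            "variant": [f"V{i:05d}" for i in range(n)],
            "p_nominal": np.clip(rng.uniform(0, 1, n), 1e-300, 1.0),
            "maf": rng.uniform(0.05, 0.5, n),
        }
    )


def perm_p_calibration(
    seed: int = 0,
    n_seeds: int = 200,
    B: int = 200,
    n_discovery: int = 200,
    pool_size: int = 2000,
) -> dict:
    """Permutation p-values are uniform when discovery pairs carry no signal.

    Discovery sets are drawn uniformly from a pool of null (uniform-p)
    pairs, so the observed pi1 statistic is exchangeable with the
    allele-frequency-matched null draws and perm_p should be uniform.
    """
    perm_ps = []
    for i in range(n_seeds):
        rng = _rng(_seed(seed, 2000 + i), "calibration")
        pool = _uniform_pool(pool_size, rng)
        disc_ix = rng.choice(pool_size, size=n_discovery, replace=False)
        discovery = pool.iloc[disc_ix]
        res = replication.replication_test(
            discovery[["gene", "variant"]],
            pool,
            B=B,
            seed=_seed(seed, 5000 + i),
        )
        perm_ps.append(res.perm_p)
    ks = stats.kstest(perm_ps, "uniform")
    return {
        "perm_p_ks_stat": float(ks.statistic),
        "perm_p_ks_pvalue": float(ks.pvalue),
        "perm_p_mean": float(np.mean(perm_ps)),
    }


def _scan_paired(sim, geno, n_pairs=None):
    """TMM + INT normalization and a paired gene_i ~ variant_i scan."""
    counts = sim.counts
    factors = normalize.tmm_factors(counts)
    norm = counts.div(factors, axis=1)
    expr = pd.DataFrame(
        np.apply_along_axis(normalize.inverse_normal_transform, 1, norm.to_numpy()),
        index=counts.index,
        columns=counts.columns,
    )
    expr.columns = sim.samples.loc[expr.columns, "donor"]
    genes = counts.index if n_pairs is None else counts.index[:n_pairs]
    pairs = pd.DataFrame(
        {
            "gene": genes,
            "variant": geno.dosage.index[: len(genes)],
            "distance": 0,
        }
    )
    return cis.nominal_scan(expr, geno, None, pairs)


def replication_power(
    seed: int = 0,
    n_seeds: int = 100,
    n_discovery: int = 200,
    frac_shared: float = 0.5,
    effect_beta: float = 1.0,
    maf: float = 0.3,
    n_donors: int = 19,
    pool_extra: int = 2000,
    B: int = 200,
) -> dict:
    """Power of the permutation test with half the discovery pairs shared.

    Each replicate simulates a 19-donor, single-tissue cohort with
    ``frac_shared`` of the discovery genes carrying a planted cis
    effect (log-scale 1.0 per allele at MAF 0.3), scans the discovery
    pairs plus a null pool, and runs the matched-null permutation test.
    """
    n_genes = n_discovery + pool_extra
    hits = 0
    pi1s = []
    for i in range(n_seeds):
        s = _seed(seed, 3000 + i)
        cfg = SimConfig(
            n_genes=n_genes,
            n_donors=n_donors,
            tissues=("hair",),
            collections_per_donor=1,
            seed=s,
            depth_mean=2.5e6,
            nb_dispersion=0.1,
        )
        sim = simulate_counts(cfg)
        geno = simulate_genotypes(n_donors, np.full(n_genes, maf), seed=s)
        n_causal = int(round(frac_shared * n_discovery))
        truth = [
            EqtlTruth(
                gene=sim.counts.index[j],
                variant=geno.dosage.index[j],
                effect_beta=effect_beta,
                maf=maf,
            )
            for j in range(n_causal)
        ]
        sim = plant_eqtls(sim, geno, truth)
        scan = _scan_paired(sim, geno)
        discovery = scan.iloc[:n_discovery][["gene", "variant"]]
        res = replication.replication_test(discovery, scan, B=B, seed=_seed(seed, 7000 + i))
        pi1s.append(res.pi1_observed)
        hits += res.perm_p < 0.05
    return {
        "replication_power": hits / n_seeds,
        "replication_mean_pi1": float(np.mean(pi1s)),
    }


# ----------------------------------------------------- counts handling


def downsample_unbiasedness(
    seed: int = 0, n_genes: int = 2000, n_mc: int = 200
) -> dict:
    """Monte-Carlo check that thinning is unbiased and hits the target depth."""
    cfg = SimConfig(
        n_genes=n_genes,
        n_donors=2,
        tissues=("hair",),
        collections_per_donor=2,
        seed=_seed(seed, 41),
        depth_mean=1e5,
        depth_cv=0.0,
    )
    sim = simulate_counts(cfg)
    counts = sim.counts
    depths = counts.sum(axis=0).astype(float)
    target = float(depths.min()) / 2.0
    p = target / depths.to_numpy()

    acc = np.zeros(counts.shape)
    for i in range(n_mc):
        spec = downsample.DownsampleSpec(target_depth=target, n_reps=1, seed=_seed(seed, 100 + i))
        acc += downsample.binomial_downsample(counts, spec, depths).to_numpy()
    mc_mean = acc / n_mc
    expected = counts.to_numpy() * p[None, :]
    big = expected >= 50
    rel_bias = float(np.abs(mc_mean[big] - expected[big]).sum() / expected[big].sum())
    total_rel_err = float(abs(mc_mean.sum() - expected.sum()) / expected.sum())

    spec5 = downsample.DownsampleSpec(target_depth=target, n_reps=5, seed=_seed(seed, 43))
    avg = downsample.binomial_downsample(counts, spec5, depths)
    depth_rel_err = float(np.abs(avg.sum(axis=0) / target - 1.0).max())
    return {
        "downsample_rel_bias": rel_bias,
        "downsample_total_rel_err": total_rel_err,
        "downsample_depth_rel_err": depth_rel_err,
    }


def normalization_conservation(seed: int = 0, n_genes: int = 2000) -> dict:
    """TPM conservation, TMM recovery of a 2x depth shift, INT symmetry."""
    cfg = SimConfig(
        n_genes=n_genes,
        n_donors=4,
        tissues=("hair",),
        collections_per_donor=1,
        seed=_seed(seed, 61),
        depth_mean=1e6,
        depth_cv=0.0,
        nb_dispersion=0.05,
    )
    sim = simulate_counts(cfg)
    counts = sim.counts
    tpm = normalize.compute_tpm(counts, sim.genes["length"])
    tpm_dev = float(np.abs(tpm.sum(axis=0) / 1e6 - 1.0).max())

    shifted = counts.copy()
    shifted["doubled"] = 2 * counts.iloc[:, 0]
    f = normalize.tmm_factors(shifted)
    ratio = f["doubled"] / f[counts.columns[0]]
    tmm_geomean = float(np.exp(np.mean(np.log(f))))
    tmm_shift_err = float(abs(ratio / 2.0 - 1.0))

    rng = _rng(_seed(seed, 62), "intcheck")
    v = rng.normal(size=500) ** 3  # skewed continuous input
    z = normalize.inverse_normal_transform(v)
    return {
        "tpm_colsum_max_rel_dev": tpm_dev,
        "tmm_geometric_mean": tmm_geomean,
        "tmm_planted_2x_rel_err": tmm_shift_err,
        "int_mean_abs": float(abs(z.mean())),
        "int_skew_abs": float(abs(stats.skew(z))),
    }


def projection_correctness(seed: int = 0, n_seeds: int = 100) -> dict:
    """Self-projection fidelity and two-cluster query assignment."""
    rng = _rng(_seed(seed, 71), "proj")
    ref = pd.DataFrame(
        rng.normal(size=(300, 40)),
        index=[f"G{i:04d}" for i in range(300)],
        columns=[f"R{i}" for i in range(40)],
    )
    hvg = projection.select_hvg(ref, n=200)
    model = projection.fit_reference_pca(ref.loc[hvg], n_components=5)
    scores = projection.project(model, ref.loc[hvg])
    z = (ref.loc[model.feature_ids].to_numpy().T - model.means) / model.sds
    self_diff = float(np.abs(scores.to_numpy() - z @ model.loadings).max())

    correct = 0
    for i in range(n_seeds):
        r = _rng(_seed(seed, 500 + i), "cluster")
        shift = np.zeros(50)
        shift[:10] = 4.0
        a = r.normal(size=(20, 50)) + shift
        b = r.normal(size=(20, 50)) - shift
        refm = pd.DataFrame(
            np.vstack([a, b]).T, index=[f"F{j}" for j in range(50)],
            columns=[f"A{j}" for j in range(20)] + [f"B{j}" for j in range(20)],
        )
        m = projection.fit_reference_pca(refm, n_components=2)
        ref_scores = projection.project(m, refm)
        q = pd.DataFrame(
            (r.normal(size=(3, 50)) + shift).T,
            index=refm.index,
            columns=["q1", "q2", "q3"],
        )
        qs = projection.project(m, q).to_numpy()[:, :2]
        cent_a = ref_scores.iloc[:20, :2].mean().to_numpy()
        cent_b = ref_scores.iloc[20:, :2].mean().to_numpy()
        d_a = np.linalg.norm(qs - cent_a, axis=1)
        d_b = np.linalg.norm(qs - cent_b, axis=1)
        correct += int((d_a < d_b).all())
    return {
        "projection_self_max_abs_diff": self_diff,
        "projection_cluster_assignment_rate": correct / n_seeds,
    }


def null_scan_calibration(seed: int = 0, n_pairs: int = 5000, n_donors: int = 19) -> dict:
    """False-positive rate of the nominal scan with no planted effects."""
    cfg = SimConfig(
        n_genes=n_pairs,
        n_donors=n_donors,
        tissues=("hair",),
        collections_per_donor=1,
        seed=_seed(seed, 81),
        depth_mean=2.5e6,
    )
    sim = simulate_counts(cfg)
    rng = _rng(_seed(seed, 82), "mafs")
    geno = simulate_genotypes(
        n_donors, rng.uniform(0.1, 0.5, n_pairs), seed=_seed(seed, 83)
    )
    scan = _scan_paired(sim, geno)
    ok = ~scan["monomorphic_in_sample"]
    p = scan.loc[ok, "p_nominal"].to_numpy()
    return {
        "null_scan_fpr_05": float((p < 0.05).mean()),
        "null_scan_fpr_01": float((p < 0.01).mean()),
        "null_scan_n_pairs": int(ok.sum()),
    }


def ses_checks(seed: int = 0, n_tables: int = 1000) -> dict:
    """The worked SES example plus monotonicity on random tables."""
    ev = pd.DataFrame(
        {
            "disease": "d",
            "gene": ["A", "B", "C"],
            "n_sources": 5,
            "score": [2.0, 1.0, 1.0],
        }
    )
    tset = disease.TissueGeneSet(tissue="t", genes=frozenset({"A", "C"}))
    worked = disease.ses(tset, ev, {"A", "B", "C"})

    rng = _rng(_seed(seed, 91), "ses")
    violations = 0
    for _ in range(n_tables):
        genes = [f"g{j}" for j in range(12)]
        evr = pd.DataFrame(
            {
                "disease": "d",
                "gene": genes,
                "n_sources": 5,
                "score": rng.uniform(0, 3, len(genes)),
            }
        )
        union = set(genes)
        members = set(rng.choice(genes, size=5, replace=False))
        base = disease.ses(disease.TissueGeneSet("t", frozenset(members)), evr, union)
        extra = rng.choice(sorted(union - members))
        grown = disease.ses(
            disease.TissueGeneSet("t", frozenset(members | {extra})), evr, union
        )
        if grown < base - 1e-12:
            violations += 1
    return {"ses_worked_example": float(worked), "ses_monotone_violations": violations}


def ase_contrast_calibration(
    seed: int = 0,
    n_null: int = 500,
    n_power: int = 100,
    n_sites: int = 100,
    depth: float = 50.0,
    imbalance: float = 0.8,
) -> dict:
    """Type-I error under the null generator and power at imbalance 0.8."""
    false_pos = 0
    for i in range(n_null):
        sites = simulate_ase_sites(n_sites, depth, 0.5, seed=_seed(seed, 10_000 + i))
        ratios = ase_mod.ref_ratio(sites)
        false_pos += ase_mod.nmd_contrast(ratios).p_value < 0.05
    detected = 0
    for i in range(n_power):
        sites = simulate_ase_sites(n_sites, depth, imbalance, seed=_seed(seed, 20_000 + i))
        ratios = ase_mod.ref_ratio(sites)
        detected += ase_mod.nmd_contrast(ratios).p_value < 0.01
    return {
        "ase_type1_rate": false_pos / n_null,
        "ase_power": detected / n_power,
    }


def triage_conservation(seed: int = 0, n_cases: int = 1000) -> dict:
    """Ledger partition on random inputs; abundance inverts the generator."""
    rng = _rng(_seed(seed, 31), "ledger")
    violations = 0
    for _ in range(n_cases):
        n = int(rng.integers(1, 200))
        ids = [f"r{j}" for j in range(n)]
        mapped = set(rng.choice(ids, size=int(rng.integers(0, n + 1)), replace=False))
        remapped = set(rng.choice(ids, size=int(rng.integers(0, n + 1)), replace=False))
        repeated = set(rng.choice(ids, size=int(rng.integers(0, n + 1)), replace=False))
        led = triage.classify_reads("s", ids, mapped, remapped, repeated)
        parts = led.n_mapped + led.n_remapped + led.n_repeated + led.n_unknown
        violations += parts != led.n_total

    lengths = np.array([1e6, 2e6, 5e5, 3e6, 1.5e6])
    profile = np.array([0.4, 0.4, 0.1, 0.05, 0.05])
    table, pairs = simulate_species_reads(
        5,
        {"buccal": profile, "saliva": profile[::-1]},
        lengths,
        n_replicate_pairs=3,
        depth=500_000,
        seed=_seed(seed, 32),
    )
    abund = triage.species_abundance(table)
    colsum_dev = float(np.abs(abund.sum(axis=0) - 1.0).max())
    buccal_cols = [c for c in abund.columns if c.startswith("buccal")]
    recovered = abund[buccal_cols].mean(axis=1).to_numpy()
    inversion_err = float(np.abs(recovered - profile).max())
    return {
        "ledger_partition_violations": violations,
        "abundance_colsum_max_dev": colsum_dev,
        "abundance_profile_max_err": inversion_err,
    }
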