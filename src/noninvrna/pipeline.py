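"""End-to-end orchestration on a declarative config, with provenance.

The pipeline runs simulate -> prep/seq QC -> downsample -> normalize ->
cis scan -> replication -> ASE contrast -> read triage on synthetic
data with known ground truth, writing every intermediate as TSV/JSON
and a manifest with config, per-stage seeds and file digests. Re-runs
with the same config and seed reproduce identical digests (floats are
rounded to 10 decimals on write).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ase as ase_mod
from . import cis, downsample, io, normalize, qc, replication, triage
from .simulate import (
    EqtlTruth,
    SimConfig,
    plant_eqtls,
    simulate_ase_sites,
    simulate_counts,
    simulate_genotypes,
    simulate_species_reads,
)

__all__ = ["DEMO_CONFIG", "validate_config", "run_pipeline"]

DEMO_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_genes": 400,
        "n_donors": 19,
        "tissues": ["hair"],
        "collections_per_donor": 2,
        "depth_mean": 200000.0,
        "depth_cv": 0.2,
        "nb_dispersion": 0.1,
    },
    "qc": {"depth_threshold": 50000.0},
    "downsample": {"target_depth": 50000.0, "n_reps": 5},
    "eqtl": {"n_causal": 40, "effect_beta": 1.0, "maf": 0.3, "B": 100},
    "ase": {"n_sites_per_class": 100, "imbalance": 0.8, "depth": 50.0},
    "triage": {"n_species": 20, "n_replicate_pairs": 3, "depth": 100000},
}

_SCHEMA = {
    "seed": int,
    "simulate": dict,
    "qc": dict,
    "downsample": dict,
    "eqtl": dict,
    "ase": dict,
    "triage": dict,
}


def validate_config(config: dict) -> dict:
    """Fill defaults from the demo config; reject unknown or mistyped keys."""
    merged = {}
    unknown = set(config) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _SCHEMA.items():
        val = config.get(key, DEMO_CONFIG[key])
        if not isinstance(val, typ):
            raise ValueError(f"config field {key!r} must be {typ.__name__}")
        if isinstance(val, dict):
            base = dict(DEMO_CONFIG[key])
            bad = set(val) - set(base)
            if bad:
                raise ValueError(f"unknown keys under {key!r}: {sorted(bad)}")
            base.update(val)
            val = base
        merged[key] = val
    return merged


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the stage graph and return the run manifest."""
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    manifest = {
        "software": f"noninvrna {__version__}",
        "config": config,
        "stages": {},
        "files": {},
    }

    def stage(name):
        manifest["stages"][name] = {"seed": seed, "t_start": time.time()}

    def done(name, **info):
        st = manifest["stages"][name]
        st["runtime_s"] = round(time.time() - st.pop("t_start"), 3)
        st.update(info)

    # --- simulate ---------------------------------------------------
    stage("simulate")
    sc = config["simulate"]
    cfg = SimConfig(
        n_genes=int(sc["n_genes"]),
        n_donors=int(sc["n_donors"]),
        tissues=tuple(sc["tissues"]),
        collections_per_donor=int(sc["collections_per_donor"]),
        seed=seed,
        depth_mean=float(sc["depth_mean"]),
        depth_cv=float(sc["depth_cv"]),
        nb_dispersion=float(sc["nb_dispersion"]),
    )
    sim = simulate_counts(cfg)
    ec = config["eqtl"]
    n_causal = int(ec["n_causal"])
    geno = simulate_genotypes(
        cfg.n_donors, np.full(cfg.n_genes, float(ec["maf"])), seed=seed
    )
    truth = [
        EqtlTruth(
            gene=sim.counts.index[i],
            variant=geno.dosage.index[i],
            effect_beta=float(ec["effect_beta"]),
            maf=float(ec["maf"]),
        )
        for i in range(n_causal)
    ]
    sim = plant_eqtls(sim, geno, truth)
    io.write_counts_tsv(sim.counts, outdir / "counts.tsv")
    io.write_table(sim.samples, outdir / "samples.tsv", index=False)
    io.write_table(sim.genes, outdir / "genes.tsv", index=False)
    io.write_dosage_tsv(geno, outdir / "dosages.tsv")
    io.write_vcf(geno, outdir / "genotypes.vcf")
    done("simulate", n_genes=cfg.n_genes, n_samples=sim.counts.shape[1], n_causal=n_causal)

    # --- qc ---------------------------------------------------------
    stage("qc")
    prep = qc.prep_qc_gate(sim.samples)
    depths = qc.coding_depth(sim.counts, sim.genes)
    deep = qc.seq_qc_gate(depths, float(config["qc"]["depth_threshold"]))
    report = prep.join(depths).join(deep)
    io.write_table(report, outdir / "qc_report.tsv")
    keep = report.index[report["pass_qc"] & report["pass_depth"]]
    counts = sim.counts[keep]
    done("qc", n_pass=len(keep), n_fail=report.shape[0] - len(keep))

    # --- downsample -------------------------------------------------
    stage("downsample")
    dc = config["downsample"]
    spec = downsample.DownsampleSpec(
        target_depth=float(dc["target_depth"]), n_reps=int(dc["n_reps"]), seed=seed
    )
    ds = downsample.binomial_downsample(counts, spec, depths[keep])
    io.write_counts_tsv(ds, outdir / "counts_downsampled.tsv")
    done("downsample", target_depth=spec.target_depth)

    # --- normalize (one sample per donor: highest coding depth) ------
    stage("normalize")
    meta = sim.samples.loc[keep]
    best = depths[keep].groupby(meta["donor"]).idxmax()
    sel = counts[best.to_numpy()]
    tpm = normalize.compute_tpm(sel, sim.genes["length"])
    expressed = normalize.expression_filter(sel, tpm, **normalize.EXPRESSION_FILTER_PRESETS["gtex"])
    factors = normalize.tmm_factors(sel.loc[expressed])
    norm = sel.loc[expressed].div(factors, axis=1)
    expr = pd.DataFrame(
        np.apply_along_axis(normalize.inverse_normal_transform, 1, norm.to_numpy()),
        index=norm.index,
        columns=norm.columns,
    )
    expr.columns = meta.loc[expr.columns, "donor"]
    io.write_table(expr, outdir / "expression_int.tsv")
    done("normalize", n_expressed=len(expressed))

    # --- cis scan + replication -------------------------------------
    stage("cis_scan")
    pairs = pd.DataFrame(
        {
            "gene": [g for g in sim.counts.index if g in expr.index],
            "distance": 0,
        }
    )
    pairs["variant"] = [
        geno.dosage.index[sim.counts.index.get_loc(g)] for g in pairs["gene"]
    ]
    scan = cis.nominal_scan(expr, geno, None, pairs)
    io.write_table(scan, outdir / "cis_scan.tsv", index=False)
    done("cis_scan", n_pairs=len(scan))

    stage("replication")
    causal = {t.gene for t in truth}
    discovery = scan[scan["gene"].isin(causal)][["gene", "variant"]]
    res = replication.replication_test(discovery, scan, B=int(ec["B"]), seed=seed)
    rep_out = {
        "tissue_pair": list(res.tissue_pair),
        "n_pairs": res.n_pairs,
        "pi1_observed": res.pi1_observed,
        "perm_p": res.perm_p,
        "B": res.B,
        "seed": res.seed,
        "null_pi1_mean": float(np.mean(res.null_pi1)),
    }
    (outdir / "replication.json").write_text(json.dumps(rep_out, indent=2) + "\n")
    done("replication", **rep_out)

    # --- ase --------------------------------------------------------
    stage("ase")
    ac = config["ase"]
    sites = simulate_ase_sites(
        int(ac["n_sites_per_class"]),
        float(ac["depth"]),
        float(ac["imbalance"]),
        seed=seed,
        n_donors=cfg.n_donors,
    )
    ratios = ase_mod.ref_ratio(sites)
    contrast = ase_mod.nmd_contrast(ratios)
    io.write_table(ratios, outdir / "ase_ratios.tsv", index=False)
    (outdir / "ase_contrast.json").write_text(
        json.dumps(contrast.__dict__, indent=2) + "\n"
    )
    done("ase", p_value=contrast.p_value)

    # --- triage -----------------------------------------------------
    stage("triage")
    tc = config["triage"]
    n_sp = int(tc["n_species"])
    rng = np.random.default_rng(seed)
    profiles = {t: rng.dirichlet(np.ones(n_sp)) for t in cfg.tissues}
    lengths = rng.integers(5e5, 5e6, size=n_sp)
    table, rep_pairs = simulate_species_reads(
        n_sp,
        profiles,
        lengths,
        n_replicate_pairs=int(tc["n_replicate_pairs"]),
        depth=int(tc["depth"]),
        seed=seed,
    )
    abund = triage.species_abundance(table)
    top = triage.top_fraction_species(abund, frac=0.25)
    rho = triage.replicate_concordance(abund, rep_pairs)
    io.write_table(abund, outdir / "species_abundance.tsv")
    io.write_table(rho.to_frame(), outdir / "replicate_concordance.tsv")
    done("triage", n_top=len(top))

    # --- manifest ---------------------------------------------------
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json":
            manifest["files"][f.name] = io.sha256_file(f)
    io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
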