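# noninvrna

Evaluation toolkit for RNA-seq from **noninvasive biospecimens** —
buccal swabs, hair follicles, saliva and urine cell pellets — aimed at
the question: are these cheap, repeatable sample types good enough to
study gene expression regulation and disease biology, compared with
invasively collected reference tissues?

The package implements the statistical pipeline behind that
evaluation as a tested, reusable library with a CLI:

* **QC gates** — library-prep gate (concentration > 2 nM, mean size
  < 600 bp) and a sequencing gate on protein-coding + lncRNA depth
  (presets 1e6 / 2.5e6 / 5e6 reads);
* **Depth matching** — averaged binomial downsampling: counts thinned
  with p = target/depth, 5 replicates, averaged (unbiased for p·count);
* **Normalization** — TPM, joint count/TPM expression filters, TMM
  scaling factors, rank-based inverse normal transform (INT);
* **Reference-space PCA** — fit on a reference cohort (top-1000 most
  variable features, centered/scaled), project query samples into that
  space; works for expression and splicing-inclusion matrices;
* **cis-eQTL scan** — variant hygiene (MAF ≥ 0.05, SNVs, polymorphic),
  windowed LD pruning (50/5/r² 0.2), genotype and expression PCs as
  covariates, nominal single-variant association within ±1 Mb of the
  TSS;
* **eQTL replication** — Storey's π1 = 1 − π̂0 of the replication
  cohort's p-values for the discovery cohort's significant pairs,
  judged against B = 1000 allele-frequency-matched null pair sets:
  perm_p = (1 + #{null π1 ≥ observed})/(B + 1);
* **Disease relevance** — OMIM gene capture above a median-TPM floor,
  and the summed evidence score
  SES = Σ(evidence of disease genes in a tissue) / Σ(evidence of
  disease genes in any analyzed tissue);
* **ASE / NMD contrast** — reference-allele ratios at heterozygous
  sites (≥ 16 reads), robust donor-outlier flagging, and a
  Mann–Whitney contrast of allelic imbalance |ratio − ½| between
  stop-gain and synonymous sites (nonsense-mediated decay signal);
* **Unmapped-read triage** — mapped / remapped / repeated / unknown
  read ledger, genome-length-normalized species abundances, top-0.5%
  species selection, technical-replicate Spearman concordance;
* **Synthetic data** — generators for all of the above with known
  ground truth (negative-binomial counts with donor/tissue structure,
  Hardy–Weinberg genotypes with planted cis effects, π1-known p-value
  mixtures, imbalanced ASE sites, length-weighted species reads), so
  the whole pipeline is testable without any external data.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Run the bundled end-to-end demo (simulate a 19-donor cohort with 40
planted cis-eQTLs → QC → downsample → TMM+INT → nominal scan →
replication test → ASE contrast → read triage):

```bash
noninvrna run --seed 0 --out demo_out
```

or equivalently from Python:

```python
from noninvrna.pipeline import run_pipeline
manifest = run_pipeline({"seed": 0}, "demo_out")
```

`demo_out/replication.json` then contains

```json
{
  "n_pairs": 40,
  "pi1_observed": 1.0,
  "perm_p": 0.009900990099009901,
  "B": 100,
  "null_pi1_mean": 0.105
}
```

— all 40 planted gene–variant pairs replicate (π1 = 1.0), while
allele-frequency-matched random pair sets average π1 ≈ 0.105, and no
null draw reaches the observed value, so the permutation p is at its
add-one floor 1/(B+1) ≈ 0.0099. `demo_out/ase_contrast.json` shows the
planted NMD signal:

```json
{
  "median_imbalance_a": 0.290,
  "median_imbalance_b": 0.050,
  "p_value": 5.16e-34
}
```

— stop-gain sites (simulated at 80:20 allelic ratio) carry a median
imbalance of 0.29 versus 0.05 at synonymous sites. Each stage's
intermediates are plain TSV/JSON, and `manifest.json` records the
config, seeds and SHA-256 digests; re-running with the same seed
reproduces identical digests.

Individual stages are also exposed as subcommands
(`simulate`, `qc`, `downsample`, `normalize`, `pca-fit`,
`pca-project`, `cis-scan`, `replicate`, `ses`, `omim-capture`, `ase`,
`triage`); run `noninvrna <cmd> --help` for options.

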