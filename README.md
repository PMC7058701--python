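# episnp

Genome-wide pairwise SNP epistasis scanning and signed weighted
interaction-network analysis for quantitative traits, with a seeded
synthetic-data generator for validation.

The pipeline, aimed at feed-efficiency-style quantitative phenotypes in
livestock genotyping panels, runs:

1. **Genotype I/O + QC** — PLINK-style PED/MAP and TPED/TFAM text input,
   minor-allele 0/1/2 coding, sample/SNP call-rate, MAF, exact
   Hardy-Weinberg and autosome filters (`episnp.genotype_io`).
2. **Phenotype derivation** — feed conversion ratio (FC/DW), residual feed
   intake (OLS residual of daily intake), ±1 SD extreme-group labels
   (`episnp.phenotypes`).
3. **Single-SNP association + top-K prefilter** — OLS slope t-tests,
   default top 7,000 SNPs (`episnp.assoc_scan`).
4. **LD-block pruning** — greedy r² chaining (threshold 0.9, max block
   1000), one representative per block (`episnp.ld_prune`).
5. **Exhaustive pairwise interaction scan** — OLS on
   `[1, g_i, g_j, g_i·g_j]` for every SNP pair, batched normal equations,
   t-test on the product coefficient, chromosome-pair quantile overview
   (`episnp.epistasis_scan`).
6. **Network + modules** — signed soft-threshold adjacency
   `((1+s)/2)^β` on normalized interaction coefficients, scale-free power
   selection, topological overlap, average-linkage clustering with a
   deterministic adaptive branch cut, eigenSNPs, module merging, soft
   connectivity (`episnp.snp_network`).
7. **Module–trait association + hubs** — Pearson eigenSNP–trait
   correlation, Bonferroni adjustment, |r| > 0.4 & p ≤ 0.05 selection,
   hub-SNP tables (`episnp.module_trait`).
8. **Annotation** — positional SNP→gene classification from local
   GFF3/BED (`episnp.annotate`).
9. **Simulation** — Gaussian-copula genotypes in AR(1) LD blocks with
   planted main and pairwise-interaction effects, trait rescaling to a
   target mean/SD, serialized ground truth (`episnp.synthetic_data`).

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalence of the batched scan, type-I calibration, estimator bias,
planted-module recovery, exhaustive HWE enumeration agreement, hub
accounting).

## CLI

```sh
# write a seeded synthetic fixture (tiny | standard | breedlike)
episnp simulate --profile tiny --out fixture/ --seed 1

# QC only
episnp qc --ped fixture/genotypes.ped --map fixture/genotypes.map --out qc/

# full pipeline from a YAML config
episnp run --config config.yaml --out run/
```

Minimal `config.yaml`:

```yaml
ped: fixture/genotypes.ped
map: fixture/genotypes.map
phenotypes: fixture/phenotypes.tsv
annotation: fixture/annotation.gff3   # optional
trait: fcr          # fcr | rfi
subset: all         # all | LFE | HFE
top_k: 7000
ld_threshold: 0.9
max_block_size: 1000
```

Every stage writes a TSV artifact plus a JSON stamp (parameter digest,
counts) into the run directory; `summary.json` reports per-stage SNP
counts (post-QC, top-K, post-pruning, modules, selected modules, hubs).

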