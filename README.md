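# kelpscan

Windowed population-genomic statistics and a DCMS composite selection scan,
with a forward Wright–Fisher simulator for generating test data under three
demographic archetypes (natural selfing beds, pool-bred cultivation stock,
founder-effect introductions).

## What it does

* **`kelpscan.synthetic_data`** — discrete-generation Wright–Fisher simulator
  (Poisson crossovers, infinite-sites mutation on a finite grid, partial
  selfing, gamete-pool mixing, founder bottlenecks with re-introduction
  pulses, optional hard sweeps with restart-on-loss) emitting a genotype
  matrix, a population map and a ground-truth record.
* **`kelpscan.variant_io`** — VCF 4.2 read/write (diploid GT), the variant
  filters (QUAL / SNP / biallelic / call-rate / MAF with first-failing-rule
  accounting), non-overlapping window tilings, and TSV/BED side files.
* **`kelpscan.diversity`** — per-window π, Watterson's θ, Tajima's D,
  H_e/H_o, F_IS; Weir–Cockerham (1984) F_ST (ratio of summed variance
  components), reduction of diversity (ROD) and ΔTajima's D for
  focal/reference pairs.
* **`kelpscan.ld`** — unphased genotype-dosage r², distance-binned decay
  profiles, and the half-maximum decay distance (linear interpolation
  between bin midpoints).
* **`kelpscan.roh`** — greedy scan for runs of homozygosity with het budget,
  gap cap, and minimum length/SNP thresholds; per-sample summaries.
* **`kelpscan.selection`** — fractional-rank empirical P values, Spearman
  correlation weights, DCMS scores, robust (median/MAD) Gaussian
  calibration, significant-window and gene-overlap reporting.
* **`kelpscan.pipeline`** — YAML-configured orchestration
  (simulate/load → filter → stats → ld → roh → scan) with a JSON manifest;
  deterministic for a fixed config + seed.

## CLI

```sh
kelpscan simulate --config sim.yaml --out-prefix out/       # VCF + popmap + truth + genes
kelpscan filter   --vcf in.vcf --maf 0.05 --max-missing 0.2 --out filtered.vcf
kelpscan stats    --vcf filtered.vcf --popmap popmap.tsv --windows 50000 \
                  --pairs cultivated:natural --out stats.tsv
kelpscan ld       --vcf filtered.vcf --popmap popmap.tsv --group natural \
                  --max-dist 100000 --bin 1000 --out ld.tsv
kelpscan roh      --vcf filtered.vcf --min-snps 50 --min-length 100000 \
                  --max-het 1 --max-gap 1000000 --out roh
kelpscan scan     --stats stats.tsv --genes genes.bed --threshold 0.025 \
                  --out-prefix scan/
kelpscan run      --config run.yaml                         # full pipeline
```

Exit codes: 0 success, 2 validation error, 1 runtime error.  All tables are
single-header TSVs with `NA` for missing values.

A minimal simulation config (`sim.yaml`):

```yaml
sample_sizes: {bed: 8, farm: 8}
categories: {bed: natural, farm: cultivated}
ancestral_N: 500
chrom_length_bp: 100000
generations: 100
mu: 1.0e-6
rho: 1.0e-6
selfing_rate: 0.3
seed: 1
```

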