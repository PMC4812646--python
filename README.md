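# pigdiv

Genetic-diversity analysis of SNP-chip genotyped populations: quality
control, three inbreeding estimators (pedigree F, ROH-based F_ROH,
SNP-by-SNP F_SNP), runs-of-homozygosity detection and sharing, linkage
disequilibrium decay, between-population correlation of linkage phase, and
LD-based historical effective population size (Ne) — plus a forward
Wright–Fisher simulator that provides ground truth (recorded pedigree,
founder-haplotype mosaics, true autozygosity, true Ne history) for every
stage.

## Layout

| module | contents |
| --- | --- |
| `pigdiv.io_formats` | PLINK ped/map and bed/bim/fam (SNP-major) readers/writers, pedigree tables (acyclicity-checked) |
| `pigdiv.qc` | sample QC (call rate, heterozygosity outliers, duplicates), IBD pi-hat pedigree checks, X-based sex check, exact HWE test, SNP QC, `apply_qc` |
| `pigdiv.pedigree` | Wright's F by the tabular method, pedigree depth (equivalent complete generations + max depth), estimator comparison |
| `pigdiv.roh` | ROH detection, F_ROH / F_SNP, per-sample and per-population summaries, shared ROH (exact/overlap matching, within/between populations), consensus regions |
| `pigdiv.ld_phase` | two-locus EM haplotype frequencies, signed r / r², LD decay in 100-kb bins, adjacent and 1-in-10-thinned LD, phase correlation between populations |
| `pigdiv.ne` | Sved relationship E(r²)=1/(4cNe+1), Ne_t=(1−r²)/(4cr²), the t = 1..10, 15..100, 150..1000 generation grid and its c-windows, Ne trajectories |
| `pigdiv.synthetic` | seeded Wright–Fisher diploid simulator with recombination, population splits, missingness/error injection, and true autozygosity |
| `pigdiv.pipeline` / `pigdiv.cli` | stage orchestration behind the `pigdiv` command |

## CLI

Every subcommand takes one YAML config plus `--out DIR` and composes on the
conventional file layout inside the output directory:

```bash
pigdiv simulate  --config run.yaml --out out/   # or point `populations` at real PLINK files
pigdiv qc        --config run.yaml --out out/
pigdiv inbreeding --config run.yaml --out out/
pigdiv roh       --config run.yaml --out out/
pigdiv ld        --config run.yaml --out out/
pigdiv ne        --config run.yaml --out out/
pigdiv phase     --config run.yaml --out out/
pigdiv report    --config run.yaml --out out/   # full chain + manifest.json
```

Example config:

```yaml
seed: 1
populations:
  la: {plink_prefix: data/la, pedigree: data/la_pedigree.tsv}
  lw: {plink_prefix: data/lw, pedigree: data/lw_pedigree.tsv}
# or instead of real inputs:
# simulate: {n_generations: 20, pop_size: 50, n_chromosomes: 10,
#            chrom_length_morgan: 1.0, n_snps: 2000,
#            split: {generation: 15, sizes: [25, 25]}}
roh: {min_snps: 50, min_length_kb: 1000, window: 50}
ld: {max_dist_bp: 10000000, bin_bp: 100000, thin_keep_every: 10}
ne: {cm_per_mb: 1.0}
phase: {headline_dist_bp: 50000}
```

All thresholds default to the standard analysis values (sample call rate
0.90, heterozygosity ±3 SD, duplicate concordance 0.99; SNP call rate 0.98,
MAF 0.03, HWE p 1e-6; ROH = 50 SNPs / 1000 kb with ≤1 heterozygous and ≤1
missing call per 50-SNP window; genome length 2,808,525 kb for F_ROH;
100-kb LD bins to 10 Mb; 1 cM ≈ 1 Mb) and are declared once in
`pigdiv.defaults`. Outputs are TSV/JSON/BED and byte-stable for a fixed
config and seed (`manifest.json` records version, config hash and input
checksums).

## ROH definition (divergence from PLINK)

`detect_roh` calls a ROH as a maximal run of consecutive SNPs in which
*every* contiguous window of `window` SNPs lying wholly inside the run has
at most `max_het_per_window` heterozygous and `max_missing_per_window`
missing calls, then drops runs shorter than `min_snps` SNPs or
`min_length_kb`. This is exactly specifiable and is verified against a
brute-force definition checker in the tests. PLINK's `--homozyg` instead
scores SNPs by the *proportion* of overlapping windows that pass
(`--homozyg-window-threshold`), and applies gap/density filters by default;
those are available here only as optional post-hoc filters. Expect calls to
differ from PLINK in edge cases.

Two maximal runs can overlap by up to `window − 1` SNPs when two
violations fall close together; calls are reported as defined rather than
merged.

## LD estimation

r is estimated per SNP pair from unphased genotypes by maximum likelihood
under random mating (EM over the double-heterozygote ambiguity, missing
genotypes deleted pairwise). The EM is initialized at the
likelihood-maximizing root of the closed-form cubic for the AB-haplotype
frequency, which makes genome-scale pair tables fast while leaving results
identical; the symmetric all-double-heterozygote tie resolves to D ≥ 0.
Cross-chromosome LD summaries are unweighted means of per-chromosome bin
means (pooled means are emitted alongside).

`ne_trajectory` accepts an optional `r2_offset` subtracted from each
window's mean r² before inverting the Sved relationship, for small samples
where r̂² is inflated by ≈1/n (n unphased diploids). It is off by default.

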