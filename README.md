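# sdmaf

Sex-difference-in-minor-allele-frequency (sdMAF) analysis for variants on
the human X chromosome.

The X chromosome splits into four regions with different male ploidy: the
tip pseudoautosomal regions PAR1/PAR2 (males diploid), the X-transposed
region in Xq21.3 (here labelled PAR3) and the remaining non-pseudoautosomal
region NPR (males hemizygous).  This package tallies sex-stratified
genotype counts from VCFs or aggregated count tables, designates the minor
allele in the sex-pooled sample, and tests every biallelic SNP for a sex
difference in that allele's frequency with a Wald chi-square statistic
whose female variance term is adjusted for Hardy-Weinberg disequilibrium
(HWD).  It also provides:

- HWD delta estimation and chi-square HWE tests in female, male and
  sex-combined scopes (expected-count and delta formulations);
- conditional exact HWE tests: the classic within-sex test, and a joint
  X-chromosomal exact test combining diploid females with hemizygous males,
  both with log-space combinatorics for large samples;
- population-stratified analysis and sqrt(n)-weighted Z-score
  meta-analysis, with minor-allele-flip detection and Bland-Altman
  difference-vs-level summaries including theoretical bounds for the
  flipped subset;
- sliding-window means of -log10 p (50-SNP windows, 25-SNP steps by
  default);
- a synthetic genotype generator (per-population trinomial females with
  explicit HWD deltas, Bernoulli hemizygous males, sex-differential
  missingness and a hemizygote-miscall error model) used for the type-I
  error / power / conservativeness experiments and for end-to-end tests.

All p-values are carried as -log10 p and computed in log space, so tests
with statistics far beyond the double underflow limit report finite,
accurate values (tables print a `<1E-300` floor string alongside the
numeric -log10 column).

## CLI

The `sdmaf` entry point exposes five subcommands:

```sh
# end-to-end: filter a VCF and test every retained SNP
sdmaf compute input.vcf --mode vcf --sex-map sex.tsv --build GRCh37 --out out/

# aggregated gnomAD-style count tables (no genotypes needed)
sdmaf compute counts.tsv --mode count_table --build GRCh38 --out out/

# sqrt(n)-weighted meta-analysis across the populations of a count table
sdmaf meta counts.tsv --out meta.tsv

# sliding windows over a results table
sdmaf window out/results.tsv --out windows.tsv

# synthetic data and per-region significance summaries
sdmaf simulate --n-variants 200 --region NPR --seed 1 \
    --out-vcf sim.vcf --out-sex-map sex.tsv
sdmaf summarize out/results.tsv --out summary.tsv
```

`compute` writes `results.tsv` (one row per variant: counts, per-sex MAFs,
sdMAF, statistic, -log10 p, HWD/HWE columns appropriate to the region, flip
flag), `region_summary.tsv`, `flips.tsv`, and in VCF mode
`filter_summary.tsv` and `windows.tsv`.

The sex map is a two-column TSV (`sample<TAB>sex`, codes F/M, 1/2 or
female/male).  PAR boundaries default to the Genome Reference Consortium
spans for GRCh37/GRCh38; the PAR3/XTR default is approximate and can be
overridden per label with `--region-bed` (BED with labels PAR1/PAR2/PAR3).

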