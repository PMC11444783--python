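# kinskew

Genetic and life-history analysis toolkit for cooperatively breeding social
groups, built around non-invasive microsatellite genotyping. The package
covers the full analysis chain:

- **simdata** — synthetic populations with a season-stepped social structure
  (one dominant pair per group, configurable reproductive skew, sex-biased
  dispersal), Mendelian genotype transmission, and a faecal-DNA noise channel
  (allelic dropout, false alleles, locus failure) over replicate samples.
  Provides pedigree ground truth for validating every estimator.
- **genotypes** — diploid genotype containers, CSV and GenePop I/O,
  replicate-to-consensus calling with dropout-aware rules, re-genotyping
  flags, and minimum-loci filtering.
- **locus_stats** — allele frequencies, observed/expected heterozygosity,
  polymorphic information content, chi-square HWE tests with rare-class
  pooling, null-allele estimates, and panel probability of identity.
- **fstats** — hierarchical F-statistics (Nei heterozygosity formulation)
  with permutation significance and pairwise group differentiation.
- **relatedness** — Queller–Goodnight pairwise relatedness, role-class
  summaries, a breeder-pair permutation test, between-group relatedness, and
  a Mantel matrix-correlation test.
- **parentage** — likelihood parentage assignment (LOD / delta over parent
  pairs) with a mistyping-aware error model, Monte-Carlo calibrated
  confidence tiers, candidate-parent rules from field metadata, and
  reproductive-skew summaries.
- **clustering** — Bayesian admixture clustering (Gibbs sampler) with
  Ln P(D) model scores and Evanno Delta-K selection over a K grid.
- **lifehistory** — daily group-size interpolation, group-season
  mean-of-means summaries, dispersal tallies, survival proportions, and
  equal-opportunity null expectations for reproductive skew.
- **pipeline / cli** — a seeded end-to-end pipeline and a `kinskew` command
  line with one subcommand per stage.

## Command line

```sh
kinskew simulate --out runs/sim --seed 1
kinskew consensus --reps runs/sim/replicates.csv --out runs/consensus.csv
kinskew locus-stats --genotypes runs/consensus.csv --out runs/locus_stats.csv
kinskew fstats --genotypes runs/sim/true_genotypes.csv --perms 999 --seed 1 --out runs/fstats.json
kinskew relatedness --genotypes runs/sim/true_genotypes.csv \
    --roles runs/sim/metadata.csv --perms 1000 --seed 1 --out runs/rel
kinskew cluster --genotypes runs/sim/true_genotypes.csv \
    --kmin 1 --kmax 8 --runs 2 --burnin 500 --iters 500 --seed 1 --out runs/cluster
kinskew run --out runs/full --seed 1          # whole pipeline
```

Genotype tables are long-format CSV (`individual_id, locus, allele1,
allele2[, group]`, `0` = missing) or GenePop (2- and 3-digit allele codes
auto-detected). Replicate tables add a `sample_id` column.

## Notes

- All randomness flows from explicit seeds; reruns are bit-identical.
- The simulator's default locus panel (13 loci, 6 alleles, Dirichlet
  concentration 0.46) targets a mean expected heterozygosity near 0.61.
  Its genotyping-error defaults are illustrative, not field estimates.
- Homozygote consensus calls require the sole observed allele in at least
  two replicates (multi-tubes convention); this is the main driver of
  missingness under heavy dropout.
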