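# admixscan

Toolkit for detecting and quantifying post-admixture positive selection
("admixture-enabled selection") in a two-source admixed population from
unphased genotype data.

The pipeline:

1. **Simulation** (`admixscan.simulate`) — coalescent simulation (msprime)
   of two source populations (split 1667 generations ago, N = 1000 each)
   and an admixed population founded 100 generations ago by a single pulse
   (24.6% from source P), as independent 1 Mb segments concatenated into
   pseudo-chromosomes. True local ancestry of every admixed haplotype is
   recorded via a census layer at the admixture time. Includes MAF-matched
   SNP ascertainment and an optional forward-simulated selected locus
   (additive selection, fitnesses 1 / 1−s / 1−2s).
2. **Local ancestry** (`admixscan.ancestry`) — a diploid hidden Markov
   model over unphased genotypes: hidden state = number of P-ancestry
   haplotypes (0–2), per-haplotype switch probability `1 − exp(−g·d)` into
   the stationary ancestry distribution, Bernoulli panel-frequency
   emissions with genotyping error. Forward–backward posterior expected
   dosage; the stationary proportion can be estimated self-consistently.
3. **Scan** (`admixscan.scan`) — per-SNP mean ancestry proportion,
   mean + k·SD thresholds (k = 2, 4, 5), region calling with a documented
   merge rule, and FWER/FDR calibration against fully re-simulated neutral
   genomes.
4. **f-statistics** (`admixscan.fstats`) — f3 admixture test (with the
   finite-sample target-heterozygosity correction), f4 and f4-ratio
   admixture-proportion estimation, all with weighted block-jackknife
   standard errors.
5. **ABC** (`admixscan.wf_abc`) — Wright–Fisher forward model with
   additive selection and rejection ABC for the selection coefficient
   (uniform prior, acceptance window = observed frequency ± 5%).
6. **LD** (`admixscan.ld`) — two-locus haplotype frequencies from unphased
   genotypes via EM, Lewontin D′ and r².

## Command line

All subcommands take `--seed`/`--out`; see `admixscan <cmd> --help`.

```bash
admixscan simulate --config demography.yaml --seed 1 --out data/ --target-snps 16236
admixscan infer-ancestry --admixed data/admixed.tsv --ref-p data/source_p.tsv \
    --ref-a data/source_a.tsv --out dosage.tsv
admixscan scan --dosage dosage.tsv --k 5 --out regions.tsv
admixscan scan-null --runs 100 --seed 1 --out fwer.json
admixscan fstats --freqs freqs.tsv --f3 "T:P,A" --block 500 --out fstats.tsv
admixscan abc --p0 0.26 --observed 0.76 --tol 0.05 --accepted 10000 --seed 1 --out posterior.tsv
admixscan ld --vcf pop.vcf --snp1 chr16:48000000 --snp2 chr16:48200000 --out ld.json
admixscan run --config pipeline.yaml --seed 1 --out results/
```

Genotype I/O supports VCF v4.x (biallelic records; multi-allelic records
are skipped with a warning) and a TSV dialect with columns
`chrom pos ref alt` followed by one alt-allele-count column per sample
(`NA` = missing).

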