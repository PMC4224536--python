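# neratio

Inference of sex-biased effective population size from paired nuclear and
mitochondrial marker data.

The package compares genetic variation of biparentally inherited
microsatellites (θn) with that of the maternally inherited mtDNA control
region (θm), converts both to effective population sizes via

    Ne  = θn / (4 μn)        (biparental, diploid)
    Nef = θm / (2 μm)        (maternal, haploid)

and propagates uniform priors on (θn, θm, μn, μm) through the ratio
Ne:Nef = θn·μm / (2·θm·μn) by Monte Carlo. In an ideal random-mating
population Ne:Nef = 2; the reported "reduction" is 100·(1 − ratio/2) %.
A strongly reduced ratio indicates high male reproductive skew (e.g. lek
mating systems).

## Components

- `neratio.simulate` — single-population Kingman-coalescent simulator for
  both marker types: sequences under a Ti/Tv (Kimura-type) mutation model,
  microsatellites under the stepwise mutation model. Everything downstream
  is testable against known θ without external data.
- `neratio.diversity` — expected heterozygosity (unbiased Nei), haplotype
  diversity ± SD, nucleotide diversity ± SD, segregating-site /
  transition–transversion summaries.
- `neratio.theta` — moment estimators (Watterson, SMM inversions) and
  Bayesian coalescent MCMC posteriors of θ for each marker type
  (Metropolis–Hastings over genealogy and θ; pruning likelihood for
  sequences, REML Brownian likelihood for allele sizes).
- `neratio.ratio` — Monte-Carlo propagation of the four uniform priors to
  the Ne:Nef posterior, with closed-form moment oracles.
- `neratio.pipeline` / `neratio.cli` — end-to-end reproducible pipeline
  with YAML config, JSON/text reports and trace files.

## CLI

```sh
neratio simulate --seed 1 --out-dir data/            # FASTA + genotype TSV
neratio diversity --fasta data/sequences.fasta --genotypes data/genotypes.tsv
neratio theta-seq  --fasta data/sequences.fasta --prior 0 0.1 --seed 1
neratio theta-msat --genotypes data/genotypes.tsv --prior 0 100 --seed 1
neratio ratio --theta-n-prior 10.0 16.5 --theta-m-prior 0.01 0.05 \
              --mu-n-prior 1e-5 1e-3 --mu-m-prior 1e-8 1e-7 --seed 1
neratio run --config config.yaml --out-dir out/      # full pipeline
```

Example pipeline config:

```yaml
seed: 42
mode: synthetic          # or: files, priors-only
synthetic: {n_tips: 18, L: 512, n_individuals: 96, n_loci: 7, theta_msat: 4.875}
mcmc: {burn_in: 500, n_samples: 1500}
priors: {source: from-theta-posteriors, mu_n: [1.0e-5, 1.0e-3], mu_m: [1.0e-8, 1.0e-7]}
ratio: {n_samples: 1000000, mode: published}
```

## Notes on units and scale

- Time is in coalescent units; mutation rates θ/2 per lineage, so the
  expected pairwise difference equals θ for both marker models.
- The default `published` ratio mode combines μm in substitutions/locus/
  year with μn per generation, reproducing the published computation as
  printed; `adjusted` multiplies μm by the generation time (default 3 y).
- The Bayesian microsatellite sampler subsamples large loci to
  `max_tips_per_locus` (default 24) gene copies: coalescent information
  about θ saturates quickly with sample size, while genealogy-space mixing
  at desk-scale chain lengths degrades sharply for very large trees.
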