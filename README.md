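# magicmap

A mapping-by-sequencing toolkit built around a simulated multi-parent
(MAGIC) cotton population.  It covers the full causal-variant discovery
workflow on synthetic data with a planted causal mutation:

- **`magicmap.popsim`** — founder panels, Poisson/Haldane meiosis, a
  half-diallel MAGIC scheme (random-mating cycles with bulked pollen, then
  single-seed-descent selfing to RILs), biparental F2s, and recessive
  phenotype assignment.
- **`magicmap.observe`** — low-coverage genotype observation (Poisson depth,
  per-read error, naive calling) emitting VCF 4.2 with GT:DP.
- **`magicmap.concordance`** — the phenotype-concordance variant filter
  (strict/permissive missing-data semantics, optional tolerant-line
  exclusion), single-marker concordance reports, and a pooled cultivar-panel
  screen.
- **`magicmap.effects`** — variant classification against exon models
  (frameshift vs in-frame, strand-aware exon ordinals, boundary detection)
  and pseudogene detection by global alignment.
- **`magicmap.segregation`** — Pearson chi-square goodness of fit against
  Mendelian ratios, plus best-ratio selection.
- **`magicmap.vigs`** — silencing-fragment design: 21-mer off-target scans
  with a Hamming mismatch budget (both strands) and minimal-off-target
  350-bp window selection.
- **`magicmap.coexpression`** — dose-series replicate summarization, Pearson
  correlation against a reference gene with a 0.7 co-induction threshold,
  and a synthetic step-induction expression generator.
- **`magicmap.pipeline`** — an end-to-end seeded driver
  (simulate → observe → filter → annotate → segregation test).

## CLI

```bash
magicmap simulate --n-sites 1000 --n-lines 550 --seed 1 --out-prefix sim
magicmap filter sim.vcf sim.phenotypes.tsv --sensitive-parent P01 --mode permissive
magicmap annotate gene_models.gff3 --variant D10:28455988:T:TA
magicmap segtest --observed 1255,440 --ratio 3,1
magicmap vigs target.fasta transcriptome.fasta --target-id GeneD10.1401
magicmap coexpress expression.tsv --reference REF --tau 0.7
magicmap run --seed 1 --outdir run1        # full pipeline
```

All commands are deterministic under `--seed`; the seed is recorded in the
VCF header and run report.

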