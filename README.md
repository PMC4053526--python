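# kirtyper

In-silico re-implementation of a medium-resolution multiplex PCR assay for
subtyping KIR3DL1/KIR3DS1 alleles. The toolkit covers:

- **SNP decision-table classification** of coding sequences into six
  functional subtype groups (one null, two low-expression, two
  high-expression, one activating) from four diagnostic CDS sites
  (193, 202, 607, 1021/1022), with homology and neighbor-joining support
  for novel sequences (`allele_catalog`, `subtype_classifier`).
- **Virtual multiplex PCR** over the five published typing reactions plus a
  shared internal control: IUPAC-degenerate primer binding-site search,
  amplicon prediction, and band-pattern simulation, including the 360 bp
  intron-3 size difference that separates the activating gene
  (`insilico_pcr`).
- **Band-pattern decoding** into genotype hypotheses, reproducing the one
  designed ambiguity (*007-group homozygote vs *002/*007 heterozygote),
  extended (3-allele) haplotype search, and Mendelian pedigree-consistency
  checking (`pattern_decoder`).
- **Population-frequency arithmetic**: cumulative frequencies,
  Hardy-Weinberg genotype frequencies, ambiguity rates, and EM estimation
  of group frequencies from typed cohorts (`population_stats`).
- **Synthetic fixtures**: deterministic genomic templates whose diagnostic
  regions are spelled out by the published primer sequences themselves and
  whose intron lengths are calibrated to the published product sizes
  (2019 / 1573 / 1933 / 1408 bp), plus cohort and pedigree simulators
  (`synthetic_fixtures`). No downloads are needed to build or test.

## Command line

```sh
kirtyper classify alleles.fasta          # subtype groups per coding sequence
kirtyper type patterns.tsv               # band patterns -> genotype hypotheses
kirtyper type --extended patterns.tsv    # allow 3-allele haplotypes
kirtyper pedigree family.tsv             # Mendelian consistency report
kirtyper freq                            # packaged cohort frequency arithmetic
kirtyper simulate --what cohort -n 100   # synthetic donors + band patterns
kirtyper tree aligned.fasta --bootstrap 100
```

Exit codes: 0 success, 2 typing incomplete/inconsistent, 1 error. Reports
embed the configuration and seeds used.

## Data files

- `src/kirtyper/data/panel.yaml` — the five-reaction panel: primer
  sequences, expected product sizes, and inert thermocycling metadata.
- `src/kirtyper/data/table1_frequencies.tsv` — allele frequencies from the
  426-donor sequenced cohort (tab-separated; `# donors:` comment carries
  the cohort size).
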