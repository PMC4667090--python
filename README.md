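# tetrasnp

Variant discovery and genotyping toolkit for amplicon panels in an
allotetraploid (AABB) crop sequenced together with its two diploid
progenitors. The central problem: a Sanger consensus of a tetraploid
amplicon superposes up to four locus copies, so variable positions mix
three very different things —

- **SNPs** — homologous variants segregating between varieties on one
  subgenome copy (the only class usable as genetic markers),
- **HSVs** — fixed homoeologous differences between the A and B subgenomes
  of every genotype,
- **PSVs** — differences between duplicated (paralogous) copies within one
  genome.

`tetrasnp` simulates such panels with exact ground truth, models the IUPAC
consensus that sequencing observes, infers which locus copies survive in the
tetraploid (sequence elimination), classifies every variable column, computes
marker statistics (PIC, variant densities, strand-collapsed class spectra,
LD r², RIL segregation chi-square), and genotypes panels with a simplified
high-resolution-melting (HRM) engine.

## Layout

| module | what it does |
|---|---|
| `tetrasnp.simpanel` | synthetic progenitors, tetraploid variety panels, RIL populations; every planted variant recorded as ground truth |
| `tetrasnp.ampliconobs` | IUPAC superposition/decomposition, consensus observations, zygosity rates |
| `tetrasnp.classify` | ambiguity-aware global alignment, copy-composition inference, SNP/HSV/PSV site classification, strand-collapsed classes |
| `tetrasnp.markerstats` | PIC (panel-denominator convention), marker summaries, variant density, class spectra, LD r², full-LD marker selection, 1:1 chi-square |
| `tetrasnp.hrmsim` | melting-temperature prediction, duplex species, melt-curve synthesis on the 72.0–90.0 °C/0.1 °C grid, normalization, difference plots, genotype clustering, amplification QC |
| `tetrasnp.pipeline` / `tetrasnp.cli` | end-to-end orchestration with a JSON run manifest |

A published 33-marker allele-count table for a 96-variety peanut panel ships
as package data (`tetrasnp/data/peanut_marker_counts.tsv`) and backs the
`pic-table` subcommand. Note on conventions: allele frequencies divide by the
full panel size (96), not the number of successfully genotyped varieties —
the convention consistent with that table (see `tetrasnp.markerstats`
docstring; `denominator="typed"` gives the alternative).

## CLI

```bash
tetrasnp run --seed 1 --out runs/demo           # full pipeline
tetrasnp simulate --seed 1 --n-loci 50 --out runs/sim
tetrasnp classify --panel panel.fasta --prog-a a.fasta --prog-b b.fasta --out runs/cls
tetrasnp stats --calls counts.tsv --out runs/stats
tetrasnp hrm --seed 1 --n-samples 96 --n-het 28 --out runs/hrm
tetrasnp pic-table --out report.tsv             # bundled published table
```

All subcommands accept `--seed`; `run`/`simulate` also accept a YAML
`--config` (keys `seed`, `sim`, `ril`, `hrm` mirroring the dataclasses in
`tetrasnp.pipeline`). Outputs are plain-text TSV/FASTA/JSON under `--out`,
plus a `manifest.json` recording config, seed and stage status; identical
configs give byte-identical outputs.

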