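# mhcdeconv

Motif-based HLA peptide scoring, eluted-ligand-style percentile-rank
calibration, allele deconvolution of detected peptide lists, and a
wildtype-vs-mutant epitope scan for protein point variants — plus a synthetic
ligandome generator so every stage is testable without any external data.

## What it does

- **`io_formats`** — FASTA proteomes, peptide-list TSVs, variant TSVs, and a
  packaged ADRD epitope table (with `TOP x%` EL-rank parsing).
- **`synthetic_data`** — seeded generators for allele anchor motifs, class I
  (8–14-mer, mode 9) and class II (11–20-mer, mode 15) ligandomes, background
  decoys, random proteomes, and variant fixtures with planted anchor-improving
  sites.
- **`binding_model`** — per-allele position-specific log2-odds matrices with
  BLOSUM62-conditional pseudocounts; direct core scoring for class I (with
  length normalisation onto a 9-mer core) and best-sliding-core scoring for
  class II; empirical percentile ranks against background proteome windows.
- **`deconvolution`** — minimum-rank allele assignment with class-specific
  retention cutoffs (< 2% class I, < 5% class II) and binder classes
  (strong < 0.5% / < 1%), length histograms, per-allele top epitopes, set
  overlap summaries, and reported-table filtering.
- **`variant_scan`** — enumerate every WT/mutant peptide window covering a
  point variant, score both against every allele, and keep mutant epitopes
  that bind at least as strongly as wildtype and clear the strong-binder
  bound.
- **`pipeline_cli`** — one seeded, config-driven pipeline
  (`simulate → train → calibrate → deconv → scan`) with bitwise-reproducible
  outputs.

## CLI

```sh
mhcdeconv run --config config.yaml            # all configured stages
mhcdeconv simulate --config config.yaml --seed 7
mhcdeconv deconv --config config.yaml --outdir out/
mhcdeconv epitope-check --cutoff 7            # filter the packaged ADRD table
```

A minimal `config.yaml`:

```yaml
alleles: {AL01: I, AL02: I, BL01: II}
anchor_positions: {AL01: [1, 8], AL02: [1, 8], BL01: [0, 3, 8]}
outdir: out
seed: 7
n_ligands_per_allele: 1000
decoy_fraction: 0.2
background_m: 10000
```

Stage outputs are plain TSV/FASTA/JSON under `outdir`, together with a
`report.json` echoing the config, seed, and per-stage record counts.

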