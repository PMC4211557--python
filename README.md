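# tcemrep

Analysis of T-cell exposed motif (TCEM) and groove-exposed motif (GEM)
usage in immunoglobulin heavy-chain variable regions: motif-register
extraction, frequency-class (FC) classification of motif re-use,
germline-vs-somatic-hypermutation (SHM) attribution, MHC
binding/cleavage presentation profiles, and overlapping
recognition-frame mapping — exercised on synthetic repertoires with
known ground truth.

## Concepts

A peptide bound in an MHC groove shows the T-cell receptor only a
non-contiguous pentamer (the TCEM); the intercalated residues facing the
groove (the GEM) set allele-specific binding affinity. Six registers are
supported over 9-mer (class I) and 15-mer (class II) windows:

| register | window | positions (1-based) |
|----------|--------|---------------------|
| TCEM I   | 9      | 4 5 6 7 8 |
| GEM I    | 9      | 1 2 3 9 |
| TCEM IIa | 15     | 5 6 8 10 11 (core 2,3,5,7,8) |
| GEM IIa  | 15     | 1 2 3 4 7 9 12 13 14 15 |
| TCEM IIb | 15     | 3 6 8 10 11 (core −1,3,5,7,8) |
| GEM IIb  | 15     | 1 2 4 5 7 9 12 13 14 15 |

A motif's frequency class is the reciprocal base-2 logarithmic category
of the fraction of repertoire molecules containing it (FC0 = in every
molecule, FC2 = 1/4, FC10 = 1/1024; non-powers round up).

## Modules

- `tcemrep.sequence_io` — FASTA I/O, curation (truncation at 130 aa,
  id-level dedup), TSV motif tables, the repertoire data model.
- `tcemrep.motif_engine` — window enumeration, the six register masks,
  central-core extraction, cleavage-site octamers (P4–P4′), the
  overlapping recognition-frame map (23-residue class II / 17-residue
  class I influence spans).
- `tcemrep.frequency_analysis` — motif counting, FC assignment and
  histograms, germline/SHM origin attribution, per-position unique-motif
  profiles, IIa/IIb co-location, motif-set overlap, FC mapping against a
  reference table, germline-usage correlation.
- `tcemrep.presentation_models` — pluggable affinity/cleavage predictor
  contracts, ensemble mean/SD aggregation, within-protein Johnson Sb
  standardization, 1σ-below-mean binding-fraction profiles,
  motif-conditioned affinity distributions, plus deterministic
  physicochemical surrogate predictors (the published neural-network
  models require external training data and are out of scope).
- `tcemrep.synthetic_repertoire` — germline libraries with family
  structure and usage weights; SHM simulation with a positional rate
  profile and CDR-like hotspots, exact per-clonotype ground truth.
- `tcemrep.cli` — end-to-end pipeline with a JSON run manifest.

## Command line

```sh
# full pipeline (synthetic mode by default)
tcemrep run --config config.yaml --seed 1 --out results/

# stages, runnable standalone
tcemrep simulate --config config.yaml
tcemrep extract --fasta repertoire.fasta --germline-fasta germline.fasta --out out/
tcemrep classify --motif-table out/motifs_TCEM_IIA.tsv --out out/fc_hist.tsv
tcemrep present --fasta repertoire.fasta --alleles "DRB1*01:01,DRB1*03:01" --out out/
tcemrep compare --table-a a.tsv --table-b b.tsv
tcemrep compare --peptides FSNYAIHWVRQAPGQ FTNYAIHWVRQAPGQ
```

A YAML config may set `input_fasta`/`germline_fasta` (real data) or
synthesis parameters (`n_germlines`, `n_clonotypes`, `base_rate`, ...),
the register list, the allele roster subset, `threshold_sd` and the FC
counting mode (`molecule` or `instance`). Every run writes a
`manifest.json` with versions, seeds, input digests and output paths.

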