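# pepcore

Design of fixed-length peptide binding cores (MHC class II, L = 9 by
default) from the evolutionary statistics of aligned native peptide sets.

Given a gap-free peptide alignment per HLA allotype, the package

1. extracts **first-order** statistics — per-position residue frequencies
   `f[i,a]`, KL-divergence positional conservation `C[i]`, and log-odds
   positional weights `k[i,a]` — and **second-order** statistics — pairwise
   joint frequencies `f[i,a,j,b]` and the weighted coupling matrix `C[i,j]`;
2. generates artificial peptide sets that reproduce those statistics via
   three strategies:
   * **FS** — independent per-position sampling from the native frequencies;
   * **MC1 / MC2** — Monte Carlo simulated annealing of a whole M-sequence
     set against the native coupling matrix (MC1: random initialization and
     uniform mutations; MC2: frequency-sampled initialization and
     frequency-guided mutations);
   * **L1 / L2** — a small convolution + multi-head-attention generative
     network trained to match joint frequencies (`loss1`) or frequencies +
     joint frequencies (`loss2`, balance coefficient λ = 65), implemented on
     a built-in numpy reverse-mode autodiff engine (no GPU frameworks
     required);
3. evaluates designs against their native targets (first-order and coupling
   Pearson correlations, conservation profiles, logo-ready exports) and
   writes bundles consumable by external affinity/structure predictors.

A synthetic-data module generates mixture-of-profiles alignments with
closed-form target statistics, used as ground truth throughout the test
suite.

## CLI

All stochastic subcommands require an explicit `--seed`; every run writes a
`run_config.yaml` reproducibility manifest into its output directory.

```sh
# synthetic 3-allotype benchmark (table + generator specs)
pepcore synth --n-allotypes 3 --m 500 --seed 1 --out runs/synth

# statistics of one allotype
pepcore stats --input runs/synth/dataset.tsv --format table \
    --allotype SYN-01 --out runs/stats

# frequency-only design
pepcore design-fs --input runs/synth/dataset.tsv --format table \
    --allotype SYN-01 --n 500 --seed 2 --out runs/fs

# simulated-annealing design (defaults: T0=15, decay 0.99, 2000x2000,
# 8% mutation, diagonal weight 0.1; reduce the loops for quick runs)
pepcore design-mcsa --input runs/synth/dataset.tsv --format table \
    --allotype SYN-01 --variant mc2 --n-outer 300 --n-inner 300 \
    --seed 3 --out runs/mc2

# train the generative network (defaults: 12 blocks, Adam 1e-4, 2000
# epochs, loss2 with lambda 65; --reduced selects the small CPU preset)
pepcore train --input runs/synth/dataset.tsv --reduced --epochs 300 \
    --seed 4 --out runs/train

# sample designs from the trained model
pepcore design-nn --model runs/train/model.npz \
    --input runs/synth/dataset.tsv --format table --allotype SYN-01 \
    --n 500 --seed 5 --out runs/l2

# compare a design against its native set and export the report bundle
pepcore evaluate --native runs/synth/dataset.tsv --format table \
    --designed runs/mc2/designed.fasta --designed-format fasta \
    --allotype SYN-01 --strategy MC2 --out runs/eval
```

Input dialects: FASTA, one-sequence-per-line text, and a two-column
(`allotype`, `peptide`) TSV/CSV table with a header row. Sequences must use
the canonical 20-letter amino-acid alphabet (ordering `ACDEFGHIKLMNPQRSTVWY`
is fixed for all arrays).

## Layout

```
src/pepcore/
  peptide_io.py    alignments, datasets, dialects, encoding, filtering
  evostats.py      frequencies, conservation, weights, joints, coupling, PCC
  synthdata.py     mixture-of-profiles generator with closed-form statistics
  design_fs.py     frequency-only sampling (FS)
  design_mcsa.py   simulated annealing with incremental pair tallies (MC1/MC2)
  nn/autodiff.py   minimal reverse-mode autodiff on numpy
  nn/model.py      generative attention network, losses, training (L1/L2)
  evaluate.py      design-vs-native reports and export bundles
  cli.py           `pepcore` entry point
```
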