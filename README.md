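# ablm

Region-aware masked language modeling for antibody Fv sequences, desk-scale
and dependency-light (NumPy; no GPU frameworks).

The package implements:

- **abcore** (`ablm.abcore`) — 25-token residue alphabet ([PAD], [UNK],
  [CLS], [SEP], [MASK] + 20 amino acids), tokenizer with [CLS]/[SEP]
  framing, seven-region (FR1..FR4, CDR1..CDR3) annotations, FASTA and
  regions-TSV I/O.
- **curation** (`ablm.curation`) — global-alignment sequence identity,
  deterministic greedy clustering, two-stage redundancy reduction
  (80% then 50% identity, longest member kept), seeded dataset splits.
- **masking** (`ablm.masking`) — CDR3-focused heavy-chain corruption
  (70% of CDR-H3 as a contiguous span, then geometric span masking of the
  remaining regions up to a total budget), light-chain span masking,
  uniform-random baseline, ALL_MASK and BERT-style 80/10/10 policies.
- **encoder** (`ablm.encoder`) — transformer encoder with disentangled
  relative-position attention (content–content, content–position,
  position–content score terms over a clamped ±128 offset table, 1/√(3dₖ)
  scaling), an absolute-position ablation mode, and an MLM output layer.
  Built on a minimal reverse-mode autodiff engine (`ablm._nn`) verified by
  finite differences.
- **pretrain** (`ablm.pretrain`) — MLM training loop: 0–3 terminal
  truncation augmentation, label-smoothed cross-entropy (ε=0.1) on masked
  positions only, AdamW (β=0.9/0.99, wd 0.01) under cosine decay with
  warmup, JSONL metrics, bit-exact resume from checkpoints.
- **evaluate** (`ablm.evaluate`) — whole-region restoration with top-k
  accuracy, slice-style truncation protocols (`10:-5` etc.), grouped CDR3
  amino-acid distribution reports with Jensen-Shannon divergence.
- **heads** (`ablm.heads`) — frozen-encoder downstream heads: contrastive
  heavy–light pairing (mean pooling, two-layer projection MLPs, L2 +
  cosine, InfoNCE with <85%-identity negatives, 5× negative-resampled
  auROC/auPRC) and CDR-H3 binding classification (per-position projection,
  flatten, two-layer MLP, repeated random splits, low-data subsampling).
- **synth** (`ablm.synth`) — synthetic antibody grammar: per-family FR
  templates, CDR1/2 motif sets, anchored variable CDR3, planted
  heavy–light compatibility rule and planted binding motif.
- **cli** (`ablm.cli`) — the `ablm` entry point.

## CLI

```bash
ablm synth --config cfg.yaml --n-heavy 5000 --n-light 2000 \
    --n-pairs 1000 --n-binding 2000 --seed 1 --out data/
ablm curate --in data/chains.fasta --t1 0.8 --t2 0.5 \
    --out kept.fasta --clusters clusters.tsv
ablm pretrain --config cfg.yaml --train data/chains.fasta \
    --regions data/regions.tsv --seed 1 --out runs/exp1
ablm mask-stats --in data/chains.fasta --regions data/regions.tsv --n 1000
ablm eval restore --checkpoint runs/exp1/encoder --test data/chains.fasta \
    --regions data/regions.tsv --truncate 10:-5 --mask CDR3 --out report.tsv
ablm eval dist --checkpoint runs/exp1/encoder --test data/chains.fasta \
    --regions data/regions.tsv --out dist.tsv
ablm pair --checkpoint runs/exp1/encoder --pairs data/pairs.csv \
    --lights data/light_pool.fasta --out pair.json
ablm bind --checkpoint runs/exp1/encoder --data data/binding.csv \
    --subsample 0.01 --n-splits 5 --out bind.json
```

Config is YAML with sections `grammar`, `masking`, `model`, `train`,
`pairing`, `binding` plus `seed`/`out_dir`/`log_level`; unknown keys are
rejected, and every run directory receives the resolved config, seed,
metrics, and logs.

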