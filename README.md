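# alnbench

Benchmark construction and evaluation for multiple alignment of non-coding
DNA. The package simulates sequence evolution along a phylogeny (F81
substitutions, indels with two-geometric-mixture lengths, conserved blocks
evolving at a reduced rate), draws evolutionary parameters per data set from
empirical distributions, scores alignment difficulty with heads-or-tails
(HoT) SPS/CS reliability scores, and evaluates predicted alignments and indel
annotations against the simulator's ground truth.

## Modules

| module | purpose |
| --- | --- |
| `alnbench.phylo` | Newick parse/write, tree scaling, overall→neutral branch-length adjustment (`t_o = t_n(αβ + 1 − α)`) |
| `alnbench.evolver` | Gillespie sequence-evolution simulator with conserved blocks, true-alignment assembly and per-branch event logs |
| `alnbench.param_sampler` | empirical parameter distributions, per-data-set draws, EM fitting of mixture weights over binned score densities |
| `alnbench.aligner_hot` | built-in progressive affine-gap aligner, HoT SPS/CS scores, external-aligner adapter |
| `alnbench.eval_metrics` | alignment agreement/sensitivity/specificity (multi-species and per-pair), indel ICA/IRA/IAC measures |
| `alnbench.block_finder` | conserved-block detection from per-column conservation scores (≥ 10 non-gapped columns at score ≥ 0.9) |
| `alnbench.cli_pipeline` | benchmark generate/evaluate orchestration, manifests, fixture generator |

## CLI

```sh
# self-contained example inputs (tree, distribution TSVs, score track)
alnbench fixtures --out fixtures/

# traditional mode: fixed parameters
alnbench generate --tree fixtures/tree.nwk --out bench/ -n 100 --seed 1

# sampled mode: per-data-set draws from empirical distributions
alnbench generate --tree fixtures/tree.nwk --out bench_sampled/ -n 100 \
    --mode sampled --dist alpha=fixtures/alpha.tsv \
    --dist sub_indel_ratio=fixtures/sub_indel_ratio.tsv \
    --dist branch_lengths=fixtures/branch_lengths.tsv

# score predicted alignments (one FASTA per data set id) against the truth
alnbench evaluate --benchmark bench/ --predictions preds/ --report report.tsv

# HoT reliability scores; external aligners plug in via a command template
alnbench hot bench/ds00000/leaves.fasta
alnbench hot --aligner-cmd 'mafft --quiet {input} > {output}' seqs.fasta

# conserved blocks from a conservation score track
alnbench blocks --alignment aln.fasta --scores scores.tsv --out blocks.tsv

# EM mixture weights over component score distributions
alnbench fit-mixture --components c1.tsv --components c2.tsv \
    --observations obs.tsv --out fit.tsv
```

Each data set directory contains `leaves.fasta`, `true_alignment.fasta`,
`events.tsv` (branch, kind, time, position, length, inserted bases, true
alignment column span) and `params.tsv`; the benchmark root carries a
`manifest.tsv` with realized and expected event counts (used for the
insertion-excess / deletion-excess stratification) and a resolved config
copy.

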