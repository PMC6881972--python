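# afmeta — alignment-free metagenome comparison with read binning

`afmeta` compares shotgun metagenomic samples without assembly or
alignment, using background-corrected k-mer (k-tuple) statistics, and adds
the key refinement that a single Markov background model is not enough for
a community of many genomes: reads are first **binned** by GC-stratified
reference models, and the statistics are accumulated per bin.

It is aimed at microbiome researchers who want beta-diversity structure —
groups of similar samples, or samples ordered along an environmental
gradient — directly from reads (FASTA/FASTQ), plus a simulator to study
when that works.

## The statistics

For a sample, count all 4^k k-tuples `X_w` over the reads and both strands,
and subtract the expectation under an order-r Markov background model:

    X̄_w = X_w − n_X · p_w

With C read bins (reads classified to the reference bin model giving the
highest log-likelihood, `argmax_c LL(Y | M_r^c)`), the centralized counts
combine the bins:

    X̄_w = Σ_c ( X_w^c − n^c · p_w^c )

Two normalized dissimilarities in [0, 1] are built from centralized
vectors of two samples (0 = identical profiles):

    d2S  : per-tuple normalizer  √(X̄_w² + Ȳ_w²)
    d2*  : per-tuple normalizer  √(E_X,w · E_Y,w)   (expected counts)

Downstream, samples are clustered with UPGMA and scored against a known
grouping by rooted **triplet distance**, or ordinated with PCoA and scored
against a known gradient by the **Pearson correlation** of the first
principal coordinate.

## Worked example

`examples/group_comparison.py` simulates three community groups (Zipf
abundances over a 12-genome panel, 5 noisy replicates each, 20k read pairs
per sample), runs the full pipeline with 4 GC bins and without binning, and
scores both trees:

```
$ python examples/group_comparison.py
samples: 15 (3 groups x 5 replicates)
triplet distance, 4 GC bins : 44
triplet distance, no binning: 94
max possible (all 3-subsets): 455
binned fraction             : 0.097
```

Of the 455 three-sample subsets, only 44 are clustered in contradiction to
the true grouping when reads are binned, versus 94 without binning — the
binned statistic recovers the group structure about twice as cleanly here.
`examples/gradient_ordination.py` does the same for a gradient design
(9 samples sweeping the Zipf exponent α = 0.30…0.70 over 100 genomes):

```
$ python examples/gradient_ordination.py
samples: 9 (alpha = 0.30 ... 0.70)
|PCC|(PC1, alpha), 4 GC bins : 0.815
|PCC|(PC1, alpha), no binning: 0.765
```

`examples/read_binning.py` shows the classification layer itself, and
`examples/cli_pipeline.sh` runs the same workflow through the CLI:

```
afmeta simulate → afmeta build-bins → afmeta compare → afmeta cluster →
afmeta evaluate
```

Every command writes a key-value manifest next to its outputs; all
randomness flows from `--seed`, so outputs are byte-reproducible.

## Library layout

| module | contents |
| --- | --- |
| `afmeta.kmer` | strand-symmetric k-tuple counting, Markov model training, tuple probabilities, read log-likelihood |
| `afmeta.binning` | GC-quantile genome bins, per-bin models, read classification, per-bin sample statistics |
| `afmeta.dissimilarity` | centralized vectors, d2S, d2*, pairwise matrices (scikit-bio `DistanceMatrix`) |
| `afmeta.beta` | UPGMA, triplet distance, reference trees, PCoA, gradient correlation |
| `afmeta.simulate` | synthetic genome panels, Zipf + noise abundances, paired-end read simulation, study designs |
| `afmeta.benchmarks` | seeded end-to-end evaluation protocols used by the tests and the acceptance script |
| `afmeta.io`, `afmeta.cli` | FASTA/FASTQ/TSV/Newick I/O and the `afmeta` command |

See `docs/methods.md` for the model details, parameter choices and the
limits of what the synthetic benchmarks demonstrate.

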