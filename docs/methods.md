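# Methods

## Background-corrected k-tuple statistics

The comparison unit is the vector of counts of all 4^k k-tuples in a
sample's reads. Raw counts are dominated by genome-wide composition (above
all GC content), which carries little between-sample signal, so each count
is centralized by its expectation under a Markov background model of order
r: `X̄_w = X_w − n_X p_w`, where `n_X` is the total tuple count and `p_w`
the tuple's probability under the model. Counting is strand symmetric —
every read is counted together with its reverse complement — so the
statistics do not depend on sequencing strand, and background models are
trained on both strands for the same reason.

Tuple probabilities factor as
`p(w) = initial(w_1…w_r) · Π_i P(w_{i+r} | w_i…w_{i+r−1})`, with the
initial distribution taken as the empirical r-tuple distribution of the
training sequence. Transition probabilities are ratios of (r+1)-tuple to
r-tuple counts, optionally with additive smoothing. The background order
is capped at r ≤ k − 2: at r = k − 1 the Markov expectation reproduces the
observed counts themselves and the centralized signal degenerates.

Two dissimilarities are formed from the centralized vectors of two
samples, both normalized to [0, 1] via the Cauchy–Schwarz inequality so
that 0 means identical profiles and 0.5 means uncorrelated ones:

* **d2S** scales each tuple's product `X̄_w Ȳ_w` by `√(X̄_w² + Ȳ_w²)`;
* **d2\*** scales it by `√(E_X,w E_Y,w)`, the geometric mean of the
  expected counts, a Poisson-variance (Pearson-correlation style)
  standardization.

Terms whose normalizer is zero are skipped: an unobserved or impossible
tuple carries no signal, and skipping (rather than imputing) preserves the
[0, 1] bounds. Accumulations use extended precision with a fixed summation
order, so results are bit-reproducible across runs; final values are
clamped to [0, 1] to absorb rounding at the boundaries. A pair of samples
whose centralized vectors are identically zero has no defined
dissimilarity and raises an explicit degenerate-input error.

## Read binning

A single background model misrepresents a community of heterogeneous
genomes. The binned variant stratifies reference genomes by GC content
into C rank-quantile bins (equal genome counts per bin, remainder to the
lowest-GC bins, ties broken by genome id), trains one Markov model per bin
on all genomic sequence in the bin, and assigns each read to the bin whose
model maximizes the read log-likelihood (ties to the lowest bin index).
Classification models are smoothed with a pseudocount of 0.5 so that a
transition absent from one bin's training sequence cannot produce a −∞
log-likelihood and veto the bin. Reads shorter than order+1 cannot be
scored and are dropped with a logged count.

Per-bin tuple counts then centralize against per-bin background models and
are summed across bins: `X̄_w = Σ_c (X_w^c − n^c p_w^c)`. For d2* under
binning, the per-tuple expectation is the bin-summed expected count
`Σ_c n^c p_w^c` — the natural mixture analog of the single-model
denominator.

Two genuinely open choices are exposed as parameters:

* **Where the expectation model comes from.** By default each bin's
  background model is re-estimated from the reads assigned to that bin of
  that sample (unsmoothed, matching the no-binning statistic, which also
  estimates its background from the sample itself); alternatively the
  reference-trained bin models can be supplied
  (`bin_sample(..., reference_background=...)`). The classification order
  and the background-expectation order are independent parameters that
  default to the same value.
* **Paired-end mates** are classified independently and pooled for
  counting; the statistic is mate-agnostic and strand symmetric, so mate
  coupling would add bookkeeping without changing the result.

With C = 1 the machinery reduces exactly — bit for bit, which the tests
check against an independent straightforward implementation — to the
original no-binning statistics.

## Beta-diversity evaluation

**Group designs** are scored by clustering the dissimilarity matrix with
UPGMA (size-weighted average linkage, merge height d/2, ties broken on the
lexicographically smallest pair of cluster representative labels so trees
are deterministic) and comparing the tree to a reference built from the
true labels: one polytomy per group under the root. The comparison is the
rooted triplet distance — the number of 3-leaf subsets whose induced
topologies conflict. Because the reference deliberately leaves
within-group order and the order of group splits unresolved, a triplet
resolved in the inferred tree but unresolved in the reference is a
compatible refinement, not an error, and does not count by default;
otherwise any binary tree would carry a fixed floor distance to a
polytomous reference regardless of clustering quality (for 3 groups of 5,
155 of 455 triplets). The strict convention that counts refinements as
differences is available as `penalize_unresolved=True`. Under either
convention the distance is symmetric, zero for identical topologies and
bounded by C(n,3).

**Gradient designs** are scored by classical PCoA (Gower-centered
eigendecomposition via scikit-bio; axes with non-positive eigenvalues
dropped, axes ordered by eigenvalue) followed by the Pearson correlation
between the first principal coordinate and the known gradient. The
correlation is reported as an absolute value because a PCoA axis has
arbitrary orientation; a signed variant exists for exploratory use.

## The simulator

The simulator emulates the statistical structure of two study designs over
a panel of synthetic genomes.

**Genome panel.** Each genome is drawn from its own Markov chain (order 2
by default) whose GC target is evenly spread across a configurable range
(default 0.3–0.7). Every transition row carries the genome's GC mass
exactly — jitter only redistributes probability inside the A/T and C/G
pairs, per context — so stratifying genomes by GC is exact while genomes
remain distinguishable through their strand-skew signatures. Order-1 skew
alone leaves genome signatures nearly collinear with the GC axis, which
the order-2 background subtraction then removes; order-2 chains leave
enough higher-order structure for community composition to be recoverable,
which is also the realistic regime — bacterial genomes differ strongly in
oligonucleotide composition beyond GC. Default genome length is 100 kb
(the benchmarks use 50 kb to keep end-to-end runs fast; at these depths
results are indistinguishable).

**Abundances.** Relative abundances follow a Zipf law
`f(m) ∝ m^{−α}` over ranks assigned by a random genome ordering. Group
designs draw one ordering per group as the group center (α = 0.3) and
perturb it per replicate; gradient designs keep one ordering and sweep α
over a grid (default 0.30…0.70 in steps of 0.02, giving 21 samples — the
grid is authoritative for the sample count). Perturbation adds the
absolute value of Gaussian noise per component and renormalizes. Two noise
scales exist: sd-scaled (noise sd equals the component value) and
variance-scaled (noise variance equals 10× the component). The sd-scaled
mode is the default for both designs: under the variance-scaled reading
the noise sd is `√(10 v_m) ≫ v_m` for any realistic component, which
leaves abundance vectors with essentially zero within-group correlation at
any community size — i.e. no group structure exists to recover, at any
sequencing depth, so it cannot describe a group study. The
variance-scaled mode remains available (`noise="variance10"`).

**Reads.** For each pair, a genome is chosen with probability proportional
to abundance × genome length (abundance is organism abundance; a pure
read-probability interpretation is available), a fragment start is
uniform, mate 1 is the forward strand and mate 2 the reverse complement of
the fragment end (insert = 2× read length by default, read length 150 bp).
Substitution errors are iid per base, uniform over the three alternatives;
no indels and no quality model beyond a constant FASTQ placeholder.
Default depth is 250,000 pairs per sample (0.5 M reads). All randomness
descends from one seed through a spawned stream hierarchy (panel →
design → per-sample reads), so study results are bit-reproducible and any
sub-result can be regenerated independently.

**What the simulator does not emulate:** real genome repertoires (gene
content, repeats, shared core genomes between related taxa), platform
error profiles, coverage bias, and contamination. Passing the synthetic
benchmarks shows the statistics recover abundance-driven structure under
Markovian composition differences; it does not by itself establish
performance on real communities, where genome signatures are both richer
and partially shared across taxa.

## Benchmarks and problem sizes

`afmeta.benchmarks` fixes two desk-scale protocols, used by the end-to-end
tests and `scripts/acceptance.py`:

* **Group analog:** 3 groups × 5 replicates, 12 genomes (GC 0.3–0.7,
  50 kb), 20k read pairs per sample, k = 5, order 2, C = 4, d2S; scored by
  triplet distance to the true grouping, binned vs unbinned on the same
  reads.
* **Gradient analog:** 9-point α grid (0.30…0.70 step 0.05) over 100
  genomes, 20k read pairs, k = 7, order 2, C = 4, d2*; scored by
  |PCC|(PC1, α). The full 100-genome community is kept here because the
  gradient signal lives in how many genomes the evenness shift
  redistributes mass over; with very small panels the sd-scaled noise
  dominates the α trend even for perfectly known abundances, and the
  benchmark would measure community size rather than the method.

A caveat on the group analog: at 12 genomes the sd-scaled noise leaves
only weak within-group abundance correlation, so group recovery operates
close to the ceiling of what the generated data supports, and seed-to-seed
variation in the triplet distance is large. The benchmark is therefore
read as a paired comparison (binned vs unbinned on identical reads)
averaged over seeds, not as a single-run guarantee.

Smaller auxiliary protocols measure read-binning accuracy (two order-1
genomes at GC 0.25 vs 0.75; accuracy at 150 bp, monotone in read length)
and Markov parameter recovery (order-1 transitions re-estimated from
100 kb of generated sequence, maximum L1 row error).

## Numerical and degenerate-input conventions

* Tuples are indexed lexicographically with A<C<G<T; windows containing N
  are skipped whole (no IUPAC expansion).
* Unobserved Markov contexts with zero pseudocount fall back to uniform
  rows, with a logged warning.
* Bins that receive no reads contribute nothing to the centralized sums
  and carry a flagged absent model.
* UPGMA rejects matrices containing NaN; PCoA returns the available axes
  with a warning when fewer positive-eigenvalue axes exist than requested.
* Read classification ties (identical log-likelihoods) resolve to the
  lowest bin index; UPGMA merge ties resolve by label order — both chosen
  for determinism, both exercised by tests.
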