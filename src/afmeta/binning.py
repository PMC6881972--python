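"""GC-quantile genome binning and maximum-likelihood read classification.

Reference genomes are ranked by GC content and split into C equal-size bins
(rank quantiles; remainders go to the lowest-GC bins).  One Markov model is
trained per bin from all genomic sequence in the bin, and each sample read
is assigned to the bin whose model gives it the highest log-likelihood.
Per-bin k-tuple counts and per-bin background models then feed the
bin-combined centralized statistics.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer import (
    KtupleCountVector,
    MarkovModel,
    count_ktuples,
    count_ktuples_matrix,
    encode,
    model_from_counts,
    train_markov,
    _window_indices,
    _window_indices_matrix,
)

log = logging.getLogger(__name__)

#: additive smoothing for bin-classification models; prevents -inf
#: log-likelihoods on reads containing transitions unseen in a bin
CLASSIFIER_PSEUDOCOUNT = 0.5


def gc_content(seq) -> float:
    """GC fraction (#G + #C) / (#A + #C + #G + #T); N bases excluded.

    Accepts a string or an iterable of strings (a multi-record genome).
    """
    if isinstance(seq, (str, np.ndarray)):
        seq = [seq]
    counts = count_ktuples(seq, 1, use_complement=False).counts
    total = counts.sum()
    if total == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return float((counts[1] + counts[2]) / total)


@dataclass
class GenomeBinSet:
    """C GC-stratified bins of reference genomes with per-bin Markov models."""

    C: int
    order: int
    boundaries: np.ndarray  # C-1 GC cut points between adjacent bins
    models: list  # C MarkovModel
    assignment: dict  # genome id -> bin index
    gc: dict = field(default_factory=dict)  # genome id -> GC fraction

    def save(self, directory: str) -> None:
        os.makedirs(directory, exist_ok=True)
        for c, model in enumerate(self.models):
            with open(os.path.join(directory, f"bin{c}.model.tsv"), "w") as fh:
                fh.write(model.to_text())
        df = pd.DataFrame(
            {
                "genome": list(self.assignment),
                "bin": [self.assignment[g] for g in self.assignment],
                "gc": [self.gc.get(g, float("nan")) for g in self.assignment],
            }
        )
        df.to_csv(os.path.join(directory, "assignments.tsv"), sep="\t", index=False)
        with open(os.path.join(directory, "binset.tsv"), "w") as fh:
            fh.write(f"C\t{self.C}\norder\t{self.order}\n")
            fh.write(
                "boundaries\t"
                + "\t".join(repr(float(b)) for b in self.boundaries)
                + "\n"
            )

    @classmethod
    def load(cls, directory: str) -> "GenomeBinSet":
        meta = {}
        with open(os.path.join(directory, "binset.tsv")) as fh:
            for line in fh:
                key, *vals = line.rstrip("\n").split("\t")
                meta[key] = vals
        C = int(meta["C"][0])
        order = int(meta["order"][0])
        boundaries = np.array([float(x) for x in meta["boundaries"] if x])
        models = []
        for c in range(C):
            with open(os.path.join(directory, f"bin{c}.model.tsv")) as fh:
                models.append(MarkovModel.from_text(fh.read()))
        df = pd.read_csv(os.path.join(directory, "assignments.tsv"), sep="\t")
        assignment = dict(zip(df["genome"], df["bin"].astype(int)))
        gc = dict(zip(df["genome"], df["gc"].astype(float)))
        return cls(C, order, boundaries, models, assignment, gc)


def build_genome_bins(
    genomes: dict,
    C: int,
    order: int,
    pseudocount: float = CLASSIFIER_PSEUDOCOUNT,
) -> GenomeBinSet:
    """Stratify genomes into C equal-size GC rank bins and train one Markov
    model per bin.

    ``genomes`` maps genome id to a sequence or list of sequences.  Genomes
    are sorted by GC (ties broken by id) and split into C consecutive rank
    groups; when C does not divide the genome count, the lowest-GC bins get
    one extra genome each.  C=1 degenerates to a single whole-panel model.
    """
    if C < 1:
        raise ValueError("number of bins C must be >= 1")
    if C > len(genomes):
        raise ValueError(
            f"C={C} exceeds the number of genomes ({len(genomes)})"
        )
    seqs = {
        g: ([s] if isinstance(s, str) else list(s)) for g, s in genomes.items()
    }
    gc = {g: gc_content(s) for g, s in seqs.items()}
    ranked = sorted(gc, key=lambda g: (gc[g], g))
    splits = np.array_split(np.arange(len(ranked)), C)
    assignment = {}
    models = []
    boundaries = []
    for c, idxs in enumerate(splits):
        members = [ranked[i] for i in idxs]
        for g in members:
            assignment[g] = c
        bin_seqs = [s for g in members for s in seqs[g]]
        models.append(train_markov(bin_seqs, order, pseudocount=pseudocount))
        if c < C - 1:
            hi = gc[ranked[idxs[-1]]]
            lo = gc[ranked[splits[c + 1][0]]]
            boundaries.append(0.5 * (hi + lo))
    return GenomeBinSet(C, order, np.array(boundaries), models, assignment, gc)


def _encode_reads(reads) -> list:
    return [r if isinstance(r, np.ndarray) else encode(r) for r in reads]


def _as_matrix(reads: list) -> np.ndarray | None:
    """Stack equal-length encoded reads into one matrix, else None."""
    if not reads:
        return None
    L = reads[0].size
    if any(r.size != L for r in reads):
        return None
    return np.vstack(reads)


def _scores_matrix(reads, models) -> tuple[np.ndarray, np.ndarray]:
    """Log-likelihood of every read under every model (C x n_reads).

    Reads whose valid-window count is zero (too short, or all windows
    contain N) are marked unusable.  Equal-length read sets take a fully
    vectorized path; mixed lengths fall back to a flat pass over all
    (r+1)-mer window indices with per-model bincount accumulation.
    """
    r = models[0].order
    reads = _encode_reads(reads)
    mat = _as_matrix(reads)
    if mat is not None:
        idx, valid = _window_indices_matrix(mat, r + 1)
        usable = valid.any(axis=1)
        scores = np.full((len(models), len(reads)), -np.inf)
        for c, model in enumerate(models):
            logt = model.log_transitions.ravel()
            w = logt[idx]
            w[~valid] = 0.0
            scores[c] = w.sum(axis=1)
        return scores, usable
    idx_chunks = []
    owner_chunks = []
    usable = np.zeros(len(reads), dtype=bool)
    for i, codes in enumerate(reads):
        idx = _window_indices(codes, r + 1)
        if idx.size:
            usable[i] = True
            idx_chunks.append(idx)
            owner_chunks.append(np.full(idx.size, i, dtype=np.int64))
    scores = np.full((len(models), len(reads)), -np.inf)
    if idx_chunks:
        flat_idx = np.concatenate(idx_chunks)
        owners = np.concatenate(owner_chunks)
        for c, model in enumerate(models):
            logt = model.log_transitions.ravel()
            scores[c] = np.bincount(
                owners, weights=logt[flat_idx], minlength=len(reads)
            )
    return scores, usable


def classify_reads(reads, bins: GenomeBinSet) -> np.ndarray:
    """Assign each read to the bin with the highest log-likelihood.

    Returns an int array of bin indices; reads too short for the model order
    (no valid window) get -1.  Ties break to the lowest bin index.
    """
    scores, usable = _scores_matrix(list(reads), bins.models)
    labels = scores.argmax(axis=0).astype(np.int64)  # first max on ties
    labels[~usable] = -1
    return labels


def classify_read(read: str, bins: GenomeBinSet) -> int:
    """Bin index for a single read (argmax log-likelihood, ties to lowest)."""
    label = int(classify_reads([read], bins)[0])
    if label < 0:
        raise ValueError(
            f"read of length {len(read)} has no window of length "
            f"order+1={bins.order + 1}; cannot classify"
        )
    return label


@dataclass
class BinnedSample:
    """Per-bin k-tuple counts and background models for one sample.

    ``per_bin_background[c]`` is the order-``background_order`` expectation
    model for bin c, or None when the bin received no reads.  The raw
    (r+1)- and r-tuple counts behind each background model are retained so
    bins can be pooled exactly (see :func:`pool_bins`).
    """

    C: int
    k: int
    background_order: int
    per_bin_counts: list  # C KtupleCountVector of k-tuples
    per_bin_background: list  # C MarkovModel or None
    n_reads_per_bin: np.ndarray
    n_dropped: int = 0
    background_pseudocount: float = 0.0
    _bg_counts: list = field(default_factory=list, repr=False)

    @property
    def per_bin_totals(self) -> np.ndarray:
        return np.array([cv.n for cv in self.per_bin_counts], dtype=np.int64)

    @property
    def total_counts(self) -> KtupleCountVector:
        counts = sum(cv.counts for cv in self.per_bin_counts)
        return KtupleCountVector(self.k, counts)


def bin_sample(
    reads,
    bins: GenomeBinSet,
    k: int,
    background_order: int,
    background_pseudocount: float = 0.0,
    reference_background: list | None = None,
) -> BinnedSample:
    """Classify reads into bins and accumulate per-bin k-tuple statistics.

    Each read is assigned by :func:`classify_reads`; per-bin k-tuple counts
    are strand-complemented; the per-bin background (expectation) model is
    re-estimated from the reads assigned to that bin, unless
    ``reference_background`` supplies per-bin models trained on the
    reference genomes instead.  Reads too short to classify are dropped with
    a logged count.
    """
    if background_order > k - 2:
        raise ValueError(
            f"background order must be <= k - 2 (got order="
            f"{background_order}, k={k})"
        )
    reads = _encode_reads(reads)
    if not reads:
        raise ValueError("empty read set")
    labels = classify_reads(reads, bins)
    mat = _as_matrix(reads)
    n_dropped = int((labels < 0).sum())
    if n_dropped:
        log.info("bin_sample: dropped %d unclassifiable reads", n_dropped)
    if n_dropped == len(reads):
        raise ValueError("all reads unclassifiable (shorter than order+1)")
    C = bins.C
    if reference_background is not None:
        if len(reference_background) != C:
            raise ValueError("reference_background must supply one model per bin")
        for m in reference_background:
            if m.order != background_order:
                raise ValueError(
                    "reference background model order does not match "
                    "background_order"
                )
    per_bin_counts = []
    per_bin_background = []
    bg_counts = []
    n_reads_per_bin = np.zeros(C, dtype=np.int64)
    r = background_order
    for c in range(C):
        members = np.flatnonzero(labels == c)
        n_reads_per_bin[c] = members.size
        if mat is not None:
            sub = mat[members]
            per_bin_counts.append(count_ktuples_matrix(sub, k))
            counts_rp1 = count_ktuples_matrix(sub, r + 1)
            counts_r = count_ktuples_matrix(sub, r) if r >= 1 else None
        else:
            bin_reads = [reads[i] for i in members]
            per_bin_counts.append(count_ktuples(bin_reads, k))
            counts_rp1 = count_ktuples(bin_reads, r + 1)
            counts_r = count_ktuples(bin_reads, r) if r >= 1 else None
        bg_counts.append((counts_rp1, counts_r))
        if members.size == 0:
            per_bin_background.append(None)
            log.info("bin_sample: bin %d received no reads", c)
            continue
        elif reference_background is not None:
            per_bin_background.append(reference_background[c])
        else:
            per_bin_background.append(
                model_from_counts(
                    r, counts_rp1, counts_r, background_pseudocount
                )
            )
    return BinnedSample(
        C=C,
        k=k,
        background_order=background_order,
        per_bin_counts=per_bin_counts,
        per_bin_background=per_bin_background,
        n_reads_per_bin=n_reads_per_bin,
        n_dropped=n_dropped,
        background_pseudocount=background_pseudocount,
        _bg_counts=bg_counts,
    )


def pool_bins(sample: BinnedSample) -> BinnedSample:
    """Collapse a binned sample to C=1 (the no-binning statistic).

    Counts are summed across bins and the background model is rebuilt from
    the pooled tuple counts, so the result is numerically identical to
    binning the same reads with a single bin.
    """
    r = sample.background_order
    counts_rp1 = sum(
        (c for c, _ in sample._bg_counts[1:]), sample._bg_counts[0][0]
    )
    if r >= 1:
        counts_r = sum(
            (c for _, c in sample._bg_counts[1:]), sample._bg_counts[0][1]
        )
    else:
        counts_r = None
    pc = sample.background_pseudocount
    model = model_from_counts(r, counts_rp1, counts_r, pc)
    return BinnedSample(
        C=1,
        k=sample.k,
        background_order=r,
        per_bin_counts=[sample.total_counts],
        per_bin_background=[model],
        n_reads_per_bin=np.array([int(sample.n_reads_per_bin.sum())]),
        n_dropped=sample.n_dropped,
        background_pseudocount=pc,
        _bg_counts=[(counts_rp1, counts_r)],
    )
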