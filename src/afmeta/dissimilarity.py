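"""Centralized k-tuple statistics and the d2S / d2* dissimilarities.

The centralized count of tuple w is the observed count minus its expectation
under the background Markov model, summed over read bins:

    Xbar_w = sum_c (X^c_w - n^c p^c_w)

d2S and d2* are the normalized dissimilarities built from two centralized
vectors; both lie in [0, 1] by the Cauchy inequality, are 0 for identical
samples and grow as the k-tuple profiles diverge.  d2S normalizes each term
by sqrt(Xbar^2 + Ybar^2); d2* by the geometric mean of the expected counts
(a Poisson-variance, Pearson-correlation style scaling).

Accumulations are in extended precision with a fixed summation order, so
repeated runs are bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix

from .binning import BinnedSample
from .kmer import ktuple_probability_vector

log = logging.getLogger(__name__)


class DegenerateSampleError(ValueError):
    """Raised when a dissimilarity is undefined (all-zero centralized
    vectors or all-zero normalizers)."""


@dataclass
class CentralizedVector:
    """Bin-combined centralized counts and total expected counts for one
    sample at tuple size k."""

    k: int
    xbar: np.ndarray  # length 4**k, observed minus expected, summed over bins
    expected: np.ndarray  # length 4**k, total expected count (for d2*)


def centralize(sample: BinnedSample, k: int) -> CentralizedVector:
    """Centralized k-tuple counts with all bins combined.

    For each bin c with n^c total tuples and background tuple probabilities
    p^c_w, accumulates X^c_w - n^c p^c_w; bins that received no reads
    contribute nothing.
    """
    if sample.k != k:
        raise ValueError(
            f"sample was counted at k={sample.k}, requested k={k}"
        )
    xbar = np.zeros(4**k, dtype=np.longdouble)
    expected = np.zeros(4**k, dtype=np.longdouble)
    for c in range(sample.C):
        model = sample.per_bin_background[c]
        counts = sample.per_bin_counts[c]
        if model is None or counts.n == 0:
            continue
        if model.order > k - 2:
            raise ValueError(
                f"background order {model.order} must be <= k - 2 = {k - 2}"
            )
        p = ktuple_probability_vector(model, k).astype(np.longdouble)
        exp_c = counts.n * p
        xbar += counts.counts - exp_c
        expected += exp_c
    return CentralizedVector(k=k, xbar=xbar, expected=expected)


def d2s(x: CentralizedVector, y: CentralizedVector) -> float:
    """d2S dissimilarity in [0, 1]; 0 for identical centralized profiles.

    d2S = (1 - D2S / (sqrt(sum Xbar^2/sqrt(Xbar^2+Ybar^2)) *
                      sqrt(sum Ybar^2/sqrt(Xbar^2+Ybar^2)))) / 2
    with D2S = sum Xbar Ybar / sqrt(Xbar^2 + Ybar^2); terms where both
    centralized counts vanish are skipped.
    """
    if x.k != y.k:
        raise ValueError("centralized vectors have different k")
    xb = x.xbar.astype(np.longdouble)
    yb = y.xbar.astype(np.longdouble)
    denom = np.sqrt(xb * xb + yb * yb)
    mask = denom > 0
    if not mask.any():
        raise DegenerateSampleError(
            "both centralized vectors are identically zero"
        )
    xbm, ybm, dm = xb[mask], yb[mask], denom[mask]
    num = np.sum(xbm * ybm / dm)
    nx = np.sqrt(np.sum(xbm * xbm / dm))
    ny = np.sqrt(np.sum(ybm * ybm / dm))
    if nx == 0 or ny == 0:
        raise DegenerateSampleError("zero normalizer in d2S")
    val = 0.5 * (1.0 - float(num / (nx * ny)))
    return min(max(val, 0.0), 1.0)


def d2star(x: CentralizedVector, y: CentralizedVector) -> float:
    """d2* dissimilarity in [0, 1]; 0 for identical centralized profiles.

    d2* = (1 - D2* / (sqrt(sum Xbar^2/E_X) * sqrt(sum Ybar^2/E_Y))) / 2
    with D2* = sum Xbar Ybar / sqrt(E_X E_Y), where E is the bin-summed
    expected count.  Terms with zero expectation are skipped.
    """
    if x.k != y.k:
        raise ValueError("centralized vectors have different k")
    xb = x.xbar.astype(np.longdouble)
    yb = y.xbar.astype(np.longdouble)
    ex = x.expected.astype(np.longdouble)
    ey = y.expected.astype(np.longdouble)
    joint = (ex > 0) & (ey > 0)
    if ((~joint) & ((xb != 0) | (yb != 0))).any():
        log.warning(
            "d2star: tuples with zero expectation but nonzero centralized "
            "count skipped"
        )
    num = np.sum(xb[joint] * yb[joint] / np.sqrt(ex[joint] * ey[joint]))
    mx = ex > 0
    my = ey > 0
    nx = np.sqrt(np.sum(xb[mx] * xb[mx] / ex[mx]))
    ny = np.sqrt(np.sum(yb[my] * yb[my] / ey[my]))
    if nx == 0 or ny == 0:
        raise DegenerateSampleError("zero normalizer in d2*")
    val = 0.5 * (1.0 - float(num / (nx * ny)))
    return min(max(val, 0.0), 1.0)


_MEASURES = {"d2s": d2s, "d2star": d2star}


def pairwise_dissimilarity(
    samples, measure: str = "d2s", k: int | None = None, labels=None
) -> DistanceMatrix:
    """Symmetric zero-diagonal matrix of d2S or d2* over all sample pairs.

    ``samples`` may be BinnedSample or precomputed CentralizedVector
    objects.  Returns a scikit-bio DistanceMatrix with the given labels
    (defaults to s0, s1, ...).
    """
    samples = list(samples)
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    if measure not in _MEASURES:
        raise ValueError(f"measure must be one of {sorted(_MEASURES)}")
    func = _MEASURES[measure]
    if isinstance(samples[0], BinnedSample):
        if k is None:
            k = samples[0].k
        vecs = [centralize(s, k) for s in samples]
    else:
        vecs = samples
    n = len(vecs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                mat[i, j] = mat[j, i] = func(vecs[i], vecs[j])
            except DegenerateSampleError as err:
                raise DegenerateSampleError(
                    f"degenerate pair (sample {i}, sample {j}): {err}"
                ) from err
    if labels is None:
        labels = [f"s{i}" for i in range(n)]
    return DistanceMatrix(mat, ids=list(labels))


def write_matrix_tsv(dm: DistanceMatrix, path: str) -> None:
    """Tab-separated square matrix with sample labels as header row/column."""
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(c) for c in df.columns])


def write_matrix_phylip(dm: DistanceMatrix, path: str) -> None:
    """PHYLIP square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label, row in zip(dm.ids, dm.data):
            fh.write(label + "\t" + "\t".join(f"{v:.10f}" for v in row) + "\n")
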