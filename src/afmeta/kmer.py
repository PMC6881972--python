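"""k-tuple counting and Markov background models.

Counting is strand-complemented by default: every sequence is counted
together with its reverse complement, so the count of any tuple equals the
count of its reverse complement and the statistics downstream are strand
symmetric.  Tuples are indexed lexicographically over A < C < G < T; windows
containing an ambiguous base (N) are skipped entirely.

A Markov model of order ``r`` is a ``4**r x 4`` table of transition
probabilities together with an empirical distribution over the ``4**r``
initial contexts.  Transitions are estimated as the ratio of (r+1)-tuple to
r-tuple counts, optionally with additive (pseudocount) smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

log = logging.getLogger(__name__)

BASES = "ACGT"

# base -> code lookup over the full byte range; ambiguous bases map to -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes A=0, C=1, G=2, T=3, other=-1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    if (codes < 0).any():
        return "".join("N" if c < 0 else BASES[c] for c in codes)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded sequence; ambiguous codes stay -1."""
    out = np.where(codes >= 0, 3 - codes, np.int8(-1))
    return out[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def tuple_index(tup: str) -> int:
    """Lexicographic index of a k-tuple (A<C<G<T)."""
    codes = encode(tup)
    if (codes < 0).any():
        raise ValueError(f"tuple {tup!r} contains non-ACGT characters")
    idx = 0
    for c in codes:
        idx = idx * 4 + int(c)
    return idx


def index_tuple(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def _window_indices_matrix(mat: np.ndarray, k: int):
    """Window indices for a batch of equal-length encoded reads.

    Returns (idx, valid): both (n_reads, L-k+1); ``valid`` marks N-free
    windows.  Built incrementally to avoid materializing the (n, W, k)
    window tensor.
    """
    n, L = mat.shape
    W = L - k + 1
    if W <= 0:
        return (
            np.empty((n, 0), dtype=np.int64),
            np.empty((n, 0), dtype=bool),
        )
    idx = np.zeros((n, W), dtype=np.int64)
    valid = np.ones((n, W), dtype=bool)
    for t in range(k):
        col = mat[:, t : t + W]
        valid &= col >= 0
        idx = idx * 4 + col
    idx[~valid] = 0
    return idx, valid


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return np.where(mat >= 0, 3 - mat, np.int8(-1))[:, ::-1]


def count_ktuples_matrix(
    mat: np.ndarray, k: int, use_complement: bool = True
) -> "KtupleCountVector":
    """Counts over a batch of equal-length encoded reads (rows of ``mat``)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = np.zeros(4**k, dtype=np.int64)
    for m in ([mat, _revcomp_matrix(mat)] if use_complement else [mat]):
        idx, valid = _window_indices_matrix(m, k)
        if idx.size:
            flat = idx[valid]
            if flat.size:
                counts += np.bincount(flat, minlength=4**k)
    return KtupleCountVector(k, counts)


def _window_indices(codes: np.ndarray, k: int) -> np.ndarray:
    """Indices of all valid (N-free) length-k windows of an encoded sequence."""
    if codes.size < k:
        return np.empty(0, dtype=np.int64)
    if k == 1:
        return codes[codes >= 0].astype(np.int64)
    win = sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win[valid].astype(np.int64) @ powers


@dataclass
class KtupleCountVector:
    """Counts of all 4**k k-tuples, lexicographic order, with total n."""

    k: int
    counts: np.ndarray  # int64, length 4**k
    n: int = field(default=-1)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4**self.k,):
            raise ValueError(
                f"counts must have length 4**k = {4**self.k}, got {self.counts.shape}"
            )
        if self.n < 0:
            self.n = int(self.counts.sum())

    def __getitem__(self, tup: str) -> int:
        return int(self.counts[tuple_index(tup)])

    def __add__(self, other: "KtupleCountVector") -> "KtupleCountVector":
        if self.k != other.k:
            raise ValueError("cannot add count vectors of different k")
        return KtupleCountVector(self.k, self.counts + other.counts)


def count_ktuples(
    seqs, k: int, use_complement: bool = True
) -> KtupleCountVector:
    """Count every N-free length-k window over a collection of sequences.

    With ``use_complement`` (the default) each sequence's reverse complement
    is counted as well, making the vector strand symmetric.  Sequences
    shorter than k contribute nothing; an empty collection yields the zero
    vector.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        codes = seq if isinstance(seq, np.ndarray) else encode(seq)
        idx = _window_indices(codes, k)
        if idx.size:
            counts += np.bincount(idx, minlength=4**k)
        if use_complement:
            idx = _window_indices(revcomp_codes(codes), k)
            if idx.size:
                counts += np.bincount(idx, minlength=4**k)
    return KtupleCountVector(k, counts)


@dataclass
class MarkovModel:
    """Order-r Markov chain over {A,C,G,T}.

    ``transitions[u, b]`` is the probability of base b following the length-r
    context with lexicographic index u; ``initial`` is a distribution over
    the 4**r contexts (the scalar 1 at order 0).
    """

    order: int
    transitions: np.ndarray  # (4**r, 4)
    initial: np.ndarray  # (4**r,)

    def __post_init__(self):
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.initial = np.asarray(self.initial, dtype=np.float64)
        nctx = 4**self.order
        if self.transitions.shape != (nctx, 4):
            raise ValueError(
                f"transitions must be ({nctx}, 4) for order {self.order}"
            )
        if self.initial.shape != (nctx,):
            raise ValueError(f"initial must have length {nctx}")

    def validate(self, tol: float = 1e-9) -> None:
        if (self.transitions < 0).any() or (self.initial < 0).any():
            raise ValueError("negative probabilities in model")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=tol):
            raise ValueError("transition rows must sum to 1")
        if abs(self.initial.sum() - 1.0) > tol:
            raise ValueError("initial distribution must sum to 1")

    @property
    def log_transitions(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.transitions)

    def to_text(self) -> str:
        """Plain-text table: header with order, one row of 4 probabilities
        per context, then the initial distribution."""
        lines = [f"order\t{self.order}"]
        for row in self.transitions:
            lines.append("\t".join(repr(float(p)) for p in row))
        lines.append("initial")
        lines.append("\t".join(repr(float(p)) for p in self.initial))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "MarkovModel":
        lines = [ln for ln in text.strip().splitlines() if ln.strip()]
        tag, order_s = lines[0].split("\t")
        if tag != "order":
            raise ValueError("malformed model file: missing order header")
        order = int(order_s)
        nctx = 4**order
        rows = [
            [float(x) for x in ln.split("\t")] for ln in lines[1 : 1 + nctx]
        ]
        if lines[1 + nctx] != "initial":
            raise ValueError("malformed model file: missing initial block")
        initial = [float(x) for x in lines[2 + nctx].split("\t")]
        return cls(order, np.array(rows), np.array(initial))


def model_from_counts(
    order: int,
    counts_rp1: KtupleCountVector,
    counts_r: KtupleCountVector | None,
    pseudocount: float = 0.0,
) -> MarkovModel:
    """Build an order-r model from (r+1)-tuple counts (transitions) and
    r-tuple counts (initial distribution; ignored at order 0).

    Contexts never observed (with zero pseudocount) fall back to a uniform
    row, with a logged warning.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    nctx = 4**order
    if counts_rp1.k != order + 1:
        raise ValueError("counts_rp1 must be (order+1)-tuple counts")
    table = counts_rp1.counts.reshape(nctx, 4).astype(np.float64) + pseudocount
    row_sums = table.sum(axis=1)
    empty = row_sums == 0
    if empty.any():
        log.warning(
            "model_from_counts: %d of %d contexts unobserved with "
            "pseudocount 0; rows left uniform",
            int(empty.sum()),
            nctx,
        )
        table[empty] = 1.0
        row_sums[empty] = 4.0
    transitions = table / row_sums[:, None]
    if order == 0:
        initial = np.array([1.0])
    else:
        tot = counts_r.counts.sum()
        if tot == 0:
            initial = np.full(nctx, 1.0 / nctx)
        else:
            initial = counts_r.counts / tot
    return MarkovModel(order, transitions, initial)


def train_markov(
    seqs, order: int, pseudocount: float = 0.0, use_complement: bool = True
) -> MarkovModel:
    """Estimate an order-r Markov model from sequences and (by default)
    their reverse complements.

    Transition probabilities are row-normalized (r+1)-tuple counts with
    additive smoothing; the initial distribution is the normalized r-tuple
    count vector.  Training on both strands makes the model strand
    symmetric, matching the strand-complemented tuple counts it provides
    expectations for; ``use_complement=False`` fits the forward strand only
    (e.g. to recover the parameters of a known single-strand chain).
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    seqs = list(seqs)
    if not any(len(s) > order for s in seqs):
        raise ValueError(
            f"training requires at least one sequence longer than order={order}"
        )
    counts1 = count_ktuples(seqs, order + 1, use_complement)
    counts_r = (
        count_ktuples(seqs, order, use_complement) if order >= 1 else None
    )
    return model_from_counts(order, counts1, counts_r, pseudocount)


def _check_order_vs_k(order: int, k: int) -> None:
    if order > k - 2:
        raise ValueError(
            f"Markov order must be <= k - 2 (got order={order}, k={k}); "
            "at higher orders the model expectation degenerates to the "
            "observed counts"
        )


def ktuple_probability_vector(model: MarkovModel, k: int) -> np.ndarray:
    """Probabilities of all 4**k tuples under the model, lexicographic order.

    p(w) = initial(w_1..w_r) * prod_i transitions(w_i..w_{i+r-1} -> w_{i+r}).
    Sums to 1 whenever the model rows and initial distribution do.
    """
    r = model.order
    _check_order_vs_k(r, k)
    probs = model.initial.copy()  # over length-r prefixes
    nctx = 4**r
    for _ in range(k - r):
        # context of each length-m prefix is its last r bases: index % 4**r
        ctx = np.arange(probs.size, dtype=np.int64) % nctx
        probs = (probs[:, None] * model.transitions[ctx]).ravel()
    return probs


def ktuple_probability(model: MarkovModel, tup: str) -> float:
    """Probability of a single k-tuple under the model."""
    r = model.order
    k = len(tup)
    _check_order_vs_k(r, k)
    codes = encode(tup)
    if (codes < 0).any():
        raise ValueError(f"tuple {tup!r} contains non-ACGT characters")
    powers_r = 4 ** np.arange(r - 1, -1, -1, dtype=np.int64)
    if r == 0:
        p = 1.0
        start = 0
    else:
        ctx0 = int(codes[:r].astype(np.int64) @ powers_r)
        p = float(model.initial[ctx0])
        start = r
    for i in range(start, k):
        if r == 0:
            ctx = 0
        else:
            ctx = int(codes[i - r : i].astype(np.int64) @ powers_r)
        p *= float(model.transitions[ctx, codes[i]])
    return p


def log_likelihood(model: MarkovModel, seq: str) -> float:
    """Log-likelihood of a read: sum of log transition probabilities over all
    N-free windows of length order+1.  Zero-probability transitions give -inf.
    """
    r = model.order
    codes = seq if isinstance(seq, np.ndarray) else encode(seq)
    if codes.size <= r:
        raise ValueError(
            f"sequence length {codes.size} must exceed model order {r}"
        )
    idx = _window_indices(codes, r + 1)
    if idx.size == 0:
        return 0.0
    logt = model.log_transitions.ravel()
    return float(logt[idx].sum())
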