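"""Seeded GF(2) engine.

Holds the deterministic pseudo-random bit stream, dense 0/1 matrix
construction, Gaussian XOR elimination (row addition = bitwise XOR), and the
random-sampling search for a generator matrix whose K-row subsets decode
with maximum probability.

The stream generator is a splitmix64-style recurrence, written out in full
so that the bit stream is identical on every platform and in every language
that reimplements it:

    out(i) = mix64((seed + (i + 1) * 0x9E3779B97F4A7C15) mod 2**64)

    mix64(z): z ^= z >> 30; z *= 0xBF58476D1CE4E5B9 (mod 2**64)
              z ^= z >> 27; z *= 0x94D049BB133111EB (mod 2**64)
              z ^= z >> 31

Bits are taken from each 64-bit output most-significant-bit first.  The
stream is addressed by ``position`` (count of 64-bit words drawn), so any
offset can be revisited without replaying the prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np

from ._seq import seq_to_indices
from .errors import CapacityError, ConfigError, LayoutError, SearchExhaustedError, UndecodableError

MASK64 = (1 << 64) - 1
_GAMMA = 0x9E3779B97F4A7C15
_MIX1 = 0xBF58476D1CE4E5B9
_MIX2 = 0x94D049BB133111EB

#: domain tags keeping derived seed streams disjoint from the candidate stream
EQ_STREAM_TAG = 0x45515542  # "EQUB"
SCORE_STREAM_TAG = 0x53434F52  # "SCOR"


def mix64(z: int) -> int:
    """The splitmix64 finalizer on a 64-bit unsigned integer."""
    z &= MASK64
    z = ((z ^ (z >> 30)) * _MIX1) & MASK64
    z = ((z ^ (z >> 27)) * _MIX2) & MASK64
    return z ^ (z >> 31)


def derive_seed(seed: int, *tags: int) -> int:
    """Deterministically fold integer tags into a 64-bit sub-stream seed."""
    s = seed & MASK64
    for t in tags:
        s = mix64(s ^ mix64(int(t) & MASK64))
    return s


class SplitMix64:
    """Stateless-reproducible 64-bit stream: (seed, position) -> next words."""

    def __init__(self, seed: int, position: int = 0):
        self.seed = int(seed) & MASK64
        self.position = int(position)

    def next_u64(self) -> int:
        self.position += 1
        return mix64((self.seed + self.position * _GAMMA) & MASK64)

    def words(self, n: int) -> np.ndarray:
        """Draw ``n`` 64-bit words, vectorised."""
        idx = np.arange(self.position + 1, self.position + n + 1, dtype=np.uint64)
        self.position += n
        z = np.uint64(self.seed) + idx * np.uint64(_GAMMA)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(_MIX1)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(_MIX2)
        return z ^ (z >> np.uint64(31))

    def bits(self, n: int) -> np.ndarray:
        """Draw ``n`` bits (uint8 0/1), MSB-first within each word."""
        if n == 0:
            return np.zeros(0, dtype=np.uint8)
        w = self.words(-(-n // 64))
        return np.unpackbits(w.byteswap().view(np.uint8))[:n]

    def bases(self, n: int) -> np.ndarray:
        """Draw ``n`` uniform base indices (2 bits per base, MSB-first)."""
        b = self.bits(2 * n).reshape(n, 2)
        return (b[:, 0] << 1 | b[:, 1]).astype(np.uint8)

    def skip(self, n_words: int) -> "SplitMix64":
        self.position += int(n_words)
        return self


def pack_adapter(adapter: str) -> int:
    """20-nt adapter -> 40-bit integer (A=00,T=01,C=10,G=11, first base MSB)."""
    if len(adapter) != 20:
        raise LayoutError(f"adapter must be exactly 20 nt, got {len(adapter)}")
    idx = seq_to_indices(adapter)
    value = 0
    for v in idx:
        value = (value << 2) | int(v)
    return value


def seed_from_adapter(adapter: str) -> int:
    """Derive the 64-bit stream seed from a 20-nt adapter.

    The adapter is packed to 40 bits and passed through ``mix64``; the
    packing is injective on the 4^20 adapter space, and mix64 is a bijection
    on 64-bit integers, so distinct adapters yield distinct seeds.
    """
    return mix64(pack_adapter(adapter))


# ---------------------------------------------------------------------------
# bit matrices


def random_bit_matrix(state: SplitMix64, t_rows: int, k_cols: int) -> np.ndarray:
    """Draw a dense uint8 0/1 matrix of fair coins from the seeded stream."""
    if t_rows < k_cols or k_cols < 1:
        raise ConfigError(f"need t_rows >= k_cols >= 1, got {t_rows}x{k_cols}")
    return state.bits(t_rows * k_cols).reshape(t_rows, k_cols)


@dataclass
class EliminationRecord:
    """Result of Gaussian XOR elimination on a square matrix.

    ``ops`` replays to ``triangular`` from the input: ("swap", i, j) swaps
    rows, ("xor", src, dst) sets row[dst] ^= row[src].
    """

    triangular: np.ndarray
    diagonal: np.ndarray  # bool per column: pivot found on the main diagonal
    ops: list

    @property
    def unique_solution(self) -> bool:
        return bool(self.diagonal.all())

    @property
    def rank(self) -> int:
        return int(self.diagonal.sum())


def gauss_xor_eliminate(matrix: np.ndarray) -> EliminationRecord:
    """Triangularise a square GF(2) matrix with row swaps and row XOR."""
    a = np.asarray(matrix, dtype=np.uint8)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ConfigError(f"square matrix required, got shape {a.shape}")
    a = a.copy()
    n = a.shape[0]
    ops: list = []
    diagonal = np.zeros(n, dtype=bool)
    row = 0
    for col in range(n):
        piv = None
        for r in range(row, n):
            if a[r, col]:
                piv = r
                break
        if piv is None:
            continue
        if piv != row:
            a[[row, piv]] = a[[piv, row]]
            ops.append(("swap", row, piv))
        below = np.nonzero(a[row + 1:, col])[0] + row + 1
        for r in below:
            a[r] ^= a[row]
            ops.append(("xor", row, int(r)))
        diagonal[col] = True
        row += 1
    return EliminationRecord(triangular=a, diagonal=diagonal, ops=ops)


def is_uniquely_solvable(matrix: np.ndarray) -> bool:
    """True iff elimination leaves an all-1 main diagonal (full GF(2) rank)."""
    return gauss_xor_eliminate(matrix).unique_solution


def _pack_rows(matrix: np.ndarray) -> list[int]:
    """Rows as arbitrary-precision integers (column 0 most significant)."""
    packed = np.packbits(np.asarray(matrix, dtype=np.uint8), axis=1)
    return [int.from_bytes(r.tobytes(), "big") for r in packed]


def _rank_packed(rows: Sequence[int]) -> int:
    pivots: dict[int, int] = {}
    rank = 0
    for row in rows:
        while row:
            b = row.bit_length() - 1
            if b in pivots:
                row ^= pivots[b]
            else:
                pivots[b] = row
                rank += 1
                break
    return rank


# ---------------------------------------------------------------------------
# generator matrix selection


@dataclass
class GeneratorMatrix:
    """A (K+m) x K generator accepted by the seeded random search."""

    matrix: np.ndarray
    seed: int
    attempt_counter: int  # index of the candidate draw (the Times value)
    score: float  # estimated fraction of K-row subsets that decode

    @property
    def k(self) -> int:
        return self.matrix.shape[1]

    @property
    def m(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]


def _candidate_words(k: int, m: int) -> int:
    return -(-((k + m) * k) // 64)


def candidate_matrix(seed: int, k: int, m: int, attempt: int) -> np.ndarray:
    """Regenerate candidate ``attempt`` of the (K+m) x K pool for a seed.

    Candidate ``i`` occupies words [i*W, (i+1)*W) of the stream, where W is
    the number of 64-bit words covering (K+m)*K bits, so the decoder can
    rebuild any candidate directly from (seed, attempt).
    """
    rng = SplitMix64(seed, position=attempt * _candidate_words(k, m))
    return random_bit_matrix(rng, k + m, k)


def _covers(matrix: np.ndarray) -> bool:
    return bool(matrix.any(axis=1).all() and matrix.any(axis=0).all())


def score_generator(matrix: np.ndarray, seed: int, attempt: int,
                    subset_samples: int = 200, exhaustive_limit: int = 1000) -> float:
    """Fraction of K-row subsets of the candidate that are uniquely solvable.

    Enumerates all C(K+m, K) subsets when that count is <= exhaustive_limit,
    otherwise scores ``subset_samples`` uniform subsets from a seeded
    side-stream (disjoint from the candidate stream).
    """
    n, k = matrix.shape
    rows = _pack_rows(matrix)
    if n == k:
        return 1.0 if _rank_packed(rows) == k else 0.0
    total = comb(n, k)
    if total <= exhaustive_limit:
        from itertools import combinations

        hits = sum(_rank_packed([rows[i] for i in sub]) == k
                   for sub in combinations(range(n), k))
        return hits / total
    rng = np.random.default_rng(derive_seed(seed, SCORE_STREAM_TAG, attempt))
    hits = 0
    for _ in range(subset_samples):
        sub = rng.choice(n, size=k, replace=False)
        hits += _rank_packed([rows[i] for i in sub]) == k
    return hits / subset_samples


def select_generator_matrix(seed: int, k: int, m: int, *,
                            search_budget: int = 64, subset_samples: int = 200,
                            max_attempt_counter: int | None = None,
                            attempt_ok=None) -> GeneratorMatrix:
    """Search the seeded candidate stream for the best-scoring generator.

    Candidates with an all-zero row or an uncovered column are rejected
    outright (every chunk must appear in the generator).  Accepted
    candidates are scored by the fraction of uniquely solvable K-row
    subsets; the best score wins, ties broken by the earliest draw so the
    Times counter stays small.  A perfect score short-circuits the search.
    ``attempt_ok`` lets the caller veto draw indices whose encoded Times
    field could never pass downstream screening.
    """
    if k < 1 or m < 0 or search_budget < 1 or subset_samples < 1:
        raise ConfigError("need k >= 1, m >= 0 and positive budgets")
    best: GeneratorMatrix | None = None
    for attempt in range(search_budget):
        if max_attempt_counter is not None and attempt > max_attempt_counter:
            break
        if attempt_ok is not None and not attempt_ok(attempt):
            continue
        cand = candidate_matrix(seed, k, m, attempt)
        if not _covers(cand):
            continue
        score = score_generator(cand, seed, attempt, subset_samples=subset_samples)
        if score <= 0.0:
            continue
        if best is None or score > best.score:
            best = GeneratorMatrix(matrix=cand, seed=seed, attempt_counter=attempt, score=score)
        if best.score >= 1.0:
            break
    if best is None:
        raise SearchExhaustedError(
            f"no decodable candidate generator in {search_budget} draws (K={k}, m={m})")
    if max_attempt_counter is not None and best.attempt_counter > max_attempt_counter:
        raise CapacityError(
            f"attempt counter {best.attempt_counter} exceeds Times capacity {max_attempt_counter}")
    return best


# ---------------------------------------------------------------------------
# solving


def solve_augmented(matrix: np.ndarray, payloads: np.ndarray, *, partial: bool = False):
    """Solve M @ chunks = payloads over GF(2) by XOR elimination.

    ``matrix`` has >= K rows of width K; ``payloads`` is one bit-vector per
    row.  Surplus rows consistent with the solution are tolerated;
    inconsistent surplus rows are reported by input index.

    Returns ``(chunks, inconsistent_rows)`` where chunks is a (K, B) bit
    array.  With ``partial=True`` returns ``(chunks, solved_mask,
    inconsistent_rows)`` where unsolved chunk rows are zero and
    ``solved_mask`` flags the uniquely determined chunks, instead of raising
    when the system is underdetermined.
    """
    a = np.asarray(matrix, dtype=np.uint8).copy()
    p = np.asarray(payloads, dtype=np.uint8).copy()
    if a.ndim != 2:
        raise ConfigError("matrix must be 2-D")
    n, k = a.shape
    if p.ndim != 2 or p.shape[0] != n:
        raise ConfigError("one payload vector per matrix row required")
    if n < k and not partial:
        raise UndecodableError(
            f"only {n} rows for {k} chunks", missing_pivots=list(range(k)))
    order = np.arange(n)  # original row index per current row
    pivot_row: dict[int, int] = {}
    row = 0
    for col in range(k):
        piv = None
        for r in range(row, n):
            if a[r, col]:
                piv = r
                break
        if piv is None:
            continue
        if piv != row:
            a[[row, piv]] = a[[piv, row]]
            p[[row, piv]] = p[[piv, row]]
            order[[row, piv]] = order[[piv, row]]
        others = np.nonzero(a[:, col])[0]
        others = others[others != row]
        if others.size:
            a[others] ^= a[row]
            p[others] ^= p[row]
        pivot_row[col] = row
        row += 1
    missing = [c for c in range(k) if c not in pivot_row]
    inconsistent = [int(order[r]) for r in range(row, n) if p[r].any()]
    if missing and not partial:
        raise UndecodableError(
            f"no uniquely solvable {k}-row subset; missing pivot columns {missing}",
            missing_pivots=missing)
    chunks = np.zeros((k, p.shape[1]), dtype=np.uint8)
    solved = np.zeros(k, dtype=bool)
    free = np.array([c for c in range(k) if c not in pivot_row], dtype=int)
    for col, r in pivot_row.items():
        # determined iff the pivot row involves no free column
        if free.size == 0 or not a[r, free].any():
            chunks[col] = p[r]
            solved[col] = True
    if partial:
        return chunks, solved, inconsistent
    return chunks, inconsistent
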