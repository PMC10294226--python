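"""Encoder/decoder pipeline.

A file is split into K fixed-width chunks; a seeded (K+m) x K GF(2)
generator matrix turns them into K+m droplets (row-guided XOR combinations);
each droplet is balanced against the biological constraints by XOR-ing
seeded random base masks until it passes, then assembled into a fixed-layout
strand:

    adapter_fwd | times | payload | eq_counter | re_eq | check | adapter_rev
        20 nt     6 nt    639 nt     10 nt       2 nt    3 nt      20 nt

Counters are base-4 big-endian integers (A=0, T=1, C=2, G=3).  On the
strand the times and eq fields are whitened by XOR with a seeded base pad
selected by the 2-nt re-equilibrium value: a plain base-4 rendering would
place long A-runs (leading zero digits) in every strand with a small
counter, making those values unusable under the homopolymer screen, and a
single fixed pad could itself render a Times value unscreenable.  The
re-equilibrium field is stored plain (2 bases cannot form a run alone), so
the decoder reads it first, derives the pad, and un-whitens the other
counters.  The Times field packs the generator draw index together with
the droplet's row: ``times = attempt * row_capacity + row_index``.  The
check field XOR-folds the inner fields in 3-nt (6-bit) words.  Decoding regenerates the generator
from (adapter seed, Times), screens strands by length and checksum, and
solves the augmented system by XOR elimination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, asdict, field

import numpy as np

from ._seq import as_indices, indices_to_seq, seq_to_indices
from .bioconstraints import ConstraintPolicy, _fast_screen
from .errors import (AlphabetError, CapacityError, ConfigError, LayoutError,
                     SearchExhaustedError, UndecodableError)
from .gf2_engine import (EQ_STREAM_TAG, GeneratorMatrix, SplitMix64, candidate_matrix,
                         derive_seed, seed_from_adapter, select_generator_matrix,
                         solve_augmented)

#: balanced 20-nt flanking primers used when the caller does not supply any;
#: the forward adapter was screened so its seeded K=23, m=2 generator stays
#: decodable after the loss of any single strand
DEFAULT_ADAPTER_FWD = "CATGTAGATCTAGGCGCTAC"
DEFAULT_ADAPTER_REV = "AGCATCGTCATGCAGTACGT"

#: domain tag for the counter-field whitening pad
COUNTER_PAD_TAG = 0x50414431  # "PAD1"


def counter_pad(seed: int, re_eq_value: int, layout: "StrandLayout") -> np.ndarray:
    """Base pad covering the times and eq fields, selected by the re-eq value."""
    n = layout.times_nt + layout.xor_eq_nt
    return SplitMix64(derive_seed(seed, COUNTER_PAD_TAG, re_eq_value)).bases(n)


@dataclass(frozen=True)
class StrandLayout:
    """Field widths (nt) of one strand, in assembly order."""

    adapter_fwd_nt: int = 20
    times_nt: int = 6
    payload_nt: int = 639
    xor_eq_nt: int = 10
    xor_re_eq_nt: int = 2
    xor_check_nt: int = 3
    adapter_rev_nt: int = 20

    @property
    def total_nt(self) -> int:
        return (self.adapter_fwd_nt + self.times_nt + self.payload_nt + self.xor_eq_nt
                + self.xor_re_eq_nt + self.xor_check_nt + self.adapter_rev_nt)

    @property
    def inner_nt(self) -> int:
        """Span between the adapters (times .. check inclusive)."""
        return self.total_nt - self.adapter_fwd_nt - self.adapter_rev_nt

    @property
    def checked_nt(self) -> int:
        """Region covered by the checksum: times .. re-equilibrium."""
        return self.times_nt + self.payload_nt + self.xor_eq_nt + self.xor_re_eq_nt

    @property
    def chunk_bits(self) -> int:
        return 2 * self.payload_nt

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StrandLayout":
        return cls(**d)


# ---------------------------------------------------------------------------
# bit/base primitives


def bits_to_bases(bits) -> str:
    """2 bits -> 1 base, A=00 T=01 C=10 G=11, MSB first."""
    b = np.asarray(bits, dtype=np.uint8)
    if b.size % 2:
        raise LayoutError(f"bit vector length {b.size} is odd; cannot pair into bases")
    pairs = b.reshape(-1, 2)
    return indices_to_seq((pairs[:, 0] << 1) | pairs[:, 1])


def bases_to_bits(seq) -> np.ndarray:
    idx = as_indices(seq)
    out = np.empty(2 * idx.size, dtype=np.uint8)
    out[0::2] = idx >> 1
    out[1::2] = idx & 1
    return out


def int_to_base_indices(value: int, n_nt: int) -> np.ndarray:
    """Unsigned integer -> big-endian base-4 digit array of width n_nt."""
    if value < 0 or value >= 4 ** n_nt:
        raise CapacityError(f"value {value} does not fit in {n_nt} nt")
    digits = np.empty(n_nt, dtype=np.uint8)
    for i in range(n_nt - 1, -1, -1):
        digits[i] = value & 3
        value >>= 2
    return digits


def base_indices_to_int(idx: np.ndarray) -> int:
    value = 0
    for d in np.asarray(idx, dtype=np.uint8):
        value = (value << 2) | int(d)
    return value


# ---------------------------------------------------------------------------
# segmentation and droplets


@dataclass
class ChunkSet:
    """K equal-width bit chunks of the source file (last chunk zero-padded)."""

    chunks: np.ndarray  # (K, chunk_bits) uint8 in {0,1}
    original_bit_length: int

    @property
    def k(self) -> int:
        return self.chunks.shape[0]

    @property
    def chunk_bits(self) -> int:
        return self.chunks.shape[1]


@dataclass
class Droplet:
    row_index: int
    payload: np.ndarray  # (chunk_bits,) uint8 bits


def segment_file(data: bytes, payload_nt: int = 639, bit_length: int | None = None) -> ChunkSet:
    """Split bytes into K = ceil(bits / (2 * payload_nt)) zero-padded chunks.

    ``bit_length`` limits the stored prefix when the logical payload is not
    a whole number of bytes (the trailing pad bits of the final byte are
    then ignored).
    """
    if len(data) == 0:
        raise ConfigError("cannot encode an empty file")
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8))
    n_bits = bits.size if bit_length is None else int(bit_length)
    if n_bits <= 0 or n_bits > bits.size:
        raise ConfigError(f"bit_length {bit_length} outside 1..{bits.size}")
    bits = bits[:n_bits]
    chunk_bits = 2 * payload_nt
    k = -(-n_bits // chunk_bits)
    padded = np.zeros(k * chunk_bits, dtype=np.uint8)
    padded[:n_bits] = bits
    return ChunkSet(chunks=padded.reshape(k, chunk_bits), original_bit_length=n_bits)


def make_droplets(chunks: ChunkSet, gen: GeneratorMatrix) -> list[Droplet]:
    """Droplet i = XOR of the chunks selected by generator row i."""
    if gen.matrix.shape[1] != chunks.k:
        raise ConfigError(
            f"generator has {gen.matrix.shape[1]} columns but chunk set has K={chunks.k}")
    payloads = (gen.matrix.astype(np.uint64) @ chunks.chunks.astype(np.uint64)) & 1
    return [Droplet(row_index=i, payload=payloads[i].astype(np.uint8))
            for i in range(gen.matrix.shape[0])]


# ---------------------------------------------------------------------------
# random equilibrium


def equilibrium_mask(seed: int, strand_index: int, counter: int, length: int) -> np.ndarray:
    """Deterministic base mask ``counter`` (>= 1) for one strand."""
    if counter < 1:
        raise ConfigError("mask counters start at 1 (0 means no mask)")
    rng = SplitMix64(derive_seed(seed, EQ_STREAM_TAG, strand_index, counter))
    return rng.bases(length)


def apply_mask(seq, seed: int, strand_index: int, counter: int):
    """Base-wise XOR with mask ``counter``; an involution (self-inverse)."""
    if counter == 0:
        return seq
    idx = as_indices(seq)
    masked = idx ^ equilibrium_mask(seed, strand_index, counter, idx.size)
    return indices_to_seq(masked) if isinstance(seq, str) else masked


def random_equilibrium(payload_seq, seed: int, strand_index: int,
                       policy: ConstraintPolicy | None = None,
                       counter_capacity: int = 4 ** 10,
                       start: int = 0):
    """Find the first mask counter whose XOR-ed payload passes the policy.

    Counter 0 means "no mask": if the unmasked payload already passes, it is
    returned unchanged.  Otherwise masks 1, 2, ... are tried in order until
    one passes or the counter space is exhausted.  ``start`` resumes the
    search (used when a later stage rejects the balanced payload).
    """
    policy = policy or ConstraintPolicy()
    idx = as_indices(payload_seq)
    was_str = isinstance(payload_seq, str)
    n = idx.size
    lo = policy.gc_min * n - 1e-9
    hi = policy.gc_max * n + 1e-9
    c = start
    if c == 0:
        if _fast_screen(idx, policy, lo, hi):
            return payload_seq, 0
        c = 1
    while c < counter_capacity:
        masked = idx ^ equilibrium_mask(seed, strand_index, c, n)
        if _fast_screen(masked, policy, lo, hi):
            return (indices_to_seq(masked) if was_str else masked), c
        c += 1
    raise SearchExhaustedError(
        f"equilibrium space exhausted for strand {strand_index} "
        f"({counter_capacity} counters)")


# ---------------------------------------------------------------------------
# checksum


def compute_xor_check(region, word_nt: int = 3) -> np.ndarray:
    """XOR-fold a base region in ``word_nt``-base (2*word_nt-bit) words.

    Base-wise XOR of aligned words equals bitwise XOR of the words, so the
    fold reduces columns of the (n_words, word_nt) reshape.  Regions shorter
    than a multiple of word_nt are zero-bit (A) padded on the right.
    """
    idx = as_indices(region)
    pad = (-idx.size) % word_nt
    if pad:
        idx = np.concatenate([idx, np.zeros(pad, dtype=np.uint8)])
    words = idx.reshape(-1, word_nt)
    return np.bitwise_xor.reduce(words, axis=0)


# ---------------------------------------------------------------------------
# strand assembly and parsing


@dataclass
class StrandRecord:
    """Parsed/assembled field values of one strand."""

    row_index: int
    attempt_counter: int
    times_value: int
    eq_counter: int
    re_eq_value: int
    payload_bits: np.ndarray  # unmasked droplet payload (chunk_bits,)
    check_seq: str
    sequence: str = ""


def _default_row_capacity(k: int, m: int) -> int:
    cap = 32
    while cap < k + m:
        cap *= 2
    return cap


def assemble_strand(droplet: Droplet, gen: GeneratorMatrix,
                    adapter_fwd: str = DEFAULT_ADAPTER_FWD,
                    adapter_rev: str = DEFAULT_ADAPTER_REV,
                    policy: ConstraintPolicy | None = None,
                    layout: StrandLayout | None = None,
                    row_capacity: int | None = None) -> tuple[str, StrandRecord]:
    """Assemble one droplet into a full strand that passes the policy.

    The payload is balanced first (equilibrium counter search on the payload
    alone); then the 2-nt re-equilibrium value is swept over its 16 settings
    to absorb violations introduced by counter fields and field boundaries.
    If no re-equilibrium value rescues the strand, the equilibrium search
    advances to the next passing payload mask and the sweep repeats.
    """
    policy = policy or ConstraintPolicy()
    layout = layout or StrandLayout()
    row_capacity = row_capacity or _default_row_capacity(gen.k, gen.m)
    if droplet.payload.size != layout.chunk_bits:
        raise LayoutError(
            f"droplet payload {droplet.payload.size} bits != {layout.chunk_bits}")
    times_value = gen.attempt_counter * row_capacity + droplet.row_index
    if times_value >= 4 ** layout.times_nt:
        raise CapacityError(
            f"times value {times_value} exceeds {layout.times_nt}-nt capacity")
    times_idx = int_to_base_indices(times_value, layout.times_nt)
    fwd_idx = seq_to_indices(adapter_fwd)
    rev_idx = seq_to_indices(adapter_rev)
    if fwd_idx.size != layout.adapter_fwd_nt or rev_idx.size != layout.adapter_rev_nt:
        raise LayoutError("adapter length does not match the layout")
    pairs = droplet.payload.reshape(-1, 2)
    payload_idx = ((pairs[:, 0] << 1) | pairs[:, 1]).astype(np.uint8)

    screen_len = layout.total_nt if policy.screen_adapters else layout.inner_nt
    lo = policy.gc_min * screen_len - 1e-9
    hi = policy.gc_max * screen_len + 1e-9

    eq_capacity = 4 ** layout.xor_eq_nt
    c = 0
    while True:
        masked, c = random_equilibrium(payload_idx, gen.seed, droplet.row_index,
                                       policy, counter_capacity=eq_capacity, start=c)
        eq_idx = int_to_base_indices(c, layout.xor_eq_nt)
        for re_eq in range(4 ** layout.xor_re_eq_nt):
            pad = counter_pad(gen.seed, re_eq, layout)
            re_idx = int_to_base_indices(re_eq, layout.xor_re_eq_nt)
            region = np.concatenate([times_idx ^ pad[: layout.times_nt],
                                     masked,
                                     eq_idx ^ pad[layout.times_nt:],
                                     re_idx])
            check_idx = compute_xor_check(region, layout.xor_check_nt)
            strand_idx = np.concatenate([fwd_idx, region, check_idx, rev_idx])
            screened = strand_idx if policy.screen_adapters else strand_idx[
                layout.adapter_fwd_nt: layout.adapter_fwd_nt + layout.inner_nt]
            if _fast_screen(screened, policy, lo, hi):
                record = StrandRecord(
                    row_index=droplet.row_index,
                    attempt_counter=gen.attempt_counter,
                    times_value=times_value,
                    eq_counter=c,
                    re_eq_value=re_eq,
                    payload_bits=droplet.payload.copy(),
                    check_seq=indices_to_seq(check_idx),
                    sequence=indices_to_seq(strand_idx),
                )
                return record.sequence, record
        c += 1
        if c >= eq_capacity:
            raise SearchExhaustedError(
                f"joint equilibrium/re-equilibrium search exhausted for row "
                f"{droplet.row_index}")


def parse_strand(seq: str, layout: StrandLayout | None = None,
                 adapter_fwd: str = DEFAULT_ADAPTER_FWD,
                 adapter_rev: str = DEFAULT_ADAPTER_REV,
                 seed: int | None = None,
                 row_capacity: int = 32) -> tuple[StrandRecord | None, str | None]:
    """Parse one candidate strand; returns (record, None) or (None, reason).

    Rejection reasons: ``adapter`` (a primer not found), ``length`` (the
    inter-adapter span differs from the layout, indicating an indel), and
    ``checksum`` (the recomputed XOR check disagrees with the stored one).
    ``seed`` is needed to un-whiten the counter fields and unmask the
    payload; without it only the structural checks run and the strand is
    reported as ``seed-required``.
    """
    layout = layout or StrandLayout()
    try:
        idx_all = seq_to_indices(seq)
    except AlphabetError:
        return None, "alphabet"
    text = indices_to_seq(idx_all)
    f = text.find(adapter_fwd)
    if f < 0:
        return None, "adapter"
    r = text.find(adapter_rev, f + len(adapter_fwd))
    if r < 0:
        return None, "adapter"
    inner = idx_all[f + len(adapter_fwd): r]
    if inner.size != layout.inner_nt:
        return None, "length"
    pos = 0
    times_idx = inner[pos: pos + layout.times_nt]; pos += layout.times_nt
    payload_idx = inner[pos: pos + layout.payload_nt]; pos += layout.payload_nt
    eq_idx = inner[pos: pos + layout.xor_eq_nt]; pos += layout.xor_eq_nt
    re_idx = inner[pos: pos + layout.xor_re_eq_nt]; pos += layout.xor_re_eq_nt
    check_idx = inner[pos: pos + layout.xor_check_nt]
    recomputed = compute_xor_check(inner[: layout.checked_nt], layout.xor_check_nt)
    if not np.array_equal(recomputed, check_idx):
        return None, "checksum"
    if seed is None:
        return None, "seed-required"
    re_eq_value = base_indices_to_int(re_idx)
    pad = counter_pad(seed, re_eq_value, layout)
    times_idx = times_idx ^ pad[: layout.times_nt]
    eq_idx = eq_idx ^ pad[layout.times_nt:]
    times_value = base_indices_to_int(times_idx)
    eq_counter = base_indices_to_int(eq_idx)
    row_index = times_value % row_capacity
    attempt = times_value // row_capacity
    if eq_counter:
        payload_idx = payload_idx ^ equilibrium_mask(seed, row_index, eq_counter,
                                                     payload_idx.size)
    bits = np.empty(2 * payload_idx.size, dtype=np.uint8)
    bits[0::2] = payload_idx >> 1
    bits[1::2] = payload_idx & 1
    record = StrandRecord(
        row_index=row_index,
        attempt_counter=attempt,
        times_value=times_value,
        eq_counter=eq_counter,
        re_eq_value=base_indices_to_int(re_idx),
        payload_bits=bits,
        check_seq=indices_to_seq(check_idx),
        sequence=text,
    )
    return record, None


# ---------------------------------------------------------------------------
# top-level encode/decode


def plan_generator(adapter_fwd: str, k: int, m: int, *,
                   layout: StrandLayout | None = None,
                   policy: ConstraintPolicy | None = None,
                   row_capacity: int | None = None,
                   search_budget: int = 64,
                   subset_samples: int = 200) -> GeneratorMatrix:
    """Select the generator matrix exactly as the encoder would, capping the
    draw budget so the accepted attempt always fits the Times field."""
    layout = layout or StrandLayout()
    policy = policy or ConstraintPolicy()
    row_capacity = row_capacity or _default_row_capacity(k, m)
    if k + m > row_capacity:
        raise CapacityError(f"row capacity {row_capacity} < K+m = {k + m}")
    max_attempt = 4 ** layout.times_nt // row_capacity - 1
    if max_attempt < 0:
        raise CapacityError("times field cannot hold any attempt at this row capacity")
    seed = seed_from_adapter(adapter_fwd)
    return select_generator_matrix(seed, k, m,
                                   search_budget=min(search_budget, max_attempt + 1),
                                   subset_samples=subset_samples,
                                   max_attempt_counter=max_attempt)


@dataclass
class EncodeResult:
    strands: list[str]
    records: list[StrandRecord]
    generator: GeneratorMatrix
    chunkset: ChunkSet
    layout: StrandLayout
    policy: ConstraintPolicy
    adapter_fwd: str
    adapter_rev: str
    row_capacity: int

    @property
    def k(self) -> int:
        return self.chunkset.k

    @property
    def m(self) -> int:
        return self.generator.m


def encode(data: bytes, *,
           adapter_fwd: str = DEFAULT_ADAPTER_FWD,
           adapter_rev: str = DEFAULT_ADAPTER_REV,
           m: int = 2,
           layout: StrandLayout | None = None,
           policy: ConstraintPolicy | None = None,
           bit_length: int | None = None,
           search_budget: int = 64,
           subset_samples: int = 200,
           row_capacity: int | None = None) -> EncodeResult:
    """Encode a file into K+m constraint-compliant strands."""
    layout = layout or StrandLayout()
    policy = policy or ConstraintPolicy()
    chunkset = segment_file(data, layout.payload_nt, bit_length=bit_length)
    k = chunkset.k
    row_capacity = row_capacity or _default_row_capacity(k, m)
    gen = plan_generator(adapter_fwd, k, m, layout=layout, policy=policy,
                         row_capacity=row_capacity, search_budget=search_budget,
                         subset_samples=subset_samples)
    droplets = make_droplets(chunkset, gen)
    strands: list[str] = []
    records: list[StrandRecord] = []
    for d in droplets:
        s, rec = assemble_strand(d, gen, adapter_fwd, adapter_rev,
                                 policy=policy, layout=layout, row_capacity=row_capacity)
        strands.append(s)
        records.append(rec)
    return EncodeResult(strands=strands, records=records, generator=gen,
                        chunkset=chunkset, layout=layout, policy=policy,
                        adapter_fwd=adapter_fwd, adapter_rev=adapter_rev,
                        row_capacity=row_capacity)


@dataclass
class DecodeReport:
    n_input: int = 0
    accepted: list = field(default_factory=list)  # (input index, row index)
    rejected: list = field(default_factory=list)  # (input index, reason)
    duplicates: list = field(default_factory=list)
    attempt_counter: int = -1
    inconsistent_rows: list = field(default_factory=list)
    missing_pivots: list = field(default_factory=list)
    n_chunks: int = 0
    n_chunks_recovered: int = 0
    file_ok: bool = False

    @property
    def chunk_recovery(self) -> float:
        return self.n_chunks_recovered / self.n_chunks if self.n_chunks else 0.0


def decode(strands, *, k: int, m: int,
           original_bit_length: int,
           adapter_fwd: str = DEFAULT_ADAPTER_FWD,
           adapter_rev: str = DEFAULT_ADAPTER_REV,
           layout: StrandLayout | None = None,
           row_capacity: int | None = None,
           partial: bool = False) -> tuple[bytes | None, DecodeReport]:
    """Recover the stored file from a (possibly damaged, unordered) strand set.

    Regenerates the generator matrix from the adapter-derived seed and the
    Times field, maps accepted strands to generator rows, and solves the
    augmented GF(2) system.  With ``partial=False`` an unsolvable system
    raises :class:`UndecodableError`; with ``partial=True`` the report
    carries the fraction of chunks recovered and the bytes are ``None``
    unless every chunk was determined.
    """
    layout = layout or StrandLayout()
    row_capacity = row_capacity or _default_row_capacity(k, m)
    seed = seed_from_adapter(adapter_fwd)
    report = DecodeReport(n_input=len(strands), n_chunks=k)
    by_row: dict[int, np.ndarray] = {}
    attempts: Counter = Counter()
    for i, seq in enumerate(strands):
        rec, reason = parse_strand(seq, layout, adapter_fwd, adapter_rev,
                                   seed=seed, row_capacity=row_capacity)
        if rec is None:
            report.rejected.append((i, reason))
            continue
        if rec.row_index in by_row or rec.row_index >= k + m:
            report.duplicates.append((i, rec.row_index))
            continue
        by_row[rec.row_index] = rec.payload_bits
        attempts[rec.attempt_counter] += 1
        report.accepted.append((i, rec.row_index))

    def fail(msg, missing):
        report.missing_pivots = list(missing)
        if partial:
            return None, report
        raise UndecodableError(msg, missing_pivots=missing)

    if len(by_row) < k:
        return fail(f"only {len(by_row)} accepted strands for K={k}", list(range(k)))
    report.attempt_counter = attempts.most_common(1)[0][0]
    gen_matrix = candidate_matrix(seed, k, m, report.attempt_counter)
    rows = sorted(by_row)
    sub = gen_matrix[rows]
    payloads = np.stack([by_row[r] for r in rows])
    if partial:
        chunks, solved, inconsistent = solve_augmented(sub, payloads, partial=True)
        report.inconsistent_rows = [rows[i] if i < len(rows) else i for i in inconsistent]
        report.n_chunks_recovered = int(solved.sum())
        if not solved.all():
            report.missing_pivots = [int(c) for c in np.flatnonzero(~solved)]
            return None, report
    else:
        try:
            chunks, inconsistent = solve_augmented(sub, payloads)
        except UndecodableError as e:
            return fail(str(e), e.missing_pivots)
        report.inconsistent_rows = list(inconsistent)
        report.n_chunks_recovered = k
    bits = chunks.reshape(-1)[:original_bit_length]
    data = np.packbits(bits).tobytes()
    report.file_ok = True
    return data, report


def density_report(n_strands: int, layout: StrandLayout | None = None,
                   stored_bits: int = 0) -> dict:
    """Bits-per-nucleotide accounting, with and without the adapters."""
    layout = layout or StrandLayout()
    if n_strands <= 0:
        raise ConfigError("n_strands must be positive")
    incl = stored_bits / (n_strands * layout.total_nt)
    excl = stored_bits / (n_strands * layout.inner_nt)
    return {
        "bits": stored_bits,
        "n_strands": n_strands,
        "nt_including_primers": n_strands * layout.total_nt,
        "nt_excluding_primers": n_strands * layout.inner_nt,
        "including_primers": incl,
        "excluding_primers": excl,
        "including_primers_2dp": round(incl, 2),
        "excluding_primers_2dp": round(excl, 2),
    }
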