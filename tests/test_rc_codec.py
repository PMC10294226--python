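"""rc_codec: segmentation, droplets, equilibrium, assembly, parsing, decode."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcdna.bioconstraints import ConstraintPolicy, passes_constraints
from rcdna.errors import (CapacityError, ConfigError, LayoutError,
                          UndecodableError)
from rcdna.gf2_engine import (GeneratorMatrix, seed_from_adapter, solve_augmented)
from rcdna.rc_codec import (DEFAULT_ADAPTER_FWD, DEFAULT_ADAPTER_REV, Droplet,
                            StrandLayout, apply_mask, assemble_strand,
                            base_indices_to_int, bases_to_bits, bits_to_bases,
                            compute_xor_check, decode, density_report, encode,
                            equilibrium_mask, int_to_base_indices, make_droplets,
                            parse_strand, random_equilibrium, segment_file)

#: relaxed run threshold keeps equilibrium searches short in unit tests
FAST_POLICY = ConstraintPolicy(max_homopolymer_run=5)


# ---------------------------------------------------------------------------
# bit/base primitives


class TestBitsBases:
    def test_paper_mapping_order(self):
        assert bits_to_bases([0, 0, 0, 1, 1, 0, 1, 1]) == "ATCG"

    def test_empty(self):
        assert bits_to_bases([]) == ""
        assert bases_to_bits("").size == 0

    def test_odd_length_rejected(self):
        with pytest.raises(LayoutError):
            bits_to_bases([1, 0, 1])

    @given(st.lists(st.integers(0, 1), min_size=0, max_size=128).filter(
        lambda b: len(b) % 2 == 0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, bits):
        np.testing.assert_array_equal(
            bases_to_bits(bits_to_bases(bits)), np.array(bits, dtype=np.uint8))

    def test_int_field_round_trip(self):
        for value in (0, 1, 63, 4095, 4 ** 6 - 1):
            assert base_indices_to_int(int_to_base_indices(value, 6)) == value

    def test_int_field_capacity(self):
        with pytest.raises(CapacityError):
            int_to_base_indices(4 ** 6, 6)


# ---------------------------------------------------------------------------
# segmentation


class TestSegmentFile:
    def test_paper_scenario_k23(self):
        data = bytes(3674)
        cs = segment_file(data, 639, bit_length=29_390)
        assert cs.k == 23
        assert cs.chunk_bits == 1278
        assert cs.original_bit_length == 29_390

    def test_exact_fit_no_padding(self, rng):
        data = rng.integers(0, 256, 160).astype(np.uint8).tobytes()
        cs = segment_file(data, 639, bit_length=1278)
        assert cs.k == 1
        np.testing.assert_array_equal(
            cs.chunks[0], np.unpackbits(np.frombuffer(data, np.uint8))[:1278])

    def test_one_extra_bit_pads_1277(self, rng):
        data = rng.integers(0, 256, 160).astype(np.uint8).tobytes()
        cs = segment_file(data, 639, bit_length=1279)
        assert cs.k == 2
        assert not cs.chunks[1][1:].any()  # 1277 zero padding bits

    def test_empty_rejected(self):
        with pytest.raises(ConfigError):
            segment_file(b"")


# ---------------------------------------------------------------------------
# droplets


def toy_generator(matrix, seed=0, attempt=0, score=1.0):
    return GeneratorMatrix(matrix=np.asarray(matrix, dtype=np.uint8),
                           seed=seed, attempt_counter=attempt, score=score)


class TestMakeDroplets:
    def test_single_one_row_copies_chunk(self, rng):
        cs = segment_file(rng.integers(0, 256, 480).astype(np.uint8).tobytes(),
                          639, bit_length=3 * 1278)
        assert cs.k == 3
        gen = toy_generator(np.eye(3))
        drops = make_droplets(cs, gen)
        for i in range(3):
            np.testing.assert_array_equal(drops[i].payload, cs.chunks[i])

    def test_row_110_xors_first_two(self, rng):
        cs = segment_file(rng.integers(0, 256, 480).astype(np.uint8).tobytes(),
                          639, bit_length=3 * 1278)
        gen = toy_generator([[1, 1, 0]])
        drops = make_droplets(cs, gen)
        np.testing.assert_array_equal(drops[0].payload, cs.chunks[0] ^ cs.chunks[1])

    def test_round_trip_through_solver(self, rng):
        cs = segment_file(rng.integers(0, 256, 6 * 160).astype(np.uint8).tobytes(), 639)
        k = cs.k
        while True:
            mat = rng.integers(0, 2, size=(k + 2, k)).astype(np.uint8)
            if mat.any(axis=1).all() and mat.any(axis=0).all():
                break
        drops = make_droplets(cs, toy_generator(mat))
        payloads = np.stack([d.payload for d in drops])
        chunks, solved, _ = solve_augmented(mat, payloads, partial=True)
        np.testing.assert_array_equal(chunks[solved], cs.chunks[solved])

    def test_dimension_mismatch(self, rng):
        cs = segment_file(b"\x01\x02", 639)
        with pytest.raises(ConfigError):
            make_droplets(cs, toy_generator(np.eye(5)))


# ---------------------------------------------------------------------------
# random equilibrium


class TestRandomEquilibrium:
    def test_passing_payload_counter_zero(self):
        seq = "ACGTACGGTCAGTCAGACGT" * 3
        balanced, c = random_equilibrium(seq, seed=1, strand_index=0)
        assert c == 0
        assert balanced == seq

    def test_failing_payload_gets_positive_counter(self, rng):
        seq = "".join("ATCG"[i] for i in rng.integers(0, 4, 120))
        balanced, c = random_equilibrium(seq, seed=1, strand_index=0,
                                         policy=FAST_POLICY)
        assert passes_constraints(balanced, FAST_POLICY)[0]
        if c:
            assert balanced != seq

    def test_mask_involution(self, rng):
        seq = "".join("ATCG"[i] for i in rng.integers(0, 4, 80))
        for c in (1, 2, 57, 4095):
            assert apply_mask(apply_mask(seq, 9, 3, c), 9, 3, c) == seq

    def test_counter_zero_is_identity(self):
        assert apply_mask("ACGT", 1, 1, 0) == "ACGT"

    def test_masks_differ_across_counters(self):
        masks = {equilibrium_mask(5, 0, c, 30).tobytes() for c in range(1, 50)}
        assert len(masks) == 49

    def test_deterministic(self, rng):
        seq = "".join("ATCG"[i] for i in rng.integers(0, 4, 100))
        a = random_equilibrium(seq, 7, 2, FAST_POLICY)
        b = random_equilibrium(seq, 7, 2, FAST_POLICY)
        assert a[1] == b[1] and a[0] == b[0]

    def test_full_policy_terminates_within_counter_space(self, rng):
        # strict run<4 / GC 45-55% search on a full-length payload
        seq = "".join("ATCG"[i] for i in rng.integers(0, 4, 645))
        balanced, c = random_equilibrium(seq, seed=11, strand_index=0)
        assert 0 <= c < 4 ** 10
        assert passes_constraints(balanced)[0]


# ---------------------------------------------------------------------------
# checksum


class TestComputeXorCheck:
    def test_all_a_folds_to_aaa(self):
        assert list(compute_xor_check("A" * 30)) == [0, 0, 0]

    def test_single_substitution_always_changes_check(self):
        rng = np.random.default_rng(3)
        region = rng.integers(0, 4, 21).astype(np.uint8)
        base_check = compute_xor_check(region)
        for pos in range(21):
            for new in range(4):
                if new == region[pos]:
                    continue
                mutated = region.copy()
                mutated[pos] = new
                assert not np.array_equal(compute_xor_check(mutated), base_check)

    @given(st.integers(0, 2 ** 32), st.integers(3, 60))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, n).astype(np.uint8)
        b = rng.integers(0, 4, n).astype(np.uint8)
        lhs = compute_xor_check(a ^ b)
        rhs = compute_xor_check(a) ^ compute_xor_check(b)
        np.testing.assert_array_equal(lhs, rhs)

    def test_short_region_zero_padded(self):
        np.testing.assert_array_equal(compute_xor_check("AT"),
                                      compute_xor_check("ATA"))


# ---------------------------------------------------------------------------
# assembly and parsing


class TestAssembleParse:
    def test_default_layout_sums_to_700(self):
        layout = StrandLayout()
        assert layout.total_nt == 700
        assert 20 + 6 + 639 + 10 + 2 + 3 + 20 == 700
        assert layout.inner_nt == 660

    def test_strand_length_and_alphabet(self, small_encoding):
        for s in small_encoding.strands:
            assert len(s) == 700
            assert set(s) <= set("ACGT")

    def test_every_strand_passes_policy(self, small_encoding):
        for s in small_encoding.strands:
            ok, reasons = passes_constraints(s, small_encoding.policy)
            assert ok, reasons

    def test_parse_round_trip_all_fields(self, small_encoding):
        seed = seed_from_adapter(small_encoding.adapter_fwd)
        for rec in small_encoding.records:
            parsed, reason = parse_strand(rec.sequence,
                                          small_encoding.layout,
                                          small_encoding.adapter_fwd,
                                          small_encoding.adapter_rev,
                                          seed=seed,
                                          row_capacity=small_encoding.row_capacity)
            assert reason is None
            assert parsed.row_index == rec.row_index
            assert parsed.attempt_counter == rec.attempt_counter
            assert parsed.eq_counter == rec.eq_counter
            assert parsed.re_eq_value == rec.re_eq_value
            np.testing.assert_array_equal(parsed.payload_bits, rec.payload_bits)

    def test_deleted_base_rejected_as_length(self, small_encoding):
        seed = seed_from_adapter(small_encoding.adapter_fwd)
        s = small_encoding.strands[0]
        damaged = s[:100] + s[101:]
        _, reason = parse_strand(damaged, small_encoding.layout,
                                 small_encoding.adapter_fwd,
                                 small_encoding.adapter_rev, seed=seed,
                                 row_capacity=small_encoding.row_capacity)
        assert reason == "length"

    def test_substitution_sweep_rejected_as_checksum(self, small_encoding):
        seed = seed_from_adapter(small_encoding.adapter_fwd)
        s = small_encoding.strands[0]
        rng = np.random.default_rng(0)
        for pos in rng.integers(20, 680, 25):
            old = s[pos]
            new = "ACGT"[("ACGT".index(old) + 1) % 4]
            damaged = s[:pos] + new + s[pos + 1:]
            _, reason = parse_strand(damaged, small_encoding.layout,
                                     small_encoding.adapter_fwd,
                                     small_encoding.adapter_rev, seed=seed,
                                     row_capacity=small_encoding.row_capacity)
            assert reason == "checksum"

    def test_missing_adapter_rejected(self, small_encoding):
        seed = seed_from_adapter(small_encoding.adapter_fwd)
        _, reason = parse_strand("ACGT" * 175, small_encoding.layout,
                                 small_encoding.adapter_fwd,
                                 small_encoding.adapter_rev, seed=seed)
        assert reason == "adapter"

    def test_assemble_oversized_droplet_rejected(self, small_encoding):
        bad = Droplet(row_index=0, payload=np.zeros(10, dtype=np.uint8))
        with pytest.raises(LayoutError):
            assemble_strand(bad, small_encoding.generator,
                            small_encoding.adapter_fwd,
                            small_encoding.adapter_rev)


# ---------------------------------------------------------------------------
# decode


class TestDecode:
    def test_intact_round_trip(self, small_encoding):
        bits = small_encoding.chunkset.original_bit_length
        data, report = decode(small_encoding.strands,
                              k=small_encoding.k, m=small_encoding.m,
                              original_bit_length=bits,
                              adapter_fwd=small_encoding.adapter_fwd,
                              adapter_rev=small_encoding.adapter_rev,
                              row_capacity=small_encoding.row_capacity)
        expected = np.packbits(small_encoding.chunkset.chunks.reshape(-1)[:bits])
        assert data == expected.tobytes()
        assert report.file_ok
        assert len(report.accepted) == small_encoding.k + small_encoding.m

    def test_leave_one_out_matches_rank_condition(self, small_encoding):
        # deleting strand j must recover exactly when the remaining rows
        # still span all chunks
        bits = small_encoding.chunkset.original_bit_length
        mat = small_encoding.generator.matrix
        n = mat.shape[0]
        expected = np.packbits(
            small_encoding.chunkset.chunks.reshape(-1)[:bits]).tobytes()
        for j in range(n):
            keep = [s for i, s in enumerate(small_encoding.strands) if i != j]
            rows = np.delete(mat, j, axis=0)
            _, solved, _ = solve_augmented(
                rows, np.zeros((n - 1, 1), dtype=np.uint8), partial=True)
            if solved.all():
                data, _ = decode(keep, k=small_encoding.k, m=small_encoding.m,
                                 original_bit_length=bits,
                                 adapter_fwd=small_encoding.adapter_fwd,
                                 adapter_rev=small_encoding.adapter_rev,
                                 row_capacity=small_encoding.row_capacity)
                assert data == expected
            else:
                with pytest.raises(UndecodableError):
                    decode(keep, k=small_encoding.k, m=small_encoding.m,
                           original_bit_length=bits,
                           adapter_fwd=small_encoding.adapter_fwd,
                           adapter_rev=small_encoding.adapter_rev,
                           row_capacity=small_encoding.row_capacity)

    def test_fewer_than_k_strands_undecodable(self, small_encoding):
        keep = small_encoding.strands[: small_encoding.k - 1]
        with pytest.raises(UndecodableError):
            decode(keep, k=small_encoding.k, m=small_encoding.m,
                   original_bit_length=small_encoding.chunkset.original_bit_length,
                   adapter_fwd=small_encoding.adapter_fwd,
                   adapter_rev=small_encoding.adapter_rev,
                   row_capacity=small_encoding.row_capacity)

    def test_order_independence(self, small_encoding):
        bits = small_encoding.chunkset.original_bit_length
        shuffled = list(reversed(small_encoding.strands))
        data, _ = decode(shuffled, k=small_encoding.k, m=small_encoding.m,
                         original_bit_length=bits,
                         adapter_fwd=small_encoding.adapter_fwd,
                         adapter_rev=small_encoding.adapter_rev,
                         row_capacity=small_encoding.row_capacity)
        expected = np.packbits(small_encoding.chunkset.chunks.reshape(-1)[:bits])
        assert data == expected.tobytes()

    def test_rejections_reported_not_fatal(self, small_encoding):
        bits = small_encoding.chunkset.original_bit_length
        strands = list(small_encoding.strands)
        strands.append(strands[0][:300] + strands[0][301:])  # indel copy
        data, report = decode(strands, k=small_encoding.k, m=small_encoding.m,
                              original_bit_length=bits,
                              adapter_fwd=small_encoding.adapter_fwd,
                              adapter_rev=small_encoding.adapter_rev,
                              row_capacity=small_encoding.row_capacity)
        assert data is not None
        assert (len(strands) - 1, "length") in report.rejected


# ---------------------------------------------------------------------------
# density


class TestDensityReport:
    def test_paper_densities(self):
        rep = density_report(25, StrandLayout(), 29_390)
        assert rep["excluding_primers_2dp"] == 1.78
        assert rep["including_primers_2dp"] == 1.68

    def test_zero_bits(self):
        rep = density_report(5, StrandLayout(), 0)
        assert rep["including_primers"] == 0.0
        assert rep["excluding_primers"] == 0.0

    def test_zero_strands_rejected(self):
        with pytest.raises(ConfigError):
            density_report(0, StrandLayout(), 100)


# ---------------------------------------------------------------------------
# end-to-end property


@pytest.mark.parametrize("model,seed", [("uniform", 5), ("zeros", 6), ("biased", 7)])
def test_end_to_end_round_trip_small(model, seed):
    from rcdna.io_cli import FixtureSpec, make_fixture

    data = make_fixture(FixtureSpec(size_bits=2 * 1278, model=model, rng_seed=seed))
    res = encode(data, m=1, search_budget=16, subset_samples=32)
    out, report = decode(res.strands, k=res.k, m=res.m,
                         original_bit_length=res.chunkset.original_bit_length,
                         adapter_fwd=res.adapter_fwd, adapter_rev=res.adapter_rev,
                         row_capacity=res.row_capacity)
    assert out[: len(data)] == data
    assert report.file_ok
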