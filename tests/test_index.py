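"""Bloom sizing, HIBF layout, build/query contracts and serialization."""

import math

import numpy as np
import pytest

from metabloom.errors import IndexFormatError, ParameterError
from metabloom.index import (IBF, IndexParams, UserBin, bloom_bits,
                             build, compute_layout, load_index, save_index)
from metabloom.sketch import MinimizerSet, SketchParams


def random_bin(target, n, rng):
    return UserBin(target, MinimizerSet(
        rng.integers(0, 2**63, size=n, dtype=np.uint64)))


class TestBloomBits:
    def test_closed_form_small_case(self):
        # n=1, p=0.5, h=1: ceil(-1 / ln(0.5)) = 2 bits
        assert bloom_bits(1, 0.5, 1) == 2

    def test_closed_form_general(self):
        expect = math.ceil(-2 * 1000 / math.log(1 - 0.05 ** 0.5))
        assert bloom_bits(1000, 0.05, 2) == expect

    def test_linear_in_n_before_ceiling(self):
        m1, m2 = bloom_bits(137, 0.03, 3), bloom_bits(274, 0.03, 3)
        assert m2 in (2 * m1 - 1, 2 * m1)

    def test_invalid_params_rejected(self):
        for bad in [(0, 0.5, 1), (10, 0.0, 1), (10, 1.0, 1), (10, 0.5, 0)]:
            with pytest.raises(ParameterError):
                bloom_bits(*bad)


class TestLayout:
    def test_similar_bins_stay_flat(self):
        rng = np.random.default_rng(0)
        bins = [random_bin(f"b{i}", 1000, rng) for i in range(20)]
        node = compute_layout(bins, t_max=64)
        assert not node.children
        assert sorted(tb.target for tb in node.tbs) == \
            sorted(b.target for b in bins)
        assert all(tb.kind == "single" for tb in node.tbs)

    def test_oversized_bin_is_split(self):
        rng = np.random.default_rng(1)
        bins = [random_bin("big", 10_000, rng)] + \
               [random_bin(f"s{i}", 1000, rng) for i in range(9)]
        node = compute_layout(bins, t_max=64)
        big_tbs = [tb for tb in node.tbs if tb.target == "big"]
        assert len(big_tbs) > 1
        assert all(tb.kind == "split" for tb in big_tbs)

    def test_overflow_bins_are_merged_with_children(self):
        rng = np.random.default_rng(2)
        bins = [random_bin(f"b{i}", 200, rng) for i in range(40)]
        node = compute_layout(bins, t_max=8)
        assert node.children  # merges are forced
        placed = node.user_bin_placements()
        assert set(placed) == {b.target for b in bins}

    def test_traversal_covers_every_bin_exactly_once(self):
        rng = np.random.default_rng(3)
        sizes = (10 ** rng.uniform(1, 3.5, size=300)).astype(int) + 1
        bins = [random_bin(f"b{i:03d}", int(n), rng)
                for i, n in enumerate(sizes)]
        node = compute_layout(bins, t_max=64)
        placed = node.user_bin_placements()
        assert set(placed) == {b.target for b in bins}
        for target, places in placed.items():
            kinds = {k for _, _, k in places}
            # one single placement, or several split parts at one level
            assert kinds == {"single"} and len(places) == 1 or \
                kinds == {"split"} and len({lv for lv, _, _ in places}) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            compute_layout([], t_max=8)


class TestBuildAndQuery:
    def test_empty_bin_rejected(self):
        with pytest.raises(ParameterError):
            build([UserBin("x", MinimizerSet())], IndexParams())

    def test_duplicate_target_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            build([random_bin("x", 10, rng), random_bin("x", 10, rng)],
                  IndexParams())

    def test_no_false_negatives_for_any_bin(self):
        rng = np.random.default_rng(4)
        bins = [random_bin(f"b{i}", int(10 ** rng.uniform(1.5, 3)), rng)
                for i in range(30)]
        hibf = build(bins, IndexParams(t_max=8))  # forces hierarchy
        for b in bins:
            counts = hibf.query(b.minimizers)
            assert counts[b.target] == b.n

    def test_empty_query_returns_no_hits(self):
        rng = np.random.default_rng(5)
        hibf = build([random_bin("b", 100, rng)], IndexParams())
        assert hibf.query(MinimizerSet()) == {}

    def test_monte_carlo_fpr_is_controlled(self):
        rng = np.random.default_rng(6)
        bins = [random_bin(f"b{i}", 2000, rng) for i in range(4)]
        hibf = build(bins, IndexParams(max_fpr=1e-4, num_hashes=3))
        probes = MinimizerSet(rng.integers(2**63, 2**64, size=10_000,
                                           dtype=np.uint64))
        counts = hibf.query(probes)  # non-members by construction
        assert sum(counts.values()) < 0.001 * 10_000 * len(bins)

    def test_counts_dominate_exact_intersection(self):
        rng = np.random.default_rng(7)
        bins = [random_bin(f"b{i}", 500, rng) for i in range(10)]
        hibf = build(bins, IndexParams(max_fpr=1e-4, t_max=4))
        universe = np.concatenate([b.minimizers.values for b in bins])
        for _ in range(50):
            q = MinimizerSet(rng.choice(universe, size=40))
            counts = hibf.query(q)
            for b in bins:
                exact = b.minimizers.intersection_count(q)
                assert counts.get(b.target, 0) >= exact

    def test_flat_hibf_equals_direct_ibf(self):
        """With one technical bin per user bin and no splits, the HIBF must
        reproduce a directly built single-level IBF bit for bit."""
        rng = np.random.default_rng(8)
        params = IndexParams(t_max=32)
        bins = [random_bin(f"b{i}", 400, rng) for i in range(12)]
        hibf = build(bins, params)
        assert not hibf.root.children

        max_n = max(b.n for b in bins)
        m = bloom_bits(max_n, params.max_fpr, params.num_hashes)
        flat = IBF(m, len(bins), params.num_hashes, params.sketch.hash_seed)
        order = sorted(bins, key=lambda b: (-b.n, b.target))
        for i, b in enumerate(order):
            flat.insert(i, b.minimizers.values)
        for _ in range(20):
            q = rng.integers(0, 2**63, size=50, dtype=np.uint64)
            direct = {order[i].target: int(c)
                      for i, c in enumerate(flat.query(np.unique(q))) if c}
            assert hibf.query(MinimizerSet(q)) == direct

    def test_sketch_mismatch_refused(self):
        rng = np.random.default_rng(9)
        hibf = build([random_bin("b", 100, rng)], IndexParams())
        with pytest.raises(ParameterError):
            hibf.check_sketch(SketchParams(k=21, w=31))


@pytest.fixture(scope="module")
def hibf():
    rng = np.random.default_rng(10)
    bins = [random_bin(f"b{i}", int(10 ** rng.uniform(1.5, 3)), rng)
            for i in range(25)]
    return build(bins, IndexParams(t_max=8, max_fpr=0.02, num_hashes=3),
                 target_taxid={f"b{i}": f"t{i}" for i in range(25)},
                 genome_sizes={f"t{i}": 1e6 for i in range(25)}), bins


class TestSerialization:

    def test_roundtrip_preserves_queries(self, hibf, tmp_path):
        idx, bins = hibf
        path = tmp_path / "x.idx"
        save_index(idx, path)
        back = load_index(path)
        rng = np.random.default_rng(11)
        universe = np.concatenate([b.minimizers.values for b in bins])
        for _ in range(100):
            q = MinimizerSet(rng.choice(universe, size=30))
            assert idx.query(q) == back.query(q)

    def test_metadata_preserved_exactly(self, hibf, tmp_path):
        idx, _ = hibf
        path = tmp_path / "x.idx"
        save_index(idx, path)
        back = load_index(path)
        assert back.params == idx.params
        assert back.user_bins == idx.user_bins
        assert back.target_taxid == idx.target_taxid
        assert back.genome_sizes == idx.genome_sizes

    def test_truncated_file_raises_format_error(self, hibf, tmp_path):
        idx, _ = hibf
        path = tmp_path / "x.idx"
        save_index(idx, path)
        data = path.read_bytes()
        trunc = tmp_path / "trunc.idx"
        trunc.write_bytes(data[:len(data) // 2])
        with pytest.raises(IndexFormatError):
            load_index(trunc)

    def test_wrong_magic_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.idx"
        bad.write_bytes(b"NOPE" + b"\x00" * 64)
        with pytest.raises(IndexFormatError):
            load_index(bad)

    def test_serialization_is_deterministic(self, hibf, tmp_path):
        idx, bins = hibf
        p1, p2 = tmp_path / "a.idx", tmp_path / "b.idx"
        save_index(idx, p1)
        rebuilt = build(bins, idx.params,
                        target_taxid=idx.target_taxid,
                        genome_sizes=idx.genome_sizes)
        save_index(rebuilt, p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_index_params_validated():
    with pytest.raises(ParameterError):
        IndexParams(max_fpr=0.0)
    with pytest.raises(ParameterError):
        IndexParams(num_hashes=0)
    with pytest.raises(ParameterError):
        IndexParams(t_max=1)
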