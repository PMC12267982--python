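"""Interleaved Bloom filter (IBF) and hierarchical IBF (HIBF) indexes.

A *user bin* is one classification target (a taxon, assembly or sequence)
with its distinct minimizer set.  An IBF holds many equally sized Bloom
filters ("technical bins") side by side so that one probe of a hash value
answers membership for every bin at once.  Technical bins within one IBF
must share a single bit length, so unbalanced reference collections waste
space in a flat IBF; the HIBF fixes this by *splitting* large user bins
across several technical bins and *merging* small user bins into shared
technical bins, each merged bin backed by a child IBF that resolves its
members — recursively, forming a hierarchy.

The layout here is a deterministic greedy procedure (sort by cardinality,
split bins above the per-bin capacity, merge the smallest overflow bins);
the compatibility surface is the query contract: per-user-bin shared-value
counts with no false negatives and Bloom-bounded false positives.

Bloom filters are sized from the maximum false-positive rate ``p`` and hash
count ``h`` by the standard model: ``m = ceil(-h * n / ln(1 - p**(1/h)))``.
"""

from __future__ import annotations

import json
import math
import os
import struct
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import IndexFormatError, ParameterError
from .sketch import MinimizerSet, SketchParams, splitmix64
from .taxonomy import TaxonomyTree

_U64 = np.uint64
_MAGIC = b"MBIX"
_FORMAT_VERSION = 1


@dataclass(frozen=True)
class IndexParams:
    """Index construction parameters.

    max_fpr
        Per-user-bin Bloom false-positive probability, in (0, 1).
    num_hashes
        Bloom hash functions per filter (h >= 1).
    t_max
        Technical bins per IBF level (>= 2).
    sketch
        k-mer / window / seed parameters shared by build and query.
    """

    max_fpr: float = 0.05
    num_hashes: int = 4
    t_max: int = 64
    sketch: SketchParams = field(default_factory=SketchParams)

    def __post_init__(self):
        if not 0.0 < self.max_fpr < 1.0:
            raise ParameterError(f"max_fpr must be in (0,1), got {self.max_fpr}")
        if self.num_hashes < 1:
            raise ParameterError("num_hashes must be >= 1")
        if self.t_max < 2:
            raise ParameterError("t_max must be >= 2")


@dataclass(frozen=True)
class UserBin:
    """One indexed target and its minimizer content."""

    target: str
    minimizers: MinimizerSet

    @property
    def n(self) -> int:
        return self.minimizers.cardinality


def bloom_bits(n: int, p: float, h: int) -> int:
    """Smallest Bloom filter bit count with predicted FPR <= p for n
    elements and h hash functions."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not 0.0 < p < 1.0:
        raise ParameterError(f"max_fpr must be in (0,1), got {p}")
    if h < 1:
        raise ParameterError("h must be >= 1")
    return math.ceil(-h * n / math.log(1.0 - p ** (1.0 / h)))


class IBF:
    """One interleaved Bloom filter: ``bins`` filters of ``m`` bits each.

    Bits are held as a boolean matrix of shape (m, bins): row ``j`` is bit
    position ``j`` of every technical bin, i.e. the interleaved order — one
    row gather answers a hash probe for all bins simultaneously.
    """

    def __init__(self, m: int, bins: int, h: int, seed: int,
                 bits: np.ndarray | None = None):
        self.m = int(m)
        self.bins = int(bins)
        self.h = int(h)
        self.seed = int(seed)
        if bits is None:
            bits = np.zeros((self.m, self.bins), dtype=bool)
        self.bits = bits
        base = (np.arange(1, h + 1, dtype=_U64) * _U64(0x9E3779B97F4A7C15))
        with np.errstate(over="ignore"):
            base = base + _U64(seed)
        self._hash_seeds = splitmix64(base)

    def _positions(self, values: np.ndarray) -> np.ndarray:
        v = values.astype(_U64, copy=False)[:, None] ^ self._hash_seeds[None, :]
        return (splitmix64(v) % _U64(self.m)).astype(np.int64)

    def insert(self, tb: int, values: np.ndarray) -> None:
        if values.size:
            pos = self._positions(values)
            self.bits[pos.ravel(), tb] = True

    def query(self, values: np.ndarray) -> np.ndarray:
        """Shared-value count per technical bin (vector of length bins)."""
        if values.size == 0:
            return np.zeros(self.bins, dtype=np.int64)
        pos = self._positions(values)          # (nv, h)
        member = self.bits[pos]                # (nv, h, bins)
        return member.all(axis=1).sum(axis=0, dtype=np.int64)


@dataclass
class TechnicalBin:
    """Content descriptor of one technical bin inside a layout level."""

    kind: str                      # "single" | "split" | "merged"
    target: str | None = None      # single / split
    part: int | None = None        # split part index
    members: list[str] | None = None  # merged: user bins resolved below


class LayoutNode:
    """One IBF level of the hierarchy: technical bins plus child levels."""

    def __init__(self):
        self.tbs: list[TechnicalBin] = []
        self.children: dict[int, "LayoutNode"] = {}
        self.contents: list[np.ndarray] | None = []  # build-time values
        self.ibf: IBF | None = None

    def user_bin_placements(self, _level: int = 0) -> dict[str, list[tuple]]:
        """target -> [(level, tb_index, kind), ...] over the whole subtree."""
        out: dict[str, list[tuple]] = {}
        for i, tb in enumerate(self.tbs):
            if tb.kind in ("single", "split"):
                out.setdefault(tb.target, []).append((_level, i, tb.kind))
        for i, child in self.children.items():
            for t, places in child.user_bin_placements(_level + 1).items():
                out.setdefault(t, []).extend(places)
        return out


def compute_layout(user_bins: Iterable[UserBin], t_max: int) -> LayoutNode:
    """Greedy HIBF layout.

    Bins are sorted by cardinality (descending).  The per-technical-bin
    capacity is ``ceil(total_n / min(t_max, B))`` for B bins: with bins of
    similar size this degenerates to one technical bin per user bin.  A bin
    above capacity is split across ``ceil(n / capacity)`` technical bins,
    its sorted minimizer values dealt round-robin.  If the remaining bins
    outnumber the free technical bins, the smallest are merged into shared
    technical bins, each spawning a recursively laid-out child level.
    """
    bins = sorted(user_bins, key=lambda b: (-b.n, b.target))
    if not bins:
        raise ParameterError("layout requires at least one user bin")
    total = sum(b.n for b in bins)
    cap = math.ceil(total / min(t_max, len(bins)))
    while True:
        split_bins = [b for b in bins if b.n > cap]
        n_split_tbs = sum(math.ceil(b.n / cap) for b in split_bins)
        rest = [b for b in bins if b.n <= cap]
        if n_split_tbs + (1 if rest else 0) <= t_max:
            break
        cap *= 2  # pathological imbalance: coarsen until the level fits

    node = LayoutNode()
    for b in split_bins:
        parts = math.ceil(b.n / cap)
        vals = b.minimizers.values
        for j in range(parts):
            node.tbs.append(TechnicalBin("split", target=b.target, part=j))
            node.contents.append(vals[j::parts])
    free = t_max - len(node.tbs)

    if len(rest) <= free:
        singles, groups = rest, []
    else:
        # merged technical bins: as few as possible while keeping each
        # child level at most t_max members (bounds recursion depth)
        n_merged = max(1, math.ceil((len(rest) - free) / (t_max - 1)))
        n_merged = min(n_merged, free)
        singles = rest[:free - n_merged]
        small = rest[free - n_merged:]
        groups = [[] for _ in range(n_merged)]
        for i, b in enumerate(reversed(small)):  # smallest first, round-robin
            groups[i % n_merged].append(b)

    for b in singles:
        node.tbs.append(TechnicalBin("single", target=b.target))
        node.contents.append(b.minimizers.values)
    for grp in groups:
        idx = len(node.tbs)
        union = np.unique(np.concatenate([b.minimizers.values for b in grp]))
        node.tbs.append(TechnicalBin(
            "merged", members=sorted(b.target for b in grp)))
        node.contents.append(union)
        node.children[idx] = compute_layout(grp, t_max)
    return node


class HIBF:
    """Hierarchy of IBFs answering per-user-bin shared-minimizer counts.

    Also carries the sample-independent metadata classification and
    reporting need: the target -> taxid map, estimated genome sizes, and
    (optionally) the taxonomy itself.
    """

    def __init__(self, params: IndexParams, root: LayoutNode,
                 user_bins: Mapping[str, int],
                 target_taxid: Mapping[str, str] | None = None,
                 genome_sizes: Mapping[str, float] | None = None,
                 taxonomy: TaxonomyTree | None = None):
        self.params = params
        self.root = root
        self.user_bins = dict(user_bins)       # target -> cardinality
        self.target_taxid = dict(target_taxid or {})
        self.genome_sizes = dict(genome_sizes or {})
        self.taxonomy = taxonomy

    def check_sketch(self, sketch: SketchParams) -> None:
        if sketch != self.params.sketch:
            raise ParameterError(
                "query sketch parameters do not match the index "
                f"({sketch} != {self.params.sketch})")

    def query(self, q: MinimizerSet | np.ndarray) -> dict[str, int]:
        """Shared-count per user-bin target; absent targets share nothing."""
        values = q.values if isinstance(q, MinimizerSet) else np.asarray(q, _U64)
        counts: dict[str, int] = {}
        if values.size:
            self._query_node(self.root, values, counts)
            # summing split parts can double-count a value through a Bloom
            # false positive in a sibling part; a count never exceeds the
            # query cardinality
            q_card = int(values.size)
            for t, c in counts.items():
                if c > q_card:
                    counts[t] = q_card
        return counts

    def _query_node(self, node: LayoutNode, values: np.ndarray,
                    out: dict[str, int]) -> None:
        tb_counts = node.ibf.query(values)
        for i, tb in enumerate(node.tbs):
            c = int(tb_counts[i])
            if c == 0:
                continue
            if tb.kind == "merged":
                # positive count on a merged bin only gates descent; counts
                # are reported at user-bin resolution in the child level
                self._query_node(node.children[i], values, out)
            else:
                out[tb.target] = out.get(tb.target, 0) + c


def build(user_bins: Iterable[UserBin], params: IndexParams,
          target_taxid: Mapping[str, str] | None = None,
          genome_sizes: Mapping[str, float] | None = None,
          taxonomy: TaxonomyTree | None = None) -> HIBF:
    """Lay out and populate an HIBF over the given user bins."""
    bins = list(user_bins)
    seen = set()
    for b in bins:
        if b.n < 1:
            raise ParameterError(f"user bin {b.target} has no minimizers")
        if b.target in seen:
            raise ParameterError(f"duplicate user bin target {b.target}")
        seen.add(b.target)
    root = compute_layout(bins, params.t_max)
    _build_node(root, params)
    return HIBF(params, root, {b.target: b.n for b in bins},
                target_taxid=target_taxid, genome_sizes=genome_sizes,
                taxonomy=taxonomy)


def _build_node(node: LayoutNode, params: IndexParams) -> None:
    max_n = max(len(c) for c in node.contents)
    m = bloom_bits(max_n, params.max_fpr, params.num_hashes)
    node.ibf = IBF(m, len(node.tbs), params.num_hashes,
                   params.sketch.hash_seed)
    for i, vals in enumerate(node.contents):
        node.ibf.insert(i, vals)
    node.contents = None  # raw values are not retained after construction
    for child in node.children.values():
        _build_node(child, params)


# -- serialization -------------------------------------------------------

def _node_header(node: LayoutNode) -> dict:
    return {
        "m": node.ibf.m,
        "bins": node.ibf.bins,
        "tbs": [[tb.kind, tb.target, tb.part, tb.members] for tb in node.tbs],
        "children": {str(i): _node_header(c) for i, c in node.children.items()},
    }


def _node_blobs(node: LayoutNode, blobs: list[bytes]) -> None:
    blobs.append(np.packbits(node.ibf.bits, axis=None).tobytes())
    for i in sorted(node.children):
        _node_blobs(node.children[i], blobs)


def save_index(hibf: HIBF, path: str | os.PathLike) -> None:
    """Write the index: magic, version, JSON header, then packed bit arrays
    of every IBF level in depth-first order."""
    header = {
        "params": {
            "max_fpr": hibf.params.max_fpr,
            "num_hashes": hibf.params.num_hashes,
            "t_max": hibf.params.t_max,
            "k": hibf.params.sketch.k,
            "w": hibf.params.sketch.w,
            "hash_seed": hibf.params.sketch.hash_seed,
        },
        "user_bins": hibf.user_bins,
        "target_taxid": hibf.target_taxid,
        "genome_sizes": hibf.genome_sizes,
        "taxonomy": hibf.taxonomy.to_records() if hibf.taxonomy else None,
        "root": _node_header(hibf.root),
    }
    blob = json.dumps(header, sort_keys=True).encode()
    blobs: list[bytes] = []
    _node_blobs(hibf.root, blobs)
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<BQ", _FORMAT_VERSION, len(blob)))
        fh.write(blob)
        for b in blobs:
            fh.write(b)


def build_from_references(fasta_paths, target_map: Mapping[str, tuple[str, str]],
                          taxonomy: TaxonomyTree,
                          params: IndexParams) -> HIBF:
    """Build an index from reference FASTA file(s) and a target map.

    ``target_map`` maps sequence id -> (target, taxid); sequences of one
    target are sketched into a single user bin.  Genome sizes are taken as
    the total sequence length per target and propagated over the taxonomy.
    """
    from . import _io
    from .sketch import minimizers
    from .taxonomy import estimate_genome_sizes

    if isinstance(fasta_paths, (str, os.PathLike)):
        fasta_paths = [fasta_paths]
    values: dict[str, list[np.ndarray]] = {}
    lengths: dict[str, int] = {}
    for path in fasta_paths:
        for seq_id, seq in _io.iter_fasta(path):
            if seq_id not in target_map:
                raise ParameterError(f"sequence {seq_id} missing from target map")
            target, _ = target_map[seq_id]
            values.setdefault(target, []).append(
                minimizers(seq, params.sketch).values)
            lengths[target] = lengths.get(target, 0) + len(seq)
    if not values:
        raise ParameterError("no reference sequences found")
    target_taxid = {t: tx for t, tx in target_map.values()}
    bins = [UserBin(t, MinimizerSet(np.concatenate(v)))
            for t, v in sorted(values.items())]
    sizes = estimate_genome_sizes(taxonomy, lengths, target_taxid)
    return build(bins, params, target_taxid=target_taxid,
                 genome_sizes=sizes, taxonomy=taxonomy)


def _read_exact(fh, n: int) -> bytes:
    data = fh.read(n)
    if len(data) != n:
        raise IndexFormatError("truncated index file")
    return data


def _load_node(header: dict, fh, params: IndexParams) -> LayoutNode:
    node = LayoutNode()
    node.contents = None
    node.tbs = [TechnicalBin(kind, target=target, part=part, members=members)
                for kind, target, part, members in header["tbs"]]
    m, bins = int(header["m"]), int(header["bins"])
    nbytes = (m * bins + 7) // 8
    raw = np.frombuffer(_read_exact(fh, nbytes), dtype=np.uint8)
    bits = np.unpackbits(raw, count=m * bins).reshape(m, bins).astype(bool)
    node.ibf = IBF(m, bins, params.num_hashes, params.sketch.hash_seed,
                   bits=bits)
    for i in sorted(header["children"], key=int):
        node.children[int(i)] = _load_node(header["children"][i], fh, params)
    return node


def load_index(path: str | os.PathLike) -> HIBF:
    with open(path, "rb") as fh:
        if _read_exact(fh, 4) != _MAGIC:
            raise IndexFormatError(f"{path}: not a metabloom index")
        version, hlen = struct.unpack("<BQ", _read_exact(fh, 9))
        if version != _FORMAT_VERSION:
            raise IndexFormatError(f"unsupported index version {version}")
        try:
            header = json.loads(_read_exact(fh, hlen))
        except json.JSONDecodeError as e:
            raise IndexFormatError(f"corrupt index header: {e}") from e
        p = header["params"]
        params = IndexParams(
            max_fpr=p["max_fpr"], num_hashes=p["num_hashes"],
            t_max=p["t_max"],
            sketch=SketchParams(k=p["k"], w=p["w"], hash_seed=p["hash_seed"]))
        root = _load_node(header["root"], fh, params)
        tax = (TaxonomyTree.from_records(header["taxonomy"])
               if header["taxonomy"] else None)
        return HIBF(params, root, header["user_bins"],
                    target_taxid=header["target_taxid"],
                    genome_sizes=header["genome_sizes"], taxonomy=tax)
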