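"""Taxonomic trees: loading, lineage/LCA queries, and genome-size estimation.

A :class:`TaxonomyTree` is a rooted tree of taxa.  Each node carries a rank
(free string; no fixed ladder is enforced, so NCBI, GTDB and custom
taxonomies are all representable) and a name.  Input is auto-detected as
either the NCBI ``nodes.dmp``/``names.dmp`` dialect (fields separated by
``\\t|\\t``) or a plain tab-separated table with columns
``taxid, parent, rank[, name]``.

Genome sizes per taxon are estimated as the arithmetic mean of the total
assembly lengths found in the taxon's subtree; taxa without any descendant
assembly inherit the nearest ancestor's estimate.  These sizes later convert
read counts (sequence abundance) into organism fractions (taxonomic
abundance).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import TaxonomyError


@dataclass(frozen=True)
class TaxNode:
    """One taxon: identifier, parent identifier, rank and display name."""

    taxid: str
    parent: str
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy supporting lineage, LCA and rank-ancestor queries.

    The root is the unique node whose parent is itself (NCBI convention,
    taxid ``1``) or whose parent is absent from the table.
    """

    def __init__(self, nodes: Mapping[str, TaxNode]):
        self.nodes: dict[str, TaxNode] = dict(nodes)
        self.root = self._find_root()
        self._depth: dict[str, int] = {}
        self._validate()
        self._children: dict[str, list[str]] | None = None

    def _find_root(self) -> str:
        roots = [n.taxid for n in self.nodes.values()
                 if n.parent == n.taxid or n.parent not in self.nodes]
        if len(roots) != 1:
            raise TaxonomyError(
                f"expected exactly one root, found {len(roots)}: {roots[:5]}")
        return roots[0]

    def _validate(self) -> None:
        # Walk every node to the root once, memoizing depth; a revisit of a
        # node on the current path is a cycle, a missing parent is dangling.
        depth = self._depth
        depth[self.root] = 0
        for start in self.nodes:
            path = []
            t = start
            while t not in depth:
                path.append(t)
                p = self.nodes[t].parent
                if p == t:
                    raise TaxonomyError(f"secondary root at taxid {t}")
                if p not in self.nodes:
                    raise TaxonomyError(f"dangling parent {p} of taxid {t}")
                if p in path:
                    raise TaxonomyError(f"cycle detected at taxid {p}")
                t = p
            base = depth[t]
            for i, u in enumerate(reversed(path)):
                depth[u] = base + i + 1

    # -- queries ---------------------------------------------------------

    def __contains__(self, taxid: str) -> bool:
        return taxid in self.nodes

    def parent(self, taxid: str) -> str:
        return self.nodes[taxid].parent

    def depth(self, taxid: str) -> int:
        return self._depth[taxid]

    def lineage(self, taxid: str) -> list[str]:
        """Taxids from the root down to (and including) ``taxid``."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        out = []
        t = taxid
        while t != self.root:
            out.append(t)
            t = self.nodes[t].parent
        out.append(self.root)
        out.reverse()
        return out

    def lca(self, taxids: Iterable[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxids."""
        ids = list(taxids)
        if not ids:
            raise TaxonomyError("lca of an empty set")
        for t in ids:
            if t not in self.nodes:
                raise TaxonomyError(f"unknown taxid {t}")
        cur = ids[0]
        for t in ids[1:]:
            cur = self._lca_pair(cur, t)
            if cur == self.root:
                break
        return cur

    def _lca_pair(self, a: str, b: str) -> str:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self.nodes[a].parent
            da -= 1
        while db > da:
            b = self.nodes[b].parent
            db -= 1
        while a != b:
            a = self.nodes[a].parent
            b = self.nodes[b].parent
        return a

    def rank_ancestor(self, taxid: str, rank: str) -> str | None:
        """The ancestor (or the node itself) at ``rank``, or None if the
        lineage has no node of that rank."""
        if taxid not in self.nodes:
            raise TaxonomyError(f"unknown taxid {taxid}")
        t = taxid
        while True:
            if self.nodes[t].rank == rank:
                return t
            if t == self.root:
                return None
            t = self.nodes[t].parent

    def children(self, taxid: str) -> list[str]:
        if self._children is None:
            ch: dict[str, list[str]] = {t: [] for t in self.nodes}
            for n in self.nodes.values():
                if n.taxid != self.root:
                    ch[n.parent].append(n.taxid)
            for lst in ch.values():
                lst.sort()
            self._children = ch
        return self._children[taxid]

    def postorder(self) -> list[str]:
        """Taxids with every node after all of its descendants."""
        order = sorted(self.nodes, key=lambda t: self._depth[t], reverse=True)
        return order

    def name(self, taxid: str) -> str:
        return self.nodes[taxid].name

    def rank(self, taxid: str) -> str:
        return self.nodes[taxid].rank

    # -- serialization ---------------------------------------------------

    def write_tsv(self, path: str | os.PathLike) -> None:
        """Write the internal 4-column table (taxid, parent, rank, name)."""
        with open(path, "w") as fh:
            for t in sorted(self.nodes):
                n = self.nodes[t]
                fh.write(f"{n.taxid}\t{n.parent}\t{n.rank}\t{n.name}\n")

    def to_records(self) -> list[tuple[str, str, str, str]]:
        return [(n.taxid, n.parent, n.rank, n.name)
                for n in sorted(self.nodes.values(), key=lambda n: n.taxid)]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str, str]]
                     ) -> "TaxonomyTree":
        nodes = {r[0]: TaxNode(r[0], r[1], r[2], r[3]) for r in records}
        return cls(nodes)


def _as_lines(source) -> Iterable[str]:
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            yield from fh
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        yield from source
    else:  # iterable of lines
        yield from source


def _split_row(line: str) -> list[str]:
    line = line.rstrip("\n")
    if "\t|" in line:  # NCBI dmp dialect: fields separated by "\t|\t"
        line = line.rstrip("|").rstrip("\t")
        return [f.strip() for f in line.split("\t|\t")]
    return line.split("\t")


def load_taxonomy(nodes_source, names_source=None) -> TaxonomyTree:
    """Build a validated :class:`TaxonomyTree` from tabular sources.

    ``nodes_source`` rows must provide taxid, parent and rank in the first
    three columns (NCBI ``nodes.dmp`` or plain TSV).  ``names_source`` may
    supply names (``names.dmp`` keeps only ``scientific name`` rows; a plain
    2+-column TSV maps taxid to name); absent, names default to the taxid.
    """
    nodes: dict[str, TaxNode] = {}
    for line in _as_lines(nodes_source):
        if not line.strip():
            continue
        fields = _split_row(line)
        if len(fields) < 3:
            raise TaxonomyError(f"nodes row with <3 columns: {line!r}")
        taxid, parent, rank = fields[0], fields[1], fields[2]
        name = fields[3] if len(fields) > 3 and "|" not in line else taxid
        nodes[taxid] = TaxNode(taxid, parent, rank, name)
    if not nodes:
        raise TaxonomyError("empty nodes source")

    if names_source is not None:
        names: dict[str, str] = {}
        for line in _as_lines(names_source):
            if not line.strip():
                continue
            fields = _split_row(line)
            if len(fields) >= 4:  # names.dmp: taxid | name | unique | class
                if fields[3] == "scientific name":
                    names[fields[0]] = fields[1]
            elif len(fields) >= 2:
                names[fields[0]] = fields[1]
        for t, nm in names.items():
            if t in nodes:
                n = nodes[t]
                nodes[t] = TaxNode(n.taxid, n.parent, n.rank, nm)
    return TaxonomyTree(nodes)


def estimate_genome_sizes(tree: TaxonomyTree,
                          assembly_sizes: Mapping[str, float],
                          target_taxid: Mapping[str, str] | None = None,
                          ) -> dict[str, float]:
    """Approximate genome size (bp) for every taxon in the tree.

    ``assembly_sizes`` maps an assembly/target identifier to its total
    sequence length; identifiers are resolved to taxids through
    ``target_taxid`` when given, otherwise they must be taxids themselves.
    A taxon's size is the mean over all assemblies in its subtree; taxa with
    no descendant assembly inherit the nearest ancestor's estimate.
    """
    if not assembly_sizes:
        raise TaxonomyError("no assembly sizes to estimate from")
    acc_sum: dict[str, float] = {t: 0.0 for t in tree.nodes}
    acc_n: dict[str, int] = {t: 0 for t in tree.nodes}
    for asm, size in assembly_sizes.items():
        if size <= 0:
            raise TaxonomyError(f"non-positive assembly size for {asm}")
        taxid = target_taxid.get(asm, asm) if target_taxid else asm
        if taxid not in tree.nodes:
            raise TaxonomyError(f"assembly {asm} maps to unknown taxid {taxid}")
        acc_sum[taxid] += float(size)
        acc_n[taxid] += 1
    # accumulate subtree sums bottom-up
    for t in tree.postorder():
        if t != tree.root:
            p = tree.parent(t)
            acc_sum[p] += acc_sum[t]
            acc_n[p] += acc_n[t]
    sizes: dict[str, float] = {}
    if acc_n[tree.root] == 0:
        raise TaxonomyError("no assembly attached anywhere in the tree")
    # top-down: mean of subtree, inheriting from parent where subtree is empty
    for t in sorted(tree.nodes, key=tree.depth):
        if acc_n[t] > 0:
            sizes[t] = acc_sum[t] / acc_n[t]
        else:
            sizes[t] = sizes[tree.parent(t)]
    return sizes
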