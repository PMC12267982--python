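"""Shared fixtures: small taxonomies, random trees, and a compact
simulated community with its index."""

import numpy as np
import pytest

from metabloom.index import IndexParams, UserBin, build
from metabloom.simulate import (CommunitySpec, random_taxonomy,
                                simulate_community, simulate_reads)
from metabloom.sketch import MinimizerSet, minimizers
from metabloom.taxonomy import TaxNode, TaxonomyTree


@pytest.fixture(scope="session")
def ladder_tree():
    """Tiny fixed-ladder tree: two species in one genus, one in another."""
    rows = [
        ("1", "1", "no rank", "root"),
        ("sk0", "1", "superkingdom", "sk0"),
        ("ph0", "sk0", "phylum", "ph0"),
        ("cl0", "ph0", "class", "cl0"),
        ("or0", "cl0", "order", "or0"),
        ("fa0", "or0", "family", "fa0"),
        ("ge0", "fa0", "genus", "ge0"),
        ("ge1", "fa0", "genus", "ge1"),
        ("spA", "ge0", "species", "A"),
        ("spB", "ge0", "species", "B"),
        ("spC", "ge1", "species", "C"),
    ]
    return TaxonomyTree({r[0]: TaxNode(*r) for r in rows})


@pytest.fixture(scope="session")
def random_tree():
    return random_taxonomy(500, seed=42)


def brute_force_lca(tree, taxids):
    """Oracle: intersect full ancestor sets, take the deepest."""
    common = None
    for t in taxids:
        anc = set(tree.lineage(t))
        common = anc if common is None else common & anc
    return max(common, key=tree.depth)


@pytest.fixture(scope="session")
def community():
    """10-species error-free paired community with its species-level index."""
    spec = CommunitySpec(n_species=10, genome_length=(40_000, 80_000),
                         n_reads=500, error_rate=0.0, seed=5)
    com = simulate_community(spec)
    reads = simulate_reads(com)
    return com, reads


@pytest.fixture(scope="session")
def community_index(community):
    com, _ = community
    params = IndexParams()
    per_species = {}
    for asm, seq in com.genomes.items():
        per_species.setdefault(com.genome_taxid[asm], []).append(
            minimizers(seq, params.sketch).values)
    bins = [UserBin(t, MinimizerSet(np.concatenate(v)))
            for t, v in sorted(per_species.items())]
    return build(bins, params, target_taxid={t: t for t in per_species},
                 genome_sizes=com.genome_sizes(), taxonomy=com.tree)
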