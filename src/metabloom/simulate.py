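"""Synthetic communities: genomes, strains, taxonomies, reads, and truth.

The simulator emulates the structure of short-read mock-community samples:
multiple species with i.i.d. uniform-ACGT genomes of unbalanced lengths,
optional near-identical strains at a controlled per-base divergence, a
known abundance vector, and error-bearing single or paired 150 bp-style
reads with an exact per-read ground truth.

Reads are drawn per genome proportionally to *abundance × genome length*
(sequence abundance); the genome-size-corrected taxonomic truth profile is
derived from the realized per-read truth through the same correction code
path used for reporting, so the two bookkeeping conventions stay
consistent by construction.  Sequencing errors are independent base
substitutions (no indels) — sufficient to stress exact k-mer matching.

Every output is deterministic under the configured seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _io, report
from .errors import ParameterError
from .reassign import Assignment
from .sketch import reverse_complement
from .taxonomy import TaxonomyTree, TaxNode, estimate_genome_sizes

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

RANK_LADDER = ("superkingdom", "phylum", "class", "order", "family",
               "genus", "species")
_RANK_PREFIX = ("sk", "ph", "cl", "or", "fa", "ge", "sp")


@dataclass(frozen=True)
class CommunitySpec:
    """Conditions of one synthetic community and its sequencing run."""

    n_species: int = 20
    genome_length: tuple[int, int] = (50_000, 150_000)
    strains_per_species: int = 1
    strain_divergence: float = 0.02
    abundances: tuple[float, ...] | None = None  # per species or per genome
    read_length: int = 150
    n_reads: int = 2_000
    error_rate: float = 0.01
    paired: bool = True
    insert_size: int = 300
    seed: int = 7

    def __post_init__(self):
        if self.n_species < 1:
            raise ParameterError("n_species must be >= 1")
        lo, hi = self.genome_length
        if not 1 <= lo <= hi:
            raise ParameterError("invalid genome_length range")
        for name in ("strain_divergence", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0,1]")
        if self.abundances is not None:
            n = len(self.abundances)
            if n not in (self.n_species,
                         self.n_species * self.strains_per_species):
                raise ParameterError(
                    "abundances must have one entry per species or per genome")
            if abs(sum(self.abundances) - 1.0) > 1e-9:
                raise ParameterError("abundances must sum to 1")
        if self.paired and self.insert_size < self.read_length:
            raise ParameterError("insert_size must be >= read_length")


@dataclass
class Community:
    """Genomes plus the taxonomy and maps needed to index and score them."""

    spec: CommunitySpec
    tree: TaxonomyTree
    genomes: dict[str, str]            # assembly id -> sequence
    genome_taxid: dict[str, str]       # assembly id -> species taxid
    abundances: dict[str, float]       # assembly id -> organism fraction

    @property
    def assembly_ids(self) -> list[str]:
        return list(self.genomes)

    def genome_sizes(self) -> dict[str, float]:
        """Per-taxon genome sizes estimated exactly as reporting does."""
        lengths = {a: len(s) for a, s in self.genomes.items()}
        return estimate_genome_sizes(self.tree, lengths, self.genome_taxid)


def _ladder_taxonomy(n_species: int) -> TaxonomyTree:
    """Fixed-ladder taxonomy: species i hangs under genus i//2, family
    i//4, ... superkingdom i//64 (so nearby species share low ranks)."""
    nodes = {"1": TaxNode("1", "1", "no rank", "root")}
    for i in range(n_species):
        idx = i
        chain = [("species", f"sp{i}")]
        for level in range(len(RANK_LADDER) - 2, -1, -1):
            idx //= 2  # halve group index at every step up the ladder
            chain.append((RANK_LADDER[level], f"{_RANK_PREFIX[level]}{idx}"))
        prev = "1"
        for rank, taxid in reversed(chain):
            if taxid not in nodes:
                nodes[taxid] = TaxNode(taxid, prev, rank, taxid)
            prev = taxid
    return TaxonomyTree(nodes)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def mutate_genome(seq: str, divergence: float, seed: int) -> str:
    """Substitute each base independently (always to a different base)
    with probability ``divergence``; deterministic under ``seed``."""
    if not 0.0 <= divergence <= 1.0:
        raise ParameterError("divergence must be in [0,1]")
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    idx = lut[codes]
    hit = rng.random(codes.size) < divergence
    shift = rng.integers(1, 4, size=codes.size).astype(np.uint8)
    new_idx = (idx + shift) % 4
    codes[hit] = _BASES[new_idx[hit]]
    return codes.tobytes().decode("ascii")


def _per_genome_abundances(spec: CommunitySpec,
                           rng: np.random.Generator) -> np.ndarray:
    s = spec.strains_per_species
    if spec.abundances is None:
        # log-normal species abundances: the long-tailed composition
        # typical of mock and environmental communities
        species_ab = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_species)
        species_ab /= species_ab.sum()
    else:
        ab = np.asarray(spec.abundances, dtype=float)
        if ab.size == spec.n_species * s:
            return ab / ab.sum()
        species_ab = ab
    return np.repeat(species_ab / s, s)


def simulate_community(spec: CommunitySpec) -> Community:
    """Genomes, strains, taxonomy, target map and abundances for one
    community; byte-identical across runs with the same spec."""
    rng = np.random.default_rng(spec.seed)
    tree = _ladder_taxonomy(spec.n_species)
    genomes: dict[str, str] = {}
    genome_taxid: dict[str, str] = {}
    lo, hi = spec.genome_length
    for i in range(spec.n_species):
        length = int(rng.integers(lo, hi + 1))
        base = random_sequence(length, rng)
        for s in range(spec.strains_per_species):
            asm = f"asm_sp{i}_{s}"
            # strain 0 is the base genome; others diverge from it at the
            # requested per-base rate
            seq = base if s == 0 else mutate_genome(
                base, spec.strain_divergence,
                seed=int(rng.integers(0, 2**31)))
            genomes[asm] = seq
            genome_taxid[asm] = f"sp{i}"
    ab = _per_genome_abundances(spec, rng)
    abundances = dict(zip(genomes, ab))
    return Community(spec, tree, genomes, genome_taxid, abundances)


@dataclass
class ReadSet:
    """Simulated reads plus exact binning and profiling ground truth."""

    reads: list[tuple[str, str, str | None]]  # (read_id, seq1, seq2|None)
    truth_binning: pd.DataFrame               # read_id, target, taxid
    truth_profile: report.Profile

    @property
    def paired(self) -> bool:
        return self.reads[0][2] is not None if self.reads else False


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i
    hit = rng.random(codes.size) < rate
    shift = rng.integers(1, 4, size=codes.size).astype(np.uint8)
    codes[hit] = _BASES[(lut[codes[hit]] + shift[hit]) % 4]
    return codes.tobytes().decode("ascii")


def simulate_reads(community: Community,
                   spec: CommunitySpec | None = None) -> ReadSet:
    """Draw reads with substitution errors and record exact truth tables.

    Source genomes are drawn by abundance × genome length; fragment
    positions are uniform; mates come from opposite strands at the insert
    distance.
    """
    spec = spec or community.spec
    rng = np.random.default_rng(spec.seed + 1)
    asm_ids = community.assembly_ids
    lengths = np.array([len(community.genomes[a]) for a in asm_ids])
    span = spec.insert_size if spec.paired else spec.read_length
    if (lengths < span).any():
        raise ParameterError("read span exceeds a genome length")
    ab = np.array([community.abundances[a] for a in asm_ids])
    p = ab * lengths
    p /= p.sum()
    counts = rng.multinomial(spec.n_reads, p)

    reads: list[tuple[str, str, str | None]] = []
    truth_rows = []
    ridx = 0
    for a, cnt in zip(asm_ids, counts):
        g = community.genomes[a]
        starts = rng.integers(0, len(g) - span + 1, size=cnt)
        for s in starts:
            rid = f"r{ridx}"
            ridx += 1
            if spec.paired:
                frag = g[s:s + spec.insert_size]
                r1 = frag[:spec.read_length]
                r2 = reverse_complement(frag[-spec.read_length:])
            else:
                r1, r2 = g[s:s + spec.read_length], None
            r1 = _apply_errors(r1, spec.error_rate, rng)
            if r2 is not None:
                r2 = _apply_errors(r2, spec.error_rate, rng)
            reads.append((rid, r1, r2))
            truth_rows.append((rid, a, community.genome_taxid[a]))
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth_rows = [truth_rows[i] for i in order]
    truth = pd.DataFrame(truth_rows, columns=["read_id", "target", "taxid"])

    # taxonomic truth profile: identical correction code path as reporting
    true_assignments = [Assignment(r, t, "truth")
                        for r, t, _ in truth.itertuples(index=False)]
    truth_profile = report.profile(
        true_assignments, community.tree, community.genome_sizes(),
        total_reads=spec.n_reads, target_taxid=community.genome_taxid)
    return ReadSet(reads, truth, truth_profile)


def random_taxonomy(n_nodes: int, seed: int,
                    rank: str = "clade") -> TaxonomyTree:
    """A random rooted tree (uniform random parent among earlier nodes);
    handy as a structural stress fixture for lineage/LCA code."""
    if n_nodes < 1:
        raise ParameterError("n_nodes must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = {"n0": TaxNode("n0", "n0", "no rank", "root")}
    for i in range(1, n_nodes):
        parent = f"n{rng.integers(0, i)}"
        nodes[f"n{i}"] = TaxNode(f"n{i}", parent, rank, f"n{i}")
    return TaxonomyTree(nodes)


# -- file output ---------------------------------------------------------

def write_community(community: Community, outdir: str | os.PathLike) -> dict:
    """Write genomes.fasta, taxonomy.tsv and targets.tsv; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genomes.fasta"),
        "taxonomy": os.path.join(outdir, "taxonomy.tsv"),
        "targets": os.path.join(outdir, "targets.tsv"),
    }
    _io.write_fasta(paths["fasta"], community.genomes.items())
    community.tree.write_tsv(paths["taxonomy"])
    with open(paths["targets"], "w") as fh:
        for a in community.assembly_ids:
            fh.write(f"{a}\t{a}\t{community.genome_taxid[a]}\n")
    return paths


def write_reads(readset: ReadSet, outdir: str | os.PathLike,
                ranks: tuple[str, ...] = RANK_LADDER) -> dict:
    """Write FASTQ file(s) and the truth tables; returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {"truth_binning": os.path.join(outdir, "truth_binning.tsv"),
             "truth_profile": os.path.join(outdir, "truth_profile.tsv")}
    if readset.paired:
        paths["fastq1"] = os.path.join(outdir, "reads_1.fq")
        paths["fastq2"] = os.path.join(outdir, "reads_2.fq")
        _io.write_fastq(paths["fastq1"],
                        ((rid, s1) for rid, s1, _ in readset.reads))
        _io.write_fastq(paths["fastq2"],
                        ((rid, s2) for rid, _, s2 in readset.reads))
    else:
        paths["fastq"] = os.path.join(outdir, "reads.fq")
        _io.write_fastq(paths["fastq"],
                        ((rid, s1) for rid, s1, _ in readset.reads))
    readset.truth_binning.to_csv(paths["truth_binning"], sep="\t",
                                 index=False, header=False)
    with open(paths["truth_profile"], "w") as fh:
        for rank in ranks:
            for taxid, pct in readset.truth_profile.abundances(rank).items():
                fh.write(f"{rank}\t{taxid}\t{pct:.10f}\n")
    return paths
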