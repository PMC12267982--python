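"""Taxonomic binning files and rank-wise abundance profiles.

Read counts are *sequence abundance*: a large genome sheds more reads than
a small one at equal organism abundance.  Profiles therefore correct by
genome size before normalizing: for every directly assigned taxon ``t``,

    mass_t       = read_count_t / genome_size_t
    abundance_t  = classified_fraction * 100 * mass_t / Σ mass

and masses/counts are then cumulated up the tree so that at every
fully-populated rank the abundances plus the unclassified percentage sum
to 100.  The unclassified fraction is carried explicitly rather than
renormalized away, so incomplete reference coverage shows up as such
instead of inflating the reported taxa.

Low-abundance thresholding removes rows at the reporting rank without
renormalizing; the removed mass is carried in a per-rank "filtered"
percentage so that conservation (abundances + filtered + unclassified =
100) remains checkable after filtering.

Output formats are the CAMI/BioBoxes text conventions: a profiling file
(TAXID, RANK, TAXPATH, TAXPATHSN, PERCENTAGE) and a binning file
(SEQUENCEID, TAXID).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import MetabloomError
from .reassign import Assignment
from .taxonomy import TaxonomyTree

DEFAULT_RANKS = ("superkingdom", "phylum", "class", "order", "family",
                 "genus", "species")

BIOBOXES_VERSION = "0.10.0"


@dataclass
class Profile:
    """Cumulative per-taxon counts and genome-size-corrected abundances.

    ``rows`` has one row per taxon on any assigned lineage with columns
    taxid, rank, lineage (pipe-joined taxids from the root), direct_count,
    read_count (cumulative) and abundance (cumulative, % of sample).
    """

    rows: pd.DataFrame
    unclassified_pct: float
    total_reads: int
    tree: TaxonomyTree | None = None
    filtered_pct: dict[str, float] = field(default_factory=dict)

    def at_rank(self, rank: str) -> pd.DataFrame:
        return self.rows[self.rows["rank"] == rank].reset_index(drop=True)

    def abundances(self, rank: str) -> dict[str, float]:
        sub = self.at_rank(rank)
        return dict(zip(sub["taxid"], sub["abundance"]))


def profile(assignments: Iterable[Assignment], tree: TaxonomyTree,
            sizes: Mapping[str, float], total_reads: int,
            target_taxid: Mapping[str, str] | None = None) -> Profile:
    """Build the rank-cumulative abundance profile of one sample."""
    target_taxid = target_taxid or {}
    direct: dict[str, int] = {}
    n_classified = 0
    for a in assignments:
        taxid = target_taxid.get(a.target, a.target)
        if taxid not in tree:
            raise MetabloomError(f"assigned target {a.target} not in taxonomy")
        direct[taxid] = direct.get(taxid, 0) + 1
        n_classified += 1
    if total_reads < n_classified:
        raise MetabloomError("total_reads smaller than classified count")

    classified_fraction = n_classified / total_reads if total_reads else 0.0
    mass: dict[str, float] = {}
    for taxid, count in direct.items():
        size = sizes.get(taxid)
        if size is None or size <= 0:
            raise MetabloomError(f"no genome size for taxid {taxid}")
        mass[taxid] = count / size
    total_mass = sum(mass.values())

    # cumulate counts and corrected masses bottom-up over the tree
    cum_count: dict[str, float] = dict(direct)
    cum_mass: dict[str, float] = dict(mass)
    for t in tree.postorder():
        if t in cum_count and t != tree.root:
            p = tree.parent(t)
            cum_count[p] = cum_count.get(p, 0) + cum_count[t]
            cum_mass[p] = cum_mass.get(p, 0.0) + cum_mass[t]

    records = []
    for taxid in sorted(cum_count, key=lambda t: (tree.depth(t), t)):
        ab = (classified_fraction * 100.0 * cum_mass[taxid] / total_mass
              if total_mass > 0 else 0.0)
        records.append({
            "taxid": taxid,
            "rank": tree.rank(taxid),
            "lineage": "|".join(tree.lineage(taxid)),
            "direct_count": direct.get(taxid, 0),
            "read_count": int(cum_count[taxid]),
            "abundance": ab,
        })
    rows = pd.DataFrame(records, columns=["taxid", "rank", "lineage",
                                          "direct_count", "read_count",
                                          "abundance"])
    unclassified_pct = 100.0 * (1.0 - classified_fraction)
    return Profile(rows, unclassified_pct, total_reads, tree=tree)


def threshold_profile(prof: Profile, min_abundance_pct: float) -> Profile:
    """Remove rows at or below the abundance threshold, rank by rank.

    Removed mass is not renormalized; it accumulates in ``filtered_pct``
    per rank so every rank still sums (kept + filtered + unclassified) to
    100 where the rank is fully populated.
    """
    if min_abundance_pct < 0:
        raise MetabloomError("min_abundance_pct must be >= 0")
    if min_abundance_pct == 0:
        return Profile(prof.rows.copy(), prof.unclassified_pct,
                       prof.total_reads, prof.tree, dict(prof.filtered_pct))
    drop = prof.rows["abundance"] <= min_abundance_pct
    filtered = dict(prof.filtered_pct)
    for rank, pct in (prof.rows[drop].groupby("rank")["abundance"].sum()
                      .items()):
        filtered[rank] = filtered.get(rank, 0.0) + float(pct)
    return Profile(prof.rows[~drop].reset_index(drop=True),
                   prof.unclassified_pct, prof.total_reads, prof.tree,
                   filtered)


def _taxpath(tree: TaxonomyTree, taxid: str, ranks: tuple[str, ...],
             names: bool) -> str:
    """Pipe-joined lineage restricted to the reporting ranks, empty fields
    for ranks missing from the lineage (CAMI convention)."""
    own_rank = tree.rank(taxid)
    upto = ranks[:ranks.index(own_rank) + 1] if own_rank in ranks else ranks
    lineage = tree.lineage(taxid)
    by_rank = {tree.rank(t): t for t in lineage}
    fields = []
    for r in upto:
        t = by_rank.get(r, "")
        fields.append((tree.name(t) if names else t) if t else "")
    return "|".join(fields)


def write_bioboxes_profile(prof: Profile, sample_id: str, path,
                           ranks: tuple[str, ...] = DEFAULT_RANKS) -> None:
    """Write a CAMI profiling file; the unclassified percentage is kept in
    a comment line (the format proper excludes it from data rows)."""
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{sample_id}\n")
        fh.write(f"@Version:{BIOBOXES_VERSION}\n")
        fh.write(f"@Ranks:{'|'.join(ranks)}\n")
        fh.write(f"#unclassified:{prof.unclassified_pct:.6f}\n")
        fh.write("@@TAXID\tRANK\tTAXPATH\tTAXPATHSN\tPERCENTAGE\n")
        tree = prof.tree
        if tree is None:
            raise MetabloomError("profile carries no taxonomy to write paths")
        for rank in ranks:
            sub = prof.at_rank(rank)
            for _, row in sub.iterrows():
                taxpath = _taxpath(tree, row["taxid"], ranks, names=False)
                taxpathsn = _taxpath(tree, row["taxid"], ranks, names=True)
                fh.write(f"{row['taxid']}\t{rank}\t{taxpath}\t{taxpathsn}\t"
                         f"{row['abundance']:.6f}\n")


def read_bioboxes_profile(path) -> tuple[pd.DataFrame, float, str]:
    """Parse a CAMI profiling file -> (rows, unclassified_pct, sample_id)."""
    records = []
    unclassified = 0.0
    sample_id = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("@SampleID:"):
                sample_id = line.split(":", 1)[1]
            elif line.startswith("#unclassified:"):
                unclassified = float(line.split(":", 1)[1])
            elif not line or line.startswith("@") or line.startswith("#"):
                continue
            else:
                taxid, rank, taxpath, taxpathsn, pct = line.split("\t")
                records.append({"taxid": taxid, "rank": rank,
                                "taxpath": taxpath, "taxpathsn": taxpathsn,
                                "abundance": float(pct)})
    return (pd.DataFrame(records, columns=["taxid", "rank", "taxpath",
                                           "taxpathsn", "abundance"]),
            unclassified, sample_id)


def write_binning(assignments: Iterable[Assignment], sample_id: str, path,
                  target_taxid: Mapping[str, str] | None = None) -> None:
    """Write a CAMI binning file: one row per classified read."""
    target_taxid = target_taxid or {}
    with open(path, "w") as fh:
        fh.write(f"@SampleID:{sample_id}\n")
        fh.write(f"@Version:{BIOBOXES_VERSION}\n")
        fh.write("@@SEQUENCEID\tTAXID\n")
        for a in assignments:
            taxid = target_taxid.get(a.target, a.target)
            fh.write(f"{a.read_id}\t{taxid}\n")


def read_binning(path) -> tuple[dict[str, str], str]:
    """Parse a CAMI binning file -> (read_id -> taxid, sample_id)."""
    pred: dict[str, str] = {}
    sample_id = ""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("@SampleID:"):
                sample_id = line.split(":", 1)[1]
            elif not line or line.startswith("@") or line.startswith("#"):
                continue
            else:
                rid, taxid = line.split("\t")[:2]
                pred[rid] = taxid
    return pred, sample_id


def write_tree_report(prof: Profile, tree: TaxonomyTree, path) -> None:
    """Human-readable TSV: taxid, rank, lineage, direct and cumulative
    reads, abundance percent."""
    with open(path, "w") as fh:
        fh.write("taxid\trank\tlineage\treads\tcumulative_reads\t"
                 "abundance_pct\n")
        for _, row in prof.rows.iterrows():
            fh.write(f"{row['taxid']}\t{row['rank']}\t{row['lineage']}\t"
                     f"{row['direct_count']}\t{row['read_count']}\t"
                     f"{row['abundance']:.6f}\n")
        fh.write(f"unclassified\t-\t-\t-\t-\t{prof.unclassified_pct:.6f}\n")
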