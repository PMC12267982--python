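"""Read classification: query the index and threshold the raw matches.

Matching follows the principle that the more minimizers a read shares with
a reference, the better the match.  Three thresholds shape the result:

cutoff
    Minimum fraction of the read's minimizers that must be shared with a
    reference to call a match at all (``count >= ceil(c * q_card)``;
    ``c = 0`` accepts any positive count).
filter
    Retention band relative to the best and worst surviving match: keep
    matches with ``count >= best - f * (best - worst)``.  ``f = 0`` keeps
    only best-score ties, ``f = 1`` keeps everything.  The filter never
    changes *whether* a read is classified, only how many matches it keeps.
spurious-match removal
    Matches whose shared count is consistent with pure Bloom-filter noise
    are removed: with query cardinality ``q`` and database false-positive
    rate ``p``, a count is kept only if it reaches the smallest ``t`` for
    which ``P(X >= t) < alpha`` under ``X ~ Binomial(q, p)``.

Paired mates are sketched jointly (one union set, one classification unit
per pair).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Iterator, Mapping

from scipy.stats import binom

from . import _io
from .errors import ParameterError
from .index import HIBF
from .sketch import sketch_reads


@dataclass(frozen=True)
class ClassifyParams:
    """Cutoff/filter/spurious-match thresholds and pairing mode."""

    cutoff: float = 0.25
    filter: float = 0.0
    alpha: float = 1e-5
    paired: bool = False

    def __post_init__(self):
        if not 0.0 <= self.cutoff <= 1.0:
            raise ParameterError("cutoff must be in [0,1]")
        if not 0.0 <= self.filter <= 1.0:
            raise ParameterError("filter must be in [0,1]")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must be in (0,1)")


@dataclass
class ReadMatches:
    """Surviving matches of one read (or mate pair), best first."""

    read_id: str
    q_card: int
    matches: list[tuple[str, int]]  # (target, shared count), count desc

    @property
    def status(self) -> str:
        if not self.matches:
            return "unclassified"
        return "unique" if len(self.matches) == 1 else "multimatch"


@dataclass
class MatchTable:
    """All per-read match lists of one sample plus summary statistics."""

    reads: list[ReadMatches] = field(default_factory=list)

    @property
    def stats(self) -> dict[str, int]:
        s = {"total": len(self.reads), "classified": 0, "unclassified": 0,
             "unique": 0, "multimatch": 0}
        for r in self.reads:
            st = r.status
            s[st] += 1
            if st != "unclassified":
                s["classified"] += 1
        return s


def apply_cutoff(hits: Mapping[str, int], q_card: int,
                 cutoff: float) -> list[tuple[str, int]]:
    """Matches with count >= ceil(cutoff * q_card), sorted best first
    (ties by target id for determinism)."""
    threshold = max(1, math.ceil(cutoff * q_card))
    kept = [(t, c) for t, c in hits.items() if c >= threshold]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return kept


def apply_filter(matches: list[tuple[str, int]],
                 f: float) -> list[tuple[str, int]]:
    """Keep matches within the retention band best - f*(best - worst).

    A read with at least one match before filtering keeps at least one
    after (the best match always survives its own band)."""
    if len(matches) <= 1:
        return list(matches)
    best, worst = matches[0][1], matches[-1][1]
    bound = best - f * (best - worst)
    return [(t, c) for t, c in matches if c >= bound]


@lru_cache(maxsize=4096)
def spurious_threshold(q_card: int, max_fpr: float, alpha: float) -> int:
    """Smallest count t with P(X >= t) < alpha, X ~ Binomial(q_card, p):
    the weakest match count not explainable as Bloom noise."""
    if q_card == 0:
        return 1
    # sf(t-1) = P(X >= t), non-increasing in t; scan from 1
    for t in range(1, q_card + 1):
        if binom.sf(t - 1, q_card, max_fpr) < alpha:
            return t
    return q_card + 1


def fpr_match_filter(matches: list[tuple[str, int]], q_card: int,
                     max_fpr: float, alpha: float) -> list[tuple[str, int]]:
    """Drop matches whose shared count is statistically consistent with
    the database's Bloom false-positive rate."""
    t_star = spurious_threshold(q_card, max_fpr, alpha)
    return [(t, c) for t, c in matches if c >= t_star]


def classify_records(hibf: HIBF,
                     records: Iterable[tuple[str, str, str | None]],
                     params: ClassifyParams) -> MatchTable:
    """Classify (read_id, seq1, seq2-or-None) records against the index.

    Pipeline per read: joint sketch -> index query -> cutoff ->
    spurious-match removal -> filter.
    """
    table = MatchTable()
    sketch_params = hibf.params.sketch
    p = hibf.params.max_fpr
    for read_id, seq1, seq2 in records:
        ms = sketch_reads(seq1, seq2, sketch_params)
        q_card = ms.cardinality
        hits = hibf.query(ms)
        matches = apply_cutoff(hits, q_card, params.cutoff)
        matches = fpr_match_filter(matches, q_card, p, params.alpha)
        matches = apply_filter(matches, params.filter)
        table.reads.append(ReadMatches(read_id, q_card, matches))
    return table


def _single_records(path) -> Iterator[tuple[str, str, None]]:
    for rid, seq in _io.iter_fastq(path):
        yield rid, seq, None


def classify_sample(hibf: HIBF, fastq1, fastq2=None,
                    params: ClassifyParams | None = None) -> MatchTable:
    """Classify a FASTQ sample (single or paired, optionally gzipped)."""
    if params is None:
        params = ClassifyParams(paired=fastq2 is not None)
    if fastq2 is not None:
        records: Iterable = _io.iter_fastq_pairs(fastq1, fastq2)
    else:
        records = _single_records(fastq1)
    return classify_records(hibf, records, params)


def write_matches(table: MatchTable, path) -> None:
    """Write the ".all" table: read_id, target, count (one row per match)."""
    with open(path, "w") as fh:
        for r in table.reads:
            for target, count in r.matches:
                fh.write(f"{r.read_id}\t{target}\t{count}\n")


def read_matches(path) -> MatchTable:
    """Parse a ".all" table back into a MatchTable (q_card not recorded)."""
    rows: dict[str, list[tuple[str, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rid, target, count = line.rstrip("\n").split("\t")
            if rid not in rows:
                rows[rid] = []
                order.append(rid)
            rows[rid].append((target, int(count)))
    table = MatchTable()
    for rid in order:
        ms = sorted(rows[rid], key=lambda tc: (-tc[1], tc[0]))
        table.reads.append(ReadMatches(rid, max(c for _, c in ms), ms))
    return table
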