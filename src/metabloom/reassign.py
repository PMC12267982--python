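"""Resolution of multi-matching reads to single targets (EM) or to
ancestral taxa (LCA).

The EM route treats the classified sample as draws from a mixture over
targets.  Reads with a unique match pin their target; reads with several
candidate matches are latent.  Target weights are initialized from the
unique-read counts (plus a pseudocount of 1 so that targets without any
unique read are not locked at zero), then iterated:

E-step
    responsibility of read r for candidate target t  ∝  weight(t),
    restricted to r's candidates;
M-step
    weight(t)  ∝  unique(t) + Σ_r responsibility(r, t).

Iteration stops when the hard (argmax) assignments no longer change, i.e.
the re-assignments have converged.  Shared-minimizer counts do not enter
the responsibilities — the reassignment follows the distribution of
uniquely matching reads — and serve only to break argmax ties, with the
lexicographically smallest target as the final tie-break.

The LCA route instead lifts every multi-matching read to the lowest common
ancestor of its candidates' taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classify import MatchTable
from .errors import ParameterError
from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class Assignment:
    """Final single assignment of one classified read."""

    read_id: str
    target: str
    method: str  # "unique" | "em" | "lca"


@dataclass
class EMState:
    """Weights and diagnostics of an EM run."""

    targets: list[str]
    weights: np.ndarray
    iterations: int = 0
    log_likelihood: list[float] = field(default_factory=list)

    def weight_of(self, target: str) -> float:
        return float(self.weights[self.targets.index(target)])


def em_reassign(table: MatchTable, max_iter: int = 100,
                tol: float = 0.0) -> tuple[list[Assignment], EMState]:
    """Resolve multi-matching reads by expectation-maximization.

    Returns the per-read assignments together with the final
    :class:`EMState` (weights and the log-likelihood trace, which is
    non-decreasing across iterations).  ``tol`` optionally stops early when
    the largest weight change drops below it; the primary stopping rule is
    an unchanged hard-assignment set.
    """
    if max_iter < 1:
        raise ParameterError("max_iter must be >= 1")
    unique: dict[str, float] = {}
    multi: list[ReadCand] = []
    targets: set[str] = set()
    for r in table.reads:
        if not r.matches:
            continue
        targets.update(t for t, _ in r.matches)
        if len(r.matches) == 1:
            unique[r.matches[0][0]] = unique.get(r.matches[0][0], 0.0) + 1.0
        else:
            multi.append(ReadCand(r.read_id,
                                  [t for t, _ in r.matches],
                                  [c for _, c in r.matches]))
    target_list = sorted(targets)
    idx = {t: i for i, t in enumerate(target_list)}
    n_t = len(target_list)
    u = np.zeros(n_t)
    for t, c in unique.items():
        u[idx[t]] = c

    # initialization: unique counts + pseudocount 1 (uniform when no
    # unique read exists anywhere)
    w = u + 1.0
    w /= w.sum() if w.sum() > 0 else 1.0
    state = EMState(target_list, w)

    if not multi:
        state.log_likelihood.append(_loglik(u, w, [], [], []))
        assignments = [Assignment(r.read_id, r.matches[0][0], "unique")
                       for r in table.reads if r.matches]
        return assignments, state

    # flattened candidate structure for vectorized E/M steps
    cand_idx = np.concatenate([[idx[t] for t in rc.targets] for rc in multi])
    read_of = np.concatenate([[i] * len(rc.targets)
                              for i, rc in enumerate(multi)])
    n_multi = len(multi)
    n_classified = u.sum() + n_multi

    prev_hard = None
    for it in range(max_iter):
        cw = w[cand_idx]
        denom = np.bincount(read_of, weights=cw, minlength=n_multi)
        resp = cw / denom[read_of]
        state.log_likelihood.append(
            float(np.sum(u * np.log(np.where(w > 0, w, 1.0)))
                  + np.log(denom).sum()))
        new_w = (u + np.bincount(cand_idx, weights=resp, minlength=n_t))
        new_w /= n_classified
        hard = _segment_argmax(resp, read_of, n_multi)
        delta = float(np.abs(new_w - w).max())
        w = new_w
        state.iterations = it + 1
        if prev_hard is not None and np.array_equal(hard, prev_hard):
            break
        if tol > 0 and delta < tol:
            prev_hard = hard
            break
        prev_hard = hard
    state.weights = w

    # final hard assignments with documented tie-breaks
    cw = w[cand_idx]
    denom = np.bincount(read_of, weights=cw, minlength=n_multi)
    resp = cw / denom[read_of]
    em_target: dict[str, str] = {}
    pos = 0
    for rc in multi:
        k = len(rc.targets)
        r = resp[pos:pos + k]
        best = r.max()
        tied = [j for j in range(k) if r[j] >= best - 1e-12]
        if len(tied) > 1:  # higher shared count first, then smallest id
            tied.sort(key=lambda j: (-rc.counts[j], rc.targets[j]))
        em_target[rc.read_id] = rc.targets[tied[0]]
        pos += k

    assignments = []
    for r in table.reads:
        if not r.matches:
            continue
        if len(r.matches) == 1:
            assignments.append(Assignment(r.read_id, r.matches[0][0], "unique"))
        else:
            assignments.append(Assignment(r.read_id, em_target[r.read_id], "em"))
    return assignments, state


@dataclass
class ReadCand:
    read_id: str
    targets: list[str]
    counts: list[int]


def _segment_argmax(resp: np.ndarray, read_of: np.ndarray,
                    n_reads: int) -> np.ndarray:
    """Index (into the flat candidate array) of each read's max
    responsibility; first occurrence wins on exact ties."""
    best = np.full(n_reads, -np.inf)
    np.maximum.at(best, read_of, resp)
    is_best = resp >= best[read_of] - 1e-15
    first = np.full(n_reads, -1, dtype=np.int64)
    flat = np.nonzero(is_best)[0][::-1]
    first[read_of[flat]] = flat
    return first


def _loglik(u, w, cand_idx, read_of, n_multi) -> float:
    safe = np.where(w > 0, w, 1.0)
    return float(np.sum(u * np.log(safe)))


def em_then_lca(table: MatchTable, tree: TaxonomyTree,
                target_taxid: Mapping[str, str] | None = None,
                max_iter: int = 100) -> tuple[list[Assignment], EMState]:
    """EM first; reads whose candidates remain exactly tied in weight are
    lifted to the LCA of the tied candidates instead of tie-broken."""
    assignments, state = em_reassign(table, max_iter=max_iter)
    widx = {t: i for i, t in enumerate(state.targets)}
    target_taxid = target_taxid or {}
    by_read = {r.read_id: r for r in table.reads}
    out = []
    for a in assignments:
        if a.method != "em":
            out.append(a)
            continue
        r = by_read[a.read_id]
        ws = [float(state.weights[widx[t]]) for t, _ in r.matches]
        top = max(ws)
        tied = [t for (t, _), w in zip(r.matches, ws) if w >= top - 1e-12]
        if len(tied) > 1:
            taxids = {target_taxid.get(t, t) for t in tied}
            out.append(Assignment(a.read_id, tree.lca(taxids), "lca"))
        else:
            out.append(a)
    return out, state


def lca_reassign(table: MatchTable, tree: TaxonomyTree,
                 target_taxid: Mapping[str, str] | None = None,
                 ) -> list[Assignment]:
    """Assign each multi-matching read to the lowest common ancestor of
    its candidates' taxa; unique reads keep their target."""
    target_taxid = target_taxid or {}

    def to_taxid(target: str) -> str:
        taxid = target_taxid.get(target, target)
        if taxid not in tree:
            raise ParameterError(
                f"target {target} has no taxid mapping in the tree")
        return taxid

    out = []
    for r in table.reads:
        if not r.matches:
            continue
        if len(r.matches) == 1:
            out.append(Assignment(r.read_id, r.matches[0][0], "unique"))
        else:
            anc = tree.lca({to_taxid(t) for t, _ in r.matches})
            out.append(Assignment(r.read_id, anc, "lca"))
    return out
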