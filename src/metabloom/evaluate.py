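"""Binning and profiling evaluation metrics against a known ground truth.

Binning is scored per read at a chosen taxonomic rank: a read is a true
positive when the rank-ancestor of its predicted taxon equals the
rank-ancestor of its true taxon; a wrong prediction at the rank counts as
a false positive *and* a false negative for the truth; a read left
unclassified, or classified only above the rank, is a false negative.
Reads whose truth has no node at the evaluation rank are excluded.

Profiling is scored per taxon: presence/absence F1 over the predicted and
true taxon sets at the rank, and the L1-norm error — the sum of absolute
differences between predicted and true abundance percentages over the
union of taxa (0 to 200 when both profiles are bounded by 100%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .taxonomy import TaxonomyTree


@dataclass(frozen=True)
class BinningMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float


@dataclass(frozen=True)
class ProfilingMetrics:
    tp: int
    fp: int
    fn: int
    precision: float
    sensitivity: float
    f1: float
    l1_norm: float


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * sensitivity / (precision + sensitivity)
          if precision + sensitivity else 0.0)
    return precision, sensitivity, f1


def binning_metrics(pred: Mapping[str, str], truth: Mapping[str, str],
                    tree: TaxonomyTree, rank: str) -> BinningMetrics:
    """Per-read precision/sensitivity/F1 at one rank.

    ``pred`` and ``truth`` map read_id -> taxid; reads absent from ``pred``
    are unclassified.
    """
    tp = fp = fn = 0
    for rid, true_tax in truth.items():
        true_anc = tree.rank_ancestor(true_tax, rank)
        if true_anc is None:
            continue  # truth does not resolve at this rank: excluded
        pred_tax = pred.get(rid)
        pred_anc = (tree.rank_ancestor(pred_tax, rank)
                    if pred_tax is not None and pred_tax in tree else None)
        if pred_anc is None:
            fn += 1
        elif pred_anc == true_anc:
            tp += 1
        else:
            fp += 1
            fn += 1
    # predictions for reads outside the truth: wrong by definition
    for rid, pred_tax in pred.items():
        if rid in truth:
            continue
        if pred_tax in tree and tree.rank_ancestor(pred_tax, rank) is not None:
            fp += 1
    precision, sensitivity, f1 = _prf(tp, fp, fn)
    return BinningMetrics(tp, fp, fn, precision, sensitivity, f1)


def profiling_metrics(pred: Mapping[str, float], truth: Mapping[str, float],
                      ) -> ProfilingMetrics:
    """Presence F1 and L1-norm error between two same-rank abundance maps
    (taxid -> percentage); restrict both to the evaluation rank first."""
    pred_taxa = {t for t, a in pred.items() if a > 0}
    true_taxa = {t for t, a in truth.items() if a > 0}
    tp = len(pred_taxa & true_taxa)
    fp = len(pred_taxa - true_taxa)
    fn = len(true_taxa - pred_taxa)
    precision, sensitivity, f1 = _prf(tp, fp, fn)
    l1 = sum(abs(pred.get(t, 0.0) - truth.get(t, 0.0))
             for t in set(pred) | set(truth))
    return ProfilingMetrics(tp, fp, fn, precision, sensitivity, f1, l1)


def read_profile_truth(path) -> dict[str, dict[str, float]]:
    """Parse a truth-profile TSV (rank, taxid, abundance_pct) into
    rank -> taxid -> percentage."""
    out: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            rank, taxid, pct = line.rstrip("\n").split("\t")[:3]
            out.setdefault(rank, {})[taxid] = float(pct)
    return out


def read_binning_truth(path) -> dict[str, str]:
    """Parse a truth-binning TSV (read_id, target, taxid) into
    read_id -> taxid."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            out[fields[0]] = fields[-1]
    return out
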