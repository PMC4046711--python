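"""Sensitivity / positive-predictive-value scoring of pairwise alignments.

A predicted alignment is compared to a reference alignment as sets of
aligned index pairs: TP = correctly aligned symbol pairs, FP = predicted
pairs absent from the reference, FN = reference pairs missed by the
prediction.  SN = TP / (TP + FN), PPV = TP / (TP + FP); a degenerate
denominator (no reference pairs, or no predicted pairs) yields 0 by
convention so aggregates stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqtypes import PairwiseAlignment


@dataclass(frozen=True)
class AlignmentMetrics:
    TP: int
    FP: int
    FN: int
    SN: float
    PPV: float


def alignment_metrics(
    predicted: PairwiseAlignment, reference: PairwiseAlignment
) -> AlignmentMetrics:
    """Score ``predicted`` against ``reference`` over aligned symbol pairs."""
    if predicted.lengths != reference.lengths:
        raise ValueError(
            f"alignments refer to different sequence lengths: "
            f"{predicted.lengths} vs {reference.lengths}"
        )
    pred = predicted.pair_set()
    ref = reference.pair_set()
    tp = len(pred & ref)
    fp = len(pred - ref)
    fn = len(ref - pred)
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    return AlignmentMetrics(TP=tp, FP=fp, FN=fn, SN=sn, PPV=ppv)


METRICS_TSV_HEADER = "pair_id\tTP\tFP\tFN\tSN\tPPV"


def metrics_tsv_row(pair_id: str, m: AlignmentMetrics) -> str:
    return f"{pair_id}\t{m.TP}\t{m.FP}\t{m.FN}\t{m.SN:.6f}\t{m.PPV:.6f}"
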