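"""Confusion-matrix scoring of a predicted gene set against a benchmark list.

The benchmark list is typically a curated cancer driver catalogue (e.g. the
Cancer Gene Census, tiers 1+2). Because true negatives — and hence accuracy
— depend on what counts as "all genes", the universe is a required, logged
parameter rather than a hidden default.
"""

from __future__ import annotations

import logging

from .types import ConfusionMetrics

logger = logging.getLogger(__name__)


def confusion_metrics(predicted, benchmark, universe) -> ConfusionMetrics:
    """Score ``predicted`` against ``benchmark`` over a gene ``universe``.

    Genes outside the universe are dropped from both sets (with a warning
    for predictions). Definitions::

        TP = |predicted & benchmark|      FP = |predicted - benchmark|
        FN = |benchmark - predicted|      TN = |universe| - TP - FP - FN

        accuracy  = (TP + TN) / |universe|
        precision = TP / (TP + FP)        recall = TP / (TP + FN)

    When a precision/recall denominator is 0 the metric is reported as 0.0
    with the corresponding ``*_defined`` flag set False.
    """
    predicted, benchmark, universe = set(predicted), set(benchmark), set(universe)
    if not universe:
        raise ValueError("the gene universe must be non-empty")
    outside = predicted - universe
    if outside:
        logger.warning(
            "%d predicted gene(s) outside the universe were dropped", len(outside)
        )
    predicted &= universe
    benchmark &= universe

    tp = len(predicted & benchmark)
    fp = len(predicted - benchmark)
    fn = len(benchmark - predicted)
    tn = len(universe) - tp - fp - fn

    precision_defined = (tp + fp) > 0
    recall_defined = (tp + fn) > 0
    return ConfusionMetrics(
        TP=tp,
        TN=tn,
        FP=fp,
        FN=fn,
        universe_size=len(universe),
        accuracy=(tp + tn) / len(universe),
        precision=tp / (tp + fp) if precision_defined else 0.0,
        recall=tp / (tp + fn) if recall_defined else 0.0,
        precision_defined=precision_defined,
        recall_defined=recall_defined,
    )
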