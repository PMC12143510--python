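"""Calling eccDNA-driven genes (EDGs) from circle intervals.

Two routes make a gene eccDNA-driven:

* **EEG** (eccDNA-encoded gene): one of its transcripts, extended 35 bp
  upstream of the transcription start site to cover the core promoter, lies
  entirely within an eccDNA interval.
* **ERG** (eccDNA-regulated gene): an enhancer lies entirely within an
  eccDNA, and the gene is that enhancer's top-scoring target by the
  gene–enhancer interaction score S_GE.

The *full* strategy demands strict containment of the whole element; the
*partial* strategy (the behaviour of earlier catalogues, kept for
comparison) accepts any >= 1 bp overlap. Full-mode calls are always a
subset of partial-mode calls on the same inputs.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .types import (
    EccDNARecord,
    EdgCall,
    EdgCatalog,
    EnhancerRecord,
    GenomicInterval,
    TranscriptRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

DEFAULT_PAD_BP = 35  # upstream promoter padding applied to transcripts

MODES = ("full", "partial")


def pad_transcript(
    transcript: TranscriptRecord,
    pad_bp: int = DEFAULT_PAD_BP,
    assume_plus: bool = False,
) -> GenomicInterval:
    """Extend a transcript ``pad_bp`` upstream of its TSS.

    On the + strand the TSS is ``start`` so the span grows left (clamped at
    0); on the − strand the TSS is ``end`` so it grows right. An unknown
    strand is an error unless ``assume_plus`` is set, in which case the +
    rule applies and a warning is logged.
    """
    if pad_bp < 0:
        raise ValueError(f"pad_bp must be >= 0, got {pad_bp}")
    iv = transcript.interval
    strand = iv.strand
    if strand == ".":
        if not assume_plus:
            raise ValidationError(
                f"transcript {transcript.transcript_id} has unknown strand; "
                "set assume_plus=True to pad as if + strand"
            )
        logger.warning(
            "transcript %s: unknown strand, padding as + strand",
            transcript.transcript_id,
        )
        strand = "+"
    if strand == "+":
        return GenomicInterval(iv.chrom, max(0, iv.start - pad_bp), iv.end, "+")
    return GenomicInterval(iv.chrom, iv.start, iv.end + pad_bp, "-")


def _ecc_trees(eccdnas: Iterable[EccDNARecord]) -> dict:
    trees: dict = defaultdict(IntervalTree)
    for rec in eccdnas:
        trees[rec.interval.chrom][rec.interval.start : rec.interval.end] = rec
    return trees


def contained_elements(
    eccdnas: Sequence[EccDNARecord],
    elements: Sequence[tuple[str, GenomicInterval]],
    mode: str = "full",
) -> list[tuple[str, str]]:
    """Pair eccDNAs with the elements they contain (or overlap).

    ``elements`` are ``(element_id, interval)`` pairs. In ``full`` mode an
    element qualifies when ``ecc.start <= elem.start`` and
    ``elem.end <= ecc.end`` on the same chromosome; in ``partial`` mode any
    1 bp overlap qualifies. Returns sorted ``(ecc_id, element_id)`` pairs.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    trees = _ecc_trees(eccdnas)
    pairs = []
    for elem_id, iv in elements:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            ecc: EccDNARecord = hit.data
            if mode == "partial" or ecc.interval.contains(iv):
                pairs.append((ecc.ecc_id, elem_id))
    return sorted(pairs)


def call_eegs(
    eccdnas: Sequence[EccDNARecord],
    transcripts: Sequence[TranscriptRecord],
    pad_bp: int = DEFAULT_PAD_BP,
    mode: str = "full",
    assume_plus: bool = False,
) -> dict[str, dict]:
    """Identify eccDNA-encoded genes.

    A gene qualifies when *any* of its transcripts, after promoter padding,
    is contained (per ``mode``) in *any* eccDNA. Returns
    ``gene_id -> {"ecc_ids": set, "element_ids": set}`` where element ids
    are the supporting transcript ids.
    """
    padded = [
        (tx.transcript_id, pad_transcript(tx, pad_bp, assume_plus))
        for tx in transcripts
    ]
    by_tx = {tx.transcript_id: tx.gene_id for tx in transcripts}
    evidence: dict[str, dict] = {}
    for ecc_id, tx_id in contained_elements(eccdnas, padded, mode):
        gene = by_tx[tx_id]
        ev = evidence.setdefault(gene, {"ecc_ids": set(), "element_ids": set()})
        ev["ecc_ids"].add(ecc_id)
        ev["element_ids"].add(tx_id)
    return evidence


def call_ergs(
    eccdnas: Sequence[EccDNARecord],
    enhancers: Sequence[EnhancerRecord],
    mode: str = "full",
) -> dict[str, dict]:
    """Identify eccDNA-regulated genes.

    For each enhancer contained in (or, in partial mode, overlapping) an
    eccDNA, exactly one gene is emitted: the target with the highest S_GE,
    ties broken by ascending gene id. Genes reached from several enhancers
    are merged with pooled evidence.
    """
    elements = [(enh.enh_id, enh.interval) for enh in enhancers]
    by_id = {enh.enh_id: enh for enh in enhancers}
    evidence: dict[str, dict] = {}
    for ecc_id, enh_id in contained_elements(eccdnas, elements, mode):
        gene = by_id[enh_id].top_target
        ev = evidence.setdefault(gene, {"ecc_ids": set(), "element_ids": set()})
        ev["ecc_ids"].add(ecc_id)
        ev["element_ids"].add(enh_id)
    return evidence


def call_edgs(
    eccdnas: Sequence[EccDNARecord],
    transcripts: Sequence[TranscriptRecord],
    enhancers: Sequence[EnhancerRecord],
    biotypes: Mapping[str, str],
    pad_bp: int = DEFAULT_PAD_BP,
    mode: str = "full",
    dataset: str | None = None,
    assume_plus: bool = False,
) -> EdgCatalog:
    """Union EEG and ERG calls into a per-dataset catalog.

    Genes absent from ``biotypes`` are assigned biotype ``unknown`` (and so
    land in the non-coding partition) with a warning.
    """
    if dataset is None:
        dataset = eccdnas[0].dataset if eccdnas else "default"
    eegs = call_eegs(eccdnas, transcripts, pad_bp, mode, assume_plus)
    ergs = call_ergs(eccdnas, enhancers, mode)

    calls: dict[str, EdgCall] = {}
    missing_biotype = []
    for gene in sorted(set(eegs) | set(ergs)):
        classes = set()
        ecc_ids: set = set()
        element_ids: set = set()
        if gene in eegs:
            classes.add("EEG")
            ecc_ids |= eegs[gene]["ecc_ids"]
            element_ids |= eegs[gene]["element_ids"]
        if gene in ergs:
            classes.add("ERG")
            ecc_ids |= ergs[gene]["ecc_ids"]
            element_ids |= ergs[gene]["element_ids"]
        biotype = biotypes.get(gene)
        if biotype is None:
            missing_biotype.append(gene)
            biotype = "unknown"
        calls[gene] = EdgCall(
            gene_id=gene,
            classes=frozenset(classes),
            supporting_ecc_ids=frozenset(ecc_ids),
            supporting_element_ids=frozenset(element_ids),
            dataset=dataset,
            biotype=biotype,
        )
    if missing_biotype:
        warnings.warn(
            f"{len(missing_biotype)} EDG(s) missing from the biotype table were "
            f"assigned to the non-coding partition: {missing_biotype[:5]}...",
            stacklevel=2,
        )
    return EdgCatalog(dataset=dataset, calls=calls)


def common_edgs(
    catalogs: Sequence[EdgCatalog],
    min_fraction: float = 0.5,
    strict: bool = True,
) -> list[str]:
    """Intersect coding EDG calls across datasets into common EDGs.

    A gene qualifies when its coding-EDG status holds in more than
    ``min_fraction`` of the datasets (``strict=True``) or in at least that
    fraction (``strict=False``). ``min_fraction=1.0, strict=False`` is the
    exact intersection. Returns genes sorted ascending.
    """
    if len(catalogs) < 2:
        raise ValueError(
            "common_edgs needs >= 2 dataset catalogs; for a single dataset use call_edgs"
        )
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    counts: dict[str, int] = defaultdict(int)
    for cat in catalogs:
        for gene in cat.coding:
            counts[gene] += 1
    n = len(catalogs)
    if strict:
        keep = {g for g, c in counts.items() if c / n > min_fraction}
    else:
        keep = {g for g, c in counts.items() if c / n >= min_fraction}
    return sorted(keep)
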