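import random

import pytest

from eccdriver.identify import (
    call_edgs,
    call_eegs,
    call_ergs,
    common_edgs,
    contained_elements,
    pad_transcript,
)
from eccdriver.types import (
    EccDNARecord,
    EdgCatalog,
    EnhancerRecord,
    GenomicInterval,
    TranscriptRecord,
    ValidationError,
)
from conftest import random_containment_fixture


def ecc(chrom, start, end, ecc_id="e0"):
    return EccDNARecord(GenomicInterval(chrom, start, end), ecc_id)


def tx(start, end, strand="+", tx_id="T1", gene="G1", chrom="chr1", biotype="protein_coding"):
    return TranscriptRecord(GenomicInterval(chrom, start, end, strand), tx_id, gene, biotype)


def enh(start, end, enh_id="E1", targets=(("A", 1.0),), chrom="chr1"):
    return EnhancerRecord(GenomicInterval(chrom, start, end), enh_id, tuple(targets))


class TestPadTranscript:
    @pytest.mark.parametrize(
        "strand,start,end,expected",
        [
            ("+", 200, 500, (165, 500)),   # pad grows left of the TSS
            ("-", 200, 500, (200, 535)),   # strand mirror: TSS is the right edge
            ("+", 10, 40, (0, 40)),        # clamped at chromosome start
        ],
    )
    def test_pad_arithmetic(self, strand, start, end, expected):
        padded = pad_transcript(tx(start, end, strand), pad_bp=35)
        assert (padded.start, padded.end) == expected

    def test_unknown_strand_requires_opt_in(self):
        t = tx(100, 200, ".")
        with pytest.raises(ValidationError):
            pad_transcript(t)
        padded = pad_transcript(t, assume_plus=True)
        assert (padded.start, padded.end) == (65, 200)

    def test_negative_pad_rejected(self):
        with pytest.raises(ValueError):
            pad_transcript(tx(100, 200), pad_bp=-1)


class TestContainment:
    @pytest.mark.parametrize(
        "elem,full,partial",
        [
            ((200, 300), True, True),     # strictly inside
            ((50, 150), False, True),     # hangs off the left edge
            ((990, 1100), False, True),   # 10 bp overlap at the right edge
            ((100, 1000), True, True),    # coextensive counts as contained
            ((1000, 1100), False, False), # half-open: touching is no overlap
            ((0, 100), False, False),
        ],
    )
    def test_full_vs_partial_boundaries(self, elem, full, partial):
        circles = [ecc("chr1", 100, 1000)]
        element = [("x", GenomicInterval("chr1", *elem))]
        assert bool(contained_elements(circles, element, "full")) is full
        assert bool(contained_elements(circles, element, "partial")) is partial

    def test_chromosome_must_match(self):
        circles = [ecc("chr1", 0, 1000)]
        element = [("x", GenomicInterval("chr2", 10, 20))]
        assert contained_elements(circles, element, "partial") == []

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            contained_elements([], [], "strict")

    def test_order_invariance(self):
        rng = random.Random(5)
        circles = [ecc("chr1", rng.randrange(0, 500), rng.randrange(600, 1200), f"e{i}")
                   for i in range(20)]
        elements = [(f"x{i}", GenomicInterval("chr1", rng.randrange(0, 800), rng.randrange(810, 1300)))
                    for i in range(20)]
        base = contained_elements(circles, elements, "full")
        shuffled_c, shuffled_e = circles[:], elements[:]
        rng.shuffle(shuffled_c)
        rng.shuffle(shuffled_e)
        assert contained_elements(shuffled_c, shuffled_e, "full") == base


class TestCallEegs:
    def test_any_transcript_rule(self):
        circles = [ecc("chr1", 100, 1000)]
        transcripts = [
            tx(200, 500, "+", "T1", "G1"),
            tx(900, 2000, "+", "T2", "G1"),  # not contained
        ]
        out = call_eegs(circles, transcripts)
        assert set(out) == {"G1"}
        assert out["G1"]["element_ids"] == {"T1"}

    def test_pad_is_part_of_the_test(self):
        # transcript coextensive with the circle: the 35 bp pad pushes the
        # padded start before the circle start, so full mode rejects it
        circles = [ecc("chr1", 100, 1000)]
        assert call_eegs(circles, [tx(100, 1000)]) == {}
        assert set(call_eegs(circles, [tx(100, 1000)], mode="partial")) == {"G1"}

    def test_no_circles(self):
        assert call_eegs([], [tx(0, 100)]) == {}


class TestCallErgs:
    def test_top1_only(self):
        circles = [ecc("chr1", 100, 1000)]
        enhancers = [enh(200, 300, "E1", (("GATA3", 12.5), ("TP53", 7.1)))]
        out = call_ergs(circles, enhancers)
        assert set(out) == {"GATA3"}

    def test_dedup_merges_evidence(self):
        circles = [ecc("chr1", 100, 1000, "e0"), ecc("chr1", 1500, 2500, "e1")]
        enhancers = [
            enh(200, 300, "E1", (("MYC", 9.0),)),
            enh(1600, 1700, "E2", (("MYC", 5.0), ("B", 1.0))),
        ]
        out = call_ergs(circles, enhancers)
        assert set(out) == {"MYC"}
        assert out["MYC"]["element_ids"] == {"E1", "E2"}
        assert out["MYC"]["ecc_ids"] == {"e0", "e1"}

    def test_score_tie_breaks_lexicographically(self):
        circles = [ecc("chr1", 100, 1000)]
        # EnhancerRecord targets come pre-sorted by the reader; construct the
        # sorted form the reader guarantees
        rec = EnhancerRecord(
            GenomicInterval("chr1", 200, 300), "E1",
            tuple(sorted([("B", 3.0), ("A", 3.0)], key=lambda t: (-t[1], t[0]))),
        )
        assert set(call_ergs(circles, [rec])) == {"A"}


class TestCallEdgs:
    def test_union_classes_and_partition(self):
        circles = [ecc("chr1", 100, 2000)]
        transcripts = [tx(200, 500, "+", "T1", "G1")]
        enhancers = [
            enh(600, 700, "E1", (("G1", 5.0),)),
            enh(800, 900, "E2", (("LNC1", 4.0),)),
        ]
        biotypes = {"G1": "protein_coding", "LNC1": "lncRNA"}
        cat = call_edgs(circles, transcripts, enhancers, biotypes)
        assert cat.calls["G1"].classes == {"EEG", "ERG"}
        assert cat.coding == {"G1"}
        assert cat.non_coding == {"LNC1"}

    def test_missing_biotype_goes_non_coding_with_warning(self):
        circles = [ecc("chr1", 100, 2000)]
        enhancers = [enh(600, 700, "E1", (("MYSTERY", 5.0),))]
        with pytest.warns(UserWarning, match="biotype"):
            cat = call_edgs(circles, [], enhancers, {})
        assert cat.non_coding == {"MYSTERY"}

    def test_empty_enhancer_table_gives_eegs_only(self):
        circles = [ecc("chr1", 100, 2000)]
        cat = call_edgs(circles, [tx(200, 500)], [], {"G1": "protein_coding"})
        assert cat.calls["G1"].classes == {"EEG"}


class TestCommonEdgs:
    def _catalog(self, dataset, genes):
        calls = {}
        for g in genes:
            cat = call_edgs(
                [ecc("chr1", 0, 10_000, f"{dataset}_e")],
                [],
                [enh(100, 200, f"{dataset}_E_{g}", ((g, 1.0),))],
                {g: "protein_coding"},
                dataset=dataset,
            )
            calls.update(cat.calls)
        return EdgCatalog(dataset=dataset, calls=calls)

    def test_strict_majority(self):
        cats = [self._catalog(d, genes) for d, genes in
                [("d1", ["A", "B"]), ("d2", ["A", "C"]), ("d3", ["A", "B"])]]
        assert common_edgs(cats, min_fraction=0.5, strict=True) == ["A", "B"]

    def test_exact_intersection_limit(self):
        cats = [self._catalog(d, genes) for d, genes in
                [("d1", ["A", "B"]), ("d2", ["A"]), ("d3", ["A", "B"])]]
        assert common_edgs(cats, min_fraction=1.0, strict=False) == ["A"]

    def test_single_dataset_error(self):
        with pytest.raises(ValueError, match="call_edgs"):
            common_edgs([self._catalog("d1", ["A"])])


@pytest.mark.parametrize("seed", range(10))
def test_full_mode_calls_are_subset_of_partial(seed):
    """On random planted fixtures, full-mode EEG/ERG sets nest in partial-mode sets."""
    ann, circles, _ = random_containment_fixture(seed)
    eeg_full = set(call_eegs(circles, ann.transcripts, mode="full"))
    eeg_part = set(call_eegs(circles, ann.transcripts, mode="partial"))
    erg_full = set(call_ergs(circles, ann.enhancers, mode="full"))
    erg_part = set(call_ergs(circles, ann.enhancers, mode="partial"))
    assert eeg_full <= eeg_part
    assert erg_full <= erg_part


@pytest.mark.parametrize("seed", range(5))
def test_evidence_reverifies(seed):
    """Every supporting element in a call is truly contained in a supporting circle."""
    ann, circles, _ = random_containment_fixture(seed)
    by_ecc = {c.ecc_id: c for c in circles}
    by_tx = {t.transcript_id: t for t in ann.transcripts}
    by_enh = {e.enh_id: e for e in ann.enhancers}
    cat = call_edgs(circles, ann.transcripts, ann.enhancers, ann.biotypes)
    for call in cat.calls.values():
        for elem_id in call.supporting_element_ids:
            if elem_id in by_tx:
                iv = pad_transcript(by_tx[elem_id])
            else:
                iv = by_enh[elem_id].interval
            assert any(
                by_ecc[eid].interval.contains(iv) for eid in call.supporting_ecc_ids
            )
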