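import numpy as np
import pytest

from helentron_scan.rep import RepMotifCall, scan_element_proteins
from helentron_scan.seq_io import GenomicInterval, SequenceRecord, reverse_complement
from helentron_scan.simulate import ElementSpec, generate_background, make_element, plant_insertions
from helentron_scan.structure import (
    PROFILES,
    ElementAnnotation,
    EvidenceCheck,
    HelitronTermini,
    ScanParams,
    StructureProfile,
    annotate_element,
    classify_structure,
    detect_helitron_termini,
    scan_genome,
)

HINE_MO = PROFILES["hine-mo"]


class TestAnnotateElement:
    def test_recovers_planted_features(self, hine_element):
        seq, truth = hine_element
        ann = annotate_element(seq, HINE_MO)
        assert ann.structure_type == "HINE"
        assert (ann.subtir5.offset, ann.subtir5.end) == truth.features["subtir5"]
        assert (ann.subtir3.offset, ann.subtir3.end) == truth.features["subtir3"]
        assert (ann.palindrome3.offset, ann.palindrome3.end) == truth.features["palindrome3"]

    def test_recovers_all_window_corners(self):
        # exercise the extremes of every printed window
        specs = [
            ElementSpec(subtir_len=12, subtir5_offset=2, subtir3_offset=38, pal3_offset=8, t3_run=2, pal3_arm=2, pal3_loop=1),
            ElementSpec(subtir_len=15, subtir5_offset=4, subtir3_offset=60, pal3_offset=35, t3_run=5, pal3_arm=5, pal3_loop=0),
        ]
        for i, spec in enumerate(specs):
            seq, truth = make_element(spec, np.random.default_rng(20 + i))
            ann = annotate_element(seq, HINE_MO)
            assert ann.structure_type == "HINE", (i, ann.evidence)
            assert (ann.subtir5.offset, ann.subtir5.end) == truth.features["subtir5"]

    def test_too_short(self):
        ann = annotate_element("ACGT" * 20, HINE_MO)
        assert ann.structure_type == "unclassified"
        assert any(e.name == "length" and "too short" in e.detail for e in ann.evidence)

    def test_random_sequence_unclassified(self):
        fp = 0
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            seq = "".join(rng.choice(np.array(list("ACGT")), size=1000))
            if annotate_element(seq, HINE_MO).structure_type != "unclassified":
                fp += 1
        assert fp <= 1

    def test_pure_function(self, hine_element):
        seq, _ = hine_element
        a1 = annotate_element(seq, HINE_MO)
        a2 = annotate_element(seq, HINE_MO)
        assert a1.structure_type == a2.structure_type
        assert a1.subtir5 == a2.subtir5
        assert a1.score == a2.score

    def test_window_invariants_validated(self, hine_element):
        seq, _ = hine_element
        ann = annotate_element(seq, HINE_MO)
        n = len(seq)
        lo5, hi5 = HINE_MO.subtir5_offset_range
        assert lo5 <= ann.subtir5.offset <= hi5
        lo3, hi3 = HINE_MO.subtir3_offset_range
        assert lo3 <= n - ann.subtir3.end <= hi3
        lop, hip = HINE_MO.palindrome3_offset_range
        assert lop <= n - ann.palindrome3.end <= hip

    def test_helentron_with_rep(self, helentron_element):
        seq, _ = helentron_element
        ann = annotate_element(seq, HINE_MO, scan_proteins=True)
        assert ann.structure_type == "Helentron"

    def test_microsat_reported(self):
        spec = ElementSpec(kind="HINE", microsat=("AG", 10))
        seq, truth = make_element(spec, np.random.default_rng(33))
        ann = annotate_element(seq, HINE_MO)
        assert ann.microsat is not None
        assert "AGAGAGAG" in seq[ann.microsat.start : ann.microsat.end]


class TestDetectHelitronTermini:
    def test_tc_ctag_matches(self):
        seq = "TC" + "GACA" * 30 + "CTAG"
        ev = detect_helitron_termini(seq, PROFILES["helitron"])
        assert ev.five_prime and ev.three_prime  # CTAG matches CTRR

    def test_cttt_fails(self):
        seq = "TC" + "GACA" * 30 + "CTTT"
        ev = detect_helitron_termini(seq, PROFILES["helitron"])
        assert ev.five_prime and not ev.three_prime  # T not in {A,G}

    def test_planted_palindrome_detected(self):
        seq, truth = make_element(
            ElementSpec(kind="canonical_Helitron", body_len=400),
            np.random.default_rng(2),
        )
        ev = detect_helitron_termini(seq, PROFILES["helitron"])
        assert ev.palindrome is not None
        assert 16 <= ev.palindrome.span <= 20
        assert (ev.palindrome.offset, ev.palindrome.end) == truth.features["palindrome3"]


def _subtir_annotation(**kw):
    ann = ElementAnnotation(element=GenomicInterval("e", 0, 300))
    ann.evidence = [
        EvidenceCheck("subtir5_window", True),
        EvidenceCheck("subtir3_window", True),
        EvidenceCheck("palindrome3_window", True),
    ]
    for k, v in kw.items():
        setattr(ann, k, v)
    return ann


def _helitron_annotation(**kw):
    ann = ElementAnnotation(element=GenomicInterval("e", 0, 300))
    ann.helitron_termini = HelitronTermini(True, True, "TC", "CTRR", None)
    for k, v in kw.items():
        setattr(ann, k, v)
    return ann


class TestClassifyStructure:
    def test_decision_table(self):
        helentron_rep = RepMotifCall(classification="Helentron")
        helitron_rep = RepMotifCall(classification="Helitron")
        assert classify_structure(_subtir_annotation(), helentron_rep) == "Helentron"
        assert classify_structure(_subtir_annotation(non_coding=True), None) == "HINE"
        assert classify_structure(_subtir_annotation(), None) == "HINE"
        assert classify_structure(_subtir_annotation(), helitron_rep) == "unclassified"
        assert classify_structure(_helitron_annotation(), helitron_rep) == "canonical_Helitron"
        assert classify_structure(_helitron_annotation(), helentron_rep) == "proto_Helentron"
        assert classify_structure(_helitron_annotation(), None) == "unclassified"

    def test_contradictory_evidence(self):
        ann = _subtir_annotation()
        ann.helitron_termini = HelitronTermini(True, True, "TC", "CTRR", None)
        assert classify_structure(ann, RepMotifCall(classification="Helentron")) == "unclassified"
        # both evidence sets retained
        assert ann.helitron_termini is not None
        assert ann.has_subtir_architecture

    def test_proto_requires_no_endonuclease(self):
        rep = RepMotifCall(classification="Helentron", has_endonuclease=True)
        assert classify_structure(_helitron_annotation(), rep) == "unclassified"

    def test_coding_indeterminate_unclassified(self):
        ann = _subtir_annotation(non_coding=False)
        assert classify_structure(ann, RepMotifCall(classification="indeterminate")) == "unclassified"


def _small_sim(seed, n_copies=4, length=120_000, minus_fraction=0.0, divergence=0.0):
    ss = np.random.SeedSequence(seed)
    bg_s, e_s = ss.spawn(2)
    bg = generate_background(length, 0.5, np.random.default_rng(bg_s))
    elem = make_element(
        ElementSpec(kind="HINE", divergence=divergence), np.random.default_rng(e_s), "e1"
    )
    return plant_insertions(bg, [elem], n_copies=n_copies, seed=seed,
                            minus_fraction=minus_fraction)


class TestScanGenome:
    def test_recovers_planted_copies(self):
        genome, truth = _small_sim(11, divergence=0.03)
        anns = scan_genome([genome], HINE_MO, params=ScanParams(max_len=2000))
        assert len(anns) == len(truth.insertions)
        for ins in truth.insertions:
            match = [
                a for a in anns
                if abs(a.element.start - ins.interval.start) <= 2
                and abs(a.element.end - ins.interval.end) <= 2
                and a.element.strand == ins.interval.strand
            ]
            assert match, ins

    def test_strand_covariance(self):
        genome, truth = _small_sim(12, minus_fraction=0.5)
        anns = scan_genome([genome], HINE_MO, params=ScanParams(max_len=2000))
        rc = SequenceRecord(genome.id, reverse_complement(genome.seq))
        anns_rc = scan_genome([rc], HINE_MO, params=ScanParams(max_len=2000))
        assert len(anns) == len(anns_rc)
        n = len(genome.seq)
        fwd = {(a.element.start, a.element.end, a.element.strand) for a in anns}
        mapped = {
            (n - a.element.end, n - a.element.start, "+" if a.element.strand == "-" else "-")
            for a in anns_rc
        }
        assert fwd == mapped

    def test_deterministic_ordering(self):
        genome, _ = _small_sim(13)
        a1 = scan_genome([genome], HINE_MO, params=ScanParams(max_len=2000))
        a2 = scan_genome([genome], HINE_MO, params=ScanParams(max_len=2000))
        assert [(x.element.start, x.element.end) for x in a1] == [
            (x.element.start, x.element.end) for x in a2
        ]
        starts = [(x.element.seqid, x.element.start) for x in a1]
        assert starts == sorted(starts)

    def test_no_overlapping_calls(self):
        genome, _ = _small_sim(14, n_copies=6)
        anns = scan_genome([genome], HINE_MO, params=ScanParams(max_len=2000))
        for a, b in zip(anns, anns[1:]):
            assert a.element.end <= b.element.start or a.element.seqid != b.element.seqid

    def test_empty_background_low_false_calls(self):
        bg = generate_background(300_000, 0.5, np.random.default_rng(77))
        anns = scan_genome([SequenceRecord("bg", bg)], HINE_MO)
        # <= 1 false call per Mbp at the default profile
        assert len(anns) <= 1

    def test_seeded_scan(self):
        genome, truth = _small_sim(15)
        # seed with the planted subTIR sequence
        seed_seq = [i for i in truth.insertions][0]
        anns = scan_genome(
            [genome], HINE_MO,
            seeds=[truthseq for truthseq in [self._planted_subtir(genome, truth)]],
            params=ScanParams(max_len=2000),
        )
        assert len(anns) == len(truth.insertions)

    @staticmethod
    def _planted_subtir(genome, truth):
        ins = truth.insertions[0]
        inner = genome.seq[ins.interval.start : ins.interval.end]
        if ins.interval.strand == "-":
            inner = reverse_complement(inner)
        # subTIR sits right after the terminal T run
        k = ins.left_t_run
        return inner[k : k + 14]

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_genome([], HINE_MO)


class TestProfiles:
    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            StructureProfile(name="bad", subtir_len_range=(15, 12))

    def test_builtin_windows(self):
        assert HINE_MO.subtir_len_range == (12, 15)
        assert HINE_MO.subtir5_offset_range == (2, 4)
        assert HINE_MO.subtir3_offset_range == (38, 60)
        assert HINE_MO.palindrome3_len_range == (5, 10)
        assert HINE_MO.palindrome3_offset_range == (8, 35)
        assert PROFILES["dine-1"].subtir_len_range == (13, 13)
        assert PROFILES["dine-1"].ir_gap_range == (3, 22)
        assert PROFILES["helitron"].helitron_5p_motifs == ("TC",)
        assert PROFILES["helitron"].helitron_3p_motifs == ("CTRR",)
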