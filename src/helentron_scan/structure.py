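"""Structural annotation and typing of rolling-circle element candidates.

A structure profile holds the positional windows of one element
architecture.  The shipped profiles encode the canonical architectures:

* ``hine-mo`` — 12-15 bp palindromic subTIRs 2-4 nt from the 5' terminus and
  38-60 bp from the 3' terminus, plus a 5-10 bp palindrome 8-35 bp from the
  3' terminus.
* ``dine-1`` — 13 bp subTIRs with a short IR 3-22 bp from the 5' subTIR.
* ``helitron`` — 5' TC / 3' CTRR termini with a 16-20 nt palindrome about
  11 bp from the 3' end.
* ``proto-helentron`` — Helitron-like termini 5' TT / 3' CTAG.

Window bounds are inclusive hard ranges, extendable by a ``slack``
parameter (default 3 bp in genome scans) since the canonical offsets are
approximate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .palindrome import (
    IRPair,
    Palindrome,
    find_hairpins_with_span,
    find_inverted_repeat_pairs,
    find_palindromes,
    palindromic_sites,
)
from .rep import RepMotifCall, scan_element_proteins
from .seq_io import GenomicInterval, SequenceRecord, reverse_complement

__all__ = [
    "StructureProfile",
    "ElementAnnotation",
    "EvidenceCheck",
    "HelitronTermini",
    "ScanParams",
    "PROFILES",
    "annotate_element",
    "detect_helitron_termini",
    "classify_structure",
    "scan_genome",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _iupac_regex(motif: str) -> str:
    return "".join(_IUPAC[ch] for ch in motif)


@dataclass(frozen=True)
class StructureProfile:
    """Positional windows describing one element architecture."""

    name: str = "custom"
    subtir_len_range: Optional[tuple[int, int]] = None
    subtir5_offset_range: Optional[tuple[int, int]] = None
    subtir3_offset_range: Optional[tuple[int, int]] = None
    palindrome3_len_range: Optional[tuple[int, int]] = None
    palindrome3_offset_range: Optional[tuple[int, int]] = None
    require_palindromic_subtir: bool = True
    subtir_max_loop: int = 1
    palindrome3_max_loop: int = 2
    ir_gap_range: Optional[tuple[int, int]] = None
    helitron_5p_motifs: tuple[str, ...] = ()
    helitron_3p_motifs: tuple[str, ...] = ()
    helitron_pal_len_range: tuple[int, int] = (16, 20)
    helitron_pal_offset_range: tuple[int, int] = (8, 14)

    def __post_init__(self) -> None:
        for rng in (
            self.subtir_len_range,
            self.subtir5_offset_range,
            self.subtir3_offset_range,
            self.palindrome3_len_range,
            self.palindrome3_offset_range,
            self.ir_gap_range,
            self.helitron_pal_len_range,
            self.helitron_pal_offset_range,
        ):
            if rng is not None and (rng[0] < 0 or rng[1] < rng[0]):
                raise ValueError(f"invalid range {rng} in profile {self.name!r}")

    @property
    def has_subtir_architecture(self) -> bool:
        return self.subtir_len_range is not None

    @property
    def has_helitron_termini(self) -> bool:
        return bool(self.helitron_5p_motifs or self.helitron_3p_motifs)


HINE_MO = StructureProfile(
    name="hine-mo",
    subtir_len_range=(12, 15),
    subtir5_offset_range=(2, 4),
    subtir3_offset_range=(38, 60),
    palindrome3_len_range=(5, 10),
    palindrome3_offset_range=(8, 35),
    require_palindromic_subtir=True,
)

DINE_1 = StructureProfile(
    name="dine-1",
    subtir_len_range=(13, 13),
    subtir5_offset_range=(2, 4),
    subtir3_offset_range=(38, 60),
    palindrome3_len_range=(5, 10),
    palindrome3_offset_range=(8, 35),
    require_palindromic_subtir=False,
    ir_gap_range=(3, 22),
)

HELITRON = StructureProfile(
    name="helitron",
    helitron_5p_motifs=("TC",),
    helitron_3p_motifs=("CTRR",),
)

PROTO_HELENTRON = StructureProfile(
    name="proto-helentron",
    helitron_5p_motifs=("TT", "TC"),
    helitron_3p_motifs=("CTAG", "CTRR"),
)

PROFILES = {
    "hine-mo": HINE_MO,
    "dine-1": DINE_1,
    "helitron": HELITRON,
    "proto-helentron": PROTO_HELENTRON,
}


@dataclass(frozen=True)
class EvidenceCheck:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class HelitronTermini:
    five_prime: bool
    three_prime: bool
    matched_5p: Optional[str]
    matched_3p: Optional[str]
    palindrome: Optional[Palindrome]
    checks: list[EvidenceCheck] = field(default_factory=list)

    @property
    def terminal_match(self) -> bool:
        return self.five_prime and self.three_prime


@dataclass
class ElementAnnotation:
    """Detected structural features of one element plus its type call.

    Feature intervals are element-local (0-based on the oriented element
    sequence); ``element`` locates the element on the forward assembly.
    """

    element: GenomicInterval
    features: dict = field(default_factory=dict)  # name -> GenomicInterval (local)
    subtir5: Optional[Palindrome] = None
    subtir3: Optional[Palindrome] = None
    palindrome3: Optional[Palindrome] = None
    pal5: Optional[Palindrome] = None
    ir: Optional[IRPair] = None
    microsat: Optional[GenomicInterval] = None
    orfs: list = field(default_factory=list)
    rep_call: Optional[RepMotifCall] = None
    helitron_termini: Optional[HelitronTermini] = None
    structure_type: str = "unclassified"
    evidence: list[EvidenceCheck] = field(default_factory=list)
    score: float = 0.0
    non_coding: Optional[bool] = None
    name: Optional[str] = None

    @property
    def has_subtir_architecture(self) -> bool:
        return all(
            any(e.name == check and e.passed for e in self.evidence)
            for check in ("subtir5_window", "subtir3_window", "palindrome3_window")
        )


def _pick_best(
    candidates: Sequence[Palindrome], window: tuple[int, int], key_pos
) -> Optional[Palindrome]:
    """Deterministic tie-break: longest net arm (arm length minus mismatches),
    then fewer mismatches, then proximity of the feature to the window center.

    Penalizing mismatches before raw arm length keeps a mismatch-extended
    variant of a perfect hairpin from displacing the exact hit."""
    if not candidates:
        return None
    center = (window[0] + window[1]) / 2
    return min(
        candidates,
        key=lambda p: (
            -(p.arm_len - p.mismatches),
            p.mismatches,
            abs(key_pos(p) - center),
            p.offset,
        ),
    )


def _arm_range_for_span(span_range: tuple[int, int], max_loop: int) -> tuple[int, int]:
    min_arm = max(2, (span_range[0] - max_loop + 1) // 2)
    max_arm = span_range[1] // 2
    return min_arm, max_arm


def _hairpin_candidates(
    region: str, span_lo: int, span_hi: int, max_loop: int, max_mismatch: int
) -> list[Palindrome]:
    """Union of maximal hairpins over every mismatch budget up to the cap.

    With a non-zero budget alone, a perfect hairpin flanked by one
    complementary-by-chance pair is reported only in its extended form; the
    budget sweep keeps the exact hit available for window tests."""
    seen: dict[tuple[int, int, int], Palindrome] = {}
    for budget in range(0, max_mismatch + 1):
        for p in find_hairpins_with_span(region, span_lo, span_hi, max_loop, budget):
            seen.setdefault((p.offset, p.arm_len, p.loop_len), p)
    out = list(seen.values())
    out.sort(key=lambda p: (p.offset, -p.arm_len, p.loop_len))
    return out


def _pair_identity(a: str, b: str) -> float:
    """Identity between the two subTIR copies, orientation-maximized."""
    def ham(x: str, y: str) -> float:
        n = min(len(x), len(y))
        if n == 0:
            return 0.0
        m = sum(1 for i in range(n) if x[i] == y[i])
        return m / max(len(x), len(y))

    return max(ham(a, b), ham(a, reverse_complement(b)))


def _find_microsat(seq: str, min_total: int = 12, max_unit: int = 6) -> Optional[GenomicInterval]:
    """Longest simple tandem run (unit 1-6 bp, >= min_total bp, >= 3 copies)."""
    best = None
    for unit_len in range(1, max_unit + 1):
        i = 0
        n = len(seq)
        while i + unit_len <= n:
            unit = seq[i : i + unit_len]
            j = i + unit_len
            while j + unit_len <= n and seq[j : j + unit_len] == unit:
                j += unit_len
            total = j - i
            if total >= max(min_total, 3 * unit_len) and len(set(unit)) >= 1:
                if best is None or total > (best[1] - best[0]):
                    best = (i, j)
                i = j
            else:
                i += 1
    if best is None:
        return None
    return GenomicInterval("element", best[0], best[1])


def detect_helitron_termini(
    seq: str, profile: StructureProfile, slack: int = 0
) -> HelitronTermini:
    """Check canonical terminal motifs and the subterminal 3' palindrome."""
    checks = []
    matched5 = None
    for motif in profile.helitron_5p_motifs:
        if re.match(_iupac_regex(motif), seq):
            matched5 = motif
            break
    checks.append(EvidenceCheck("helitron_5p_motif", matched5 is not None, str(matched5)))
    matched3 = None
    for motif in profile.helitron_3p_motifs:
        if re.search(_iupac_regex(motif) + "$", seq):
            matched3 = motif
            break
    checks.append(EvidenceCheck("helitron_3p_motif", matched3 is not None, str(matched3)))

    lo, hi = profile.helitron_pal_offset_range
    lo = max(0, lo - slack)
    hi = hi + slack
    span_lo, span_hi = profile.helitron_pal_len_range
    pal = None
    region_start = max(0, len(seq) - hi - span_hi - 2)
    region = seq[region_start:]
    if len(region) >= span_lo:
        cands = [
            p
            for p in find_hairpins_with_span(region, span_lo, span_hi, 4, 0)
            if lo <= len(seq) - (region_start + p.end) <= hi
        ]
        pal = _pick_best(cands, (lo, hi), lambda p: len(seq) - (region_start + p.end))
        if pal is not None:
            pal = Palindrome(
                pal.offset + region_start, pal.arm_len, pal.loop_len, pal.mismatches, pal.seq
            )
    checks.append(EvidenceCheck("helitron_3p_palindrome", pal is not None))
    return HelitronTermini(
        five_prime=matched5 is not None,
        three_prime=matched3 is not None,
        matched_5p=matched5,
        matched_3p=matched3,
        palindrome=pal,
        checks=checks,
    )


def annotate_element(
    seq: str,
    profile: StructureProfile,
    rep_call: Optional[RepMotifCall] = None,
    slack: int = 0,
    subtir_max_mismatch: int = 0,
    pair_min_identity: float = 0.9,
    min_len: int = 100,
    seqid: str = "element",
    scan_proteins: bool = False,
    rep_min_aa: int = 300,
    accessory_min_aa: int = 100,
) -> ElementAnnotation:
    """Detect the subTIR/palindrome architecture of one element sequence.

    The sequence is assumed oriented (5'->3' on the element strand) with
    boundaries at the sequence ends.  Evidence records every window test.
    """
    n = len(seq)
    ann = ElementAnnotation(element=GenomicInterval(seqid, 0, max(n, 1)))
    if not profile.has_subtir_architecture:
        ann.helitron_termini = detect_helitron_termini(seq, profile, slack)
        ann.evidence.extend(ann.helitron_termini.checks)
        ann.structure_type = classify_structure(ann, rep_call)
        return ann

    lo5, hi5 = profile.subtir5_offset_range
    lo3, hi3 = profile.subtir3_offset_range
    lop, hip = profile.palindrome3_offset_range
    span_lo, span_hi = profile.subtir_len_range
    min_span = (lo5) + span_lo + span_lo + (lop) + profile.palindrome3_len_range[0]
    if n < max(min_len, min_span):
        ann.structure_type = "unclassified"
        ann.evidence.append(EvidenceCheck("length", False, "too short"))
        return ann

    lo5s, hi5s = max(0, lo5 - slack), hi5 + slack
    lo3s, hi3s = max(0, lo3 - slack), hi3 + slack
    lops, hips = max(0, lop - slack), hip + slack

    max_loop = profile.subtir_max_loop if profile.require_palindromic_subtir else span_hi
    min_arm, max_arm = _arm_range_for_span((span_lo, span_hi), profile.subtir_max_loop)

    if profile.require_palindromic_subtir:
        # 5' subTIR: palindromic segment starting within the 5' window
        region5 = seq[: hi5s + span_hi + 2]
        cands5 = [
            p
            for p in _hairpin_candidates(
                region5, span_lo, span_hi, profile.subtir_max_loop, subtir_max_mismatch
            )
            if lo5s <= p.offset <= hi5s
        ]
        sub5 = _pick_best(cands5, (lo5s, hi5s), lambda p: p.offset)
        # 3' subTIR: palindromic segment ending within the 3' window
        r3_start = max(0, n - hi3s - span_hi - 2)
        region3 = seq[r3_start:]
        cands3 = [
            p
            for p in _hairpin_candidates(
                region3, span_lo, span_hi, profile.subtir_max_loop, subtir_max_mismatch
            )
            if lo3s <= n - (r3_start + p.end) <= hi3s
        ]
        cands3 = [
            Palindrome(p.offset + r3_start, p.arm_len, p.loop_len, p.mismatches, p.seq)
            for p in cands3
        ]
        sub3 = _pick_best(cands3, (lo3s, hi3s), lambda p: n - p.end)
    else:
        # non-palindromic subTIRs: the 5' and 3' copies form an IR pair
        # across the element
        sub5 = sub3 = None
        pairs = find_inverted_repeat_pairs(
            seq,
            min_arm=max(2, span_lo),
            min_gap=0,
            max_gap=n,
            max_mismatch=subtir_max_mismatch,
            max_arm=span_hi,
            seqid=seqid,
        )
        good = [
            pr
            for pr in pairs
            if lo5s <= pr.left.start <= hi5s and lo3s <= n - pr.right.end <= hi3s
        ]
        if good:
            pr = min(good, key=lambda p: (-p.arm_len, p.mismatches, p.left.start))
            sub5 = Palindrome(pr.left.start, pr.arm_len, 0, pr.mismatches,
                              seq[pr.left.start : pr.left.end])
            sub3 = Palindrome(pr.right.start, pr.arm_len, 0, pr.mismatches,
                              seq[pr.right.start : pr.right.end])

    ann.subtir5 = sub5
    ann.subtir3 = sub3
    ann.evidence.append(
        EvidenceCheck(
            "subtir5_window", sub5 is not None,
            f"offset={sub5.offset} span={sub5.span}" if sub5 else "no candidate",
        )
    )
    ann.evidence.append(
        EvidenceCheck(
            "subtir3_window", sub3 is not None,
            f"end_offset={n - sub3.end} span={sub3.span}" if sub3 else "no candidate",
        )
    )

    pair_ok = True
    if sub5 is not None and sub3 is not None and profile.require_palindromic_subtir:
        # shift-tolerant: chance complements at the flanks can extend one
        # subTIR copy but not the other, so compare by longest shared stretch
        # against the minimum subTIR length rather than positional identity
        from .families import shared_subtir_length

        shared = shared_subtir_length(sub5.seq, sub3.seq)
        # effective length: the shorter chosen copy minus 1 bp of boundary
        # fuzz (chance complements can extend one copy), floored at span_lo
        effective = max(span_lo, min(sub5.span, sub3.span) - 1)
        needed = int(-(-pair_min_identity * effective // 1))
        pair_ok = shared >= needed
        ann.evidence.append(
            EvidenceCheck(
                "subtir_pair_identity", pair_ok, f"shared={shared} needed={needed}"
            )
        )
        if not pair_ok:
            # demote the weaker evidence: architecture requires matching copies
            ann.evidence = [
                e if e.name != "subtir3_window" else EvidenceCheck(e.name, False, e.detail)
                for e in ann.evidence
            ]

    # 3' palindrome (stem loop)
    plo, phi = profile.palindrome3_len_range
    rp_start = max(0, n - hips - phi - 2)
    regionp = seq[rp_start:]
    pal_cands = []
    if len(regionp) >= plo:
        pal_cands = [
            p
            for p in _hairpin_candidates(
                regionp, plo, phi, profile.palindrome3_max_loop, subtir_max_mismatch
            )
            if lops <= n - (rp_start + p.end) <= hips
        ]
        pal_cands = [
            Palindrome(p.offset + rp_start, p.arm_len, p.loop_len, p.mismatches, p.seq)
            for p in pal_cands
        ]
        # the stem loop must sit 3' of the 3' subTIR
        if sub3 is not None:
            pal_cands = [p for p in pal_cands if p.offset >= sub3.end]
    pal3 = _pick_best(pal_cands, (lops, hips), lambda p: n - p.end)
    ann.palindrome3 = pal3
    ann.evidence.append(
        EvidenceCheck(
            "palindrome3_window", pal3 is not None,
            f"end_offset={n - pal3.end} span={pal3.span}" if pal3 else "no candidate",
        )
    )

    # optional DINE-1-style IR near the 5' subTIR
    if profile.ir_gap_range is not None and sub5 is not None:
        glo, ghi = profile.ir_gap_range
        region_ir = seq[sub5.offset : min(n, sub5.end + ghi + 40)]
        irs = [
            pr
            for pr in find_inverted_repeat_pairs(
                region_ir, 3, 0, ghi + 40, subtir_max_mismatch, seqid=seqid
            )
            if glo <= (pr.right.start + sub5.offset) - sub5.end <= ghi
        ]
        ir = min(irs, key=lambda p: (-p.arm_len, p.mismatches, p.gap)) if irs else None
        if ir is not None:
            ir = IRPair(
                left=ir.left.shifted(sub5.offset),
                right=ir.right.shifted(sub5.offset),
                arm_len=ir.arm_len,
                mismatches=ir.mismatches,
                gap=ir.gap,
            )
        ann.ir = ir
        ann.evidence.append(EvidenceCheck("ir_near_subtir5", ir is not None))

    # 5' palindrome (Helitron2-style architecture evidence, reported only)
    region5p = seq[:45]
    if len(region5p) >= 10:
        p5 = [
            p
            for p in find_palindromes(region5p, 4, 12, 0, 4, subtir_max_mismatch)
            if p.span >= 10 and p.offset <= 40
        ]
        ann.pal5 = max(p5, key=lambda p: p.arm_len) if p5 else None

    ann.microsat = _find_microsat(seq[sub5.end : sub3.offset] if sub5 and sub3 else seq)
    if ann.microsat is not None and sub5 is not None:
        ann.microsat = ann.microsat.shifted(sub5.end)

    if profile.has_helitron_termini:
        ann.helitron_termini = detect_helitron_termini(seq, profile, slack)
        ann.evidence.extend(ann.helitron_termini.checks)

    if scan_proteins and rep_call is None:
        pscan = scan_element_proteins(
            seq, min_aa=rep_min_aa, accessory_min_aa=accessory_min_aa, seqid=seqid
        )
        ann.orfs = pscan.orfs
        ann.non_coding = pscan.non_coding
        rep_call = pscan.rep_call if not pscan.non_coding else None
        ann.rep_call = rep_call
    else:
        ann.rep_call = rep_call

    # populate local feature intervals for serialization
    for nm, feat in (("subtir5", sub5), ("subtir3", sub3), ("palindrome3", pal3)):
        if feat is not None:
            ann.features[nm] = GenomicInterval(seqid, feat.offset, feat.end)
    if ann.ir is not None:
        ann.features["ir"] = GenomicInterval(seqid, ann.ir.left.start, ann.ir.right.end)

    ann.score = sum(
        f.span - f.mismatches for f in (sub5, sub3, pal3) if f is not None
    )
    ann.structure_type = classify_structure(ann, ann.rep_call)
    return ann


def classify_structure(
    annotation: ElementAnnotation, rep_call: Optional[RepMotifCall]
) -> str:
    """Decision table mapping structural evidence + Rep call to a type.

    subTIR architecture with a Helentron Rep -> Helentron; with no coding
    capacity -> HINE.  Helitron termini with a Helitron Rep -> canonical
    Helitron; with a Helentron-class Rep and no endonuclease evidence ->
    proto-Helentron.  Palindromes at both ends with a Rep known to lack the
    endonuclease -> Helitron2-like.  Contradictory or insufficient evidence
    -> unclassified (both evidence sets retained).
    """
    subtir_ok = annotation.has_subtir_architecture
    heli = annotation.helitron_termini
    heli_ok = heli is not None and heli.terminal_match
    non_coding = annotation.non_coding
    rep_class = rep_call.classification if rep_call is not None else None

    if subtir_ok and heli_ok:
        return "unclassified"
    if subtir_ok:
        if rep_class == "Helentron":
            return "Helentron"
        if rep_class == "Helitron":
            return "unclassified"  # contradictory evidence
        if non_coding is False:
            return "unclassified"  # coding but Rep class unresolved
        return "HINE"
    if heli_ok:
        if rep_class == "Helitron":
            return "canonical_Helitron"
        if rep_class == "Helentron" and (
            rep_call.has_endonuclease in (None, False)
        ):
            return "proto_Helentron"
        return "unclassified"
    if (
        annotation.pal5 is not None
        and annotation.palindrome3 is not None
        and rep_call is not None
        and rep_call.has_endonuclease is False
    ):
        return "Helitron2_like"
    return "unclassified"


# ---------------------------------------------------------------------------
# genome scanning


@dataclass(frozen=True)
class ScanParams:
    min_len: int = 150
    max_len: int = 20000
    slack: int = 3
    # 0 by default (discovery against consensus-grade architecture); raise to
    # 1 to tolerate divergence within the structural features of genomic copies
    subtir_scan_mismatch: int = 0
    pair_min_identity: float = 0.9
    scan_proteins: bool = True
    rep_min_aa: int = 300
    accessory_min_aa: int = 100
    require_boundary_t_run: bool = True
    min_boundary_t_run: int = 2
    # minimum summed feature score (spans minus mismatches); random near-
    # architectures rarely exceed the high 20s, real elements with the
    # default windows score in the mid 30s
    min_score: float = 30.0


def _walk_5p_boundary(s: str, subtir_start: int, max_skip: int, min_run: int) -> Optional[int]:
    """Element start: first base of the contiguous T run preceding the 5'
    subTIR (skipping up to ``max_skip`` non-T bases)."""
    i = subtir_start - 1
    skipped = 0
    while i >= 0 and s[i] != "T" and skipped < max_skip:
        i -= 1
        skipped += 1
    if i < 0 or s[i] != "T":
        return None
    run_end = i
    while i >= 0 and s[i] == "T":
        i -= 1
    if run_end - i < min_run:
        return None
    return i + 1


def _walk_3p_boundary(s: str, pal_end: int, max_skip: int, min_run: int) -> Optional[int]:
    """Element end (exclusive): last base of the contiguous T run following
    the 3' stem loop (skipping up to ``max_skip`` non-T bases)."""
    n = len(s)
    i = pal_end
    skipped = 0
    while i < n and s[i] != "T" and skipped < max_skip:
        i += 1
        skipped += 1
    if i >= n or s[i] != "T":
        return None
    run_start = i
    while i < n and s[i] == "T":
        i += 1
    if i - run_start < min_run:
        return None
    return i


def _candidate_subtirs(
    s: str, profile: StructureProfile, params: ScanParams, seeds: Optional[Sequence[str]]
) -> list[Palindrome]:
    span_lo, span_hi = profile.subtir_len_range
    if seeds:
        out = []
        for seed in seeds:
            for probe in {seed, reverse_complement(seed)}:
                start = 0
                while True:
                    idx = s.find(probe, start)
                    if idx == -1:
                        break
                    out.append(Palindrome(idx, len(probe) // 2, len(probe) % 2, 0, probe))
                    start = idx + 1
        out.sort(key=lambda p: p.offset)
        return out
    return palindromic_sites(
        s, span_lo, span_hi, params.subtir_scan_mismatch, profile.subtir_max_loop
    )


def scan_genome(
    genome: Sequence[SequenceRecord],
    profile: StructureProfile,
    seeds: Optional[Sequence[str]] = None,
    params: Optional[ScanParams] = None,
) -> list[ElementAnnotation]:
    """Scan genome records on both strands for profile-conforming elements.

    Candidate subTIR sites (palindromic segments, or seed matches when
    ``seeds`` are given) are paired across plausible element spans, element
    boundaries are placed at the flanking T runs, and each candidate window
    is annotated; overlapping candidates are resolved greedily by score.
    Output is deterministic, ordered by (seqid, start).
    """
    if not genome:
        raise ValueError("empty genome")
    if not profile.has_subtir_architecture:
        raise ValueError("scan_genome requires a subTIR-architecture profile")
    params = params or ScanParams()
    lo5, hi5 = profile.subtir5_offset_range
    lo3, hi3 = profile.subtir3_offset_range
    lop, hip = profile.palindrome3_offset_range
    candidates: list[tuple[float, GenomicInterval, ElementAnnotation]] = []
    for rec in genome:
        length = len(rec.seq)
        for strand in ("+", "-"):
            s = rec.seq if strand == "+" else reverse_complement(rec.seq)
            sites = _candidate_subtirs(s, profile, params, seeds)
            offsets = [p.offset for p in sites]
            for i, c5 in enumerate(sites):
                # plausible 3' partners: subTIR3 *end* sits ~hi3 bp before the
                # element end, so partner start lies within the length bounds
                min_d = params.min_len - hi3 - c5.span - hi5
                max_d = params.max_len
                for c3 in sites[i + 1 :]:
                    d = c3.offset - c5.offset
                    if d < max(min_d, c5.span):
                        continue
                    if d > max_d:
                        break
                    if abs(c3.span - c5.span) > 2:
                        continue
                    if _pair_identity(c5.seq, c3.seq) < params.pair_min_identity:
                        continue
                    ann = _evaluate_candidate(
                        s, rec.id, strand, length, c5, c3, profile, params
                    )
                    if ann is not None:
                        candidates.append((ann.score, ann.element, ann))
    # greedy non-overlap selection: best score first; at equal score prefer the
    # shorter candidate (guards against chimeric pairings of subTIRs from two
    # neighbouring copies of the same family)
    candidates.sort(
        key=lambda t: (-t[0], t[1].end - t[1].start, t[1].seqid, t[1].start, t[1].strand)
    )
    kept: list[ElementAnnotation] = []
    for score, interval, ann in candidates:
        plain = GenomicInterval(interval.seqid, interval.start, interval.end)
        if any(
            plain.overlaps(GenomicInterval(k.element.seqid, k.element.start, k.element.end))
            for k in kept
        ):
            continue
        kept.append(ann)
    kept.sort(key=lambda a: (a.element.seqid, a.element.start))
    return kept


def _evaluate_candidate(
    s: str,
    seqid: str,
    strand: str,
    length: int,
    c5: Palindrome,
    c3: Palindrome,
    profile: StructureProfile,
    params: ScanParams,
) -> Optional[ElementAnnotation]:
    lo5, hi5 = profile.subtir5_offset_range
    lop, hip = profile.palindrome3_offset_range
    lo3, hi3 = profile.subtir3_offset_range
    slack = params.slack

    # locate the 3' stem loop downstream of the candidate 3' subTIR
    plo, phi = profile.palindrome3_len_range
    search_hi = min(len(s), c3.end + (hi3 + slack))
    region = s[c3.end : search_hi]
    if len(region) < plo:
        return None
    pals = _hairpin_candidates(
        region, plo, phi, profile.palindrome3_max_loop, params.subtir_scan_mismatch
    )
    if not pals:
        return None
    start = _walk_5p_boundary(
        s, c5.offset, hi5 + slack, params.min_boundary_t_run
    )
    if start is None:
        if params.require_boundary_t_run:
            return None
        start = max(0, c5.offset - lo5)
    best_end = None
    for p in sorted(pals, key=lambda p: (-p.arm_len, p.offset)):
        pal_end = c3.end + p.end
        end = _walk_3p_boundary(
            s, pal_end, hip + slack, params.min_boundary_t_run
        )
        if end is None and not params.require_boundary_t_run:
            end = min(len(s), pal_end + lop)
        if end is None:
            continue
        if lop - slack <= end - pal_end <= hip + slack and lo3 - slack <= end - c3.end <= hi3 + slack:
            best_end = end
            break
    if best_end is None:
        return None
    end = best_end
    if not (params.min_len <= end - start <= params.max_len):
        return None
    sub = s[start:end]
    ann = annotate_element(
        sub,
        profile,
        slack=slack,
        subtir_max_mismatch=params.subtir_scan_mismatch,
        pair_min_identity=params.pair_min_identity,
        min_len=params.min_len,
        seqid=seqid,
        scan_proteins=params.scan_proteins,
        rep_min_aa=params.rep_min_aa,
        accessory_min_aa=params.accessory_min_aa,
    )
    if not ann.has_subtir_architecture or ann.score < params.min_score:
        return None
    if strand == "+":
        ann.element = GenomicInterval(seqid, start, end, "+")
    else:
        ann.element = GenomicInterval(seqid, length - end, length - start, "-")
    return ann
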