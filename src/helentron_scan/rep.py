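"""ORF discovery and Rep-protein diagnostic classification.

The replication-initiator motif-2 block ``(V/I)ExQxRG(S/L)(P/L)HxH`` carries
the residue between the conserved G and the following P/L that separates the
two protein classes: S for the endonuclease-bearing (Helentron) class, L for
the canonical Helitron class.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq

from .seq_io import GenomicInterval, reverse_complement

__all__ = [
    "OrfHit",
    "RepMotifCall",
    "ProteinScan",
    "MOTIF2_PATTERN",
    "find_orfs",
    "locate_rep_motif2",
    "classify_rep",
    "scan_element_proteins",
]

# 12-position motif: [VI] E x Q x R G [SL] [PL] H x H
MOTIF2_PATTERN = re.compile(r"[VI]E[A-Z]Q[A-Z]RG([SL])([PL])H[A-Z]H")

DIAG1_PATTERN = re.compile(r"[FY][WLYK]R")


@dataclass(frozen=True)
class OrfHit:
    frame: int  # +1..+3 / -1..-3
    nuc_interval: GenomicInterval  # forward-strand coordinates, stop excluded
    aa_seq: str
    length_aa: int


@dataclass
class RepMotifCall:
    classification: str  # Helentron | Helitron | indeterminate
    motif_span: Optional[tuple[int, int]] = None
    matched: Optional[str] = None
    diag2_residue: Optional[str] = None
    diag1_residues: Optional[str] = None
    evidence: list[str] = field(default_factory=list)
    # external domain-call hook (CDD-style evidence supplied by the user)
    has_endonuclease: Optional[bool] = None


@dataclass
class ProteinScan:
    orfs: list[OrfHit]
    rep_call: RepMotifCall
    n_rep_orfs: int
    n_accessory_orfs: int
    non_coding: bool
    notes: list[str] = field(default_factory=list)


def find_orfs(
    seq: str,
    min_aa: int = 100,
    require_atg: bool = True,
    seqid: str = "query",
) -> list[OrfHit]:
    """Scan all six frames for ORFs of at least ``min_aa`` residues.

    An ORF is the segment from the first ATG of a stop-free stretch (or the
    stretch start when ``require_atg=False``) to the stop.  Coordinates are
    on the forward strand; the stop codon is excluded.
    """
    n = len(seq)
    hits: list[OrfHit] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else reverse_complement(seq)
        for f in range(3):
            usable = (n - f) // 3
            if usable == 0:
                continue
            aa = str(Seq(s[f : f + 3 * usable]).translate())
            start = 0
            for seg in _stop_free_segments(aa):
                a0, a1 = seg
                if require_atg:
                    m = aa.find("M", a0, a1)
                    if m == -1:
                        continue
                    a0 = m
                if a1 - a0 < min_aa:
                    continue
                nuc0 = f + 3 * a0
                nuc1 = f + 3 * a1
                if strand == "+":
                    gi = GenomicInterval(seqid, nuc0, nuc1, "+")
                    frame = f + 1
                else:
                    gi = GenomicInterval(seqid, n - nuc1, n - nuc0, "-")
                    frame = -(f + 1)
                hits.append(OrfHit(frame, gi, aa[a0:a1], a1 - a0))
    hits.sort(key=lambda h: (-h.length_aa, h.nuc_interval.start, h.frame))
    return hits


def _stop_free_segments(aa: str):
    start = 0
    for i, ch in enumerate(aa):
        if ch == "*":
            if i > start:
                yield start, i
            start = i + 1
    if len(aa) > start:
        yield start, len(aa)


def locate_rep_motif2(protein: str, diag1_offset: Optional[int] = None):
    """Leftmost motif-2 match in ``protein``, or None.

    Returns ``(match, all_matches)`` where ``match`` is an ``re.Match``.
    ``diag1_offset`` optionally positions the secondary 3-residue diagnostic
    relative to the match start (disabled by default; its exact placement is
    configuration-dependent and never overrides the primary diagnostic).
    """
    matches = list(MOTIF2_PATTERN.finditer(protein))
    if not matches:
        return None, []
    return matches[0], matches


def classify_rep(protein: str, diag1_offset: Optional[int] = None) -> RepMotifCall:
    """Classify a Rep translation from the motif-2 diagnostic residue.

    S between G and P/L -> Helentron; L -> Helitron; no motif -> indeterminate.
    """
    m, all_matches = locate_rep_motif2(protein)
    if m is None:
        return RepMotifCall(classification="indeterminate", evidence=["no motif-2 match"])
    diag2 = m.group(1)
    classification = "Helentron" if diag2 == "S" else "Helitron"
    evidence = [f"motif-2 at {m.start()}-{m.end()}: {m.group(0)}"]
    if len(all_matches) > 1:
        evidence.append(
            "additional motif-2 matches at "
            + ",".join(str(x.start()) for x in all_matches[1:])
        )
    diag1 = None
    if diag1_offset is not None:
        lo = m.start() + diag1_offset
        if 0 <= lo and lo + 3 <= len(protein):
            diag1 = protein[lo : lo + 3]
            if DIAG1_PATTERN.fullmatch(diag1):
                evidence.append(f"diag1 {diag1!r} corroborates")
            else:
                evidence.append(f"diag1 {diag1!r} does not match [FY][WLYK]R (ignored)")
    return RepMotifCall(
        classification=classification,
        motif_span=(m.start(), m.end()),
        matched=m.group(0),
        diag2_residue=diag2,
        diag1_residues=diag1,
        evidence=evidence,
    )


def scan_element_proteins(
    seq: str,
    min_aa: int = 300,
    accessory_min_aa: int = 100,
    require_atg: bool = True,
    merge_adjacent: bool = False,
    seqid: str = "query",
) -> ProteinScan:
    """Find ORFs in an element and derive its Rep classification.

    ``min_aa`` is the putative Rep/Helicase threshold, ``accessory_min_aa``
    the accessory-ORF threshold; an element with no ORF reaching the
    accessory threshold is declared non-coding (HINE-compatible).
    """
    orfs = find_orfs(seq, min_aa=accessory_min_aa, require_atg=require_atg, seqid=seqid)
    notes: list[str] = []
    rep_call = RepMotifCall(classification="indeterminate", evidence=["no motif-bearing ORF"])
    for orf in orfs:
        call = classify_rep(orf.aa_seq)
        if call.classification != "indeterminate":
            rep_call = call
            break
    if merge_adjacent and rep_call.classification == "indeterminate":
        merged = _merge_adjacent_orfs(orfs)
        for aa, note in merged:
            call = classify_rep(aa)
            if call.classification != "indeterminate":
                call.evidence.append(note)
                rep_call = call
                notes.append(note)
                break
    n_rep = sum(1 for o in orfs if o.length_aa >= min_aa)
    n_acc = len(orfs)
    return ProteinScan(
        orfs=orfs,
        rep_call=rep_call,
        n_rep_orfs=n_rep,
        n_accessory_orfs=n_acc,
        non_coding=(n_acc == 0),
        notes=notes,
    )


def _merge_adjacent_orfs(orfs: list[OrfHit], max_gap: int = 200):
    """Concatenate translations of adjacent same-strand ORFs (flagged only).

    Stands in for manual stop/frameshift correction without inventing
    sequence: the merged translation is examined but the ORFs themselves are
    left untouched.
    """
    by_strand: dict[str, list[OrfHit]] = {"+": [], "-": []}
    for o in orfs:
        by_strand[o.nuc_interval.strand].append(o)
    out = []
    for strand, group in by_strand.items():
        group.sort(key=lambda o: o.nuc_interval.start)
        for a, b in zip(group, group[1:]):
            if b.nuc_interval.start - a.nuc_interval.end <= max_gap:
                aa = (a.aa_seq + b.aa_seq) if strand == "+" else (b.aa_seq + a.aa_seq)
                out.append((aa, "putative corrected ORF (merged adjacent ORFs)"))
    return out
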