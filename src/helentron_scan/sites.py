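"""Paralogous empty-site validation and target-site analysis.

Boundary confirmation follows the chimeric-query method: the 50 bp flanks of
an insertion are concatenated and searched against the genome; a paralogous
locus aligning at >= 90% identity over >= 90% of the query is an empty
(pre-insertion) site.  Target-site reports cover the flanking T runs, the TT
dinucleotide at the reconstructed pre-insertion junction, the A|T junction of
canonical Helitron insertions, and the absence of a target-site duplication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from ._align import local_align
from .seq_io import GenomicInterval, as_mapping, reverse_complement

__all__ = [
    "EmptySiteParams",
    "EmptySiteHit",
    "TargetSiteReport",
    "InsufficientFlankError",
    "UnsupportedPolicyError",
    "build_chimeric_query",
    "find_empty_sites",
    "analyze_target_site",
    "canonicalize_boundaries",
]


class InsufficientFlankError(ValueError):
    """The element sits too close to a contig edge for the requested flank."""


class UnsupportedPolicyError(ValueError):
    """Raised for the 'split' boundary policy (genuinely ambiguous)."""


@dataclass(frozen=True)
class EmptySiteParams:
    flank: int = 50
    min_identity: float = 0.90
    min_coverage: float = 0.90
    seed_k: int = 9
    region_margin: int = 30

    def __post_init__(self) -> None:
        if self.flank < 20:
            raise ValueError("flank must be >= 20")
        for frac in (self.min_identity, self.min_coverage):
            if not (0 < frac <= 1):
                raise ValueError("identity/coverage fractions must be in (0, 1]")


@dataclass
class EmptySiteHit:
    insertion_locus: Optional[GenomicInterval]
    empty_locus: GenomicInterval
    identity: float
    coverage: float
    junction_offset: Optional[int]  # position within the hit where flanks abut
    score: float = 0.0


@dataclass
class TargetSiteReport:
    left_t_run: int
    right_t_run: int
    tt_at_insertion: bool
    tsd: Optional[str]
    at_insertion: bool


def build_chimeric_query(
    genome,
    element: GenomicInterval,
    flank: int = 50,
) -> tuple[str, int]:
    """Concatenate the upstream and downstream flanks of an element.

    Returns ``(query, junction_offset)`` with ``junction_offset == flank``.
    """
    records = as_mapping(genome)
    if element.seqid not in records:
        raise KeyError(f"unknown sequence {element.seqid!r}")
    seq = records[element.seqid].seq
    if element.start < flank or element.end + flank > len(seq):
        raise InsufficientFlankError(
            f"element {element.seqid}:{element.start}-{element.end} has less than "
            f"{flank} bp of assembled flank"
        )
    query = seq[element.start - flank : element.start] + seq[element.end : element.end + flank]
    return query, flank


def _seed_regions(query: str, target: str, k: int, margin: int, qlen: int) -> list[tuple[int, int]]:
    """Diagonal-clustered candidate target regions from exact k-mer seeds."""
    index: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        index.setdefault(query[i : i + k], []).append(i)
    diagonals: set[int] = set()
    n = len(target)
    for j in range(n - k + 1):
        hits = index.get(target[j : j + k])
        if hits:
            for qpos in hits:
                diagonals.add(j - qpos)
    regions: list[tuple[int, int]] = []
    for d in sorted(diagonals):
        lo = max(0, d - margin)
        hi = min(n, d + qlen + margin)
        if regions and lo <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], hi))
        else:
            regions.append((lo, hi))
    return regions


def _mask_sequence(seq: str, masks: Sequence[tuple[int, int]]) -> str:
    if not masks:
        return seq
    chars = list(seq)
    for lo, hi in masks:
        lo = max(0, lo)
        hi = min(len(seq), hi)
        for i in range(lo, hi):
            chars[i] = "N"  # N matches nothing under the shared scoring
    return "".join(chars)


def find_empty_sites(
    query: str,
    genome,
    params: Optional[EmptySiteParams] = None,
    insertion_locus: Optional[GenomicInterval] = None,
    mask: Iterable[GenomicInterval] = (),
) -> list[EmptySiteHit]:
    """Seed-and-extend search of a chimeric query against both genome strands.

    Hits pass when local-alignment identity (gap columns counting as errors)
    is >= ``min_identity`` and the aligned query span covers at least
    ``min_coverage`` of the query.  The insertion locus itself (plus one
    flank of margin) and any ``mask`` intervals are masked out.  Hits are
    sorted by identity, descending.
    """
    params = params or EmptySiteParams()
    records = as_mapping(genome)
    qlen = len(query)
    hits: list[EmptySiteHit] = []
    for seqid, rec in records.items():
        masks = []
        if insertion_locus is not None and insertion_locus.seqid == seqid:
            masks.append(
                (insertion_locus.start - params.flank, insertion_locus.end + params.flank)
            )
        for m in mask:
            if m.seqid == seqid:
                masks.append((m.start, m.end))
        target = _mask_sequence(rec.seq, masks)
        for strand in ("+", "-"):
            q = query if strand == "+" else reverse_complement(query)
            regions = _seed_regions(q, target, params.seed_k, params.region_margin, qlen)
            for lo, hi in regions:
                aln = local_align(q, target[lo:hi])
                if aln is None:
                    continue
                coverage = (aln.query_end - aln.query_start) / qlen
                if aln.identity < params.min_identity or coverage < params.min_coverage:
                    continue
                t0, t1 = lo + aln.target_start, lo + aln.target_end
                if strand == "+":
                    junction = aln.map_query_to_target(params.flank)
                    junction_offset = None if junction is None else junction + lo - t0
                else:
                    # junction offset in the oriented (element-strand) view of
                    # the hit locus, i.e. within revcomp(genome[t0:t1])
                    junction = aln.map_query_to_target(qlen - params.flank)
                    junction_offset = (
                        None if junction is None else t1 - (junction + lo)
                    )
                hits.append(
                    EmptySiteHit(
                        insertion_locus=insertion_locus,
                        empty_locus=GenomicInterval(seqid, t0, t1, strand),
                        identity=aln.identity,
                        coverage=coverage,
                        junction_offset=junction_offset,
                        score=aln.score,
                    )
                )
    # greedy de-duplication of overlapping hits, best score first
    hits.sort(key=lambda h: (-h.score, h.empty_locus.seqid, h.empty_locus.start))
    kept: list[EmptySiteHit] = []
    for h in hits:
        stripped = GenomicInterval(
            h.empty_locus.seqid, h.empty_locus.start, h.empty_locus.end
        )
        if any(
            stripped.overlaps(
                GenomicInterval(k.empty_locus.seqid, k.empty_locus.start, k.empty_locus.end)
            )
            for k in kept
        ):
            continue
        kept.append(h)
    kept.sort(key=lambda h: (-h.identity, h.empty_locus.seqid, h.empty_locus.start))
    return kept


def _t_run(seq: str, start: int, step: int) -> int:
    run = 0
    i = start
    while 0 <= i < len(seq) and seq[i] == "T":
        run += 1
        i += step
    return run


def analyze_target_site(
    genome,
    element: GenomicInterval,
    empty: Optional[EmptySiteHit] = None,
    max_tsd: int = 20,
    min_tsd: int = 4,
) -> TargetSiteReport:
    """Target-site report for one insertion.

    T runs are measured immediately inside the element boundaries on the
    element strand; the pre-insertion junction is reconstructed from the
    empty-site hit when available, else by flank concatenation.  The TSD scan
    tests every k in ``min_tsd``..``max_tsd`` for identical k-mers
    immediately flanking both boundaries and reports the longest, or None.
    ``min_tsd`` defaults to 4 (the shortest TSD any major class-2 superfamily
    leaves); 2-3-mers match by background chance at a few percent of sites
    and would drown the signal.
    """
    records = as_mapping(genome)
    seq = records[element.seqid].seq
    elem_seq = seq[element.start : element.end]
    if element.strand == "-":
        elem_seq = reverse_complement(elem_seq)
    left_t = _t_run(elem_seq, 0, +1)
    right_t = _t_run(elem_seq, len(elem_seq) - 1, -1)

    left_base = seq[element.start - 1] if element.start > 0 else ""
    right_base = seq[element.end] if element.end < len(seq) else ""

    tt = left_base == "T" and right_base == "T"
    if empty is not None and empty.junction_offset is not None:
        emp = records[empty.empty_locus.seqid].seq[
            empty.empty_locus.start : empty.empty_locus.end
        ]
        if empty.empty_locus.strand == "-":
            emp = reverse_complement(emp)
        j = empty.junction_offset
        if 0 < j < len(emp):
            tt = emp[j - 1 : j + 1] == "TT"

    tsd = None
    for k in range(max_tsd, min_tsd - 1, -1):
        if element.start - k < 0 or element.end + k > len(seq):
            continue
        left_k = seq[element.start - k : element.start]
        right_k = seq[element.end : element.end + k]
        if left_k == right_k:
            tsd = left_k
            break

    at = left_base == "A" and right_base == "T"
    if element.strand == "-":
        # A|T junction read on the element strand
        at = left_base == "A" and right_base == "T"
    return TargetSiteReport(
        left_t_run=left_t,
        right_t_run=right_t,
        tt_at_insertion=tt,
        tsd=tsd,
        at_insertion=at,
    )


def canonicalize_boundaries(
    genome,
    element: GenomicInterval,
    policy: str = "inclusive",
) -> GenomicInterval:
    """Resolve the boundary-T assignment ambiguity by policy.

    ``inclusive`` extends the element over all contiguous flanking Ts;
    ``exclusive`` strips contiguous boundary Ts from the element.  ``split``
    is deliberately unsupported: the T distribution between element and host
    is genuinely ambiguous, so no symmetric split is defensible.
    """
    if policy == "split":
        raise UnsupportedPolicyError(
            "the distribution of boundary Ts between element and host is "
            "ambiguous; use 'inclusive' or 'exclusive'"
        )
    if policy not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown policy {policy!r}")
    records = as_mapping(genome)
    seq = records[element.seqid].seq
    start, end = element.start, element.end
    if policy == "inclusive":
        while start > 0 and seq[start - 1] == "T":
            start -= 1
        while end < len(seq) and seq[end] == "T":
            end += 1
    else:
        while start < end and seq[start] == "T":
            start += 1
        while end > start and seq[end - 1] == "T":
            end -= 1
        if start >= end:
            raise ValueError("element is a pure T run; cannot take exclusive boundary")
    return GenomicInterval(element.seqid, start, end, element.strand)
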