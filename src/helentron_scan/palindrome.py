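"""Palindrome / hairpin / inverted-repeat primitives.

All structure detection rests on these detectors.  A *hairpin* here is a pair
of reverse-complementary arms separated by a loop; a perfect self-palindrome
is the ``loop_len == 0`` case.  N never matches anything (not even N), so
assembly gaps cannot seed spurious hits.

Detectors report *maximal* hits only: a hit is maximal when growing both arms
by one base — either outward (span + 2) or inward (loop − 2) — would violate
a constraint (arm bound, loop bound, mismatch budget, or sequence bounds).
Sub-hits are recoverable by trimming.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .seq_io import DNA_ALPHABET, GenomicInterval

__all__ = [
    "Palindrome",
    "IRPair",
    "is_self_palindromic",
    "find_palindromes",
    "find_inverted_repeat_pairs",
    "palindromic_sites",
]

_PAIRS = frozenset({"AT", "TA", "GC", "CG"})


def _check_dna(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-DNA characters: {sorted(bad)}")


def _complementary(a: str, b: str) -> bool:
    return a + b in _PAIRS


@dataclass(frozen=True)
class Palindrome:
    """A hairpin candidate located within a query sequence."""

    offset: int
    arm_len: int
    loop_len: int
    mismatches: int
    seq: str

    @property
    def span(self) -> int:
        return 2 * self.arm_len + self.loop_len

    @property
    def end(self) -> int:
        return self.offset + self.span


@dataclass(frozen=True)
class IRPair:
    """A dispersed inverted-repeat arm pair."""

    left: GenomicInterval
    right: GenomicInterval
    arm_len: int
    mismatches: int
    gap: int


def is_self_palindromic(seq: str) -> bool:
    """True iff ``seq`` equals its own reverse complement.

    Odd-length strings can never satisfy this; N never matches.
    """
    _check_dna(seq)
    n = len(seq)
    if n % 2:
        return False
    return all(_complementary(seq[i], seq[n - 1 - i]) for i in range(n // 2))


def _scan_hairpins(
    seq: str,
    min_arm: int,
    max_arm: int,
    min_loop: int,
    max_loop: int,
    max_mismatch: int,
) -> Iterable[tuple[int, int, int, int]]:
    """Yield maximal ``(offset, arm, loop, mismatches)`` hairpins."""
    n = len(seq)
    for loop in range(min_loop, max_loop + 1):
        # loop occupies [ls, ls + loop); arms grow symmetrically around it
        for ls in range(1, n):
            geo_max = min(ls, n - (ls + loop))
            if geo_max < min_arm:
                continue
            probe_max = min(max_arm + 1, geo_max)
            cum = []
            mm = 0
            for k in range(1, probe_max + 1):
                if not _complementary(seq[ls - k], seq[ls + loop + k - 1]):
                    mm += 1
                cum.append(mm)
            if loop >= 2:
                inner_pair_mm = 0 if _complementary(seq[ls], seq[ls + loop - 1]) else 1
            else:
                inner_pair_mm = None
            for k in range(min_arm, min(max_arm, geo_max) + 1):
                if cum[k - 1] > max_mismatch:
                    continue
                out_ok = (
                    k + 1 <= max_arm
                    and k + 1 <= geo_max
                    and cum[k] <= max_mismatch
                )
                in_ok = (
                    inner_pair_mm is not None
                    and loop - 2 >= min_loop
                    and k + 1 <= max_arm
                    and cum[k - 1] + inner_pair_mm <= max_mismatch
                )
                if not out_ok and not in_ok:
                    yield ls - k, k, loop, cum[k - 1]


def find_palindromes(
    seq: str,
    min_arm: int,
    max_arm: int,
    min_loop: int = 0,
    max_loop: int = 0,
    max_mismatch: int = 0,
) -> list[Palindrome]:
    """All maximal hairpins in ``seq`` subject to the given constraints.

    Sorted by offset, then descending arm length.
    """
    _check_dna(seq)
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if max_arm < min_arm or min_loop < 0 or max_loop < min_loop or max_mismatch < 0:
        raise ValueError("inconsistent hairpin parameters")
    hits = [
        Palindrome(o, a, l, mm, seq[o : o + 2 * a + l])
        for o, a, l, mm in _scan_hairpins(seq, min_arm, max_arm, min_loop, max_loop, max_mismatch)
    ]
    hits.sort(key=lambda p: (p.offset, -p.arm_len, p.loop_len))
    return hits


def find_hairpins_with_span(
    seq: str,
    span_min: int,
    span_max: int,
    max_loop: int,
    max_mismatch: int = 0,
) -> list[Palindrome]:
    """Maximal hairpins whose total span lies in ``[span_min, span_max]``.

    Runs the maximal-hairpin scan once per loop length with the arm bound
    derived from the span cap, so a hit is maximal *subject to the span
    constraint* (an arm extension that would overflow the span cap does not
    disqualify it).
    """
    hits: list[Palindrome] = []
    for loop in range(0, max_loop + 1):
        min_arm = max(2, -(-(span_min - loop) // 2))
        max_arm = (span_max - loop) // 2
        if max_arm < min_arm:
            continue
        hits.extend(
            p
            for p in find_palindromes(seq, min_arm, max_arm, loop, loop, max_mismatch)
            if span_min <= p.span <= span_max
        )
    hits.sort(key=lambda p: (p.offset, -p.arm_len, p.loop_len))
    return hits


def find_inverted_repeat_pairs(
    seq: str,
    min_arm: int,
    min_gap: int,
    max_gap: int,
    max_mismatch: int = 0,
    max_arm: Optional[int] = None,
    seqid: str = "query",
) -> list[IRPair]:
    """All maximal dispersed inverted-repeat arm pairs with gap in range.

    A perfect hairpin is the ``gap == loop`` special case and is reported
    whenever the gap bounds allow it.  Arms never overlap (gap >= 0).
    """
    _check_dna(seq)
    if min_arm < 2:
        raise ValueError("min_arm must be >= 2")
    if min_gap < 0 or max_gap < min_gap or max_mismatch < 0:
        raise ValueError("inconsistent IR parameters")
    if max_arm is None:
        max_arm = len(seq) // 2
    pairs = []
    for o, a, gap, mm in _scan_hairpins(seq, min_arm, max_arm, min_gap, max_gap, max_mismatch):
        left = GenomicInterval(seqid, o, o + a)
        right = GenomicInterval(seqid, o + a + gap, o + 2 * a + gap)
        pairs.append(IRPair(left=left, right=right, arm_len=a, mismatches=mm, gap=gap))
    pairs.sort(key=lambda p: (p.left.start, -p.arm_len, p.gap))
    return pairs


# ---------------------------------------------------------------------------
# vectorized genome-scale candidate scan

_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC[_b] = _i
# complement codes; N (4) maps to 5 so it never equals any code
_COMP = np.array([3, 2, 1, 0, 5], dtype=np.uint8)


def encode_dna(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def palindromic_sites(
    seq: str,
    span_min: int,
    span_max: int,
    max_mismatch: int = 0,
    max_loop: int = 1,
) -> list[Palindrome]:
    """Fast scan for near-palindromic segments of total span in range.

    Used for genome-wide subTIR candidate discovery; unlike
    :func:`find_palindromes` it reports every qualifying (offset, span)
    site without a maximality filter (overlapping candidates are resolved
    downstream by scoring).  Loops are restricted to ``<= max_loop``
    (palindromic subTIRs have loop 0, odd-length ones loop 1).
    """
    _check_dna(seq)
    n = len(seq)
    code = encode_dna(seq)
    comp = _COMP[code]
    out: list[Palindrome] = []
    for span in range(span_min, span_max + 1):
        if span > n:
            continue
        arm = span // 2
        loop = span - 2 * arm
        if loop > max_loop or arm < 2:
            continue
        width = n - span + 1
        mm = np.zeros(width, dtype=np.int16)
        for i in range(arm):
            mm += code[i : i + width] != comp[span - 1 - i : span - 1 - i + width]
        for o in np.nonzero(mm <= max_mismatch)[0]:
            o = int(o)
            out.append(Palindrome(o, arm, loop, int(mm[o]), seq[o : o + span]))
    out.sort(key=lambda p: (p.offset, -p.span))
    return out
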