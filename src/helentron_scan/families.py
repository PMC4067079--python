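"""Family/subfamily classification, naming, and deletion-derivative linking.

Families group elements whose subTIRs share a long-enough identical stretch
(longest common substring, orientation-maximized, >= 11 bp by default);
subfamilies group family members whose 3'-terminal windows (last 60 bp by
default, covering the 3' subTIR and stem-loop) align at >= 80% identity.
Both relations are closed by single linkage, so partitions are deterministic
and permutation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._align import global_affine, local_align
from .seq_io import reverse_complement

__all__ = [
    "ClassificationParams",
    "FamilyAssignment",
    "LinkReport",
    "shared_subtir_length",
    "assign_families",
    "three_prime_identity",
    "assign_subfamilies",
    "link_deletion_derivative",
    "name_element",
]


@dataclass(frozen=True)
class ClassificationParams:
    family_min_shared_subtir: int = 11
    subfamily_min_identity: float = 0.80
    subfamily_window: int = 60
    gap_inclusive_identity: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.subfamily_min_identity <= 1):
            raise ValueError("subfamily_min_identity must be in (0, 1]")
        if self.subfamily_window < self.family_min_shared_subtir:
            raise ValueError("subfamily_window smaller than subTIR threshold")


@dataclass
class FamilyAssignment:
    element_id: str
    family: int
    subfamily: str
    variant_index: int = 1
    autonomous: bool = False


@dataclass
class LinkReport:
    five_prime_identity: float
    three_prime_identity: float
    link: bool
    end_window: int


def _lcs_length(a: str, b: str) -> int:
    """Longest common substring length (classic DP; inputs are short)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        ai = a[i - 1]
        for j in range(1, len(b) + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def shared_subtir_length(a: str, b: str) -> int:
    """Longest identical stretch shared by two subTIRs, orientation-maximized."""
    if not a or not b:
        raise ValueError("empty subTIR")
    return max(_lcs_length(a, b), _lcs_length(a, reverse_complement(b)))


class _UnionFind:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root choice
            lo, hi = sorted((ra, rb))
            self.parent[hi] = lo


def assign_families(
    elements: Mapping[str, Sequence[str]],
    params: Optional[ClassificationParams] = None,
) -> tuple[dict[str, int], list[str]]:
    """Partition elements into families by shared subTIR length.

    ``elements`` maps element id to its detected subTIR sequences (either
    end; the pairwise relation takes the maximum over all subTIR pairs).
    Returns ``(id -> family number, excluded ids)``.  Family numbers are
    assigned by descending family size, ties broken by the lexicographically
    smallest subTIR in the family.
    """
    params = params or ClassificationParams()
    excluded = sorted(eid for eid, tirs in elements.items() if not tirs)
    ids = sorted(eid for eid in elements if elements[eid])
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = max(
                shared_subtir_length(x, y)
                for x in elements[a]
                for y in elements[b]
            )
            if shared >= params.family_min_shared_subtir:
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for eid in ids:
        groups.setdefault(uf.find(eid), []).append(eid)
    ordered = sorted(
        groups.values(),
        key=lambda members: (
            -len(members),
            min(min(elements[m]) for m in members),
        ),
    )
    assignment = {}
    for fam_no, members in enumerate(ordered, start=1):
        for m in members:
            assignment[m] = fam_no
    return assignment, excluded


def three_prime_identity(
    a: str,
    b: str,
    window: int = 60,
    gap_inclusive: bool = True,
) -> float:
    """Identity of the globally aligned 3'-terminal windows of two elements.

    Global alignment at match +1 / mismatch -1 / gap open -2 / gap extend -1;
    identity is matches over alignment columns (gap columns count against
    identity unless ``gap_inclusive=False``).
    """
    if len(a) < window or len(b) < window:
        raise ValueError(f"sequences must be >= window ({window} bp)")
    aln = global_affine(a[-window:], b[-window:])
    return aln.identity if gap_inclusive else aln.identity_ungapped


def _subfamily_letters(index: int) -> str:
    """0 -> A, 25 -> Z, 26 -> AA, ... (spreadsheet style)."""
    letters = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def assign_subfamilies(
    families: Mapping[str, int],
    sequences: Mapping[str, str],
    params: Optional[ClassificationParams] = None,
) -> dict[str, tuple[int, str]]:
    """Single-linkage subfamily partition within each family.

    Returns ``id -> (family, subfamily letter)``.  Letters run A, B, ... by
    descending subfamily size, ties broken by smallest member id; beyond Z
    they continue AA, AB, ...
    """
    params = params or ClassificationParams()
    out: dict[str, tuple[int, str]] = {}
    by_family: dict[int, list[str]] = {}
    for eid, fam in families.items():
        by_family.setdefault(fam, []).append(eid)
    for fam, members in by_family.items():
        members = sorted(members)
        uf = _UnionFind(members)
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                ident = three_prime_identity(
                    sequences[a],
                    sequences[b],
                    window=params.subfamily_window,
                    gap_inclusive=params.gap_inclusive_identity,
                )
                if ident >= params.subfamily_min_identity:
                    uf.union(a, b)
        groups: dict[str, list[str]] = {}
        for eid in members:
            groups.setdefault(uf.find(eid), []).append(eid)
        ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
        for idx, group in enumerate(ordered):
            letter = _subfamily_letters(idx)
            for eid in group:
                out[eid] = (fam, letter)
    return out


def link_deletion_derivative(
    autonomous: str,
    candidate: str,
    min_identity: float = 0.84,
    end_window: int = 200,
) -> LinkReport:
    """Test whether ``candidate`` is a deletion derivative of ``autonomous``.

    Both terminal windows of the candidate are locally aligned to the
    autonomous element; the link holds when both end identities reach
    ``min_identity`` (default 0.84; derivative-partner identities typically
    run from the mid-80s up to near-identity).
    """
    if len(autonomous) < len(candidate):
        raise ValueError("autonomous element must be at least as long as candidate")
    w = min(end_window, len(candidate))
    ends = [candidate[:w], candidate[-w:]]
    idents = []
    for end_seq in ends:
        aln = local_align(end_seq, autonomous)
        if aln is None or aln.aligned_columns < 0.5 * w:
            idents.append(0.0)
        else:
            # identity over the end window: unaligned query bases count as errors
            idents.append(aln.matches / max(w, aln.columns))
    link = idents[0] >= min_identity and idents[1] >= min_identity
    return LinkReport(idents[0], idents[1], link, w)


def name_element(
    species_code: str,
    assignment: Optional[FamilyAssignment],
    kind: str,
) -> str:
    """Canonical element name, e.g. HINE-Mo-1A.1 / Helentron-Cq-32A."""
    if kind == "proto-Helentron":
        return f"proto-Helentron-{species_code}"
    if assignment is None:
        raise ValueError(f"{kind} naming requires a family assignment")
    stem = f"{assignment.family}{assignment.subfamily}"
    if kind == "Helentron":
        return f"Helentron-{species_code}-{stem}"
    if kind == "HINE":
        return f"HINE-{species_code}-{stem}.{assignment.variant_index}"
    raise ValueError(f"unknown element kind {kind!r}")
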