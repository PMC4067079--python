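"""Pairwise alignment kernels shared by the classifier and empty-site search.

Scoring convention throughout: match +1, mismatch -1, first gap column -2,
each additional gap column -1 (affine).  Identity is matches / alignment
columns, gap columns counting against identity unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio import Align

__all__ = ["Alignment", "global_affine", "local_align"]

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -2.0  # cost of the first gap column
GAP_EXTEND = -1.0


@dataclass
class Alignment:
    """A pairwise alignment summary with block structure for coordinate maps."""

    score: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    matches: int
    columns: int
    aligned_columns: int  # columns with a residue on both rows
    blocks: list = field(default_factory=list)  # [((qs,qe),(ts,te)), ...]

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0

    @property
    def identity_ungapped(self) -> float:
        return self.matches / self.aligned_columns if self.aligned_columns else 0.0

    def map_query_to_target(self, qpos: int) -> Optional[int]:
        """Target coordinate aligned to (or immediately right of) ``qpos``."""
        for (qs, qe), (ts, te) in self.blocks:
            if qpos < qs:
                return ts
            if qs <= qpos < qe:
                return ts + (qpos - qs)
        return self.target_end if qpos >= self.query_end else None


def _summarize(query: str, target: str, aln, score: float) -> Alignment:
    qa = aln.aligned[0]
    ta = aln.aligned[1]
    blocks = []
    matches = 0
    aligned_cols = 0
    for (qs, qe), (ts, te) in zip(qa, ta):
        qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
        blocks.append(((qs, qe), (ts, te)))
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    if not blocks:
        return Alignment(score, 0, 0, 0, 0, 0, 0, 0, [])
    q0, q1 = blocks[0][0][0], blocks[-1][0][1]
    t0, t1 = blocks[0][1][0], blocks[-1][1][1]
    # gap columns between consecutive blocks
    gap_cols = 0
    for i in range(1, len(blocks)):
        dq = blocks[i][0][0] - blocks[i - 1][0][1]
        dt = blocks[i][1][0] - blocks[i - 1][1][1]
        gap_cols += dq + dt
    columns = aligned_cols + gap_cols
    return Alignment(score, q0, q1, t0, t1, matches, columns, aligned_cols, blocks)


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    # custom matrix so that N never matches anything (including N); used to
    # mask regions out of the empty-site search
    alphabet = "ACGTN"
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = MATCH if (a == b and a != "N") else MISMATCH
    aligner.substitution_matrix = mat
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_GLOBAL = None
_LOCAL = None


def _get_aligner(mode: str) -> Align.PairwiseAligner:
    global _GLOBAL, _LOCAL
    if mode == "global":
        if _GLOBAL is None:
            _GLOBAL = _aligner("global")
        return _GLOBAL
    if _LOCAL is None:
        _LOCAL = _aligner("local")
    return _LOCAL


def global_affine(query: str, target: str) -> Alignment:
    """Needleman-Wunsch/Gotoh global alignment at the shared scoring."""
    if not query or not target:
        raise ValueError("empty sequence")
    aligner = _get_aligner("global")
    aln = aligner.align(target, query)[0]
    summary = _summarize_global(query, target, aln, float(aln.score))
    return summary


def _summarize_global(query: str, target: str, aln, score: float) -> Alignment:
    # biopython orders (target, query); swap back
    ta = aln.aligned[0]
    qa = aln.aligned[1]
    blocks = []
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
        blocks.append(((qs, qe), (ts, te)))
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    # global alignment: columns include terminal gaps
    gap_cols = 0
    prev_q, prev_t = 0, 0
    for (qs, qe), (ts, te) in blocks:
        gap_cols += (qs - prev_q) + (ts - prev_t)
        prev_q, prev_t = qe, te
    gap_cols += (len(query) - prev_q) + (len(target) - prev_t)
    columns = aligned_cols + gap_cols
    return Alignment(score, 0, len(query), 0, len(target), matches, columns, aligned_cols, blocks)


def local_align(query: str, target: str) -> Optional[Alignment]:
    """Best Smith-Waterman local alignment at the shared scoring, or None."""
    if not query or not target:
        return None
    aligner = _get_aligner("local")
    try:
        aln = aligner.align(target, query)[0]
    except (IndexError, ValueError):
        return None
    score = float(aln.score)
    if score <= 0:
        return None
    ta = aln.aligned[0]
    qa = aln.aligned[1]
    blocks = []
    matches = 0
    aligned_cols = 0
    for (ts, te), (qs, qe) in zip(ta, qa):
        qs, qe, ts, te = int(qs), int(qe), int(ts), int(te)
        blocks.append(((qs, qe), (ts, te)))
        aligned_cols += qe - qs
        matches += sum(1 for a, b in zip(query[qs:qe], target[ts:te]) if a == b)
    if not blocks:
        return None
    q0, q1 = blocks[0][0][0], blocks[-1][0][1]
    t0, t1 = blocks[0][1][0], blocks[-1][1][1]
    gap_cols = 0
    for i in range(1, len(blocks)):
        gap_cols += blocks[i][0][0] - blocks[i - 1][0][1]
        gap_cols += blocks[i][1][0] - blocks[i - 1][1][1]
    columns = aligned_cols + gap_cols
    return Alignment(score, q0, q1, t0, t1, matches, columns, aligned_cols, blocks)
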