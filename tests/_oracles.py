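"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from scratch (plain enumeration /
textbook DP) and shares no code with the package's production paths.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def _pairs(a: str, b: str) -> bool:
    return (a, b) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def _hairpin_mismatches(seq: str, offset: int, arm: int, loop: int) -> int:
    mm = 0
    for i in range(arm):
        if not _pairs(seq[offset + i], seq[offset + 2 * arm + loop - 1 - i]):
            mm += 1
    return mm


def _valid(seq, offset, arm, loop, min_arm, max_arm, min_loop, max_loop, max_mm):
    if arm < min_arm or arm > max_arm or loop < min_loop or loop > max_loop:
        return False
    if offset < 0 or offset + 2 * arm + loop > len(seq):
        return False
    return _hairpin_mismatches(seq, offset, arm, loop) <= max_mm


def brute_force_hairpins(
    seq: str, min_arm: int, max_arm: int, min_loop: int, max_loop: int, max_mm: int
) -> set[tuple[int, int, int, int]]:
    """Every maximal (offset, arm, loop, mismatches) hairpin, by enumeration.

    A hit is maximal when neither the outward extension (offset-1, arm+1,
    same loop) nor the inward extension (same offset, arm+1, loop-2) is
    valid under the same constraints.
    """
    out = set()
    n = len(seq)
    for offset in range(n):
        for arm in range(min_arm, max_arm + 1):
            for loop in range(min_loop, max_loop + 1):
                if not _valid(seq, offset, arm, loop, min_arm, max_arm, min_loop, max_loop, max_mm):
                    continue
                outward = _valid(
                    seq, offset - 1, arm + 1, loop,
                    min_arm, max_arm, min_loop, max_loop, max_mm,
                )
                inward = _valid(
                    seq, offset, arm + 1, loop - 2,
                    min_arm, max_arm, min_loop, max_loop, max_mm,
                )
                if not outward and not inward:
                    out.add((offset, arm, loop, _hairpin_mismatches(seq, offset, arm, loop)))
    return out


# ---------------------------------------------------------------------------
# global alignment oracle (plain affine Needleman-Wunsch with traceback)

_NEG = -1e9


def nw_global(a: str, b: str, match=1.0, mismatch=-1.0, gopen=-2.0, gext=-1.0):
    """Global affine alignment; returns (score, matches, columns).

    Convention: the first gap column costs ``gopen``, later ones ``gext``.
    """
    m, n = len(a), len(b)
    M = [[_NEG] * (n + 1) for _ in range(m + 1)]
    X = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in b (consumes a)
    Y = [[_NEG] * (n + 1) for _ in range(m + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, m + 1):
        X[i][0] = gopen + (i - 1) * gext
    for j in range(1, n + 1):
        Y[0][j] = gopen + (j - 1) * gext
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gopen, X[i - 1][j] + gext, Y[i - 1][j] + gopen)
            Y[i][j] = max(M[i][j - 1] + gopen, Y[i][j - 1] + gext, X[i][j - 1] + gopen)
    # traceback (prefer diagonal on ties)
    i, j = m, n
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i][j])
    score = {"M": M, "X": X, "Y": Y}[state][i][j]
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        columns += 1
        if state == "M":
            if a[i - 1] == b[j - 1]:
                matches += 1
            s = match if a[i - 1] == b[j - 1] else mismatch
            prev = M[i - 1][j - 1] + s
            for cand in ("M", "X", "Y"):
                if abs({"M": M, "X": X, "Y": Y}[cand][i - 1][j - 1] + s - M[i][j]) < 1e-6:
                    state = cand
                    break
            i, j = i - 1, j - 1
        elif state == "X":
            target = X[i][j]
            if abs(M[i - 1][j] + gopen - target) < 1e-6:
                state = "M"
            elif abs(X[i - 1][j] + gext - target) < 1e-6:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            target = Y[i][j]
            if abs(M[i][j - 1] + gopen - target) < 1e-6:
                state = "M"
            elif abs(Y[i][j - 1] + gext - target) < 1e-6:
                state = "Y"
            else:
                state = "X"
            j -= 1
    return score, matches, columns


# ---------------------------------------------------------------------------
# full Smith-Waterman oracle (numba-compiled textbook affine local DP)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


@njit(cache=False)
def _sw_fill(q, t, match, mismatch, gopen, gext):
    m, n = q.shape[0], t.shape[0]
    H = np.zeros((m + 1, n + 1), np.float32)
    E = np.full((m + 1, n + 1), -1e9, np.float32)
    F = np.full((m + 1, n + 1), -1e9, np.float32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = H[i][j - 1] + gopen
            if E[i][j - 1] + gext > e:
                e = E[i][j - 1] + gext
            E[i][j] = e
            f = H[i - 1][j] + gopen
            if F[i - 1][j] + gext > f:
                f = F[i - 1][j] + gext
            F[i][j] = f
            if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1][j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0.0
            H[i][j] = h
    return H, E, F


def _sw_traceback(q, t, H, E, F, i, j, match, mismatch, gopen, gext):
    matches = 0
    columns = 0
    qi, tj = i, j
    state = "H"
    while H[qi][tj] > 0:
        if state == "H":
            s = match if (q[qi - 1] == t[tj - 1] and q[qi - 1] != 4) else mismatch
            if abs(H[qi][tj] - (H[qi - 1][tj - 1] + s)) < 1e-4:
                columns += 1
                if q[qi - 1] == t[tj - 1] and q[qi - 1] != 4:
                    matches += 1
                qi -= 1
                tj -= 1
            elif abs(H[qi][tj] - E[qi][tj]) < 1e-4:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if abs(E[qi][tj] - (H[qi][tj - 1] + gopen)) < 1e-4:
                state = "H"
            tj -= 1
        else:
            columns += 1
            if abs(F[qi][tj] - (H[qi - 1][tj] + gopen)) < 1e-4:
                state = "H"
            qi -= 1
    return qi, tj, matches, columns


def sw_best_hit(query: str, target_codes: np.ndarray, match=1.0, mismatch=-1.0,
                gopen=-2.0, gext=-1.0):
    """Best local alignment of query against encoded target.

    Returns (score, q0, q1, t0, t1, matches, columns) or None.
    """
    q = encode(query)
    H, E, F = _sw_fill(q, target_codes, match, mismatch, gopen, gext)
    i, j = np.unravel_index(np.argmax(H), H.shape)
    score = float(H[i][j])
    if score <= 0:
        return None
    q0, t0, matches, columns = _sw_traceback(
        q, target_codes, H, E, F, int(i), int(j), match, mismatch, gopen, gext
    )
    return score, q0, int(i), t0, int(j), matches, columns


def oracle_empty_sites(
    query: str,
    genome: str,
    min_identity: float = 0.90,
    min_coverage: float = 0.90,
    min_score: float = 40.0,
) -> list[tuple[str, int, int, float, float]]:
    """All empty-site hits by exhaustive full-genome local DP + masking.

    Returns (strand, t0, t1, identity, coverage) tuples for passing hits,
    sorted by genome position.  ``min_score`` bounds the iteration (any hit
    passing the thresholds scores far above it).
    """
    hits = []
    qlen = len(query)
    for strand, q in (("+", query), ("-", revcomp(query))):
        codes = encode(genome).copy()
        while True:
            best = sw_best_hit(q, codes)
            if best is None or best[0] < min_score:
                break
            score, q0, q1, t0, t1, matches, columns = best
            identity = matches / columns if columns else 0.0
            coverage = (q1 - q0) / qlen
            if identity >= min_identity and coverage >= min_coverage:
                hits.append((strand, t0, t1, identity, coverage))
            codes[t0:t1] = 4  # mask and rescan
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits
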