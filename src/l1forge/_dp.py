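"""Numba dynamic-programming kernels.

Three kernels live here, all deliberately free of Python objects so that
numba can compile them to tight machine loops:

* ``profile_align_core`` — affine-gap (Gotoh) alignment of two alignment
  profiles, used by the progressive nucleotide MSA.
* ``codon_align_core`` — codon-level alignment of a nucleotide sequence
  against an in-frame reference, with explicit 1–2 nt frameshift moves,
  used by the codon-aware MSA.
* ``hsp_scan_core`` — ungapped high-scoring-segment extraction along
  seeded diagonals, used by the genome annotation scanner.

Tie-breaking in all tracebacks prefers diagonal over vertical over
horizontal moves so results are deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1.0e30

# ---------------------------------------------------------------------------
# Profile Gotoh alignment
# ---------------------------------------------------------------------------
# States: 0 = M (column aligned to column), 1 = E (gap column in A, consume B),
# 2 = F (gap column in B, consume A).
# Pointer packing per cell (uint8): m_src | e_src << 2 | f_src << 4.


@njit(cache=True)
def profile_align_core(SA, SB, gap_open, gap_ext, free_end):
    """Align two profiles.

    SA: (LA, 5) profile of A; SB: (LB, 5) profile of B already multiplied by
    the 5x5 substitution matrix, so the match score of columns (i, j) is
    dot(SA[i], SB[j]). Returns (ptr, end_i, end_j, end_state, score).
    """
    LA = SA.shape[0]
    LB = SB.shape[0]
    ptr = np.zeros((LA + 1, LB + 1), dtype=np.uint8)

    prevM = np.full(LB + 1, NEG)
    prevE = np.full(LB + 1, NEG)
    prevF = np.full(LB + 1, NEG)
    curM = np.full(LB + 1, NEG)
    curE = np.full(LB + 1, NEG)
    curF = np.full(LB + 1, NEG)

    prevM[0] = 0.0
    for j in range(1, LB + 1):
        if free_end:
            prevE[j] = 0.0
        else:
            prevE[j] = -(gap_open + (j - 1) * gap_ext)
        ptr[0, j] = 1 << 2  # E from E

    best_score = NEG
    best_i = LA
    best_j = LB
    best_state = 0

    for i in range(1, LA + 1):
        for j in range(LB + 1):
            curM[j] = NEG
            curE[j] = NEG
            curF[j] = NEG
        if free_end:
            curF[0] = 0.0
        else:
            curF[0] = -(gap_open + (i - 1) * gap_ext)
        ptr[i, 0] = 2 << 4  # F from F

        for j in range(1, LB + 1):
            # match score of A column i-1 vs B column j-1
            s = 0.0
            for x in range(5):
                s += SA[i - 1, x] * SB[j - 1, x]

            # M: from (i-1, j-1), prefer M > E > F
            bm = prevM[j - 1]
            src = 0
            if prevE[j - 1] > bm:
                bm = prevE[j - 1]
                src = 1
            if prevF[j - 1] > bm:
                bm = prevF[j - 1]
                src = 2
            curM[j] = bm + s
            p = src

            # F: vertical (gap in B), from (i-1, j); prefer M > E, extension F
            bf = prevM[j] - gap_open
            fsrc = 0
            if prevE[j] - gap_open > bf:
                bf = prevE[j] - gap_open
                fsrc = 1
            if prevF[j] - gap_ext > bf:
                bf = prevF[j] - gap_ext
                fsrc = 2
            curF[j] = bf
            p |= fsrc << 4

            # E: horizontal (gap in A), from (i, j-1)
            be = curM[j - 1] - gap_open
            esrc = 0
            if curF[j - 1] - gap_open > be:
                be = curF[j - 1] - gap_open
                esrc = 2
            if curE[j - 1] - gap_ext > be:
                be = curE[j - 1] - gap_ext
                esrc = 1
            curE[j] = be
            p |= esrc << 2

            ptr[i, j] = p

        if free_end and i == LA:
            for j in range(LB + 1):
                for st in range(3):
                    v = curM[j] if st == 0 else (curE[j] if st == 1 else curF[j])
                    if v > best_score:
                        best_score = v
                        best_i = i
                        best_j = j
                        best_state = st
        if free_end:
            # candidates in the last column
            for st in range(3):
                v = curM[LB] if st == 0 else (curE[LB] if st == 1 else curF[LB])
                if v > best_score:
                    best_score = v
                    best_i = i
                    best_j = LB
                    best_state = st

        tmp = prevM
        prevM = curM
        curM = tmp
        tmp = prevE
        prevE = curE
        curE = tmp
        tmp = prevF
        prevF = curF
        curF = tmp

    if not free_end:
        best_score = prevM[LB]
        best_state = 0
        if prevE[LB] > best_score:
            best_score = prevE[LB]
            best_state = 1
        if prevF[LB] > best_score:
            best_score = prevF[LB]
            best_state = 2
        best_i = LA
        best_j = LB

    return ptr, best_i, best_j, best_state, best_score


def profile_traceback(ptr, end_i, end_j, end_state, LA, LB):
    """Decode a profile-alignment pointer matrix into two gap masks.

    Returns boolean arrays (ncols,) per input profile: True where the output
    column consumes a column of that profile.
    """
    path = []  # list of (consume_a, consume_b)
    # trailing free end gaps
    for _ in range(LA - end_i):
        path.append((True, False))
    for _ in range(LB - end_j):
        path.append((False, True))
    i, j, st = end_i, end_j, end_state
    while i > 0 or j > 0:
        p = ptr[i, j]
        if st == 0:
            if i == 0 or j == 0:
                break
            src = p & 3
            path.append((True, True))
            i -= 1
            j -= 1
            st = src
        elif st == 1:
            src = (p >> 2) & 3
            path.append((False, True))
            j -= 1
            st = src
            if j == 0 and i == 0:
                break
        else:
            src = (p >> 4) & 3
            path.append((True, False))
            i -= 1
            st = src
    # leading free end gaps
    for _ in range(i):
        path.append((True, False))
    for _ in range(j):
        path.append((False, True))
    path.reverse()
    a_mask = np.array([a for a, _ in path], dtype=np.bool_)
    b_mask = np.array([b for _, b in path], dtype=np.bool_)
    return a_mask, b_mask


# ---------------------------------------------------------------------------
# Codon-aware alignment with frameshift moves
# ---------------------------------------------------------------------------
# DP over (i = query nt consumed, c = reference codons consumed).
# States: 0 = M, 1 = GA (codon gap in query / ref codon unmatched),
# 2 = GB (codon insertion in query).
# M moves: 0 = codon/codon (i-3, c-1); 1 = fs-del2 (i-2, c-1);
#          2 = fs-del1 (i-1, c-1); 3 = fs-ins1 (i-1, c); 4 = fs-ins2 (i-2, c).
# Pointer packing (uint16): m_move | m_src << 3 | ga_src << 5 | gb_src << 7.

M_MOVES = np.array([[3, 1], [2, 1], [1, 1], [1, 0], [2, 0]], dtype=np.int64)


@njit(cache=True)
def codon_align_core(aa_q, aa_r, B, stop_code, gap_open, gap_ext,
                     frameshift_cost, stop_cost, free_end):
    """aa_q[i] = amino-acid code of query codon ending at nt i (i >= 3),
    aa_r[c] = code of reference codon c (0-based). B is the aa score matrix.
    """
    n = aa_q.shape[0] - 1  # query nt length
    m = aa_r.shape[0]      # reference codons
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint16)

    M = np.full((n + 1, m + 1), NEG)
    GA = np.full((n + 1, m + 1), NEG)
    GB = np.full((n + 1, m + 1), NEG)

    M[0, 0] = 0.0
    for c in range(1, m + 1):
        if free_end:
            GA[0, c] = 0.0
        else:
            GA[0, c] = -(gap_open + (c - 1) * gap_ext)
        ptr[0, c] = 1 << 5
    for i in range(3, n + 1, 3):
        if free_end:
            GB[i, 0] = 0.0
        else:
            GB[i, 0] = -(gap_open + (i // 3 - 1) * gap_ext)
        ptr[i, 0] = 2 << 7

    for i in range(1, n + 1):
        for c in range(m + 1):
            # --- M state ---
            best = NEG
            move = 0
            src = 0
            for mv in range(5):
                di = M_MOVES[mv, 0]
                dc = M_MOVES[mv, 1]
                if i - di < 0 or c - dc < 0:
                    continue
                if mv == 0:
                    add = float(B[aa_q[i], aa_r[c - 1]])
                    # stop penalty applies to internal stops only: the
                    # query's final codon is a legitimate terminator
                    if aa_q[i] == stop_code and i <= n - 3:
                        add -= stop_cost
                else:
                    add = -frameshift_cost
                pm = M[i - di, c - dc]
                pa = GA[i - di, c - dc]
                pb = GB[i - di, c - dc]
                v = pm
                s = 0
                if pa > v:
                    v = pa
                    s = 1
                if pb > v:
                    v = pb
                    s = 2
                v += add
                if v > best:
                    best = v
                    move = mv
                    src = s
            M[i, c] = best
            p = move | (src << 3)

            # --- GA: reference codon against gap ---
            if c >= 1:
                v = M[i, c - 1] - gap_open
                s = 0
                if GB[i, c - 1] - gap_open > v:
                    v = GB[i, c - 1] - gap_open
                    s = 2
                if GA[i, c - 1] - gap_ext > v:
                    v = GA[i, c - 1] - gap_ext
                    s = 1
                GA[i, c] = v
                p |= s << 5

            # --- GB: query codon insertion ---
            if i >= 3:
                v = M[i - 3, c] - gap_open
                s = 0
                if GA[i - 3, c] - gap_open > v:
                    v = GA[i - 3, c] - gap_open
                    s = 1
                if GB[i - 3, c] - gap_ext > v:
                    v = GB[i - 3, c] - gap_ext
                    s = 2
                GB[i, c] = v
                p |= s << 7

            ptr[i, c] = p

    # pick alignment end
    best_score = NEG
    end_i = n
    end_c = m
    end_state = 0
    if free_end:
        for c in range(m + 1):
            for st in range(3):
                v = M[n, c] if st == 0 else (GA[n, c] if st == 1 else GB[n, c])
                if v > best_score:
                    best_score = v
                    end_i = n
                    end_c = c
                    end_state = st
        for i in range(n + 1):
            for st in range(3):
                v = M[i, m] if st == 0 else (GA[i, m] if st == 1 else GB[i, m])
                if v > best_score:
                    best_score = v
                    end_i = i
                    end_c = m
                    end_state = st
    else:
        for st in range(3):
            v = M[n, m] if st == 0 else (GA[n, m] if st == 1 else GB[n, m])
            if v > best_score:
                best_score = v
                end_state = st

    return ptr, end_i, end_c, end_state, best_score


def codon_traceback(ptr, end_i, end_c, end_state, n, m):
    """Decode codon-alignment pointers.

    Returns (ops, n_frameshifts) where ops is a list of
    (query_nt_consumed, ref_codons_consumed) steps in 5'->3' order, with
    trailing/leading free gaps included.
    """
    ops = []
    nfs = 0
    # trailing unconsumed pieces (free end): pad with gap ops
    ti = n - end_i
    while ti >= 3:
        ops.append((3, 0))
        ti -= 3
    if ti:
        ops.append((ti, 0))  # unaligned overhang, not a frameshift event
    for _ in range(m - end_c):
        ops.append((0, 1))
    i, c, st = end_i, end_c, end_state
    while i > 0 or c > 0:
        p = ptr[i, c]
        if st == 0:
            if i == 0 and c == 0:
                break
            move = p & 7
            src = (p >> 3) & 3
            di, dc = int(M_MOVES[move, 0]), int(M_MOVES[move, 1])
            if di == 0 and dc == 0:
                break
            ops.append((di, dc))
            if move != 0:
                nfs += 1
            i -= di
            c -= dc
            st = src
        elif st == 1:
            src = (p >> 5) & 3
            ops.append((0, 1))
            c -= 1
            st = src
        else:
            src = (p >> 7) & 3
            ops.append((3, 0))
            i -= 3
            st = src
    # leading free-end remainders
    while i >= 3:
        ops.append((3, 0))
        i -= 3
    if i:
        ops.append((i, 0))  # unaligned overhang, not a frameshift event
    for _ in range(c):
        ops.append((0, 1))
    ops.reverse()
    return ops, nfs


# ---------------------------------------------------------------------------
# Ungapped HSP extraction along diagonals
# ---------------------------------------------------------------------------


@njit(cache=True)
def hsp_scan_core(q, s, diags, match, mismatch, smin):
    """Extract maximal ungapped segments with score >= smin on given diagonals.

    q, s: int8 code arrays (4 = ambiguous, always mismatched).
    diags: sorted int64 array of diagonals d = s_pos - q_pos to examine.
    Returns flat int64 array of records (q_start, q_end_excl, diag, score).
    """
    out = []
    nq = q.shape[0]
    ns = s.shape[0]
    for t in range(diags.shape[0]):
        d = diags[t]
        k0 = 0 if d >= 0 else -d
        k1 = min(nq, ns - d)
        if k1 <= k0:
            continue
        run = 0.0
        best = 0.0
        run_start = k0
        best_end = k0 - 1
        for k in range(k0, k1):
            a = q[k]
            b = s[k + d]
            if a < 4 and a == b:
                run += match
            else:
                run += mismatch
            if run <= 0.0:
                if best >= smin and best_end >= run_start:
                    out.append(run_start)
                    out.append(best_end + 1)
                    out.append(d)
                    out.append(int(best))
                run = 0.0
                best = 0.0
                run_start = k + 1
                best_end = k
            elif run > best:
                best = run
                best_end = k
        if best >= smin and best_end >= run_start:
            out.append(run_start)
            out.append(best_end + 1)
            out.append(d)
            out.append(int(best))
    res = np.empty(len(out), dtype=np.int64)
    for idx in range(len(out)):
        res[idx] = out[idx]
    return res
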