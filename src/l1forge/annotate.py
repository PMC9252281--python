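"""Genome re-annotation with composite subfamily models.

A seeded ungapped local-alignment scanner finds high-scoring segments of
each subfamily model on both strands of a genome, converts raw scores to
E-values with Karlin-Altschul statistics (lambda solved exactly from the
scoring system; K a configurable constant), applies per-class E-value
cutoffs (older, more degenerate subfamilies get a laxer cutoff), and then
defragments the hits: same-subfamily hits within 50 bp are joined,
different-subfamily hits overlapping by more than 30 bp (150 bp for
old-class hits) are grouped, and each group resolves to its lowest-E-value
member (bit-score tie-break, then a seeded random choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from . import seqio
from ._dp import hsp_scan_core

DEFAULT_K = 0.1  # conventional ungapped prefactor; overridable in config


@dataclass
class ScoringCalibration:
    """Karlin-Altschul parameters: E = K * m * n * exp(-lambda * S)."""

    lam: float
    K: float = DEFAULT_K

    def evalue(self, score: float, m: int, n: int) -> float:
        return self.K * m * n * np.exp(-self.lam * score)

    def min_score(self, e_cutoff: float, m: int, n: int) -> float:
        """Smallest raw score with E <= e_cutoff."""
        return np.log(self.K * m * n / e_cutoff) / self.lam


def calibrate_scoring(match: float, mismatch: float,
                      background=(0.25, 0.25, 0.25, 0.25),
                      K: float = DEFAULT_K) -> ScoringCalibration:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda by bisection.

    Requires a negative expected per-letter score (otherwise no positive
    root exists).
    """
    bg = np.asarray(background, dtype=float)
    S = np.full((4, 4), mismatch, dtype=float)
    np.fill_diagonal(S, match)
    expected = float(bg @ S @ bg)
    if expected >= 0:
        raise ValueError("expected per-letter score must be negative")

    def f(lam):
        return float(np.exp(lam * S).T @ bg @ bg) - 1.0

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e3:
            raise RuntimeError("failed to bracket lambda")
    lam = brentq(f, 1e-9, hi, xtol=1e-12)
    return ScoringCalibration(lam=float(lam), K=K)


@dataclass
class AnnotationHit:
    contig: str
    start: int
    end: int
    strand: str
    subfamily: str
    raw_score: float
    e_value: float
    hit_id: int = -1
    joined_from: list[int] = field(default_factory=list)
    log10_e: float = 0.0       # log10 E-value (robust to underflow)
    log10_kmn: float = 0.0     # log10(K*m*n) of the scan that produced it

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


def _seed_diagonals(q: np.ndarray, s: np.ndarray, k: int = 12) -> np.ndarray:
    """Diagonals (s_pos - q_pos) carrying at least one exact k-mer match."""
    if q.shape[0] < k or s.shape[0] < k:
        return np.empty(0, dtype=np.int64)

    def kmers(codes):
        n = codes.shape[0] - k + 1
        vals = np.zeros(n, dtype=np.int64)
        ok = np.ones(n, dtype=bool)
        for off in range(k):
            vals = vals * 4 + codes[off:n + off]
            ok &= codes[off:n + off] < 4
        return vals, ok

    qv, qok = kmers(q)
    sv, sok = kmers(s)
    order = np.argsort(qv[qok], kind="stable")
    q_sorted = qv[qok][order]
    q_pos = np.where(qok)[0][order]
    s_idx = np.where(sok)[0]
    s_vals = sv[sok]
    lo = np.searchsorted(q_sorted, s_vals, side="left")
    hi = np.searchsorted(q_sorted, s_vals, side="right")
    diags = []
    for t in range(s_vals.shape[0]):
        if lo[t] == hi[t]:
            continue
        spos = s_idx[t]
        diags.append(spos - q_pos[lo[t]:hi[t]])
    if not diags:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(diags))


def scan_genome(contigs: dict[str, str], models: dict[str, str],
                cutoffs: dict[str, float],
                calibration: ScoringCalibration | None = None,
                params=None, seed_k: int = 12) -> list[AnnotationHit]:
    """Scan a genome with subfamily models on both strands.

    ``cutoffs`` maps each model/subfamily name to its E-value cutoff (the
    per-class cutoffs are resolved by the caller). Hits are ungapped
    high-scoring segments on k-mer-seeded diagonals; fragmented hits are
    reassembled downstream by :func:`join_and_group_hits`.
    """
    from .align import AlignmentParams

    params = params or AlignmentParams()
    calibration = calibration or calibrate_scoring(params.match, params.mismatch)
    hits: list[AnnotationHit] = []
    hid = 0
    for contig_id in sorted(contigs):
        contig_seq = contigs[contig_id]
        s_fwd = seqio.encode(contig_seq)
        n = s_fwd.shape[0]
        for model_id in sorted(models):
            model_seq = models[model_id]
            q = seqio.encode(model_seq)
            m = q.shape[0]
            e_cut = cutoffs.get(model_id, 1e-6)
            smin = calibration.min_score(e_cut, m, n)
            for strand in ("+", "-"):
                sarr = s_fwd if strand == "+" else seqio.encode(
                    seqio.revcomp(contig_seq))
                diags = _seed_diagonals(q, sarr, k=seed_k)
                if diags.size == 0:
                    continue
                rec = hsp_scan_core(q, sarr, diags, params.match,
                                    params.mismatch, float(smin))
                for r in range(0, rec.shape[0], 4):
                    qs, qe, d, score = rec[r], rec[r + 1], rec[r + 2], rec[r + 3]
                    ss, se = int(qs + d), int(qe + d)
                    if strand == "-":
                        ss, se = n - se, n - ss
                    log10_kmn = float(np.log10(calibration.K)
                                      + np.log10(m) + np.log10(n))
                    log10_e = log10_kmn - calibration.lam * float(score) \
                        / np.log(10.0)
                    if log10_e > np.log10(e_cut):
                        continue
                    hits.append(AnnotationHit(
                        contig=contig_id, start=ss, end=se, strand=strand,
                        subfamily=model_id, raw_score=float(score),
                        e_value=float(10.0 ** max(log10_e, -300.0)),
                        hit_id=hid, log10_e=log10_e, log10_kmn=log10_kmn))
                    hid += 1
    hits.sort(key=lambda h: (h.contig, h.start, h.end, h.subfamily, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Join / group / resolve
# ---------------------------------------------------------------------------


def _join_same_subfamily(hits: list[AnnotationHit], join_gap: int,
                         calibration: ScoringCalibration | None
                         ) -> list[AnnotationHit]:
    out: list[AnnotationHit] = []
    keyed: dict = {}
    for h in hits:
        keyed.setdefault((h.contig, h.strand, h.subfamily), []).append(h)
    for key in sorted(keyed):
        group = sorted(keyed[key], key=lambda h: (h.start, h.end))
        cur = None
        for h in group:
            if cur is not None and h.start - cur.end <= join_gap:
                cur.end = max(cur.end, h.end)
                cur.raw_score += h.raw_score
                if calibration is not None:
                    # E-value of the join from its combined score, reusing
                    # the member's K*m*n prefactor (log space: large scores
                    # underflow linear E-values)
                    cur.log10_e = cur.log10_kmn - calibration.lam \
                        * cur.raw_score / np.log(10.0)
                else:
                    cur.log10_e = min(cur.log10_e, h.log10_e)
                cur.e_value = float(10.0 ** max(cur.log10_e, -300.0))
                cur.joined_from.extend(h.joined_from or [h.hit_id])
            else:
                if cur is not None:
                    out.append(cur)
                cur = AnnotationHit(
                    contig=h.contig, start=h.start, end=h.end,
                    strand=h.strand, subfamily=h.subfamily,
                    raw_score=h.raw_score, e_value=h.e_value,
                    hit_id=h.hit_id,
                    joined_from=list(h.joined_from or [h.hit_id]),
                    log10_e=h.log10_e, log10_kmn=h.log10_kmn)
        if cur is not None:
            out.append(cur)
    out.sort(key=lambda h: (h.contig, h.start, h.end, h.subfamily))
    return out


def join_and_group_hits(hits: list[AnnotationHit], join_gap: int = 50,
                        overlap_min: int = 30, overlap_min_old: int = 150,
                        old_classes: set[str] | frozenset = frozenset(),
                        seed: int = 0,
                        calibration: ScoringCalibration | None = None
                        ) -> list[AnnotationHit]:
    """Defragment and de-conflict annotation hits.

    Same-subfamily, same-strand hits within ``join_gap`` bp are joined; with
    a calibration the join's E-value is recomputed from its combined score,
    otherwise it is the minimum member E-value. Joined hits from different
    subfamilies are grouped when they overlap by more than ``overlap_min``
    bases (``overlap_min_old`` when either member is old-class), and each
    group keeps only its lowest-E-value member, with bit/raw-score tie-break
    and finally a seeded random choice.
    """
    rng = np.random.default_rng(seed)
    joined = _join_same_subfamily(hits, join_gap, calibration)

    # union-find over grouping pairs
    parent = list(range(len(joined)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_contig: dict = {}
    for i, h in enumerate(joined):
        by_contig.setdefault(h.contig, []).append(i)
    for contig in sorted(by_contig):
        idx = sorted(by_contig[contig], key=lambda i: joined[i].start)
        for a_pos in range(len(idx)):
            i = idx[a_pos]
            for b_pos in range(a_pos + 1, len(idx)):
                j = idx[b_pos]
                if joined[j].start >= joined[i].end:
                    break
                if joined[i].subfamily == joined[j].subfamily:
                    continue
                ov = min(joined[i].end, joined[j].end) - joined[j].start
                thresh = overlap_min
                if (joined[i].subfamily in old_classes
                        or joined[j].subfamily in old_classes):
                    thresh = overlap_min_old
                if ov > thresh:
                    union(i, j)

    groups: dict = {}
    for i in range(len(joined)):
        groups.setdefault(find(i), []).append(i)

    out = []
    for root in sorted(groups):
        members = groups[root]
        best_e = min(joined[i].log10_e for i in members)
        pool = [i for i in members if joined[i].log10_e == best_e]
        if len(pool) > 1:
            best_s = max(joined[i].raw_score for i in pool)
            pool = [i for i in pool if joined[i].raw_score == best_s]
        if len(pool) > 1:
            pool = [pool[int(rng.integers(0, len(pool)))]]
        out.append(joined[pool[0]])
    out.sort(key=lambda h: (h.contig, h.start, h.end, h.subfamily))
    return out


# ---------------------------------------------------------------------------
# Evaluation against truth and tables
# ---------------------------------------------------------------------------


def base_accuracy(hits: list[AnnotationHit], truth_bed) -> float:
    """Bases assigned to the true subfamily / bases assigned at all."""
    correct = 0
    assigned = 0
    truth_by_contig: dict = {}
    for _, row in truth_bed.iterrows():
        truth_by_contig.setdefault(row["chrom"], []).append(
            (row["start"], row["end"], row["subfamily"]))
    for h in hits:
        intervals = truth_by_contig.get(h.contig, [])
        length = h.end - h.start
        assigned += length
        for s, e, sub in intervals:
            ov = min(h.end, e) - max(h.start, s)
            if ov > 0 and sub == h.subfamily:
                correct += ov
    if assigned == 0:
        return float("nan")
    return correct / assigned


def hits_to_dataframe(hits: list[AnnotationHit]):
    import pandas as pd

    return pd.DataFrame([{
        "chrom": h.contig, "start": h.start, "end": h.end,
        "name": h.subfamily, "score": h.raw_score, "strand": h.strand,
        "evalue": h.e_value, "log10_e": h.log10_e,
        "joined_from": ",".join(map(str, h.joined_from)) or str(h.hit_id),
    } for h in hits])
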