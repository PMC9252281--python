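"""Alignment machinery for the reconstruction pipeline.

Four operations are provided:

* :func:`pairwise_align` — affine-gap global/local nucleotide alignment
  (delegates to Biopython's ``PairwiseAligner``).
* :func:`progressive_msa` — guide-tree progressive profile alignment of
  nucleotide sequences, the workhorse for aligning L1 copies prior to
  ancestral reconstruction.
* :func:`codon_aware_msa` — codon-level alignment of putative coding
  sequences with explicit, heavily penalised 1–2 nt frameshift moves, used
  to repair reading frames before ORF reconstruction.
* :func:`translated_search` — local search of a nucleotide query, translated
  in the three forward frames, against a protein subject with
  Karlin–Altschul bit scores and E-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import seqio
from ._dp import (codon_align_core, codon_traceback, profile_align_core,
                  profile_traceback)

# Published Karlin-Altschul parameters for gapped BLOSUM62 with open 11 /
# extend 1, as used by BLASTX; configurable per call.
BLOSUM62_GAPPED_LAMBDA = 0.267
BLOSUM62_GAPPED_K = 0.041

AA_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
STOP_CODE = AA_INDEX["*"]


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 as a dense int array over AA_ALPHABET."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(AA_ALPHABET), len(AA_ALPHABET)), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = int(m[a, b])
    return out


_BLOSUM62 = _blosum62_matrix()


@dataclass
class AlignmentParams:
    """Scoring parameters for all alignment modes.

    Nucleotide defaults are match +5 / mismatch -4 with affine gap cost
    ``gap_open + k * gap_extend`` for a gap of length k. Amino-acid mode
    uses BLOSUM62 with open 11 / extend 1. Codon mode charges
    ``frameshift_cost`` per 1-2 nt frameshift event and ``stop_cost`` per
    stop codon placed in the alignment.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 1.0
    aa_gap_open: float = 11.0
    aa_gap_extend: float = 1.0
    frameshift_cost: float = 30.0
    stop_cost: float = 100.0
    # penalty for an observed internal stop when aligning degraded fossil
    # copies to a coding scaffold: must stay below 2*frameshift_cost or the
    # aligner hallucinates compensating frameshifts around genuine stops
    stop_cost_degraded: float = 10.0
    aa_matrix: np.ndarray = field(default_factory=lambda: _BLOSUM62, repr=False)

    def __post_init__(self):
        if self.gap_open < self.gap_extend:
            raise ValueError("gap_open must be >= gap_extend")
        if self.frameshift_cost <= self.gap_extend:
            raise ValueError("frameshift_cost must exceed gap_extend")


@dataclass
class Msa:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: list[str]
    rows: list[str]
    frameshifts: dict[str, int] | None = None

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def column_map(self, i: int) -> np.ndarray:
        """Map column -> 0-based ungapped coordinate in row i (-1 at gaps)."""
        codes = np.frombuffer(self.rows[i].encode(), dtype=np.uint8)
        isres = codes != ord("-")
        out = np.cumsum(isres) - 1
        out[~isres] = -1
        return out

    def codes(self) -> np.ndarray:
        """(nrows, ncols) int8 encoding, gaps/N = 4."""
        return np.vstack([seqio.encode(r) for r in self.rows])

    def write(self, path) -> None:
        seqio.write_fasta(path, zip(self.ids, self.rows))

    @classmethod
    def read(cls, path) -> "Msa":
        recs = seqio.read_fasta(path)
        return cls(list(recs), list(recs.values()))


@dataclass
class LocalHit:
    """One local alignment hit from translated search.

    ``query_span`` is in nucleotide coordinates on the query;
    ``subject_span`` in amino-acid coordinates on the subject.
    """

    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    frame: int
    raw_score: float
    bit_score: float
    e_value: float


# ---------------------------------------------------------------------------
# Pairwise alignment (Biopython backend)
# ---------------------------------------------------------------------------


def _nt_aligner(params: AlignmentParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


def pairwise_align(a: str, b: str, params: AlignmentParams | None = None,
                   mode: str = "global") -> tuple[str, str, float]:
    """Optimal affine-gap alignment of two nucleotide sequences.

    Returns the two gapped rows and the optimal score. ``mode`` is
    ``"global"`` or ``"local"`` (maximal-scoring subpair).
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if mode not in ("global", "local"):
        raise ValueError(f"unknown mode {mode!r}")
    params = params or AlignmentParams()
    al = _nt_aligner(params, mode)
    aln = al.align(a.upper(), b.upper())
    best = aln[0]
    return best[0], best[1], float(best.score)


def pairwise_align_spans(a: str, b: str, params: AlignmentParams | None = None,
                         mode: str = "local"):
    """Like :func:`pairwise_align` but also returns the aligned spans
    (a_start, a_end, b_start, b_end) in ungapped coordinates."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    params = params or AlignmentParams()
    al = _nt_aligner(params, mode)
    best = al.align(a.upper(), b.upper())[0]
    coords = best.coordinates
    spans = (int(coords[0, 0]), int(coords[0, -1]),
             int(coords[1, 0]), int(coords[1, -1]))
    return best[0], best[1], float(best.score), spans


# ---------------------------------------------------------------------------
# Progressive nucleotide MSA
# ---------------------------------------------------------------------------


def kmer_distance_matrix(seqs: list[str], k: int = 6) -> np.ndarray:
    """Distance d = 1 - |shared k-mers| / min(|A|, |B|) over distinct k-mers."""
    sets = []
    for s in seqs:
        codes = seqio.encode(s)
        if codes.shape[0] < k:
            sets.append(frozenset())
            continue
        valid = codes < 4
        kmers = np.zeros(codes.shape[0] - k + 1, dtype=np.int64)
        ok = np.ones(codes.shape[0] - k + 1, dtype=bool)
        for off in range(k):
            kmers = kmers * 4 + codes[off:codes.shape[0] - k + 1 + off]
            ok &= valid[off:codes.shape[0] - k + 1 + off]
        sets.append(frozenset(kmers[ok].tolist()))
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j]))
            if denom == 0:
                dij = 1.0
            else:
                dij = 1.0 - len(sets[i] & sets[j]) / denom
            d[i, j] = d[j, i] = dij
    return d


def _merge_order(dist: np.ndarray) -> list[tuple]:
    """Guide topology as a nested tuple structure of leaf indices, built by
    neighbor joining on the k-mer distance matrix."""
    n = dist.shape[0]
    if n == 2:
        return [(0, 1)]
    from . import phylo

    ids = [f"_s{i}" for i in range(n)]
    tree = phylo.neighbor_joining(dist, ids)
    order: list[tuple] = []

    def visit(node):
        if node.is_tip():
            return int(node.name[2:])
        children = [visit(c) for c in node.children]
        cur = children[0]
        for nxt in children[1:]:
            order.append((cur, nxt))
            cur = ("join", len(order) - 1)
        return cur

    visit(tree)
    return order


_PROFILE_S = None


def _profile_submatrix(params: AlignmentParams) -> np.ndarray:
    s = np.zeros((5, 5))
    s[:4, :4] = params.mismatch
    np.fill_diagonal(s[:4, :4], params.match)
    return s


def _align_groups(mat_a: np.ndarray, mat_b: np.ndarray,
                  params: AlignmentParams, free_end: bool) -> np.ndarray:
    """Align two alignments (int8 matrices) and return the merged matrix."""
    S = _profile_submatrix(params)
    pa = np.zeros((mat_a.shape[1], 5), dtype=np.float64)
    pb = np.zeros((mat_b.shape[1], 5), dtype=np.float64)
    for x in range(5):
        pa[:, x] = (mat_a == x).mean(axis=0)
        pb[:, x] = (mat_b == x).mean(axis=0)
    sb = pb @ S.T
    go = params.gap_open + params.gap_extend
    ptr, ei, ej, est, _ = profile_align_core(pa, sb, go, params.gap_extend,
                                             free_end)
    a_mask, b_mask = profile_traceback(ptr, ei, ej, est,
                                       mat_a.shape[1], mat_b.shape[1])
    ncols = a_mask.shape[0]
    out = np.full((mat_a.shape[0] + mat_b.shape[0], ncols), 4, dtype=np.int8)
    out[: mat_a.shape[0], a_mask] = mat_a
    out[mat_a.shape[0]:, b_mask] = mat_b
    return out


def progressive_msa(seqs: list[str], params: AlignmentParams | None = None,
                    ids: list[str] | None = None, k: int = 6,
                    free_end_gaps: bool = True) -> Msa:
    """Guide-tree progressive profile alignment.

    The guide tree is built by neighbor joining on k-mer distances; groups
    are merged bottom-up with affine-gap profile alignment. Terminal gaps
    are free by default, which suits 5'-truncated transposon copies.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    params = params or AlignmentParams()
    seqs = seqio.as_str_list(seqs)
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(seqs))]

    dist = kmer_distance_matrix(seqs, k=k)
    order = _merge_order(dist)

    groups: dict = {}  # key -> (matrix, row ids)
    for i, s in enumerate(seqs):
        groups[i] = (seqio.encode(s).reshape(1, -1), [ids[i]])

    results = []
    for step, (a, b) in enumerate(order):
        ka = a if not isinstance(a, tuple) else ("join", a[1])
        kb = b if not isinstance(b, tuple) else ("join", b[1])
        mat_a, ids_a = groups.pop(ka)
        mat_b, ids_b = groups.pop(kb)
        merged = _align_groups(mat_a, mat_b, params, free_end_gaps)
        groups[("join", step)] = (merged, ids_a + ids_b)
        results = groups[("join", step)]

    mat, row_ids = results
    # restore input order
    perm = [row_ids.index(x) for x in ids]
    rows = [seqio.decode(mat[perm[i]]) for i in range(len(ids))]
    return Msa(ids=ids, rows=rows)


# ---------------------------------------------------------------------------
# Codon-aware MSA
# ---------------------------------------------------------------------------

# codon -> aa code lookup table over int codes (4**3 entries)
_CODON_AA = None


def _codon_table() -> np.ndarray:
    global _CODON_AA
    if _CODON_AA is None:
        from Bio.Seq import Seq

        tab = np.full(64, AA_INDEX["X"], dtype=np.int64)
        for i in range(64):
            codon = seqio.DNA[i // 16] + seqio.DNA[(i // 4) % 4] + seqio.DNA[i % 4]
            aa = str(Seq(codon).translate())
            tab[i] = AA_INDEX.get(aa, AA_INDEX["X"])
        _CODON_AA = tab
    return _CODON_AA


def _aa_codes_by_end(codes: np.ndarray) -> np.ndarray:
    """aa_q[i] = aa code of the codon ending at nt position i (1-based end)."""
    tab = _codon_table()
    n = codes.shape[0]
    out = np.full(n + 1, AA_INDEX["X"], dtype=np.int64)
    for i in range(3, n + 1):
        c0, c1, c2 = codes[i - 3], codes[i - 2], codes[i - 1]
        if c0 < 4 and c1 < 4 and c2 < 4:
            out[i] = tab[c0 * 16 + c1 * 4 + c2]
    return out


def count_stops(seq: str, frame: int = 0, terminal_window: int = 2) -> int:
    """Stop codons in the given frame, excluding the final ``terminal_window``
    codons."""
    aa = seqio.translate(seq[frame:])
    core = aa[: max(0, len(aa) - terminal_window)]
    return core.count("*")


def codon_pairwise(query: str, ref_inframe: str,
                   params: AlignmentParams | None = None,
                   free_end: bool = False, stop_cost: float | None = None):
    """Codon-aware alignment of ``query`` against an in-frame reference.

    Returns (query_row, ref_row, n_frameshifts, score): gapped strings where
    the reference row advances in whole codons and frameshift moves consume
    1-2 query nt against a reference codon or against nothing.
    """
    params = params or AlignmentParams()
    q = seqio.encode(query)
    rlen = len(ref_inframe) - len(ref_inframe) % 3
    r = seqio.encode(ref_inframe[:rlen])
    aa_q = _aa_codes_by_end(q)
    tab = _codon_table()
    aa_r = np.array([
        tab[r[3 * c] * 16 + r[3 * c + 1] * 4 + r[3 * c + 2]]
        if r[3 * c] < 4 and r[3 * c + 1] < 4 and r[3 * c + 2] < 4
        else AA_INDEX["X"]
        for c in range(rlen // 3)
    ], dtype=np.int64)
    go = 3.0 * (params.aa_gap_open + params.aa_gap_extend)
    ge = 3.0 * params.aa_gap_extend
    sc = params.stop_cost if stop_cost is None else stop_cost
    ptr, ei, ec, est, score = codon_align_core(
        aa_q, aa_r, params.aa_matrix, STOP_CODE, go, ge,
        params.frameshift_cost, sc, free_end)
    ops, nfs = codon_traceback(ptr, ei, ec, est, len(q), rlen // 3)

    qrow = []
    rrow = []
    qi = 0
    ci = 0
    for dq, dc in ops:
        qpart = query[qi:qi + dq]
        qi += dq
        if dc == 1:
            rpart = ref_inframe[3 * ci:3 * ci + 3]
            ci += 1
            qrow.append(qpart + "-" * (3 - dq))
            rrow.append(rpart)
        else:
            qrow.append(qpart)
            rrow.append("-" * dq)
    # leftover reference nt (non-multiple-of-3 tail)
    tail = ref_inframe[rlen:]
    if tail:
        qrow.append("-" * len(tail))
        rrow.append(tail)
    return "".join(qrow), "".join(rrow), nfs, float(score)


def _pick_reference(seqs: list[str]) -> int:
    stops = [count_stops(s) for s in seqs]
    best = min(range(len(seqs)),
               key=lambda i: (stops[i], -len(seqs[i]), i))
    return best


def codon_pairwise_protein(query_nt: str, ref_aa: str,
                           params: AlignmentParams | None = None,
                           free_end: bool = False,
                           stop_cost: float | None = None):
    """Codon-aware alignment of a nucleotide query against a reference
    protein (MACSE-like: all sequences descend from a common coding
    ancestor, and the reference protein supplies the clean frame).

    Returns (ops, n_frameshifts, score) where ops are
    (query_nt_consumed, ref_aa_consumed) steps in order.
    """
    params = params or AlignmentParams()
    q = seqio.encode(query_nt)
    aa_q = _aa_codes_by_end(q)
    aa_r = np.array([AA_INDEX.get(ch, AA_INDEX["X"]) for ch in ref_aa.upper()],
                    dtype=np.int64)
    go = 3.0 * (params.aa_gap_open + params.aa_gap_extend)
    ge = 3.0 * params.aa_gap_extend
    sc = params.stop_cost if stop_cost is None else stop_cost
    ptr, ei, ec, est, score = codon_align_core(
        aa_q, aa_r, params.aa_matrix, STOP_CODE, go, ge,
        params.frameshift_cost, sc, free_end)
    ops, nfs = codon_traceback(ptr, ei, ec, est, len(q), len(aa_r))
    return ops, nfs, float(score)


def _pick_reference(seqs: list[str]) -> int:
    stops = [count_stops(s) for s in seqs]
    best = min(range(len(seqs)),
               key=lambda i: (stops[i], -len(seqs[i]), i))
    return best


def _merge_on_scaffold(seqs, ops_per_seq, ncod, scaffold_codons=None):
    """Merge per-sequence codon alignments that share a scaffold of ``ncod``
    codon slots. ``scaffold_codons`` optionally supplies a reference row."""
    ins_w = np.zeros(ncod + 1, dtype=int)
    parsed = []
    for seq, ops in zip(seqs, ops_per_seq):
        before = [""] * (ncod + 1)
        at = [""] * ncod
        qi = 0
        c = 0
        for dq, dc in ops:
            piece = seq[qi:qi + dq]
            qi += dq
            if dc == 1:
                at[c] = piece
                c += 1
            else:
                before[c] += piece
        parsed.append((before, at))
        for c in range(ncod + 1):
            ins_w[c] = max(ins_w[c], len(before[c]))
    rows = []
    for before, at in parsed:
        parts = []
        for c in range(ncod):
            parts.append(before[c] + "-" * (ins_w[c] - len(before[c])))
            parts.append(at[c] + "-" * (3 - len(at[c])))
        parts.append(before[ncod] + "-" * (ins_w[ncod] - len(before[ncod])))
        rows.append("".join(parts))
    scaffold_row = None
    if scaffold_codons is not None:
        parts = []
        for c in range(ncod):
            parts.append("-" * ins_w[c])
            parts.append(scaffold_codons[c])
        parts.append("-" * ins_w[ncod])
        scaffold_row = "".join(parts)
    return rows, scaffold_row


def codon_aware_msa(orf_seqs: list[str], params: AlignmentParams | None = None,
                    ids: list[str] | None = None,
                    ref_protein: str | None = None,
                    ref_index: int | None = None) -> Msa:
    """Codon-aware multiple alignment of putative coding sequences.

    With ``ref_protein`` (preferred), every sequence is aligned against the
    reference protein's clean codon scaffold and the pairwise alignments are
    merged on protein coordinates — robust even when every input carries
    frameshifts. Otherwise a reference sequence (fewest frame-0 stops,
    longest on ties) is chosen from the inputs and used as an in-frame
    scaffold. Per-row frameshift-event counts are reported in
    ``Msa.frameshifts``.
    """
    if not orf_seqs:
        raise ValueError("no sequences")
    params = params or AlignmentParams()
    seqs = seqio.as_str_list(orf_seqs)
    ids = list(ids) if ids is not None else [f"orf{i}" for i in range(len(seqs))]
    if len(seqs) == 1 and ref_protein is None:
        return Msa(ids=ids, rows=list(seqs), frameshifts={ids[0]: 0})

    if ref_protein is not None:
        ncod = len(ref_protein)
        ops_all = []
        fs = {}
        for sid, s in zip(ids, seqs):
            ops, nfs, _ = codon_pairwise_protein(
                s, ref_protein, params, stop_cost=params.stop_cost_degraded)
            ops_all.append(ops)
            fs[sid] = nfs
        rows, _ = _merge_on_scaffold(seqs, ops_all, ncod)
        return Msa(ids=ids, rows=rows, frameshifts=fs)

    ref_i = ref_index if ref_index is not None else _pick_reference(seqs)
    ref = seqs[ref_i]
    rlen = len(ref) - len(ref) % 3
    ncod = rlen // 3
    tail = ref[rlen:]
    others = [i for i in range(len(seqs)) if i != ref_i]
    ops_all = []
    fs = {ids[ref_i]: 0}
    for i in others:
        qrow, rrow, nfs, _ = codon_pairwise(
            seqs[i], ref, params, stop_cost=params.stop_cost_degraded)
        fs[ids[i]] = nfs
        # convert the gapped rows back to (dq, dc) ops over ref codons
        ops = []
        pos = 0
        consumed = 0
        while pos < len(rrow) and consumed < ncod:
            if rrow[pos] == "-":
                dq = 0
                while pos < len(rrow) and rrow[pos] == "-":
                    dq += 1 if qrow[pos] != "-" else 0
                    pos += 1
                if dq:
                    ops.append((dq, 0))
            else:
                dq = sum(1 for k in range(3) if qrow[pos + k] != "-")
                ops.append((dq, 1))
                pos += 3
                consumed += 1
        # anything left in the query (vs the ref tail) is an insertion
        dq = sum(1 for k in range(pos, len(qrow)) if qrow[k] != "-")
        if dq:
            ops.append((dq, 0))
        ops_all.append(ops)
    scaffold = [ref[3 * c:3 * c + 3] for c in range(ncod)]
    rows, ref_row = _merge_on_scaffold([seqs[i] for i in others], ops_all,
                                       ncod, scaffold)
    if tail:
        rows = [r + "-" * len(tail) for r in rows]
        ref_row += tail
    out_rows = []
    it = iter(rows)
    for i in range(len(seqs)):
        out_rows.append(ref_row if i == ref_i else next(it))
    return Msa(ids=ids, rows=out_rows, frameshifts=fs)


# ---------------------------------------------------------------------------
# Translated local search
# ---------------------------------------------------------------------------


def _aa_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -(params.aa_gap_open + params.aa_gap_extend)
    al.extend_gap_score = -params.aa_gap_extend
    return al


def bit_score(raw: float, lam: float = BLOSUM62_GAPPED_LAMBDA,
              k: float = BLOSUM62_GAPPED_K) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def translated_search(query_nt: str, subject_aa: str,
                      params: AlignmentParams | None = None,
                      e_cutoff: float = 10.0,
                      bit_cutoff: float = 0.0,
                      max_hits_per_frame: int = 4,
                      lam: float = BLOSUM62_GAPPED_LAMBDA,
                      kparam: float = BLOSUM62_GAPPED_K) -> list[LocalHit]:
    """BLASTX-style search: translate the query in the 3 forward frames and
    locally align each translation against the protein subject.

    Within a frame, hits are extracted greedily: best local alignment, mask,
    realign (up to ``max_hits_per_frame``). Hits passing the E-value and bit
    cutoffs are returned sorted by bit score (descending).
    """
    if len(query_nt) < 3:
        raise ValueError("query must be at least 3 nt")
    params = params or AlignmentParams()
    subject_aa = subject_aa.upper()
    al = _aa_aligner(params)
    m_total = len(subject_aa)
    hits: list[LocalHit] = []
    for frame in range(3):
        aa = seqio.translate(query_nt[frame:])
        if not aa:
            continue
        work = list(aa)
        n_q = len(aa)
        for _ in range(max_hits_per_frame):
            try:
                alns = al.align("".join(work), subject_aa)
                best = alns[0]
            except (IndexError, ValueError):
                break
            raw = float(best.score)
            bits = bit_score(raw, lam, kparam)
            evalue = n_q * m_total * 2.0 ** (-bits)
            qa0, qa1 = int(best.coordinates[0, 0]), int(best.coordinates[0, -1])
            sa0, sa1 = int(best.coordinates[1, 0]), int(best.coordinates[1, -1])
            if raw <= 0 or evalue > e_cutoff or bits < bit_cutoff:
                break
            hits.append(LocalHit(
                query_span=(frame + 3 * qa0, frame + 3 * qa1),
                subject_span=(sa0, sa1),
                frame=frame,
                raw_score=raw,
                bit_score=bits,
                e_value=evalue,
            ))
            for p in range(qa0, qa1):
                work[p] = "X"
    hits.sort(key=lambda h: (-h.bit_score, h.frame, h.query_span))
    return hits


def hits_to_table(hits: list[LocalHit], qid: str = "query",
                  sid: str = "subject"):
    """LocalHit list as an outfmt-6-like pandas DataFrame."""
    import pandas as pd

    rows = []
    for h in hits:
        rows.append({
            "qid": qid, "sid": sid, "frame": h.frame,
            "qstart": h.query_span[0], "qend": h.query_span[1],
            "sstart": h.subject_span[0], "send": h.subject_span[1],
            "evalue": h.e_value, "bitscore": h.bit_score,
        })
    return pd.DataFrame(rows)
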