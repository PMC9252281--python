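"""Alignment machinery: DP optimality, MSA invariants, codon mode, search."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from l1forge import align, seqio

DNA = st.text(alphabet="ACGT", min_size=1, max_size=12)


# ---------------------------------------------------------------------------
# Independent oracle: enumerate every monotone alignment path and score it
# under the affine gap model (gap of length k costs open + k*ext).
# ---------------------------------------------------------------------------


def brute_force_global(a: str, b: str, match=5.0, mismatch=-4.0,
                       open_=10.0, ext=1.0) -> float:
    best = [-np.inf]

    def rec(i, j, score, prev_gap):
        # prev_gap: None, 'a' (gap in a), or 'b' (gap in b)
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            rec(i + 1, j + 1, score + s, None)
        if j < len(b):  # gap in a
            cost = ext if prev_gap == "a" else open_ + ext
            rec(i, j + 1, score - cost, "a")
        if i < len(a):  # gap in b
            cost = ext if prev_gap == "b" else open_ + ext
            rec(i + 1, j, score - cost, "b")

    rec(0, 0, 0.0, None)
    return best[0]


def test_global_identity_score():
    a, b, score = align.pairwise_align("ACGT", "ACGT")
    assert (a, b, score) == ("ACGT", "ACGT", 20.0)


def test_global_single_gap_example():
    a, b, score = align.pairwise_align("ACGT", "AGT")
    assert score == 4.0  # 3 matches (15) minus an 11-point length-1 gap
    assert a == "ACGT" and b.replace("-", "") == "AGT"


@pytest.mark.parametrize("seed", range(8))
def test_global_matches_exhaustive_enumeration(seed):
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(1, 8, size=2)
    a = "".join("ACGT"[i] for i in rng.integers(0, 4, n1))
    b = "".join("ACGT"[i] for i in rng.integers(0, 4, n2))
    _, _, score = align.pairwise_align(a, b)
    assert score == pytest.approx(brute_force_global(a, b))


@settings(max_examples=30, deadline=None)
@given(DNA, DNA)
def test_pairwise_score_symmetry_and_roundtrip(a, b):
    ra, rb, s_ab = align.pairwise_align(a, b)
    _, _, s_ba = align.pairwise_align(b, a)
    assert s_ab == pytest.approx(s_ba)
    assert ra.replace("-", "") == a
    assert rb.replace("-", "") == b


def test_local_recovers_planted_segment():
    rng = np.random.default_rng(7)
    core = "".join("ACGT"[i] for i in rng.integers(0, 4, 20))
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, 90))
    query = left + core + right
    _, _, score, (a0, a1, b0, b1) = align.pairwise_align_spans(
        query, core, mode="local")
    assert score == 100.0
    assert (a0, a1) == (90, 110)
    assert (b0, b1) == (0, 20)


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        align.pairwise_align("", "ACGT")


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def test_msa_identical_sequences_gap_free():
    seqs = ["ACGTACGTGGTTACGT"] * 5
    msa = align.progressive_msa(seqs)
    assert all("-" not in r for r in msa.rows)
    assert msa.n_cols == len(seqs[0])


def test_msa_single_insertion_makes_one_gap_block():
    base = "ACGTTGCAGGCTAACGGTAC"
    with_ins = base[:10] + "AAA" + base[10:]
    msa = align.progressive_msa([base, base, with_ins], free_end_gaps=False)
    for row_id, row in zip(msa.ids, msa.rows):
        gaps = [i for i, ch in enumerate(row) if ch == "-"]
        if msa.ungapped(msa.ids.index(row_id)) == base:
            assert len(gaps) == 3
            assert gaps[2] - gaps[0] == 2  # contiguous block
        else:
            assert not gaps


def test_msa_gap_strip_round_trip_with_truncation():
    rng = np.random.default_rng(3)
    anc = "".join("ACGT"[i] for i in rng.integers(0, 4, 400))

    def mutate(trunc):
        arr = [c if rng.random() > 0.08 else "ACGT"[rng.integers(0, 4)]
               for c in anc]
        return "".join(arr)[trunc:]

    seqs = [mutate(t) for t in (0, 0, 150, 250, 40)]
    msa = align.progressive_msa(seqs)
    assert [msa.ungapped(i) for i in range(5)] == seqs
    cm = msa.column_map(2)
    assert cm.max() == len(seqs[2]) - 1


def test_msa_column_count_stays_near_ancestral_length():
    from l1forge import simulate

    spec = simulate.ProgenitorSpec()
    root = simulate.simulate_progenitor(spec, seed=5)
    params = simulate.EvolutionParams(copies_per_subfamily=10,
                                      divergence_per_copy=0.08,
                                      truncation_prob=0.0, seed=5)
    truth = simulate.generate_copies(root, params)
    msa = align.progressive_msa([c.sequence for c in truth.copies])
    assert msa.n_cols <= 1.2 * len(root.progenitor_seq)


def test_msa_requires_two_sequences():
    with pytest.raises(ValueError):
        align.progressive_msa(["ACGT"])


# ---------------------------------------------------------------------------
# Codon-aware alignment
# ---------------------------------------------------------------------------

ORF = ("ATGGCTAAAGCTCGTGCTGGTACCTTGGACGAACGTATCAAAGAGCTGAAAGCC"
       "CGTATGGATCAGTTGGAAGCTCGTCTGAAAGAATAA")


def test_codon_identical_orfs_align_gap_free():
    msa = align.codon_aware_msa([ORF, ORF])
    assert msa.rows[0] == msa.rows[1] == ORF
    assert set(msa.frameshifts.values()) == {0}


def test_codon_single_deletion_annotated_and_frame_restored():
    broken = ORF[:31] + ORF[32:]  # 1-nt deletion mid-ORF
    msa = align.codon_aware_msa([ORF, broken, ORF], ids=["a", "x", "b"])
    assert msa.frameshifts["x"] == 1
    assert msa.frameshifts["a"] == msa.frameshifts["b"] == 0
    assert msa.ungapped(1) == broken
    # downstream of the frameshift, x realigns in frame with the others
    xrow, arow = msa.rows[1], msa.rows[0]
    tail_cols = range(msa.n_cols - 30, msa.n_cols)
    assert all(xrow[c] == arow[c] for c in tail_cols)


def test_codon_protein_scaffold_roundtrip():
    prot = seqio.translate(ORF)[:-1]
    broken = ORF[:40] + "G" + ORF[40:]
    msa = align.codon_aware_msa([ORF, broken], ref_protein=prot,
                                ids=["clean", "ins"])
    assert msa.ungapped(0) == ORF
    assert msa.ungapped(1) == broken
    assert msa.frameshifts["ins"] == 1
    assert msa.frameshifts["clean"] == 0


# ---------------------------------------------------------------------------
# Translated search
# ---------------------------------------------------------------------------


def test_translated_search_exact_backtranslation():
    subject = seqio.translate(ORF)[:-1]
    hits = align.translated_search(ORF, subject)
    best = hits[0]
    assert best.frame == 0
    assert best.query_span == (0, 3 * len(subject))
    assert best.subject_span == (0, len(subject))


def test_translated_search_insertion_splits_frames():
    subject = seqio.translate(ORF)[:-1]
    mid = len(ORF) // 2 - (len(ORF) // 2) % 3
    query = ORF[:mid] + "G" + ORF[mid:]
    hits = align.translated_search(query, subject)
    frames = {h.frame for h in hits}
    assert len(frames) >= 2
    for frame in sorted(frames)[:2]:
        span = max(h.subject_span[1] - h.subject_span[0]
                   for h in hits if h.frame == frame)
        assert span >= 0.4 * len(subject)


def test_translated_search_random_query_rarely_hits():
    rng = np.random.default_rng(0)
    subject = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                      for i in rng.integers(0, 20, 300))
    n_hits = 0
    for _ in range(100):
        query = "".join("ACGT"[i] for i in rng.integers(0, 4, 1000))
        n_hits += bool(align.translated_search(query, subject,
                                               e_cutoff=1e-6))
    assert n_hits <= 5  # no spurious hit in >=95% of random queries
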