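"""Simulator: structure invariants, edit traces, rates, genome round trips."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import binom

from l1forge import seqio, simulate
from l1forge.simulate import (EvolutionParams, ProgenitorSpec,
                              SubfamilyTruth, assemble_genome,
                              copy_coordinate_map, derive_gold_standards,
                              evolve_succession, extract_bed_span,
                              generate_copies, replay_copy,
                              simulate_kzfp_data, simulate_progenitor)


def test_progenitor_is_deterministic(default_spec):
    a = simulate_progenitor(default_spec, seed=1)
    b = simulate_progenitor(ProgenitorSpec(), seed=1)
    assert a.progenitor_seq == b.progenitor_seq
    assert simulate_progenitor(default_spec, 2).progenitor_seq \
        != a.progenitor_seq


def test_orf1_translates_to_338_aa(root_truth):
    a, b = root_truth.spec.orf1_span
    assert b - a == 1017
    aa = seqio.translate(root_truth.progenitor_seq[a:b])
    assert len(aa) == 339 and aa[-1] == "*" and "*" not in aa[:-1]
    assert aa[0] == "M"


def test_domain_motifs_encoded_verbatim(root_truth):
    spec = root_truth.spec
    for orf_id in ("ORF1", "ORF2"):
        a, b = spec.orf_span(orf_id)
        aa = seqio.translate(root_truth.progenitor_seq[a:b])
        for dom_id, motif, dom_orf, off in spec.domain_motifs:
            if dom_orf == orf_id:
                assert aa[off:off + len(motif)] == motif


@pytest.mark.parametrize("bad", [
    dict(total_length=6500, utr5_span=(0, 900), orf1_span=(900, 1916),
         igr_span=(1916, 2016), orf2_span=(2016, 5844),
         utr3_span=(5844, 6500)),                      # ORF1 not mult of 3
    dict(total_length=6500, utr5_span=(0, 800), orf1_span=(900, 1917),
         igr_span=(1917, 2017), orf2_span=(2017, 5845),
         utr3_span=(5845, 6500)),                      # spans do not tile
])
def test_invalid_spans_rejected(bad):
    with pytest.raises(ValueError):
        ProgenitorSpec(**bad)


def test_succession_zero_rate_identity(root_truth):
    params = EvolutionParams(succession_divergence=0.0, seed=4)
    succ = evolve_succession(root_truth, 3, params)
    assert all(s.progenitor_seq == root_truth.progenitor_seq for s in succ)


def test_succession_caterpillar_and_orf_integrity(root_truth):
    params = EvolutionParams(seed=4)
    succ = evolve_succession(root_truth, 5, params)
    assert succ[-1].genealogy == "((((S1,S2),S3),S4),S5);"
    for s in succ:
        a, b = s.spec.orf2_span
        aa = seqio.translate(s.progenitor_seq[a:b])
        assert aa[-1] == "*" and "*" not in aa[:-1]


def test_succession_site_loss_event():
    spec = ProgenitorSpec(
        kzfp_sites=[(simulate.DEFAULT_KZFP_ID, 300, True)])
    root = simulate_progenitor(spec, seed=2)
    succ = evolve_succession(root, 3, EvolutionParams(seed=2),
                             site_events=[(1, simulate.DEFAULT_KZFP_ID,
                                           "loss")])
    cons = simulate.DEFAULT_KZFP_CONSENSUS
    assert cons in succ[0].progenitor_seq
    for s in succ[1:]:
        assert cons not in s.progenitor_seq
        assert s.kzfp_sites[0][2] is False


def test_zero_divergence_copies_equal_progenitor(root_truth):
    params = EvolutionParams(divergence_per_copy=0.0, indel_rate=0.0,
                             copies_per_subfamily=10, seed=6)
    truth = generate_copies(root_truth, params)
    for c in truth.copies:
        expect = root_truth.progenitor_seq[c.truncation_point:] \
            if c.truncated else root_truth.progenitor_seq
        assert c.sequence == expect


def test_truncation_count_within_binomial_bounds(root_truth):
    params = EvolutionParams(copies_per_subfamily=200, truncation_prob=0.7,
                             divergence_per_copy=0.01, indel_rate=0.0, seed=8)
    truth = generate_copies(root_truth, params)
    n_trunc = sum(c.truncated for c in truth.copies)
    lo, hi = binom.ppf([0.0005, 0.9995], 200, 0.7)
    assert lo <= n_trunc <= hi
    assert 120 <= n_trunc <= 160


def test_saturated_divergence_rejected(root_truth):
    with pytest.raises(ValueError):
        generate_copies(root_truth,
                        EvolutionParams(divergence_per_copy=0.8))


def test_cpg_transitions_run_hotter():
    rng = np.random.default_rng(3)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 10000))
    params = EvolutionParams(cpg_transition_multiplier=10.0, seed=3)
    mutated, events = simulate._simulate_substitutions(seq, 0.02, params,
                                                       rng)
    codes = seqio.encode(seq)
    cpg = np.zeros(len(seq), dtype=bool)
    cpg[:-1] |= (codes[:-1] == 1) & (codes[1:] == 2)
    cpg[1:] |= (codes[1:] == 2) & (codes[:-1] == 1)
    ts_pairs = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}
    hit_cpg = hit_other = 0
    for pos, new in events:
        if (seq[pos], new) in ts_pairs:
            if cpg[pos]:
                hit_cpg += 1
            else:
                hit_other += 1
    rate_cpg = hit_cpg / max(1, cpg.sum())
    rate_other = hit_other / (len(seq) - cpg.sum())
    assert 6.0 <= rate_cpg / rate_other <= 14.0


def test_edit_trace_replay_reproduces_copies(root_truth):
    params = EvolutionParams(copies_per_subfamily=20, seed=5)
    truth = generate_copies(root_truth, params)
    for c in truth.copies:
        assert replay_copy(root_truth.progenitor_seq, c) == c.sequence


def test_coordinate_map_consistency(root_truth):
    params = EvolutionParams(copies_per_subfamily=10, seed=5)
    truth = generate_copies(root_truth, params)
    prog = root_truth.progenitor_seq
    for c in truth.copies:
        cmap = copy_coordinate_map(len(prog), c)
        substituted = {pos for pos, _ in c.subs}
        alive = np.where(cmap >= 0)[0]
        for i in alive[:: max(1, len(alive) // 50)]:
            if i not in substituted:
                assert c.sequence[cmap[i]] == prog[i]


def test_genome_roundtrip_and_determinism(root_truth):
    params = EvolutionParams(copies_per_subfamily=12, seed=5)
    truth = generate_copies(root_truth, params)
    contigs, bed = assemble_genome([truth], spacer_mean=300, seed=7)
    contigs2, bed2 = assemble_genome([truth], spacer_mean=300, seed=7)
    assert contigs == contigs2 and bed.equals(bed2)
    for i, (_, row) in enumerate(bed.iterrows()):
        assert extract_bed_span(contigs, row) == truth.copies[i].sequence


def test_single_copy_no_spacer_contig_equals_copy(root_truth):
    params = EvolutionParams(copies_per_subfamily=1, truncation_prob=0.0,
                             seed=5)
    truth = generate_copies(root_truth, params)
    contigs, bed = assemble_genome([truth], spacer_mean=0, seed=1)
    row = bed.iloc[0]
    assert len(bed) == 1
    assert extract_bed_span(contigs, row) == truth.copies[0].sequence
    assert len(contigs[row["chrom"]]) == len(truth.copies[0].sequence)


def test_gold_standards_tail_and_noise(root_truth):
    clean = derive_gold_standards([root_truth], tail_length=900,
                                  noise_rate=0.0, seed=1)
    assert clean["gold_S1"] == root_truth.progenitor_seq[-900:]
    noisy = derive_gold_standards([root_truth], tail_length=900,
                                  noise_rate=0.02, seed=1)
    ham = sum(a != b for a, b in zip(noisy["gold_S1"],
                                     root_truth.progenitor_seq[-900:]))
    assert 8 <= ham <= 28  # central binomial interval for Bin(900, 0.02)
    with pytest.warns(UserWarning):
        full = derive_gold_standards([root_truth], tail_length=10 ** 7,
                                     noise_rate=0.0, seed=1)
    assert full["gold_S1"] == root_truth.progenitor_seq


def _kzfp_truth(seed, present, n_copies=50):
    spec = ProgenitorSpec(
        kzfp_sites=[(simulate.DEFAULT_KZFP_ID, 6200, present)])
    root = simulate_progenitor(spec, seed=seed)
    params = EvolutionParams(copies_per_subfamily=n_copies, seed=seed)
    return generate_copies(root, params)


def test_kzfp_peaks_background_only_when_absent():
    truth = _kzfp_truth(3, present=False, n_copies=10)
    contigs, bed = assemble_genome([truth], seed=3)
    peaks, table = simulate_kzfp_data([truth], contigs, bed,
                                      simulate.DEFAULT_KZFP_ID,
                                      background_peaks=40, seed=3)
    assert len(peaks) == 40
    assert peaks["name"].str.startswith("peak_b").all()
    assert not table["bound"].any()


def test_kzfp_peaks_cover_site_bearing_copies():
    truth = _kzfp_truth(4, present=True, n_copies=50)
    contigs, bed = assemble_genome([truth], spacer_mean=5000, seed=4)
    peaks, table = simulate_kzfp_data([truth], contigs, bed,
                                      simulate.DEFAULT_KZFP_ID,
                                      background_peaks=20, seed=4)
    assert table["bound"].all()
    true_peaks = peaks[peaks["name"].str.startswith("peak_t")]
    n_overlap = 0
    for _, pk in true_peaks.iterrows():
        hit = bed[(bed["start"] < pk["end"]) & (bed["end"] > pk["start"])]
        n_overlap += int(len(hit) > 0)
    assert n_overlap >= 40
    peaks2, _ = simulate_kzfp_data([truth], contigs, bed,
                                   simulate.DEFAULT_KZFP_ID,
                                   background_peaks=20, seed=4)
    assert peaks.equals(peaks2)
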