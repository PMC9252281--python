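"""PWM construction, exact thresholds, scanning, and enrichment calls."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from l1forge import kzfp, seqio, simulate
from l1forge.kzfp import (Pwm, pfm_to_pwm, scan_pwm, score_distribution,
                          shuffle_peaks, threshold_from_pvalue)
from l1forge.kzfp import test_subfamily_enrichment as call_enrichment


def test_pwm_weight_formula():
    pfm = np.array([[10, 1], [0, 1], [0, 1], [0, 1]], dtype=float)
    pwm = pfm_to_pwm(pfm, pseudocount=1e-4)
    want_a = np.log2(((10 + 1e-4) / (10 + 4e-4)) / 0.25)
    assert pwm.weights[0, 0] == pytest.approx(want_a, abs=1e-12)
    assert pwm.weights[0, 0] == pytest.approx(2.0, abs=1e-4)
    # uniform column gives all-zero weights
    np.testing.assert_allclose(pwm.weights[:, 1], 0.0, atol=1e-12)
    # zero-count cells are finite (pseudocount prevents -inf)
    assert np.isfinite(pwm.weights).all()
    assert pwm.weights[1, 0] < -10


def test_pwm_rejects_bad_input():
    with pytest.raises(ValueError):
        pfm_to_pwm(np.zeros((4, 3)))
    with pytest.raises(ValueError):
        pfm_to_pwm(np.ones((3, 5)))


def _random_pwm(width, seed):
    rng = np.random.default_rng(seed)
    pfm = rng.integers(0, 60, size=(4, width)).astype(float) + rng.random((4, width))
    return pfm_to_pwm(pfm, motif_id=f"m{seed}")


def enumerate_distribution(pwm: Pwm):
    """Exhaustive background score distribution over all 4^w words, on the
    same discretized-score grid as the DP."""
    iw = np.round(pwm.weights / kzfp.SCORE_BIN).astype(np.int64)
    scores = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(iw[b, j] for j, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        scores[s] = scores.get(s, 0.0) + p
    return scores


def test_threshold_p_one_is_min_score():
    pwm = _random_pwm(5, 0)
    t = threshold_from_pvalue(pwm, 1.0)
    min_score = pwm.weights.min(axis=0).sum()
    assert t == pytest.approx(min_score, abs=2 * kzfp.SCORE_BIN)


def test_threshold_top_word_width3():
    # unique per-column maxima: p = 1/64 admits exactly the best word
    pfm = np.array([[90, 2, 2], [2, 90, 2], [2, 2, 90], [2, 2, 2]],
                   dtype=float)
    pwm = pfm_to_pwm(pfm)
    t = threshold_from_pvalue(pwm, 1.0 / 64.0)
    assert t == pytest.approx(pwm.weights.max(axis=0).sum(),
                              abs=2 * kzfp.SCORE_BIN)


@pytest.mark.parametrize("seed", range(4))
def test_dp_distribution_matches_enumeration(seed):
    pwm = _random_pwm(int(np.random.default_rng(seed).integers(3, 7)), seed)
    scores, probs = score_distribution(pwm)
    iscores = np.round(scores / kzfp.SCORE_BIN).astype(np.int64)
    want = enumerate_distribution(pwm)
    got = {int(s): float(p) for s, p in zip(iscores, probs) if p > 0}
    assert set(got) == set(want)
    for s in want:
        assert got[s] == pytest.approx(want[s], rel=1e-9)


def test_tiny_pvalue_warns_and_exceeds_max():
    pwm = _random_pwm(4, 3)
    with pytest.warns(UserWarning):
        t = threshold_from_pvalue(pwm, 1e-12)  # below 4^-4 point mass
    assert t > pwm.max_score


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


@pytest.fixture()
def fixture_pwm():
    return pfm_to_pwm(simulate.default_kzfp_pfm(),
                      motif_id=simulate.DEFAULT_KZFP_ID)


def _sequence_with_site(seed, pos=137, rc=False):
    rng = np.random.default_rng(seed)
    seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, 400)))
    site = simulate.DEFAULT_KZFP_CONSENSUS
    if rc:
        site = seqio.revcomp(site)
    seq[pos:pos + len(site)] = list(site)
    return "".join(seq)


def test_scan_finds_planted_site(fixture_pwm):
    hits = scan_pwm({"s": _sequence_with_site(1)}, fixture_pwm)
    assert any(h.position == 137 and h.strand == "+" for h in hits)


def test_scan_reports_minus_strand_in_plus_coords(fixture_pwm):
    hits = scan_pwm({"s": _sequence_with_site(2, rc=True)}, fixture_pwm)
    assert any(h.position == 137 and h.strand == "-" for h in hits)


def test_scan_of_reverse_complement_flips_strands(fixture_pwm):
    seq = _sequence_with_site(3)
    fwd = scan_pwm({"s": seq}, fixture_pwm)
    rev = scan_pwm({"s": seqio.revcomp(seq)}, fixture_pwm)
    L = len(seq)
    w = fixture_pwm.width
    mirrored = sorted((L - h.position - w, "+-"[h.strand == "+"])
                      for h in rev)
    assert mirrored == sorted((h.position, h.strand) for h in fwd)


def test_scan_count_calibration(fixture_pwm):
    """On i.i.d. uniform sequence the hit count matches the exact tail mass
    at the returned threshold (which is bounded by p), within Poisson
    fluctuation — and for a dense-support random PWM that tail is close to
    p itself, so the count tracks 2 * (L - w + 1) * p."""
    rng = np.random.default_rng(8)
    L = 200_000
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, L))

    def exact_tail(pwm, p):
        t = threshold_from_pvalue(pwm, p)
        scores, dist = score_distribution(pwm)
        tail = np.cumsum(dist[::-1])[::-1]
        i = np.searchsorted(scores, t - kzfp.SCORE_BIN / 2)
        return float(tail[i])

    smooth = _random_pwm(12, 99)  # moderate counts: dense score support
    for pwm in (fixture_pwm, smooth):
        for p in (1e-3, 1e-4):
            mass = exact_tail(pwm, p)
            assert mass <= p + 1e-12
            hits = scan_pwm({"s": seq}, pwm, p=p)
            lam = 2 * (L - pwm.width + 1) * mass
            assert abs(len(hits) - lam) <= 3 * np.sqrt(lam) + 1
    # dense support: the achievable tail sits within a few percent of p
    for p in (1e-3, 1e-4):
        assert exact_tail(smooth, p) >= 0.5 * p


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def _peaks(n, starts, chrom="c1", width=100, score_hi=True):
    return pd.DataFrame({
        "chrom": chrom, "start": list(starts)[:n],
        "end": [s + width for s in list(starts)[:n]],
        "name": [f"p{i}" for i in range(n)],
        "score": np.linspace(100, 50, n) if score_hi else np.linspace(9, 1, n),
        "strand": ".",
    })


def _loci(starts, chrom="c1", width=4000):
    return pd.DataFrame({"chrom": chrom, "start": list(starts),
                         "end": [s + width for s in starts],
                         "name": "locus", "subfamily": "S1", "strand": "+"})


def test_enrichment_dual_criterion():
    loci = _loci(range(0, 400_000, 10_000))
    inside = [s + 100 for s in range(0, 400_000, 10_000)]
    outside = range(1_000_000, 6_000_000, 10_000)
    obs = pd.concat([_peaks(40, inside), _peaks(460, outside)],
                    ignore_index=True)
    ctrl = _peaks(500, range(2_000_000, 8_000_000, 12_000))
    ctrl_hits = pd.concat([_peaks(2, inside[:2]), ctrl.iloc[2:]],
                          ignore_index=True)
    call = call_enrichment(obs, loci, ctrl_hits, subfamily="S1")
    assert call.n_top_peaks_overlapping == 40
    assert call.fisher_p < 1e-10
    assert call.enriched


def test_enrichment_count_rule_blocks_small_overlap():
    loci = _loci(range(0, 90_000, 10_000))
    inside = [s + 100 for s in range(0, 90_000, 10_000)]
    obs = pd.concat([_peaks(9, inside),
                     _peaks(491, range(1_000_000, 6_000_000, 10_000))],
                    ignore_index=True)
    ctrl = _peaks(500, range(2_000_000, 8_000_000, 12_000))
    call = call_enrichment(obs, loci, ctrl, subfamily="S1")
    assert call.n_top_peaks_overlapping == 9
    assert not call.enriched  # p may be tiny but 9 < 10 overlapping peaks


def test_enrichment_zero_overlap_p_one():
    loci = _loci([0])
    obs = _peaks(500, range(1_000_000, 6_000_000, 10_000))
    ctrl = _peaks(500, range(2_000_000, 8_000_000, 12_000))
    call = call_enrichment(obs, loci, ctrl, subfamily="S1")
    assert call.n_top_peaks_overlapping == 0
    assert call.fisher_p == pytest.approx(1.0)
    assert not call.enriched


def test_shuffled_controls_match_widths():
    obs = _peaks(50, range(0, 50_000, 1000), width=137)
    ctrl = shuffle_peaks(obs, {"c1": 10_000_000}, seed=4)
    assert ((ctrl["end"] - ctrl["start"]) == 137).all()
    assert (ctrl["start"] >= 0).all()
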