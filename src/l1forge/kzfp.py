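"""KZFP motif scanning and subfamily binding-enrichment calls.

Position frequency matrices are converted to log2-odds PWMs against a
uniform 0.25 background with pseudocount 1e-4; scan score thresholds are
derived from exact p-values by dynamic programming over the discretized
score distribution of background words (MOODS semantics). Subfamily-level
binding is called from ranked ChIP peaks with the dual criterion: one-tailed
Fisher exact p < 1e-10 against matched control peaks AND at least 10 of the
top 500 peaks overlapping the subfamily's genomic loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from . import seqio


def fisher_one_tailed(table) -> float:
    """One-tailed (greater) Fisher exact p for a 2x2 table: the upper
    hypergeometric tail of the top-left cell."""
    _, p = fisher_exact(table, alternative="greater")
    return float(p)

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)
DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_SCAN_P = 1e-6
ENRICH_P = 1e-10
ENRICH_MIN_PEAKS = 10
ENRICH_TOP_N = 500

SCORE_BIN = 1e-3  # bits; discretization for the exact-threshold DP


@dataclass
class Pwm:
    motif_id: str
    weights: np.ndarray          # (4, width) log2-odds
    background: np.ndarray
    pseudocount: float

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=0).sum())


@dataclass
class MotifHit:
    sequence_id: str
    position: int                # 0-based, plus-strand coordinates
    strand: str
    score: float
    p_value_bound: float


@dataclass
class EnrichmentCall:
    kzfp_id: str
    subfamily: str
    n_top_peaks_overlapping: int
    n_control_overlapping: int
    fisher_p: float
    enriched: bool


# ---------------------------------------------------------------------------
# PFM -> PWM
# ---------------------------------------------------------------------------


def pfm_to_pwm(pfm: np.ndarray, motif_id: str = "motif",
               background=DEFAULT_BACKGROUND,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> Pwm:
    """weights[i,j] = log2(((count+pc) / (colsum+4*pc)) / background[i])."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4:
        raise ValueError("PFM must be a 4 x width count matrix")
    if np.any(pfm < 0):
        raise ValueError("PFM counts must be non-negative")
    colsum = pfm.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("PFM has an all-zero column")
    bg = np.asarray(background, dtype=float)
    probs = (pfm + pseudocount) / (colsum + 4.0 * pseudocount)
    weights = np.log2(probs / bg[:, None])
    return Pwm(motif_id=motif_id, weights=weights, background=bg,
               pseudocount=pseudocount)


def read_jaspar_pfm(path, motif_id: str | None = None) -> Pwm:
    """Read a JASPAR-style 4-row count matrix (A/C/G/T rows)."""
    rows = {}
    name = motif_id
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = name or line[1:].split()[0]
                continue
            base = line[0].upper()
            nums = line.split("[")[-1].split("]")[0].split()
            rows[base] = [float(x) for x in nums]
    pfm = np.array([rows[b] for b in "ACGT"])
    return pfm_to_pwm(pfm, motif_id=name or "motif")


# ---------------------------------------------------------------------------
# Exact p-value score threshold
# ---------------------------------------------------------------------------


def _discretized_weights(pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Integer-scaled weights (4, w) and per-column minimum offsets."""
    iw = np.round(pwm.weights / SCORE_BIN).astype(np.int64)
    return iw, iw.min(axis=0)


def score_distribution(pwm: Pwm) -> tuple[np.ndarray, np.ndarray]:
    """Exact background score distribution of the discretized PWM.

    Returns (scores_in_bits, probabilities), dense over the achievable
    integer-score range, computed by column-wise convolution DP.
    """
    iw, mins = _discretized_weights(pwm)
    offsets = iw - mins[None, :]
    span = int(offsets.max(axis=0).sum()) + 1
    dist = np.zeros(span)
    dist[0] = 1.0
    width_used = 1
    for j in range(pwm.width):
        new = np.zeros(span)
        for b in range(4):
            o = offsets[b, j]
            new[o:o + width_used] += pwm.background[b] * dist[:width_used]
        dist = new
        width_used = min(span, width_used + int(offsets[:, j].max()))
    base = int(mins.sum())
    scores = (np.arange(span) + base) * SCORE_BIN
    return scores, dist


def threshold_from_pvalue(pwm: Pwm, p: float) -> float:
    """Smallest achievable score T with Pr_background(score >= T) <= p.

    T is reported on the support of the word-score distribution, so it is
    the lowest-scoring word the scan will still accept.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    scores, dist = score_distribution(pwm)
    tail = np.cumsum(dist[::-1])[::-1]
    ok = (tail <= p + 1e-15) & (dist > 0.0)
    idx = np.where(ok)[0]
    if idx.size == 0:
        warnings.warn("p below the minimal achievable point mass; "
                      "returning max score + epsilon")
        return float(scores[-1]) + SCORE_BIN
    return float(scores[idx[0]])


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------


_AMBIG_PENALTY = -(10 ** 9)


def _scan_scores(codes: np.ndarray, iweights: np.ndarray) -> np.ndarray:
    """Discretized window scores at every start position (windows containing
    an ambiguous base score far below any threshold)."""
    w = iweights.shape[1]
    L = codes.shape[0]
    if L < w:
        return np.empty(0, dtype=np.int64)
    padded = np.vstack([iweights,
                        np.full((1, w), _AMBIG_PENALTY, dtype=np.int64)])
    scores = np.zeros(L - w + 1, dtype=np.int64)
    for j in range(w):
        scores = scores + padded[codes[j:L - w + 1 + j], j]
    return scores


def scan_pwm(seqs: dict[str, str], pwm: Pwm, p: float = DEFAULT_SCAN_P,
             threshold: float | None = None) -> list[MotifHit]:
    """Exhaustive both-strand PWM scan at an exact p-value threshold.

    Scanning uses the same discretized score grid as the threshold DP, so
    the accepted word set is exactly the one the p-value bound defines.
    Minus-strand hits are reported on plus-strand coordinates (the hit
    interval is [position, position + width) either way).
    """
    if threshold is None:
        threshold = threshold_from_pvalue(pwm, p)
    t_int = round(threshold / SCORE_BIN)
    iw, _ = _discretized_weights(pwm)
    rc_iw = iw[::-1, ::-1]  # reverse-complement scan
    hits: list[MotifHit] = []
    for sid in seqs:
        codes = seqio.encode(seqs[sid])
        for strand, wmat in (("+", iw), ("-", rc_iw)):
            scores = _scan_scores(codes, wmat)
            for pos in np.where(scores >= t_int)[0]:
                hits.append(MotifHit(sequence_id=sid, position=int(pos),
                                     strand=strand,
                                     score=float(scores[pos]) * SCORE_BIN,
                                     p_value_bound=p))
    hits.sort(key=lambda h: (h.sequence_id, h.position, h.strand))
    return hits


def hits_to_bed(hits: list[MotifHit], pwm: Pwm):
    import pandas as pd

    return pd.DataFrame([{
        "chrom": h.sequence_id, "start": h.position,
        "end": h.position + pwm.width, "name": pwm.motif_id,
        "score": h.score, "strand": h.strand} for h in hits])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------


def _overlaps_any(peaks, loci) -> np.ndarray:
    """Boolean per peak: shares >=1 base with any locus (same chrom)."""
    flags = np.zeros(len(peaks), dtype=bool)
    by_chrom = {}
    for _, row in loci.iterrows():
        by_chrom.setdefault(row["chrom"], []).append((row["start"], row["end"]))
    sorted_loci = {c: sorted(v) for c, v in by_chrom.items()}
    for i, (_, pk) in enumerate(peaks.iterrows()):
        intervals = sorted_loci.get(pk["chrom"])
        if not intervals:
            continue
        starts = np.array([s for s, _ in intervals])
        ends = np.array([e for _, e in intervals])
        j = np.searchsorted(starts, pk["end"])
        if j > 0 and np.any(ends[:j] > pk["start"]):
            flags[i] = True
    return flags


def shuffle_peaks(peaks, contig_lengths: dict[str, int], seed: int = 0):
    """Width-matched uniformly placed control peaks."""
    rng = np.random.default_rng(seed)
    out = peaks.copy().reset_index(drop=True)
    starts = []
    for _, row in out.iterrows():
        width = row["end"] - row["start"]
        L = contig_lengths[row["chrom"]]
        starts.append(int(rng.integers(0, max(1, L - width))))
    out["start"] = starts
    out["end"] = out["start"] + (peaks["end"].values - peaks["start"].values)
    out["name"] = [f"ctrl_{i}" for i in range(len(out))]
    return out


def test_subfamily_enrichment(peaks, subfamily_loci, control_peaks,
                              kzfp_id: str = "kzfp", subfamily: str = "",
                              n_top: int = ENRICH_TOP_N,
                              p_threshold: float = ENRICH_P,
                              min_peaks: int = ENRICH_MIN_PEAKS
                              ) -> EnrichmentCall:
    """Dual-criterion enrichment call for one KZFP/subfamily pair.

    ``peaks`` must be ranked best-first; the top ``n_top`` are contrasted
    against the same number of control peaks in a 2x2 table (overlapping
    subfamily loci or not), tested one-tailed (greater) by Fisher's exact
    test / hypergeometric upper tail.
    """
    if len(peaks) < n_top:
        warnings.warn(f"only {len(peaks)} peaks available; using all")
    top = peaks.head(n_top)
    ctrl = control_peaks.head(n_top)
    k_obs = int(_overlaps_any(top, subfamily_loci).sum())
    k_ctl = int(_overlaps_any(ctrl, subfamily_loci).sum())
    table = [[k_obs, len(top) - k_obs], [k_ctl, len(ctrl) - k_ctl]]
    pval = fisher_one_tailed(table)
    enriched = (pval < p_threshold) and (k_obs >= min_peaks)
    return EnrichmentCall(kzfp_id=kzfp_id, subfamily=subfamily,
                          n_top_peaks_overlapping=k_obs,
                          n_control_overlapping=k_ctl,
                          fisher_p=float(pval), enriched=enriched)


def enrichment_table(calls: list[EnrichmentCall]):
    import pandas as pd

    return pd.DataFrame([{
        "kzfp": c.kzfp_id, "subfamily": c.subfamily,
        "n_overlap": c.n_top_peaks_overlapping,
        "n_control": c.n_control_overlapping,
        "fisher_p": c.fisher_p, "enriched": c.enriched} for c in calls])


def propagate_generalized_enrichment(calls: list[EnrichmentCall],
                                     mapping: dict[str, list[str]]
                                     ) -> list[EnrichmentCall]:
    """Propagate enrichment from generalized models to member subfamilies.

    ``mapping`` sends a generalized model name to its member subfamilies; in
    synthetic mode the mapping is the identity and this is a no-op.
    """
    out = list(calls)
    by_sub = {c.subfamily: c for c in calls}
    for model, members in mapping.items():
        src = by_sub.get(model)
        if src is None or not src.enriched:
            continue
        for member in members:
            if member == model:
                continue
            cur = by_sub.get(member)
            if cur is None or not cur.enriched:
                out.append(EnrichmentCall(
                    kzfp_id=src.kzfp_id, subfamily=member,
                    n_top_peaks_overlapping=src.n_top_peaks_overlapping,
                    n_control_overlapping=src.n_control_overlapping,
                    fisher_p=src.fisher_p, enriched=True))
    return out
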