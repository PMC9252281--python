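"""ORF refinement: locate, reconstruct, score, select and splice ORFs.

The bicistronic L1 ORFs (ORF1 ~338 aa RNA chaperone; ORF2 ~1275 aa
endonuclease + reverse transcriptase) are located in genomic copies by
translated local search against reference protein sequences, re-aligned
codon-aware, reconstructed by ancestral inference, scored for the expected
protein domains in the three forward frames, and the best candidate per
subfamily is selected by a fixed cascade (domains -> reading frames ->
premature stops -> length -> genome age, with early exit once a single
candidate survives). Winning ORFs are spliced into the selected full-length
backbone to form the subfamily's composite sequence.

Domain models are position-specific score matrices built from the
simulator's planted motifs (synthetic stand-ins for the diagnostic L1
domain profiles); a domain is "complete" only if a full-width window in a
single reading frame scores above the calibrated cutoff — truncated or
frame-split homology counts as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from . import align as _align
from . import phylo as _phylo
from . import seqio

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA20_INDEX = {a: i for i, a in enumerate(AA20)}

ORF1_TARGET_AA = 338
ORF2_TARGET_AA = 1275


# ---------------------------------------------------------------------------
# Domain profiles
# ---------------------------------------------------------------------------


@dataclass
class DomainProfile:
    """A fixture amino-acid PSSM for one diagnostic domain."""

    domain_id: str
    aa_pssm: np.ndarray          # (width, 20) log2-odds vs uniform background
    score_cutoff: float
    min_coverage: float = 0.9

    @property
    def width(self) -> int:
        return self.aa_pssm.shape[0]


def profile_from_motif(domain_id: str, motif: str, match_prob: float = 0.7,
                       n_calib: int = 300, calib_len: int = 500,
                       seed: int = 2024) -> DomainProfile:
    """Build a PSSM from a planted motif.

    Each column gives probability ``match_prob`` to the motif residue and
    spreads the rest uniformly; the score cutoff is the 99th percentile of
    best-window scores over random amino-acid sequences, so shuffled
    sequences score below it in >=99% of trials.
    """
    if len(motif) < 10:
        raise ValueError("profile width must be >= 10")
    w = len(motif)
    probs = np.full((w, 20), (1.0 - match_prob) / 19.0)
    for i, aa in enumerate(motif):
        probs[i, AA20_INDEX[aa]] = match_prob
    pssm = np.log2(probs / (1.0 / 20.0))

    rng = np.random.default_rng(seed)
    best = np.empty(n_calib)
    for t in range(n_calib):
        seq = rng.integers(0, 20, calib_len)
        windows = np.lib.stride_tricks.sliding_window_view(seq, w)
        scores = pssm[np.arange(w)[None, :], windows].sum(axis=1)
        best[t] = scores.max()
    cutoff = float(np.quantile(best, 0.99))
    return DomainProfile(domain_id=domain_id, aa_pssm=pssm, score_cutoff=cutoff)


@lru_cache(maxsize=1)
def default_profiles() -> tuple[DomainProfile, ...]:
    from .simulate import DEFAULT_DOMAIN_MOTIFS

    return tuple(profile_from_motif(dom_id, motif)
                 for dom_id, motif, _orf, _off in DEFAULT_DOMAIN_MOTIFS)


def orf_profiles(orf_id: str) -> tuple[DomainProfile, ...]:
    """The diagnostic domain profiles expected in one ORF."""
    from .simulate import DEFAULT_DOMAIN_MOTIFS

    wanted = {dom_id for dom_id, _m, orf, _o in DEFAULT_DOMAIN_MOTIFS
              if orf == orf_id}
    return tuple(p for p in default_profiles() if p.domain_id in wanted)


def _scan_translation(aa: str, profile: DomainProfile):
    """Best full-width window score and span, or None if none fits."""
    w = profile.width
    if len(aa) < w:
        return None
    codes = np.array([AA20_INDEX.get(ch, -1) for ch in aa])
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    ok = (windows >= 0).all(axis=1)
    if not ok.any():
        return None
    scores = np.full(windows.shape[0], -np.inf)
    idx = np.where(ok)[0]
    scores[idx] = profile.aa_pssm[np.arange(w)[None, :], windows[idx]].sum(axis=1)
    best = int(np.argmax(scores))
    return float(scores[best]), (best, best + w)


# ---------------------------------------------------------------------------
# Domain scoring of a reconstructed ORF
# ---------------------------------------------------------------------------


@dataclass
class OrfCandidate:
    subfamily: str
    source_genome: str
    orf_id: str                  # "ORF1" or "ORF2"
    nt_sequence: str
    indel_method: str = "ML"
    age_rank: int = 0
    domain_hits: list[tuple] = field(default_factory=list)
    n_domains: int = 0
    n_frames_used: int = 0
    n_premature_stops: int = 0
    aa_length: int = 0
    mean_max_posterior: float = float("nan")

    @property
    def candidate_id(self) -> str:
        return f"{self.subfamily}|{self.orf_id}|{self.source_genome}|{self.indel_method}"


def score_domains(orf_nt: str, profiles) -> tuple[list[tuple], int, int, int]:
    """Scan the 3 forward-frame translations with every domain profile.

    Returns (domain_hits, n_frames_used, n_premature_stops, aa_length).
    Each hit is (domain_id, frame, (aa_start, aa_end), complete). A domain is
    complete when a full-width single-frame window clears the profile cutoff;
    premature stops are counted only in frames carrying complete domains,
    excluding the final two codons.
    """
    hits: list[tuple] = []
    if len(orf_nt) < 30:
        return [], 0, 0, len(orf_nt) // 3
    translations = [seqio.translate(orf_nt[f:]) for f in range(3)]
    frames_used: set[int] = set()
    for profile in profiles:
        best = None
        for frame, aa in enumerate(translations):
            res = _scan_translation(aa, profile)
            if res is None:
                continue
            score, span = res
            if score >= profile.score_cutoff and (
                    best is None or score > best[0]):
                best = (score, frame, span)
        if best is not None:
            _score, frame, span = best
            hits.append((profile.domain_id, frame, span, True))
            frames_used.add(frame)
    n_stops = 0
    for frame in sorted(frames_used):
        aa = translations[frame]
        n_stops += aa[: max(0, len(aa) - 2)].count("*")
    return hits, len(frames_used), n_stops, len(orf_nt) // 3


# ---------------------------------------------------------------------------
# Locating ORF-homologous regions
# ---------------------------------------------------------------------------


def merge_query_spans(hits: list["_align.LocalHit"], merge_dist: int = 400,
                      bit_min: float = 25.0) -> list[tuple[int, int, float]]:
    """Merge translated-search hits with bit >= bit_min whose query spans lie
    within ``merge_dist`` nt of one another. Returns (start, end, total_bits)
    sorted by position."""
    spans = sorted((h.query_span[0], h.query_span[1], h.bit_score)
                   for h in hits if h.bit_score >= bit_min)
    merged: list[list[float]] = []
    for s, e, b in spans:
        if merged and s - merged[-1][1] <= merge_dist:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2] += b
        else:
            merged.append([s, e, b])
    return [(int(s), int(e), float(b)) for s, e, b in merged]


def locate_orf_region(seq: str, reference_orf_aa: str,
                      params: "_align.AlignmentParams | None" = None,
                      merge_dist: int = 400, bit_min: float = 25.0,
                      min_total_bits: float = 50.0
                      ) -> tuple[int, int] | None:
    """Maximal ORF-homologous nt span on one sequence, or None.

    Merged spans whose summed bit score stays below ``min_total_bits`` are
    rejected: isolated near-threshold hits on non-homologous sequence would
    otherwise inject junk regions into the codon alignment.
    """
    hits = _align.translated_search(seq, reference_orf_aa, params,
                                    bit_cutoff=bit_min)
    merged = merge_query_spans(hits, merge_dist, bit_min)
    if not merged:
        return None
    s, e, bits = max(merged, key=lambda t: t[2])
    if bits < min_total_bits:
        return None
    return (s, e)


def locate_orf_regions(copies: list[str], reference_orf_aa: str,
                       params: "_align.AlignmentParams | None" = None,
                       merge_dist: int = 400, bit_min: float = 25.0
                       ) -> list[tuple[int, int] | None]:
    return [locate_orf_region(c, reference_orf_aa, params, merge_dist, bit_min)
            for c in copies]


# ---------------------------------------------------------------------------
# ORF reconstruction
# ---------------------------------------------------------------------------


def reconstruct_orf(orf_region_seqs: list[str],
                    params: "_align.AlignmentParams | None" = None,
                    profiles=None, subfamily: str = "", source_genome: str = "",
                    indel_method: str = "ml", age_rank: int = 0,
                    ids: list[str] | None = None,
                    ref_protein: str | None = None) -> OrfCandidate:
    """Codon-aware MSA -> NJ -> GTR -> marginal root, then domain scoring.

    ``ref_protein`` (when available) provides the clean codon scaffold for
    the alignment; without it the least-frameshifted input is the scaffold.
    """
    if len(orf_region_seqs) < 3:
        raise ValueError("need at least 3 ORF region sequences")
    profiles = profiles if profiles is not None else default_profiles()
    msa = _align.codon_aware_msa(orf_region_seqs, params, ids=ids,
                                 ref_protein=ref_protein)
    rec = _phylo.marginal_root_reconstruction(msa, indel_method=indel_method)
    hits, nframes, nstops, aalen = score_domains(rec.root_sequence, profiles)
    return OrfCandidate(
        subfamily=subfamily, source_genome=source_genome, orf_id="",
        nt_sequence=rec.root_sequence, indel_method=indel_method,
        age_rank=age_rank, domain_hits=hits, n_domains=len(hits),
        n_frames_used=nframes, n_premature_stops=nstops, aa_length=aalen,
        mean_max_posterior=rec.mean_max_posterior)


# ---------------------------------------------------------------------------
# Best-ORF cascade
# ---------------------------------------------------------------------------


def select_best_orf(candidates: list[OrfCandidate], target_aa_len: int
                    ) -> tuple[OrfCandidate, list[tuple[str, int, int]]]:
    """Sequential filters: (1) max domains, (2) min reading frames,
    (3) min premature stops, (4) length nearest target, (5) oldest genome.
    Steps after a singleton survivor are not applied. Returns (winner, audit).
    """
    if not candidates:
        raise ValueError("no ORF candidates")
    pool = list(candidates)
    audit: list[tuple[str, int, int]] = []
    steps = [
        ("max-domains", lambda c: -c.n_domains),
        ("min-frames", lambda c: c.n_frames_used),
        ("min-stops", lambda c: c.n_premature_stops),
        ("length-nearest", lambda c: abs(c.aa_length - target_aa_len)),
        ("oldest-genome", lambda c: -c.age_rank),
    ]
    for name, key in steps:
        if len(pool) == 1:
            break
        best = min(key(c) for c in pool)
        kept = [c for c in pool if key(c) == best]
        audit.append((name, len(pool), len(kept)))
        pool = kept
    pool.sort(key=lambda c: c.candidate_id)
    return pool[0], audit


# ---------------------------------------------------------------------------
# Composite assembly
# ---------------------------------------------------------------------------


@dataclass
class CompositeSequence:
    """Per-subfamily composite model: backbone with ORF spans replaced."""

    subfamily: str
    sequence: str
    segments: list[tuple[int, int, str]]          # (start, end, provenance)
    replaced: dict[str, tuple[int, int]] = field(default_factory=dict)
    # replaced: orf_id -> backbone span that was swapped out

    def __post_init__(self):
        pos = 0
        for s, e, _prov in self.segments:
            if s != pos or e < s:
                raise ValueError("segments must tile the sequence")
            pos = e
        if pos != len(self.sequence):
            raise ValueError("segments must tile the sequence")


def assemble_composite(backbone, best_orf1: OrfCandidate | None,
                       best_orf2: OrfCandidate | None,
                       ref_orf1_aa: str, ref_orf2_aa: str,
                       params: "_align.AlignmentParams | None" = None,
                       merge_dist: int = 400, bit_min: float = 25.0
                       ) -> CompositeSequence:
    """Replace the backbone's ORF-homologous spans with the best
    reconstructed ORFs (which may come from different source genomes).

    A missing ORF candidate leaves the backbone span in place, flagged in
    the segment provenance.
    """
    seq = backbone.sequence
    genome = backbone.source_genome
    spans: list[tuple[str, tuple[int, int] | None, OrfCandidate | None]] = []
    for orf_id, ref_aa, cand in (("ORF1", ref_orf1_aa, best_orf1),
                                 ("ORF2", ref_orf2_aa, best_orf2)):
        span = locate_orf_region(seq, ref_aa, params, merge_dist, bit_min)
        spans.append((orf_id, span, cand))

    # keep spans ordered and non-overlapping (ORF1 truncated at ORF2 start)
    placed = [(oid, sp, cand) for oid, sp, cand in spans if sp is not None]
    placed.sort(key=lambda t: t[1][0])
    for i in range(1, len(placed)):
        prev = placed[i - 1]
        if prev[1][1] > placed[i][1][0]:
            placed[i - 1] = (prev[0], (prev[1][0], placed[i][1][0]), prev[2])

    parts: list[str] = []
    segments: list[tuple[int, int, str]] = []
    replaced: dict[str, tuple[int, int]] = {}
    cursor = 0
    out_pos = 0

    def emit(piece: str, provenance: str):
        nonlocal out_pos
        if not piece:
            return
        parts.append(piece)
        segments.append((out_pos, out_pos + len(piece), provenance))
        out_pos += len(piece)

    for orf_id, span, cand in placed:
        s, e = span
        emit(seq[cursor:s], f"backbone:{genome}")
        if cand is None:
            emit(seq[s:e], f"backbone:{genome}|missing:{orf_id}")
        else:
            emit(cand.nt_sequence, f"{orf_id}:{cand.source_genome}")
            replaced[orf_id] = (s, e)
        cursor = e
    emit(seq[cursor:], f"backbone:{genome}")

    return CompositeSequence(subfamily=backbone.subfamily,
                             sequence="".join(parts), segments=segments,
                             replaced=replaced)


def revert_composite(composite: CompositeSequence, backbone_seq: str) -> str:
    """Undo the splice: restore backbone spans for every replaced ORF."""
    out = []
    for s, e, prov in composite.segments:
        kind = prov.split(":", 1)[0]
        if kind in ("ORF1", "ORF2"):
            bs, be = composite.replaced[kind]
            out.append(backbone_seq[bs:be])
        else:
            out.append(composite.sequence[s:e])
    return "".join(out)


def domain_hits_table(candidates: list[OrfCandidate]):
    import pandas as pd

    rows = []
    for c in candidates:
        for dom_id, frame, (a, b), complete in c.domain_hits:
            rows.append({"candidate": c.candidate_id, "orf_id": c.orf_id,
                         "domain_id": dom_id, "frame": frame,
                         "start": a, "end": b, "complete": complete})
    return pd.DataFrame(rows)
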