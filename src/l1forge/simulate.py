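"""Transposon-evolution simulator.

Generates L1-like progenitor sequences (5'UTR — ORF1 — IGR — ORF2 — 3'UTR
with embedded protein-domain motifs and optional KZFP binding sites), a
master-lineage succession of subfamilies, degraded genomic copies (GTR
substitutions with CpG-hypermutable transitions, indels, frequent 5'
truncation), noisy 3'-end "gold standards", an assembled genome with truth
intervals, and synthetic ChIP peak sets — everything the reconstruction
pipeline consumes, with machine-readable truth.

Substitutions are simulated as a continuous-time Markov jump process: each
site waits an exponential time governed by the GTR rate matrix, with the
transition rate multiplied at CpG-context sites; the context is re-evaluated
after every event, so the CpG correction applied downstream is genuinely
testable against the simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq

from . import seqio
from .seqio import DNA

# ---------------------------------------------------------------------------
# Fixture domain motifs and KZFP motif
# ---------------------------------------------------------------------------

# (domain_id, amino-acid motif, orf_id, aa offset within the ORF translation)
# Analogs of the six diagnostic L1 protein domains: ORF1 coiled-coil / RRM /
# CTD, ORF2 endonuclease / reverse transcriptase / DUF cysteine-rich region.
DEFAULT_DOMAIN_MOTIFS: list[tuple[str, str, str, int]] = [
    ("coiled_coil", "LEQRIENLEKEVAQLKQKLA", "ORF1", 60),
    ("rrm", "GKVFVKMTSWDQVKDFFSKY", "ORF1", 160),
    ("ctd", "RPQNWTPESAMKHQFDVSRW", "ORF1", 260),
    ("endonuclease", "HDVICGDFNMPLDPMWDKSA", "ORF2", 50),
    ("rt", "YADDLVLFAKAMPQGSILGP", "ORF2", 500),
    ("duf_cys", "CWKCGEHVETMHHMIWECPK", "ORF2", 1150),
]

DEFAULT_KZFP_ID = "zfp_sim1"
DEFAULT_KZFP_CONSENSUS = "TGCATTACAGGTAC"

# JASPAR-style 4 x width count matrix (rows A, C, G, T) for the fixture
# KZFP: strongly informative columns around the consensus above.


def default_kzfp_pfm() -> np.ndarray:
    pfm = np.full((4, len(DEFAULT_KZFP_CONSENSUS)), 4.0)
    for j, base in enumerate(DEFAULT_KZFP_CONSENSUS):
        pfm[DNA.index(base), j] = 88.0
    return pfm


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


def _default_spans(total_length: int = 6500):
    """Canonical bicistronic layout: ORF1 encodes 338 aa, ORF2 1275 aa."""
    utr5 = (0, 900)
    orf1 = (900, 900 + 1017)          # 338 aa + stop
    igr = (orf1[1], orf1[1] + 100)
    orf2 = (igr[1], igr[1] + 3828)    # 1275 aa + stop
    utr3 = (orf2[1], total_length)
    if utr3[0] >= total_length:
        raise ValueError("total_length too short for the default ORF layout")
    return utr5, orf1, igr, orf2, utr3


@dataclass
class ProgenitorSpec:
    """Structural blueprint of a progenitor sequence."""

    total_length: int = 6500
    utr5_span: tuple[int, int] | None = None
    orf1_span: tuple[int, int] | None = None
    igr_span: tuple[int, int] | None = None
    orf2_span: tuple[int, int] | None = None
    utr3_span: tuple[int, int] | None = None
    domain_motifs: list[tuple[str, str, str, int]] = field(
        default_factory=lambda: list(DEFAULT_DOMAIN_MOTIFS))
    kzfp_sites: list[tuple[str, int, bool]] = field(default_factory=list)
    kzfp_consensus: dict[str, str] = field(
        default_factory=lambda: {DEFAULT_KZFP_ID: DEFAULT_KZFP_CONSENSUS})

    def __post_init__(self):
        if self.utr5_span is None:
            (self.utr5_span, self.orf1_span, self.igr_span,
             self.orf2_span, self.utr3_span) = _default_spans(self.total_length)
        self.validate()

    @property
    def spans(self):
        return [("5UTR", self.utr5_span), ("ORF1", self.orf1_span),
                ("IGR", self.igr_span), ("ORF2", self.orf2_span),
                ("3UTR", self.utr3_span)]

    def orf_span(self, orf_id: str) -> tuple[int, int]:
        return self.orf1_span if orf_id == "ORF1" else self.orf2_span

    def validate(self):
        if not 0 < self.total_length:
            raise ValueError("total_length must be positive")
        prev_end = 0
        for name, (a, b) in self.spans:
            if a != prev_end or b <= a:
                raise ValueError(f"spans must be ordered, disjoint and tile "
                                 f"[0, total_length): bad span {name}")
            prev_end = b
        if prev_end != self.total_length:
            raise ValueError("spans must tile [0, total_length)")
        for name in ("ORF1", "ORF2"):
            a, b = self.orf_span(name)
            if (b - a) % 3:
                raise ValueError(f"{name} span length must be a multiple of 3")
        for dom_id, motif, orf_id, off in self.domain_motifs:
            a, b = self.orf_span(orf_id)
            n_aa = (b - a) // 3 - 1
            if off < 1 or off + len(motif) > n_aa:
                raise ValueError(f"domain {dom_id} does not fit in {orf_id}")
            if "*" in motif:
                raise ValueError("domain motifs cannot contain stops")
        for motif_id, off, _present in self.kzfp_sites:
            cons = self.kzfp_consensus[motif_id]
            end = off + len(cons)
            if end > self.total_length:
                raise ValueError("KZFP site outside sequence")
            for _, (a, b) in self.spans[1:4:2]:  # ORF spans
                if off < b and end > a:
                    raise ValueError("KZFP sites must not overlap ORFs")


@dataclass
class EvolutionParams:
    """Rates governing copy degradation and subfamily succession."""

    gtr_rates: tuple = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)  # AC AG AT CG CT GT
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    cpg_transition_multiplier: float = 10.0
    indel_rate: float = 0.002          # events per site per copy
    indel_length_mean: float = 3.0     # geometric
    truncation_prob: float = 0.7
    truncation_quantile_max: float = 0.9
    copies_per_subfamily: int = 60
    divergence_per_copy: float = 0.08  # expected substitutions/site
    succession_divergence: float = 0.05
    seed: int = 0

    def __post_init__(self):
        freqs = np.asarray(self.base_freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must sum to 1")
        if np.any(np.asarray(self.gtr_rates) <= 0):
            raise ValueError("gtr_rates must be positive")
        for p in (self.truncation_prob, self.truncation_quantile_max):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0,1]")
        if self.divergence_per_copy < 0:
            raise ValueError("divergence must be non-negative")


@dataclass
class CopyRecord:
    """One genomic copy plus the edit trace that produced it."""

    copy_id: str
    truncated: bool
    truncation_point: int
    sequence: str
    subs: list[tuple[int, str]] = field(default_factory=list)
    indels: list[tuple] = field(default_factory=list)


@dataclass
class SubfamilyTruth:
    """A simulated subfamily: progenitor, structure, copies, genealogy."""

    subfamily_id: str
    progenitor_seq: str
    spec: ProgenitorSpec
    parent_subfamily: str | None = None
    copies: list[CopyRecord] = field(default_factory=list)
    genealogy: str = ""
    kzfp_sites: list[tuple[str, int, bool]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Progenitor synthesis
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def _codon_tables():
    fwd = {}
    for i in range(64):
        codon = DNA[i // 16] + DNA[(i // 4) % 4] + DNA[i % 4]
        aa = str(Seq(codon).translate())
        fwd.setdefault(aa, []).append(codon)
    return fwd


_AA_TO_CODONS = _codon_tables()


def _random_orf(n_codons: int, rng: np.random.Generator) -> list[str]:
    """ATG + (n_codons-2) random sense codons + random stop."""
    sense = [c for aa, cods in _AA_TO_CODONS.items() if aa not in ("*", "M")
             for c in cods]
    sense = sorted(sense)
    codons = ["ATG"]
    idx = rng.integers(0, len(sense), n_codons - 2)
    codons.extend(sense[i] for i in idx)
    codons.append(sorted(_STOPS)[rng.integers(0, 3)])
    return codons


def _encode_motif(motif: str, rng: np.random.Generator) -> list[str]:
    out = []
    for aa in motif:
        choices = _AA_TO_CODONS[aa]
        out.append(choices[rng.integers(0, len(choices))])
    return out


def simulate_progenitor(spec: ProgenitorSpec, seed: int) -> SubfamilyTruth:
    """Synthesize a root progenitor satisfying the structural spec."""
    spec.validate()
    rng = np.random.default_rng(seed)
    seq = list("".join(DNA[i] for i in rng.integers(0, 4, spec.total_length)))

    for orf_id in ("ORF1", "ORF2"):
        a, b = spec.orf_span(orf_id)
        codons = _random_orf((b - a) // 3, rng)
        for dom_id, motif, dom_orf, off in spec.domain_motifs:
            if dom_orf != orf_id:
                continue
            for k, codon in enumerate(_encode_motif(motif, rng)):
                codons[off + k] = codon
        seq[a:b] = list("".join(codons))

    for motif_id, off, present in spec.kzfp_sites:
        if present:
            cons = spec.kzfp_consensus[motif_id]
            seq[off:off + len(cons)] = list(cons)

    truth = SubfamilyTruth(
        subfamily_id="S1",
        progenitor_seq="".join(seq),
        spec=spec,
        kzfp_sites=list(spec.kzfp_sites),
        genealogy="S1;",
    )
    _check_progenitor(truth)
    return truth


def _check_progenitor(truth: SubfamilyTruth) -> None:
    spec = truth.spec
    seq = truth.progenitor_seq
    for orf_id in ("ORF1", "ORF2"):
        a, b = spec.orf_span(orf_id)
        orf = seq[a:b]
        aa = seqio.translate(orf)
        if not orf.startswith("ATG") or aa[-1] != "*" or "*" in aa[:-1]:
            raise ValueError(f"{orf_id} violates ORF invariants")
        for dom_id, motif, dom_orf, off in spec.domain_motifs:
            if dom_orf == orf_id and aa[off:off + len(motif)] != motif:
                raise ValueError(f"domain {dom_id} not encoded verbatim")


# ---------------------------------------------------------------------------
# GTR substitution process with CpG-context hypermutability
# ---------------------------------------------------------------------------


def _build_q(params: EvolutionParams) -> np.ndarray:
    from .phylo import RATE_PAIRS

    pi = np.asarray(params.base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for k, (i, j) in enumerate(RATE_PAIRS):
        Q[i, j] = params.gtr_rates[k] * pi[j]
        Q[j, i] = params.gtr_rates[k] * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


_TRANSITION_OF = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _site_rates(codes, Q, mult):
    """Per-site total substitution rate given current CpG context."""
    base_rate = -np.diag(Q)[codes]
    cpg = np.zeros(codes.shape[0], dtype=bool)
    cpg[:-1] |= (codes[:-1] == 1) & (codes[1:] == 2)   # the C of CpG
    cpg[1:] |= (codes[1:] == 2) & (codes[:-1] == 1)    # the G of CpG
    ts_rate = Q[codes, [_TRANSITION_OF[int(c)] for c in codes]]
    rates = base_rate + np.where(cpg, (mult - 1.0) * ts_rate, 0.0)
    return rates, cpg


def _simulate_substitutions(seq: str, t: float, params: EvolutionParams,
                            rng: np.random.Generator,
                            reject=None) -> tuple[str, list[tuple[int, str]]]:
    """Jump-process simulation for total time t (expected subs/site).

    ``reject(codes, pos, new_code)`` may veto an event (used to keep
    succession progenitors coding-intact); vetoed events are redrawn as if
    the site were unchanged.
    """
    if t <= 0:
        return seq, []
    codes = seqio.encode(seq).astype(np.int64)
    L = codes.shape[0]
    Q = _build_q(params)
    mult = params.cpg_transition_multiplier
    rates, _ = _site_rates(codes, Q, mult)
    total = float(rates.sum())
    bound = float(-np.diag(Q).min() * max(mult, 1.0))
    events: list[tuple[int, str]] = []
    now = 0.0
    while True:
        if total <= 0:
            break
        now += rng.exponential(1.0 / total)
        if now >= t:
            break
        # rejection-sample the site
        while True:
            pos = int(rng.integers(0, L))
            if rng.random() * bound < rates[pos]:
                break
        s = int(codes[pos])
        qrow = Q[s].copy()
        qrow[s] = 0.0
        is_cpg = ((s == 1 and pos + 1 < L and codes[pos + 1] == 2) or
                  (s == 2 and pos - 1 >= 0 and codes[pos - 1] == 1))
        if is_cpg:
            qrow[_TRANSITION_OF[s]] *= mult
        target = int(rng.choice(4, p=qrow / qrow.sum()))
        if reject is not None and reject(codes, pos, target):
            continue
        codes[pos] = target
        events.append((pos, DNA[target]))
        lo = max(0, pos - 1)
        hi = min(L, pos + 2)
        old = rates[lo:hi].sum()
        rates[lo:hi], _ = _site_rates_window(codes, Q, mult, lo, hi)
        total += float(rates[lo:hi].sum() - old)
    return seqio.decode(codes), events


def _site_rates_window(codes, Q, mult, lo, hi):
    """Recompute _site_rates for codes[lo:hi] with 1-site context margin."""
    a = max(0, lo - 1)
    b = min(codes.shape[0], hi + 1)
    sub = codes[a:b]
    r, cpg = _site_rates(sub, Q, mult)
    # interior CpG context is exact; clip to the requested window
    return r[lo - a:hi - a], cpg[lo - a:hi - a]


def apply_substitutions(seq: str, subs: list[tuple[int, str]]) -> str:
    arr = list(seq)
    for pos, base in subs:
        arr[pos] = base
    return "".join(arr)


# ---------------------------------------------------------------------------
# Succession
# ---------------------------------------------------------------------------


def _caterpillar(labels: list[str]) -> str:
    if len(labels) == 1:
        return f"{labels[0]};"
    tree = f"({labels[0]},{labels[1]})"
    for lab in labels[2:]:
        tree = f"({tree},{lab})"
    return tree + ";"


def _orf_guard(spec: ProgenitorSpec):
    """Event veto keeping succession progenitors coding-intact.

    Rejects substitutions that create or destroy stop codons / the start
    codon in either ORF, or that change the amino acid of a planted domain
    motif (synonymous drift is allowed).
    """
    protected = []
    for orf_id in ("ORF1", "ORF2"):
        a, b = spec.orf_span(orf_id)
        doms = [(off, off + len(motif)) for _, motif, dom_orf, off
                in spec.domain_motifs if dom_orf == orf_id]
        protected.append((a, b, doms))

    tab = _AA_TO_CODONS  # noqa: F841 - documents intent

    def reject(codes, pos, target) -> bool:
        for a, b, doms in protected:
            if not a <= pos < b:
                continue
            ci = (pos - a) // 3
            n_codons = (b - a) // 3
            cod_start = a + 3 * ci
            old = seqio.decode(codes[cod_start:cod_start + 3])
            new = list(old)
            new[pos - cod_start] = DNA[target]
            new = "".join(new)
            old_aa = str(Seq(old).translate())
            new_aa = str(Seq(new).translate())
            if ci == 0:
                return True  # keep ATG
            if ci == n_codons - 1:
                return new not in _STOPS  # must remain a stop
            if new in _STOPS:
                return True  # no premature stop
            for lo, hi in doms:
                if lo <= ci < hi and new_aa != old_aa:
                    return True
            return False
        return False

    return reject


def evolve_succession(root: SubfamilyTruth, n_subfamilies: int,
                      params: EvolutionParams,
                      site_events: list[tuple[int, str, str]] | None = None,
                      ) -> list[SubfamilyTruth]:
    """Master-lineage succession: subfamily k derives from k-1 by
    substitutions (ORFs kept coding-intact), with optional planted KZFP
    site gain/loss events ``(subfamily_index, motif_id, "gain"|"loss")``
    applied when the given 0-based subfamily is spawned.
    """
    if n_subfamilies < 1:
        raise ValueError("n_subfamilies must be >= 1")
    site_events = site_events or []
    rng = np.random.default_rng(params.seed)
    guard = _orf_guard(root.spec)

    labels = [f"S{i + 1}" for i in range(n_subfamilies)]
    first = replace(root, subfamily_id=labels[0], genealogy=_caterpillar(labels[:1]))
    out = [first]
    for k in range(1, n_subfamilies):
        prev = out[-1]
        sites = list(prev.kzfp_sites)
        seq, _ = _simulate_substitutions(
            prev.progenitor_seq, params.succession_divergence, params, rng,
            reject=_site_guard(guard, sites, prev.spec))
        seq, sites = _apply_site_events(seq, sites, prev.spec, site_events, k, rng)
        out.append(SubfamilyTruth(
            subfamily_id=labels[k],
            progenitor_seq=seq,
            spec=prev.spec,
            parent_subfamily=prev.subfamily_id,
            kzfp_sites=sites,
            genealogy=_caterpillar(labels[:k + 1]),
        ))
    return out


def _site_guard(orf_reject, sites, spec):
    """Extend the ORF guard to also freeze present KZFP sites."""
    spans = [(off, off + len(spec.kzfp_consensus[mid]))
             for mid, off, present in sites if present]

    def reject(codes, pos, target) -> bool:
        for lo, hi in spans:
            if lo <= pos < hi:
                return True
        return orf_reject(codes, pos, target)

    return reject


def _apply_site_events(seq, sites, spec, site_events, k, rng):
    seq = list(seq)
    sites = list(sites)
    for ev_k, motif_id, kind in site_events:
        if ev_k != k:
            continue
        cons = spec.kzfp_consensus[motif_id]
        idx = next((i for i, (mid, _, _) in enumerate(sites)
                    if mid == motif_id), None)
        if idx is None:
            raise ValueError(f"no planted site for motif {motif_id}")
        mid, off, _present = sites[idx]
        if kind == "gain":
            seq[off:off + len(cons)] = list(cons)
            sites[idx] = (mid, off, True)
        elif kind == "loss":
            # knock out the site with 5 targeted substitutions: enough to
            # push any realistic PWM hit well below scan thresholds
            for j in rng.choice(len(cons), size=5, replace=False):
                cur = seq[off + j]
                alt = DNA[(DNA.index(cur) + 2) % 4]  # transition
                seq[off + j] = alt
            sites[idx] = (mid, off, False)
        else:
            raise ValueError(f"unknown site event {kind!r}")
    return "".join(seq), sites


# ---------------------------------------------------------------------------
# Copy generation
# ---------------------------------------------------------------------------


def generate_copies(truth: SubfamilyTruth, params: EvolutionParams
                    ) -> SubfamilyTruth:
    """Populate a subfamily with degraded genomic copies."""
    if params.divergence_per_copy >= 0.75:
        raise ValueError("divergence_per_copy >= 0.75: saturated")
    rng = np.random.default_rng(
        np.random.SeedSequence([params.seed, _stable_hash(truth.subfamily_id)]))
    copies = []
    L0 = len(truth.progenitor_seq)
    for i in range(params.copies_per_subfamily):
        seq, subs = _simulate_substitutions(
            truth.progenitor_seq, params.divergence_per_copy, params, rng)
        indels: list[tuple] = []
        n_indels = rng.poisson(params.indel_rate * L0)
        for _ in range(n_indels):
            cur_len = len(seq)
            length = int(rng.geometric(1.0 / params.indel_length_mean))
            pos = int(rng.integers(0, cur_len + 1))
            if rng.random() < 0.5:
                ins = "".join(DNA[b] for b in rng.integers(0, 4, length))
                seq = seq[:pos] + ins + seq[pos:]
                indels.append(("ins", pos, ins))
            else:
                length = min(length, cur_len - pos)
                if length <= 0:
                    continue
                seq = seq[:pos] + seq[pos + length:]
                indels.append(("del", pos, length))
        truncated = bool(rng.random() < params.truncation_prob)
        tpoint = 0
        if truncated:
            tpoint = int(rng.uniform(0.0, params.truncation_quantile_max
                                     * len(seq)))
            seq = seq[tpoint:]
        copies.append(CopyRecord(
            copy_id=f"{truth.subfamily_id}_c{i}",
            truncated=truncated,
            truncation_point=tpoint,
            sequence=seq,
            subs=subs,
            indels=indels,
        ))
    return replace(truth, copies=copies)


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2 ** 31 - 1)
    return h


def replay_copy(progenitor: str, copy: CopyRecord) -> str:
    """Replay a copy's recorded edit trace; must reproduce the stored copy."""
    seq = apply_substitutions(progenitor, copy.subs)
    for op in copy.indels:
        if op[0] == "ins":
            _, pos, ins = op
            seq = seq[:pos] + ins + seq[pos:]
        else:
            _, pos, length = op
            seq = seq[:pos] + seq[pos + length:]
    if copy.truncated:
        seq = seq[copy.truncation_point:]
    return seq


def copy_coordinate_map(progenitor_len: int, copy: CopyRecord) -> np.ndarray:
    """Map progenitor coordinates to copy coordinates (-1 where lost)."""
    cur = np.arange(progenitor_len, dtype=np.int64)
    alive = np.ones(progenitor_len, dtype=bool)
    for op in copy.indels:
        if op[0] == "ins":
            _, pos, ins = op
            cur[alive & (cur >= pos)] += len(ins)
        else:
            _, pos, length = op
            dead = alive & (cur >= pos) & (cur < pos + length)
            alive[dead] = False
            cur[alive & (cur >= pos + length)] -= length
    if copy.truncated:
        dead = alive & (cur < copy.truncation_point)
        alive[dead] = False
        cur[alive] -= copy.truncation_point
    cur[~alive] = -1
    return cur


# ---------------------------------------------------------------------------
# Genome assembly
# ---------------------------------------------------------------------------


def assemble_genome(subfamilies: list[SubfamilyTruth], spacer_mean: int = 500,
                    seed: int = 0, contig_id: str = "contig1"):
    """Place every copy on a contig with random spacers and strands.

    Returns (contigs: {id: seq}, truth BED DataFrame with columns
    chrom, start, end, name, subfamily, strand).
    """
    import pandas as pd

    copies = [(t.subfamily_id, c) for t in subfamilies for c in t.copies]
    if not copies:
        raise ValueError("no copies to place")
    rng = np.random.default_rng(seed)
    parts = []
    rows = []
    pos = 0
    for subfam, copy in copies:
        spacer_len = int(rng.poisson(spacer_mean)) if spacer_mean > 0 else 0
        spacer = "".join(DNA[b] for b in rng.integers(0, 4, spacer_len))
        parts.append(spacer)
        pos += spacer_len
        strand = "+" if rng.random() < 0.5 else "-"
        placed = copy.sequence if strand == "+" else seqio.revcomp(copy.sequence)
        parts.append(placed)
        rows.append({"chrom": contig_id, "start": pos,
                     "end": pos + len(placed), "name": copy.copy_id,
                     "subfamily": subfam, "strand": strand})
        pos += len(placed)
    contigs = {contig_id: "".join(parts)}
    bed = pd.DataFrame(rows)
    return contigs, bed


def extract_bed_span(contigs: dict[str, str], row) -> str:
    """Sequence of one truth-BED interval, minus-strand reverse-complemented."""
    seq = contigs[row["chrom"]][row["start"]:row["end"]]
    return seq if row["strand"] == "+" else seqio.revcomp(seq)


# ---------------------------------------------------------------------------
# Gold standards
# ---------------------------------------------------------------------------


def derive_gold_standards(subfamilies: list[SubfamilyTruth],
                          tail_length: int = 900, noise_rate: float = 0.02,
                          seed: int = 0) -> dict[str, str]:
    """Noisy 3'-terminal tails of the true progenitors, one per subfamily."""
    rng = np.random.default_rng(seed)
    out = {}
    for truth in subfamilies:
        seq = truth.progenitor_seq
        tl = tail_length
        if tl > len(seq):
            warnings.warn(f"tail_length {tl} exceeds progenitor; clamping")
            tl = len(seq)
        tail = list(seq[-tl:])
        n = rng.binomial(tl, noise_rate)
        for p in rng.choice(tl, size=n, replace=False):
            cur = DNA.index(tail[p])
            tail[p] = DNA[(cur + 1 + int(rng.integers(0, 3))) % 4]
        out[f"gold_{truth.subfamily_id}"] = "".join(tail)
    return out


# ---------------------------------------------------------------------------
# KZFP peaks
# ---------------------------------------------------------------------------


def simulate_kzfp_data(subfamilies: list[SubfamilyTruth],
                       contigs: dict[str, str], bed, motif_id: str,
                       n_top_peaks: int = 500, background_peaks: int = 500,
                       seed: int = 0, peak_halfwidth: int = 100,
                       jitter_sd: float = 15.0):
    """Synthetic ChIP peak set for one KZFP.

    Peaks are centered (with Gaussian jitter) on planted motif instances in
    the genomic copies of site-bearing subfamilies and given high signal
    scores; ``background_peaks`` uniform peaks with low scores are added.
    Returns (peaks DataFrame sorted by descending score, truth DataFrame
    with per-subfamily bound flags).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    placement = {r["name"]: r for _, r in bed.iterrows()}
    rows = []
    truth_rows = []
    k = 0
    for truth in subfamilies:
        site = next(((off, present) for mid, off, present in truth.kzfp_sites
                     if mid == motif_id), None)
        bound = site is not None and site[1]
        truth_rows.append({"kzfp": motif_id,
                           "subfamily": truth.subfamily_id,
                           "bound": bound})
        if not bound:
            continue
        off = site[0]
        width = len(truth.spec.kzfp_consensus[motif_id])
        L0 = len(truth.progenitor_seq)
        for copy in truth.copies:
            cmap = copy_coordinate_map(L0, copy)
            site_pos = cmap[off:off + width]
            site_pos = site_pos[site_pos >= 0]
            if site_pos.size < width // 2:
                continue  # site lost to truncation/deletion
            center_local = int(site_pos.mean())
            row = placement[copy.copy_id]
            if row["strand"] == "+":
                center = row["start"] + center_local
            else:
                center = row["end"] - 1 - center_local
            center += int(round(rng.normal(0.0, jitter_sd)))
            start = max(0, center - peak_halfwidth)
            end = min(len(contigs[row["chrom"]]), center + peak_halfwidth)
            rows.append({"chrom": row["chrom"], "start": start, "end": end,
                         "name": f"peak_t{k}",
                         "score": float(rng.uniform(10.0, 100.0)),
                         "strand": "."})
            k += 1
    for b in range(background_peaks):
        contig = sorted(contigs)[int(rng.integers(0, len(contigs)))]
        L = len(contigs[contig])
        center = int(rng.integers(peak_halfwidth, max(peak_halfwidth + 1,
                                                      L - peak_halfwidth)))
        rows.append({"chrom": contig, "start": center - peak_halfwidth,
                     "end": center + peak_halfwidth, "name": f"peak_b{b}",
                     "score": float(rng.uniform(1.0, 9.0)), "strand": "."})
    peaks = pd.DataFrame(rows).sort_values(
        "score", ascending=False, kind="mergesort").reset_index(drop=True)
    truth_df = pd.DataFrame(truth_rows)
    return peaks, truth_df
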