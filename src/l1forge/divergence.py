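"""CpG-corrected Kimura 2-parameter divergence.

Measures how far a genomic copy has drifted from a reference model,
separating transitions (P) from transversions (Q) and down-weighting
transitions at hypermutable reference CpG dinucleotides: each CpG transition
counts 1/10 of a substitution, except that a CpG whose C and G positions
have both transitioned counts 1 in total. The weighted P and raw Q feed the
K2P closed form d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).

CpG context is determined on the (ungapped) reference strand only;
transversions are never re-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import align as _align
from .phylo import SaturationError, k2p_from_counts


@dataclass
class DivergenceEstimate:
    P: float
    Q: float
    d: float
    n_sites: int
    n_cpg_sites: int

    def __post_init__(self):
        if not 0.0 <= self.P + self.Q <= 1.0 + 1e-9:
            raise ValueError("P+Q out of range")
        if self.n_cpg_sites > self.n_sites:
            raise ValueError("n_cpg_sites exceeds n_sites")


_PURINE_PAIRS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _is_transition(a: str, b: str) -> bool:
    return (a, b) in _PURINE_PAIRS


def cpg_adjusted_k2p(reference: str, copy: str, prealigned: bool = False,
                     cpg_weight: float = 0.1,
                     params: "_align.AlignmentParams | None" = None
                     ) -> DivergenceEstimate:
    """CpG-corrected K2P divergence of ``copy`` from ``reference``.

    If ``prealigned`` the two strings are equal-length gapped rows;
    otherwise they are globally aligned first. Raises
    :class:`~l1forge.phylo.SaturationError` when the distance is undefined.
    """
    reference = reference.upper()
    copy = copy.upper()
    if not prealigned:
        reference, copy, _ = _align.pairwise_align(reference, copy,
                                                   params, mode="global")
    if len(reference) != len(copy):
        raise ValueError("prealigned rows must have equal length")

    # CpG context on the ungapped reference: a column is CpG-context if the
    # reference base there is the C or the G of an ungapped-adjacent CG.
    ref_cols = [i for i, ch in enumerate(reference) if ch != "-"]
    cpg_partner = {}  # column -> partner column of the same CpG
    for a, b in zip(ref_cols, ref_cols[1:]):
        if reference[a] == "C" and reference[b] == "G":
            cpg_partner[a] = b
            cpg_partner[b] = a

    n_sites = 0
    n_cpg = 0
    transversions = 0
    plain_transitions = 0
    cpg_ts_cols = set()
    for i, (r, c) in enumerate(zip(reference, copy)):
        if r == "-" or c == "-" or r not in "ACGT" or c not in "ACGT":
            continue
        n_sites += 1
        if i in cpg_partner:
            n_cpg += 1
        if r == c:
            continue
        if _is_transition(r, c):
            if i in cpg_partner:
                cpg_ts_cols.add(i)
            else:
                plain_transitions += 1
        else:
            transversions += 1

    weighted = float(plain_transitions)
    seen = set()
    for i in sorted(cpg_ts_cols):
        if i in seen:
            continue
        j = cpg_partner[i]
        if j in cpg_ts_cols:
            weighted += 1.0  # doubly-hit CpG caps at one substitution
            seen.update((i, j))
        else:
            weighted += cpg_weight
            seen.add(i)

    if n_sites == 0:
        raise ValueError("no shared ungapped sites")
    d = k2p_from_counts(n_sites, weighted, transversions)
    return DivergenceEstimate(P=weighted / n_sites, Q=transversions / n_sites,
                              d=d, n_sites=n_sites, n_cpg_sites=n_cpg)


def divergence_table(reference: str, copies: dict[str, str],
                     subfamily: str = "", **kw):
    """Per-copy divergence as a DataFrame (TSV-ready)."""
    import pandas as pd

    rows = []
    for cid, seq in copies.items():
        try:
            est = cpg_adjusted_k2p(reference, seq, **kw)
            rows.append({"copy_id": cid, "subfamily": subfamily,
                         "P": est.P, "Q": est.Q, "d": est.d,
                         "n_sites": est.n_sites,
                         "n_cpg_sites": est.n_cpg_sites})
        except SaturationError:
            rows.append({"copy_id": cid, "subfamily": subfamily,
                         "P": float("nan"), "Q": float("nan"),
                         "d": float("nan"), "n_sites": 0, "n_cpg_sites": 0})
    return pd.DataFrame(rows)
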