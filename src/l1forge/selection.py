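"""Best-candidate selection for full-length progenitor reconstructions.

Each subfamily yields up to two reconstructed candidates per source genome
(one per indel method). Candidates are scored for percent identity to gold
standard sequences — 100 * (a - b) / a, where a is the length of the shorter
sequence and b the mismatch count in their pairwise local alignment, indels
unpenalized — and a fixed cascade picks the winner:

1. drop candidates whose best identity is more than 1.5 percentage points
   below the global maximum over all candidate x standard pairs;
2. drop candidates longer than 8 kb;
3. rank by best identity (descending);
4. rank by normalized length, where every length in [6 kb, 8 kb] is equally
   preferable (normalized 1.0) and shorter candidates score L / 6000.

Remaining ties break deterministically: older source genome, ML indel
solution over parsimony, then candidate id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from . import align as _align


@dataclass
class CandidateProgenitor:
    subfamily: str
    source_genome: str
    indel_method: str            # "ML" or "parsimony"
    sequence: str
    age_rank: int = 0            # larger = older source genome
    identities: dict[str, float] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence.replace("-", ""))

    @property
    def best_identity(self) -> float:
        return max(self.identities.values()) if self.identities else 0.0

    @property
    def candidate_id(self) -> str:
        return f"{self.subfamily}|{self.source_genome}|{self.indel_method}"


@dataclass
class SelectionOutcome:
    chosen: CandidateProgenitor
    audit: list[tuple[str, int, int]]  # (filter name, n in, n out)


class NoCandidateError(ValueError):
    """All candidates were eliminated by the cascade."""


def identity_to_standard(candidate: str, standard: str,
                         params: "_align.AlignmentParams | None" = None
                         ) -> float:
    """Percent identity 100*(a-b)/a with a = shorter length, b = local
    alignment mismatches; gap columns are ignored (indels unpenalized)."""
    if not candidate or not standard:
        raise ValueError("empty sequence")
    a = min(len(candidate), len(standard))
    row_c, row_s, score = _align.pairwise_align(candidate, standard, params,
                                                mode="local")
    if score <= 0:
        warnings.warn("no positive-scoring local alignment; identity 0")
        return 0.0
    b = sum(1 for x, y in zip(row_c, row_s)
            if x != "-" and y != "-" and x != y)
    return 100.0 * (a - b) / a


def score_candidates(candidates: list[CandidateProgenitor],
                     standards: dict[str, str],
                     params: "_align.AlignmentParams | None" = None) -> None:
    """Fill each candidate's identity map against every gold standard."""
    for cand in candidates:
        for gid, gseq in standards.items():
            cand.identities[gid] = identity_to_standard(cand.sequence, gseq,
                                                        params)


def normalized_length(length: int, plateau: tuple[int, int] = (6000, 8000)
                      ) -> float:
    lo, hi = plateau
    if lo <= length <= hi:
        return 1.0
    if length < lo:
        return length / lo
    return 0.0  # above the plateau; such candidates are discarded anyway


def select_best_candidate(candidates: list[CandidateProgenitor],
                          identity_window: float = 1.5,
                          max_length: int = 8000,
                          plateau: tuple[int, int] = (6000, 8000)
                          ) -> SelectionOutcome:
    """Apply the selection cascade and return the winner with an audit trail."""
    if not candidates:
        raise NoCandidateError("no candidates supplied")
    if all(not c.identities for c in candidates):
        raise NoCandidateError("no candidate has identity scores")
    audit = []

    global_max = max(c.best_identity for c in candidates)
    pool = [c for c in candidates
            if c.best_identity >= global_max - identity_window]
    audit.append(("identity-window", len(candidates), len(pool)))

    pool2 = [c for c in pool if c.length <= max_length]
    audit.append(("length-cap", len(pool), len(pool2)))
    if not pool2:
        raise NoCandidateError("all candidates eliminated by the cascade")

    def sort_key(c: CandidateProgenitor):
        return (-c.best_identity,
                -normalized_length(c.length, plateau),
                -c.age_rank,
                0 if c.indel_method.upper() == "ML" else 1,
                c.candidate_id)

    ranked = sorted(pool2, key=sort_key)
    audit.append(("identity-rank", len(pool2), len(pool2)))
    audit.append(("length-rank", len(pool2), 1))
    return SelectionOutcome(chosen=ranked[0], audit=audit)


def candidates_table(candidates: list[CandidateProgenitor],
                     chosen: CandidateProgenitor | None = None):
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append({"subfamily": c.subfamily, "genome": c.source_genome,
                     "indel_method": c.indel_method, "length": c.length,
                     "best_identity": c.best_identity,
                     "chosen": chosen is not None
                     and c.candidate_id == chosen.candidate_id})
    return pd.DataFrame(rows)
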