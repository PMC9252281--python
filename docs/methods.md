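# Methods

`l1forge` reconstructs full-length LINE-1 (L1) subfamily progenitor
sequences from degraded genomic copies and validates every step of that
procedure on a transposon-evolution simulator with machine-readable truth.
This note documents the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments do and do not show.

## The reconstruction problem

An L1 subfamily is a set of genomic copies descended from one active
progenitor: a 6–7 kb element with a 5′ UTR carrying promoter activity, two
protein-coding ORFs (ORF1, an RNA-binding chaperone of ~338 aa; ORF2, an
endonuclease + reverse transcriptase of ~1275 aa), and a 3′ UTR. Copies
degrade after insertion — substitutions (with strongly elevated transition
rates at methylated CpG dinucleotides), small indels, and, most
destructively, 5′ truncation at insertion time, which removes the promoter
and ORF1 from most copies. Reference models for older subfamilies cover only
~900 nt of the 3′ end, so the full-length progenitor must be inferred.

The pipeline proceeds: annotate a genome with per-subfamily models → take
the ≤100 longest hits ≥3 kb per subfamily → progressive nucleotide MSA →
neighbor-joining tree → GTR ancestral sequence reconstruction with two indel
solutions (maximum likelihood and parsimony) → score candidates against
gold-standard 3′ ends and select one per subfamily → relocate and
re-reconstruct the two ORFs with a codon-aware, frameshift-penalized
alignment → splice the best ORFs into the selected backbone to form a
composite sequence → scan composites for KZFP binding motifs and call
subfamily-level ChIP enrichment → re-annotate the genome with the
composites.

## The simulator

`simulate` generates the study conditions. A progenitor is synthesized to a
structural blueprint (default 6,500 nt: 900 nt 5′UTR, 1,017 nt ORF1 = 338 aa
+ stop, 100 nt IGR, 3,828 nt ORF2 = 1275 aa + stop, 655 nt 3′UTR) with six
planted amino-acid domain motifs (analogs of the coiled-coil, RRM and CTD in
ORF1 and the endonuclease, RT and cysteine-rich domains in ORF2) and
optional KZFP binding sites in non-coding regions.

Substitutions are simulated as a continuous-time Markov jump process under
a GTR rate matrix (default exchangeabilities 1,4,1,1,4,1 — a 4:1
transition bias — uniform base frequencies, matrix scaled to one expected
substitution per site). Transitions at CpG-context sites are multiplied by
10, and the context is re-evaluated after every event; this makes the
downstream CpG divergence correction genuinely testable, and it means the
*realized* substitution load exceeds the nominal clock `divergence_per_copy`
(the clock refers to the non-CpG process; the CpG-adjusted K2P estimator
recovers it, the raw estimator does not). Indels arrive at 0.002 events per
site with geometric lengths (mean 3 nt, insertions:deletions 1:1), and 70%
of copies are 5′-truncated at a point uniform on (0, 0.9·length) — the
distribution is unstated in the source material, so uniform is declared
here. Every copy stores its full edit trace; replaying the trace reproduces
the copy exactly, and a coordinate map through the trace lets the ChIP-peak
simulator place peaks on surviving planted sites.

Subfamily successions evolve the progenitor along a master lineage
(default 5% divergence per step). Succession progenitors stay functional: a
rejection guard vetoes substitutions that create premature stops, destroy
the start/stop codons, or change a planted domain's amino acid (synonymous
drift is allowed); planted KZFP sites are frozen except at scheduled
gain/loss events, and a loss knocks out five positions of the site so no
realistic PWM threshold still fires.

What the simulator does *not* emulate: host rearrangements, segmental
duplication, non-L1 repeats, nested insertions, lineage-specific base
composition, among-site rate variation beyond the CpG effect, and the ORF0
antisense peptide. Passing tests therefore demonstrate that the pipeline's
inferential machinery is correct under its own model assumptions — not that
real ancestral genomes are accurate.

## Alignment machinery

Pairwise nucleotide alignment (match +5, mismatch −4, affine gap
10 + k·1) and translated protein search (BLOSUM62, gap 11 + k·1) delegate to
Biopython's `PairwiseAligner`. Translated search converts raw scores to bits
with the published gapped BLOSUM62 Karlin–Altschul parameters
(λ = 0.267, K = 0.041) and extracts up to four hits per reading frame by
best-hit-then-mask iteration.

The progressive MSA builds a neighbor-joining guide tree on 6-mer
distances (1 − shared/min distinct k-mers) and merges groups bottom-up with
an affine-gap profile aligner (a numba kernel; deterministic diagonal >
vertical > horizontal tie-break). Terminal gaps are free by default — the
correct treatment for 5′-truncated copies.

The codon-aware aligner works on (query-nt × reference-codon) cells with
three affine states plus explicit 1–2 nt frameshift moves (cost 30/event)
and a stop-codon penalty (100/event; the query's final codon is exempt).
For multiple alignment, every sequence is aligned against a clean protein
scaffold — the reference ORF protein when available, otherwise the
least-frameshifted input — and the pairwise alignments are merged on
scaffold coordinates. Two numerical choices matter here:

* **Degraded-sequence stop penalty.** Fossil copies genuinely contain stop
  codons. Penalizing them at the full 100 makes the optimal alignment
  "frameshift around" each stop (a 1-nt insertion plus a 2-nt deletion costs
  60 < 104), littering the alignment with false frameshift columns. Copies
  are therefore aligned to the scaffold with a reduced stop penalty of 10 —
  a stop is scored like a bad mismatch — mirroring the dual reliable /
  less-reliable cost sets of published codon aligners.
* **Frameshift counting.** A row's frameshift count is the number of 1–2 nt
  moves in its scaffold alignment, excluding free-end overhangs.

## Phylogenetics and ancestral reconstruction

K2P distances use the closed form d = −½ln(1−2P−Q) − ¼ln(1−2Q) over
pairwise shared ungapped columns; saturated pairs raise an error by default
but can be capped (distance 5.0) when the matrix only guides tree building
over possibly degraded inputs. Neighbor joining and newick I/O delegate to
scikit-bio (negative branch lengths are clamped to zero with a warning);
Robinson–Foulds comparison delegates to dendropy's unrooted bipartition
machinery.

The GTR model is built from empirical base frequencies and six
exchangeabilities fitted by coordinate ascent (GT fixed at 1; bounded Brent
steps on each log-rate; accepted steps never decrease the pruning
log-likelihood). For long alignments the rate optimization runs on a
deterministic 2,000-column subsample — exchangeabilities are global
parameters and stabilize well below that. Transition matrices come from the
eigendecomposition of the symmetrized rate matrix; pruning uses unique-site
patterns with per-node rescaling.

Reconstruction is marginal: the root posterior is π ⊙ L(root), normalized
per column; the emitted base is the argmax ("maximum-likelihood
nucleotide") and the mean maximum posterior summarizes confidence. The root
is the midpoint of the NJ tree (no rooting rule is prescribed by the
procedure being reproduced); NJ branch lengths are used as-is. Columns
gapped in >90% of rows are dropped before reconstruction as alignment-edge
artifacts.

Indels are reconstructed on binary gap-block characters (contiguous columns
with identical row patterns) by either Fitch parsimony (ambiguous root
resolves to *present*) or a two-state reversible model with one gain/loss
rate fitted by 1-D likelihood maximization (root posterior ≥ 0.5 =>
present). Both solutions are emitted, mirroring the dual indel outputs of
the reconstruction tool being reproduced. One modeling decision is central
to 5′ quality: **leading and trailing gap runs of a row are missing data,
not deletion evidence** — they arise from 5′ truncation and alignment
edges. Treating them as deletions systematically amputates the 5′ end of
the reconstruction (and measurably did, before this rule); treating them as
unknown lets the covered rows decide.

## Selection cascades

Percent identity to a gold standard is 100·(a−b)/a with a the shorter
sequence's length and b the mismatch count in the pairwise local alignment;
indels are not penalized. The full-length cascade drops candidates more
than 1.5 percentage points below the global best identity, discards
candidates over 8 kb, and ranks by identity then normalized length (lengths
6–8 kb form an equal-preference plateau; shorter candidates score L/6000 —
the sub-6 kb rule is declared here, monotone toward 6 kb). Residual ties
break deterministically: older source genome, ML indel solution, candidate
id. The ORF cascade filters sequentially — most complete domains, fewest
reading frames, fewest premature stops (summed over domain-bearing frames,
excluding the final two codons), length nearest the 338/1275 aa targets,
oldest genome — skipping all later steps once a single candidate survives.

Domain models are PSSMs built from the simulator's planted motifs (the
curated domain databases are external services): each column gives
probability 0.7 to the motif residue, log2-odds against a uniform
background, with the score cutoff at the 99th percentile of best-window
scores on random sequences. A domain is *complete* only when a full-width
window in a single reading frame clears the cutoff — truncated or
frame-split homology counts as absent.

Composites splice the best reconstructed ORFs into the selected backbone at
the spans found by translated search with the merge rule (bit score ≥ 25,
spans within 400 bp merged; merged spans below 50 total bits are rejected
as spurious); a missing ORF leaves the backbone span in place, flagged in
the per-segment provenance. The splice is reversible from the recorded
replaced spans.

## KZFP scanning and enrichment

PFMs become log2-odds PWMs against a uniform 0.25 background with
pseudocount 1e-4. Scan thresholds are exact: the score distribution of
background words is computed by column-wise convolution on a 1-millibit
discretized grid, and the threshold is the smallest *achievable* word score
whose upper tail is ≤ p (default 1e-6). Scanning uses the same discretized
weights as the threshold DP — with a sharp PWM most of the tail mass sits
exactly at the boundary score class, so float/grid inconsistencies of even
a few millibits visibly distort hit counts. Both strands are scanned
exhaustively; minus-strand hits are reported on plus-strand coordinates.

Subfamily binding is called from ranked peaks with the dual criterion:
one-tailed Fisher exact p < 1e-10 for top-500-peak overlap against
width-matched, seeded-shuffled control peaks, AND at least 10 of the top
500 peaks overlapping the subfamily's loci (≥1 shared base). The
contingency null (shuffled controls) is one of two defensible choices; a
genome-fraction binomial would be the alternative. The planted gain/loss
recovery experiment uses 5 subfamilies × 60 copies with 40 kb intergenic
spacers and 50 background peaks: this emulates the real regime in which
subfamily loci are a small fraction of the genome and the top peaks are
dominated by genuine binding — with repeat-dense toy genomes the
p < 1e-10 criterion is unreachable by construction, which is a property of
the criterion, not of the caller.

## Genome annotation

The scanner extracts ungapped high-scoring segments along 12-mer-seeded
diagonals of each model against both strands, scores them with
λ solved exactly from Σ pᵢpⱼe^(λ·sᵢⱼ) = 1 by bisection and a conventional
prefactor K = 0.1 (config-overridable), and applies per-class E-value
cutoffs (1e-3 for designated old subfamilies, 1e-6 otherwise). E-values are
tracked in log10 space; raw scores in the thousands underflow linear
E-values.

Defragmentation follows the published heuristic: same-subfamily,
same-strand hits within 50 bp are joined — the join's E-value is recomputed
from its combined score, which is what lets a fragmented true-subfamily hit
outrank an unbroken sibling-subfamily hit — and joined hits of different
subfamilies overlapping by >30 bp (≥150 bp when an old-class hit is
involved) group and resolve to the lowest-E member, with score and then
seeded-random tie-breaks. The operation is idempotent.

## Problem sizes and determinism

Default study conditions: 3-subfamily successions of 30 copies at 5%
divergence for the end-to-end pipeline; 60 copies at 8% divergence with 70%
truncation for the recovery experiment; 20-copy ORF sets (matching the
median input-set size of the original analysis, ~29) with 1-nt indels in
30% of copies for the frameshift-repair experiment. Recovery is scored over
the progenitor's 3′ half, where gold standards exist. Reconstruction errors
concentrate at CpG sites, where the tenfold transition rate produces
recurrent parallel C→T changes that a site-homogeneous model cannot
distinguish from ancestral state — with small input sets this occasionally
plants a stop codon (CGA→TGA); majority evidence suppresses it from ~20
copies up. Every stochastic component takes an explicit seed; identical
seeds give byte-identical pipeline outputs, verified by manifest checksums.

## Known limitations

* The scanner is ungapped-segment based; very high divergence fragments
  hits more than a gapped search would (the 50 bp join absorbs most of it).
* The codon MSA is scaffold-anchored (star-shaped), not a full simultaneous
  multiple alignment; with a clean reference protein this is robust, but
  regions with no detectable homology to the reference are not aligned.
* No among-site rate variation; only the root's reconstruction is emitted.
* K in the E-value formula is a convention, not the full Karlin–Altschul
  computation; per-class cutoffs operate on a consistent but approximate
  absolute scale.
* Posterior probabilities are not calibrated against the CpG process: at
  hypermutable sites the reported confidence overstates accuracy.
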