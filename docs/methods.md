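# Methods

`tmspath` implements a sequence-only workflow for detecting distant
homology among α-helical membrane-protein families, in which conserved
transmembrane-segment (TMS) architecture — not just residue similarity —
carries the evolutionary signal. This note documents the models and
procedures, the parameters that matter, and the limits of what the tests
establish.

## Alignment and significance

Local pairwise alignment uses the Smith–Waterman algorithm with affine
gaps (Gotoh), scored with BLOSUM50, gap open 10 and gap extend 2 by
default; a gap of length L costs `10 + 2L` (the SSEARCH/FASTA convention).
Non-standard residues (U, O, J, \*) are scored as X. Among co-optimal
alignments the one ending at the smallest `(q_end, s_end)` is reported,
examining at most 100 co-optimal candidates; results are deterministic for
fixed inputs.

Significance is calibrated per pair by shuffling: the second sequence is
permuted uniformly K times (default K = 1000), preserving composition —
important because membrane proteins are strongly biased toward hydrophobic
residues, which inflates raw alignment scores between unrelated sequences.
A Gumbel (type-I extreme value) distribution is fitted to the K shuffled
optimal scores by maximum likelihood, and

```
E = K' · P(S ≥ s_obs)
```

where K′ is the number of pairwise comparisons in the search context
(1 for a single pair; the database size during screening; |A|·|D| for the
all-pairs family comparison). A z-score against the shuffled mean/SD is
reported alongside as a cross-check. If the shuffled score distribution is
degenerate (zero variance) the E-value is reported as the K′/K upper bound
and flagged. Calibration is verified empirically: on unrelated random
pairs the fraction with E ≤ 0.05 matches 0.05 within binomial error.

Bit scores use `(λS − ln K)/ln 2` with published ungapped Karlin–Altschul
constants per matrix (BLOSUM50: λ = 0.232, K = 0.112), or constants implied
by an empirical Gumbel fit. Because a single (λ, K) pair is applied to
gapped scores, bit values are comparative quantities within a run, which
is all the clustering needs.

Redundancy reduction is greedy and longest-first (CD-HIT style): a
sequence joins an existing representative at ≥ 90% identity over ≥ 80% of
the shorter sequence.

## Hydropathy and TMS calling

Hydropathy profiles are centred moving averages (default Kyte–Doolittle,
window 19, the classical transmembrane setting; windows shrink at sequence
ends and those positions are flagged). The native TMS caller takes maximal
runs with profile ≥ 1.0, merges runs separated by < 4 residues, splits
runs longer than 30 recursively at their interior hydropathy minimum, and
finally drops runs shorter than 15. The order — merge, split, then length
filter — keeps fragments of one helix together before any are discarded.
The caller is a testable stand-in for an external topology predictor;
imported annotations (HMMTOP one-line output or TSV) always take
precedence when supplied.

MSA summaries report per-column average hydropathy over non-gap residues,
average pairwise substitution score min/max-normalised to [0, 1] (NaN for
columns with fewer than two residues), and gap fraction. Column trimming
keeps positions with *less than* a gap-fraction threshold (default 0.30),
so a column exactly at the threshold is removed; trimming is idempotent.
Note that duplicating a single MSA row genuinely changes unweighted column
means, so the invariance the package guarantees (and tests) is to row
order and to duplication of the whole row set.

TMS complexity classification approximates TMSOC-style reasoning with two
segment measures: Shannon entropy (20-letter, bits) and mean hydropathy.
Simple ⇔ entropy < 2.0 and mean KD > 2.0; twilight when entropy ∈
[2.0, 3.0] or mean KD ∈ [1.0, 2.0]; otherwise complex. The exact published
discriminant is not reproduced; the classification is advisory (simple
TMSs are bias-prone and weaken alignment evidence).

## Repeat-unit detection

For a chosen bundle size k (typically 4, the ancestral repeat-unit size in
the transporter superfamilies this workflow targets), every contiguous
window of k TMSs is sliced out with a 5-residue flank (flank configurable;
whether loops belong to a bundle is not settled, so the choice is logged).
Within one protein, all non-overlapping bundle pairs are aligned and hits
with E ≤ 10⁻³ reported (borderline repeat evidence in this literature sits
near 5×10⁻⁴). Across two homologs, all bundle pairs at *offset* TMS
ordinals are compared — same-ordinal pairs only demonstrate homology, not
internal repetition. Only equal-k bundle pairs are enumerated; unequal
bundle sizes (e.g. 3 vs 4 after TMS loss) are explored by varying k.

## Transitivity-path inference

Family A and family D are linked through screened homologs B and C:

1. **Screening**: database hits with E < 10⁻⁴ and ≥ 40% coverage of the
   shorter sequence, then 90%-identity redundancy reduction. Coverage is
   alignment columns (gaps included) over the shorter sequence length.
2. **Path significance**: every E-value on A–B, B–C, C–D must be < 10⁻⁵.
3. **Topology**: TMSs of B and C are paired through alignment columns —
   TMS i of B pairs with TMS j of C when their column images overlap by
   ≥ 50% of the shorter image; crossing candidates are resolved greedily
   by overlap size, so the pairing is colinear. A candidate needs ≥ 3
   matched TMS pairs (the stricter reading of "3 TMSs in the alignment";
   per-protein spanned-TMS counts are also reported). Final congruence of
   the pairing with a family's repeat-unit history is a recorded manual
   verdict — the toolkit computes the correspondence, a human accepts it.
4. **Domains**: each side's domain hit must intersect the aligned span
   over ≥ 3 TMSs, or entirely when the domain itself covers fewer; shared
   clan membership between different domain accessions counts as support
   and is flagged. Domains can be projected onto members without direct
   hits by aligning donor hit regions (E < 10⁻⁵, ≥ 40% donor coverage);
   the family's characteristic domain is the one present in ≥ 50% of
   members, ties broken by lower median E-value.
5. **Decision**: with 3D structures available, accept at ≥ 4 of 5
   criteria; without, criterion 5 is not considered and criteria 1–4 must
   all pass. Motif and structure criteria are recorded flags from external
   evidence. Manual/unset flags block automatic acceptance
   (`needs_review`) rather than forcing rejection.

## Confidence scoring and network

Each accepted inference scores `−N·log10(E)` with N the matched-TMS count
and E the B–C E-value. Scores are normalised by the run maximum (so norms
are not comparable across runs) and banded: high ≥ 0.6, 0.6 > medium ≥
0.4, low < 0.4. The family network keeps one edge per family pair (best
norm score) with node degree as the shading value; export is edge-list TSV
and GraphML.

## Clustering

Distances are `1 − b(i,j)/min(b(i,i), b(j,j))` from bit scores, clamped to
[0, 1] (a max-self variant is available; the transform is a package choice,
and the coefficient below can shift slightly between the two). Average-
linkage agglomerative clustering (scipy's Lance–Williams implementation)
produces the merge tree; the agglomerative coefficient is the mean over
items of `1 − m(i)/M` (first-merge height over final height): 0 for n = 2
or all-equal distances, → 1 for tight well-separated families. Trees are
exported as Newick/Nexus with branch lengths encoding merge-height
differences (leaves at height 0). A greedy max-min diversity picker with
per-family target counts assists representative-set construction.

## Synthetic families (the test world)

Proteins are alternating hydrophilic loops (8–40 residues) and hydrophobic
TMSs (18–24 residues). Residue usage is weighted to resemble real membrane
proteins — helices rich in L/I/V/F, loops rich in G/S/T/P with charged
residues — because uniform draws over the residue sets give unrealistically
weak hydropathy contrast at helix edges. Families evolve by explicit
events (bundle duplication 4 → 4+4, N-terminal TMS loss → 3+4, central TMS
insertion → 4+N+4, fusion), then per-member divergence: substitutions with
probabilities ∝ 2^(S(a,b)/2) from BLOSUM50 exchangeabilities, and
geometric-length indels confined to loops so planted TMS coordinates stay
exact (TMS gain/loss is an event, not drift). Benchmarks pair two families
diverged independently from one founder with decoy families built by
residue-shuffling real members — composition-matched by construction,
matching the compositional-bias concern that motivates shuffle
calibration. Everything is reproducible from (spec, seed).

What the generator does *not* emulate: site-rate heterogeneity,
phylogenetic tree structure within families, helix-length drift, signal
peptides, re-entrant loops and amphipathic helices. Green tests therefore
establish algorithmic correctness and calibration under the planted model,
not predictor accuracy on natural proteins.

## Numerical choices and degenerate inputs

- E-values are floored at 1e-300 to stay positive under underflow; the
  degenerate-fit bound K′/K is flagged explicitly.
- Alignments with no positive-scoring cell return an empty alignment with
  raw score 0 (e.g. all-X sequences under a matrix scoring X ≤ 0).
- Per-pair RNG streams are derived from (run seed, CRC32 of the sequence
  pair), so results are independent of call order and reproducible.
- Merge-queue ties in clustering follow scipy's deterministic ordering;
  clustering is input-order invariant up to label permutation for distinct
  distances.
- Thresholds and seeds in effect are logged by every pipeline stage, so a
  run is reconstructable from its log.

## Known limitations

- Printed E-values of the original SSEARCH-based analyses are reproducible
  only to order of magnitude: the shuffle/Gumbel-ML calibration here is a
  different estimator from that tool's internal regression statistics.
- Criterion 4 (motifs) and criterion 5 (structure) are recorded flags, not
  computations: motif discovery/scanning and 3D bundle superposition are
  external to this package.
- The bit-score → distance transform and the MSA-guided section-point
  choice for repeat searches are package choices where the underlying
  method leaves the detail unspecified; both are configurable and logged.
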