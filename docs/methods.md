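# Methods

## Domain model

The canonical R2R3 MYB DNA-binding domain is treated as a fixed 105-position
coordinate system (`CanonicalDomainTemplate`): repeat R2 spans positions
1–52 and R3 spans 53–105.  Constrained positions are the five landmark
tryptophans (6, 26, 46, 78, 97), thirteen additional highly conserved
residues (10 E, 11 D, 14 L, 22 G, 42 C, 43 R, 45 R in R2; 63 E, 75 G, 82 A,
88 R, 94 K, 95 N in R3), the L insertion at 35, the LRPD linker, and the
first R3 tryptophan slot, which in plants generally carries a hydrophobic F
or I instead of W.  Two coordinates are not fixed by the biology we encode
and are therefore configurable with documented defaults: the R3 first slot
sits at position 58 (inside R3 helix 1, between linker and landmark 78) and
the LRPD linker at 50–53 (immediately after the last R2 landmark).

### Repeat detection

Repeats are found with a windowed, **no-indel** log-odds scan: every window
of profile width w is scored `Σ_j log2 f_j(x_j) / b(x_j)`, hits above a bit
threshold are selected greedily (highest score first, ties to the smaller
start) without overlap, and consecutive hits with spacing in [0, 20]
residues form one tandem-repeat group.  Repeat count maps to MYB class
(1 → MYB-related, 2 → R2R3, 3 → 3R, ≥4 → 4R).  This deliberately replaces a
full profile HMM: every downstream rule operates on fixed landmark
coordinates, and a gapless 52-position window suffices at this scale.
Sequences with indels *inside* a repeat are out of recall scope (they
surface as "incomplete repeat" rejections, the same fate the curation rule
assigns them).

The default scanning profile is derived from the template itself: column j
mixes, in equal parts, the residue law of template position j (R2) and of
position 52 + j (R3) — a point mass on constrained positions, the uniform
background elsewhere — with 1% uniform smoothing.  Because unconstrained
columns sit exactly at background, an intact repeat's score has a
deterministic floor from its constrained columns alone, independent of the
unconstrained residues and hence of the substitution load placed there.
Profiles can equally be estimated from alignments (`build_profile`, with
Laplace-style pseudocounts and >50%-gap columns dropped).

### Threshold calibration

The default threshold of **5 bits** is calibrated from both sides
(`scripts/calibrate_scan_threshold.py`): a repeat missing two landmark
tryptophans — the worst case the integrity rule must still be able to judge
— has a score floor of ≈5.6 bits, while composition-matched random
200-mers produce a window above 5 bits in <1% of draws (measured 0/300 and
2/1000).  Between those two numbers any threshold behaves identically; 5 is
the round value.

### Integrity rule

A candidate fails curation when fewer than two repeats are detected
(incomplete repeat) or when **more than two** of the five landmark
tryptophans are missing — i.e. `w_match_count ≥ 3` passes.  The F/I slot
never counts toward `w_match_count`; the landmark census is the five
W positions only.  The rule is monotone in landmark destruction (verified
by test).

### Sequence logos

Per-column information content is `log2 20 − H(column)` in bits (optional
small-sample correction `19/(2 ln2 · n)`, clipped at 0); letter height is
frequency × IC.  Columns with >50% gaps are excluded, mirroring how rare
indels are left out of logo representations.

## Family curation

* **Representative isoform**: longest CDS; if its domain fails integrity,
  the next-longest passing isoform; if none passes, the gene keeps its
  longest isoform and that isoform's class.  Length ties break on mRNA id.
* **Ambiguity/expression filter**: a gene is dropped only when its CDS
  contains Ns **and** its maximum TPM is below 1 — both conditions, a
  conjunction.
* **Naming**: genome letter A < B, chromosomes 1–7, start coordinate
  ascending within a chromosome; unplaced (U) genes follow all placed genes
  ordered by gene id (their coordinates are not trusted).  Names carry a
  global zero-padded ordinal (`TdMYB1A001 … TdMYBU233` for 233 genes).
  Within-chromosome order by start coordinate is a design choice; the
  alternative (annotation-id order) would permute a handful of neighbours.
* **pI/Mw**: average (not monoisotopic) ExPASy residue masses plus one
  water; pI by bisection on the Henderson–Hasselbalch net charge under the
  Bjellqvist pK set (shipped as constants).  Bisection stops on
  |charge| < 1e-4 once the pH bracket is below 1e-5, so shallow titration
  curves still converge in pH; agreement with a brute-force 1e-4-step grid
  scan is within 1e-3 (tested), and with Biopython's independent
  implementation of the same model within 0.05.
* **Domain→genome mapping**: protein span [a,b] → CDS nucleotides
  [3a−2, 3b] → genomic intervals split at exon boundaries; minus-strand
  CDSs walk exons from the rightmost end leftward.  Interval lengths always
  sum to 3× the span length, and a mapped minus-strand span
  reverse-complements and re-translates to the original peptide (tested).

## Motif clades

Motifs are position probability matrices 6–53 columns wide.  Presence =
best ungapped window score ≥ 0.8 × the maximum attainable score; the 0.8
fraction is calibrated so random sequences are called present in <5% of
draws (threshold 0 is the degenerate everything-present call).  Clade rules
in priority order: PS1 ∧ motif12 ∧ ¬PS2 → Poaceae-specific group A;
PS1 ∧ PS2 ∧ ¬motif12 → group B; PS3 → Poaceae-unique; PS4 ∧ PS5 →
Poaceae-basal; else unclassified.  Priority only guards degenerate inputs —
the documented clades are disjoint — and known exceptional identifiers are
pinned via an override map, not extra rule branches.

Motif–motif similarity slides the shorter matrix along the longer (minimum
overlap: half the shorter width) and reports the best mean column-wise
Pearson correlation of probability vectors.  Columns with zero variance
compare as 1 when equal, 0 otherwise.  An occurrence-level view
(`presence_correlation`, the phi coefficient on presence columns) is also
exposed since published motif-correlation figures can be computed either
way.  Subfamily assignment walks each query leaf of a rooted Newick tree to
the smallest enclosing clade containing a reference leaf and takes the
majority reference subgroup (ties → "ambiguous").

## Expression

`2^-ΔΔCt`: technical replicates are averaged per biological replicate;
ΔCt = Ct_target − Ct_reference per replicate; ΔΔCt = mean ΔCt(stressed) −
mean ΔCt(control); the t test runs on the biological-replicate ΔCt sets
(standard Livak practice — testing on the fold scale would be the main
alternative).  The fold-scale spread is reported as the fold equivalent of
the ΔΔCt standard error, `rel · (2^SE − 1)`.  Detection statuses: both
conditions undetected → `not_expressed`; exactly one detected →
`not_quantifiable` (no finite ratio exists); otherwise `quantified`.
Significance tiers: * p < 0.1, ** p < 0.05, *** p < 0.01.

Matrix operations: expressed-gene filter keeps TPM **strictly** above 5 in
at least one sample; the replicate filter keeps (study, condition) arms
with ≥3 biological replicates; display summaries are log2(TPM+1) of the
replicate mean (mean first, then log).

The differential-expression test is an explicit **stand-in**, not DESeq2:
median-of-ratios size factors, Welch's t on log2(normalised count + 1),
Benjamini–Hochberg adjustment; DE requires fold change strictly above 2 and
adjusted p < 0.05.  Its output columns match what an imported DESeq2 result
table would provide, so the downstream interface is unchanged if one is
substituted.

## Regulatory network and enrichment

Per target gene (standardised to unit variance), a random-forest of
regression trees (bootstrap resampling; `sqrt`-sized random candidate
subset per split; splits maximise variance reduction) predicts the target
from all candidate regulators except itself; the edge weight is the
regulator's total variance reduction averaged over trees (unnormalised
importances).  Defaults: 100 trees, `sqrt` candidate rule.  Sample order is
canonicalised internally, so results are invariant to column permutations
of the input; because splits depend only on within-feature orderings,
weights are also invariant under strictly monotone transforms of a
regulator's profile (in its regulator role).  Constant targets contribute
zero-weight edges with a warning.  Edges are ranked by weight (ties broken
lexicographically on regulator, target) and pruned to the global top-k
(default 16,000); per-regulator sub-networks report out-degree 0 for query
TFs absent from the pruned list.

GO biological-process enrichment uses the hypergeometric upper tail, with
categories restricted to 10–1,000 annotated genes.  FWER control is the
permutation min-p method: random query sets of equal size define the null
of the minimum p-value and the adjusted p is the add-one-smoothed fraction
of permutations at or below the observed p (Bonferroni available as a fast
fallback).  With heavily tied discrete p-values the procedure is mildly
conservative — measured null flag rate 3/100 runs at α = 0.05.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with planted truth: protein
families (true members plus four decoy classes: single repeat, internally
truncated repeat, ≥3 destroyed landmark tryptophans, prepended third
repeat), multi-isoform gene models on 1A–7B + U chromosomes with the
planted representative and expected names, replicated Ct tables with known
folds, expression matrices from a known TF→target network, and GO maps with
one enriched category.  All randomness flows from one integer seed through
one `numpy` generator per call; identical spec + seed is byte-identical.

Two generator behaviours are worth spelling out:

* **Domain fills.**  By default each member's unconstrained domain
  positions are drawn independently, so only the constrained scaffold is
  conserved across the family and column statistics outside it sit at
  background — that is what makes a ≥90%-tryptophan census recover exactly
  the five landmarks.  Passing a concrete `domain_sequence` instead embeds
  one shared domain in every member (then `mutation_rate=0` reproduces it
  exactly), emulating a recently expanded, near-identical family.
* **qPCR noise.**  A single `ct_noise_sd` applies per technical well;
  biological-replicate variation arises from averaged technical noise.
  This keeps the null t test exactly calibrated (tested: 5% ± 2% over
  1,000 tables) but understates real biological replicate dispersion.

Other simplifications relative to real data: substitutions are uniform
(no amino-acid exchange matrix), flanks are iid (10–80 residues a side),
gene models have no UTRs or alternative splicing beyond CDS-length
variation, expression is log-normal rather than count-overdispersed, and
GO categories are sampled independently rather than as a DAG.  Passing
tests therefore demonstrate correctness of the *rules and estimators*, not
robustness to every artefact of real genomes.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to leave wide margins:
landmark census on 200 members at 5% substitution; GRN recovery on 200
genes / 20 TFs / 100 samples with 50 trees (AUPR ≥ 8× the random baseline
across 10 seeds, against the ≥5× requirement); GO FWER calibration with
200 permutations × 100 seeds; qPCR null calibration over 1,000 tables.

## Known limitations

* No indel handling inside repeats (by design; see above).
* The DE stand-in has no dispersion shrinkage; with <3 replicates or very
  low counts its p-values are anti-conservative relative to DESeq2.
* `assign_subfamily` assumes the reference annotation is internally
  consistent; it does not detect paraphyletic reference subgroups.
* Motif presence thresholds are global per motif, not per-sequence
  composition-corrected.
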