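# Methods

This note documents the models and procedures implemented in
`clonescape`, their assumptions, the parameters that matter, and the
design choices made where the methodology left genuine freedom.

## Cancer cell fractions and clonality (`clonality`)

A somatic mutation observed at VAF `v` in a tumour of purity ρ, sitting
in a segment of total copy number `CNt`, present on `m` chromosomal
copies in a fraction `CCF` of tumour cells, has expected VAF

    v = ρ · m · CCF / (ρ · CNt + (1 − ρ) · 2),

assuming the contaminating normal cells are diploid at the locus. The
multiplicity estimator inverts this at CCF = 1: `m = round(v · (ρ·CNt +
(1−ρ)·2) / ρ)`, clamped to `[1, CN_major]` — the multiplicity cannot
exceed the major-allele copy number. No published estimator was
prescribed; rounding is the simplest consistent choice and is documented
as such. Mutations with no covering segment are assigned the
diploid-heterozygous state (CNt 2, minor 1) and flagged rather than
dropped; samples with missing purity or ploidy abort CCF-dependent
stages rather than imputing.

Clonal/subclonal labels come from a two-component mixture on CCF values
capped at 1.5 (super-clonal values, which arise from multiplicity
misestimation, are labelled clonal outright):

- a **clonal peak**: Beta distribution on CCF/1.5, initialised at mean
  0.95 (CCF scale) and moderate concentration;
- a **subclonal tail**: truncated power law `f(x) ∝ x^−α` on the
  observed range, initialised at α = 2 — the shape neutral drift
  produces in VAF space.

EM runs at most 200 iterations to a log-likelihood tolerance of 1e-6;
the M-steps are weighted method-of-moments (Beta) and bounded
one-dimensional MLE (tail exponent). Labels are maximum responsibility.
Three guarded exits all fall back to a plain CCF ≥ 0.75 threshold with a
logged warning: fewer than 20 mutations, non-convergence, and a
degenerate fit whose "peak" lands below the threshold (then there is no
clonal peak to separate). This mixture is deliberately simpler than full
published subclonal-deconvolution models: the package needs only the
peak/tail semantics, not cluster counts, and the simplification keeps
the fit deterministic and fast. There is no multi-sample joint
clustering and no indel-specific CCF handling.

## Maximum-parsimony phylogenies (`phylogeny`)

Samples are taxa; each non-tail mutation is a binary character (1 =
detected in the sample). Tail mutations are excluded by default because
neutral-tail sharing between regions reflects sampling depth, not
ancestry; `tail_policy="include"` exists for sensitivity analysis. An
explicit all-zero germline outgroup roots the tree, so somatic states
are derived. Patients need ≥ 3 samples and ≥ 2 variable characters.

Scoring is Fitch small parsimony, vectorised over characters, with the
germline join enforcing state 0 at the root. The search is a parsimony
ratchet: start from an average-linkage joining tree on Hamming
distances; each iteration doubles the weight of a random 25 % of
characters, hill-climbs on the weighted matrix from a random SPR kick of
the incumbent, re-optimises on unit weights, and accepts improvements;
at least 10 iterations, stopping after 10 without improvement (1000
max). The hill climb uses the full subtree-prune-regraft neighbourhood
(a superset of nearest-neighbour interchange) with bounded plateau
drift: when no move improves the score, up to 64 equal-score trees are
explored breadth-first before concluding — parsimony landscapes are
plateau-rich, and without drift the climb stalls one rearrangement short
of the optimum on a measurable fraction of random matrices. All
randomness flows from the seed; among equally parsimonious trees the
lexicographically smallest canonical newick is returned, so results are
reproducible to the byte.

Ancestral states use the accelerated-transformation (acctran) refinement
of the Fitch sets: root fixed to 0, each node takes its parent's state
when its first-pass set allows, otherwise its own unique state, placing
changes as rootward as the reconstruction permits. Per-branch gains
define clade lengths, driver-gene labels and neoantigenic-SNV counts;
the gains plus losses always sum to the parsimony score. The homoplasy
index is `1 − (number of variable characters) / score`. Bootstrap
support resamples characters with replacement (default 100 replicates —
the replicate count was not prescribed; it is configurable) and reports
the frequency of each ingroup clade.

## Treatment epochs, spectra and signatures (`epochs`)

Epochs are assigned set-wise by first detection: present in any sample
of timepoint A → treatment-naive; first detected at B → acquired under
chemotherapy (CTx) in both groups; first detected at C → CTx in
responders (who receive no radiation before resection) and
radiochemotherapy (RCTx) in non-responders. First detection wins, so a
mutation new at B and persisting at C is CTx only — the alternative
reading (counting it again at C) would double-count and is rejected. A
`use_phylo`-style assignment from acctran branches is possible via the
phylogeny module's branch sets; the set-based rule is the default
because it needs no tree.

Spectra collapse substitutions to the pyrimidine strand (G>T counts as
C>A, and collapsing an already-collapsed class is a no-op); six-class
proportions always sum to 1, and 96-bin trinucleotide catalogs are
produced when context is supplied. Group comparisons are two-sided
Wilcoxon rank-sum tests per class with Benjamini–Hochberg adjustment
reported alongside raw p-values.

Signature exposures are refit — not extracted de novo — against a
user-supplied 96-bin signature matrix by non-negative least squares,
renormalised to sum to 1. The prevalence filter then drops any signature
whose fitted weight falls below 5 % in at least one response-group ×
timepoint cell and refits on the retained set. The "at least one cell"
reading is the stricter of the two the rule admits; `mode="all_cells"`
(drop only if below 5 % everywhere) is available. Tests use a bundled
synthetic signature matrix (sparse Dirichlet columns) rather than any
published catalogue.

## Copy-number dynamics (`cna`)

The category map from (CNt, minor) is: loss CNt ≤ 1; cnLOH = (2, 0);
high LOH = CNt ≥ 3 with minor 0; diploid = (2, 1); amplification
CNt ≥ 5; gain otherwise. The "high LOH" boundary (minor 0 at CNt ≥ 3)
and the amplification cutoff are defaults exposed in `CNThresholds`,
since no exact boundaries were prescribed; users should treat the
high-LOH rule as a documented convention, not an established standard.
"Altered" means any non-(2,1) state; a ploidy-relative mode (altered =
CNt ≠ round(ploidy)) is a switch.

All cross-sample quantities first harmonise a patient's segments to the
union of breakpoints, conserving covered length on the shared support.
CNA clonality: a non-diploid category present (identical category, the
stricter of the two possible definitions) in all samples is clonal, in
more than 1/3 but not all subclonal, in at most 1/3 private; two-sample
patients collapse the last two into subclonal/private. Turnover between
two timepoints is the length-weighted fraction of shared exome whose
allele-specific (CNt, minor) pair differs — symmetric, exactly 0 on
identical profiles; a total-CN-only mode exists. Fragment-size
statistics compare per-class segment lengths by rank-sum tests.

## Neoantigens and immune escape (`immune`)

NeoSNV status is consumed as a precomputed flag (peptide–MHC prediction
is out of scope). The CN-category enrichment ratio weights each neoSNV
by 2/CNt — per-copy, relative to diploid — renormalises weights to sum
to 1 per sample, and divides each category's weight share by its genome
length share. Under placement uniform per genome copy this ratio is 1 in
expectation for every category, which anchors the diploid category at
~1; the weight-conservation identity Σ_c ratio_c · length_frac_c = 1
holds exactly. An unweighted count mode is provided because the exact
form of the "copy-number adjustment" admits readings; the per-copy
weighting is the default because it is the only reading with the
diploid-ratio-1 anchor.

Escape mechanisms:

- **HLA-LOH**: candidates have minor-allele copy number 0 at the HLA
  locus; confirmation requires allelic-imbalance p < 0.01, lost-allele
  CN < 0.5 with its confidence-interval upper bound < 0.7, kept-allele
  CN > 0.75, and > 10 mismatched sites. Every inequality is strict, and
  the caller is monotone: worsening any one criterion never flips a
  negative call positive. The CI is consumed as given (the simulator
  emits it); no internal CI estimation.
- **B2M / HLA mutation**: any exonic protein-altering mutation
  (nonsynonymous, frameshift, stop-gain, stop-loss); synonymous changes
  never count.
- **PD-L1 overexpression**: expression ≥ mean + k·SD of the
  treatment-naive samples (population SD; ≥ 2 naive samples required).
  Both k = 1 and k = 2 appear in the source conventions; the default is
  k = 1 with the multiplier exposed, and analyses should state which
  was used.

`genetic_escape = hla_mutation ∨ b2m_mutation ∨ hla_loh`;
`any_escape = genetic_escape ∨ pdl1_over`; a patient is escaped when at
least one sample is, and an escape is "early" when first observed at
timepoint A. Association tests against response group and Becker grade
default to patient-level units and use chi-square without continuity
correction, replaced by Fisher's exact test when any expected cell count
is below 5; degenerate tables are reported as not applicable.

## TCR dynamics (`tcr`)

Counts are normalised to TCRs/million within each sample and chain
(alpha and beta are never merged); the per-million values of a
sample+chain sum to exactly 1e6. A clone has expanded between timepoints
X and Y when `per_million_Y / max(per_million_X, floor) ≥ k` for
k ∈ {4, 8}, where the floor is half a count converted to per-million of
X's total — clones absent at baseline use the floor and are reported as
de novo — and a minimum later count of 2 suppresses singleton artefacts.
Folds are computed on per-million proportions, not raw counts, so
library-size differences cancel. The ≥ 8 set is a subset of the ≥ 4 set
by construction. Anchored clones (expanded A→C by default) are tracked
across all timepoints for fishplots; per-patient expansion counts are
compared between groups by two-sided Mann-Whitney U tests. Note that a
two-sided exact U test cannot fall below p = 0.1 at 3 vs 3 patients;
significance claims need ≥ 4 patients per group.

## The synthetic cohort generator (`simulate`)

The generator emulates the study design, not any particular dataset:

- **Genome**: pseudo-chromosomes of 1 Mb exonic blocks (default 4 × 10).
  All downstream statistics are length- and count-based, so no reference
  sequence is needed.
- **Clone trees**: 3–6 clones at baseline, one truncal; new clones
  appear at B and C carrying the corresponding epoch truth. Clone
  fractions are a Dirichlet draw at A, perturbed log-normally at B/C
  with response-group-specific strength (SD 1.0 for RE, 0.4 for NR —
  responders' clonal composition is shaken harder by effective
  treatment), with subtree-closed dropout (p = 0.25) emulating the
  mosaic-of-clones sampling of multi-region biopsies. A clone's CCF is
  its subtree mass, so descendant CCF never exceeds ancestor CCF.
- **Reads**: depth ~ Poisson(300) per site — the cohort's sequencing
  depth — and alt counts binomial at the expected VAF from the CCF
  formula; sites with fewer than 3 alt reads are unobserved, coupling
  detection to the candidate filter.
- **Mutation placement** is uniform per genome copy (probability ∝
  segment length × CNt): a region present in four copies accrues twice
  the mutations of a diploid region. This is the placement model under
  which the 2/CNt neoantigen weighting is exactly calibrated.
- **Copy numbers**: per-segment states drawn from a mix centred on
  diploid; each later timepoint toggles each segment independently with
  probability 0.10, so the expected turnover fraction equals the
  configured probability.
- **Escape truth**: mechanism flags drawn per sample (NR samples more
  likely escaped), LOHHLA-style inputs emitted with confirmed-level or
  benign values, and PD-L1 expression injected relative to the realised
  naive baseline so flagged samples sit above the 1-SD threshold and
  unflagged samples below it.
- **TCR repertoires**: rank-frequency power law (exponent 2, 3000
  clones, 30,000 reads by default) drawn multinomially at baseline.
  Background clones persist across timepoints by default
  (`tcr_background_noise = 0`), emulating a maximally reproducible
  repertoire; injected clones are raised at the final timepoint to an
  exact ≥ k per-million fold with a half-way abundance at B. With
  background noise enabled, low-abundance clones can produce spurious
  fold-8 events by sampling alone — real repertoires will, too, which is
  what the count floor and minimum-later-count guards are for.

What the simulator does **not** model: sequence context beyond a
96-bin multinomial, subclonal copy number, kataegis/clustered mutations,
sample contamination or purity misestimation, and TCR sequencing error.
Passing tests therefore demonstrate correctness of the computations under
the stated generative model, not robustness to every artefact of real
data.

## Problem sizes and determinism

Test and acceptance runs use deliberately compact problems — 200 random
matrices of ≤ 6 samples × ≤ 15 characters for search-oracle equivalence,
500 mutations at depth 300 for classifier accuracy, 10,000 placements
for the enrichment anchor, 50,000 mutations for signature recovery,
50 replicate repertoires of 10,000 clones for expansion recovery —
chosen so each check is statistically decisive while the whole suite
stays fast. Every stochastic component takes an explicit seed and all
randomness flows from one generator per run; repeated runs at a fixed
seed are byte-identical, including tree tie-breaks.
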