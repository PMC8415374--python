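# Methods

`enhevo` implements a comparative-epigenomics analysis of developmental
enhancers: how conserved accessible regulatory regions are across two
distantly related species at matched embryonic stages, and whether the
substitutions that accumulated on a focal lineage show signatures of
directional (positive) selection on chromatin accessibility.  All
components run end to end on a synthetic two-species world with known
ground truth, so every statistical property of the method is testable
without external data.

## The analysis

### Enhancer definition and stage specificity

Inputs are per-stage accessibility peak sets (BED) for five embryonic
time points (`TP1`–`TP5`) in each of two species.  Distal elements
("enhancers") are peaks whose distance to every annotated TSS exceeds
500 bp (strict inequality; a TSS is a point, distance 0 inside a peak,
otherwise the count of intervening bases).  A peak is *stage-specific*
when it overlaps (≥ 1 bp, half-open coordinates — touching intervals do
not overlap) no peak of any other stage.  Temporal pleiotropy is
summarized as, per stage, the fraction of peaks used in 1..5 stages and,
for TP2–TP4, the fraction also used in both/one/neither adjacent stage.

### Cross-species conservation

Coordinates are projected between species through a block map: an
ordered list of gapless alignment blocks (a reduced PSL/chain; a
converter from real PSL files is a documented extension point).  Every
aligned base of an interval is projected; the image is the span from
first to last mapped base, with the mapped-base count retained.  Images
touching more than one chromosome or strand are discarded as not
one-to-one.  A stage-specific enhancer is *conserved* under the strict
definition when its image overlaps (≥ 1 bp) a same-stage-specific
enhancer of the other species, and under the relaxed definition when the
edge-to-edge distance to the nearest one is strictly below 1 kb.
Per-stage conservation is reported as the Jaccard index
|conserved| / (|A| + |B| − |conserved|) and as proportions over species
A, species B, and pooled (the literature leaves the denominator
unstated, so all three are reported).  Stage contrasts use two-sided
Fisher exact tests against TP3, computed by exact integer enumeration of
the hypergeometric support (no floating-point tie epsilons), with
Benjamini–Hochberg adjustment reported alongside the raw values.

### Accessibility model (gapped k-mer classifier)

Per stage, a linear classifier is trained to separate stage-specific
enhancer sequences from an equal number of genome-background windows
matched per positive for length (exactly), GC content (±0.02) and
repeat fraction (±0.1, lowercase = masked); the matching tolerances
double, with a warning, if 10,000 draws fail.  Features are gapped
k-mers: for every 10-bp window, all C(10,6) = 210 masks of 6 informative
positions, canonicalized with their reverse-complement mirror so that
scoring is exactly strand-symmetric.  Counts are L2-normalized per
sequence and fit with L2-regularized logistic regression (liblinear,
deterministic; `C` = 1 by default).  The word length 10 follows gkmSVM
practice for regulatory sequence; k = 6 is a configuration knob.

The trained model exposes a *weight* for every possible 10-mer (the sum
of its canonical feature weights) and a sequence *score* = Σ window
weights + intercept.  Because the score is a sum over windows, the score
difference between two same-length sequences (deltaSVM) decomposes into
windows overlapping the differing positions; both the decomposition and
strand symmetry are exact, which the test suite asserts at 1e-9 and
bit-exactness respectively.  (Exact strand symmetry requires summing
each window's feature weights in sorted order, since float addition is
not associative.)  Classifier quality is measured by stratified
five-fold cross-validated ROC AUC on pooled out-of-fold scores, and
cross-stage transfer by the 5×5 matrix of each stage's model applied to
each stage's held-out positives/negatives.  An externally produced
all-10-mers weight table (`word TAB weight`) can be imported in place of
the internal model for parity runs.

### Positive-selection test (in-silico mutagenesis)

For each enhancer a three-way alignment (focal, sister, outgroup — the
*D. melanogaster* / *D. simulans* / *D. yakuba* configuration in the
motivating system) is reduced to a parsimony ancestor of focal+sister on
focal coordinates: equal focal/sister bases are ancestral; where they
differ, the outgroup breaks the tie (outgroup = sister ⇒ focal-branch
substitution; outgroup = focal ⇒ sister-branch change).  Columns with
three distinct bases, any gap, or N are excluded from substitution
calling rather than guessed.  Substitutions with a neighbor at distance
1 are flagged as dinucleotide events and can be excluded (both from the
statistic and from the substitution count) as a mutational-mechanism
control.

The observed deltaSVM is score(focal) − score(ancestor).  Its empirical
null re-introduces the same number of substitutions at distinct
positions drawn uniformly from non-excluded ancestor positions, with the
alternative base drawn uniformly, transition-weighted 3:1:1, or from the
estimated substitution spectrum; 10,000 draws in the full design (scaled
to ~500–1,000 in the test suite).  Scoring runs on a cached dense table
of all 4^10 word weights (8 MB, built once per model by broadcasting
each mask's canonical feature weights over the non-informative
positions), so a substitution's effect reduces to base-4 digit
arithmetic on precomputed window indexes.  A single-substitution delta
table handles draws whose positions are mutually ≥ 10 bp apart
(window-disjoint, hence exactly additive); interacting draws get an
exact per-cluster correction, so the fast path is an optimization, not
an approximation — the suite asserts agreement with full rescoring and
with brute-force 10-mer enumeration at 1e-9.  Empirical p-values use the
(r+1)/(N+1) pseudo-count estimator — never 0, super-uniform under the
null — rather than the literal r/N.  The upper tail (accessibility
gains) is the default; lower and two-sided tails are available because
directional selection may push accessibility either way.  Enhancers with
fewer than 2 applied substitutions are dropped (counted after
dinucleotide exclusion when that control is on).  Benjamini–Hochberg
q-values are computed within each tested set and `q < 0.05` defines a
positive call.

The substitution spectrum pools, over all enhancers, counts of each
X→Y substitution divided by the count of ancestral X (split by CpG
context: the ancestral base participates in a CG dinucleotide on either
strand).  The transition/transversion ratio is the per-opportunity
transition rate over the per-opportunity transversion rate (each base
has one transition and two transversion alternatives).

#### Cross-fitting

Scoring an enhancer with a model whose training set contained that very
sequence biases deltaSVM upward: the focal sequence's own k-mers carry
trained-in weight that the ancestor and the null's pseudo-focals lack.
At the scale of the real data (thousands of training enhancers per
stage) the per-sequence effect is small, but at simulation scale it
dominates — with ~100–200 training positives the neutral rejection rate
at p < 0.05 reached ~0.36.  The pipeline therefore splits each stage's
enhancers into two folds and scores each fold with the model trained on
the other (q-values are then computed across the stage's union).  With
this cross-fitting, and equally with a fully independent training draw,
the neutral rejection rate is ~0.04–0.05 and p-values pass a KS
uniformity check.  Cross-fitting can be disabled (`cross_fit: false`)
to reproduce the literal same-set design.

### Substitution/polymorphism excess

Positive calls are validated population-genetically: adaptive fixation
increases fixed differences and depletes segregating variation, so the
pooled 2×2 table (positive/nonpositive × substitutions/polymorphisms) is
tested with the two-sided Fisher exact test, alongside per-group
substitution/polymorphism ratios.  SNPs are counted within the enhancer
irrespective of which alignment columns entered the selection test, and
no frequency or quality filter is applied.  Pooled-count contingency is
used (per-enhancer ratios are diagnostics only).

## The synthetic world

The generator emulates the study's inputs with known truth labels:

- **Motifs and enhancers.**  Each stage has its own set of 3 random
  PWMs (width 8).  Per column, probability concentrates on one random
  major base at an information content of 1.5 ± 0.1 bits.  An enhancer
  is 300 bp of i.i.d. background at GC 0.4 with 4 non-overlapping motif
  instances sampled from the PWMs.
- **Ground-truth accessibility** is the positive-part sum of PWM
  log-odds over all windows, summed over motifs: every intact instance
  contributes, so damaging any instance lowers the phenotype and
  repairing any raises it.  (A per-motif best-hit (max) scorer was
  evaluated first and rejected: selection under a max is indifferent to
  destroying redundant motif copies, which a window-sum statistic like
  deltaSVM rightly sees as damage — observed deltas under "up" selection
  came out negative and power was nil.  The positive-part sum keeps the
  truth scorer PWM-based and independent of the gapped k-mer model while
  making the selection modes mean what they say.)
- **Branch evolution** is a fixed-count conditional process, matching
  the test's conditioning on the observed substitution count: the count
  is Poisson(branch length × sites), positions are distinct, and the
  alternative base follows a transition/transversion ratio kappa = 3.
  Defaults: focal and sister branches 0.03 expected substitutions/site
  (a *D. melanogaster*–*D. simulans*-like divergence split over the two
  branches), outgroup segment 0.09.  Under directional selection the
  focal branch chooses each substitution from a 24-proposal pool with
  probability ∝ exp(±s·Δtruth); s = 5 by default.  An optional flag
  plants adjacent-pair substitutions to exercise the dinucleotide
  control.  No indels occur inside triples (the test scores only
  substitutions); the cross-species block map does contain indels.
- **Two-species layout.**  Species A's chromosome alternates spacers
  and enhancers; species B is built in the same walk as mutated copies
  of aligned segments (5% divergence).  Spacer middles vary among
  aligned / deleted-in-B / B-insertion variants so translation is
  nontrivial, while 550 bp aligned pads flanking every enhancer keep
  neighboring images > 1 kb apart in B — necessary so the relaxed
  (< 1 kb) conservation definition cannot be satisfied by accident.
  Conserved enhancers sit in aligned blocks with a same-stage B peak at
  the image; nonconserved ones either fall in unaligned gaps (no
  ortholog) or align to peak-free regions.  Shared (multi-stage) peaks
  and promoter-proximal peaks with their TSSs exercise the
  stage-specificity and distal filters.  Default per-stage conserved
  fractions peak at TP3 (0.50 vs 0.25–0.30) and true-selection fractions
  dip at TP3 (conserved/nonconserved 0.15/0.45 elsewhere, 0.00/0.15 at
  TP3), encoding the hourglass structure the pipeline is asked to
  recover.
- **Polymorphisms.**  Neutral enhancers draw Poisson(θ·length) SNPs
  (θ = 0.01/bp, a *D. melanogaster*-like diversity); enhancers under
  selection draw Poisson(θ·length·0.3), a selective-sweep deficit.
- **Determinism.**  All randomness derives from one root seed through
  named SHA-256 substreams, so any component regenerates independently
  and whole worlds are bit-identical under a fixed seed.

What the generator does **not** emulate: real *Drosophila* genome
composition (isochores, repeats, codon structure), indel evolution
within enhancers, read-level noise or peak-calling uncertainty, linked
selection, and demography behind the SNP counts.  Passing tests
therefore demonstrate the statistical machinery's correctness and
calibration under the model's assumptions, not robustness to every
property of real data.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere, including on disk.
- The generator's default geometry (4 sites × 8 bp at 1.5 bits/column,
  branch 0.03) was chosen so the emulated study sits in the method's
  intended operating regime — classifier AUC ≥ 0.9 and detectable
  selection — mirroring the motivating system, where the classifier is
  strongly predictive and positive calls are frequent.  Measured under
  these defaults: neutral rejection rate 0.04–0.06 at p < 0.05 (KS
  uniformity not rejected), and power 0.43 / 0.78 / 0.88 at selection
  strengths 0.5 / 2 / 8 (q < 0.05, independent training, 60 enhancers,
  paired across strengths).
- The method's validity degrades with divergence (ancestor inference
  and the substitution-count conditioning both assume sparse changes);
  no hard threshold is imposed, but branch length is a simulator knob
  and ancestor accuracy is asserted ≥ 99% per site at branch 0.02.
- Fisher tests are two-sided; raw p-values are primary and BH-adjusted
  values are reported alongside, matching how stage contrasts are
  usually presented.
- An enhancer overlapping both muscle and neuron reference sets is
  labelled `ambiguous` and excluded from the three-way tissue split
  rather than assigned by precedence.
- Null position resampling does not exclude the observed substitution
  positions (keeping the draw exchangeable with the observation).
- Degenerate inputs: empty TSS annotations keep all peaks with a
  warning; zero-margin Fisher tables return p = 1; enhancers with no
  applied substitutions have deltaSVM exactly 0 and are excluded from
  testing by the ≥ 2-substitution rule.

## Problem sizes in the shipped tests

The full design (10,000 permutations, thousands of enhancers per stage)
is scaled down in the test suite and acceptance script as the package's
own verification sizes: 500 enhancers × 1,000 permutations for null
calibration, 450 × 600 for the transition-bias control, 50 enhancers per
selection-strength condition, 500+500 sequences for classifier CV,
100 enhancers/stage × 1,000 permutations for the end-to-end hourglass
world, and 60/stage × 800 in `scripts/acceptance.py`.  All sizes are
plain function arguments; nothing in the code depends on them.
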