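# Methods

`loopwalk` implements the analytics of a "loop-walking" thermostability
screen: simultaneous randomisation of three consecutive loop residues, a
heat-challenge activity assay, and machine-learning prioritisation of the
residue triples that were never assayed.

## Screening arithmetic

Each screened variant carries two measurements in the same units (U/mL):
enzymatic activity without heat treatment, and residual activity after the
heat challenge (60 °C, 30 min in the motivating assay). The modelled
response — *thermostability activity* — is their ratio, reported as a
percentage retained. Comparisons against the wild-type enzyme use relative
activity and relative residual activity (percent of the wild-type value);
a variant is plotted in quadrant I of the (relative activity, relative
residual) plane when both exceed 100%. Values exactly at 100% are classed
as non-improved; real assays essentially never produce an exact tie, so the
convention only matters for constructed inputs.

Reporting conventions: percent retained is rounded to the nearest integer;
relative residual activity to two significant figures. With the packaged
worked example (wild type 1000/52 U/mL; triple mutants 1580/560, 1350/800,
1220/800) these rules give 5%, 35%, 59%, 66% retained and relative
residuals of 1100% and 1500%.

Synergy of a triple mutation against its three single mutants is scored on
a multiplicative null: the expected log10 relative-residual fraction of the
triple is the sum of the single-mutant log10 fractions, and synergy is
observed minus expected. A log-additive null is the standard reference for
ratio-valued effects; zero means the triple effect is exactly the product
of the single effects.

## Physicochemical encoding

Residue triples are encoded with 13 amino-acid scales (one value per
canonical amino acid, AAindex-style), position-major: 13 descriptors ×
3 positions = 39 features. Encoding is a pure lookup; two triples differing
at one position differ only in that position's 13-feature block.

The packaged descriptor set covers isoelectric point, normalized van der
Waals volume, alpha-helix and beta-strand indices for beta-proteins,
side-chain contribution to protein stability, a knowledge-based atom–atom
potential stability scale, hydropathy, normalized turn frequency, free
energies in the beta-strand and alpha-helical regions, polarity, a
side-chain interaction parameter, and amino-acid distribution.
**Provenance:** rows whose citation field names a publication are
transcriptions of the published scale (Kyte–Doolittle hydropathy, Zimmerman
isoelectric point and polarity, Fauchère normalized van der Waals volume,
Chou–Fasman turn propensity). The remaining rows are *synthetic stand-in
scales*: constructed profiles whose extreme residues follow the documented
behaviour of the named property (side-chain stability contribution highest
for Phe and Trp; the atom–atom potential scale highest for Phe, Trp, Tyr;
strand and helix free-energy cost highest for Pro and Gly; side-chain
interaction highest for Lys, Pro, Gln, Glu, Asp) and whose remaining
entries were chosen, within plausible bounded ranges, to minimise
correlation with every other packaged scale. The decorrelation is
deliberate and matters: the descriptor set's premise is that the 13 scales
are quasi-independent representatives of distinct correlation clusters,
and sparse support recovery is only identifiable when no scale has a
strongly correlated substitute within the table (an early draft of the
fixture with |r| up to 0.96 between two rows made weight-sign recovery
provably impossible at any penalty). Residual correlations among the
genuine published scales (e.g. hydropathy vs polarity, r ≈ −0.67) are kept
as-is. No quantitative claim of the package depends on the exact values —
only on a fixed, full-variance, quasi-independent 13 × 20 table. Users
with an AAindex1 flat file can load genuine scales with
`DescriptorTable.from_aaindex1`; records with `NA` entries are rejected by
name.

`select_representative_descriptors` de-duplicates a larger descriptor
collection by average-linkage hierarchical clustering on the distance
1 − |Pearson r| between scales (absolute correlation, because a scale and
its negation carry the same information), cutting the tree to a requested
number of clusters and keeping, per cluster, the member with the highest
mean absolute correlation to its co-members. Zero-variance scales are
excluded with a warning.

Features are standardized (population SD) before any penalised fit,
because L1 penalties are scale-sensitive and standardized weights are
comparable across descriptors. Constant columns standardize to zero and
are flagged.

## Tertile stratification

Thermostability activities are ranked (descending) and labelled: the top
`ceil(0.34 n)` records *high*, the bottom `ceil(0.34 n)` *low*, the rest
*medium*; ties resolve by stable input order, so stratification is
seed-free. For n = 214 this yields 73 high, 73 low and 68 medium. Note the
quota arithmetic is convention-dependent — 34% tails of 214 with other
rounding rules give a medium stratum anywhere between 68 and 72 — and the
package always reports the counts exactly as its stated rule computes them
rather than adjusting them toward any external expectation.

## The discrimination cascade

Two L1-penalised logistic discriminators are fitted on the standardized
39-feature encoding:

1. **stage 1** — improved (high + medium) vs non-improved (low); used to
   discard unpromising candidates at P(improved) ≤ 0.5;
2. **stage 2** — high vs medium improvement; its probability of the high
   class ranks the surviving candidates.

Logistic rather than linear discrimination is the default because the
cascade needs calibrated class probabilities for screening and ranking; an
L1 linear-regression-on-0/1-labels variant (`family="linear"`, probability
clipped to (0,1)) is retained for sensitivity analysis.

All 20³ = 8000 residue triples not observed in the screen (8000 − 214 =
7786 under the default conditions) are synthesized in silico, encoded,
screened by stage 1 and ranked by stage 2; exact probability ties break
lexicographically in the fixed alphabet order (A R N D C Q E G H I L K M F
P S T W Y V), and ranks run consecutively from 1. Candidate selection
takes the top *n* ranked entries as the predicted-high set and the best
*n* entries with P(high) ≤ 0.5 as the predicted-medium set; the sets are
disjoint by construction.

The stage-2 weight vector reshapes position-major into a 13 × 3 table
(descriptors × positions) whose positive cells are evidence for the high
class; features removed by the penalty appear as exact zeros.

### Penalty selection and solver

λ is chosen per fit by stratified k-fold cross-validated deviance (default
k = 5, seeded shuffle) over a data-adaptive path: starting at the largest
penalty with any active feature (λ_max, via `sklearn.svm.l1_min_c`) and
descending 2.5 decades in 6 log-spaced steps, in the spirit of glmnet's
default path. Anchoring at λ_max matters numerically: on nearly separable
screens the near-unpenalised regime makes L1-logistic solvers orders of
magnitude slower while never winning the deviance comparison. Deviance
ties resolve toward the sparser end. A fixed penalty is available as
`lambda_policy="fixed:<lambda>"`.

Fits use liblinear with a tight final tolerance (1e-8; 1e-4 during the
path search, where only deviance comparisons matter) and a pinned internal
row-shuffling seed so that identical inputs give bit-identical models.
liblinear formally penalises the intercept; the package sets
`intercept_scaling = 1000`, which makes the intercept penalty negligible —
in the overwhelming-penalty limit all 39 weights are exactly zero and the
predicted probability approaches the majority-class fraction (to within
the scaling approximation, a few percent).

### Validation

Both models are validated by leave-one-out cross-validation: each sample
is predicted by a model refitted on the other n − 1, with the λ policy
re-applied inside every fold. A fold that would lose one class entirely
(only possible when a class has a single member) is predicted by the
majority class and flagged in the report.

## Synthetic screens and what they do (and do not) show

Because the motivating 214-mutant screen was never published, all
quantitative claims are made against the packaged generator, which is
first-class, tested code. Its defaults are the study conditions:

* 214 distinct triples drawn uniformly without replacement from 20³;
* a sparse latent stability model on the standardized encoding
  (standardization over the full 8000-triple space, so it is
  library-independent): five nonzero weights, three in the position-1
  block (isoelectric point −1.0, side-chain stability −1.3, polarity
  +0.9) and one in each other block (side-chain interaction +0.5 at
  position 2, atom–atom potential −0.8 at position 3). The concentration
  on position 1 mirrors the strong positional asymmetry real loop screens
  show; the acid-friendly, aromatics-averse sign pattern is the kind of
  rule such screens recover;
* intercept −1.0, so a typical variant retains well under 50%;
* Gaussian noise on the latent score with SD 0.25 × the latent signal SD
  (configurable; `noise_sd=None` means this relative default);
* retained fraction = logistic(latent), strictly inside (0, 1) as a
  physical retention must be;
* untreated activity log-normal around 1000 U/mL with CV 15% (typical
  assay error), residual activity = untreated × retained.

The generator does **not** model codon-level mutagenesis bias, expression
artefacts, plate effects, or apparent retention above 100%; real screens
show all of these. Passing recovery tests therefore demonstrates that the
pipeline's statistics are implemented correctly and can recover a sparse
physicochemical rule at realistic noise — not that any particular real
enzyme's screen will reach the same accuracies.

Ground-truth labels apply the same tertile rule to the noiseless latent
scores, so at zero noise they coincide exactly with the pipeline's labels,
and agreement decays as noise grows.

## Problem sizes used by the test suite and acceptance script

Unit tests run the cascade on 45–60-mutant screens; the recovery study
uses the full study conditions (n = 214) over 20 seeded replicates in the
test suite and 12 in `scripts/acceptance.py`, reporting medians. One LOOCV
pass at n = 214 performs 214 refits (each with its own 5-fold path search)
and takes roughly half a minute on a single CPU.

## Known limitations

* The packaged descriptor table is part-synthetic (see provenance above);
  results on real screens should use genuine AAindex records.
* The linear-family probability is a clipped fitted value, not a
  calibrated probability; it is intended for rank-order sensitivity
  checks only.
* The intercept is only approximately unpenalised (liblinear convention).
* Quadrant classification and hit rates carry no significance testing;
  assay error (~15% CV) is modelled in the generator but not propagated
  into the reports.
* Duplicate triples are accepted only with identical activities; replicate
  merging is the caller's responsibility.
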