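# Methods

`vocalkin` implements a complete quantitative workflow for asking whether
animals *socially accommodate* their calls — converge toward, or diverge
away from, the calls of the conspecifics they share housing (or group
membership) with — and how that interacts with genetic relatedness, sex and
morphometry.  The design follows the bioacoustic analysis of multi-syllable
trill calls in a captive breeding colony: individuals carry stable vocal
signatures, females are housed matrilineally, males mostly with non-kin,
and the question is whether co-housing time reshapes the signatures.

## 1. Acoustic description of a trill

A trill is a train of up to 30 frequency-modulated ultrasonic syllables.
Its 29-parameter description consists of the whole-call duration and
syllable count plus nine F0 landmarks for each of three *key syllables*:

* first syllable (index 1), end syllable (index *n*), and the middle
  syllable at index ⌈*n*/2⌉ — half the syllable count, rounded up
  (19 syllables → syllable 10);
* per key syllable: duration, start/end/min/max/mean F0, F0 range, and the
  relative time (0–1 of syllable duration) of the F0 minimum and maximum,
  ties resolved to the first occurrence.

Syllables are segmented as runs of continuous supra-threshold short-time
energy (default −40 dB relative to the loudest frame; runs separated by
gaps < 5 ms are merged; runs < 5 ms are dropped).  F0 is tracked by
short-time spectral peak picking (Hann window of 256 samples, hop 64) with
parabolic interpolation of the log-magnitude spectrum, which is accurate to
well under one bin for the clean FM tones the bundled synthesizer produces.
The exact nine-parameter set is a declared canonical choice: it preserves
the published parameter count (29) and every parameter name the analysis
reports (durations, `timeminF0`), with standard F0 landmarks completing the
set.  Real recordings with harmonics, noise or amplitude modulation would
need a more robust F0 tracker (e.g. autocorrelation with a voicing
decision); the synthesis-extraction round trip validates bookkeeping and
landmark geometry, not robustness to natural signals.

## 2. Signature statistics

* **Sex differences** — one linear mixed model per parameter,
  `parameter ~ sex + (1 | individual)`, ML-fitted; reported t = estimate/se
  with a conservative df of *n*_individuals − 2 (calls of one sender are
  pseudo-replicates, so call-level df would overstate certainty).
* **PCA** — on the correlation matrix (z-scored parameters), retaining
  components with eigenvalue > 1 (Kaiser criterion), no rotation.  Retained
  scores are uncorrelated, a prerequisite for the information criterion.
* **DFA** — Gaussian linear discriminant with pooled within-class
  covariance; priors proportional to class sizes by default (an `equal`
  flag is exposed).  Leave-one-out cross-validation refits the discriminant
  excluding each call.  A singular pooled covariance is ridge-regularised
  with λ = 1e-6 · trace/dim and logged.
* **Nested permuted DFA (pDFA)** — for a between-individual factor such as
  sex.  For each of `n_selections` (default 100) random splits the DFA is
  trained on `n_train_per_individual` calls per individual (default
  min over individuals of ⌈2/3 · calls⌉) and held-out calls are
  cross-classified; observed statistics are means over selections.  The
  null permutes whole individuals across factor levels (preserving level
  sizes), one split per permutation (default `n_perm` 1000);
  p = (#{null ≥ observed} + 1)/(n_perm + 1) and the chance level is the
  null mean.  Note that averaging the observed statistic over many
  selections while each permutation uses one split makes the observed less
  variable than the null; for exact null calibration (uniform p) use
  `n_selections = 1`, which is what the calibration tests do.
* **Per-individual binomial tests** — exact one-sided binomial tail of the
  individual's correct original classifications against its class prior
  *n_i*/N (the class-size-dependent convention; `uniform` = 1/k and
  explicit probabilities are exposed, since the printed "chance level"
  is ambiguous between conventions).
* **Cohen's κ** — (p_o − p_e)/(1 − p_e) from the confusion matrix
  marginals.
* **Beecher's H_s** — identity information in bits: for each retained
  (uncorrelated) component with one-way ANOVA ratio F_i between
  individuals, H_s = Σ log₂ √F_i over components with F_i > 1.  The formula
  is not printed in the source analysis; this is the cited Beecher
  statistic with the standard guard that components whose between-
  individual variance does not exceed the within-individual variance
  contribute zero bits.

## 3. Dyadic score matrices

All four matrices are built per sex (the analyses are within-sex).

* **Acoustic dissimilarity** — per-individual parameter medians, z-scored
  across individuals (constant parameters dropped with a warning),
  pairwise Euclidean distances.
* **Genetic relatedness** — autosomal kinship φ by the recursive pedigree
  algorithm in topological order: φ(i,i) = ½(1 + φ(sire, dam)),
  φ(i,j) = ½(φ(sire_i, j) + φ(dam_i, j)); founders and unknown parents are
  unrelated and non-inbred.  φ = 0.5 for a non-inbred self, 0.25 for
  parent–offspring and full sibs, above 0.5 under inbreeding.  Validated
  against a gene-dropping Monte-Carlo oracle.
* **Social contact** — whole days a dyad shared a cage *before the focal
  individual's recording date* (partial days count as one).  Because dyad
  partners are recorded in different years (up to 9 apart), the matrix is
  directional/asymmetric.
* **Body-weight dissimilarity** — like the acoustic score, from median
  weekly weights over each individual's recording calendar year (the
  reference window is a package choice: weights drift seasonally and the
  recording-year median is the closest stable proxy).

Scaling: distance- and contact-type scores are divided by the maximal
off-diagonal value, i.e. min–max scaling anchored at the theoretical
minimum 0.  This keeps the printed semantics exact — 0 means *identical*
(or *never co-housed*), 1 marks the extreme observed dyad — and a score of
exactly 0 occurs only for identical medians, which observed-minimum
anchoring would not guarantee.  Diagonals are excluded from scaling and
from every analysis.

## 4. Matrix inference

* **Mantel test** — Pearson r of the unordered-dyad vectors; asymmetric
  matrices are symmetrized by the dyad mean first (the directional cells
  are retained for the mixed models).  The null permutes the object labels
  of the second matrix (rows and columns simultaneously), default 999
  permutations; two-tailed p counts |r_perm| ≥ |r_obs| with +1 smoothing so
  p is never 0.
* **Partial Mantel** — first-order partial correlation
  r_AB·C = (r_AB − r_AC r_BC)/√((1−r_AC²)(1−r_BC²)) of the dyad vectors,
  same permutation null on B.  The degenerate A-vs-B-given-B case returns 0.
* **Contact-restricted Pearson** — because most dyads never shared a cage,
  the contact matrix is zero-inflated and a Mantel r is dampened; the
  correlation of acoustic dissimilarity with contact over dyads with
  contact > 0 (parametric two-tailed p, n − 2 df) isolates the
  accommodation signal.  Contact is a similarity correlated against a
  dissimilarity, so r < 0 is convergence and r > 0 divergence.

## 5. Dyadic mixed models and backward elimination

One row per ordered within-sex dyad (the directed layout keeps the
asymmetric contact score; time difference = recording year of individual 1
− individual 2).  Full model:

    acoustic ~ genetic * contact * weight + contact * time_difference,
    random intercepts for both dyad members

ML-fitted via variance components (one crossed component per dyad
position — the practical surrogate for a nested individual1/individual2
specification; a failed fit falls back to a single random intercept with a
logged warning).  Reported p-values use t with the single-residual-df
convention df = n_dyads − n_fixed.

Backward elimination removes at each step the highest-level *removable*
interaction (not contained in a retained higher-order interaction) with the
highest non-significant p (α = 0.05), never a main term.  Each removal is
validated by a likelihood-ratio χ² between the nested ML fits (the Wald p
of the dropped coefficient is recorded alongside; the two agree
asymptotically and the LR is well-defined for ML fits).  Terminal states:
only main terms left; all remaining interactions significant; or the model
comparison is significant (the previous model is kept).

A calibration caveat worth stating: with five null interaction terms tested
at α = 0.05, a correctly calibrated procedure reduces to the pure
main-effects model in only ≈ 0.95⁵ ≈ 77% of datasets — spurious interaction
retention at the nominal rate is expected behaviour, not a defect.

The dyad-relationship models restrict to socialized dyads (contact > 0),
contrast first-degree (parent/sibling) against unrelated same-sex dyads on
the acoustic, genetic or contact score, with the same random structure.

## 6. The synthetic colony generator

The generator is the test bed: it emulates the study conditions — 22
females and 14 males contributing 482 trills in total, matrilineal female
housing vs mostly-unrelated male housing in cages of 2–3 over multiple
epochs, weekly weights, and recording dates spread over nine years — with a
*known* effect structure, so every estimator can be checked for sign and
calibration.  On a standardized latent scale (mapped affinely to physical
units resembling published trill statistics: ~1 s calls, tens-of-ms
syllables, 15–30 kHz F0):

    y_call = μ + β_sex·male + b_individual + contact_shift + ε

* `b_individual` ~ MVN across individuals with covariance
  σ_ind²[(1 − β_kin)I + β_kin Ā], Ā the unit-diagonal-normalised numerator
  relationship matrix 2φ from the generated pedigree; β_kin ∈ [0,1] sets
  how strongly kin share baselines (default 0.5).
* `contact_shift` — the accommodation term, computed with the *same*
  contact definition the estimators use: individual i moves along
  (b_i − b_j) for each cage partner j with weight β_contact · c_ij
  (averaged over partners).  β_contact < 0 is convergence, > 0 divergence,
  and may be given per sex.  A convergence pull is bounded at −0.5 per
  partner so a dyad meets in the middle rather than overshooting past each
  other (unbounded strong negative coefficients would paradoxically
  *increase* dissimilarity).
* `ε` ~ N(0, σ_call²) i.i.d. per call and parameter.

Defaults: σ_ind = 1, σ_call = 0.6 (strong individual signatures, matching
the high classification accuracies such datasets show), β_sex = 0.8 on
roughly half (15/29) of the parameters, β_kin = 0.5, β_contact = 0 — the
study gives no accommodation effect size, so the accommodation coefficient
is a free parameter that simulations set explicitly.  Everything is
deterministic under the seed; identical seeds give bit-identical tables.

What the generator does *not* emulate: real spectro-temporal structure of
calls (features are drawn, not extracted from audio), oestrus/seasonality,
unequal recording effort beyond the randomized per-individual call counts,
or measurement failure.  Passing tests therefore demonstrate correctness
and calibration of the statistics, not robustness to raw-field-recording
pathology.

## 7. Problem sizes and numerical choices

Simulation-based tests use scaled problem sizes chosen as sensible
desk-scale designs: Mantel calibration over 200 replicates of 10-individual
matrices with 199 permutations; pDFA calibration over 200 replicates
(n_perm = 200, one selection) and power at 24 individuals × 8 calls;
accommodation sign recovery over 50 full-size colonies; elimination
recovery over 50 tables of 12 individuals (132 directed dyads).  Pipeline
report defaults: 999 Mantel permutations, 200 pDFA permutations × 20
selections.

Tolerances and tie-breaks: F0 landmark assertions allow 2 spectral bins;
time positions of F0 extrema take the first occurrence; min–max scaling
warns and leaves a matrix unscaled when all off-diagonal values are zero;
z-scores use the sample standard deviation (ddof = 1); permutation p-values
use +1 smoothing; MixedLM fits try L-BFGS then conjugate gradients and fall
back to a simpler random structure on failure.

## 8. Known limitations

* The nine per-syllable parameters are a canonical substitute for an
  unavailable original definition table; only the count and the named
  parameters are guaranteed to correspond.
* Whether z-scoring of the dissimilarity inputs should pool the sexes is
  unresolved in the source; the package computes within sex (matching the
  per-sex analyses) but the functions accept any individual subset.
* The single-residual-df convention for dyadic models is reported metadata,
  not an exact small-sample distribution; dyadic dependence beyond the two
  member intercepts (e.g. pair-level noise) is not modelled.
* pDFA p-values with selection-averaged observed statistics are mildly
  conservative/anticonservative depending on the direction of the
  averaging effect; exact calibration holds at one selection.
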