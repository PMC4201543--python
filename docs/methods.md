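# Methods

## The prediction problem

Caspases are cysteine proteases that cleave their substrates almost
exclusively C-terminal to an aspartate (P1 = D, Schechter–Berger
nomenclature; the scissile bond lies between P1 and P1′).  Beyond the
near-absolute P1 constraint, specificity is loose: executioner caspases
prefer a DxxD-[AGST] consensus, with E favoured at P3 and small uncharged
residues (A, G, S, T, N) at P1′.  `caspcleave` treats cleavage-site
prediction as binary classification of the 8-residue P5…P3′ context around
every candidate aspartate (optionally glutamate, which can sporadically
substitute for D at P1).

## Position weight matrix

Positive windows are aligned on the scissile bond and counted per position.
With background amino-acid distribution *b(i)* and a background-proportional
pseudocount of total weight *c* (default 1), the stored matrix is

    PWM(i, j) = log2( (count(i, j) + c·b(i)) / ((n_j + c) · b(i)) )

where *n_j* is the number of unpadded residues observed at position *j*.
This form has two properties the implementation relies on:

- **Exact mass conservation**: Σ_i b(i)·2^PWM(i,j) = 1 at every position,
  so the matrix always encodes a proper probability ratio.  This is checked
  as an invariant on every computed matrix.
- **Shrinkage**: entries move monotonically toward 0 as the pseudocount
  grows, and no entry is ever −∞.

The background defaults to the amino-acid composition of the full substrate
protein sequences supplied at training time (Laplace-smoothed, +1 count per
residue, 'X' excluded); a uniform background or a user-supplied table are
alternatives.  Padded window positions ('X' at protein termini) are excluded
from the counts and carry feature value 0.

## Feature layout

Each window contributes 8 numeric features — the PWM entry of the observed
residue at each of P5…P3′ — plus per-residue secondary-structure
(helix H / sheet E / loop `_`) and disorder (ordered `.` / disordered `*`)
labels, one-hot expanded to 24 + 8 numeric columns (40 features in total).
One PWM value per position (rather than a 160-wide one-hot-by-residue
expansion) matches a per-record line layout in which each sequence
contributes one value per position; the categorical labels are expanded
because forests and SVMs need numeric input, and one-hot coding imposes no
ordinal scale on the three structure states.

## Structural context

Structure is predicted (or loaded) for the **full protein** and sliced per
window, so every window sees its real flanking context rather than a
truncated 8-mer.  Two sources sit behind one interface:

- a **bundled baseline predictor**: Chou–Fasman helix/sheet propensities
  averaged over a 7-residue window with argmax against a loop threshold of
  1.03 (ties → loop), and a FoldIndex-style disorder call over a 9-residue
  window (I = 2.785·⟨hydropathy₀₁⟩ − |⟨charge⟩| − 1.151, disordered where
  I < 0, Kyte–Doolittle hydropathy rescaled to [0, 1], charges D/E = −1,
  K/R = +1, H = +0.5);
- a **file adapter** for labels computed by any external secondary-structure
  or disorder predictor (three lines per protein: id, ss string, disorder
  string).

The baseline is a deterministic single-sequence propensity method; it is not
expected to match profile-based predictors in accuracy, and swapping sources
changes feature values but never feature-vector shape.

## Training data construction

Positives are the windows of annotated cleavage positions, deduplicated on
the 8-mer string.  Negatives use the sliding-window scheme: the residues at
offsets −2, −1, +1, +2 from each verified P1 are tentatively treated as P1,
giving ≤ 4 near-site non-cleavage windows per positive and an overall ≈1:4
class ratio.  All window strings in a training set are unique; a negative
candidate that collides with a positive window is discarded (the verified
label wins — discarding the positive would corrupt the labels).  Candidates
whose pseudo-P1 happens to be D are kept: the rule is positional, not
residue-based.  Terminal candidates are built with 'X' padding rather than
dropped.  Train/test splitting is stratified by class (preserving the 1:4
ratio in both partitions) and deterministic per seed.

## Classifier

The production classifier is a random forest with 1500 trees and unlimited
depth, the optimized configuration; naive-Bayes, single-decision-tree and
RBF-kernel SVM analogs (gamma 0.01, C 1, standardized inputs) are available
behind the same interface for comparison.  A window is called cleaved when
the positive-class probability is ≥ 0.5.

Evaluation pools confusion counts at that threshold and reports accuracy,
precision and specificity (percent), Cohen's kappa, MCC, rank-based
(Mann–Whitney, midrank ties) ROC AUC, and a configurable cost
c_fp·FP + c_fn·FN (defaults 1/1; no specific cost weighting is asserted
because none can be inferred uniquely from published cost values).  Metrics
whose closed form divides by zero are reported as undefined, never as 0.

Cross-validation is stratified k-fold (default 10), seeded.  The PWM is
**recomputed inside each fold** from that fold's training positives only:
computing it once from all positives lets every held-out window contribute
to the matrix it is scored against, which measurably inflates out-of-fold
AUC on null data (~0.57 instead of 0.5 in our checks).  The final fitted
model uses the all-positives matrix, which is stored inside the model file
so scoring is self-contained.

## Applying the model

- **Scanning** scores every D (optionally E) in a protein and reports the
  P5-P5′ display window with '-' at the bond, the probability, and the
  yes/no call, sorted by descending score (ties by ascending position).
  E-at-P1 scanning reuses the same matrix (its E column at P1); no separate
  model is trained.
- **Motif search** (grammar `DEVD-A/G/S/T`: left-to-right toward the bond,
  '/' alternatives, 'X' wildcard, '-' the scissile bond) returns all
  matching positions; with a model supplied each hit carries exactly the
  score scanning would assign there.
- **Variant re-scoring** recomputes the probability after a substitution
  inside P5…P3′ of a site.  By default the baseline structure predictor is
  re-run on the mutated sequence; fixed (file-derived) labels are an option,
  in which case only window residues can change the score.
- **Conservation mapping** aligns substrate and ortholog globally (BLOSUM62,
  affine gaps: open 10, extend 0.5 — a self-contained dynamic-programming
  aligner rather than an external alignment binary) and reports, per site,
  the aligned ortholog position, the residue there, a conserved flag
  (aligned residue ∈ {D, E}, no gap) and the identity fraction over the
  aligned P5…P3′.

## Synthetic data generator

The generator emulates the curated training data's structure: i.i.d.
background sequence with a Swiss-Prot-like human amino-acid composition,
carrying planted sites whose P5…P3′ residues are drawn from per-position
distributions.  The `casp3-like` preset encodes the executioner consensus
(P4: D 0.55, some I/L/V; P3: E 0.50; P2: mild V/P/A preference; P1: D fixed;
P1′: A 0.22 > G 0.18 > S 0.16 > T 0.10 > N 0.06; P2′: mild G/S/A), with
unlisted residues sharing the remaining mass in proportion to the
background.  A single `effect_size` dial interpolates each column linearly
in probability space between background (0) and the full preset (1),
renormalized; P1 stays a point mass on D at every effect size.  The
training-scale condition is 520 proteins of 300–700 residues carrying 661
sites — the size and structure of the curated set.

Two negative constructions serve different purposes:

- **sliding-window negatives** reproduce the published training-set
  construction and are used wherever that pipeline is being exercised;
- **D-centred background decoys** are the matched null: every window in
  both classes has D at P1, so at effect size 0 the classes are exchangeable
  by construction and cross-validated AUC tends to 0.5.  (With sliding
  negatives the fixed P1 = D alone separates the classes, so the null is
  not testable through them.)

What the generator does **not** emulate: real substrate heterogeneity
(planted windows are cleanly drawn from one preset, so classes are far more
separable than curated data — near-ceiling AUC here does not promise the
same on real proteins), residue correlations between positions, homologous
redundancy between proteins, and any coupling between planted sites and
true structural context (structure labels come from the baseline predictor run
on the generated sequence).  Parameter recovery is assessed as the RMS
deviation over finite entries between the matrix estimated from 5,000
planted windows and the generator's true log2 matrix; a per-entry bound at
this sample size is not statistically meaningful, since the binomial
standard deviation of a log2 frequency exceeds 0.15 for any residue with
probability below ≈0.17.  The degenerate P1 column (true −∞ off D) is
excluded from the comparison.

## Numerical and problem-size choices

Defaults: pseudocount 1 (background-proportional), loop threshold 1.03,
disorder windows 7/9, planted-site spacing ≥ 10 residues, score threshold
0.5, 10 folds, seed 0.  Test-suite and acceptance runs use the
training-scale condition (661 sites) for reproduction checks, 200-site sets
for planted-recovery and null checks, and 5,000 windows for parameter
recovery; smaller forests (100–300 trees) are used where the tree count is
not itself the quantity under test.

## Known limitations

- The baseline structure predictor is a propensity heuristic; its labels
  correlate only weakly with profile-based predictions, and structural
  feature effects (e.g. on variant re-scoring) inherit its biases — a
  substitution that raises helix propensity can lower the score even when
  the sequence preference favours the substituted residue.
- On cleanly separable synthetic data the forest's probability is
  insensitive to changes within the positive-looking range of a single
  feature (no split thresholds fall there), so small variant effects that
  a model trained on heterogeneous curated data would register can be
  invisible here.
- Cleavage is scored per-site from local sequence and predicted structure;
  substrate availability, exosites and PTMs are out of scope, so
  over-prediction on whole proteomes is expected and ranking, not the raw
  yes/no call, is the intended use.
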