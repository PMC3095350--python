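# Methods

## The problem and the model

Tandem 3′ splice acceptors (NAGNAG) offer the spliceosome two AG
dinucleotides 3 nt apart.  Observed transcript evidence classifies each
site as constitutive at the proximal AG (E), constitutive at the distal AG
(I), or alternative (EI).  Because sampling depth limits direct
observation, the package also predicts the outcome from sequence alone with
a 3-class Naïve Bayes model over 31 features.  The feature set encodes the
local splicing determinants: the acceptor dinucleotide context (the two N
wildcards and the immediate neighbourhood), polypyrimidine-tract strength
(Y-content), and the strengths of both candidate acceptors.

Naïve Bayes assumes feature independence given the class.  That is clearly
wrong in detail (adjacent nucleotides covary), but the decision problem is
dominated by a handful of nearly independent signals (N1, N2, the PPT), and
the model is deterministic, fast, and well calibrated enough for ranking by
posterior.

## Coordinates and scanning

Coordinates are 1-based inclusive (GFF3 convention); a junction coordinate
is the last intronic base of its acceptor AG.  Introns are derived from
consecutive exons of each transcript; introns whose coding-strand sequence
does not end in AG are flagged non-canonical and excluded from scanning
rather than silently kept.  The scanner inspects the ±3 window around each
annotated acceptor: an AG ending 3 nt inside the intron makes the annotated
acceptor distal, an AG at downstream-exon positions +2/+3 makes it
proximal.  A NAGNAGNAG triple therefore yields two overlapping sites — the
enumeration preserves information rather than guessing which pair is real.
Sites with non-ACGT letters at an N position are skipped (the categorical
features cannot represent them).  Sites shared by several transcripts are
deduplicated on (seqid, strand, proximal junction), keeping the lowest
intron ordinal as representative.

The 49-nt context is: last 3 exonic nt, 30 intronic nt immediately upstream
of the motif, the 6-nt motif, 10 nt downstream.  The upstream window is
confined to the intron; shortfalls are padded with an `X` sentinel, and any
site with a sentinel inside the 28 positional feature slots is excluded
from training/prediction and reported.

## Evidence rules

Alignment filters: identity ≥ 0.95, read-length coverage ≥ 0.90, every
block gap ≤ 20,000 nt, multi-block only.  Alignments missing quality fields
are rejected with the reason logged.  An alignment whose terminal boundary
(its genomic start or end) lies within ±3 nt of either junction of a site
is ignored *at that site only* — its terminus is indistinguishable from an
unspliced continuation there — but its unambiguous junctions still count at
other sites.  This per-site interpretation (rather than discarding such
alignments globally) keeps the most information; it is a design choice
where the convention is genuinely open.

Labels: E (proximal support only), I (distal only), EI (both), uncovered
(none).  Training criteria: constitutive needs ≥ 10 reads for one variant
and 0 for the other; alternative needs ≥ 2 reads per variant and a minor
fraction ≥ 0.10.  Merging evidence pools is an element-wise sum with the
per-pool breakdown preserved, so a site with single-acceptor support in two
different pools can flip to EI after merging.

Percentages in reports are computed as 100·k/n and rounded half-up — one
decimal for site tallies, integers for validation rates.

## Acceptor strength scores

Splice-site strength is scored by a transparent position-specific log-odds
model: a 23-position window (−20…−1 intronic with the AG at −2/−1, +1…+3
exonic), trained on the used-acceptor windows of constitutive training
sites with an add-one pseudocount, against genome mononucleotide
frequencies, scores in bits.  `score_E` and `score_I` score the two
candidate junctions with windows offset by 3 nt.  The model assumes
positional independence (no dinucleotide coupling, no branch-point term);
scores are rank-compatible measures of acceptor strength rather than
calibrated probabilities, so absolute score scales — and therefore absolute
AUC parity with richer scorers — are not meaningful to compare.

## Classifier

Priors are class frequencies.  Categorical features get per-class letter
tables with Laplace pseudocount 1 (configurable); numeric features
(y_content, score_E, score_I) get class-conditional Gaussians with a
variance floor of 1e-9 to survive constant features.  Posteriors are
computed in log space and normalised with log-sum-exp, so 31 features
cannot under/overflow.  Missing feature values drop that feature's
likelihood term.  `predict_class` is the posterior argmax with exact ties
broken in the fixed order E > I > EI.

Cross-validation is stratified with a mandatory seed (scikit-learn provides
the fold assignment); out-of-fold posteriors are pooled and one-vs-rest AUC
per class is computed by the rank-based (Mann–Whitney) estimator with
midrank tie handling, which equals the trapezoidal area under the empirical
ROC.  Other toolkits differ in whether folds are stratified and whether
numeric features are discretised before fitting, so absolute AUC values on
real data should be compared across implementations qualitatively, not to
the third decimal.

Information gain ranks features in bits: IG = H(Class) − H(Class|Feature),
with numeric features discretised into equal-frequency bins (default 10;
tied values share a bin, constant features get IG = 0).  The reduced
5-feature view (N1, N2, up_m1, up_m2, down_p1) supports cross-dataset
transfer where distal positional numbering is not comparable;
`transfer_predict(..., reduced=True)` simply restricts the likelihood terms
to those features.

## The simulator

`simulate_dataset` emulates the three inputs: a single-chromosome genome of
multi-exon genes (default 150 genes, 2 introns each, 90-nt exons and
introns, both strands), GFF3 gene models, and BED12 spliced reads with
identity/coverage in two extra columns.  Defaults reflect the conditions
the evaluation experiments assume:

* 70% of acceptors carry a planted NAGNAG; the class mixture is balanced
  (1/3 each) so every outcome is equally represented for classifier
  evaluation — the mixture is a config knob, not a constant.
* Class signal: functional acceptor Ns follow C (0.45) > T (0.35) >
  A (0.15) > G (0.05); dead acceptor Ns are G-enriched (0.60) — echoing
  the rarity of functional GAG acceptors.  Per-base pyrimidine probability
  in the 20-nt PPT window: 0.85 at EI sites, 0.65 at constitutive sites,
  0.55 background.  The `signal` knob interpolates all of this linearly to
  background, so `signal=0` is an exact null (class-independent sequence).
  The AG-avoidance patches that keep the planted tandem unique near the
  annotated acceptor are applied identically regardless of class or
  annotated side, so they cannot leak class information.
* Reads: a site is covered with probability 0.92; covered sites draw
  Poisson(14) reads; EI sites draw a minor-isoform fraction uniform on
  [0.15, 0.40] and split reads binomially.  An EI site can therefore
  legitimately present as constitutive when the minor isoform goes
  unsampled — exactly the censoring the strict training criteria exist to
  limit — and truth tables record the realised counts so tests can make
  exact comparisons.
* Decoys: five alignments per type violating exactly one filter
  (identity 0.90, coverage 0.80, single block, 21,000-nt gap), plus
  boundary-ending reads that pass all filters but terminate exactly at a
  tandem junction and must be ignored there.  Boundary decoys are emitted
  for sites in the second or later intron of plus-strand genes — a
  bookkeeping simplification; the per-site ignore rule itself is exercised
  on both strands by the unit tests.

What the simulator does **not** emulate: sequencing error profiles and
quality strings, expression-level and tissue structure, intron length
variation, alternative donors, paralogy.  Passing recovery tests therefore
demonstrates that the pipeline's logic is correct and that the classifier
recovers a planted signal of plausible shape — not that real-data AUCs of
any particular magnitude are guaranteed.

## Evaluation experiments and problem sizes

`nagnag.experiments.run_recovery_experiment` generates 1800 genes (~2500
tandem sites), runs the full pipeline, draws a balanced 600-sites-per-class
training subset, and cross-validates with stratified 10-fold CV.  Under the
default signal the per-class AUCs land around 0.92–0.95 with 100% scanner
recall and 100% evidence-label agreement; with `signal=0` they sit within
a few hundredths of 0.5.  These sizes keep the whole experiment under ten
seconds while leaving comfortable statistical resolution (AUC standard
error ≈ 0.015 at 600 positives).

## Known limitations

* The scanner trusts the annotation; unannotated acceptors and recursive
  splicing are invisible to it.
* Reads are matched to junctions by exact coordinate; small alignment
  wobble around junctions is not modelled (real aligners usually normalise
  it away, but noisy BED input would undercount).
* The PWM scorer ignores the branch point and dinucleotide dependencies.
* Naïve Bayes posteriors are useful for ranking; their absolute calibration
  degrades when features are strongly correlated.
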